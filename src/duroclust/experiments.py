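"""In-silico experiments: single runs, replicate ensembles, sweeps.

The four study conditions toggle durotaxis and substrate degradation:
(durotaxis, degradation) in {(on, on), (on, off), (off, on), (off, off)}.
Cluster-shape and connectivity summaries pool clusters of at least four
cells (the size class tabulated for simulated ensembles); cluster-speed
summaries pool the cells belonging to clusters of at least two cells.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .clusters import (
    ClusterPartition,
    ClusterShape,
    analyze_partition,
    cluster_numbers,
    find_clusters,
)
from .dynamics import SimRecord, Simulation
from .params import ModelParams

logger = logging.getLogger("duroclust")

#: Minimum cluster size entering shape/connectivity pooling.
SHAPE_MIN_SIZE = 4
#: Minimum cluster size for a cell to count as "clustered" in speed pooling.
SPEED_MIN_SIZE = 2
#: Normal-theory 95% interval multiplier.
Z95 = 1.96

CONDITIONS: dict[str, tuple[bool, bool]] = {
    "both": (True, True),
    "durotaxis_only": (True, False),
    "degradation_only": (False, True),
    "neither": (False, False),
}


@dataclass
class RunResult:
    """Everything recorded from one simulation run."""

    params: ModelParams
    seed: int
    record: SimRecord
    times: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    degraded_percent: np.ndarray
    mean_speed: np.ndarray
    tdegr: float | None
    final_partition: ClusterPartition
    final_shapes: list[ClusterShape]
    final_speeds: np.ndarray          # per-cell |v| at the last step
    final_positions: np.ndarray

    def post_tdegr_mean_S1(self) -> float:
        """Mean of the S1 series over frames after the arrest time."""
        if self.tdegr is None:
            raise ValueError("run never arrested; no post-arrest window")
        mask = self.times > self.tdegr
        if not mask.any():
            return float(self.S1[-1])
        return float(self.S1[mask].mean())

    def clustered_speed(self, min_size: int = SPEED_MIN_SIZE) -> float:
        """Mean final speed of cells in clusters of at least ``min_size``."""
        sizes = self.final_partition.sizes()
        labels = self.final_partition.labels
        mask = np.array([sizes[l] >= min_size for l in labels])
        if not mask.any():
            return float("nan")
        return float(self.final_speeds[mask].mean())


def run_scenario(
    condition: tuple[bool, bool] | str,
    params: ModelParams | None = None,
    seed: int = 0,
    *,
    stop_after_arrest: bool = False,
    arrest_margin: float = 5.0,
    record_trajectory: bool = True,
) -> RunResult:
    """Run the model under one condition and collect cluster statistics.

    ``condition`` is either a ``(durotaxis_on, degradation_on)`` pair or
    one of the names ``both | durotaxis_only | degradation_only | neither``.
    The same seed always reproduces the identical metric series.
    """
    if isinstance(condition, str):
        try:
            condition = CONDITIONS[condition]
        except KeyError:
            raise ValueError(
                f"unknown condition {condition!r}; pick from {sorted(CONDITIONS)}"
            ) from None
    duro, degr = condition
    params = (params or ModelParams()).replace(
        durotaxis_on=bool(duro), degradation_on=bool(degr), seed=int(seed)
    )
    sim = Simulation(params)
    logger.info(
        "run condition=(durotaxis=%s, degradation=%s) seed=%d Nc=%d N=%d",
        duro, degr, seed, params.Nc, params.N,
    )
    try:
        rec = sim.run(
            record_trajectory=record_trajectory,
            stop_after_arrest=stop_after_arrest,
            arrest_margin=arrest_margin,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"condition (durotaxis={duro}, degradation={degr}), seed {seed}: {err}"
        ) from err

    if rec.trajectory is not None:
        S1 = np.empty(len(rec.times))
        S2 = np.empty(len(rec.times))
        for k in range(len(rec.times)):
            part = find_clusters(
                rec.trajectory[k, :, :2], params.cutoff, periodic=True, Lstar=params.Lstar
            )
            S1[k], S2[k] = cluster_numbers(part)
    else:
        S1 = S2 = np.full(len(rec.times), np.nan)

    final_partition = find_clusters(
        sim.cells.positions, params.cutoff, periodic=True, Lstar=params.Lstar
    )
    final_shapes = analyze_partition(
        final_partition, params.d, min_size=2, connectivity_min_size=SHAPE_MIN_SIZE
    )
    final_speeds = np.hypot(sim.last_velocities[:, 0], sim.last_velocities[:, 1])
    return RunResult(
        params=params,
        seed=seed,
        record=rec,
        times=rec.times,
        S1=S1,
        S2=S2,
        degraded_percent=rec.degraded_percent,
        mean_speed=rec.mean_speed,
        tdegr=rec.tdegr,
        final_partition=final_partition,
        final_shapes=final_shapes,
        final_speeds=final_speeds,
        final_positions=sim.cells.positions.copy(),
    )


def _summary_row(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    if n == 0:
        return {"mean": float("nan"), "sd": float("nan"), "sem": float("nan"),
                "ci95": float("nan"), "n": 0}
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    sem = sd / math.sqrt(n) if n > 1 else 0.0
    return {"mean": float(values.mean()), "sd": sd, "sem": sem, "ci95": Z95 * sem, "n": n}


@dataclass
class EnsembleSummary:
    """Replicate ensemble of one condition with summary statistics."""

    condition: tuple[bool, bool]
    n_replicates: int
    runs: list[RunResult]
    failed_seeds: list[int]
    pooled: dict[str, np.ndarray]
    table: pd.DataFrame

    @property
    def total_clusters(self) -> int:
        """Count of pooled clusters (>= SHAPE_MIN_SIZE cells) over replicates."""
        return int(len(self.pooled["aspect_ratio"]))


def ensemble(
    condition: tuple[bool, bool] | str,
    params: ModelParams | None = None,
    n_replicates: int = 10,
    base_seed: int = 0,
    *,
    stop_after_arrest: bool = False,
    arrest_margin: float = 5.0,
    seeds: Sequence[int] | None = None,
) -> EnsembleSummary:
    """Independent replicates (seeds ``base_seed + k``) of one condition.

    Reports, per replicate and pooled: final S1/S2, cluster aspect
    ratios and connectivity indices (clusters of >= 4 cells), clustered
    cell speed normalized by ``Vprop``, cluster counts and the arrest
    time.  An explicit ``seeds`` list overrides ``base_seed + k``.
    Failed replicates are excluded with a warning; more than 20%
    failures is an error.
    """
    if seeds is not None:
        seeds = list(seeds)
        n_replicates = len(seeds)
    if n_replicates < 2:
        raise ValueError("an ensemble needs at least 2 replicates")
    params = params or ModelParams()
    runs: list[RunResult] = []
    failed: list[int] = []
    for k in range(n_replicates):
        seed = seeds[k] if seeds is not None else base_seed + k
        try:
            runs.append(
                run_scenario(
                    condition, params, seed,
                    stop_after_arrest=stop_after_arrest, arrest_margin=arrest_margin,
                )
            )
        except RuntimeError as err:
            warnings.warn(f"replicate seed {seed} failed and was excluded: {err}", stacklevel=2)
            failed.append(seed)
    if len(failed) > 0.2 * n_replicates:
        raise RuntimeError(
            f"{len(failed)}/{n_replicates} replicates failed (seeds {failed})"
        )

    aspect, conn, big_counts, all_counts = [], [], [], []
    per_rep_aspect = []
    for r in runs:
        big = [s for s in r.final_shapes if s.size >= SHAPE_MIN_SIZE]
        aspect.extend(s.aspect_ratio for s in big)
        conn.extend(s.connectivity_index for s in big if s.connectivity_index is not None)
        big_counts.append(len(big))
        all_counts.append(r.final_partition.n_clusters)
        per_rep_aspect.append(np.mean([s.aspect_ratio for s in big]) if big else np.nan)

    vprop = runs[0].params.Vprop
    metrics = {
        "final_S1": np.array([r.S1[-1] for r in runs]),
        "final_S2": np.array([r.S2[-1] for r in runs]),
        "clustered_speed_norm": np.array([r.clustered_speed() / vprop for r in runs]),
        "clusters_ge4": np.array(big_counts, dtype=float),
        "clusters_all": np.array(all_counts, dtype=float),
        "aspect_ratio_replicate_mean": np.array(per_rep_aspect),
        "tdegr": np.array([np.nan if r.tdegr is None else r.tdegr for r in runs]),
    }
    pooled = {
        "aspect_ratio": np.array(aspect, dtype=float),
        "connectivity_index": np.array(conn, dtype=float),
    }
    rows = {name: _summary_row(vals) for name, vals in metrics.items()}
    rows["aspect_ratio_pooled"] = _summary_row(pooled["aspect_ratio"])
    rows["connectivity_pooled"] = _summary_row(pooled["connectivity_index"])
    table = pd.DataFrame(rows).T
    cond = runs[0].params.condition
    return EnsembleSummary(
        condition=cond,
        n_replicates=n_replicates,
        runs=runs,
        failed_seeds=failed,
        pooled=pooled,
        table=table,
    )


def _post_arrest_metrics(runs: list[RunResult], cutoff: float, Lstar: float) -> tuple[float, float]:
    """(mean post-arrest S1, mean final connectivity over clusters >= 2)."""
    s1_vals, conn_vals = [], []
    for r in runs:
        if r.tdegr is not None:
            s1_vals.append(r.post_tdegr_mean_S1())
        else:
            s1_vals.append(float(r.S1[-1]))
        for members in r.final_partition.clusters:
            if len(members) >= 2:
                from .clusters import connectivity_index, unwrap_positions

                pos = unwrap_positions(r.final_positions[members], cutoff, Lstar)
                conn_vals.append(connectivity_index(pos, cutoff))
    return float(np.mean(s1_vals)), float(np.mean(conn_vals)) if conn_vals else float("nan")


def sensitivity_sweep(
    params: ModelParams | None = None,
    gamma2_factors: Sequence[float] = (),
    ksigma_factors: Sequence[float] = (),
    n_replicates: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Vary the degradation rate and durotaxis gain about the baseline.

    For the baseline and each multiplicative factor, runs a replicate
    ensemble (durotaxis and degradation on) and reports the post-arrest
    mean cluster size S1 and the mean connectivity index of final
    clusters (>= 2 cells), with normal-theory intervals and fold-changes
    relative to baseline.
    """
    params = (params or ModelParams()).replace(durotaxis_on=True, degradation_on=True)
    cases: list[tuple[str, float, ModelParams]] = [("baseline", 1.0, params)]
    for f in gamma2_factors:
        cases.append(("gamma2", f, params.replace(gamma2=params.gamma2 * f)))
    for f in ksigma_factors:
        cases.append(("k_sigma", f, params.replace(k_sigma=params.k_sigma * f)))

    rows = []
    baseline_s1 = baseline_conn = None
    for name, factor, p in cases:
        runs = []
        for k in range(n_replicates):
            runs.append(
                run_scenario((True, True), p, base_seed + k, stop_after_arrest=True)
            )
        s1_list = np.array([
            r.post_tdegr_mean_S1() if r.tdegr is not None else float(r.S1[-1]) for r in runs
        ])
        s1_mean, conn_mean = _post_arrest_metrics(runs, p.cutoff, p.Lstar)
        s1_stats = _summary_row(s1_list)
        if name == "baseline":
            baseline_s1, baseline_conn = s1_mean, conn_mean
        rows.append(
            {
                "parameter": name,
                "factor": factor,
                "post_tdegr_S1": s1_mean,
                "post_tdegr_S1_ci95": s1_stats["ci95"],
                "connectivity": conn_mean,
                "S1_fold_vs_baseline": s1_mean / baseline_s1 if baseline_s1 else np.nan,
                "connectivity_fold_vs_baseline": (
                    conn_mean / baseline_conn if baseline_conn and np.isfinite(conn_mean) else np.nan
                ),
                "n": n_replicates,
            }
        )
    return pd.DataFrame(rows)


def fixture_generator(kind: str, rng: np.random.Generator, **kwargs: Any) -> dict[str, Any]:
    """Deterministic synthetic inputs with known ground truth, for tests.

    Kinds: ``collinear_chain``, ``square``, ``random_blobs``,
    ``plane_wave_u``, ``constant_C``.
    """
    if kind == "collinear_chain":
        m = kwargs.get("m", 4)
        spacing = kwargs.get("spacing", 1.5)
        angle = kwargs.get("angle", 0.0)
        origin = np.asarray(kwargs.get("origin", (5.0, 5.0)), dtype=float)
        direction = np.array([math.cos(angle), math.sin(angle)])
        pos = origin + spacing * np.arange(m)[:, None] * direction
        return {"positions": pos, "truth": {"n_clusters": 1, "spacing": spacing}}
    if kind == "square":
        side = kwargs.get("side", 1.0)
        origin = np.asarray(kwargs.get("origin", (5.0, 5.0)), dtype=float)
        pos = origin + side * np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        return {"positions": pos, "truth": {"isotropic": True}}
    if kind == "random_blobs":
        k = kwargs.get("k", 3)
        n_per = kwargs.get("n_per", 5)
        sep = kwargs.get("sep", 8.0)
        jitter = kwargs.get("jitter", 0.3)
        centers = sep * np.arange(k)[:, None] * np.array([[1.0, 0.35]])
        pos = np.concatenate(
            [c + jitter * rng.standard_normal((n_per, 2)) for c in centers]
        )
        return {"positions": pos, "truth": {"n_clusters": k, "n_per": n_per}}
    if kind == "plane_wave_u":
        N = kwargs.get("N", 32)
        dx = kwargs.get("dx", 0.25)
        k_index = kwargs.get("k_index", 1)
        amplitude = kwargs.get("amplitude", 1e-2)
        L = N * dx
        x = dx * np.arange(N)
        kwav = 2.0 * math.pi * k_index / L
        uy = amplitude * np.sin(kwav * x)[:, None] * np.ones(N)[None, :]
        ux = np.zeros((N, N))
        k_disc2 = (2.0 / dx * math.sin(0.5 * kwav * dx)) ** 2
        return {"ux": ux, "uy": uy, "dx": dx, "truth": {"k_discrete_sq": k_disc2}}
    if kind == "constant_C":
        N = kwargs.get("N", 32)
        value = kwargs.get("value", 0.5)
        return {"C": np.full((N, N), value), "truth": {"value": value}}
    raise ValueError(f"unknown fixture kind {kind!r}")
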