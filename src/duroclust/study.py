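"""Canonical study protocols: the runs behind the headline numbers.

Two problem-size profiles are used throughout:

* the *headline* profile — the default 200^2 grid (dx = 0.1) with
  Nc = 40 cells — for the degraded-area-at-arrest measurement;
* the *ensemble* profile — a 128^2 grid (dx = 0.15625), verified to
  reproduce the fine-grid dynamics (see docs/methods.md) — for
  replicate ensembles and parameter sweeps.

All protocols are deterministic given their base seed.
"""

from __future__ import annotations

import numpy as np

from .experiments import SHAPE_MIN_SIZE, EnsembleSummary, RunResult, ensemble, run_scenario
from .params import ModelParams

#: grid spacing of the replicate-ensemble profile (128 nodes per side)
ENSEMBLE_DX = 20.0 / 128.0


def headline_params(**overrides) -> ModelParams:
    """Default fine-grid parameters (200^2, Nc = 40)."""
    return ModelParams(**overrides)


def ensemble_params(Nc: int = 20, **overrides) -> ModelParams:
    """Replicate-ensemble profile (128^2 grid)."""
    return ModelParams(Nc=Nc, dx=ENSEMBLE_DX, **overrides)


def degraded_area_at_arrest(seed: int) -> tuple[float, float]:
    """One full-model headline run; returns (degraded % at Tdegr, Tdegr).

    Runs durotaxis + degradation with Nc = 40 on the 200^2 grid until
    arrest is detected and evaluates (1 - mean rho) * 100 at the
    detected arrest time.
    """
    r = run_scenario((True, True), headline_params(), seed,
                     stop_after_arrest=True, arrest_margin=0.5,
                     record_trajectory=False)
    if r.tdegr is None:
        raise RuntimeError(f"seed {seed}: no arrest detected before T_end")
    k = int(np.argmin(np.abs(r.times - r.tdegr)))
    return float(r.degraded_percent[k]), float(r.tdegr)


def table2_ensemble(degradation: bool, base_seed: int, n_replicates: int = 10) -> EnsembleSummary:
    """Durotaxis-on ensemble of Nc = 20 runs to T = 50 (Table-2 protocol)."""
    return ensemble((True, degradation), ensemble_params(Nc=20),
                    n_replicates=n_replicates, base_seed=base_seed)


def pooled_aspect_mean(summary: EnsembleSummary) -> float:
    """Mean aspect ratio pooled over clusters of >= 4 cells."""
    return float(summary.table.loc["aspect_ratio_pooled", "mean"])


def clustered_speed_mean(summary: EnsembleSummary) -> float:
    """Mean final clustered-cell speed in units of v0 = Vprop."""
    return float(summary.table.loc["clustered_speed_norm", "mean"])


def scaled_cluster_total(summary: EnsembleSummary, reference_replicates: int = 40) -> float:
    """Pooled >= 4-cell cluster count rescaled to a reference replicate count."""
    per_rep = summary.table.loc["clusters_ge4", "mean"]
    return float(per_rep * reference_replicates)


def post_arrest_S1(runs: list[RunResult]) -> float:
    """Mean over replicates of the S1 average after each run's arrest."""
    vals = []
    for r in runs:
        if r.tdegr is not None:
            vals.append(r.post_tdegr_mean_S1())
        else:
            vals.append(float(r.S1[-1]))
    return float(np.mean(vals))


def gamma2_fold(base_runs: list[RunResult], base_seed: int, n_replicates: int = 10,
                factor: float = 10.0) -> tuple[float, float, float]:
    """Post-arrest S1 fold-change when gamma2 is scaled by ``factor``.

    Returns (fold, baseline post-arrest S1, scaled post-arrest S1); the
    baseline comes from ``base_runs`` (a degradation-on ensemble).
    """
    p = ensemble_params(Nc=20)
    scaled = ensemble((True, True), p.replace(gamma2=p.gamma2 * factor),
                      n_replicates=n_replicates, base_seed=base_seed,
                      stop_after_arrest=True, arrest_margin=2.0)
    s_base = post_arrest_S1(base_runs)
    s_scaled = post_arrest_S1(scaled.runs)
    return s_base / s_scaled, s_base, s_scaled


def ksigma_fold(base_runs: list[RunResult], base_seed: int, n_replicates: int = 10,
                factor: float = 10.0) -> tuple[float, float, float]:
    """Post-arrest S1 fold-change when k_sigma is scaled by ``factor``."""
    p = ensemble_params(Nc=20)
    scaled = ensemble((True, True), p.replace(k_sigma=p.k_sigma * factor),
                      n_replicates=n_replicates, base_seed=base_seed,
                      stop_after_arrest=True, arrest_margin=2.0)
    s_base = post_arrest_S1(base_runs)
    s_scaled = post_arrest_S1(scaled.runs)
    return s_scaled / s_base, s_base, s_scaled


def no_durotaxis_time_averages(base_seed: int, n_replicates: int = 10,
                               Nc: int = 40) -> np.ndarray:
    """Per-replicate time-averaged S1 without durotaxis (no degradation).

    Without durotaxis cells neither deform the substrate (mechanically
    decoupled) nor respond to it, so the runs are cheap active-Brownian
    dynamics with steric repulsion.
    """
    out = []
    for k in range(n_replicates):
        r = run_scenario((False, False), ensemble_params(Nc=Nc), base_seed + k)
        out.append(float(r.S1.mean()))
    return np.array(out)


def no_durotaxis_final_S1(base_seed: int, n_replicates: int = 10,
                          Nc: int = 20) -> np.ndarray:
    """Final S1 without durotaxis (no degradation) at seeds base_seed + k.

    Pairs with a durotaxis-on ensemble at the same seeds for the
    matched-seed condition comparison.
    """
    return np.array([
        float(run_scenario((False, False), ensemble_params(Nc=Nc), base_seed + k).S1[-1])
        for k in range(n_replicates)
    ])
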