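"""Synthetic TA expression time courses generated from the Z-model.

The generator emulates the shape of the real dataset this kind of analysis
targets: 11 TA pairs, 10 timepoints over roughly one working day of
stationary-phase sampling (0-10 h), two curves per pair (toxin and
antitoxin), values on the convention where raw expression has been
multiplied by a constant c = 1e5 so the fitted numbers are O(1)-O(100).

Kinetic parameters are drawn per pair from a "central" region — rates
within a decade of 1/h, strong complex feedback on the antitoxin promoter,
a stable toxin — and a configurable number of "outlier" pairs whose
strictly positive constants are displaced by a fixed number of decades in
per-pair random directions.  The planted central/outlier partition is a
testing construction of this package, not a claim about why real TA pairs
separate.  Observation noise is multiplicative lognormal (i.i.d. per
point), the standard stand-in for expression measurement noise; additive
Gaussian is available as an option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .fitting import (
    InitialConditionMode,
    OptConfig,
    TimeCourse,
    fit_pair,
    objective,
    predict_curves,
)
from .model import (
    FULL_PARAM_NAMES,
    POSITIVE_PARAMS,
    SimulationError,
    SolverConfig,
    ZParams,
    simulate,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruthEntry",
    "GroundTruth",
    "sample_params",
    "generate_pair",
    "generate_dataset",
    "recovery_experiment",
    "DEFAULT_PARAM_RANGES",
]

#: Per-parameter sampling ranges for the central region.  Strictly positive
#: constants are drawn log-uniformly, bm/bc/c0 uniformly.  The region keeps
#: rates on the hours timescale, a toxin markedly more stable than the
#: antitoxin (d2 < d1), strong complex repression of antitoxin production
#: (small s1) and active toxin feedbacks (bm, bc of order 1), so every
#: ingredient of the full model shapes the curves.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "k1": (2.0, 5.0),
    "k2": (0.5, 2.0),
    "d1": (1.0, 3.0),
    "d2": (0.2, 0.5),
    "d3": (0.5, 2.0),
    "s1": (0.05, 0.2),
    "s2": (1.0, 3.0),
    "bm": (0.5, 2.0),
    "bc": (0.5, 2.0),
    "c0": (0.5, 2.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped synthetic dataset settings.

    ``n_central`` pairs share the central parameter region; ``n_outliers``
    pairs have their strictly positive constants displaced by
    ``displacement_decades`` in random per-pair directions.  ``noise_sigma``
    is the lognormal sigma (0 = noiseless); ``noise_model`` may be set to
    ``"additive"`` for Gaussian noise with standard deviation
    ``noise_sigma`` x curve mean.
    """

    n_central: int = 7
    n_outliers: int = 4
    n_times: int = 10
    t_start: float = 0.0
    t_end: float = 10.0
    noise_model: str = "lognormal"  # or "additive"
    noise_sigma: float = 0.0
    scale_c: float = 1e5
    param_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_RANGES)
    )
    displacement_decades: float = 2.0
    n_displaced_params: int = 3
    master_seed: int = 0
    max_retries: int = 5

    @property
    def n_pairs(self) -> int:
        return self.n_central + self.n_outliers

    @property
    def times(self) -> np.ndarray:
        if self.n_times < 3:
            raise ValueError("need at least 3 timepoints")
        return np.linspace(self.t_start, self.t_end, self.n_times)


@dataclass(frozen=True)
class GroundTruthEntry:
    pair_label: str
    params: ZParams
    true_antitoxin: np.ndarray
    true_toxin: np.ndarray
    planted_label: str  # "central" or "outlier"


@dataclass(frozen=True)
class GroundTruth:
    times: np.ndarray
    entries: tuple[GroundTruthEntry, ...]

    def labels(self) -> dict[str, str]:
        return {e.pair_label: e.planted_label for e in self.entries}


def sample_params(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> ZParams:
    """Draw one parameter set from the central region.

    Log-uniform for strictly positive constants, uniform for bm, bc, c0;
    a degenerate range [a, a] yields exactly a.
    """
    values = {}
    for name in FULL_PARAM_NAMES:
        lo, hi = cfg.param_ranges[name]
        if lo > hi:
            raise ValueError(f"empty sampling range for {name}: [{lo}, {hi}]")
        if name in POSITIVE_PARAMS:
            if lo <= 0:
                raise ValueError(f"{name} requires a strictly positive range")
            values[name] = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi))
        else:
            values[name] = rng.uniform(lo, hi)
    return ZParams(**values)


def _displace(params: ZParams, cfg: GeneratorConfig, rng: np.random.Generator) -> ZParams:
    """Push a central draw into an outlier region.

    A per-pair random subset of the strictly positive constants is moved by
    ``displacement_decades`` decades, each in a random direction, so
    different outliers end up displaced along different axes and do not
    themselves form a dense cluster.
    """
    names = sorted(POSITIVE_PARAMS)
    k = min(cfg.n_displaced_params, len(names))
    chosen = rng.choice(len(names), size=k, replace=False)
    updates = {}
    for idx in chosen:
        name = names[idx]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        updates[name] = getattr(params, name) * 10.0 ** (sign * cfg.displacement_decades)
    return replace(params, **updates)


def generate_pair(
    params: ZParams,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    pair_label: str = "TA01",
    planted_label: str = "central",
) -> tuple[TimeCourse, GroundTruthEntry]:
    """Simulate one pair from (0, 0, c0) and apply observation noise."""
    times = cfg.times
    last_err: SimulationError | None = None
    for attempt in range(cfg.max_retries + 1):
        try:
            traj = simulate(params, (0.0, 0.0, params.c0), times)
            break
        except SimulationError as err:
            last_err = err
            warnings.warn(
                f"{pair_label}: integration failed ({err}); resampling parameters "
                f"(attempt {attempt + 1}/{cfg.max_retries})",
                stacklevel=2,
            )
            if attempt == cfg.max_retries:
                raise
            params = sample_params(cfg, rng)
            if planted_label == "outlier":
                params = _displace(params, cfg, rng)
    a_true, t_true = traj.z1.copy(), traj.z2.copy()
    a_obs, t_obs = a_true.copy(), t_true.copy()
    if cfg.noise_sigma > 0:
        if cfg.noise_model == "lognormal":
            a_obs = a_true * np.exp(rng.normal(0.0, cfg.noise_sigma, size=a_true.size))
            t_obs = t_true * np.exp(rng.normal(0.0, cfg.noise_sigma, size=t_true.size))
        elif cfg.noise_model == "additive":
            a_obs = np.clip(
                a_true + rng.normal(0.0, cfg.noise_sigma * a_true.mean(), a_true.size),
                0.0, None,
            )
            t_obs = np.clip(
                t_true + rng.normal(0.0, cfg.noise_sigma * t_true.mean(), t_true.size),
                0.0, None,
            )
        else:
            raise ValueError(f"unknown noise model {cfg.noise_model!r}")
    tc = TimeCourse(
        pair_label=pair_label,
        times=times,
        antitoxin_values=a_obs,
        toxin_values=t_obs,
        scale_applied=cfg.scale_c,
    )
    entry = GroundTruthEntry(pair_label, params, a_true, t_true, planted_label)
    return tc, entry


def generate_dataset(cfg: GeneratorConfig) -> tuple[list[TimeCourse], GroundTruth]:
    """Generate the full planted-structure dataset, deterministic in the seed."""
    rng = np.random.default_rng(cfg.master_seed)
    timecourses: list[TimeCourse] = []
    entries: list[GroundTruthEntry] = []
    n_total = cfg.n_pairs
    for i in range(n_total):
        planted = "central" if i < cfg.n_central else "outlier"
        label = f"TA{i + 1:02d}"
        params = sample_params(cfg, rng)
        if planted == "outlier":
            params = _displace(params, cfg, rng)
        tc, entry = generate_pair(params, cfg, rng, pair_label=label, planted_label=planted)
        timecourses.append(tc)
        entries.append(entry)
    return timecourses, GroundTruth(cfg.times, tuple(entries))


def trajectory_error(
    fitted_params: ZParams,
    entry: GroundTruthEntry,
    times: np.ndarray,
    ic_mode: InitialConditionMode = InitialConditionMode.zero_zero_c0,
    solver: SolverConfig | None = None,
) -> float:
    """Max mean-normalised discrepancy between fitted and true curves.

    For each curve the pointwise |fitted - true| is divided by the true
    curve's mean (relative error on the curve's own scale, finite even at
    near-zero points); the maximum over both curves and all timepoints is
    returned.
    """
    tc = TimeCourse(
        entry.pair_label, times, entry.true_antitoxin, entry.true_toxin
    )
    z1, z2 = predict_curves(fitted_params, tc, ic_mode, solver)
    err_a = np.abs(z1 - entry.true_antitoxin) / entry.true_antitoxin.mean()
    err_t = np.abs(z2 - entry.true_toxin) / entry.true_toxin.mean()
    return float(max(err_a.max(), err_t.max()))


def recovery_experiment(
    cfg: GeneratorConfig,
    opt: OptConfig | None = None,
    fit_seed: int = 0,
) -> "pd.DataFrame":
    """Fit the full model to every generated pair and score recovery.

    Returns one row per pair with the fitted chi2, the objective evaluated
    at the generating parameters, the max mean-normalised trajectory error
    and the median |log10(fitted/true)| over the strictly positive
    parameters.  Deterministic given (cfg.master_seed, fit_seed).
    """
    import pandas as pd

    from .fitting import _subseed  # deterministic per-pair sub-seeding

    opt = opt or OptConfig()
    timecourses, truth = generate_dataset(cfg)
    by_label = {e.pair_label: e for e in truth.entries}
    rows = []
    for tc in timecourses:
        entry = by_label[tc.pair_label]
        fit = fit_pair(tc, "full", opt, seed=_subseed(fit_seed, tc.pair_label, "full"))
        chi2_truth = objective(
            entry.params.as_vector(), "full", tc, opt.ic_mode, opt.solver
        )
        log_ratios = [
            abs(math.log10(getattr(fit.params, n) / getattr(entry.params, n)))
            for n in sorted(POSITIVE_PARAMS)
        ]
        rows.append(
            {
                "pair": tc.pair_label,
                "planted_label": entry.planted_label,
                "chi2_fit": fit.chi2,
                "chi2_truth": chi2_truth,
                "traj_max_rel_err": trajectory_error(
                    fit.params, entry, tc.times, opt.ic_mode, opt.solver
                ),
                "median_abs_log10_param_ratio": float(np.median(log_ratios)),
            }
        )
    return pd.DataFrame(rows)
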