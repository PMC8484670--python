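"""Fitting the Z-model and its variants to toxin/antitoxin time courses.

Each TA pair contributes two observed curves (antitoxin and toxin) on a
shared time grid.  Because the two curves can sit on very different scales,
the objective is a *mean-weighted* sum of squared residuals: each curve's
residuals are divided by the square of that curve's mean, so low-abundance
curves are not ignored.

Optimisation runs in a transformed coordinate space: strictly positive
constants are searched as log10 values inside a box (default [-4, 4]),
the non-negative constants bm, bc, c0 linearly inside [0, 1e4].  A global
basin-hopping loop perturbs the coordinates; each hop runs a local
Nelder-Mead simplex followed by a trust-region least-squares refinement of
the residual vector.  The contract is a *local* minimum, deterministic for
a given seed; nothing guarantees globality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import OptimizeResult, basinhopping, least_squares, minimize

from .model import (
    POSITIVE_PARAMS,
    SimulationError,
    SolverConfig,
    VariantSpec,
    VARIANTS,
    ZParams,
    apply_variant,
    simulate,
)

__all__ = [
    "TimeCourse",
    "InitialConditionMode",
    "OptConfig",
    "FitResult",
    "curve_weights",
    "objective",
    "weighted_residuals",
    "weighted_ssr",
    "fit_pair",
    "fit_all",
    "PENALTY_OBJECTIVE",
]

#: Large finite value returned when the integrator fails inside the
#: objective, so the simplex can retreat instead of crashing.
PENALTY_OBJECTIVE = 1e12


class InitialConditionMode(str, Enum):
    """How z1(0), z2(0) are chosen; z3(0) = c0 is fitted in every mode.

    ``zero_zero_c0``   -- z1(0) = z2(0) = 0 (default; the pre-induction
                          assumption that free toxin and antitoxin start
                          from zero while some complex c0 is present).
    ``first_timepoint``-- z1, z2 start at the earliest observed values.
    ``dataset_average``-- z1, z2 start at each curve's mean value.
    """

    zero_zero_c0 = "zero_zero_c0"
    first_timepoint = "first_timepoint"
    dataset_average = "dataset_average"


@dataclass(frozen=True)
class TimeCourse:
    """Observed antitoxin/toxin expression series for one TA pair.

    Values are stored on the fitting scale, i.e. raw expression multiplied
    by ``scale_applied`` (default 1e5) to avoid tiny-number round-off
    during optimisation.
    """

    pair_label: str
    times: np.ndarray
    antitoxin_values: np.ndarray
    toxin_values: np.ndarray
    scale_applied: float = 1e5

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.antitoxin_values, dtype=float)
        x = np.asarray(self.toxin_values, dtype=float)
        if t.ndim != 1 or t.size < 3:
            raise ValueError("a time course needs at least 3 timepoints")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if a.shape != t.shape or x.shape != t.shape:
            raise ValueError("curve lengths must match the time grid")
        if np.any(a < 0) or np.any(x < 0):
            raise ValueError("expression values must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "antitoxin_values", a)
        object.__setattr__(self, "toxin_values", x)

    @property
    def n_times(self) -> int:
        return int(self.times.size)


def curve_weights(tc: TimeCourse) -> tuple[float, float]:
    """Per-curve weights 1/mean(curve)^2 for the weighted objective."""
    mean_a = float(np.mean(tc.antitoxin_values))
    mean_t = float(np.mean(tc.toxin_values))
    if mean_a <= 0 or mean_t <= 0:
        raise ValueError(
            f"pair {tc.pair_label!r}: both curves need a strictly positive mean "
            "for mean-weighting; filter empty curves or rescale the input"
        )
    return (1.0 / mean_a**2, 1.0 / mean_t**2)


# ---------------------------------------------------------------------------
# free-vector <-> optimizer-coordinate transforms

LOG_BOX = (-4.0, 4.0)       # log10 box for strictly positive parameters
LIN_BOX = (0.0, 1.0e4)      # linear box for bm, bc, c0


def _encode(free_values: Sequence[float], free_names: Sequence[str]) -> np.ndarray:
    x = np.empty(len(free_names))
    for i, (v, n) in enumerate(zip(free_values, free_names)):
        if n in POSITIVE_PARAMS:
            x[i] = math.log10(max(float(v), 10.0 ** LOG_BOX[0]))
        else:
            x[i] = float(v)
    return x


def _decode(x: np.ndarray, free_names: Sequence[str]) -> np.ndarray:
    v = np.empty(len(free_names))
    for i, n in enumerate(free_names):
        if n in POSITIVE_PARAMS:
            v[i] = 10.0 ** min(max(x[i], LOG_BOX[0]), LOG_BOX[1])
        else:
            v[i] = min(max(x[i], LIN_BOX[0]), LIN_BOX[1])
    return v


def _initial_state(tc: TimeCourse, params: ZParams, ic_mode: InitialConditionMode):
    if ic_mode is InitialConditionMode.zero_zero_c0:
        return (0.0, 0.0, params.c0)
    if ic_mode is InitialConditionMode.first_timepoint:
        return (float(tc.antitoxin_values[0]), float(tc.toxin_values[0]), params.c0)
    if ic_mode is InitialConditionMode.dataset_average:
        return (
            float(np.mean(tc.antitoxin_values)),
            float(np.mean(tc.toxin_values)),
            params.c0,
        )
    raise ValueError(f"unknown initial-condition mode {ic_mode!r}")


def predict_curves(
    params: ZParams,
    tc: TimeCourse,
    ic_mode: InitialConditionMode = InitialConditionMode.zero_zero_c0,
    solver: SolverConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Model antitoxin (z1) and toxin (z2) values on the observation grid.

    The initial condition is imposed at t = 0; if the grid starts later,
    integration starts at 0 and the leading point is discarded.
    """
    solver = solver or SolverConfig()
    times = tc.times
    prepend = times[0] > 0.0
    grid = np.concatenate(([0.0], times)) if prepend else times
    traj = simulate(params, _initial_state(tc, params, ic_mode), grid, solver)
    z1 = traj.z1[1:] if prepend else traj.z1
    z2 = traj.z2[1:] if prepend else traj.z2
    return z1, z2


def weighted_ssr(
    pred_antitoxin: Sequence[float], pred_toxin: Sequence[float], tc: TimeCourse
) -> float:
    """Mean-weighted sum of squared differences for given predictions.

    chi2 = w_A * sum_t (pred_A - A_t)^2 + w_T * sum_t (pred_T - T_t)^2
    with per-curve weights w = 1/mean(curve)^2.
    """
    w_a, w_t = curve_weights(tc)
    d_a = np.asarray(pred_antitoxin, dtype=float) - tc.antitoxin_values
    d_t = np.asarray(pred_toxin, dtype=float) - tc.toxin_values
    return w_a * float(d_a @ d_a) + w_t * float(d_t @ d_t)


def weighted_residuals(
    free_vector: Sequence[float],
    variant: VariantSpec | str,
    tc: TimeCourse,
    ic_mode: InitialConditionMode = InitialConditionMode.zero_zero_c0,
    solver: SolverConfig | None = None,
) -> np.ndarray:
    """sqrt(w)-scaled residual vector over both curves (length 2 x times).

    The sum of its squares is the mean-weighted objective.  Integrator
    failures yield a constant vector whose squared sum equals the finite
    ``PENALTY_OBJECTIVE``, keeping search algorithms alive.
    """
    params = apply_variant(variant, free_vector)
    w_a, w_t = curve_weights(tc)
    n = 2 * tc.n_times
    try:
        z1, z2 = predict_curves(params, tc, ic_mode, solver)
    except SimulationError:
        return np.full(n, math.sqrt(PENALTY_OBJECTIVE / n))
    res = np.concatenate(
        [
            math.sqrt(w_a) * (z1 - tc.antitoxin_values),
            math.sqrt(w_t) * (z2 - tc.toxin_values),
        ]
    )
    if not np.all(np.isfinite(res)):
        return np.full(n, math.sqrt(PENALTY_OBJECTIVE / n))
    return res


def objective(
    free_vector: Sequence[float],
    variant: VariantSpec | str,
    tc: TimeCourse,
    ic_mode: InitialConditionMode = InitialConditionMode.zero_zero_c0,
    solver: SolverConfig | None = None,
) -> float:
    """Mean-weighted sum of squared residuals over both curves.

    chi2 = w_A * sum_t (z1(t) - A_t)^2 + w_T * sum_t (z2(t) - T_t)^2
    with w = 1/mean(curve)^2.  Integrator failures return the finite
    ``PENALTY_OBJECTIVE`` instead of raising, keeping simplex search alive.
    """
    return float(np.sum(weighted_residuals(free_vector, variant, tc, ic_mode, solver) ** 2))


@dataclass(frozen=True)
class OptConfig:
    """Budget and search-region settings for one fit.

    ``n_hops`` basin-hopping iterations of step ``hop_step`` (log10 units
    for positive parameters).  Each hop's local search is Nelder-Mead
    limited to ``local_maxiter`` iterations and — when ``polish`` is on
    (default) — a trust-region least-squares refinement of the weighted
    residual vector from the simplex's endpoint, which pulls smooth basins
    down to solver-tolerance floors the simplex alone reaches only with a
    far larger budget.  ``n_starts`` independent seeded starts are drawn
    uniformly from ``start_box_log`` / ``start_box_lin`` (a deliberately
    moderate region: dynamics on an hours timescale live within a few
    decades of 1).  Fitting uses its own, looser integration tolerance
    than plotting-quality simulation.
    """

    n_hops: int = 50
    hop_step: float = 0.5
    local_maxiter: int = 2000
    polish: bool = True
    ls_max_nfev: int = 100
    n_starts: int = 1
    start_box_log: tuple[float, float] = (-1.5, 1.5)
    start_box_lin: tuple[float, float] = (0.0, 3.0)
    solver: SolverConfig = field(default_factory=lambda: SolverConfig(rtol=1e-6, atol=1e-8))
    ic_mode: InitialConditionMode = InitialConditionMode.zero_zero_c0
    #: in fit_all: each pair is additionally polished from the best
    #: ``portfolio_size`` solutions found on *other* pairs for the same
    #: variant (cross-pair warm starts); 0 disables the sharing
    portfolio_size: int = 3
    #: least-squares iteration cap for warm-start/nesting re-polishes,
    #: which start at or near a local optimum and converge fast
    refine_max_nfev: int = 60


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one variant to one TA pair."""

    pair_label: str
    variant_name: str
    free_vector: np.ndarray
    params: ZParams
    chi2: float
    n_points: int
    converged: bool
    n_restarts: int
    seed: int

    def to_record(self) -> dict:
        rec = {
            "pair": self.pair_label,
            "variant": self.variant_name,
            "chi2": float(self.chi2),
            "n_points": int(self.n_points),
            "nv": len(self.free_vector),
            "converged": bool(self.converged),
            "seed": int(self.seed),
        }
        rec.update(self.params.to_dict())
        return rec


def _make_local_minimizer(resid_fun, opt: OptConfig):
    """Composite local step: Nelder-Mead simplex, then optional
    least-squares (TRF) refinement of the residual vector; the better of
    the two endpoints wins.  Shaped as a scipy custom-method callable so
    ``basinhopping`` can drive it."""

    def local_minimize(fun, x0, args=(), skip_simplex=False, **unused):
        if skip_simplex:
            x, f = np.asarray(x0, dtype=float), float(fun(x0))
        else:
            res = minimize(
                fun,
                x0,
                method="Nelder-Mead",
                options={
                    "maxiter": opt.local_maxiter,
                    "xatol": 1e-6,
                    "fatol": 1e-10,
                    "adaptive": True,
                },
            )
            x, f = np.asarray(res.x), float(res.fun)
        if opt.polish:
            # FD step well above the integrator tolerance so the numerical
            # Jacobian is smooth
            ls = least_squares(
                resid_fun, x, method="trf", max_nfev=opt.ls_max_nfev,
                diff_step=1e-4,
            )
            f_ls = float(np.sum(ls.fun**2))
            if f_ls < f:
                x, f = np.asarray(ls.x), f_ls
        return OptimizeResult(x=x, fun=f, success=True)

    return local_minimize


def fit_pair(
    tc: TimeCourse,
    variant: VariantSpec | str,
    opt: OptConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit one variant to one pair's time course.

    Deterministic for fixed (tc, variant, opt, seed).  Returns the best
    local minimum encountered across the seeded multi-start basin-hopping
    protocol; globality is not guaranteed.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    opt = opt or OptConfig()
    rng = np.random.default_rng(seed)
    names = variant.free_names

    def fun(x):
        return objective(_decode(x, names), variant, tc, opt.ic_mode, opt.solver)

    def resid(x):
        return weighted_residuals(_decode(x, names), variant, tc, opt.ic_mode, opt.solver)

    local_minimize = _make_local_minimizer(resid, opt)
    best_x = None
    best_f = np.inf
    for _ in range(max(1, opt.n_starts)):
        x0 = np.array(
            [
                rng.uniform(*opt.start_box_log)
                if n in POSITIVE_PARAMS
                else rng.uniform(*opt.start_box_lin)
                for n in names
            ]
        )
        if opt.n_hops > 0:
            res = basinhopping(
                fun,
                x0,
                niter=opt.n_hops,
                stepsize=opt.hop_step,
                minimizer_kwargs={"method": local_minimize},
                seed=rng,
            )
            x_cand, f_cand = np.asarray(res.x), float(res.fun)
        else:
            res = local_minimize(fun, x0)
            x_cand, f_cand = np.asarray(res.x), float(res.fun)
        if f_cand < best_f:
            best_f, best_x = f_cand, x_cand

    if best_x is None or not math.isfinite(best_f) or best_f >= PENALTY_OBJECTIVE:
        raise RuntimeError(
            f"fit of variant {variant.name!r} to pair {tc.pair_label!r} never "
            f"reached a finite objective (best {best_f:g}) across "
            f"{max(1, opt.n_starts)} starts"
        )
    free = _decode(best_x, names)
    return FitResult(
        pair_label=tc.pair_label,
        variant_name=variant.name,
        free_vector=free,
        params=apply_variant(variant, free),
        chi2=best_f,
        n_points=2 * tc.n_times,
        converged=True,
        n_restarts=max(1, opt.n_starts),
        seed=seed,
    )


def refine_fit(
    fit: FitResult,
    tc: TimeCourse,
    variant: VariantSpec | str,
    start_params: ZParams,
    opt: OptConfig,
) -> FitResult:
    """Re-polish a fit from an explicit parameter start; keep the better one.

    Used to share optima across pairs (warm starts) and across the nested
    family: any constrained variant's optimum is a feasible full-model
    point, so polishing the full model from it can only lower (or keep)
    the full model's chi2.  Only the least-squares refinement runs here —
    the start is already a local optimum of some related problem.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    names = variant.free_names
    x0 = _encode([getattr(start_params, n) for n in names], names)
    opt = replace(opt, ls_max_nfev=min(opt.ls_max_nfev, opt.refine_max_nfev))

    def fun(x):
        return objective(_decode(x, names), variant, tc, opt.ic_mode, opt.solver)

    def resid(x):
        return weighted_residuals(_decode(x, names), variant, tc, opt.ic_mode, opt.solver)

    res = _make_local_minimizer(resid, opt)(fun, x0, skip_simplex=True)
    if float(res.fun) < fit.chi2:
        free = _decode(np.asarray(res.x), names)
        return replace(
            fit,
            free_vector=free,
            params=apply_variant(variant, free),
            chi2=float(res.fun),
        )
    return fit


def _subseed(master_seed: int, pair_label: str, variant_name: str) -> int:
    import zlib

    h = zlib.crc32(f"{pair_label}|{variant_name}".encode())
    return int(np.random.SeedSequence([master_seed, h]).generate_state(1)[0] % (2**31))


def fit_all(
    dataset: Iterable[TimeCourse],
    variants: Sequence[VariantSpec | str] | None = None,
    opt: OptConfig | None = None,
    seed: int = 0,
    ensure_nesting: bool = True,
    n_jobs: int = 1,
) -> list[FitResult]:
    """Fit every (pair, variant) combination.

    Sub-seeds derive deterministically from (seed, pair, variant), so
    results do not depend on iteration or scheduling order.  Two optimum-
    sharing refinements follow the independent fits (both deterministic):
    cross-pair warm starts — each pair is re-polished from the best
    ``opt.portfolio_size`` optima found on other pairs for the same
    variant, exploiting that pairs with a shared mechanism live in nearby
    parameter basins — and, with ``ensure_nesting``, the full model is
    polished from each constrained variant's optimum on the same pair
    (every constrained optimum is a feasible full-model point).
    Per-combination failures are collected and reported together rather
    than aborting the whole run.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    opt = opt or OptConfig()
    variants = [VARIANTS[v] if isinstance(v, str) else v for v in (variants or VARIANTS.values())]

    jobs = [(tc, v) for tc in dataset for v in variants]

    def run_one(tc: TimeCourse, v: VariantSpec):
        return fit_pair(tc, v, opt, seed=_subseed(seed, tc.pair_label, v.name))

    failures: list[str] = []
    results: dict[tuple[str, str], FitResult] = {}
    if n_jobs != 1:
        from joblib import Parallel, delayed

        out = Parallel(n_jobs=n_jobs)(delayed(run_one)(tc, v) for tc, v in jobs)
        for (tc, v), r in zip(jobs, out):
            results[(tc.pair_label, v.name)] = r
    else:
        for tc, v in jobs:
            try:
                results[(tc.pair_label, v.name)] = run_one(tc, v)
            except RuntimeError as exc:
                failures.append(str(exc))
    if failures:
        raise RuntimeError(
            "fit_all: %d (pair, variant) fits failed:\n%s" % (len(failures), "\n".join(failures))
        )

    variant_names = [v.name for v in variants]
    if opt.portfolio_size > 0 and len(dataset) > 1:
        for v in variants:
            ranked = sorted(
                (results[(tc.pair_label, v.name)] for tc in dataset),
                key=lambda f: (f.chi2, f.pair_label),
            )
            portfolio = ranked[: opt.portfolio_size]
            for tc in dataset:
                fit = results[(tc.pair_label, v.name)]
                for donor in portfolio:
                    if donor.pair_label == tc.pair_label:
                        continue
                    fit = refine_fit(fit, tc, v, donor.params, opt)
                results[(tc.pair_label, v.name)] = fit

    if ensure_nesting and "full" in variant_names:
        for tc in dataset:
            fit_full = results[(tc.pair_label, "full")]
            for vn in variant_names:
                if vn == "full":
                    continue
                fit_full = refine_fit(
                    fit_full, tc, "full", results[(tc.pair_label, vn)].params, opt
                )
            results[(tc.pair_label, "full")] = fit_full

    return [results[(tc.pair_label, v.name)] for tc in dataset for v in variants]
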