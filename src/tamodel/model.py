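"""Minimal ODE model of type II toxin-antitoxin (TA) gene expression.

A type II TA operon encodes a stable toxin T and an unstable antitoxin A.
The two proteins form a complex AT that represses the operon (negative
feedback), while free toxin slows cell growth, which in turn lowers protein
production and dilution.  The module defines two equivalent ODE systems:

* the *original* system in physical concentrations ``(y1, y2, y3)`` =
  (antitoxin, toxin, complex), with primed kinetic constants, and
* the *Z-model*, a rescaled version in which toxin production is absorbed
  into the units (``y1 = k2' z1``, ``y2 = k2' z2``, ``y3 = (k2'/d3) z3``),
  leaving 10 adjustable constants including the initial complex level c0.

The Z-model right-hand side is::

    dz1/dt = -d1 z1 + k1 / ((1 + z3/s1)(bm z2 + 1)) - k2 z1 z2 + z3
    dz2/dt = -d2 z2 / (bc z2 + 1) - k2 z1 z2 + z3
             + 1 / ((1 + z3/s2)(bm z2 + 1))
    dz3/dt = -d3 (-k2 z1 z2 + z3)

Seven nested variants constrain the Z-model by tying s1=s2 and/or fixing
bm, bc (and, for the simplest variant, s1=s2=1).  ``VARIANTS`` holds their
definitions with a fixed free-parameter order so fitted vectors are
comparable across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "OriginalParams",
    "ZParams",
    "Trajectory",
    "VariantSpec",
    "VARIANTS",
    "VARIANT_NAMES",
    "FULL_PARAM_NAMES",
    "SolverConfig",
    "SimulationError",
    "z_rhs",
    "original_rhs",
    "rescale",
    "apply_variant",
    "simulate",
    "simulate_original",
]

#: Canonical order of the full Z-model's adjustable constants.
FULL_PARAM_NAMES: tuple[str, ...] = (
    "k1", "k2", "d1", "d2", "d3", "s1", "s2", "bm", "bc", "c0",
)

#: Parameters that must be strictly positive; the rest are non-negative.
POSITIVE_PARAMS = frozenset({"k1", "k2", "d1", "d2", "d3", "s1", "s2"})


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails (e.g. step-size collapse).

    Carries the parameter set and the time at which integration stopped,
    so a fitting loop can log and penalise the offending point.
    """

    def __init__(self, message: str, params=None, failed_time: float | None = None):
        super().__init__(message)
        self.params = params
        self.failed_time = failed_time


def _check_finite_nonneg(state, what: str = "state") -> None:
    arr = np.asarray(state, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{what} must have exactly 3 components, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains non-finite values: {arr}")


@dataclass(frozen=True)
class OriginalParams:
    """Kinetic constants of the unscaled TA system.

    Units: production rates in concentration/h, first-order rates in 1/h,
    the association rate ``k3`` in 1/(concentration*h), feedback scales
    ``s1p``/``s2p`` in concentration, inhibition coefficients ``bmp``/``bcp``
    in 1/concentration.  ``k2p`` (maximal toxin production) doubles as the
    rescaling factor that maps this system onto the Z-model.
    """

    k1p: float
    k2p: float
    k3: float
    d1: float
    d2: float
    d3: float
    s1p: float
    s2p: float
    bmp: float = 0.0
    bcp: float = 0.0

    def __post_init__(self):
        for name in ("k1p", "k2p", "k3", "d1", "d2", "d3", "s1p", "s2p"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"OriginalParams.{name} must be strictly positive, got {v}")
        for name in ("bmp", "bcp"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"OriginalParams.{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class ZParams:
    """Adjustable constants of the rescaled Z-model.

    ``k1`` is the antitoxin/toxin production ratio (dimensionless), ``k2``
    the effective complex association rate, ``d1``/``d2``/``d3`` first-order
    decay rates (1/h), ``s1``/``s2`` the repression scales of the complex on
    antitoxin and toxin production, ``bm`` the toxin's expression-inhibition
    coefficient, ``bc`` its growth(-degradation) inhibition coefficient and
    ``c0`` the unobserved initial complex concentration z3(0).
    """

    k1: float
    k2: float
    d1: float
    d2: float
    d3: float
    s1: float
    s2: float
    bm: float = 0.0
    bc: float = 0.0
    c0: float = 0.0

    def __post_init__(self):
        for name in sorted(POSITIVE_PARAMS):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"ZParams.{name} must be strictly positive, got {v}")
        for name in ("bm", "bc", "c0"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"ZParams.{name} must be non-negative, got {v}")

    def as_vector(self) -> np.ndarray:
        """Values in the canonical ``FULL_PARAM_NAMES`` order."""
        return np.array([getattr(self, n) for n in FULL_PARAM_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in FULL_PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ZParams":
        return cls(**{n: float(d[n]) for n in FULL_PARAM_NAMES})


@dataclass(frozen=True)
class Trajectory:
    """A simulated (z1, z2, z3) time course on a caller-supplied grid."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 3)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        if s.shape != (t.size, 3):
            raise ValueError(f"states shape {s.shape} does not match {t.size} times")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)

    @property
    def z1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def z2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def z3(self) -> np.ndarray:
        return self.states[:, 2]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.times, "z1": self.z1, "z2": self.z2, "z3": self.z3}
        )


def z_rhs(state: Sequence[float], params: ZParams) -> tuple[float, float, float]:
    """Time derivatives (dz1/dt, dz2/dt, dz3/dt) of the Z-model.

    The repression factors are evaluated as ``s/(s + z3)``, algebraically
    identical to ``1/(1 + z3/s)`` for s > 0 but immune to overflow when
    ``z3/s`` is huge.
    """
    _check_finite_nonneg(state)
    z1, z2, z3 = (float(v) for v in state)
    p = params
    rep1 = p.s1 / (p.s1 + z3)
    rep2 = p.s2 / (p.s2 + z3)
    growth = 1.0 / (p.bm * z2 + 1.0)
    assoc = p.k2 * z1 * z2
    dz1 = -p.d1 * z1 + p.k1 * rep1 * growth - assoc + z3
    dz2 = -p.d2 * z2 / (p.bc * z2 + 1.0) - assoc + z3 + rep2 * growth
    dz3 = -p.d3 * (z3 - assoc)
    return (dz1, dz2, dz3)


def original_rhs(state: Sequence[float], params: OriginalParams) -> tuple[float, float, float]:
    """Time derivatives of the unscaled (y1, y2, y3) system."""
    _check_finite_nonneg(state)
    y1, y2, y3 = (float(v) for v in state)
    p = params
    rep1 = p.s1p / (p.s1p + y3)
    rep2 = p.s2p / (p.s2p + y3)
    growth = 1.0 / (p.bmp * y2 + 1.0)
    exchange = p.d3 * y3 - p.k3 * y1 * y2
    dy1 = p.k1p * rep1 * growth - p.d1 * y1 + exchange
    dy2 = p.k2p * rep2 * growth - p.d2 * y2 / (p.bcp * y2 + 1.0) + exchange
    dy3 = -exchange
    return (dy1, dy2, dy3)


def rescale(params: OriginalParams) -> dict[str, float]:
    """Map original kinetic constants onto Z-model constants.

    Returns a dict of the nine kinetic Z-constants (everything except c0,
    which is an initial condition, not a kinetic constant):
    ``k1 = k1p/k2p``, ``k2 = k2p*k3``, ``s1 = d3*s1p/k2p``,
    ``s2 = d3*s2p/k2p``, ``bm = bmp*k2p``, ``bc = bcp*k2p``; the decay
    rates pass through unchanged.
    """
    p = params
    return {
        "k1": p.k1p / p.k2p,
        "k2": p.k2p * p.k3,
        "d1": p.d1,
        "d2": p.d2,
        "d3": p.d3,
        "s1": p.d3 * p.s1p / p.k2p,
        "s2": p.d3 * p.s2p / p.k2p,
        "bm": p.bmp * p.k2p,
        "bc": p.bcp * p.k2p,
    }


@dataclass(frozen=True)
class VariantSpec:
    """One member of the nested model family.

    ``ties`` maps a dropped parameter to the free parameter it must equal
    (e.g. ``{"s2": "s1"}``); ``fixed`` maps dropped parameters to constants
    (e.g. ``{"bm": 0.0}``).  ``free_names`` is the ordered list of remaining
    adjustable constants and ``nv`` its length, the parameter count used by
    the information-criterion penalties.
    """

    name: str
    ties: Mapping[str, str] = field(default_factory=dict)
    fixed: Mapping[str, float] = field(default_factory=dict)

    @property
    def free_names(self) -> tuple[str, ...]:
        dropped = set(self.ties) | set(self.fixed)
        return tuple(n for n in FULL_PARAM_NAMES if n not in dropped)

    @property
    def nv(self) -> int:
        return len(self.free_names)


def _make_variants() -> dict[str, VariantSpec]:
    v = [
        VariantSpec("full"),
        VariantSpec("s1=s2", ties={"s2": "s1"}),
        VariantSpec("s1=s2_no_bm", ties={"s2": "s1"}, fixed={"bm": 0.0}),
        VariantSpec("s1=s2_no_bc", ties={"s2": "s1"}, fixed={"bc": 0.0}),
        VariantSpec("s1=s2_no_bm_bc", ties={"s2": "s1"}, fixed={"bm": 0.0, "bc": 0.0}),
        VariantSpec("s1!=s2_no_bm", fixed={"bm": 0.0}),
        VariantSpec("s1!=s2_no_bc", fixed={"bc": 0.0}),
        VariantSpec(
            "no_s1_s2_bm_bc", fixed={"s1": 1.0, "s2": 1.0, "bm": 0.0, "bc": 0.0}
        ),
    ]
    return {spec.name: spec for spec in v}


#: The full Z-model and its seven constrained variants, keyed by name.
VARIANTS: dict[str, VariantSpec] = _make_variants()
VARIANT_NAMES: tuple[str, ...] = tuple(VARIANTS)


def apply_variant(variant: VariantSpec | str, free_vector: Sequence[float]) -> ZParams:
    """Expand a variant's free-parameter vector into complete ``ZParams``."""
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    free_vector = np.asarray(free_vector, dtype=float)
    if free_vector.shape != (variant.nv,):
        raise ValueError(
            f"variant {variant.name!r} expects {variant.nv} free parameters, "
            f"got {free_vector.shape}"
        )
    values = dict(zip(variant.free_names, free_vector.tolist()))
    values.update({k: float(v) for k, v in variant.fixed.items()})
    for target, source in variant.ties.items():
        values[target] = values[source]
    return ZParams(**values)


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive-integrator settings (LSODA: stiffness-switching)."""

    rtol: float = 1e-8
    atol: float = 1e-10
    mxstep: int = 10000


_DEFAULT_SOLVER = SolverConfig()


def _integrate(rhs_flat, y0, times, cfg: SolverConfig, params):
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a non-empty 1-D array")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    y, info = odeint(
        rhs_flat,
        np.asarray(y0, dtype=float),
        times,
        rtol=cfg.rtol,
        atol=cfg.atol,
        mxstep=cfg.mxstep,
        full_output=True,
        printmessg=False,
    )
    if info["message"] != "Integration successful.":
        reached = float(info["tcur"][-1]) if len(info.get("tcur", [])) else times[0]
        raise SimulationError(
            f"ODE integration failed: {info['message']} (reached t={reached:.4g})",
            params=params,
            failed_time=reached,
        )
    if not np.all(np.isfinite(y)):
        raise SimulationError(
            "ODE integration produced non-finite values", params=params
        )
    return y


def simulate(
    params: ZParams,
    initial: Sequence[float],
    times: Sequence[float],
    solver: SolverConfig = _DEFAULT_SOLVER,
) -> Trajectory:
    """Integrate the Z-model from ``initial`` over the requested grid.

    ``times`` must be strictly increasing; the first entry is the time of
    the initial condition.  Non-negativity is preserved by tolerance choice
    (no clipping); excursions below ``-10*atol`` raise ``SimulationError``.
    """
    _check_finite_nonneg(initial, "initial state")
    p = params

    def rhs(z, t):
        z1, z2, z3 = z
        rep1 = p.s1 / (p.s1 + z3)
        rep2 = p.s2 / (p.s2 + z3)
        growth = 1.0 / (p.bm * z2 + 1.0)
        assoc = p.k2 * z1 * z2
        return (
            -p.d1 * z1 + p.k1 * rep1 * growth - assoc + z3,
            -p.d2 * z2 / (p.bc * z2 + 1.0) - assoc + z3 + rep2 * growth,
            -p.d3 * (z3 - assoc),
        )

    y = _integrate(rhs, initial, times, solver, params)
    if np.min(y) < -10.0 * solver.atol * max(1.0, float(np.max(np.abs(y)))):
        raise SimulationError(
            f"trajectory left the non-negative orthant (min={np.min(y):.3g})",
            params=params,
        )
    return Trajectory(times=np.asarray(times, dtype=float), states=y)


def simulate_original(
    params: OriginalParams,
    initial: Sequence[float],
    times: Sequence[float],
    solver: SolverConfig = _DEFAULT_SOLVER,
) -> Trajectory:
    """Integrate the unscaled (y1, y2, y3) system; used to verify rescaling."""
    _check_finite_nonneg(initial, "initial state")
    p = params

    def rhs(y, t):
        y1, y2, y3 = y
        rep1 = p.s1p / (p.s1p + y3)
        rep2 = p.s2p / (p.s2p + y3)
        growth = 1.0 / (p.bmp * y2 + 1.0)
        exchange = p.d3 * y3 - p.k3 * y1 * y2
        return (
            p.k1p * rep1 * growth - p.d1 * y1 + exchange,
            p.k2p * rep2 * growth - p.d2 * y2 / (p.bcp * y2 + 1.0) + exchange,
            -exchange,
        )

    y = _integrate(rhs, initial, times, solver, params)
    return Trajectory(times=np.asarray(times, dtype=float), states=y)
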