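"""Model selection across the nested TA-model family via AIC/BIC.

For least-squares fits with N data points and Nv adjustable parameters the
criteria reduce to

    aic = N ln(chi2 / N) + 2 Nv
    bic = N ln(chi2 / N) + ln(N) Nv

where chi2 is the (weighted) sum of squared residuals.  The *collective*
comparison sums chi2 over all TA pairs and counts N as the total number of
timepoints across pairs — a pair's timepoint count enters once, not once
per curve (11 pairs x 10 timepoints -> N = 110).  A switch is provided to
count the two curves separately for sensitivity analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .fitting import FitResult
from .model import VARIANTS

__all__ = [
    "SelectionRow",
    "information_criteria",
    "collective_selection",
    "per_pair_selection",
    "best_model",
    "CHI2_FLOOR",
]

#: Substituted (with a warning) when a fit's chi2 is numerically zero.
CHI2_FLOOR = 1e-12


@dataclass(frozen=True)
class SelectionRow:
    variant_name: str
    chi2: float
    n: int
    nv: int
    aic: float
    bic: float

    def to_record(self) -> dict:
        return {
            "variant": self.variant_name,
            "chi2": self.chi2,
            "N": self.n,
            "Nv": self.nv,
            "aic": self.aic,
            "bic": self.bic,
        }


def information_criteria(chi2: float, n: int, nv: int) -> tuple[float, float]:
    """Closed-form AIC and BIC for a least-squares fit."""
    if chi2 <= 0:
        raise ValueError(
            "information criteria need chi2 > 0 (the log of a perfect fit is "
            f"undefined); got {chi2!r} — substitute a solver-tolerance floor"
        )
    if n < 1:
        raise ValueError(f"need at least one data point, got N={n}")
    if nv < 0:
        raise ValueError(f"parameter count must be non-negative, got Nv={nv}")
    goodness = n * math.log(chi2 / n)
    return goodness + 2.0 * nv, goodness + math.log(n) * nv


def _floored_chi2(chi2: float, label: str) -> float:
    if chi2 <= CHI2_FLOOR:
        warnings.warn(
            f"{label}: chi2={chi2:g} at or below numerical zero; "
            f"flooring to {CHI2_FLOOR:g} for the information criteria",
            stacklevel=3,
        )
        return CHI2_FLOOR
    return chi2


def collective_selection(
    fit_results: Iterable[FitResult],
    criterion: str = "bic",
    count_curves_separately: bool = False,
) -> list[SelectionRow]:
    """One row per variant, pooling chi2 over all pairs.

    Every variant must have a fit for every pair.  Nv is the per-model
    adjustable-parameter count (the full model's 10), not the total over
    independent per-pair fits.  Rows are sorted ascending by ``criterion``.
    """
    fits = list(fit_results)
    if not fits:
        raise ValueError("no fit results supplied")
    pairs = sorted({f.pair_label for f in fits})
    variants = sorted({f.variant_name for f in fits})
    by_key = {(f.pair_label, f.variant_name): f for f in fits}
    gaps = [
        f"({p}, {v})" for v in variants for p in pairs if (p, v) not in by_key
    ]
    if gaps:
        raise ValueError(
            "collective selection needs every pair fitted for every variant; "
            "missing: " + ", ".join(gaps)
        )

    rows = []
    for v in variants:
        chi2 = sum(by_key[(p, v)].chi2 for p in pairs)
        # n_points on FitResult counts both curves (2 x timepoints); the
        # collective N counts each timepoint once unless asked otherwise.
        n = sum(
            by_key[(p, v)].n_points // (1 if count_curves_separately else 2)
            for p in pairs
        )
        nv = VARIANTS[v].nv if v in VARIANTS else len(by_key[(pairs[0], v)].free_vector)
        aic, bic = information_criteria(_floored_chi2(chi2, f"variant {v}"), n, nv)
        rows.append(SelectionRow(v, chi2, n, nv, aic, bic))
    return sorted(rows, key=lambda r: getattr(r, criterion))


def per_pair_selection(
    fit_results: Iterable[FitResult], criterion: str = "bic"
) -> dict[str, list[SelectionRow]]:
    """Selection rows computed independently for each TA pair."""
    out: dict[str, list[SelectionRow]] = {}
    fits = list(fit_results)
    for pair in sorted({f.pair_label for f in fits}):
        rows = []
        for f in fits:
            if f.pair_label != pair:
                continue
            n = f.n_points // 2
            nv = len(f.free_vector)
            aic, bic = information_criteria(
                _floored_chi2(f.chi2, f"pair {pair}, variant {f.variant_name}"), n, nv
            )
            rows.append(SelectionRow(f.variant_name, f.chi2, n, nv, aic, bic))
        out[pair] = sorted(rows, key=lambda r: getattr(r, criterion))
    return out


def best_model(rows: Sequence[SelectionRow], criterion: str = "bic") -> str:
    """Variant with the smallest criterion; ties favour fewer parameters,
    then lexicographic name."""
    if not rows:
        raise ValueError("no selection rows")
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    best = min(rows, key=lambda r: (getattr(r, criterion), r.nv, r.variant_name))
    return best.variant_name
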