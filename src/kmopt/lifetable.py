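"""Kaplan-Meier life-table arithmetic for two-arm survival curves.

Given digitized survival probabilities at a set of timepoints and a candidate
censoring pattern, this module reconstructs the full life table — events,
numbers at risk, and expected events under the null of equal hazards — and
summarises it into the meta-analysis quantities: hazard ratio, ln(HR),
var ln(HR), the log-rank chi-square and the achieved P value.

The arithmetic is deliberately continuous: event and censor counts are real
numbers, not integers, so that the censoring pattern can be treated as a
smooth decision vector by a constrained optimiser.  Counts are reported
unrounded; round only for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "CurvePoints",
    "CensorVector",
    "LifeTable",
    "SummaryStats",
    "InfeasibleTableError",
    "km_step",
    "events_from_survival",
    "build_life_table",
    "expected_events",
    "summarise",
    "p_to_chisq",
    "chisq_to_p",
]

N_GROUPS = 2  # everything here is two-arm


class InfeasibleTableError(ValueError):
    """A censoring pattern removes more people than remain at risk."""


@dataclass(frozen=True)
class CurvePoints:
    """Digitized survival-curve points shared by both arms.

    ``times`` must be strictly increasing with ``times[0] == 0`` and both
    survival series must start at 1 and be non-increasing.  Every timepoint
    carries a survival value for both arms; construction enforces the
    invariants.
    """

    times: np.ndarray
    s1: np.ndarray
    s2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "s1", np.asarray(self.s1, dtype=float))
        object.__setattr__(self, "s2", np.asarray(self.s2, dtype=float))
        t, s1, s2 = self.times, self.s1, self.s2
        if not (t.shape == s1.shape == s2.shape) or t.ndim != 1:
            raise ValueError("times, s1 and s2 must be 1-d arrays of equal length")
        if t.size < 2:
            raise ValueError("need at least the baseline plus one timepoint")
        if t[0] != 0.0:
            raise ValueError("first timepoint must be t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, s in (("s1", s1), ("s2", s2)):
            if s[0] != 1.0:
                raise ValueError(f"{name}[0] must be 1 (survival at baseline)")
            if np.any((s < 0) | (s > 1)):
                raise ValueError(f"{name} values must lie in [0, 1]")
            if np.any(np.diff(s) > 0):
                raise ValueError(f"{name} must be non-increasing")
            # S = 0 is absorbing: permitted only from the final timepoint on
            zero = np.flatnonzero(s == 0.0)
            if zero.size and zero[0] < s.size - 1 and np.any(s[zero[0]:] != 0.0):
                raise ValueError(f"{name} reaches 0 before the final timepoint")

    @property
    def n_timepoints(self) -> int:
        """Number of post-baseline timepoints (the unknowns per arm)."""
        return self.times.size - 1

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class CensorVector:
    """Per-timepoint censor counts for both arms (baseline entry fixed 0).

    A censor recorded at timepoint j leaves the risk set *after* j: it is
    subtracted, together with the events at j, when computing the number at
    risk at j+1.
    """

    c1: np.ndarray
    c2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "c1", np.asarray(self.c1, dtype=float))
        object.__setattr__(self, "c2", np.asarray(self.c2, dtype=float))
        if self.c1.shape != self.c2.shape or self.c1.ndim != 1:
            raise ValueError("c1 and c2 must be 1-d arrays of equal length")

    @classmethod
    def zeros(cls, n_times: int) -> "CensorVector":
        return cls(np.zeros(n_times), np.zeros(n_times))

    def __len__(self) -> int:
        return self.c1.size


@dataclass
class LifeTable:
    """Complete two-arm life table on a common time grid.

    All count arrays have one entry per timepoint, index 0 being the
    baseline (no events, no censoring, full cohort at risk).  Counts are
    real-valued.
    """

    times: np.ndarray
    n1: np.ndarray
    e1: np.ndarray
    c1: np.ndarray
    n2: np.ndarray
    e2: np.ndarray
    c2: np.ndarray
    n1_0: float
    n2_0: float
    exp1: np.ndarray = field(default=None)  # type: ignore[assignment]
    exp2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        exp1 = self.exp1 if self.exp1 is not None else np.full_like(self.e1, np.nan)
        exp2 = self.exp2 if self.exp2 is not None else np.full_like(self.e2, np.nan)
        return pd.DataFrame(
            {
                "time": self.times,
                "n1": self.n1,
                "e1": self.e1,
                "c1": self.c1,
                "E1": exp1,
                "n2": self.n2,
                "e2": self.e2,
                "c2": self.c2,
                "E2": exp2,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SummaryStats:
    """Log-rank summary of a life table: the meta-analysis outputs.

    ``hr`` is arm 1 versus arm 2, (O1/E1)/(O2/E2).  ``var_ln_hr`` follows the
    expected-events convention 1/E1 + 1/E2 by default (see ``summarise``).
    A degenerate arm (zero observed events) yields an infinite ln(HR) rather
    than an exception.
    """

    o1: float
    o2: float
    e1: float
    e2: float
    hr: float
    ln_hr: float
    var_ln_hr: float
    chi_sq: float
    p_achieved: float
    g: int = N_GROUPS

    def ci95(self) -> tuple[float, float]:
        """Derived 95% CI for the HR: exp(ln_hr ± 1.96·sqrt(var))."""
        half = 1.96 * math.sqrt(self.var_ln_hr)
        return math.exp(self.ln_hr - half), math.exp(self.ln_hr + half)


def km_step(s_prev: float, e_j: float, n_j: float) -> float:
    """One product-limit step: S(t_j) = S(t_{j-1}) * (1 - e_j / n_j)."""
    if n_j <= 0:
        if e_j > 0:
            raise ValueError("events recorded with no one at risk")
        return s_prev
    return s_prev * (1.0 - e_j / n_j)


def events_from_survival(n_j, s_j, s_prev):
    """Invert the product-limit step: e_j = n_j * (1 - S(t_j)/S(t_{j-1})).

    Vectorised over numpy arrays; scalar in, scalar out.
    """
    s_prev = np.asarray(s_prev, dtype=float)
    if np.any(s_prev <= 0):
        raise ValueError("survival already zero: no further events are defined")
    return np.asarray(n_j, dtype=float) * (1.0 - np.asarray(s_j, dtype=float) / s_prev)


def _arm_recursion(
    s: np.ndarray, c: np.ndarray, n0: float, strict: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Forward recursion for one arm: at-risk and event counts per timepoint."""
    m = s.size
    n = np.empty(m)
    e = np.empty(m)
    n[0] = n0
    e[0] = 0.0
    for j in range(1, m):
        n[j] = n[j - 1] - (c[j - 1] + e[j - 1])
        if strict and n[j] < -1e-9:
            raise InfeasibleTableError(
                f"number at risk becomes negative ({n[j]:.4g}) at timepoint {j}"
            )
        if s[j - 1] > 0:
            e[j] = n[j] * (1.0 - s[j] / s[j - 1])
        else:  # absorbed at S = 0; no further events possible
            e[j] = 0.0
    return n, e


def build_life_table(
    points: CurvePoints,
    censors: CensorVector,
    n1_0: float,
    n2_0: float,
    *,
    strict: bool = True,
) -> LifeTable:
    """Reconstruct the two-arm life table implied by survival points and censors.

    Each arm is processed independently: the number at risk is carried
    forward (n_j = n_{j-1} - censor_{j-1} - e_{j-1}) and the events at each
    timepoint recovered from the survival ratio.  With ``strict=True`` a
    negative intermediate at-risk count raises :class:`InfeasibleTableError`;
    the optimiser disables this and instead penalises the violation through
    an explicit constraint, keeping the map x -> table smooth.
    """
    if len(censors) != len(points):
        raise ValueError("censor vector length must match the number of timepoints")
    if n1_0 < 1 or n2_0 < 1:
        raise ValueError("starting numbers at risk must be >= 1")
    # baseline censors (index 0) are legal: they represent subjects leaving
    # before the first recorded timepoint.  The optimiser never exposes that
    # slot as an unknown, but exact ground-truth tables may populate it.
    n1, e1 = _arm_recursion(points.s1, censors.c1, float(n1_0), strict)
    n2, e2 = _arm_recursion(points.s2, censors.c2, float(n2_0), strict)
    return LifeTable(
        times=points.times.copy(),
        n1=n1,
        e1=e1,
        c1=censors.c1.copy(),
        n2=n2,
        e2=e2,
        c2=censors.c2.copy(),
        n1_0=float(n1_0),
        n2_0=float(n2_0),
    )


def expected_events(table: LifeTable) -> LifeTable:
    """Allocate expected events under the null of equal hazards.

    At each timepoint the total events are split in proportion to each arm's
    share of the combined risk set: E_ij = (e_1j + e_2j) * n_ij / (n_1j + n_2j).
    Conservation (E_1j + E_2j = e_1j + e_2j) holds per timepoint.
    """
    total_e = table.e1 + table.e2
    total_n = table.n1 + table.n2
    if np.any((total_n == 0) & (total_e > 0)):
        raise ValueError("events present at a timepoint with no one at risk")
    # negative risk sets only arise on the optimiser's relaxed path, where the
    # allocation extends smoothly and the n >= 0 constraints push back
    nonzero = total_n != 0
    frac1 = np.where(nonzero, table.n1 / np.where(nonzero, total_n, 1.0), 0.0)
    exp1 = total_e * frac1
    exp2 = total_e - exp1
    return replace(table, exp1=exp1, exp2=exp2)


def summarise(table: LifeTable, *, variance: str = "expected") -> SummaryStats:
    """Collapse a life table into log-rank summary statistics.

    ``variance`` selects the var ln(HR) convention: ``"expected"`` (default)
    gives 1/E1 + 1/E2, ``"observed"`` gives 1/O1 + 1/O2.
    """
    if table.exp1 is None or table.exp2 is None:
        table = expected_events(table)
    o1 = float(np.sum(table.e1))
    o2 = float(np.sum(table.e2))
    e1 = float(np.sum(table.exp1))
    e2 = float(np.sum(table.exp2))
    if e1 <= 0 or e2 <= 0:
        raise ValueError("expected events must be positive in both arms")
    if o1 <= 0 or o2 <= 0:
        # degenerate HR: signal with +/- infinity rather than crash
        hr = 0.0 if o1 <= 0 and o2 > 0 else math.inf
        ln_hr = -math.inf if hr == 0.0 else math.inf
    else:
        hr = (o1 / e1) / (o2 / e2)
        ln_hr = math.log(hr)
    if variance == "expected":
        var = 1.0 / e1 + 1.0 / e2
    elif variance == "observed":
        if o1 <= 0 or o2 <= 0:
            var = math.inf
        else:
            var = 1.0 / o1 + 1.0 / o2
    else:
        raise ValueError(f"unknown variance convention: {variance!r}")
    chi_sq = (o1 - e1) ** 2 / e1 + (o2 - e2) ** 2 / e2
    p = float(chi2.sf(chi_sq, df=1))
    return SummaryStats(
        o1=o1, o2=o2, e1=e1, e2=e2,
        hr=hr, ln_hr=ln_hr, var_ln_hr=var,
        chi_sq=chi_sq, p_achieved=p,
    )


def p_to_chisq(p: float) -> float:
    """1-df chi-square value whose right-tail probability equals ``p``.

    The inverse survival function: p = 0.05 gives 3.841, p = 0.95 gives
    3.9e-3, p = 1 gives 0.  Strictly decreasing in p.
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    return float(chi2.isf(p, df=1))


def chisq_to_p(x: float) -> float:
    """Right-tail probability of a 1-df chi-square value (inverse of p_to_chisq)."""
    if x < 0:
        raise ValueError("chi-square value must be non-negative")
    return float(chi2.sf(x, df=1))
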