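"""Read and validate digitized survival-curve points and published P values.

The input contract mirrors what reading points off a published Kaplan-Meier
plot produces: a three-column CSV (time, s1, s2) with a baseline row
(0, 1, 1), strictly increasing times, and non-increasing survival in both
arms.  Every rejection names the offending row and the rule it broke, so a
digitization slip is caught before any optimisation runs.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .lifetable import CurvePoints
from .optimizer import PValueSpec

__all__ = [
    "PointValidationError",
    "read_point_csv",
    "validate_points",
    "align_final_timepoint",
    "parse_pvalue",
]

REQUIRED_COLUMNS = ("time", "s1", "s2")


class PointValidationError(ValueError):
    """Input points violate a structural rule; carries row index and rule name."""

    def __init__(self, row: int | None, rule: str, message: str):
        self.row = row
        self.rule = rule
        where = f" (row {row})" if row is not None else ""
        super().__init__(f"{message}{where} [rule: {rule}]")


def read_point_csv(path) -> pd.DataFrame:
    """Parse a comma-separated, dot-decimal points file with header time,s1,s2."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    missing = [c for c in REQUIRED_COLUMNS if c not in cols]
    if missing:
        raise PointValidationError(
            None, "header", f"missing required column(s): {', '.join(missing)}"
        )
    df = df[list(REQUIRED_COLUMNS)]
    for c in REQUIRED_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def align_final_timepoint(df: pd.DataFrame) -> pd.DataFrame:
    """Extend the shorter arm to the common final time by carrying its last value.

    Digitized curves often end at different times; the arm whose plot ends
    earlier keeps its last survival probability up to the other arm's final
    time.  Trailing missing values in either survival column are filled with
    that column's last observed value; the result is unchanged when already
    aligned.
    """
    df = df.copy()
    for col in ("s1", "s2"):
        vals = df[col].to_numpy(dtype=float)
        obs = np.flatnonzero(~np.isnan(vals))
        if obs.size == 0:
            raise PointValidationError(None, "empty_arm", f"column {col} has no values")
        last = obs[-1]
        vals[last + 1 :] = vals[last]
        df[col] = vals
    return df


def validate_points(df: pd.DataFrame) -> CurvePoints:
    """Check the structural rules and return normalised curve points.

    Rules: at least 3 rows including the baseline; finite numerics; t strictly
    increasing with t[0]=0; survival starting at 1, within [0,1], and
    non-increasing (flat segments are fine — they are censoring-only
    intervals); survival 0 only at the final timepoint.  Idempotent:
    accepted output always re-validates.
    """
    if isinstance(df, CurvePoints):
        df = pd.DataFrame({"time": df.times, "s1": df.s1, "s2": df.s2})
    if len(df) < 3:
        raise PointValidationError(
            None, "too_few_rows", "need at least 3 rows (baseline + 2 timepoints)"
        )
    t = df["time"].to_numpy(dtype=float)
    s1 = df["s1"].to_numpy(dtype=float)
    s2 = df["s2"].to_numpy(dtype=float)
    for name, v in (("time", t), ("s1", s1), ("s2", s2)):
        bad = np.flatnonzero(~np.isfinite(v))
        if bad.size:
            raise PointValidationError(
                int(bad[0]), "non_finite", f"column {name} is missing or non-numeric"
            )
    if t[0] != 0:
        raise PointValidationError(0, "baseline_time", "first time must be 0")
    dup = np.flatnonzero(np.diff(t) == 0)
    if dup.size:
        raise PointValidationError(
            int(dup[0] + 1), "duplicate_time", "time values must not be duplicated"
        )
    dec = np.flatnonzero(np.diff(t) < 0)
    if dec.size:
        raise PointValidationError(
            int(dec[0] + 1), "time_order", "times must be strictly increasing"
        )
    for name, s in (("s1", s1), ("s2", s2)):
        if s[0] != 1:
            raise PointValidationError(
                0, "baseline_survival", f"{name} must be 1 at baseline"
            )
        out = np.flatnonzero((s < 0) | (s > 1))
        if out.size:
            raise PointValidationError(
                int(out[0]), "range", f"{name} must lie in [0, 1]"
            )
        inc = np.flatnonzero(np.diff(s) > 0)
        if inc.size:
            raise PointValidationError(
                int(inc[0] + 1),
                "monotonicity",
                f"{name} increases; survival curves cannot rise",
            )
        # S = 0 is absorbing: once an arm hits 0 it must stay there.  A
        # trailing zero plateau is legal (the other arm's curve may continue);
        # monotonicity above already rejects any rise out of it.
    return CurvePoints(times=t, s1=s1, s2=s2)


_P_NUMBER = r"(\d*\.?\d+(?:[eE][+-]?\d+)?)"


def parse_pvalue(text: str) -> PValueSpec:
    """Turn a published P value string into a chi-square anchor spec.

    Accepts exact values ("0.03", "p = 0.03"), bounds ("<0.01", "p<0.001"),
    non-significance markers ("ns", "n.s.", ">0.05"), and a direct
    chi-square statistic via the prefix "chisq:" for papers that print the
    statistic instead of P.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty P value specification")
    raw = text.strip().lower()
    cleaned = re.sub(r"^\s*p\s*(value)?\s*", "", raw).strip()
    if cleaned.startswith("="):
        cleaned = cleaned[1:].strip()
    if raw.startswith("chisq:") or raw.startswith("chi2:"):
        stat = float(raw.split(":", 1)[1])
        return PValueSpec.exact_chisq(stat)
    if re.fullmatch(r"n\.?s\.?", cleaned):
        return PValueSpec.nonsignificant()
    m = re.fullmatch(r"<\s*" + _P_NUMBER, cleaned)
    if m:
        p = float(m.group(1))
        _check_p(p, text)
        return PValueSpec.less_than(p)
    m = re.fullmatch(r">\s*" + _P_NUMBER, cleaned)
    if m:
        p = float(m.group(1))
        _check_p(p, text)
        if p < NONSIG_MIN_BOUND:
            raise ValueError(
                f"'>{p}' is too weak an anchor; non-significant bounds start at 0.05"
            )
        return PValueSpec.nonsignificant(p_low=p)
    m = re.fullmatch(_P_NUMBER, cleaned)
    if m:
        p = float(m.group(1))
        _check_p(p, text)
        return PValueSpec.exact(p)
    raise ValueError(f"cannot parse P value specification: {text!r}")


NONSIG_MIN_BOUND = 0.05


def _check_p(p: float, original: str) -> None:
    if not 0 < p <= 1:
        raise ValueError(f"P value out of (0, 1]: {original!r}")
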