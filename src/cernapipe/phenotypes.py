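"""Closed-form physiology metrics and group comparisons.

Implements the glucose-tolerance summary used for OGTT/ITT panels (a
trapezoidal area under the 0/30/60/120-min blood-glucose curve, in
mmol/L·h), the HOMA-IR insulin-resistance index, and the per-group
mean ± SD / one-way ANOVA summaries used for phenotype tables.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

#: Fixed OGTT/ITT sampling times in minutes.
GLUCOSE_TIMES = (0, 30, 60, 120)

#: Trapezoid half-widths in hours for the 0-30, 30-60 and 60-120 min panels.
_AUC_WEIGHTS = (Decimal("0.25"), Decimal("0.25"), Decimal("0.5"))


class PhenotypeError(ValueError):
    """Invalid physiology input."""


def auc_trapezoid(series) -> float:
    """Trapezoidal AUC of a 4-point glucose series (mmol/L·h).

    ``series`` holds blood glucose (mmol/L) at 0, 30, 60 and 120 min.
    The area is ``0.25·(BG0+BG30) + 0.25·(BG30+BG60) + 0.5·(BG60+BG120)``,
    i.e. the trapezoid rule over a 2-hour window. Full precision is
    returned; use :func:`round_half_up` for the 2-decimal table value.
    """
    vals = np.asarray(series, dtype=float)
    if vals.shape != (4,):
        raise PhenotypeError(f"glucose series must have exactly 4 readings, got shape {vals.shape}")
    if not np.all(np.isfinite(vals)) or np.any(vals < 0):
        raise PhenotypeError("glucose readings must be finite and non-negative")
    b0, b30, b60, b120 = vals
    return 0.25 * (b0 + b30) + 0.25 * (b30 + b60) + 0.5 * (b60 + b120)


def auc_trapezoid_reported(series) -> float:
    """AUC rounded half-up to 2 decimals, matching printed tables.

    Decimal arithmetic on the printed inputs avoids binary-float
    round-to-even artefacts on exact .xx5 values.
    """
    vals = np.asarray(series, dtype=float)
    auc_trapezoid(vals)  # validation
    dec = [Decimal(repr(float(v))) for v in vals]
    total = (
        _AUC_WEIGHTS[0] * (dec[0] + dec[1])
        + _AUC_WEIGHTS[1] * (dec[1] + dec[2])
        + _AUC_WEIGHTS[2] * (dec[2] + dec[3])
    )
    return float(total.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def homa_ir(fbg: float, fins: float) -> float:
    """HOMA-IR = FBG (mmol/L) × FINS (mIU/L) / 22.5 (dimensionless)."""
    if not (fbg > 0 and fins > 0):
        raise PhenotypeError("FBG and FINS must both be positive")
    return fbg * fins / 22.5


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (SPSS-style tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def group_summary(values_by_group: dict) -> pd.DataFrame:
    """Per-group mean and sample SD (n−1 denominator).

    Returns a frame with columns ``group, mean, sd, n``; a single
    observation yields sd 0 with n = 1 so degenerate groups are visible.
    """
    rows = []
    for group, values in values_by_group.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise PhenotypeError(f"group {group!r} is empty")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        rows.append({"group": group, "mean": float(arr.mean()), "sd": sd, "n": int(arr.size)})
    return pd.DataFrame(rows)


def one_way_anova(values_by_group: dict) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across ≥2 groups.

    F = (SSB/(k−1)) / (SSW/(N−k)); p from the F(k−1, N−k) distribution.
    Identical groups give F = 0, p = 1. Zero within-group variance with
    unequal means makes F infinite; zero within-variance with equal means
    is undefined and raises.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise PhenotypeError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise PhenotypeError("every group needs n >= 2")
    grand = np.concatenate(groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ssb = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in groups)
    df_between = len(groups) - 1
    df_within = grand.size - len(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            raise PhenotypeError("F undefined: zero variance within and between groups")
        return float("inf"), 0.0
    f_stat = (ssb / df_between) / (ssw / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


def pairwise_welch(values_by_group: dict, reference: str) -> pd.DataFrame:
    """Welch t-tests of every group against ``reference`` (no correction).

    Mirrors the tables' per-group significance stars against the disease
    control; the study does not name its post-hoc procedure, so unadjusted
    Welch tests are used and reported as such.
    """
    if reference not in values_by_group:
        raise PhenotypeError(f"reference group {reference!r} not present")
    ref = np.asarray(values_by_group[reference], dtype=float)
    rows = []
    for group, values in values_by_group.items():
        if group == reference:
            continue
        res = stats.ttest_ind(np.asarray(values, dtype=float), ref, equal_var=False)
        rows.append({"group": group, "vs": reference, "t": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)


def summarize_glucose_tables(tidy: pd.DataFrame, group_order=None) -> pd.DataFrame:
    """OGTT/ITT summary: per-test, per-group mean ± SD at each time plus AUC.

    ``tidy`` columns: sample_id, group, variable (``OGTT``/``ITT``),
    time_min, value. Per-animal AUCs are averaged; by linearity of the
    trapezoid rule this equals the AUC of the group-mean curve.
    """
    rows = []
    tests = [v for v in ("OGTT", "ITT") if v in set(tidy["variable"])]
    for test in tests:
        sub = tidy[tidy["variable"] == test]
        groups = group_order or list(dict.fromkeys(sub["group"]))
        for group in groups:
            g = sub[sub["group"] == group]
            wide = g.pivot_table(index="sample_id", columns="time_min", values="value")
            wide = wide[list(GLUCOSE_TIMES)]
            aucs = wide.apply(auc_trapezoid, axis=1)
            row = {"test": test, "group": group, "n": len(wide)}
            for t in GLUCOSE_TIMES:
                row[f"mean_{t}min"] = round_half_up(wide[t].mean())
                row[f"sd_{t}min"] = round_half_up(wide[t].std(ddof=1)) if len(wide) > 1 else 0.0
            # linearity: AUC of the mean curve = mean of per-animal AUCs;
            # the Decimal path keeps exact .xx5 values rounding half-up
            row["auc_mean"] = auc_trapezoid_reported(
                [round_half_up(wide[t].mean(), 6) for t in GLUCOSE_TIMES])
            row["auc_sd"] = round_half_up(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0
            rows.append(row)
    return pd.DataFrame(rows)
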