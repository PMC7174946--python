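"""Differential RNA screening on count matrices.

Counts are normalized to counts-per-million and log2(x+1) transformed;
each feature is tested with a moderated two-sample t statistic whose
per-feature variance is shrunk toward a pooled empirical-Bayes prior
(a scaled inverse-chi-square fit to the observed variances, the classic
limma-style squeeze). Calls require both a fold-change gate
(FC > 1.5 or FC < 0.667 by default; an absolute-log2FC gate of 0.667 is
available as the alternative published reading) and BH FDR < 0.05,
computed within each RNA category.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

CATEGORIES = ("mRNA", "ncRNA", "circRNA", "miRNA")

DIFF_COLUMNS = ["feature", "category", "comparison", "log2fc", "pvalue", "fdr", "direction"]


class DiffError(ValueError):
    """Invalid differential-screen input."""


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample; errors on an all-zero sample."""
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise DiffError(f"all-zero sample(s): {', '.join(map(str, zero.index))}")
    return counts / libsize * 1e6


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1)."""
    return np.log2(cpm(counts) + 1.0)


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Pipeline normalization: CPM then log2(x+1)."""
    return log_cpm(counts)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DiffError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone, well-behaved)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-feature variances.

    Fits a scaled inverse chi-square prior (d0, s0²) to the observed
    sample variances via the moments of log s² and returns the posterior
    variances (d0·s0² + df·s²)/(d0 + df) together with (d0, s0²).
    d0 = inf (all variances pooled to s0²) when the observed spread of
    log s² is no larger than the sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.median(s2)) if s2.size else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) * (1 - 1.0 / ok.sum())  # slight moment correction
    evar = evar - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
        post = np.full_like(s2, s0_sq)
    return post, d0, s0_sq


def moderated_ttest(log_a: np.ndarray, log_b: np.ndarray) -> pd.DataFrame:
    """Moderated t per feature between two log-expression matrices (A vs B).

    Rows are features, columns samples; log2fc = mean(A) − mean(B).
    The pooled per-feature variance is squeezed toward the EB prior and
    the t statistic referred to df = d0 + (nA + nB − 2).
    """
    a = np.asarray(log_a, dtype=float)
    b = np.asarray(log_b, dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise DiffError("each side needs at least 2 samples")
    df_resid = n_a + n_b - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / df_resid
    s2_post, d0, _ = squeeze_var(s2, df_resid)
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    log2fc = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)))
    df_total = df_resid if not np.isfinite(d0) else df_resid + d0
    p = 2.0 * stats.t.sf(np.abs(t), df_total if np.isfinite(df_total) else 1e6)
    p = np.where(np.isfinite(t), p, 0.0)
    p = np.where((se == 0) & (log2fc == 0), 1.0, p)
    return pd.DataFrame({"log2fc": log2fc, "t": t, "pvalue": p})


def welch_ttest(log_a: np.ndarray, log_b: np.ndarray) -> pd.DataFrame:
    """Plain Welch t per feature, the sensitivity alternative to the EB test."""
    a = np.asarray(log_a, dtype=float)
    b = np.asarray(log_b, dtype=float)
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    p = np.where(np.isnan(res.pvalue), np.where(log2fc == 0, 1.0, 0.0), res.pvalue)
    return pd.DataFrame({"log2fc": log2fc, "t": np.nan_to_num(res.statistic), "pvalue": p})


def de_screen(
    mat_a: pd.DataFrame,
    mat_b: pd.DataFrame,
    fc_hi: float = 1.5,
    fc_lo: float = 0.667,
    fdr_max: float = 0.05,
    category: str = "mRNA",
    comparison: str = "A vs B",
    method: str = "moderated",
    logfc_gate: float | None = None,
) -> pd.DataFrame:
    """Screen differential features between two count matrices (A vs B).

    Returns one record per feature with log2fc, p, BH FDR and direction
    (``up``/``down``/``ns``). A feature is called when FDR < ``fdr_max``
    and its fold change 2**log2fc exceeds ``fc_hi`` or falls below
    ``fc_lo``; passing ``logfc_gate`` replaces the FC gates with
    |log2fc| > gate.
    """
    if list(mat_a.index) != list(mat_b.index):
        if set(mat_a.index) != set(mat_b.index):
            raise DiffError("feature sets differ between the two matrices")
        mat_b = mat_b.loc[mat_a.index]
    joint = pd.concat([mat_a, mat_b], axis=1)
    logged = normalize_counts(joint)
    log_a = logged.iloc[:, : mat_a.shape[1]].to_numpy()
    log_b = logged.iloc[:, mat_a.shape[1]:].to_numpy()
    test = moderated_ttest if method == "moderated" else welch_ttest
    if method not in ("moderated", "welch"):
        raise DiffError(f"unknown test method {method!r}")
    res = test(log_a, log_b)
    res.index = mat_a.index
    res["fdr"] = bh_fdr(res["pvalue"].to_numpy())
    fc = np.power(2.0, res["log2fc"].to_numpy())
    if logfc_gate is not None:
        fc_pass = np.abs(res["log2fc"].to_numpy()) > logfc_gate
    else:
        fc_pass = (fc > fc_hi) | (fc < fc_lo)
    called = fc_pass & (res["fdr"].to_numpy() < fdr_max) & (res["log2fc"].to_numpy() != 0)
    direction = np.where(called, np.where(res["log2fc"] > 0, "up", "down"), "ns")
    out = pd.DataFrame(
        {
            "feature": mat_a.index,
            "category": category,
            "comparison": comparison,
            "log2fc": res["log2fc"].to_numpy(),
            "pvalue": res["pvalue"].to_numpy(),
            "fdr": res["fdr"].to_numpy(),
            "direction": direction,
        }
    ).reset_index(drop=True)
    return out


def screen_all(
    matrices: dict[str, pd.DataFrame],
    design: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`de_screen` for every category × comparison.

    ``matrices`` maps category → counts (features × samples); ``design``
    has columns sample_id, group; ``comparisons`` are (test, reference)
    group pairs. FDR is computed within each category separately.
    """
    frames = []
    for category, counts in matrices.items():
        for test_grp, ref_grp in comparisons:
            ids_a = design.loc[design["group"] == test_grp, "sample_id"]
            ids_b = design.loc[design["group"] == ref_grp, "sample_id"]
            frames.append(
                de_screen(
                    counts[list(ids_a)],
                    counts[list(ids_b)],
                    category=category,
                    comparison=f"{test_grp} vs {ref_grp}",
                    **kwargs,
                )
            )
    return pd.concat(frames, ignore_index=True)


def summarize_deg_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison up/down counts per category plus the row total.

    Mirrors the published differential-RNA bookkeeping: eight cells
    (category × direction) and their sum per comparison.
    """
    cols = []
    for cat in CATEGORIES:
        cols += [f"{cat}_up", f"{cat}_down"]
    comparisons = list(dict.fromkeys(records["comparison"])) if len(records) else []
    rows = []
    for comp in comparisons:
        sub = records[records["comparison"] == comp]
        row = {"comparison": comp}
        for cat in CATEGORIES:
            cat_sub = sub[sub["category"] == cat]
            row[f"{cat}_up"] = int((cat_sub["direction"] == "up").sum())
            row[f"{cat}_down"] = int((cat_sub["direction"] == "down").sum())
        row["total"] = sum(row[c] for c in cols)
        rows.append(row)
    if not rows:
        rows = [{"comparison": "none", **{c: 0 for c in cols}, "total": 0}]
    return pd.DataFrame(rows, columns=["comparison", *cols, "total"])


def deg_table_from_cells(cells: dict[str, tuple]) -> pd.DataFrame:
    """Bookkeeping table from externally supplied per-comparison cells.

    Each value holds the eight category × direction counts (a trailing
    printed total, if present, is ignored); the returned total is always
    recomputed as the sum of the eight cells.
    """
    cols = []
    for cat in CATEGORIES:
        cols += [f"{cat}_up", f"{cat}_down"]
    rows = []
    for comp, values in cells.items():
        eight = list(values[:8])
        if len(eight) != 8:
            raise DiffError(f"comparison {comp!r} needs 8 cells, got {len(values)}")
        row = {"comparison": comp, **dict(zip(cols, (int(v) for v in eight)))}
        row["total"] = int(sum(eight))
        rows.append(row)
    return pd.DataFrame(rows, columns=["comparison", *cols, "total"])
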