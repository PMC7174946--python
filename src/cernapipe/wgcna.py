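"""Weighted coexpression modules and module–treatment association.

An unsigned weighted network a_ij = |cor(x_i, x_j)|^β is built from
log-expression, with β picked as the smallest soft power whose
connectivity distribution satisfies the scale-free fit criterion. The
topological overlap matrix (TOM) combines direct adjacency with shared
neighborhood; modules are average-linkage clusters of 1−TOM under a
static cut, labelled by size with WGCNA-style color names ("grey" =
unassigned). Module eigengenes (first principal component) are
correlated with one-hot treatment indicators for module–trait calls.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

MODULE_COLORS = [
    "turquoise", "blue", "green", "red", "brown", "yellow", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
]

GREY = "grey"


class CoexpressionError(ValueError):
    """Invalid coexpression input."""


def _drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"removed {len(constant)} constant feature(s)", stacklevel=2)
        expr = expr.drop(index=constant)
    return expr


def adjacency(expr: pd.DataFrame, beta: float) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|^β (features × features)."""
    if beta < 1:
        raise CoexpressionError("soft power must be >= 1")
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(expr.to_numpy())
    cor = np.nan_to_num(cor, nan=0.0)
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def scale_free_r2(adj: np.ndarray, n_bins: int = 10) -> float:
    """R² of the log-log connectivity-distribution fit.

    Connectivity k_i = Σ_{j≠i} a_ij is binned; R² is from the linear
    regression of log10 p(k) on log10 mean(k) over occupied bins.
    """
    k = adj.sum(axis=1) - np.diag(adj)
    if np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 3:
        return 0.0
    slope, intercept, r, *_ = stats.linregress(xs, ys)
    return float(r**2)


def pick_soft_power(
    expr: pd.DataFrame,
    powers=range(1, 21),
    r2_target: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest β meeting the scale-free criterion, with the fit table.

    Falls back to the argmax-R² power (with a warning) when no power
    reaches ``r2_target``. Constant features are removed first.
    """
    expr = _drop_constant(expr)
    if expr.shape[0] < 2 or expr.shape[1] < 4:
        raise CoexpressionError("need >= 2 variable features and >= 4 samples")
    rows = []
    chosen = None
    for beta in powers:
        r2 = scale_free_r2(adjacency(expr, beta))
        rows.append({"power": int(beta), "r2": r2})
        if chosen is None and r2 >= r2_target:
            chosen = int(beta)
    table = pd.DataFrame(rows)
    if chosen is None:
        chosen = int(table.loc[table["r2"].idxmax(), "power"])
        warnings.warn(
            f"no power reached scale-free R^2 {r2_target}; using argmax power {chosen}",
            stacklevel=2,
        )
    return chosen, table


def adjacency_tom(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Topological overlap similarity of the soft-threshold network.

    TOM_ij = (Σ_u a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij) with
    unit diagonal, where k is connectivity excluding the diagonal.
    """
    adj = adjacency(expr, beta)
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=expr.index, columns=expr.index)


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = 10,
    cut_height: float = 0.95,
) -> pd.Series:
    """Average-linkage modules of the TOM dissimilarity 1−TOM.

    The dendrogram is cut statically at ``cut_height``; clusters below
    ``min_size`` fall into "grey". Labels are size-ordered color names
    (largest = "turquoise"). Deterministic for a fixed matrix.
    """
    if tom.shape[0] != tom.shape[1]:
        raise CoexpressionError("TOM must be square")
    features = list(tom.index)
    if len(features) < 2:
        return pd.Series([GREY] * len(features), index=features, name="module")
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    order = sorted(
        [c for c in sizes.index if sizes[c] >= min_size],
        key=lambda c: (-sizes[c], c),
    )
    color_of = {c: MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module-{i + 1}"
                for i, c in enumerate(order)}
    labels = [color_of.get(c, GREY) for c in raw]
    return pd.Series(labels, index=features, name="module")


def module_eigengene(expr_members: pd.DataFrame) -> np.ndarray:
    """First principal component of a module's standardized expression.

    Rows are member features, columns samples; the returned per-sample
    vector has unit norm and is sign-oriented so the mean feature
    loading is positive. A single-member module returns that feature's
    standardized profile.
    """
    x = expr_members.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    if z.shape[0] == 1:
        v = z[0]
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    loadings = z @ eig
    if loadings.mean() < 0:
        eig = -eig
    return eig


def module_trait_significance(
    modules: pd.Series,
    expr: pd.DataFrame,
    design: pd.DataFrame,
    include_grey: bool = False,
) -> pd.DataFrame:
    """Module eigengene × treatment-indicator correlations with t-test p.

    One row per (module, group): Pearson r between the eigengene and the
    one-hot group indicator over samples, p from the exact t reference
    with n−2 df, significance at p < 0.05.
    """
    sample_order = [s for s in expr.columns]
    groups = list(dict.fromkeys(design["group"]))
    group_of = dict(zip(design["sample_id"], design["group"]))
    rows = []
    for module in sorted(set(modules)):
        if module == GREY and not include_grey:
            continue
        members = modules[modules == module].index
        eig = module_eigengene(expr.loc[members, sample_order])
        for group in groups:
            indicator = np.array([1.0 if group_of[s] == group else 0.0 for s in sample_order])
            if indicator.std() == 0 or eig.std() == 0:
                r, p = 0.0, 1.0
            else:
                r, p = stats.pearsonr(eig, indicator)
            rows.append(
                {"module": module, "group": group, "size": int(len(members)),
                 "r": float(r), "pvalue": float(p), "significant": bool(p < 0.05)}
            )
    return pd.DataFrame(rows, columns=["module", "group", "size", "r", "pvalue", "significant"])
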