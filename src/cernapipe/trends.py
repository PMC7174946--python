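"""Expression-trend profiling over the (NC, DM, treatment) state sequence.

Every differential RNA is matched against the eight possible monotone
sign patterns of (DM−NC, Treat−DM) by Pearson correlation of its
three-point group-mean profile; an assignment requires r ≥ 0.85. A
drug-efficacy trend is a disease displacement that the treatment
reverses back toward the normal control: sign(DM−NC) = −sign(Treat−DM)
and |Treat−NC| ≤ α·|DM−NC|. In the canonical numbering below the two
restoration profiles are ids 2 and 5.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

#: Sign patterns (s1, s2) of (DM−NC, Treat−DM), excluding the flat (0, 0),
#: in lexicographic order; id 2 = (−1, +1) down-then-restored, id 5 =
#: (+1, −1) up-then-restored.
SIGN_PATTERNS = tuple(p for p in product((-1, 0, 1), repeat=2) if p != (0, 0))

#: Profile ids whose pattern is sign-opposed (the efficacy candidates).
EFFICACY_PROFILE_IDS = tuple(
    i for i, (s1, s2) in enumerate(SIGN_PATTERNS) if s1 == -s2 != 0
)


def profile_templates() -> dict[int, np.ndarray]:
    """Eight 3-point template vectors (0, s1, s1+s2), keyed by profile id."""
    return {
        i: np.array([0.0, s1, s1 + s2]) for i, (s1, s2) in enumerate(SIGN_PATTERNS)
    }


def _pearson3(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return np.nan
    return float(np.dot(xc, yc) / denom)


def assign_trend(profile, min_r: float = 0.85) -> tuple[int | None, float]:
    """Best-matching template for a (NC, DM, Treat) group-mean profile.

    Returns (profile id, r) for the argmax-correlation template when
    r ≥ ``min_r``, else (None, r). Flat profiles are unassignable and
    report r = 0. Ties go to the lowest profile id.
    """
    vec = np.asarray(profile, dtype=float)
    if vec.shape != (3,):
        raise ValueError("profile must contain exactly 3 group means")
    if not np.all(np.isfinite(vec)):
        raise ValueError("profile means must be finite")
    if np.ptp(vec) == 0:
        return None, 0.0
    best_id, best_r = None, -np.inf
    for pid, template in profile_templates().items():
        r = _pearson3(vec, template)
        if np.isnan(r):
            continue
        if r > best_r + 1e-12:
            best_id, best_r = pid, r
    if best_r >= min_r:
        return best_id, best_r
    return None, best_r


def is_efficacy(nc: float, dm: float, treat: float, alpha: float = 0.5) -> bool:
    """Treatment-restoration rule on raw group means.

    True iff the disease shift and treatment shift are sign-opposed and
    the treated mean lies within ``alpha`` of the disease displacement
    from the normal control: |Treat−NC| ≤ α·|DM−NC|.
    """
    s1 = np.sign(dm - nc)
    s2 = np.sign(treat - dm)
    if s1 == 0 or s1 != -s2:
        return False
    return abs(treat - nc) <= alpha * abs(dm - nc)


def trend_table(
    group_means: pd.DataFrame,
    treatment: str,
    min_r: float = 0.85,
    alpha: float = 0.5,
    category: str | None = None,
) -> pd.DataFrame:
    """Per-feature trend assignment and efficacy flag for one treatment.

    ``group_means`` is features × groups and must contain NC, DM and the
    treatment column. Group means (not per-sample profiles) feed the
    correlation, and the efficacy rule is applied on the same means.
    """
    for col in ("NC", "DM", treatment):
        if col not in group_means.columns:
            raise ValueError(f"group means lack column {col!r}")
    rows = []
    for feature, row in group_means.iterrows():
        profile = np.array([row["NC"], row["DM"], row[treatment]], dtype=float)
        pid, r = assign_trend(profile, min_r=min_r)
        eff = pid is not None and is_efficacy(*profile, alpha=alpha)
        rows.append(
            {
                "feature": feature,
                "category": category,
                "treatment": treatment,
                "profile_id": pid,
                "r": r,
                "efficacy": bool(eff),
            }
        )
    return pd.DataFrame(rows)


def efficacy_filter(
    group_means: pd.DataFrame,
    treatment: str,
    min_r: float = 0.85,
    alpha: float = 0.5,
) -> set:
    """Features passing the drug-efficacy trend rule for ``treatment``."""
    table = trend_table(group_means, treatment, min_r=min_r, alpha=alpha)
    return set(table.loc[table["efficacy"], "feature"])


def trend_sign(group_means: pd.DataFrame, treatment: str) -> pd.Series:
    """Sign of the treatment response (Treat−DM) per feature; 0 when flat."""
    return np.sign(group_means[treatment] - group_means["DM"]).astype(int)


def cross_treatment_overlap(efficacy_sets: dict[str, set]) -> pd.DataFrame:
    """Counts for the 7 non-empty regions of the 3-treatment Venn diagram.

    ``efficacy_sets`` maps treatment → feature set; regions are labelled
    by the exact membership combination (e.g. ``SP&FJG``) and their
    counts sum to the size of the union.
    """
    names = list(efficacy_sets)
    if len(names) != 3:
        raise ValueError("overlap is defined for exactly 3 treatment sets")
    sets = [set(efficacy_sets[n]) for n in names]
    rows = []
    for mask in range(1, 8):
        members = [i for i in range(3) if mask >> i & 1]
        inside = set.intersection(*(sets[i] for i in members))
        outside = set.union(set(), *(sets[i] for i in range(3) if i not in members))
        region = inside - outside
        rows.append({"region": "&".join(names[i] for i in members), "count": len(region)})
    return pd.DataFrame(rows)
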