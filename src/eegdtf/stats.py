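"""Two-group statistics with assumption-based test routing, effect sizes,
Benjamini-Hochberg FDR and Pearson correlations.

Routing follows standard clinical-EEG practice: Shapiro-Wilk normality in
both groups plus Levene's homogeneity of variance (centered on the mean, as
in SPSS) route a comparison to the pooled-variance Student t with Cohen's d;
any violation routes to the Mann-Whitney U with Cliff's delta.  The
effect-size sign convention is positive = first group (MCI) larger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "route_test",
    "two_group_test",
    "t_from_summary",
    "cohens_d",
    "cliffs_delta",
    "chi_square_2x2",
    "bh_fdr",
    "pearson_r",
    "compare_groups",
    "correlate_edges_with_score",
]


def route_test(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> str:
    """Choose "student_t" or "mann_whitney" for comparing samples x and y.

    Student t iff Shapiro-Wilk p > alpha in BOTH groups AND Levene p >
    alpha; otherwise (or when a sample is too small/degenerate for
    Shapiro-Wilk) Mann-Whitney.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 3:
        warnings.warn("sample too small for Shapiro-Wilk; routing to Mann-Whitney",
                      stacklevel=2)
        return "mann_whitney"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # constant sample: normality untestable, t undefined
        return "mann_whitney"
    sw_x = sps.shapiro(x).pvalue
    sw_y = sps.shapiro(y).pvalue
    lev = sps.levene(x, y, center="mean").pvalue
    if sw_x > alpha and sw_y > alpha and lev > alpha:
        return "student_t"
    return "mann_whitney"


def t_from_summary(m1: float, s1: float, n1: int,
                   m2: float, s2: float, n2: int) -> float:
    """Pooled-variance two-sample t statistic from group summaries:
    t = (m1 - m2) / (s_p sqrt(1/n1 + 1/n2)),
    s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        if m1 == m2:
            return 0.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    return (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation; positive = x larger."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta in [-1, 1], computed exactly over all pairs:
    (#{x_i > y_j} - #{x_i < y_j}) / (n_x n_y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    gt = (x[:, None] > y[None, :]).sum()
    lt = (x[:, None] < y[None, :]).sum()
    return float((gt - lt) / (x.size * y.size))


def chi_square_2x2(table: Sequence[Sequence[float]]) -> float:
    """Pearson chi-square WITHOUT continuity correction on a 2x2 count table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: expected counts undefined")
    stat, _, _, expected = sps.chi2_contingency(table, correction=False)
    if (expected <= 0).any():
        raise ValueError("all expected counts must be > 0")
    return float(stat)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def two_group_test(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> Dict[str, object]:
    """Route and run one two-group comparison of x (MCI) vs y (NC).

    Returns test name, statistic, p, effect size and its type; degenerate
    all-tied data yield p = 1 and zero effect.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return {"test": "mann_whitney", "statistic": float(x.size * y.size / 2),
                "p": 1.0, "effect": 0.0, "effect_type": "cliffs_delta"}
    route = route_test(x, y, alpha=alpha)
    if route == "student_t":
        res = sps.ttest_ind(x, y, equal_var=True)
        return {"test": "student_t", "statistic": float(res.statistic),
                "p": float(res.pvalue), "effect": cohens_d(x, y),
                "effect_type": "cohens_d"}
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return {"test": "mann_whitney", "statistic": float(res.statistic),
            "p": float(res.pvalue), "effect": cliffs_delta(x, y),
            "effect_type": "cliffs_delta"}


def compare_groups(
    table: pd.DataFrame,
    value_col: str = "power",
    unit_cols: Union[str, Sequence[str]] = "electrode",
    band_col: str = "band",
    group_col: str = "group",
    groups: Tuple[str, str] = ("MCI", "NC"),
    alpha: float = 0.05,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-unit (electrode or directed edge) two-group comparison with
    BH-FDR applied separately within each band.

    ``table`` is long-format with one row per subject x unit x band.
    Returns one row per unit x band with test, statistic, p, q, effect,
    effect_type, direction ("MCI>NC"/"MCI<NC") and significant (q < fdr_alpha).
    """
    if isinstance(unit_cols, str):
        unit_cols = [unit_cols]
    else:
        unit_cols = list(unit_cols)
    g1, g2 = groups
    for g in groups:
        if (table[group_col] == g).sum() == 0:
            raise ValueError(f"insufficient data: no rows for group {g!r}")
    key_cols = unit_cols + [band_col]
    rows: List[dict] = []
    for key, sub in table.groupby(key_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        x = sub.loc[sub[group_col] == g1, value_col].to_numpy(dtype=float)
        y = sub.loc[sub[group_col] == g2, value_col].to_numpy(dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError(f"insufficient data for unit {key}: "
                             f"n={x.size}/{y.size} per group")
        res = two_group_test(x, y, alpha=alpha)
        row = dict(zip(key_cols, key))
        row.update(res)
        row["mean_" + g1] = float(x.mean())
        row["mean_" + g2] = float(y.mean())
        row["direction"] = f"{g1}>{g2}" if x.mean() > y.mean() else f"{g1}<{g2}"
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for band, idx in out.groupby(band_col).groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["q"] < fdr_alpha
    return out


def correlate_edges_with_score(
    conn_table: pd.DataFrame,
    value_col: str = "value",
    score_col: str = "moca",
    edges: Optional[Sequence[Tuple[str, str, str]]] = None,
) -> pd.DataFrame:
    """Pearson correlation between per-subject edge strength and a cognitive
    score, pooled across all subjects.

    ``edges`` optionally restricts to (band, source, target) triples
    (typically the group-significant edges); default is every edge present.
    Returns rows (band, source, target, r, p, n).
    """
    rows: List[dict] = []
    grouped = conn_table.groupby(["band", "source", "target"], sort=True)
    wanted = set(edges) if edges is not None else None
    for (band, src, tgt), sub in grouped:
        if wanted is not None and (band, src, tgt) not in wanted:
            continue
        sub = sub.dropna(subset=[value_col, score_col])
        n = len(sub)
        if n < 3:
            continue
        vals = sub[value_col].to_numpy(dtype=float)
        score = sub[score_col].to_numpy(dtype=float)
        if np.ptp(vals) == 0 or np.ptp(score) == 0:
            continue
        r, p = pearson_r(vals, score)
        rows.append({"band": band, "source": src, "target": tgt,
                     "r": r, "p": p, "n": n})
    return pd.DataFrame(rows, columns=["band", "source", "target", "r", "p", "n"])
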