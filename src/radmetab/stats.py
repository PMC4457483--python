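"""Per-metabolite univariate statistics: Welch, Wilcoxon, ANOVA, BH-FDR, fold changes.

Tests run on log-scale abundances (variance roughly stabilized); fold changes
are ratios of arithmetic group means on the sham-normalized natural scale,
recovered from the log table by exponentiation.  The significance gate is the
joint rule p < 0.05 AND q < 0.10, with the Welch p as the primary p-value for
two-group comparisons and Benjamini-Hochberg q-values computed within one
family per tissue x comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import SCALE_LOG, AbundanceTable, validate_metadata

logger = logging.getLogger(__name__)

#: The four dose contrasts the validation cascade consumes, in cascade order.
CASCADE_COMPARISONS = (
    ("50Gy_vs_0Gy", "50Gy", "0Gy"),
    ("50Gy_vs_untreated", "50Gy", "untreated"),
    ("10Gy_vs_0Gy", "10Gy", "0Gy"),
    ("10Gy_vs_untreated", "10Gy", "untreated"),
)

P_THRESHOLD = 0.05
Q_THRESHOLD = 0.10

#: Largest combined sample size at which the exact rank-sum null is enumerated.
EXACT_RANKSUM_MAX_N = 12


@dataclass
class StatResult:
    """Univariate result for one metabolite in one two-group comparison."""

    metabolite: str
    comparison: str
    p_welch: float
    p_wilcoxon: float
    p_anova: float
    q: float
    ratio: float
    direction: str
    significant: bool
    n_a: int
    n_b: int
    testable: bool = True


def _direction(ratio: np.ndarray) -> np.ndarray:
    out = np.where(ratio > 1, "up", np.where(ratio < 1, "down", "flat"))
    return np.where(np.isnan(ratio), "flat", out)


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch p over columns with the zero-variance degenerate rule.

    If both groups are constant the t statistic is undefined; equal means are
    then indistinguishable (p = 1) and unequal means are perfectly separated
    (p = 0).
    """
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant columns
        p = sps.ttest_ind(a, b, axis=0, equal_var=False, nan_policy="omit").pvalue
    p = np.asarray(p, dtype=float)
    var_a = np.nanvar(a, axis=0)
    var_b = np.nanvar(b, axis=0)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        equal = np.isclose(np.nanmean(a, axis=0), np.nanmean(b, axis=0))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
        logger.info("zero-variance Welch rule applied to %d metabolite(s)", degenerate.sum())
    return p


def _ranksum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p: exact for small tie-free samples, else normal
    approximation with tie correction."""
    n_a, n_b = a.shape[0], b.shape[0]
    m = a.shape[1]
    p = np.empty(m)
    small = n_a + n_b <= EXACT_RANKSUM_MAX_N
    for j in range(m):
        x = a[:, j]
        y = b[:, j]
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        combined = np.concatenate([x, y])
        if np.unique(combined).size == 1:
            p[j] = 1.0  # all observations tied: no evidence either way
            continue
        has_ties = np.unique(combined).size < combined.size
        method = "exact" if small and not has_ties else "asymptotic"
        p[j] = sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    return np.minimum(p, 1.0)


def compare_groups(
    log_table: AbundanceTable,
    meta: pd.DataFrame,
    group_a: str,
    group_b: str,
    comparison: str | None = None,
) -> pd.DataFrame:
    """All-metabolite two-group comparison (group_a over group_b).

    Returns a DataFrame indexed by metabolite with p_welch, p_wilcoxon, ratio,
    direction, group sizes and a testable flag (>= 2 non-missing observations
    per group).  q-values are attached later by :func:`run_comparisons` so the
    FDR family is explicit.
    """
    if log_table.scale != SCALE_LOG:
        raise ValueError("compare_groups expects a log-scale table")
    m = validate_metadata(log_table, meta)
    idx_a = m.index[m["group"] == group_a]
    idx_b = m.index[m["group"] == group_b]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"empty group in comparison {group_a} vs {group_b}")
    a = log_table.data.loc[idx_a].to_numpy()
    b = log_table.data.loc[idx_b].to_numpy()
    n_a = (~np.isnan(a)).sum(axis=0)
    n_b = (~np.isnan(b)).sum(axis=0)
    testable = (n_a >= 2) & (n_b >= 2)

    p_welch = np.full(a.shape[1], np.nan)
    p_wilcoxon = np.full(a.shape[1], np.nan)
    if testable.any():
        p_welch[testable] = _welch(a[:, testable], b[:, testable])
        p_wilcoxon[testable] = _ranksum(a[:, testable], b[:, testable])
    with np.errstate(invalid="ignore"):
        ratio = np.nanmean(np.exp(a), axis=0) / np.nanmean(np.exp(b), axis=0)
    out = pd.DataFrame(
        {
            "comparison": comparison or f"{group_a}_vs_{group_b}",
            "p_welch": p_welch,
            "p_wilcoxon": p_wilcoxon,
            "ratio": ratio,
            "direction": _direction(ratio),
            "n_a": n_a,
            "n_b": n_b,
            "testable": testable,
        },
        index=pd.Index(log_table.metabolite_ids, name="metabolite"),
    )
    return out


def test_two_groups(
    log_table: AbundanceTable,
    meta: pd.DataFrame,
    group_a: str,
    group_b: str,
    metabolite: str,
) -> StatResult:
    """Single-metabolite convenience wrapper around :func:`compare_groups`."""
    df = compare_groups(log_table, meta, group_a, group_b)
    row = df.loc[metabolite]
    return StatResult(
        metabolite=metabolite,
        comparison=row["comparison"],
        p_welch=row["p_welch"],
        p_wilcoxon=row["p_wilcoxon"],
        p_anova=np.nan,
        q=np.nan,
        ratio=row["ratio"],
        direction=row["direction"],
        significant=False,
        n_a=int(row["n_a"]),
        n_b=int(row["n_b"]),
        testable=bool(row["testable"]),
    )


def anova_dose(log_table: AbundanceTable, meta: pd.DataFrame) -> pd.Series:
    """One-way fixed-effects ANOVA across all dose groups of the table.

    Groups with fewer than two observations are left out of the F test.
    Returns the per-metabolite p-value; NaN where fewer than two usable
    groups remain or the within-group variance is zero everywhere.
    """
    m = validate_metadata(log_table, meta)
    arrays = []
    for g, idx in m.groupby("group", sort=False).groups.items():
        block = log_table.data.loc[idx].to_numpy()
        if block.shape[0] >= 2:
            arrays.append(block)
    if len(arrays) < 2:
        return pd.Series(np.nan, index=log_table.metabolite_ids, name="p_anova")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = sps.f_oneway(*arrays, axis=0).pvalue
    return pd.Series(np.asarray(p, dtype=float), index=log_table.metabolite_ids, name="p_anova")


def adjust_fdr(pvalues: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one comparison family.

    NaN entries (untestable metabolites) are excluded from the family and
    returned as NaN; q is monotone in p and q_i >= p_i.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return q
    q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def run_comparisons(
    log_table: AbundanceTable,
    meta: pd.DataFrame,
    comparisons: list[tuple[str, str, str]] | None = None,
    p_threshold: float = P_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Full univariate screen for one tissue x modality table.

    ``comparisons`` is a list of (label, numerator group, denominator group);
    it defaults to the cascade contrasts restricted to the groups actually
    present.  Output is long format, one row per metabolite x comparison,
    with BH q-values per comparison family and the joint significance gate
    (primary p = Welch) applied.
    """
    m = validate_metadata(log_table, meta)
    present = set(m["group"])
    if comparisons is None:
        comparisons = [c for c in CASCADE_COMPARISONS if {c[1], c[2]} <= present]
        if not comparisons:
            raise ValueError(f"no standard comparisons possible among groups {sorted(present)}")
    p_anova = anova_dose(log_table, meta)
    frames = []
    for label, ga, gb in comparisons:
        df = compare_groups(log_table, meta, ga, gb, comparison=label)
        df["p_anova"] = p_anova
        family_p = df["p_welch"].where(df["testable"])
        df["q"] = adjust_fdr(family_p)
        df["significant"] = (df["p_welch"] < p_threshold) & (df["q"] < q_threshold)
        df["significant"] = df["significant"].fillna(False).astype(bool)
        frames.append(df)
    out = pd.concat(frames).reset_index()
    out.insert(1, "tissue", log_table.tissue)
    out.insert(2, "modality", log_table.modality)
    n_sig = int(out["significant"].sum())
    logger.info(
        "univariate screen %s/%s: %d metabolites, %d comparisons, %d significant calls",
        log_table.tissue,
        log_table.modality,
        log_table.shape[1],
        len(comparisons),
        n_sig,
    )
    cols = [
        "metabolite",
        "tissue",
        "modality",
        "comparison",
        "p_welch",
        "p_wilcoxon",
        "p_anova",
        "q",
        "ratio",
        "direction",
        "significant",
        "n_a",
        "n_b",
        "testable",
    ]
    return out[cols]
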