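"""Spearman correlation, liver-plasma concordance, clustering and ontology maps.

Correlations are computed over all dose groups pooled, so a metabolite pair
that both track dose shows a high rho even if they are independent within a
group — that pooled association is exactly what makes a plasma metabolite a
usable surrogate for a liver one.  Pathway-level ("CoolMap"-style) matrices
collapse the metabolite-level matrix with an aggregator (mean, median, min,
max) over all leaf pairs spanning two pathways.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import AbundanceTable, validate_metadata

logger = logging.getLogger(__name__)

MIN_PAIRS = 3

AGGREGATORS = {
    "mean": np.mean,
    "average": np.mean,  # alias kept for the original tool's naming
    "median": np.median,
    "min": np.min,
    "max": np.max,
}


@dataclass
class CorrelationResult:
    a: str
    b: str
    rho: float
    n_pairs: int
    testable: bool = True


def spearman(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> CorrelationResult:
    """Spearman rho between two sample-aligned vectors.

    Missing entries are removed pairwise; ties get average ranks.  Fewer than
    three complete pairs, or a constant vector, gives an untestable result
    (rho = NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be sample-aligned (equal length)")
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < MIN_PAIRS:
        return CorrelationResult("x", "y", np.nan, n, testable=False)
    xv, yv = x[mask], y[mask]
    if np.unique(xv).size == 1 or np.unique(yv).size == 1:
        return CorrelationResult("x", "y", np.nan, n, testable=False)
    rho = sps.spearmanr(xv, yv).statistic
    return CorrelationResult("x", "y", float(rho), n)


def _pair_tables_by_animal(
    liver: AbundanceTable, plasma: AbundanceTable, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reindex both tables to animal ids, keeping animals present in both."""
    ml = validate_metadata(liver, meta)
    mp = validate_metadata(plasma, meta)
    lv = liver.data.set_axis(ml["animal_id"].to_numpy(), axis=0)
    pl = plasma.data.set_axis(mp["animal_id"].to_numpy(), axis=0)
    animals = lv.index.intersection(pl.index)
    if len(animals) == 0:
        raise ValueError("no animals shared between liver and plasma tables")
    return lv.loc[animals], pl.loc[animals]


def liver_plasma_concordance(
    liver: AbundanceTable, plasma: AbundanceTable, meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-metabolite Spearman rho between its liver and plasma profiles.

    Samples are aligned by animal id; groups are pooled.  Only metabolites
    measured in both tissues appear; output is sorted by rho, descending
    (the ranked-concordance table layout).
    """
    lv, pl = _pair_tables_by_animal(liver, plasma, meta)
    shared = lv.columns.intersection(pl.columns)
    if len(shared) == 0:
        warnings.warn("no shared metabolite ids between liver and plasma", stacklevel=2)
        return pd.DataFrame(columns=["metabolite", "rho", "n_pairs"])
    rows = []
    for met in shared:
        res = spearman(lv[met].to_numpy(), pl[met].to_numpy())
        if res.testable:
            rows.append((met, res.rho, res.n_pairs))
    out = pd.DataFrame(rows, columns=["metabolite", "rho", "n_pairs"])
    return out.sort_values("rho", ascending=False, kind="stable").reset_index(drop=True)


def correlation_matrix(
    table: AbundanceTable,
    second: AbundanceTable | None = None,
    meta: pd.DataFrame | None = None,
    linkage_method: str = "average",
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """All-pairs Spearman matrix with an average-linkage leaf ordering.

    With ``second`` given, the two tables are aligned by animal id and
    concatenated column-wise with ``@tissue`` suffixes, producing the
    cross-tissue matrix.  Constant metabolites (zero rank variance) are
    excluded with a warning.  Returns (matrix, leaf order, linkage matrix);
    clustering distance is 1 - rho.
    """
    if second is not None:
        if meta is None:
            raise ValueError("meta is required to pair two tables by animal id")
        lv, pl = _pair_tables_by_animal(table, second, meta)
        data = pd.concat(
            [lv.add_suffix(f"@{table.tissue}"), pl.add_suffix(f"@{second.tissue}")], axis=1
        )
    else:
        data = table.data
    if data.shape[1] < 2:
        raise ValueError("need at least 2 metabolites for a correlation matrix")
    constant = data.columns[data.nunique(dropna=True) <= 1]
    if len(constant):
        warnings.warn(
            f"excluding {len(constant)} constant metabolite(s): {list(constant[:5])}",
            stacklevel=2,
        )
        data = data.drop(columns=constant)
    corr = data.corr(method="spearman", min_periods=MIN_PAIRS)
    np.fill_diagonal(corr.values, 1.0)
    dist = 1.0 - corr.to_numpy()
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    order = [corr.columns[i] for i in hierarchy.leaves_list(link)]
    return corr, order, link


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(link)

    def build(node, parent_height: float) -> str:
        length = max(parent_height - (0.0 if node.is_leaf() else node.dist), 0.0)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist).rsplit(":", 1)[0] + ";"


def aggregate_ontology(
    corr: pd.DataFrame,
    ontology: dict[str, str],
    aggregator: str = "mean",
) -> tuple[pd.DataFrame, dict[tuple[str, str], list[tuple[str, str]]]]:
    """Collapse a metabolite correlation matrix to pathway level.

    Entry (A, B) aggregates every leaf correlation rho(a, b) with a in A and
    b in B.  On the diagonal (A = B) self-pairs are excluded so the entry
    reflects within-pathway coherence rather than the trivial rho(a, a) = 1;
    a singleton pathway's diagonal entry falls back to the leaf value 1.
    Unmapped metabolites (the "known unknowns") are ignored here — see
    :func:`correlate_unknowns`.  Returns the pathway matrix and a provenance
    map (pathway pair) -> contributing leaf pairs.
    """
    if aggregator not in AGGREGATORS:
        raise ValueError(
            f"unknown aggregator {aggregator!r}; valid: {sorted(set(AGGREGATORS))}"
        )
    agg = AGGREGATORS[aggregator]
    members: dict[str, list[str]] = {}
    for met in corr.columns:
        pw = ontology.get(met)
        if pw is not None:
            members.setdefault(pw, []).append(met)
    if not members:
        raise ValueError("no metabolite in the matrix is mapped by the ontology")
    pathways = sorted(members)
    out = pd.DataFrame(np.nan, index=pathways, columns=pathways)
    provenance: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for i, pa in enumerate(pathways):
        for pb in pathways[i:]:
            if pa == pb:
                ms = members[pa]
                pairs = [(a, b) for k, a in enumerate(ms) for b in ms[k + 1 :]]
                if not pairs:  # singleton pathway: only the self leaf exists
                    pairs = [(ms[0], ms[0])]
            else:
                pairs = [(a, b) for a in members[pa] for b in members[pb]]
            values = np.array([corr.at[a, b] for a, b in pairs], dtype=float)
            values = values[~np.isnan(values)]
            val = float(agg(values)) if values.size else np.nan
            out.at[pa, pb] = out.at[pb, pa] = val
            provenance[(pa, pb)] = pairs
    return out, provenance


def correlate_unknowns(
    corr: pd.DataFrame,
    ontology: dict[str, str],
    unknowns: list[str] | None = None,
    aggregator: str = "mean",
) -> pd.DataFrame:
    """Pathway-association profile for each unmapped ("known unknown") feature.

    Each unknown's correlations with the mapped members of a pathway are
    summarized by ``aggregator``; the pathway with the largest |association|
    is reported as ``top_pathway``.  Profiles are bounded in [-1, 1].
    """
    if aggregator not in AGGREGATORS:
        raise ValueError(
            f"unknown aggregator {aggregator!r}; valid: {sorted(set(AGGREGATORS))}"
        )
    agg = AGGREGATORS[aggregator]
    mapped = [m for m in corr.columns if m in ontology]
    if not mapped:
        raise ValueError("no mapped metabolites in the matrix")
    if unknowns is None:
        unknowns = [m for m in corr.columns if m not in ontology]
    if not unknowns:
        raise ValueError("no unknown metabolites to profile")
    pathways = sorted({ontology[m] for m in mapped})
    profile = pd.DataFrame(np.nan, index=pd.Index(unknowns, name="unknown"), columns=pathways)
    for u in unknowns:
        for pw in pathways:
            vals = np.array(
                [corr.at[u, m] for m in mapped if ontology[m] == pw and m != u], dtype=float
            )
            vals = vals[~np.isnan(vals)]
            if vals.size:
                profile.at[u, pw] = float(agg(vals))
    top = profile.abs().idxmax(axis=1)
    out = profile.copy()
    out["top_pathway"] = top
    out["top_association"] = [
        profile.at[u, top[u]] if isinstance(top[u], str) else np.nan for u in unknowns
    ]
    return out
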