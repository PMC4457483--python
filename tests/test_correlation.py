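import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from radmetab.correlation import (
    aggregate_ontology,
    correlate_unknowns,
    correlation_matrix,
    linkage_to_newick,
    liver_plasma_concordance,
    spearman,
)
from radmetab.io import SCALE_LOG, preprocess
from radmetab.simulate import PlantedEffect, SyntheticConfig, generate_cohort

from conftest import make_table


def brute_force_spearman(x, y):
    """Independent oracle: average ranks by sorting, then textbook Pearson."""

    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(np.asarray(x, float)), avg_ranks(np.asarray(y, float))
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def test_spearman_matches_brute_force_oracle_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(300):
        n = rng.integers(4, 15)
        x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        y = rng.integers(0, 6, size=n).astype(float)
        if np.unique(x).size == 1 or np.unique(y).size == 1:
            continue
        assert spearman(x, y).rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)


def test_spearman_hand_example_with_ties():
    x, y = np.array([1.0, 2.0, 2.0, 4.0]), np.array([1.0, 3.0, 2.0, 4.0])
    assert spearman(x, y).rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)


def test_spearman_rank_invariance_and_reversal():
    x = np.array([0.3, 1.2, 2.0, 3.3, 4.8])
    assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
    assert spearman(np.arange(5.0), np.arange(5.0)[::-1]).rho == pytest.approx(-1.0)


def test_spearman_pairwise_deletion_and_min_pairs():
    x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
    y = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
    res = spearman(x, y)
    assert res.n_pairs == 3 and res.testable
    res = spearman(np.array([1.0, np.nan, 3.0]), np.array([1.0, 2.0, np.nan]))
    assert not res.testable and np.isnan(res.rho)


@pytest.fixture(scope="module")
def concordant_cohort():
    planted = [
        PlantedEffect(f"S{i + 1:03d}", "both", lfc_10=np.log(3.0), lfc_50=np.log(10.0))
        for i in range(3)
    ]
    cfg = SyntheticConfig(
        n_features_liver=40,
        n_features_plasma=35,
        n_shared=20,
        n_pathways=4,
        planted_biomarkers=planted,
        log_noise_sd=0.1,
        animal_effect_sd=0.2,
        dropout_rate=0.0,
        seed=77,
    )
    liver, plasma, meta, truth = generate_cohort(cfg)
    sub = meta[meta.modality == "WLI"]
    _, log_l = preprocess(liver, sub[sub.tissue == "liver"])
    _, log_p = preprocess(plasma, sub[sub.tissue == "plasma"])
    return log_l, log_p, sub, truth


def test_concordance_recovers_planted_cross_tissue_biomarkers(concordant_cohort):
    log_l, log_p, meta, truth = concordant_cohort
    ranked = liver_plasma_concordance(log_l, log_p, meta)
    top = ranked.set_index("metabolite")
    for met in truth.planted_ids():
        assert top.loc[met, "rho"] > 0.9
    # sorted descending
    assert (ranked.rho.diff().dropna() <= 1e-12).all()
    # liver-only metabolites are absent
    assert not any(m.startswith("L") for m in ranked.metabolite)


def test_shuffled_pairing_destroys_concordance(concordant_cohort):
    log_l, log_p, meta, truth = concordant_cohort
    rng = np.random.default_rng(5)
    planted = truth.planted_ids()
    baseline = liver_plasma_concordance(log_l, log_p, meta)
    base_mean = baseline.set_index("metabolite").loc[planted, "rho"].mean()
    shuffled_means = []
    for _ in range(30):
        perm_meta = meta.copy()
        is_plasma = perm_meta.tissue == "plasma"
        perm_meta.loc[is_plasma, "animal_id"] = rng.permutation(
            perm_meta.loc[is_plasma, "animal_id"].to_numpy()
        )
        ranked = liver_plasma_concordance(log_l, log_p, perm_meta)
        shuffled_means.append(ranked.set_index("metabolite").loc[planted, "rho"].mean())
    assert base_mean > 0.9
    assert abs(np.mean(shuffled_means)) < 0.3


def test_correlation_matrix_symmetry_unit_diagonal_and_duplicates():
    rng = np.random.default_rng(8)
    base = rng.normal(size=20)
    data = np.column_stack([base, base.copy(), rng.normal(size=20), rng.normal(size=20)])
    table = make_table(data, scale=SCALE_LOG, metabolites=["a", "a2", "b", "c"])
    corr, order, link = correlation_matrix(table)
    np.testing.assert_array_equal(np.diag(corr.to_numpy()), 1.0)
    pd.testing.assert_frame_equal(corr, corr.T)
    assert link[0, 2] == pytest.approx(0.0)  # identical metabolites merge first at height 0
    merged = {int(link[0, 0]), int(link[0, 1])}
    assert merged == {0, 1}


def test_constant_metabolite_excluded():
    data = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0)[::-1]])
    table = make_table(data, scale=SCALE_LOG, metabolites=["const", "x", "y"])
    with pytest.warns(UserWarning, match="constant"):
        corr, _, _ = correlation_matrix(table)
    assert "const" not in corr.columns


def test_block_structure_recovers_pathway_partition():
    cfg = SyntheticConfig(
        n_features_liver=60,
        n_features_plasma=30,
        n_shared=20,
        frac_known=1.0,
        n_pathways=4,
        pathway_block_rho=0.8,
        dropout_rate=0.0,
        seed=13,
    )
    liver, _, meta, truth = generate_cohort(cfg)
    sub = meta[(meta.tissue == "liver") & (meta.modality == "WLI")]
    _, log = preprocess(liver, sub)
    corr, _, link = correlation_matrix(log)
    labels = hierarchy.fcluster(link, t=4, criterion="maxclust")
    true_labels = truth.features.loc[corr.columns, "pathway"].to_numpy()
    assert adjusted_rand_score(true_labels, labels) >= 0.9


def test_newick_export_contains_all_leaves():
    rng = np.random.default_rng(2)
    table = make_table(rng.normal(size=(12, 5)), scale=SCALE_LOG,
                       metabolites=list("abcde"))
    _, _, link = correlation_matrix(table)
    nwk = linkage_to_newick(link, list("abcde"))
    assert nwk.endswith(";")
    for leaf in "abcde":
        assert leaf in nwk


def brute_force_aggregate(corr, ontology, agg=np.mean):
    """Direct enumeration oracle over all leaf pairs."""
    pathways = sorted(set(ontology.values()))
    out = pd.DataFrame(np.nan, index=pathways, columns=pathways)
    for pa in pathways:
        for pb in pathways:
            pairs = [
                corr.at[a, b]
                for a in corr.columns
                if ontology.get(a) == pa
                for b in corr.columns
                if ontology.get(b) == pb and (pa != pb or a != b)
            ]
            if not pairs:  # singleton diagonal
                (a,) = [m for m in corr.columns if ontology.get(m) == pa]
                pairs = [corr.at[a, a]]
            out.at[pa, pb] = agg(pairs)
    return out


def random_corr(rng, mets):
    raw = rng.normal(size=(25, len(mets)))
    return pd.DataFrame(np.corrcoef(raw, rowvar=False), index=mets, columns=mets)


def test_aggregate_singleton_pathways_identity():
    rng = np.random.default_rng(3)
    mets = ["a", "b", "c"]
    corr = random_corr(rng, mets)
    ontology = {m: f"pw_{m}" for m in mets}
    for agg in ("mean", "median", "min", "max"):
        out, _ = aggregate_ontology(corr, ontology, agg)
        renamed = out.rename(index=lambda p: p[3:], columns=lambda p: p[3:])
        pd.testing.assert_frame_equal(
            renamed.loc[mets, mets], corr, check_exact=False, atol=1e-12
        )


def test_aggregate_mean_hand_example():
    corr = pd.DataFrame(
        [[1.0, 0.5, 0.2], [0.5, 1.0, 0.6], [0.2, 0.6, 1.0]],
        index=["a1", "a2", "b1"],
        columns=["a1", "a2", "b1"],
    )
    out, prov = aggregate_ontology(corr, {"a1": "A", "a2": "A", "b1": "B"}, "mean")
    assert out.at["A", "B"] == pytest.approx((0.2 + 0.6) / 2)
    assert out.at["A", "A"] == pytest.approx(0.5)  # self-pairs excluded
    assert set(prov[("A", "B")]) == {("a1", "b1"), ("a2", "b1")}


def test_aggregate_matches_enumeration_oracle_random():
    rng = np.random.default_rng(17)
    for _ in range(10):
        n = int(rng.integers(4, 15))
        mets = [f"m{i}" for i in range(n)]
        corr = random_corr(rng, mets)
        n_pw = int(rng.integers(1, 6))
        ontology = {m: f"pw{rng.integers(0, n_pw)}" for m in mets}
        out, _ = aggregate_ontology(corr, ontology, "mean")
        expected = brute_force_aggregate(corr, ontology)
        pd.testing.assert_frame_equal(out, expected, atol=1e-12)


def test_aggregate_bounded_by_leaf_extremes():
    rng = np.random.default_rng(23)
    mets = [f"m{i}" for i in range(8)]
    corr = random_corr(rng, mets)
    ontology = {m: f"pw{i % 3}" for i, m in enumerate(mets)}
    mn, _ = aggregate_ontology(corr, ontology, "min")
    mx, _ = aggregate_ontology(corr, ontology, "max")
    for agg in ("mean", "median"):
        out, _ = aggregate_ontology(corr, ontology, agg)
        assert ((out >= mn - 1e-12) & (out <= mx + 1e-12)).all().all()


def test_unknown_aggregator_lists_valid_names():
    corr = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
    with pytest.raises(ValueError, match="mean"):
        aggregate_ontology(corr, {"a": "A"}, "geometric")


def test_correlate_unknowns_recovers_coupled_pathway():
    rng = np.random.default_rng(9)
    factor_a = rng.normal(size=30)
    factor_b = rng.normal(size=30)
    data = np.column_stack(
        [
            factor_a + rng.normal(0, 0.3, 30),
            factor_a + rng.normal(0, 0.3, 30),
            factor_b + rng.normal(0, 0.3, 30),
            factor_b + rng.normal(0, 0.3, 30),
            factor_b + rng.normal(0, 0.4, 30),  # coupled unknown
            rng.normal(size=30),  # independent unknown
        ]
    )
    mets = ["a1", "a2", "b1", "b2", "X-1", "X-2"]
    table = make_table(data, scale=SCALE_LOG, metabolites=mets)
    corr, _, _ = correlation_matrix(table)
    profile = correlate_unknowns(corr, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    assert profile.at["X-1", "top_pathway"] == "B"
    assert profile[["A", "B"]].abs().le(1.0).all().all()
    assert abs(profile.at["X-2", "top_association"]) < 0.5
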