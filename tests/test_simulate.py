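from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from radmetab.io import write_abundance
from radmetab.simulate import (
    ConfigError,
    PlantedEffect,
    SyntheticConfig,
    default_panel_config,
    generate_cohort,
    generate_wbi_companion,
    ontology_map,
)


def test_cohort_shapes_and_groups(small_cohort, small_config):
    liver, plasma, meta, truth = small_cohort
    assert liver.shape == (30, small_config.n_features_liver)
    assert plasma.shape == (30, small_config.n_features_plasma)
    wli = meta[meta.modality == "WLI"]
    assert wli.groupby("group").animal_id.nunique().to_dict() == {
        "untreated": 6, "0Gy": 8, "10Gy": 8, "50Gy": 8,
    }


def test_pairing_animal_ids_match_across_tissues(small_cohort):
    liver, plasma, meta, _ = small_cohort
    m = meta.set_index("sample_id")
    liver_animals = set(m.loc[liver.sample_ids, "animal_id"])
    plasma_animals = set(m.loc[plasma.sample_ids, "animal_id"])
    assert liver_animals == plasma_animals


def test_determinism_byte_identical(tmp_path, small_config):
    out = []
    for run in range(2):
        liver, _, _, _ = generate_cohort(replace(small_config))
        path = tmp_path / f"run{run}.csv"
        write_abundance(liver, path)
        out.append(path.read_bytes())
    assert out[0] == out[1]


def test_different_seeds_differ(small_config):
    liver1, _, _, _ = generate_cohort(small_config)
    liver2, _, _, _ = generate_cohort(replace(small_config, seed=small_config.seed + 1))
    assert not liver1.data.equals(liver2.data)


def test_abundances_positive_without_dropout(small_config):
    cfg = replace(small_config, dropout_rate=0.0)
    liver, plasma, _, _ = generate_cohort(cfg)
    assert (liver.data.to_numpy() > 0).all()
    assert (plasma.data.to_numpy() > 0).all()


def test_mnar_dropout_monotone_in_abundance():
    cfg = SyntheticConfig(
        n_features_liver=500,
        n_features_plasma=10,
        n_shared=10,
        n_pathways=3,
        dropout_rate=0.2,
        dropout_mnar_strength=2.0,
        seed=5,
    )
    with_na, _, _, _ = generate_cohort(cfg)
    reference, _, _, _ = generate_cohort(replace(cfg, dropout_rate=0.0))
    true_log = np.log(reference.data.to_numpy()).ravel()
    missing = with_na.data.isna().to_numpy().ravel()
    deciles = pd.qcut(true_log, 10, labels=False)
    rates = pd.Series(missing).groupby(deciles).mean()
    assert rates.iloc[0] > rates.iloc[-1] + 0.1
    assert sps.spearmanr(rates.index, rates.values).statistic < -0.9


def test_null_welch_p_uniform():
    cfg = SyntheticConfig(
        n_features_liver=600,
        n_features_plasma=10,
        n_shared=10,
        n_pathways=1,
        pathway_block_rho=0.0,
        animal_effect_sd=0.0,
        dropout_rate=0.0,
        group_sizes={"0Gy": 8, "50Gy": 8},
        seed=9,
    )
    liver, _, meta, _ = generate_cohort(cfg)
    sub = meta[(meta.tissue == "liver") & (meta.modality == "WLI")]
    m = sub.set_index("sample_id").loc[liver.sample_ids]
    log = np.log(liver.data.to_numpy())
    a = log[(m.group == "50Gy").to_numpy()]
    b = log[(m.group == "0Gy").to_numpy()]
    p = sps.ttest_ind(a, b, axis=0, equal_var=False).pvalue
    frac = (p < 0.05).mean()
    assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / len(p))


def direct_fold_oracle(n_seeds=2000, fold=4.0, sd=0.1, n=8, rng=None):
    """Independent direct simulation of the log-normal two-group model."""
    rng = rng or np.random.default_rng(123)
    treated = np.exp(np.log(fold) + rng.normal(0, sd, size=(n_seeds, n)))
    control = np.exp(rng.normal(0, sd, size=(n_seeds, n)))
    return treated.mean(axis=1) / control.mean(axis=1)


def test_planted_fold_recovered_within_oracle_band():
    """Group-mean ratio of a planted 4-fold effect lands in the band the
    direct log-normal oracle predicts ([3.4, 4.7] central 95%)."""
    oracle = direct_fold_oracle()
    lo, hi = np.quantile(oracle, [0.025, 0.975])
    assert lo > 3.4 - 0.15 and hi < 4.7 + 0.15  # the stated band, oracle-checked
    base = SyntheticConfig(
        n_features_liver=5,
        n_features_plasma=5,
        n_shared=5,
        frac_known=1.0,
        n_pathways=1,
        pathway_block_rho=0.0,
        animal_effect_sd=0.0,
        dropout_rate=0.0,
        log_noise_sd=0.1,
        group_sizes={"0Gy": 8, "50Gy": 8},
        planted_biomarkers=[PlantedEffect("S001", "both", lfc_10=0.0, lfc_50=np.log(4.0))],
    )
    inside = 0
    n_seeds = 60
    for seed in range(n_seeds):
        liver, _, meta, _ = generate_cohort(replace(base, seed=seed))
        m = meta.set_index("sample_id").loc[liver.sample_ids]
        vals = liver.data["S001"]
        ratio = vals[(m.group == "50Gy").to_numpy()].mean() / vals[(m.group == "0Gy").to_numpy()].mean()
        inside += 3.4 <= ratio <= 4.7
    assert inside / n_seeds >= 0.90  # 95% band, Monte-Carlo slack at n=60


def test_wbi_companion_sizes_and_flip(small_cohort, small_config):
    _, _, _, truth = small_cohort
    wbi_liver, wbi_plasma, wbi_meta = generate_wbi_companion(small_config, truth)
    assert wbi_liver.shape[0] == 24 and wbi_plasma.shape[0] == 24
    m = wbi_meta.set_index("sample_id").loc[wbi_plasma.sample_ids]
    vals = wbi_plasma.data["S001"]  # planted up 2-fold at 10 Gy WLI, flipped for WBI
    ratio = vals[(m.group == "10Gy").to_numpy()].mean() / vals[(m.group == "0Gy").to_numpy()].mean()
    assert ratio < 1.0


def test_empty_flip_set_preserves_signs(small_config):
    cfg = replace(small_config, wbi_flip_set=[], dropout_rate=0.0, seed=404)
    liver, _, meta, truth = generate_cohort(cfg)
    wbi_liver, _, wbi_meta = generate_wbi_companion(cfg, truth)
    mw = wbi_meta.set_index("sample_id").loc[wbi_liver.sample_ids]
    for met in truth.planted_ids():
        lfc = truth.features.at[met, "lfc_10_liver"]
        if lfc == 0 or not truth.features.at[met, "in_liver"]:
            continue
        vals = wbi_liver.data[met]
        ratio = vals[(mw.group == "10Gy").to_numpy()].mean() / vals[(mw.group == "0Gy").to_numpy()].mean()
        assert (ratio > 1) == (lfc > 0)


def test_flip_set_unknown_id_rejected(small_cohort, small_config):
    _, _, _, truth = small_cohort
    bad = replace(small_config, wbi_flip_set=["nonexistent"])
    with pytest.raises(ConfigError, match="nonexistent"):
        generate_wbi_companion(bad, truth)


@pytest.mark.parametrize(
    "override,message",
    [
        ({"n_shared": 100}, "n_shared"),
        ({"frac_known": 1.5}, "frac_known"),
        ({"dropout_rate": -0.1}, "dropout_rate"),
        ({"group_sizes": {"0Gy": 0}}, "positive"),
        ({"group_sizes": {"3Gy": 5}}, "unknown dose group"),
        ({"log_noise_sd": -1.0}, "log_noise_sd"),
    ],
)
def test_config_invariants_named_in_errors(override, message):
    cfg = SyntheticConfig(n_features_liver=50, n_features_plasma=50, n_shared=20)
    for k, v in override.items():
        setattr(cfg, k, v)
    with pytest.raises(ConfigError, match=message):
        cfg.validate()


def test_planted_effect_validation():
    with pytest.raises(ConfigError, match="liver/plasma/both"):
        PlantedEffect("m", "serum", 0.1, 0.2)
    cfg = SyntheticConfig(
        n_features_liver=20, n_features_plasma=20, n_shared=10, frac_known=1.0,
        planted_biomarkers=[PlantedEffect("L001", "both", 0.1, 0.2)],
    )
    with pytest.raises(ConfigError, match="shared"):
        generate_cohort(cfg)


def test_ontology_covers_knowns_only(small_cohort):
    _, _, _, truth = small_cohort
    onto = ontology_map(truth)
    feats = truth.features
    assert set(onto) == set(feats.index[feats.known])
    assert not any(m.startswith("X-") for m in onto)


def test_truth_record_accounting(small_cohort, small_config):
    _, _, _, truth = small_cohort
    feats = truth.features
    assert feats.index.is_unique
    assert sorted(truth.planted_ids()) == sorted(
        {p.metabolite for p in small_config.planted_biomarkers}
    )
    assert feats.pathway.notna().all()
    assert feats.wbi_flipped.sum() == len(small_config.wbi_flip_set)


def test_default_panel_config_is_valid_and_study_sized():
    cfg = default_panel_config(seed=1)
    cfg.validate()
    assert sum(cfg.group_sizes.values()) == 30
    assert cfg.wbi_group_sizes == {"0Gy": 12, "10Gy": 12}
    liver, plasma, meta, truth = generate_cohort(cfg)
    assert liver.shape[1] == 407 and plasma.shape[1] == 347
    folds = [np.exp(abs(p.lfc_50)) for p in cfg.planted_biomarkers]
    assert max(folds) == pytest.approx(20.0)
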