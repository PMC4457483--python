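"""Synthetic paired-tissue, multi-dose metabolomics cohorts with planted truth.

The generative model is a log-normal hierarchy chosen as the simplest model
that reproduces the features downstream stages depend on: per-metabolite
log-baselines; a per-animal latent factor per pathway that induces
within-pathway block correlation; an additive per-animal offset shared by the
two tissues of the same animal; multiplicative dose-group effects planted on
designated biomarkers; and Gaussian residual noise.  On the natural scale

    abundance = exp(baseline + loading * pathway_factor + dose_effect
                    + sham_effect + animal + noise)

so a planted log-fold effect of log(4) at 50 Gy is a 4-fold change of the
group geometric mean.  Missingness is missing-not-at-random: the dropout
probability rises logistically as the (log) abundance falls, mirroring the
low-abundance censoring of MS platforms.

The whole-body-irradiation companion cohort reuses the same metabolite
universe and applies each metabolite's 10 Gy whole-liver effect — with the
sign reversed for the configured flip set, emulating responses that move in
opposite directions under whole-body versus liver-only exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GROUPS, SCALE_RAW, AbundanceTable

logger = logging.getLogger(__name__)

SURGERY_GROUPS = ("0Gy", "10Gy", "50Gy")  # groups that underwent laparotomy


class ConfigError(ValueError):
    """A SyntheticConfig invariant is violated; the message names it."""


@dataclass
class PlantedEffect:
    """A ground-truth dose effect on one metabolite.

    ``lfc_10`` / ``lfc_50`` are natural-log fold effects at 10 and 50 Gy
    (log(4) means a 4-fold change of the group geometric mean).  ``tissue``
    is "liver", "plasma" or "both"; a both-tissue effect applies identically
    — hence with the same sign — in the two tissues and requires a shared
    metabolite id.
    """

    metabolite: str
    tissue: str
    lfc_10: float
    lfc_50: float

    def __post_init__(self) -> None:
        if self.tissue not in ("liver", "plasma", "both"):
            raise ConfigError(f"planted effect tissue must be liver/plasma/both, got {self.tissue!r}")
        if not (np.isfinite(self.lfc_10) and np.isfinite(self.lfc_50)):
            raise ConfigError(f"non-finite planted effect for {self.metabolite!r}")
        self.lfc_10 = float(self.lfc_10)
        self.lfc_50 = float(self.lfc_50)

    @property
    def sign(self) -> int:
        ref = self.lfc_50 if self.lfc_50 != 0 else self.lfc_10
        return int(np.sign(ref)) or 1


@dataclass
class SyntheticConfig:
    """Study design and generative parameters for one synthetic experiment.

    Defaults mirror the emulated study: whole-liver cohorts of 6 untreated /
    8 sham / 8 at 10 Gy / 8 at 50 Gy with paired liver and plasma per animal,
    a whole-body companion of 12 + 12, 407 liver and 347 plasma features of
    which 159 are shared, ~35% carrying known identities.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"untreated": 6, "0Gy": 8, "10Gy": 8, "50Gy": 8}
    )
    n_features_liver: int = 407
    n_features_plasma: int = 347
    n_shared: int = 159
    frac_known: float = 0.35
    n_pathways: int = 20
    pathway_block_rho: float = 0.6
    planted_biomarkers: list[PlantedEffect] = field(default_factory=list)
    cross_tissue_coupling: float = 1.0
    wbi_flip_set: list[str] = field(default_factory=list)
    wbi_group_sizes: dict[str, int] = field(default_factory=lambda: {"0Gy": 12, "10Gy": 12})
    dropout_rate: float = 0.05
    dropout_mnar_strength: float = 1.0
    sham_surgery_effect_sd: float = 0.0
    log_noise_sd: float = 0.3
    animal_effect_sd: float = 0.1
    unknown_pathway_coupling: float = 0.3
    baseline_mean: float = 2.0
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for sizes in (self.group_sizes, self.wbi_group_sizes):
            for g, n in sizes.items():
                if g not in GROUPS:
                    raise ConfigError(f"unknown dose group {g!r}; expected one of {GROUPS}")
                if n < 1:
                    raise ConfigError(f"group size for {g!r} must be positive, got {n}")
        if self.n_shared > min(self.n_features_liver, self.n_features_plasma):
            raise ConfigError(
                "n_shared exceeds min(n_features_liver, n_features_plasma): "
                f"{self.n_shared} > {min(self.n_features_liver, self.n_features_plasma)}"
            )
        for name in (
            "frac_known",
            "pathway_block_rho",
            "cross_tissue_coupling",
            "dropout_rate",
            "unknown_pathway_coupling",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.pathway_block_rho >= 1.0:
            raise ConfigError("pathway_block_rho must be < 1")
        for name in ("dropout_mnar_strength", "log_noise_sd", "animal_effect_sd",
                     "sham_surgery_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_pathways < 1:
            raise ConfigError("n_pathways must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_biomarkers"] = [asdict(p) for p in self.planted_biomarkers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["planted_biomarkers"] = [PlantedEffect(**p) for p in d.get("planted_biomarkers", [])]
        return cls(**d)


@dataclass
class TruthRecord:
    """Planted ground truth: one row per metabolite in ``features``.

    Columns: in_liver/in_plasma, known, pathway, is_planted, per-tissue
    log-fold effects per dose, wbi_flipped.  The baseline/loading columns are
    the latent per-metabolite parameters, kept so the whole-body companion
    reuses the same metabolite universe.
    """

    features: pd.DataFrame
    config: SyntheticConfig

    def planted_ids(self) -> list[str]:
        return list(self.features.index[self.features["is_planted"]])


def _feature_layout(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out metabolite ids, known/unknown labels and pathway assignment.

    Shared ids S###, liver-only L###, plasma-only P###; unknown features are
    labeled X-<id>.  Every feature gets a latent pathway (total, non-
    overlapping); the ontology exported downstream covers knowns only.
    """

    def ids(prefix: str, n: int) -> tuple[list[str], list[bool]]:
        n_known = int(round(config.frac_known * n))
        names = [f"{prefix}{i + 1:03d}" for i in range(n_known)]
        names += [f"X-{prefix}{i + 1:03d}" for i in range(n - n_known)]
        return names, [True] * n_known + [False] * (n - n_known)

    shared, shared_known = ids("S", config.n_shared)
    liver, liver_known = ids("L", config.n_features_liver - config.n_shared)
    plasma, plasma_known = ids("P", config.n_features_plasma - config.n_shared)
    feats = pd.DataFrame(
        {
            "known": shared_known + liver_known + plasma_known,
            "in_liver": [True] * len(shared) + [True] * len(liver) + [False] * len(plasma),
            "in_plasma": [True] * len(shared) + [False] * len(liver) + [True] * len(plasma),
        },
        index=pd.Index(shared + liver + plasma, name="metabolite"),
    )
    feats["pathway"] = [
        f"pathway_{k + 1:02d}" for k in rng.integers(0, config.n_pathways, size=len(feats))
    ]
    # knowns always load on their pathway factor; a configurable fraction of
    # unknowns is coupled too (these are the "known unknowns" that later sort
    # into pathways by correlation alone)
    coupled_unknown = rng.random(len(feats)) < config.unknown_pathway_coupling
    feats["loads_pathway"] = feats["known"] | coupled_unknown
    rho = config.pathway_block_rho
    lam = config.log_noise_sd * np.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0
    feats["loading"] = np.where(feats["loads_pathway"], lam, 0.0)
    for tissue in ("liver", "plasma"):
        feats[f"baseline_{tissue}"] = rng.normal(
            config.baseline_mean, config.baseline_sd, size=len(feats)
        )
        feats[f"lfc_10_{tissue}"] = 0.0
        feats[f"lfc_50_{tissue}"] = 0.0
    sham_hit = rng.random(len(feats)) < 0.3
    feats["sham_effect"] = np.where(
        sham_hit, rng.normal(0.0, 1.0, size=len(feats)) * config.sham_surgery_effect_sd, 0.0
    )
    feats["is_planted"] = False
    return feats


def _apply_planted(config: SyntheticConfig, feats: pd.DataFrame) -> None:
    for eff in config.planted_biomarkers:
        if eff.metabolite not in feats.index:
            raise ConfigError(f"planted effect references unknown metabolite id {eff.metabolite!r}")
        row = feats.loc[eff.metabolite]
        tissues = ("liver", "plasma") if eff.tissue == "both" else (eff.tissue,)
        if eff.tissue == "both" and not (row["in_liver"] and row["in_plasma"]):
            raise ConfigError(
                f"both-tissue effect on {eff.metabolite!r} requires a shared metabolite id"
            )
        for t in tissues:
            if not row[f"in_{t}"]:
                raise ConfigError(f"planted effect on {eff.metabolite!r} targets absent tissue {t}")
            feats.at[eff.metabolite, f"lfc_10_{t}"] = eff.lfc_10
            feats.at[eff.metabolite, f"lfc_50_{t}"] = eff.lfc_50
        feats.at[eff.metabolite, "is_planted"] = True


def _simulate_tissue(
    feats: pd.DataFrame,
    tissue: str,
    animals: pd.DataFrame,
    pathway_factors: pd.DataFrame,
    animal_effects: pd.Series,
    config: SyntheticConfig,
    rng: np.random.Generator,
    modality: str,
    lfc_columns: dict[str, str],
) -> AbundanceTable:
    sub = feats[feats[f"in_{tissue}"]]
    n_s, n_m = len(animals), len(sub)
    log_x = np.tile(sub[f"baseline_{tissue}"].to_numpy(), (n_s, 1))
    factor = pathway_factors.loc[animals["animal_id"], sub["pathway"]].to_numpy()
    log_x += factor * sub["loading"].to_numpy()[None, :]
    log_x += animal_effects.loc[animals["animal_id"]].to_numpy()[:, None]
    groups = animals["group"].to_numpy()
    for g, col in lfc_columns.items():
        mask = groups == g
        if mask.any():
            log_x[mask] += sub[f"{col}_{tissue}"].to_numpy()[None, :]
    surgery = np.isin(groups, SURGERY_GROUPS)
    log_x[surgery] += sub["sham_effect"].to_numpy()[None, :]
    log_x += rng.normal(0.0, config.log_noise_sd, size=(n_s, n_m))

    abundance = np.exp(log_x)
    if config.dropout_rate > 0:
        z = (log_x - log_x.mean()) / max(log_x.std(), 1e-12)
        p_drop = np.clip(
            2.0 * config.dropout_rate / (1.0 + np.exp(config.dropout_mnar_strength * z)),
            0.0,
            1.0,
        )
        abundance = np.where(rng.random(size=abundance.shape) < p_drop, np.nan, abundance)

    sample_ids = [f"{a}_{tissue}" for a in animals["animal_id"]]
    data = pd.DataFrame(abundance, index=sample_ids, columns=sub.index.to_list())
    return AbundanceTable(data, scale=SCALE_RAW, tissue=tissue, modality=modality)


def _make_animals(group_sizes: dict[str, int], modality: str) -> pd.DataFrame:
    rows = []
    k = 0
    for g in GROUPS:
        for _ in range(group_sizes.get(g, 0)):
            k += 1
            rows.append({"animal_id": f"{modality}_A{k:02d}", "group": g})
    return pd.DataFrame(rows)


def _metadata(animals: pd.DataFrame, modality: str) -> pd.DataFrame:
    rows = []
    for tissue in ("liver", "plasma"):
        for _, r in animals.iterrows():
            rows.append(
                {
                    "sample_id": f"{r['animal_id']}_{tissue}",
                    "animal_id": r["animal_id"],
                    "tissue": tissue,
                    "modality": modality,
                    "group": r["group"],
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "animal_id", "tissue", "modality", "group"])


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[AbundanceTable, AbundanceTable, pd.DataFrame, TruthRecord]:
    """Generate the whole-liver-irradiation cohort.

    Returns (liver table, plasma table, metadata, truth).  Both tables hold
    raw-scale abundances (strictly positive before dropout); liver and plasma
    rows are paired by animal id.  Identical config (including seed) gives
    identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    feats = _feature_layout(config, rng)
    _apply_planted(config, feats)
    feats["wbi_flipped"] = feats.index.isin(config.wbi_flip_set)

    animals = _make_animals(config.group_sizes, "WLI")
    pathways = [f"pathway_{k + 1:02d}" for k in range(config.n_pathways)]
    pathway_factors = pd.DataFrame(
        rng.normal(size=(len(animals), config.n_pathways)),
        index=animals["animal_id"],
        columns=pathways,
    )
    animal_effects = pd.Series(
        rng.normal(0.0, config.animal_effect_sd, size=len(animals)),
        index=animals["animal_id"],
    )
    lfc_cols = {"10Gy": "lfc_10", "50Gy": "lfc_50"}
    liver = _simulate_tissue(
        feats, "liver", animals, pathway_factors, animal_effects, config, rng, "WLI", lfc_cols
    )
    plasma = _simulate_tissue(
        feats, "plasma", animals, pathway_factors, animal_effects, config, rng, "WLI", lfc_cols
    )
    meta = _metadata(animals, "WLI")
    truth = TruthRecord(features=feats, config=config)
    logger.info(
        "synthetic WLI cohort: %d animals, %d liver + %d plasma features (%d shared, %d planted)",
        len(animals),
        liver.shape[1],
        plasma.shape[1],
        config.n_shared,
        int(feats["is_planted"].sum()),
    )
    return liver, plasma, meta, truth


def generate_wbi_companion(
    config: SyntheticConfig, truth: TruthRecord
) -> tuple[AbundanceTable, AbundanceTable, pd.DataFrame]:
    """Generate the whole-body-irradiation companion cohort.

    Two groups (0 Gy and 10 Gy, sizes from ``config.wbi_group_sizes``), fresh
    animals, same metabolite universe.  Every metabolite receives its WLI
    10 Gy effect; metabolites in ``config.wbi_flip_set`` receive it with the
    sign reversed.
    """
    config.validate()
    unknown = [m for m in config.wbi_flip_set if m not in truth.features.index]
    if unknown:
        raise ConfigError(f"wbi_flip_set references unknown metabolite id(s): {unknown}")
    rng = np.random.default_rng([config.seed, 0x5EED])
    feats = truth.features.copy()
    flip = feats.index.isin(config.wbi_flip_set)
    for t in ("liver", "plasma"):
        feats[f"wbi_lfc_10_{t}"] = np.where(flip, -feats[f"lfc_10_{t}"], feats[f"lfc_10_{t}"])

    animals = _make_animals(config.wbi_group_sizes, "WBI")
    pathways = [f"pathway_{k + 1:02d}" for k in range(config.n_pathways)]
    pathway_factors = pd.DataFrame(
        rng.normal(size=(len(animals), config.n_pathways)),
        index=animals["animal_id"],
        columns=pathways,
    )
    animal_effects = pd.Series(
        rng.normal(0.0, config.animal_effect_sd, size=len(animals)),
        index=animals["animal_id"],
    )
    lfc_cols = {"10Gy": "wbi_lfc_10"}
    liver = _simulate_tissue(
        feats, "liver", animals, pathway_factors, animal_effects, config, rng, "WBI", lfc_cols
    )
    plasma = _simulate_tissue(
        feats, "plasma", animals, pathway_factors, animal_effects, config, rng, "WBI", lfc_cols
    )
    return liver, plasma, _metadata(animals, "WBI")


def ontology_map(truth: TruthRecord) -> dict[str, str]:
    """Metabolite -> pathway map over known-identity features only."""
    known = truth.features[truth.features["known"]]
    return dict(zip(known.index, known["pathway"]))


def default_panel_config(seed: int = 0) -> SyntheticConfig:
    """The default study emulation: a 17-metabolite cross-tissue panel, a
    ~20-fold plasma spike, a 2-9-fold liver pathway block, generalized
    amino-acid-style depletion, and a WBI flip subset.
    """
    planted: list[PlantedEffect] = []
    # 17 cross-tissue biomarkers on shared known ids (panel-scale anchor);
    # half the log-fold at 10 Gy, i.e. a square-root dose response
    for i in range(17):
        fold_50 = 4.0 + (i % 5)  # folds 4..8
        sign = -1.0 if i % 4 == 3 else 1.0
        planted.append(
            PlantedEffect(
                metabolite=f"S{i + 1:03d}",
                tissue="both",
                lfc_10=sign * np.log(fold_50) / 2.0,
                lfc_50=sign * np.log(fold_50),
            )
        )
    # high-dose plasma spike (bradykinin-like)
    planted.append(PlantedEffect("P001", "plasma", lfc_10=np.log(2.0), lfc_50=np.log(20.0)))
    # liver pathway block, 2-9-fold (pentose-phosphate-like)
    for i, fold in enumerate((3.0, 5.0, 9.0, 2.0, 4.0)):
        planted.append(
            PlantedEffect(f"L{i + 1:03d}", "liver", lfc_10=np.log(fold) / 2, lfc_50=np.log(fold))
        )
    # generalized amino-acid depletion in liver
    for i, fold in enumerate((0.5, 0.6, 0.7, 0.4, 0.65, 0.55)):
        planted.append(
            PlantedEffect(f"L{i + 6:03d}", "liver", lfc_10=np.log(fold) / 2, lfc_50=np.log(fold))
        )
    flip = [f"S{i + 1:03d}" for i in range(0, 17, 2)]  # alternating flip subset
    return SyntheticConfig(planted_biomarkers=planted, wbi_flip_set=flip, seed=seed)
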