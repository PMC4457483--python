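import numpy as np
import pandas as pd
import pytest

from radmetab.io import SCALE_LOG, SCALE_RAW, SCALE_SHAM, AbundanceTable
from radmetab.simulate import PlantedEffect, SyntheticConfig, generate_cohort


def make_table(values, samples=None, metabolites=None, scale=SCALE_RAW, tissue="liver",
               modality="WLI"):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    metabolites = metabolites or [f"m{j}" for j in range(values.shape[1])]
    return AbundanceTable(
        pd.DataFrame(values, index=samples, columns=metabolites),
        scale=scale, tissue=tissue, modality=modality,
    )


def make_meta(samples, groups, tissue="liver", modality="WLI", animals=None):
    animals = animals or [f"A{i:02d}" for i in range(len(samples))]
    return pd.DataFrame(
        {
            "sample_id": samples,
            "animal_id": animals,
            "tissue": tissue,
            "modality": modality,
            "group": groups,
        }
    )


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort with a handful of strong planted biomarkers."""
    planted = [
        PlantedEffect("S001", "both", lfc_10=np.log(2.0), lfc_50=np.log(5.0)),
        PlantedEffect("S002", "both", lfc_10=-np.log(1.5), lfc_50=-np.log(4.0)),
        PlantedEffect("L001", "liver", lfc_10=np.log(1.5), lfc_50=np.log(6.0)),
        PlantedEffect("P001", "plasma", lfc_10=np.log(2.0), lfc_50=np.log(20.0)),
    ]
    return SyntheticConfig(
        n_features_liver=80,
        n_features_plasma=70,
        n_shared=40,
        n_pathways=5,
        planted_biomarkers=planted,
        wbi_flip_set=["S001"],
        dropout_rate=0.02,
        seed=2024,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)
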