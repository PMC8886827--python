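import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methylator import (BetaMatrix, CohortSpec, ProbeManifest, generate_cohort)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture()
def sdc2_manifest() -> ProbeManifest:
    """The four-probe SDC2 promoter block plus one distant decoy probe."""
    return ProbeManifest(table=pd.DataFrame({
        "probe_id": ["cg16935295", "cg04261408", "cg14625631", "cg10292139",
                     "cg99999999"],
        "chrom": ["chr8"] * 5,
        "pos": [97506030, 97506140, 97506250, 97506360, 97606360],
        "gene": ["SDC2"] * 5,
        "tss_distance": [-1500, -1390, -1280, -1170, 98830],
    }))


@pytest.fixture()
def small_beta(sdc2_manifest) -> BetaMatrix:
    """Two tumors and two normals over the SDC2 probes.

    The first, second and fourth probes clear the 0.3 tumor-normal delta;
    the third (cg14625631) and the decoy do not.
    """
    probes = list(sdc2_manifest.table["probe_id"])
    values = pd.DataFrame(
        [[0.60, 0.70, 0.30, 0.80, 0.10],
         [0.70, 0.60, 0.20, 0.70, 0.15],
         [0.10, 0.20, 0.10, 0.20, 0.10],
         [0.20, 0.10, 0.10, 0.10, 0.05]],
        index=["T1", "T2", "N1", "N2"], columns=probes)
    phenotype = pd.Series(["tumor", "tumor", "normal", "normal"],
                          index=values.index)
    return BetaMatrix(values=values, phenotype=phenotype)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-spec synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def cohort_300():
    """Larger cohort used by the end-to-end recovery checks."""
    return generate_cohort(CohortSpec(n_tumor=300, seed=5))


def tumor_accuracy(calls: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Group-call accuracy over tumor samples with valid calls."""
    t = truth.set_index("sample_id")
    tum = calls[calls["sample_id"].map(t["phenotype"]) == "tumor"]
    tum = tum[tum["group"] != "invalid"]
    return float((tum["group"].to_numpy() ==
                  t.loc[tum["sample_id"], "group"].to_numpy()).mean())
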