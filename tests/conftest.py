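import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nihlkit.cohort import CohortTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_panel(snp_ids, mafs=None):
    rows = []
    for i, snp in enumerate(snp_ids):
        rows.append({"snp_id": snp, "gene": f"G{i}", "wild_allele": "A",
                     "variant_allele": "G"})
    panel = pd.DataFrame(rows).set_index("snp_id")
    if mafs is not None:
        panel["maf"] = list(mafs)
    return panel


def make_cohort(genotype_rows, statuses, snp_ids=("rs1",), covariates=None,
                stage_label="test"):
    """Tiny cohort from explicit genotype strings and statuses."""
    n = len(statuses)
    ids = [f"S{i}" for i in range(n)]
    subjects = pd.DataFrame({"status": list(statuses)},
                            index=pd.Index(ids, name="subject_id"))
    if covariates:
        for k, v in covariates.items():
            subjects[k] = v
    geno = pd.DataFrame(genotype_rows, index=subjects.index, columns=list(snp_ids))
    return CohortTable(panel=make_panel(snp_ids), subjects=subjects,
                       genotypes=geno, stage_label=stage_label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240111)


@pytest.fixture
def balanced_cohort():
    """40 subjects, 1 SNP, genotypes spread over all three calls."""
    calls = (["AA"] * 10 + ["AB"] * 6 + ["BB"] * 4) + (["AA"] * 12 + ["AB"] * 6 + ["BB"] * 2)
    statuses = ["case"] * 20 + ["control"] * 20
    return make_cohort([[c] for c in calls], statuses)
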