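import numpy as np
import pandas as pd
import pytest

from flipmoa import (
    DRUG_RULE,
    PERTURBATION_RULE,
    SimConfig,
    classify_flip,
    nb_wald_contrast,
    simulate_all,
)
from flipmoa.diffexp import DEResult
from flipmoa.io import CountMatrix


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic study shared across tests (seed fixed)."""
    return simulate_all(SimConfig(seed=11))


@pytest.fixture(scope="session")
def de_pair(bundle):
    cm = bundle["counts"]
    de_p = nb_wald_contrast(cm, "control", "perturbed")
    de_d = nb_wald_contrast(cm, "control", "perturbed_drug")
    return de_p, de_d


@pytest.fixture(scope="session")
def flipset(de_pair):
    de_p, de_d = de_pair
    return classify_flip(de_p, de_d, PERTURBATION_RULE, DRUG_RULE)


@pytest.fixture()
def small_cm():
    """3 genes x 6 samples, 2 samples per condition."""
    counts = np.array(
        [[10, 12, 50, 55, 20, 22], [0, 1, 0, 2, 1, 0], [100, 90, 80, 85, 95, 88]]
    )
    samples = ["c1", "c2", "p1", "p2", "d1", "d2"]
    condition = {
        "c1": "control",
        "c2": "control",
        "p1": "perturbed",
        "p2": "perturbed",
        "d1": "perturbed_drug",
        "d2": "perturbed_drug",
    }
    return CountMatrix(["gA", "gB", "gC"], samples, counts, condition)


@pytest.fixture()
def de_builder():
    return make_de


def make_de(table_dict, ref="control", alt="perturbed") -> DEResult:
    """Build a DEResult from {gene: (log2fc, p)} with BH fdr filled in."""
    genes = sorted(table_dict)
    lfc = np.array([table_dict[g][0] for g in genes], float)
    p = np.array([table_dict[g][1] for g in genes], float)
    from flipmoa import bh_adjust

    t = pd.DataFrame(
        {
            "base_mean": np.full(len(genes), 50.0),
            "log2fc": lfc,
            "se": np.ones(len(genes)),
            "p": p,
            "fdr": bh_adjust(p),
        },
        index=pd.Index(genes, name="gene"),
    )
    return DEResult(table=t, ref=ref, alt=alt)
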