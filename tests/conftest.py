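import numpy as np
import pytest
from hypothesis import settings

import eamkit as ek

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    """The bundled GhSus EcoTILLING catalog (24 SNPs, 8 genes, 277 accessions)."""
    return ek.load_bundled_catalog()


@pytest.fixture(scope="session")
def ld_groups():
    return ek.load_bundled_ld_groups()


@pytest.fixture(scope="session")
def default_sim():
    """One realization of the default synthetic study (seed 11)."""
    scenario = ek.default_scenario(11)
    q, panel, pheno, truth = ek.simulate_all(scenario)
    return scenario, q, panel, pheno, truth


@pytest.fixture(scope="session")
def default_scan(default_sim):
    """Full joint scan of the default synthetic study (shared; ~1-2 s)."""
    scenario, q, panel, pheno, truth = default_sim
    result = ek.scan(panel, pheno, scenario.trait_name, q, scenario.tag_loci())
    return scenario, truth, result


def make_inbred_panel(calls, loci=None, prefix="acc"):
    """Tiny GenotypePanel from a 0/2-coded array."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    loci = loci or [f"ToyG{j + 1:02d}At-A{100 + j}G" for j in range(m)]
    return ek.GenotypePanel(
        accessions=[f"{prefix}{i + 1:03d}" for i in range(n)],
        loci=list(loci),
        calls=calls,
    )
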