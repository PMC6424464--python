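import numpy as np
import pytest
from hypothesis import settings

import photosite as ps

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return ps.default_mass_table()


@pytest.fixture(scope="session")
def adducts():
    return ps.default_adducts()


@pytest.fixture(scope="session")
def alpha1_tm4():
    """The alpha1 TM4 tryptic peptide, residues 398-423."""
    return ps.Peptide("IAFPLLFGIFNLVYWATYLNREPQLK", "alpha1", 398)


@pytest.fixture(scope="session")
def beta3_tm4():
    """The beta3 TM4 tryptic peptide, residues 426-445."""
    return ps.Peptide("IVFPFTFSLFNLVYWLYYVN", "beta3", 426)


@pytest.fixture()
def simple_run(alpha1_tm4, adducts):
    """One labeled species (KK123 on Y415, 1% efficiency), seeded."""
    sp = ps.SpeciesConfig(
        alpha1_tm4, adducts["KK123"], true_site=18, efficiency_pct=1.0
    )
    cfg = ps.SyntheticRunConfig([sp], seed=7)
    run, truth = ps.generate_run(cfg)
    return run, truth, sp
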