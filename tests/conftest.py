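"""Shared fixtures: the demo panel and a small simulated two-group study."""

import pytest
from hypothesis import settings

import bisamp as B

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def panel():
    return B.islet_demo_panel()


@pytest.fixture(scope="session")
def meg3(panel):
    return next(a for a in panel if a.name == "MEG3")


@pytest.fixture(scope="session")
def pde7b(panel):
    return next(a for a in panel if a.name == "PDE7B")


@pytest.fixture(scope="session")
def small_study(panel, tmp_path_factory):
    """Two groups x 2 samples, 300 pairs/amplicon, clean conversion."""
    outdir = tmp_path_factory.mktemp("study")
    profiles = B.islet_study_profiles(
        n_pairs=300, conversion_rate=1.0, error_rate=0.0
    )
    return B.simulate_study(panel, profiles, n_per_group=2, seed=11, outdir=outdir)


def perfect_reads(assay, read_length=150, methylated=True):
    """Deterministic error-free mate pair from a fully (un)methylated molecule."""
    mol = B.bisulfite_convert(assay.region_seq, protect_cpg=methylated)
    read_length = min(read_length, len(mol))
    r1 = mol[:read_length]
    r2 = _revcomp(mol[-read_length:])
    return r1, r2, mol


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
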