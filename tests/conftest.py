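import logging

import pytest

from mirseedsnp.records import MatureMirna, MirnaPrecursor
from mirseedsnp.synthetic import SimulationConfig, simulate

logging.getLogger("mirseedsnp").setLevel(logging.ERROR)


@pytest.fixture
def let7_mature() -> MatureMirna:
    """A let-7-style mature on the + strand with the canonical 22 nt sequence."""
    return MatureMirna(
        id="MIMAT0000001", name="syn-let-7", precursor_id="MI0000001",
        chrom="chr1", start=1000, end=1021, strand="+",
        sequence="UGAGGUAGUAGGUUGUAUAGUU",
    )


@pytest.fixture
def let7_precursor() -> MirnaPrecursor:
    return MirnaPrecursor(id="MI0000001", name="syn-mir-let7", chrom="chr1",
                          start=990, end=1070, strand="+")


@pytest.fixture(scope="session")
def small_simulation(tmp_path_factory):
    """A small deterministic simulation shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("sim")
    cfg = SimulationConfig(seed=11, n_precursors=40, n_seed_snps=30,
                           n_genes=520, n_background_snps=40)
    ground_truth = simulate(cfg, outdir)
    return cfg, outdir, ground_truth
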