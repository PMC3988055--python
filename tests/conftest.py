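import pytest

from isocurate import SimulationConfig, simulate


def make_alignment(exons, id="t1", chrom="chr1", strand="+", source="long_read"):
    from isocurate import TranscriptAlignment

    return TranscriptAlignment(id, chrom, strand, tuple(exons), source)


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free simulation: no truncation, no shifts, full evidence."""
    cfg = SimulationConfig(
        seed=11,
        p_truncate_5p=0.0,
        p_truncate_3p=0.0,
        p_donor_shift=0.0,
        p_junction_unsupported=0.0,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Default study conditions: truncation on, junction evidence complete."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def hidden_gene_dataset():
    """Error-free reads with 5 of 20 genes hidden from the annotation."""
    cfg = SimulationConfig(
        seed=13,
        n_hidden_genes=5,
        n_hidden_isoforms=3,
        p_truncate_5p=0.0,
        p_truncate_3p=0.0,
    )
    return simulate(cfg)
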