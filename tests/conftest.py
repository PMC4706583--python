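import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from clandiv import (
    AnnotatedSequence,
    Lineage,
    SimulationConfig,
    simulate_family,
    write_alignment,
    write_lineages,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_alignment(rng, n, length, gap_fraction=0.0):
    """Random aligned sequences (optionally with gaps/X) for oracle tests."""
    seqs = []
    for i in range(n):
        chars = [AA[rng.integers(20)] for _ in range(length)]
        for j in range(length):
            u = rng.random()
            if u < gap_fraction / 2:
                chars[j] = "-"
            elif u < gap_fraction:
                chars[j] = "X"
        seqs.append(AnnotatedSequence(f"S{i}", "".join(chars)))
    return seqs


def make_lineage(
    sk="Bacteria", kingdom=None, phylum="P", class_="C", order="O",
    family="F", genus="G", organism="G org",
):
    return Lineage(sk, kingdom, phylum, class_, order, family, genus, organism)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_family():
    """A small simulated family shared by taxonomy-level tests."""
    cfg = SimulationConfig(seq_length=300, seed=7)
    return simulate_family(cfg)


@pytest.fixture
def family_files(tmp_path, small_family):
    seqs, lineages, truth = small_family
    fasta = tmp_path / "family.fasta"
    tsv = tmp_path / "lineages.tsv"
    write_alignment(seqs, fasta)
    write_lineages(lineages, tsv)
    return fasta, tsv, truth
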