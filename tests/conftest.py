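import pytest

from genepanel import fixtures
from genepanel.model import GeneModel


@pytest.fixture(scope="session")
def table1():
    """(stats rows, gene->group mapping) for the bundled 42-gene table."""
    return fixtures.table1_fixture()


@pytest.fixture(scope="session")
def table1_models() -> list[GeneModel]:
    return fixtures.table1_gene_models()


@pytest.fixture(scope="session")
def bundle() -> fixtures.FixtureBundle:
    """A 42-gene synthetic tree+motif+domain+promoter bundle (fixed seed)."""
    return fixtures.synth_meme_and_domains(fixtures.FixtureConfig(seed=11))


def brute_force_projection(model: GeneModel, aa_start: int, aa_end: int):
    """Per-nucleotide oracle: enumerate every coding base in translation
    order, take the requested codon range, and group the genomic positions
    into maximal ascending runs."""
    cds = model.cds_segments()
    coords: list[int] = []
    if model.strand == "+":
        for s in cds:
            coords.extend(range(s.start, s.end + 1))
    else:
        for s in reversed(cds):
            coords.extend(range(s.end, s.start - 1, -1))
    picked = sorted(coords[3 * aa_start - 3 : 3 * aa_end])
    runs: list[tuple[int, int]] = []
    for g in picked:
        if runs and g == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], g)
        else:
            runs.append((g, g))
    return [tuple(r) for r in runs]
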