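import pytest

from phycorg.genome import extract_cds
from phycorg.simulate import CladeConfig, SimConfig, generate_genome


def small_config(seed=0, **kw):
    """A compact genome config for fast tests: 6 PCGs, 4 tRNAs, 1 rRNA,
    1 ORF, ~6 kb."""
    defaults = dict(seed=seed, pcg_count=6, trna_count=4, rrna_count=1,
                    orf_count=1, total_pcg_nt=5400, rrna_lens=(300,),
                    orf_lens=(150,), spacer_total=300,
                    overlap_sizes=(10, 8), genome_id="toy")
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def mt_genome():
    """Full-size synthetic mitogenome with planted edits."""
    return generate_genome(SimConfig(seed=11, planted_edits=80))


@pytest.fixture(scope="session")
def mt_cds(mt_genome):
    genome, _ = mt_genome
    return extract_cds(genome)


@pytest.fixture(scope="session")
def clade_panel():
    """14-taxon two-subgenus panel with the planted 89/108 site split."""
    from phycorg.simulate import generate_clade_panel
    return generate_clade_panel(CladeConfig(seed=23))
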