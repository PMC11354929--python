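"""Ortholog alignment, SNP calling with effect classification, and
diagnostic-site identification (with a brute-force oracle on small
panels)."""

from itertools import combinations

import pytest

from phycorg.genome import TaxonLabel, extract_cds
from phycorg.snps import (align_orthologs, call_snps, diagnostic_sites,
                          is_diagnostic, per_gene_snp_density)


def test_align_identical_sequences_has_no_variable_columns():
    aln = align_orthologs({"a": "ATGGCTTAA", "b": "ATGGCTTAA"}, gene="g")
    assert call_snps(aln) == []


def test_align_equal_length_positional():
    a = "ATGGCTGCTGCTTAA"
    b = "ATGGCAGCTACTTAA"  # 2 variable columns
    aln = align_orthologs({"a": a, "b": b}, gene="g")
    assert aln.length == len(a)
    sites = call_snps(aln)
    assert [s.column for s in sites] == [6, 10]


def test_align_codon_insertion_gets_in_frame_gap():
    a = "ATGGCTAAATTTTGCTAA"
    b = "ATGGCTAAAGGGTTTTGCTAA"  # one extra codon
    aln = align_orthologs({"a": a, "b": b}, gene="g")
    assert aln.length % 3 == 0
    gap = aln.rows["a"].index("-")
    assert aln.rows["a"].count("-") == 3
    assert gap % 3 == 0  # gap placed on a codon boundary


def test_align_rejects_non_orthologs():
    with pytest.raises(ValueError):
        align_orthologs({"a": "ATGAAACCCGGGTTTAAACCCTAA",
                         "b": "ATGTGTGGATGGTACGACTGGTAA"}, gene="g")


def test_call_snps_effect_classification():
    # GGA vs GGC: Gly 4-fold third position -> synonymous
    aln = align_orthologs({"a": "ATGGGATAA", "b": "ATGGGCTAA"}, gene="g")
    (site,) = call_snps(aln)
    assert site.effect == "synonymous" and site.column == 6
    # AAA vs GAA at codon position 1 -> K/E nonsynonymous
    aln = align_orthologs({"a": "ATGAAATAA", "b": "ATGGAATAA"}, gene="g")
    (site,) = call_snps(aln)
    assert site.effect == "nonsynonymous" and site.column == 4


def test_call_snps_skips_gapped_columns():
    from phycorg.snps import OrthologAlignment
    aln = OrthologAlignment("g", ["a", "b"], {"a": "ATG---AAA",
                                              "b": "ATGCCCAGA"})
    cols = [s.column for s in call_snps(aln)]
    assert cols == [8]  # the gapped codon is not a SNP


def test_diagnostic_sites_two_group_example():
    taxa = {t: TaxonLabel(species=t, subgenus=g)
            for t, g in [("A", "g1"), ("B", "g1"), ("C", "g2"), ("D", "g2")]}
    seqs = {"A": "ATGTTTTAA", "B": "ATGTTTTAA",
            "C": "ATGTTCTAA", "D": "ATGTTCTAA"}
    sites = call_snps(align_orthologs(seqs, gene="g"))
    assert len(sites) == 1
    d1 = diagnostic_sites(sites, taxa, "subgenus", "g1")
    d2 = diagnostic_sites(sites, taxa, "subgenus", "g2")
    assert len(d1) == len(d2) == 1
    assert ("subgenus", "g1") in d1[0].diagnostic_for


def test_diagnostic_sites_singleton_group():
    taxa = {t: TaxonLabel(species=t) for t in "ABCD"}
    seqs = {"A": "ATGTATTAA", "B": "ATGCATTAA",
            "C": "ATGCATTAA", "D": "ATGCATTAA"}
    sites = call_snps(align_orthologs(seqs, gene="g"))
    assert len(diagnostic_sites(sites, taxa, "species", "A")) == 1
    assert diagnostic_sites(sites, taxa, "species", "B") == []
    with pytest.raises(ValueError):
        diagnostic_sites(sites, taxa, "species", "nobody")


@pytest.mark.parametrize("seed", range(6))
def test_diagnostic_oracle_equivalence(seed):
    """Exhaustive check on small panels: diagnostic_sites equals direct
    enumeration over all (site, group) pairs."""
    import numpy as np

    rng = np.random.default_rng(300 + seed)
    taxa_names = list("ABCDEF")
    taxa = {t: TaxonLabel(species=t, subgenus="G1" if i < 3 else "G2")
            for i, t in enumerate(taxa_names)}
    ncod = 17  # 51 columns
    rows = {}
    base = "".join(rng.choice(["GGA", "CCA", "TCA", "GTA"], ncod))
    for t in taxa_names:
        row = list(base)
        for _ in range(int(rng.integers(1, 6))):
            col = int(rng.integers(ncod)) * 3 + 2  # third positions
            row[col] = str(rng.choice(list("ACGT")))
        rows[t] = "ATG" + "".join(row) + "TAA"
    sites = call_snps(align_orthologs(rows, gene="g"))
    for level, group in [("subgenus", "G1"), ("subgenus", "G2")] + \
            [("species", t) for t in taxa_names]:
        members = {t for t in taxa_names if taxa[t].level(level) == group}
        expected = []
        for s in sites:
            inside = {s.alleles[t] for t in members}
            outside = {s.alleles[t] for t in taxa_names if t not in members}
            if len(inside) == 1 and not inside & outside:
                expected.append(s.column)
        got = [s.column for s in diagnostic_sites(sites, taxa, level, group)]
        assert got == expected


def test_clade_panel_recovers_planted_structure(clade_panel):
    genomes, truth = clade_panel
    panel = {}
    for g in genomes:
        for c in extract_cds(g) + extract_cds(g, "ORF"):
            panel.setdefault(c.gene, {})[g.id] = c.nt
    sites = []
    for gene, per in sorted(panel.items()):
        sites.extend(call_snps(align_orthologs(per, gene=gene)))
    assert len(sites) == 197
    assert sum(s.effect == "nonsynonymous" for s in sites) == 89
    assert sum(s.effect == "synonymous" for s in sites) == 108
    taxa = {g.id: g.taxon for g in genomes}
    for grp in ("Bactrophycus", "Sargassum"):
        diag = diagnostic_sites(sites, taxa, "subgenus", grp)
        assert len(diag) == 197  # fixed differences identify both groups
    # planted coordinates match called coordinates exactly
    planted = {(d["gene"], d["cds_pos"]) for d in truth.snp_sites}
    called = {(s.gene, s.column) for s in sites}
    assert planted == called


def test_taxon_input_order_invariance(clade_panel):
    genomes, _ = clade_panel
    some = [g for g in genomes[:4]]
    gene = "cox1"
    per = {g.id: next(c.nt for c in extract_cds(g) if c.gene == gene)
           for g in some}
    s1 = call_snps(align_orthologs(per, gene=gene))
    per_rev = dict(reversed(list(per.items())))
    s2 = call_snps(align_orthologs(per_rev, gene=gene))
    assert [(s.column, s.alleles, s.effect) for s in s1] == \
           [(s.column, s.alleles, s.effect) for s in s2]


def test_per_gene_snp_density_ranking(clade_panel):
    genomes, truth = clade_panel
    panel = {}
    for g in genomes:
        for c in extract_cds(g) + extract_cds(g, "ORF"):
            panel.setdefault(c.gene, {})[g.id] = c.nt
    sites = []
    for gene, per in sorted(panel.items()):
        sites.extend(call_snps(align_orthologs(per, gene=gene)))
    lengths = {g: len(next(iter(per.values())))
               for g, per in panel.items()}
    df = per_gene_snp_density(sites, lengths)
    assert df["n_snps"].is_monotonic_decreasing
    assert df["n_snps"].sum() == 197
    assert df["share"].sum() == pytest.approx(1.0)
    assert (df["per_kb"] > 0).all()
    assert per_gene_snp_density([]).empty


def test_disjoint_groups_have_disjoint_diagnostic_alleles(clade_panel):
    genomes, _ = clade_panel
    taxa = {g.id: g.taxon for g in genomes}
    panel = {}
    for g in genomes[:6]:
        for c in extract_cds(g):
            panel.setdefault(c.gene, {})[g.id] = c.nt
    gene = "cox1"
    sites = call_snps(align_orthologs(panel[gene], gene=gene))
    members = {t for t in taxa if taxa[t].subgenus == "Bactrophycus"
               and t in panel[gene]}
    for s in sites:
        if is_diagnostic(s, members):
            inside = {s.alleles[t] for t in s.alleles if t in members}
            outside = {s.alleles[t] for t in s.alleles if t not in members}
            assert not inside & outside
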