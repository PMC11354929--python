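"""Per-gene ortholog alignment, SNP calling with synonymous/non-synonymous
classification, and hierarchical diagnostic-site identification.

A site is *diagnostic* for a taxonomic group when all group members share
one allele, the site is monomorphic inside the group, and that allele is
absent from every taxon outside the group — the only definition under
which a single sequence identifies the group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .genome import CodingSequence, TaxonLabel
from .codon import codon_to_aa, stop_codons


@dataclass
class OrthologAlignment:
    """Codon-aware nucleotide alignment of one gene across taxa."""

    gene: str
    taxa: list[str]
    rows: dict[str, str]  # taxon -> aligned nt (gaps '-'), frame preserved

    def __post_init__(self):
        lens = {len(r) for r in self.rows.values()}
        if len(lens) != 1:
            raise ValueError("alignment rows differ in length")
        (self.length,) = lens

    def column(self, col: int) -> dict[str, str]:
        """1-based alignment column."""
        return {t: self.rows[t][col - 1] for t in self.taxa}


@dataclass
class SnpSite:
    gene: str
    column: int  # 1-based alignment position
    alleles: dict[str, str]  # taxon -> base
    effect: str  # synonymous | nonsynonymous
    diagnostic_for: list[tuple[str, str]] = field(default_factory=list)


def _translated_identity(a: str, b: str) -> float:
    pa, pb = str(Seq(a).translate()), str(Seq(b).translate())
    n = min(len(pa), len(pb))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(pa[:n], pb[:n])) / n


def align_orthologs(cds_per_taxon: dict[str, CodingSequence | str],
                    gene: str = "", identity_floor: float = 0.5
                    ) -> OrthologAlignment:
    """Codon-aware alignment of one gene's CDS across taxa.

    Equal-length inputs are aligned positionally (the panel case for
    closely related congeners).  Unequal lengths are handled by aligning
    each translation to the longest sequence's translation and threading
    the nucleotides back in-frame, so gaps always come in multiples of
    three.  Raises when translated identity to the reference falls below
    ``identity_floor`` (mis-orthology guard).
    """
    if len(cds_per_taxon) < 2:
        raise ValueError("need at least two taxa")
    nts = {t: (c.nt if isinstance(c, CodingSequence) else c)
           for t, c in sorted(cds_per_taxon.items())}
    if not gene:
        any_cds = next(iter(cds_per_taxon.values()))
        gene = any_cds.gene if isinstance(any_cds, CodingSequence) else ""
    taxa = sorted(nts)
    ref_taxon = max(taxa, key=lambda t: (len(nts[t]), t))
    for t in taxa:
        if t != ref_taxon and \
                _translated_identity(nts[t], nts[ref_taxon]) < identity_floor:
            raise ValueError(
                f"{gene}: {t} translated identity to {ref_taxon} below "
                f"{identity_floor}; orthology doubtful")

    if len({len(x) for x in nts.values()}) == 1:
        return OrthologAlignment(gene, taxa, dict(nts))

    # codon-aware: align translations to the reference, back-thread nt
    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-1, open_gap_score=-5,
                                    extend_gap_score=-0.5)
    ref_aa = str(Seq(nts[ref_taxon]).translate()).rstrip("*")

    threaded: dict[str, list[str]] = {}
    ins_after: dict[int, int] = {}  # ref aa pos -> max insertion codons
    per_taxon: dict[str, tuple[list[str | None], list[tuple[int, str]]]] = {}
    for t in taxa:
        aa = str(Seq(nts[t]).translate()).rstrip("*")
        if t == ref_taxon:
            per_taxon[t] = ([i for i in range(len(ref_aa))], [])
            continue
        aln = aligner.align(aa, ref_aa)[0]
        qmap: list[int | None] = [None] * len(aa)
        for (qs, qe), (ts_, te) in zip(*aln.aligned):
            for qi, ti in zip(range(qs, qe), range(ts_, te)):
                qmap[qi] = ti
        inserts: list[tuple[int, str]] = []
        last_ref = -1
        run = 0
        for qi, ti in enumerate(qmap):
            if ti is None:
                run += 1
            else:
                if run:
                    inserts.append((last_ref, str(run)))
                    ins_after[last_ref] = max(ins_after.get(last_ref, 0), run)
                    run = 0
                last_ref = ti
        if run:
            inserts.append((last_ref, str(run)))
            ins_after[last_ref] = max(ins_after.get(last_ref, 0), run)
        per_taxon[t] = (qmap, inserts)

    # build rows codon-by-codon over reference positions with insert slots
    for t in taxa:
        aa = str(Seq(nts[t]).translate()).rstrip("*")
        qmap = per_taxon[t][0]
        by_ref: dict[int, str] = {}
        ins_codons: dict[int, list[str]] = {}
        last_ref = -1
        for qi in range(len(aa)):
            codon = nts[t][3 * qi:3 * qi + 3]
            ti = qmap[qi]
            if ti is None:
                ins_codons.setdefault(last_ref, []).append(codon)
            else:
                by_ref[ti] = codon
                last_ref = ti
        parts: list[str] = []
        if -1 in ins_after:
            have = ins_codons.get(-1, [])
            parts.extend(have + ["---"] * (ins_after[-1] - len(have)))
        for ti in range(len(ref_aa)):
            parts.append(by_ref.get(ti, "---"))
            if ti in ins_after:
                have = ins_codons.get(ti, [])
                parts.extend(have + ["---"] * (ins_after[ti] - len(have)))
        threaded[t] = parts
    rows = {t: "".join(p) for t, p in threaded.items()}
    return OrthologAlignment(gene, taxa, rows)


def call_snps(aln: OrthologAlignment, transl_table: int = 1) -> list[SnpSite]:
    """Every gap-free column with ≥2 distinct alleles becomes one SNP site.

    Columns containing a gap are excluded (indels are not SNPs).  The
    effect is computed by substituting each allele into the panel-majority
    codon at that column (ties broken toward the alphabetically first
    codon): synonymous iff every allele yields the same amino acid.
    """
    aa_map = codon_to_aa(transl_table)
    stops = stop_codons(transl_table)
    sites = []
    for col in range(1, aln.length + 1):
        alleles = aln.column(col)
        vals = set(alleles.values())
        if "-" in vals or len(vals) < 2:
            continue
        ci = (col - 1) // 3  # codon index
        offset = (col - 1) % 3
        codons = Counter()
        for t in aln.taxa:
            codon = aln.rows[t][3 * ci:3 * ci + 3]
            if "-" not in codon:
                codons[codon] += 1
        if not codons:
            continue
        top = max(codons.items(), key=lambda kv: (kv[1], ), default=None)[1]
        majority = min(c for c, n in codons.items() if n == top)
        aas = set()
        for allele in vals:
            codon = majority[:offset] + allele + majority[offset + 1:]
            aas.add("*" if codon in stops else aa_map.get(codon, "X"))
        effect = "synonymous" if len(aas) == 1 else "nonsynonymous"
        sites.append(SnpSite(gene=aln.gene, column=col,
                             alleles=dict(sorted(alleles.items())),
                             effect=effect))
    return sites


def is_diagnostic(site: SnpSite, members: set[str]) -> bool:
    """Diagnostic predicate: monomorphic inside the group and the group's
    allele absent outside."""
    inside = {site.alleles[t] for t in site.alleles if t in members}
    outside = {site.alleles[t] for t in site.alleles if t not in members}
    return len(inside) == 1 and not (inside & outside)


def diagnostic_sites(snps: list[SnpSite],
                     taxa: dict[str, TaxonLabel],
                     level: str, group: str) -> list[SnpSite]:
    """Sites diagnostic for ``group`` at taxonomic rank ``level``.

    Singleton groups are allowed (species-level identification); every
    taxon in the SNP table must carry an assignment at the rank.
    """
    members = {t for t, lab in taxa.items() if lab.level(level) == group}
    if not members:
        raise ValueError(f"no taxa in group {group!r} at level {level!r}")
    for s in snps:
        for t in s.alleles:
            if t not in taxa:
                raise ValueError(f"taxon {t} has no label")
    out = []
    for s in snps:
        if is_diagnostic(s, members):
            tag = (level, group)
            if tag not in s.diagnostic_for:
                s.diagnostic_for.append(tag)
            out.append(s)
    return out


def per_gene_snp_density(snps: list[SnpSite],
                         gene_lengths: dict[str, int] | None = None
                         ) -> pd.DataFrame:
    """Genes ranked by SNP count and, when lengths are known, by count/kb."""
    counts = Counter(s.gene for s in snps)
    if not counts:
        return pd.DataFrame(columns=["gene", "n_snps", "share", "per_kb"])
    total = sum(counts.values())
    rows = []
    for gene, n in counts.items():
        per_kb = (1000 * n / gene_lengths[gene]
                  if gene_lengths and gene in gene_lengths else float("nan"))
        rows.append({"gene": gene, "n_snps": n, "share": n / total,
                     "per_kb": per_kb})
    df = pd.DataFrame(rows).sort_values(["n_snps", "gene"],
                                        ascending=[False, True])
    return df.reset_index(drop=True)
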