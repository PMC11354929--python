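"""Truth-known synthetic organellar genomes and genome panels.

The generator emulates the structures the analysis stages consume: a
circular annotated genome with a brown-algal mitogenome layout (35
protein-coding genes, 25 tRNAs, 3 rRNAs, 2 ORFs; 26,340 nt of coding
sequence; 188 bp of planned gene overlap in 12 pairs; 1,597 bp of
intergenic spacer), codon usage biased toward A/U-ending codons, and —
on request — planted microsatellites, tandem and dispersed repeats,
C→U-editable codons with a matching homolog panel, and clade-structured
substitutions with controlled synonymous/non-synonymous status.

Everything is a pure function of the seed: the same config yields a
byte-identical genome.  Every planted feature is returned in a
:class:`TruthRecord` so downstream detectors can be scored exactly.
Planted repeats are wrapped in mismatching guard bases so each is maximal
at exactly its recorded span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import (AnnotatedGenome, CodingSequence, GeneFeature,
                     TaxonLabel, revcomp)
from .codon import code_families, codon_to_aa, stop_codons

# mitogenome-style gene rosters
MT_PCGS = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7",
    "nad8", "nad9", "nad11", "rpl2", "rpl5", "rpl6", "rpl16", "rpl31",
    "rps2", "rps3", "rps4", "rps7", "rps8", "rps10", "rps11", "rps12",
    "rps13", "rps14", "rps19", "tatC",
)
MT_TRNAS = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM1", "trnM2", "trnN", "trnP", "trnQ",
    "trnR1", "trnR2", "trnS1", "trnS", "trnT", "trnV", "trnW", "trnY",
    "trnI2",
)
MT_RRNAS = ("rnl", "rns", "rrn5")
MT_ORFS = ("orf1", "orf2")
#: genes written on the light chain (strand '-') by default
LIGHT_CHAIN = frozenset({"rpl2", "rpl16", "rps3", "rps19", "tatC"})

_COMP = str.maketrans("ACGT", "TGCA")


def default_codon_weights(transl_table: int = 1) -> dict[str, float]:
    """A/U-ending codons favoured 4:1, with an extra boost for UUA and
    GUU (the strongly preferred Leu/Val codons of Fucales organelles)."""
    w = {}
    for fam in code_families(transl_table).values():
        for c in fam:
            w[c] = 4.0 if c[2] in "AT" else 1.0
    w["TTA"] = 8.0
    w["GTT"] = 8.0
    return w


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome."""

    seed: int = 0
    genome_id: str = "synthetic-mt"
    organelle: str = "mt"
    taxon: TaxonLabel | None = None
    pcg_count: int = 35
    trna_count: int = 25
    rrna_count: int = 3
    orf_count: int = 2
    total_pcg_nt: int = 26340  # incl. start and stop codons -> 8,780 codons
    trna_len: int = 72
    rrna_lens: tuple[int, ...] = (2900, 1500, 120)
    orf_lens: tuple[int, ...] = (360, 300)
    spacer_total: int = 1597
    overlap_sizes: tuple[int, ...] = (30, 25, 20, 18, 16, 15, 14, 12,
                                      10, 10, 10, 8)  # sums to 188
    background_gc: float = 0.365
    codon_weights: dict[str, float] | None = None
    bias_strength_range: tuple[float, float] = (0.4, 1.6)
    transl_table: int = 1
    non_atg_gene: str | None = None  # plant a GTG start on this gene
    planted_edits: int = 0
    planted_ssrs: tuple[tuple[str, int], ...] = ()  # (motif, copies)
    planted_tandems: tuple[tuple[str, int], ...] = ()  # (unit, copies)
    planted_dispersed: tuple[tuple[int, str], ...] = ()  # (length, kind)


@dataclass
class TruthRecord:
    """Ground truth of everything planted into a synthetic dataset."""

    gene_layout: list[tuple[str, str, int, int, str]] = field(
        default_factory=list)  # (name, class, start, end, strand)
    cds: dict[str, str] = field(default_factory=dict)  # gene -> CDS nt
    edits: list[dict] = field(default_factory=list)
    ssrs: list[tuple[str, int, int, int]] = field(default_factory=list)
    tandems: list[tuple[str, int, int, int]] = field(default_factory=list)
    dispersed: list[tuple[str, int, int, int]] = field(default_factory=list)
    snp_sites: list[dict] = field(default_factory=list)
    tree_groups: dict[str, list[str]] = field(default_factory=dict)
    omega: dict[str, float] = field(default_factory=dict)


def random_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def random_cds(n_codons: int, weights: dict[str, float],
               rng: np.random.Generator, transl_table: int = 1,
               start: str = "ATG", stop: str = "TAA") -> str:
    """One in-frame CDS of ``n_codons`` codons (start and stop included),
    interior codons drawn from the weighted sense-codon distribution."""
    if n_codons < 3:
        raise ValueError("CDS needs at least start, one codon, stop")
    sense = sorted(codon_to_aa(transl_table))
    w = np.array([weights.get(c, 1.0) for c in sense])
    w = w / w.sum()
    body = rng.choice(sense, size=n_codons - 2, p=w)
    return start + "".join(body) + stop


def _editable_codons(transl_table: int = 1) -> list[tuple[str, int, str]]:
    """(codon, position, edited_codon) triples where a single C→T is
    non-synonymous and does not create a stop."""
    aa_map = codon_to_aa(transl_table)
    stops = stop_codons(transl_table)
    out = []
    for codon, aa in sorted(aa_map.items()):
        for p in range(3):
            if codon[p] != "C":
                continue
            edited = codon[:p] + "T" + codon[p + 1:]
            if edited not in stops and aa_map[edited] != aa:
                out.append((codon, p + 1, edited))
    return out


def _split_lengths(total_codons: int, n: int, rng: np.random.Generator,
                   jitter: int = 40, min_codons: int = 60) -> list[int]:
    base, rem = divmod(total_codons, n)
    lens = [base + (1 if i < rem else 0) for i in range(n)]
    for i in range(n // 2):
        d = int(rng.integers(0, jitter + 1))
        if lens[i] + d >= min_codons and lens[n - 1 - i] - d >= min_codons:
            lens[i] += d
            lens[n - 1 - i] -= d
    return lens


def _other_base(forbidden: set[str], rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b not in forbidden]
    return choices[int(rng.integers(len(choices)))]


def _tandem_guards(core: str, k: int, rng: np.random.Generator
                   ) -> tuple[str, str]:
    """Guard strings whose k-spaced comparisons all mismatch, long enough
    that the qualifying-window slack of the core cannot bridge them."""
    g = max(k, int(0.3 * len(core)) + k)
    right = []
    for t in range(g):
        prev = core[len(core) - k + t] if t < k else right[t - k]
        right.append(_other_base({prev}, rng))
    left: list[str] = [""] * g
    for t in range(g - 1, -1, -1):
        nxt = core[t + k - g] if t + k >= g else left[t + k]
        left[t] = _other_base({nxt}, rng)
    return "".join(left), "".join(right)


@dataclass
class _Block:
    kind: str  # "ssr" | "tandem" | "disp"
    label: str
    core: str
    left: str
    right: str

    @property
    def text(self) -> str:
        return self.left + self.core + self.right


def _planted_blocks(cfg: SimConfig, rng: np.random.Generator) -> list[_Block]:
    blocks: list[_Block] = []
    for motif, copies in cfg.planted_ssrs:
        core = motif * copies
        left = _other_base({motif[-1]}, rng)
        right = _other_base({motif[0]}, rng)
        blocks.append(_Block("ssr", motif, core, left, right))
    for unit, copies in cfg.planted_tandems:
        core = unit * copies
        left, right = _tandem_guards(core, len(unit), rng)
        blocks.append(_Block("tandem", unit, core, left, right))
    for pi, (length, kind) in enumerate(cfg.planted_dispersed):
        seg = random_sequence(length, 0.5, rng)
        mate = {"forward": seg, "palindromic": revcomp(seg),
                "reverse": seg[::-1],
                "complement": seg.translate(_COMP)}[kind]
        guards = {"forward": ("A", "A", "C", "C"),
                  "reverse": ("A", "A", "C", "C"),
                  "complement": ("A", "A", "A", "A"),
                  "palindromic": ("A", "A", "A", "A")}[kind]
        gl1, gr1, gl2, gr2 = guards
        blocks.append(_Block("disp", f"{kind}:{pi}:1", seg, gl1, gr1))
        blocks.append(_Block("disp", f"{kind}:{pi}:2", mate, gl2, gr2))
    return blocks


def _build_order(cfg: SimConfig) -> list[tuple[str, str]]:
    """(name, gene_class) placement order with the Fucales-style
    trnS–trnD–trnA–rps10 block kept contiguous."""

    def take(roster, count, prefix):
        names = list(roster[:count])
        while len(names) < count:
            names.append(f"{prefix}{len(names) + 1}")
        return names

    pcgs = take(MT_PCGS, cfg.pcg_count, "gene")
    trnas = take(MT_TRNAS, cfg.trna_count, "trnX")
    rrnas = take(MT_RRNAS, cfg.rrna_count, "rrnX")
    orfs = take(MT_ORFS, cfg.orf_count, "orfX")

    block = [t for t in ("trnS", "trnD", "trnA") if t in trnas]
    rest = [t for t in trnas if t not in block]
    order: list[tuple[str, str]] = []
    ti = 0
    for i, p in enumerate(pcgs):
        if p == "rps10" and block:
            order.extend((t, "tRNA") for t in block)
        order.append((p, "PCG"))
        if ti < len(rest) and i % 3 == 2:
            order.append((rest[ti], "tRNA"))
            ti += 1
    order.extend((t, "tRNA") for t in rest[ti:])
    order.extend((r, "rRNA") for r in rrnas)
    order.extend((o, "ORF") for o in orfs)
    return order


def generate_genome(cfg: SimConfig) -> tuple[AnnotatedGenome, TruthRecord]:
    """Emit one circular annotated genome plus its ground truth.

    Overlaps are planned between a gene and a following tRNA (never
    between two protein-coding genes, whose sequences are constrained);
    the realized spacer and overlap totals equal the configured targets
    exactly.  Raises before emission when the requested features cannot
    be packed.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = TruthRecord()
    weights = cfg.codon_weights or default_codon_weights(cfg.transl_table)
    lo, hi = cfg.bias_strength_range

    order = _build_order(cfg)
    n_genes = len(order)

    # per-gene sequences
    pcg_names = [n for n, c in order if c == "PCG"]
    orf_names = [n for n, c in order if c == "ORF"]
    pcg_codons = _split_lengths(cfg.total_pcg_nt // 3, len(pcg_names), rng)
    gene_seqs: dict[str, str] = {}
    for name, n_cod in zip(pcg_names, pcg_codons):
        s = float(rng.uniform(lo, hi))
        w = {c: v ** s for c, v in weights.items()}
        start = "GTG" if name == cfg.non_atg_gene else "ATG"
        gene_seqs[name] = random_cds(n_cod, w, rng, cfg.transl_table,
                                     start=start)
    for name, ln in zip(orf_names, cfg.orf_lens):
        gene_seqs[name] = random_cds(ln // 3, weights, rng, cfg.transl_table)
    for name, ln in zip([n for n, c in order if c == "rRNA"], cfg.rrna_lens):
        gene_seqs[name] = random_sequence(ln, cfg.background_gc, rng)
    for name, c in order:
        if c == "tRNA":
            gene_seqs[name] = random_sequence(cfg.trna_len,
                                              cfg.background_gc, rng)

    # planted edits: substitute editable codons inside plus-strand PCGs
    if cfg.planted_edits:
        pool = _editable_codons(cfg.transl_table)
        plus_pcgs = [n for n in pcg_names if n not in LIGHT_CHAIN]
        used: set[tuple[str, int]] = set()
        aa_map = codon_to_aa(cfg.transl_table)
        for k in range(cfg.planted_edits):
            gene = plus_pcgs[k % len(plus_pcgs)]
            n_cod = len(gene_seqs[gene]) // 3
            ci = next((c for c in _scan(rng, 2, n_cod)
                       if (gene, c) not in used), None)
            if ci is None:
                raise ValueError("cannot pack requested edits: too few "
                                 "codons available")
            used.add((gene, ci))
            codon, pos, edited = pool[int(rng.integers(len(pool)))]
            s = gene_seqs[gene]
            gene_seqs[gene] = s[:3 * (ci - 1)] + codon + s[3 * ci:]
            truth.edits.append({
                "gene": gene, "codon_index": ci, "codon_pos": pos,
                "ref_codon": codon, "edited_codon": edited,
                "ref_aa": aa_map[codon], "edited_aa": aa_map[edited]})

    # overlaps: attach each planned overlap to a (prev gene, tRNA) adjacency
    overlap_at: dict[int, int] = {}
    protected = {"trnS", "trnD", "trnA"}
    candidates = [i for i in range(1, n_genes)
                  if order[i][1] == "tRNA" and order[i][0] not in protected
                  and order[i - 1][1] != "tRNA"]
    if len(candidates) < len(cfg.overlap_sizes):
        raise ValueError("not enough gene/tRNA adjacencies for the "
                         "requested overlaps")
    step = max(1, len(candidates) // max(len(cfg.overlap_sizes), 1))
    picked = (candidates[::step] + candidates)[:len(cfg.overlap_sizes)]
    picked = sorted(set(picked))[:len(cfg.overlap_sizes)]
    while len(picked) < len(cfg.overlap_sizes):
        extra = [c for c in candidates if c not in picked]
        picked.append(extra[0])
    for idx, size in zip(sorted(picked), cfg.overlap_sizes):
        if size >= cfg.trna_len:
            raise ValueError(f"overlap {size} exceeds tRNA length")
        overlap_at[idx] = size

    # spacer pieces: one before each non-overlapped gene plus a closing one
    open_slots = [i for i in range(n_genes) if i not in overlap_at] + [n_genes]
    blocks = _planted_blocks(cfg, rng)
    need = sum(len(b.text) for b in blocks)
    if need > cfg.spacer_total:
        raise ValueError("planted repeats do not fit in the spacer budget")
    if len(blocks) > len(open_slots):
        raise ValueError("more planted repeats than spacer slots")

    remaining = cfg.spacer_total - need
    shares = rng.multinomial(remaining,
                             np.ones(len(open_slots)) / len(open_slots))
    # biggest blocks into the slots with the most padding
    slot_rank = sorted(range(len(open_slots)), key=lambda s: -shares[s])
    block_rank = sorted(range(len(blocks)),
                        key=lambda b: -len(blocks[b].text))
    assigned = {slot_rank[j]: block_rank[j] for j in range(len(blocks))}

    spacer_strs: dict[int, str] = {}
    marks: dict[int, list[tuple[_Block, int]]] = {}  # slot -> (block, offset)
    for si, slot in enumerate(open_slots):
        budget = int(shares[si])
        if si in assigned:
            b = blocks[assigned[si]]
            lpad = budget // 2
            piece = (random_sequence(lpad, cfg.background_gc, rng) + b.text
                     + random_sequence(budget - lpad, cfg.background_gc, rng))
            marks.setdefault(slot, []).append((b, lpad + len(b.left)))
            spacer_strs[slot] = piece
        else:
            spacer_strs[slot] = random_sequence(budget, cfg.background_gc,
                                                rng)

    # assembly
    parts: list[str] = []
    pos = 0
    features: list[GeneFeature] = []
    disp_pending: dict[str, tuple[int, int]] = {}

    def note_marks(slot: int, slot_start: int) -> None:
        for b, off in marks.get(slot, []):
            s0, e0 = slot_start + off + 1, slot_start + off + len(b.core)
            if b.kind == "ssr":
                truth.ssrs.append((b.label, len(b.label), s0, e0))
            elif b.kind == "tandem":
                truth.tandems.append((b.label, len(b.label), s0, e0))
            else:
                orient, pair, _which = b.label.split(":")
                key = f"{orient}:{pair}"
                if key in disp_pending:
                    p1 = disp_pending.pop(key)
                    truth.dispersed.append((orient, len(b.core),
                                            min(p1[0], s0), max(p1[0], s0)))
                else:
                    disp_pending[key] = (s0, e0)

    for i, (name, cls) in enumerate(order):
        if i in overlap_at:
            size = overlap_at[i]
            start = pos - size
            parts.append(gene_seqs[name][size:])
            pos = start + len(gene_seqs[name])
        else:
            note_marks(i, pos)
            parts.append(spacer_strs[i])
            pos += len(spacer_strs[i])
            start = pos
            parts.append(revcomp(gene_seqs[name]) if name in LIGHT_CHAIN
                         else gene_seqs[name])
            pos += len(gene_seqs[name])
        strand = "-" if name in LIGHT_CHAIN else "+"
        features.append(GeneFeature(
            name=name, gene_class=cls, strand=strand,
            intervals=((start + 1, start + len(gene_seqs[name])),),
            transl_table=cfg.transl_table))
        truth.gene_layout.append((name, cls, start + 1,
                                  start + len(gene_seqs[name]), strand))
    note_marks(n_genes, pos)
    parts.append(spacer_strs[n_genes])

    truth.cds = {n: gene_seqs[n] for n, c in order if c in ("PCG", "ORF")}
    genome = AnnotatedGenome(cfg.genome_id, cfg.organelle, "circular",
                             "".join(parts), features, cfg.taxon)
    return genome, truth


def _scan(rng: np.random.Generator, lo: int, hi: int):
    """Indices in [lo, hi) starting from a random point, wrapping once."""
    if hi <= lo:
        return
    start = int(rng.integers(lo, hi))
    for k in range(hi - lo):
        yield lo + (start - lo + k) % (hi - lo)


# ---------------------------------------------------------------------------
# homolog panels for editing prediction


def plant_edit_panel(cds_set: list[CodingSequence], truth: TruthRecord,
                     panel_size: int = 6, agreement: float = 1.0,
                     seed: int = 0) -> dict[str, list[str]]:
    """Build per-gene aligned homolog protein panels consistent with the
    planted edits.

    The panel consensus carries the *edited* amino acid at every planted
    site and the genomic amino acid elsewhere; each panel member then
    disagrees with the consensus independently at rate ``1 − agreement``.
    """
    if panel_size < 2:
        raise ValueError("panel needs at least 2 members")
    rng = np.random.default_rng(seed)
    by_gene: dict[str, list[dict]] = {}
    for e in truth.edits:
        by_gene.setdefault(e["gene"], []).append(e)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    panels: dict[str, list[str]] = {}
    for cds in cds_set:
        base = list(cds.aa[:-1] if cds.aa.endswith("*") else cds.aa)
        n_c = cds.nt.count("C")
        if len(by_gene.get(cds.gene, [])) > n_c:
            raise ValueError(f"more edits than C positions in {cds.gene}")
        for e in by_gene.get(cds.gene, []):
            base[e["codon_index"] - 1] = e["edited_aa"]
        members = []
        for _ in range(panel_size):
            row = list(base)
            for i in range(len(row)):
                if rng.random() > agreement:
                    choices = [a for a in alphabet if a != base[i]]
                    row[i] = choices[int(rng.integers(len(choices)))]
            members.append("".join(row))
        panels[cds.gene] = members
    return panels


# ---------------------------------------------------------------------------
# clade panels with planted diagnostic SNPs


@dataclass
class CladeConfig:
    seed: int = 0
    genome: SimConfig = field(default_factory=SimConfig)
    level: str = "subgenus"
    groups: dict[str, int] = field(
        default_factory=lambda: {"Bactrophycus": 7, "Sargassum": 7})
    nonsyn_sites: int = 89
    syn_sites: int = 108
    private_per_species: int = 0
    private_nonsyn_fraction: float = 0.4
    sections: dict[str, str] = field(default_factory=dict)  # species -> sect


def _pick_syn_site(nt: str, used: set[int], rng: np.random.Generator,
                   transl_table: int):
    from .kaks import classify_degeneracy
    aa_map = codon_to_aa(transl_table)
    for ci in _scan(rng, 2, len(nt) // 3):
        if ci in used:
            continue
        codon = nt[3 * (ci - 1):3 * ci]
        if codon in aa_map and \
                classify_degeneracy(codon, 3, transl_table) == 4:
            anc = codon[2]
            der = {"A": "G", "G": "A", "C": "T", "T": "C"}[anc]
            return ci, 3, anc, der
    return None


def _pick_nonsyn_site(nt: str, used: set[int], rng: np.random.Generator,
                      transl_table: int):
    aa_map = codon_to_aa(transl_table)
    stops = stop_codons(transl_table)
    for ci in _scan(rng, 2, len(nt) // 3):
        if ci in used:
            continue
        codon = nt[3 * (ci - 1):3 * ci]
        if codon not in aa_map:
            continue
        for p in (1, 2, 3):
            for b in "ACGT":
                if b == codon[p - 1]:
                    continue
                alt = codon[:p - 1] + b + codon[p:]
                if alt not in stops and aa_map[alt] != aa_map[codon]:
                    return ci, p, codon[p - 1], b
    return None


def generate_clade_panel(cfg: CladeConfig
                         ) -> tuple[list[AnnotatedGenome], TruthRecord]:
    """A panel of genomes descended from one synthetic ancestor with
    planted group-diagnostic and species-private substitutions.

    Substitutions are single-base changes at chosen degeneracy classes
    (four-fold third positions for synonymous, amino-acid-changing first
    or second positions otherwise), so their effect is exact by
    construction; each planted site is recorded with its gene, codon
    coordinates, effect and the group fixed for the derived allele.
    Only plus-strand coding genes receive substitutions, keeping genomic
    and CDS coordinates trivially congruent.
    """
    if len(cfg.groups) < 2:
        raise ValueError("clade spec needs at least 2 groups")
    rng = np.random.default_rng(cfg.seed)
    genome, truth = generate_genome(replace(cfg.genome, seed=cfg.seed + 1))

    species: list[tuple[str, str]] = []
    for grp, n in sorted(cfg.groups.items()):
        species.extend((f"{grp}_sp{i + 1}", grp) for i in range(n))
    truth.tree_groups = {g: [s for s, gg in species if gg == g]
                         for g in cfg.groups}

    plus_genes = [f for f in genome.features
                  if f.gene_class in ("PCG", "ORF") and f.strand == "+"]
    used: dict[str, set[int]] = {f.name: set() for f in plus_genes}
    seqs = {sp: list(genome.sequence) for sp, _ in species}
    groups = sorted(cfg.groups)

    def plant(effect: str, carriers: list[str], tag: tuple[str, str]):
        for feat in (plus_genes[int(rng.integers(len(plus_genes)))]
                     for _ in range(300)):
            nt = truth.cds[feat.name]
            picker = (_pick_syn_site if effect == "synonymous"
                      else _pick_nonsyn_site)
            site = picker(nt, used[feat.name], rng, cfg.genome.transl_table)
            if site is None:
                continue
            ci, p, anc, der = site
            used[feat.name].add(ci)
            gpos = feat.start + 3 * (ci - 1) + (p - 1)
            for sp in carriers:
                seqs[sp][gpos - 1] = der
            truth.snp_sites.append({
                "gene": feat.name, "codon_index": ci, "codon_pos": p,
                "cds_pos": 3 * (ci - 1) + p, "genome_pos": gpos,
                "ancestral": anc, "derived": der, "effect": effect,
                "level": tag[0], "group": tag[1]})
            return
        raise ValueError("substitution budget exceeds sequence capacity")

    specs = (["nonsynonymous"] * cfg.nonsyn_sites
             + ["synonymous"] * cfg.syn_sites)
    for k, effect in enumerate(specs):
        grp = groups[k % len(groups)]
        plant(effect, truth.tree_groups[grp], (cfg.level, grp))

    if cfg.private_per_species:
        n_non = int(round(cfg.private_per_species
                          * cfg.private_nonsyn_fraction))
        for sp, _ in species:
            for j in range(cfg.private_per_species):
                eff = "nonsynonymous" if j < n_non else "synonymous"
                plant(eff, [sp], ("species", sp))

    genomes = []
    for sp, grp in species:
        lab = TaxonLabel(species=sp, genus="Sargassum", subgenus=grp,
                         section=cfg.sections.get(sp, ""), order="Fucales",
                         family="Sargassaceae")
        genomes.append(AnnotatedGenome(
            sp, genome.organelle, genome.topology, "".join(seqs[sp]),
            list(genome.features), lab))
    return genomes, truth


# ---------------------------------------------------------------------------
# pairwise CDS divergence with a planted dN/dS


_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _lwl_sites(nt: str, transl_table: int) -> tuple[float, float]:
    """Synonymous and non-synonymous site counts of one CDS under the
    degeneracy-class convention (S = L2/3 + L4, N = L0 + 2·L2/3),
    interior codons only."""
    from .kaks import classify_degeneracy
    aa_map = codon_to_aa(transl_table)
    L = {0: 0, 2: 0, 4: 0}
    for ci in range(1, len(nt) // 3 - 1):
        codon = nt[3 * ci:3 * ci + 3]
        if codon not in aa_map:
            continue
        for pos in (1, 2, 3):
            L[classify_degeneracy(codon, pos, transl_table)] += 1
    return L[2] / 3 + L[4], L[0] + 2 * L[2] / 3


from functools import lru_cache


@lru_cache(maxsize=None)
def _codon_change_table(transl_table: int = 1
                        ) -> dict[str, tuple[tuple[tuple[int, str], ...],
                                             tuple[tuple[int, str], ...]]]:
    """Per-codon single-base changes whose effect is unambiguous in the
    degeneracy-class bookkeeping: synonymous changes at four-fold sites or
    as two-fold-site transitions; non-synonymous, non-stop changes at
    zero-fold sites or as two-fold-site transversions."""
    from .kaks import classify_degeneracy
    aa_map = codon_to_aa(transl_table)
    stops = stop_codons(transl_table)
    table = {}
    for codon in aa_map:
        syn, non = [], []
        for p in range(3):
            cls = classify_degeneracy(codon, p + 1, transl_table)
            for b in "ACGT":
                if b == codon[p]:
                    continue
                alt = codon[:p] + b + codon[p + 1:]
                if alt in stops:
                    continue
                is_ts = _TS_PARTNER[codon[p]] == b
                same = aa_map[alt] == aa_map[codon]
                cls_alt = classify_degeneracy(alt, p + 1, transl_table)
                # booked synonymous on one side iff four-fold, or a
                # transition at a two-fold site; keep only changes booked
                # the same way from both codons' viewpoints
                booked = tuple(c == 4 or (c == 2 and is_ts)
                               for c in (cls, cls_alt))
                if same and booked == (True, True):
                    syn.append((p, b))
                elif not same and booked == (False, False):
                    non.append((p, b))
        table[codon] = (tuple(syn), tuple(non))
    return table


def _change_sets(s: list[str], transl_table: int
                 ) -> tuple[list[tuple[int, str]], list[tuple[int, str]]]:
    table = _codon_change_table(transl_table)
    syn: list[tuple[int, str]] = []
    non: list[tuple[int, str]] = []
    for ci in range(1, len(s) // 3 - 1):
        codon = s[3 * ci] + s[3 * ci + 1] + s[3 * ci + 2]
        entry = table.get(codon)
        if entry is None:
            continue
        syn.extend((3 * ci + p, b) for p, b in entry[0])
        non.extend((3 * ci + p, b) for p, b in entry[1])
    return syn, non


def evolve_cds(nt: str, n_substitutions: int, omega: float,
               rng: np.random.Generator, transl_table: int = 1) -> str:
    """Evolve a CDS so the planted substitution-rate ratio equals ω in
    the degeneracy-class site currency.

    The budget is split so that (non-synonymous events / N) equals
    ω·(synonymous events / S), with S and N the ancestor's two- and
    four-fold site tallies (S = L2/3 + L4, N = L0 + 2·L2/3).  Each event
    is then drawn uniformly from the current truly-synonymous
    (four-fold, or transition at a two-fold site) or truly-non-synonymous
    (zero-fold, or transversion at a two-fold site; never creating a
    stop) single-base changes, so every planted event is booked in the
    class that matches its real effect.  Start/stop codons are never
    touched; multiple hits at one site are allowed.
    """
    s = list(nt)
    if len(nt) // 3 < 4:
        raise ValueError("CDS too short to evolve")
    S, N = _lwl_sites(nt, transl_table)
    x = n_substitutions * omega * N / (omega * N + S)
    n_non = int(x) + (1 if rng.random() < x - int(x) else 0)
    n_syn = n_substitutions - n_non
    events = ["non"] * n_non + ["syn"] * n_syn
    rng.shuffle(events)
    hit: set[int] = set()  # one substitution per codon keeps booking exact
    for kind in events:
        syn, non = _change_sets(s, transl_table)
        choices = [(pos, b) for pos, b in (syn if kind == "syn" else non)
                   if pos // 3 not in hit]
        if not choices:
            raise RuntimeError("no eligible change left to plant")
        pos, b = choices[int(rng.integers(len(choices)))]
        s[pos] = b
        hit.add(pos // 3)
    return "".join(s)
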