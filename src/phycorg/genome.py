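"""Domain types and I/O for annotated organellar genomes.

The central object is :class:`AnnotatedGenome`: a circular (or linear) DNA
molecule together with typed gene features and a taxonomic label.  All
coordinates are 1-based inclusive, the GenBank convention.  Features on
circular molecules may cross the origin; such features are normalized into
an ordered list of intervals (e.g. ``join(900..1000,1..50)`` becomes
``[(900, 1000), (1, 50)]``) kept in biological (5'→3' on the annotated
strand reading) order.

Reading and writing of GenBank flat files is delegated to Biopython; this
module only maps between Biopython records and the normalized domain types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
#: Unambiguous bases; everything else is excluded from GC and codon counts.
UNAMBIGUOUS = set("ACGT")

GENE_CLASSES = ("PCG", "tRNA", "rRNA", "ORF", "tmRNA", "intron")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TaxonLabel:
    """Taxonomic hierarchy of one genome; empty strings mean 'not assigned'.

    ``species`` must be non-empty; ``subgenus`` and ``section`` are the
    intrageneric ranks used in Sargassum classification and are optional.
    """

    species: str
    order: str = ""
    family: str = ""
    genus: str = ""
    subgenus: str = ""
    section: str = ""

    def __post_init__(self):
        if not self.species:
            raise ValueError("TaxonLabel.species must be non-empty")

    def level(self, name: str) -> str:
        """Return the group name of this taxon at a rank ('order', ...,
        'species')."""
        return getattr(self, name)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene.

    ``intervals`` is a list of (start, end) pairs, 1-based inclusive, in
    biological order; a circular feature that crosses the origin carries two
    intervals.  ``strand`` '-' means the coding sequence is the reverse
    complement of the interval (the "light chain").
    """

    name: str
    gene_class: str
    strand: str
    intervals: tuple[tuple[int, int], ...]
    codon_start: int = 1
    transl_table: int = 1

    def __post_init__(self):
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene_class {self.gene_class!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for s, e in self.intervals:
            if s < 1 or e < s:
                raise ValueError(f"bad interval ({s}, {e}) in {self.name}")

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    @property
    def start(self) -> int:
        """Genomic position of the first annotated base (biological order)."""
        return self.intervals[0][0]

    def wraps(self) -> bool:
        return len(self.intervals) > 1 and self.intervals[0][1] > self.intervals[-1][0]


@dataclass
class CodingSequence:
    """An in-frame CDS with its translation.

    Flags record annotation oddities instead of raising: a non-ATG start
    codon, an internal stop, or a length not divisible by three (incomplete).
    """

    gene: str
    genome_id: str
    nt: str
    aa: str
    transl_table: int = 1
    strand: str = "+"
    non_atg_start: bool = False
    internal_stop: bool = False
    incomplete: bool = False


@dataclass
class AnnotatedGenome:
    id: str
    organelle: str  # "mt" | "cp"
    topology: str  # "circular" | "linear"
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    taxon: TaxonLabel | None = None

    def __post_init__(self):
        bad = set(self.sequence.upper()) - IUPAC_DNA
        if bad:
            raise ValueError(f"non-IUPAC symbols in sequence: {sorted(bad)}")
        self.sequence = self.sequence.upper()
        for f in self.features:
            for s, e in f.intervals:
                if e > len(self.sequence):
                    raise ValueError(
                        f"feature {f.name} interval ({s}, {e}) exceeds "
                        f"genome length {len(self.sequence)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice; wraps the origin when start > end on a
        circular molecule."""
        if start <= end:
            return self.sequence[start - 1:end]
        if self.topology != "circular":
            raise ValueError("origin-wrapping slice on a linear genome")
        return self.sequence[start - 1:] + self.sequence[:end]

    def feature_seq(self, feat: GeneFeature) -> str:
        """Feature sequence in biological orientation (reverse-complemented
        for strand '-')."""
        parts = [self.slice(s, e) for s, e in feat.intervals]
        seq = "".join(parts)
        return revcomp(seq) if feat.strand == "-" else seq


def gc_content(seq: str) -> float:
    """GC fraction; IUPAC ambiguity codes are excluded from both numerator
    and denominator.  Raises on an empty (or all-ambiguous) sequence."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    n = sum(seq.count(b) for b in "ACGT")
    if n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / n


def rotate(genome: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Rotate a circular genome so that old position ``offset + 1`` becomes
    position 1.  Feature content is preserved; coordinates shift mod L."""
    if genome.topology != "circular":
        raise ValueError("can only rotate a circular genome")
    L = genome.length
    offset %= L
    seq = genome.sequence[offset:] + genome.sequence[:offset]

    def shift(p: int) -> int:
        return (p - 1 - offset) % L + 1

    feats = []
    for f in genome.features:
        ivs: list[tuple[int, int]] = []
        for s, e in f.intervals:
            ns, ne = shift(s), shift(e)
            if ns <= ne:
                ivs.append((ns, ne))
            else:  # interval now crosses the new origin: split
                ivs.append((ns, L))
                ivs.append((1, ne))
        # merge intervals that became contiguous across the old origin
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and merged[-1][1] + 1 == s:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        feats.append(replace(f, intervals=tuple(merged)))
    return AnnotatedGenome(genome.id, genome.organelle, genome.topology,
                           seq, feats, genome.taxon)


# ---------------------------------------------------------------------------
# CDS extraction


def extract_cds(genome: AnnotatedGenome,
                gene_class: str = "PCG") -> list[CodingSequence]:
    """Extract in-frame coding sequences for every feature of ``gene_class``.

    The terminal stop codon is retained.  Features whose length (after the
    codon_start correction) is not divisible by three are flagged
    ``incomplete`` and excluded from downstream codon statistics by callers;
    non-ATG starts and internal stops are flagged but kept.
    """
    out = []
    for f in genome.features:
        if f.gene_class != gene_class:
            continue
        nt = genome.feature_seq(f)[f.codon_start - 1:]
        incomplete = len(nt) % 3 != 0
        if incomplete:
            log.warning("CDS %s length %d not divisible by 3; flagged "
                        "incomplete", f.name, len(nt))
            nt = nt[: len(nt) - len(nt) % 3]
        aa = str(Seq(nt).translate(table=f.transl_table))
        internal_stop = "*" in aa[:-1]
        non_atg = not nt.startswith("ATG")
        out.append(CodingSequence(
            gene=f.name, genome_id=genome.id, nt=nt, aa=aa,
            transl_table=f.transl_table, strand=f.strand,
            non_atg_start=non_atg, internal_stop=internal_stop,
            incomplete=incomplete))
    return out


# ---------------------------------------------------------------------------
# GenBank I/O

_CLASS_TO_KEY = {"PCG": "CDS", "ORF": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                 "tmRNA": "tmRNA", "intron": "intron"}


def _location_to_intervals(loc) -> tuple[tuple[int, int], ...]:
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    return tuple((int(p.start) + 1, int(p.end)) for p in parts)


def _intervals_to_location(feat: GeneFeature) -> SimpleLocation | CompoundLocation:
    strand = 1 if feat.strand == "+" else -1
    parts = [SimpleLocation(s - 1, e, strand) for s, e in feat.intervals]
    if strand == -1:
        # GenBank complement(join(...)) lists parts in genomic order;
        # biological order for '-' features is the reverse.
        parts = parts[::-1]
    if len(parts) == 1:
        return parts[0]
    return CompoundLocation(parts)


def _infer_class(key: str, name: str) -> str | None:
    if key == "CDS":
        return "ORF" if name.lower().startswith("orf") else "PCG"
    if key in ("tRNA", "rRNA", "tmRNA", "intron"):
        return key
    return None


def read_genbank(path) -> AnnotatedGenome:
    """Parse a GenBank flat file into a normalized :class:`AnnotatedGenome`.

    ``join()`` and origin-wrapping locations are resolved into interval
    lists; gene_class is inferred from the feature key (CDS features named
    ``orf*`` become ORFs); topology comes from the LOCUS line.
    """
    rec = SeqIO.read(path, "genbank")
    if len(rec.seq) == 0:
        raise ValueError(f"{path}: record has no sequence")
    topology = rec.annotations.get("topology", "linear")
    organelle, taxon = "mt", None
    feats: list[GeneFeature] = []
    for sf in rec.features:
        if sf.type == "source":
            q = sf.qualifiers
            organelle = {"mitochondrion": "mt", "plastid": "cp"}.get(
                q.get("organelle", [""])[0], "mt")
            species = q.get("organism", [""])[0]
            ranks = dict(kv.split("=", 1) for kv in q.get("note", [])
                         if "=" in kv)
            if species:
                taxon = TaxonLabel(species=species,
                                   order=ranks.get("order", ""),
                                   family=ranks.get("family", ""),
                                   genus=ranks.get("genus", ""),
                                   subgenus=ranks.get("subgenus", ""),
                                   section=ranks.get("section", ""))
            continue
        name = (sf.qualifiers.get("gene") or sf.qualifiers.get("product")
                or sf.qualifiers.get("locus_tag") or [""])[0]
        cls = _infer_class(sf.type, name)
        if cls is None:
            continue
        if sf.location is None:
            raise ValueError(f"{path}: feature {name!r} has a malformed location")
        ivs = _location_to_intervals(sf.location)
        strand = "-" if sf.location.strand == -1 else "+"
        if strand == "-" and len(ivs) > 1:
            ivs = ivs[::-1]  # back to biological order
        feats.append(GeneFeature(
            name=name, gene_class=cls, strand=strand, intervals=ivs,
            codon_start=int(sf.qualifiers.get("codon_start", ["1"])[0]),
            transl_table=int(sf.qualifiers.get("transl_table", ["1"])[0])))
    return AnnotatedGenome(rec.id or rec.name, organelle, topology,
                           str(rec.seq), feats, taxon)


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Emit a GenBank record that :func:`read_genbank` round-trips."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    src_q = {"organelle": ["mitochondrion" if genome.organelle == "mt"
                           else "plastid"]}
    if genome.taxon is not None:
        t = genome.taxon
        src_q["organism"] = [t.species]
        # one note per rank: GenBank line wrapping must not split tokens
        src_q["note"] = [f"{k}={getattr(t, k)}"
                         for k in ("order", "family", "genus", "subgenus",
                                   "section")]
    rec.features.append(SeqFeature(
        SimpleLocation(0, genome.length, 1), type="source", qualifiers=src_q))
    for f in genome.features:
        q = {"gene": [f.name]}
        key = _CLASS_TO_KEY[f.gene_class]
        if key == "CDS":
            q["codon_start"] = [str(f.codon_start)]
            q["transl_table"] = [str(f.transl_table)]
        rec.features.append(SeqFeature(_intervals_to_location(f), type=key,
                                       qualifiers=q))
    with open(path, "w") as fh:
        SeqIO.write(rec, fh, "genbank")
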