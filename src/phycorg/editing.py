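"""Homology-guided C-to-U RNA-editing prediction and classification.

The predictor follows the PREP idea: a genomic C is called an editing site
when changing it to T (U in the transcript) converts the encoded amino acid
into the one conserved across a panel of homologous proteins.  Only
non-synonymous C→T candidates are scorable this way — a synonymous edit
leaves the protein unchanged and is invisible to homology — so synonymous
edits are excluded by design.

Classification of a predicted edit into hydropathy categories uses a fixed
lookup of (reference aa → edited aa) pairs; pairs outside the lookup fall
back to the sign of the Kyte–Doolittle index and are flagged extrapolated.
The lookup deliberately keeps R→W in the unchanged-hydrophobic category
(conventionally R is hydrophilic) so that published organellar edit-type
tallies reproduce; the flag on the site records that the assignment came
from the pinned table rather than the hydropathy scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio import Align

from .genome import CodingSequence
from .codon import codon_to_aa, stop_codons

UNCHANGED_HYDROPHILIC = "unchanged-hydrophilic"
UNCHANGED_HYDROPHOBIC = "unchanged-hydrophobic"
BECAME_HYDROPHOBIC = "became-hydrophobic"
BECAME_HYDROPHILIC = "became-hydrophilic"

CATEGORIES = (UNCHANGED_HYDROPHILIC, UNCHANGED_HYDROPHOBIC,
              BECAME_HYDROPHOBIC, BECAME_HYDROPHILIC)

#: Pinned (ref_aa, edited_aa) → category assignments for the edit types
#: observed in brown-algal organelles.
_CATEGORY_LOOKUP: dict[tuple[str, str], str] = {
    ("H", "Y"): UNCHANGED_HYDROPHILIC,
    ("R", "C"): UNCHANGED_HYDROPHILIC,
    ("L", "F"): UNCHANGED_HYDROPHOBIC,
    ("R", "W"): UNCHANGED_HYDROPHOBIC,
    ("P", "L"): UNCHANGED_HYDROPHOBIC,
    ("A", "V"): UNCHANGED_HYDROPHOBIC,
    ("T", "M"): BECAME_HYDROPHOBIC,
    ("S", "L"): BECAME_HYDROPHOBIC,
    ("S", "F"): BECAME_HYDROPHOBIC,
    ("T", "I"): BECAME_HYDROPHOBIC,
    ("P", "S"): BECAME_HYDROPHILIC,
}

#: Kyte–Doolittle hydropathy index (positive = hydrophobic).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


@dataclass
class EditSite:
    """One predicted C→U event.  ``codon_index`` is 1-based over the CDS;
    ``codon_pos`` is the edited position within the codon (1–3)."""

    gene: str
    codon_index: int
    codon_pos: int
    ref_codon: str
    edited_codon: str
    ref_aa: str
    edited_aa: str
    support: float
    category: str = ""
    extrapolated: bool = False

    def __post_init__(self):
        diffs = [p for p in range(3)
                 if self.ref_codon[p] != self.edited_codon[p]]
        if diffs != [self.codon_pos - 1] or \
                self.ref_codon[self.codon_pos - 1] != "C" or \
                self.edited_codon[self.codon_pos - 1] != "T":
            raise ValueError(
                f"{self.ref_codon}->{self.edited_codon} is not a single "
                f"C->T change at codon position {self.codon_pos}")
        if self.ref_aa == self.edited_aa:
            raise ValueError("synonymous edit violates EditSite invariant")


def classify_edit(ref_aa: str, edited_aa: str) -> tuple[str, bool]:
    """Category of an amino-acid change; the boolean flags pairs outside
    the pinned lookup (classified by Kyte–Doolittle sign)."""
    if ref_aa == edited_aa:
        raise ValueError("synonymous edit has no category")
    key = (ref_aa, edited_aa)
    if key in _CATEGORY_LOOKUP:
        return _CATEGORY_LOOKUP[key], False
    ref_hb = KYTE_DOOLITTLE[ref_aa] > 0
    new_hb = KYTE_DOOLITTLE[edited_aa] > 0
    if ref_hb == new_hb:
        return (UNCHANGED_HYDROPHOBIC if ref_hb
                else UNCHANGED_HYDROPHILIC), True
    return (BECAME_HYDROPHOBIC if new_hb else BECAME_HYDROPHILIC), True


# ---------------------------------------------------------------------------
# prediction


def _column_map(panel: list[str], translation: str,
                identity_floor: float) -> list[int | None]:
    """Map each position of ``translation`` to a panel alignment column.

    Columns gapped in ≥50% of panel members are skipped.  If the remaining
    column count equals the translation length the mapping is positional;
    otherwise the translation is globally aligned to the column-majority
    consensus.  Raises when identity to the consensus is below the floor
    (mis-orthology guard).
    """
    ncol = len(panel[0])
    kept = [j for j in range(ncol)
            if sum(row[j] == "-" for row in panel) / len(panel) < 0.5]
    cons = []
    for j in kept:
        col = [row[j] for row in panel if row[j] != "-"]
        cons.append(Counter(col).most_common(1)[0][0])
    consensus = "".join(cons)

    if len(kept) == len(translation):
        pairs = list(zip(range(len(translation)), range(len(kept))))
    else:
        aligner = Align.PairwiseAligner(mode="global", open_gap_score=-10,
                                        extend_gap_score=-0.5,
                                        match_score=1, mismatch_score=-1)
        aln = aligner.align(translation, consensus)[0]
        pairs = []
        for (qs, qe), (ts, te) in zip(*aln.aligned):
            pairs.extend(zip(range(qs, qe), range(ts, te)))
    ident = sum(translation[i] == consensus[j] for i, j in pairs)
    if not pairs or ident / len(translation) < identity_floor:
        raise ValueError(
            "CDS translation does not align to the homolog panel "
            f"(identity {ident / max(len(translation), 1):.2f} < "
            f"{identity_floor})")
    mapping: list[int | None] = [None] * len(translation)
    for i, j in pairs:
        mapping[i] = kept[j]
    return mapping


def predict_edits(cds: CodingSequence, panel: list[str],
                  threshold: float = 0.8,
                  identity_floor: float = 0.5) -> list[EditSite]:
    """Predict C→U editing sites on one CDS against an aligned protein
    panel.

    A site is predicted iff the edited amino acid matches at least
    ``threshold`` of the homologs at its aligned column while the unedited
    amino acid matches fewer than ``threshold``.  Sites are reported
    5'→3'.  ``threshold`` must be in (0.5, 1].
    """
    if not panel or len(panel) < 2:
        raise ValueError("homolog panel must contain at least 2 proteins")
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    if len({len(p) for p in panel}) != 1:
        raise ValueError("panel proteins must be aligned (equal length)")
    stops = stop_codons(cds.transl_table)
    aa_map = codon_to_aa(cds.transl_table)

    translation = cds.aa[:-1] if cds.aa.endswith("*") else cds.aa
    mapping = _column_map(panel, translation, identity_floor)

    sites: list[EditSite] = []
    for i in range(len(translation)):
        codon = cds.nt[3 * i:3 * i + 3]
        if codon in stops or codon not in aa_map:
            continue
        ref_aa = aa_map[codon]
        col = mapping[i]
        if col is None:
            continue
        column = [row[col] for row in panel if row[col] != "-"]
        if not column:
            continue
        for p in range(3):
            if codon[p] != "C":
                continue
            edited = codon[:p] + "T" + codon[p + 1:]
            if edited in stops:
                continue
            edited_aa = aa_map[edited]
            if edited_aa == ref_aa:
                continue  # synonymous: undetectable by homology
            support = sum(a == edited_aa for a in column) / len(column)
            unedited = sum(a == ref_aa for a in column) / len(column)
            if support >= threshold and unedited < threshold:
                cat, extra = classify_edit(ref_aa, edited_aa)
                sites.append(EditSite(
                    gene=cds.gene, codon_index=i + 1, codon_pos=p + 1,
                    ref_codon=codon, edited_codon=edited,
                    ref_aa=ref_aa, edited_aa=edited_aa,
                    support=support, category=cat, extrapolated=extra))
    return sites


# ---------------------------------------------------------------------------
# summaries


@dataclass
class EditSummary:
    total: int
    transition_counts: Counter  # (ref_codon, edited_codon) -> count
    category_counts: Counter
    category_percent: dict[str, float]
    position_counts: Counter  # codon position (1..3) -> count
    position_percent: dict[int, float]
    gene_counts: Counter = field(default_factory=Counter)
    density_percent: float = 0.0  # 100 * edits / genome length


def _codon_pos(ref: str, edited: str) -> int:
    diffs = [p for p in range(3) if ref[p] != edited[p]]
    if len(diffs) != 1 or ref[diffs[0]] != "C" or edited[diffs[0]] != "T":
        raise ValueError(f"{ref}->{edited} is not a single C->T change")
    return diffs[0] + 1


def summarize_edits(sites, genome_length: int,
                    transl_table: int = 1) -> EditSummary:
    """Tally edits by transition type, category, codon position and gene.

    ``sites`` is either a list of :class:`EditSite` or a list of
    ``(ref_codon, edited_codon, count)`` rows (a published summary table
    re-used as input).  ``density_percent`` is 100·(#edits)/genome length.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if not sites:
        raise ValueError("empty edit collection")
    aa_map = codon_to_aa(transl_table)
    transitions: Counter = Counter()
    cats: Counter = Counter()
    positions: Counter = Counter()
    genes: Counter = Counter()
    total = 0
    for item in sites:
        if isinstance(item, EditSite):
            ref, edited, n = item.ref_codon, item.edited_codon, 1
            cat = item.category or classify_edit(item.ref_aa,
                                                 item.edited_aa)[0]
            genes[item.gene] += 1
        else:
            ref, edited, n = item
            ref, edited = ref.upper().replace("U", "T"), \
                edited.upper().replace("U", "T")
            cat = classify_edit(aa_map[ref], aa_map[edited])[0]
        transitions[(ref, edited)] += n
        cats[cat] += n
        positions[_codon_pos(ref, edited)] += n
        total += n
    return EditSummary(
        total=total, transition_counts=transitions, category_counts=cats,
        category_percent={c: 100 * cats[c] / total for c in CATEGORIES},
        position_counts=positions,
        position_percent={p: 100 * positions[p] / total for p in (1, 2, 3)},
        gene_counts=genes,
        density_percent=100 * total / genome_length)
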