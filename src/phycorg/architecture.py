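"""Genome-architecture statistics: gene inventories, coding fraction,
pairwise gene overlaps, intergenic-spacer totals, and gene order.

All span arithmetic is done on circular topology via interval lists; a
wrap-around feature contributes two linear intervals.  The bookkeeping
invariant is that the union of all feature spans plus the spacer total
tiles the genome exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .genome import AnnotatedGenome, GeneFeature


def _linear_intervals(feat: GeneFeature) -> list[tuple[int, int]]:
    return list(feat.intervals)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _union_len(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in _merge(intervals))


def _intersect_len(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                total += hi - lo + 1
    return total


@dataclass
class GenomeSummary:
    genome_id: str
    length: int
    gc: float
    class_counts: dict[str, int]
    pcg_fraction: float
    overlap_pairs: list[tuple[str, str, int]]
    overlap_total: int
    spacer_total: int
    coding_coverage: int = 0

    def as_row(self) -> dict:
        row = {"genome_id": self.genome_id, "length": self.length,
               "gc": round(self.gc, 4),
               "pcg_fraction": round(self.pcg_fraction, 4),
               "overlap_total": self.overlap_total,
               "spacer_total": self.spacer_total,
               "genes": sum(self.class_counts.values())}
        row.update(self.class_counts)
        return row


def summarize_genome(genome: AnnotatedGenome) -> GenomeSummary:
    """Compute the Table-1-style architecture summary of one genome.

    * ``spacer_total`` = genome length − |union of all feature spans|
      (intron features count toward the span, so annotated introns do not
      inflate the spacer total).
    * ``pcg_fraction`` = |union of PCG spans| / length (no double counting
      of overlapping genes; intron features are excluded).
    * Overlaps are counted once per unordered pair of distinct named genes.
    """
    from .genome import gc_content

    all_ivs: list[tuple[int, int]] = []
    pcg_ivs: list[tuple[int, int]] = []
    counts: Counter = Counter()
    for f in genome.features:
        counts[f.gene_class] += 1
        all_ivs.extend(_linear_intervals(f))
        if f.gene_class == "PCG":
            pcg_ivs.extend(_linear_intervals(f))

    if not genome.features:
        return GenomeSummary(genome.id, genome.length,
                             gc_content(genome.sequence), {}, 0.0, [], 0,
                             genome.length, 0)

    covered = _union_len(all_ivs)
    spacer = genome.length - covered

    # pairwise overlaps between distinct named genes, each pair once
    pairs: dict[tuple[str, str], int] = {}
    feats = genome.features
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            a, b = feats[i], feats[j]
            if a.name == b.name:
                continue
            ov = _intersect_len(_linear_intervals(a), _linear_intervals(b))
            if ov > 0:
                key = tuple(sorted((a.name, b.name)))
                pairs[key] = pairs.get(key, 0) + ov
    overlap_pairs = sorted((a, b, n) for (a, b), n in pairs.items())
    return GenomeSummary(
        genome_id=genome.id, length=genome.length,
        gc=gc_content(genome.sequence), class_counts=dict(counts),
        pcg_fraction=_union_len(pcg_ivs) / genome.length,
        overlap_pairs=overlap_pairs,
        overlap_total=sum(n for _, _, n in overlap_pairs),
        spacer_total=spacer, coding_coverage=covered)


@dataclass
class GeneOrder:
    genome_id: str
    order: list[tuple[str, str]] = field(default_factory=list)

    def names(self) -> list[str]:
        return [n for n, _ in self.order]

    def contains_run(self, run: list[str]) -> bool:
        """True if ``run`` occurs as a contiguous subsequence of the
        circular gene order (either reading direction)."""
        names = self.names()
        doubled = names + names
        rev = doubled[::-1]
        k = len(run)
        for seq in (doubled, rev):
            for i in range(len(names)):
                if seq[i:i + k] == run:
                    return True
        return False


def gene_order(genome: AnnotatedGenome, anchor: str) -> GeneOrder:
    """Circular gene order rotated so ``anchor`` comes first.

    Ordering key is the genomic position of each feature's first annotated
    base, which makes the result invariant to rotations of the genome.
    """
    feats = sorted(genome.features, key=lambda f: (f.start, f.name))
    names = [f.name for f in feats]
    if anchor not in names:
        raise ValueError(
            f"anchor gene {anchor!r} not found; available: {sorted(names)}")
    i = names.index(anchor)
    ordered = feats[i:] + feats[:i]
    return GeneOrder(genome.id, [(f.name, f.strand) for f in ordered])


@dataclass
class GeneContentReport:
    core: set[str]
    groups: dict[str, dict[str, set[str]]]  # group -> {present, private, missing}
    pairwise: dict[tuple[str, str], tuple[set[str], set[str]]]


def compare_gene_content(genomes: list[AnnotatedGenome],
                         gene_class: str = "PCG") -> GeneContentReport:
    """Venn-style set comparison of gene content, grouped by taxon order.

    ``core`` is the set shared by every genome.  Per group, ``private`` is
    present in every genome of the group and absent everywhere else, and
    ``missing`` is absent from the group but present in every other group
    (the petL-in-Laminariales pattern).
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    per_genome = {}
    for g in genomes:
        names = {f.name for f in g.features if f.gene_class == gene_class}
        if not names:
            raise ValueError(f"genome {g.id} has no {gene_class} genes")
        per_genome[g.id] = (g.taxon.order if g.taxon else "", names)

    core = set.intersection(*(n for _, n in per_genome.values()))
    group_names: dict[str, list[set[str]]] = {}
    for grp, names in per_genome.values():
        group_names.setdefault(grp, []).append(names)
    group_all = {g: set.intersection(*ns) for g, ns in group_names.items()}
    group_any = {g: set.union(*ns) for g, ns in group_names.items()}

    groups = {}
    for g in group_all:
        others_any = set().union(*(group_any[h] for h in group_any if h != g)) \
            if len(group_all) > 1 else set()
        others_all = [group_all[h] for h in group_all if h != g]
        missing = (set.intersection(*others_all) - group_any[g]
                   if others_all else set())
        groups[g] = {"present": group_all[g],
                     "private": group_all[g] - others_any,
                     "missing": missing}

    pairwise = {}
    ids = sorted(per_genome)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = per_genome[ids[i]][1], per_genome[ids[j]][1]
            pairwise[(ids[i], ids[j])] = (a - b, b - a)
    return GeneContentReport(core=core, groups=groups, pairwise=pairwise)
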