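"""Codon-usage-bias suite: codon counts, RSCU, positional GC, Wright's
effective number of codons (ENC), the ENC-GC3 expected curve, neutrality
regression, PR2 coordinates, and ΔRSCU optimal-codon calls.

Codons are held as DNA strings (T, not U) throughout; use :func:`as_rna`
for display.  Stop codons and codons containing ambiguity symbols never
enter RSCU/ENC/GC statistics.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable
from scipy import stats

from .genome import UNAMBIGUOUS, CodingSequence

log = logging.getLogger(__name__)


def as_rna(codon: str) -> str:
    return codon.replace("T", "U")


@lru_cache(maxsize=None)
def code_families(transl_table: int = 1) -> dict[str, tuple[str, ...]]:
    """Synonymous codon families of a genetic code: amino acid → codons
    (stop codons excluded)."""
    table = CodonTable.unambiguous_dna_by_id[transl_table]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in fams.items()}


@lru_cache(maxsize=None)
def codon_to_aa(transl_table: int = 1) -> dict[str, str]:
    return dict(CodonTable.unambiguous_dna_by_id[transl_table].forward_table)


@lru_cache(maxsize=None)
def stop_codons(transl_table: int = 1) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[transl_table].stop_codons)


def iter_codons(nt: str):
    for i in range(0, len(nt) - len(nt) % 3, 3):
        yield nt[i:i + 3]


@dataclass
class CodonUsageTable:
    """64-codon counts with RSCU and amino-acid frequencies.

    ``counts`` holds sense codons only; stop codons are tallied separately
    in ``stop_counts``.  RSCU of a codon is its observed count divided by
    the expected count under uniform use within its synonymous family;
    families never observed are reported as missing, not zero.
    """

    counts: Counter = field(default_factory=Counter)
    stop_counts: Counter = field(default_factory=Counter)
    transl_table: int = 1
    dropped_ambiguous: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def rscu(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for aa, fam in code_families(self.transl_table).items():
            fam_total = sum(self.counts[c] for c in fam)
            if fam_total == 0:
                continue  # unobserved family: RSCU missing
            expected = fam_total / len(fam)
            for c in fam:
                out[c] = self.counts[c] / expected
        return out

    def aa_freq(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {}
        fams = code_families(self.transl_table)
        return {aa: sum(self.counts[c] for c in fam) / tot
                for aa, fam in fams.items()}

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        if self.transl_table != other.transl_table:
            raise ValueError("cannot pool tables with different codes")
        return CodonUsageTable(self.counts + other.counts,
                               self.stop_counts + other.stop_counts,
                               self.transl_table,
                               self.dropped_ambiguous + other.dropped_ambiguous)


def count_codons(cds_set: list[CodingSequence] | list[str],
                 drop_stops: bool = True,
                 transl_table: int = 1) -> CodonUsageTable:
    """Count codons over a set of in-frame CDS.

    Stop codons are excluded from the sense-codon table (tallied apart)
    when ``drop_stops``; codons containing ambiguity symbols are dropped
    and logged.  Raises if no complete codon is found.
    """
    table = CodonUsageTable(transl_table=transl_table)
    stops = stop_codons(transl_table)
    seen = False
    for cds in cds_set:
        nt = cds.nt if isinstance(cds, CodingSequence) else cds
        for codon in iter_codons(nt):
            seen = True
            if set(codon) - UNAMBIGUOUS:
                table.dropped_ambiguous += 1
                continue
            if codon in stops:
                table.stop_counts[codon] += 1
                if not drop_stops:
                    table.counts[codon] += 1
            else:
                table.counts[codon] += 1
    if not seen:
        raise ValueError("no complete codons in input")
    if table.dropped_ambiguous:
        log.warning("dropped %d codons containing ambiguity symbols",
                    table.dropped_ambiguous)
    return table


def rscu(table: CodonUsageTable) -> dict[str, float]:
    return table.rscu()


def high_frequency_codons(table: CodonUsageTable) -> tuple[set[str], float]:
    """Codons with RSCU strictly > 1 and the fraction of all codon
    occurrences falling in that set."""
    values = table.rscu()
    hi = {c for c, v in values.items() if v > 1.0}
    tot = table.total
    frac = sum(table.counts[c] for c in hi) / tot if tot else 0.0
    return hi, frac


# ---------------------------------------------------------------------------
# positional GC and PR2


@dataclass
class PositionalGC:
    gc_all: float
    gc1: float
    gc2: float
    gc3: float
    a3: int
    t3: int
    g3: int
    c3: int

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2


def positional_gc(cds_set: list[CodingSequence] | list[str],
                  transl_table: int = 1) -> PositionalGC:
    """GC content at each codon position over a CDS set; stop codons and
    ambiguous codons are excluded, consistent with :func:`count_codons`.
    Third-position base counts are retained for the PR2 plot."""
    stops = stop_codons(transl_table)
    gc = [0, 0, 0]
    n = 0
    third: Counter = Counter()
    for cds in cds_set:
        nt = cds.nt if isinstance(cds, CodingSequence) else cds
        for codon in iter_codons(nt):
            if codon in stops or set(codon) - UNAMBIGUOUS:
                continue
            n += 1
            for p in range(3):
                if codon[p] in "GC":
                    gc[p] += 1
            third[codon[2]] += 1
    if n == 0:
        raise ValueError("no usable codons")
    g1, g2, g3 = (g / n for g in gc)
    return PositionalGC(gc_all=(gc[0] + gc[1] + gc[2]) / (3 * n),
                        gc1=g1, gc2=g2, gc3=g3,
                        a3=third["A"], t3=third["T"],
                        g3=third["G"], c3=third["C"])


def pr2_point(pg: PositionalGC) -> tuple[float | None, float | None]:
    """Parity-rule-2 coordinates (G3/(G3+C3), A3/(A3+T3)).  (0.5, 0.5) is
    the no-strand-bias centre (A=T, G=C).  A zero denominator yields None
    for that coordinate."""
    x = pg.g3 / (pg.g3 + pg.c3) if pg.g3 + pg.c3 > 0 else None
    y = pg.a3 / (pg.a3 + pg.t3) if pg.a3 + pg.t3 > 0 else None
    return x, y


def neutrality_fit(points: list[tuple[float, float]]
                   ) -> tuple[float, float, float]:
    """OLS regression of GC12 on GC3 over per-gene points.

    Returns (slope, intercept, r).  The slope is read as the share of
    codon-usage bias attributable to mutation pressure.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 (gc3, gc12) points")
    x = [p[0] for p in points]
    y = [p[1] for p in points]
    if max(x) == min(x):
        raise ValueError("zero variance in GC3")
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue


# ---------------------------------------------------------------------------
# effective number of codons


@dataclass
class EncResult:
    gene: str
    enc: float | None
    gc3: float
    n_codons: int
    short: bool = False  # fewer codons than the advisory minimum


def _family_F(counts: list[int]) -> float | None:
    """Wright's homozygosity estimate for one synonymous family."""
    n = sum(counts)
    if n < 2:
        return None
    s = sum((c / n) ** 2 for c in counts)
    F = (n * s - 1) / (n - 1)
    return F if F > 0 else None


def enc_from_counts(counts: Counter, transl_table: int = 1) -> float | None:
    """Wright's Nc from a sense-codon count table.

    Families are grouped by degeneracy (family size 2, 3, 4, 6); the class
    mean homozygosity F̄ is taken over observed families; a missing class is
    imputed from the mean of the available 2- and 4-fold class means (the
    3-fold Ile class per Wright's own rule).  Result capped into [20, 61];
    None when no multi-codon family is usable.
    """
    fams = code_families(transl_table)
    class_F: dict[int, list[float]] = {}
    class_sizes: Counter = Counter(len(f) for f in fams.values())
    for fam in fams.values():
        if len(fam) == 1:
            continue
        F = _family_F([counts[c] for c in fam])
        if F is not None:
            class_F.setdefault(len(fam), []).append(F)
    mean_F = {k: sum(v) / len(v) for k, v in class_F.items()}
    if 2 not in mean_F and 4 not in mean_F:
        return None
    avail = [mean_F[k] for k in (2, 4) if k in mean_F]
    impute = sum(avail) / len(avail)
    nc = class_sizes.get(1, 0) * 1.0
    for k in (2, 3, 4, 6):
        nk = class_sizes.get(k, 0)
        if nk == 0:
            continue
        Fk = mean_F.get(k, impute)
        nc += nk / Fk
    return min(max(nc, 20.0), 61.0)


def enc(cds: CodingSequence, min_codons: int = 30) -> EncResult:
    """Per-gene ENC with its GC3 (for the ENC–GC3 plot)."""
    table = count_codons([cds], transl_table=cds.transl_table)
    pg = positional_gc([cds], transl_table=cds.transl_table)
    short = table.total < min_codons
    if short:
        log.warning("gene %s has only %d codons (< %d); ENC may be noisy",
                    cds.gene, table.total, min_codons)
    return EncResult(gene=cds.gene,
                     enc=enc_from_counts(table.counts, cds.transl_table),
                     gc3=pg.gc3, n_codons=table.total, short=short)


def enc_expected(gc3: float) -> float:
    """Expected ENC under mutation pressure alone:
    Nc = 2 + GC3 + 29 / (GC3² + (1 − GC3)²)."""
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError(f"gc3 must be in [0, 1], got {gc3}")
    return 2 + gc3 + 29 / (gc3 ** 2 + (1 - gc3) ** 2)


# ---------------------------------------------------------------------------
# optimal codons via ΔRSCU between expression pools


@dataclass
class OptimalCodonReport:
    high_pool: list[str]
    low_pool: list[str]
    rscu_high: dict[str, float]
    rscu_low: dict[str, float]
    delta_rscu: dict[str, float]
    optimal: set[str]


def optimal_codons(enc_results: list[EncResult],
                   per_gene_usage: dict[str, CodonUsageTable],
                   delta_threshold: float = 0.08,
                   low_enc_is_high_expression: bool = True
                   ) -> OptimalCodonReport:
    """ΔRSCU optimal-codon identification.

    The top and bottom ENC deciles (ceil(0.10·N) genes each; ties broken by
    gene name) form the expression pools.  By default the lowest-ENC decile
    is the high-expression pool — strongest bias is read as highest
    expression, the standard assumption behind the ΔRSCU method — with a
    flag to invert.  Optimal codons have RSCU > 1 in the high-expression
    pool and ΔRSCU = RSCU_high − RSCU_low ≥ ``delta_threshold``.
    """
    usable = sorted((r for r in enc_results if r.enc is not None),
                    key=lambda r: (r.enc, r.gene))
    if len(usable) < 10:
        raise ValueError(f"need ≥10 genes with defined ENC, got {len(usable)}")
    k = math.ceil(0.10 * len(usable))
    low_enc = [r.gene for r in usable[:k]]
    high_enc = [r.gene for r in usable[-k:]]
    if low_enc_is_high_expression:
        high_pool, low_pool = low_enc, high_enc
    else:
        high_pool, low_pool = high_enc, low_enc

    def pooled(genes: list[str]) -> CodonUsageTable:
        tables = [per_gene_usage[g] for g in genes]
        out = tables[0]
        for t in tables[1:]:
            out = out + t
        return out

    r_hi = pooled(high_pool).rscu()
    r_lo = pooled(low_pool).rscu()
    delta = {c: r_hi[c] - r_lo[c] for c in r_hi if c in r_lo}
    optimal = {c for c, d in delta.items()
               if r_hi[c] > 1.0 and d >= delta_threshold}
    return OptimalCodonReport(sorted(high_pool), sorted(low_pool),
                              r_hi, r_lo, delta, optimal)
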