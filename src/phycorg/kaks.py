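"""Pairwise Ka, Ks and Ka/Ks by degeneracy-class counting.

Two variants are pinned here:

* LWL — the classical counting method: every codon position is classified
  as non-degenerate (0-fold), two-fold or four-fold; transitions at
  two-fold sites are taken as synonymous; per-class transition (P) and
  transversion (Q) proportions receive the Kimura two-parameter
  correction, A = ½ln(1/(1−2P−Q)) − ¼ln(1/(1−2Q)) and B = ½ln(1/(1−2Q));
  then

      Ks = (L2·A2 + L4·(A4+B4)) / (L2/3 + L4)
      Ka = (L2·B2 + L0·(A0+B0)) / (2·L2/3 + L0)

  under the equal-rate assumption that one third of a two-fold site is
  synonymous.

* MLWL — the modified method: the synonymous fraction of a two-fold site
  is weighted by the observed transition/transversion ratio R = ts/tv
  (weight R/(R+1) instead of 1/3), and the sites whose degeneracy runs
  through transversions are reassigned to their own subtypes instead of
  being forced into the transition-degenerate mould:

  - first positions of CGA/CGG/AGA/AGG (one synonymous transversion):
    synonymous site weight 1/(2R+2); half the transversion distance is
    synonymous;
  - third position of ATA (both transversions synonymous, the transition
    is not): weight 1/(R+1); the whole transversion distance is
    synonymous and the transition distance is non-synonymous;
  - third positions of ATT/ATC (transition plus one transversion
    synonymous): weight (2R+1)/(2R+2); transition distance plus half the
    transversion distance is synonymous.

  When no transversions (or no transitions) are observed the weights go
  to their respective limits.

Codons differing at more than one position are resolved by averaging over
all substitution pathways that avoid stop-codon intermediates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import pandas as pd

from .genome import CodingSequence, UNAMBIGUOUS
from .codon import codon_to_aa, stop_codons

_TRANSITIONS = ({"A", "G"}, {"C", "T"})

#: Arg codons whose first position is degenerate through a transversion.
_TV_DEGENERATE_FIRST = {"CGA", "CGG", "AGA", "AGG"}


def is_transition(a: str, b: str) -> bool:
    return {a, b} in _TRANSITIONS


def classify_degeneracy(codon: str, position: int,
                        transl_table: int = 1) -> int:
    """Fold class (0, 2 or 4) of one codon position.

    Counts how many of the three alternative bases preserve the amino
    acid: none → 0-fold, all three → 4-fold, otherwise 2-fold (the 3-fold
    Ile sites land in the 2-fold class, the LWL convention).  Raises on a
    stop codon.
    """
    aa_map = codon_to_aa(transl_table)
    if codon not in aa_map:
        raise ValueError(f"{codon} is a stop codon or invalid")
    p = position - 1
    aa = aa_map[codon]
    preserved = sum(
        1 for b in "ACGT" if b != codon[p]
        and aa_map.get(codon[:p] + b + codon[p + 1:]) == aa)
    return {0: 0, 3: 4}.get(preserved, 2)


@dataclass
class KaKsResult:
    gene: str
    taxon_a: str
    taxon_b: str
    method: str
    L: dict[str, float]  # site counts per class: '0', '2', '2V', '4'
    P: dict[str, float] = field(default_factory=dict)
    Q: dict[str, float] = field(default_factory=dict)
    A: dict[str, float] = field(default_factory=dict)
    B: dict[str, float] = field(default_factory=dict)
    Ka: float | None = None
    Ks: float | None = None
    ratio: float | None = None
    saturated: bool = False
    n_codons: int = 0


def _site_class(codon: str, pos: int, method: str,
                transl_table: int) -> str:
    cls = classify_degeneracy(codon, pos, transl_table)
    if method == "MLWL" and cls == 2:
        if pos == 1 and codon in _TV_DEGENERATE_FIRST:
            return "2V"
        if pos == 3 and codon == "ATA":
            return "2A"
        if pos == 3 and codon in ("ATT", "ATC"):
            return "2B"
    return str(cls)


def _pathways(ca: str, cb: str, diffs: list[int], stops: frozenset[str]):
    """Substitution pathways between two codons, avoiding stop
    intermediates when possible.  Yields lists of (codon_from, pos,
    codon_to) steps."""
    paths = []
    blocked = []
    for order in permutations(diffs):
        cur = ca
        steps = []
        ok = True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1:]
            steps.append((cur, p, nxt))
            if nxt in stops and nxt != cb:
                ok = False
            cur = nxt
        (paths if ok else blocked).append(steps)
    return paths if paths else blocked


def kaks_pair(cds_a: CodingSequence | str, cds_b: CodingSequence | str,
              method: str = "MLWL", transl_table: int = 1,
              gene: str = "", taxon_a: str = "A", taxon_b: str = "B"
              ) -> KaKsResult:
    """Ka, Ks and their ratio for one codon-aligned CDS pair.

    Inputs must be equal length; codons containing gaps, ambiguity symbols
    or stops in either sequence are dropped pairwise.  ``ratio`` is None
    when Ks is 0 (or either distance is saturated).
    """
    if method not in ("LWL", "MLWL"):
        raise ValueError("method must be 'LWL' or 'MLWL'")
    a = cds_a.nt if isinstance(cds_a, CodingSequence) else cds_a
    b = cds_b.nt if isinstance(cds_b, CodingSequence) else cds_b
    if isinstance(cds_a, CodingSequence) and not gene:
        gene = cds_a.gene
    if len(a) != len(b):
        raise ValueError("sequences must be codon-aligned to equal length")
    stops = stop_codons(transl_table)
    classes = ("0", "2", "2V", "2A", "2B", "4")
    L = {c: 0.0 for c in classes}
    ts = {c: 0.0 for c in classes}
    tv = {c: 0.0 for c in classes}
    n_codons = 0
    for i in range(0, len(a) - len(a) % 3, 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if (set(ca) | set(cb)) - UNAMBIGUOUS or ca in stops or cb in stops:
            continue
        n_codons += 1
        for pos in (1, 2, 3):
            L[_site_class(ca, pos, method, transl_table)] += 0.5
            L[_site_class(cb, pos, method, transl_table)] += 0.5
        diffs = [p for p in range(3) if ca[p] != cb[p]]
        if not diffs:
            continue
        paths = _pathways(ca, cb, diffs, stops)
        w = 1.0 / len(paths)
        for steps in paths:
            for cur, p, nxt in steps:
                if cur in stops or nxt in stops:
                    continue
                half = {}
                for c in (cur, nxt):
                    cl = _site_class(c, p + 1, method, transl_table)
                    half[cl] = half.get(cl, 0.0) + 0.5
                bucket = ts if is_transition(cur[p], nxt[p]) else tv
                for cl, frac in half.items():
                    bucket[cl] += w * frac
    if n_codons == 0:
        raise ValueError("no comparable codons")

    res = KaKsResult(gene=gene, taxon_a=taxon_a, taxon_b=taxon_b,
                     method=method, L=L, n_codons=n_codons)
    saturated = False
    A: dict[str, float] = {}
    B: dict[str, float] = {}
    for c in classes:
        if L[c] <= 0:
            A[c] = B[c] = 0.0
            res.P[c] = res.Q[c] = 0.0
            continue
        P = ts[c] / L[c]
        Q = tv[c] / L[c]
        res.P[c], res.Q[c] = P, Q
        arg_a, arg_b = 1 - 2 * P - Q, 1 - 2 * Q
        if arg_a <= 0 or arg_b <= 0:
            saturated = True
            A[c] = B[c] = math.nan
            continue
        B[c] = 0.5 * math.log(1 / arg_b)
        A[c] = 0.5 * math.log(1 / arg_a) - 0.5 * B[c]
    res.A, res.B = A, B
    res.saturated = saturated
    if saturated:
        return res

    L0, L2, L4 = L["0"], L["2"], L["4"]
    K0, K4 = A["0"] + B["0"], A["4"] + B["4"]
    if method == "LWL":
        # transversion-degenerate sites were folded into class '2'
        syn_num = L2 * A["2"] + L4 * K4
        syn_sites = L2 / 3 + L4
        non_num = L2 * B["2"] + L0 * K0
        non_sites = 2 * L2 / 3 + L0
    else:
        ts_tot = sum(ts.values())
        tv_tot = sum(tv.values())
        if tv_tot > 0 and ts_tot > 0:
            R = ts_tot / tv_tot
            w2 = R / (R + 1)
            w2v = 1 / (2 * R + 2)
            w2a = 1 / (R + 1)
            w2b = (2 * R + 1) / (2 * R + 2)
        elif tv_tot == 0 and ts_tot > 0:  # R -> infinity
            w2, w2v, w2a, w2b = 1.0, 0.0, 0.0, 1.0
        elif ts_tot == 0 and tv_tot > 0:  # R -> 0
            w2, w2v, w2a, w2b = 0.0, 0.5, 1.0, 0.5
        else:
            w2 = w2v = w2a = w2b = 1 / 3
        L2v, L2a, L2b = L["2V"], L["2A"], L["2B"]
        syn_num = (L2 * A["2"] + L4 * K4
                   + L2v * B["2V"] / 2
                   + L2a * B["2A"]
                   + L2b * (A["2B"] + B["2B"] / 2))
        syn_sites = L2 * w2 + L4 + L2v * w2v + L2a * w2a + L2b * w2b
        non_num = (L2 * B["2"] + L0 * K0
                   + L2v * (A["2V"] + B["2V"] / 2)
                   + L2a * A["2A"]
                   + L2b * B["2B"] / 2)
        non_sites = (L2 * (1 - w2) + L0 + L2v * (1 - w2v)
                     + L2a * (1 - w2a) + L2b * (1 - w2b))

    res.Ks = max(syn_num / syn_sites, 0.0) if syn_sites > 0 else (
        0.0 if syn_num == 0 else None)
    res.Ka = max(non_num / non_sites, 0.0) if non_sites > 0 else (
        0.0 if non_num == 0 else None)
    if res.Ka is not None and res.Ks is not None and res.Ks > 0:
        res.ratio = res.Ka / res.Ks
    return res


def kaks_matrix(alignments: dict[str, "object"], reference_taxon: str,
                method: str = "MLWL", transl_table: int = 1) -> pd.DataFrame:
    """Per-gene, per-taxon Ka/Ks against a reference taxon.

    ``alignments`` maps gene → :class:`~phycorg.snps.OrthologAlignment`
    (or gene → {taxon: aligned nt}).  Gapped codons are dropped pairwise.
    Returns a tidy frame with columns gene, taxon, Ka, Ks, ratio,
    positive_selection; a gene missing in a taxon yields missing cells.
    """
    rows = []
    for gene, aln in sorted(alignments.items()):
        seqs = aln.rows if hasattr(aln, "rows") else aln
        if reference_taxon not in seqs:
            raise ValueError(f"reference {reference_taxon} missing for {gene}")
        ref = seqs[reference_taxon]
        for taxon, nt in sorted(seqs.items()):
            if taxon == reference_taxon:
                continue
            if nt is None:
                rows.append({"gene": gene, "taxon": taxon, "Ka": None,
                             "Ks": None, "ratio": None,
                             "positive_selection": None})
                continue
            # drop codons gapped in either row
            ka, kb = [], []
            for i in range(0, min(len(ref), len(nt)) - 2, 3):
                c1, c2 = ref[i:i + 3], nt[i:i + 3]
                if "-" in c1 or "-" in c2:
                    continue
                ka.append(c1)
                kb.append(c2)
            res = kaks_pair("".join(ka), "".join(kb), method=method,
                            transl_table=transl_table, gene=gene,
                            taxon_a=reference_taxon, taxon_b=taxon)
            rows.append({"gene": gene, "taxon": taxon, "Ka": res.Ka,
                         "Ks": res.Ks, "ratio": res.ratio,
                         "positive_selection":
                             None if res.ratio is None else res.ratio > 1})
    return pd.DataFrame(rows)
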