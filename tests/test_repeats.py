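"""Repeat detectors against direct-definition brute-force oracles on
short sequences, plus planted-repeat recovery on synthetic genomes."""

import numpy as np
import pytest

from phycorg.genome import revcomp
from phycorg.repeats import (SSR_DEFAULT_THRESHOLDS, find_dispersed,
                             find_ssrs, find_tandem, _consensus_stats)
from phycorg.simulate import SimConfig, generate_genome, random_sequence

# --- brute-force oracles -------------------------------------------------


def ssr_oracle(seq, thresholds=None):
    """Enumerate every maximal primitive perfect run position by position,
    then drop phase-shifted sub-runs of the same unit length."""
    thresholds = thresholds or SSR_DEFAULT_THRESHOLDS
    n = len(seq)
    runs = []
    for u, min_copies in thresholds.items():
        for i in range(n - u + 1):
            motif = seq[i:i + u]
            primitive = all(motif != motif[:d] * (u // d)
                            for d in range(1, u) if u % d == 0)
            if not primitive or set(motif) - set("ACGT"):
                continue
            if i >= u and seq[i - u:i] == motif:
                continue
            copies = 1
            while seq[i + copies * u:i + (copies + 1) * u] == motif:
                copies += 1
            if copies >= min_copies:
                runs.append((motif, u, copies, i + 1, i + copies * u))
    kept = [r for r in runs
            if not any(o[1] == r[1] and o != r and o[3] <= r[3]
                       and r[4] <= o[4] and o[4] - o[3] > r[4] - r[3]
                       for o in runs)]
    return sorted(kept)


def tandem_oracle(seq, match_prob=0.8, min_span=14, max_period=None):
    """All maximal qualifying intervals per period by direct enumeration,
    then the period-multiplicity and consensus filters."""
    n = len(seq)
    max_period = max_period or n // 2
    qualifying = {}
    for k in range(1, max_period + 1):
        m = [seq[i] == seq[i + k] for i in range(n - k)]
        good = []
        for a in range(len(m)):
            if not m[a]:
                continue
            for e in range(a + max(min_span, 2 * k), n + 1):
                j = e - k  # number of comparisons consumed
                if j - 1 >= len(m) or not m[j - 1]:
                    continue
                frac = sum(m[a:j]) / (j - a)
                if frac >= match_prob - 1e-9:
                    good.append((a, e))
        maximal = [(a, e) for a, e in good
                   if not any((a2 <= a and e <= e2 and (a2, e2) != (a, e))
                              for a2, e2 in good)]
        for a, e in maximal:
            qualifying[(k, a, e)] = True
    kept = []
    for k, a, e in sorted(qualifying):
        if any(kk < k and k % kk == 0 and a >= aa and e <= ee
               for kk, aa, ee in kept):
            continue
        kept.append((k, a, e))
    out = []
    for k, a, e in kept:
        _, frac = _consensus_stats(seq[a:e], k)
        if frac + 1e-9 >= match_prob:
            out.append((k, a + 1, e))
    return sorted(out)


def dispersed_oracle(seq, min_len=30):
    """Maximal pairs per orientation via diagonal run-lengths (numpy)."""
    comp = str.maketrans("ACGT", "TGCA")
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out = set()
    transforms = {"forward": seq, "reverse": seq[::-1],
                  "complement": seq.translate(comp),
                  "palindromic": revcomp(seq)}
    for kind, tseq in transforms.items():
        tarr = np.frombuffer(tseq.encode(), dtype="S1")
        for shift in range(-n + min_len, n - min_len + 1):
            # compare arr[i] with tarr[i - shift]
            i0, i1 = max(0, shift), min(n, n + shift)
            if i1 - i0 < min_len:
                continue
            eq = arr[i0:i1] == tarr[i0 - shift:i1 - shift]
            # maximal runs of True
            idx = np.flatnonzero(np.diff(np.concatenate(
                [[0], eq.view(np.int8), [0]])))
            for s, e in zip(idx[::2], idx[1::2]):
                L = int(e - s)
                if L < min_len:
                    continue
                i = int(i0 + s)
                q = i - shift
                j = q if kind in ("forward", "complement") else n - q - L
                if i == j:
                    continue
                p1, p2 = min(i, j), max(i, j)
                if kind == "forward" and p2 - p1 == L:
                    continue
                out.add((kind, L, p1 + 1, p2 + 1))
    return sorted(out)


# --- SSR ------------------------------------------------------------------


@pytest.mark.parametrize("seq,expected", [
    ("A" * 9, []),
    ("A" * 10, [("A", 1, 10, 1, 10)]),
    ("ATATATATATAT", [("AT", 2, 6, 1, 12)]),  # primitive motif, not (ATAT)x3
])
def test_ssr_threshold_and_primitivity(seq, expected):
    got = [(r.motif, r.unit_length, r.copies, r.start, r.end)
           for r in find_ssrs(seq)]
    assert got == expected


def test_ssr_planted_dinucleotide_in_background():
    rng = np.random.default_rng(15)
    bg = random_sequence(2000, 0.4, rng)
    seq = bg[:1000] + "C" + "AT" * 7 + "G" + bg[1000:]
    di = [r for r in find_ssrs(seq) if r.unit_length == 2]
    assert [(r.motif, r.copies, r.start) for r in di] == [("AT", 7, 1002)]
    assert ssr_oracle(seq) == sorted(
        (r.motif, r.unit_length, r.copies, r.start, r.end)
        for r in find_ssrs(seq))


@pytest.mark.parametrize("seed", range(25))
def test_ssr_oracle_equivalence(seed):
    rng = np.random.default_rng(seed)
    seq = random_sequence(600, 0.5, rng)
    # salt with low-complexity stretches so SSRs actually occur
    pos = rng.integers(0, 500)
    seq = seq[:pos] + "A" * int(rng.integers(5, 15)) + seq[pos:]
    got = sorted((r.motif, r.unit_length, r.copies, r.start, r.end)
                 for r in find_ssrs(seq))
    assert got == ssr_oracle(seq)


# --- tandem ---------------------------------------------------------------


def test_tandem_exact_repeat():
    (t,) = find_tandem("ACGTT" * 5)
    assert (t.period, t.copies, t.matches) == (5, 5.0, 1.0)
    assert (t.start, t.end) == (1, 25)


def test_tandem_with_one_substitution():
    s = "ACGTT" * 5
    s = s[:13] + "G" + s[14:]  # one substitution mid-repeat
    (t,) = find_tandem(s)
    assert t.period == 5
    assert t.matches == pytest.approx(24 / 25)
    assert (t.start, t.end) == (1, 25)


def test_tandem_random_sequence_has_no_long_repeat():
    rng = np.random.default_rng(42)
    seq = random_sequence(2000, 0.5, rng)
    hits = [t for t in find_tandem(seq)
            if t.period <= 10 and t.end - t.start + 1 >= 30]
    assert hits == []


@pytest.mark.parametrize("seed", range(8))
def test_tandem_oracle_equivalence(seed):
    rng = np.random.default_rng(100 + seed)
    seq = random_sequence(260, 0.5, rng)
    if seed % 2:  # plant a noisy tandem
        unit = random_sequence(int(rng.integers(3, 8)), 0.5, rng)
        rep = list(unit * 4)
        rep[int(rng.integers(len(rep)))] = "ACGT"[int(rng.integers(4))]
        pos = int(rng.integers(0, 200))
        seq = seq[:pos] + "".join(rep) + seq[pos:]
    got = sorted((t.period, t.start, t.end)
                 for t in find_tandem(seq, max_period=12))
    assert got == tandem_oracle(seq, max_period=12)


# --- dispersed ------------------------------------------------------------


def test_dispersed_planted_forward_pair():
    rng = np.random.default_rng(5)
    seg = random_sequence(30, 0.5, rng)
    seq = ("T" + random_sequence(100, 0.5, rng) + "A" + seg + "A"
           + random_sequence(100, 0.5, rng) + "C" + seg + "C")
    hits = find_dispersed(seq)
    fw = [h for h in hits if h.kind == "forward"]
    assert len(fw) == 1 and fw[0].length == 30


def test_dispersed_planted_palindromic_pair():
    rng = np.random.default_rng(6)
    seg = random_sequence(30, 0.5, rng)
    seq = ("A" + random_sequence(90, 0.5, rng) + "A" + seg + "A"
           + random_sequence(90, 0.5, rng) + "A" + revcomp(seg) + "A")
    hits = [h for h in find_dispersed(seq) if h.kind == "palindromic"]
    assert len(hits) == 1 and hits[0].length == 30


def test_dispersed_random_sequence_empty():
    rng = np.random.default_rng(7)
    seq = random_sequence(2000, 0.5, rng)
    assert find_dispersed(seq) == []
    assert dispersed_oracle(seq) == []


@pytest.mark.parametrize("seed", range(10))
def test_dispersed_oracle_equivalence(seed):
    rng = np.random.default_rng(200 + seed)
    seq = random_sequence(400, 0.5, rng)
    kind = ("forward", "reverse", "complement", "palindromic")[seed % 4]
    seg = random_sequence(30 + int(rng.integers(0, 10)), 0.5, rng)
    mate = {"forward": seg, "reverse": seg[::-1],
            "complement": seg.translate(str.maketrans("ACGT", "TGCA")),
            "palindromic": revcomp(seg)}[kind]
    p1, p2 = 50, 250
    seq = seq[:p1] + seg + seq[p1:p2] + mate + seq[p2:]
    got = sorted((d.kind, d.length, d.pos1, d.pos2)
                 for d in find_dispersed(seq))
    assert got == dispersed_oracle(seq)
    assert any(k == kind for k, _, _, _ in got)


def test_dispersed_reverse_complement_symmetry():
    rng = np.random.default_rng(9)
    seq = random_sequence(300, 0.5, rng)
    seg = random_sequence(34, 0.5, rng)
    seq = seq[:60] + seg + seq[60:200] + seg + seq[200:]
    fwd = find_dispersed(seq)
    rc = find_dispersed(revcomp(seq))
    n = len(seq)
    mapped = sorted((d.kind, d.length, n - (d.pos2 + d.length - 1) + 1,
                     n - (d.pos1 + d.length - 1) + 1) for d in rc)
    assert mapped == sorted((d.kind, d.length, d.pos1, d.pos2) for d in fwd)


# --- planted recovery on full genomes --------------------------------------


def test_planted_repeats_recovered_with_exact_spans():
    cfg = SimConfig(seed=31, planted_ssrs=(("AT", 7), ("CAA", 6)),
                    planted_tandems=(("ACGTTG", 5),),
                    planted_dispersed=((33, "forward"),
                                       (40, "palindromic"),
                                       (31, "reverse")))
    genome, truth = generate_genome(cfg)
    ssrs = {(r.motif, r.start, r.end)
            for r in find_ssrs(genome.sequence, circular=True)}
    for motif, _, s, e in truth.ssrs:
        assert (motif, s, e) in ssrs
    tandems = {(t.period, t.start, t.end)
               for t in find_tandem(genome.sequence, circular=True)}
    for unit, period, s, e in truth.tandems:
        assert (period, s, e) in tandems
    disp = {(d.kind, d.length, d.pos1, d.pos2)
            for d in find_dispersed(genome.sequence, circular=True)}
    for kind, length, p1, p2 in truth.dispersed:
        assert (kind, length, p1, p2) in disp
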