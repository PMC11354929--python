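"""Codon-usage suite: RSCU, positional GC, ENC (against an independent
re-implementation of Wright's formulas), expected-ENC curve, neutrality
fit, PR2 and ΔRSCU optimal codons."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phycorg.codon import (CodonUsageTable, as_rna, code_families,
                           count_codons, enc, enc_expected, enc_from_counts,
                           high_frequency_codons, neutrality_fit,
                           optimal_codons, positional_gc, pr2_point, rscu)
from phycorg.genome import CodingSequence


def test_count_codons_example():
    t = count_codons(["ATGTGGTAA"])
    assert dict(t.counts) == {"ATG": 1, "TGG": 1}
    assert dict(t.stop_counts) == {"TAA": 1}


def test_count_codons_concatenation_invariance():
    a, b = "ATGGCTTGCTAA", "ATGAAATTTTAG"
    pooled = count_codons([a, b])
    summed = count_codons([a]) + count_codons([b])
    assert pooled.counts == summed.counts
    assert pooled.stop_counts == summed.stop_counts


def test_count_codons_drops_ambiguous_and_requires_codons():
    t = count_codons(["ATGNNGTGA"])
    assert t.dropped_ambiguous == 1
    with pytest.raises(ValueError):
        count_codons(["AT"])


def test_generator_codon_bookkeeping(mt_cds):
    total_nt = sum(len(c.nt) for c in mt_cds)
    assert total_nt == 26340
    t = count_codons(mt_cds)
    assert t.total + sum(t.stop_counts.values()) == 8780


def test_rscu_leucine_example():
    # Leu family size 6; counts UUA:3, UUG:1 -> RSCU(UUA) = 3/(4/6) = 4.5
    t = CodonUsageTable(Counter({"TTA": 3, "TTG": 1}))
    vals = t.rscu()
    assert vals["TTA"] == pytest.approx(4.5)
    assert vals["CTA"] == 0.0
    # unobserved families are missing, not zero
    assert "GGA" not in vals


def test_rscu_uniform_four_fold_family():
    t = CodonUsageTable(Counter({c: 5 for c in ("GGT", "GGC", "GGA", "GGG")}))
    assert all(t.rscu()[c] == pytest.approx(1.0) for c in ("GGT", "GGA"))


def test_rscu_single_codon_families_are_unbiased(mt_cds):
    vals = count_codons(mt_cds).rscu()
    assert vals["ATG"] == 1.0 and vals["TGG"] == 1.0


@given(st.dictionaries(
    st.sampled_from(sorted(sum(map(list, code_families().values()), []))),
    st.integers(min_value=0, max_value=50), min_size=1))
@settings(max_examples=60, deadline=None)
def test_rscu_family_sums_equal_family_size(counts):
    t = CodonUsageTable(Counter(counts))
    vals = t.rscu()
    for aa, fam in code_families().items():
        if sum(t.counts[c] for c in fam) == 0:
            assert all(c not in vals for c in fam)
        else:
            assert sum(vals[c] for c in fam) == pytest.approx(len(fam),
                                                              abs=1e-9)


def test_positional_gc_hand_example():
    pg = positional_gc(["ATGGCC"])
    assert (pg.gc1, pg.gc2, pg.gc3) == (0.5, 0.5, 1.0)
    assert pg.gc12 == 0.5
    pg2 = positional_gc(["ATTAAATTA"])
    assert (pg2.gc1, pg2.gc2, pg2.gc3) == (0, 0, 0)


def test_positional_gc12_definitional(mt_cds):
    pg = positional_gc(mt_cds)
    assert pg.gc12 == pytest.approx((pg.gc1 + pg.gc2) / 2)
    assert 0 < pg.gc3 < pg.gc1  # planted A/U bias at third positions


# --- ENC ---------------------------------------------------------------


def enc_oracle(counts: Counter) -> float | None:
    """Independent evaluation of Wright's Nc: per-family homozygosity
    F = (nΣp²−1)/(n−1), class means over family sizes, Wright's imputation
    for missing classes from the available 2- and 4-fold means."""
    F_by_size: dict[int, list[float]] = {}
    sizes = Counter()
    for aa, fam in code_families().items():
        sizes[len(fam)] += 1
        ns = [counts[c] for c in fam]
        n = sum(ns)
        if len(fam) == 1 or n < 2:
            continue
        F = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if F > 0:
            F_by_size.setdefault(len(fam), []).append(F)
    means = {k: sum(v) / len(v) for k, v in F_by_size.items()}
    avail = [means[k] for k in (2, 4) if k in means]
    if not avail:
        return None
    fill = sum(avail) / len(avail)
    nc = sizes[1]
    for k in (2, 3, 4, 6):
        if sizes[k]:
            nc += sizes[k] / means.get(k, fill)
    return min(max(nc, 20.0), 61.0)


def test_enc_extremes():
    # one codon per observed family, many observations -> maximal bias, 20
    one_per_family = Counter()
    for fam in code_families().values():
        one_per_family[fam[0]] = 100
    assert enc_from_counts(one_per_family) == pytest.approx(20.0)
    # perfectly uniform synonymous usage -> no bias, 61
    uniform = Counter({c: 300 for fam in code_families().values()
                       for c in fam})
    assert enc_from_counts(uniform) == pytest.approx(61.0)


@pytest.mark.parametrize("seed", range(10))
def test_enc_matches_independent_oracle(seed):
    rng = np.random.default_rng(seed)
    sense = sorted(sum(map(list, code_families().values()), []))
    w = rng.dirichlet(np.ones(len(sense)) * 0.3)
    draws = rng.choice(sense, size=200, p=w)
    counts = Counter(draws)
    got = enc_from_counts(counts)
    want = enc_oracle(counts)
    assert got == pytest.approx(want, abs=1e-9)


def test_enc_monotone_in_family_skew():
    base = Counter({c: 25 for fam in code_families().values() for c in fam})
    prev = enc_from_counts(base)
    for skew in (10, 20, 24):
        c = Counter(base)
        c["GGA"] += skew
        c["GGC"] -= skew
        cur = enc_from_counts(c)
        assert cur <= prev + 1e-12
        prev = cur


def test_enc_per_gene_result(mt_cds):
    r = enc(mt_cds[0])
    assert r.gene == mt_cds[0].gene
    assert 20 <= r.enc <= 61
    assert not r.short


@pytest.mark.parametrize("gc3,expected", [(0.0, 31.0), (0.5, 60.5),
                                          (1.0, 32.0)])
def test_enc_expected_curve(gc3, expected):
    assert enc_expected(gc3) == pytest.approx(expected)


@given(st.floats(min_value=0.0, max_value=0.5))
@settings(max_examples=40, deadline=None)
def test_enc_expected_symmetry(g):
    # enc_expected(g) - g is symmetric under g <-> 1-g
    assert enc_expected(g) - g == pytest.approx(enc_expected(1 - g) - (1 - g))


def test_enc_expected_domain():
    with pytest.raises(ValueError):
        enc_expected(1.2)


# --- neutrality and PR2 -------------------------------------------------


def test_neutrality_fit_degenerate_slopes():
    pts_flat = [(0.1, 0.4), (0.3, 0.4), (0.6, 0.4)]
    slope, intercept, _ = neutrality_fit(pts_flat)
    assert slope == pytest.approx(0.0)
    assert intercept == pytest.approx(0.4)
    pts_diag = [(x, x) for x in (0.1, 0.2, 0.5, 0.9)]
    slope, _, r = neutrality_fit(pts_diag)
    assert slope == pytest.approx(1.0) and r == pytest.approx(1.0)
    with pytest.raises(ValueError):
        neutrality_fit([(0.2, 0.1), (0.2, 0.3), (0.2, 0.5)])


def test_pr2_examples():
    from phycorg.codon import PositionalGC
    assert pr2_point(PositionalGC(0, 0, 0, 0, a3=2, t3=2, g3=3, c3=3)) == \
        (0.5, 0.5)
    assert pr2_point(PositionalGC(0, 0, 0, 0, a3=1, t3=3, g3=3, c3=1)) == \
        (0.75, 0.25)
    x, y = pr2_point(PositionalGC(0, 0, 0, 0, a3=0, t3=4, g3=1, c3=1))
    assert y == 0.0
    x, y = pr2_point(PositionalGC(0, 0, 0, 0, a3=1, t3=1, g3=0, c3=0))
    assert x is None


# --- optimal codons and high-frequency codons ---------------------------


def _usage_tables(cds_list):
    return {c.gene: count_codons([c]) for c in cds_list}


def test_optimal_codons_identical_pools_empty():
    # 10 genes with identical usage: ΔRSCU == 0 everywhere
    nt = "ATG" + "TTAGTTGGA" * 20 + "TAA"
    cds = [CodingSequence(f"g{i:02d}", "x", nt, "") for i in range(10)]
    rep = optimal_codons([enc(c) for c in cds], _usage_tables(cds))
    assert rep.optimal == set()
    assert all(abs(v) < 1e-12 for v in rep.delta_rscu.values())


def test_optimal_codons_constructed_case():
    # biased genes use TTA heavily; unbiased genes spread the Leu family
    biased = "ATG" + "TTA" * 40 + "GGA" * 10 + "TAA"
    mixed = ("ATG" + "TTATTGCTTCTCCTACTG" * 8 +
             "GGTGGCGGAGGG" * 4 + "TAA")
    cds = [CodingSequence(f"b{i}", "x", biased, "") for i in range(5)] + \
          [CodingSequence(f"m{i}", "x", mixed, "") for i in range(5)]
    rep = optimal_codons([enc(c) for c in cds], _usage_tables(cds))
    assert set(rep.high_pool) <= {f"b{i}" for i in range(5)}
    assert "TTA" in rep.optimal
    assert rep.delta_rscu["TTA"] >= 0.08 and rep.rscu_high["TTA"] > 1


def test_optimal_codons_order_invariance_and_consensus(mt_cds):
    results = [enc(c) for c in mt_cds]
    usage = _usage_tables(mt_cds)
    rep = optimal_codons(results, usage)
    rep_rev = optimal_codons(results[::-1], usage)
    assert rep.optimal == rep_rev.optimal
    assert rep.high_pool == rep_rev.high_pool
    # Fucales-style planted bias: UUA and GUU called optimal
    assert {"TTA", "GTT"} <= rep.optimal


def test_optimal_codons_requires_ten_genes(mt_cds):
    with pytest.raises(ValueError):
        optimal_codons([enc(c) for c in mt_cds[:5]],
                       _usage_tables(mt_cds[:5]))


def test_high_frequency_codons():
    uniform = CodonUsageTable(Counter(
        {c: 7 for fam in code_families().values() for c in fam}))
    hi, frac = high_frequency_codons(uniform)
    assert hi == set() and frac == 0.0
    leu = CodonUsageTable(Counter({"TTA": 12}))
    hi, _ = high_frequency_codons(leu)
    assert hi == {"TTA"}
    assert leu.rscu()["TTA"] == pytest.approx(6.0)


def test_high_frequency_codons_end_in_AU(mt_cds):
    hi, frac = high_frequency_codons(count_codons(mt_cds))
    au = sum(1 for c in hi if c[2] in "AT")
    assert au / len(hi) >= 0.95
    assert frac > 0.5


def test_as_rna():
    assert as_rna("TTA") == "UUA"
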