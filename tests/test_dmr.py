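"""Differential methylation: 2x2 tests, seeds, extension and full calling."""

import numpy as np
import pytest
from scipy import stats

from rrbskit.dmr import (CpGPair, DMRegion, call_dmcs_dmrs, cpg_series,
                         extend_region, find_seeds, fisher_exact_2x2)
from rrbskit.dmr import test_2x2 as table_test
from rrbskit.dmr import test_site as site_test
from rrbskit.methylation import Methylome, SiteMethylation


def pair(pos, m1, u1, m2, u2):
    return CpGPair(pos, m1, u1, m2, u2)


# --- 2x2 machinery --------------------------------------------------------

def test_fisher_worked_examples():
    # [[0,5],[5,0]]: only 2 of the 252 equiprobable tables are this extreme
    assert fisher_exact_2x2(0, 5, 5, 0) == pytest.approx(2 / 252)
    assert fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(1.0825e-5,
                                                           rel=1e-4)
    assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)


def test_fisher_degenerate_margins():
    assert fisher_exact_2x2(0, 0, 3, 4) == 1.0
    assert fisher_exact_2x2(3, 0, 4, 0) == 1.0
    assert fisher_exact_2x2(0, 3, 0, 4) == 1.0


def test_fisher_matches_scipy_oracle(rng):
    for _ in range(400):
        a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
        if (a + b == 0) or (c + d == 0):
            continue
        ours = fisher_exact_2x2(a, b, c, d)
        ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(ref, abs=1e-9)


def test_chi_square_matches_closed_form(rng):
    """Independent oracle: X^2 = N (ad-bc)^2 / (r1 r2 c1 c2)."""
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(5, 60, 4))
        p, used = table_test(a, b, c, d)
        assert used == "chi-square"
        n = a + b + c + d
        x2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert p == pytest.approx(stats.chi2.sf(x2, 1), rel=1e-10)


def test_small_count_switch_boundary():
    assert table_test(5, 5, 5, 5)[1] == "chi-square"
    assert table_test(4, 5, 5, 5)[1] == "fisher"
    assert table_test(100, 100, 100, 4)[1] == "fisher"


def test_2x2_input_validation():
    with pytest.raises(ValueError):
        table_test(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        table_test(0, 0, 0, 0)


def site(pos, m, u, strand="+"):
    return SiteMethylation("c", pos, strand, "CpG", m, u)


def test_test_site_worked_examples():
    # perfectly switched small table: Fisher, clearly differential
    r = site_test(site(1, 0, 5), site(1, 5, 0))
    assert r.test_used == "fisher"
    assert r.p_value == pytest.approx(2 / 252)
    assert r.is_dmc and r.delta == pytest.approx(-1.0)
    # identical rates: never a DMC
    r = site_test(site(1, 5, 5), site(1, 50, 50))
    assert not r.is_dmc and r.delta == 0.0
    # significant but tiny difference fails the effect-size gate
    r = site_test(site(1, 550, 450), site(1, 450, 550), min_delta=0.25)
    assert r.p_value < 0.05 and not r.is_dmc
    # uncovered site is untestable
    assert site_test(site(1, 0, 0), site(1, 3, 4)) is None


def test_test_site_symmetry():
    a, b = site(1, 9, 3), site(1, 2, 10)
    r1, r2 = site_test(a, b), site_test(b, a)
    assert r1.p_value == pytest.approx(r2.p_value)
    assert r1.delta == pytest.approx(-r2.delta)
    assert r1.is_dmc == r2.is_dmc


# --- CpG series -----------------------------------------------------------

def _methylome(entries):
    m = Methylome()
    for pos, strand, nm, nu in entries:
        m._sites[("c", pos, strand)] = SiteMethylation("c", pos, strand,
                                                       "CpG", nm, nu)
    return m


def test_cpg_series_pools_strands_and_requires_shared_coverage():
    m1 = _methylome([(10, "+", 3, 1), (11, "-", 2, 2), (20, "+", 1, 0)])
    m2 = _methylome([(10, "+", 0, 4), (30, "+", 5, 5)])
    series = cpg_series(m1, m2)
    assert list(series) == ["c"]
    assert [(p.pos, p.m1, p.u1, p.m2, p.u2) for p in series["c"]] == \
        [(10, 5, 3, 0, 4)]


def test_cpg_series_min_depth():
    m1 = _methylome([(10, "+", 1, 0)])
    m2 = _methylome([(10, "+", 4, 4)])
    assert cpg_series(m1, m2, min_depth=2) == {}
    assert len(cpg_series(m1, m2, min_depth=1)["c"]) == 1


# --- seeds and extension --------------------------------------------------

def diff_pair(pos, depth=20, hi=True):
    m = int(round(depth * 0.9)) if hi else int(round(depth * 0.1))
    return pair(pos, m, depth - m, depth - m, m)


def flat_pair(pos, depth=20):
    m = depth // 2
    return pair(pos, m, depth - m, m, depth - m)


def test_find_seeds_examples():
    # five strongly differential CpGs form exactly one seed
    pairs = [diff_pair(10 * i) for i in range(5)]
    assert find_seeds(pairs, seed_size=5) == [(0, 5)]
    # a sign flip inside the window blocks it
    pairs[2] = diff_pair(20, hi=False)
    assert find_seeds(pairs, seed_size=5) == []
    # flat background yields nothing
    assert find_seeds([flat_pair(10 * i) for i in range(12)]) == []


def test_find_seeds_are_non_overlapping_and_resume_after_hit():
    pairs = [diff_pair(10 * i) for i in range(10)]
    seeds = find_seeds(pairs, seed_size=5)
    assert seeds == [(0, 5), (5, 10)]


def test_extend_region_grows_over_consistent_neighbors():
    pairs = ([diff_pair(10 * i) for i in range(8)]
             + [flat_pair(80 + 10 * i) for i in range(4)])
    region, (lo, hi) = extend_region(pairs, (0, 5), chrom="c")
    assert (lo, hi) == (0, 8)
    assert region.n_cpgs == 8
    assert region.direction == "hyper"
    assert region.start == 0 and region.end == 72  # last CpG pos 70 + 2


def test_extend_region_stops_at_sign_flip():
    pairs = ([diff_pair(0, hi=False)]
             + [diff_pair(10 + 10 * i) for i in range(6)])
    region, (lo, hi) = extend_region(pairs, (1, 6), chrom="c")
    assert lo == 1  # the opposite-sign CpG on the left is rejected
    assert hi == 7
    assert region.direction == "hyper"


def test_extend_region_respects_min_index():
    pairs = [diff_pair(10 * i) for i in range(10)]
    _, (lo, hi) = extend_region(pairs, (5, 10), chrom="c", min_index=5)
    assert lo == 5 and hi == 10


def test_extension_never_breaks_the_region_definition(rng):
    """Whatever the data, an emitted region satisfies the DMR gates."""
    from rrbskit.dmr import _pooled

    for _ in range(50):
        depth = 15
        pairs = []
        for i in range(20):
            m1 = int(rng.integers(0, depth + 1))
            m2 = int(rng.integers(0, depth + 1))
            pairs.append(pair(10 * i, m1, depth - m1, m2, depth - m2))
        for seed in find_seeds(pairs):
            region, (lo, hi) = extend_region(pairs, seed, chrom="c")
            if region is None:
                continue
            delta, p, _ = _pooled(pairs[lo:hi])
            assert p < 0.05 and abs(delta) > 0.1
            assert region.delta == pytest.approx(delta)


# --- end-to-end calling ---------------------------------------------------

def _paired_methylomes(pairs):
    m1 = _methylome([(p.pos, "+", p.m1, p.u1) for p in pairs])
    m2 = _methylome([(p.pos, "+", p.m2, p.u2) for p in pairs])
    return m1, m2


def test_call_dmcs_dmrs_finds_planted_block():
    pairs = ([flat_pair(10 * i) for i in range(6)]
             + [diff_pair(60 + 10 * i) for i in range(7)]
             + [flat_pair(130 + 10 * i) for i in range(6)])
    m1, m2 = _paired_methylomes(pairs)
    dmcs, regions = call_dmcs_dmrs(m1, m2)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end) == (60, 122)
    assert r.n_cpgs == 7 and r.direction == "hyper"
    assert {d.pos for d in dmcs if d.is_dmc} == {60 + 10 * i
                                                 for i in range(7)}
    assert all(d.q_value is not None for d in dmcs)


def test_self_comparison_yields_no_regions():
    pairs = [pair(10 * i, 12, 8, 12, 8) for i in range(30)]
    m1, m2 = _paired_methylomes(pairs)
    dmcs, regions = call_dmcs_dmrs(m1, m2)
    assert regions == []
    assert not any(d.is_dmc for d in dmcs)


def test_swap_symmetry_of_regions():
    pairs = ([flat_pair(10 * i) for i in range(3)]
             + [diff_pair(30 + 10 * i) for i in range(6)])
    m1, m2 = _paired_methylomes(pairs)
    _, fwd = call_dmcs_dmrs(m1, m2)
    _, rev = call_dmcs_dmrs(m2, m1)
    assert [(r.start, r.end, r.n_cpgs) for r in fwd] == \
        [(r.start, r.end, r.n_cpgs) for r in rev]
    assert [r.direction for r in fwd] == ["hyper"]
    assert [r.direction for r in rev] == ["hypo"]


def test_disjoint_methylomes_warn_and_return_empty():
    m1 = _methylome([(10, "+", 3, 3)])
    m2 = _methylome([(50, "+", 3, 3)])
    with pytest.warns(UserWarning, match="share no covered sites"):
        assert call_dmcs_dmrs(m1, m2) == ([], [])


def test_null_dmc_rate_within_type_i_bound(rng):
    """Two samples drawn from one binomial: the DMC fraction stays near
    or below alpha (discrete tests are conservative)."""
    n_sites, depth, rate = 2000, 30, 0.5
    n_dmc = 0
    for i in range(n_sites):
        m1 = int(rng.binomial(depth, rate))
        m2 = int(rng.binomial(depth, rate))
        r = site_test(site(i, m1, depth - m1), site(i, m2, depth - m2))
        if r is not None and r.is_dmc:
            n_dmc += 1
    # binomial(2000, 0.05) three-sigma upper bound ~ 0.065
    assert n_dmc / n_sites <= 0.065
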