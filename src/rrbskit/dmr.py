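"""Differential methylation: per-cytosine tests and seed-and-extend regions.

Two samples are compared site by site on 2x2 tables of methylated /
unmethylated counts: Pearson's chi-square without continuity correction,
replaced by Fisher's exact test whenever any cell is below 5. A site is
a DMC when p < alpha and the methylation-rate difference exceeds
min_delta (defaults 0.05 and 0.1).

Regions are called by seed and extension: a window of consecutive CpGs
(default 5) whose pooled table is significant with a consistent per-CpG
difference sign forms a seed, which is then prolonged one CpG at a time
on both sides. A candidate CpG is accepted while its difference keeps
the seed's sign and the extended region stays significant by both the
pooled chi-square/Fisher test and a paired t-test on per-CpG rates; the
first rejection on a side ("a change in the trend") stops that side.
CpG counts are pooled across the two strands of each dinucleotide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from rrbskit.methylation import Methylome, SiteMethylation


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for [[a,b],[c,d]].

    Conditions on both margins and sums the hypergeometric probability
    of every table as extreme as the observed one (probability at most
    that observed). Likelihoods are compared as exact integers
    (``C(r1,k)·C(r2,n-k)``), so ties are handled without a floating
    tolerance.
    """
    r1, r2, n = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or n == 0 or n == r1 + r2:
        return 1.0
    k_min, k_max = max(0, n - r2), min(r1, n)
    weights = [comb(r1, k) * comb(r2, n - k) for k in range(k_min, k_max + 1)]
    observed = weights[a - k_min]
    return float(sum(w for w in weights if w <= observed)
                 / comb(r1 + r2, n))


def test_2x2(a: int, b: int, c: int, d: int) -> tuple[float, str]:
    """p-value for independence in [[a,b],[c,d]] with the small-count switch.

    Chi-square (no continuity correction) when all cells are >= 5,
    otherwise Fisher's exact two-sided test.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    if min(a, b, c, d) < 5:
        return fisher_exact_2x2(a, b, c, d), "fisher"
    _, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(p), "chi-square"


@dataclass
class SiteTestResult:
    chrom: str
    pos: int
    strand: str
    context: str
    rate1: float
    rate2: float
    delta: float
    p_value: float
    test_used: str
    is_dmc: bool
    q_value: Optional[float] = None


@dataclass
class DMRegion:
    chrom: str
    start: int
    end: int
    n_cpgs: int
    rate1: float  # site-weighted mean over the region, sample 1
    rate2: float
    delta: float  # pooled rate difference, sample1 - sample2
    p_value: float
    direction: str  # hyper | hypo (sample 1 relative to sample 2)


def test_site(site1: SiteMethylation, site2: SiteMethylation,
              alpha: float = 0.05, min_delta: float = 0.1
              ) -> Optional[SiteTestResult]:
    """Test one cytosine between two samples; None when untestable."""
    if site1.total == 0 or site2.total == 0:
        return None
    p, test = test_2x2(site1.n_meth, site1.n_unmeth,
                       site2.n_meth, site2.n_unmeth)
    delta = site1.rate - site2.rate
    return SiteTestResult(site1.chrom, site1.pos, site1.strand, site1.context,
                          site1.rate, site2.rate, delta, p, test,
                          is_dmc=(p < alpha and abs(delta) > min_delta))


# --- CpG series: per-dinucleotide paired counts ---------------------------

@dataclass
class CpGPair:
    """Strand-pooled counts of one CpG in the two samples."""

    pos: int  # + strand C position of the dinucleotide
    m1: int
    u1: int
    m2: int
    u2: int

    @property
    def rate1(self) -> float:
        return self.m1 / (self.m1 + self.u1)

    @property
    def rate2(self) -> float:
        return self.m2 / (self.m2 + self.u2)

    @property
    def delta(self) -> float:
        return self.rate1 - self.rate2


def cpg_series(methylome1: Methylome, methylome2: Methylome,
               min_depth: int = 1) -> dict[str, list[CpGPair]]:
    """Sorted per-chromosome CpG series covered in both samples."""
    merged1 = methylome1.merged_cpg_counts()
    merged2 = methylome2.merged_cpg_counts()
    series: dict[str, list[CpGPair]] = {}
    for key in sorted(set(merged1) & set(merged2)):
        m1, u1 = merged1[key]
        m2, u2 = merged2[key]
        if m1 + u1 < min_depth or m2 + u2 < min_depth:
            continue
        series.setdefault(key[0], []).append(CpGPair(key[1], m1, u1, m2, u2))
    return series


def _pooled(pairs: Sequence[CpGPair]) -> tuple[float, float, str]:
    """(pooled delta, p, test) over a run of CpGs."""
    m1 = sum(p.m1 for p in pairs)
    u1 = sum(p.u1 for p in pairs)
    m2 = sum(p.m2 for p in pairs)
    u2 = sum(p.u2 for p in pairs)
    p_val, test = test_2x2(m1, u1, m2, u2)
    return m1 / (m1 + u1) - m2 / (m2 + u2), p_val, test


def _window_is_seed(pairs: Sequence[CpGPair], alpha: float,
                    min_delta: float) -> bool:
    signs = {np.sign(p.delta) for p in pairs}
    if len(signs) != 1 or 0 in signs:
        return False
    delta, p, _ = _pooled(pairs)
    return p < alpha and abs(delta) > min_delta


def find_seeds(pairs: Sequence[CpGPair], seed_size: int = 5,
               alpha: float = 0.05, min_delta: float = 0.1
               ) -> list[tuple[int, int]]:
    """Non-overlapping seed windows as (start_index, end_index) pairs.

    Windows are scanned left to right; when one qualifies the scan
    resumes after it, so returned seeds never overlap.
    """
    seeds = []
    i = 0
    while i + seed_size <= len(pairs):
        window = pairs[i : i + seed_size]
        if _window_is_seed(window, alpha, min_delta):
            seeds.append((i, i + seed_size))
            i += seed_size
        else:
            i += 1
    return seeds


def _t_test_ok(pairs: Sequence[CpGPair], alpha: float) -> bool:
    """Paired two-sided t-test on per-CpG rates; waived when degenerate.

    With identical per-CpG differences the t statistic is undefined
    (zero variance); the criterion is then waived and the pooled
    chi-square governs.
    """
    r1 = np.array([p.rate1 for p in pairs])
    r2 = np.array([p.rate2 for p in pairs])
    diffs = r1 - r2
    if np.allclose(diffs, diffs[0]):
        return True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.ttest_rel(r1, r2)
    return bool(np.isnan(p)) or p < alpha


def extend_region(pairs: Sequence[CpGPair], seed: tuple[int, int],
                  alpha: float = 0.05, min_delta: float = 0.1,
                  chrom: str = "", min_index: int = 0
                  ) -> tuple[Optional[DMRegion], tuple[int, int]]:
    """Prolong a seed one CpG at a time, alternately right then left.

    Returns the region (or None if the fully elongated run no longer
    meets the DMR definition) and the final (start, end) index span.
    ``min_index`` caps leftward growth so regions from one run never
    overlap.
    """
    lo, hi = seed
    sign = np.sign(pairs[lo].delta)

    def accepts(new_lo: int, new_hi: int, cand: CpGPair) -> bool:
        if np.sign(cand.delta) != sign:
            return False
        ext = pairs[new_lo:new_hi]
        delta, p, _ = _pooled(ext)
        if not (p < alpha and abs(delta) > min_delta):
            return False
        return _t_test_ok(ext, alpha)

    right_open, left_open = True, True
    while right_open or left_open:
        if right_open:
            if hi < len(pairs) and accepts(lo, hi + 1, pairs[hi]):
                hi += 1
            else:
                right_open = False
        if left_open:
            if lo > min_index and accepts(lo - 1, hi, pairs[lo - 1]):
                lo -= 1
            else:
                left_open = False
    region = pairs[lo:hi]
    delta, p, _ = _pooled(region)
    if not (p < alpha and abs(delta) > min_delta):
        return None, (lo, hi)
    rate1 = float(np.mean([c.rate1 for c in region]))
    rate2 = float(np.mean([c.rate2 for c in region]))
    return DMRegion(chrom, region[0].pos, region[-1].pos + 2, len(region),
                    rate1, rate2, delta, p,
                    "hyper" if delta > 0 else "hypo"), (lo, hi)


def call_dmcs_dmrs(methylome1: Methylome, methylome2: Methylome,
                   alpha: float = 0.05, min_delta: float = 0.1,
                   seed_size: int = 5, min_depth: int = 1
                   ) -> tuple[list[SiteTestResult], list[DMRegion]]:
    """DMCs for every shared cytosine and DMRs by seed-and-extend.

    Thresholding uses raw p-values; Benjamini-Hochberg q-values are
    reported alongside for the DMCs.
    """
    keys1 = {(s.chrom, s.pos, s.strand) for s in methylome1.sites()}
    keys2 = {(s.chrom, s.pos, s.strand) for s in methylome2.sites()}
    shared = sorted(keys1 & keys2)
    if not shared:
        warnings.warn("the two methylomes share no covered sites")
        return [], []
    dmcs: list[SiteTestResult] = []
    for chrom, pos, strand in shared:
        res = test_site(methylome1.get(chrom, pos, strand),
                        methylome2.get(chrom, pos, strand), alpha, min_delta)
        if res is not None:
            dmcs.append(res)
    if dmcs:
        qs = stats.false_discovery_control([r.p_value for r in dmcs])
        for r, q in zip(dmcs, qs):
            r.q_value = float(q)

    regions: list[DMRegion] = []
    for chrom, pairs in cpg_series(methylome1, methylome2, min_depth).items():
        i = 0
        floor = 0
        while i + seed_size <= len(pairs):
            window = pairs[i : i + seed_size]
            if not _window_is_seed(window, alpha, min_delta):
                i += 1
                continue
            region, (lo, hi) = extend_region(pairs, (i, i + seed_size),
                                             alpha, min_delta, chrom, floor)
            if region is not None:
                regions.append(region)
            i = hi
            floor = hi
    regions.sort(key=lambda r: (r.chrom, r.start))
    return dmcs, regions


def write_dmc_tsv(dmcs: Sequence[SiteTestResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tcontext\trate1\trate2\tdelta\t"
                 "p_value\tq_value\ttest\tis_dmc\n")
        for r in dmcs:
            q = f"{r.q_value:.6g}" if r.q_value is not None else "NA"
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.strand}\t{r.context}\t"
                     f"{r.rate1:.6f}\t{r.rate2:.6f}\t{r.delta:+.6f}\t"
                     f"{r.p_value:.6g}\t{q}\t{r.test_used}\t"
                     f"{int(r.is_dmc)}\n")


def write_dmr_tsv(regions: Sequence[DMRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_cpgs\trate1\trate2\tdelta\t"
                 "p_value\tdirection\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.n_cpgs}\t"
                     f"{r.rate1:.6f}\t{r.rate2:.6f}\t{r.delta:+.6f}\t"
                     f"{r.p_value:.6g}\t{r.direction}\n")
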