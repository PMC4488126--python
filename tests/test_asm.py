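"""Allele-specific methylation: allele resolution, linking and testing."""

import numpy as np
import pytest

from rrbskit.asm import (HetSNP, LinkedPairTable, call_asm, link_pairs,
                         load_het_snps, resolve_allele, screen_het_snps)
from rrbskit.asm import test_asm as asm_test
from rrbskit.examples import _header, make_read
from rrbskit.reference import Genome, index_cytosines
from rrbskit.simulate import (ASMSegmentSpec, SimulationConfig, simulate_asm,
                              write_truth_vcf)

# A/T het SNP at position 2, CpG dinucleotide at 8 (+ strand C)
ASM_REF = "TTATTTTTCGTTTTTT"


@pytest.mark.parametrize("ref,alt,base,strand,expected", [
    ("A", "T", "A", "W", "A"), ("A", "T", "T", "W", "T"),
    ("A", "T", "G", "W", None),  # base matches neither allele
    ("C", "T", "C", "W", "C"),
    ("C", "T", "T", "W", None),  # T could be a converted C on Watson
    ("C", "T", "T", "C", "T"),   # on Crick the T is trustworthy
    ("G", "A", "A", "C", None),  # A could be a converted G on Crick
    ("G", "A", "A", "W", "A"),
    ("G", "A", "G", "C", "G"),
])
def test_resolve_allele_cases(ref, alt, base, strand, expected):
    assert resolve_allele(ref, alt, base, strand) == expected


def test_het_snp_validation():
    with pytest.raises(ValueError):
        HetSNP("c", 1, "A", "A")


def _asm_reads(n_ref_meth, n_alt_unmeth, n_ref_unmeth=0, n_alt_meth=0):
    h = _header(len(ASM_REF))
    reads = []

    def add(n, allele, meth, tag):
        seq = list(ASM_REF)
        seq[2] = allele
        if not meth:
            seq[8] = "T"
        for i in range(n):
            reads.append(make_read(h, f"{tag}{i}", 0, "".join(seq)))

    add(n_ref_meth, "A", True, "rm")
    add(n_ref_unmeth, "A", False, "ru")
    add(n_alt_meth, "T", True, "am")
    add(n_alt_unmeth, "T", False, "au")
    return reads


def _asm_index():
    return index_cytosines(Genome({"frag": ASM_REF}))


SNP = HetSNP("frag", 2, "A", "T")


def test_link_pairs_builds_expected_table():
    tables, stats = link_pairs(_asm_reads(10, 10), [SNP], _asm_index())
    assert len(tables) == 1
    t = tables[0]
    assert (t.snp.pos, t.cpg_pos) == (2, 8)
    assert t.counts == [[10, 0], [0, 10]]
    assert stats["n_fragments"] == 20
    assert stats["n_discarded_snp_observations"] == 0


def test_link_pairs_pe_fragment_counts_once():
    """Both mates see the SNP and the CpG; the fragment contributes one
    phased observation, not two."""
    h = _header(len(ASM_REF))
    reads = [make_read(h, "p", 0, ASM_REF[:12], mate=1),
             make_read(h, "p", 2, ASM_REF[2:], mate=2)]
    tables, _ = link_pairs(reads, [SNP], _asm_index())
    assert tables[0].counts == [[1, 0], [0, 0]]


def test_link_pairs_discards_ambiguous_snp_base():
    """With a C/T SNP every Watson T is discarded, so only the C-allele
    row fills; the discard counter records the others."""
    snp = HetSNP("frag", 2, "T", "C")
    reads = _asm_reads(10, 10)  # A-allele reads match neither -> discarded too
    tables, stats = link_pairs(reads, [snp], _asm_index())
    assert stats["n_discarded_snp_observations"] == 20
    assert tables == []


def test_link_pairs_unlinked_when_no_shared_fragment():
    h = _header(len(ASM_REF))
    # this read sees the SNP but ends before the CpG
    reads = [make_read(h, "s", 0, ASM_REF[:6])]
    tables, _ = link_pairs(reads, [SNP], _asm_index())
    assert tables == []


def test_asm_detects_fully_switched_table():
    tables, _ = link_pairs(_asm_reads(10, 10), [SNP], _asm_index())
    ev = asm_test(tables[0])
    assert ev is not None
    assert ev.p_value == pytest.approx(1.0825e-5, rel=1e-4)
    assert ev.test_used == "fisher"
    assert ev.rate_ref == 1.0 and ev.rate_alt == 0.0
    assert ev.delta == pytest.approx(1.0)
    assert ev.allele_balance == pytest.approx(0.5)


def test_asm_no_event_without_allele_effect():
    t = LinkedPairTable(SNP, "frag", 8, [[5, 5], [5, 5]])
    assert asm_test(t) is None
    # one empty allele row is untestable
    assert asm_test(LinkedPairTable(SNP, "frag", 8, [[10, 0], [0, 0]])) is None


def test_asm_label_symmetry():
    t1 = LinkedPairTable(SNP, "frag", 8, [[9, 1], [1, 9]])
    t2 = LinkedPairTable(SNP, "frag", 8, [[1, 9], [9, 1]])
    e1, e2 = asm_test(t1), asm_test(t2)
    assert e1.p_value == pytest.approx(e2.p_value)
    assert e1.delta == pytest.approx(-e2.delta)


def test_call_asm_summary_counts():
    events, summary = call_asm(_asm_reads(10, 10), [SNP], _asm_index())
    assert summary["n_snps"] == 1
    assert summary["n_pairs_linked"] == summary["n_pairs_tested"] == 1
    assert summary["n_events"] == summary["n_asm_snps"] == 1
    assert events[0].cpg_pos == 8


def test_call_asm_without_snps_warns():
    with pytest.warns(UserWarning, match="no heterozygous SNPs"):
        events, summary = call_asm([], [], _asm_index())
    assert events == [] and summary["n_events"] == 0


# --- heterozygous-SNP screen ----------------------------------------------

def test_screen_finds_unambiguous_het():
    """G/T het: the G allele is visible on Watson reads (where T is
    bisulfite-ambiguous) and the T allele on Crick reads."""
    ref = "TTGTTTTTTTTTTTTT"
    genome = Genome({"frag": ref})
    h = _header(len(ref))
    reads = []
    for i in range(10):
        reads.append(make_read(h, f"w{i}", 0, ref, xg="CT"))  # G allele
        alt = ref[:2] + "T" + ref[3:]
        reads.append(make_read(h, f"c{i}", 0, alt, xg="GA"))  # T allele
    snps = screen_het_snps(reads, genome, min_depth=5)
    got = [s for s in snps if s.pos == 2]
    assert len(got) == 1
    assert (got[0].ref, got[0].alt) == ("G", "T")
    assert got[0].confounded  # a G allele loses Crick evidence


def test_screen_ignores_watson_c_t_evidence():
    """A C/T polymorphism is invisible to Watson reads: both bases are
    excluded, so no call is made from Watson data alone."""
    ref = "TTCTTTTTTTTTTTTT"
    genome = Genome({"frag": ref})
    h = _header(len(ref))
    reads = []
    for i in range(20):
        seq = list(ref)
        if i % 2:
            seq[2] = "T"
        reads.append(make_read(h, f"r{i}", 0, "".join(seq)))
    assert screen_het_snps(reads, genome, min_depth=5) == []


def test_screen_homozygous_site_not_called():
    genome = Genome({"frag": ASM_REF})
    h = _header(len(ASM_REF))
    reads = [make_read(h, f"r{i}", 0, ASM_REF) for i in range(20)]
    assert screen_het_snps(reads, genome, min_depth=5) == []


def test_load_het_snps_round_trip(tmp_path, small_genome):
    from rrbskit.simulate import TruthSNP

    snps = [TruthSNP("chrSim", 10, "A", "T", "het", False),
            TruthSNP("chrSim", 20, "C", "T", "het", True),
            TruthSNP("chrSim", 30, "G", "C", "hom", False)]
    path = tmp_path / "t.vcf"
    write_truth_vcf(snps, small_genome, path)
    loaded = load_het_snps(path)
    assert [(s.pos, s.ref, s.alt, s.confounded) for s in loaded] == \
        [(10, "A", "T", False), (20, "C", "T", True)]


# --- end-to-end recovery on simulated data --------------------------------

def test_simulated_asm_segments_are_recovered(small_genome, small_fragments,
                                              small_index, tmp_path):
    """Fully switched allele rates (1.0 vs 0.0) at default coverage are
    all detected; the truth anchors match the called SNPs."""
    frags = small_fragments
    segs = [ASMSegmentSpec(f.chrom, f.start, f.end, 1.0, 0.0)
            for f in frags[::6][:5]]
    cfg = SimulationConfig(seed=11, read_length=90, coverage=10,
                           snp_rate=0.0005)
    truth = simulate_asm(small_genome, frags, segs, cfg, tmp_path / "asm",
                         index=small_index)
    assert truth.asm_pairs, "simulation produced no linked truth pairs"
    snps = load_het_snps(tmp_path / "asm.truth.vcf")
    events, summary = call_asm(str(tmp_path / "asm.truth.sam"), snps,
                               small_index, fragments=frags)
    called = {(e.snp.pos, e.cpg_pos) for e in events}
    truth_pairs = {(t["snp_pos"], t["cpg_pos"]) for t in truth.asm_pairs}
    assert truth_pairs <= called
    # a monoclonal het sample has balanced allele contributions
    balances = [e.allele_balance for e in events
                if (e.snp.pos, e.cpg_pos) in truth_pairs]
    assert all(0.2 < b < 0.8 for b in balances)


def test_null_simulation_event_rate_is_bounded(small_genome, small_fragments,
                                               small_index, tmp_path):
    """No ASM segments: events among tested pairs stay near the test
    size (false positives only)."""
    cfg = SimulationConfig(seed=13, read_length=90, coverage=10,
                           snp_rate=0.01, default_cpg_rate=0.5)
    from rrbskit.simulate import simulate_reads, inject_snps, assign_methylation

    rng = np.random.default_rng(13)
    haps, snps = inject_snps(small_genome, 0.01, rng, 0.5, small_fragments)
    rates = assign_methylation(small_index, [], default_cpg_rate=0.5)
    simulate_reads(small_genome, small_fragments, cfg, tmp_path / "null",
                   site_rates=rates, haplotypes=haps, snps=snps,
                   index=small_index, rng=rng)
    write_truth_vcf(snps, small_genome, tmp_path / "null.vcf")
    het = load_het_snps(tmp_path / "null.vcf")
    events, summary = call_asm(str(tmp_path / "null.truth.sam"), het,
                               small_index, fragments=small_fragments)
    assert summary["n_pairs_tested"] >= 50
    assert summary["n_events"] / summary["n_pairs_tested"] <= 0.07


def test_polyclonal_mixture_detected_with_skewed_balance(
        small_genome, small_fragments, small_index, tmp_path):
    segs = [ASMSegmentSpec(f.chrom, f.start, f.end, 1.0, 0.0,
                           allele_fraction=0.7)
            for f in small_fragments[::6][:3]]
    cfg = SimulationConfig(seed=17, read_length=90, coverage=20,
                           snp_rate=0.0)
    truth = simulate_asm(small_genome, small_fragments, segs, cfg,
                         tmp_path / "poly", index=small_index)
    snps = load_het_snps(tmp_path / "poly.truth.vcf")
    events, _ = call_asm(str(tmp_path / "poly.truth.sam"), snps,
                         small_index, fragments=small_fragments)
    truth_pairs = {(t["snp_pos"], t["cpg_pos"]) for t in truth.asm_pairs}
    hits = [e for e in events if (e.snp.pos, e.cpg_pos) in truth_pairs]
    assert truth_pairs <= {(e.snp.pos, e.cpg_pos) for e in events}
    mean_balance = np.mean([e.allele_balance for e in hits])
    assert 0.6 < mean_balance < 0.8
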