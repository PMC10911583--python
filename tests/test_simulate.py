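"""Synthetic genome pair, SV planting, reads, depth and fluctuation cultures."""

import math

import numpy as np
import pytest
from scipy import stats

from tyhybrid.simulate import (
    GenomeSpec,
    SVEvent,
    SVPlan,
    plant_svs,
    seq_to_str,
    simulate_depth,
    simulate_fluctuation_cultures,
    simulate_parental_pair,
    simulate_reads,
)


def _count_full_length(ann):
    return int((ann.completeness == "full-length").sum())


class TestParentalPair:
    def test_zero_divergence_gives_no_variants(self):
        spec = GenomeSpec(
            n_chromosomes=1, chrom_length=100_000, snp_divergence=0.0,
            n_full_length={"Ty1": 1}, n_solo_ltr={"Ty1": 0}, seed=1,
        )
        pair = simulate_parental_pair(spec)
        assert pair.variants.empty
        for c in pair.p1.chroms:
            assert np.array_equal(pair.p1.chroms[c], pair.p2.chroms[c])

    def test_element_counts_and_no_overlap(self):
        spec = GenomeSpec(
            n_chromosomes=1, chrom_length=500_000, snp_divergence=0.0,
            n_full_length={"Ty1": 5}, n_solo_ltr={"Ty1": 0}, seed=2,
        )
        pair = simulate_parental_pair(spec)
        ann = pair.annotations["P1"]
        assert _count_full_length(ann) == 5
        spans = sorted(zip(ann.start, ann.end))
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_variant_count_binomial(self):
        # no elements -> every position mutable; expect Binomial(L, d)
        spec = GenomeSpec(
            n_chromosomes=1, chrom_length=500_000, snp_divergence=0.01,
            te_families=(), n_full_length={}, n_solo_ltr={}, seed=3,
        )
        pair = simulate_parental_pair(spec)
        n, d = 500_000, 0.01
        sd = math.sqrt(n * d * (1 - d))
        assert abs(len(pair.variants) - n * d) <= 3 * sd

    def test_deterministic_per_seed(self):
        spec = GenomeSpec(n_chromosomes=2, chrom_length=120_000,
                          n_full_length={"Ty1": 3}, n_solo_ltr={"Ty1": 1},
                          seed=7)
        a = simulate_parental_pair(spec)
        b = simulate_parental_pair(spec)
        for c in a.p1.chroms:
            assert np.array_equal(a.p1.chroms[c], b.p1.chroms[c])
        assert a.variants.equals(b.variants)

    def test_planted_elements_have_exact_tsds(self, small_pair):
        for _, el in small_pair.elements.iterrows():
            seq = small_pair.p1.chroms[el.chrom]
            left = seq_to_str(seq[el.start - el.tsd_len : el.start])
            right = seq_to_str(seq[el.end : el.end + el.tsd_len])
            assert left == right == el.tsd

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(snp_divergence=0.3).validate()
        with pytest.raises(ValueError):
            GenomeSpec(chrom_length=10_000).validate()

    def test_overfull_chromosome_errors(self):
        spec = GenomeSpec(
            n_chromosomes=1, chrom_length=150_000,
            n_full_length={"Ty1": 20}, n_solo_ltr={"Ty1": 0}, seed=1,
        )
        with pytest.raises(RuntimeError, match="chr"):
            simulate_parental_pair(spec)


class TestPlantSvs:
    def test_empty_plan_is_identity(self, small_pair):
        truth = plant_svs(small_pair, SVPlan(line_id="l0"), seed=0)
        for sub in ("P1", "P2"):
            g = small_pair.genome(sub)
            for c in g.chroms:
                assert np.array_equal(truth.sequences[sub][c], g.chroms[c])
        assert set(truth.true_classes.sv_class) == {"no_change"}

    def test_excision_leaves_solo_ltr_with_original_tsd(self, small_pair):
        el = small_pair.elements[
            small_pair.elements.completeness == "full-length"
        ].iloc[0]
        plan = SVPlan(
            events=[SVEvent("excision", subgenome="P1", locus_id=el.locus_id)],
            line_id="lx",
        )
        truth = plant_svs(small_pair, plan, seed=0)
        ann = truth.annotations["P1"]
        solo = ann[ann.locus_id == el.locus_id]
        assert len(solo) == 1
        assert solo.completeness.iloc[0] == "solo-LTR"
        assert int(solo.end.iloc[0] - solo.start.iloc[0]) == el.ltr_len
        seq = truth.sequences["P1"][el.chrom]
        s, e = int(solo.start.iloc[0]), int(solo.end.iloc[0])
        left = seq_to_str(seq[s - el.tsd_len : s])
        right = seq_to_str(seq[e : e + el.tsd_len])
        assert left == right == el.tsd

    def test_denovo_insertion_has_exact_tsd(self, small_pair):
        plan = SVPlan(
            events=[SVEvent("denovo", subgenome="P2", tsd_length=5)],
            line_id="ld",
        )
        truth = plant_svs(small_pair, plan, seed=1)
        rec = truth.denovo_records.iloc[0]
        ann = truth.annotations["P2"]
        dn = ann[ann.locus_id == rec.locus_id].iloc[0]
        seq = truth.sequences["P2"][dn.chrom]
        left = seq_to_str(seq[dn.start - 5 : dn.start])
        right = seq_to_str(seq[dn.end : dn.end + 5])
        assert left == right == rec.tsd
        assert len(rec.tsd) == 5

    def test_full_length_bookkeeping(self, small_pair):
        el = small_pair.elements
        fulls = el[el.completeness == "full-length"]
        plan = SVPlan(
            events=[
                SVEvent("denovo", subgenome="P1"),
                SVEvent("deletion", subgenome="P1",
                        locus_id=fulls.locus_id.iloc[0]),
                SVEvent("excision", subgenome="P1",
                        locus_id=fulls.locus_id.iloc[1]),
                SVEvent("truncation", subgenome="P1",
                        locus_id=fulls.locus_id.iloc[2]),
            ],
            line_id="lb",
        )
        truth = plant_svs(small_pair, plan, seed=2)
        n_parent = _count_full_length(small_pair.annotations["P1"])
        n_line = _count_full_length(truth.annotations["P1"])
        # + 1 de novo - 1 deletion - 1 excision - 1 truncation
        assert n_line == n_parent + 1 - 3

    def test_conflicting_events_rejected(self, small_pair):
        locus = small_pair.elements[
            small_pair.elements.completeness == "full-length"
        ].locus_id.iloc[0]
        plan = SVPlan(
            events=[
                SVEvent("excision", subgenome="P1", locus_id=locus),
                SVEvent("deletion", subgenome="P1", locus_id=locus),
            ],
            line_id="lc",
        )
        with pytest.raises(ValueError, match="conflict"):
            plant_svs(small_pair, plan, seed=0)

    def test_loh_swaps_copy_number_reciprocally(self, small_pair):
        el = small_pair.elements[
            small_pair.elements.completeness == "full-length"
        ].iloc[3]
        start = max(int(el.start) - 50_000, 0)
        end = int(el.end) + 50_000
        plan = SVPlan(
            events=[SVEvent("loh", subgenome="P1", chrom=el.chrom,
                            start=start, end=end)],
            line_id="ll",
        )
        truth = plant_svs(small_pair, plan, seed=0)
        mid = (el.start + el.end) // 2
        assert truth.copies_at("P1", el.chrom, mid) == 0
        assert truth.copies_at("P2", el.chrom, mid) == 2
        # locus annotation removed from the losing subgenome representation
        assert el.locus_id not in set(truth.annotations["P1"].locus_id)


class TestReads:
    def test_error_free_reads_report_own_parent(self, small_pair):
        truth = plant_svs(small_pair, SVPlan(line_id="r0"), seed=0)
        reads = simulate_reads(truth, 300, variant_error_rate=0.0, seed=1)
        for r in reads:
            assert all(a == r.true_origin for _v, a in r.observed_alleles)

    def test_zero_divergence_reads_have_no_observations(self):
        spec = GenomeSpec(
            n_chromosomes=2, chrom_length=120_000, snp_divergence=0.0,
            n_full_length={"Ty1": 2}, n_solo_ltr={"Ty1": 0}, seed=4,
        )
        pair = simulate_parental_pair(spec)
        truth = plant_svs(pair, SVPlan(line_id="rz"), seed=0)
        reads = simulate_reads(truth, 50, seed=1)
        assert all(not r.observed_alleles for r in reads)

    def test_flip_fraction_binomial(self, small_pair):
        truth = plant_svs(small_pair, SVPlan(line_id="rf"), seed=0)
        reads = simulate_reads(
            truth, 2000, variant_error_rate=0.05, seed=2
        )
        n = flipped = 0
        for r in reads:
            for _v, a in r.observed_alleles:
                n += 1
                flipped += a != r.true_origin
        sd = math.sqrt(n * 0.05 * 0.95)
        assert abs(flipped - 0.05 * n) <= 3 * sd

    def test_invalid_error_rate_rejected(self, small_pair):
        truth = plant_svs(small_pair, SVPlan(line_id="re"), seed=0)
        with pytest.raises(ValueError):
            simulate_reads(truth, 10, variant_error_rate=0.6, seed=0)


class TestDepth:
    def test_uniform_cn_noise_free_is_constant(self, small_pair):
        truth = plant_svs(small_pair, SVPlan(line_id="d0"), seed=0)
        tracks = simulate_depth(truth, mean_depth=30, noise_sd=0, seed=0)
        assert np.allclose(tracks["P1"].depth, 30.0)

    def test_chromosome_gain_doubles_depth(self, small_pair):
        chrom = list(small_pair.p1.chroms)[1]
        plan = SVPlan(
            events=[SVEvent("aneuploidy", subgenome="P1", chrom=chrom,
                            copies=2)],
            line_id="d2",
        )
        truth = plant_svs(small_pair, plan, seed=0)
        tracks = simulate_depth(truth, mean_depth=30, noise_sd=0, seed=0)
        t = tracks["P1"]
        assert np.allclose(t.loc[t.chrom == chrom, "depth"], 60.0)
        assert np.allclose(t.loc[t.chrom != chrom, "depth"], 30.0)

    def test_noise_is_gaussian(self, small_pair):
        truth = plant_svs(small_pair, SVPlan(line_id="dn"), seed=0)
        tracks = simulate_depth(
            truth, mean_depth=30, noise_sd=3.0, window=1000, seed=5
        )
        z = (tracks["P1"].depth.to_numpy() - 30.0) / 3.0
        z = z[:1000]
        assert stats.normaltest(z).pvalue > 0.01


class TestFluctuationCultures:
    def test_mu_zero_all_counts_zero(self):
        c = simulate_fluctuation_cultures(0.0, 500, 1_000_000, 100, seed=0)
        assert np.all(c == 0)

    def test_zero_fraction_matches_p0(self):
        mu, n0, nt = 1e-6, 500, 1_024_000
        c = simulate_fluctuation_cultures(mu, n0, nt, 1000, seed=1)
        m = mu * nt
        p0 = math.exp(-m)
        sd = math.sqrt(1000 * p0 * (1 - p0))
        assert abs((c == 0).sum() - 1000 * p0) <= 3 * sd

    def test_deterministic_per_seed(self):
        a = simulate_fluctuation_cultures(1e-6, 500, 1_000_000, 50, seed=9)
        b = simulate_fluctuation_cultures(1e-6, 500, 1_000_000, 50, seed=9)
        assert np.array_equal(a, b)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_fluctuation_cultures(1e-6, 1000, 500, 10, seed=0)
        with pytest.raises(ValueError):
            simulate_fluctuation_cultures(0.5, 500, 1_000_000, 10, seed=0)
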