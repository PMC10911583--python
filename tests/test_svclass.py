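"""Locus-state classification hierarchy, sub-classification and tallies."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tyhybrid.svclass import (
    LocusState,
    SVCall,
    assembly_presence,
    classify_locus,
    consistency_filter,
    subclassify_cn_change,
    tally_and_test,
)

FL = ("Ty1", "full-length")
SOLO = ("Ty1", "solo-LTR")
TRUNC = ("Ty1", "truncated")


def _state(**kw):
    base = dict(
        cluster_id="C1",
        line_id="l1",
        subgenome="P1",
        chrom="chr01",
        span=(10_000, 16_000),
        is_complex=False,
        parent_types=(FL,),
        ma_types=(FL,),
        cn_ma=1.0,
        cn_parent=1.0,
        assembly_present=True,
    )
    base.update(kw)
    return LocusState(**base)


def _blocks(spans):
    return pd.DataFrame(
        [[s, e, s, e] for s, e in spans],
        columns=["src_start", "src_end", "dst_start", "dst_end"],
    )


class TestAssemblyPresence:
    def test_identity_map_present(self):
        rev = {"chr01": _blocks([(0, 100_000)])}
        assert assembly_presence((10_000, 16_000), "chr01", 100_000, rev)

    def test_missing_region_absent(self):
        rev = {"chr01": _blocks([(0, 5_000)])}
        assert not assembly_presence((10_000, 16_000), "chr01", 100_000, rev)

    def test_single_mapping_flank_is_absent(self):
        # only the left flank maps; both are required
        rev = {"chr01": _blocks([(0, 10_000)])}
        assert not assembly_presence((10_000, 16_000), "chr01", 100_000, rev)

    def test_small_tsd_gap_tolerated(self):
        # a deletion removed the element plus 6 bases of one flank
        rev = {"chr01": _blocks([(0, 10_000), (16_006, 100_000)])}
        assert assembly_presence((10_000, 16_000), "chr01", 100_000, rev)


class TestConsistencyFilter:
    @pytest.mark.parametrize(
        "cn,present,expected",
        [
            (0, False, "keep"),
            (0, True, "exclude"),
            (2, False, "exclude"),
            (1, True, "keep"),
        ],
    )
    def test_rule(self, cn, present, expected):
        assert consistency_filter(cn, present) == expected

    def test_negative_cn_rejected(self):
        with pytest.raises(ValueError):
            consistency_filter(-1, True)


class TestClassifyLocus:
    def test_identical_locus_is_no_change(self):
        call = classify_locus(_state())
        assert call.sv_class == "no_change"
        assert call.cn_delta == 0.0

    def test_cn_shift_with_same_content(self):
        call = classify_locus(_state(cn_ma=2.0))
        assert call.sv_class == "cn_change"
        assert call.cn_delta == 1.0

    def test_full_loss_with_absent_assembly_is_cn_change(self):
        call = classify_locus(
            _state(ma_types=(), cn_ma=0.0, assembly_present=False)
        )
        assert call.sv_class == "cn_change"
        assert call.cn_delta == -1.0

    def test_truncation(self):
        call = classify_locus(_state(ma_types=(TRUNC,)))
        assert call.sv_class == "truncation"
        assert call.cn_delta == -1.0

    def test_excision(self):
        call = classify_locus(_state(ma_types=(SOLO,)))
        assert call.sv_class == "excision"
        assert call.cn_delta == -1.0

    def test_denovo_candidate_fresh_site(self):
        call = classify_locus(_state(parent_types=(), ma_types=(FL,)))
        assert call.sv_class == "denovo_candidate"
        assert call.cn_delta == 1.0

    def test_denovo_candidate_next_to_parental_copy(self):
        call = classify_locus(
            _state(parent_types=(FL,), ma_types=(FL, FL), is_complex=True)
        )
        assert call.sv_class == "denovo_candidate"

    def test_deletion(self):
        call = classify_locus(_state(ma_types=(), assembly_present=True))
        assert call.sv_class == "deletion"
        assert call.cn_delta == -1.0

    def test_unresolvable_state_is_unclassified(self):
        call = classify_locus(
            _state(parent_types=(SOLO,), ma_types=(FL, FL, FL))
        )
        assert call.sv_class == "unclassified"

    def test_contradictory_state_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            _state(ma_types=(), ma_has_annotation=True)


class TestSubclassify:
    def _cn_call(self, delta=1.0):
        return SVCall("C1", "l1", "P1", "cn_change", delta)

    def test_ploidy_metadata_wins(self):
        tr = pd.DataFrame(
            [["chr01", 0, 100_000, 2.0, 2.0]],
            columns=["chrom", "start", "end", "level", "copy_number"],
        )
        out = subclassify_cn_change(
            self._cn_call(), (10_000, 16_000), "chr01", tr, tr, 100_000,
            ploidy=2,
        )
        assert out.sv_class == "polyploidy"

    def test_whole_chromosome_tract_is_aneuploidy(self):
        tr = pd.DataFrame(
            [["chr01", 0, 100_000, 2.0, 2.0]],
            columns=["chrom", "start", "end", "level", "copy_number"],
        )
        hom = pd.DataFrame(
            [["chr01", 0, 100_000, 1.0, 1.0]],
            columns=["chrom", "start", "end", "level", "copy_number"],
        )
        out = subclassify_cn_change(
            self._cn_call(), (10_000, 16_000), "chr01", tr, hom, 100_000,
            ploidy=1,
        )
        assert out.sv_class == "aneuploidy"

    def test_reciprocal_segment_is_loh(self):
        tr = pd.DataFrame(
            [
                ["chr01", 0, 40_000, 1.0, 1.0],
                ["chr01", 40_000, 240_000, 2.0, 2.0],
                ["chr01", 240_000, 1_000_000, 1.0, 1.0],
            ],
            columns=["chrom", "start", "end", "level", "copy_number"],
        )
        hom = pd.DataFrame(
            [
                ["chr01", 0, 40_000, 1.0, 1.0],
                ["chr01", 40_000, 240_000, 0.0, 0.0],
                ["chr01", 240_000, 1_000_000, 1.0, 1.0],
            ],
            columns=["chrom", "start", "end", "level", "copy_number"],
        )
        out = subclassify_cn_change(
            self._cn_call(), (100_000, 106_000), "chr01", tr, hom, 1_000_000,
            ploidy=1,
        )
        assert out.sv_class == "loh"

    def test_segmental_without_reciprocal_defaults_to_aneuploidy(self):
        tr = pd.DataFrame(
            [
                ["chr01", 0, 40_000, 1.0, 1.0],
                ["chr01", 40_000, 240_000, 2.0, 2.0],
                ["chr01", 240_000, 1_000_000, 1.0, 1.0],
            ],
            columns=["chrom", "start", "end", "level", "copy_number"],
        )
        hom = pd.DataFrame(
            [["chr01", 0, 1_000_000, 1.0, 1.0]],
            columns=["chrom", "start", "end", "level", "copy_number"],
        )
        out = subclassify_cn_change(
            self._cn_call(), (100_000, 106_000), "chr01", tr, hom, 1_000_000,
            ploidy=1,
        )
        assert out.sv_class == "aneuploidy"

    def test_missing_homolog_tracts_rejected(self):
        tr = pd.DataFrame(
            [["chr01", 0, 100_000, 2.0, 2.0]],
            columns=["chrom", "start", "end", "level", "copy_number"],
        )
        with pytest.raises(ValueError, match="homolog"):
            subclassify_cn_change(
                self._cn_call(), (10_000, 16_000), "chr01", tr,
                pd.DataFrame(), 100_000, ploidy=1,
            )


def _calls(rows):
    return pd.DataFrame(
        rows, columns=["line_id", "subgenome", "cross", "sv_class", "cn_delta"]
    )


class TestTallyAndTest:
    def test_all_zero_cross_not_applicable(self):
        calls = _calls(
            [[f"l{i}", "P1", "X", "no_change", 0.0] for i in range(6)]
        )
        out = tally_and_test(calls)
        assert out["tests"].status.iloc[0] == "n/a"
        assert out["net"].net.sum() == 0.0

    def test_consistent_gains_are_significant(self):
        # +2 planted gains in 10/10 lines; exact two-sided signed-rank null
        # for all-positive n=10 is 2/2^10 < 0.01
        calls = _calls(
            [[f"l{i}", "P1", "X", "aneuploidy", 2.0] for i in range(10)]
        )
        out = tally_and_test(calls)
        p = out["tests"].p_value.iloc[0]
        assert p == pytest.approx(2 / 2**10, rel=0.01)
        assert p < 0.01

    def test_symmetric_null_rarely_significant(self):
        rng = np.random.default_rng(0)
        false_pos = 0
        n_sim = 100
        for s in range(n_sim):
            deltas = rng.choice([-1.0, 1.0], size=10)
            calls = _calls(
                [[f"l{i}", "P1", "X", "loh", d] for i, d in enumerate(deltas)]
            )
            tests = tally_and_test(calls)["tests"]
            if tests.status.iloc[0] == "ok" and tests.p_value.iloc[0] <= 0.05:
                false_pos += 1
        assert false_pos <= 10

    def test_bookkeeping_identity(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(8):
            for j in range(5):
                rows.append(
                    [f"l{i}", "P1", "X", "loh", float(rng.integers(-2, 3))]
                )
        calls = _calls(rows)
        out = tally_and_test(calls)
        per_class = out["per_class"]
        merged = per_class.groupby("line_id")[["gain", "loss"]].sum()
        net = out["net"].set_index("line_id").net
        for line in merged.index:
            assert merged.loc[line, "gain"] - merged.loc[line, "loss"] == (
                pytest.approx(net[line])
            )

    def test_fdr_correction_across_crosses(self):
        rows = []
        for c in range(4):
            for i in range(10):
                rows.append([f"c{c}l{i}", "P1", f"X{c}", "aneuploidy", 1.0])
        out = tally_and_test(_calls(rows))
        tests = out["tests"]
        assert (tests.p_fdr >= tests.p_value - 1e-15).all()
        assert tests.significant.all()

    def test_size_correlation_reported(self):
        rng = np.random.default_rng(2)
        rows, sizes = [], []
        for i in range(12):
            delta = float(rng.integers(-3, 4))
            rows.append([f"l{i}", "P1", "X", "aneuploidy", delta])
            sizes.append([f"l{i}", "P1", delta * 0.006 + rng.normal(0, 0.001)])
        out = tally_and_test(
            _calls(rows),
            pd.DataFrame(sizes, columns=["line_id", "subgenome", "delta_mb"]),
        )
        assert out["size_correlation"]["rho"] > 0.5
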