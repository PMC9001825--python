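import numpy as np
import pytest

from tripssa.construct import MismatchSpec, build_reference_construct
from tripssa.quantify import (
    AmpliconCall,
    UmiVote,
    call_barcodes,
    calls_to_frame,
    conflict_rate,
    global_bias,
    parse_amplicon_pair,
    run_quantification,
    swap_strand_labels,
    tabulate_umis,
)
from tripssa.simulate import (
    SimConfig,
    simulate_barcode_panel,
    simulate_repair_outcomes,
    simulate_umi_amplicon_reads,
)

from conftest import as_pairs

BARCODE = "ACGTACGTACGTACGTACGT"


def make_pair(construct, pathway, strand=None, umi="A" * 18):
    """Generator round-trip: emit one clean read pair for a known outcome."""
    from tripssa.simulate import FWD_CORE_START, REV_CORE_END
    from tripssa.construct import complement, revcomp

    if pathway == "NHEJ":
        fwd_core = construct.right_repeat[FWD_CORE_START:]
        rev_core = construct.left_repeat[:REV_CORE_END]
    else:
        mm = construct.mismatch
        top_base = (
            mm.top_allele if strand == "top" else complement(mm.bottom_allele)
        )
        seg = construct.repeat_with_top_base(top_base)
        fwd_core = seg[FWD_CORE_START:]
        rev_core = seg[:REV_CORE_END]
    return (
        BARCODE + construct.watermark + fwd_core,
        umi + revcomp(rev_core),
    )


@pytest.fixture(scope="module")
def gt():
    return build_reference_construct(MismatchSpec.from_code("G:T"), BARCODE)


class TestParseAmplicon:
    @pytest.mark.parametrize("code", ["A:G", "T:G", "A:C", "T:C", "G:T"])
    @pytest.mark.parametrize("strand", ["top", "bottom"])
    def test_ssa_roundtrip(self, code, strand):
        c = build_reference_construct(MismatchSpec.from_code(code), BARCODE)
        fwd, rev = make_pair(c, "SSA", strand)
        rec = parse_amplicon_pair(fwd, rev, c)
        assert rec.accepted
        assert rec.call == strand
        assert rec.barcode == BARCODE

    def test_nhej_reads_do_not_overlap(self, gt):
        fwd, rev = make_pair(gt, "NHEJ")
        assert parse_amplicon_pair(fwd, rev, gt).call == "NHEJ"

    def test_non_complementary_mismatch_rejected(self, gt):
        # Corrupt the variant base on the forward read only: the two reads
        # no longer reverse-complement each other at the mismatch position.
        fwd, rev = make_pair(gt, "SSA", "top")
        pos = fwd.index(gt.watermark) + len(gt.watermark) + 3
        corrupted = fwd[:pos] + "C" + fwd[pos + 1 :]
        rec = parse_amplicon_pair(corrupted, rev, gt)
        assert not rec.accepted

    def test_missing_watermark_rejected(self, gt):
        rec = parse_amplicon_pair("A" * 100, "T" * 100, gt)
        assert rec.reject_reason == "no_watermark"

    def test_tolerates_errors_in_half_segments(self, gt):
        fwd, rev = make_pair(gt, "SSA", "top")
        # Five substitutions away from the variant position stay within the
        # 10-edit budget for identifying the half F segments.
        fwd_mut = list(fwd)
        for pos in (50, 55, 60, 65, 70):
            fwd_mut[pos] = "A" if fwd[pos] != "A" else "G"
        rec = parse_amplicon_pair("".join(fwd_mut), rev, gt)
        assert rec.accepted and rec.call == "top"


class TestTabulateUmis:
    def rec(self, barcode, umi, call):
        return AmpliconCall(barcode, umi, call)

    def test_single_read_pairs_dropped(self):
        records = [self.rec("B" * 20, "U" * 18, "top")]
        assert tabulate_umis(records) == []

    def test_read_majority_and_tie_rejection(self):
        b, u = "B" * 20, "U" * 18
        votes = tabulate_umis(
            [self.rec(b, u, "top"), self.rec(b, u, "top"), self.rec(b, u, "bottom")]
        )
        assert len(votes) == 1 and votes[0].call == "top" and votes[0].read_count == 3
        tied = tabulate_umis([self.rec(b, u, "top"), self.rec(b, u, "bottom")])
        assert tied == []

    def test_chimeric_umi_dropped(self):
        u = "U" * 18
        b1, b2 = "A" * 20, "G" * 20
        records = [
            self.rec(b1, u, "top"),
            self.rec(b1, u, "top"),
            self.rec(b2, u, "top"),
            self.rec(b2, u, "top"),
        ]
        assert tabulate_umis(records) == []

    def test_umi_errors_cluster_corrected(self):
        b = "A" * 20
        u1, u2 = "U" * 18, "U" * 17 + "T"  # one substitution apart
        votes = tabulate_umis(
            [self.rec(b, u1, "top"), self.rec(b, u1, "top"), self.rec(b, u2, "top")]
        )
        assert len(votes) == 1 and votes[0].read_count == 3


class TestCallBarcodes:
    def votes(self, barcode, calls):
        return [UmiVote(barcode, f"U{i:017d}", 2, c) for i, c in enumerate(calls)]

    def test_more_nhej_than_ssa_removed(self):
        calls = call_barcodes(self.votes("b1", ["NHEJ"] * 3 + ["top"] * 2))
        assert calls[0].filter_reason == "more_nhej_than_ssa"

    def test_nhej_tie_retained(self):
        calls = call_barcodes(self.votes("b1", ["NHEJ", "NHEJ", "top", "bottom"]))
        assert calls[0].retained

    def test_single_umi_removed(self):
        calls = call_barcodes(self.votes("b1", ["top"]))
        assert calls[0].filter_reason == "single_umi"

    def test_control_barcode_removed(self):
        calls = call_barcodes(self.votes("b1", ["top", "top"]), {"b1"})
        assert calls[0].filter_reason == "in_control"

    def test_conflict_and_majority(self):
        calls = call_barcodes(self.votes("b1", ["top", "top", "bottom"]))
        assert calls[0].majority_allele == "top"
        assert calls[0].has_conflict

    def test_filters_idempotent(self):
        votes = self.votes("b1", ["top", "top"]) + self.votes("b2", ["NHEJ", "NHEJ", "top"])
        first = call_barcodes(votes)
        retained_votes = [
            v for v in votes if any(c.barcode == v.barcode and c.retained for c in first)
        ]
        second = call_barcodes(retained_votes)
        assert all(c.retained for c in second)
        assert {c.barcode for c in second} == {c.barcode for c in first if c.retained}


class TestBiasEstimates:
    def test_simple_proportions(self):
        votes = [UmiVote("b1", f"U{i:017d}", 2, "top") for i in range(80)]
        votes += [UmiVote("b1", f"V{i:017d}", 2, "bottom") for i in range(20)]
        est = global_bias(call_barcodes(votes))
        assert est.bias == pytest.approx(0.8)
        assert est.ci_low < 0.8 < est.ci_high

    def test_all_top_gives_one(self):
        votes = [UmiVote("b1", f"U{i:017d}", 2, "top") for i in range(10)]
        assert global_bias(call_barcodes(votes)).bias == 1.0

    def test_unanimous_barcodes_have_zero_conflict(self):
        votes = [UmiVote("b1", f"U{i:017d}", 2, "top") for i in range(5)]
        assert conflict_rate(call_barcodes(votes)) == 0.0

    def test_strand_relabeling_involution(self):
        rng = np.random.default_rng(3)
        votes = [
            UmiVote(f"b{i % 40:020d}", f"U{i:017d}", 2, "top" if rng.random() < 0.7 else "bottom")
            for i in range(400)
        ]
        b = global_bias(call_barcodes(votes)).bias
        b_swapped = global_bias(call_barcodes(swap_strand_labels(votes))).bias
        assert b_swapped == pytest.approx(1.0 - b, abs=1e-12)


class TestPipelineRecovery:
    @pytest.mark.parametrize("strand_bias", [0.2, 0.5, 0.8])
    def test_parameter_recovery(self, strand_bias):
        config = SimConfig(
            seed=17,
            n_barcodes=600,
            n_replicates=1,
            construct="G:T",
            mode="PCR",
            strand_bias=strand_bias,
            unrepaired_fraction=0.0,
        )
        panel = simulate_barcode_panel(config)
        outcomes = simulate_repair_outcomes(panel, config)
        fwd, rev = simulate_umi_amplicon_reads(outcomes, config, 0)[:2]
        construct = build_reference_construct(MismatchSpec.from_code("G:T"), BARCODE)
        calls, _, _ = run_quantification(as_pairs(fwd, rev), construct)
        est = global_bias(calls)
        se = np.sqrt(strand_bias * (1 - strand_bias) / est.n_umis) + 1e-6
        # The generative truth for this run, not the nominal parameter:
        sub = outcomes[(outcomes.pathway == "SSA") & outcomes.repaired]
        truth = (sub.resolved_strand == "top").mean()
        assert abs(est.bias - truth) < max(4 * se, 0.02)

    def test_error_free_run_recovers_every_allele(self):
        config = SimConfig(
            seed=18,
            n_barcodes=150,
            n_replicates=1,
            construct="T:G",
            mode="PCR",
            unrepaired_fraction=0.0,
            ssa_fraction=1.0,
            sequencing_error=0.0,
            polymerase_error=0.0,
            template_switch_rate=0.0,
            deamination_meth=0.0,
            deamination_unmeth=0.0,
        )
        panel = simulate_barcode_panel(config)
        outcomes = simulate_repair_outcomes(panel, config)
        fwd, rev, _ = simulate_umi_amplicon_reads(outcomes, config, 0)
        construct = build_reference_construct(MismatchSpec.from_code("T:G"), BARCODE)
        calls, _, _ = run_quantification(as_pairs(fwd, rev), construct)
        truth = outcomes.set_index("barcode")["resolved_strand"]
        retained = [c for c in calls if c.retained]
        assert retained
        for call in retained:
            assert call.majority_allele == truth[call.barcode]
            assert not call.has_conflict
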