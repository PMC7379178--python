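"""Switch detection, block splitting, parental flipping and their invariants."""

import pytest

from phaseqc.block_correction import (
    Breakpoint,
    CorrectionConfig,
    apply_breakpoints,
    correct_with_parents,
    detect_all_breakpoints,
    detect_breakpoints,
)
from phaseqc.linkage_pairs import build_pair_list, index_pairs
from phaseqc.quality_report import n50
from phaseqc.synthetic_fixtures import SimConfig, simulate_panel, simulate_proband
from phaseqc.trio_benchmark import TrioTruth, benchmark
from phaseqc.vcf_phase_io import extract_blocks

from conftest import pair_index_from, parse_records, phased_block


def switch_block(n=10, switch_at=5, step=100):
    """A block whose SNVs at index >= switch_at are on the wrong haplotype."""
    positions = [100 + step * i for i in range(n)]
    hap = {p: (0 if i < switch_at else 1) for i, p in enumerate(positions)}
    return phased_block(hap), positions


def cis_pairs(positions, window=2):
    return pair_index_from([
        (positions[i], positions[j], "cis")
        for i in range(len(positions))
        for j in range(i + 1, min(i + 1 + window, len(positions)))
    ])


class TestDetectBreakpoints:
    def test_cut_at_first_conflicting_snv_of_a_switch(self):
        block, positions = switch_block(n=10, switch_at=5)
        breakpoints = detect_breakpoints(block, cis_pairs(positions),
                                         CorrectionConfig(lookback=2))
        assert len(breakpoints) == 1
        bp = breakpoints[0]
        assert bp.cut_before_pos == positions[5]
        assert bp.n_mismatch >= 2 and bp.n_match == 0

    def test_concordant_block_yields_no_breakpoints(self):
        block, positions = switch_block(switch_at=10)  # never switches
        assert detect_breakpoints(block, cis_pairs(positions)) == []

    def test_single_mismatching_pair_is_below_min_evidence(self):
        # a flip seen by exactly one pair: 1 mismatch < min_mismatches
        positions = [100 + 100 * i for i in range(10)]
        hap = {p: 0 for p in positions}
        hap[positions[7]] = 1
        block = phased_block(hap)
        idx = pair_index_from([(positions[6], positions[7], "cis")])
        assert detect_breakpoints(block, idx) == []

    def test_tied_evidence_does_not_cut(self):
        # 2 matches vs 2 mismatches at the decision point: ratio 1 is not < 1
        positions = [100 + 100 * i for i in range(8)]
        hap = {p: 0 for p in positions}
        hap[positions[4]] = 1
        block = phased_block(hap)
        idx = pair_index_from([
            (positions[0], positions[4], "cis"),    # mismatch at t=4
            (positions[1], positions[4], "cis"),    # mismatch at t=4
            (positions[2], positions[4], "trans"),  # match at t=4
            (positions[3], positions[4], "trans"),  # match at t=4
        ])
        cfg = CorrectionConfig(min_mismatches=2, lookback=4)
        assert detect_breakpoints(block, idx, cfg) == []
        # one fewer match and the same evidence cuts
        idx2 = pair_index_from([
            (positions[0], positions[4], "cis"),
            (positions[1], positions[4], "cis"),
            (positions[2], positions[4], "trans"),
        ])
        assert len(detect_breakpoints(block, idx2, cfg)) == 1

    def test_blocks_with_no_pair_coverage_yield_nothing(self):
        block, _ = switch_block()
        assert detect_breakpoints(block, pair_index_from([])) == []

    def test_short_blocks_are_skipped(self):
        block = phased_block({100: 0, 200: 1})
        assert detect_breakpoints(block, pair_index_from([(100, 200, "cis")])) == []


class TestApplyBreakpoints:
    def test_split_conserves_variants_and_gts(self):
        cfg = SimConfig(seed=3, n_sites=100, n_blocks=1, switch_runs=((40, 30),))
        vcf, _ = simulate_proband(cfg)
        idx = {cfg.chrom: index_pairs(build_pair_list(simulate_panel(cfg)))}
        bps = detect_all_breakpoints(vcf, idx)
        assert len(bps) == 2     # entry and exit of the inverted run
        corrected = apply_breakpoints(vcf, bps)
        before = sorted((v.pos, v._sample_fields()[v.gt_index])
                        for v in vcf.all_variants())
        after = sorted((v.pos, v._sample_fields()[v.gt_index])
                       for v in corrected.all_variants())
        assert before == after   # only PS may change
        blocks = extract_blocks(corrected.variants[cfg.chrom])
        assert len(blocks) == 1 + len(bps)
        assert sum(b.n_snvs for b in blocks) == 100

    def test_new_ps_is_position_of_new_block_start(self):
        block, positions = switch_block(n=10, switch_at=5)
        records = [("1", p, "A", "G", "GT:PS",
                    f"{a}|{1 - a}:{positions[0]}")
                   for p, a in zip(positions, [0] * 5 + [1] * 5)]
        vcf = parse_records(records)
        bp = Breakpoint("1", str(positions[0]), positions[5], 0, 2)
        corrected = apply_breakpoints(vcf, [bp])
        blocks = extract_blocks(corrected.variants["1"])
        assert [b.block_id for b in blocks] == [str(positions[0]), str(positions[5])]
        assert all(v.phase_set == str(positions[5])
                   for v in blocks[1].variants)

    def test_zero_breakpoints_is_identity(self):
        vcf, _ = simulate_proband(SimConfig(seed=4, n_sites=50, n_blocks=2))
        corrected = apply_breakpoints(vcf, [])
        assert [v.to_line() for v in corrected.all_variants()] == [
            v.to_line() for v in vcf.all_variants()
        ]

    def test_two_cuts_give_three_blocks_with_recomputed_n50(self):
        positions = [1000 * (i + 1) for i in range(12)]
        records = [("1", p, "A", "G", "GT:PS", "0|1:1000") for p in positions]
        vcf = parse_records(records)
        cuts = [Breakpoint("1", "1000", positions[4], 0, 2),
                Breakpoint("1", "1000", positions[10], 0, 2)]
        corrected = apply_breakpoints(vcf, cuts)
        blocks = extract_blocks(corrected.variants["1"])
        assert [b.n_snvs for b in blocks] == [4, 6, 2]
        assert n50([b.span_bp for b in blocks]) == 5000   # spans 3000,5000,1000

    def test_unknown_cut_position_is_an_error(self):
        vcf, _ = simulate_proband(SimConfig(seed=4, n_sites=50, n_blocks=1))
        block = extract_blocks(vcf.variants["1"])[0]
        bad = Breakpoint("1", block.block_id, block.positions[0] + 1, 0, 2)
        with pytest.raises(ValueError, match="not a variant"):
            apply_breakpoints(vcf, [bad])


class TestLinkageCorrectionProperties:
    def make_fixture(self, seed=11):
        cfg = SimConfig(seed=seed, n_sites=600, n_blocks=3,
                        switch_runs=((80, 25), (250, 30), (430, 40)))
        vcf, truth = simulate_proband(cfg)
        panel = simulate_panel(cfg)
        idx = {cfg.chrom: index_pairs(build_pair_list(panel))}
        return cfg, vcf, truth, idx

    def test_correction_removes_injected_long_switches(self):
        _, vcf, truth, idx = self.make_fixture()
        pre = benchmark(vcf, truth.to_trio_truth())
        assert pre.n_long_switch == 3
        corrected = apply_breakpoints(vcf, detect_all_breakpoints(vcf, idx))
        post = benchmark(corrected, truth.to_trio_truth())
        assert post.n_long_switch <= pre.n_long_switch
        assert post.n_long_switch == 0
        assert post.n_compared == pre.n_compared == 600

    def test_rerunning_correction_is_idempotent(self):
        _, vcf, _, idx = self.make_fixture()
        corrected = apply_breakpoints(vcf, detect_all_breakpoints(vcf, idx))
        assert detect_all_breakpoints(corrected, idx) == []

    def test_cuts_land_near_true_switch_boundaries(self):
        cfg, vcf, truth, idx = self.make_fixture()
        cfg_corr = CorrectionConfig()
        bps = detect_all_breakpoints(vcf, idx, cfg_corr)
        true_edges = [int(truth.positions[i]) for i in truth.switch_boundaries]
        pos_index = {int(p): i for i, p in enumerate(truth.positions)}
        for bp in bps:
            nearest = min(abs(pos_index[bp.cut_before_pos] - pos_index[e])
                          for e in true_edges)
            assert nearest <= cfg_corr.lookback

    def test_raising_ratio_threshold_only_adds_cuts(self):
        _, vcf, _, idx = self.make_fixture()
        cuts = {}
        for ratio in (0.5, 1.0, 2.0):
            cfg = CorrectionConfig(ratio_threshold=ratio)
            cuts[ratio] = {(b.chrom, b.cut_before_pos)
                           for b in detect_all_breakpoints(vcf, idx, cfg)}
        assert cuts[0.5] <= cuts[1.0] <= cuts[2.0]


class TestParentalCorrection:
    def test_flips_disagreeing_snvs_only(self):
        records = [
            ("1", 100, "A", "G", "GT:PS", "1|0:100"),   # truth 0|1 -> flip
            ("1", 200, "C", "T", "GT:PS", "0|1:100"),   # agrees -> unchanged
            ("1", 300, "G", "A", "GT:PS", "1|0:100"),   # not in truth -> unchanged
        ]
        vcf = parse_records(records)
        truth = TrioTruth(orientations={("1", 100, "A", "G"): 0,
                                        ("1", 200, "C", "T"): 0})
        corrected = correct_with_parents(vcf, truth)
        v100, v200, v300 = corrected.variants["1"]
        assert v100.columns[9] == "0|1:100"             # flipped, same PS
        assert v200.columns[9] == "0|1:100"
        assert v300.columns[9] == "1|0:100"
        assert len(extract_blocks(corrected.variants["1"])) == 1   # no splits

    def test_parental_mode_zeroes_the_benchmark(self):
        cfg = SimConfig(seed=9, n_sites=400, n_blocks=2, flip_rate=0.02,
                        switch_runs=((50, 25), (250, 40)))
        vcf, truth = simulate_proband(cfg)
        corrected = correct_with_parents(vcf, truth.to_trio_truth())
        result = benchmark(corrected, truth.to_trio_truth())
        assert result.hamming_error_rate == 0.0
        assert (result.n_flip, result.n_short_switch, result.n_long_switch) == (0, 0, 0)


def test_correction_config_validation():
    with pytest.raises(ValueError):
        CorrectionConfig(min_mismatches=0)
    with pytest.raises(ValueError):
        CorrectionConfig(ratio_threshold=0)
    with pytest.raises(ValueError):
        CorrectionConfig(lookback=0)
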