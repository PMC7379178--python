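"""Switch-error detection and phase-block splitting from linkage evidence.

A switch error inverts the haplotype assignment of every SNV downstream of
some point in a block, so linkage pairs that straddle the switch point
mismatch while pairs on either side still match.  The detector scans each
block in position order, accumulating match/mismatch evidence from pairs to
recent upstream SNVs; when a "suspicion streak" gathers at least
``min_mismatches`` mismatches and its matches/mismatches ratio falls below
``ratio_threshold``, the block is cut so that the first conflicting SNV
starts a new phase block.  Only block membership (PS) changes; no genotype
is ever altered in linkage mode, because population linkage lacks the
resolution to fix single flips.

Parental mode is the converse: with trio-derived truth available, single
SNVs are flipped to the truth orientation and no block is split.
"""

from __future__ import annotations

from dataclasses import dataclass

from phaseqc.linkage_pairs import PairIndex
from phaseqc.quality_report import pair_match
from phaseqc.trio_benchmark import TrioTruth
from phaseqc.vcf_phase_io import PhaseBlock, PhasedVcf, extract_blocks


@dataclass
class CorrectionConfig:
    """Cut-decision parameters.

    min_mismatches
        Minimum mismatching pairs in a streak before a cut is considered
        (default 2).
    ratio_threshold
        Cut only while streak matches/mismatches < this ratio (default 1.0;
        a tie — ratio exactly 1 — never cuts).
    lookback
        How many upstream het SNVs of the current block each SNV is
        compared against (default 3, matching the pair-list window).
    """

    min_mismatches: int = 2
    ratio_threshold: float = 1.0
    lookback: int = 3

    def __post_init__(self) -> None:
        if self.min_mismatches < 1:
            raise ValueError("min_mismatches must be >= 1")
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be > 0")
        if self.lookback < 1:
            raise ValueError("lookback must be >= 1")


@dataclass(frozen=True)
class Breakpoint:
    """A decided cut: the SNV at ``cut_before_pos`` starts a new block."""

    chrom: str
    block_id: str
    cut_before_pos: int
    n_match: int
    n_mismatch: int


def detect_breakpoints(
    block: PhaseBlock,
    pair_index: PairIndex,
    cfg: CorrectionConfig | None = None,
) -> list[Breakpoint]:
    """Scan one block for switch evidence and decide cut positions.

    Streak semantics: the first SNV contributing a mismatch opens a streak;
    subsequent SNVs add their pair tallies to it.  The streak ends either
    with a cut — once mismatches >= ``min_mismatches`` and
    matches/mismatches < ``ratio_threshold`` — placed at the streak's first
    SNV, or with a fully matching SNV whose evidence restores the ratio to
    at least the threshold.  After a cut the scan continues with the new
    block's first SNV as the segment start; pairs crossing a cut carry no
    phase information and are ignored.
    """
    cfg = cfg or CorrectionConfig()
    variants = block.variants
    if len(variants) < 3:
        return []

    breakpoints: list[Breakpoint] = []
    segment_start = 0            # index of current block's first SNV
    streak_start: int | None = None
    n_match = n_mismatch = 0

    for t in range(1, len(variants)):
        vt = variants[t]
        t_match = t_mismatch = 0
        low = max(segment_start, t - cfg.lookback)
        for s in range(low, t):
            pair = pair_index.relation(variants[s].pos, vt.pos)
            if pair is None:
                continue
            if pair_match(variants[s].hap_a_allele, vt.hap_a_allele, pair):
                t_match += 1
            else:
                t_mismatch += 1

        if streak_start is None:
            if t_mismatch == 0:
                continue
            streak_start = t
        n_match += t_match
        n_mismatch += t_mismatch

        if (n_mismatch >= cfg.min_mismatches
                and n_match / n_mismatch < cfg.ratio_threshold):
            breakpoints.append(
                Breakpoint(
                    chrom=block.chrom,
                    block_id=block.block_id,
                    cut_before_pos=variants[streak_start].pos,
                    n_match=n_match,
                    n_mismatch=n_mismatch,
                )
            )
            segment_start = streak_start
            streak_start = None
            n_match = n_mismatch = 0
        elif (t_mismatch == 0 and t_match > 0
                and n_match / n_mismatch >= cfg.ratio_threshold):
            # evidence restored: close the streak without cutting
            streak_start = None
            n_match = n_mismatch = 0

    return breakpoints


def detect_all_breakpoints(
    vcf: PhasedVcf,
    pair_indexes: dict[str, PairIndex],
    cfg: CorrectionConfig | None = None,
) -> list[Breakpoint]:
    """Run breakpoint detection over every block of every chromosome."""
    cfg = cfg or CorrectionConfig()
    breakpoints: list[Breakpoint] = []
    for chrom, variants in vcf.variants.items():
        idx = pair_indexes.get(chrom)
        if idx is None:
            continue
        for block in extract_blocks(variants):
            breakpoints.extend(detect_breakpoints(block, idx, cfg))
    return breakpoints


def apply_breakpoints(vcf: PhasedVcf, breakpoints: list[Breakpoint]) -> PhasedVcf:
    """Split blocks at the decided cuts and return a corrected copy.

    Every phased het SNV at or after a cut position receives the new
    block's PS, which is the position of the new block's first variant.
    Genotypes, orientations and all other record fields are untouched; the
    number of blocks grows by exactly the number of breakpoints.
    """
    corrected = vcf.copy()
    cuts_by_block: dict[tuple[str, str], list[int]] = {}
    for bp in breakpoints:
        cuts_by_block.setdefault((bp.chrom, bp.block_id), []).append(bp.cut_before_pos)

    for (chrom, block_id), cut_positions in cuts_by_block.items():
        blocks = {b.block_id: b for b in extract_blocks(corrected.variants[chrom])}
        block = blocks.get(block_id)
        if block is None:
            raise ValueError(f"breakpoint refers to unknown block {chrom}/{block_id}")
        block_positions = set(block.positions)
        for cut in cut_positions:
            if cut not in block_positions:
                raise ValueError(
                    f"cut position {chrom}:{cut} is not a variant of block {block_id}"
                )
        for v in block.variants:
            past = [c for c in sorted(cut_positions) if c <= v.pos]
            if past:
                v.set_phase_set(past[-1])
    return corrected


def correct_with_parents(vcf: PhasedVcf, truth: TrioTruth) -> PhasedVcf:
    """Flip phased het SNVs that contradict trio-derived truth.

    Each phased het SNV found in the truth map with the opposite
    orientation is flipped (0|1 <-> 1|0); PS values are untouched and no
    block is split.  SNVs absent from the truth are left as reported.
    """
    corrected = vcf.copy()
    for v in corrected.all_variants():
        if not (v.phased and v.zygosity == "het" and v.is_snv):
            continue
        true_hap_a = truth.orientation(v.chrom, v.pos, v.ref_allele, v.alt_allele)
        if true_hap_a is not None and true_hap_a != v.hap_a_allele:
            v.flip()
    return corrected


def breakpoints_to_frame(breakpoints: list[Breakpoint]):
    """Audit table of cuts (chrom, old PS, cut position, evidence counts)."""
    import pandas as pd

    return pd.DataFrame(
        [(b.chrom, b.block_id, b.cut_before_pos, b.n_match, b.n_mismatch)
         for b in breakpoints],
        columns=["chrom", "block_id", "cut_before_pos", "n_match", "n_mismatch"],
    )
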