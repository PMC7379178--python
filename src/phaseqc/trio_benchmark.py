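"""Trio-derived truth phasing and phasing benchmarks.

Truth construction follows the classic exclusive-overlap rule: a proband
het SNV whose variant (chrom, pos, ref, alt) appears in only the father's
call set is phased 0|1, only the mother's 1|0; SNVs found in both or
neither parent carry no information and are excluded.

Benchmarking compares predicted phase blocks to that truth.  Because the
global orientation of a block is arbitrary, each block is first normalised
by majority vote (if most of its truth-overlapping SNVs disagree, the whole
comparison is inverted).  Remaining disagreement runs are classified by
length in het SNVs: 1 = flip error, 2–20 = short switch, >=21 = long
switch.  The Hamming error rate is the fraction of compared SNVs that
disagree after normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from phaseqc.vcf_phase_io import PhaseBlock, PhasedVcf, extract_blocks

SHORT_SWITCH_MAX = 20   # runs of 2..20 disagreeing SNVs are short switches


@dataclass
class TrioTruth:
    """Truth orientations keyed by (chrom, pos, ref, alt).

    Orientation is the truth's first-haplotype allele index: 0 for 0|1
    (father-only overlap), 1 for 1|0 (mother-only overlap).
    """

    orientations: dict[tuple[str, int, str, str], int] = field(default_factory=dict)
    n_father_only: int = 0
    n_mother_only: int = 0
    n_excluded_both: int = 0
    n_excluded_neither: int = 0

    def orientation(self, chrom: str, pos: int, ref: str, alt: str) -> int | None:
        return self.orientations.get((chrom, pos, ref, alt))

    def __len__(self) -> int:
        return len(self.orientations)

    def to_vcf(self, son_vcf: PhasedVcf) -> PhasedVcf:
        """Materialise the truth as a phased VCF over the son's records.

        Truth-overlapping het SNVs get GT 0|1 / 1|0 with a whole-chromosome
        phase set; all other records are dropped.
        """
        out = son_vcf.copy()
        for chrom in list(out.variants):
            kept = []
            for v in out.variants[chrom]:
                o = self.orientation(v.chrom, v.pos, v.ref_allele, v.alt_allele)
                if o is None or v.zygosity != "het" or not v.is_snv:
                    continue
                gt = "0|1" if o == 0 else "1|0"
                fmt_fields = v.columns[8].split(":")
                sample_fields = v.columns[v.sample_col].split(":")
                sample_fields[v.gt_index] = gt
                if "PS" not in fmt_fields:
                    fmt_fields.append("PS")
                    sample_fields.append("1")
                    v.columns[8] = ":".join(fmt_fields)
                    v.ps_index = len(fmt_fields) - 1
                else:
                    sample_fields[v.ps_index] = "1"
                v.columns[v.sample_col] = ":".join(sample_fields)
                v.phased = True
                v.hap_a_allele = o
                v.phase_set = "1"
                kept.append(v)
            out.variants[chrom] = kept
        return out

    @classmethod
    def from_vcf(cls, truth_vcf: PhasedVcf) -> "TrioTruth":
        """Rebuild a truth map from a phased truth VCF (0|1 / 1|0 records)."""
        truth = cls()
        for v in truth_vcf.all_variants():
            if v.phased and v.zygosity == "het" and v.is_snv:
                truth.orientations[(v.chrom, v.pos, v.ref_allele, v.alt_allele)] = (
                    v.hap_a_allele
                )
        return truth


def _call_set(vcf: PhasedVcf, require_alt: bool) -> set[tuple[str, int, str, str]]:
    calls = set()
    for v in vcf.all_variants():
        if not v.is_snv or v.zygosity == "missing":
            continue
        if require_alt and v.zygosity == "hom_ref":
            continue
        calls.add((v.chrom, v.pos, v.ref_allele, v.alt_allele))
    return calls


def build_trio_truth(
    son_vcf: PhasedVcf,
    father_vcf: PhasedVcf,
    mother_vcf: PhasedVcf,
    strict: bool = False,
) -> TrioTruth:
    """Assign truth orientations to the son's het SNVs from parental overlap.

    ``strict`` additionally requires the parent record to carry the
    alternate allele (het or hom-alt); by default any matching call counts.
    """
    father = _call_set(father_vcf, strict)
    mother = _call_set(mother_vcf, strict)
    truth = TrioTruth()
    for v in son_vcf.all_variants():
        if v.zygosity != "het" or not v.is_snv:
            continue
        key = (v.chrom, v.pos, v.ref_allele, v.alt_allele)
        in_f, in_m = key in father, key in mother
        if in_f and not in_m:
            truth.orientations[key] = 0       # 0|1
            truth.n_father_only += 1
        elif in_m and not in_f:
            truth.orientations[key] = 1       # 1|0
            truth.n_mother_only += 1
        elif in_f and in_m:
            truth.n_excluded_both += 1
        else:
            truth.n_excluded_neither += 1
    return truth


def normalize_block_orientation(
    block: PhaseBlock, truth: TrioTruth
) -> tuple[list[bool], bool, bool]:
    """Per-SNV disagreement vector after majority-orientation normalisation.

    Returns ``(disagree, inverted, ambiguous)``: the position-ordered
    disagreement flags over the block's truth-overlapping SNVs, whether the
    block comparison was inverted, and whether the majority vote was an
    exact tie (in which case the reported orientation is kept).
    """
    disagree = []
    for v in block.variants:
        o = truth.orientation(v.chrom, v.pos, v.ref_allele, v.alt_allele)
        if o is None:
            continue
        disagree.append(v.hap_a_allele != o)
    n_dis = sum(disagree)
    n_agr = len(disagree) - n_dis
    inverted = n_dis > n_agr
    if inverted:
        disagree = [not d for d in disagree]
    return disagree, inverted, n_dis == n_agr and bool(disagree)


def classify_runs(disagree: list[bool]) -> list[int]:
    """Lengths of maximal runs of consecutive disagreements."""
    runs = []
    current = 0
    for d in disagree:
        if d:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


@dataclass
class BenchmarkResult:
    """Phasing benchmark vs trio truth."""

    hamming_error_rate: float
    n_flip: int
    n_short_switch: int
    n_long_switch: int
    n_compared: int
    n_blocks_compared: int
    n_blocks_skipped: int          # blocks with zero truth overlap
    per_block: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["hamming_error_rate", "n_flip", "n_short_switch",
                           "n_long_switch", "n_compared", "n_blocks_compared"],
                "value": [self.hamming_error_rate, self.n_flip,
                          self.n_short_switch, self.n_long_switch,
                          self.n_compared, self.n_blocks_compared],
            }
        )


def hamming_error_rate(
    blocks: list[PhaseBlock], truth: TrioTruth, averaging: str = "pooled"
) -> float:
    """Disagreeing SNVs over compared SNVs, after block normalisation.

    ``averaging="pooled"`` (default) divides total disagreements by total
    compared SNVs; ``"per_block_mean"`` averages block-wise rates instead.
    Returns NaN when no SNV is comparable.
    """
    if averaging not in ("pooled", "per_block_mean"):
        raise ValueError(f"unknown averaging mode {averaging!r}")
    rates = []
    n_dis = n_cmp = 0
    for block in blocks:
        disagree, _, _ = normalize_block_orientation(block, truth)
        if not disagree:
            continue
        n_dis += sum(disagree)
        n_cmp += len(disagree)
        rates.append(sum(disagree) / len(disagree))
    if n_cmp == 0:
        return math.nan
    if averaging == "pooled":
        return n_dis / n_cmp
    return sum(rates) / len(rates)


def count_switches(blocks: list[PhaseBlock], truth: TrioTruth) -> BenchmarkResult:
    """Classify disagreement runs into flips and short/long switches."""
    n_flip = n_short = n_long = 0
    n_dis = n_cmp = 0
    n_skipped = 0
    rows = []
    for block in blocks:
        disagree, inverted, ambiguous = normalize_block_orientation(block, truth)
        if not disagree:
            n_skipped += 1
            continue
        runs = classify_runs(disagree)
        b_flip = sum(r == 1 for r in runs)
        b_short = sum(2 <= r <= SHORT_SWITCH_MAX for r in runs)
        b_long = sum(r > SHORT_SWITCH_MAX for r in runs)
        n_flip += b_flip
        n_short += b_short
        n_long += b_long
        n_dis += sum(disagree)
        n_cmp += len(disagree)
        rows.append({
            "chrom": block.chrom, "block_id": block.block_id,
            "n_compared": len(disagree), "n_disagree": sum(disagree),
            "n_flip": b_flip, "n_short_switch": b_short,
            "n_long_switch": b_long, "inverted": inverted,
            "ambiguous_majority": ambiguous,
        })
    return BenchmarkResult(
        hamming_error_rate=(n_dis / n_cmp) if n_cmp else math.nan,
        n_flip=n_flip,
        n_short_switch=n_short,
        n_long_switch=n_long,
        n_compared=n_cmp,
        n_blocks_compared=len(rows),
        n_blocks_skipped=n_skipped,
        per_block=pd.DataFrame(rows),
    )


def benchmark(pred_vcf: PhasedVcf, truth: TrioTruth) -> BenchmarkResult:
    """Benchmark a predicted phased VCF against trio truth, all chromosomes."""
    blocks = [
        b for chrom in pred_vcf.variants.values() for b in extract_blocks(chrom)
    ]
    return count_switches(blocks, truth)
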