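"""Phasing-quality metrics: block quality, N50, phase rate and the QC report.

Block quality is the fraction of a block's phased het SNVs with no
mismatching linkage pair; a pair mismatches when the observed relative
phase of its two SNVs (same haplotype vs opposite) contradicts the
population expectation (cis vs trans).  Phase rate is the summed block
span divided by the distance between a chromosome's first and last SNV.
N50 is the smallest block length such that blocks at least that long cover
half the total phased length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from phaseqc.linkage_pairs import LinkagePair, PairIndex
from phaseqc.vcf_phase_io import PhaseBlock, PhasedVcf, extract_blocks


def pair_match(hap_a_i: int, hap_a_j: int, pair: LinkagePair) -> bool:
    """Does the observed relative phase of two SNVs agree with a pair?

    The two SNVs are observed in *cis* when their first-haplotype allele
    indices are equal.  A cis pair matches cis observation; a trans pair
    matches opposite observation.
    """
    observed_cis = hap_a_i == hap_a_j
    return observed_cis == (pair.relation == "cis")


@dataclass
class BlockQuality:
    """Per-block linkage agreement summary."""

    block_id: str
    n_snvs: int
    n_conflicting: int
    n_covered: int          # SNVs with at least one incident intra-block pair

    @property
    def quality(self) -> float:
        return (self.n_snvs - self.n_conflicting) / self.n_snvs

    @property
    def has_coverage(self) -> bool:
        return self.n_covered > 0


def iter_block_pairs(block: PhaseBlock, pair_index: PairIndex):
    """Yield (variant_i, variant_j, pair, match) for intra-block pairs."""
    pos_to_var = {v.pos: v for v in block.variants}
    for v in block.variants:
        for pair in pair_index.lookup(v.pos):
            if pair.pos_i != v.pos:       # visit each pair once, from pos_i
                continue
            other = pos_to_var.get(pair.pos_j)
            if other is None:             # partner outside block: skip
                continue
            yield v, other, pair, pair_match(v.hap_a_allele, other.hap_a_allele, pair)


def block_quality(block: PhaseBlock, pair_index: PairIndex) -> BlockQuality:
    """Fraction of a block's SNVs with no conflicting linkage pair.

    A mismatching pair marks its downstream endpoint as conflicting: the
    pair is read as evidence about the later SNV given the phase already
    established upstream, mirroring the scan direction of the correction
    step, so each suspect site is counted once.  SNVs with no incident pair
    count as non-conflicting (absence of evidence), which the ``n_covered``
    field lets callers weigh.
    """
    conflicting: set[int] = set()
    covered: set[int] = set()
    for vi, vj, _pair, match in iter_block_pairs(block, pair_index):
        covered.update((vi.pos, vj.pos))
        if not match:
            conflicting.add(vj.pos)
    return BlockQuality(
        block_id=block.block_id,
        n_snvs=block.n_snvs,
        n_conflicting=len(conflicting),
        n_covered=len(covered),
    )


def n50(block_lengths) -> float:
    """Smallest length L with cumulative length of blocks >= L covering
    half the total phased length."""
    lengths = sorted(block_lengths, reverse=True)
    if not lengths:
        raise ValueError("N50 is undefined for an empty length list")
    total = sum(lengths)
    cum = 0
    for length in lengths:
        cum += length
        if cum >= total / 2:
            return length
    return lengths[-1]   # unreachable for non-negative lengths


def phase_rate(blocks: list[PhaseBlock], snv_positions) -> float:
    """Summed block span over the first-to-last SNV distance of a chromosome.

    Returns NaN (with a warning) for a chromosome with fewer than two SNVs
    and 0.0 when there are no blocks.
    """
    if not blocks:
        return 0.0
    positions = sorted(snv_positions)
    if len(positions) < 2:
        warnings.warn("phase rate undefined on a chromosome with <2 SNVs",
                      stacklevel=2)
        return math.nan
    denom = positions[-1] - positions[0]
    if denom == 0:
        return math.nan
    return sum(b.span_bp for b in blocks) / denom


@dataclass
class QualityReport:
    """Per-chromosome QC table plus genome-wide aggregates.

    The table has one row per chromosome and a TOTAL row.  Counts cover
    genotyped SNVs only (``./.`` records are excluded everywhere; indels and
    multi-allelic records are tallied separately in ``n_non_snv``).
    """

    table: pd.DataFrame
    per_block: pd.DataFrame

    def to_tsv(self, path, per_block_path=None) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        if per_block_path is not None:
            self.per_block.to_csv(per_block_path, sep="\t", index=False,
                                  float_format="%.6g")

    def chrom_row(self, chrom: str) -> pd.Series:
        return self.table.set_index("chrom").loc[chrom]

    @property
    def total(self) -> pd.Series:
        return self.chrom_row("TOTAL")

    def plot(self, path) -> None:
        """Bar panels of the headline metrics per chromosome."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rows = self.table[self.table["chrom"] != "TOTAL"]
        metrics = ["n50_bp", "n_phased_het", "n_unphased_het",
                   "mean_block_quality", "phase_rate"]
        fig, axes = plt.subplots(len(metrics), 1,
                                 figsize=(max(4, 0.5 * len(rows) + 2), 10),
                                 sharex=True)
        for ax, metric in zip(axes, metrics):
            ax.bar(rows["chrom"].astype(str), rows[metric])
            ax.set_ylabel(metric)
        axes[-1].set_xlabel("chromosome")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


REPORT_COLUMNS = [
    "chrom", "n_het", "n_hom", "n_phased_het", "n_unphased_het",
    "n_non_snv", "n_blocks", "n50_bp", "phase_rate",
    "mean_block_quality", "pair_coverage",
]


def make_report(
    vcf: PhasedVcf,
    pair_indexes: dict[str, PairIndex] | None = None,
    snv_weighted_quality: bool = False,
) -> QualityReport:
    """Compute the per-chromosome QC report for a parsed phased VCF.

    ``pair_indexes`` maps chromosome to :class:`PairIndex`; when omitted the
    quality columns are reported as NaN.  ``snv_weighted_quality`` switches
    the per-chromosome mean block quality from an unweighted mean over
    blocks (the default) to an SNV-weighted mean.
    """
    rows = []
    block_rows = []
    for chrom, variants in vcf.variants.items():
        snvs = [v for v in variants if v.is_snv and v.zygosity != "missing"]
        n_het = sum(v.zygosity == "het" for v in snvs)
        n_hom = sum(v.zygosity == "hom_alt" for v in snvs)
        n_non_snv = sum((not v.is_snv) and v.zygosity != "missing" for v in variants)
        blocks = extract_blocks(variants)
        n_phased_het = sum(b.n_snvs for b in blocks)
        multi_lengths = [b.span_bp for b in blocks if b.n_snvs >= 2]
        n50_bp = float(n50(multi_lengths)) if multi_lengths else math.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rate = phase_rate(blocks, [v.pos for v in snvs]) if snvs else math.nan

        qualities = []
        weights = []
        coverage_num = coverage_den = 0
        if pair_indexes is not None and chrom in pair_indexes and blocks:
            idx = pair_indexes[chrom]
            for b in blocks:
                bq = block_quality(b, idx)
                qualities.append(bq.quality)
                weights.append(bq.n_snvs)
                coverage_num += bq.n_covered
                coverage_den += bq.n_snvs
                block_rows.append({
                    "chrom": chrom, "block_id": b.block_id,
                    "n_snvs": bq.n_snvs, "span_bp": b.span_bp,
                    "n_conflicting": bq.n_conflicting,
                    "n_covered": bq.n_covered, "quality": bq.quality,
                })
        if qualities:
            if snv_weighted_quality:
                mean_quality = float(np.average(qualities, weights=weights))
            else:
                mean_quality = float(np.mean(qualities))
            coverage = coverage_num / coverage_den if coverage_den else math.nan
        else:
            mean_quality = math.nan
            coverage = math.nan

        rows.append({
            "chrom": chrom,
            "n_het": n_het,
            "n_hom": n_hom,
            "n_phased_het": n_phased_het,
            "n_unphased_het": n_het - n_phased_het,
            "n_non_snv": n_non_snv,
            "n_blocks": len(blocks),
            "n50_bp": n50_bp,
            "phase_rate": rate,
            "mean_block_quality": mean_quality,
            "pair_coverage": coverage,
        })

    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    total = _total_row(table, vcf)
    table = pd.concat([table, pd.DataFrame([total])], ignore_index=True)
    per_block = pd.DataFrame(
        block_rows,
        columns=["chrom", "block_id", "n_snvs", "span_bp", "n_conflicting",
                 "n_covered", "quality"],
    )
    return QualityReport(table=table, per_block=per_block)


def _total_row(table: pd.DataFrame, vcf: PhasedVcf) -> dict:
    """Genome-wide aggregates: counts summed, N50 over pooled blocks,
    mean block quality averaged over chromosomes."""
    all_lengths = []
    spans = 0
    denom = 0
    for chrom, variants in vcf.variants.items():
        blocks = extract_blocks(variants)
        all_lengths.extend(b.span_bp for b in blocks if b.n_snvs >= 2)
        positions = vcf.snv_positions(chrom)
        if len(positions) >= 2:
            spans += sum(b.span_bp for b in blocks)
            denom += max(positions) - min(positions)
    quality_vals = table["mean_block_quality"].dropna()
    return {
        "chrom": "TOTAL",
        "n_het": int(table["n_het"].sum()),
        "n_hom": int(table["n_hom"].sum()),
        "n_phased_het": int(table["n_phased_het"].sum()),
        "n_unphased_het": int(table["n_unphased_het"].sum()),
        "n_non_snv": int(table["n_non_snv"].sum()),
        "n_blocks": int(table["n_blocks"].sum()),
        "n50_bp": float(n50(all_lengths)) if all_lengths else math.nan,
        "phase_rate": spans / denom if denom else math.nan,
        "mean_block_quality": float(quality_vals.mean()) if len(quality_vals) else math.nan,
        "pair_coverage": float(table["pair_coverage"].dropna().mean())
        if table["pair_coverage"].notna().any() else math.nan,
    }
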