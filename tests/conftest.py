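"""Shared builders for hand-constructed VCFs, blocks and pair lists."""

from __future__ import annotations

import pytest

from phaseqc.linkage_pairs import LinkagePair, index_pairs
from phaseqc.vcf_phase_io import extract_blocks, read_phased_vcf_lines

HEADER = [
    "##fileformat=VCFv4.2\n",
    "##contig=<ID=1>\n",
    "##contig=<ID=2>\n",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
    '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n',
]


def vcf_text(records, sample="S1"):
    """Render record tuples (chrom, pos, ref, alt, fmt, sample_value) to VCF text."""
    lines = list(HEADER)
    lines.append(
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
    )
    for chrom, pos, ref, alt, fmt, value in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t60\tPASS\t.\t{fmt}\t{value}\n")
    return "".join(lines)


def parse_records(records, sample="S1", **kwargs):
    """Parse record tuples straight into a PhasedVcf."""
    return read_phased_vcf_lines(vcf_text(records, sample).splitlines(keepends=True),
                                 **kwargs)


def phased_block(hap_a_by_pos, chrom="1", ps=None):
    """A single phase block with given {position: hap_a_allele} assignments."""
    positions = sorted(hap_a_by_pos)
    ps = ps if ps is not None else positions[0]
    records = [
        (chrom, pos, "A", "G", "GT:PS",
         f"{hap_a_by_pos[pos]}|{1 - hap_a_by_pos[pos]}:{ps}")
        for pos in positions
    ]
    vcf = parse_records(records)
    (block,) = extract_blocks(vcf.variants[chrom])
    return block


def pair_index_from(relations, chrom="1"):
    """PairIndex from (pos_i, pos_j, relation[, support]) tuples."""
    pairs = [
        LinkagePair(chrom, *t) if len(t) == 4 else LinkagePair(chrom, *t, 1.0)
        for t in relations
    ]
    return index_pairs(pairs)


@pytest.fixture
def write_vcf(tmp_path):
    """Write record tuples to a VCF file and return its path."""

    def _write(records, sample="S1", name="test.vcf"):
        path = tmp_path / name
        path.write_text(vcf_text(records, sample))
        return path

    return _write
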