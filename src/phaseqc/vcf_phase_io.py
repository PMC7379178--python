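"""Phased-VCF input/output and phase-block extraction.

Records are carried as the tab-split text columns of the original VCF line,
so that rewriting a file reproduces it byte-for-byte except for fields this
package deliberately edits (GT orientation, PS values) and one provenance
header line.  Parsing is restricted to the fields the phasing logic needs:
CHROM, POS, REF, ALT and the selected sample's GT/PS.
"""

from __future__ import annotations

import copy
import gzip
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator

logger = logging.getLogger(__name__)

_GT_SEPARATORS = ("|", "/")


class VcfFormatError(ValueError):
    """Raised when a VCF violates the format assumptions (e.g. no GT tag)."""


def _open_text(path):
    """Open plain or gzip text transparently (sniffs the gzip magic bytes)."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class PhasedVariant:
    """One VCF record for the selected sample.

    ``hap_a_allele`` is the allele index (0=REF, 1=ALT) on the first
    haplotype and is defined only for phased heterozygous SNVs; the relative
    orientation of two SNVs in the same phase set is *cis* when their
    ``hap_a_allele`` values are equal and *trans* otherwise.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    zygosity: str                 # het | hom_ref | hom_alt | missing | other
    phased: bool
    hap_a_allele: int | None
    phase_set: str | None
    is_snv: bool
    columns: list[str] = field(repr=False)
    sample_col: int = field(repr=False, default=9)
    gt_index: int = field(repr=False, default=0)
    ps_index: int | None = field(repr=False, default=None)

    # -- mutation helpers used by the correction module ------------------

    def _sample_fields(self) -> list[str]:
        return self.columns[self.sample_col].split(":")

    def _set_sample_field(self, index: int, value: str) -> None:
        fields = self._sample_fields()
        fields[index] = value
        self.columns[self.sample_col] = ":".join(fields)

    def set_phase_set(self, new_ps: int | str) -> None:
        """Assign this record to a (possibly new) phase set."""
        if self.ps_index is None:
            raise VcfFormatError(
                f"{self.chrom}:{self.pos}: cannot set PS, no PS tag in FORMAT"
            )
        self._set_sample_field(self.ps_index, str(new_ps))
        self.phase_set = str(new_ps)

    def flip(self) -> None:
        """Swap the haplotype assignment: 0|1 <-> 1|0."""
        if not (self.phased and self.zygosity == "het"):
            raise VcfFormatError(
                f"{self.chrom}:{self.pos}: flip requires a phased het record"
            )
        gt = self._sample_fields()[self.gt_index]
        a, b = gt.split("|")
        self._set_sample_field(self.gt_index, f"{b}|{a}")
        if self.hap_a_allele is not None:
            self.hap_a_allele = 1 - self.hap_a_allele

    def to_line(self) -> str:
        return "\t".join(self.columns)


@dataclass
class PhaseBlock:
    """An ordered run of phased heterozygous SNVs sharing one PS value."""

    chrom: str
    block_id: str
    variants: list[PhasedVariant]

    @property
    def n_snvs(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> list[int]:
        return [v.pos for v in self.variants]

    @property
    def span_bp(self) -> int:
        return self.variants[-1].pos - self.variants[0].pos

    def __iter__(self) -> Iterator[PhasedVariant]:
        return iter(self.variants)


@dataclass
class PhasedVcf:
    """A parsed phased VCF: header lines plus per-chromosome records."""

    header_lines: list[str]       # meta lines + the #CHROM line, in order
    samples: list[str]
    sample: str
    variants: dict[str, list[PhasedVariant]]

    @property
    def chroms(self) -> list[str]:
        return list(self.variants)

    def all_variants(self) -> Iterator[PhasedVariant]:
        for chrom_variants in self.variants.values():
            yield from chrom_variants

    def snv_positions(self, chrom: str) -> list[int]:
        """Positions of all genotyped SNV records on a chromosome."""
        return [
            v.pos
            for v in self.variants.get(chrom, [])
            if v.is_snv and v.zygosity != "missing"
        ]

    def copy(self) -> "PhasedVcf":
        return copy.deepcopy(self)


def _classify_gt(gt: str) -> tuple[str, bool, list[str]]:
    """Return (zygosity, phase-separator-present, allele tokens)."""
    phased_sep = "|" in gt
    for sep in _GT_SEPARATORS:
        if sep in gt:
            alleles = gt.split(sep)
            break
    else:
        alleles = [gt]
    if any(a in (".", "") for a in alleles):
        return "missing", phased_sep, alleles
    if len(alleles) != 2:
        return "other", phased_sep, alleles
    a, b = alleles
    if a == b:
        return ("hom_ref" if a == "0" else "hom_alt"), phased_sep, alleles
    return "het", phased_sep, alleles


def read_phased_vcf(
    path,
    sample: str | None = None,
    missing_ps: str = "warn",
) -> PhasedVcf:
    """Read a phased VCF (plain or gzipped).

    Parameters
    ----------
    path
        VCF v4.1+ file with a GT tag; PS is expected on phased het records.
    sample
        Sample name to assess; defaults to the first sample column.
    missing_ps
        What to do with a phased het GT that lacks a PS value: ``"warn"``
        (demote to unphased with a warning, the default) or ``"error"``.
    """
    with _open_text(path) as fh:
        return read_phased_vcf_lines(fh, sample=sample, missing_ps=missing_ps)


def read_phased_vcf_lines(
    lines,
    sample: str | None = None,
    missing_ps: str = "warn",
) -> PhasedVcf:
    """Parse an iterable of VCF text lines (see :func:`read_phased_vcf`)."""
    header_lines: list[str] = []
    samples: list[str] = []
    sample_col = 9
    variants: dict[str, list[PhasedVariant]] = {}
    n_missing_ps = 0

    for raw in lines:
        line = raw.rstrip("\n")
        if line.startswith("##"):
            header_lines.append(line)
            continue
        if line.startswith("#CHROM"):
            header_lines.append(line)
            cols = line.split("\t")
            if len(cols) < 10:
                raise VcfFormatError("VCF has no sample columns")
            samples = cols[9:]
            if sample is None:
                sample = samples[0]
            if sample not in samples:
                raise VcfFormatError(f"sample {sample!r} not in VCF")
            sample_col = 9 + samples.index(sample)
            continue
        if not line:
            continue
        if not samples:
            raise VcfFormatError("records before #CHROM header line")
        columns = line.split("\t")
        variant, demoted = _parse_record(columns, sample_col, missing_ps)
        n_missing_ps += demoted
        variants.setdefault(variant.chrom, []).append(variant)

    if not samples:
        raise VcfFormatError("no #CHROM header line found")
    for chrom_variants in variants.values():
        chrom_variants.sort(key=lambda v: v.pos)
    if n_missing_ps:
        warnings.warn(
            f"{n_missing_ps} phased het genotype(s) had no PS value and were "
            "treated as unphased",
            stacklevel=2,
        )
    return PhasedVcf(header_lines, samples, sample, variants)


def _parse_record(
    columns: list[str], sample_col: int, missing_ps: str
) -> tuple[PhasedVariant, bool]:
    if len(columns) <= sample_col:
        raise VcfFormatError(f"record with too few columns: {columns[:2]}")
    chrom, pos_s, _id, ref, alt = columns[0], columns[1], columns[2], columns[3], columns[4]
    fmt = columns[8].split(":")
    if "GT" not in fmt:
        raise VcfFormatError(f"record {chrom}:{pos_s} has no GT in FORMAT")
    gt_index = fmt.index("GT")
    ps_index = fmt.index("PS") if "PS" in fmt else None
    sample_fields = columns[sample_col].split(":")
    gt = sample_fields[gt_index]

    zygosity, phased_sep, alleles = _classify_gt(gt)
    multi_allelic = "," in alt
    is_snv = (
        len(ref) == 1
        and not multi_allelic
        and len(alt) == 1
        and alt in "ACGTacgt"
        and all(a in ("0", "1", ".") for a in alleles)
    )

    phase_set = None
    if ps_index is not None and len(sample_fields) > ps_index:
        ps_val = sample_fields[ps_index]
        if ps_val not in (".", ""):
            phase_set = ps_val

    phased = False
    hap_a = None
    demoted = False
    if zygosity == "het" and phased_sep:
        if phase_set is None:
            if missing_ps == "error":
                raise VcfFormatError(
                    f"{chrom}:{pos_s}: phased het GT {gt!r} without PS"
                )
            demoted = True
        else:
            phased = True
            if is_snv:
                hap_a = int(alleles[0])

    variant = PhasedVariant(
        chrom=chrom,
        pos=int(pos_s),
        ref_allele=ref,
        alt_allele=alt,
        zygosity=zygosity,
        phased=phased,
        hap_a_allele=hap_a,
        phase_set=phase_set,
        is_snv=is_snv,
        columns=columns,
        sample_col=sample_col,
        gt_index=gt_index,
        ps_index=ps_index,
    )
    return variant, demoted


def extract_blocks(variants: list[PhasedVariant]) -> list[PhaseBlock]:
    """Group the phased het SNVs of one chromosome into phase blocks.

    One block per distinct PS value; blocks are ordered by the position of
    their first variant, variants within a block by position.
    """
    by_ps: dict[str, list[PhasedVariant]] = {}
    for v in sorted(variants, key=lambda v: v.pos):
        if v.phased and v.zygosity == "het" and v.is_snv and v.phase_set is not None:
            by_ps.setdefault(v.phase_set, []).append(v)
    blocks = [
        PhaseBlock(chrom=vs[0].chrom, block_id=ps, variants=vs)
        for ps, vs in by_ps.items()
    ]
    blocks.sort(key=lambda b: b.variants[0].pos)
    return blocks


def extract_all_blocks(vcf: PhasedVcf) -> dict[str, list[PhaseBlock]]:
    """Phase blocks for every chromosome of a parsed VCF."""
    return {chrom: extract_blocks(vs) for chrom, vs in vcf.variants.items()}


PROVENANCE_PREFIX = "##phaseqc="


def write_phased_vcf(vcf: PhasedVcf, path, provenance: str = "processed") -> None:
    """Write a (possibly corrected) phased VCF.

    The output differs from the input only in fields edited through
    :class:`PhasedVariant` (GT orientation, PS) plus a single
    ``##phaseqc=`` provenance line inserted before the #CHROM line.
    Output is gzipped when ``path`` ends in ``.gz``.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for line in vcf.header_lines[:-1]:
            out.write(line + "\n")
        out.write(f"{PROVENANCE_PREFIX}{provenance}\n")
        out.write(vcf.header_lines[-1] + "\n")
        records = [v for chrom in vcf.variants.values() for v in chrom]
        for v in records:
            out.write(v.to_line() + "\n")
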