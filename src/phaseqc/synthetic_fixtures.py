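"""Internally consistent synthetic inputs with exported ground truth.

The generator emulates the full input set of the toolkit for one
chromosome: a population haplotype panel with tunable local LD, a phased
proband VCF with block structure and injected phasing errors, and parental
call sets for trio benchmarking.  Everything derives from one pair of
complementary founder haplotypes:

* the proband's two true haplotypes *are* the founders, so every site is
  heterozygous and the true relative phase of any two sites is read off the
  founders (equal founder-A alleles = cis);
* each panel haplotype copies one founder and switches template with
  probability ``copy_switch_prob`` per site — a minimal haplotype-copying
  model in which ``copy_switch_prob`` sets the LD decay rate;
* parental call sets contain each alternate allele on exactly the side the
  truth convention demands (alt on the second haplotype -> father-only).

Phasing errors are injected on top of the truth: switch runs invert the
orientation of a contiguous stretch of SNVs inside a block; flips invert
single isolated SNVs.  All randomness flows from ``SimConfig.seed`` through
independent named streams, so a config fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from phaseqc.linkage_pairs import HaplotypePanel
from phaseqc.trio_benchmark import TrioTruth
from phaseqc.vcf_phase_io import PhasedVcf, read_phased_vcf_lines

_BASES = np.array(list("ACGT"))

# independent RNG sub-streams per component
_STREAM_FOUNDERS = 0
_STREAM_PANEL = 1
_STREAM_PROBAND = 2
_STREAM_PARENTS = 3


@dataclass
class SimConfig:
    """Study conditions for one simulated chromosome.

    Defaults mirror a realistic long-read phasing scenario at desk scale:
    ~1.5 kb between het SNVs (human het density), a 500-haplotype panel
    (the population-phasing sample count used for pair lists), weak LD
    decay, and a handful of phase blocks.
    """

    seed: int = 0
    chrom: str = "1"
    n_sites: int = 1000
    site_spacing_bp: int = 1500
    n_panel_haps: int = 500
    copy_switch_prob: float = 0.005
    n_blocks: int = 5
    flip_rate: float = 0.0
    switch_runs: tuple[tuple[int, int], ...] = ()
    sample_noise: float = 0.0
    ambiguous_fraction: float = 0.0
    n_hom_sites: int = 0
    unphased_fraction: float = 0.0
    sample_name: str = "PROBAND"

    def __post_init__(self) -> None:
        for name in ("copy_switch_prob", "flip_rate", "sample_noise",
                     "ambiguous_fraction", "unphased_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.n_panel_haps < 2:
            raise ValueError("n_panel_haps must be >= 2")
        if not 1 <= self.n_blocks <= self.n_sites:
            raise ValueError("n_blocks must be in [1, n_sites]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _founders(cfg: SimConfig):
    """Deterministic founder haplotypes, positions and alleles for a config."""
    rng = cfg.rng(_STREAM_FOUNDERS)
    founder_a = rng.integers(0, 2, size=cfg.n_sites, dtype=np.uint8)
    gaps = rng.integers(1, 2 * cfg.site_spacing_bp, size=cfg.n_sites)
    positions = 1000 + np.cumsum(gaps)
    ref_idx = rng.integers(0, 4, size=cfg.n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=cfg.n_sites)) % 4
    return positions, founder_a, _BASES[ref_idx], _BASES[alt_idx]


def block_partition(cfg: SimConfig) -> np.ndarray:
    """Block index per site: ``n_blocks`` contiguous, near-equal groups."""
    return np.repeat(
        np.arange(cfg.n_blocks),
        [len(c) for c in np.array_split(np.arange(cfg.n_sites), cfg.n_blocks)],
    )


@dataclass
class SimTruth:
    """Ground truth of one simulated proband, consistent with its VCF."""

    chrom: str
    positions: np.ndarray          # het SNV positions, increasing
    ref: np.ndarray
    alt: np.ndarray
    true_hap_a: np.ndarray         # founder-A allele per site (truth 0|1 / 1|0)
    block_of_site: np.ndarray      # block index per site
    switch_runs: tuple[tuple[int, int], ...]   # (start_index, run_length)
    flip_indices: np.ndarray
    unphased_indices: np.ndarray
    ambiguous_indices: np.ndarray  # sites excluded from parental truth
    observed_hap_a: np.ndarray     # truth after injected switches and flips

    @property
    def switch_boundaries(self) -> list[int]:
        """Site indices where the injected orientation changes (run starts
        and the first site after each run)."""
        edges = []
        for start, length in self.switch_runs:
            edges.append(start)
            if start + length < len(self.positions):
                edges.append(start + length)
        return edges

    def to_trio_truth(self) -> TrioTruth:
        """The exact truth map (every het site, no parental ambiguity)."""
        truth = TrioTruth()
        for i in range(len(self.positions)):
            truth.orientations[
                (self.chrom, int(self.positions[i]), str(self.ref[i]), str(self.alt[i]))
            ] = int(self.true_hap_a[i])
        return truth

    def to_frame(self) -> pd.DataFrame:
        n = len(self.positions)
        in_run = np.zeros(n, dtype=bool)
        for start, length in self.switch_runs:
            in_run[start:start + length] = True
        flipped = np.zeros(n, dtype=bool)
        flipped[self.flip_indices] = True
        return pd.DataFrame({
            "chrom": self.chrom,
            "pos": self.positions,
            "ref": self.ref,
            "alt": self.alt,
            "true_hap_a": self.true_hap_a,
            "observed_hap_a": self.observed_hap_a,
            "block": self.block_of_site,
            "in_switch_run": in_run,
            "flipped": flipped,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_panel(cfg: SimConfig) -> HaplotypePanel:
    """Panel of haplotypes copied from the two complementary founders.

    Each haplotype starts from a random founder and switches template with
    ``copy_switch_prob`` at every site; ``sample_noise`` then flips
    individual alleles, emulating per-sample discordance of repeated
    population-phasing draws.
    """
    positions, founder_a, ref, alt = _founders(cfg)
    rng = cfg.rng(_STREAM_PANEL)
    start = rng.integers(0, 2, size=cfg.n_panel_haps, dtype=np.uint8)
    switches = rng.random((cfg.n_panel_haps, cfg.n_sites)) < cfg.copy_switch_prob
    # template indicator: 0 = founder A, 1 = founder B (= complement of A)
    template = (start[:, None] + np.cumsum(switches, axis=1)) % 2
    alleles = np.where(template == 0, founder_a[None, :], 1 - founder_a[None, :])
    if cfg.sample_noise > 0:
        noise = rng.random((cfg.n_panel_haps, cfg.n_sites)) < cfg.sample_noise
        alleles = np.where(noise, 1 - alleles, alleles)
    meta = pd.DataFrame({
        "id": [f"snv{i}" for i in range(cfg.n_sites)],
        "ref": ref, "alt": alt,
        "af": alleles.mean(axis=0),
    })
    return HaplotypePanel(
        chrom=cfg.chrom,
        positions=positions,
        alleles=alleles.astype(np.uint8),
        site_meta=meta,
    )


def _validate_runs(cfg: SimConfig, blocks: np.ndarray) -> None:
    covered: set[int] = set()
    for start, length in cfg.switch_runs:
        if length < 1 or start < 0 or start + length > cfg.n_sites:
            raise ValueError(f"switch run {(start, length)} outside the site range")
        sites = range(start, start + length)
        if covered.intersection(sites):
            raise ValueError("injected switch runs overlap")
        if blocks[start] != blocks[start + length - 1]:
            raise ValueError(f"switch run {(start, length)} crosses a block boundary")
        covered.update(sites)


def simulate_proband(cfg: SimConfig) -> tuple[PhasedVcf, SimTruth]:
    """Phased proband VCF (GT/PS) plus its complete ground truth.

    The proband's true haplotypes are the founder pair; sites are split
    into ``n_blocks`` contiguous phase blocks whose PS is the position of
    the block's first variant.  Injected switch runs invert the orientation
    of their sites; flip errors invert isolated single sites (flips never
    touch or neighbour a switch run, so the injected error counts are
    exactly recoverable by benchmarking).
    """
    positions, founder_a, ref, alt = _founders(cfg)
    blocks = block_partition(cfg)
    _validate_runs(cfg, blocks)
    rng = cfg.rng(_STREAM_PROBAND)

    observed = founder_a.copy()
    in_run = np.zeros(cfg.n_sites, dtype=bool)
    for start, length in cfg.switch_runs:
        observed[start:start + length] = 1 - observed[start:start + length]
        in_run[max(0, start - 1):start + length + 1] = True   # +1bp guard band

    flip_candidates = np.flatnonzero(~in_run)
    chosen = flip_candidates[rng.random(flip_candidates.size) < cfg.flip_rate]
    flips = []
    last = -2
    for i in chosen:                       # keep flips isolated
        if i - last > 1:
            flips.append(int(i))
            last = i
    flips = np.array(flips, dtype=int)
    observed[flips] = 1 - observed[flips]

    het_unphased = np.zeros(cfg.n_sites, dtype=bool)
    if cfg.unphased_fraction > 0:
        het_unphased = rng.random(cfg.n_sites) < cfg.unphased_fraction

    ambiguous = np.flatnonzero(
        cfg.rng(_STREAM_PARENTS).random(cfg.n_sites) < cfg.ambiguous_fraction
    )

    # PS per block = position of the block's first *phased* variant
    ps_of_block: dict[int, int] = {}
    for i in range(cfg.n_sites):
        if not het_unphased[i] and blocks[i] not in ps_of_block:
            ps_of_block[blocks[i]] = int(positions[i])

    records = []
    for i in range(cfg.n_sites):
        if het_unphased[i]:
            sample = "0/1:."
        else:
            a = int(observed[i])
            sample = f"{a}|{1 - a}:{ps_of_block[blocks[i]]}"
        records.append((int(positions[i]), str(ref[i]), str(alt[i]), "GT:PS", sample))

    if cfg.n_hom_sites:
        hom_rng = cfg.rng(_STREAM_PROBAND + 10)
        existing = set(int(p) for p in positions)
        lo, hi = int(positions[0]), int(positions[-1])
        added = 0
        while added < cfg.n_hom_sites:
            p = int(hom_rng.integers(lo, hi + 1))
            if p in existing:
                continue
            existing.add(p)
            r_idx = int(hom_rng.integers(0, 4))
            a_idx = (r_idx + int(hom_rng.integers(1, 4))) % 4
            records.append((p, str(_BASES[r_idx]), str(_BASES[a_idx]),
                            "GT:PS", "1/1:."))
            added += 1
    records.sort(key=lambda r: r[0])

    vcf = read_phased_vcf_lines(_vcf_lines(cfg.chrom, records, cfg.sample_name))
    truth = SimTruth(
        chrom=cfg.chrom,
        positions=positions,
        ref=ref.astype(str),
        alt=alt.astype(str),
        true_hap_a=founder_a,
        block_of_site=blocks,
        switch_runs=tuple(cfg.switch_runs),
        flip_indices=flips,
        unphased_indices=np.flatnonzero(het_unphased),
        ambiguous_indices=ambiguous,
        observed_hap_a=observed,
    )
    return vcf, truth


def simulate_parent_sets(cfg: SimConfig, truth: SimTruth) -> tuple[PhasedVcf, PhasedVcf]:
    """Father and mother call sets realising the truth orientations.

    A site with the alternate allele on the second haplotype (truth 0|1)
    appears only in the father's set; truth 1|0 only in the mother's.
    ``cfg.ambiguous_fraction`` of sites is made uninformative instead —
    alternating between present-in-both and present-in-neither — to
    exercise the trio-truth exclusion paths.
    """
    ambiguous_rank = {int(i): r for r, i in enumerate(sorted(truth.ambiguous_indices))}
    father_rows, mother_rows = [], []
    for i in range(len(truth.positions)):
        rec = (int(truth.positions[i]), str(truth.ref[i]), str(truth.alt[i]),
               "GT", "0/1")
        if i in ambiguous_rank:
            if ambiguous_rank[i] % 2 == 0:   # alternate both / neither
                father_rows.append(rec)
                mother_rows.append(rec)
        elif truth.true_hap_a[i] == 0:       # alt on second haplotype -> father
            father_rows.append(rec)
        else:
            mother_rows.append(rec)

    father = read_phased_vcf_lines(_vcf_lines(truth.chrom, father_rows, "FATHER"))
    mother = read_phased_vcf_lines(_vcf_lines(truth.chrom, mother_rows, "MOTHER"))
    return father, mother


def _vcf_lines(chrom: str, records, sample_name: str):
    yield "##fileformat=VCFv4.2\n"
    yield f"##contig=<ID={chrom}>\n"
    yield '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    yield '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n'
    yield ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
           f"{sample_name}\n")
    for pos, ref, alt, fmt, sample in records:
        yield f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t60\tPASS\t.\t{fmt}\t{sample}\n"


def write_fixture_set(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Generate and write the complete fixture set to a directory."""
    from phaseqc.linkage_pairs import build_pair_list, write_pair_list
    from phaseqc.vcf_phase_io import write_phased_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = simulate_panel(cfg)
    proband, truth = simulate_proband(cfg)
    father, mother = simulate_parent_sets(cfg, truth)
    pairs = build_pair_list(panel)

    paths = {
        "proband": outdir / "proband.vcf",
        "father": outdir / "father.vcf",
        "mother": outdir / "mother.vcf",
        "hap": outdir / "panel.hap",
        "legend": outdir / "panel.legend",
        "pairs": outdir / "pairs.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_phased_vcf(proband, paths["proband"], provenance="simulated")
    write_phased_vcf(father, paths["father"], provenance="simulated")
    write_phased_vcf(mother, paths["mother"], provenance="simulated")
    np.savetxt(paths["hap"], panel.alleles.T, fmt="%d")
    legend = pd.DataFrame({
        "id": panel.site_meta["id"],
        "position": panel.positions,
        "a0": panel.site_meta["ref"],
        "a1": panel.site_meta["alt"],
        "af": panel.site_meta["af"],
    })
    legend.to_csv(paths["legend"], sep=" ", index=False)
    write_pair_list(pairs, paths["pairs"])
    truth.to_tsv(paths["truth"])
    return paths
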