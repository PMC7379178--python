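"""Population-linkage pair lists: expected cis/trans relations between SNV pairs.

A pair list records, for pairs of nearby SNV positions, whether the two
alternate alleles are expected on the same haplotype (*cis*) or on opposite
haplotypes (*trans*), together with the fraction of haplotype samples
supporting that call.  Pairs are called from an IMPUTE-format haplotype
matrix — either repeated population-phasing samples of the focal individual
("sample mode") or a population reference panel restricted to common
variants ("panel mode"); the calling rule is identical in both.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_RELATIONS = ("cis", "trans")


@dataclass
class HaplotypePanel:
    """H haplotypes over M biallelic sites (0 = reference, 1 = alternate)."""

    chrom: str
    positions: np.ndarray          # (M,) 1-based, strictly increasing
    alleles: np.ndarray            # (H, M) uint8 in {0, 1}
    site_meta: pd.DataFrame | None = None   # optional ref/alt/af per site

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (haplotypes x sites) matrix")
        if self.alleles.shape[0] < 2:
            raise ValueError("panel needs at least 2 haplotypes")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("alleles column count must match positions")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("panel alleles must be 0 or 1")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def restrict_to_af(self, min_af: float) -> "HaplotypePanel":
        """Subset to sites with allele frequency >= ``min_af``.

        Uses the ``af`` column of ``site_meta`` if present, otherwise the
        empirical alternate-allele frequency of the panel itself.
        """
        if self.site_meta is not None and "af" in self.site_meta.columns:
            af = self.site_meta["af"].to_numpy(dtype=float)
        else:
            af = self.alleles.mean(axis=0)
        keep = af >= min_af
        meta = self.site_meta.loc[keep].reset_index(drop=True) if self.site_meta is not None else None
        return HaplotypePanel(
            chrom=self.chrom,
            positions=self.positions[keep],
            alleles=self.alleles[:, keep],
            site_meta=meta,
        )


@dataclass(frozen=True)
class LinkagePair:
    """Expected relative phase of two SNVs, with its sample support."""

    chrom: str
    pos_i: int
    pos_j: int
    relation: str                  # "cis" (same haplotype) or "trans"
    support: float                 # fraction of haplotype samples agreeing

    def __post_init__(self) -> None:
        if self.relation not in _RELATIONS:
            raise ValueError(f"relation must be cis/trans, got {self.relation!r}")
        if not self.pos_i < self.pos_j:
            raise ValueError("pair positions must satisfy pos_i < pos_j")


@dataclass
class PairListConfig:
    """Pair-calling parameters.

    agreement_threshold
        Minimum fraction of haplotype samples that must agree on the
        cis/trans call (default 0.9; a tie at exactly the threshold passes).
    n_samples
        Number of haplotype samples the population phaser is asked to draw
        (default 500); informational — the matrix row count is what is used.
    neighbor_window
        Each site is paired with up to this many downstream het neighbours
        (default 3).
    max_span_bp
        Pairs farther apart than this are not formed (default 100 kb).
    min_af
        Allele-frequency floor applied to the panel in panel mode
        (default 0.01).
    """

    agreement_threshold: float = 0.9
    n_samples: int = 500
    neighbor_window: int = 3
    max_span_bp: int = 100_000
    min_af: float = 0.01

    def __post_init__(self) -> None:
        if not 0.5 < self.agreement_threshold <= 1.0:
            raise ValueError("agreement_threshold must be in (0.5, 1]")
        if self.neighbor_window < 1:
            raise ValueError("neighbor_window must be >= 1")


def build_pair_list(
    panel: HaplotypePanel,
    cfg: PairListConfig | None = None,
    panel_mode: bool = False,
) -> list[LinkagePair]:
    """Call cis/trans pairs from a haplotype matrix.

    For every candidate pair (index distance <= ``neighbor_window`` and
    genomic distance <= ``max_span_bp``) the haplotypes with equal alleles
    at the two sites are counted; the pair is reported *cis* when that
    fraction reaches the agreement threshold, *trans* when the opposite
    fraction does, and omitted otherwise.  Degenerate sites (monomorphic
    columns) never form pairs.
    """
    cfg = cfg or PairListConfig()
    if panel_mode:
        panel = panel.restrict_to_af(cfg.min_af)
    if panel.n_sites < 2:
        return []

    H = panel.n_haplotypes
    alleles = panel.alleles
    positions = panel.positions
    degenerate = (alleles == alleles[0]).all(axis=0)
    n_degen = int(degenerate.sum())
    if n_degen:
        logger.info("skipping %d degenerate (monomorphic) site(s)", n_degen)

    pairs: list[LinkagePair] = []
    for d in range(1, cfg.neighbor_window + 1):
        if d >= panel.n_sites:
            break
        eq_frac = (alleles[:, :-d] == alleles[:, d:]).mean(axis=0)
        span_ok = (positions[d:] - positions[:-d]) <= cfg.max_span_bp
        usable = span_ok & ~degenerate[:-d] & ~degenerate[d:]
        cis_hit = usable & (eq_frac >= cfg.agreement_threshold)
        trans_hit = usable & ((1.0 - eq_frac) >= cfg.agreement_threshold)
        for i in np.flatnonzero(cis_hit | trans_hit):
            cis = bool(cis_hit[i])
            pairs.append(
                LinkagePair(
                    chrom=panel.chrom,
                    pos_i=int(positions[i]),
                    pos_j=int(positions[i + d]),
                    relation="cis" if cis else "trans",
                    support=float(eq_frac[i] if cis else 1.0 - eq_frac[i]),
                )
            )
    pairs.sort(key=lambda p: (p.pos_i, p.pos_j))
    return pairs


def read_impute_panel(hap_path, legend_path, chrom: str = "1") -> HaplotypePanel:
    """Read IMPUTE-format ``.hap`` / ``.legend`` files (optionally gzipped).

    The hap file holds one whitespace-delimited row of 0/1 alleles per site
    (columns are haplotypes); the legend holds one row per site with at
    least an id and a position, optionally ref/alt alleles and an allele
    frequency column (any header ending in ``af``).
    """
    legend = pd.read_csv(_maybe_gz(legend_path), sep=r"\s+")
    if "position" not in legend.columns:
        # headerless legend: assume id/position[/ref/alt] ordering
        legend = pd.read_csv(_maybe_gz(legend_path), sep=r"\s+", header=None)
        names = ["id", "position", "ref", "alt"][: legend.shape[1]]
        legend.columns = names + [f"col{i}" for i in range(len(names), legend.shape[1])]
    matrix = np.loadtxt(_maybe_gz(hap_path), dtype=np.uint8, ndmin=2)
    if matrix.shape[0] != len(legend):
        raise ValueError(
            f"hap file has {matrix.shape[0]} site rows but legend has {len(legend)}"
        )

    meta = pd.DataFrame({"id": legend["id"].astype(str)})
    for src, dst in (("a0", "ref"), ("a1", "alt"), ("ref", "ref"), ("alt", "alt")):
        if src in legend.columns:
            meta[dst] = legend[src].astype(str)
    af_cols = [c for c in legend.columns if c.lower().endswith("af") or c.lower().endswith("aaf")]
    if af_cols:
        meta["af"] = legend[af_cols[0]].astype(float)

    order = np.argsort(legend["position"].to_numpy())
    return HaplotypePanel(
        chrom=chrom,
        positions=legend["position"].to_numpy(dtype=np.int64)[order],
        alleles=matrix[order].T,   # sites-by-haplotypes -> haplotypes-by-sites
        site_meta=meta.iloc[order].reset_index(drop=True),
    )


def _maybe_gz(path):
    return gzip.open(path, "rt") if str(path).endswith(".gz") else path


PAIR_COLUMNS = ["chrom", "pos_i", "pos_j", "relation", "support"]


def write_pair_list(pairs: list[LinkagePair], path) -> None:
    """Write pairs as a TSV with columns chrom, pos_i, pos_j, relation, support."""
    df = pd.DataFrame(
        [(p.chrom, p.pos_i, p.pos_j, p.relation, p.support) for p in pairs],
        columns=PAIR_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_pair_list(path) -> list[LinkagePair]:
    """Read a pair-list TSV; relation tokens are case-insensitive."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pair list missing column(s): {sorted(missing)}")
    dup = df.duplicated(subset=["chrom", "pos_i", "pos_j"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate pair row(s) in {path}")
    pairs = []
    for row in df.itertuples(index=False):
        relation = str(row.relation).lower()
        if relation not in _RELATIONS:
            raise ValueError(f"bad relation token {row.relation!r}")
        pairs.append(
            LinkagePair(str(row.chrom), int(row.pos_i), int(row.pos_j),
                        relation, float(row.support))
        )
    return pairs


@dataclass
class PairIndex:
    """Position-keyed lookup of linkage pairs on one chromosome."""

    by_position: dict[int, list[LinkagePair]] = field(default_factory=dict)
    by_pair: dict[tuple[int, int], LinkagePair] = field(default_factory=dict)

    def lookup(self, pos: int) -> list[LinkagePair]:
        """All pairs incident to a position (either endpoint)."""
        return self.by_position.get(pos, [])

    def relation(self, pos_a: int, pos_b: int) -> LinkagePair | None:
        """The pair covering an unordered position pair, if any."""
        key = (pos_a, pos_b) if pos_a < pos_b else (pos_b, pos_a)
        return self.by_pair.get(key)

    def __len__(self) -> int:
        return len(self.by_pair)


def index_pairs(pairs: list[LinkagePair]) -> PairIndex:
    """Index pairs of one chromosome for O(1) incident-pair lookup."""
    index = PairIndex()
    for p in pairs:
        index.by_position.setdefault(p.pos_i, []).append(p)
        index.by_position.setdefault(p.pos_j, []).append(p)
        index.by_pair[(p.pos_i, p.pos_j)] = p
    return index


def index_pairs_by_chrom(pairs: list[LinkagePair]) -> dict[str, PairIndex]:
    """Split a multi-chromosome pair list into per-chromosome indexes."""
    by_chrom: dict[str, list[LinkagePair]] = {}
    for p in pairs:
        by_chrom.setdefault(p.chrom, []).append(p)
    return {chrom: index_pairs(ps) for chrom, ps in by_chrom.items()}
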