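# Methods

This note records the model behind `phaseqc`, the parameters that matter,
the choices made where the underlying procedure was genuinely open, and
what the synthetic fixtures do and do not demonstrate.

## Data model

A phased VCF is parsed into `PhasedVariant` records carrying the tab-split
text columns of the original line; only CHROM/POS/REF/ALT and the selected
sample's GT/PS are interpreted. Rewriting therefore reproduces the input
byte-for-byte apart from deliberately edited fields and one `##phaseqc=`
provenance header line. A *phase block* is the set of phased heterozygous
SNVs sharing a PS value, ordered by position; its span is last − first
position (1-based, inclusive coordinates throughout).

Conventions for irregular input:

* a phased het genotype without a PS value is demoted to unphased with a
  warning (an `error` mode is available) — real files violate the PS
  assumption often enough that hard failure would be hostile;
* `./.` genotypes are excluded from every count;
* indels and multi-allelic records are parsed and carried through rewriting
  but excluded from all SNV metrics; they are tallied in `n_non_snv`;
* homozygous counts report hom-alt genotypes (`1/1`); hom-ref lines, when a
  caller emits them, are classified but not counted as variants;
* only chromosomes present in the file are reported.

## Pair lists

Population linkage enters as a pair list: (pos_i, pos_j, relation,
support), with relation *cis* (alternate alleles on the same haplotype) or
*trans*. It is called from an H×M haplotype matrix by counting, for each
candidate pair, the haplotypes whose alleles at the two sites are equal.

Parameters (defaults chosen once, used everywhere):

| parameter | default | meaning |
|---|---|---|
| `agreement_threshold` | 0.9 | minimum supporting fraction; **non-strict** (support = 0.9 passes) |
| `n_samples` | 500 | haplotype samples requested from the population phaser |
| `neighbor_window` | 3 | each site is paired with up to 3 downstream het neighbours |
| `max_span_bp` | 100 000 | pairs farther apart carry little reliable linkage |
| `min_af` | 0.01 | allele-frequency floor in panel mode |

Which pairs to form is not dictated by the pair-list idea itself; we pair
each het site with its next `neighbor_window` neighbours within
`max_span_bp` because the correction scan needs multiple upstream
informants per SNV — adjacent-only pairs would give at most one mismatch
per site and could never reach the two-mismatch evidence floor.
Monomorphic panel columns carry no phase information and never form pairs
(logged). Sample mode (repeated population-phasing draws of the focal
individual) and panel mode (population haplotypes filtered to AF ≥
`min_af`) differ only in where the matrix comes from; the calling rule is
identical. Running the population phaser itself is out of scope — the
module consumes its IMPUTE-format `.hap`/`.legend` outputs.

## Quality metrics

* **Pair match.** SNVs *i, j* of one block are observed cis iff their
  first-haplotype allele indices agree; match ⇔ observed relation equals
  expected relation. Pairs whose endpoints lie in different blocks are
  skipped entirely — blocks have no defined mutual orientation, so such
  pairs are neither matches nor mismatches.
* **Block quality** = (n_snvs − n_conflicting) / n_snvs. A mismatching
  pair marks its *downstream* endpoint as conflicting: the pair is read as
  evidence about the later SNV given the phase already established
  upstream, which mirrors the correction scan and counts each suspect site
  once. SNVs with no incident pair count as non-conflicting — the score
  measures evidence of error, not absence of evidence — and per-block pair
  coverage is reported alongside so users can weigh thin coverage.
* **Mean block quality** per chromosome is the unweighted mean over blocks;
  an SNV-weighted variant sits behind `snv_weighted_quality=True`. The
  genome-wide figure averages the per-chromosome means.
* **N50** is computed over spans of blocks with ≥ 2 SNVs (singleton blocks
  have span 0: counted in block totals, contributing no length; it is
  undefined — an error — on an empty list).
* **Phase rate** = Σ block span / (last − first SNV position), using all
  genotyped SNVs of the chromosome in the denominator, per the metric's
  literal definition. Undefined (NaN, with a warning) on chromosomes with
  fewer than two SNVs; 0 with no blocks. Splitting a block can only remove
  the inter-block gap from the numerator, so correction never raises it.

## Switch-error correction

Blocks are scanned in position order. At SNV *t*, every pair from *t* to
the previous `lookback` SNVs of the current (possibly already re-cut) block
is classified match/mismatch. The first mismatching SNV opens a *suspicion
streak*; subsequent SNVs add their tallies. The streak ends in one of two
ways:

* **cut** — mismatches ≥ `min_mismatches` (default 2) and
  matches/mismatches < `ratio_threshold` (default 1; a tie, ratio exactly
  1, never cuts). The cut is placed at the streak's **first** SNV, which
  becomes the first variant — and the PS value — of the new block. Tallies
  reset and scanning continues with the new block as context; pairs
  crossing a cut are ignored from then on, since the two blocks no longer
  have a defined relative phase.
* **close** — a fully matching SNV restores the streak ratio to ≥ the
  threshold; tallies reset without a cut.

The streak bookkeeping is one consistent reading of a scan that is
underdetermined by the verbal rule ("enough upstream mismatches, more
mismatches than matches, cut at the first conflicting SNV"); both the
evidence floor and the ratio are parameters, and the audit TSV records the
evidence behind every cut. A single pass per chromosome suffices: the test
suite asserts that re-running correction on its own output makes no further
cuts.

Linkage mode never edits genotypes. A flip error is visible to the pair
list only as a point conflict with no downstream persistence, which is not
enough signal to re-orient a site confidently — so flips are left to
parental mode, which flips every phased het SNV that contradicts
trio-derived truth (and never splits blocks).

## Trio truth and benchmarking

A proband het SNV matching (chrom, pos, ref, alt) in exactly one parent's
call set is truth-phased (father-only → `0|1`, mother-only → `1|0`);
both/neither → excluded, with counts reported. "Present in the parent"
means any genotyped call by default, because parental zygosity is not part
of the rule; a `strict` flag additionally requires the parent to carry the
alternate allele.

Benchmark pipeline per block: compare orientations to truth; if
disagreements outnumber agreements, invert the block's comparison (an exact
tie keeps the reported orientation and is flagged ambiguous); run-length
encode the remaining disagreements. Run length 1 = flip, 2–20 = short
switch, ≥ 21 = long switch — lengths are counted in het SNVs, not base
pairs, the only unit consistent with runs of mismatching genotypes.
Hamming error rate divides total disagreements by total compared SNVs
(pooled, the default); a per-block mean is available. Blocks with zero
truth overlap are skipped and counted, not averaged in.

## Synthetic fixtures

The generator builds every input from one pair of complementary founder
haplotypes: the proband's true haplotypes are the founders (making every
site het, so `n_sites` is the het SNV count); each of `n_panel_haps = 500`
panel haplotypes copies a founder and switches template with probability
`copy_switch_prob = 0.005` per site — a deliberately minimal
haplotype-copying model in which that probability alone sets LD decay.
Two consequences make the fixtures good oracles: the true relation of any
site pair is read directly off the founders, and any pair passing the 0.9
support threshold necessarily has the true relation (panel majority always
sides with the founders for `copy_switch_prob` < 0.5). Defaults model a
realistic long-read scenario: ~1.5 kb mean spacing between het SNVs (human
heterozygosity), 5 phase blocks, no errors unless injected.

Injected errors are exact by construction: switch runs invert a contiguous
index range inside one block (runs may not overlap or cross block
boundaries); flips invert isolated single sites, kept non-adjacent to each
other and to runs so the benchmark recovers the injected counts exactly.
Parental call sets place each alternate allele on the side the truth
convention demands; an `ambiguous_fraction` makes sites uninformative
(alternating both-parents / neither) to exercise the exclusion paths. All
randomness flows from `SimConfig.seed` through named sub-streams; a config
fully determines every output file.

What the fixtures do **not** emulate: genotyping error and false-positive
calls, indels, recombination- and demography-shaped LD (no coalescent),
reference bias, or the block-length distributions of particular sequencing
technologies. Passing tests therefore demonstrate correctness of the
metrics and the correction logic under clean, well-posed conditions — not
expected error rates on real data, where pair lists are sparser and
linkage conflicts also arise from wrong variant calls.

## Problem sizes and runtime

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which every behaviour of interest is exercised with margin:
5,000 het SNVs × 500 panel haplotypes for closure and switch-recovery
fixtures (10 injected 25-SNV runs), 1,000 random vectors (length ≤ 200)
for the run-length oracle, and hand-sized inputs for the exact metric
checks. The whole suite completes in a few seconds on one CPU; all
heavier real-data workflows (whole-genome VCFs, 1000G-scale panels) stream
through the same code paths and scale linearly in sites × window.

## Known limitations

* Short switches and flips are detectable but not correctable from linkage
  alone; parental mode is the only flip-fixing path.
* Correction can split at a flip when pair coverage is dense (a flip
  yields ≥ 2 simultaneous mismatches); the split is harmless for phasing
  correctness but fragments the block. The audit TSV makes such cuts easy
  to review.
* Blocks are only ever split, never re-joined or re-phased.
* Trio truth uses exact (chrom, pos, ref, alt) matching; no haplotype-aware
  variant comparison.
* The ratio-threshold monotonicity of cut sets is guaranteed on
  high-support pair lists (the fixture regime); with noisy, conflicting
  pairs the streak close rule can shift streak starts between thresholds.
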