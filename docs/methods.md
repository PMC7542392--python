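# Methods

This note documents the models, parameters and numerical conventions behind
methylbench, and what its synthetic benchmarks do and do not show about
real sequencing data.

## Coordinates and context classification

All coordinates are 0-based half-open internally; 1-based coordinates
appear only in CX-report output. A cytosine's context is the reference
triplet read 5'→3' on its strand (reverse complement, walking leftwards,
for the minus strand): CG if the next base is G, CHG if the second base is
G, CHH otherwise (H = A, T or C). A triplet truncated by the contig end or
interrupted by an N is UNDEF; UNDEF sites receive simulated calls (they are
cytosines) but are excluded from all counts, with the number of dropped
calls reported in the QC summary. One consequence of the edge rule is that
a CG pair touching a contig end can have one UNDEF partner, so the exact
+/− CG count symmetry holds only away from contig ends.

## Synthetic genome

`simulate_genome` builds nuclear contigs with a central pericentromeric
block (annotated heterochromatin, slightly AT-shifted, TE-dense) flanked by
euchromatic arms carrying genes and sparser TEs, plus one unmethylated
organelle-control contig. Local GC content follows a smooth sinusoidal
gradient (default amplitude 0.07 around a base of 0.36) so that 400-bp bins
span roughly 25–48% GC once binomial composition noise is added — wide
enough for GC-bias diagnostics to have signal. Defaults (two 150-kb
contigs, 30% pericentromere, gene density 0.35 of arm bp, TE density 0.5 of
pericentromeric bp and a quarter of that in arms, 30-kb organelle) are a
desk-scale caricature of a small plant genome, not a rescaled real one.

## Truth methylome

Each (compartment, context) pair maps to either a point probability or a
two-component mixture (fraction `frac_high` of sites at `level_high`, rest
at `level_low`); each site draws its own methylation probability m once,
and molecules covering it are methylated Bernoulli(m). The default rules
emulate a flowering-plant methylome:

| compartment | CG | CHG | CHH |
|---|---|---|---|
| gene body | mixture 0.25 @ 0.90 / 0.02 | 0.01 | 0.01 |
| TE (arm) | mixture 0.80 @ 0.90 / 0.05 | 0.35 | mixture 0.06 @ 0.50 / 0.03 |
| TE (pericentromere) | mixture 0.90 @ 0.95 / 0.05 | 0.55 | mixture 0.12 @ 0.60 / 0.05 |
| intergenic | mixture 0.10 @ 0.90 / 0.02 | 0.02 | 0.015 |
| organelle control | 0 | 0 | 0 |

CG mixtures encode the bimodal (all-or-nothing) character of plant CG
methylation. CHH rules are mixtures rather than point probabilities because
per-site CHH methylation in vivo is heterogeneous — a minority of
siRNA-targeted sites carries most of the signal — and a single point value
would leave the methylated-C density spectrum degenerate (no site would
ever qualify as "methylated" under a 0.5 level threshold even where CHH
methylation is dense). Genome-wide means under the defaults land near
CG ≈ 0.30, CHG ≈ 0.12, CHH ≈ 0.035, in the range reported for Arabidopsis.

## Protocol bias models

The conversion chemistry's failure modes are described in the literature
only qualitatively; the quantitative forms here are the simplest monotone
models exposing each described mechanism with one parameter:

* **molecule-level non-conversion** — with probability `p_molecule_nc` a
  molecule escapes conversion entirely (failed strand denaturation) and
  reads out methylated at every cytosine;
* **per-base errors** — an unmethylated C reads M with `eps_fail` (the
  background the organelle estimates); a true 5-mC reads U with `eps_over`;
* **degradation** — a molecule with u unmethylated cytosines survives with
  probability exp(−λu), modelling preferential chemical damage at
  unmethylated cytosines; λ has units of per-unmethylated-C;
* **PCR bias** — a surviving molecule is amplified with weight
  exp(γ · cycles · (g − ḡ)), g its post-conversion G+C fraction. γ is
  negative in the bisulfite preset: converted (AT-rich) templates amplify
  preferentially, which reproduces both the over-coverage of AT-rich bins
  and the growth of composition bias with cycle number. Degradation and
  PCR jointly also bias methylation estimates upward: within a locus,
  molecules whose cytosines happened to be methylated carry fewer
  convertible Cs and survive selection better, and the distortion grows
  with local methylated-C density. For this net within-locus effect to be
  upward (as observed in bisulfite data) λ must exceed |γ|·cycles / L.

Fragment length equals read length (single-end 100 bp); there is no
insert-size, base-quality or non-cytosine sequencing-error model. Reads are
sampled from surviving molecules with replacement proportional to PCR
weight, so duplication arises from resampling and grows with weight
dispersion (hence with cycle number when γ ≠ 0) and shrinks with library
complexity (`n_input_molecules`).

Preset values — EM-seq: eps_fail 0.001, eps_over 0.002, no destructive or
amplification bias (the enzymatic chemistry is non-destructive and its
polymerase nearly unbiased). WGBS: eps_fail 0.005, eps_over 0.002,
p_molecule_nc 0.02, λ 0.06, γ −0.2, 12 cycles. These magnitudes were chosen
once to reproduce the *directions and orderings* of the documented effects
at desk scale (background roughly five-fold higher for bisulfite, a clear
negative coverage–GC trend, a rising methylation excess with mC density);
they are not calibrated to any real library's numbers.

All randomness derives from a single protocol seed through named
sub-streams (fragmentation, methylation, conversion, degradation, PCR), so
every stage is independently reproducible.

## Extraction

Processing order is: non-conversion filter, then positional deduplication
(first record kept per (contig, start, strand)), then pileup. Filtering
first mirrors pipelines that drop unconverted reads before any counting;
"three consecutive methylated CHHs" is read as three consecutive
CHH-context sites of the read in genomic order, ignoring interleaved
CG/CHG sites (an uncalled CHH breaks a run). The per-read discard
probability for converted reads follows the standard no-run recursion
q(n) = q(n−1) − p³(1−p)·q(n−4), exposed as `expected_discard_probability`.

CG counts are kept per cytosine, never pooled across the palindromic pair;
strand-symmetric analyses handle pairing downstream. Weighted levels use
min_coverage 1 by default. Organelle sites are excluded from genome-wide
levels and reserved for background estimation.

## DMR calling

Windows of 100 bp sliding by 50 bp; a window needs ≥ 4 context sites and a
pooled per-sample coverage ≥ `min_cov` (default 4). The test is a two-sided
Fisher's exact on the pooled 2×2 table, computed by summing hypergeometric
point probabilities not exceeding the observed table's (with a 1e−9
relative tolerance against floating-point ties); an all-zero table returns
p = 1. Raw P < 0.01 with the context minimum difference defines
significance (no multiple-testing correction, matching the published
contract; a Benjamini–Hochberg option exists but is off by default).
Same-direction overlapping or abutting windows merge; opposite directions
never merge.

The default coverage floor of 4 is deliberately permissive. For *calibrated*
null behaviour — zero calls between technical replicates at the
tissue-comparison thresholds — the floor must match the design depth:
windows whose pooled coverage is far below min_sites × per-site depth admit
chance differences above 0.2 at P < 0.01. The acceptance benchmarks
therefore run the null calibration at ~45x with min_cov 150 and the
planted-recall benchmark at ~30x with min_cov 100 (both ≈ min_sites ×
deduplicated per-site depth), yielding zero false calls over 20 seed pairs
and recall and precision of 1.0 on 2-kb intervals planted at a CG
difference of 0.4.

Shuffled controls place regions of identical lengths uniformly over contigs
(weighted by the number of valid placements, never crossing ends);
enrichment is the observed any-bp overlap fraction divided by the shuffle
mean, expected 1 under a uniform null.

## Profiles

Metaplot body bins use floor-rounded proportional boundaries
(start + ⌊i·L/20⌋), which spreads the rounding remainder over later bins
and makes profiles bit-reproducible; features shorter than the bin count
are skipped with a warning; minus-strand features are orientation-flipped.
Coverage-by-GC groups 400-bp bins by rounded integer GC percent, suppresses
classes with fewer than 5 bins, and normalizes by expected depth = total
read bases / genome length. Dinucleotide coverage counts reference top-strand
dinucleotides inside read footprints against their genome-wide frequencies;
pairs containing N are excluded from both counts.

The methylated-C density analysis needs a per-site "methylated" definition
the published description leaves open: here a site is methylated when its
level is ≥ 0.5 at coverage ≥ 4 in a designated reference sample (default:
the first/less-biased sample). For CG, bins with an odd number of CG sites
are excluded, since an odd count means the bin grid split a palindromic
pair.

## What the benchmarks do and do not show

Passing tests demonstrate internal consistency: the estimator recovers the
truth the simulator encodes, and each bias model moves the diagnostics in
the direction documented for real libraries. They do not validate the bias
magnitudes against real data — the simulator has no alignment or mapping
errors, no base-calling noise, no paired-end structure, no M-bias, and its
compartment model is far simpler than a real epigenome. Quantities that
depend on those features (absolute duplication or filter rates, real DMR
counts) are outside what this package can reproduce.

## Problem sizes

The shipped benchmarks use genomes of 40–400 kb with 10–30-kb organelle
contigs at 20–45x depth, sizes at which every pipeline stage is exact (no
subsampling) and the complete suite runs in minutes on one CPU.
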