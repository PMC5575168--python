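# Methods

`symbiorad` models the reference-guided RADseq strategy for symbiotic
metagenomes: simulate GBS loci from genomes, recover loci from metagenomic
reads, keep only the loci that derive from a target symbiont by mapping them
to its reference genome, and run comparative analytics over the resulting
homologous locus clusters. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## In-silico digestion and locus extraction

A restriction enzyme is a recognition motif over the IUPAC alphabet plus a
0-based top-strand cut offset (ApeKI = G|CWGC: motif `GCWGC`, offset 1).
Digestion expands the motif into its concrete A/C/G/T forms, scans both
strands (for the built-in panel the expanded sets are closed under reverse
complement, so the bottom-strand scan only re-finds the same cuts), and cuts
a linear molecule at every occurrence, including overlapping ones. N bases
never match, so runs of N suppress sites. Fragments are the intervals between
cuts; they tile the contig, and conservation (Σ fragment lengths = contig
length) is enforced by property tests.

The **cut model is a single coordinate** at the forward-strand offset; the
3-nt ApeKI overhang is ignored because fragment boundaries, not sticky ends,
determine locus content. One consequence worth knowing: digesting the reverse
complement of a genome mirrors all interior fragment lengths exactly, but the
two terminal fragments shift by the overhang (motif length − 2·offset). This
is intrinsic to any single-coordinate model of a staggered cutter.

Size selection keeps fragments in an inclusive window, default **200–500 bp**
("between 200 and 500 bp" is read inclusively; the choice moves counts by a
fraction of a percent). From each selected fragment the first and last
**143 bp** are extracted (150 bp single-end reads minus adapter/barcode). RAD
assembly pipelines merge loci overlapping by more than ~30%, so fragments
shorter than **243 bp** (2·143 − 243 = 43 ≈ 30% of 143) contribute one
whole-fragment locus instead. A fragment of exactly 243 bp yields two reads —
the boundary is taken literally as "shorter than 243", even though the
implied overlap (43/143 = 30.07%) sits marginally above 30%. The 3' locus is
stored reverse-complemented so both loci read inward from a cut site, as GBS
sequencing from either fragment end produces them; every downstream
comparison is therefore orientation-insensitive.

## Synthetic holobiont data

The generator produces everything the pipeline consumes, at desk scale:

* **Genomes** — i.i.d. bases at a chosen GC content. The default 0.2–1 Mb
  target stands in for a ~40 Mb fungal assembly; per-locus behaviour
  (digestion, clustering, filtering) is scale-free, only absolute locus
  counts shrink proportionally.
* **Divergence** — a Jukes–Cantor-like uniform substitution model: each site
  mutates with probability `rate · branch_length` (branch lengths in Myr,
  rate in substitutions/site/Myr) to a uniformly chosen different base;
  optional indels (lengths 1–5, uniform, insertion/deletion equiprobable) at
  their own event rate. Identity-threshold behaviour depends on overall
  divergence, not the fine structure of the substitution process, so nothing
  richer is modelled. Genomes evolve recursively along a Newick tree, so
  sister tips share ancestral mutations and carry genuine phylogenetic
  signal. Under the uniform model two tips at per-branch substitution
  probability p differ at a fraction 2p(1−p) + (2/3)p² of sites — the
  closed form the calibration tests check against.
* **Reads** — two protocols. `rad` (default) digests every source genome
  (target + contaminants), size-selects, and sequences each extracted locus
  at a depth set by `coverage`; reads span whole loci because the >30%
  overlap merge is already realized at extraction time. `shotgun` draws
  fixed-length reads with uniform starts, for coverage-style experiments.
  In both, the per-read source is chosen by mixture weight, reads are
  reverse-complemented with probability 1/2, errors substitute bases i.i.d.,
  qualities are constant Q40 (unused downstream), and read names record the
  true source as ground truth for filter benchmarking.
* **Contaminant mixture** — no canonical composition exists for holobiont
  pools; the default (target 50%, alga 30%, bacteria 20%) echoes metagenomic
  GBS libraries in which roughly half the loci derive from the target
  fungus.

What the generator does **not** emulate: realistic error/quality profiles,
PCR duplicates, adapter read-through, coverage biases, genome repeat
structure, methylation sensitivity. Passing tests therefore demonstrate the
pipeline's bookkeeping, thresholds and statistical behaviour, not robustness
to those artefacts.

Every operation is deterministic under its seed (regression-tested
byte-for-byte).

## Clustering

Identity between two loci is `1 − editDistance / max(|a|, |b|)` (edlib
global alignment), maximised over the two orientations of one sequence.
Normalising by the longer sequence makes a 143 bp read score low against a
240 bp merged locus, which is the desired behaviour for a threshold of
**0.90** (the Wclust convention).

*Within-sample*: reads are dereplicated on their orientation-free canonical
form and processed in descending-abundance (then lexicographic) order; each
unique sequence joins the best-matching centroid at ≥ threshold or founds a
new cluster (greedy, vsearch-style, with a shared-k-mer prefilter). Clusters
below **min_depth = 4** reads are discarded. The consensus is a weighted
per-column majority over a star alignment to the centroid — haploid, no
ambiguity codes, ties to the lexicographically smaller base, columns where
deletions outnumber bases dropped.

*Across-sample*: all samples' consensus loci are clustered at the same
threshold using **exact single-linkage semantics** — connected components of
the pairwise identity-threshold graph. Small instances (≤600 loci) are
solved by all-pairs comparison; larger ones use a canonical-12-mer prefilter
(stride 2) whose probability of missing a ≥0.90-identity pair over ~100+ bp
is below 10⁻³ at the threshold boundary and far smaller away from it. The
choice of single linkage over order-dependent greedy assignment makes the
partition order-independent and provably equal to a brute-force
single-linkage oracle, which the tests exploit. Clusters observed in fewer
than **min_samples = 4** samples (MinCov) are dropped. If a sample
contributes two loci to one cluster, only the deepest is kept and the
cluster is flagged as a possible paralog collapse. The cluster alignment is
a star alignment to the deepest member (insertions relative to it are
dropped — adequate for ≥90%-identical short loci; full MSA is out of scope).

*Final filtering* is two-pass: cluster, remove samples with fewer than
`min_loci_per_sample` final loci (5000 at full scale; desk-scale runs set it
lower), re-cluster the survivors once. A sample with exactly the threshold
count is retained ("fewer than" is strict).

*Unlinked SNPs*: per cluster with at least one variable column (≥2 distinct
non-gap bases), exactly one such column is chosen uniformly under the run
seed. Samples absent from a cluster are `N` at its column; alignment gaps are
`-`. Dataset statistics report cluster counts, per-sample final locus
counts, concatenated alignment length, and a gap percentage in which missing
sample × cluster cells count as gaps.

## Reference filtering

The short-read-mapper settings used for this task (1 permitted seed
mismatch, seed length 20, up to 20 extension attempts, up to 3 re-seedings)
are translated into an explicit, testable contract rather than an emulation
of any particular mapper's scoring: a locus is **target** iff some hit
aligns it at ≥ **0.85 identity** over ≥ **50% of its length**. Congeners
within the divergence range of interest (≲6 Myr at typical fungal rates)
sit well inside 85% identity; unrelated loci essentially never reach it.

Mechanics: forward-strand 20-mers of the reference are stored as sorted
2-bit integer codes (binary-search lookup). Seeds are sampled at evenly
spaced starts, ≤20 per round, with round r shifting the frame by
r·seed_len/3 — a deterministic analogue of re-seeding; each seed is looked
up exactly and through its ≤1-mismatch Hamming neighborhood, in both locus
orientations. Each hit is extended by aligning the entire locus to a
reference window (hit diagonal ± 20 bp band) in infix mode, so locus
coverage is 1.0 by construction and identity alone decides; the
`min_locus_coverage` parameter remains in the contract for alternative
extension modes. Ties break to the highest identity, then the leftmost
reference coordinate. Raising `min_identity` can only shrink the target set
(screening monotonicity), and expected recall decreases with divergence
from the reference — the mechanism behind divergence-dependent locus
recovery.

## Downstream analytics

* **Shared-loci matrix** — entry(i,j) = |clusters containing both| /
  min(|loci_i|, |loci_j|). The min-normalisation (1.0 for nested sets) is
  this package's choice; upstream tools do not publish their formula.
* **Divergence regression** — ordinary least squares of per-sample locus or
  fragment counts on divergence time, with R² and the two-sided slope
  p-value (scipy.stats.linregress; tests check it against the normal
  equations to 1e-10).
* **NJ topology check** — p-distances with pairwise deletion over the
  unlinked-SNP matrix (a pair with zero overlapping sites is an explicit
  error naming the pair), canonical neighbor-joining, negative branch
  lengths clamped to 0. This is an internal topology check standing in for
  external maximum-likelihood inference, which is out of scope.
* **DAPC** — sites with more than 20% missing data are dropped; the rest
  are coded 0/1 by major allele (haploid; multi-allelic sites collapse to
  most-frequent-alternate with a warning), missing entries imputed with the
  per-site mean; PCA (centering only — scaling conventions differ between
  implementations and centering-only is the documented choice here) retains
  5 components by default, reduced with a warning if the rank is lower; the
  discriminant step maximises between/within scatter on the PC scores with
  a pooled covariance, retaining groups−1 axes by default; membership
  probabilities are Gaussian class-conditional densities on the discriminant
  axes with equal priors, so rows sum to 1 (to 1e-9). New samples are
  projected through the stored PCA+DA with training-mean imputation for
  missing retained sites. Gaussian posteriors are sharp: for strongly
  separated groups a genuinely intermediate sample can still receive an
  extreme membership in a single replicate; the divided-membership
  behaviour is an on-average property, and is tested as such.

## Pipelines and determinism

The simulated arm digests each genome and runs the shared tail
(cluster → sample filter → SNPs → stats → NJ). The empirical arm clusters
reads within samples, filters the consensus loci against the reference,
optionally merges simulated samples (hybrid mode), and runs the same tail;
its per-sample report carries raw reads, within-sample clusters, mapped
(target) loci and final loci. With zero contamination, zero error and
saturating coverage the two arms produce identical final clusters — the
strongest internal consistency check the design admits, and an acceptance
test. Every run writes a manifest (full configuration, seed, per-stage
counts) sufficient to re-run bit-identically; all writers use stable
ordering and no timestamps, so identical configuration + seed reproduces
every output byte for byte.

## Problem sizes used in tests

Property tests run at desk scale, chosen once as the smallest sizes at which
the measured quantities are statistically stable: 10–100 kb genomes for
digestion bookkeeping, twenty 1 Mb genomes for analytic site-count
calibration, ≤50-locus instances for the clustering oracle, a 1 Mb reference
with 500+500 loci for filter operating characteristics, a 200 kb genome ×
6 samples at 30× for arms agreement, and 50 replicates of a 100 kb-genome
quartet (internal branch 4 Myr vs terminal 0.5 Myr at 0.005
substitutions/site/Myr) for topology recovery.

## Known limitations

* No quality-based error/heterozygosity model (haploid majority consensus
  only); no diploid genotype calling; no chimera detection.
* Star alignments discard insertions relative to the centroid; indel-rich
  clusters under-report variable columns.
* The filter is a classifier, not a mapper: no SAM output, no multi-reference
  competitive binning, and its 0.85/0.50 contract is a tunable convention,
  not a claim about any external mapper's acceptance region.
* Single-linkage clustering can chain through intermediate sequences in
  dense locus families; the paralog flag marks the symptomatic cases.
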