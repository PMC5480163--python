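# Methods

## The generative model behind the synthetic data

The simulator (`centsat.sim`) produces the minimal genome that exposes the
statistical structure the analysis depends on:

* **Background sequence** is i.i.d. uniform over {A,C,G,T}. At the scales
  used here (hundreds of kb to a few Mb) this makes every non-repetitive
  150-mer effectively unique, so the internal unique mapper behaves like a
  MAPQ-based uniqueness filter does on a real complex centromere.
* **Satellite arrays** are tandem concatenations of a circular monomer
  (the bundled 156-bp CentC and 180-bp knob180 consensi, or any
  user-supplied monomer), each copy independently mutated at a per-base
  substitution rate. A substituted base is always replaced by a different
  base (one of 3 alternatives, uniform), so the expected identity of a
  copy to the monomer is exactly `1 − rate`. The default study condition
  is `rate = 0.04`, matching the ~96% identity of genomic satellite
  copies to their consensus; `rate = 0` produces a perfectly homogenized
  array whose reads cannot be placed uniquely. The model is
  substitution-only; an indel process is deliberately not part of the
  default model so that alignment-length filters (125 bp / 90 bp) keep a
  fixed meaning. Identity, not length polymorphism, is the quantity the
  analysis reads out.
* **cenH3 domains** weight ChIP read-start sampling by a fold-enrichment
  factor f: a start position inside a domain carries weight f, all others
  weight 1, and the input channel ignores domains entirely (f = 1
  reproduces input statistics exactly). No published generative model
  exists for the shape of cenH3 enrichment, so this flat-weight model is
  an artifact-level choice; the default f = 20 produces the unambiguous
  peaks the caller is meant to find, and the peak-recovery tests use
  f = 10–12 so that success is not trivial.
* **Reads** are 150-nt single-end by default, sampled with replacement,
  uniform strand, with i.i.d. substitution sequencing errors
  (default 0.2%, a typical modern short-read error rate) and constant
  base quality Q35. A `low_q_tail` knob marks a fraction of reads with a
  low-quality 3' tail to exercise the quality trimmer.

Everything the generator plants is recorded in a `TruthSet` (genome,
array BED, per-copy identities, domain BED), which is what the
parameter-recovery tests compare against.

What the simulator does **not** emulate: GC bias and non-uniform
coverage, PCR duplicates, indels and structural variation, heterozygous
or diploid genomes, realistic quality-score trajectories, and the graph
structure of real repeat families. Tests passing on this generator
therefore demonstrate correctness of the estimators under their stated
assumptions, not robustness to every artifact of real libraries.

## Read preprocessing

`quality_trim` removes 3' bases while the terminal base quality is below
the threshold (default 20) — the simplest reading of a 3' quality
trimmer; retained bases are never altered and the output is a prefix of
the input. `adapter_trim` removes the best 3' occurrence of the adapter
(default `AGATCGGAAGAGC`) allowing a 5% mismatch fraction, down to a
1-base suffix overlap, with ties broken toward the longest removed
suffix; reads shorter than 100 nt afterwards are discarded. Matching is
substitution-only (N counts as a mismatch). Note that 1-base-overlap
semantics are intentionally aggressive and not idempotent in general: a
retained insert ending in the adapter's first base loses that base on a
second pass. `fixed_trim` truncates reads to a common length (100 nt) for
k-mer work. The pipeline asserts read-count conservation
(`in = out + discarded`) across every stage.

## Circular-consensus alignment

Reads are aligned against the consensus **dimer** so that any rotation of
the circular monomer — including reads spanning the junction between
tandem copies — aligns at full length; alignments longer than one
monomer are impossible by construction, which is why read-vs-monomer
identity is rotation-invariant. Scoring is match +1, mismatch −1, gap
open −2, gap extend −1; identity is matches / alignment columns with
gaps counted (the blast convention). The alignment engine is
Biopython's `PairwiseAligner` (exact local affine-gap dynamic
programming in C); an independent pure-Python Gotoh implementation in the
test suite serves as the brute-force oracle.

Two filters define a hit:

* **length** ≥ 125 columns against the dimer (90 upstream of the k-mer
  analysis);
* **score** above a significance threshold standing in for an E-value
  cutoff of 1e-5: local-alignment scores of random reads follow an
  extreme-value law, so the threshold is the upper 1e-5 quantile of a
  Gumbel distribution fitted to the best-of-both-strands scores of 300
  random reads of the working read length. For 150-nt reads against the
  CentC dimer this lands near score ≈ 30, far below any true satellite
  read and far above typical random scores (~15–20).

For bulk quantification an optional exact-word prescreen (12-mers shared
with the dimer, either strand) skips the dynamic programming for
background reads; a 12-mer survives 4% divergence with probability ~0.61
at each position, so satellite reads are essentially never lost, and the
prescreen is disabled wherever exact oracle equivalence is being tested.

`build_consensus` refines a monomer from reads by iterated column-wise
majority vote in monomer coordinates (dimer position mod monomer
length), keeping the current base on ties and flagging columns covered by
fewer than 3 reads; the result is reported in canonical
(lexicographically minimal) rotation. With ≥50× coverage and 4%
independent substitution the per-column majority is wrong with
probability far below 1/monomer-length, which is why exact recovery is a
testable expectation rather than luck.

## k-mer homogenization spectra

From a without-replacement sample of satellite reads (30,000 at
production scale; smaller in the test suite) trimmed to a common length,
all k-mers are counted. The default orientation is **consensus-oriented**
(minus-strand reads are reverse-complemented before counting, using the
strand call from dimer alignment): for a circular repeat, strand mixing
roughly doubles the apparent number of distinct k-mers and would halve
the apparent homogenization, so the stranded mode is the honest default;
an as-read mode is provided for sensitivity analysis, and neither mode is
claimed to be what any particular external counter did. k-mers containing
N are skipped and tallied separately.

The analytic homogeneous baseline `(read_len − k + 1) · n_reads /
monomer_len` (= 9807.7 ≈ 9808 at the 100-nt / 30,000-read / 50-mer /
156-bp design point) is the mean copy number per distinct k-mer when all
copies are identical; the copy-number histogram reports the fraction of
distinct k-mers below thresholds (100 and 2000 by default) as the
homogenization readout.

## Mapping, enrichment, peak calling

The internal mapper indexes every 20-mer of the genome and verifies
seed candidates by full-length Hamming distance (substitution-only, like
the simulator's error model; up to 8 mismatches). A read is **unique**
iff exactly one locus attains the best score; reads whose candidate set
exceeds 200 loci are declared non-unique without verification — on an
i.i.d. background only genuine repeats generate that many exact 20-mer
hits, and such reads could at best tie anyway. Externally aligned SAM/BAM
is ingested with the literal MAPQ ≥ 20 uniqueness rule instead.

Enrichment is computed in fixed 20-kb bins as
`(chip_i/chip_total)/(input_i/input_total)`, which makes the track
invariant under library-size rescaling. Bins with zero input are masked,
as are bins overlapping annotated satellite positions (found by exact
13-mer matches to the consensus dimer merged within one monomer length);
both masks mark bins whose apparent enrichment is unreliable.

Complex centromeres are maximal runs of unmasked bins with enrichment ≥
`min_enrich`, tolerating up to `max_gap_bins` consecutive interior
sub-threshold or masked bins, whose genomic span strictly exceeds
500 kb. `min_enrich = 2.0` and `max_gap_bins = 2` are declared free
parameters (no published enrichment level defines a "peak"); both are
config-exposed. Two or more peaks on one chromosome count as a single
complex centromere, since heterozygosity can split one centromere into
two apparent peaks. Rank correlation between per-sample complex-centromere
counts and repeat fractions uses Spearman's rho with midranks.

## Drift statistics

No standard statistic exists for cenH3 positional drift, so the package
defines a minimal trio at the level of binned, unit-mass-normalized
profiles over a window (default: union of called peaks ± 500 kb):
centroid shift in bp (B − A), normalized L1 distance in [0, 2], and the
asymmetry delta (right-half mass minus left-half mass, B − A). All three
are symmetric/antisymmetric and scale-invariant by construction. The
replicate-concordance floor — the same statistics between two random
halves of one ChIP — is the yardstick: shifts within the floor are
technical noise, shifts beyond it are positional variation. Thresholds
are reported, never hard-coded into verdicts.

## Numerical and design notes

* Coordinates are 0-based half-open everywhere internally and in BED
  outputs; bins are left-closed.
* All randomness flows through `numpy.random.Generator`; the CLI derives
  independent per-stage substreams from one root seed via CRC32-keyed
  `SeedSequence` spawning, so stages are reproducible independently.
* Problem sizes in the test suite (2-Mb genomes, 10–100k reads, 30,000
  circular reads for the homogeneous-limit check) were chosen as the
  smallest sizes at which the binomial/multinomial error bars are tight
  enough for 3-standard-error recovery assertions to be meaningful.
* Display binning is 20 kb by default; peak "length" is the genomic span
  including tolerated gap bins.
* Ties in consensus majority voting keep the incumbent base;
  equal-scoring alignment strands resolve to the forward strand.

## Known limitations

* The unique mapper is substitution-only and unspliced; it is a
  desk-scale stand-in for production aligners, not a replacement.
* Satellite annotation by exact-word matching can shave array edges by
  up to ~one monomer; the tests allow that tolerance.
* The enrichment model has no fragment-length or dispersion model; bins
  are treated as independent Poisson-like counts, adequate for the
  planted-truth recovery the package targets.
* Complex-centromere counting depends on the declared `min_enrich`
  threshold; conclusions should be checked across a threshold range for
  real data.
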