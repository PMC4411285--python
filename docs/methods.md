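# Methods

This note documents the models and algorithms implemented in `pananchor`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Coordinates and the error scale

Genome positions are 1-based and linearised as
`global = chromosome · 10^9 + position`.  The transform is injective and
order-preserving for positions below 10^9, and makes the genetic-to-
physical error a plain subtraction.  It has a known edge artefact: the end
of one chromosome and the start of the next are numerically adjacent, so
cross-chromosome pairs near boundaries can look close on this scale.  All
chromosome-agreement statistics in the package are therefore computed from
the chromosome field, never from distance bands; distances are used only
where the cross-chromosome penalty (≈10^9 bp) is intended to dominate, as
in the accuracy model's response.

## The binomial association scan

For a tag and a SNP, `n` counts taxa that carry the tag *and* have a
non-missing genotype call; `x` counts those carrying the minor allele;
`p` is the SNP's panel-wide MAF.  Under independence `X ~ B(n, p)`.  The
test is two-sided via the doubled smaller tail, because a linked tag may
ride either allele.  A one-sided variant is available
(`alternative="greater"`).  p-values are evaluated through the
regularized incomplete beta function in log space: with hundreds of taxa
in perfect LD the tail underflows double precision, so ranking and all
derived attributes use `-log10 p` and ties at equal evidence break to the
smaller global position for determinism.

Choices worth stating:

* MAF is panel-wide over non-missing calls, one vote per inbred taxon; a
  tie at 0.5 takes the lexicographically smaller allele as minor.
* Heterozygous calls (rare in inbreds) count as carrying the minor allele
  by default (`het_policy="minor"`); the alternative treats them as
  missing.
* Structure is not corrected in the scan.  This is a deliberate trade of
  specificity for speed; the accuracy model downstream carries structure
  attributes precisely because of it.

## Joint-linkage mapping

Step 1 runs the binomial test within each family with MAF recomputed on
the family's taxa (sites monomorphic in the family are skipped).  Step 2
groups segregating families (p < 0.05) by best-SNP chromosome.  Step 3
pools the winning group's taxa and re-runs the test restricted to that
chromosome with pooled counts and pooled-subset MAF; restricting to the
winning chromosome is a config flag (`restrict_to_chromosome`), since the
alternative reading — a genome-wide rescan on pooled taxa — is defensible.
Group-size ties break by larger summed per-family evidence (equivalently
the smaller product of best p-values), then lower chromosome index.  No
multiple-testing correction is applied within families; the raw 0.05
threshold is part of the procedure.

## Accuracy attributes

Per mapped tag, the G class uses nine attributes: best `-log10 p`; the gap
to the best evidence on any other chromosome; the number, bp span and
best-chromosome fraction of sub-threshold SNPs (profile capped at the
1,000 most significant); tag count and frequency; best-SNP MAF; and the
maximum |Pearson r| between the presence pattern and the first three
principal components of a 5,000-SNP genotype sample.  The J class adds the
number of segregating families and the winning-group fraction (its base
attributes come from the pooled scan, whose best `-log10 p` is the pooled
value); GJ adds the joint-linkage extras plus two cross-method agreement
attributes (log10 distance between the two genetic positions, chromosome
agreement).  The set is intentionally mechanism-driven — association
strength, profile sharpness, structure confounding, cross-method
agreement — and is extensible in `features.ATTRIBUTE_NAMES`.

Attributes are Box-Cox normalised: per attribute, a shift enforces
positivity, lambda is fitted by maximum likelihood and bounded to
[-2, 2] (outside that range the power transform overflows on
genomic-scale values while adding no usable shape change), and the
transformed column is standardised with the training mean and standard
deviation so the downstream least squares is well conditioned.  Training
parameters are stored with the model and applied unchanged to new data;
out-of-domain values clamp at a small positive floor rather than
producing infinities.

## M5 rule model

The error model is an M5 model tree with rule extraction:

* **Growth** maximises the standard-deviation reduction
  `SDR = sd(T) − Σ |T_i|/|T| · sd(T_i)`; nodes stop below `min_leaf · 2`
  instances or when their sd falls under 5% of the root's.
* **Node models** may use only the attributes tested in the node's
  subtree (leaves start intercept-only) and are fitted by greedy forward
  selection under the `(n+v)/(n−v)` penalty, capped at `n/3` coefficients;
  small nodes therefore cannot interpolate with large cancelling
  coefficients.
* **Pruning** compares each node's penalized model error against its
  subtree's raw error penalized with the subtree's *full* parameter count
  (leaf coefficients plus two per split, for the attribute and the
  threshold).  Charging the splits is what counteracts the selection
  optimism of SDR-chosen children; without it, noise-chasing splits always
  beat the node model on training error.
* **Smoothing** blends each leaf's model with its ancestors
  (`p' = (n·p_child + k·p_parent)/(n + k)`, k = 15); since every model is
  linear, the smoothed leaf model is itself a single linear model, which
  is what a rule stores.
* **Rules** are extracted iteratively: build a tree on the not-yet-covered
  instances, turn the leaf covering the most instances into a rule (path
  conditions + smoothed model), drop its instances, repeat.  A global
  linear model serves as the default for vectors no rule matches, and
  predictions are clamped to the training response range — like any
  tree-family model, the rules should not extrapolate.

The response is `log10(distance + 1)`: raw distances span 0 to ~10^10
under the global transform and would dominate least squares.  Selection
thresholds (G 50 kb, J/GJ 100 kb) are applied after back-transforming to
bp.  `train_accuracy_model` chooses `min_leaf` by deterministic 5-fold
cross-validation over {4, 8, 16, 32, 64}: at the few hundred training
instances of desk-scale runs, the literature default of 4 chases noise.
The reported model fit (`r2_*` in the run summary) is the merged-data r²
between predicted and observed log-error over all training instances —
the same quantity the rule-model literature quotes; held-out r² on the
standard benchmark is lower (≈0.5), reflecting the irreducible randomness
of which near-tied SNP wins a scan.

Training instances are the mapped tags with a unique, perfect, full-length
reference alignment; their physical position is taken as truth.  Classes
with fewer than 100 such tags are skipped (logged), and contribute no
anchors.

## PAV calling

An anchor is PAV iff no alignment lies within 10 Mb of its genetic
position on the same chromosome — either because the tag aligned nowhere,
or only far away.  "Within 10 Mb" is read as a maximum distance of 10 Mb;
the ±5 Mb reading is available by halving `--pav-window`.  Growing the
window is monotone: it can only clear flags.  Density tracks divide PAV
anchor counts by reference-tag anchor counts per 1-Mb window (restriction
-enzyme and methylation biases make raw tag counts uneven); windows
without reference tags report a missing value.

The built-in exact matcher reports every perfect occurrence of each tag on
both strands, via a vectorised rolling 64-mer hash (odd multiplier,
arithmetic mod 2^64, per-window recovery through modular inverses) with
candidate hits verified by string comparison.  It is the test path and the
demo path; production alignments from Bowtie2-class aligners are ingested
from SAM (perfect-match = all-match CIGAR and NM:0), BED, or a simple TSV.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
not sequence evolution:

* **Founders** carry biallelic SNP alleles drawn from ancestral
  subpopulation frequencies under a Balding-Nichols model (default 3
  subpopulations, Fst 0.1).
* **NAM mode** crosses a common parent to each family founder and selfs
  (default 6 generations) under a Haldane (no-interference) crossover
  model, 2 Morgans per chromosome per meiosis.
* **Panel mode** builds each parent as an *ancestral mosaic*: founder
  segments whose breakpoints accumulate over `ancestral_generations`
  (default 150) of random mating in a large population, sampled directly
  as a Poisson process — this grants the panel the deep recombination
  history that gives real diversity panels their fast LD decay, which a
  biparental family lacks, and avoids the drift and fixation a small
  forward-simulated pool would suffer.  Founders differ in mobility:
  per subpopulation, one founder's haplotype stays private while the
  others also migrate as admixed segments (rate 0.45).  Tags on private
  founders are structure-confounded and map poorly; tags on mobile
  founders map well — reproducing the empirical link between mapping
  error and structure correlation that the accuracy model exploits.
* **Tags** mark one founder's haplotype at one locus: a taxon carries the
  tag iff it inherited that founder's segment there (plus a 5% dropout
  emulating missed GBS coverage).  Genotype calls are homozygous (the
  first haplotype's allele) with 10% missingness: GBS callers on inbred
  panels emit hom calls, and this makes file round trips exact.
* **PAV truth**: a configurable fraction of tags (default 26%) are
  excluded from the generated reference.  Half of those receive a decoy
  copy at least 50 Mb away (or on another chromosome) carrying two
  substitutions — a distant copy of sequence missing from its orthologous
  region is a diverged paralog, and an exact matcher must not rediscover
  it.  The far-alignment PAV branch is exercised through ingested
  alignment fixtures, where tolerant aligners do report such hits.
* **Scale**: the standard benchmark is 400 taxa, 2 chromosomes x 50 Mb,
  2,000 candidate SNPs, 1,000 tags — sized so a full pipeline run takes
  about a minute while every stage has enough data to be measured.

What passing tests on this generator do **not** show: performance under
real LD (which decays over kb, not the ~100 kb of the mosaic model),
sequencing error in tag identity, reference assembly errors, paralogy
beyond single diverged decoys, or anything about the absolute accuracy
numbers at the million-tag, 681k-SNP scale of a real panel — those depend
on marker density and population size, and the desk-scale benchmark is
two orders of magnitude smaller.

## Numerical and degenerate-input conventions

* Binomial ties: smallest global position wins; group ties in joint
  linkage: evidence sum, then chromosome index.
* Constant presence vectors have structure correlation 0; constant
  attributes get lambda 1 and pass through the normaliser unchanged.
* Monomorphic and multi-allelic input sites are dropped with a logged
  count; duplicate tag sequences merge by OR of presence; tags observed in
  no taxon are dropped.
* Density windows with zero reference tags report NaN, not infinity.
* Every stochastic component takes an explicit seed; identical seeds give
  bit-identical simulation bundles and byte-identical anchor tables.

## Known limitations

* The attribute list stands in for a larger production set; sequencing
  depth and imputation-density attributes are deliberately absent (they
  measure ~0 incremental signal and would require read-level simulation).
* Single-marker trait p-values in `simpop` are a test utility for the
  enrichment stage, not a GWAS: no structure correction, no mixed model.
* The enrichment MAF cutoff equalises distributions only approximately on
  arbitrary data; the KS diagnostic is reported, not enforced.
* Joint-linkage step 3 pools taxa and recomputes MAF in the pooled subset;
  a weighted per-family meta-analysis would be a reasonable alternative
  the interface does not currently expose.
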