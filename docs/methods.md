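# Methods

## The estimation problem

A mutation accumulation line (MAL) is a lineage pushed through repeated
single-cell bottlenecks. Because every bottleneck resets the effective
population size to one, selection has almost no opportunity to act, and the
mutations observed in the end-point clone are an (almost) unbiased sample
of the spontaneous mutation process. With `m_i` de novo mutations observed
in replicate `i` over `T` generations and `L` callable bases, the
per-replicate rate is

    mu_i = m_i / (L * T)

and the strain rate is the arithmetic mean of the `mu_i` with its standard
error across replicates. The pooled estimate `sum(m_i) / (r * L * T)` is
reported alongside; the two coincide whenever all replicates share `L` and
`T`. Counts are Poisson, so at yeast scale (L ≈ 1.2 × 10⁷, T in the
thousands, tens of mutations per replicate) the mean-of-replicates
estimator is unbiased with relative Monte-Carlo error `1/sqrt(r * m)`.

**Callable length.** `L` is the reference length of the compartment
(nuclear or mitochondrial) minus excluded-region bases. It is computed and
logged, never hard-coded, because the denominator is the main source of
small discrepancies between published rates. Aneuploid chromosomes are not
double-counted: under a per-locus mutation model an extra chromosome copy
does not add callable sites (an explicit assumption, logged).

**Strain comparisons** use Welch's unequal-variance two-sample *t*-test on
the per-replicate rates (two-sided) plus the fold change of strain means.
Degenerate inputs are resolved explicitly: two zero-variance identical
replicate vectors give p = 1, a zero control mean flags the fold change as
undefined rather than emitting infinity.

## Variant curation

De novo calls are the intersection of two callers' outputs keyed on
(chromosome, position, ref, alt), minus ancestor-shared calls, minus calls
in excluded complex regions (subtelomere-like intervals supplied as BED,
0-based half-open), minus calls with depth below 11 (i.e. rejecting the
≤ 10 poor-depth class). The three filters commute; the filter log records
counts removed per filter per replicate. INDELs are left-normalised before
key comparison — full reference-based left-alignment when the genome is
available, parsimony trimming otherwise — because callers anchor the same
homopolymer event differently. Multi-allelic records are split on read.
A call with no recorded depth is kept with a warning (the depth filter
presumes depth is known).

Cross-contamination between replicates is screened by the shared-mutation
fraction |A ∩ B| / min(|A|, |B|); pairs at or above 0.2 (configurable, no
published value exists) are flagged for exclusion. Independent MAL
replicates should share essentially nothing, so the threshold is
deliberately loose.

## Spectra and signatures

SNVs are folded onto the pyrimidine strand (purine-reference substitutions
reverse-complemented), giving six classes C>A, C>G, C>T, T>A, T>C, T>G.
Ts/Tv = (C>T + T>C) / (four transversion classes); the G/C→A/T bias is
(C>A + C>T) / (T>C + T>G). Zero denominators are reported as undefined,
never as 0 or infinity. With flanking reference bases each SNV maps to one
of 96 trinucleotide channels ordered class-major then 5' then 3' flank
(A[C>A]A … T[T>G]T), the row order of SBS signature matrices;
chromosome-terminal SNVs lack a flank and are skipped with a warning.
Collapsing the 96 channels over flanks reproduces the 6-class counts
exactly, and the profile is invariant to reverse-complementing genome and
variants together — both are tested properties.

**Strict signature refitting.** A profile is decomposed over a signature
matrix by nonnegative least squares (SciPy's active-set solver; the
contract is KKT optimality, tested directly). Plain NNLS over a large
catalogue notoriously smears weight across spurious signatures, so the
strict refit prunes: repeatedly remove the signature with the smallest
current contribution (ties broken by name), refit, and accept the removal
while the cosine similarity between profile and reconstruction drops by
less than `max_delta = 0.004` relative to the previously accepted fit; the
first rejected removal is restored and the loop stops. The loop is
deterministic, never eliminates the last signature, and satisfies the
accounting bound final_similarity ≥ all-signature similarity −
(#removals × max_delta). For small catalogues the greedy result is checked
in tests against an exhaustive search over all elimination orders.
Cosine similarity is computed on raw count vectors, with a zero-vector
guard returning 0.

## Effect annotation and neutrality

A minimal codon-level classifier stands in for a full effect predictor:
a SNV inside a CDS has its codon reconstructed from the reference
(reverse-complemented for minus-strand genes) and translated with the
standard nuclear code — synonymous (low impact), missense (moderate), or
nonsense (high) on stop gain; stop-loss is folded into missense. "Genic"
means within the gene span, "coding" within CDS; INDELs and mitochondrial
variants are annotated genic/intergenic only. Variants in overlapping genes
take the most severe category. A reference-allele mismatch against the
genome raises, naming the position, to guard corrupted inputs.

Under neutral accumulation the non-synonymous fraction of coding SNVs and
the genic fraction of all SNVs should match mutational opportunity. The
yeast nuclear constants 0.76 and 0.74 are literature values used as
configuration, not recomputed from the annotation; for synthetic toy
annotations the pipeline instead defaults the genic expectation to the
annotation's actual genic coverage, which is the correct null there. The
observed/expected comparison is a two-sided exact binomial test by default;
a Fisher 2×2 construction (observed counts vs rounded expected counts) is
available since the published analyses name Fisher's test without printing
the table. Randomness of placement is additionally checked by ordinary
least squares (with intercept) of per-chromosome SNV counts on chromosome
lengths; constant counts give slope 0 and R² = 0, all-zero counts leave R²
undefined and flagged.

## Depth-based copy number

All copy estimates are ratios of median depths, hence invariant to overall
sequencing depth. Medians rather than means throughout, so CNV windows do
not contaminate baselines.

* **mtDNA copy number** = (median mito window depth / nuclear baseline) ×
  ploidy, where the nuclear baseline is the median of per-chromosome median
  depths — robust to a single aneuploid chromosome, which measurably biases
  a pooled window median. Ratios below 1% of the baseline report copy 0
  (rho0, complete mtDNA loss).
* **Aneuploidy**: per-chromosome estimated copy = ploidy × (chromosome
  median / median of per-chromosome medians), rounded half-up to an integer
  call; the raw estimate is always reported so borderline calls are
  auditable. A single-chromosome genome is flagged undecidable.
* **Segmental CNV**: recursive binary segmentation of windowed depths with
  a BIC-style penalty (3 σ² log n per change point, σ estimated robustly
  from first differences, so a noise-free flat track yields no splits and a
  noise-free step splits exactly at the boundary). The euploid baseline is
  the majority segment's mean (tie → the lower-depth state, duplications
  being the common event) unless an expected baseline is supplied. Adjacent
  segments with equal rounded copy are merged; segments deviating from
  ploidy by ≥ 0.5 copies over ≥ 5 windows are reported, with breakpoint
  distances to the nearest repeat interval when a repeat BED is given.
  Detection is depth-only; split-read evidence is out of scope.

## The synthetic experiment generator

The generator emulates the observable layer of a MAL sequencing study on a
toy genome (random sequence at yeast-like 38% GC; chromosome count and
sizes configurable; realistic chromosome sequences are deliberately not
attempted):

* Per replicate, mutation counts are Poisson(rate × L × T) per compartment
  and class. Substitution classes (or 96-channel contexts, when the
  spectrum is a signature mixture) are drawn first, then a uniform site
  with matching reference base/trinucleotide, so the realised spectrum
  matches the configured one in expectation regardless of base composition.
  One mutation per site per replicate (infinite-sites), matching the rarity
  regime of real MALs.
* Spectrum parametrisation: transition mass p = TsTv/(1+TsTv) split between
  C>T and T>C by the configured G/C→A/T bias; GC-changing transversions
  share half the transversion mass with the same split; GC-neutral classes
  split the rest evenly. Both summary statistics are exact by construction.
* INDEL lengths are geometric(0.5) capped at 10 bp, insertion/deletion
  equiprobable, in VCF anchor-base representation (only INDEL counts are
  analysed downstream, not INDEL spectra).
* Each of two callers reports the truth minus independent Bernoulli false
  negatives plus caller-specific Poisson false positives at independent
  uniform positions — the reason consensus intersection removes them in
  expectation. Ancestor variants appear in the ancestor call set and in
  every replicate's caller sets. Per-call depths are negative-binomial
  around the configured mean.
* Depth tracks: per-window depth is negative-binomial with
  variance = dispersion × mean (default dispersion 2, the overdispersion
  typical of short-read coverage; dispersion 1 degrades to Poisson;
  noise can be disabled, giving exact expected depths). Mitochondrial
  windows scale by the configured copy ratio (default 14 mtDNA copies per
  haploid nuclear genome at 88× mean coverage); whole-chromosome or
  segmental events scale affected windows by copy/ploidy.
* A single integer seed fixes all randomness; identical inputs give
  byte-identical outputs. The pipeline derives per-strain child seeds from
  the master seed via `numpy.random.SeedSequence`.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: read-level artefacts (mapping bias,
systematic caller error correlated between callers, context-dependent
error), real yeast sequence composition and repeats, clonal interference
or selection during propagation, and mtDNA heteroplasmy. Recovery results
demonstrate that the estimators are correct under the stated stochastic
model, not that the model captures every property of Illumina data.

## Problem sizes and numerical choices

Recovery tests run the simulator at the study's own design scale: callable
nuclear length 1.2 × 10⁷, mtDNA-scale compartment of 75 kb, 3–4 replicates,
1260 or 2520 generations, 88× coverage. Rate recovery averages over
200–1600 seeded experiments (more at mtDNA scale, where a replicate
carries only ~2–3 mutations, to push Monte-Carlo error near 1% against a
5% band); spectrum recovery uses 500 experiments of 149–162 SNVs; copy
number 100 track sets. The full test suite runs in well under a minute on
one CPU; the acceptance script in a few seconds.

Tolerances: probability vectors must sum to 1 within 1e-9; signature
columns within 1e-4 of 1 on load (then normalised exactly); the strict
refit's acceptance comparison carries a 1e-12 slack so `max_delta = 0`
still permits removals that leave similarity numerically unchanged.
Integer copy calls round half away from zero. Mean Ts/Tv across finite
experiments sits slightly above the configured ratio (a ratio-of-counts
Jensen effect, ~1–2% at n ≈ 150), well inside the recovery tolerance.

## Known limitations

* The effect classifier handles single-exon and multi-exon CDS but not
  splice sites, UTRs or regulatory features; "genic" is purely span-based.
* Segmental CNV breakpoints are window-resolution, not base-resolution.
* The contamination screen is pairwise and threshold-based; it flags, it
  does not deconvolve mixtures.
* The Fisher-test table construction against a rounded expectation is one
  of several defensible choices; the binomial test is the default for that
  reason.
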