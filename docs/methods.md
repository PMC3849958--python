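# Methods

This note documents the models, rules and numerical choices behind `nilkit`,
and what the synthetic-data generator does and does not emulate.

## Coordinate system and call alphabet

Markers live on a shared map with an integer chromosome, a genetic position
(cM) and a 1-based physical position (bp). Physical intervals are closed
`[start_bp, end_bp]` and introgression lengths are `end − start + 1` bp.
Marker ids of the form `C<chrom>_<bp>` must agree with their coordinates and
can be parsed into a map when none is supplied.

Genotype calls use the closed alphabet `{D, R, H, U, M}`: donor homozygous,
recurrent homozygous, heterozygous, undetermined (a call was attempted but
could not be classified) and missing (insufficient data). U and M are kept
distinct because they arise from different failure modes of
reduced-representation genotyping, but both are treated as uninformative by
every downstream rule.

## Breeding-scheme simulator

Meiosis follows the Haldane model: the number of crossovers per chromosome is
Poisson(L_cM/100) with breakpoints uniform on the genetic map and no
interference. Interference is deliberately omitted — nothing downstream
depends on it, and it would add a parameter the data cannot constrain.
Haplotypes are founder-label mosaics (breakpoint lists), so simulation truth
(exact segment boundaries, per-line donor fractions) is available to tests.

The default genome has 5 chromosomes with Arabidopsis-like physical lengths
(≈119 Mb total) and a 450.8 cM genetic map distributed proportionally to
physical length. Genetic↔physical interpolation is piecewise linear between
anchor pairs, by default one pair per chromosome end; users can supply more
anchors where a nonuniform recombination landscape matters. Round-trips are
consistent to 1 bp.

The default program mirrors a marker-assisted NIL design: 346 RILs (selfed
k = 6 generations by single-seed descent, leaving ~(1/2)⁶ ≈ 1.6 % residual
heterozygosity, the raw material for heterogeneous-inbred-family-style
fine-mapping), chromosome-isogenic RIL selection, 25 BC1 families of 24
plants each from F1 × recurrent backcrosses, marker-assisted retention of
BC1 plants carrying donor alleles on the focal chromosome, and three selfing
generations (BC1S1–BC1S3). Accidental selfs during crossing can be simulated
at a configurable rate (default 0) and are culled by F1 confirmation
genotyping, as a real program would.

The marker panel mixes 81 evenly spaced anchor (SSR/SNP-style) markers with
930 RAD-style loci placed uniformly at random, 1011 in total (2.24
markers/cM), allocated to chromosomes in proportion to genetic length. Calls
are masked to missing independently at 15 % by default — reduced-
representation genotyping with strict scoring thresholds loses a substantial
fraction of calls, and the run-calling rules are designed to tolerate that.
Read counts per sample×locus are Poisson(λ = 20 by default) with a symmetric
per-read error e = 0.005; a heterozygote emits either allele with probability
1/2 regardless of e.

What the generator does **not** emulate: segregation distortion, mutation,
genotyping batch effects, non-uniform RAD locus recovery, linked selection
during the real program's manual line choices, and real recombination
landscapes (hot/cold spots). Passing tests therefore demonstrate correctness
of the algorithms under a neutral, no-interference model — not that real
libraries will match the simulated summary statistics.

## Threshold genotype calling

Each sample×locus read pile is classified by minor allele frequency:
coverage below the minimum (10× for library samples, 20× for parents) →
missing; MAF < 1 % → homozygous for the major allele; MAF > 25 % →
heterozygous; 1 % ≤ MAF ≤ 25 % → undetermined. The boundaries are assigned
conservatively to "undetermined" because only the strict inequalities are
unambiguous. With more than two alleles, MAF = (coverage − max count) /
coverage, so error-like third alleles push a locus toward undetermined
rather than silently vanishing. Note a direct consequence of the 1 % rule: at
20–100× a single error read makes a true homozygote undetermined, which is
the main source of missing data at realistic coverages.

Homozygous sample calls are compared with the parental genotypes to encode D
or R; loci where the parents share a genotype, or where either parent is
unknown after imputation from a resequencing reference, are dropped as
uninformative (with a report). A homozygous call matching neither parent is
discordant and becomes U with a warning count, not an error — heavy
missingness is expected and tolerated.

The segregation filter removes loci that cannot segregate in the pedigree:
loci with a constant homozygous call across all lines, and loci that
contradict pedigree constraints (e.g. a chromosome known to be fixed
recurrent) in more than a tolerance fraction (default 20 %) of constrained
informative lines. The exact constraint set is configurable because real
pedigrees differ; the default rules are documented approximations.

## Introgression calling

An introgression is a run of ≥ `min_run` (default 3) markers of one target
class (D → homozygous, H → heterozygous, scored independently), terminated
only by `boundary_run` (default 3) *consecutive informative* calls of a
different class or the chromosome end. Two deliberate conventions:

* **M/U transparency.** Missing and undetermined calls neither support nor
  terminate a run. Terminating on missing data would shatter true segments
  under 15 % missingness; counting them as support would inflate runs.
* **Isolated opposite calls are treated as genotyping errors.** A single R
  call inside a donor run does not end it and does not count as support;
  three consecutive opposite informative calls do end it.

Run bounds are the positions of the outermost *supporting* markers (inner
bound), so reported lengths are conservative. A brute-force oracle —
grouping target-call positions split wherever ≥ `boundary_run` informative
non-target calls intervene — is verified against the scanner exhaustively
for all length-10 call strings and on random length-30 strings.

Population summaries aggregate counts, ranges and closed-bp lengths by
zygosity and chromosome. The coarse-vs-dense comparison re-calls
introgressions on a marker subset and reports dense-only discoveries, count
ratios and mean-size ratios; under the default simulated conditions, the
coarse map finds fewer and (as a detected set) larger introgressions, the
same direction as in real libraries though the magnitude depends on panel
geometry. The density analysis draws uniform random marker subsets
genome-wide (not stratified by chromosome), 10 repetitions per density, and
fits the saturation curve y = a·(1 − e^(−b·x)) by bounded least squares
(a₀ = max(y), b₀ solved from the first positive point); the asymptote a
estimates the total discoverable introgressions.

## Selection algorithms

*Chromosome-isogenic RILs*: a line qualifies for a chromosome when every
informative call there is D, with at most `max_missing` M/U calls and at
least one D.

*Genome-covering NIL subset*: greedy weighted cover. Each step selects the
line maximizing (newly covered target-introgression bp) − weight ×
(background donor bp outside the line's largest target introgression),
ties broken by smaller background then lexicographic id; weight defaults to
0.5. Greedy set cover is not optimal in general, but matches exhaustive
search on the toy instances in the test suite and is what a breeding program
can execute incrementally. With `fill_to_k`, ranking continues past coverage
saturation — remaining ranks go to lines carrying at least one target
introgression, cleanest background first — to build a redundant library of a
chosen size rather than a minimal cover.

*Sub-NIL recombinants*: progeny are grouped by their exact genotype vector
over the interval markers after dropping non-segregating markers (reported).
Crossover counts are dosage steps (D = 2, H = 1, R = 0) between adjacent
informative markers; a class is a double recombinant when its dosage path is
non-monotonic, and the absence of any such class is flagged. Class ranking
prefers fully homozygous vectors, then fewest missing calls; heterozygous
classes are retained because one further selfing can fix them.

*Interval refinement*: under a single-causal-locus assumption the candidate
region is the intersection, over significant lines, of their donor coverage
on the focal chromosome; each significant line's exclusion is the region
inside other lines' introgressions but outside its own. Endpoints follow a
closure convention — results are bounded by the flanking marker coordinates
themselves, so an introgression ending at x excludes `[x, …]`, matching how
marker-delimited regions are reported in practice. An empty intersection is
flagged (`no_consistent_interval`), signalling a multi-locus architecture or
an error, rather than raised.

## Quantitative genetics

*Heritability*: one-way random-effects method of moments. V_E is the
within-line mean square, V_G = (MS_among − MS_within)/n₀ with the unbalanced
n₀ = (N − Σnᵢ²/N)/(a − 1), V_P = V_G + V_E; negative V_G is truncated to 0 so
H² ∈ [0, 1]. This is the simplest estimator consistent with a
"ratio-of-variance-components" definition and is exactly invariant to affine
phenotype transforms.

*Haley–Knott scan*: phenotypes are reduced to line means (replicate
structure enters only there; permutations shuffle line means, the standard
choice for RIL scans). At each pseudomarker on a cM grid the expected donor
dosage is computed from the nearest informative flanking markers via a
Markov conditional with Haldane recombination fractions adjusted for selfed
RILs, R = 2c/(1 + 2c) (configurable to raw c). H/U/M calls are uninformative
for conditioning — H is rare in RIL-type matrices and carries little dosage
information for an additive scan. A line with no informative markers on a
chromosome gets dosage 0.5 there; a chromosome with no informative markers
at all is skipped with a warning. LOD = (n/2)·log₁₀(RSS₀/RSS₁); at a fully
observed marker this reduces exactly to single-marker regression. Variance
explained at the peak is 1 − RSS₁/RSS₀. The permutation threshold is the
empirical (1 − α) quantile of the genome-wide maximum LOD over n_perm
(default 1000) seeded permutations; n_perm < 1/α triggers a quantile-
instability warning. Multiple-QTL model search and composite interval
mapping are out of scope: the scan is single-QTL.

*NIL validation*: a fixed-effects linear model, phenotype ~ genotype +
block, replaces the full mixed model with random block/row/column used in
field practice — the reproducible content (block-adjusted genotype means and
their contrasts) does not require REML machinery, and the simplification is
stated prominently. Genotypes with fewer than two replicates are dropped
with a warning. The table reports block-adjusted means, standard errors,
each NIL − recurrent difference with t and p, plus all pairwise NIL-vs-NIL
contrasts (identical off-target backgrounds would show there).

## Problem sizes used in the automated checks

The acceptance computations use the study-scale defaults where they matter:
a 1011-marker panel, 346 RILs, 25 BC1 families, a 75-line selected library;
calibration studies use 200 replicate genomes for the permutation-threshold
type-I error (1000 permutations each, 200 RIL lines, 2 cM grid) and 200
replicates for localization of a planted QTL explaining 9 % of variance in
346 RILs. Monte-Carlo assertions use 3-sigma bands around the analytic
expectations. The exhaustive run-caller check covers all 4¹⁰ length-10 call
strings over {D, R, H, M} plus 10⁴ random length-30 strings over the full
alphabet.

## Known limitations

* The run caller is a deterministic rule, not a probabilistic ancestry HMM;
  it inherits the rule's blind spots (introgressions spanning < 3 markers
  are invisible; bounds are inner, so lengths are underestimates).
* Simulated library summary statistics (introgression counts and totals)
  depend on selection-rule details a real program applies by hand; the
  simulator's greedy selection is cleaner than human choices, so its
  libraries carry somewhat fewer background introgressions than a real one.
* The validation model ignores row/column field structure unless supplied as
  covariates, and the heritability estimator assumes uncorrelated residuals.
* No VCF/PED ingestion; genotype CSV, marker-map TSV and counts TSV are the
  interchange formats.
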