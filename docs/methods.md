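# Methods

This note records the statistical models herdstat implements, the
conventions and numerical choices behind them, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Data model and quality control

A panel is a sample × marker matrix of B-allele dosages in {0, 1, 2}
(NaN for missing) with a marker map (opaque chromosome labels, 1-based
bp positions) and a group label per sample. Genome order is defined as
chromosomes in order of first appearance in the map, positions strictly
ascending within a chromosome; input files in any order are re-sorted on
read. No strand or allele matching is attempted: AB coding is taken at
face value, and the tool operates on a single panel.

QC applies three strict (">") filters in a fixed order: marker call
rate, then sample call rate (computed over the markers that survived the
first filter), then MAF — with allele frequencies recomputed on the
surviving samples, since MAF depends on who remains. Defaults are
MAF > 0.01 and call rate > 0.95 for both markers and samples. MAF is
min(p, 1−p) on the combined post-sample-QC panel, not per group, because
group analyses downstream all start from one jointly filtered panel.
The order itself is a design choice (reasonable alternatives exist); it
is documented here rather than inferred from anything.

Missing dosages are mean-imputed per marker before GRM and LD stages.
This preserves allele frequencies exactly but carries no linkage
information — it is a deliberate, simple stand-in for haplotype-based
imputation, adequate at the low missingness rates QC admits (< 5%), and
it produces fractional dosages, which all downstream estimators accept.

## Heterozygosity and F_ST

H_exp = 2p(1−p) per marker from the group's allele frequency; H_obs is
the heterozygote proportion among non-missing genotypes. Both are
summarised as mean ± SD across markers.

Pairwise divergence uses the Weir–Cockerham estimator. Per marker, with
r groups of size nᵢ, frequency pᵢ and observed heterozygote proportion
hᵢ (from genotypes, not a Hardy–Weinberg assumption):

    n̄ = Σnᵢ/r                     n_c = (r n̄ − Σnᵢ²/(r n̄))/(r−1)
    p̄ = Σnᵢpᵢ/(r n̄)               s² = Σnᵢ(pᵢ−p̄)²/((r−1) n̄)
    h̄ = Σnᵢhᵢ/(r n̄)

    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
    c = h̄/2

θ_W sums a and a+b+c across markers before dividing (ratio of sums, not
mean of ratios — the two disagree and the test suite pins the
difference). Negative per-marker components stay in the sums. Markers
monomorphic across the pair, or with any group below n = 2, are skipped
and counted per pair (not globally), so each pair uses every marker
informative for it. Each pair uses only its own two groups' frequencies.
Small negative θ̂ values are legitimate sampling outcomes for undiverged
groups and are reported as-is.

## GRM, inbreeding, block relatedness, PCA

G = (M − 2P)(M − 2P)′ / (2Σⱼ pⱼ(1−pⱼ)). Reference frequencies default
to the included samples, which makes every column of G sum to zero
exactly; a supplied frequency set overrides this (e.g. to relate new
samples on a fixed base). Recomputing G on a subset with the subset's
own frequencies is not the same as slicing the full-panel G: the
re-centering typically lowers the mean diagonal when the subset is more
homogeneous than the full panel, and both routes are exposed because the
difference is itself informative about structure.

F_VR = G_ii − 1, summarised per group as min / mean ± SD / max, plus
the grand mean diagonal as a heterogeneity diagnostic. Block relatedness
is the mean of the off-diagonal block of G for each group pair;
within-group blocks exclude the diagonal; singleton groups have
undefined (NaN) internal relatedness. Each group also carries an
"external mean" — its mean relatedness to all samples outside the group
— used as the diagonal replacement in heatmap-style layouts.

PCA decomposes G itself (eigh), not the centered dosage matrix; the two
agree in exact arithmetic and G is the declared interface. POV uses
trace(G) as denominator (equal to the full eigenvalue sum, no full
decomposition needed in truncated mode). Numerically negative
eigenvalues are clamped to zero for POV and counted. Scores are
eigenvector × √λ. Component signs are fixed by making each component's
largest-magnitude loading positive, so runs and plots reproduce exactly.

## LD and effective population size

r² between two markers is the squared Pearson correlation of dosage
vectors (composite LD). The classical haplotype-frequency formula
(p_AB − p_A p_B)²/(p_A q_A p_B q_B) needs phase, which real chip panels
lack; under random mating the dosage correlation converges to it, and a
test pins the correspondence on the forward simulator's phased output.

For each marker, r² is computed against its next `max_depth` (default
400) successors in genome order. Windows crossing a chromosome boundary
form the non-syntenic set; its single mean estimates the sampling floor
(≈ 1/N for N samples, ≈ 1/(N−1) exactly for independent loci). The
syntenic decay curve restricts to markers with the full depth of
same-chromosome successors — so every depth bin averages the same
marker set — and maps depth to distance as depth × mean adjacent
spacing (a global, not per-pair, convention; a per-pair mode exists in
the records for anyone who wants it). Pairs involving a monomorphic
marker are undefined and counted, not zero-filled.

The sample-size experiment recomputes the non-syntenic mean on random
subsamples of N = 2^n individuals and regresses it on 1/N. The
correction applied is subtraction of the 1/n sampling expectation,
floored at zero with a flag (true small LD at small n inevitably goes
negative); an uncorrected "report" mode returns the raw value with the
expectation alongside.

Ne_t = (1 − r²)/(4cr²) per depth bin, with c = distance × (1 Morgan /
100 Mb) and t = 1/(2c). The trajectory is reported for t ∈ [2, 500].
"Current" Ne is the bin whose t is nearest 20 generations, ties to the
smaller t — a convention, since any fixed timepoint inside the
well-estimated range would do. r² = 0 bins are undefined (flagged);
r² = 1 gives Ne = 0 (flagged). No admixture correction is applied, and
no LD is estimated below one mean marker spacing.

## Synthetic-data generators

The generators exist to validate the estimators by parameter recovery,
not to model any real livestock population.

**Divergence (Balding–Nichols).** Ancestral frequency p ~ Uniform(0.1,
0.9) per marker (configurable; the bounds avoid boundary monomorphism),
subpopulation frequency ~ Beta(p(1−θ)/θ, (1−p)(1−θ)/θ) — mean p,
variance θp(1−p) — genotypes Binomial(2, p_pop). This parameterization
is chosen because its expected Weir–Cockerham F_ST equals θ, giving a
clean recovery target. Loci are unlinked: the panel has structure but no
decay-generating LD.

**Wright–Fisher forward simulation.** N diploids, discrete generations,
uniform random mating with replacement, one recombinant gamete per
parent. Founder haplotypes carry each allele independently at frequency
0.5; crossovers are placed independently per adjacent interval with
probability spacing × (Morgans/bp), an adequate small-c approximation of
Haldane's map at chip-like spacings (50 kb ⇒ c = 5×10⁻⁴). No mutation,
no selection, no sex structure, no overlapping generations — so Ne
equals census N by construction, and polymorphism decays by drift only
(about half the loci fix over 200 generations at N = 100; fixed loci
are dropped from the output and the realized map keeps the survivors'
true positions). Phased haplotypes are returned alongside the dosages
for oracle use.

**Half-sib families.** Progeny take one gamete from an assigned sire
and one from a dam drawn at random per progeny, by independent Mendelian
sampling per marker (no linkage); the group label is the sire family.
Expected GRM relatedness between paternal half sibs is 0.25 above the
base level, which the recovery test measures as the within-family minus
across-family block-mean difference.

All generators are bit-reproducible from (spec, seed), and missingness
injection is a separate seeded operation so QC behaviour can be tested
on any panel.

What passing these recovery tests shows is that the estimators are
correctly implemented under their own assumptions. Real panels add
ascertainment bias in SNP selection, non-uniform marker spacing and
recombination, mutation, selection, migration and overlapping
generations — none of which the generators emulate, so recovery here
does not certify accuracy on real data, only correctness of the
arithmetic and the estimator logic.

## Pipeline and reproducibility

The pipeline runs QC → imputation → frequencies → heterozygosity → F_ST
→ GRM/F_VR/block relatedness/PCA → LD → Ne from one YAML config, writing
labelled TSV tables (a fixed `%.10g` float format makes reruns
byte-identical) and a JSON manifest (config snapshot, version, seed,
per-stage counts, timestamps). One master seed is split per stage via
CRC-tagged SeedSequences, so any stage can be re-run in isolation with
the same stream. Groups below 64 samples are excluded from LD/Ne tables
(the 1/N inflation makes their r² unreliable) but kept, flagged,
everywhere else; named overrides can force small groups in, which tags
their rows with a caution flag that the report surfaces.

## Problem sizes used in validation

The test suite and acceptance script run the recovery experiments at:
F_ST — 2 × 200 samples, 5,000 markers, 20 seeds per θ; GRM/half-sib —
200 progeny, 2,000 markers, 10 seeds; LD floors — 256 samples, 20 × 50
independent markers, depth 50; Ne — N = 100, 2 × 500 markers at 50 kb,
200 generations, depth 100, 10 seeds; syntenic arithmetic — the full
47,789-marker / 25-chromosome map shape. These sizes give Monte-Carlo
error comfortably inside the stated tolerances (e.g. replicate SD of
θ̂ ≈ 0.002 at θ = 0.10) while keeping a full run to minutes on one CPU.

## Known limitations

- Composite (dosage-correlation) r² assumes random mating within the
  group analysed; strong substructure inflates it.
- Mean-dosage imputation shrinks genotypes toward the mean; at high
  missingness it would attenuate LD and GRM off-diagonals, which is why
  QC precedes it.
- The depth → distance mapping uses the global mean adjacent spacing;
  on maps with very uneven spacing the nominal distances misstate true
  distances bin by bin.
- Ne_t assumes drift-recombination equilibrium (Sved); recent
  bottlenecks, admixture or selection violate it, and estimates at
  large t rest on very short-range LD that chip density limits.
- VCF input, haplotype-based imputation, intensity-based QC and
  model-based ancestry estimation are out of scope.
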