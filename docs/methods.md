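# Methods

## Scope and data model

`abqtl` analyses advanced-backcross (AB) introgression populations: lines
derived from an elite × exotic-donor F1 by `b` backcrosses to the elite
parent and `s` selfings (default b = s = 2, a BC₂F₃-derived line). All
coordinates are genetic (cM) on the 21 hexaploid wheat chromosomes
(1A..7A, 1B..7B, 1D..7D); no physical coordinates exist anywhere in the
package. Genotypes use a single coding — 0 missing, 1 homozygous
cultivated (CC), 2 heterozygous, 3 homozygous exotic (EE) — and phenotypes
are grain yield in dt/ha (deciton = 100 kg per hectare), long-format with
one plot per line and environment.

## Marker-trait model

Per marker the model is `Y_ijk = μ + M_i + E_j + (M×E)_ij + ε_k(ij)` with
the two homozygous marker classes `M` fixed, environment `E` and the
class-by-environment interaction random, and lines as replicates `k`
within a class. Heterozygous and missing calls are excluded *per marker*
(not per line): after repeated selfing, a field plot descending from a
heterozygous plant is a mixture of both homozygotes, so its mean would
misestimate heterozygote performance; the homozygous contrast is the only
clean one.

**Test statistic.** From the expected mean squares of this design,

    E[MS_M]   = σ²_ε + n̄·σ²_M×E + n̄·b·φ_M
    E[MS_M×E] = σ²_ε + n̄·σ²_M×E

so the exact test of the fixed marker effect is F = MS_M / MS_M×E with
(1, n_env − 1) degrees of freedom. The implementation computes it from the
2 × n_env table of per-environment class means ("least-squares means per
environment"); the per-cell replicate count cancels from the ratio, so on
balanced data this equals the raw-data mean-square ratio exactly (the test
suite verifies agreement with an independently coded sums-of-squares ANOVA
to 6 significant digits), and under moderate class imbalance it is the
unweighted-means approximation, which is appropriate here because class
sizes within an environment are constant across environments. No separate
REML machinery is carried: with this test, estimated variance components
would not be consumed by any downstream quantity.

**Least-squares means.** LSM_CC and LSM_EE are the unweighted averages of
the per-environment class means, so environments with different means
contribute equally regardless of class size.

**Degenerate cases.** A marker is skipped (with a recorded reason) when a
homozygous class has fewer than 2 lines (variance estimability) or fewer
than 2 environments are observed in both classes. When the interaction sum
of squares is exactly zero, p is 1 if the marker sum of squares is also
zero, else the smallest positive double — this keeps p in (0, 1] and
LOD = −log10(p) finite on noise-free constructions.

**Multiplicity.** Benjamini–Hochberg q-values are computed once across all
tested markers of a scan (per dataset, not per chromosome); classes are
`***` for q < 0.001 and `**` for q < 0.01, matching the two reported star
levels. `fdr_classify` delegates to
`statsmodels.stats.multitest.multipletests`; the test suite checks it
against a hand-coded step-up.

**RP(EE).** `RP(EE) = 100 · (LSM_EE − LSM_CC) / LSM_CC` percent, computed
on unrounded means and rounded to one decimal only for display (the
written scan table keeps a machine-readable companion with full
precision). LSM_CC ≤ 0 is a domain error.

**QTL merging.** Among markers sorted by (chromosome, position),
significant markers with the same sign of RP(EE) are chained while each
consecutive gap is ≤ 20 cM; a chromosome change, an intervening
non-significant marker, a sign flip or a larger gap closes the region.
"Same effect" is operationalised as same RP(EE) sign, since allele
identity across markers is unobservable in this design. The peak is the
member with the smallest p (ties: larger |RP(EE)|, then lower cM).

## Synthetic-data generator

**Meiosis.** The Haldane map function r = ½(1 − e^(−2d/100)) converts cM
to recombination fractions; crossovers are independent per interval (no
interference). This matches standard cM semantics and has closed forms for
testing; real wheat shows positive interference, so simulated double
recombinants are slightly too common at short distances.

**Pedigree.** Each line descends independently: F1 (one elite, one donor
haplotype per chromosome), then `b` backcrosses taking one gamete of the
current plant against the deterministic gamete of the fully homozygous
elite parent, then `s` selfings of a single descendant. Single-locus
genotype frequencies therefore follow the exact Markov chain — exotic
allele (1/2)^(b+1), heterozygosity (1/2)^(b+s) — which the test suite
checks against an independent enumeration, as it does the two-locus
distribution behind the recombination-rate estimator.

**Trial.** `Y_ij = μ + Σ_q (a_q·dose + d_q·het) + E_j + G_ij + ε_ij` with
dose the exotic-allele count (codes 1/2/3 → 0/1/2), E_j ~ N(0, σ²_E) per
environment, G_ij ~ N(0, σ²_G×E) per line × environment and plot residual
ε. Defaults, chosen once as a realistic managed multi-site winter-wheat
series: μ = 74.5 dt/ha, σ²_E = 16 (environment SD 4 dt/ha), σ²_G×E = 2.25,
σ²_ε = 9 (plot SD 3 dt/ha ≈ 4 % CV), 5 environments, one plot per line and
environment. An `n_reps` knob adds replicate plots for balanced-ANOVA
cross-checks only. Optional masking of a fraction of genotype calls to
missing is a separate operation applied after phenotype generation, so
masking never alters simulated phenotypes.

**What the generator does not emulate** — and what passing tests therefore
do not establish about real data: selection during population development,
seed-multiplication drift, field spatial trends, genotyping error,
crossover interference, clustered marker maps (generated maps are evenly
spaced), and population structure. The marker scan itself applies
unchanged to real TSV inputs.

## Marker statistics

Per-genome summaries use the observed marker span (max − min cM per
chromosome, summed) as map length; density is markers per cM, flagged
undefined (not infinite) when the span is zero. The percent recombination
rate is the fraction of adjacent-marker pairs, over lines where both calls
are homozygous, whose codes differ. This transparent proxy has an exact
oracle under the simulator's pedigree; it is not a likelihood-based
multipoint estimator and will underestimate meiotic recombination per
meiosis since AB lines accumulate several meioses while double crossovers
cancel.

## Visualisation

Every plot first writes the exact table it draws (TSV), then renders it
with matplotlib. The circular QTL map shows, per chromosome of one genome
(default D): 5 cM marker-density bins coloured linearly white→red; an
allele-effect ring plotting 100·(LSM − population mean)/population mean
for the exotic class (both classes behind a flag, since either convention
is defensible) with the population mean as reference circle, clipped at
±12 % (clipping affects drawing only — the table keeps the raw value); and
a LOD Manhattan ring (scale 0–30) with significant markers highlighted.
Track lengths are proportional to cM span. The needle plot draws one bar
per homozygous line sorted by descending mean yield (ties broken by line
id for determinism), CC blue and EE red.

## Pipeline and reproducibility

The CLI is a thin layer over the library. A single top-level seed is
expanded through `numpy.random.SeedSequence.spawn` into independent
per-stage substreams (population, trial, masking — per population), so any
stage can be reproduced in isolation; all table outputs are byte-stable
under a fixed seed. The demo uses 250- and 150-line populations, 210
markers over 21 chromosomes of 150 cM (a realistic per-chromosome genetic
length), and injected QTL of ±1.5–2 dt/ha per allele.

## Power and known limitations

With 5 environments the marker test has only 4 denominator degrees of
freedom, so single-marker p-values are volatile: the test suite's
recovery experiment (a +3 dt/ha-per-allele QTL, 150 lines, 5 environments,
200 markers, default variances) recovers the QTL as the genome-wide peak
significant marker within 10 cM in only ~43 % of replicates — about 40 %
of replicates yield no BH-significant marker at all, and in a further ~15 %
linkage moves the peak to a neighbouring marker 18.75 cM away. This is a
property of the design, not of the implementation: reliable detection of
effects of this size needs more environments (the same experiment at 10
environments has 9 denominator df and p-values orders of magnitude
smaller), quieter plots, or larger populations. Null calibration is
conservative: with no injected QTL the mean fraction of BH-significant
markers at q < 0.01 is far below the nominal level.

Other limitations: the scan fits one marker at a time (no composite
interval mapping, no epistasis, no kinship correction); the
unweighted-means F-test is approximate under severe imbalance combined
with missing cells; and the merge rule's sign-based "same effect"
definition can split one true QTL whose flanking markers disagree in sign
near RP(EE) = 0.
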