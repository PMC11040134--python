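# Methods

## Overview

`mitoribo` models a three-genotype (control / het / homo) cell-line study
that measures translation two ways: paired Ribo-seq and RNA-seq libraries
giving per-gene ribosome occupancy (RPF/mRNA), and a 16-plex TMT proteomics
experiment giving relative protein abundance. The package covers the full
path from raw reads and peptide reporter intensities to a per-gene joint
verdict on whether translation load and protein output move together.

## Synthetic data generator

The generator is the package's testing substrate and defines the study
conditions; its defaults are fixed, not tuned per analysis.

**Annotation.** 13 mitochondrially encoded OXPHOS protein-coding genes
(mt-Nd1 ... mt-Atp8), 20 nuclear OXPHOS genes, 12 mitochondria-associated
genes, 20 background genes, and a contaminant pool of 2 rRNA + 22 tRNA
records. Sequences are uniform random nucleotides (no homology structure),
so reads of footprint length map uniquely with overwhelming probability;
CDS intervals are transcript-space, 0-based half-open, a whole number of
codons, with no UTR margin on mitochondrial transcripts and 50 nt on
nuclear ones (both configurable).

**Counts.** Per sample, per gene: negative binomial with
`var = mu + phi mu^2`. The mRNA mean is `base_g x mrna_fc(genotype)`; the
RPF mean multiplies in the occupancy fold change. Defaults: 50,000
reads/sample, dispersion `phi = 0.02` (cell-line replicates sharing a
genetic background are substantially less variable than animal cohorts),
baseline expression lognormal with sigma = 1, contaminant fraction 0.10.
Per-assay scale factors are computed once from the *baseline* composition,
so sample totals drift with planted effects rather than being renormalized
to fixed depth: this keeps the raw per-gene RPF/mRNA ratio an unbiased
estimator of the planted occupancy fold change. Real libraries are instead
sequenced to target depth, which confounds raw ratios with composition —
that normalization problem is deliberately outside what the generator
emulates, and passing recovery tests therefore says nothing about
composition-robust normalization on real data.

**Reads.** RPF insert lengths are uniform on 26-32 nt; mRNA inserts on
28-38 nt (so that at the 50 nt read length the 3' adapter is always
present with >= 4 bases, keeping trimming exact). Footprint 5' starts are
drawn from a linearly tilted density over the CDS,
`w(i) ∝ 1 + s (2i/(n-1) - 1)` with skew `s in [-1, 1]`: positive
concentrates footprints toward the 3' end. Raw reads are NEXTflex-style:
4 random bases + insert + 4 random bases + adapter, truncated at 50 nt.
Contaminant reads are exact substrings of the rRNA/tRNA pool. No sequencing
errors, chimeras, or splicing are simulated; every read's origin is logged
so downstream bookkeeping can be checked exactly.

**TMT.** Peptide log2 intensities are protein baseline (N(18, 2)) +
peptide offset (N(0, 1)) + channel loading (N(0, 0.15)) + planted genotype
shift + noise (N(0, 0.10)). Reporter crosstalk mixes 2% into each adjacent
channel (the matrix is emitted for correction); dropout probability is a
decreasing logistic in observed log2 intensity (midpoint 12, scale 1),
emulating the data-dependent-acquisition bias toward abundant peptides.
The default plex follows the interleaved homo/het layout with one unused
channel and five controls.

## Read processing

Adapter trimming finds the longest read suffix equal to an adapter prefix
(minimum overlap 3, the cutadapt convention; ties are impossible at fixed
overlap length, so longest-match resolves everything), then removes 4 nt
from each end, then drops reads shorter than 23 nt. Contaminant filtering
removes reads occurring as exact substrings of either strand of the
rRNA/tRNA pool. Size selection keeps 26-32 nt RPF reads (mRNA bypasses).
Assignment is an exact-substring k-mer-seeded matcher (k = 12, optional
mismatch budget with pigeonhole seeding); this replaces an external
EM-based transcriptome quantifier because synthetic reads are error-free —
for real data, externally aligned SAM/BAM can be ingested instead (records
with MAPQ < 5 dropped). Multimappers are resolved by EM over transcript
abundances (uniform start, tolerance 1e-8, max 1,000 iterations, reads
collapsed into equivalence classes); the data log-likelihood is returned
and is non-decreasing by construction. RPF matching is sense-strand only
(directional libraries). Coverage profiles count footprint 5' ends within
the CDS; no A/P-site offsetting is applied, since any fixed offset cancels
in the polarity summary below.

Every read ends in exactly one disposition — adapter-discarded,
contaminant-removed, size-rejected, unmapped, assigned — and the
disposition log partitions the input set exactly.

## Occupancy statistics

Occupancy is computed per replicate pair as RPF/mRNA from raw counts
(default) or CPM (offered because raw ratios are library-size confounded;
both appear in outputs). A zero mRNA count makes the value undefined (NaN),
never infinite; genes with any undefined replicate are excluded from
testing and reported `untested` rather than imputed. Genotype summaries are
reported both as mean-of-ratios (default) and median-of-ratios.

Per gene: one-way ANOVA across genotypes on the occupancy values, then
Dunnett many-to-one contrasts `t_i = (m_i - m_0) / sqrt(MSE (1/n_i + 1/n_0))`
with `df = N - k`. The single-step adjusted p,
`P(max_j |T_j| >= |t_i|)`, is evaluated by quadrature over the
common-factor representation of the equicorrelated multivariate t
(48-node Gauss-Hermite for the shared normal factor, 64-node
Gauss-Legendre over the studentizing chi variable; agreement with
`scipy.stats.dunnett` to ~1e-4 and with a seeded 10^6-draw Monte-Carlo to
~1e-3; large vectors go through a cached 4001-point grid, interpolation
error < 1e-5). With two treatment groups the contrast correlation
`sqrt(lambda_het lambda_homo)`, `lambda_i = n_i/(n_i + n_0)`, is exact even
unbalanced. A seeded Monte-Carlo mode is available. With only two genotypes
the module falls back to a pooled-variance Student t test. Zero
within-group variance is flagged `degenerate` (untestable) rather than
producing p = 0.

On null simulations the realized per-gene family-wise rate is ~0.047
against the nominal 0.05 — slightly conservative, as expected for t-based
procedures applied to right-skewed ratio-scale data at n = 3.

**Polarity.** For a CDS coverage vector c, the score is the
coverage-weighted mean of `w_i = 2i/(L-1) - 1`: -1 means all footprints at
the 5' end, +1 all at the 3' end, ~0 uniform. This is the simplest signed
summary whose sign matches qualitative 5'/3' accumulation calls; it is not
a pause-site detector.

**Verdicts.** `up`/`down` require Dunnett-adjusted p < 0.05 with the
matching sign of the mean difference; otherwise `unchanged`; `untested`
propagates. "Unchanged" is significance-based, not equivalence-tested — an
optional fold-change band can tighten it, but the default mirrors
figure-legend alpha conventions.

## TMT statistics

Impurity correction solves `observed = Mᵀ·true` per peptide row (linear
solve; nonnegative least squares when the direct solution goes negative;
pass-through with a warning if no nonnegative solution exists). Missing
values stay missing. Normalization is the median sweep on the log2 scale —
each occupied channel's peptide-level median is equalized, the grand median
restored — which is the fixed-effects median solution of the ANOVA-style
normalization model; full mixed-model estimation is out of scope. Rollup is
the per-channel mean of a protein's peptides (shared peptides dropped by
default; `assign_first` available). Statistics: one-way ANOVA per protein,
Benjamini-Hochberg step-up over all testable proteins, and pairwise
t-tests (Welch by default, since equal channel variances are not
guaranteed after dropout; pooled mode available). A protein "passes" a
comparison only when `bh_q < 0.05` **and** that comparison's t-test
`p < 0.05` — the gated cascade. Log2 fold changes are reported for all
proteins regardless. Upstream peptide/protein identification probabilities
(0.99/0.93) are recorded in configuration for provenance only; PSM-level
inference is out of scope. Mitochondrial annotation is a case-insensitive
symbol match against a user-supplied MitoCarta-style list.

## Integration

Occupancy and protein verdicts are full-outer-joined on gene symbol
(identity id-map by default; duplicate symbols after mapping are an error).
Genes missing from proteomics get `not_detected` — deliberate, because
data-dependent acquisition routinely misses low-abundance membrane
proteins. The category map is a total function over the 4x5 verdict grid;
het and homo comparisons are never pooled (effects can be allele-specific).
Stratified reports count verdicts and categories per gene class.

## Calibration studies (`mitoribo.calibration`)

Replicated-simulation studies double as power analysis and self-checks:
recovery of a planted het occupancy fold change of 3 on 20 mitochondrial
genes (geometric-mean estimate within a few percent of 3; detection power
~0.99 at 50,000 reads/sample, n = 3); Dunnett family-wise rate on 50 null
simulations of 500 genes (~0.047); mean realized false-discovery
proportion of the ANOVA+BH gate on 50 null TMT simulations of 2,000
proteins (~0.04-0.06); and end-to-end dichotomy recovery of planted
category-1/category-2 genes (~0.94-0.96). Misassignments come from three
honest sources: occupancy detection misses when the pooled MSE is inflated
by the effect itself (ratio variance scales with the squared mean),
nominal-rate occupancy false positives on flat genes, and proteins whose
low-abundance peptides drop out below the two-observations-per-group
requirement. All study sizes (50 simulations each) keep the full suite
under a minute of simulation time.

## Reproducibility and numerical choices

All randomness flows through `numpy.random.default_rng` seeded from the
run configuration; a run's manifest records SHA-256 hashes of every
artifact, and identical config + seed reproduces identical hashes.
Coordinates are 0-based half-open everywhere internally (BED-native).
EM tolerance 1e-8 on the max abundance change; impurity round-trip accuracy
~1e-8 for well-conditioned matrices; `-log10 p` is capped (default 10) for
p = 0 in plot tables. Unknown configuration keys are rejected, and the
resolved configuration is serialized next to every run's outputs.

## Known limitations

Random sequences carry no codon structure, paralogy, or mappability
artifacts, so multimapper resolution is exercised only by synthetic
sharing, not by realistic gene families. The generator's library-size
convention (see above) sidesteps composition normalization. No sequencing
error model beyond none; no UMI deduplication; no A/P-site calibration; no
isobaric co-isolation interference beyond the linear impurity matrix; no
protein-level imputation. The dichotomy is a significance-based
classification, not a causal model of stalling or decay.
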