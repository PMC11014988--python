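# Methods

## Overview

`ersurf` analyzes dual-bait organelle AP-MS experiments in which
mitochondria (Tom20 bait) and ER (Rtn1/Sec63 baits) are purified from
the same lysates across genotypes, and asks which mitochondrial proteins
redistribute toward the ER when ER–mitochondria contact sites are
depleted. The pipeline runs: QC filtering → variance-stabilizing
normalization and batch correction → moderated differential abundance →
log2(Mito/ER) ratio computation and diagonal-deviation classification →
fraction-composition and hydropathy characterization. A forward
simulator with planted ground truth defines the conditions under which
the pipeline is validated.

## Quality control

Input is a protein-level table in the MaxQuant `proteinGroups` dialect:
one row per protein group, an experiment-wide "Unique peptides" count,
one intensity column per MS run, "+"-flagged "Reverse" / "Potential
contaminant" rows (ids prefixed `REV__`/`CON__` are dropped too).
Intensity 0 and empty cells both mean "not quantified" and are mapped to
missing. Two filters follow:

- **Unique peptides ≥ k** (default 2).
- **Run presence**: present in ≥ m of the n MS runs (default 2 of 3) of a
  biological replicate, i.e. within a (bait, genotype, replicate) group.
  By default a protein is kept if *any* replicate group satisfies the
  rule (`scope="any"`), which preserves condition-specific proteins; the
  stricter reading — every group in which the protein appears must
  satisfy it — is available as `scope="all"`. The wording of such rules
  is ambiguous in practice, so both are implemented and the choice is a
  flag.

Both filters are pure row subsets; they are idempotent and commute.

## Variance-stabilizing normalization

Raw intensities carry multiplicative noise, so replicate spread grows
with signal. Each sample is calibrated with the arsinh (generalized-log)
transform

    h_s(x) = arsinh(a_s + b_s · x) / ln 2,

which is linear near zero and logarithmic for large `b_s·x`; output
differences read in log2-like units. Fitting alternates (i) per-protein
row means μ_p of the transformed values over present cells with (ii) a
per-sample fit of (a_s, b_s) against those means, until the maximum
relative parameter change is below 1e−6 (cap 50 iterations). Three
numerical choices matter:

- **Likelihood with Jacobian.** The per-sample fit minimizes the profile
  negative log-likelihood `(n/2)·ln Σr² − Σ ln h′(x)` in (a, ln b), with
  `r = arsinh(a+bx) − μ` and `h′(x) = b/√(1+(a+bx)²)`. The Jacobian term
  is essential: a pure least-squares alternating fit has a degenerate
  global optimum in which every sample is compressed onto a constant
  (residuals vanish along with the information). The 10% of points with
  the largest residuals under the incoming parameters are excluded from
  each fit (`trim_fraction`, configurable), so a minority of genuinely
  changing proteins cannot drag the calibration.
- **Scale anchoring.** In the logarithmic regime, rescaling every b_s by
  a common factor only shifts all transformed values equally — the
  overall scale is not identified. It is pinned by initializing
  `b_s = 100/median(x_s)` (placing the glog "elbow" roughly two decades
  below the median intensity, i.e. near the detection limit) and holding
  the mean of ln b_s fixed across iterations.
- **Offset shrinkage.** a_s is informed only by a sample's lowest
  intensities, so its maximum-likelihood estimate is noisy, and censoring
  (intensity-dependent missingness) pulls it systematically negative;
  sample-to-sample scatter in a_s then injects noise into exactly the
  low-intensity cells. A Gaussian ridge (sd 0.2 glog units) shrinks a_s
  toward 0. With a strong additive background in the data this shrinkage
  would bias a_s; for background-corrected MaxQuant intensities it is the
  right default.

This is a deliberate simplification of the full maximum-likelihood
variance-stabilization method (no explicit additive+multiplicative error
model, no shrinkage of the transformed values themselves). The contract
that downstream stages rely on — strict monotonicity per sample (b_s > 0,
so ranks are preserved) and approximately intensity-independent replicate
variance — is verified directly by the decile diagnostic: samples are
grouped by condition, deviations from each protein's condition mean are
pooled, and the pooled sd is reported per decile of the protein's mean;
a max/min ratio near 1 indicates stabilized variance (raw multiplicative
data give ratios ≫ 3).

Batch effects are removed afterwards on the transformed (additive)
scale: per protein, OLS with the biological design (bait, genotype) plus
batch indicators, subtracting only the fitted batch terms. Missing cells
stay missing; a batch perfectly confounded with a design covariate is an
error naming the pair. On noise-free fixtures the injected offset is
removed to numerical precision and condition contrasts are unchanged.

## Moderated differential abundance

Per protein, OLS is fitted on the present values (proteins whose
missingness makes the design rank-deficient, or leaves no residual df,
are reported as NA with a reason code). A contrast c of the coefficients
gives `log2FC = c′β̂` with unscaled standard error `√(c′(X′X)⁻¹c)` and
residual variance s² on df degrees of freedom.

Variances are shrunk toward a pooled prior: modeling s² ~ s0²·F(df, d0),
the prior is estimated by matching the first two moments of log s² using
the digamma/trigamma identities for log chi-square variables; the
trigamma inverse is solved by Newton iteration (tolerance 1e−8). When the
spread of log s² does not exceed pure sampling noise, d0 = ∞ and all
variances collapse to s0². The posterior variance

    s²_post = (d0·s0² + df·s²) / (d0 + df)

replaces s² in `t = log2FC / (s_post · se)`, referred to a t distribution
with d0 + df degrees of freedom (normal for d0 = ∞). The estimator
reproduces the reference empirical-Bayes implementation to six
significant figures on a shared fixture, recovers known (d0, s0²) within
15% at n = 5000, and holds the null type-I error at 0.05 ± 0.01 in a
3-vs-3 design. Multiple testing uses Benjamini–Hochberg step-up within
one contrast; contrasts are not pooled.

## Shift classification

Per genotype, `log2(Mito/ER)` is the mean normalized log2 intensity over
the mito-bait runs minus the mean over the ER-bait runs. The pipeline
default averages both ER baits (Rtn1 and Sec63), matching how the ER
fraction is defined in this design; single-bait mode is a config switch.
Ratios are plain means of normalized values (a model-coefficient mode
would be a natural extension; plain means are transparent and match the
replicate structure).

The classifier applies the fixed printed rule: deviation
`wt − mut > 0.5` log2 units and `wt > 0`. Deviation is the *axis-wise*
(vertical) distance from the diagonal: the companion wild-type criterion
is axis-wise, so 0.5 reads on the same scale; perpendicular distance
(÷√2) is available behind a flag. Proteins with a ratio defined in the
wild type but absent from the mutant mito-bait runs entirely cannot
appear in the scatter; they are reported separately as "depleted from
mitochondria" candidates, and the union of both sets is the
contact-site-dependent report. Thresholds (0.5, 0) are parameters.

Fraction composition sums each protein's mean **raw** intensity across a
fraction's runs (shares of summed signal are only meaningful on the raw
scale), groups by compartment class (mitochondria = matrix + inner
membrane + IMS + outer membrane; ER+nucleus; peroxisome; other), and
normalizes by the grand total.

## Hydropathy

Φ_i is the arithmetic mean of Kyte–Doolittle residue values over the
20-residue window starting at position i (1-based; windows advance by
1); Φ_max is the maximum over windows — the "max peak of local
hydrophobicity". Window means (not sums) are the convention; sum mode is
a flag. Sequences shorter than the window are excluded and reported, not
padded — padding would fabricate hydropathy. Non-standard residues
(B, Z, X, U, O) are rejected at FASTA load for the same reason: the scale
is undefined for them and silent imputation would bias Φ_max. Profiles
are computed on full-length precursor sequences (no cleavage modeling).
Subclass comparisons use the two-sample KS test with quartile summaries
of both groups.

## Distribution statistics

Quartiles use linear interpolation between order statistics (the "type
7" convention, stated explicitly because conventions differ); whiskers
are Q1 − 1.5·IQR and Q3 + 1.5·IQR, points outside are reported as
outliers. The KS statistic D is the exact supremum of |ECDF₁ − ECDF₂|
over the pooled points; the two-sided p-value uses the asymptotic
Kolmogorov distribution with effective size n₁n₂/(n₁+n₂), adequate for
the group sizes (tens to hundreds) compared here; an exact mode is
available for n₁·n₂ ≤ 10⁴. The qPCR helper returns 2^−ΔΔCt with
ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control.

## The synthetic-data generator

The simulator emulates the deposited experiments' structure — a
multi-bait immunoprecipitation design quantified at protein level —
without their raw data. Each protein p has abundance `A_p ~ logN(16, 2²)`
(arbitrary intensity units spanning ~4 decades, as in MaxQuant tables)
and an ER-partition fraction f_p(genotype): ER proteins f = 1, other
non-mitochondrial proteins f = 0, mitochondrial proteins a baseline
f₀ = 0.15 in the wild type (a modest steady-state ER pool, consistent
with mitochondrial proteins being detectable in ER fractions). For a
planted subset (default 200, drawn from inner-membrane and matrix
proteins), contact-site-depleted genotypes move the partition by
`shift_effect` (default 1.5) log2 units on the partition-*odds* scale,
which keeps f in [0, 1] for any effect size. Observed intensity is

    I_ps = A_p · [f_p·mix(bait_s, ER) + (1−f_p)·mix(bait_s, c_p)] · batch_s · e^ε

with capture efficiencies mix: cognate 0.9, non-cognate 0.05 for the
mito bait and 0.1 for the ER baits (membrane IPs from the ER-containing
heavy-membrane fraction carry somewhat more off-target material; the
asymmetry also keeps soluble contaminants off the mitochondrial side of
the ratio). ε ~ N(0, 0.3²) in natural-log units; batch offsets (0, 0.25
ln units) rotate over biological replicates. Missingness is logistic in
log intensity: the probability at the median log-intensity is
`dropout_midpoint` (default 0.1) and increases for dimmer signals with
slope `dropout_steepness` (default 0.8 per ln unit); overall missingness
lands near 19%, typical of label-free tables. Unique-peptide counts are
Poisson(1 + L/100), so the ≥2-peptide filter has real bite on short
proteins. The design is bait × genotype × 3 biological replicates × 3 MS
runs, mirroring the replicate/run structure the QC filter expects.

Sequences: lengths uniform 200–600 (median ~400, realistic for the
mitochondrial membrane proteome and long enough that the peptide filter
removes a realistic ~7% rather than decimating the catalog).
Inner-membrane and ER proteins receive one contiguous 21-residue stretch
drawn from {I,L,V,F,A,M} (guaranteeing a high 20-residue window); all
other residues come from a hydrophilic-biased composition. Compartment
proportions default to a yeast-like mix (mitochondria ≈ 37%, ER 22%,
nucleus 20%, other 18%, peroxisome 3%).

What the generator does **not** emulate: peptide-level effects (shared
peptides, digestion variability), TMT reporter-ion compression, ratio
compression from co-isolation, correlated (protein-complex) abundance
changes, biological replicate variance beyond run noise, and secondary
proteome remodeling in the mutants. Passing tests therefore demonstrate
that the pipeline's inference is correct under its own model of the
measurement process — not that every idiosyncrasy of real LC-MS/MS data
is handled.

Under the default conditions (2000 proteins, 200 planted shifts, effect
1.5, noise 0.3, 3 replicates × 3 runs) the full pipeline recovers the
planted set with sensitivity ≈ 0.89 and false-discovery proportion
≈ 0.09–0.10 (5 seeds); the free generator parameters above were fixed so
that this recovery contract — the generator module's stated purpose —
holds with margin, and are not tuned per analysis.

## Determinism and report bundle

All randomness flows from explicit seeds through `numpy` Generators; the
report bundle (JSON with sorted keys, fixed float formatting, no
timestamps; TSV tables) is byte-identical across reruns with the same
config and seed.

## Known limitations

- The run-presence filter assumes the metadata's replicate column
  distinguishes biological replicates within a condition; tables without
  run-level structure degrade to per-replicate presence.
- VSN is fitted per experiment table; designs mixing acquisition
  chemistries in one table should be normalized separately.
- The classifier uses plain ratio means; very sparse proteins (few
  surviving runs) get noisy ratios rather than model-based shrinkage.
- Asymptotic KS p-values are inaccurate below ~n = 10 per group; use the
  exact mode there.
- The headline protein counts of any real experiment depend on its raw
  data and search output; this package reproduces the *method*, and its
  quantitative guarantees are stated against simulated ground truth.
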