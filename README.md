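# ersurf

Quantitative analysis of dual-bait organelle affinity-purification mass
spectrometry (AP-MS), built to detect mitochondrial proteins that
relocalize to the surface of the endoplasmic reticulum when
ER–mitochondria contact sites are lost.

## The scientific problem

Many mitochondrial precursor proteins can reach mitochondria via the ER
surface (the ER-SURF pathway), with contact sites between the two
organelles — the ERMES tether and the import receptor Tom70 — acting as
transfer points. When contact sites are depleted, such proteins strand
on the ER. A dual-bait AP-MS design makes this visible: tagged baits
purify mitochondria (Tom20) and ER (Rtn1, Sec63) from the same lysate,
and each protein's enrichment between the two fractions is summarized as

    log2(Mito/ER) = mean log2 intensity (mito bait) − mean log2 intensity (ER bait)

computed per genotype. Plotting the wild-type ratio against the mutant
ratio, unaffected proteins fall on the diagonal; a protein that moves
toward the ER in the mutant falls below it. The classifier flags proteins
with

    deviation = log2(Mito/ER)_WT − log2(Mito/ER)_mut > 0.5   and
    log2(Mito/ER)_WT > 0

i.e. genuinely mitochondrial proteins in the wild type whose partition
shifts by more than 0.5 log2 units toward the ER when tethering is lost.
Proteins that disappear from the mitochondrial fraction outright are
reported alongside as "depleted from mitochondria" candidates.

The surrounding pipeline provides everything such an analysis needs:

- **QC** of MaxQuant-style `proteinGroups` tables — reverse/contaminant
  removal, ≥2 unique peptides, presence in ≥2 of 3 MS runs per replicate;
- **normalization** — per-sample arsinh (generalized-log) variance
  stabilization `h(x) = arsinh(a_s + b_s·x)` plus per-protein linear-model
  batch correction that protects the biological design;
- **differential abundance** — per-protein OLS with empirical-Bayes
  moderated t statistics: `s²_post = (d0·s0² + df·s²)/(d0 + df)`,
  `t = β̂ / (s_post·se)` on `d0 + df` degrees of freedom,
  Benjamini–Hochberg FDR;
- **hydropathy** — 20-residue sliding-window Kyte–Doolittle profiles Φ and
  the max-peak statistic Φ_max that characterizes the shifted set
  (membrane proteins with transmembrane segments score high);
- **distribution statistics** — quartile/whisker summaries, two-sample
  Kolmogorov–Smirnov tests, and the 2^−ΔΔCt qPCR fold-change formula;
- **a synthetic-data generator** that simulates the whole design (bait
  capture with contamination, log-normal abundance and noise, batch
  effects, intensity-dependent dropout, planted partition shifts) with a
  ground-truth manifest, so every stage is verifiable without downloads.

## Worked example

```bash
python examples/classify_shifts.py
```

runs the full pipeline on a simulated experiment (2000 proteins, 200
planted shifts, 3 baits × 2 genotypes × 3 replicates × 3 MS runs) and
prints:

```
QC: 1862 / 2000 proteins pass
classified as shifted toward the ER: 183 (+11 lost from the mito fraction entirely)
by compartment: {'IMS': 1, 'inner_membrane': 89, 'matrix': 92, 'outer_membrane': 1}
recovery vs planted truth: sensitivity = 0.90, FDP = 0.07
hydropathy, shifted vs other mito proteins: KS D = 0.14, p = 7.7e-03 (medians 1.26 vs 0.83)
```

Reading the numbers: 183 proteins satisfy the diagonal-deviation rule and
11 more vanish from the mitochondrial fraction; 90% of the planted
shifted proteins are recovered with a 7% false-discovery proportion; the
recovered set is dominated by inner-membrane and matrix proteins (where
the shifts were planted) and is more hydrophobic than the rest of the
mitochondrial proteome.

The other examples each demonstrate one capability: `simulate_experiment.py`
(write a synthetic experiment to disk), `hydropathy_profiles.py`
(per-compartment Φ_max with KS tests), `differential_volcano.py`
(moderated testing in one bait fraction). A thin CLI wraps the same
functions (`ersurf simulate|qc|normalize|diffabund|shift|hydrophobicity|run`).

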