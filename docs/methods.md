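# Methods

This note documents the models and procedures the package implements, the
defaults it ships with, and what the synthetic-data tests do and do not
establish about real data.

## LFQ proteomics stage

**Replicate averaging.** Technical replicates of the same biological
sample are averaged per protein over non-missing values; a cell whose
replicates are all missing stays missing. Replicate groups spanning
different experimental groups are a design error and rejected.

**Two-tier imputation.** LFQ missingness mixes two mechanisms.
Left-censoring (a protein below the detection limit in a whole condition)
is handled at the protein-by-group level: if a protein is detected in
fewer than 50% of the samples of a group, *all* of that group's values —
including the sporadically observed ones — are replaced by draws from

    Normal(mu_all − 2·sd_all, (0.3·sd_all)²)

where `mu_all`, `sd_all` are the mean and sample s.d. of every observed
log2 intensity in the dataset. Overwriting the observed values treats the
whole group as censored and controls zero inflation; the
`overwrite_observed=False` flag restricts replacement to missing cells for
users who prefer the conservative variant. The narrow width (0.3× the
global s.d.) keeps the imputed block from dominating the variance.
Remaining sporadic missing values are assumed recoverable from
between-sample correlation and filled by chained equations: iterated
per-sample linear regressions on all other samples (scikit-learn's
`IterativeImputer`, 10 iterations, seeded). Chained models are per-sample
rather than per-protein because samples are few and highly correlated
while proteins are many; this is the canonical continuous-data MICE
orientation for omics matrices.

**QC by PCA.** Samples are scored on the first two principal components
(proteins as features, centered). The outlier rule must work for n ≈ 10
samples, so it is robust and scale-free: distances from the centroid in
the component-scaled PC1–2 plane are flagged when their modified z-score
(median and MAD, consistency factor 1.4826) exceeds 3. Removal is left to
the caller.

**Differential abundance.** Per protein, an equal-variance two-sided
Student's t-test between groups on log2 intensities; `log2fc` is
mean(case) − mean(control); family-wise error is controlled by Bonferroni,
`p_bonf = min(1, m·p_raw)` over the m tested proteins. Complex-level
comparisons first collapse each sample to the mean LFQ of the complex's
member proteins, then run one-way ANOVA across groups; for two groups this
satisfies F = t² exactly. Ranking by log2FC breaks ties by lexicographic
protein id so output is deterministic.

## Enrichment stage

The statistic is the weighted Kolmogorov–Smirnov running sum: walking the
list from highest to lowest score, in-set genes add `|score|^p`
(normalised over the in-set total; default p = 1), others subtract
`1/(N − n)`; ES is the signed maximum deviation. Degenerate walks (set =
whole list, or all in-set scores zero under positive weighting) are
guarded. The null is gene-label permutation with same-size random sets;
`NES = ES / mean(|null ES| of the same sign)` and
`p = (1 + k)/(1 + m)` over same-sign nulls, so p is never zero. With p = 0
weighting, ES is invariant to any strictly monotone transform of the
scores — a property test enforced against a brute-force enumeration
oracle. Pathway dot-size values ("scaled mean expression") are the mean
log2 LFQ of member proteins over control samples, min–max scaled across
the reported collection, so they read as baseline abundance in healthy
tissue; a single-pathway (degenerate-range) call returns 1.0 with a
warning.

## Biosensor stage

Ratiometric sensors report analyte concentration as a two-channel
intensity ratio; the quantification chain is:

1. per-channel background = median of non-ROI voxels, subtracted and
   clipped at zero (the median resists stray foreground contamination);
2. per-axon ratio = mean over three equal sub-regions (slabs along the
   axon's principal axis, a deterministic stand-in for manually placed
   regions) of the region-mean pixel-by-pixel ratio. The
   mean-of-pixel-ratios convention is the default; `ratio_of_means` is
   exposed because the two differ on heterogeneous regions and the choice
   should be explicit;
3. normalisation to the control-group mean removes batch effects; the
   control group then has mean 1 by construction;
4. FRET sensors first remove donor bleed-through from the acceptor:
   `cFRET = acceptor − α·donor`, reported as the cFRET:donor ratio.

Threshold read-outs use the sample (n−1) s.d.: an organelle is an outlier
when above control mean + k·s.d. (default k = 3; Gaussian-null expectation
1 − Φ(3) ≈ 0.00135). Paired near/far lesion gradients use a two-sided
paired t-test on (near − far), with the zero-variance case reported as
no-difference (t = 0, p = 1) or a certain shift (p = 0). Marker puncta are
connected components above 1.2× the reference-mask mean intensity, ≥ 4
pixels, restricted to the reference mask; occupancy is puncta/reference
area, and integrated density = occupancy × mean puncta intensity. COX
occupancy is the percentage of axonal area covered by COX-active pixels,
with a 25 µm minimum axon length when lengths are supplied. FAD staging
(0 normal, 1 swollen, 2 fragmented) is an input annotation — morphological
staging is a manual call, not computed here.

## Kinetic model

A deliberately reduced ODE network of mitochondrial ATP production with
eight states: substrate S, two TCA intermediates M1/M2, NADH/NAD, ATP/ADP
and the inner-membrane potential Δψ (mV). Reactions: saturable substrate
supply (product-inhibited), three Michaelis–Menten TCA segments (the
first and third NADH-producing, mapped to Idh3 and Mdh2; the middle to
Ogdh/Sdh), a respiratory-chain lump (Michaelis–Menten in NADH with a
sigmoidal Δψ back-pressure, pumping 10 protons per NADH), ATP synthase
(Michaelis–Menten in ADP, sigmoidally activated by Δψ, consuming 3
protons per ATP), a saturating Δψ-dependent proton leak, and the
hyperbolic load sink `v_ATP = k_load·ATP/(ATP + K_m)`. Proton fluxes
integrate into Δψ through an effective capacitance. ATP+ADP and NADH+NAD
are conserved by the stoichiometry; both pool members are integrated
explicitly, so conservation is a verified property of the solved system
(linear invariants are preserved by the multistep integrator to well
below the 1e−8 relative test tolerance).

Units are mM and seconds for concentrations and fluxes, mV for Δψ. The
reference ("healthy control") parameterisation is chosen to rest in a
respiration-limited regime — Δψ ≈ 175 mV, ATP/ADP ≈ 9, NADH fraction
≈ 0.7, resting ATP turnover ≈ 0.5 mM/s — so that depleting TCA enzymes
genuinely limits NADH supply and hence ATP production, which is the
regime of interest. Parameters are configuration, not fits; overriding
any subset via `build_reference_model(config)` is supported and
validated.

**Proteomic scaling.** `v_max(sample) = v_max(normal) ×
E(sample)/E(mean control)` per mapped enzyme; multi-subunit reactions use
the arithmetic mean of subunit factors (geometric mean available) —
symmetric, simple, and exact for the single-enzyme case. Proteins missing
from a profile are held at 1 by default or raise under
`missing_policy="error"`.

**Steady state and load titration.** Steady states are found by stiff
integration (LSODA, rtol 1e−10) in chunks until the relative residual
max|dx/dt|/scale < 1e−8 (non-convergence is flagged, not raised).
Metabolic load is titrated by geometric k_load steps (×1.25 from the
resting value) until the ATP consumption flux increases by less than
1e−3 relative between steps; the plateau is the model's maximal ATP
production rate.

**Rectification.** For each named protein group, the case profile is
copied with that group's factors reset to 1 (control), the reference
model rescaled and re-solved. Reported per group: steady-state ATP and
ATP/ADP, the ATP gain over the un-rectified case, the residual gap to
full control, and optionally the rectified maximal ATP production.
Because scaling by a unit profile is bit-exact, rectifying every mapped
protein reproduces the control model identically.

**Coverage scores.** QC score = % of model-mapped proteins present in the
profile. QSM score = % of scalable reactions whose protein requirement is
covered; when a model declares redundant isoform groups for a reaction,
each covered group counts, which is how the score can exceed 100%. Both
are compared against the standard 75% suitability cutoff.

## Synthetic data: what it emulates, what it does not

The LFQ generator draws protein-specific log2 locations from
Normal(25, 2), adds planted group effects, biological noise (s.d. 0.4)
per biosample and technical noise (s.d. 0.1) per replicate — the
technical-replicate variance is not constrained by published values and
is configurable. The default cohort is 6 control vs 5 case biological
samples with paired technical replicates and a planted depletion of TCA
(−1.0 log2FC) and ETC (−0.5) pathway proteins, the structure the analysis
is designed to detect. Censoring applies a per-sample intensity threshold
at the `censor_quantile` with a 0.95 Bernoulli acceptance, making
missingness intensity-dependent (MNAR) by construction. The generator
does not emulate peptide-level evidence, shared peptides, normalisation
artefacts or correlated protein modules; passing tests therefore
establish that the *formulas and decision rules* behave as specified, not
that the pipeline is robust to every pathology of real LFQ data.

The imaging generator paints straight axon tubes with exact channel
arithmetic (ratio, background, crosstalk, Gaussian noise); it has no PSF,
no depth attenuation and no segmentation errors, so recovery tests verify
the ratio algebra, not image segmentation. Organelle tables draw ratios
and shape factors from stage-dependent parametric distributions.

## Numerical choices

Seeded `numpy.random.default_rng` everywhere; identical design + seed is
bit-reproducible. Ranking ties break lexicographically. Degenerate inputs
have defined behaviour: zero-variance datasets and empty control sets
raise; denominator-zero axon regions return NaN with a warning; the
all-in-set enrichment walk returns ES = 0. Pipeline manifests record
sha256 checksums of every output; PCA coordinates are written with 10
significant digits because BLAS threading perturbs the last bit from run
to run.

## Known limitations

The kinetic network is a minimal carrier of three contracts (abundance
scaling, load titration, group rectification); its absolute fluxes and
concentrations are not calibrated to tissue measurements, so only
directions and ratios across conditions are meaningful. The enrichment
null permutes gene labels, not phenotypes, and therefore tests set
membership against the given ranking rather than between-sample
variability. The PCA outlier rule and the QSM redundancy rule are
documented interpretations where no published formula exists.
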