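# Methods

`cinnaprint` implements a complete ¹H-NMR workflow for authenticating
cinnamon (*Cinnamomum burmannii*, *C. cassia*, *C. verum*) products:
simulation of spectra with known metabolite content, reduction of spectra to
chemometric fingerprints, hierarchical clustering, absolute quantification
of 16 metabolites, multivariate species classification, and a coumarin
exposure screen. This note records the models, the parameters that matter,
and the design choices made where practice leaves the design open.

## Spectrum model

A spectrum is rendered on a uniform grid of 32,768 points over
−0.5…12.5 ppm, emulating a 400 MHz instrument. Each metabolite signal is a
Lorentzian line with full width at half maximum of 1.0 Hz (0.0025 ppm at
400 MHz), the canonical NMR lineshape. The integrated area of a line is

    A = s · C · n

where `C` is the molar concentration of the analyte in the measurement
tube, `n` the number of equivalent protons producing the signal, and `s`
the instrument sensitivity (area per molar per proton; default 100, set by
`SimulationParams.reference_area`). The molar concentration follows from
the tissue content `c` (mg of analyte per g of sample) via the extraction
constants — 300 mg of homogenized sample extracted into 2.0 mL of
methanol/methanol-d₄ — assuming idealized 100 % recovery, so that
round-trip tests are exact by construction:

    C [mol/L] = c · m_sample / (M · V_extract · 1000)

with `M` the molecular weight. A calibration reference line of known
equivalent concentration (default 10 mM, 1 proton) sits at 0.0 ppm, and
residual water (4.90 ppm) and methanol (3.31 ppm) lines sit inside the
standard exclusion regions. Gaussian noise of standard deviation
`noise_sd` (default 0.01 in intensity units, roughly the noise floor of a
well-shimmed 64-scan acquisition relative to a 10 mM reference) is added
last; the RNG is fully determined by the seed.

Two numerical choices matter:

* **Truncated line support.** Lorentzian tails decay slowly; each line is
  evaluated only within ±0.2 ppm of its centre and renormalized to carry
  its full mass there. This keeps intensity exactly zero away from any
  line (so an analyte-free region is genuinely empty), makes numeric
  integrals match nominal areas, and prevents the strong solvent residuals
  from bleeding into nearby quantification windows.
* **Equal-width integration windows.** Every quantification window,
  including the reference window, is 0.10 ppm wide. A 0.10 ppm window
  captures the same fraction (≈98.4 %) of any 1 Hz Lorentzian, so the
  finite-window coverage cancels exactly in the analyte/reference area
  ratio. Noise-free recovery is then limited only by grid resolution
  (relative error ~10⁻⁸).

## Metabolite catalogue

The 16 quantified metabolites (cinnamaldehyde, coumarin,
methoxycinnamaldehyde, cinnamic acid, benzoic acid, methyl salicylate,
quinic acid, eugenol, α- and β-glucose, fructose, formic acid, choline,
shikimic acid, succinic acid, alanine) are bundled with formula, molecular
weight, a quantification signal (centre, window, proton count) and
secondary signals used only by the simulator. Signal positions follow
literature-standard shifts where the crowding of the 3.7–4.5 ppm
carbohydrate region allows; where it does not, positions were spaced so all
quantification windows are pairwise disjoint, at least 0.10 ppm from any
foreign signal, and clear of the solvent-exclusion regions. Since
simulator and quantifier share the catalogue, every round-trip result is
independent of the absolute positions chosen. Choline is catalogued as the
free cation (104.17 g/mol) — quantification reports the analyte, the
counterion being unknown — and its quantification signal is the OCH₂
multiplet, keeping the window away from residual methanol. The glucose
anomers are separate entries sharing one formula but distinct
anomeric-proton signals.

## Fingerprinting

Spectra are reduced to rectangular buckets of positive intensity
(negative intensities clipped to zero) over 1–12 ppm with 0.01 ppm width:
1100 half-open cells `[lo, hi)`, each value the trapezoidal integral over
the cell, no scaling. Buckets overlapping (nonzero-length intersection)
the residual-solvent regions — water 4.75–5.06, methanol 3.16–3.45,
TMS/TMSP −0.05–0.05 ppm — are discarded, retaining 1040 buckets. Retained
values are normalized per spectrum: values at or below the spectrum-wise
mean map to 0, values above it map onto the integers 1…100 by a min–max
affine map with round-half-up. "At or below the mean → 0" and
"per-spectrum min–max onto 1…100" are one reading of a procedure that
commercial software leaves underdocumented; the mapping is isolated in
`normalize_fingerprint` so alternatives are pluggable.

## Clustering

Fingerprints are compared by Euclidean distance and agglomerated with Ward
linkage (both configurable) via `scipy.cluster.hierarchy`; these are the
standard chemometric defaults for binned NMR data. Agglomeration is
deterministic, merging the earliest-indexed pair among ties. Cutting the
dendrogram into k groups gives a flat partition whose agreement with
species labels is summarized as purity (fraction of samples in the
majority label of their cluster). Dendrograms export to Newick with
ultrametric branch lengths (leaf depth = merge height / 2).

## Quantification

The quantifier implements the external-reference qNMR ratio — the
mathematics behind electronically referenced calibration schemes:

    C_met = (A_met / A_ref) · (n_ref / n_met) · C_ref
    c [mg/g] = C_met · V_extract · M · 1000 / m_sample

Integrals are trapezoidal over the closed windows. Samples are measured in
triplicate; reports carry the replicate mean and sample standard deviation
rounded to two decimals (full precision retained internally). A
metabolite is "not detected" (ND) when its integral is non-positive or its
signal-to-noise ratio — window peak height over the noise floor, estimated
as the intensity SD in the signal-free 11.5–12 ppm region — falls below 3
in every replicate. ND is below-LOD information, not zero; zero-imputation
is an explicit choice made only at the classification stage.

## Classification and ordination

PCA of the samples × metabolites matrix (ND → 0) summarizes the
between-species structure; the variance explained by the two leading
components is the headline number of the 2-D ordination plot. Column
pretreatment is configurable among {none, center, autoscale, pareto};
autoscaling (centre, unit variance) is the default so each metabolite gets
equal prior weight regardless of its concentration scale. On the bundled
48-sample reference table the two-component variance is 92.77 % (none or
center), 84.92 % (pareto) and 70.27 % (autoscale); component signs are
fixed by making the largest-magnitude loading positive. Species calls use
a nearest-centroid rule in the autoscaled space with lexicographic
tie-breaking, evaluated by leave-one-out accuracy; diagnostic ratios
(coumarin:cinnamaldehyde, methoxycinnamaldehyde:coumarin, cinnamic
acid:coumarin, eugenol level) are reported as evidence rather than as
hard-coded cutoffs, since no published thresholds exist.

## Safety screen

The coumarin tolerable daily intake (TDI) is 0.1 mg per kg body weight per
day. For content `c` mg/g the daily product amount reaching the TDI is
`0.1 · bw / c` grams; a sample is flagged when the configured serving
exceeds this limit. Defaults — 60 kg body weight, 1 g/day serving — are
explicit and configurable, because a content in mg/g can only be compared
to a body-weight-based limit through a serving size.

## Synthetic cohorts: what they do and do not show

`species_profiles_from_table` reduces a concentration table to
per-species, per-metabolite location/scale (mean and SD, ND as 0);
`generate_cohort` draws each metabolite independently from a normal
truncated at zero (arithmetic mean ± SD parameterize the normal directly,
matching how such tables are reported) and renders three replicate spectra
per sample with independent noise. Ground-truth tables censor values below
a configurable LOD (default 0.05 mg/g) as ND.

Two features of real data are deliberately not emulated: inter-metabolite
correlation within a sample (real products share a common
dilution/processing factor across metabolites, which synthetic independent
draws destroy) and peak-position variation (pH/temperature shifts,
overlapping multiplets). Consequently, passing recovery tests demonstrate
the correctness of the integration/calibration chain, not robustness to
peak overlap; and species-separation results on synthetic cohorts
understate what pattern-based fingerprints achieve on real correlated
samples. Indeed, with the reference table's full within-species SDs —
which span raw bark through concentrated extracts — the three species'
marginal distributions overlap so strongly that neither dendrogram purity
nor leave-one-out accuracy reaches 1.0 on synthetic cohorts (purity ≈ 0.6
at 10 samples/species; leave-one-out nearest-centroid accuracy on the
48-sample reference table itself is 0.46). With within-species scatter
reduced to one tenth, the same pipeline attains purity 1.0 and
leave-one-out accuracy 1.0, confirming that the limitation lies in the
cohort model's overlap, not the clustering/classification chain.

## Problem sizes and budgets

Default test and demonstration runs use 10 samples per species (30
samples, 90 spectra) at 32,768 points, and smaller grids (8,192 points)
for pipeline smoke tests; these sizes exercise every stage end-to-end in
seconds while keeping statistical summaries (median recovery error,
purity) stable across seeds.

## Known limitations

* No peak alignment, baseline roll, phase errors, or ¹³C satellites in
  the simulator; no deconvolution of overlapping multiplets in the
  quantifier.
* The bucket normalization reading ("below means → 0, above means →
  1…100") is one defensible interpretation of an underdocumented
  commercial procedure.
* The reference concentration of the calibration sample is a required
  input; no default is claimed beyond the simulator's own convention.
* Nearest-centroid is the only classifier by design; no PLS-DA or other
  supervised chemometrics.
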