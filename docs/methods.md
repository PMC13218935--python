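# Methods

## Model

A ¹⁵N tracer panel measures, for every (condition, tracer, metabolite)
triple, an isotopologue intensity vector over nominal mass shifts
M+0 … M+n, where n is the metabolite's nitrogen count. The generative
model underlying both the correction and the synthetic data is a linear
convolution: if xⱼ is the fraction of the metabolite pool carrying
exactly j tracer-derived ¹⁵N atoms, the expected observed spectrum is
m = C·x, with column j of the correction matrix C the theoretical
spectrum of a molecule with j labelled atoms.

In **resolved** mode (the default) only the tracer element contributes:
the j-labelled column is the (n−j)-fold convolution of nitrogen's
single-atom natural distribution, shifted by j — a Binomial(n−j, a₁₅N)
for a two-isotope element. This assumes the mass analyser separates ¹⁵N
isotopologues from isobaric ¹³C interference, valid at the 60,000–240,000
FWHM resolving powers of modern orbitrap acquisition. **Unresolved** mode
additionally convolves the natural heavy-isotope distributions of all
non-tracer elements (¹³C, ²H, ¹⁷O/¹⁸O, ³³S/³⁴S/³⁶S — deuterium and ¹⁷O
are negligible but included so the exhaustive-enumeration oracle matches
exactly) and truncates at shift n to keep the matrix square; truncated
columns then sum to less than one. Mass shifts are nominal integers
throughout; fine-structure exact-mass spectra are out of scope.

Natural abundances ship as an editable CSV of standard IUPAC values
(¹³C 0.0107, ²H 0.000115, ¹⁵N 0.003663, ¹⁷O 0.00038, ¹⁸O 0.00205,
³³S 0.0075, ³⁴S 0.0425, ³⁶S 0.0001).

## Correction

Correction inverts m = C·x as a non-negative least-squares problem
followed by renormalisation to Σx = 1; the residual norm is kept as a QC
field. Non-negativity is preferred over plain triangular
back-substitution with clipping because noisy spectra can otherwise
produce negative enrichments that clipping redistributes inconsistently;
NNLS matches established correction practice. As an implementation
detail, batch correction first solves the (lower-triangular, positive
diagonal, hence invertible) resolved-mode system exactly by
back-substitution and re-solves with NNLS only the spectra whose
unconstrained solution has a meaningfully negative component — identical
results where the constraint is slack, the constrained solution where it
binds. Noiseless round trips recover planted fractions to < 1e-9;
at 5% multiplicative noise the median absolute FE error is < 0.02.

All-zero vectors are an error for single-vector correction; in batch and
pixel-grid correction they yield NaN (missing) so sparse images do not
abort. Pixel grids with under 1% nonzero pixels log a warning. Missing
isotopologue rows in input tables are zero intensity: exported peak
tables omit undetected peaks.

## Enrichment tables

Per-sample corrected fractions are averaged **per replicate** (mean and
s.e.m. of per-sample FEs, not FE of summed intensities) so reported
errors reflect replicate variation. A replicate in which a metabolite has
no signal is excluded from that metabolite's average rather than treated
as zero. Total labelling, 1 − FE(M+0), is the primary readout for
multi-atom tracers; individual M+k fractions are retained (e.g. M+1
de-novo vs M+2 salvage readouts for UMP). Precursor normalisation
(product labelling divided by the precursor's cognate isotopologue FE)
uses the condition's own replicate-mean precursor FE; ratios above 1 are
logged, not clamped. Time courses are compared by trapezoidal AUC
(FE·hours); sigmoidal dose–response fitting is out of scope.

## Normalisation and pool sizes

Probabilistic quotient normalisation uses the per-metabolite median
across all samples in the run as the reference spectrum (the cited
method's default; a per-condition reference is a config away but not
default). Metabolites missing from more than half the samples are
excluded from quotient computation to guard against zero-inflated
quotients. PQN applies to raw pool intensities only — enrichment
fractions are scale-free and unaffected, so the order of PQN vs
correction is immaterial for labelling readouts. Pool-size filtering
uses raw (pre-PQN) intensities by default (config-switchable). The
steady-state contrast is an unpaired two-tailed t-test per metabolite,
switching to Welch's form when an F test of variance equality gives
P < 0.05; p-values are reported without multiple-testing adjustment,
with the fold change as log₂ of the ratio of group means.

## Filter cascade

Five rules run independently and accumulate reasons: LOW_QUANT
(quantified, i.e. intensity > 0, in fewer than 2 samples), LOW_POOL
(mean pool over quantifying samples below an experiment-defined
threshold; presets 2×10⁶ and 1×10⁵ for the two supported assay scales),
LOW_LABEL (< 1% summed labelling), CONTROL_CONTAM (> 3% labelling in any
tracer-free control sample), OVER_LABEL (> 500% summed labelling).
"Summed labelling across all conditions" is interpreted as the **sum**
over all (condition, tracer) pairs of total labelling, in percent: a
single pair cannot exceed 100%, which is the only reading under which a
1% lower bound and 500% upper bound are simultaneously meaningful; a
`max` aggregate is available in the config for the alternative reading.
Boundary inclusivity is taken literally: "less than 1%" and "greater
than" are strict, so ties keep the metabolite. LOW_QUANT and
CONTROL_CONTAM are evaluated per sample; the remaining rules on the
replicate-mean table. Absent control samples skip CONTROL_CONTAM with a
logged warning.

## Scoring and flows

DLS = |ln(FE₁/FE₂)| × (FE₁ − FE₂) on total labelling per pair (a
specific-isotopologue mode exists via the `k` argument). Log arguments
are clamped below at ε = 1e-6 — the 1% pre-filter makes exact zeros rare,
but the score must stay finite when they occur; the difference term is
unclamped, so sign and magnitude semantics are unaffected. Condition
order (which condition is "1") comes from the run config and fixes the
sign convention. Waterfall ranking is descending by score with
deterministic (tracer, metabolite) lexicographic tie-breaks, so reruns
are byte-identical. Sankey edges connect tracers to
pathway-representative metabolites with weight equal to total labelling,
excluding metabolites strictly below 5% (default); nodes order by total
edge weight for stable rendering. Output is a CSV edge list and a
nodes[]/links[] JSON document; a minimal matplotlib ribbon rendering is
included, interactive visualisation is not.

## Synthetic data

The generator emulates the profiling design: 30 tracer media (20
proteinogenic amino acids; taurine; ornithine and citrulline;
hypoxanthine and uridine; nitrate and ammonium; urea and uric acid; plus
an amide-¹⁵N glutamine positional variant), a catalog of 103 nitrogenous
metabolites across 12 pathway classes with designated representatives
(UMP/UDP/UTP, glutamate, glutathione among them), two paired conditions,
n = 1 sample per tracer per condition by default (matching profiling
practice; replicates configurable for statistical tests), and tracer-free
controls per condition. The packaged registry and catalog are synthetic
stand-ins: tracer identities follow the enumerated nutrient classes, and
catalog identities are standard nitrogen-metabolism coverage rather than
a published list.

Planted transfer has two channels per (tracer, metabolite): `single`
places the fraction at M+1 (transamination-like single-nitrogen
transfer) and `intact` at M+m for an m-atom tracer (salvage-like intact
incorporation, capped at the metabolite's nitrogen count). Every tracer
carries a cognate intact transfer into its own pool (default fraction
0.7 — media replacement labels the intracellular pool heavily but
incompletely) in every condition. Intensities are the forward-convolved
true fractions scaled by a per-metabolite pool mean (default 1×10⁷,
clear of the 2×10⁶ pool filter) times multiplicative lognormal noise
(default CV 10%; the noise is mean-one so expectations are unbiased).
Multiplicative noise is chosen over additive because MS intensity error
scales with signal. Generators are pure functions of (model, seed).

What the generator does **not** emulate: chromatographic drift and batch
effects, detector saturation, isotopic impurity of tracers, peak-picking
errors, compartmentation or kinetics (transfer fractions are planted
steady states, not flux solutions), and missingness correlated with
abundance. Passing tests therefore demonstrate correctness of the
computational pipeline under its own generative assumptions, not
robustness to every artefact of real acquisitions.

The imaging phantom plants region-specific FEs on a pixel grid whose
boolean masks must partition the image, with per-pixel lognormal noise;
time courses follow FE(t) = FE_sat·(1 − e^(−rate·t)).

## Problem sizes and numerical choices

Default test and verification sizes: full-panel simulations are
30 tracers × 103 metabolites × 2 conditions (≥ 3,000 scoreable pairs,
~22,000 peak rows); correction round trips use 1,000 Dirichlet draws
across 20 catalog formulas; recovery and rediscovery scenarios run 100
seeds at 5% noise; the imaging phantom is 30 × 20 pixels. Isotope
distributions are computed by truncated convolution with
exponentiation-by-squaring (exact to machine precision at these sizes).
Abundance tables must sum to 1 within 1e-9 per element; corrected
fractions sum to 1 within 1e-6 after renormalisation. Ties in the
waterfall break lexicographically; ties at filter boundaries keep.

## Known limitations

Single-element tracing only (no simultaneous ¹³C+¹⁵N); nominal mass
shifts; no imzML/mzML parsing (pixel grids enter as exported x, y, M+k
tables); no peak picking or integration; no kinetic flux estimation or
positional isotopomer modelling; the DLS is a ranking device without an
attached significance test (profiling runs have n = 1 per tracer).
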