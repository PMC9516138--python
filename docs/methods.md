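# Methods

## Isotopologue envelope model

Peptide elemental compositions are the sum of residue compositions (shipped
as a versioned table, `data/residue_composition.tsv`) plus one water, with
carbamidomethyl applied to every cysteine by default (iodoacetamide
alkylation is assumed in sample preparation; oxidized methionine is not
modeled). Envelopes are probability vectors over the extra-neutron count k of
the neutral molecule. The per-element distribution of extra neutrons
(binomial for C, H, N; multinomial for O, S) is computed by
binary-exponentiation convolution of the single-atom distribution, elements
are convolved together, and trailing tail mass below 1e−13 is truncated
before renormalization. The 1e−13 cutoff keeps every envelope within 1e−10
of the exact rational-arithmetic expansion while keeping vectors short; the
retained tail guarantee is much stricter than the 1e−9 the estimators
require. Nitrogen uses natural abundance 0.00364 for pre-existing protein
and a configurable label enrichment `p_label` (default 0.98) for protein
synthesized during labeling — labeled-medium nitrogen is nominally purer,
but amino-acid recycling dilutes the effective enrichment of new protein, so
the value is exposed in configuration and can optionally be fitted per
observation.

Envelopes are indexed on a unit neutron grid rather than m/z: the ~0.006 Da/z
spacing difference between ¹³C and ¹⁵N mass offsets is collapsed, because
envelope intensities, not exact masses, carry the LPF signal on Q-TOF-class
data. Charge is carried on `PeptideIon` for provenance and for any future
peak-table adapter but does not enter the envelope model.

## LPF estimation

The observed progressive-labeling envelope is L1-normalized (only shape
identifies LPF) and fitted by least squares to the two-population mixture.
Since the mixture is linear in LPF, the bounded minimizer is the projection
of the observation onto the segment between the natural and labeled
envelopes, clamped to [0, 1] — exact, deterministic, and verified against a
10⁻⁴-step grid search. With `fit_p_label=True` the enrichment is jointly
fitted by bounded scalar minimization over p_label with the LPF profiled out;
this is opt-in because at low LPF the labeled component is weak and the
enrichment poorly identified. Observations need at least two nonzero
channels; all-zero envelopes are rejected.

Spike-in observations keep their raw scale. They are decomposed by
nonnegative least squares onto the natural envelope (¹⁴N sample) and the
fully labeled envelope (¹⁵N reference pool); the coefficient ratio
light/heavy is the abundance ratio to reference. A heavy coefficient at or
below numerical zero raises "no reference signal".

## Peptide → protein summarization

Peptide × sample matrices (samples = genotype × condition × replicate) are
summarized by Tukey median polish: alternating row/column median sweeps until
the largest sweep adjustment falls below 1e−6 or 20 iterations, NaN cells
ignored, mid-point medians for ties. The protein value in a sample is the
overall effect plus that sample's column effect, which is robust to aberrant
peptides. LPF is polished on its natural scale and clamped to [0, 1];
abundance ratios are polished on the log2 scale (multiplicative error) and
back-transformed. Peptides mapping to more than one protein are dropped
before aggregation; shared-peptide reassignment is out of scope.

## Degradation rates and deltas

With first-order degradation and exponential tissue growth, the unlabeled
fraction after labeling time t is exp(−K_D·t)/FCP with FCP = e^(g·t), giving
K_D = −(1/t)·ln((1 − LPF)·FCP). Defaults: t = 3 d; g = 0.1 d⁻¹ (shoot) and
0.5 d⁻¹ (root), both g and FCP directly overridable since growth can be
measured either as a rate or as a fold-change of the protein pool. One scalar
FCP per tissue is used. LPF below the growth-dilution floor yields a negative
K_D, which is retained with a `negative-rate` qc flag rather than truncated
at zero — truncation would bias group contrasts. LPF above 0.999 means the
label is saturated and K_D is reported missing (`saturated-label`).

Normalized abundance divides each protein's ratio-to-reference by its median
across the genotype × replicate samples of a condition, centring every
protein at 1. Changes are the bounded relative difference
(a − b)/mean(a, b) ∈ (−2, 2), antisymmetric in its arguments, applied to both
K_D and abundance; group means use biological replicates and significance is
a two-tailed pooled-variance Student's t-test. No multiple-testing correction
is applied by default, matching the raw P < 0.05 convention of the targeted
workflow; Benjamini–Hochberg can be layered on the delta table by the caller.

## Quadrant classification and summaries

Quadrant membership depends only on the delta signs: Group 1 (ΔK_D < 0,
ΔAb > 0, putative cargo), Group 2 (>, <, compensatory degradation), Group 3
(>, >, enhanced synthesis), Group 4 (<, <, feedback-reduced synthesis). A
protein is classified only if at least one of the two tests is significant
(OR gate; a stricter AND gate is a flag). Exact-zero deltas are boundary
cases and stay unclassified. Compartment summaries report n, N and the
half-up-rounded integer percentage per compartment, folding compartments past
the top three into "Others". Distribution-level contrasts use the two-sample
Kolmogorov–Smirnov test with asymptotic p-values; samples need at least 3
values.

## Synthetic data

The generator emulates the labeling study design: per-protein K_D drawn
lognormal (median 0.2 d⁻¹, ln-sd 0.4 — mid-range of typical plant tissue
medians), base abundance lognormal (median 1, ln-sd 0.5), 1 + Poisson(4)
tryptic-like peptides per protein (random sequences, length 7–25, ending
K/R — realistic nitrogen counts without a genome), compartments from a
categorical distribution over ten plant compartments, 3 genotypes × 2
conditions × 3 replicates, t = 3 d at the configured enrichment. A
configurable cargo subset (default 10%) gets K_D × 0.5 and abundance × 1.5
in both mutants. Noise is lognormal multiplicative per isotopologue channel
(default CV 0.05), reflecting scale-dependent intensity noise; the mean is
unity so intensities are unbiased. Mutant abundance effects apply to the ¹⁴N
sample only; the ¹⁵N reference is one fixed pool shared by all samples,
mirroring the common-reference design.

Features of real data *not* emulated: chromatographic interference and
missing peptides by ionization, peptide misidentification, between-replicate
biological variance beyond measurement noise, co-eluting envelope overlap,
and condition-dependent (−Pi) kinetic effects (the condition axis is carried
through the pipeline but has no true effect by default). Passing recovery
tests therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to identification errors or biological
heterogeneity.

## Numerical and design choices

- Envelope fits pad natural/labeled/observed vectors to a common length;
  padding with exact zeros is safe because truncated tails carry < 1e−13
  mass.
- Median polish convergence is by the largest sweep adjustment; an exactly
  additive matrix converges in one double sweep with zero residuals.
- Determinism: every random draw flows from one `numpy` Generator seeded from
  the run seed; two runs with the same configuration produce byte-identical
  tables (output-path differences excluded from the configuration hash).
- Problem sizes: the default synthetic experiment is 200 proteins (~1000
  peptides, ~36,000 envelope fits), which characterizes estimator error well
  (median relative K_D error and cargo recall are stable to ~1% across
  seeds); tests use smaller panels where only interface behavior is checked.

## Known limitations

- Single-timepoint K_D assumes proteome steady state over the labeling
  window; multi-timepoint fitting is out of scope.
- The unit-neutron grid ignores isotope fine structure; not suitable for
  FT-class resolution where ¹³C/¹⁵N offsets resolve.
- Compartment annotation is taken as given (one label per protein);
  dual-localized proteins count once.
- No FDR control on the per-protein tests by design; interpret Group calls as
  a ranked candidate list, not a controlled discovery set.
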