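# Methods

This note documents the models, algorithms and numerical conventions behind
`synaptoscope`, the defaults it ships with and why, and what its synthetic
data can and cannot demonstrate.

## 1. Synthetic image fields

One generated field emulates a 20× epifluorescence field of view of a
dissociated neuronal culture at 0.5 μm/pixel (default 696 × 520 px), with
four aligned planes: Hoechst-like nuclei, MAP2 (somata and dendrites; axons
are MAP2-negative and therefore absent), vGLUT1 and vGAT.

**Geometry.** Somata are non-overlapping disks (radius 7.5 ± 0.8 μm
hippocampal, 7.0 ± 0.8 μm cortical) placed by rejection sampling; placement
failure beyond a retry limit raises an error naming `neurons_per_field`.
Each neuron grows 2–4 unbranched dendrites as smooth random polylines
(3-px steps, Gaussian heading jitter of 0.18 rad/step) rooted exactly on the
soma boundary; growth stops at field borders or foreign somata, and the
recorded ground-truth length is the actual polyline arc length. The neuron
count per field is deterministic per profile; field-to-field variability
comes from the stochastic geometry and Poisson puncta counts.

**Puncta.** Dendritic puncta are placed along each polyline with Poisson
counts (density × available length) at uniformly random arc positions
subject to a 2 μm hard-core minimum spacing, which models the physical size
of presynaptic boutons; a perpendicular jitter (σ = 0.5 px, clipped at
1.5 px) keeps every dendritic punctum within the 2-px contact tolerance of
its polyline. Cell-body puncta are placed uniformly in the soma disk with a
2.5 μm hard core. Background distractors are placed farther than
tolerance + 2 μm from every neuron. The vGLUT1 plane additionally carries
continuous low-intensity axon-like streaks (peak 3.5× the noise s.d.) that
own no ground-truth puncta and must be rejected by the detector.

**Rendering.** Puncta are isotropic Gaussian spots (σ = 1.5 px, peak 200
intensity units = 10× the read-noise s.d., so detection tests measure the
algorithm rather than the photon budget); nuclei and MAP2 structures are
drawn and blurred analogously; every plane receives a constant offset (100)
plus Gaussian read noise (σ = 20) and is clipped at zero. Intensities are
arbitrary 16-bit-range units since real per-channel exposure scales vary by
instrument. All draws come from one `numpy.random.Generator`, so identical
(parameters, seed) give bit-identical planes.

**Ontogeny presets.** Built-in profiles for hippocampal and cortical
cultures at DIV 7/14/21/28 encode the qualitative developmental structure
this assay is designed to resolve: all puncta densities non-decreasing with
DIV; hippocampal cell bodies switching to vGAT (inhibitory) dominance from
DIV 14 while their dendrites stay vGLUT1-dominated; cortical neurons keeping
an excitatory majority in both compartments, with more, slightly smaller
neurons per field and slower dendrite growth. The absolute numbers are
synthetic choices at realistic orders of magnitude (e.g. 0.06 → 0.24 vGLUT1
puncta/μm dendrite across DIV in hippocampal cultures), not measurements.

## 2. Image analysis

All detection thresholds are expressed in robust units of each plane:
background = median, spread = 1.4826 × median absolute deviation, feature
threshold = background + *n*σ. This makes the defaults transferable across
exposure scales. Every parameter lives in `HCIParams` and is overridable.

1. **Nuclei** — connected components above 6σ with area in [30, 300] px.
2. **Cell bodies** — the MAP2 mask (5σ) is opened with a 4-px disk to strip
   dendrites; surviving blobs containing a detected nucleus become cell
   bodies, multi-nucleus blobs are split by nearest-nucleus label growth,
   and the final mask is dilated 5 px to restore the opened-away outline
   (overlaps again resolved by proximity). Nuclei without surrounding MAP2
   signal produce no neuron. The pre-dilation core is kept separately and
   used during tracing so the dilation does not consume dendrite roots.
3. **Dendrites** — the MAP2 mask is thinned (`skimage.morphology.
   skeletonize`); skeleton pixels inside soma cores are discarded and each
   remaining component is attached to the soma it approaches within 3 px
   (majority vote), or ignored if none. Length sums the minimum spanning
   forest of the 8-connected pixel graph — 1 per orthogonal step, √2 per
   diagonal, × pixel size — which counts each step once and drops redundant
   corner edges. A 100-px straight process at 0.5 μm/px measures exactly
   49.5 μm (49.5·√2 on the diagonal).
4. **Puncta** — a white top-hat (4-px disk) removes diffuse background, a
   matched Gaussian filter (σ = 1 px) boosts spot-to-noise, and components
   above 5σ with area ≥ 2 px are kept. Touching spots are split at the
   maxima of the negative Laplacian-of-Gaussian response (σ = 1.4 px).
   Elongated components (eccentricity > 0.98, area > 12 px) are rejected as
   continuous axonal labelling unless they resolve into ≥ 2 strong,
   isotropic blob peaks — "strong" meaning the LoG value exceeds a global
   7σ floor and the Hessian principal-curvature ratio at the peak exceeds
   0.3 (blobs are isotropic, ridges are not; the same discrimination used
   for edge rejection in classical keypoint detectors). Oversized
   components (> 60 px) survive only by splitting into ≤ 60 px shares.
5. **Assignment** — sequential rule: soma containment first (rounded
   centroid lookup in the label image), then nearest skeleton pixel within
   the contact tolerance (KD-tree; exact distance ties go to the lowest
   neuron id), else excluded. "Contact" is not metrically standardised in
   this assay class, so the tolerance (default 2 px = 1 μm) is exposed in
   the configuration.
6. **Endpoints** — per-neuron endpoints are field totals divided by neuron
   count (mean, matching the per-neuron phrasing of the endpoint list);
   per-μm endpoints divide dendritic counts by total traced length. Zero
   neurons or zero traced length yield NaN ("missing"), never 0/0. E/I
   ratios with a zero numerator or denominator are missing — no pseudocount
   — so wells are averaged over defined values only. Neurons touching the
   field border are retained but flagged.

The two synaptic channels are quantified independently against one shared
neuron segmentation; this matches sequential two-channel quantification
without imposing any inter-channel dependence.

## 3. MEA analysis

Traces are band-passed with an order-2 Butterworth (300–5000 Hz corners)
applied forward-backward (zero phase, effective order 4; the order is a
package choice). Channel noise is estimated robustly as median(|x|)/0.6745
by default — insensitive to the spikes themselves — with plain RMS
selectable. Spikes are bipolar threshold crossings at 6× the noise RMS,
grouped with a 1 ms dead time and time-stamped at the extremum sample;
detection is therefore invariant to rescaling the trace. The first 180 s of
each 1980-s recording are excluded and times re-referenced; shorter
recordings either raise or, for scaled-down runs, skip the exclusion
(`on_short="zero"`). An electrode is active iff its rate is ≥ 5 spikes/min
(boundary inclusive) and inactive electrodes enter no further analysis.

Bursts follow the max-interval convention: maximal runs with inter-spike
intervals ≤ 0.1 s (the max-ISI parameter is not part of the printed
criteria; it defaults to the inter-burst interval and is configurable),
filtered to ≥ 4 spikes and ≥ 0.02 s duration, with runs closer than 0.1 s
merged and the criteria re-checked. Well summaries average spikes/min and
bursts/min over active electrodes only. Viability from paired stain counts
is (Hoechst − PI)/Hoechst × 100, with zero Hoechst flagged missing.

The synthetic recording generator embeds Poisson background spikes plus
bursts (≥ 4 spikes, intra-burst ISIs strictly below the stated parameter,
starts ≥ 1 s apart) into Gaussian noise of requested RMS, rendering a
biphasic ~1.2 ms waveform at 12,500 samples/s (a plausible rate for this
hardware class, comfortably above the 5 kHz corner; the true rate is
configurable).

## 4. Statistics

Endpoints are analysed at the well level (well means of usable fields).
`two_way_anova` fits the fixed-effects interaction model via
`statsmodels` OLS with Type II sums of squares (identical to the classical
decomposition in balanced designs, a stated convention otherwise). Guards:
≥ 2 levels per factor, ≥ 2 replicates per cell (else the interaction is
untestable and an explicit error is raised), zero-variance responses raise
`DegenerateDataError` instead of producing a numeric F. Missing values are
dropped with a logged count.

Post-hoc contrasts use the pooled residual error of the interaction model.
With a significant interaction (α = 0.05) two families are built: cell types
within each time point, and time points within each cell type (all pairwise
by default; versus the first time point selectable). Without an
interaction, each significant main effect is followed up on data collapsed
over the other factor, using the collapsed one-way model's error. Each
family is Sidak-adjusted with m = family size. When the pooled error is
exactly zero (a degenerate noiseless endpoint), contrasts report p = 0 for
unequal means and p = 1 otherwise rather than dividing by zero.

ELISA plates are normalised by subtracting the plate's mean blank;
triplicates are averaged per sample, and sub-blank values are kept (flagged)
rather than clipped.

## 5. The study harness

`run_all` chains generator → quantification → statistics for an imaging
arm, an MEA arm (spike-time mode by default; raw-trace rendering is
supported but costly at full scale) and an ELISA arm, writing CSV tables
plus a provenance record (config hash, seed, version). Outputs are
byte-identical across runs of the same seed: per-field seeds derive
deterministically from the master seed via `SeedSequence`, and CSVs are
written with a fixed float format. The default design is desk-scale —
256 × 320 px fields, 3 wells × 12 fields per condition, 16 electrodes per
well — chosen so a full two-cell-type, four-DIV study completes in minutes
on one core; all sizes scale up in configuration. The MEA and ELISA
activity presets encode the expected study structure (activity peaking at
DIV 14 with cortical cultures firing and bursting harder; synaptophysin
rising with DIV identically in both cell types).

## 6. What the synthetic data does and does not show

The generator reproduces the *spatial logic* of the assay — compartment
geometry, MAP2-negative distractors, SNR-controlled spots, Poisson/burst
spike statistics — with exact labels, so passing tests demonstrate that the
algorithms recover known structure and transmit the encoded E/I patterns
through the full pipeline. It does not model out-of-focus light, uneven
illumination, antibody cross-reactivity, branching dendrite morphology
(dendrites are unbranched polylines), overlapping cells in dense cultures,
electrode drift, or spike-waveform variability; performance on real data
therefore still requires per-instrument parameter review, which is why
every threshold is exposed in configuration. Absolute counts are synthetic
choices — only the qualitative ontogeny and compartment structure are
meaningful.

## 7. Known limitations

* Dendrite crossings between neurons can merge skeleton components; length
  is then attributed by proximity majority, which is unbiased at field
  level but can misallocate between neighbouring neurons.
* Very bright continuous streaks are genuinely ambiguous with chains of
  puncta; the ridge/blob discrimination is calibrated for low-intensity
  axonal labelling.
* The ANOVA treats wells as independent; replicate-culture (batch) random
  effects are out of scope.
* Spike detection assumes stationary noise per channel; no spike sorting or
  cross-electrode network bursts are attempted.
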