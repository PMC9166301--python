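# Methods

This note records the models, decision rules and numerical conventions the
package implements, the reasoning behind the genuinely open design choices,
and what the validation studies do and do not demonstrate.

## Signal model

Every simulated intensity is generated, per event and detector `d`, as

```
gain          g_d(V) = (V / v_ref)^γ_d
reference     S_d    = Σ_f load_f · spill[f, d] + AF_d
observed      x_d    = g_d · (S_d + ε_shot) + ε_bg
clipped       x_d   -> clip(x_d, scale_min, adc_max)
```

* `load_f` — fluorophore load of the event, log-normal around
  `multiplier × brightness_f` with sigma `expression_sigma` (default 0.25,
  a typical staining CV); `multiplier` comes from the population definition
  (0 = negative, 1 = fully stained, saturation-binding fractions for
  titrations, geometric series for bead ladders).
* `AF_d` — autofluorescence, log-normal (median 50, sigma 0.25 by default,
  in reference-gain intensity units).  Autofluorescence is light, so it is
  amplified by the PMT like any other signal; the model therefore applies
  the gain to it (the detector mean is `Σ load·spill·gain + AF·gain`).
* `ε_shot ~ N(0, √(q_d·S_d))` — photon shot noise, entering *before*
  amplification with variance proportional to the expected signal
  (`photoelectron_scale` q_d, default 3 intensity units per photoelectron at
  reference gain).  Because it is amplified, its contribution grows with
  gain and with brightness — this is the mechanism that makes spillover
  *spread* grow with the spilling signal and survive compensation.
* `ε_bg ~ N(0, background_sd)` — electronics/ADC noise added after
  amplification, voltage-independent (default 30).  Because this term does
  not scale with gain, raising the voltage lifts dim signals out of it:
  the stain index rises with voltage until amplified photon noise
  dominates, producing the steep-then-flat SI curve whose knee the voltage
  titration seeks.  Analytically,
  `SI(V) ≈ A·g / (2·√(g²σ_i² + σ_bg²))` with `σ_i²` the intrinsic
  (autofluorescence + shot) variance at reference gain — a saturating
  curve whose transition sits where `g·σ_i ≈ σ_bg`.
* Gain law — a power law with γ = 6 by default (typical PMT response
  steepness); instruments treat gain empirically, but ground-truth recovery
  experiments need a parametric law.
* Clipping — 18-bit full scale (262,144) and floor 0; clip fractions are
  recorded so "on scale" checks are testable.  Populations with
  `scatter_sigma > 0` receive independent per-detector log-normal
  distortions and model multidimensional scattered debris.

The `analytic_*` functions invert the exact CDF of this model (Gauss–Hermite
quadrature over the two log-normal factors, Brent root-finding) and provide
distribution-level predictions — medians, percentiles, clip fractions, SI
curves — that serve as independent oracles and as the "truth" in parameter-
recovery experiments: the event-level simulator and the quadrature share no
code path beyond the model definition itself.

## Decision rules

All thresholds live in `cytotune.defaults` and are echoed into every report.

**Robust SD.** `rSD = (P84.13 − P15.87)/2`, the convention of mainstream
cytometry software; equals σ for Gaussian data.  A MAD-based alternative
(×1.4826) is selectable because the convention used by any given analysis
program is rarely documented.  Percentiles use linear interpolation with
order statistics anchored at `(i−1)/(n−1)`; bead peak ratios depend on the
convention, so it is fixed, not configurable.  Voltration SI is computed on
uncompensated data (the voltage walk is acquired without compensation).

**Knee detection.** After a moving-median smoothing (window 3, robust to
single-tube noise without reshaping the curve), the knee is the lowest grid
voltage after which the relative SI gain per 25 V step stays below 10% —
*provided* the curve had a steep phase first (some earlier step ≥ 2× the
threshold).  The extra condition is what distinguishes a genuine inflection
from curves that merely grow slowly: a straight line through a large
intercept has every relative gain below 10% yet no inflection, and must
fall through to the same-laser fallback rather than return its first
voltage.  Curves whose total excursion is below the threshold are flat
(degenerate): the lowest voltage is returned with a diagnostic, so
noise-free simulations stay computable.  Ties among knee candidates resolve
to the lowest voltage (avoids needlessly bright signals).

**On-scale checks.** Negative resolved ⇔ ≥ 99% of negative events strictly
above the scale floor; positive on scale ⇔ ≤ 0.1% of positive events at the
ADC ceiling.  A knee that clips positives moves down to the highest
non-clipping grid voltage; a knee with an unresolved negative moves up to
the nearest passing voltage; both moves are flagged and noted.

**Criterion (v) fallback.** "Closer wavelengths" is qualitative; the
implemented proxy is nearness in the configured detector order within the
same laser, taking the median chosen voltage of the two–three nearest
laser-mates and snapping to the grid.  The report states this.

**Population splitting.** The mixture method k-means-partitions the arcsinh
values into two components and cuts at the midpoint of the component
medians.  Separability requires the median gap to exceed 2.5× the pooled
rSD of the components: the halves of a single Gaussian sit ~2.2 pooled-rSD
apart, so any smaller factor would declare an unstained blob "split".

**Bead peak detection.** One-dimensional k-means (quantile-initialized,
hence deterministic) on the arcsinh scale, relabeled by increasing median;
MFI/p90/rSD are computed on linear values.  Because k-means always returns
k clusters, genuine peak structure is verified by counting modes of the
smoothed intensity histogram (bin width 0.6× the median within-cluster rSD,
3-bin smoothing, 5% prominence): fewer modes than requested peaks raises a
merge error naming the closest pair.  Pairwise gap-versus-rSD thresholds
were tried first and sat on a knife edge between "sliced unimodal blob" and
genuinely dim peaks; the mode count separates the two cleanly and, usefully,
rejects low-gain acquisitions whose dim peaks are truly unresolved —
pipelines treat such voltages as unusable, like out-of-scale ones.

**Gain-range tool.** Separation distance = log10(MFI of first positive
peak) − log10(p90 of the negative peak); linearity distance = log10 MFI
ratio of the second to first positive peak.  The *p90 anchor* for the
negative is deliberate: a median anchor is invariant to the symmetric
electronic noise floor (the median of signal-plus-symmetric-noise is the
signal), so a median-based distance never saturates with voltage and the
tool would always pick the top of the grid.  The 90th percentile feels the
noise floor — exactly why the QSBC ratios are themselves anchored at
p90(M1) — and reproduces the observed behaviour: separation grows until the
negative peak lifts off the floor, then plateaus.  Candidates are voltages
within 5% of the maximal separation whose brightest peak is on scale;
the selected range is the longest contiguous candidate run over which
linearity varies ≤ 5%.  A candidate set collapsing to the top voltage is
flagged `saturation_not_reached`.

**QSBC refinement.** `M2 ratio = MFI(M2)/p90(M1)` and
`M5 ratio = MFI(M5)/p90(M1)`, evaluated over the selected range ± one 25 V
step.  Within a linear-amplification model both ratios are monotone
saturating in voltage, so the interior optimum is created by the on-scale
constraint: voltages whose M5 peak piles up at the ceiling are excluded
(flagged), and the M2 ratio is maximized over the rest.  Ties break by the
M5 ratio, then by the lower voltage; disagreement between the M2- and
M5-optima is reported, never silent — M2 takes precedence because dim-peak
separation is the quantity the refinement exists to protect.

**Spillover and spread.** Coefficients are background-subtracted median
ratios from single stains; a control whose primary-channel median
difference is ≤ 2× the negative rSD is unusable (a strict ≤ 0 rule misses
half of all unstained tubes, whose difference is near zero with random
sign).  Negative estimates clip to 0 with a warning.  Compensation is the
matrix inverse on linear values, negatives preserved.  Spread entries are
`√max(rSD_pos² − rSD_neg², 0)` in the affected channel of the *compensated*
control, scaled by `√(B_ref/B_control)` to a reference brightness of 10,000
(spread grows with the square root of the spilling signal).  The implied
double-positive SI loss is `1 − rSD/√(rSD² + σ_spread²)`, computed from the
measured quantities; `dp_resolution_impact` provides the independent
simulation route (four populations, compensate, compare DP-vs-affecting SI
with SP-vs-negative SI).  One subtlety: the *uncompensated* off-channel
width of a positive control also contains spilled cell-to-cell brightness
variation, which tracks the primary signal per event and is removed exactly
by compensation — by design, since it is signal, not noise.  The
"compensation cannot remove spread" property is therefore asserted with
expression variation off, isolating the photon-noise component that the
claim is about.

**Panel rules.** (i) dim/low-density markers must not sit on detectors
receiving σ_spread above threshold (default 50 intensity units at reference
brightness) from co-expressed markers' dyes; (ii) bright markers should
avoid dyes whose total generated spread exceeds the per-detector budget;
(iii) low-density antigens belong on bright dyes; (iv) high-density
antigens on dim dyes.  Dye brightness classes are caller-supplied (the
field's brightness knowledge is tacit); thresholds are printed in every
report.

**Titration.** Argmax SI; concentrations within 5% of the maximum plateau
to the lowest (flagged `plateau`); strictly rising series select the top
concentration with an `unsaturated` flag.  The rule logic is exposed
separately (`apply_plateau_rule`) so it can be audited on any SI series.

**Density censoring.** Density = 1/(distance to the k-th nearest neighbour),
k = 30, on arcsinh-transformed channels; exactly `floor(fraction/100·N)`
events are censored (3% default), ties broken by stable sort on (density,
original index).  This k-NN estimate stands in for spanning-tree density
normalization: equivalent censoring behaviour at desk scale, O(N log N)
with a spatial index.  Scattered debris is removed preferentially while
dense rare islands keep their frequency — and, as a negative control, a
rare subset *placed* in the low-density tail is depleted, demonstrating the
operation censors by density, not by subset size.

**Clustering delegation.** Embedding and community detection are external
algorithms behind a contract: k-NN graph (k configurable, 10 in the panel
study) partitioned by seeded Leiden; optional UMAP embedding; excluded
channels (viability dye, lineage pre-gates) honored; outputs feed the
capture metrics and per-cluster median tables.  Capture: the best cluster
for a subset is the one holding its largest share (recall), purity is the
subset's share of that cluster, and a subset is fragmented when more than
one cluster holds ≥ 5% of it.

**arcsinh cofactor.** 150 per channel by default (common for
fluorescence-cytometry channel scales), settable per channel.

## Validation studies (`cytotune.scenarios`)

The named scenarios fix the conditions of every validation; their constants
derive from the protocol settings (voltage grids 250–750/25 V for voltage
walks and 250–800/50 V for beads, 1:2 dilution series, 3% censoring,
0.1–1% rare subsets) plus instrument-plausible noise parameters placed by
the algebra above:

* *voltration_study* — four detectors, background SD 10/25/50/100, knees
  analytically at 475/550/625/675 V; 20,000 events per tube.  Recovery is
  scored against the analytic knee (same rule applied to the quadrature SI
  curve).
* *bead_study* — one detector matching voltration detector 2.  Ladder
  levels (base 1200, ratio 2.335) put the brightest peak off scale above
  600 V; QSBC loads (base 89.6, ratio 8) keep M5 on scale to 575 V; the
  geometry places the bead-refined voltage within one grid step of the
  550 V knee, probing the cross-method agreement the two calibration
  procedures are supposed to show.  30,000 events per QSBC tube keep the
  M2-ratio increments several standard errors above estimator noise.
* *spillover_study* — four dyes, off-diagonal truth up to 0.3, 10⁴-event
  controls.
* *spread_study* — a bright dye (50,000) spilling a variable coefficient
  into a dim neighbour, strong shot noise (q = 10).
* *titration_study* — six 1:2 dilutions (0.2–6.4), kd 0.35 so 90%
  occupancy falls at 3.15, between the two top concentrations; nonspecific
  background slope 0.001 of full brightness per unit concentration, small
  enough that background growth does not mask saturation within the series
  yet visible in the SI shape.
* *censor_study / panel_study* — dense bulk populations, a 0.5% tight rare
  subset, and 4–5% scattered debris.  The debris matters: the 3% cut
  removes the lowest-density events, and in a debris-free acquisition that
  would be the rare island itself.  The panel study adds a viability-like
  channel excluded from clustering and a tetramer channel positive only on
  the rare subset.

Problem sizes (events per tube, seeds per study) are chosen so each study
runs in seconds to a couple of minutes on a single CPU; recovery studies
use 25–50 seeded replicates.

## What the simulator does not emulate

Time-dependent acquisition drift (the domain of signal-stability cleaning,
which simulated data does not need), doublets and aggregates beyond generic
scattered debris, wavelength-structured spillover (the matrix is free-form),
tandem-dye degradation, laser cross-excitation timing, and spectral
unmixing with more detectors than dyes.  Passing validations demonstrate
that the decision rules recover the truth of *this* signal model; on real
instruments the gain law is only approximately a power law and noise has
heavier tails, so thresholds may need site-specific adjustment — which is
why every threshold is a named default echoed into reports.

## Numerical notes

FCS files are written as FCS 3.1, list mode, little-endian 32-bit floats,
one dataset; 3.0/3.1 with F/D/I data types are read.  Scalar acquisition
metadata rides in custom keywords; per-event truth vectors live in sidecar
CSVs, never in the FCS payload.  Quadrature uses 48 Gauss–Hermite nodes per
log-normal factor.  Degenerate stain indices (zero negative rSD) are
flagged values (+inf), not exceptions.  All stochastic operations take
explicit seeds and are bit-reproducible; per-tube seeds derive from a
`SeedSequence` spawn of the study seed.
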