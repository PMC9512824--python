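# Methods

`csretina` models how the classical center–surround receptive field (RF) of
retinal bipolar cells (BCs) makes them preferentially responsive to *newly
appearing* objects — stimuli that emerge from behind an occluder — and
provides the analysis machinery used to quantify that preference in
glutamate-imaging data. This note documents the models, their assumptions,
the parameters that matter, and the choices made where the design was open.

## 1. Outer-retina circuit model (`csretina.opl_sim`)

A one-dimensional array (default 1500 µm, 150 cells at 10 µm spacing) of
photoreceptors, horizontal cells (HC) and bipolar cells, advanced with
explicit per-millisecond difference equations (dt is fixed at 1 ms; the
update divisors are the time constants expressed in ms).

**Photoreceptor.** The light response is the difference of two first-order
activation functions with instantaneous rise and decay constants 60 and
400 ms, weighted 1 : 0.8 — a biphasic, transient-then-sustained
hyperpolarization. A sustained drive `D` settles at `0.2 D`.

**Drive.** Each photoreceptor combines the local luminance `VS` with HC
feedback through a divisive expression

    drive_i = g · (E_HC · ⟨HC⟩_i + E_VS · VS_i) / (⟨|HC|⟩_i + VS_i + 1)

with `g = 0.5`, `E_HC = 2 mV`, `E_VS = −10 mV`, and `⟨·⟩` a Gaussian-weighted
average over the HC population (weights normalized to unit sum; an
unnormalized sum lets the feedback loop dominate the light term and spread
across the whole array, destroying spatial locality — see the shunting term
in the denominator, which is what makes feedback net-suppressive). The
Ph↔HC cycle is broken with a one-step lag: the drive at `t` consumes HC
from `t − 1`.

**Horizontal cell.** HCs average photoreceptor output over a wide RF
(FWHM 300 µm), pass it through the saturation `E_Ph·x/(x + E_Ph)`
(`E_Ph = 10 mV`) and relax with τ = 300 ms. Because the HC kernel reaches
far ahead of a moving bar while the light drive is local, the HC signal at a
given position starts rising long before the bar arrives — the "preceding
inhibition" that suppresses responses to established motion. At an
emergence boundary there is no approach phase, so HC and photoreceptor
engage together and the response is left unsuppressed.

**Bipolar cells.** The photoreceptor→BC synapse is a sigmoidal release
function of presynaptic voltage, baseline-subtracted and summed over a
narrow RF (FWHM 50 µm):

    BC∞_i = −Σ_j d_ij [σ(Ph_j) − σ(0)],   σ(v) = 1/(1 + e^{slope·(half − v)})

(transient: slope 1.1 /mV, half 4 mV; sustained: 0.1 /mV, 1 mV). The
synaptic state relaxes with τ = 50 ms and is converted to membrane voltage
through the conductance-like stage `Vm = E_Ph(E_Ph·BC + E_AC·AC)/(|BC| +
|AC| + E_Ph)`. With `E_AC = 0` the amacrine input acts purely as a shunt.

**Amacrine circuit (optional).** A separate "driver" BC population
(slope 2 /mV, half 4 mV) excites amacrine cells through a sigmoid
(gain 1, slope 1.5 /mV, half 7 mV, τ = 80 ms, RF FWHM 300 µm); the
distance-normalized AC output shunts the transient/sustained BCs. With the
gain at 0 the circuit is bit-identical to the AC-disabled model.

**Spatial kernels.** Two conventions are shipped. `normalized_fwhm`
(default) realizes the nominal FWHM exactly: `exp(−4 ln2 · x²/FWHM²)`.
`literal` evaluates `exp(−x²/(FWHM/11.09)²)`, an alternative transcription
in circulation whose realized width is far narrower than its nominal FWHM;
it is preserved verbatim because the two cannot be reconciled under any
standard Gaussian convention. All results in this package use the default unless stated.

**HC lead time.** "Initiation" of the HC signal is defined as the first
crossing of 10 % of its eventual peak magnitude (the threshold is exposed —
there is no canonical value); the lead is the interval from initiation to
the moment the bar first covers the cell. Under the defaults the maximum
lead over interior cells (≥300 µm from the array ends) is ≈266 ms; it is
very sensitive to the initiation threshold (20 % → 132 ms, 30 % → 43 ms)
and to the kernel convention (the literal kernel gives a *negative* lead),
so any single number for the lead should be read as order-of-magnitude.
The robust, convention-independent facts are: the lead is strictly positive
during established motion, collapses to ≈0 (or below) at an emergence
boundary, and shrinks when the HC RF is narrowed.

**Known limitation.** The printed release sigmoid saturates for
hyperpolarizing photoreceptor input (the response is capped at
`σ(0) × kernel mass`), so the steep "transient" sigmoid *compresses* ratio
metrics: in this model the emerging-object enhancement of the transient BC
(~5 %) is smaller than that of the sustained BC (~12 %), and a sweep over
(slope, half) shows enhancement decreasing monotonically with slope. The
qualitative ordering emerging > continuous ≈ exit holds for both types.

## 2. Linear center–surround population (`csretina.linear_rf`)

Each unit weighs the stimulus with two concentric Gaussians — center
half-width 50 µm, surround 200 µm ("half width" is read as half-width at
half-maximum; a switch selects the FWHM reading) — normalized to unit mass
over the sampled grid, low-pass filters each component with a
single-exponential step update (τ_center = 20 ms, τ_surround = 100 ms,
dt = 1 ms) and reports

    RF_full = RF_center − factor_surround · RF_surround ,

the same factor for every unit in a run (0 = center-only). Units are not
rectified; downstream peak detection decides polarity. The model is exactly
linear in the stimulus, which the implementation exploits: one
center/surround simulation serves every surround factor.

Units live on a 1000 × 1000 µm grid (spacing 10 µm by default; the original
density is unstated). Movies with a coarser frame interval are frame-held
to 1 ms before temporal filtering.

## 3. Stimuli (`csretina.stimuli`)

Model-input movies use background = 0 and bar amplitude equal to the
Michelson contrast (the drive amplitude fed to the models is not dictated by
the display contrast; 1.0 is the default). The battery comprises: 2-s
full-field flashes; 1-mm bars moving at 0.5 mm/s (dwell 2 s per position);
occluding masks (e.g. the outer 300 µm of the circuit array) that turn
motion into *emerging* (out from behind the mask) or *exiting* (into the
mask) conditions; and apparent-motion sequences of 25 µm × 350 µm bars
flashed 50 ms each at 14 positions tiling 350 µm, either sequentially or in
seven fixed pseudorandom orders generated once from a named seed. Movies
carry a 200-ms pre-stimulus baseline; masks are half-open µm intervals and
masking is idempotent.

**Synthetic naturalistic movies.** A 100 × 100-sample frame at 10 µm/sample
(1 × 1 mm) refreshed every 20 ms. The background is Gaussian-smoothed noise
(FWHM 5 samples) rescaled to mean 128, SD 30 on the 8-bit scale; the
stimulus is an irregular bright silhouette (mean 2 SD above background,
diameter ≈500 µm — roughly half the field, the scale of a bird of prey in
such a crop) translating rightward at 0.5 mm/s; the occluder is a static
textured band (mean 128, SD 30) with an irregular boundary near x = 400 µm.
The foreground scene (silhouette, its texture, the occluder) is drawn once
from a fixed scene seed; each trial redraws only the background, so an
ensemble of trials is an ensemble of background permutations. The masked
and unmasked members of a trial share every random draw. Each movie
records where and when the stimulus first becomes visible and the silhouette
centroid at full emergence.

What this generator does *not* emulate: the 1/f spectrum, long-range
structure and luminance nonstationarity of real natural footage, and any
object other than one moving silhouette. Passing tests therefore show that
the information-theoretic machinery behaves correctly under the stated
first- and second-order statistics, not that the absolute information rates
transfer to arbitrary natural scenes.

## 4. Novelty information (`csretina.infotheory`)

For each cell, the response to a trial is the rectified peak of `RF_full`
in a 500-ms window starting when the stimulus reaches the cell's position
(emergence time plus travel at 0.5 mm/s; identical for both members of a
pair). Peaks are rounded to the nearest integer and the plug-in mutual
information `I = H(VS) − H(VS|R)` between the mask condition and the
discretized peak is computed per cell from the empirical joint counts — no
bias correction, matching the direct estimator definition. Cells are
selected within 100 µm of the emergence site.

The *site* is anchored at the silhouette centroid at full emergence rather
than at the first visible sliver: cells whose center kernel overlaps the
occluder are never (or only partially) stimulated in the masked condition
and would carry near-perfect information about the occluder itself — even
with no surround — which is occluder detection, not novelty detection. The
measured center-only MI of ≈0.00 bits validates this choice; anchoring at
the first-visibility point instead yields center-only MI ≈0.4 bits.

At the default conditions (1000 paired trials, factor 0.5) the mean per-cell
MI is ≈0.51 bits, rising steeply from 0 with surround strength and
saturating above factor ≈0.5 (0.58 bits at factor 1). The enhancement
profile — mean masked-minus-unmasked peak versus distance from the occluder
boundary — peaks ≈110 µm past the boundary and has a half-maximum width of
≈114 µm, set jointly by the surround time constant (100 ms × 0.5 mm/s =
50 µm of travel) and the center kernel's occluder-overlap zone.

## 5. Imaging pipeline (`csretina.roi_pipeline`)

Preprocessing: repeat averaging, 2 × 2 spatial binning, zero-phase 4th-order
Butterworth low-pass at 20 Hz, dF/F against the pre-stimulus baseline.
Pixels with peak dF/F > 20 % across conditions enter clustering. Primary
(within-field) clustering builds per-pixel features from concatenated 1-s
windows ([−200, +800] ms) around stimulus entrance, one per condition,
computes 1 − Pearson distances (amplitude-invariant; Euclidean optional) and
partitions by farthest-point (maximin) clustering: seeds start at the item
with the largest summed distance and grow until the farthest item is within
the threshold (default 0.5); spatially connected members of a cluster become
ROIs. Curation drops ROIs whose across-pixel coefficient of variation
(mean over strong timepoints of SD/|mean|) exceeds 1 (strict inequality).

Secondary (across-experiment) clustering uses average-linkage agglomeration
on the 1-s static-flash waveforms only (motion responses shift with RF
position and would confound shape comparison), with the c-index
`C = (S − S_min)/(S_max − S_min)` evaluated for each candidate k. The
chosen k is the *first local minimum* of the curve within plausibility
bounds (default 3–15): validity curves fall steeply to the true cluster
count and dip again when near-identical sub-groups are split, so global
late minima are reported but not selected. A known limitation, shared with
the method itself: when clusters are internally tight and one pair of
cluster centers is much closer than the rest, merging that pair is nearly
free for the c-index, so the resolvable number of types saturates — in our
synthetic benchmark, recovery is exact for 3 and 5 types and succeeds in
only ≈2/5 seeded runs at 8 types.

## 6. Synthetic ground truth (`csretina.synthetic_data`)

Kinetic templates are logistic-rise / exponential-decay waveforms with
optional plateau, sustained pedestal, undershoot and a secondary
(multiphasic) release lobe, parameterized by rise t50 (40–280 ms), decay τ
(120–1500 ms, log-uniform), latency (0–200 ms) and amplitude (0.5–1.5
dF/F). A set of k templates is chosen by greedy maximin selection from a
seeded candidate pool on 1-s-waveform correlation distance (pool enlarged
until a 0.3 separation floor is met where the waveform space permits), so
the ground truth is distinguishable by construction and every k ≥ 2 set
contains a clearly transient and a clearly sustained member.

Movies place non-overlapping square pixel patches (one ROI each) in a
64 × 64-px field, cycling templates; motion conditions shift each patch's
onset by `rf_x / 0.5 mm s⁻¹` and apply per-template motion modifiers, making
motion-versus-stationary kinetics a controlled ground truth rather than an
emergent artifact. Per-patch jitter (default 5 % on rise/decay/amplitude
plus latency jitter) emulates within-type cell-to-cell variability — without
it, identical-waveform patches make internal validity indices degenerate.
Noise is additive white Gaussian on dF/F (realized SD within 2 % of
nominal); raw-fluorescence mode (`F = 1 + dF/F`, with a repeat axis)
exercises the full preprocessing path.

## 7. Numerical and interface choices

- Determinism: every stochastic component takes a seed; same seed ⇒
  bit-identical movies, templates and ensembles.
- Problem sizes: the validation suite runs the circuit at its native size
  (150 cells, ≤5.4 s of simulated time), the novelty ensemble at 1000
  paired trials with analysis cells on a 10-µm grid around the emergence
  zone, and the clustering benchmark at 12 ROIs per template in a
  64 × 64-px field — the scales at which the reported numbers were
  measured.
- Degenerate inputs are rejected loudly (empty grids, geometry mismatches,
  missing baselines) or flagged (NaN transiency for non-positive peaks,
  `fit_ok=False` for unfittable kinetics).
- The transiency index is reported as `TI = 1 − mean/peak` (0 = plateau,
  →1 = impulse); the raw peak/mean ratio is available behind an option.
  The literal ratio definition conflicts with the stated semantics of a
  sustained plateau scoring near zero.
- File formats: movies as multi-page TIFF + JSON sidecar, traces as HDF5,
  tables as CSV; a `csretina` command-line entry point wraps the main
  library operations.
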