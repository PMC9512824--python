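# csretina

Center–surround receptive-field modelling and glutamate-imaging analysis for
novel-object detection in the retina.

Retinal bipolar cells respond more strongly to objects that *newly appear*
in a scene — a bar emerging from behind an occluder, a predator breaking
cover — than to the same objects in established motion. `csretina`
implements the computational machinery behind that observation for
modellers and imaging labs:

- **`csretina.opl_sim`** — a mechanistic outer-retina circuit: biphasic
  photoreceptors, wide-field horizontal-cell (HC) feedback through a
  divisive drive, sigmoidal photoreceptor→bipolar synapses
  (transient/sustained populations) and an optional feed-forward amacrine
  circuit, advanced as explicit 1-ms difference equations.
- **`csretina.linear_rf`** — linear spatiotemporal center–surround units
  (Gaussian center/surround half-widths 50/200 µm, single-exponential
  kinetics τ = 20/100 ms):
  `RF_full = RF_center − Factor_surround · RF_surround`.
- **`csretina.stimuli`** — flashes, moving bars, occluding masks
  (emergence/exit conditions), apparent-motion sequences and synthetic
  naturalistic movies (textured background, mean 128 / SD 30 on the 8-bit
  scale, with a bright silhouette emerging from behind a static occluder).
- **`csretina.infotheory`** — plug-in mutual information
  `I(VS; R) = H(VS) − H(VS|R)` between occluder condition and
  integer-discretized peak responses, surround-strength sweeps and
  enhancement-versus-distance profiles.
- **`csretina.metrics`** — transiency index, static-edge and
  emerging-object enhancement (`R_from/R_to − 1`), direction-selectivity
  index (vector sum), RF-position estimation from opposed motion trials and
  sigmoid/exponential kinetics fits.
- **`csretina.roi_pipeline`** — the imaging pipeline: preprocessing,
  dF/F-threshold pixel selection, farthest-point primary clustering into
  ROIs, coefficient-of-variation curation and hierarchical secondary
  clustering with c-index model selection.
- **`csretina.synthetic_data`** — ground-truth-labelled kinetic templates
  and iGluSnFR-like imaging movies so every stage is testable without any
  recording.

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

Simulate the circuit's response to a bar emerging from behind an occluder
versus continuous full-field motion, and measure the HC lead:

```python
import numpy as np
from csretina import stimuli, opl_sim, metrics

bar = stimuli.BarSpec(bar_length=1000.0, speed=0.5, contrast=1.0)
full = stimuli.make_moving_bar(bar, extent=1500.0, dx=10.0)
emerging = stimuli.apply_mask(full, (0.0, 300.0))   # occluder on the left

tr_full = opl_sim.run_simulation(full)
tr_em = opl_sim.run_simulation(emerging)

cell = 35  # 50 µm past the occluder edge
r_from = tr_em["bc_vm_transient"].values[cell].max()
r_to = tr_full["bc_vm_transient"].values[cell].max()
print(f"emerging vs continuous peak: {r_from:.3f} / {r_to:.3f} mV")
print(f"enhancement: {metrics.emerging_enhancement(r_from, r_to):+.1%}")

leads, max_lead = opl_sim.hc_lead_time(tr_full, full)
print(f"max HC lead during established motion: {max_lead:.0f} ms")
```

prints

```
emerging vs continuous peak: 0.509 / 0.488 mV
enhancement: +4.3%
max HC lead during established motion: 266 ms
```

— the bipolar response to the emerging bar exceeds the response to the same
bar in mid-trajectory motion (because the HC surround, which starts
integrating hundreds of ms before a moving bar arrives, has no approach
phase at the occluder edge), and the HC signal leads direct light arrival by
hundreds of milliseconds during established motion.

The information-theoretic readout on naturalistic movies:

```python
from csretina import infotheory

ens = infotheory.run_novelty_ensemble(factors=(0.0, 0.5), n_trials=200, seed=1)
for f in (0.5, 0.0):
    _, mi = infotheory.per_cell_mi(ens, factor=f)
    print(f"surround factor {f}: {mi:.2f} bits/cell")
```

```
surround factor 0.5: 0.51 bits/cell
surround factor 0.0: 0.00 bits/cell
```

— center–surround units near the emergence site tell a downstream observer
about half a bit per trial about whether the object appeared from behind an
occluder; center-only units carry essentially none.

## Command line

A thin CLI wraps the library:

```bash
csretina stimuli-make --kind natural --out movie.tiff
csretina linear-rf --stimulus movie.tiff --factor-surround 0.5 --out traces.csv
csretina opl-sim --stimulus builtin:emerging --out traces.h5
csretina info-mi --trials 200 --out mi.json
csretina synth-make --k 3 --out synth/
```
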