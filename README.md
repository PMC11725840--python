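# premotion

Detection and characterization of **asymmetric extraclassical ("PRE")
motion responses** in retinal ganglion cell (RGC) spike trains, together
with a synthetic-retina simulator that generates spike data with the
statistical structure the analysis assumes — so every stage of the
pipeline can be validated against known ground truth without any recorded
data.

## The scientific problem

Most RGCs respond when a stimulus crosses their classical receptive field
(RF). A subset of sustained ON cells, however, fires *before* a moving bar
reaches the RF — driven by an asymmetric **activation zone** in the
extraclassical surround, located on one side of the cell. Because the zone
sits on one side, the response is direction-selective in a non-canonical
way: motion from the zone toward the RF (the preferred direction, PD)
evokes spikes in the approach epoch, motion from the opposite side (null
direction, ND) does not. Pooled across the retina these zones point toward
the optic disc, and analogous responses appear in the visual thalamus.

The package screens spike tables for this phenomenon and dissects its
mechanisms (desensitization after classical-RF stimulation vs an inherent
DS gain in the zone), using per-cell stimulus-geometry windows:

* **PRE window** — from the bar's leading edge entering the per-cell
  annulus (radius = `Distance_min`, the distance from the RF center to the
  recording edge; cells with `Distance_min` < 450 µm are excluded) until it
  enters the fixed **Central area** (350 µm radius; 11.7° for thalamic
  recordings in visual degrees).
* **Central window** — leading-edge entry to trailing-edge exit of the
  Central area.
* **POST window** — trailing-edge exit of the Central area to its exit
  from the annulus.

For the standard bar (width *w* = 900 µm at *v* = 600 µm/s) the Central
crossing times are ±(350 + *w*/2)/*v* = ±1.333 s around bar/RF-center
alignment.

A PRE (or POST) response counts as **asymmetric** when, over the eight
motion directions with mean spike counts *r<sub>d</sub>*:

* motion asymmetry index `mAI = (r_PD − r_ND) / (r_PD + r_ND) > 0.3`
  with PD the argmax direction and ND its opposite,
* normalized vector sum `NVS = |Σ_d r_d e^{iθ_d}| / Σ_d r_d > 0.15`,
* the PD mean count is ≥ 2 spikes per repetition, and
* a direction-label permutation test rejects at α = 0.05 (resultant-length
  statistic, 1000 seeded shuffles).

Population analyses include optic-disc alignment and temporal- vs
nasal-dorsal comparison (Kuiper two-sample), a previous-trial split that
quantifies desensitization, central-mask experiments that dissociate
desensitization from the inherent DS component, multi-speed tuning
(Friedman with Tukey–Kramer post hocs), full-field PSTH clustering, and
paired pharmacology-style comparisons. All circular statistics (Rao
spacing, Kuiper two-sample, one-sample mean-angle, common-median
multisample) use seeded Monte-Carlo / permutation nulls.

## Worked example

```python
from premotion import RetinaGeometry, RunConfig, run_screen
from premotion.simulate import (MovingBarProtocol, WhiteNoiseProtocol,
                                make_population, simulate_session)

geom = RetinaGeometry.rectangle(1600, 1600)          # recorded tissue, um
cells = make_population(24, seed=7, geometry=geom,   # 25% carry an
                        frac_az=0.25,                # activation zone
                        az_angle="random")
rec = simulate_session(
    cells,
    [WhiteNoiseProtocol(duration=150.0), MovingBarProtocol()],
    geom, seed=8)

res = run_screen(rec, RunConfig(), seed=9)           # STA -> gates -> tuning
hits = res.reports[res.reports["pre_asymmetric"]]
print(f"included {len(res.reports)} cells, "
      f"{len(hits)} with an asymmetric PRE response "
      f"({100 * res.pre_fraction:.1f}%)")
```

prints

```
included 24 cells, 6 with an asymmetric PRE response (25.0%)
```

— exactly the six cells that were simulated with an activation zone.
Their recovered preferred directions match the injected zone angles to a
few degrees, e.g. `c0001: PD 314.1 deg (true zone angle 314.5), mAI 0.49,
NVS 0.31, p 0.001, enhanced`: the zone adds spikes above baseline in the
PD approach epoch (`enhanced`), the contrast between PD and ND approach
responses is ~0.5, and the permutation test is at its floor
(p = 1/1001 ≈ 0.001).

The same pipeline runs from files (spike CSV + stimulus-log JSON +
geometry JSON) through the CLI:

```bash
premotion simulate --config sim.yaml --seed 3 --out rec/
premotion screen --from-sim rec/ --seed 4 --out report/
premotion stats rao angles.csv
```

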