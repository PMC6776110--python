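# porebiofilm

Quantification of multispecies biofilm architecture in porous fluidic
devices, for microbial ecologists and biofilm researchers working with
time-lapse transmitted-light imaging of grain/pore ("streambed-on-a-chip")
systems.

Biofilms growing around the grains of a porous landscape differentiate into
two architectures: an annular **base biofilm (BB)** coating each grain, and
elongated **streamers** protruding downstream into the pore space. This
package implements the full measurement and modelling chain for that
differentiation:

* **Segmentation** — background subtraction against the biofilm-free first
  frame, Otsu (or fixed) thresholding, grain exclusion, despeckling.
* **Architecture morphometrics** — BB identified by the ring rule (BB
  extends through the consecutive run of 10 µm annuli with ≥ 35% biomass
  coverage); thickness profiles at 0.1° steps; boundary perimeter `P_BB`
  and tortuosity `P_BB / 2π(r + h̄)`; streamers delineated by single-linkage
  merging of clusters closer than 45 µm, with length `L` (end-corrected
  skeleton graph diameter), width `W` (2 × mean EDT over the skeleton) and
  internal porosity.
* **Growth models** — logistic fits `y(t) = K / (1 + exp(−r(t − t0)))` of
  coverage/area series (statsmodels-style `LogisticGrowthModel.fit()` →
  results object with `summary()`); normalized carrying capacity `nK`;
  exponential-phase doubling time; plateau/overshoot detection.
* **Streamer filtration model** — `W(t) = 2βvCVt/π`, where β is the
  filtration efficiency, v the pore fluid velocity, C the bulk cell
  concentration and V the single-cell volume; forward prediction with an
  uncertainty band and β estimation from observed width series.
* **Oxygen time scales** — bulk uptake `T_u = [O₂]/(R·C)`, in-streamer
  uptake `T_us`, diffusion `T_d = L²/2D` and advection `T_a = L/v` over half
  a pore throat, with the oxygen-limitation verdict that explains the
  downstream BB gap.
* **Gap and net gain** — detection of the downstream thickness gap,
  gap-filling biomass `G`, and the net gain of architectural
  differentiation `(S − G)/(B + G) × 100` with a paired Wilcoxon
  signed-rank test.
* **Community statistics** — OTU-table rarefaction, Jaccard and Bray–Curtis
  similarity with bootstrap confidence intervals, shared/unique OTU
  accounting, and cross-architecture abundance correlation.
* **Synthetic data** — a ground-truthed generator of device geometries,
  time-lapse stacks and OTU tables so the whole pipeline can be exercised
  and validated without any external data.

## Worked example

Render the default desk-scale study (2 × 2 mm sub-domain at 5 µm/px, 4
grains, 23 frames over 220 h), quantify it, and fit the growth model:

```python
import porebiofilm as pb
from porebiofilm.growth import fit_logistic

geom = pb.desk_geometry()
scenario = pb.desk_scenario(seed=11)
stack, truth = pb.simulate_timelapse(geom, scenario)

images = pb.ImageStack(stack, scenario.times_h, geom.pixel_size_um)
masks = pb.binarize(pb.background_subtract(images), geom)
result = pb.quantify_stack(masks, geom)

print(fit_logistic(result["coverage"].time_h, 100 * result["coverage"].TB).summary())
```

```
Logistic growth fit  y(t) = K / (1 + exp(-r (t - t0)))
  n obs : 23    RSE : 0.3018
  K  = 8.51728  (se 0.0823)
  r  = 0.131705 1/h  (se 0.0119)
  t0 = 62.6907 h  (se 0.788)
```

Total biofilm coverage saturates at K ≈ 8.5% of the pore space with an
inflection at ≈ 63 h; the RSE is in coverage percentage points. At 220 h the
same run yields 8 streamers (two per grain) with mean length 0.613 mm, mean
width 0.0383 mm and internal biomass fraction 0.84, and a mean BB tortuosity
of 1.35 — the boundary is strongly fingered relative to a smooth annulus.

The oxygen time-scale report for the default parameters (respiration
1 fmol O₂ cell⁻¹ h⁻¹, 10⁷ cells ml⁻¹ bulk, 10% streamer cell volume
fraction, half-throat transport length 0.305 mm):

```python
from porebiofilm.oxygen import OxygenParams, compare_timescales
print(compare_timescales(OxygenParams()))
```

```
T_u  = 28 h (bulk uptake)
T_us = 10.1 s (in-streamer uptake)
T_d  = 22.1 s (diffusion; 2.20x T_us)
T_a  = 30.5 s (advection; 3.03x T_us)
verdict: oxygen-limited
```

Consumption inside the streamer-confined space outpaces both diffusive and
advective resupply by factors ≈ 2–3, which is why a BB gap opens downstream
of the grains.

A command-line interface mirrors the pipeline stages
(`porebiofilm simulate|quantify|model|community`, see `porebiofilm --help`).

## Layout

```
src/porebiofilm/
  synthgen.py      geometry, time-lapse and OTU-table generators + ground truth
  imgcore.py       stack I/O, background subtraction, binarisation
  architecture.py  BB/streamer partition and morphometrics
  growth.py        logistic model, nK, doubling time, plateau detection
  filtration.py    streamer width filtration model
  oxygen.py        oxygen time-scale analysis
  gap.py           gap detection, net gain, paired test
  community.py     OTU-table statistics
  cli.py           click-based command-line interface
docs/methods.md    model assumptions, conventions, and limitations
```
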