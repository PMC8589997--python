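# phasorflim

Label-free metabolic imaging reads the redox state of living tissue from
the autofluorescence decay kinetics of two cofactors: NAD(P)H and FAD.
Their fluorescence lifetimes shift on enzyme binding, so the **fraction of
bound cofactor** (*f*<sub>B</sub>) tracks the NAD(P)⁺/NAD(P)H and
FAD/FADH₂ redox ratios — *f*<sub>B</sub> NAD(P)H rises and
*f*<sub>B</sub> FAD falls under oxidative phosphorylation or oxidative
stress.  `phasorflim` is a tested, reusable implementation of the full
analysis chain used to quantify the UVA1 (longwave ultraviolet A)
stress response of reconstructed human skin with two-photon fluorescence
lifetime microscopy (FLIM):

* **TCSPC decay simulation** — two-channel time-resolved photon-count
  image stacks (24 temporal bins over a 12.48 ns laser period), with
  keratinocyte/fibroblast scene geometry, collagen bleed-through
  background, Poisson photon statistics, reference solutions, and planted
  condition × timepoint × dose effects with ground truth;
* **phasor analysis** — per pixel, the first-harmonic Fourier coordinates
  g = Σ I(t)cos(ωt)/ΣI, s = Σ I(t)sin(ωt)/ΣI (ω = 2π/12.48 rad/ns), so a
  mono-exponential of lifetime τ sits on the universal semicircle at
  g = 1/(1+(ωτ)²), s = ωτ·g;
* **reference calibration** — one complex factor fitted on SHG (0 ns) or
  fluorescein at pH 9 (4 ns) absorbs the IRF and TDC binning;
* **metabolic maps** — phase lifetime τ<sub>Φ</sub> = s/(gω), modulation
  lifetime τ<sub>M</sub> = ω⁻¹√(1/(g²+s²)−1), and *f*<sub>B</sub> from the
  phasor position between the free and bound anchors (free NAD(P)H 0.4 ns,
  free FAD 3 ns);
* **single-fibroblast segmentation** — a compact encoder-decoder pixel
  classifier on four aligned planes (two intensities + two τ<sub>Φ</sub>
  maps) with 0.5-probability threshold, 8-connected labeling and area
  filtering, plus a classical threshold fallback;
* **stress-response statistics** — per-ROI (basal layer) and per-cell
  (dermis) summaries as mean ± s.e.m., two-sided rank-sum contrasts with
  the ns/*/**/*** tiers, a machine-readable dynamics matrix of the
  *f*<sub>B</sub> time courses, and dose-response contrasts
  (25 vs 40 J/cm²).

The scientific model, parameter defaults, and numerical choices are
documented in [`docs/methods.md`](docs/methods.md).

## Worked example

```python
import numpy as np
import phasorflim as pf

meta = pf.AcquisitionMeta()                      # 12.48 ns period, 24 bins
cal = pf.calibrate_channels({"NADPH": meta})["NADPH"]

# recover the reference-solution lifetimes through the pipeline
for solution in ("free_NADPH", "free_FAD", "fluorescein"):
    stack = pf.simulate_reference(solution, noiseless=True, shape=(8, 8))
    ph = cal.transform(pf.phasor_transform(stack)["NADPH"])
    tau_phi, tau_mod = pf.lifetimes_from_phasor(ph)
    print(f"{solution:12s} tau_phi = {np.nanmean(tau_phi):.4f} ns, "
          f"tau_mod = {np.nanmean(tau_mod):.4f} ns")

# fraction of bound NAD(P)H of a noisy mixture, 1000 photons/px
model = pf.BiomarkerModel(tau_free=0.4, tau_bound=3.2, f_bound=0.3)
stack = pf.simulate_homogeneous(model, photons=1000, shape=(64, 64), seed=0)
ph = pf.smooth_phasor(cal.transform(pf.phasor_transform(stack)["NADPH"]))
fb = pf.fraction_bound(ph, pf.monoexp_phasor(0.4, meta.omega),
                       pf.monoexp_phasor(3.2, meta.omega))
print(f"recovered f_bound = {np.nanmean(fb):.4f} (truth 0.3000)")
```

prints

```
free_NADPH   tau_phi = 0.4000 ns, tau_mod = 0.4000 ns
free_FAD     tau_phi = 3.0000 ns, tau_mod = 3.0000 ns
fluorescein  tau_phi = 4.0000 ns, tau_mod = 4.0000 ns
recovered f_bound = 0.3002 (truth 0.3000)
```

The three solution lifetimes come back exactly after a single zero-lifetime
calibration — the binning/IRF factor is lifetime-independent by
construction — and the bound fraction of a shot-noise-limited mixture is
recovered to ~2 × 10⁻⁴ after 3×3 median smoothing of the phasor
coordinates.  τ<sub>Φ</sub> = τ<sub>M</sub> confirms the inputs are
mono-exponential.

A full synthetic study (simulate → phasor → segment → analyze) runs from
the shell:

```sh
phasorflim study --seed 0 --out study_out/
```

and prints the per-(layer, biomarker, condition, timepoint) dynamics
matrix; with the default planted effects, fibroblast *f*<sub>B</sub>
NAD(P)H is significantly up already 30 min post exposure, keratinocytes
respond only at 2 h, *f*<sub>B</sub> FAD is down from 30 min in both
layers, and the control and sunscreen arms stay null.

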