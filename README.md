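# memgp — membrane lipid-order imaging analysis

`memgp` quantifies lipid packing and optical resolution in confocal and
STED (stimulated emission depletion) images of membranes stained with
polarity-sensitive probes (Laurdan, Di-4-ANEPPDHQ, Di-4-AN(F)EPPTEA,
NR12S and relatives).  It is written for microscopists who record
two-channel, λ-stack, or time-series TIFFs of giant plasma-membrane
vesicles (GPMVs), live cells, or single virions and want reproducible,
scriptable versions of the standard analyses:

* **Generalized polarization (GP) mapping** — the pixel-wise lipid-order
  index

  `GP = (I₁ − I₂) / (I₁ + I₂)`

  with I₁ the ordered (blue-shifted, 520–570 nm) and I₂ the disordered
  (red-shifted, 620–700 nm) detection channel; GP runs from +1
  (maximally ordered) to −1 (maximally disordered).  Includes background
  masking, per-ROI statistics, interdomain differences, and the
  red-to-blue GP rendering.
* **Contour-perpendicular FWHM profiling** — resample a membrane contour
  every 3 px, draw 40-px perpendicular lines, fit Gaussians, and report
  FWHM = 2√(2 ln 2)·σ.  Since a bilayer (≈8 nm) is far below optical
  resolution, the mean membrane FWHM estimates the effective PSF, and
  the confocal/STED ratio of means is the resolution gain.
* **λ-stack spectral analysis** — per-ROI emission spectra from 9-nm
  spectral windows, peak positions with parabolic refinement, the
  ordered/disordered peak shift, per-window phase intensity ratios, and
  two-band recombination (e.g. separating GFP at 500–530 nm from a
  membrane probe at 570–691 nm).
* **Photostability** — membrane-ROI intensity over sequential frames
  normalised to the first frame, fractional loss after N frames, and a
  one-parameter geometric decay fit.
* **Synthetic phantoms** — a fully ground-truthed generator of membrane
  rings, phase arcs, sub-resolution discs, λ-stacks and bleaching series
  under Gaussian PSFs (confocal 240 nm / STED 80 nm presets) with
  Poisson noise, used by the test-suite recovery checks and usable for
  power analysis of your own designs.

## Worked example

Render a STED phantom of a phase-separated vesicle carrying a 500-nm
disordered nanodomain (true GP −0.19 in a +0.08 surround) and recover
both from the GP map:

```python
from memgp import preset, render_phantom
from memgp.gp_mapping import gp_pipeline

spec = preset("fig5-nanodomain", mode="sted", seed=7)
stack, truth, rois = render_phantom(spec)
gp_map, stats = gp_pipeline(stack, rois, roi_labels=["domain", "surround"])
for s in stats:
    print(f"{s.label}: GP = {s.mean_gp:+.3f} ± {s.sd_gp:.3f} "
          f"(truth {truth.gp_true[s.label]:+.3f})")
```

prints

```
domain: GP = -0.176 ± 0.095 (truth -0.190)
surround: GP = +0.061 ± 0.098 (truth +0.080)
```

i.e. the domain's lower lipid order is recovered within the pixel shot
noise; under the confocal preset the same domain's GP magnitude is
systematically diluted toward its surround — the reason sub-diffraction
imaging is needed for nanodomain GP at all.

The same workflows run from the shell:

```sh
memgp simulate --preset fig5-nanodomain --mode sted --seed 7 --out sim/
memgp gpmap --image sim/phantom.tif --roi sim/phantom.rois.json --out gp/
memgp fwhm --image sim/phantom.tif --roi sim/phantom.rois.json --out fwhm/
memgp spectra --stack sim/phantom.tif --roi sim/phantom.rois.json --out spec/
memgp bleach --stack sim/phantom.tif --roi sim/phantom.rois.json --out bleach/
```

Each subcommand writes a results CSV plus a run-parameters JSON and is
bit-reproducible under a fixed seed.

## The analysis scripts

`analysis/` contains numbered narrative drivers, each writing its tables
under `results/`:

| script | what it shows |
| --- | --- |
| `01_simulate_phantoms.py` | renders one of each phantom preset with its ground truth |
| `02_fwhm_resolution.py` | confocal 240.0 ± 9.9 nm vs STED 81.2 ± 2.7 nm → ratio 2.96 |
| `03_gp_maps.py` | nanodomain/endosome GP recovery, confocal vs STED |
| `04_spectra.py` | 39.8-nm ordered→disordered peak shift; GFP/probe band separation |
| `05_photostability.py` | 20.8% signal loss over 20 frames; fitted survival 0.9868 |

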