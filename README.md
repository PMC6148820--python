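# rvseg

Semi-automatic right-ventricle (RV) segmentation for short-axis cine cardiac
MR, with the surrounding measurement science: ventricular volumetry,
contour-agreement metrics, observer-study statistics, and a fully synthetic
cine phantom with analytic ground truth for end-to-end validation.

## What it does

Manual delineation of the RV endocardium on every slice and phase of a cine
stack is slow and observer-dependent; the RV's crescent shape and thin wall
make automatic segmentation hard. `rvseg` takes a middle road: the user (or a
script) supplies one rough seed contour inside the RV blood pool on a single
mid-ventricular slice per cardiac phase, and the tool does the rest:

1. **Cellular-automaton refinement** (`rvseg.automaton`). The seed interior
   becomes foreground, the image border plus temporally static pixels far
   from the seed become background, and labels then compete: each labeled
   pixel attacks its 8 neighbours with a strength attenuated by intensity
   dissimilarity, and a pixel is conquered when the attack exceeds its
   current strength. Iterated synchronously to a fixpoint, this grows the
   seed to the blood-pool boundary.
2. **Inter-slice propagation** (`rvseg.propagation`). Each refined contour
   seeds its neighbour slice, after a joint integer-shift / isotropic-scale
   search (scored by normalized cross-correlation in a window around the
   contour) compensates breath-hold misalignment between slices and the
   shrink-and-drift of the ventricle toward the apex. Slices whose refined
   region collapses below a minimum area are omitted with a warning.
   Optionally the RV contour is attached to a left-ventricle epicardial
   contour along the septum (`attach_to_lv`).
3. **Volumetry** (`rvseg.volumetrics`). Simpson's rule: per-slice contour
   areas × (slice thickness + gap), summed over the ventricular slices at
   end-diastole (ED) and end-systole (ES); ejection fraction
   EF = (EDV − ESV)/EDV × 100.
4. **Evaluation** (`rvseg.contour_metrics`, `rvseg.agreement`). Dice overlap
   on rasterized masks and Hausdorff distance in mm between contours;
   Bland–Altman limits of agreement, Wilcoxon signed-rank tests and linear
   fits for inter-/intra-observer protocols.
5. **Synthetic phantom** (`rvseg.phantom`). An SSFP-like cine stack with a
   two-disc left ventricle and a circular-lune RV blood pool that contracts
   through the cycle and tapers to the apex, with per-slice misalignment,
   noise, exact polygonal ground-truth contours and closed-form volumes.

Everything is importable; a thin `rvseg` CLI wraps the common workflows
(`phantom`, `segment`, `volumes`, `metrics`, `agree`, `e2e`).

## Worked example

```python
from rvseg.phantom import PhantomSpec, generate_phantom, perturb_seed
from rvseg.pipeline import middle_slice, segment_study
from rvseg.volumetrics import volumes_from_contours

ds = generate_phantom(PhantomSpec(rng_seed=7))
ann = ds.annotations

seeds = {}
for i, phase_name in enumerate(("ed", "es")):
    phase = ann.phase_index(phase_name)
    sl = middle_slice(ann, phase_name)
    truth = ds.truth.get(phase, sl, "rv_endo")
    seeds[phase] = (perturb_seed(truth, 2.0, 100 + i, ds.spec.pixel_spacing_mm), sl)

contours = segment_study(ds.stack, ann, seeds)
vols = volumes_from_contours(contours, ann)
print(vols.ed_volume_ml, vols.es_volume_ml, vols.ef_percent)
```

prints `166.2 mL, 74.6 mL, 55.1 %` against ground truth
`166.6 mL, 75.0 mL, 55.0 %` — per-slice Dice vs truth is 0.997–1.000 on all
16 segmented slices (see `examples/03_full_segmentation_and_volumes.py`).
The `examples/` directory holds one narrative script per capability.

Command-line equivalent of the whole study:

```bash
rvseg e2e --subjects 3 --seed 7 --out scratch/demo
```

## Layout

- `src/rvseg/` — the library (`io_formats`, `phantom`, `automaton`,
  `propagation`, `volumetrics`, `contour_metrics`, `agreement`, `pipeline`,
  `cli`)
- `examples/` — runnable narrative scripts
- `tests/` — unit, property-based and end-to-end suites with independent
  oracles
- `docs/methods.md` — model, parameters, numerical choices and limitations
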