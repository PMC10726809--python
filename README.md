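# mitomorph

Quantitative analytics for studies of mitochondrial structure and function
across aging cohorts: 3D morphometry of serial-section electron-microscopy
label volumes, 2D TEM cross-section metrics with a cristae-integrity score,
cohort statistics, ∆∆Ct qPCR quantification, mito-stress-test oxygen
consumption summaries, and lipidomics differential abundance with lipid-set
enrichment. A first-class synthetic-data module generates every input the
pipeline consumes — voxel phantoms, young/aged cohorts, TEM scenes, qPCR
plates, OCR traces, lipid tables — with known ground truth, so every
estimator can be validated end to end.

## Who this is for

Groups quantifying mitochondrial morphology from segmented serial
block-face SEM stacks (one integer label per mitochondrion, anisotropic
voxel spacing, e.g. 10×10×50 nm) and pairing that morphometry with the
standard companion assays of an aging or knockout study: RT-qPCR fold
changes, Seahorse-style extracellular-flux stress tests, and shotgun
lipidomics.

## The quantities at the core

For a mitochondrion of volume *V* (µm³) and surface area *SA* (µm²):

- **sphericity** Ψ = π^⅓ (6V)^⅔ / SA — equals 1 for a sphere, falls with
  elongation and branching;
- **mitochondrial complexity index** MCI = SA³ / (16π² V²) — scale-invariant
  and rising with shape complexity (a sphere scores 9/4π ≈ 0.716); a
  sphere-normalized variant SA³/(36π V²) = Ψ⁻³ is also provided;
- volume is exact voxel counting; surface area comes from an anti-aliased
  marching-cubes isosurface honoring the anisotropic spacing; perimeter is
  the mean per-slice exposed-boundary length; 3D length is the maximal
  Feret diameter.

Companion stages: the 0–4 ordinal cristae score; per-animal aggregation
with unpaired *t*, exact Mann–Whitney, one-way ANOVA + Fisher's protected
LSD, and the `*`/`**`/`***`/`****` star convention; fold change =
2^(−∆∆Ct); OCR decomposition into non-mitochondrial, basal, ATP-linked,
proton-leak, maximal and reserve respiration; moderated-*t* differential
lipid abundance with BH-FDR and a GSEA-style permutation lipid-set
enrichment over class and chain-length sets.

## Worked example

Measure a rasterized sphere phantom (radius 0.5 µm) at the acquisition
spacing and check the estimators against the closed forms:

```python
from mitomorph.synthetic import make_phantom
from mitomorph.morphometry3d import measure_object

vol, truth = make_phantom("sphere", {"r_nm": 500.0})
rec = measure_object(vol, 1)
print(f"volume    {rec.volume_um3:.6f} um^3 (analytic {truth.volume_um3:.6f})")
print(f"surface   {rec.surface_um2:.6f} um^2 (analytic {truth.surface_um2:.6f})")
print(f"sphericity {rec.sphericity:.4f}   MCI {rec.mci:.4f}")
```

prints

```
volume    0.521575 um^3 (analytic 0.523599)
surface   3.150817 um^2 (analytic 3.141593)
sphericity 0.9945   MCI 0.7281
```

— volume within 0.4% of 4/3·πr³, surface within 0.3% of 4πr², sphericity
within half a percent of the spherical maximum 1, MCI within 2% of 9/4π.

A ∆∆Ct example: a simulated plate with a true 4-fold induction,

```python
from mitomorph.synthetic import make_qpcr
from mitomorph.qpcr import ddct

plate = make_qpcr({"myGene": 4.0}, ct_noise_sd=0.0)
r = ddct(plate, "myGene", "reference", "control", "experimental")
print(r.ddct, r.fold_change)   # -2.0 4.0
```

The same functions drive the CLI: `mitomorph simulate`, `mitomorph
morph3d`, `mitomorph qpcr`, `mitomorph ocr summarize`, `mitomorph lipids
de|lsea`.

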