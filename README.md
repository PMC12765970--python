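# ligaquant

Bio-compositional and microstructural analysis of knee collateral
ligament sections, for researchers studying how joint injury remodels
connective tissue.  The package implements two measurement chains and
the statistics to compare their outcomes between experimental groups:

* **FTIR microspectroscopy** — per-pixel infrared absorbance spectra
  are masked (Otsu on mean intensity), denoised (Savitzky–Golay,
  order 2, window 21), corrected for Mie scattering with an iterative
  extended multiplicative signal correction whose interferent subspace
  is spanned by principal components of van de Hulst extinction curves
  (ME-EMSC, 99.99% explained variance, ≤45 iterations, RMSE-based
  pixel rejection at 0.05 a.u.), and quantified as integrated band
  areas (AUC) above a local chord baseline: amide I/II/B, 1450, 1334,
  1234 and 2919 cm⁻¹ collagen bands and the 1000–1184 cm⁻¹
  carbohydrate (proteoglycan) region.
* **qPLM crimp morphometry** — slow-axis azimuth images give the local
  collagen fiber direction.  Angles are folded to [0°, 90°] about the
  ligament long axis; within retardance-ranked ROIs a signed
  orientation profile is split into ascending/descending limbs at zero
  crossings, giving the crimp angle θ = ½(φ_up + φ_down) and the crimp
  length (mean valley-to-valley distance).
* **Group comparison** — REML linear mixed models (ligament and group
  fixed, random intercepts per animal, optional knee-within-animal;
  natural-log transform for morphometrics), estimated marginal means,
  and pairwise contrasts with Satterthwaite degrees of freedom and
  Tukey familywise adjustment.

Because raw images from such studies are rarely shared, the package
includes a first-class synthetic phantom generator (`ligaquant.synth`)
that emulates both modalities with known ground truth — collagen-like
band structure, scattering baselines, periodic fiber-orientation waves,
an emulated 39-ligament study design — so every stage is validated by
parameter recovery.  See `docs/methods.md` for the model details.

## Worked example

Recover crimp morphometry from a noisy synthetic orientation image
(`examples/04_crimp_morphometry.py`):

```python
from ligaquant import sample_crimp_summary
from ligaquant.synth import PhantomSpecQPLM, generate_qplm_phantom

spec = PhantomSpecQPLM(
    crimp_angle_true=22.2,    # degrees
    crimp_length_true=153.1,  # micrometres
    orientation_noise_sd=2.0, # degrees of azimuth noise
    seed=1,
)
image, truth = generate_qplm_phantom(spec)
m = sample_crimp_summary(image)
```

This prints:

```
accepted ROIs: 5
crimp angle   true  22.20 deg  recovered  22.20 deg
crimp length  true  153.1 um   recovered  153.5 um
mean fiber angle (normalized, 0-90 deg): 22.20 (true 22.20)
```

The phantom's angle signal alternates between ±22.2° with a 153.1 µm
period plus 2° of noise; the pipeline recovers the crimp angle to
0.01° and the length to 0.3% — the measurement chain is effectively
transparent at this noise level.  The FTIR counterpart
(`examples/03_ftir_pipeline.py`) runs the full spectral chain on a
scatter-distorted 64×64 cube and recovers all eight band means within
2.3%.

Other examples: `01_synthetic_spectrum.py` (forward model),
`02_mie_correction.py` (ME-EMSC round trip), `05_group_comparison.py`
(mixed model on the emulated design), `06_full_study.py` (end-to-end
study).  The same stages are scriptable from the shell:

```bash
ligaquant all --out study_dir --seed 5 --force
```

which writes HDF5 cubes, orientation TIFFs, per-sample outcome tables,
marginal-mean/contrast CSVs, annotated boxplots and per-stage run
manifests.

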