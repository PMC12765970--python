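"""Recover band means from a noisy, scatter-distorted FTIR phantom.

A 64 x 64 hyperspectral cube is generated with per-pixel band areas set
to the surgically-destabilised group means, 5% lognormal pixel
jitter, a 0.3 Mie extinction mixture, and absorbance noise.  The full
chain — Otsu tissue mask, Savitzky-Golay 2/21 denoising, ME-EMSC,
RMSE-based pixel rejection, chord baseline, trapezoidal band
integration — recovers each configured mean to within a few percent,
which is the parameter-recovery check the phantom design exists for.
"""

from ligaquant.pipeline import run_ftir_sample
from ligaquant.synth import (
    MieDistortionParams,
    PhantomSpecFTIR,
    generate_ftir_phantom,
)

spec = PhantomSpecFTIR(
    grid=(64, 64),
    noise_sd=0.005,
    mie=MieDistortionParams(mixing_weight=0.3),
    seed=6,
)
cube, truth = generate_ftir_phantom(spec, group="ACLT")
means, counts = run_ftir_sample(cube)

print(
    f"tissue pixels {counts['pixels_tissue']}, rejected "
    f"{counts['pixels_rejected']}, analysed {counts['pixels_final']}\n"
)
print(f"{'band':14s} {'true':>8s} {'recovered':>10s} {'error':>8s}")
for name, true_area in truth.band_areas.items():
    rec = means[name]
    print(f"{name:14s} {true_area:8.2f} {rec:10.2f} {rec / true_area - 1:+8.2%}")
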