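"""Distort a spectrum with Mie scattering and undo it with ME-EMSC.

A van de Hulst extinction curve (sphere diameter 5 um, refractive index
1.3) is mixed into the pure spectrum at weight 0.3, emulating the
oscillatory baseline that scattering from cell-scale structures imprints
on infrared microspectra.  The iterative extended multiplicative signal
correction projects the distorted spectrum onto a principal-component
subspace of extinction curves and removes it.  The printed band areas
show the distortion pushing integrals off-truth and the correction
restoring them to within a few percent.
"""

from ligaquant import (
    MEEMSCConfig,
    MieDistortionParams,
    apply_mie_distortion,
    band_auc,
    build_spectrum,
    collagen_like_peaks,
    default_bands,
    me_emsc_correct,
    wavenumber_axis,
)

axis = wavenumber_axis()
pure = build_spectrum(collagen_like_peaks(), axis=axis)
distorted = apply_mie_distortion(pure, MieDistortionParams(mixing_weight=0.3), axis)

result = me_emsc_correct(distorted, MEEMSCConfig(reference_spectrum=pure), axis)
print(
    f"correction converged={result.converged} after {result.n_iterations} "
    f"iteration(s), fit RMSE {result.rmse:.2e} a.u.\n"
)
print(f"{'band':14s} {'true':>8s} {'distorted':>10s} {'corrected':>10s}")
for band in default_bands():
    t = band_auc(pure, band, axis).value
    d = band_auc(distorted, band, axis).value
    c = band_auc(result.corrected, band, axis).value
    print(f"{band.name:14s} {t:8.2f} {d:10.2f} {c:10.2f}")
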