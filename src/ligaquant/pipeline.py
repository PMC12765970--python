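"""Configuration-driven orchestration of the full analysis.

The four stages mirror how the measurements are processed in practice:

* ``cmd_synth``  — write a phantom study (FTIR cubes, orientation
  images, metadata and ground-truth tables) for a configurable design.
* ``cmd_ftir``   — tissue mask, Savitzky-Golay denoising, ME-EMSC,
  RMSE-based pixel rejection, band integration, per-sample means.
* ``cmd_qplm``   — orientation normalization, ROI selection, crimp
  detection, per-sample summaries.
* ``cmd_stats``  — mixed-model group comparison with marginal means,
  pairwise contrasts and annotated boxplots.

Every run emits a manifest with per-stage record counts so pixel and
ROI attrition stay auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .ftir_preprocess import (
    HyperspectralCube,
    MEEMSCConfig,
    SGConfig,
    build_tissue_mask,
    correct_cube,
    quality_filter,
    sg_denoise,
)
from .ftir_quantify import sample_mean_auc
from .qplm_crimp import CrimpConfig, sample_crimp_summary
from .spectra import GROUP_AREAS
from .stats_compare import (
    LMESpec,
    estimated_marginal_means,
    fit_lme,
    pairwise_posthoc,
    significance_stars,
)
from .synth import (
    MieDistortionParams,
    PhantomSpecFTIR,
    PhantomSpecQPLM,
    generate_ftir_phantom,
    generate_qplm_phantom,
    study_design,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_ftir_sample",
    "cmd_synth",
    "cmd_ftir",
    "cmd_qplm",
    "cmd_stats",
    "GROUP_QPLM_PARAMS",
]

#: default (group, ligament) ground-truth crimp parameters of the
#: phantom study: crimp angle (deg), crimp length (um), fiber tilt (deg)
GROUP_QPLM_PARAMS: dict[tuple[str, str], dict[str, float]] = {
    ("ACLT", "MCL"): {"crimp_angle": 22.2, "crimp_length": 153.1, "fiber_tilt": 15.8},
    ("ACLT", "LCL"): {"crimp_angle": 18.8, "crimp_length": 153.1, "fiber_tilt": 15.8},
    ("contralateral", "MCL"): {
        "crimp_angle": 7.4,
        "crimp_length": 107.2,
        "fiber_tilt": 11.6,
    },
    ("contralateral", "LCL"): {
        "crimp_angle": 8.1,
        "crimp_length": 107.2,
        "fiber_tilt": 11.6,
    },
    ("control", "MCL"): {"crimp_angle": 15.2, "crimp_length": 97.3, "fiber_tilt": 7.9},
    ("control", "LCL"): {"crimp_angle": 15.2, "crimp_length": 97.3, "fiber_tilt": 7.9},
}


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end run, serializable to YAML."""

    out_dir: str = "ligaquant_run"
    seed: int = 0
    n_aclt_animals: int = 6
    n_control_animals: int = 4
    ftir_grid: tuple[int, int] = (64, 64)
    qplm_grid: tuple[int, int] = (640, 640)
    noise_sd: float = 0.005
    area_jitter_sd: float = 0.05
    mie_mixing: float = 0.3
    orientation_noise_sd: float = 2.0
    # biological variance of the phantom study: multiplicative lognormal
    # factors shared per animal / drawn per sample, so the mixed model
    # has real between-animal structure to estimate.  The FTIR sds sit
    # near the printed group scatter (~3%); the crimp sds mirror the
    # much wider morphometric scatter (~10-15% on the log scale).
    ftir_animal_sd: float = 0.02
    ftir_sample_sd: float = 0.03
    qplm_animal_sd: float = 0.10
    qplm_sample_sd: float = 0.15
    sg: SGConfig = field(default_factory=SGConfig)
    meemsc: MEEMSCConfig = field(default_factory=MEEMSCConfig)
    rmse_cap: float = 0.05
    crimp: CrimpConfig = field(default_factory=CrimpConfig)
    posthoc_adjust: str = "tukey"

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "n_aclt_animals": self.n_aclt_animals,
            "n_control_animals": self.n_control_animals,
            "ftir_grid": list(self.ftir_grid),
            "qplm_grid": list(self.qplm_grid),
            "noise_sd": self.noise_sd,
            "area_jitter_sd": self.area_jitter_sd,
            "mie_mixing": self.mie_mixing,
            "orientation_noise_sd": self.orientation_noise_sd,
            "ftir_animal_sd": self.ftir_animal_sd,
            "ftir_sample_sd": self.ftir_sample_sd,
            "qplm_animal_sd": self.qplm_animal_sd,
            "qplm_sample_sd": self.qplm_sample_sd,
            "sg": {"poly_order": self.sg.poly_order, "window_length": self.sg.window_length},
            "meemsc": {
                "explained_variance_target": self.meemsc.explained_variance_target,
                "max_iterations": self.meemsc.max_iterations,
                "rmse_stop": self.meemsc.rmse_stop,
                "n_grid": list(self.meemsc.n_grid),
                "d_grid": list(self.meemsc.d_grid),
                "weight_region": list(self.meemsc.weight_region),
            },
            "rmse_cap": self.rmse_cap,
            "crimp": asdict(self.crimp),
            "posthoc_adjust": self.posthoc_adjust,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        sg = SGConfig(**doc.pop("sg", {}))
        me = doc.pop("meemsc", {})
        for key in ("n_grid", "d_grid", "weight_region"):
            if key in me:
                me[key] = tuple(me[key])
        meemsc = MEEMSCConfig(**me)
        crimp = CrimpConfig(**doc.pop("crimp", {}))
        for key in ("ftir_grid", "qplm_grid"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(sg=sg, meemsc=meemsc, crimp=crimp, **doc)


@dataclass
class RunManifest:
    """Auditable record of one pipeline stage."""

    stage: str
    config_hash: str
    counts: dict[str, int] = field(default_factory=dict)
    started: float = field(default_factory=time.time)

    def write(self, out_dir: str | Path) -> Path:
        from importlib.metadata import PackageNotFoundError, version

        try:
            ver = version("ligaquant")
        except PackageNotFoundError:
            ver = "unknown"
        doc = {
            "stage": self.stage,
            "config_hash": self.config_hash,
            "package_version": ver,
            "counts": self.counts,
            "started": self.started,
            "finished": time.time(),
        }
        path = Path(out_dir) / f"manifest_{self.stage}.json"
        path.write_text(json.dumps(doc, indent=2))
        return path


def _config_hash(config: PipelineConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stage: synth
# ---------------------------------------------------------------------------


def cmd_synth(config: PipelineConfig, force: bool = False) -> pd.DataFrame:
    """Write the phantom study to ``out_dir`` and return its metadata."""
    out = Path(config.out_dir)
    meta_path = out / "metadata.csv"
    if meta_path.exists() and not force:
        raise FileExistsError(f"{meta_path} exists; pass force=True to overwrite")
    (out / "ftir").mkdir(parents=True, exist_ok=True)
    (out / "qplm").mkdir(parents=True, exist_ok=True)

    meta = study_design(config.n_aclt_animals, config.n_control_animals)
    bio_rng = np.random.default_rng((config.seed * 99991 + 17) % (2**31))

    def _lognormal(rng, sd):
        if sd <= 0:
            return 1.0
        sigma = np.sqrt(np.log(1.0 + sd**2))
        return float(rng.lognormal(-0.5 * sigma**2, sigma))

    from dataclasses import replace as _replace

    from .spectra import build_spectrum, collagen_like_peaks, default_group_peaks
    from .spectra import wavenumber_axis as _wavenumber_axis

    base_peaks = default_group_peaks()
    band_names = sorted(
        {("carbohydrate" if p.name.startswith("carb") else p.name) for p in
         base_peaks["control"]}
    )
    # animal-level factors shared by all samples of one animal
    animal_factors = {
        a: {
            "bands": {b: _lognormal(bio_rng, config.ftir_animal_sd) for b in band_names},
            "angle": _lognormal(bio_rng, config.qplm_animal_sd),
            "length": _lognormal(bio_rng, config.qplm_animal_sd),
        }
        for a in meta["animal_id"].unique()
    }

    # the iterative scatter correction normalises every pixel to the
    # reference amplitude, so a global per-sample scale (section
    # thickness) would be removed by design.  Biological variation is
    # therefore injected as per-band compositional factors and each
    # sample is renormalised to unit EMSC-visible amplitude.
    axis = _wavenumber_axis()
    ref = build_spectrum(collagen_like_peaks(), axis=axis)
    wsel = (axis >= 1000.0) & (axis <= 4000.0)
    ref_w = ref[wsel]
    ref_norm = float(ref_w @ ref_w)

    def _compositional_peaks(group: str, factors: dict[str, float]):
        scaled = [
            _replace(
                p,
                area=p.area
                * factors["carbohydrate" if p.name.startswith("carb") else p.name],
            )
            for p in base_peaks[group]
        ]
        s = build_spectrum(scaled, axis=axis)
        kappa = float(s[wsel] @ ref_w) / ref_norm
        return [_replace(p, area=p.area / kappa) for p in scaled]

    truth_rows = []
    for idx, row in meta.iterrows():
        seed = (config.seed * 100003 + idx) % (2**31)
        af = animal_factors[row["animal_id"]]
        factors = {
            b: af["bands"][b] * _lognormal(bio_rng, config.ftir_sample_sd)
            for b in band_names
        }
        peaks = {row["group"]: _compositional_peaks(row["group"], factors)}
        ftir_spec = PhantomSpecFTIR(
            grid=config.ftir_grid,
            peaks_by_group=peaks,
            noise_sd=config.noise_sd,
            area_jitter_sd=config.area_jitter_sd,
            mie=MieDistortionParams(mixing_weight=config.mie_mixing),
            seed=seed,
        )
        cube, ftruth = generate_ftir_phantom(ftir_spec, group=row["group"])
        lio.write_cube(out / "ftir" / f"{row['sample_id']}.h5", cube, ftruth)

        qp = GROUP_QPLM_PARAMS[(row["group"], row["ligament"])]
        qplm_spec = PhantomSpecQPLM(
            grid=config.qplm_grid,
            crimp_angle_true=min(
                qp["crimp_angle"] * af["angle"] * _lognormal(bio_rng, config.qplm_sample_sd),
                89.0,
            ),
            crimp_length_true=qp["crimp_length"]
            * af["length"]
            * _lognormal(bio_rng, config.qplm_sample_sd),
            fiber_tilt=qp["fiber_tilt"],
            orientation_noise_sd=config.orientation_noise_sd,
            seed=seed,
        )
        image, qtruth = generate_qplm_phantom(qplm_spec)
        lio.write_orientation(out / "qplm" / f"{row['sample_id']}.tif", image)
        truth_rows.append(
            {
                "sample_id": row["sample_id"],
                **{f"true_{k}": v for k, v in ftruth.band_areas.items()},
                "true_crimp_angle": qtruth.crimp_angle_true,
                "true_crimp_length": qtruth.crimp_length_true,
                "true_mean_fiber_angle": qtruth.mean_fiber_angle_true,
            }
        )
    meta.to_csv(meta_path, index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    manifest = RunManifest("synth", _config_hash(config))
    manifest.counts = {"samples": len(meta)}
    manifest.write(out)
    return meta


# ---------------------------------------------------------------------------
# stage: ftir
# ---------------------------------------------------------------------------


def run_ftir_sample(
    cube: HyperspectralCube,
    sg: SGConfig = SGConfig(),
    meemsc: MEEMSCConfig | None = None,
    rmse_cap: float = 0.05,
    bands=None,
) -> tuple[pd.Series, dict[str, int]]:
    """Full FTIR chain for one cube: mask, denoise, ME-EMSC, quality
    filter, band integration.  Returns the per-band means and the
    attrition counts (pixels masked / rejected)."""
    meemsc = MEEMSCConfig() if meemsc is None else meemsc
    mask = build_tissue_mask(cube)
    denoised = HyperspectralCube(
        wavenumbers=cube.wavenumbers,
        absorbance=sg_denoise(cube.absorbance, sg),
        pixel_step=cube.pixel_step,
        mask=mask,
    )
    # process the reference through the same smoothing as the data so
    # the EMSC fit compares like with like
    ref = meemsc.resolve_reference(cube.wavenumbers)
    meemsc_run = MEEMSCConfig(
        reference_spectrum=sg_denoise(ref, sg),
        explained_variance_target=meemsc.explained_variance_target,
        max_iterations=meemsc.max_iterations,
        rmse_stop=meemsc.rmse_stop,
        n_grid=meemsc.n_grid,
        d_grid=meemsc.d_grid,
        weight_region=meemsc.weight_region,
        weights=meemsc.weights,
    )
    corrected, diag = correct_cube(denoised, meemsc_run)
    final_mask = quality_filter(diag, mask, rmse_cap)
    means = sample_mean_auc(corrected, bands, final_mask)
    counts = {
        "pixels_total": int(np.prod(cube.shape)),
        "pixels_tissue": int(mask.sum()),
        "pixels_rejected": int(mask.sum() - final_mask.sum()),
        "pixels_final": int(final_mask.sum()),
    }
    return means, counts


def cmd_ftir(config: PipelineConfig) -> pd.DataFrame:
    """Run the FTIR chain on every cube of a phantom study directory."""
    out = Path(config.out_dir)
    meta = pd.read_csv(out / "metadata.csv")
    rows = []
    counts_total = {"pixels_tissue": 0, "pixels_rejected": 0}
    for _, row in meta.iterrows():
        cube = lio.read_cube(out / "ftir" / f"{row['sample_id']}.h5")
        means, counts = run_ftir_sample(
            cube, config.sg, config.meemsc, config.rmse_cap
        )
        counts_total["pixels_tissue"] += counts["pixels_tissue"]
        counts_total["pixels_rejected"] += counts["pixels_rejected"]
        rows.append({"sample_id": row["sample_id"], **means.to_dict()})
    table = meta.merge(pd.DataFrame(rows), on="sample_id")
    table.to_csv(out / "ftir_bands.csv", index=False)
    manifest = RunManifest("ftir", _config_hash(config))
    manifest.counts = {"samples": len(table), **counts_total}
    manifest.write(out)
    return table


# ---------------------------------------------------------------------------
# stage: qplm
# ---------------------------------------------------------------------------


def qc_overlay(image, measurement, path) -> None:
    """QC figure: normalized-orientation image with accepted ROI boxes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    from .qplm_crimp import normalize_orientation

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(normalize_orientation(image), cmap="twilight", vmin=0, vmax=90)
    for rec in measurement.per_roi:
        roi = rec["roi"]
        ax.add_patch(
            Rectangle(
                (roi.col, roi.row), roi.width, roi.height,
                fill=False, edgecolor="lime", linewidth=1.2,
            )
        )
    fig.colorbar(im, ax=ax, shrink=0.8, label="fiber angle (deg)")
    ax.set_title(
        f"theta={measurement.theta:.1f} deg, "
        f"L={measurement.crimp_length:.0f} um, n_rois={measurement.n_rois}"
    )
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def cmd_qplm(config: PipelineConfig, overlays: bool = False) -> pd.DataFrame:
    """Run the crimp chain on every orientation image of a study."""
    out = Path(config.out_dir)
    meta = pd.read_csv(out / "metadata.csv")
    rows = []
    n_rois_accepted = 0
    for _, row in meta.iterrows():
        image = lio.read_orientation(out / "qplm" / f"{row['sample_id']}.tif")
        m = sample_crimp_summary(image, config.crimp)
        if overlays:
            (out / "qc").mkdir(exist_ok=True)
            qc_overlay(image, m, out / "qc" / f"{row['sample_id']}.png")
        n_rois_accepted += m.n_rois
        rows.append(
            {
                "sample_id": row["sample_id"],
                "theta_deg": m.theta,
                "crimp_length_um": m.crimp_length,
                "mean_fiber_angle_deg": m.mean_fiber_angle,
                "n_rois": m.n_rois,
                "excluded": m.excluded,
            }
        )
    table = meta.merge(pd.DataFrame(rows), on="sample_id")
    table.to_csv(out / "qplm_crimp.csv", index=False)
    manifest = RunManifest("qplm", _config_hash(config))
    manifest.counts = {
        "samples": len(table),
        "rois_accepted": n_rois_accepted,
        "samples_excluded": int(table["excluded"].sum()),
    }
    manifest.write(out)
    return table


# ---------------------------------------------------------------------------
# stage: stats
# ---------------------------------------------------------------------------

FTIR_OUTCOMES = list(GROUP_AREAS["control"].keys()) + ["amide_II", "p2919"]
QPLM_OUTCOMES = ["theta_deg", "crimp_length_um", "mean_fiber_angle_deg"]


def _specs_for(columns: list[str]) -> list[LMESpec]:
    specs = []
    for col in columns:
        if col in QPLM_OUTCOMES:
            specs.append(
                LMESpec(col, interaction=True, random="animal", transform="natural_log")
            )
        else:
            specs.append(LMESpec(col, interaction=False, random="animal_knee"))
    return specs


def cmd_stats(config: PipelineConfig, make_figures: bool = True) -> pd.DataFrame:
    """Mixed-model comparison of every outcome; writes the model and
    contrast tables plus annotated boxplot figures."""
    out = Path(config.out_dir)
    tables = []
    for name in ("ftir_bands.csv", "qplm_crimp.csv"):
        p = out / name
        if p.exists():
            tables.append(pd.read_csv(p))
    if not tables:
        raise FileNotFoundError("no outcome tables found; run ftir/qplm first")

    emm_rows, pair_rows, model_rows = [], [], []
    for table in tables:
        meta_cols = {"sample_id", "animal_id", "knee", "ligament", "group",
                     "n_rois", "excluded"}
        outcomes = [c for c in table.columns if c not in meta_cols]
        if "excluded" in table.columns:
            table = table[~table["excluded"].astype(bool)]
        for spec in _specs_for(outcomes):
            sub = table.dropna(subset=[spec.outcome])
            if sub.empty:
                raise ValueError(
                    f"outcome {spec.outcome!r} has no data; available: {outcomes}"
                )
            fit = fit_lme(sub, spec)
            for term, est in fit.params.items():
                model_rows.append(
                    {
                        "outcome": spec.outcome,
                        "term": term,
                        "estimate": est,
                        "se": fit.bse[term],
                        "loglik": fit.loglike,
                        "converged": fit.converged,
                        **{f"var_{k}": v for k, v in fit.var_components.items()},
                    }
                )
            emm = estimated_marginal_means(fit)
            emm.insert(0, "outcome", spec.outcome)
            emm_rows.append(emm)
            for cmp_ in pairwise_posthoc(fit, adjust=config.posthoc_adjust):
                pair_rows.append(
                    {
                        "outcome": spec.outcome,
                        "ligament": cmp_.ligament,
                        "contrast": cmp_.contrast,
                        "estimate": cmp_.estimate,
                        "se": cmp_.se,
                        "df": cmp_.df,
                        "t": cmp_.t,
                        "p_value": cmp_.p_value,
                        "p_adjusted": cmp_.p_adjusted,
                        "stars": significance_stars(cmp_.p_adjusted),
                    }
                )
            if make_figures:
                _boxplot(table, spec.outcome, out)
    emms = pd.concat(emm_rows, ignore_index=True)
    pairs = pd.DataFrame(pair_rows)
    emms.to_csv(out / "emmeans.csv", index=False)
    pairs.to_csv(out / "pairwise.csv", index=False)
    pd.DataFrame(model_rows).to_csv(out / "models.csv", index=False)
    manifest = RunManifest("stats", _config_hash(config))
    manifest.counts = {"outcomes": emms["outcome"].nunique(), "contrasts": len(pairs)}
    manifest.write(out)
    return pairs


def _boxplot(table: pd.DataFrame, outcome: str, out_dir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = ["control", "contralateral", "ACLT"]
    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2), sharey=True)
    for ax, ligament in zip(axes, ("LCL", "MCL")):
        data = [
            table.loc[
                (table["ligament"] == ligament) & (table["group"] == g), outcome
            ].dropna()
            for g in groups
        ]
        ax.boxplot(data, tick_labels=groups)
        ax.set_title(ligament)
        ax.tick_params(axis="x", rotation=20)
    axes[0].set_ylabel(outcome)
    fig.tight_layout()
    path = out_dir / f"boxplot_{outcome}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
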