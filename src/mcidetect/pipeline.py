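"""End-to-end pipeline: simulate → preprocess → train → score → detect → report.

A run is fully described by a :class:`RunConfig` (serializable to YAML)
plus its seed: identical config + seed reproduces identical numeric
outputs.  Every stage writes its artifacts under the run directory and a
manifest records SHA-256 hashes for integrity checks.

Stages are ordered; a disabled stage (and everything after it that needs
its outputs) is skipped, leaving earlier artifacts unchanged.  Because the
simulator is deterministic, any stage can be recomputed from the config
alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envi
from .chemometrics import (
    BINARY,
    ONE_VS_ALL,
    class_dendrogram,
    compute_roc,
    confusion_matrix,
    cross_validate,
    fit_multiclass_plsda,
    fit_plsda,
    select_n_factors,
)
from .detection import (
    CleanConfig,
    SegmentConfig,
    clean_score_image,
    detect_tumor,
    evaluate_detection,
    synthesize_rgb,
)
from .hypercube import (
    concat_spectra,
    correct_instrument_response,
    crop_spectral_range,
    extract_roi_spectra,
    reflectance_to_absorbance,
    vector_normalize,
)
from .score_imaging import (
    WavelengthPair,
    evaluate_score_image,
    plsda_score_image,
    ratiometric_score_image,
    select_wavelength_pair,
)
from .synthetic import default_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "train", "score", "detect", "evaluate", "report")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; YAML-serializable."""

    seed: int = 0
    out_dir: str = "runs/demo"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # cohort
    n_specimens: int = 6
    n_fovs: int = 2
    noise_sd: float = 0.01
    glare_fraction: float = 0.01
    shape: tuple[int, int] = (80, 80)
    write_cubes: bool = False  # ENVI output is bulky; opt-in
    # preprocessing
    crop_lo_nm: float = 520.0
    crop_hi_nm: float = 1050.0
    reflectance_floor: float = 1e-6
    rois_per_class: int = 10
    roi_shape: tuple[int, int] = (3, 3)
    # training
    n_factors: int = 5
    multiclass_factors: int = 7
    cv_scheme: str = "leave_one_fov_out"
    positive_class: str = "tumor"
    run_factor_selection: bool = True
    max_factors: int = 8
    # scoring
    pair_scope: str = "consistent_case"
    pair_selection_cubes: int = 3
    pair_max_pixels: int = 3000
    # detection
    clean: CleanConfig = field(default_factory=CleanConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "clean" in data and isinstance(data["clean"], dict):
            data["clean"] = CleanConfig(**data["clean"])
        if "segment" in data and isinstance(data["segment"], dict):
            data["segment"] = SegmentConfig(**data["segment"])
        if "shape" in data:
            data["shape"] = tuple(data["shape"])
        if "roi_shape" in data:
            data["roi_shape"] = tuple(data["roi_shape"])
        cfg = cls(**data)
        for stage in cfg.stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Stage errors propagate with the stage name attached, leaving the
    artifacts written so far in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"stages": {}, "artifacts": {}}
    t_start = time.time()

    enabled = [s for s in STAGES if s in config.stages]
    state: dict = {}
    for stage in enabled:
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        logger.info("stage %s finished in %.2fs", stage, time.time() - t0)

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)
    manifest["total_seconds"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> None:
    cohort = default_cohort(
        n_specimens=config.n_specimens,
        n_fovs=config.n_fovs,
        noise_sd=config.noise_sd,
        glare_fraction=config.glare_fraction,
        seed=config.seed,
        shape=config.shape,
    )
    state["cohort"] = cohort
    stage_dir = out / "simulate"
    stage_dir.mkdir(exist_ok=True)
    scene_meta = []
    for fov in cohort:
        if config.write_cubes:
            envi.write_envi(fov.cube, stage_dir / f"{fov.field_of_view_id}.img")
        mask_png = stage_dir / f"{fov.field_of_view_id}_mask.png"
        import imageio.v3 as iio

        iio.imwrite(mask_png, fov.mask.labels.astype(np.uint8))
        scene_meta.append(
            {
                "specimen_id": fov.specimen_id,
                "field_of_view_id": fov.field_of_view_id,
                "class_names": fov.mask.class_names,
                "class_counts": fov.mask.class_counts(),
            }
        )
    (stage_dir / "scenes.yaml").write_text(yaml.safe_dump(scene_meta, sort_keys=False))


def _stage_preprocess(config: RunConfig, out: Path, state: dict) -> None:
    cohort = state["cohort"]
    corrected, corrected_full, absorbance, spectra_sets = [], [], [], []
    for i, fov in enumerate(cohort):
        corr = correct_instrument_response(fov.cube, fov.reference)
        corrected_full.append(corr)
        corr_crop = crop_spectral_range(corr, config.crop_lo_nm, config.crop_hi_nm)
        absorb = reflectance_to_absorbance(corr_crop, floor=config.reflectance_floor)
        corrected.append(corr_crop)
        absorbance.append(absorb)
        spectra_sets.append(
            extract_roi_spectra(
                absorb,
                fov.mask,
                rois_per_class=config.rois_per_class,
                roi_shape=config.roi_shape,
                seed=(config.seed * 1009 + i) % (2**31 - 1),
            )
        )
    spectra = vector_normalize(concat_spectra(spectra_sets))
    state["corrected"] = corrected
    state["corrected_full"] = corrected_full
    state["absorbance"] = absorbance
    state["spectra"] = spectra
    stage_dir = out / "preprocess"
    stage_dir.mkdir(exist_ok=True)
    spectra.to_csv(stage_dir / "signatures.csv")


def _stage_train(config: RunConfig, out: Path, state: dict) -> None:
    spectra = state["spectra"]
    stage_dir = out / "train"
    stage_dir.mkdir(exist_ok=True)

    cv = cross_validate(
        spectra,
        scheme=config.cv_scheme,
        mode=BINARY,
        positive_class=config.positive_class,
        n_factors=config.n_factors,
    )
    roc = compute_roc(cv.scores, cv.binary_truth(config.positive_class))
    state["cv_roc"] = roc
    pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
    ).to_csv(stage_dir / "roc_curve.csv", index=False, float_format="%.8f")

    model = fit_plsda(spectra, config.positive_class, config.n_factors)
    model.decision_threshold = roc.optimal_threshold
    model.save(stage_dir / "plsda_model.npz")
    state["model"] = model

    mc_cv = cross_validate(
        spectra,
        scheme=config.cv_scheme,
        mode=ONE_VS_ALL,
        n_factors=config.multiclass_factors,
    )
    cm = confusion_matrix(
        mc_cv.predicted_classes(), mc_cv.truth, spectra.classes
    )
    cm.to_dataframe().to_csv(stage_dir / "confusion_matrix.csv", float_format="%.4f")
    state["confusion"] = cm

    mc_model = fit_multiclass_plsda(spectra, config.multiclass_factors)
    dendro = class_dendrogram(mc_model, spectra)
    state["dendrogram"] = dendro
    np.savetxt(stage_dir / "dendrogram_linkage.csv", dendro.linkage, delimiter=",")

    if config.run_factor_selection:
        curve = select_n_factors(
            spectra,
            positive_class=config.positive_class,
            scheme=config.cv_scheme,
            max_factors=config.max_factors,
        )
        curve.to_dataframe().to_csv(
            stage_dir / "factor_selection.csv", index=False, float_format="%.8f"
        )
        state["factor_curve"] = curve

    summary = {
        "cv_auroc": round(roc.auroc, 6),
        "optimal_threshold": round(roc.optimal_threshold, 6),
        "sensitivity_at_optimum": round(roc.sensitivity_at_optimum, 6),
        "specificity_at_optimum": round(roc.specificity_at_optimum, 6),
        "n_factors": config.n_factors,
        "chosen_n_factors": (
            state["factor_curve"].chosen_n_factors
            if "factor_curve" in state
            else None
        ),
        "skipped_folds": cv.skipped_folds,
    }
    (stage_dir / "training_summary.json").write_text(json.dumps(summary, indent=2))


def _stage_score(config: RunConfig, out: Path, state: dict) -> None:
    cohort = state["cohort"]
    corrected = state["corrected"]
    absorbance = state["absorbance"]
    model = state["model"]
    stage_dir = out / "score"
    stage_dir.mkdir(exist_ok=True)

    pair = select_wavelength_pair(
        [(corrected[i], cohort[i].mask) for i in range(
            min(config.pair_selection_cubes, len(cohort))
        )],
        target_class=config.positive_class,
        scope=config.pair_scope,
        max_pixels_per_cube=config.pair_max_pixels,
        seed=config.seed,
    )
    state["pair"] = pair
    (stage_dir / "wavelength_pair.json").write_text(
        json.dumps(
            {
                "numerator_nm": pair.numerator_nm,
                "denominator_nm": pair.denominator_nm,
                "min_auroc": pair.contrast_score,
                "scope": pair.scope,
            },
            indent=2,
        )
    )

    plsda_scores, ratio_scores = [], []
    for i, fov in enumerate(cohort):
        s_pls = plsda_score_image(absorbance[i], model)
        s_ratio = ratiometric_score_image(corrected[i], pair)
        s_pls.save(stage_dir / f"{fov.field_of_view_id}_plsda.tiff")
        s_ratio.save(stage_dir / f"{fov.field_of_view_id}_ratiometric.tiff")
        plsda_scores.append(s_pls)
        ratio_scores.append(s_ratio)
    state["plsda_scores"] = plsda_scores
    state["ratio_scores"] = ratio_scores


def _stage_detect(config: RunConfig, out: Path, state: dict) -> None:
    cohort = state["cohort"]
    stage_dir = out / "detect"
    stage_dir.mkdir(exist_ok=True)
    import imageio.v3 as iio

    detections = []
    for i, fov in enumerate(cohort):
        rgb = synthesize_rgb(state["corrected_full"][i])
        truth = fov.mask.class_mask(config.positive_class)
        result = detect_tumor(
            state["ratio_scores"][i],
            rgb=rgb,
            truth=truth,
            clean_config=config.clean,
            segment_config=config.segment,
        )
        iio.imwrite(
            stage_dir / f"{fov.field_of_view_id}_mask.png",
            (result.mask * 255).astype(np.uint8),
        )
        if result.overlay is not None:
            iio.imwrite(stage_dir / f"{fov.field_of_view_id}_overlay.png", result.overlay)
        detections.append(result)
    state["detections"] = detections


def _stage_evaluate(config: RunConfig, out: Path, state: dict) -> None:
    cohort = state["cohort"]
    stage_dir = out / "evaluate"
    stage_dir.mkdir(exist_ok=True)
    rows = []
    for i, fov in enumerate(cohort):
        pls_eval = evaluate_score_image(
            state["plsda_scores"][i], fov.mask, config.positive_class
        )
        ratio_eval = evaluate_score_image(
            state["ratio_scores"][i], fov.mask, config.positive_class
        )
        det = state["detections"][i].metrics
        rows.append(
            {
                "specimen_id": fov.specimen_id,
                "field_of_view_id": fov.field_of_view_id,
                "plsda_snr": pls_eval.snr,
                "plsda_auroc": pls_eval.auroc,
                "ratiometric_snr": ratio_eval.snr,
                "ratiometric_auroc": ratio_eval.auroc,
                "iou": det.iou,
                "sensitivity": det.sensitivity,
                "specificity": det.specificity,
                "accuracy": det.accuracy,
            }
        )
    metrics = pd.DataFrame(rows)
    metrics.to_csv(stage_dir / "metrics.csv", index=False, float_format="%.6f")
    state["metrics"] = metrics


def _stage_report(config: RunConfig, out: Path, state: dict) -> None:
    generate_report(out, state=state)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "score": _stage_score,
    "detect": _stage_detect,
    "evaluate": _stage_evaluate,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def generate_report(run_dir: Path | str, state: dict | None = None) -> Path:
    """Aggregate a completed run into ``report.md`` plus plots.

    Per-specimen and aggregate (mean ± s.d.) metric tables, the selected
    wavelength pair and factor count, and ROC / factor-selection plots.
    Missing stages leave flagged gaps rather than failing.
    """
    run_dir = Path(run_dir)
    report_dir = run_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# MCI pipeline run report", ""]
    gaps = []

    metrics_path = run_dir / "evaluate" / "metrics.csv"
    if metrics_path.exists():
        metrics = pd.read_csv(metrics_path)
        if metrics.empty:
            raise ValueError("metrics table is empty (empty cohort)")
        per_specimen = metrics.drop(columns=["field_of_view_id"]).groupby(
            "specimen_id"
        ).mean()
        numeric = per_specimen
        agg = pd.DataFrame(
            {"mean": numeric.mean(), "std": numeric.std(ddof=1)}
        )
        lines += ["## Per-specimen metrics (mean over FOVs)", ""]
        lines.append(per_specimen.round(4).to_markdown())
        lines += ["", "## Aggregate (mean ± s.d. over specimens)", ""]
        agg_fmt = pd.DataFrame(
            {
                "value": [
                    f"{m:.3f} ± {s:.3f}" for m, s in zip(agg["mean"], agg["std"])
                ]
            },
            index=agg.index,
        )
        lines.append(agg_fmt.to_markdown())
        lines.append("")
        per_specimen.round(6).to_csv(report_dir / "per_specimen_metrics.csv")
        agg.round(6).to_csv(report_dir / "aggregate_metrics.csv")
    else:
        gaps.append("evaluate/metrics.csv missing — metric tables omitted")

    pair_path = run_dir / "score" / "wavelength_pair.json"
    if pair_path.exists():
        pair = json.loads(pair_path.read_text())
        lines.append(
            f"Selected ratiometric pair: {pair['numerator_nm']:g} / "
            f"{pair['denominator_nm']:g} nm ({pair['scope']}, "
            f"worst-case AUROC {pair['min_auroc']:.3f})."
        )
    else:
        gaps.append("score/wavelength_pair.json missing")

    summary_path = run_dir / "train" / "training_summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        lines.append(
            f"Binary PLS-DA: {summary['n_factors']} factors, cross-validated "
            f"AUROC {summary['cv_auroc']:.3f}, optimal threshold "
            f"{summary['optimal_threshold']:.3f}."
        )
        if summary.get("chosen_n_factors"):
            lines.append(
                f"Automated factor selection chose {summary['chosen_n_factors']} factors."
            )
    else:
        gaps.append("train/training_summary.json missing")

    _plot_curves(run_dir, report_dir, lines, gaps)

    if gaps:
        lines += ["", "## Gaps", ""] + [f"- {g}" for g in gaps]
    path = run_dir / "report" / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path


def _plot_curves(run_dir: Path, report_dir: Path, lines: list, gaps: list) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    roc_path = run_dir / "train" / "roc_curve.csv"
    if roc_path.exists():
        roc = pd.read_csv(roc_path)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(1 - roc["specificity"], roc["sensitivity"], "k-")
        ax.plot([0, 1], [0, 1], "k:", lw=0.5)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title("Cross-validated ROC (tumor vs rest)")
        fig.tight_layout()
        fig.savefig(report_dir / "roc_curve.png", dpi=120)
        plt.close(fig)
        lines.append("![ROC](roc_curve.png)")
    else:
        gaps.append("train/roc_curve.csv missing — ROC plot omitted")

    curve_path = run_dir / "train" / "factor_selection.csv"
    if curve_path.exists():
        curve = pd.read_csv(curve_path)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(curve["n_factors"], curve["one_minus_auroc"], "k-o", label="1 - AUROC")
        ax.plot(
            curve["n_factors"],
            curve["distance_from_ideal"],
            "k--s",
            label="distance from ideal sensor",
        )
        ax.set_xlabel("factors retained")
        ax.legend()
        fig.tight_layout()
        fig.savefig(report_dir / "factor_selection.png", dpi=120)
        plt.close(fig)
        lines.append("![Factor selection](factor_selection.png)")
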