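"""End-to-end experiment orchestration.

Three experiments probe how a face-ethnicity classifier uses its visual
input, each summarized against the human observer benchmark:

1. color vs. grayscale continua (does color help or hurt?);
2. feature-occlusion battery — original plus masked {both eyes, left eye,
   right eye, nose, mouth} (which features are necessary?);
3. feature-only battery — {eyes, nose, mouth} visible through boxes of
   three sizes (are isolated features sufficient?).

Each run evaluates the model's psychometric curve per condition, fits and
gates it, t-tests valid PSEs against the human group with Bonferroni
correction, and extracts stage-wise activation maps with attention metrics.
All randomness funnels through one root seed expanded into named sub-seeds
(data, training, observers), so reports are bitwise reproducible.
"""

from __future__ import annotations

import importlib.metadata
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import camlib, faces, netlab, psychophysics, stimuli
from .psychophysics import GateThresholds, HumanBenchmark


@dataclass
class ExperimentConfig:
    """Shared configuration for the three experiment drivers."""

    seed: int = 0
    canvas_size: tuple[int, int] = (140, 190)  # quarter-scale reference canvas
    reference_canvas: tuple[int, int] = faces.DEFAULT_CANVAS  # box coordinates
    input_size: int = 48
    n_levels: int = 21
    n_per_class: int = 200
    epochs: int = 5
    box_sizes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(stimuli.BOX_SIZES))
    benchmark: HumanBenchmark = field(default_factory=HumanBenchmark)
    gate: GateThresholds = field(default_factory=GateThresholds)
    # family policy: "all" counts every attempted comparison, "valid_only"
    # counts only comparisons whose fit passed the gate
    family_policy: dict[int, str] = field(
        default_factory=lambda: {1: "all", 2: "valid_only", 3: "valid_only"})
    cam_method: str = "layer_cam"
    # attention maps are rendered for the Caucasian class on the level-0
    # (Caucasian-prototype) image: the class evidence there is localized,
    # so the maps show where the network reads its features from
    cam_level_index: int = 0
    cam_class_index: int = 0

    def subseeds(self) -> dict[str, int]:
        """Named 31-bit sub-seeds derived from the root seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("data", "training", "observers")
        states = ss.generate_state(len(names)) % (2 ** 31)
        return dict(zip(names, (int(s) for s in states)))


@dataclass
class Assets:
    """Everything an experiment needs: prototypes, continuum, trained model."""

    proto_a: faces.PrototypeFace
    proto_b: faces.PrototypeFace
    continuum: faces.MorphContinuum  # luminance-equalized
    model: netlab.TinyCNN
    train_result: netlab.TrainResult
    config: ExperimentConfig


def prepare_assets(config: ExperimentConfig) -> Assets:
    """Generate stimuli and train the reference CNN from the root seed."""
    seeds = config.subseeds()
    proto_a, proto_b = faces.make_prototype_pair(seeds["data"], config.canvas_size)
    continuum = faces.make_morph_continuum(proto_a, proto_b, config.n_levels)
    eq = stimuli.equalize_luminance(continuum.images)
    continuum = faces.MorphContinuum(continuum.levels, eq.images,
                                     continuum.feature_layout, continuum.canvas_size)
    corpus = faces.make_training_corpus(proto_a, proto_b, config.n_per_class,
                                        seed=seeds["data"])
    model = netlab.build_tiny_cnn(seed=seeds["training"],
                                  input_size=config.input_size)
    result = netlab.train_classifier(
        model, corpus, netlab.desk_config(seed=seeds["training"],
                                          epochs=config.epochs))
    return Assets(proto_a, proto_b, continuum, result.model, result, config)


@dataclass
class ComparisonReport:
    """Tabular results of one experiment plus its activation-map artifacts."""

    experiment: int
    results: pd.DataFrame  # one row per (model x condition)
    curves: pd.DataFrame  # level-wise probabilities and fitted values
    attention: pd.DataFrame  # per-stage attention metrics
    family_size: int
    discarded: list[dict]
    cam_maps: dict[tuple[str, str], list[camlib.CAMap]]
    sample_images: dict[str, np.ndarray]
    config: ExperimentConfig
    log: list[str] = field(default_factory=list)


def _evaluate_battery(experiment: int, model_id: str, model: netlab.TinyCNN,
                      sets: list[stimuli.StimulusSet],
                      config: ExperimentConfig,
                      test_invalid: bool = False) -> ComparisonReport:
    """Shared evaluation loop: curves, fits, t-tests, CAMs per condition."""
    rows, curve_rows, att_rows, log = [], [], [], []
    cam_maps, sample_images = {}, {}
    fits, stats_pending = {}, {}
    for sset in sets:
        curve = psychophysics.response_curve(model, sset)
        fit = psychophysics.fit_psychometric(curve, config.gate)
        fits[sset.condition] = (curve, fit)
        log.append(f"experiment={experiment} model={model_id} "
                   f"condition={sset.condition} valid={fit.valid}")
        img, layout = stimuli.resize_with_masks(
            sset.images[config.cam_level_index], sset.feature_layout,
            (model.input_size, model.input_size))
        maps = camlib.stage_maps(model, img, class_index=config.cam_class_index,
                                 method=config.cam_method)
        cam_maps[(model_id, sset.condition)] = maps
        sample_images[f"{model_id}_{sset.condition}"] = img
        for m in maps:
            met = camlib.attention_metrics(m, layout)
            att_rows.append({
                "model": model_id, "condition": sset.condition, "stage": m.stage,
                "method": m.method, "defined": met.defined,
                **{f"overlap_{k}": v for k, v in met.overlap.items()},
                "centroid_x": met.centroid[0], "centroid_y": met.centroid[1],
                "asymmetry": met.left_right_asymmetry,
            })

    n_valid = sum(1 for _, f in fits.values() if f.valid)
    policy = config.family_policy[experiment]
    family = len(fits) if policy == "all" else max(1, n_valid)

    tested = {}
    for cond, (curve, fit) in fits.items():
        if fit.valid or (test_invalid and np.isfinite(fit.pse)):
            tested[cond] = psychophysics.pse_ttest(fit.pse, config.benchmark)
    corrected = dict(zip(tested.keys(),
                         psychophysics.bonferroni(list(tested.values()), family)))

    discarded = []
    for cond, (curve, fit) in fits.items():
        res = corrected.get(cond)
        rows.append({
            "model": model_id, "condition": cond,
            "pse": fit.pse, "beta": fit.beta, "r_squared": fit.r_squared,
            "valid": fit.valid, "invalid_reason": fit.invalid_reason,
            "t": res.t if res else np.nan, "df": res.df if res else np.nan,
            "p_uncorrected": res.p_uncorrected if res else np.nan,
            "p_corrected": res.p_corrected if res else np.nan,
            "family_size": family,
        })
        if not fit.valid:
            discarded.append({"model": model_id, "condition": cond,
                              "reason": fit.invalid_reason})
        pred = (psychophysics.logistic(curve.levels, fit.pse, fit.beta)
                if np.isfinite(fit.pse) else np.full_like(curve.levels, np.nan))
        for lev, p, f in zip(curve.levels, curve.p_asian, pred):
            curve_rows.append({"model": model_id, "condition": cond,
                               "level": lev, "p_asian": p, "fitted": f})

    return ComparisonReport(
        experiment=experiment,
        results=pd.DataFrame(rows),
        curves=pd.DataFrame(curve_rows),
        attention=pd.DataFrame(att_rows),
        family_size=family, discarded=discarded, cam_maps=cam_maps,
        sample_images=sample_images, config=config, log=log)


def run_experiment1(config: ExperimentConfig,
                    assets: Assets | None = None,
                    model_id: str = "tiny_cnn") -> ComparisonReport:
    """Color vs. grayscale continua; family = 2 comparisons per model."""
    assets = prepare_assets(config) if assets is None else assets
    sets = [
        stimuli.continuum_set(assets.continuum, "color"),
        stimuli.continuum_set(assets.continuum, "grayscale", grayscale=True),
    ]
    return _evaluate_battery(1, model_id, assets.model, sets, config)


def run_experiment2(config: ExperimentConfig,
                    assets: Assets | None = None,
                    model_id: str = "tiny_cnn") -> ComparisonReport:
    """Feature-occlusion battery: original + 5 masked conditions."""
    assets = prepare_assets(config) if assets is None else assets
    sets = stimuli.occlusion_battery(assets.continuum,
                                     box_size=config.box_sizes["default"],
                                     reference_canvas=config.reference_canvas)
    return _evaluate_battery(2, model_id, assets.model, sets, config)


def run_experiment3(config: ExperimentConfig,
                    assets: Assets | None = None,
                    model_id: str = "tiny_cnn") -> ComparisonReport:
    """Feature-only battery: {eyes, nose, mouth} x {small, default, large}.

    Fits are attempted but expected to be largely invalid; activation maps
    and attention metrics are emitted for every condition regardless.
    """
    assets = prepare_assets(config) if assets is None else assets
    sets = stimuli.visibility_battery(assets.continuum,
                                      box_sizes=config.box_sizes,
                                      reference_canvas=config.reference_canvas)
    return _evaluate_battery(3, model_id, assets.model, sets, config)


def _versions() -> dict[str, str]:
    out = {}
    for pkg in ("facebench", "numpy", "scipy", "pandas", "scikit-image"):
        try:
            out[pkg] = importlib.metadata.version(pkg)
        except importlib.metadata.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def write_report(report: ComparisonReport, outdir: str | Path) -> dict[str, Path]:
    """Persist a report: CSV tables, overlay PNGs, manifest, and log."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("results", report.results), ("curves", report.curves),
                        ("attention", report.attention)):
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p

    overlay_dir = outdir / "overlays"
    overlay_dir.mkdir(exist_ok=True)
    for (model_id, cond), maps in report.cam_maps.items():
        img = report.sample_images[f"{model_id}_{cond}"]
        for m in maps:
            ov = camlib.overlay(m, img)
            p = overlay_dir / f"{model_id}_{cond}_{m.stage}.png"
            Image.fromarray((ov * 255).astype(np.uint8)).save(p)
    paths["overlays"] = overlay_dir

    manifest = {
        "experiment": report.experiment,
        "seed": report.config.seed,
        "subseeds": report.config.subseeds(),
        "canvas_size": list(report.config.canvas_size),
        "input_size": report.config.input_size,
        "n_levels": report.config.n_levels,
        "family_size": report.family_size,
        "family_policy": report.config.family_policy[report.experiment],
        "discarded": report.discarded,
        "versions": _versions(),
    }
    p = outdir / "manifest.yaml"
    p.write_text(yaml.safe_dump(manifest, sort_keys=True))
    paths["manifest"] = p
    p = outdir / "run.log"
    p.write_text("\n".join(report.log) + "\n")
    paths["log"] = p
    return paths
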