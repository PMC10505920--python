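"""Stage orchestration: simulate -> segment -> features -> train ->
classify -> stats, with flat CSV interchange between stages.

Each stage reads the previous stage's files from the run directory and
writes its own, so stages are individually re-runnable and auditable.
Classifier training uses dedicated labelled object galleries rendered by
the generator (standing in for user-supervised labelling); the exported
rules files alone drive classification of the experiment, mirroring
prospective classification of new datasets without retraining.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import features as feat
from . import fgboost, phenostats, segtrack, synthgen
from .synthgen import HYPER, IN_FOCUS, OUT_OF_FOCUS, SPHERICAL, SynthConfig

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

#: feature families (stable column-name groups)
SHAPE_FEATURES = ["Area", "Perimeter", "FormFactor", "Eccentricity",
                  "Solidity", "EquivalentDiameter", "RadiusMean",
                  "RadiusMax", "RadiusSD"]
INTENSITY_FEATURES = ["IntensityMean", "IntensitySD", "IntensityMAD"]
TEXTURE_FEATURES = ["Haralick_ASM", "Haralick_Contrast",
                    "Haralick_Correlation", "Haralick_Entropy"]
GRANULARITY_FEATURES = [f"Granularity_{r}"
                        for r in feat.DEFAULT_GRANULARITY_RADII]
MOVEMENT_FEATURES = ["Displacement", "CumulativeDisplacement"]
ALL_FEATURES = (SHAPE_FEATURES + INTENSITY_FEATURES + TEXTURE_FEATURES
                + GRANULARITY_FEATURES + MOVEMENT_FEATURES)
#: focus QC uses appearance only (blur does not change shape or movement)
FOCUS_FEATURES = INTENSITY_FEATURES + TEXTURE_FEATURES + GRANULARITY_FEATURES
#: morphology uses shape and size, as the imaging readout intends
PHENOTYPE_FEATURES = SHAPE_FEATURES


@dataclass
class PipelineConfig:
    """Single config driving the whole pipeline."""

    synth: SynthConfig
    control: str = "control"
    chunk_hours: int = phenostats.DEFAULT_CHUNK_HOURS
    alpha: float = phenostats.DEFAULT_ALPHA
    n_rounds: int = fgboost.DEFAULT_N_ROUNDS
    n_train_per_class: int = 300
    bonferroni_m: int | None = None
    min_area: int = segtrack.DEFAULT_MIN_AREA
    max_displacement: float = segtrack.DEFAULT_MAX_DISPLACEMENT
    seed: int = 0

    def to_yaml_text(self) -> str:
        d = dataclasses.asdict(self)
        d["synth"]["radius_range"] = list(self.synth.radius_range)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sd = d.pop("synth")
        sd["radius_range"] = tuple(sd.get("radius_range", (10.0, 14.0)))
        sd["conditions"] = [synthgen.ConditionSpec(**c)
                            for c in sd["conditions"]]
        return cls(synth=SynthConfig(**sd), **d)


def default_config(seed: int = 0) -> PipelineConfig:
    """Small two-condition demo configuration."""
    synth = SynthConfig(
        conditions=[
            synthgen.ConditionSpec(name="control", p_hyper=0.1),
            synthgen.ConditionSpec(name="invasive", p_hyper=0.7),
        ],
        n_frames=24, n_experiments=3, wells_per_condition=2,
        spheroids_per_well=4, seed=seed)
    return PipelineConfig(synth=synth, seed=seed)


def _freeze(cfg: PipelineConfig, outdir: Path) -> None:
    text = cfg.to_yaml_text()
    (outdir / "pipeline_config.yaml").write_text(text)
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "seed": cfg.seed,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> synthgen.SynthExperiment:
    outdir.mkdir(parents=True, exist_ok=True)
    _freeze(cfg, outdir)
    exp = synthgen.simulate_experiment(cfg.synth, render=True)
    synthgen.write_experiment(exp, outdir / "images")
    logger.info("simulated %d wells, %d truth records",
                len(exp.stacks), len(exp.truth))
    return exp


def segment_and_track_stacks(stacks, min_area, max_displacement,
                             label_dir: Path | None = None):
    """Segment + link every well stack; returns observations with track
    ids set and per-well frame dictionaries for feature extraction."""
    all_obs: list[segtrack.SpheroidObservation] = []
    all_tracks: list[segtrack.Track] = []
    frames_by_key: dict[tuple, dict[int, np.ndarray]] = {}
    track_offset = 0
    for (e, c, w), stack in sorted(stacks.items()):
        obs = segtrack.segment_stack(stack, min_area=min_area)
        for o in obs:
            o.experiment, o.condition, o.well = e, c, w
        tracks = segtrack.link_tracks(obs, max_displacement=max_displacement)
        for tr in tracks:
            tr.track_id += track_offset
        for o in obs:
            o.track_id += track_offset
        track_offset += len(tracks)
        all_obs.extend(obs)
        all_tracks.extend(tracks)
        frames_by_key[(e, c, w)] = {t + 1: stack[t]
                                    for t in range(stack.shape[0])}
        if label_dir is not None:
            d = label_dir / e / c
            d.mkdir(parents=True, exist_ok=True)
            by_frame: dict[int, list] = {}
            for o in obs:
                by_frame.setdefault(o.frame, []).append(o)
            lab = np.stack([
                segtrack.label_image(by_frame.get(t + 1, []),
                                     stack.shape[1:])
                for t in range(stack.shape[0])])
            tifffile.imwrite(d / f"{w}_labels.tif", lab)
    return all_obs, all_tracks, frames_by_key


def stage_segment(cfg: PipelineConfig, outdir: Path):
    stacks = synthgen.read_stacks(outdir / "images")
    obs, tracks, frames = segment_and_track_stacks(
        stacks, cfg.min_area, cfg.max_displacement,
        label_dir=outdir / "labels")
    df = segtrack.observations_to_dataframe(obs)
    df.to_csv(outdir / "observations.csv", index=False)
    logger.info("segmented %d object-frames into %d tracks",
                len(obs), len(tracks))
    return obs, tracks, frames


def stage_features(cfg: PipelineConfig, outdir: Path, obs=None, tracks=None,
                   frames=None) -> pd.DataFrame:
    if obs is None:
        obs, tracks, frames = stage_segment(cfg, outdir)
    parts = []
    by_key: dict[tuple, list] = {}
    for o in obs:
        by_key.setdefault((o.experiment, o.condition, o.well), []).append(o)
    tr_by_id = {t.track_id: t for t in tracks}
    for key, olist in sorted(by_key.items()):
        tids = sorted({o.track_id for o in olist})
        table = feat.compute_feature_table(
            olist, [tr_by_id[t] for t in tids], frames[key])
        parts.append(table)
    out = (pd.concat(parts, ignore_index=True) if parts
           else pd.DataFrame(columns=feat.METADATA_COLUMNS + ALL_FEATURES))
    out.to_csv(outdir / "features.csv", index=False)
    return out


def gallery_feature_table(n_per_class: int, kind: str, seed: int,
                          image_size: int = 128,
                          blur_sigma: float = 3.0,
                          radius_range: tuple[float, float] = (14.0, 22.0),
                          min_area: int = 150):
    """Labelled training features from a single-object gallery.

    Renders 2 x ``n_per_class`` single-spheroid frames, segments each and
    extracts the full feature vector.  Frames where segmentation fails
    are dropped (logged).  Returns (feature DataFrame, label list).
    """
    imgs, labels = synthgen.simulate_object_gallery(
        n_per_class, kind=kind, seed=seed, image_size=image_size,
        blur_sigma=blur_sigma, radius_range=radius_range)
    rows = []
    kept_labels = []
    for i in range(imgs.shape[0]):
        obs = segtrack.segment_frame(imgs[i], min_area=min_area, frame=1)
        if not obs:
            logger.info("gallery frame %d: no object segmented; dropped", i)
            continue
        o = max(obs, key=lambda x: x.area)
        o.track_id = i
        tr = segtrack.Track(track_id=i, steps=[(1, o.object_id)])
        table = feat.compute_feature_table([o], [tr], {1: imgs[i]})
        rows.append(table)
        kept_labels.append(labels[i])
    table = pd.concat(rows, ignore_index=True)
    return table[ALL_FEATURES], kept_labels


def stage_train(cfg: PipelineConfig, outdir: Path):
    """Train both classifiers on generator-labelled galleries and export
    their rules files."""
    blur = max(c.blur_sigma for c in cfg.synth.conditions)
    r_lo, r_hi = cfg.synth.radius_range
    g_max = max(c.growth_rate for c in cfg.synth.conditions)
    radius_range = (r_lo, r_hi * (1.0 + g_max * (cfg.synth.n_frames - 1)))

    xf, yf = gallery_feature_table(
        cfg.n_train_per_class, "focus", seed=cfg.seed + 101,
        blur_sigma=blur if blur > 0 else 3.0, radius_range=radius_range)
    focus_model = fgboost.train(xf[FOCUS_FEATURES], yf,
                                n_rounds=cfg.n_rounds, seed=cfg.seed)
    fgboost.save_rules(focus_model, outdir / "rules_focus.txt")

    xp, yp = gallery_feature_table(
        cfg.n_train_per_class, "morphology", seed=cfg.seed + 202,
        radius_range=radius_range)
    pheno_model = fgboost.train(xp[PHENOTYPE_FEATURES], yp,
                                n_rounds=cfg.n_rounds, seed=cfg.seed)
    fgboost.save_rules(pheno_model, outdir / "rules_phenotype.txt")
    return focus_model, pheno_model


def stage_classify(cfg: PipelineConfig, outdir: Path,
                   feature_table: pd.DataFrame | None = None
                   ) -> pd.DataFrame:
    """Apply exported rules files prospectively to the feature table."""
    if feature_table is None:
        feature_table = pd.read_csv(outdir / "features.csv")
    focus_model = fgboost.load_rules(outdir / "rules_focus.txt")
    pheno_model = fgboost.load_rules(outdir / "rules_phenotype.txt")
    labelled = fgboost.two_stage_classify(feature_table, focus_model,
                                          pheno_model,
                                          outoffocus_label=OUT_OF_FOCUS)
    labelled.to_csv(outdir / "labelled.csv", index=False)

    counts = (labelled.assign(
        n_outoffocus=lambda d: d["focus_label"] == OUT_OF_FOCUS,
        n_spherical=lambda d: d["phenotype_label"] == SPHERICAL,
        n_hyper=lambda d: d["phenotype_label"] == HYPER)
        .groupby("condition")
        .agg(n_object_frames=("frame", "size"),
             n_outoffocus=("n_outoffocus", "sum"),
             n_spherical=("n_spherical", "sum"),
             n_hyper=("n_hyper", "sum"))
        .reset_index())
    counts.to_csv(outdir / "counts.csv", index=False)
    logger.info("classification counts:\n%s", counts.to_string(index=False))
    return labelled


def stage_stats(cfg: PipelineConfig, outdir: Path,
                labelled: pd.DataFrame | None = None) -> pd.DataFrame:
    if labelled is None:
        labelled = pd.read_csv(outdir / "labelled.csv")
    binned = phenostats.bin_chunks(labelled, chunk_hours=cfg.chunk_hours)
    binned.to_csv(outdir / "binned.csv", index=False)
    summary = phenostats.summarize(binned, control=cfg.control,
                                   alpha=cfg.alpha,
                                   bonferroni_m=cfg.bonferroni_m)
    summary.to_csv(outdir / "stats.csv", index=False)
    areas = phenostats.area_summary(labelled, control=cfg.control,
                                    chunk_hours=cfg.chunk_hours)
    areas.to_csv(outdir / "area_zscores.csv", index=False)
    if not summary.empty:
        phenostats.bubble_heatmap(summary, path=outdir / "heatmap.png",
                                  alpha=cfg.alpha)
    return summary


def run_all(cfg: PipelineConfig, outdir: str | Path) -> pd.DataFrame:
    """Run the full pipeline; returns the statistical summary table."""
    outdir = Path(outdir)
    stage_simulate(cfg, outdir)
    obs, tracks, frames = stage_segment(cfg, outdir)
    table = stage_features(cfg, outdir, obs, tracks, frames)
    stage_train(cfg, outdir)
    labelled = stage_classify(cfg, outdir, table)
    return stage_stats(cfg, outdir, labelled)


# ---------------------------------------------------------------------------
# benchmarks
# ---------------------------------------------------------------------------

def classifier_benchmark(kind: str, n_per_class: int = 600, seed: int = 42,
                         n_rounds: int = fgboost.DEFAULT_N_ROUNDS,
                         test_frac: float = 0.3, blur_sigma: float = 3.0
                         ) -> tuple[float, int]:
    """Held-out accuracy of one classifier on a labelled object gallery.

    Renders ``n_per_class`` objects per class, extracts features, trains
    Fast Gentle Boosting on a stratified 70% split and scores the held-out
    30%.  ``kind="morphology"`` uses the full feature vector for Spherical
    vs Hyper-protrusive; ``kind="focus"`` uses appearance features for
    InFocus vs OutOfFocus (blur sigma in px).  Returns (accuracy,
    n_objects).
    """
    x, y = gallery_feature_table(n_per_class, kind, seed=seed,
                                 blur_sigma=blur_sigma)
    cols = ALL_FEATURES if kind == "morphology" else FOCUS_FEATURES
    _, res = fgboost.holdout_evaluate(x[cols], y, n_rounds=n_rounds,
                                      seed=seed, test_frac=test_frac)
    return res.accuracy, len(y)


def parameter_recovery_run(seed: int, p_ctrl: float = 0.1,
                           p_cond: float = 0.7, n_experiments: int = 3,
                           wells: int = 4, spheroids: int = 12,
                           n_frames: int = 72) -> pd.DataFrame:
    """One seeded simulation of the statistical readout at study scale.

    Simulates the replicate hierarchy (truth table only), feeds the
    ground-truth labels through chunking and the stratified statistics,
    and returns the summary table — the fast path for power and type-I
    simulations of the pipeline's inference layer.
    """
    cfg = SynthConfig(
        conditions=[synthgen.ConditionSpec("control", p_hyper=p_ctrl),
                    synthgen.ConditionSpec("condition", p_hyper=p_cond)],
        n_frames=n_frames, n_experiments=n_experiments,
        wells_per_condition=wells, spheroids_per_well=spheroids, seed=seed)
    exp = synthgen.simulate_experiment(cfg, render=False)
    lab = truth_labelled_table(exp.truth)
    binned = phenostats.bin_chunks(lab)
    return phenostats.summarize(binned, control="control")


# ---------------------------------------------------------------------------
# truth matching (for validation and truth-driven statistics)
# ---------------------------------------------------------------------------

def match_observations_to_truth(obs_df: pd.DataFrame, truth: pd.DataFrame,
                                max_dist: float = 10.0) -> pd.DataFrame:
    """Attach ground-truth morphology/focus to observations by nearest
    centroid within the same (experiment, condition, well, frame)."""
    keys = ["experiment", "condition", "well", "frame"]
    t_groups = {k: g for k, g in truth.groupby(keys)}
    rows = []
    for k, g in obs_df.groupby(keys):
        tg = t_groups.get(k)
        for _, row in g.iterrows():
            rec = row.to_dict()
            rec.update(morphology=pd.NA, focus=pd.NA, truth_id=pd.NA)
            if tg is not None:
                d = np.hypot(tg["centroid_row"] - row["centroid_row"],
                             tg["centroid_col"] - row["centroid_col"])
                i = d.idxmin()
                if d.loc[i] <= max_dist:
                    rec.update(morphology=tg.loc[i, "morphology"],
                               focus=tg.loc[i, "focus"],
                               truth_id=tg.loc[i, "spheroid_id"])
            rows.append(rec)
    return pd.DataFrame(rows)


def truth_labelled_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Reshape a generator truth table into the labelled-observations
    schema (fast path for statistical simulations: classification is the
    ground truth itself, out-of-focus frames excluded)."""
    df = truth.rename(columns={"spheroid_id": "track_id"}).copy()
    df["phenotype_label"] = df["morphology"].where(df["focus"] == IN_FOCUS,
                                                   pd.NA)
    df["focus_label"] = df["focus"]
    return df[["experiment", "condition", "well", "frame", "track_id",
               "focus_label", "phenotype_label"]]
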