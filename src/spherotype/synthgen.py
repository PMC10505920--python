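"""Seeded synthetic time-lapse spheroid experiments with ground truth.

Emulates an IncuCyte-style live-imaging assay of multicellular spheroids
embedded in extracellular matrix: one phase-contrast-like field per well,
hourly frames, spheroids that grow, drift, occasionally go out of focus,
and adopt one of two morphologies — compact "Spherical" or invasive
"Hyper-protrusive" (radial protrusions into the matrix).  Every rendered
object is accompanied by a ground-truth record so that downstream
segmentation, classification and statistics can be validated against a
known generative model.

The generator is deterministic: a config seed fully determines both the
pixel data and the truth table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

logger = logging.getLogger(__name__)

SPHERICAL = "Spherical"
HYPER = "Hyper-protrusive"
IN_FOCUS = "InFocus"
OUT_OF_FOCUS = "OutOfFocus"

#: Intensity model (arbitrary units in [0, 1]): matrix background, dark
#: halo ring around each spheroid, bright textured body.
BACKGROUND_LEVEL = 0.35
HALO_LEVEL = 0.15
BODY_LEVEL = 0.65
BODY_TEXTURE_AMPLITUDE = 0.25
HALO_WIDTH_PX = 3

#: Morphology priors for the protrusive class (drawn once per spheroid).
HYPER_N_PROTRUSIONS = (4, 8)          # inclusive range
HYPER_PROTRUSION_LENGTH = (0.5, 0.9)  # fraction of body radius
HYPER_PROTRUSION_WIDTH = (0.12, 0.25)  # angular width at base, radians

#: Out-of-focus runs span a few consecutive frames (focus drift, not
#: per-object defocus).
BLUR_RUN_FRAMES = (3, 6)

TRUTH_COLUMNS = [
    "experiment", "condition", "well", "frame", "spheroid_id",
    "morphology", "focus", "centroid_row", "centroid_col", "radius",
    "n_protrusions", "protrusion_length",
]


@dataclass
class ConditionSpec:
    """One experimental condition (genotype / treatment arm).

    Parameters
    ----------
    name
        Condition label, e.g. ``"control"`` or ``"PTEN-KO"``.
    p_hyper
        Probability that a spheroid adopts the Hyper-protrusive
        morphology.  Drawn once per spheroid.
    growth_rate
        Fractional radius increase per frame: ``R(t) = R0 * (1 + g*t)``.
    p_outfocus
        Probability that a well contains one run of blurred frames.
    blur_sigma
        Gaussian sigma (px) applied to out-of-focus frames.
    drift_sd
        Per-frame centroid random-walk step s.d. (px).
    hyper_onset
        Optional frame (1-based hour) at which protrusive spheroids
        switch on their protrusions; before it they render as Spherical.
        ``None`` means protrusive from the first frame.
    """

    name: str
    p_hyper: float = 0.1
    growth_rate: float = 0.01
    p_outfocus: float = 0.1
    blur_sigma: float = 3.0
    drift_sd: float = 1.0
    hyper_onset: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hyper <= 1.0:
            raise ValueError(f"p_hyper must be in [0, 1], got {self.p_hyper}")
        if not 0.0 <= self.p_outfocus <= 1.0:
            raise ValueError(f"p_outfocus must be in [0, 1], got {self.p_outfocus}")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")


@dataclass
class SynthConfig:
    """Full description of a synthetic multi-condition experiment."""

    conditions: list[ConditionSpec]
    image_size: int = 256
    n_frames: int = 72
    n_experiments: int = 3
    wells_per_condition: int = 4
    spheroids_per_well: int = 5
    radius_range: tuple[float, float] = (10.0, 14.0)
    pixel_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name, v in [("image_size", self.image_size),
                        ("n_experiments", self.n_experiments),
                        ("wells_per_condition", self.wells_per_condition),
                        ("spheroids_per_well", self.spheroids_per_well)]:
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        self.conditions = [
            c if isinstance(c, ConditionSpec) else ConditionSpec(**c)
            for c in self.conditions
        ]

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["radius_range"] = list(self.radius_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["radius_range"] = tuple(d.get("radius_range", (10.0, 14.0)))
        d["conditions"] = [ConditionSpec(**c) for c in d["conditions"]]
        return cls(**d)


@dataclass
class SpheroidState:
    """Renderable state of one spheroid in one frame."""

    centroid: tuple[float, float]  # (row, col)
    radius: float
    n_protrusions: int = 0
    protrusion_length: float = 0.0
    protrusion_width: float = 0.18
    angles: np.ndarray = field(default_factory=lambda: np.empty(0))
    texture_phase: int = 0


@dataclass
class SynthExperiment:
    """Rendered stacks (may be empty when render=False) plus truth table."""

    config: SynthConfig
    stacks: dict[tuple[str, str, str], np.ndarray]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def render_spheroid(radius: float,
                    n_protrusions: int = 0,
                    protrusion_length: float = 0.0,
                    protrusion_width: float = 0.18,
                    angles: np.ndarray | list[float] | None = None,
                    supersample: int = 4) -> np.ndarray:
    """Render a spheroid silhouette as a boolean mask.

    The body is a disk of the given radius; the protrusive morphology adds
    ``n_protrusions`` radial spikes of length ``protrusion_length * radius``
    that taper from an angular base width ``protrusion_width`` to a point.
    Rendering happens on a ``supersample``-times finer grid and is reduced
    by area coverage, which keeps the digitized outline smooth.

    Returns a tight square mask centred on the spheroid.
    """
    if radius < 3:
        raise ValueError(f"radius must be >= 3 px, got {radius}")
    if n_protrusions < 0:
        raise ValueError("n_protrusions must be >= 0")
    if not 0.0 <= protrusion_length <= 2.0:
        raise ValueError("protrusion_length must be in [0, 2]")
    if angles is None:
        angles = np.linspace(0, 2 * np.pi, max(n_protrusions, 1), endpoint=False)
    angles = np.asarray(angles, dtype=float)[:n_protrusions]

    extent = radius * (1.0 + (protrusion_length if n_protrusions else 0.0))
    half = int(math.ceil(extent)) + 2
    size = 2 * half + 1
    s = int(supersample)
    # supersampled pixel-centre coordinates relative to the mask centre
    coords = (np.arange(size * s) + 0.5) / s - 0.5 - half
    rr = coords[:, None]
    cc = coords[None, :]
    r = np.hypot(rr, cc)
    inside = r <= radius

    if n_protrusions and protrusion_length > 0:
        theta = np.arctan2(rr, cc)
        tip = radius * (1.0 + protrusion_length)
        with np.errstate(invalid="ignore", divide="ignore"):
            taper = 1.0 - (r - radius) / (tip - radius)
        taper = np.clip(taper, 0.0, 1.0)
        shell = (r > radius) & (r <= tip)
        for a in angles:
            d = np.angle(np.exp(1j * (theta - a)))
            inside |= shell & (np.abs(d) <= 0.5 * protrusion_width * taper)

    cover = inside.reshape(size, s, size, s).mean(axis=(1, 3))
    return cover >= 0.5


def _paste(canvas: np.ndarray, patch: np.ndarray, center: tuple[int, int],
           op) -> None:
    """Apply ``op(dst, src)`` of a centred patch onto the canvas, clipped."""
    ph, pw = patch.shape
    r0 = center[0] - ph // 2
    c0 = center[1] - pw // 2
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + ph, canvas.shape[0]), min(c0 + pw, canvas.shape[1])
    if re <= rs or ce <= cs:
        return
    sub = patch[rs - r0:re - r0, cs - c0:ce - c0]
    canvas[rs:re, cs:ce] = op(canvas[rs:re, cs:ce], sub)


def render_frame(states: list[SpheroidState],
                 rng: np.random.Generator,
                 image_size: int = 256,
                 pixel_noise_sd: float = 0.02,
                 blur_sigma: float = 0.0) -> np.ndarray:
    """Render one grayscale frame from a list of spheroid states.

    Phase-contrast-like look: bright textured body, dark halo ring, mid-grey
    background.  Out-of-focus frames are the same scene convolved with a
    Gaussian of ``blur_sigma`` before camera noise is added.  Intensities
    are clipped to [0, 1].
    """
    img = np.full((image_size, image_size), BACKGROUND_LEVEL, dtype=np.float64)
    if states:
        # granular internal texture: one smoothed speckle field per frame
        speckle = ndimage.gaussian_filter(rng.random(img.shape), 1.2)
        lo, hi = speckle.min(), speckle.max()
        speckle = (speckle - lo) / (hi - lo) if hi > lo else speckle * 0
    body_total = np.zeros_like(img, dtype=bool)
    for st in states:
        mask = render_spheroid(st.radius, st.n_protrusions,
                               st.protrusion_length, st.protrusion_width,
                               st.angles)
        halo = ndimage.binary_dilation(mask, iterations=HALO_WIDTH_PX) & ~mask
        center = (int(round(st.centroid[0])), int(round(st.centroid[1])))
        full_mask = np.zeros_like(body_total)
        _paste(full_mask, mask, center, lambda d, s: d | s)
        full_halo = np.zeros_like(body_total)
        _paste(full_halo, halo, center, lambda d, s: d | s)
        img[full_halo] = HALO_LEVEL
        img[full_mask] = BODY_LEVEL + BODY_TEXTURE_AMPLITUDE * speckle[full_mask]
        body_total |= full_mask
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma)
    if pixel_noise_sd > 0:
        img = img + rng.normal(0.0, pixel_noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# experiment simulation
# ---------------------------------------------------------------------------

def _place_centers(rng: np.random.Generator, n: int, image_size: int,
                   margins: np.ndarray, max_tries: int = 200) -> np.ndarray:
    """Rejection-sample non-overlapping centres; may return fewer than n."""
    centers: list[np.ndarray] = []
    kept: list[int] = []
    for i in range(n):
        m = margins[i]
        if image_size - 2 * m <= 1:
            logger.warning("spheroid %d too large for field; dropped", i)
            continue
        for _ in range(max_tries):
            p = rng.uniform(m, image_size - m, size=2)
            if all(np.linalg.norm(p - c) >= margins[j] + m + 2
                   for c, j in zip(centers, kept)):
                centers.append(p)
                kept.append(i)
                break
        else:
            logger.warning(
                "could not place spheroid %d without overlap; "
                "reducing objects in this field", i)
    out = np.full((n, 2), np.nan)
    for c, j in zip(centers, kept):
        out[j] = c
    return out


def _simulate_well(cond: ConditionSpec, cfg: SynthConfig,
                   rng: np.random.Generator, render: bool):
    """One well: draw spheroid identities, trajectories, blur run; render."""
    n = cfg.spheroids_per_well
    r0 = rng.uniform(*cfg.radius_range, size=n)
    is_hyper = rng.random(n) < cond.p_hyper
    n_prot = np.where(is_hyper,
                      rng.integers(HYPER_N_PROTRUSIONS[0],
                                   HYPER_N_PROTRUSIONS[1] + 1, size=n), 0)
    p_len = np.where(is_hyper,
                     rng.uniform(*HYPER_PROTRUSION_LENGTH, size=n), 0.0)
    p_wid = rng.uniform(*HYPER_PROTRUSION_WIDTH, size=n)
    angles = [rng.uniform(0, 2 * np.pi, size=int(k)) for k in n_prot]

    r_final = r0 * (1.0 + cond.growth_rate * (cfg.n_frames - 1))
    margins = r_final * (1.0 + p_len) + HALO_WIDTH_PX + 3
    pos = _place_centers(rng, n, cfg.image_size, margins)
    alive = ~np.isnan(pos[:, 0])

    blurred = np.zeros(cfg.n_frames, dtype=bool)
    if rng.random() < cond.p_outfocus and cfg.n_frames >= BLUR_RUN_FRAMES[0]:
        run = int(rng.integers(BLUR_RUN_FRAMES[0],
                               min(BLUR_RUN_FRAMES[1], cfg.n_frames) + 1))
        start = int(rng.integers(0, cfg.n_frames - run + 1))
        blurred[start:start + run] = True

    stack = (np.empty((cfg.n_frames, cfg.image_size, cfg.image_size),
                      dtype=np.float32) if render else None)
    records = []
    for t in range(cfg.n_frames):
        hour = t + 1
        radius_t = r0 * (1.0 + cond.growth_rate * t)
        if t > 0:
            step = rng.normal(0.0, cond.drift_sd, size=(n, 2))
            pos = pos + step
            for i in np.nonzero(alive)[0]:
                pos[i] = np.clip(pos[i], margins[i],
                                 cfg.image_size - margins[i])
        active_hyper = is_hyper & (
            cond.hyper_onset is None or hour >= (cond.hyper_onset or 0))
        states = []
        for i in np.nonzero(alive)[0]:
            hy = bool(active_hyper[i])
            states.append(SpheroidState(
                centroid=(pos[i, 0], pos[i, 1]),
                radius=float(radius_t[i]),
                n_protrusions=int(n_prot[i]) if hy else 0,
                protrusion_length=float(p_len[i]) if hy else 0.0,
                protrusion_width=float(p_wid[i]),
                angles=angles[i]))
            records.append({
                "frame": hour, "spheroid_id": int(i),
                "morphology": HYPER if hy else SPHERICAL,
                "focus": OUT_OF_FOCUS if blurred[t] else IN_FOCUS,
                "centroid_row": float(round(pos[i, 0])),
                "centroid_col": float(round(pos[i, 1])),
                "radius": float(radius_t[i]),
                "n_protrusions": int(n_prot[i]) if hy else 0,
                "protrusion_length": float(p_len[i]) if hy else 0.0,
            })
        if render:
            stack[t] = render_frame(
                states, rng, cfg.image_size, cfg.pixel_noise_sd,
                blur_sigma=cond.blur_sigma if blurred[t] else 0.0)
    return stack, records


def simulate_experiment(config: SynthConfig,
                        render: bool = True) -> SynthExperiment:
    """Simulate the full condition x experiment x well hierarchy.

    Each well gets its own random stream derived from
    ``(seed, experiment, condition, well)``, so output is independent of
    iteration order and bit-identical across runs.  With ``render=False``
    only the ground-truth table is produced (fast path for statistical
    simulations).
    """
    stacks: dict[tuple[str, str, str], np.ndarray] = {}
    rows = []
    for e in range(config.n_experiments):
        exp_id = f"E{e + 1}"
        for ci, cond in enumerate(config.conditions):
            for w in range(config.wells_per_condition):
                well_id = f"W{w + 1}"
                ss = np.random.SeedSequence([config.seed, e, ci, w])
                rng = np.random.default_rng(ss)
                stack, recs = _simulate_well(cond, config, rng, render)
                if render:
                    stacks[(exp_id, cond.name, well_id)] = stack
                for r in recs:
                    r.update(experiment=exp_id, condition=cond.name,
                             well=well_id)
                rows.extend(recs)
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return SynthExperiment(config=config, stacks=stacks, truth=truth)


def simulate_object_gallery(n_per_class: int,
                            kind: str = "morphology",
                            seed: int = 0,
                            image_size: int = 128,
                            pixel_noise_sd: float = 0.02,
                            blur_sigma: float = 3.0,
                            radius_range: tuple[float, float] = (14.0, 22.0)):
    """Render single-spheroid frames for classifier training.

    ``kind="morphology"`` yields ``n_per_class`` Spherical (no protrusions)
    and ``n_per_class`` Hyper-protrusive objects, all sharp.
    ``kind="focus"`` yields sharp vs Gaussian-blurred frames of otherwise
    identically distributed spheroids.

    Returns ``(frames, labels)`` where frames is a (2n, H, W) float array
    and labels a list of class-name strings.
    """
    if kind not in ("morphology", "focus"):
        raise ValueError("kind must be 'morphology' or 'focus'")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 917]))
    frames = np.empty((2 * n_per_class, image_size, image_size),
                      dtype=np.float32)
    labels: list[str] = []
    classes = ([SPHERICAL, HYPER] if kind == "morphology"
               else [IN_FOCUS, OUT_OF_FOCUS])
    for i in range(2 * n_per_class):
        cls = classes[i % 2]
        radius = rng.uniform(*radius_range)
        protrusive = (kind == "morphology" and cls == HYPER)
        if kind == "focus":
            # focus pairs share the morphology prior of a mixed population
            protrusive = rng.random() < 0.3
        if protrusive:
            k = int(rng.integers(HYPER_N_PROTRUSIONS[0],
                                 HYPER_N_PROTRUSIONS[1] + 1))
            st = SpheroidState(
                centroid=(image_size / 2, image_size / 2), radius=radius,
                n_protrusions=k,
                protrusion_length=float(rng.uniform(*HYPER_PROTRUSION_LENGTH)),
                protrusion_width=float(rng.uniform(*HYPER_PROTRUSION_WIDTH)),
                angles=rng.uniform(0, 2 * np.pi, size=k))
        else:
            st = SpheroidState(centroid=(image_size / 2, image_size / 2),
                               radius=radius)
        sigma = blur_sigma if (kind == "focus" and cls == OUT_OF_FOCUS) else 0.0
        frames[i] = render_frame([st], rng, image_size, pixel_noise_sd,
                                 blur_sigma=sigma)
        labels.append(cls)
    return frames, labels


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def write_experiment(exp: SynthExperiment, outdir: str | Path) -> None:
    """Write per-well multi-page TIFF stacks, truth CSV and config YAML.

    Layout: ``<outdir>/<experiment>/<condition>/<well>.tif`` (float32,
    one page per hourly frame), ``truth.csv``, ``synth_config.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (e, c, w), stack in exp.stacks.items():
        d = outdir / e / c
        d.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(d / f"{w}.tif", stack)
    exp.truth.to_csv(outdir / "truth.csv", index=False)
    exp.config.to_yaml(outdir / "synth_config.yaml")


def read_stacks(indir: str | Path) -> dict[tuple[str, str, str], np.ndarray]:
    """Read back stacks written by :func:`write_experiment`."""
    indir = Path(indir)
    stacks = {}
    for tif in sorted(indir.glob("*/*/*.tif")):
        e, c, w = tif.parent.parent.name, tif.parent.name, tif.stem
        stacks[(e, c, w)] = tifffile.imread(tif)
    return stacks
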