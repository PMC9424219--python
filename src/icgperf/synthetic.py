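"""Seeded synthetic ROI patches, labeled datasets and tracking sequences.

The surgical videos this method was developed on are not publicly
deposited, so this module generates image material with the statistical
structure the classifier and tracker assume:

* **adequate** perfusion — the ROI's green channel is uniformly bright
  (ICG fluorescence fills the whole region);
* **inadequate, low green** — uniformly dim green (little or no dye
  reached the segment);
* **inadequate, non-uniform** — only a left fraction of the ROI columns
  is bright (partial ICG diffusion across the segment).

Red and blue channels carry a tissue-colored background with Gaussian
noise.  All pixel draws are clipped to [0, 255] and quantized to uint8,
and every random quantity flows from one seeded generator per call, so
identical parameters and seed give byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SceneParams",
    "LabeledSample",
    "TrackingSequence",
    "ADEQUATE",
    "INADEQUATE",
    "generate_roi_patch",
    "generate_dataset",
    "generate_tracking_sequence",
    "write_dataset",
    "write_tracking_sequence",
]

ADEQUATE = 1
INADEQUATE = 0

#: green mean below which a uniformly filled ROI no longer counts as adequate
ADEQUACY_GREEN_THRESHOLD = 150.0


@dataclass(frozen=True)
class SceneParams:
    """Generating parameters for one synthetic ROI patch.

    ``perfused_fraction`` is the fraction of ROI *columns* (from the
    left) whose green channel is drawn around ``green_mu_high``; the
    remaining columns are drawn around ``green_mu_low``.  A fraction of
    1.0 with a bright mean models adequate perfusion; 0.0 models the
    uniformly dim failure mode and intermediate values the non-uniform
    one.
    """

    roi_width: int = 64
    roi_height: int = 48
    green_mu_high: float = 180.0
    green_mu_low: float = 20.0
    green_sigma: float = 12.0
    perfused_fraction: float = 1.0
    red_mu: float = 80.0
    blue_mu: float = 70.0
    noise_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.roi_width <= 0 or self.roi_height <= 0:
            raise ValueError(
                f"ROI must have positive area, got "
                f"{self.roi_width}x{self.roi_height}"
            )
        for name in ("green_mu_high", "green_mu_low", "red_mu", "blue_mu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if not 0.0 <= self.perfused_fraction <= 1.0:
            raise ValueError(
                f"perfused_fraction={self.perfused_fraction} outside [0, 1]"
            )
        if self.green_sigma < 0 or self.noise_sd < 0:
            raise ValueError("sigma values must be non-negative")

    @property
    def label(self) -> int:
        """Ground-truth perfusion label implied by the parameters alone."""
        if (
            self.perfused_fraction >= 1.0
            and self.green_mu_high >= ADEQUACY_GREEN_THRESHOLD
        ):
            return ADEQUATE
        return INADEQUATE


@dataclass(frozen=True)
class LabeledSample:
    """One ROI patch with its generator-determined perfusion label."""

    patch: np.ndarray  # (H, W, 3) uint8, logical RGB
    label: int
    params: SceneParams


@dataclass(frozen=True)
class TrackingSequence:
    """Frames plus per-frame ground truth for tracker evaluation.

    ``truth_boxes[i]`` is ``(x, y, w, h)`` or ``None`` exactly on frames
    inside ``occlusion_interval`` (inclusive range), where the target is
    hidden behind background.
    """

    frames: list  # list of (H, W, 3) uint8 arrays
    truth_boxes: list  # list of tuple | None
    occlusion_interval: Optional[tuple]


def _clipped_normal(rng: np.random.Generator, mu, sigma, shape) -> np.ndarray:
    vals = rng.normal(mu, sigma, size=shape) if np.any(np.asarray(sigma) > 0) else np.broadcast_to(np.asarray(mu, dtype=float), shape).copy()
    return np.clip(np.rint(vals), 0, 255).astype(np.uint8)


def generate_roi_patch(params: SceneParams) -> LabeledSample:
    """Draw one synthetic ROI patch from :class:`SceneParams`.

    The green channel is per-pixel ``clip(round(N(mu, green_sigma)))``
    with ``mu = green_mu_high`` for the leftmost ``perfused_fraction``
    of the columns and ``green_mu_low`` elsewhere; red/blue come from
    ``N(red_mu/blue_mu, noise_sd)``.  Deterministic given ``seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.roi_height, params.roi_width
    n_bright = int(round(params.perfused_fraction * w))

    mu = np.full(w, params.green_mu_low, dtype=float)
    mu[:n_bright] = params.green_mu_high
    green = _clipped_normal(rng, np.broadcast_to(mu, (h, w)), params.green_sigma, (h, w))
    red = _clipped_normal(rng, params.red_mu, params.noise_sd, (h, w))
    blue = _clipped_normal(rng, params.blue_mu, params.noise_sd, (h, w))

    patch = np.stack([red, green, blue], axis=-1)
    return LabeledSample(patch=patch, label=params.label, params=params)


def generate_dataset(
    n: int,
    class_balance: float = 0.5,
    base_params: Optional[SceneParams] = None,
    seed: int = 0,
    nonuniform_fraction: float = 0.5,
) -> list:
    """Generate ``n`` labeled samples with an exact class split.

    Exactly ``round(n * class_balance)`` samples are adequate.  The
    inadequate remainder is split between the low-green and non-uniform
    variants (``nonuniform_fraction`` of them non-uniform, default
    50/50).  Per-sample means and fractions are jittered from one
    seeded stream:

    * adequate: ``green_mu_high ~ U[150, 230]``, full coverage;
    * low green: ``green_mu_low ~ U[5, 20]``, zero coverage;
    * non-uniform: bright/dim means as above, coverage ``U[0.3, 0.7]``.

    Dim means stay below the default feature-extraction threshold k=25,
    whose purpose is exactly to exclude pixels with low green: tissue
    without adequate ICG uptake contributes (almost) nothing to the
    histogram area.

    Sample order is shuffled by the same stream; labels never leak from
    the feature pipeline — they are fixed by the generating parameters.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if not 0.0 <= class_balance <= 1.0:
        raise ValueError(f"class_balance={class_balance} outside [0, 1]")
    base = base_params if base_params is not None else SceneParams()
    base.validate()
    rng = np.random.default_rng(seed)

    n_adequate = int(round(n * class_balance))
    n_inadequate = n - n_adequate
    n_nonuniform = int(round(n_inadequate * nonuniform_fraction))
    n_lowgreen = n_inadequate - n_nonuniform

    specs = []
    for _ in range(n_adequate):
        specs.append(
            dict(green_mu_high=float(rng.uniform(150, 230)), perfused_fraction=1.0)
        )
    for _ in range(n_lowgreen):
        specs.append(
            dict(green_mu_low=float(rng.uniform(5, 20)), perfused_fraction=0.0)
        )
    for _ in range(n_nonuniform):
        specs.append(
            dict(
                green_mu_high=float(rng.uniform(150, 230)),
                green_mu_low=float(rng.uniform(5, 20)),
                perfused_fraction=float(rng.uniform(0.3, 0.7)),
            )
        )

    order = rng.permutation(len(specs))
    samples = []
    for idx in order:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params = dataclasses.replace(base, seed=sub_seed, **specs[idx])
        samples.append(generate_roi_patch(params))
    return samples


def _tissue_background(
    rng: np.random.Generator, height: int, width: int, params: SceneParams
) -> np.ndarray:
    bg = np.empty((height, width, 3), dtype=np.uint8)
    bg[..., 0] = _clipped_normal(rng, params.red_mu, params.noise_sd, (height, width))
    bg[..., 1] = _clipped_normal(rng, params.green_mu_low, params.noise_sd, (height, width))
    bg[..., 2] = _clipped_normal(rng, params.blue_mu, params.noise_sd, (height, width))
    return bg


def generate_tracking_sequence(
    params: Optional[SceneParams] = None,
    n_frames: int = 60,
    velocity: tuple = (0, 0),
    occlusion: Optional[tuple] = None,
    seed: int = 0,
    frame_shape: tuple = (240, 320),
    start: Optional[tuple] = None,
) -> TrackingSequence:
    """A bright, textured green patch translating over noisy background.

    ``velocity`` is integer ``(vx, vy)`` pixels/frame; the target keeps
    a fixed texture (drawn once, seeded) so correlation trackers have
    structure to lock onto.  During the inclusive ``occlusion`` frame
    range the patch is not drawn, its position is frozen, and the truth
    box is recorded as absent (``None``).

    Raises ``ValueError`` if the motion would push the target outside
    the frame.
    """
    params = params if params is not None else SceneParams()
    params.validate()
    fh, fw = frame_shape
    th, tw = params.roi_height, params.roi_width
    vx, vy = int(velocity[0]), int(velocity[1])
    if start is None:
        x0, y0 = (fw - tw) // 4, (fh - th) // 2
    else:
        x0, y0 = start

    rng = np.random.default_rng(seed)
    # fixed target appearance: bright green patch + frozen smooth texture
    # (fluorescent tissue is smoothly mottled, not white noise; smoothness
    # also gives correlation trackers the low-frequency structure real
    # targets have)
    from scipy.ndimage import gaussian_filter

    raw = rng.normal(0.0, 1.0, size=(th, tw))
    smooth = gaussian_filter(raw, sigma=2.5, mode="reflect")
    texture = smooth * (25.0 / max(smooth.std(), 1e-9))
    target = np.empty((th, tw, 3), dtype=np.uint8)
    target[..., 0] = np.clip(np.rint(params.red_mu + texture), 0, 255)
    target[..., 1] = np.clip(np.rint(params.green_mu_high + texture), 0, 255)
    target[..., 2] = np.clip(np.rint(params.blue_mu + texture), 0, 255)

    def occluded(i: int) -> bool:
        return occlusion is not None and occlusion[0] <= i <= occlusion[1]

    # pre-validate trajectory
    x, y = x0, y0
    positions = []
    for i in range(n_frames):
        positions.append((x, y))
        if not (0 <= x <= fw - tw and 0 <= y <= fh - th):
            raise ValueError(
                f"target leaves the frame at frame {i}: box ({x},{y},{tw},{th})"
            )
        if not occluded(i):
            x, y = x + vx, y + vy

    frames, truth = [], []
    for i in range(n_frames):
        frame = _tissue_background(rng, fh, fw, params)
        px, py = positions[i]
        if occluded(i):
            truth.append(None)
        else:
            frame[py : py + th, px : px + tw] = target
            truth.append((px, py, tw, th))
        frames.append(frame)
    return TrackingSequence(frames=frames, truth_boxes=truth, occlusion_interval=occlusion)


def write_dataset(samples: Sequence[LabeledSample], outdir) -> Path:
    """Write patches as PNGs plus a CSV manifest; returns manifest path."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        fname = f"patch_{i:05d}.png"
        iio.imwrite(outdir / fname, s.patch)
        row = {"filename": fname, "label": s.label}
        row.update(dataclasses.asdict(s.params))
        rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_tracking_sequence(seq: TrackingSequence, outdir) -> Path:
    """Write numbered PNG frames plus a CSV of truth boxes."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (frame, box) in enumerate(zip(seq.frames, seq.truth_boxes)):
        fname = f"frame_{i:05d}.png"
        iio.imwrite(outdir / fname, frame)
        if box is None:
            rows.append({"frame": i, "x": "", "y": "", "w": "", "h": "", "visible": 0})
        else:
            x, y, w, h = box
            rows.append({"frame": i, "x": x, "y": y, "w": w, "h": h, "visible": 1})
    truth = outdir / "truth_boxes.csv"
    pd.DataFrame(rows).to_csv(truth, index=False)
    return truth
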