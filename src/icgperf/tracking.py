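"""Adaptive correlation-filter (MOSSE) tracking of the operator's ROI.

The Minimum Output Sum of Squared Error tracker learns a correlation
filter H over the ROI window in the frequency domain by minimising the
squared error between the filtered window and a Gaussian peak centred
on the target.  Per frame it correlates H with the window at the last
known position, moves the box to the response peak, and updates H with
exponential forgetting.  Tracking confidence is the peak-to-sidelobe
ratio (PSR) of the response map; when PSR drops below a threshold the
target is considered lost (e.g. the surgeon covers it), the tracker
pauses — leaving the filter untouched and the search window where it
was — and it resumes automatically when PSR recovers.

Tracking runs on the grayscale projection of the frame: locating the
ROI and assessing its perfusion are separate concerns, so the green
channel is reserved for the feature extractor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "ROIBox",
    "TrackerConfig",
    "TrackerStatus",
    "MosseTracker",
    "psr",
]

MIN_ROI_SIDE = 16
PSR_EXCLUSION = 11  # side of the window around the peak excluded from the sidelobe
REG_EPS = 1e-5  # regulariser added to the filter denominator


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned box: 0-based top-left corner, half-open extent.

    Covered columns are ``x .. x+w-1`` and rows ``y .. y+h-1``.
    """

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive size, got {self.w}x{self.h}")

    @property
    def center(self) -> Tuple[float, float]:
        return (self.x + (self.w - 1) / 2.0, self.y + (self.h - 1) / 2.0)

    def within(self, frame_shape: Tuple[int, int]) -> bool:
        fh, fw = frame_shape[:2]
        return 0 <= self.x and 0 <= self.y and self.x + self.w <= fw and self.y + self.h <= fh

    def clamped(self, frame_shape: Tuple[int, int]) -> "ROIBox":
        fh, fw = frame_shape[:2]
        x = min(max(self.x, 0), fw - self.w)
        y = min(max(self.y, 0), fh - self.h)
        return replace(self, x=x, y=y)


class TrackerStatus(Enum):
    TRACKING = "tracking"
    PAUSED = "paused"


@dataclass(frozen=True)
class TrackerConfig:
    """MOSSE constants (canonical published recipe, all overridable).

    ``learning_rate`` is the exponential-forgetting weight of the newest
    frame in the filter update; ``gaussian_sigma`` the width in pixels
    of the target response peak; ``n_perturbations`` the number of small
    random affine warps aggregated at initialisation; PSR below
    ``psr_pause_threshold`` pauses tracking and PSR at or above
    ``psr_resume_threshold`` resumes it.
    """

    learning_rate: float = 0.125
    gaussian_sigma: float = 2.0
    n_perturbations: int = 8
    psr_pause_threshold: float = 8.0
    psr_resume_threshold: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")


def psr(response: np.ndarray, exclusion: int = PSR_EXCLUSION) -> float:
    """Peak-to-sidelobe ratio of a correlation response map.

    ``(peak - mean(sidelobe)) / std(sidelobe)`` where the sidelobe is
    every pixel outside an ``exclusion`` x ``exclusion`` window centred
    on the peak.  The first peak in row-major order breaks ties.  A
    zero-variance sidelobe (e.g. a single spike in a constant field)
    yields ``math.inf`` as a documented sentinel meaning "confidence not
    measurable but the peak is unambiguous".
    """
    response = np.asarray(response, dtype=float)
    if response.size == 0:
        raise ValueError("empty response map")
    py, px = np.unravel_index(np.argmax(response), response.shape)
    peak = response[py, px]
    half = exclusion // 2
    mask = np.ones_like(response, dtype=bool)
    mask[max(0, py - half) : py + half + 1, max(0, px - half) : px + half + 1] = False
    side = response[mask]
    if side.size == 0:
        return math.inf
    sd = side.std()
    if sd == 0.0:
        return math.inf if peak > side.mean() else 0.0
    return float((peak - side.mean()) / sd)


def _grayscale(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return frame.astype(float)
    # ITU-R 601 luma of the logical RGB triple
    return frame[..., 0] * 0.299 + frame[..., 1] * 0.587 + frame[..., 2] * 0.114


def _preprocess(window: np.ndarray, hann: np.ndarray) -> np.ndarray:
    # log compression tames lighting variation; zero-mean unit-norm then
    # a cosine window suppresses boundary discontinuities
    w = np.log1p(window.astype(float))
    w -= w.mean()
    norm = np.linalg.norm(w)
    if norm > 0:
        w /= norm
    return w * hann


def _gaussian_peak(h: int, w: int, sigma: float) -> np.ndarray:
    ys, xs = np.mgrid[0:h, 0:w]
    cy, cx = h // 2, w // 2
    return np.exp(-((ys - cy) ** 2 + (xs - cx) ** 2) / (2.0 * sigma**2))


def _random_warp(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Small random rotation/scale about the patch centre (init augmentation)."""
    angle = rng.uniform(-0.1, 0.1)  # radians
    scale = rng.uniform(0.95, 1.05)
    c, s = math.cos(angle) * scale, math.sin(angle) * scale
    mat = np.array([[c, -s], [s, c]])
    h, w = patch.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - mat @ center
    return ndimage.affine_transform(patch, mat, offset=offset, mode="reflect", order=1)


class MosseTracker:
    """Stateful single-target tracker over a fixed-size ROI window.

    Usage::

        tracker = MosseTracker(config)
        tracker.init(frame0, ROIBox(x, y, w, h))
        box, psr_value = tracker.update(frame1)   # box is None while paused

    Attributes (after ``init``)
    ---------------------------
    status : TrackerStatus
        TRACKING or PAUSED.
    last_box_ : ROIBox
        Most recent target location (kept while paused).
    filter_numerator_, filter_denominator_ : complex ndarray
        The running MOSSE filter terms over the window's FFT grid.
    """

    def __init__(self, config: Optional[TrackerConfig] = None):
        self.config = config if config is not None else TrackerConfig()
        self.config.validate()
        self.status: Optional[TrackerStatus] = None

    # -- lifecycle -----------------------------------------------------

    def init(self, frame: np.ndarray, roi: ROIBox) -> "MosseTracker":
        frame = np.asarray(frame)
        if roi.w < MIN_ROI_SIDE or roi.h < MIN_ROI_SIDE:
            raise ValueError(
                f"ROI {roi.w}x{roi.h} smaller than minimum "
                f"{MIN_ROI_SIDE}x{MIN_ROI_SIDE}"
            )
        if not roi.within(frame.shape):
            raise ValueError(f"ROI {roi} extends past frame bounds {frame.shape[:2]}")

        self._frame_shape = frame.shape[:2]
        self._hann = np.outer(np.hanning(roi.h), np.hanning(roi.w))
        self._goal = np.fft.fft2(_gaussian_peak(roi.h, roi.w, self.config.gaussian_sigma))

        gray = _grayscale(frame)
        patch = gray[roi.y : roi.y + roi.h, roi.x : roi.x + roi.w]
        rng = np.random.default_rng(self.config.seed)

        num = np.zeros((roi.h, roi.w), dtype=complex)
        den = np.zeros((roi.h, roi.w), dtype=complex)
        variants = [patch] + [
            _random_warp(patch, rng) for _ in range(self.config.n_perturbations)
        ]
        for p in variants:
            F = np.fft.fft2(_preprocess(p, self._hann))
            num += self._goal * np.conj(F)
            den += F * np.conj(F)
        self.filter_numerator_ = num
        self.filter_denominator_ = den
        self.last_box_ = roi
        self.status = TrackerStatus.TRACKING
        return self

    # -- per-frame update ----------------------------------------------

    def _response(self, gray: np.ndarray, box: ROIBox) -> np.ndarray:
        window = gray[box.y : box.y + box.h, box.x : box.x + box.w]
        F = np.fft.fft2(_preprocess(window, self._hann))
        H = self.filter_numerator_ / (self.filter_denominator_ + REG_EPS)
        return np.real(np.fft.ifft2(H * F))

    def update(self, frame: np.ndarray):
        """Advance one frame; returns ``(box_or_None, psr_value)``.

        While TRACKING, the box follows the response peak and the filter
        is refreshed with exponential forgetting.  A PSR below the pause
        threshold switches to PAUSED: the box is reported absent and the
        filter is left bitwise unchanged until the PSR at the last box
        recovers past the resume threshold.
        """
        if self.status is None:
            raise RuntimeError("tracker not initialised; call init() first")
        frame = np.asarray(frame)
        if frame.shape[:2] != self._frame_shape:
            raise ValueError(
                f"frame size {frame.shape[:2]} differs from initialisation "
                f"size {self._frame_shape}"
            )
        gray = _grayscale(frame)
        box = self.last_box_
        resp = self._response(gray, box)
        confidence = psr(resp)

        if self.status is TrackerStatus.PAUSED:
            if confidence >= self.config.psr_resume_threshold:
                self.status = TrackerStatus.TRACKING
            else:
                return None, confidence
        elif confidence < self.config.psr_pause_threshold:
            self.status = TrackerStatus.PAUSED
            return None, confidence

        # integer peak localisation; displacement relative to window centre
        py, px = np.unravel_index(np.argmax(resp), resp.shape)
        dy, dx = py - box.h // 2, px - box.w // 2
        new_box = ROIBox(box.x + dx, box.y + dy, box.w, box.h).clamped(self._frame_shape)

        # filter update on the window at the new location
        window = gray[new_box.y : new_box.y + new_box.h, new_box.x : new_box.x + new_box.w]
        F = np.fft.fft2(_preprocess(window, self._hann))
        lr = self.config.learning_rate
        self.filter_numerator_ = (
            lr * self._goal * np.conj(F) + (1 - lr) * self.filter_numerator_
        )
        self.filter_denominator_ = (
            lr * F * np.conj(F) + (1 - lr) * self.filter_denominator_
        )
        self.last_box_ = new_box
        return new_box, confidence
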