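"""End-to-end frame loop: track the ROI, extract features, classify.

For every frame the tracker proposes the ROI's current location.  While
it reports TRACKING, the boxed patch goes through the green-band
histogram-area extractor and the trained classifier, yielding a score
(probability of adequate perfusion) and a binary label.  While the
tracker is PAUSED (target hidden, low PSR) the frame is logged as
SKIPPED with no label — the system never guesses perfusion for tissue
it cannot see.

The offline entry point (``run_offline``) and the streaming one
(``run_stream``) share the same per-frame code path, so a file-backed
stream and an offline run over identical frames produce bit-identical
predictions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional

import numpy as np
import pandas as pd

from .classifier import FeedForwardNetClassifier
from .features import HistogramSpec, extract_features
from .tracking import MosseTracker, ROIBox, TrackerConfig, TrackerStatus

__all__ = [
    "PipelineConfig",
    "FramePrediction",
    "iter_frames",
    "run_offline",
    "run_stream",
    "predictions_frame",
    "save_model",
    "load_model",
    "annotate_frame",
]

SKIPPED = "SKIPPED"

FRAME_EXTENSIONS = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")


@dataclass
class PipelineConfig:
    """Everything the frame loop needs besides the frames themselves."""

    roi: ROIBox
    model: object = None  # a fitted classifier; or set model_path
    model_path: Optional[str] = None
    k: int = 25
    normalize: bool = False
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    seed: int = 0

    def resolve_model(self):
        if self.model is not None:
            return self.model
        if self.model_path is None:
            raise ValueError("pipeline needs a model or a model_path")
        path = Path(self.model_path)
        if not path.exists():
            raise FileNotFoundError(f"model file not found: {path}")
        return load_model(path)


@dataclass(frozen=True)
class FramePrediction:
    """Per-frame pipeline output; label is SKIPPED while the tracker pauses."""

    frame_index: int
    roi_used: Optional[ROIBox]
    psr: float
    status: str
    score: Optional[float]
    label: object  # int label, or SKIPPED
    latency_s: float = 0.0


def iter_frames(source) -> Iterator[np.ndarray]:
    """Yield RGB uint8 frames from a directory of images or a video file.

    A directory is read as its image files in sorted name order.  For a
    video container an imageio plugin capable of decoding it must be
    available; otherwise a clear input error is raised.
    """
    import imageio.v3 as iio

    path = Path(source)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in FRAME_EXTENSIONS
        )
        if not files:
            raise ValueError(f"no image frames found in directory {path}")
        for f in files:
            yield _as_rgb(iio.imread(f))
        return
    if not path.exists():
        raise FileNotFoundError(f"input not found: {path}")
    try:
        for frame in iio.imiter(path):
            yield _as_rgb(np.asarray(frame))
    except Exception as exc:  # plugin missing or corrupt file
        raise ValueError(
            f"cannot decode {path}: {exc}. Provide a directory of PNG/TIFF "
            "frames, or install an imageio video plugin."
        ) from exc


def _as_rgb(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        frame = np.stack([frame] * 3, axis=-1)
    return frame[..., :3]


def _frame_loop(
    frames: Iterable[np.ndarray], config: PipelineConfig
) -> Iterator[FramePrediction]:
    model = config.resolve_model()
    spec = HistogramSpec(k=config.k)
    tracker = MosseTracker(config.tracker)
    initialised = False
    for i, frame in enumerate(frames):
        t0 = time.perf_counter()
        if not initialised:
            tracker.init(frame, config.roi)
            box, psr_value = config.roi, float("inf")
            initialised = True
        else:
            box, psr_value = tracker.update(frame)
        status = tracker.status.value
        if box is None:
            yield FramePrediction(
                i, None, psr_value, status, None, SKIPPED,
                time.perf_counter() - t0,
            )
            continue
        patch = frame[box.y : box.y + box.h, box.x : box.x + box.w]
        feats = extract_features(patch, spec, normalize=config.normalize)
        score = float(model.decision_scores(feats[None, :])[0])
        label = int(score > 0.5)
        yield FramePrediction(
            i, box, psr_value, status, score, label, time.perf_counter() - t0
        )


def run_stream(
    frames: Iterable[np.ndarray],
    config: PipelineConfig,
    csv_path=None,
) -> List[FramePrediction]:
    """Consume a frame iterator; per-frame latency is measured and logged.

    The CSV log is flushed even if the source disconnects mid-stream,
    so a partial log survives a broken camera feed.
    """
    preds: List[FramePrediction] = []
    try:
        for p in _frame_loop(frames, config):
            preds.append(p)
    finally:
        if csv_path is not None and preds:
            predictions_frame(preds).to_csv(csv_path, index=False)
    if not preds:
        raise ValueError("input produced no frames")
    return preds


def run_offline(
    source,
    config: PipelineConfig,
    csv_path=None,
    annotate_dir=None,
) -> List[FramePrediction]:
    """Analyse a recorded video or frame directory.

    Optionally writes a per-frame CSV log and annotated PNG frames
    (box drawn green for adequate, red for inadequate, gray while the
    tracker is paused).
    """
    frames = list(iter_frames(source))
    if not frames:
        raise ValueError(f"input {source} produced no frames")
    preds = run_stream(iter(frames), config, csv_path=csv_path)
    if annotate_dir is not None:
        import imageio.v3 as iio

        outdir = Path(annotate_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for frame, p in zip(frames, preds):
            iio.imwrite(
                outdir / f"frame_{p.frame_index:05d}.png", annotate_frame(frame, p)
            )
    return preds


def predictions_frame(preds: List[FramePrediction]) -> pd.DataFrame:
    rows = []
    for p in preds:
        b = p.roi_used
        rows.append(
            {
                "frame_index": p.frame_index,
                "x": b.x if b else "",
                "y": b.y if b else "",
                "w": b.w if b else "",
                "h": b.h if b else "",
                "psr": p.psr,
                "status": p.status,
                "score": "" if p.score is None else p.score,
                "label": p.label,
                "latency_s": p.latency_s,
            }
        )
    return pd.DataFrame(rows)


_COLORS = {1: (0, 220, 0), 0: (220, 0, 0), SKIPPED: (150, 150, 150)}


def annotate_frame(frame: np.ndarray, pred: FramePrediction, thickness: int = 2) -> np.ndarray:
    """Copy of the frame with the tracked box drawn in the label's color."""
    out = frame.copy()
    box = pred.roi_used
    if box is None:
        return out
    color = _COLORS.get(pred.label, _COLORS[SKIPPED])
    x0, y0, x1, y1 = box.x, box.y, box.x + box.w - 1, box.y + box.h - 1
    t = thickness
    out[y0 : y0 + t, x0 : x1 + 1] = color
    out[max(y1 - t + 1, 0) : y1 + 1, x0 : x1 + 1] = color
    out[y0 : y1 + 1, x0 : x0 + t] = color
    out[y0 : y1 + 1, max(x1 - t + 1, 0) : x1 + 1] = color
    return out


# -- model persistence -------------------------------------------------


def save_model(model, path) -> Path:
    """Serialise a fitted classifier to one file, config embedded.

    Feed-forward networks are stored as ``.npz`` (weights plus a JSON
    header of hyperparameters); other estimators (SVMs) go through
    joblib.
    """
    import json

    path = Path(path)
    if isinstance(model, FeedForwardNetClassifier):
        header = json.dumps(
            {
                "kind": "ffnn",
                "params": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in model.get_params().items()
                },
                "n_out": model._n_out,
                "n_features_in": int(model.n_features_in_),
            }
        )
        arrays = {}
        for i, w in enumerate(model.coefs_):
            arrays[f"W{i}"] = w
        for i, b in enumerate(model.intercepts_):
            arrays[f"b{i}"] = b
        with open(path, "wb") as fh:  # keep the exact filename, whatever suffix
            np.savez(fh, header=np.array(header), **arrays)
        return path
    import joblib

    joblib.dump(model, path)
    return path


def load_model(path):
    """Inverse of :func:`save_model`."""
    import json

    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as data:
            if "header" not in data:
                raise ValueError("not an icgperf model archive")
            header = json.loads(str(data["header"]))
            params = header["params"]
            if "hidden_layer_sizes" in params:
                params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
            if isinstance(params.get("activation"), list):
                params["activation"] = tuple(params["activation"])
            model = FeedForwardNetClassifier(**params)
            n_layers = sum(1 for k in data.files if k.startswith("W"))
            model.coefs_ = [data[f"W{i}"] for i in range(n_layers)]
            model.intercepts_ = [data[f"b{i}"] for i in range(n_layers)]
            model._n_out = header["n_out"]
            model.n_features_in_ = header["n_features_in"]
            model.classes_ = np.array([0, 1])
            model.n_parameters_ = int(
                sum(w.size for w in model.coefs_)
                + sum(b.size for b in model.intercepts_)
            )
            return model
    except (ValueError, OSError):
        pass
    import joblib

    return joblib.load(path)
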