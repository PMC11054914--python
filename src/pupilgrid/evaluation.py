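"""Accuracy statistics for pupil-center detection.

The statistics are the ones eye-tracking papers report:

* per-image pixel error — the Euclidean distance between detected and
  hand-labeled centers;
* DRk, the detection rate at k pixels — the percentage of images whose
  pixel error is <= k (inclusive threshold); DR5 is the usual headline
  operating point and the curve is tabulated at integer k = 0..10;
* sigma — the population standard deviation of the pixel errors, a proxy
  for on-screen cursor stability;
* lost frames — images with error > 10 px.

Pooling across datasets concatenates raw distances and recomputes the
statistics (never an average of per-dataset rates).

:func:`temporal_smooth` is a consecutive-frame stabilizer for live use:
within an odd sliding window, coordinates too far from the window median
are discarded and the remainder averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import PupilAnnotation
from .errors import ConfigError, CountError

LOST_FRAME_THRESHOLD = 10.0  # px
DRK_MAX = 10  # DRk curve tabulated at k = 0..10


def pixel_error(ideal: PupilAnnotation, detected: PupilAnnotation) -> float:
    """Euclidean distance between two centers, in pixels."""
    return float(np.hypot(ideal.cx - detected.cx, ideal.cy - detected.cy))


def detection_rate(distances: Sequence[float], k: float) -> float:
    """Percentage of distances <= k (inclusive)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise CountError("distance list is empty")
    if k < 0:
        raise CountError(f"k must be >= 0, got {k}")
    return 100.0 * float(np.count_nonzero(d <= k)) / d.size


def sigma(distances: Sequence[float]) -> float:
    """Population standard deviation of the pixel-error distribution."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise CountError("distance list is empty")
    return float(np.std(d))


@dataclass
class EvalReport:
    distances: list
    drk: list = field(default_factory=list)  # [(k, rate%)] for k = 0..10
    dr5: float = 0.0
    sigma: float = 0.0
    n_images: int = 0
    lost_frames: int = 0
    source_tag: str = ""

    @classmethod
    def from_distances(cls, distances, source_tag: str = "") -> "EvalReport":
        d = [float(x) for x in distances]
        if not d:
            raise CountError("cannot build a report from zero images")
        drk = [(k, detection_rate(d, k)) for k in range(DRK_MAX + 1)]
        return cls(
            distances=d,
            drk=drk,
            dr5=detection_rate(d, 5),
            sigma=sigma(d),
            n_images=len(d),
            lost_frames=int(np.count_nonzero(
                np.asarray(d) > LOST_FRAME_THRESHOLD)),
            source_tag=source_tag,
        )

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "dr5": self.dr5,
            "sigma": self.sigma,
            "lost_frames": self.lost_frames,
            "drk": [[k, r] for k, r in self.drk],
            "source_tag": self.source_tag,
            "distances": self.distances,
        }


def evaluate(x_params, y_params, samples, source_tag: str = "") -> EvalReport:
    """Run the X/Y classifier pair on every sample and score the errors."""
    from .network import predict_centers_batch

    if not samples:
        raise CountError("no samples to evaluate")
    images = np.stack([s.image for s in samples])
    preds = predict_centers_batch(x_params, y_params, images)
    dists = [pixel_error(s.annotation, p) for s, p in zip(samples, preds)]
    return EvalReport.from_distances(dists, source_tag)


def evaluate_predictor(predict_fn, samples, source_tag: str = "") -> EvalReport:
    """Score an arbitrary ``image -> PupilAnnotation`` predictor."""
    if not samples:
        raise CountError("no samples to evaluate")
    dists = [
        pixel_error(s.annotation, predict_fn(s.image)) for s in samples
    ]
    return EvalReport.from_distances(dists, source_tag)


def pooled_report(reports: Sequence[EvalReport]) -> EvalReport:
    """Concatenate raw distances of several reports and recompute.

    Never averages rates — a 10-image and a 30-image report pool as 40
    individual distances.
    """
    if not reports:
        raise CountError("no reports to pool")
    dists = [d for r in reports for d in r.distances]
    tags = sorted({r.source_tag for r in reports if r.source_tag})
    return EvalReport.from_distances(dists, source_tag="+".join(tags))


def temporal_smooth(
    centers: Sequence[PupilAnnotation],
    window: int,
    outlier_threshold: float,
) -> list:
    """Median-anchored smoothing of a time-ordered center sequence.

    For every frame, the coordinates inside the (truncated at the ends)
    window whose Euclidean distance to the componentwise window median
    exceeds ``outlier_threshold`` are dropped; the remaining coordinates are
    averaged and rounded.  If the rejection empties the window, the frame's
    own coordinate is kept.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"window must be odd and >= 1, got {window}")
    pts = np.asarray([(c.cx, c.cy) for c in centers], dtype=float)
    half = window // 2
    out = []
    for i in range(len(pts)):
        lo, hi = max(0, i - half), min(len(pts), i + half + 1)
        win = pts[lo:hi]
        med = np.median(win, axis=0)
        keep = np.hypot(*(win - med).T) <= outlier_threshold
        sel = win[keep] if keep.any() else pts[i:i + 1]
        mean = sel.mean(axis=0)
        out.append(
            PupilAnnotation(int(np.floor(mean[0] + 0.5)),
                            int(np.floor(mean[1] + 0.5)))
        )
    return out
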