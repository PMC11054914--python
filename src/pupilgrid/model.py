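"""Model/Results front-end for the pupil-center classifiers.

:class:`PupilCenterModel` is built from labeled samples and an architecture
name; ``fit()`` runs the staged SGD protocol and returns a
:class:`PupilCenterResults` carrying the trained parameters, the per-epoch
history, the evaluation report on the held-out test split and a
``summary()`` table.

Two architectures are supported:

``lowres``
    the fully connected 300-class position classifier for 20x15 images;
``cnn``
    the parallel pair of slim convolutional classifiers for 320x240 images,
    one predicting the column (x) and one the row (y) of the pupil center.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from . import network
from .dataio import LabeledSample, PupilAnnotation, class_to_coord
from .errors import ConfigError, ShapeError
from .evaluation import EvalReport, evaluate, evaluate_predictor
from .netspec import coordinate_cnn_spec, count_parameters, lowres_spec
from .training import (
    TrainConfig,
    lowres_target,
    split_dataset,
    train,
    x_target,
    y_target,
)

_ARCHS = ("lowres", "cnn")


def _derived_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0]
               % (2**31))


class PupilCenterModel:
    """A pupil-center detection model bound to a labeled dataset.

    Parameters
    ----------
    samples : sequence of LabeledSample
        The full dataset; ``fit`` splits it into train/val/test.
    arch : {'lowres', 'cnn'}
    """

    def __init__(self, samples: Sequence[LabeledSample], arch: str = "lowres"):
        if arch not in _ARCHS:
            raise ConfigError(f"arch must be one of {_ARCHS}, got {arch!r}")
        self.arch = arch
        self.samples = list(samples)
        if arch == "lowres":
            self.specs = {"grid": lowres_spec()}
        else:
            self.specs = {"x": coordinate_cnn_spec("x"),
                          "y": coordinate_cnn_spec("y")}
        h, w = next(iter(self.specs.values())).input_shape
        for s in self.samples:
            if s.image.shape != (h, w):
                raise ShapeError(
                    f"arch {arch!r} expects {w}x{h} images, got "
                    f"{s.image.shape[1]}x{s.image.shape[0]}"
                )

    @classmethod
    def from_directory(cls, path, arch: str = "lowres") -> "PupilCenterModel":
        from .dataio import load_dataset

        return cls(load_dataset(path), arch=arch)

    @property
    def n_parameters(self) -> int:
        return sum(count_parameters(s) for s in self.specs.values())

    def fit(self, config: Optional[TrainConfig] = None,
            verbose: bool = False) -> "PupilCenterResults":
        config = config or TrainConfig()
        config.validate()
        splits = split_dataset(self.samples, config.split, config.seed)
        params = {}
        histories = {}
        if self.arch == "lowres":
            p, h = train(self.specs["grid"], lowres_target, splits, config,
                         verbose=verbose)
            params["grid"], histories["grid"] = p, h
        else:
            for name, extractor, stream in (
                ("x", x_target, 11), ("y", y_target, 13)
            ):
                cfg = dataclasses.replace(
                    config, seed=_derived_seed(config.seed, stream)
                )
                p, h = train(self.specs[name], extractor, splits, cfg,
                             verbose=verbose)
                params[name], histories[name] = p, h
        return PupilCenterResults(self, config, params, histories, splits)


class PupilCenterResults:
    """Fit results: trained parameters, history, diagnostics."""

    def __init__(self, model, config, params, histories, splits):
        self.model = model
        self.arch = model.arch
        self.config = config
        self.params = params
        self.histories = histories
        self.train_set, self.val_set, self.test_set = splits
        self._test_report: Optional[EvalReport] = None

    # -- prediction --------------------------------------------------------

    def predict_one(self, image: np.ndarray) -> PupilAnnotation:
        if self.arch == "lowres":
            p = network.forward(self.params["grid"], image)
            width = self.model.specs["grid"].input_shape[1]
            return class_to_coord(network.decode_coordinate(p) + 1, width)
        return network.predict_center(self.params["x"], self.params["y"],
                                      image)

    def predict(self, images) -> list:
        return [self.predict_one(np.asarray(img)) for img in images]

    # -- evaluation --------------------------------------------------------

    def evaluate(self, samples=None, source_tag: str = "") -> EvalReport:
        """Score on a sample list (default: the held-out test split)."""
        if samples is None:
            if self._test_report is not None:
                return self._test_report
            samples = self.test_set
            source_tag = source_tag or "test"
        if self.arch == "cnn":
            report = evaluate(self.params["x"], self.params["y"], samples,
                              source_tag)
        else:
            report = evaluate_predictor(self.predict_one, samples, source_tag)
        if samples is self.test_set:
            self._test_report = report
        return report

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        rep = self.evaluate()
        lines = []
        rule = "=" * 62
        lines.append(rule)
        lines.append("Pupil-center classifier fit".center(62))
        lines.append(rule)
        lines.append(f"{'Architecture:':<28}{self.arch}")
        for name, spec in self.model.specs.items():
            lines.append(
                f"{'Parameters (' + name + '):':<28}"
                f"{count_parameters(spec):,}"
            )
        lines.append(
            f"{'Split (train/val/test):':<28}"
            f"{len(self.train_set)}/{len(self.val_set)}/{len(self.test_set)}"
        )
        for name, hist in self.histories.items():
            last = hist.records[-1]
            lines.append(
                f"{'Epochs run (' + name + '):':<28}{len(hist)}"
            )
            lines.append(
                f"{'Final val/test acc (' + name + '):':<28}"
                f"{last.val_accuracy:.3f} / {last.test_accuracy:.3f}"
            )
        lines.append("-" * 62)
        lines.append("Held-out test set")
        lines.append(f"{'  images:':<28}{rep.n_images}")
        lines.append(f"{'  DR5 (%):':<28}{rep.dr5:.2f}")
        lines.append(f"{'  sigma (px):':<28}{rep.sigma:.2f}")
        lines.append(f"{'  lost frames (>10 px):':<28}{rep.lost_frames}")
        lines.append(rule)
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path_prefix: str) -> None:
        """Write one ``.npz`` archive per trained network."""
        for name, p in self.params.items():
            network.save_params(
                f"{path_prefix}_{name}.npz", p,
                meta={"arch": self.arch, "net": name,
                      "seed": self.config.seed},
            )
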