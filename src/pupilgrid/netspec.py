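"""Declarative network specifications, shape propagation and parameter counting.

Two architectures are provided:

* :func:`lowres_spec` — a fully connected softmax classifier over the 300
  position classes of a 20x15 image (one class per pixel, row-major).
* :func:`coordinate_cnn_spec` — a slim convolutional classifier that outputs
  a single pupil-center coordinate (x or y) of a 320x240 image.  Casting 2-D
  localization as two 1-D classifications shrinks the output layer from
  ``h*v`` (76,800) neurons to ``h + v`` (560).

Conventions baked into these specs:

* convolutions are "valid" (no padding), stride 1; pooling is 2x2, stride 2;
* the first convolution is fully connected over its (single) input channel,
  later convolutions are per-map (depthwise): each feature map convolves only
  its corresponding input map.  This connectivity is what gives the
  X-classifier its 858,990 trainable parameters;
* hidden dense/conv layers use ReLU, the output layer is a softmax.

Feature-map shapes are reported as ``(maps, width, height)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

from .errors import SpecError

Connectivity = Literal["full", "per_map"]


@dataclass(frozen=True)
class Input:
    """Input layer: a grayscale image of ``height`` x ``width`` pixels."""

    height: int
    width: int


@dataclass(frozen=True)
class Dense:
    """Fully connected hidden layer with ``n_out`` ReLU neurons."""

    n_out: int
    activation: str = "relu"


@dataclass(frozen=True)
class Conv:
    """Valid convolution, stride 1, ``n_maps`` feature maps, ReLU.

    ``connectivity='full'`` connects every map to every input channel;
    ``'per_map'`` (depthwise) connects map i only to input channel i and
    requires ``n_maps`` to equal the number of incoming channels.
    """

    kernel_h: int
    kernel_w: int
    n_maps: int
    connectivity: Connectivity = "full"


@dataclass(frozen=True)
class MaxPool:
    """2x2 max pooling, stride 2."""

    pool_h: int = 2
    pool_w: int = 2


@dataclass(frozen=True)
class Softmax:
    """Output layer: dense map to ``n_classes`` scores, softmax normalized."""

    n_classes: int


Layer = Union[Input, Dense, Conv, MaxPool, Softmax]


@dataclass(frozen=True)
class NetworkSpec:
    """An ordered, immutable stack of layer descriptors."""

    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        if not self.layers or not isinstance(self.layers[0], Input):
            raise SpecError("first layer must be Input")
        if not isinstance(self.layers[-1], Softmax):
            raise SpecError("last layer must be Softmax")

    @property
    def input_shape(self) -> tuple[int, int]:
        inp = self.layers[0]
        assert isinstance(inp, Input)
        return inp.height, inp.width

    @property
    def n_classes(self) -> int:
        out = self.layers[-1]
        assert isinstance(out, Softmax)
        return out.n_classes


def lowres_spec() -> NetworkSpec:
    """Fully connected position classifier for 20x15 images.

    300 input neurons (the normalized pixel intensities), two hidden layers
    of 100 ReLU neurons, and 300 output classes — one per pixel position of
    the pupil center.  Totals 70,500 trainable parameters.
    """
    return NetworkSpec(
        (
            Input(15, 20),
            Dense(100),
            Dense(100),
            Softmax(300),
        )
    )


def coordinate_cnn_spec(axis: str) -> NetworkSpec:
    """Slim CNN that classifies one pupil-center coordinate of a 320x240 image.

    Parameters
    ----------
    axis : {'x', 'y'}
        'x' yields a 640-neuron dense layer and 320 output classes (columns);
        'y' yields 480 dense neurons and 240 output classes (rows).
    """
    if axis not in ("x", "y"):
        raise SpecError(f"axis must be 'x' or 'y', got {axis!r}")
    dense_n, out_n = (640, 320) if axis == "x" else (480, 240)
    return NetworkSpec(
        (
            Input(240, 320),
            Conv(5, 5, 5, "full"),
            MaxPool(),
            Conv(5, 5, 5, "per_map"),
            MaxPool(),
            Conv(4, 4, 5, "per_map"),
            MaxPool(),
            Conv(4, 4, 5, "per_map"),
            MaxPool(),
            Dense(dense_n),
            Softmax(out_n),
        )
    )


def infer_shapes(spec: NetworkSpec) -> list:
    """Propagate shapes through ``spec``; one entry per non-input layer.

    Spatial layers report ``(maps, width, height)``; dense and softmax layers
    report a bare neuron count.  Raises :class:`SpecError` when a kernel does
    not fit its feature map or pooling meets an odd dimension.
    """
    inp = spec.layers[0]
    assert isinstance(inp, Input)
    maps, h, w = 1, inp.height, inp.width
    flat: int | None = None  # set once the stack goes dense
    shapes: list = []
    for layer in spec.layers[1:]:
        if isinstance(layer, Conv):
            if flat is not None:
                raise SpecError("convolution after a dense layer")
            if layer.kernel_h > h or layer.kernel_w > w:
                raise SpecError(
                    f"kernel {layer.kernel_h}x{layer.kernel_w} exceeds "
                    f"feature map {h}x{w}"
                )
            if layer.connectivity == "per_map" and layer.n_maps != maps:
                raise SpecError("per_map conv requires n_maps == input maps")
            h = h - layer.kernel_h + 1
            w = w - layer.kernel_w + 1
            maps = layer.n_maps
            shapes.append((maps, w, h))
        elif isinstance(layer, MaxPool):
            if flat is not None:
                raise SpecError("pooling after a dense layer")
            if h % layer.pool_h or w % layer.pool_w:
                raise SpecError(f"pooling requires even dimensions, got {h}x{w}")
            h //= layer.pool_h
            w //= layer.pool_w
            shapes.append((maps, w, h))
        elif isinstance(layer, Dense):
            n_in = flat if flat is not None else maps * h * w
            flat = layer.n_out
            shapes.append(layer.n_out)
        elif isinstance(layer, Softmax):
            flat = layer.n_classes
            shapes.append(layer.n_classes)
        else:  # pragma: no cover - Input cannot reappear past __post_init__
            raise SpecError(f"unexpected layer {layer!r}")
    return shapes


def _fan_in(spec: NetworkSpec) -> list:
    """Per-layer (n_in, layer) pairs for parameterized layers; None otherwise."""
    inp = spec.layers[0]
    assert isinstance(inp, Input)
    maps, h, w = 1, inp.height, inp.width
    flat: int | None = None
    out = []
    for layer in spec.layers[1:]:
        if isinstance(layer, Conv):
            if layer.connectivity == "full":
                out.append((layer.kernel_h * layer.kernel_w * maps, layer))
            else:
                out.append((layer.kernel_h * layer.kernel_w, layer))
            h, w = h - layer.kernel_h + 1, w - layer.kernel_w + 1
            maps = layer.n_maps
        elif isinstance(layer, MaxPool):
            out.append((None, layer))
            h, w = h // layer.pool_h, w // layer.pool_w
        elif isinstance(layer, (Dense, Softmax)):
            n_in = flat if flat is not None else maps * h * w
            out.append((n_in, layer))
            flat = layer.n_out if isinstance(layer, Dense) else layer.n_classes
        else:  # pragma: no cover
            raise SpecError(f"unexpected layer {layer!r}")
    return out


def count_parameters(spec: NetworkSpec) -> int:
    """Exact count of trainable weights and biases.

    Dense/softmax layers contribute ``n_in*n_out + n_out``; a full conv
    contributes ``n_maps*(kh*kw*n_in_maps + 1)``; a per-map conv
    ``n_maps*(kh*kw + 1)``; pooling contributes nothing.
    """
    infer_shapes(spec)  # validates the stack
    total = 0
    for n_in, layer in _fan_in(spec):
        if isinstance(layer, Conv):
            total += layer.n_maps * (n_in + 1)
        elif isinstance(layer, Dense):
            total += n_in * layer.n_out + layer.n_out
        elif isinstance(layer, Softmax):
            total += n_in * layer.n_classes + layer.n_classes
    return total
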