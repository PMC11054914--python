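"""Parameter initialization, forward inference and backpropagation.

Everything here operates on plain numpy arrays.  Batches are carried as
``(N, C, H, W)`` tensors internally; the public single-image API takes a
``(H, W)`` grayscale image with intensities in [0, 1].

The backward pass returns gradients of the *mean* cross-entropy over the
batch, so the SGD learning rate is independent of batch size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dataio import PupilAnnotation
from .errors import RangeError, ShapeError, SpecError
from .netspec import (
    Conv,
    Dense,
    Input,
    MaxPool,
    NetworkSpec,
    Softmax,
    _fan_in,
    infer_shapes,
)


@dataclass
class NetworkParams:
    """Trainable weights/biases aligned with ``spec.layers[1:]``.

    ``layers[i]`` is a ``{"W": ..., "b": ...}`` dict for parameterized layers
    and ``None`` for pooling layers.
    """

    spec: NetworkSpec
    layers: list

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.spec,
            [None if p is None else {k: v.copy() for k, v in p.items()}
             for p in self.layers],
        )

    def weight_arrays(self) -> list:
        return [p["W"] for p in self.layers if p is not None]


def init_params(spec: NetworkSpec, seed: int) -> NetworkParams:
    """Gaussian weights scaled by 1/sqrt(fan_in); zero biases; seeded."""
    rng = np.random.default_rng(seed)
    layers = []
    for n_in, layer in _fan_in(spec):
        if isinstance(layer, Conv):
            if layer.connectivity == "full":
                in_maps = n_in // (layer.kernel_h * layer.kernel_w)
                shape = (layer.n_maps, in_maps, layer.kernel_h, layer.kernel_w)
            else:
                shape = (layer.n_maps, layer.kernel_h, layer.kernel_w)
            W = rng.standard_normal(shape) / np.sqrt(n_in)
            layers.append({"W": W, "b": np.zeros(layer.n_maps)})
        elif isinstance(layer, (Dense, Softmax)):
            n_out = layer.n_out if isinstance(layer, Dense) else layer.n_classes
            W = rng.standard_normal((n_in, n_out)) / np.sqrt(n_in)
            layers.append({"W": W, "b": np.zeros(n_out)})
        else:
            layers.append(None)
    return NetworkParams(spec, layers)


# ---------------------------------------------------------------------------
# layer primitives (shifted-slice convolutions keep memory small on 320x240)
# ---------------------------------------------------------------------------

def _conv_fwd(x, W, b, per_map):
    kh, kw = W.shape[-2:]
    N, C, H, Wd = x.shape
    Ho, Wo = H - kh + 1, Wd - kw + 1
    out = np.empty((N, W.shape[0], Ho, Wo))
    out[:] = b[None, :, None, None]
    for u in range(kh):
        for v in range(kw):
            xs = x[:, :, u:u + Ho, v:v + Wo]
            if per_map:
                out += W[None, :, u, v, None, None] * xs
            else:
                out += np.einsum("nchw,mc->nmhw", xs, W[:, :, u, v])
    return out


def _conv_bwd(x, W, dout, per_map, need_dx):
    kh, kw = W.shape[-2:]
    Ho, Wo = dout.shape[-2:]
    dW = np.zeros_like(W)
    db = dout.sum(axis=(0, 2, 3))
    dx = np.zeros_like(x) if need_dx else None
    for u in range(kh):
        for v in range(kw):
            xs = x[:, :, u:u + Ho, v:v + Wo]
            if per_map:
                dW[:, u, v] = np.einsum("nchw,nchw->c", xs, dout)
                if need_dx:
                    dx[:, :, u:u + Ho, v:v + Wo] += (
                        W[None, :, u, v, None, None] * dout
                    )
            else:
                dW[:, :, u, v] = np.einsum("nchw,nmhw->mc", xs, dout)
                if need_dx:
                    dx[:, :, u:u + Ho, v:v + Wo] += np.einsum(
                        "nmhw,mc->nchw", dout, W[:, :, u, v]
                    )
    return dW, db, dx


def _pool_fwd(x):
    N, C, H, W = x.shape
    xr = (
        x.reshape(N, C, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, H // 2, W // 2, 4)
    )
    idx = xr.argmax(axis=-1)  # ties -> first element (deterministic)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_bwd(dout, idx, in_shape):
    N, C, H, W = in_shape
    d4 = np.zeros((N, C, H // 2, W // 2, 4))
    np.put_along_axis(d4, idx[..., None], dout[..., None], axis=-1)
    return (
        d4.reshape(N, C, H // 2, W // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, H, W)
    )


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# network forward / backward
# ---------------------------------------------------------------------------

def forward_batch(params: NetworkParams, images: np.ndarray, cache: bool = False):
    """Probabilities for a batch of images ``(N, H, W)``.

    With ``cache=True`` also returns the intermediates that
    :func:`backward_batch` needs.
    """
    spec = params.spec
    h, w = spec.input_shape
    if images.ndim != 3 or images.shape[1:] != (h, w):
        raise ShapeError(
            f"expected batch of {h}x{w} images, got array of shape {images.shape}"
        )
    x = np.asarray(images, dtype=np.float64)[:, None]  # (N,1,H,W)
    caches = []
    spatial = True
    for layer, p in zip(spec.layers[1:], params.layers):
        if isinstance(layer, Conv):
            pre = _conv_fwd(x, p["W"], p["b"], layer.connectivity == "per_map")
            mask = pre > 0
            caches.append(("conv", x, mask, layer))
            x = pre * mask
        elif isinstance(layer, MaxPool):
            out, idx = _pool_fwd(x)
            caches.append(("pool", x.shape, idx))
            x = out
        elif isinstance(layer, Dense):
            shape_in = x.shape
            flat = x.reshape(x.shape[0], -1) if spatial else x
            spatial = False
            pre = flat @ p["W"] + p["b"]
            mask = pre > 0
            caches.append(("dense", flat, mask, shape_in))
            x = pre * mask
        elif isinstance(layer, Softmax):
            shape_in = x.shape
            flat = x.reshape(x.shape[0], -1) if spatial else x
            spatial = False
            probs = _softmax(flat @ p["W"] + p["b"])
            caches.append(("softmax", flat, shape_in))
            x = probs
        else:  # pragma: no cover
            raise SpecError(f"unexpected layer {layer!r}")
    if cache:
        return x, caches
    return x


def backward_batch(params: NetworkParams, caches, probs, targets):
    """Gradients of the batch-mean cross-entropy w.r.t. every parameter.

    ``targets`` are 0-based class indices.  Returns a list aligned with
    ``params.layers`` of ``{"W": dW, "b": db}`` (``None`` for pooling).
    """
    n = len(targets)
    delta = probs.copy()
    delta[np.arange(n), targets] -= 1.0
    delta /= n
    grads = [None] * len(params.layers)
    for i in range(len(params.layers) - 1, -1, -1):
        entry = caches[i]
        p = params.layers[i]
        kind = entry[0]
        if kind == "softmax":
            _, flat, shape_in = entry
            grads[i] = {"W": flat.T @ delta, "b": delta.sum(axis=0)}
            if i > 0:
                delta = delta @ p["W"].T
                delta = delta.reshape(shape_in)
        elif kind == "dense":
            _, flat, mask, shape_in = entry
            delta = delta * mask
            grads[i] = {"W": flat.T @ delta, "b": delta.sum(axis=0)}
            if i > 0:
                delta = delta @ p["W"].T
                delta = delta.reshape(shape_in)
        elif kind == "pool":
            _, in_shape, idx = entry
            delta = _pool_bwd(delta, idx, in_shape)
        elif kind == "conv":
            _, x_in, mask, layer = entry
            delta = delta * mask
            dW, db, dx = _conv_bwd(
                x_in, p["W"], delta,
                per_map=layer.connectivity == "per_map",
                need_dx=i > 0,
            )
            grads[i] = {"W": dW, "b": db}
            delta = dx
    return grads


def forward(params: NetworkParams, img: np.ndarray) -> np.ndarray:
    """Probability vector over coordinate classes for one ``(H, W)`` image."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ShapeError(f"expected a 2-D grayscale image, got ndim={img.ndim}")
    return forward_batch(params, img[None])[0]


def decode_coordinate(p: np.ndarray) -> int:
    """Argmax class index; ties broken toward the lowest index."""
    p = np.asarray(p)
    if p.size == 0:
        raise RangeError("cannot decode an empty probability vector")
    return int(np.argmax(p))


def predict_center(
    x_params: NetworkParams, y_params: NetworkParams, img: np.ndarray
) -> PupilAnnotation:
    """Pupil center from the parallel X/Y classifier pair."""
    cx = decode_coordinate(forward(x_params, img))
    cy = decode_coordinate(forward(y_params, img))
    return PupilAnnotation(cx, cy)


def predict_centers_batch(
    x_params: NetworkParams,
    y_params: NetworkParams,
    images: np.ndarray,
    batch_size: int = 32,
) -> list:
    """Vectorized :func:`predict_center` over ``(N, H, W)`` images."""
    out = []
    for i in range(0, len(images), batch_size):
        chunk = images[i:i + batch_size]
        px = forward_batch(x_params, chunk)
        py = forward_batch(y_params, chunk)
        for j in range(len(chunk)):
            out.append(PupilAnnotation(int(px[j].argmax()), int(py[j].argmax())))
    return out


# ---------------------------------------------------------------------------
# serialization: one .npz archive with the spec and seed metadata embedded
# ---------------------------------------------------------------------------

def _spec_to_obj(spec: NetworkSpec) -> list:
    out = []
    for layer in spec.layers:
        d = {"kind": type(layer).__name__}
        d.update(vars(layer))
        out.append(d)
    return out


def _spec_from_obj(obj: list) -> NetworkSpec:
    kinds = {"Input": Input, "Dense": Dense, "Conv": Conv,
             "MaxPool": MaxPool, "Softmax": Softmax}
    layers = []
    for d in obj:
        d = dict(d)
        cls = kinds[d.pop("kind")]
        layers.append(cls(**d))
    return NetworkSpec(tuple(layers))


def save_params(path, params: NetworkParams, meta: Optional[dict] = None) -> None:
    arrays = {}
    for i, p in enumerate(params.layers):
        if p is not None:
            arrays[f"layer{i}_W"] = p["W"]
            arrays[f"layer{i}_b"] = p["b"]
    header = json.dumps({"spec": _spec_to_obj(params.spec), "meta": meta or {}})
    arrays["header"] = np.frombuffer(header.encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_params(path):
    """Returns ``(NetworkParams, meta)``."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        spec = _spec_from_obj(header["spec"])
        layers = []
        for i in range(len(spec.layers) - 1):
            if f"layer{i}_W" in data:
                layers.append({"W": data[f"layer{i}_W"], "b": data[f"layer{i}_b"]})
            else:
                layers.append(None)
    return NetworkParams(spec, layers), header["meta"]
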