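"""Seeded renderer of labeled synthetic infrared-style eye images.

Real eye-tracker footage is awkward to redistribute, so this module draws
dark-pupil images with the nuisance factors such recordings exhibit:
elliptical off-axis pupils, corneal glints (small bright specular spots),
eyelash/mascara-like dark strokes, a drooping eyelid, non-uniform
illumination, sensor noise, and pupils near the image border.  Intensities
follow the dark-pupil regime: pupil darker than iris, iris darker than
sclera.

Everything is deterministic: a (seed, profile, size) triple reproduces the
identical scene, and rendering a scene twice gives bit-identical images.
The ground-truth annotation is the continuous ellipse center used to draw
the pupil, rounded to the nearest pixel — labels are correct by
construction.

Three difficulty presets are provided:

``easy``
    no occluders, no illumination gradient, noise sd <= 0.02, pupil away
    from the border.
``realistic``
    occasional eyelashes and eyelid droop, moderate gradient and noise.
``hard``
    occluders may overlap the pupil, glints may sit on the pupil boundary,
    strong gradients, pupils allowed at the border.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dataio import LabeledSample, PupilAnnotation
from .errors import CountError, SizeError


@dataclass
class SceneParams:
    """Full geometric/photometric description of one synthetic eye image."""

    pupil_center: tuple        # (cx, cy), continuous pixels
    pupil_axes: tuple          # (a, b) semi-axes, pixels
    pupil_angle: float         # radians
    pupil_intensity: float
    iris_radius: float
    iris_intensity: float
    sclera_intensity: float
    glints: list = field(default_factory=list)      # (x, y, radius, intensity)
    occluders: list = field(default_factory=list)   # dicts, see _draw_occluder
    illumination_gradient: tuple = (0.0, 0.0, 0.0)  # (gx, gy, strength)
    noise_sd: float = 0.0
    eyelid_coverage: float = 0.0
    noise_seed: int = 0

    def validate(self, width: int, height: int) -> None:
        cx, cy = self.pupil_center
        if not (0 <= cx < width and 0 <= cy < height):
            raise ValueError(f"pupil center {self.pupil_center} out of bounds")
        if not (self.pupil_intensity < self.iris_intensity
                < self.sclera_intensity):
            raise ValueError("dark-pupil ordering violated")
        for v in (self.pupil_intensity, self.iris_intensity,
                  self.sclera_intensity):
            if not 0.0 <= v <= 1.0:
                raise ValueError("intensities must lie in [0,1]")
        if min(self.pupil_axes) <= 0:
            raise ValueError("pupil axes must be positive")


@dataclass(frozen=True)
class DifficultyProfile:
    """Sampling ranges for every SceneParams field."""

    name: str
    center_margin: float          # fraction of each dimension kept clear
    pupil_axis_range: tuple       # fractions of min(h, w)
    axis_ratio_range: tuple       # b/a
    pupil_intensity_range: tuple
    iris_radius_range: tuple      # fractions of min(h, w)
    iris_intensity_range: tuple
    sclera_intensity_range: tuple
    n_glints_range: tuple         # inclusive
    glint_on_pupil: bool          # may a glint sit on/inside the pupil?
    n_occluders_range: tuple
    occluders_over_pupil: bool
    eyelid_coverage_range: tuple
    gradient_strength_range: tuple
    noise_sd_range: tuple


PROFILES = {
    "easy": DifficultyProfile(
        name="easy",
        center_margin=0.06,
        pupil_axis_range=(0.09, 0.18),
        axis_ratio_range=(0.75, 1.0),
        pupil_intensity_range=(0.02, 0.08),
        iris_radius_range=(0.30, 0.42),
        iris_intensity_range=(0.28, 0.42),
        sclera_intensity_range=(0.62, 0.82),
        n_glints_range=(0, 1),
        glint_on_pupil=False,
        n_occluders_range=(0, 0),
        occluders_over_pupil=False,
        eyelid_coverage_range=(0.0, 0.0),
        gradient_strength_range=(0.0, 0.0),
        noise_sd_range=(0.004, 0.02),
    ),
    "realistic": DifficultyProfile(
        name="realistic",
        center_margin=0.04,
        pupil_axis_range=(0.07, 0.20),
        axis_ratio_range=(0.55, 1.0),
        pupil_intensity_range=(0.02, 0.10),
        iris_radius_range=(0.28, 0.45),
        iris_intensity_range=(0.24, 0.44),
        sclera_intensity_range=(0.58, 0.85),
        n_glints_range=(1, 3),
        glint_on_pupil=False,
        n_occluders_range=(0, 3),
        occluders_over_pupil=False,
        eyelid_coverage_range=(0.0, 0.15),
        gradient_strength_range=(0.0, 0.25),
        noise_sd_range=(0.02, 0.05),
    ),
    "hard": DifficultyProfile(
        name="hard",
        center_margin=0.0,
        pupil_axis_range=(0.06, 0.22),
        axis_ratio_range=(0.45, 1.0),
        pupil_intensity_range=(0.02, 0.12),
        iris_radius_range=(0.26, 0.48),
        iris_intensity_range=(0.22, 0.46),
        sclera_intensity_range=(0.55, 0.88),
        n_glints_range=(1, 4),
        glint_on_pupil=True,
        n_occluders_range=(1, 6),
        occluders_over_pupil=True,
        eyelid_coverage_range=(0.0, 0.35),
        gradient_strength_range=(0.1, 0.45),
        noise_sd_range=(0.05, 0.10),
    ),
}


def get_profile(profile) -> DifficultyProfile:
    if isinstance(profile, DifficultyProfile):
        return profile
    try:
        return PROFILES[profile]
    except KeyError:
        raise KeyError(
            f"unknown profile {profile!r}; choose from {sorted(PROFILES)}"
        ) from None


def sample_scene(rng_seed: int, profile, width: int, height: int) -> SceneParams:
    """Draw one SceneParams from the profile's ranges, deterministically."""
    if width < 20 or height < 15:
        raise SizeError(f"image size {width}x{height} below minimum 20x15")
    prof = get_profile(profile)
    rng = np.random.default_rng(rng_seed)
    mind = min(width, height)

    mx = prof.center_margin * width
    my = prof.center_margin * height
    cx = rng.uniform(mx, width - 1 - mx)
    cy = rng.uniform(my, height - 1 - my)

    a = rng.uniform(*prof.pupil_axis_range) * mind
    b = a * rng.uniform(*prof.axis_ratio_range)
    angle = rng.uniform(0.0, np.pi)
    pupil_i = rng.uniform(*prof.pupil_intensity_range)
    iris_r = max(rng.uniform(*prof.iris_radius_range) * mind, a + 2.0)
    iris_i = rng.uniform(*prof.iris_intensity_range)
    sclera_i = rng.uniform(*prof.sclera_intensity_range)

    glints = []
    for _ in range(rng.integers(prof.n_glints_range[0],
                                prof.n_glints_range[1] + 1)):
        if prof.glint_on_pupil:
            # anywhere in the iris disk, incl. the pupil boundary
            gr = rng.uniform(0.0, iris_r)
        else:
            gr = rng.uniform(min(a + 2.0, iris_r), iris_r)
        theta = rng.uniform(0.0, 2 * np.pi)
        glints.append(
            (
                float(np.clip(cx + gr * np.cos(theta), 0, width - 1)),
                float(np.clip(cy + gr * np.sin(theta), 0, height - 1)),
                float(rng.uniform(0.015, 0.04) * mind + 0.6),
                float(rng.uniform(0.5, 0.95)),
            )
        )

    occluders = []
    for _ in range(rng.integers(prof.n_occluders_range[0],
                                prof.n_occluders_range[1] + 1)):
        # eyelash-like stroke: a shallow arc of dark stamps from the top
        x0 = rng.uniform(0, width - 1)
        y0 = rng.uniform(0, 0.4 * height)
        if prof.occluders_over_pupil and rng.random() < 0.5:
            x0, y0 = (cx + rng.uniform(-a, a), cy + rng.uniform(-b, 0))
        length = rng.uniform(0.2, 0.6) * mind
        direction = rng.uniform(np.pi / 4, 3 * np.pi / 4)  # mostly downward
        curve = rng.uniform(-0.3, 0.3)
        occluders.append(
            {
                "x0": float(x0), "y0": float(y0),
                "length": float(length), "angle": float(direction),
                "curve": float(curve),
                "thickness": float(rng.uniform(0.02, 0.05) * mind + 0.5),
                "intensity": float(rng.uniform(0.03, 0.18)),
            }
        )

    strength = rng.uniform(*prof.gradient_strength_range)
    gdir = rng.uniform(0.0, 2 * np.pi)
    scene = SceneParams(
        pupil_center=(float(cx), float(cy)),
        pupil_axes=(float(a), float(b)),
        pupil_angle=float(angle),
        pupil_intensity=float(pupil_i),
        iris_radius=float(iris_r),
        iris_intensity=float(iris_i),
        sclera_intensity=float(sclera_i),
        glints=glints,
        occluders=occluders,
        illumination_gradient=(float(np.cos(gdir)), float(np.sin(gdir)),
                               float(strength)),
        noise_sd=float(rng.uniform(*prof.noise_sd_range)),
        eyelid_coverage=float(rng.uniform(*prof.eyelid_coverage_range)),
        noise_seed=int(rng.integers(0, 2**31 - 1)),
    )
    scene.validate(width, height)
    return scene


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _soft_disk(xx, yy, cx, cy, radius):
    """Anti-aliased disk mask: ~1 inside, ~0 outside, 1-px soft edge."""
    d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    return np.clip(radius - d + 0.5, 0.0, 1.0)


def _ellipse_mask(xx, yy, cx, cy, a, b, angle):
    """Anti-aliased mask of a rotated ellipse (soft ~1-px edge)."""
    ct, st = np.cos(angle), np.sin(angle)
    u = ct * (xx - cx) + st * (yy - cy)
    v = -st * (xx - cx) + ct * (yy - cy)
    f = (u / a) ** 2 + (v / b) ** 2
    # (1 - f) scaled by the minor semi-axis approximates a signed distance
    return np.clip((1.0 - f) * min(a, b) * 0.5 + 0.5, 0.0, 1.0)


def _draw_occluder(img, xx, yy, occ):
    n = max(int(occ["length"] * 2), 2)
    t = np.linspace(0.0, 1.0, n)
    ang = occ["angle"] + occ["curve"] * t
    px = occ["x0"] + occ["length"] * np.cumsum(np.cos(ang)) / n
    py = occ["y0"] + occ["length"] * np.cumsum(np.sin(ang)) / n
    alpha = np.zeros_like(img)
    for x, y in zip(px, py):
        alpha = np.maximum(alpha, _soft_disk(xx, yy, x, y, occ["thickness"]))
    return img * (1 - alpha) + occ["intensity"] * alpha


def render_eye(scene: SceneParams, width: int, height: int):
    """Rasterize a scene; returns ``(image, PupilAnnotation)``.

    The annotation is the continuous pupil center rounded to the nearest
    pixel (ties toward +inf) — correct by construction.
    """
    scene.validate(width, height)
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    cx, cy = scene.pupil_center

    img = np.full((height, width), scene.sclera_intensity)

    # iris disk centered on the pupil
    m_iris = _soft_disk(xx, yy, cx, cy, scene.iris_radius)
    img = img * (1 - m_iris) + scene.iris_intensity * m_iris

    # pupil ellipse (dark)
    a, b = scene.pupil_axes
    m_pupil = _ellipse_mask(xx, yy, cx, cy, a, b, scene.pupil_angle)
    img = img * (1 - m_pupil) + scene.pupil_intensity * m_pupil

    # eyelid: a curved band descending from the top edge
    if scene.eyelid_coverage > 0:
        lid_y = scene.eyelid_coverage * height
        boundary = lid_y * (1.0 - 0.35 * ((xx / max(width - 1, 1)) - 0.5) ** 2 * 4)
        m_lid = np.clip(boundary - yy + 0.5, 0.0, 1.0)
        lid_i = min(scene.sclera_intensity * 0.85 + 0.1, 1.0)
        img = img * (1 - m_lid) + lid_i * m_lid

    # eyelash / mascara strokes
    for occ in scene.occluders:
        img = _draw_occluder(img, xx, yy, occ)

    # corneal reflections: small bright Gaussian spots (additive)
    for gx, gy, gr, gi in scene.glints:
        img = img + gi * np.exp(
            -((xx - gx) ** 2 + (yy - gy) ** 2) / (2 * (gr / 1.5) ** 2)
        )

    # non-uniform illumination (additive planar ramp)
    dx, dy, strength = scene.illumination_gradient
    if strength > 0:
        img = img + strength * (
            dx * (xx / max(width - 1, 1) - 0.5)
            + dy * (yy / max(height - 1, 1) - 0.5)
        )

    if scene.noise_sd > 0:
        nrng = np.random.default_rng(scene.noise_seed)
        img = img + nrng.normal(0.0, scene.noise_sd, img.shape)

    img = np.clip(img, 0.0, 1.0)
    ann = PupilAnnotation(
        int(np.clip(np.floor(cx + 0.5), 0, width - 1)),
        int(np.clip(np.floor(cy + 0.5), 0, height - 1)),
    )
    return img, ann


def generate_dataset(
    n: int, profile, width: int, height: int, seed: int
) -> list:
    """Render ``n`` labeled samples; fully reproducible from ``seed``."""
    if n <= 0:
        raise CountError(f"n must be >= 1, got {n}")
    prof = get_profile(profile)
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n)
    samples = []
    for s in scene_seeds:
        scene = sample_scene(int(s), prof, width, height)
        img, ann = render_eye(scene, width, height)
        samples.append(LabeledSample(img, ann, source_tag=prof.name))
    return samples
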