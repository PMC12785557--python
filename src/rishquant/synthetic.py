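"""Synthetic duplex chromogenic RISH field generator.

Emulates brightfield micrographs of RNAscope-style duplex in situ
hybridization: a pale counterstained tissue background carrying small
blue dots (HRP chromogen, wild-type transcript) and red dots (AP
chromogen, truncated transcript). Every generated field comes with
pixel-exact per-channel binary masks and known dot counts, so the whole
segmentation/counting/scoring pipeline can be exercised and validated
without any real slides.

Dots are filled ellipses with mild axis jitter rather than perfect
circles; backgrounds carry low-frequency texture and the image additive
Gaussian noise, so segmentation is learnable but not trivial. The
generator does not attempt photorealistic histology (no nuclei, cells or
scanner artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse

__all__ = [
    "SyntheticFieldSpec",
    "SyntheticField",
    "CohortSpec",
    "generate_field",
    "generate_cohort",
    "FieldTooCrowdedError",
]

#: chromogen appearance in 8-bit RGB: HRP blue, AP red, eosin-pale background
BLUE_RGB = (60.0, 70.0, 150.0)
RED_RGB = (190.0, 60.0, 70.0)
BACKGROUND_RGB = (235.0, 225.0, 230.0)


class FieldTooCrowdedError(RuntimeError):
    """Requested dots cannot be placed at the required separation."""


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Parameters of one synthetic RISH field.

    Intensities are on the 8-bit [0, 255] scale; sizes in pixels.
    ``min_center_separation`` applies across both channels; keeping it
    above twice the maximum radius guarantees non-touching dots and
    mutually exclusive channel masks.
    """

    height: int = 256
    width: int = 256
    n_blue: int = 12
    n_red: int = 5
    dot_radius_range: tuple[float, float] = (2.0, 5.0)
    background_mean_rgb: tuple[float, float, float] = BACKGROUND_RGB
    background_texture_sigma: float = 6.0
    dot_color_jitter: float = 15.0
    noise_sigma: float = 5.0
    min_center_separation: float = 12.0
    allow_touching: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_blue < 0 or self.n_red < 0:
            raise ValueError("dot counts must be non-negative")
        rmin, rmax = self.dot_radius_range
        if not (1.0 <= rmin <= rmax):
            raise ValueError("dot_radius_range must satisfy 1 <= min <= max")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class SyntheticField:
    """A generated field: 8-bit RGB image, per-channel 0/1 masks, truth."""

    image: np.ndarray  # (H, W, 3) uint8
    blue_mask: np.ndarray  # (H, W) uint8, values {0, 1}
    red_mask: np.ndarray  # (H, W) uint8
    true_blue_count: int
    true_red_count: int
    spec: SyntheticFieldSpec
    sample_id: str = "S0"
    field_index: int = 0


def _place_centers(
    rng: np.random.Generator,
    n: int,
    h: int,
    w: int,
    margin: float,
    min_sep: float,
    existing: list[tuple[float, float]],
    max_tries: int = 2000,
) -> list[tuple[float, float]]:
    """Rejection-sample dot centers with a minimum pairwise separation."""
    centers = list(existing)
    placed: list[tuple[float, float]] = []
    lo_r, hi_r = margin, h - 1 - margin
    lo_c, hi_c = margin, w - 1 - margin
    if hi_r < lo_r or hi_c < lo_c:
        raise FieldTooCrowdedError(
            f"field {h}x{w} too small for dots of margin {margin}"
        )
    sep2 = min_sep**2
    for _ in range(n):
        for attempt in range(max_tries):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all((r - rr) ** 2 + (c - cc) ** 2 >= sep2 for rr, cc in centers):
                centers.append((r, c))
                placed.append((r, c))
                break
        else:
            raise FieldTooCrowdedError(
                f"could not place {n} dots at separation {min_sep} "
                f"in a {h}x{w} field: field too crowded"
            )
    return placed


def _draw_channel(
    rng: np.random.Generator,
    image: np.ndarray,
    mask: np.ndarray,
    centers: list[tuple[float, float]],
    base_rgb: tuple[float, float, float],
    spec: SyntheticFieldSpec,
) -> None:
    rmin, rmax = spec.dot_radius_range
    for r, c in centers:
        radius = rng.uniform(rmin, rmax)
        # +/-30% axis jitter turns circles into mild ellipses
        a = radius * (1.0 + rng.uniform(-0.3, 0.3))
        b = radius * (1.0 + rng.uniform(-0.3, 0.3))
        theta = rng.uniform(0.0, np.pi)
        rr, cc = ellipse(r, c, max(a, 1.0), max(b, 1.0), shape=mask.shape, rotation=theta)
        color = np.array(base_rgb) + rng.uniform(
            -spec.dot_color_jitter, spec.dot_color_jitter, size=3
        )
        image[rr, cc] = np.clip(color, 0, 255)
        mask[rr, cc] = 1


def _textured_background(
    rng: np.random.Generator, spec: SyntheticFieldSpec
) -> np.ndarray:
    h, w = spec.height, spec.width
    img = np.ones((h, w, 3), dtype=np.float64) * np.asarray(spec.background_mean_rgb)
    if spec.background_texture_sigma > 0:
        # low-frequency texture: coarse noise grid blown up to field size
        ch, cw = max(2, h // 16), max(2, w // 16)
        coarse = rng.normal(0.0, spec.background_texture_sigma, size=(ch, cw, 3))
        img += ndimage.zoom(coarse, (h / ch, w / cw, 1.0), order=1)
    return img


def generate_field(spec: SyntheticFieldSpec) -> SyntheticField:
    """Generate one synthetic duplex field; deterministic for a fixed spec.

    Raises :class:`FieldTooCrowdedError` when the requested dots cannot
    be placed at ``min_center_separation`` within a bounded number of
    rejection-sampling retries.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = _textured_background(rng, spec)
    blue_mask = np.zeros((h, w), dtype=np.uint8)
    red_mask = np.zeros((h, w), dtype=np.uint8)

    rmax = spec.dot_radius_range[1]
    margin = rmax * 1.3 + 1.0  # keep jittered ellipses fully inside the field
    min_sep = 0.0 if spec.allow_touching else spec.min_center_separation
    blue_centers = _place_centers(rng, spec.n_blue, h, w, margin, min_sep, [])
    red_centers = _place_centers(rng, spec.n_red, h, w, margin, min_sep, blue_centers)

    _draw_channel(rng, img, blue_mask, blue_centers, BLUE_RGB, spec)
    _draw_channel(rng, img, red_mask, red_centers, RED_RGB, spec)

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    image = np.clip(img, 0, 255).round().astype(np.uint8)
    return SyntheticField(
        image=image,
        blue_mask=blue_mask,
        red_mask=red_mask,
        true_blue_count=spec.n_blue,
        true_red_count=spec.n_red,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortSpec:
    """Sampling rules for a synthetic patient cohort.

    Per-sample mean dot counts are drawn uniformly from
    ``blue_mean_range`` / ``red_mean_range`` (one expression level per
    sample, emulating between-patient variability); per-field counts are
    then Poisson around the sample mean unless ``fixed_counts`` pins
    them exactly.
    """

    n_samples: int = 3
    fields_per_sample: int = 10
    blue_mean_range: tuple[float, float] = (10.0, 90.0)
    red_mean_range: tuple[float, float] = (5.0, 45.0)
    fixed_counts: tuple[int, int] | None = None
    field: SyntheticFieldSpec = field(default_factory=SyntheticFieldSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fields_per_sample < 1:
            raise ValueError("fields_per_sample must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for lo, hi in (self.blue_mean_range, self.red_mean_range):
            if not (0 <= lo <= hi):
                raise ValueError("count mean ranges must satisfy 0 <= low <= high")


_RACES = ("White", "Black", "Asian")
_STAGES = ("2B", "3", "4")
_GLEASON = ("3+3", "3+4", "4+3", "4+4", "4+5", "5+4")


def generate_cohort(
    cohort: CohortSpec,
) -> tuple[list[SyntheticField], pd.DataFrame]:
    """Generate ``n_samples`` x ``fields_per_sample`` fields plus metadata.

    The returned metadata table has one row per sample with synthetic
    race/stage/Gleason labels (for group-summary demonstrations) and the
    per-sample true mean counts; determinism is guaranteed per seed, with
    each field's RNG derived from (cohort seed, sample index, field index).
    """
    master = np.random.default_rng((cohort.seed, 0xC0))
    fields: list[SyntheticField] = []
    rows = []
    for s in range(cohort.n_samples):
        sample_id = f"S{s:03d}"
        if cohort.fixed_counts is not None:
            blue_mean, red_mean = map(float, cohort.fixed_counts)
        else:
            blue_mean = master.uniform(*cohort.blue_mean_range)
            red_mean = master.uniform(*cohort.red_mean_range)
        race = master.choice(_RACES)
        stage = master.choice(_STAGES)
        gleason = master.choice(_GLEASON)
        true_blues, true_reds = [], []
        for f in range(cohort.fields_per_sample):
            frng = np.random.default_rng((cohort.seed, s, f))
            if cohort.fixed_counts is not None:
                n_blue, n_red = cohort.fixed_counts
            else:
                n_blue = int(frng.poisson(blue_mean))
                n_red = int(frng.poisson(red_mean))
            fspec = replace(
                cohort.field,
                n_blue=n_blue,
                n_red=n_red,
                seed=int(frng.integers(0, 2**31 - 1)),
            )
            fld = generate_field(fspec)
            fld.sample_id = sample_id
            fld.field_index = f
            fields.append(fld)
            true_blues.append(n_blue)
            true_reds.append(n_red)
        rows.append(
            {
                "sample_id": sample_id,
                "race": race,
                "stage": stage,
                "gleason": gleason,
                "true_mean_blue": float(np.mean(true_blues)),
                "true_mean_red": float(np.mean(true_reds)),
            }
        )
    return fields, pd.DataFrame(rows)
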