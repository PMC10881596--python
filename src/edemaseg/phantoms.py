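"""Seeded synthetic abdominal-CT-like phantoms with exact ground truth.

A phantom is an annular subcutaneous-fat compartment (near-Gaussian density
around ~-100 HU) with embedded heterogeneous edema blobs whose densities are
truncated to the [-50, 50] HU annotation window, plus additive acquisition
noise. Each sample carries the exact adipose-ring and edema masks, so
segmentation accuracy can be scored against known truth. The generator also
emits paired (binary, grayscale) edema-free mask sets, the desk-scale analogue
of the mask pairs a mask-to-texture generative model would be trained on.

Determinism: one global seed feeds a named sub-stream per sample index, so a
suite can grow without perturbing earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .imaging import BinaryMask, DensityImage, GrayscaleMask, SliceStack, apply_mask

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_phantom_pair",
    "generate_training_pairs",
    "generate_stack",
    "EDEMA_HU_WINDOW",
]

#: HU annotation window for edema; generated edema densities are truncated to it.
EDEMA_HU_WINDOW = (-50.0, 50.0)

_MAX_BLOB_ATTEMPTS = 200


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic slice.

    Defaults place fat and fluid densities far apart (adipose -100 +/- 15 HU,
    edema 0 +/- 15 HU, 5 HU acquisition noise) on a 256x256 grid with an
    80/110 px ring; these are fixture parameters, not measurements.
    """

    grid_size: tuple[int, int] = (256, 256)
    ring_inner: float = 80.0
    ring_outer: float = 110.0
    adipose_mean: float = -100.0
    adipose_std: float = 15.0
    edema_mean: float = 0.0
    edema_std: float = 15.0
    edema_blob_count: int = 4
    blob_radius_range: tuple[float, float] = (5.0, 12.0)
    noise_std: float = 5.0
    background_hu: float = 40.0
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 5.0

    def __post_init__(self) -> None:
        rows, cols = self.grid_size
        if not (0 < self.ring_inner < self.ring_outer < min(rows, cols) / 2):
            raise ValueError("require 0 < inner < outer < min(grid)/2")
        if min(self.adipose_std, self.edema_std, self.noise_std) < 0:
            raise ValueError("standard deviations must be non-negative")
        lo, hi = self.blob_radius_range
        if not (0 < lo <= hi):
            raise ValueError("blob radii must be positive and ordered")
        if self.edema_blob_count < 0:
            raise ValueError("edema_blob_count must be >= 0")
        if not (EDEMA_HU_WINDOW[0] <= self.edema_mean <= EDEMA_HU_WINDOW[1]):
            raise ValueError("edema_mean must lie inside the [-50, 50] HU window")


@dataclass(frozen=True)
class PhantomSample:
    """Generated slice plus exact ground truth and provenance."""

    image: DensityImage
    adipose_mask: BinaryMask  # full ring, edema included
    edema_mask: BinaryMask    # ground truth
    spec: PhantomSpec
    seed: int


def _radius_grid(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.grid_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    return np.hypot(rr - cy, cc - cx)


def _place_blob(spec: PhantomSpec, ring: np.ndarray, rng: np.random.Generator,
                radius_range: tuple[float, float]) -> np.ndarray:
    """One edema blob: a union of three jittered overlapping discs, rejection-
    sampled until it fits inside the ring."""
    rows, cols = spec.grid_size
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc = np.mgrid[0:rows, 0:cols]
    for _ in range(_MAX_BLOB_ATTEMPTS):
        r_blob = rng.uniform(*radius_range)
        lo = spec.ring_inner + r_blob
        hi = spec.ring_outer - r_blob
        if hi <= lo:
            continue  # blob too fat for the annulus at this radius draw
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rad = rng.uniform(lo, hi)
        by, bx = cy + rad * np.sin(theta), cx + rad * np.cos(theta)
        blob = np.zeros((rows, cols), dtype=bool)
        for _sub in range(3):
            jy = by + rng.normal(0.0, r_blob / 3.0)
            jx = bx + rng.normal(0.0, r_blob / 3.0)
            r_sub = r_blob * rng.uniform(0.6, 1.0)
            blob |= (rr - jy) ** 2 + (cc - jx) ** 2 <= r_sub ** 2
        blob &= ring
        if blob.any():
            return blob
    raise ValueError("edema blob could not be placed inside the ring "
                     f"after {_MAX_BLOB_ATTEMPTS} attempts")


def _edema_draws(spec: PhantomSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Edema densities: Normal(edema_mean, edema_std) truncated to [-50, 50] HU."""
    if spec.edema_std == 0:
        return np.full(n, spec.edema_mean)
    lo, hi = EDEMA_HU_WINDOW
    a = (lo - spec.edema_mean) / spec.edema_std
    b = (hi - spec.edema_mean) / spec.edema_std
    return stats.truncnorm.rvs(a, b, loc=spec.edema_mean, scale=spec.edema_std,
                               size=n, random_state=rng)


def _generate(spec: PhantomSpec, seed_seq: np.random.SeedSequence,
              slice_index: int = 0,
              extra_blob_count: int = 0,
              extra_radius_range: tuple[float, float] | None = None,
              ) -> PhantomSample | tuple[PhantomSample, PhantomSample]:
    """Build a sample; with extra blobs requested, return the base sample and
    a paired sample identical except for the added blobs."""
    main_ss, extra_ss, noise_ss = seed_seq.spawn(3)
    rng = np.random.default_rng(main_ss)
    radius = _radius_grid(spec)
    ring = (radius >= spec.ring_inner) & (radius < spec.ring_outer)

    edema = np.zeros(spec.grid_size, dtype=bool)
    for _ in range(spec.edema_blob_count):
        edema |= _place_blob(spec, ring, rng, spec.blob_radius_range)

    base = np.full(spec.grid_size, spec.background_hu, dtype=np.float64)
    base[ring] = rng.normal(spec.adipose_mean, spec.adipose_std, int(ring.sum()))
    base[edema] = _edema_draws(spec, int(edema.sum()), rng)

    pair_values = pair_edema = None
    if extra_blob_count > 0:
        erng = np.random.default_rng(extra_ss)
        rr_range = extra_radius_range or spec.blob_radius_range
        extra = np.zeros(spec.grid_size, dtype=bool)
        for _ in range(extra_blob_count):
            for _try in range(_MAX_BLOB_ATTEMPTS):
                blob = _place_blob(spec, ring, erng, rr_range)
                if not (blob & edema).any() and not (blob & extra).any():
                    extra |= blob
                    break
            else:
                raise ValueError("could not place an extra blob disjoint from "
                                 "the existing edema")
        pair_values = base.copy()
        pair_values[extra] = _edema_draws(spec, int(extra.sum()), erng)
        pair_edema = edema | extra

    if spec.noise_std > 0:
        noise = np.random.default_rng(noise_ss).normal(0.0, spec.noise_std,
                                                       spec.grid_size)
        base = base + noise
        if pair_values is not None:
            pair_values = pair_values + noise

    def _sample(values: np.ndarray, edema_mask: np.ndarray) -> PhantomSample:
        return PhantomSample(
            image=DensityImage(values=values, pixel_spacing=spec.pixel_spacing,
                               slice_thickness=spec.slice_thickness,
                               slice_index=slice_index),
            adipose_mask=BinaryMask(ring.astype(np.uint8)),
            edema_mask=BinaryMask(edema_mask.astype(np.uint8)),
            spec=spec,
            seed=int(seed_seq.entropy) if isinstance(seed_seq.entropy, int) else -1,
        )

    base_sample = _sample(base, edema)
    if pair_values is None:
        return base_sample
    return base_sample, _sample(pair_values, pair_edema)


def generate_phantom(spec: PhantomSpec, seed: int, slice_index: int = 0) -> PhantomSample:
    """Generate one phantom slice; identical (spec, seed) reproduce it exactly."""
    return _generate(spec, np.random.SeedSequence(seed), slice_index)


def generate_phantom_pair(spec: PhantomSpec, seed: int,
                          extra_blob_count: int = 3,
                          extra_radius_range: tuple[float, float] = (2.0, 4.0),
                          ) -> tuple[PhantomSample, PhantomSample]:
    """Paired samples differing only by added small, isolated edema blobs.

    Both samples share the ring densities, the primary blobs and the noise
    field; the second additionally contains ``extra_blob_count`` small blobs
    disjoint from the primary edema.
    """
    return _generate(spec, np.random.SeedSequence(seed),
                     extra_blob_count=extra_blob_count,
                     extra_radius_range=extra_radius_range)


def generate_training_pairs(spec: PhantomSpec, n: int, seed: int
                            ) -> list[tuple[BinaryMask, GrayscaleMask]]:
    """n edema-free (binary mask, grayscale mask) pairs for prior fitting."""
    if n < 1:
        raise ValueError("n must be >= 1")
    clean = replace(spec, edema_blob_count=0)
    pairs = []
    for child in np.random.SeedSequence(seed).spawn(n):
        sample = _generate(clean, child)
        pairs.append((sample.adipose_mask,
                      apply_mask(sample.image, sample.adipose_mask)))
    return pairs


def generate_stack(spec: PhantomSpec, n_slices: int, seed: int
                   ) -> tuple[SliceStack, SliceStack, SliceStack]:
    """An ordered stack of phantom slices: (images, adipose masks, edema masks)."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    samples = [_generate(spec, child, slice_index=i)
               for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_slices))]
    return (SliceStack(tuple(s.image for s in samples)),
            SliceStack(tuple(s.adipose_mask for s in samples)),
            SliceStack(tuple(s.edema_mask for s in samples)))
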