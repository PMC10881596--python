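"""Density histograms, normalized correlation, and the adipose density prior.

The prior constraint compares the binned density distribution of the evolving
adipose region, G(I_ns), with that of an edema-free adipose reference, G(I_s),
through the normalized (Pearson) correlation of the two count vectors:

    F = sum((G1 - mean(G1)) * (G2 - mean(G2)))
        / sqrt(sum((G1 - mean(G1))**2) * sum((G2 - mean(G2))**2))

Counts are used raw: mean-centering makes any positive rescaling irrelevant.
The edema-free reference would come from a mask-to-texture generative model in
a full clinical pipeline; here it is a pluggable interface whose default is a
statistical surrogate that fills a binary mask with draws from a fitted
Gaussian adipose density model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import stats

from .imaging import BinaryMask, GrayscaleMask

__all__ = [
    "DensityHistogram",
    "PriorModel",
    "build_histogram",
    "normalized_correlation",
    "prior_dissimilarity",
    "fit_prior",
    "generate_prior_mask",
    "PriorMaskGenerator",
    "GaussianSurrogateGenerator",
    "ExternalMaskAdapter",
    "DEFAULT_N_BINS",
    "DEFAULT_HIST_RANGE",
]

DEFAULT_N_BINS = 64
DEFAULT_HIST_RANGE = (-200.0, 100.0)


@dataclass(frozen=True)
class DensityHistogram:
    """Binned HU distribution: N+1 strictly increasing edges, N counts >= 0.

    Bins are half-open [e_i, e_{i+1}) with the last bin closed. A histogram
    with all counts equal is constructible but cannot enter a correlation
    (zero variance)."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        counts = np.asarray(self.counts, dtype=np.float64)
        if edges.ndim != 1 or counts.ndim != 1 or edges.size != counts.size + 1:
            raise ValueError("need N+1 edges for N counts")
        if counts.size < 2:
            raise ValueError("at least 2 bins required")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def hu_range(self) -> tuple[float, float]:
        return (float(self.bin_edges[0]), float(self.bin_edges[-1]))


def build_histogram(values: Sequence[float], n_bins: int = DEFAULT_N_BINS,
                    hu_range: tuple[float, float] = DEFAULT_HIST_RANGE
                    ) -> DensityHistogram:
    """Bin densities over a fixed HU range; out-of-range values are clipped
    into the end bins so every sample is counted."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("cannot build a histogram from an empty value list")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(hu_range[0]), float(hu_range[1])
    counts, edges = np.histogram(np.clip(values, lo, hi), bins=n_bins,
                                 range=(lo, hi))
    return DensityHistogram(bin_edges=edges, counts=counts.astype(np.float64))


def _check_compatible(h1: DensityHistogram, h2: DensityHistogram) -> None:
    if h1.n_bins != h2.n_bins or not np.allclose(h1.bin_edges, h2.bin_edges):
        raise ValueError("histograms must share identical bin edges")


def normalized_correlation(h1: DensityHistogram, h2: DensityHistogram) -> float:
    """Pearson correlation of the two count vectors, in [-1, 1].

    Raises on mismatched edges or a zero-variance (constant) histogram, for
    which the denominator is undefined.
    """
    _check_compatible(h1, h2)
    d1 = h1.counts - h1.counts.mean()
    d2 = h2.counts - h2.counts.mean()
    denom_sq = float(np.sum(d1 ** 2)) * float(np.sum(d2 ** 2))
    if denom_sq == 0.0:
        raise ValueError("zero-variance histogram: correlation undefined")
    r = float(np.sum(d1 * d2)) / np.sqrt(denom_sq)
    return float(np.clip(r, -1.0, 1.0))  # guard float drift past Cauchy-Schwarz


def prior_dissimilarity(h_region: DensityHistogram,
                        h_prior: DensityHistogram) -> float:
    """1 - correlation: 0 when the region matches the prior, up to 2 when
    anti-correlated. Grows with the edema fraction of the region."""
    return 1.0 - normalized_correlation(h_region, h_prior)


@dataclass(frozen=True)
class PriorModel:
    """Edema-free adipose density model: Gaussian moments + pooled histogram."""

    adipose_mean: float
    adipose_std: float
    fitted_histogram: DensityHistogram
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.adipose_std > 0:
            raise ValueError("degenerate std: prior requires adipose_std > 0")

    def expected_histogram(self, n_bins: int = DEFAULT_N_BINS,
                           hu_range: tuple[float, float] = DEFAULT_HIST_RANGE
                           ) -> DensityHistogram:
        """Gaussian bin masses on an arbitrary grid (correlation is scale-free,
        so the absolute normalization is irrelevant)."""
        edges = np.linspace(hu_range[0], hu_range[1], n_bins + 1)
        cdf = stats.norm.cdf(edges, loc=self.adipose_mean, scale=self.adipose_std)
        masses = np.diff(cdf)
        # clipped binning sends both tails into the end bins
        masses[0] += cdf[0]
        masses[-1] += 1.0 - cdf[-1]
        return DensityHistogram(bin_edges=edges, counts=masses)

    def histogram_for(self, n_bins: int, hu_range: tuple[float, float]
                      ) -> DensityHistogram:
        """The fitted histogram when its grid matches, else the analytic one."""
        h = self.fitted_histogram
        if h.n_bins == n_bins and np.allclose(
                h.bin_edges, np.linspace(hu_range[0], hu_range[1], n_bins + 1)):
            return h
        return self.expected_histogram(n_bins, hu_range)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "adipose_mean": self.adipose_mean,
            "adipose_std": self.adipose_std,
            "bin_edges": self.fitted_histogram.bin_edges.tolist(),
            "counts": self.fitted_histogram.counts.tolist(),
            "provenance": self.provenance,
        }, indent=2))

    @classmethod
    def from_json(cls, path) -> "PriorModel":
        d = json.loads(Path(path).read_text())
        return cls(adipose_mean=float(d["adipose_mean"]),
                   adipose_std=float(d["adipose_std"]),
                   fitted_histogram=DensityHistogram(
                       bin_edges=np.asarray(d["bin_edges"]),
                       counts=np.asarray(d["counts"])),
                   provenance=d.get("provenance", ""))


def fit_prior(pairs: Sequence[tuple[BinaryMask, GrayscaleMask]],
              n_bins: int = DEFAULT_N_BINS,
              hu_range: tuple[float, float] = DEFAULT_HIST_RANGE) -> PriorModel:
    """Fit the adipose prior from edema-free (binary, grayscale) mask pairs.

    Moments and the pooled histogram are computed over in-support densities
    only (the support mask, never a zero test).
    """
    if len(pairs) == 0:
        raise ValueError("at least one training pair required")
    pool = np.concatenate([gm.masked_values() for _bm, gm in pairs])
    if pool.size == 0:
        raise ValueError("empty density pool")
    mean = float(pool.mean())
    std = float(pool.std(ddof=1)) if pool.size > 1 else 0.0
    if std <= 0:
        raise ValueError("degenerate std: pooled densities are constant")
    return PriorModel(
        adipose_mean=mean, adipose_std=std,
        fitted_histogram=build_histogram(pool, n_bins, hu_range),
        provenance=f"fitted from {len(pairs)} mask pairs, {pool.size} voxels")


def generate_prior_mask(mask: BinaryMask, prior: PriorModel, seed: int
                        ) -> GrayscaleMask:
    """Fill a binary mask with i.i.d. Normal(adipose_mean, adipose_std) draws:
    the statistical surrogate for a generated edema-free grayscale mask."""
    rng = np.random.default_rng(seed)
    values = np.zeros(mask.shape, dtype=np.float64)
    inside = mask.as_bool()
    values[inside] = rng.normal(prior.adipose_mean, prior.adipose_std,
                                int(inside.sum()))
    return GrayscaleMask(values=values, support=mask)


class PriorMaskGenerator(Protocol):
    """Anything that maps a binary adipose mask to an edema-free grayscale
    mask. Lets an externally trained image-to-image model slot in without
    code change."""

    def __call__(self, mask: BinaryMask, seed: int) -> GrayscaleMask: ...


@dataclass(frozen=True)
class GaussianSurrogateGenerator:
    """Default generator: i.i.d. Gaussian fill from a fitted prior."""

    prior: PriorModel

    def __call__(self, mask: BinaryMask, seed: int) -> GrayscaleMask:
        return generate_prior_mask(mask, self.prior, seed)


@dataclass(frozen=True)
class ExternalMaskAdapter:
    """Adapter around a user-supplied callable producing synthetic grayscale
    masks (e.g. inference of a separately trained network)."""

    produce: Callable[[BinaryMask], GrayscaleMask]

    def __call__(self, mask: BinaryMask, seed: int) -> GrayscaleMask:
        out = self.produce(mask)
        if out.shape != mask.shape:
            raise ValueError("external generator returned a mismatched shape")
        return out
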