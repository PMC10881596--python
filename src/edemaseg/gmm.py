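"""Two-class Gaussian mixture baseline for edema vs adipose densities.

The baseline models the HU distribution inside the subcutaneous adipose
compartment as a two-component 1-D Gaussian mixture (adipose ~ -100 HU,
edema near water) fitted by EM, and labels a voxel edema when the posterior
of the higher-mean component reaches 0.5 (MAP). It has no spatial coupling,
which is exactly what the level-set method adds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .imaging import BinaryMask, DensityImage

__all__ = ["TwoClassGMM", "fit_gmm_em", "classify_edema_gmm",
           "SIGMA_FLOOR", "W_FLOOR"]

SIGMA_FLOOR = 0.5  # HU; guards collapse on near-constant regions
W_FLOOR = 0.01


@dataclass(frozen=True)
class TwoClassGMM:
    """Fitted mixture; component 0 is adipose (lower mean), 1 is edema."""

    weights: tuple[float, float]
    means: tuple[float, float]
    stds: tuple[float, float]
    log_likelihood: float
    n_iter: int
    loglik_trace: tuple = ()

    def __post_init__(self) -> None:
        w1, w2 = self.weights
        if not (0 < w1 < 1 and 0 < w2 < 1 and abs(w1 + w2 - 1) < 1e-9):
            raise ValueError("weights must be in (0,1) and sum to 1")
        if min(self.stds) < SIGMA_FLOOR:
            raise ValueError(f"stds must be >= sigma floor {SIGMA_FLOOR}")
        if not all(np.isfinite(self.means)):
            raise ValueError("means must be finite")
        if self.means[0] >= self.means[1]:
            raise ValueError("components must be ordered mu_adipose < mu_edema")

    @property
    def mu_adipose(self) -> float:
        return self.means[0]

    @property
    def mu_edema(self) -> float:
        return self.means[1]


def _median_split_init(x: np.ndarray):
    """Deterministic init: split at the median, moments per half."""
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if lo.size == 0 or hi.size == 0:  # heavy ties at the median
        xs = np.sort(x)
        half = xs.size // 2
        lo, hi = xs[:half], xs[half:]
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.maximum([lo.std(), hi.std()], SIGMA_FLOOR)
    w = np.array([lo.size, hi.size], dtype=float) / x.size
    w = np.clip(w, W_FLOOR, 1 - W_FLOOR)
    return w / w.sum(), mu, sd


def fit_gmm_em(values, tol: float = 1e-6, max_iter: int = 500,
               seed: int | None = None) -> TwoClassGMM:
    """Fit the two-component 1-D mixture by EM.

    Initialization is a deterministic median split, so ``seed`` only exists
    for API symmetry with the stochastic modules. Stops when the
    log-likelihood gain drops below ``tol``. The log-likelihood is asserted
    non-decreasing at every step. Raises on degenerate data (all values
    identical) or a collapsed component (std at the floor with weight below
    ``W_FLOOR``).
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 20:
        raise ValueError("need at least 20 values to fit the mixture")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all values identical")

    w, mu, sd = _median_split_init(x)
    prev_ll = -np.inf
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        log_comp = np.log(w)[:, None] + norm.logpdf(x[None, :], mu[:, None],
                                                    sd[:, None])
        log_mix = logsumexp(log_comp, axis=0)
        ll = float(log_mix.sum())
        assert ll >= prev_ll - 1e-9 * max(1.0, abs(prev_ll)), \
            "EM log-likelihood decreased"
        trace.append(ll)
        gain = ll - prev_ll
        prev_ll = ll
        if gain < tol:
            break
        resp = np.exp(log_comp - log_mix[None, :])
        # M-step
        nk = resp.sum(axis=1)
        w = nk / x.size
        mu = (resp @ x) / nk
        var = (resp @ x ** 2) / nk - mu ** 2
        sd = np.sqrt(np.maximum(var, 0.0))
        collapsed = (sd < SIGMA_FLOOR) & (w < W_FLOOR)
        if collapsed.any():
            raise ValueError("degenerate fit: a component collapsed")
        sd = np.maximum(sd, SIGMA_FLOOR)
        w = np.clip(w, W_FLOOR, 1 - W_FLOOR)
        w = w / w.sum()

    order = np.argsort(mu)  # adipose (lower mean) first
    w, mu, sd = w[order], mu[order], sd[order]
    return TwoClassGMM(weights=(float(w[0]), float(w[1])),
                       means=(float(mu[0]), float(mu[1])),
                       stds=(float(sd[0]), float(sd[1])),
                       log_likelihood=prev_ll, n_iter=n_iter,
                       loglik_trace=tuple(trace))


def edema_posterior(values, gmm: TwoClassGMM) -> np.ndarray:
    """Posterior probability of the edema (higher-mean) component."""
    x = np.asarray(values, dtype=np.float64)
    log_a = np.log(gmm.weights[0]) + norm.logpdf(x, gmm.means[0], gmm.stds[0])
    log_e = np.log(gmm.weights[1]) + norm.logpdf(x, gmm.means[1], gmm.stds[1])
    return np.exp(log_e - np.logaddexp(log_a, log_e))


def classify_edema_gmm(image: DensityImage, adipose_mask: BinaryMask,
                       gmm: TwoClassGMM) -> BinaryMask:
    """MAP labelling: edema iff inside the adipose mask and the posterior of
    the edema component is >= 0.5."""
    if image.shape != adipose_mask.shape:
        raise ValueError("image and mask shapes differ")
    out = np.zeros(image.shape, dtype=np.uint8)
    inside = adipose_mask.as_bool()
    post = edema_posterior(image.values[inside], gmm)
    out[inside] = (post >= 0.5).astype(np.uint8)
    return BinaryMask(values=out)
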