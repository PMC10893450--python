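"""Gaussian-mixture peak detection in Ks age distributions.

A WGD leaves a burst of paralog pairs of similar age, visible as a
Gaussian-like mode in the Ks distribution.  We fit univariate Gaussian
mixtures by weighted EM directly on the raw Ks values (each observation
contributing its redundancy weight to the responsibilities), select the
component count by BIC, and report components above a weight cutoff as
candidate WGD peaks.  Peaks are then placed relative to the mode of an
interspecific (ortholog-divergence) distribution: a peak older than the
divergence mode means the duplication predates the speciation.

Conventions: BIC = -2 logL + p ln(n_eff) with p = 3k - 1 free parameters
and n_eff the total observation weight, minimised; component variances are
floored at 1e-4; restarts are initialised k-means++-style from a seeded
generator, so the same seed reproduces the same fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .kaks import KsDistribution

log = logging.getLogger(__name__)

__all__ = ["MixtureModel", "WGDPeak", "PeakPlacement",
           "fit_gmm", "select_model", "extract_peaks", "place_peak"]

VAR_FLOOR = 1e-4


@dataclass
class MixtureModel:
    components: list                 # (weight, mean, sd), sorted by mean
    n_obs: float                     # effective sample size (sum of weights)
    log_likelihood: float
    bic: float
    converged: bool
    n_iter: int
    loglik_path: list = field(default_factory=list, repr=False)

    @property
    def k(self) -> int:
        return len(self.components)


@dataclass
class WGDPeak:
    mean_ks: float
    sd: float
    weight: float
    source: str = ""


@dataclass
class PeakPlacement:
    peak: WGDPeak
    divergence_peak_ks: float
    relation: str                    # before_divergence | after_divergence | coincident


def _weighted_loglik(x, w, pi, mu, var):
    # component-wise log density, (k, n)
    lp = (
        -0.5 * np.log(2 * np.pi * var)[:, None]
        - 0.5 * (x[None, :] - mu[:, None]) ** 2 / var[:, None]
        + np.log(pi)[:, None]
    )
    col = logsumexp(lp, axis=0)
    return float(np.sum(w * col)), lp, col


def _init_means(x, w, k, rng):
    """k-means++-style seeding on the weighted observations."""
    p = w / w.sum()
    means = [x[rng.choice(len(x), p=p)]]
    for _ in range(1, k):
        d2 = np.min((x[:, None] - np.array(means)[None, :]) ** 2, axis=1)
        probs = w * d2
        tot = probs.sum()
        if tot <= 0:
            means.append(x[rng.choice(len(x), p=p)])
        else:
            means.append(x[rng.choice(len(x), p=probs / tot)])
    return np.array(means, dtype=float)


def _em(x, w, k, rng, tol, max_iter):
    n_eff = w.sum()
    mu = _init_means(x, w, k, rng)
    var0 = max(float(np.average((x - np.average(x, weights=w)) ** 2, weights=w)), VAR_FLOOR)
    var = np.full(k, var0)
    pi = np.full(k, 1.0 / k)
    ll_path = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, lp, col = _weighted_loglik(x, w, pi, mu, var)
        ll_path.append(ll)
        resp = np.exp(lp - col[None, :])          # (k, n)
        rw = resp * w[None, :]
        nk = rw.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        pi = nk / n_eff
        mu = (rw @ x) / nk
        var = np.maximum((rw * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk, VAR_FLOOR)
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll
    ll, _, _ = _weighted_loglik(x, w, pi, mu, var)
    ll_path.append(ll)
    order = np.argsort(mu)
    comps = [(float(pi[i]), float(mu[i]), float(np.sqrt(var[i]))) for i in order]
    return comps, ll, converged, it, ll_path


def fit_gmm(
    dist: KsDistribution | np.ndarray,
    k_max: int = 4,
    n_restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    weights: np.ndarray | None = None,
) -> list[MixtureModel]:
    """Fit weighted Gaussian mixtures for k = 1..k_max; per k the best of
    ``n_restarts`` EM runs by log-likelihood is kept.  k values with fewer
    observations than free parameters are skipped with a warning."""
    if isinstance(dist, KsDistribution):
        x, w = dist.values, dist.weights
    else:
        x = np.asarray(dist, dtype=float)
        w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 effective observations")
    n_eff = float(w.sum())
    rng = np.random.default_rng(seed)
    models = []
    for k in range(1, k_max + 1):
        p = 3 * k - 1
        if len(x) <= p:
            log.warning("k=%d skipped: %d observations <= %d parameters", k, len(x), p)
            continue
        best = None
        for _ in range(n_restarts):
            comps, ll, conv, it, path = _em(x, w, k, rng, tol, max_iter)
            if best is None or ll > best[1]:
                best = (comps, ll, conv, it, path)
        comps, ll, conv, it, path = best
        bic = -2.0 * ll + p * np.log(n_eff)
        models.append(MixtureModel(comps, n_eff, ll, float(bic), conv, it, path))
    return models


def select_model(models: list[MixtureModel]) -> MixtureModel:
    """Minimum-BIC model; ties break toward fewer components."""
    if not models:
        raise ValueError("no models to select from")
    return min(models, key=lambda m: (m.bic, m.k))


def extract_peaks(model: MixtureModel, min_weight: float = 0.1,
                  source: str = "") -> list[WGDPeak]:
    """Components with weight >= min_weight, sorted by mean Ks ascending."""
    peaks = [
        WGDPeak(mean_ks=mu, sd=sd, weight=w, source=source)
        for (w, mu, sd) in model.components
        if w >= min_weight
    ]
    peaks.sort(key=lambda p: p.mean_ks)
    return peaks


def place_peak(
    peak: WGDPeak,
    divergence_dist: KsDistribution,
    tolerance: float = 0.1,
    k_max: int = 3,
    seed: int = 0,
) -> PeakPlacement:
    """Place a WGD peak relative to an ortholog-divergence distribution.

    The divergence peak is the dominant (highest-weight) component of a
    BIC-selected mixture fit to the interspecific distribution.  A WGD
    peak *older* (larger Ks) than the divergence peak predates the
    speciation: relation ``before_divergence``; younger: ``after_divergence``;
    within ``tolerance``: ``coincident``."""
    if not divergence_dist.entries:
        raise ValueError("empty divergence distribution")
    if len(divergence_dist.entries) >= 10:
        model = select_model(fit_gmm(divergence_dist, k_max=k_max, seed=seed))
        div = max(model.components, key=lambda c: c[0])[1]
    else:
        div = float(np.average(divergence_dist.values, weights=divergence_dist.weights))
    if peak.mean_ks > div + tolerance:
        rel = "before_divergence"
    elif peak.mean_ks < div - tolerance:
        rel = "after_divergence"
    else:
        rel = "coincident"
    return PeakPlacement(peak=peak, divergence_peak_ks=float(div), relation=rel)
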