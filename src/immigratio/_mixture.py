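"""Weighted 1-D two-component Gaussian mixture, fitted by EM.

Used to locate the split of the abundance-weighted log10-ratio distribution.
Observation weights (per-OTU digester read abundances) enter the E- and
M-steps directly, which standard mixture implementations do not support —
hence this small, dedicated estimator.  sklearn-style surface: ``fit`` plus
trailing-underscore fitted attributes.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ArgumentError

_SIGMA_FLOOR = 1e-3


def _weighted_loglik(x, w, pis, mus, sigmas):
    dens = np.zeros_like(x)
    for pi, mu, sd in zip(pis, mus, sigmas):
        dens += pi * np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    return float(np.sum(w * np.log(np.maximum(dens, 1e-300))))


class WeightedGMM2:
    """Two-component weighted Gaussian mixture on the real line.

    Parameters
    ----------
    n_restarts : int
        EM restarts from random initial splits; the best weighted
        log-likelihood wins.
    tol : float
        Convergence tolerance on the weighted log-likelihood.
    random_state : int
        Seed for the restart initializations.

    Attributes (after ``fit``)
    --------------------------
    means_, sigmas_, weights_ : ndarray of shape (2,)
        Component parameters, ordered by increasing mean.
    loglik_ : float
        Best weighted log-likelihood reached.
    """

    def __init__(self, n_restarts: int = 50, tol: float = 1e-8,
                 max_iter: int = 500, random_state: int = 0):
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, x, sample_weight=None) -> "WeightedGMM2":
        x = np.asarray(x, dtype=float)
        if sample_weight is None:
            sample_weight = np.ones_like(x)
        w = np.asarray(sample_weight, dtype=float)
        if x.ndim != 1 or w.shape != x.shape:
            raise ArgumentError("x and sample_weight must be 1-D and aligned")
        keep = w > 0
        x, w = x[keep], w[keep]
        if np.unique(x).size < 2:
            raise ArgumentError("need at least 2 distinct values to fit a mixture")
        w = w / w.sum()
        rng = np.random.default_rng(self.random_state)
        best = None
        order = np.argsort(x)
        xs, ws = x[order], w[order]
        cw = np.cumsum(ws)
        for r in range(self.n_restarts):
            # initialize from a split at a random weighted quantile
            q = 0.5 if r == 0 else float(rng.uniform(0.05, 0.95))
            idx = int(np.searchsorted(cw, q))
            idx = min(max(idx, 1), len(xs) - 1)
            init = self._moments_from_split(xs, ws, idx)
            fitted = self._em(x, w, *init)
            if fitted is not None and (best is None or fitted[-1] > best[-1]):
                best = fitted
        if best is None:
            raise ArgumentError("EM failed to converge from any restart")
        pis, mus, sigmas, ll = best
        order2 = np.argsort(mus)
        self.weights_ = pis[order2]
        self.means_ = mus[order2]
        self.sigmas_ = sigmas[order2]
        self.loglik_ = ll
        return self

    @staticmethod
    def _moments_from_split(xs, ws, idx):
        pis, mus, sigmas = np.empty(2), np.empty(2), np.empty(2)
        for k, sl in enumerate((slice(None, idx), slice(idx, None))):
            wk = ws[sl]
            xk = xs[sl]
            pis[k] = max(wk.sum(), 1e-6)
            mus[k] = np.average(xk, weights=wk) if wk.sum() > 0 else xs.mean()
            var = np.average((xk - mus[k]) ** 2, weights=wk) if wk.sum() > 0 else 1.0
            sigmas[k] = max(np.sqrt(var), _SIGMA_FLOOR)
        pis /= pis.sum()
        return pis, mus, sigmas

    def _em(self, x, w, pis, mus, sigmas):
        pis, mus, sigmas = pis.copy(), mus.copy(), sigmas.copy()
        ll_old = -np.inf
        for _ in range(self.max_iter):
            # E-step: responsibilities
            log_dens = np.empty((2, x.size))
            for k in range(2):
                log_dens[k] = (
                    np.log(pis[k])
                    - np.log(sigmas[k])
                    - 0.5 * np.log(2 * np.pi)
                    - 0.5 * ((x - mus[k]) / sigmas[k]) ** 2
                )
            m = log_dens.max(axis=0)
            resp = np.exp(log_dens - m)
            resp /= resp.sum(axis=0)
            # M-step with observation weights
            wk = resp * w
            mass = wk.sum(axis=1)
            if (mass < 1e-12).any():
                return None
            pis = mass / mass.sum()
            mus = (wk @ x) / mass
            diff = x[None, :] - mus[:, None]
            sigmas = np.sqrt(np.maximum((wk * diff**2).sum(axis=1) / mass, _SIGMA_FLOOR**2))
            ll = _weighted_loglik(x, w, pis, mus, sigmas)
            if abs(ll - ll_old) < self.tol:
                break
            ll_old = ll
        return pis, mus, sigmas, _weighted_loglik(x, w, pis, mus, sigmas)

    def density_dip(self, n_grid: int = 4001) -> float:
        """Valley depth of the fitted mixture density, as dip / minor peak.

        Returns the ratio of the lowest density between the two highest
        local maxima to the smaller of those maxima; 1.0 when the density
        is unimodal (no valley).  A genuine two-mode distribution has a
        deep valley (ratio near 0); a "shoulder" fit of a unimodal
        distribution has a shallow one (ratio near 1).
        """
        lo = float(self.means_.min() - 3 * self.sigmas_.max())
        hi = float(self.means_.max() + 3 * self.sigmas_.max())
        xs = np.linspace(lo, hi, n_grid)
        dens = np.zeros_like(xs)
        for pi, mu, sd in zip(self.weights_, self.means_, self.sigmas_):
            dens += pi * np.exp(-0.5 * ((xs - mu) / sd) ** 2) / sd
        d = np.diff(dens)
        peaks = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
        if len(peaks) < 2:
            return 1.0
        top2 = peaks[np.argsort(dens[peaks])][-2:]
        i, j = int(top2.min()), int(top2.max())
        dip = float(dens[i:j + 1].min())
        minor = float(min(dens[i], dens[j]))
        return dip / minor if minor > 0 else 1.0

    # -- split geometry ----------------------------------------------------
    def equal_posterior_point(self) -> float | None:
        """x between the component means where the weighted posteriors cross.

        Solves pi1 N(x|mu1,s1) = pi2 N(x|mu2,s2) analytically (quadratic in
        x) and returns the root inside the open interval between the means,
        or None when the posteriors never cross there (one component
        dominates throughout — effectively unimodal).
        """
        (p1, p2), (m1, m2), (s1, s2) = self.weights_, self.means_, self.sigmas_
        lo, hi = (m1, m2) if m1 < m2 else (m2, m1)
        a = 1.0 / s2**2 - 1.0 / s1**2
        b = 2.0 * (m1 / s1**2 - m2 / s2**2)
        c = (m2**2 / s2**2 - m1**2 / s1**2) + 2.0 * np.log((p1 * s2) / (p2 * s1))
        if abs(a) < 1e-12:
            if abs(b) < 1e-12:
                return None
            roots = [-c / b]
        else:
            disc = b**2 - 4 * a * c
            if disc < 0:
                return None
            roots = [(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)]
        inside = [r for r in roots if lo < r < hi]
        if not inside:
            return None
        return float(min(inside, key=lambda r: abs(r - 0.5 * (lo + hi))))

    def grid_split(self, n_grid: int = 20001) -> float | None:
        """Dense-grid search for the posterior crossing (independent check)."""
        lo, hi = sorted(self.means_)
        if hi - lo < 1e-12:
            return None
        xs = np.linspace(lo, hi, n_grid)
        (p1, p2), (m1, m2), (s1, s2) = self.weights_, self.means_, self.sigmas_
        d1 = p1 * np.exp(-0.5 * ((xs - m1) / s1) ** 2) / s1
        d2 = p2 * np.exp(-0.5 * ((xs - m2) / s2) ** 2) / s2
        diff = d1 - d2
        signs = np.sign(diff)
        crossings = np.where(np.diff(signs) != 0)[0]
        if len(crossings) == 0:
            return None
        i = crossings[np.argmin(np.abs(xs[crossings] - 0.5 * (lo + hi)))]
        return float(0.5 * (xs[i] + xs[i + 1]))
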