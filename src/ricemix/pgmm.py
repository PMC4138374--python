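"""Parsimonious Gaussian mixture models: mixtures of factor analyzers.

Each component has covariance ``Sigma_g = Lambda_g @ Lambda_g.T + Psi_g`` with
a p x q loading matrix ``Lambda_g`` (q latent factors) and diagonal noise
``Psi_g``.  Constraint codes are three letters over (loadings common?, noise
common?, noise isotropic?), C = constrained/common, U = unconstrained:
UUU is the fully unconstrained mixture of factor analyzers.

Supported: UUU, UCU, UUC, UCC (component-specific loadings; closed-form
CM-steps) and CCU, CCC (common loadings with common noise).  CUU and CUC need
an iterative row-wise loading solver and are rejected.

Fitting is by AECM: cycle 1 updates weights and means with the component
labels as missing data; cycle 2 updates loadings and noise with (labels,
latent factors) as missing data.  Component inverses use the Woodbury
identity.  BIC = 2*loglik - m*log(n), maximized, as in :mod:`ricemix.gpcm`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

CONSTRAINTS = ("UUU", "UCU", "UUC", "UCC", "CCU", "CCC")
_UNSUPPORTED = ("CUU", "CUC")


class DegeneratePGMMError(RuntimeError):
    pass


def max_factors(p: int) -> int:
    """Largest admissible latent dimension for p observed variables.

    Ceiling of the Ledermann root (2p + 1 - sqrt(8p + 1)) / 2; gives q <= 2
    for the 4-condition profiles this package clusters.
    """
    return max(1, math.ceil((2 * p + 1 - math.sqrt(8 * p + 1)) / 2))


def _parse_constraint(code: str) -> tuple[bool, bool, bool]:
    if code in _UNSUPPORTED:
        raise ValueError(
            f"constraint {code!r} (common loadings, component noise) requires a "
            f"row-wise iterative solver and is not supported; use one of {CONSTRAINTS}"
        )
    if code not in CONSTRAINTS:
        raise ValueError(f"unknown constraint {code!r}; expected one of {CONSTRAINTS}")
    return code[0] == "C", code[1] == "C", code[2] == "C"


def n_free_params(constraint: str, G: int, q: int, p: int) -> int:
    common_load, common_psi, iso_psi = _parse_constraint(constraint)
    load = p * q - q * (q - 1) // 2
    if not common_load:
        load *= G
    psi = 1 if iso_psi else p
    if not common_psi:
        psi *= G
    return (G - 1) + G * p + load + psi


@dataclass
class PGMMFit:
    G: int
    q: int
    constraint: str
    weights: np.ndarray        # (G,)
    means: np.ndarray          # (G, p)
    loadings: np.ndarray       # (G, p, q)
    psi: np.ndarray            # (G, p) diagonal noise
    responsibilities: np.ndarray
    log_likelihood: float
    n_params: int
    bic: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def component_covariance(self, g: int) -> np.ndarray:
        L = self.loadings[g]
        return L @ L.T + np.diag(self.psi[g])


# ---------------------------------------------------------------------------
# Woodbury helpers
# ---------------------------------------------------------------------------

def woodbury_inverse(Lambda: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Inverse of Lambda@Lambda.T + diag(psi) via the Woodbury identity.

    O(p*q^2) instead of O(p^3); exact for positive psi.
    """
    psi_inv = 1.0 / psi
    PiL = psi_inv[:, None] * Lambda                      # Psi^-1 Lambda, (p, q)
    core = np.eye(Lambda.shape[1]) + Lambda.T @ PiL      # I + L' Psi^-1 L
    return np.diag(psi_inv) - PiL @ np.linalg.solve(core, PiL.T)


def _logdet_sigma(Lambda: np.ndarray, psi: np.ndarray) -> float:
    core = np.eye(Lambda.shape[1]) + Lambda.T @ (Lambda / psi[:, None])
    sign, logdet_core = np.linalg.slogdet(core)
    return float(np.sum(np.log(psi)) + logdet_core)


def _log_gaussian_lowrank(X, mean, Lambda, psi):
    p = X.shape[1]
    inv = woodbury_inverse(Lambda, psi)
    diff = X - mean
    maha = np.einsum("ij,jk,ik->i", diff, inv, diff)
    return -0.5 * (p * np.log(2.0 * np.pi) + _logdet_sigma(Lambda, psi) + maha)


def _e_step(X, weights, means, loadings, psi):
    n = X.shape[0]
    G = len(weights)
    logp = np.empty((n, G))
    for g in range(G):
        logp[:, g] = np.log(weights[g]) + _log_gaussian_lowrank(X, means[g], loadings[g], psi[g])
    norm = logsumexp(logp, axis=1)
    return float(norm.sum()), np.exp(logp - norm[:, None])


# ---------------------------------------------------------------------------
# AECM
# ---------------------------------------------------------------------------

def _init_params(X, G, q, rng, psi_floor):
    n, p = X.shape
    if G == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=G, init="k-means++", n_init=1,
                    random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(X)
    weights = np.array([(labels == g).mean() for g in range(G)])
    if np.any(weights * n < 1.0):
        return None
    means = np.array([X[labels == g].mean(axis=0) for g in range(G)])
    loadings = np.empty((G, p, q))
    psi = np.empty((G, p))
    for g in range(G):
        Xg = X[labels == g]
        S = np.cov(Xg.T, bias=True) if len(Xg) > 1 else np.eye(p)
        S = np.atleast_2d(S)
        vals, vecs = np.linalg.eigh(S)
        vals = np.maximum(vals[::-1], psi_floor)
        vecs = vecs[:, ::-1]
        noise = max(float(vals[q:].mean()) if p > q else psi_floor, psi_floor)
        loadings[g] = vecs[:, :q] * np.sqrt(np.maximum(vals[:q] - noise, psi_floor))
        psi[g] = noise
    return weights, means, loadings, psi


def _cm_step2(X, z, means, loadings, psi, constraint, psi_floor):
    """Update loadings and noise given responsibilities and new means."""
    common_load, common_psi, iso_psi = _parse_constraint(constraint)
    n, p = X.shape
    G = z.shape[1]
    q = loadings.shape[2]
    ng = z.sum(axis=0)

    S = np.empty((G, p, p))
    beta = np.empty((G, q, p))
    theta = np.empty((G, q, q))
    for g in range(G):
        diff = X - means[g]
        S[g] = ((z[:, g][:, None] * diff).T @ diff) / ng[g]
        inv = woodbury_inverse(loadings[g], psi[g])
        beta[g] = loadings[g].T @ inv
        theta[g] = np.eye(q) - beta[g] @ loadings[g] + beta[g] @ S[g] @ beta[g].T

    new_load = np.empty_like(loadings)
    if common_load:
        num = sum(ng[g] * S[g] @ beta[g].T for g in range(G))
        den = sum(ng[g] * theta[g] for g in range(G))
        L = num @ np.linalg.inv(den)
        new_load[:] = L
    else:
        for g in range(G):
            new_load[g] = S[g] @ beta[g].T @ np.linalg.inv(theta[g])

    resid = np.empty((G, p))  # diag(S_g - Lambda_new beta_g S_g)
    for g in range(G):
        resid[g] = np.diag(S[g]) - np.einsum("ij,jk,ki->i", new_load[g], beta[g], S[g])
    new_psi = np.empty((G, p))
    if common_psi:
        pooled = (ng[:, None] * resid).sum(axis=0) / n
        if iso_psi:
            pooled = np.full(p, pooled.mean())
        new_psi[:] = pooled
    else:
        for g in range(G):
            r = resid[g]
            new_psi[g] = np.full(p, r.mean()) if iso_psi else r
    new_psi = np.maximum(new_psi, psi_floor)
    return new_load, new_psi


def fit_pgmm(
    profiles: np.ndarray,
    G: int,
    q: int = 1,
    constraint: str = "UUU",
    init: str = "kmeans",
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_starts: int = 10,
) -> PGMMFit:
    """Fit a mixture of factor analyzers by AECM.

    The observed-data log-likelihood is non-decreasing per full AECM cycle; a
    fit that hits ``max_iter`` without converging is returned flagged.  Noise
    variances are floored at 1e-6 times the data variance.
    """
    X = np.asarray(profiles, dtype=float)
    n, p = X.shape
    if not 1 <= q <= max_factors(p):
        raise ValueError(f"q={q} outside [1, {max_factors(p)}] for p={p}")
    if n <= G:
        raise ValueError(f"need n > G (got n={n}, G={G})")
    _parse_constraint(constraint)

    psi_floor = 1e-6 * float(np.var(X)) if np.var(X) > 0 else 1e-12
    rng = np.random.default_rng(seed)
    starts = 1 if G == 1 else n_starts

    best = None
    for _ in range(starts):
        params = _init_params(X, G, q, rng, psi_floor)
        if params is None:
            continue
        weights, means, loadings, psi = params
        trace = []
        prev = -np.inf
        converged = False
        n_iter = 0
        failed = False
        for n_iter in range(1, max_iter + 1):
            # cycle 1: labels missing -> update weights, means
            _, z = _e_step(X, weights, means, loadings, psi)
            ng = z.sum(axis=0)
            if np.any(ng < 1.0):
                failed = True
                break
            weights = ng / n
            means = (z.T @ X) / ng[:, None]
            # cycle 2: (labels, factors) missing -> update loadings, noise
            _, z = _e_step(X, weights, means, loadings, psi)
            if np.any(z.sum(axis=0) < 1.0):
                failed = True
                break
            loadings, psi = _cm_step2(X, z, means, loadings, psi, constraint, psi_floor)
            ll, z = _e_step(X, weights, means, loadings, psi)
            trace.append(ll)
            if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
            prev = ll
        if failed or not trace:
            continue
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], weights, means, loadings, psi, z, trace, converged, n_iter)
    if best is None:
        raise DegeneratePGMMError(
            f"all {starts} restart(s) degenerate for {constraint}, G={G}, q={q}"
        )
    ll, weights, means, loadings, psi, z, trace, converged, n_iter = best
    m = n_free_params(constraint, G, q, p)
    return PGMMFit(
        G=G, q=q, constraint=constraint,
        weights=weights, means=means, loadings=loadings, psi=psi,
        responsibilities=z, log_likelihood=ll, n_params=m,
        bic=2.0 * ll - m * np.log(n), n_iter=n_iter, converged=converged,
        loglik_trace=np.asarray(trace),
    )


def predict_labels(fit: PGMMFit) -> np.ndarray:
    return np.argmax(fit.responsibilities, axis=1)


def select_pgmm(
    profiles: np.ndarray,
    G_range=range(1, 6),
    q_range=(1,),
    constraints=("UUU",),
    seed: int | None = None,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[PGMMFit, pd.DataFrame]:
    """BIC-maximizing fit over the (G, q, constraint) grid, plus the grid."""
    X = np.asarray(profiles, dtype=float)
    n, p = X.shape
    G_range, q_range = list(G_range), list(q_range)
    if not G_range or not q_range or not constraints:
        raise ValueError("grids must be non-empty")
    bound = max_factors(p)
    rows = []
    fits: dict[tuple[int, int, str], PGMMFit] = {}
    ss = np.random.SeedSequence(seed)
    for G in G_range:
        for q in q_range:
            for code in constraints:
                sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
                if q > bound or n <= G:
                    rows.append({"G": G, "q": q, "constraint": code, "status": "unfitted",
                                 "loglik": np.nan, "n_params": np.nan, "bic": np.nan})
                    continue
                try:
                    fit = fit_pgmm(X, G, q, code, seed=sub_seed, tol=tol,
                                   max_iter=max_iter, n_starts=n_starts)
                except DegeneratePGMMError:
                    rows.append({"G": G, "q": q, "constraint": code, "status": "degenerate",
                                 "loglik": np.nan, "n_params": np.nan, "bic": np.nan})
                    continue
                fits[(G, q, code)] = fit
                rows.append({"G": G, "q": q, "constraint": code, "status": "ok",
                             "loglik": fit.log_likelihood, "n_params": fit.n_params,
                             "bic": fit.bic})
    grid = pd.DataFrame(rows)
    if not fits:
        raise DegeneratePGMMError(f"no (G, q, constraint) cell could be fitted; grid:\n{grid}")
    best_key = min(
        fits,
        key=lambda k: (-fits[k].bic, k[0], k[1], CONSTRAINTS.index(k[2])),
    )
    return fits[best_key], grid
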