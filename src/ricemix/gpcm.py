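"""Gaussian parsimonious clustering models (GPCM).

Finite Gaussian mixtures whose component covariances are constrained through
the eigen-decomposition ``Sigma_g = lambda_g * D_g @ A_g @ D_g.T`` — volume
``lambda_g`` (scalar), orientation ``D_g`` (orthogonal), shape ``A_g``
(diagonal, unit determinant).  Constraining each factor to be equal (E) or
variable (V) across components, with identity (I) orientation/shape where
applicable, gives the model family.  Eight models are supported:

====== ======================== ==========================
code   covariance               free covariance parameters
====== ======================== ==========================
EII    lambda * I               1
VII    lambda_g * I             G
EEI    lambda * A               p
VEI    lambda_g * A             G + (p - 1)
EVI    lambda * A_g             1 + G*(p - 1)
VVI    lambda_g * A_g           G*p
EEE    lambda * D A D'          p*(p + 1)/2
VVV    lambda_g * D_g A_g D_g'  G*p*(p + 1)/2
====== ======================== ==========================

Fitting is by EM from k-means++ initializations; model and component-count
selection maximizes BIC = 2*loglik - m*log(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

MODEL_NAMES = ("EII", "VII", "EEI", "VEI", "EVI", "VVI", "EEE", "VVV")

_DIAGONAL_MODELS = {"EII", "VII", "EEI", "VEI", "EVI", "VVI"}


class DegenerateFitError(RuntimeError):
    """All restarts collapsed (vanishing component or singular covariance)."""


def n_covariance_params(model_name: str, G: int, p: int) -> int:
    if model_name == "EII":
        return 1
    if model_name == "VII":
        return G
    if model_name == "EEI":
        return p
    if model_name == "VEI":
        return G + (p - 1)
    if model_name == "EVI":
        return 1 + G * (p - 1)
    if model_name == "VVI":
        return G * p
    if model_name == "EEE":
        return p * (p + 1) // 2
    if model_name == "VVV":
        return G * p * (p + 1) // 2
    raise ValueError(f"unsupported model {model_name!r}; expected one of {MODEL_NAMES}")


def n_free_params(model_name: str, G: int, p: int) -> int:
    """Total free parameters: weights + means + covariance structure."""
    return (G - 1) + G * p + n_covariance_params(model_name, G, p)


@dataclass
class GPCMFit:
    """A fitted eigen-decomposed Gaussian mixture."""

    G: int
    model_name: str
    weights: np.ndarray          # (G,)
    means: np.ndarray            # (G, p)
    covariances: np.ndarray      # (G, p, p)
    volumes: np.ndarray          # (G,) lambda_g
    orientations: np.ndarray     # (G, p, p) D_g
    shapes: np.ndarray           # (G, p) diagonal of A_g, det 1
    responsibilities: np.ndarray  # (n, G)
    log_likelihood: float
    n_params: int
    bic: float
    n_iter: int
    converged: bool
    regularized: bool = False
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n(self) -> int:
        return self.responsibilities.shape[0]


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

_LOG_2PI = np.log(2.0 * np.pi)


def _is_diagonal(cov: np.ndarray) -> bool:
    return not np.any(cov[~np.eye(cov.shape[0], dtype=bool)])


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    p = X.shape[1]
    diff = X - mean
    if _is_diagonal(cov):  # fast path for the six diagonal models
        d = np.diag(cov)
        if np.any(d <= 0):
            raise np.linalg.LinAlgError("non-positive diagonal covariance")
        maha = (diff * diff / d).sum(axis=1)
        logdet = np.log(d).sum()
    else:
        L = np.linalg.cholesky(cov)
        sol = np.linalg.solve(L, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (p * _LOG_2PI + logdet + maha)


def _e_step(X, weights, means, covs):
    """Return (log-likelihood, responsibilities)."""
    n, _ = X.shape
    G = len(weights)
    logw = np.log(weights)
    logp = np.empty((n, G))
    for g in range(G):
        logp[:, g] = logw[g] + _log_gaussian(X, means[g], covs[g])
    peak = logp.max(axis=1)
    z = np.exp(logp - peak[:, None])
    tot = z.sum(axis=1)
    norm = peak + np.log(tot)
    z /= tot[:, None]
    return float(norm.sum()), z


# ---------------------------------------------------------------------------
# M-step: constrained covariance updates
# ---------------------------------------------------------------------------

def _floor_eigenvalues(covs: np.ndarray, floor: float) -> tuple[np.ndarray, bool]:
    """Clip covariance eigenvalues at ``floor``; report whether any were clipped."""
    out = np.empty_like(covs)
    touched = False
    for g in range(covs.shape[0]):
        if _is_diagonal(covs[g]):  # eigenvalues are the diagonal itself
            d = np.diag(covs[g])
            if d.min() < floor:
                touched = True
                out[g] = np.diag(np.maximum(d, floor))
            else:
                out[g] = covs[g]
            continue
        vals, vecs = np.linalg.eigh(covs[g])
        if vals[0] < floor:
            touched = True
            vals = np.maximum(vals, floor)
            out[g] = (vecs * vals) @ vecs.T
        else:
            out[g] = covs[g]
    return out, touched


def _m_step_cov(model_name, W, Wg, ng, n, p, state):
    """Covariance update given pooled scatter W, per-component scatters Wg.

    ``state`` carries warm-start information across EM iterations (the shared
    shape of VEI), so the inner coordinate ascent never decreases Q.
    """
    G = len(ng)
    covs = np.empty((G, p, p))
    if model_name == "EII":
        lam = np.trace(W) / (n * p)
        covs[:] = lam * np.eye(p)
    elif model_name == "VII":
        for g in range(G):
            covs[g] = (np.trace(Wg[g]) / (ng[g] * p)) * np.eye(p)
    elif model_name == "EEI":
        covs[:] = np.diag(np.diag(W) / n)
    elif model_name == "VEI":
        dW = np.array([np.diag(Wg[g]) for g in range(G)])  # (G, p)
        B = state.get("vei_shape")
        if B is None:
            tot = dW.sum(axis=0)
            B = tot / np.prod(tot) ** (1.0 / p)
        B = np.maximum(B, 1e-300)
        for _ in range(20):
            lam = (dW / B).sum(axis=1) / (ng * p)  # (G,)
            B_raw = (dW / lam[:, None]).sum(axis=0)
            B_new = B_raw / np.prod(B_raw) ** (1.0 / p)
            if np.max(np.abs(B_new - B)) < 1e-12 * (1.0 + np.max(B)):
                B = B_new
                break
            B = B_new
        state["vei_shape"] = B
        lam = (dW / B).sum(axis=1) / (ng * p)
        for g in range(G):
            covs[g] = np.diag(lam[g] * B)
    elif model_name == "EVI":
        dW = np.array([np.diag(Wg[g]) for g in range(G)])
        dW = np.maximum(dW, 1e-300)
        # geometric mean via logs; floored so a collapsed component cannot
        # underflow the normalization (the eigenvalue floor cleans up after)
        dets = np.maximum(np.exp(np.log(dW).sum(axis=1) / p), 1e-300)
        lam = dets.sum() / n
        for g in range(G):
            covs[g] = np.diag(lam * dW[g] / dets[g])
    elif model_name == "VVI":
        for g in range(G):
            covs[g] = np.diag(np.diag(Wg[g]) / ng[g])
    elif model_name == "EEE":
        covs[:] = W / n
    elif model_name == "VVV":
        for g in range(G):
            covs[g] = Wg[g] / ng[g]
    else:
        raise ValueError(f"unsupported model {model_name!r}; expected one of {MODEL_NAMES}")
    return covs


def _m_step(X, z, model_name, floor, state):
    n, p = X.shape
    ng = z.sum(axis=0)
    if np.any(ng < 1.0):  # component weight below 1/n: degenerate start
        return None
    weights = ng / n
    means = (z.T @ X) / ng[:, None]
    G = z.shape[1]
    Wg = np.empty((G, p, p))
    for g in range(G):
        diff = X - means[g]
        Wg[g] = (z[:, g][:, None] * diff).T @ diff
    W = Wg.sum(axis=0)
    covs = _m_step_cov(model_name, W, Wg, ng, n, p, state)
    covs, touched = _floor_eigenvalues(covs, floor)
    return weights, means, covs, touched


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _init_responsibilities(X, G, init, rng):
    n = X.shape[0]
    if isinstance(init, np.ndarray):
        z = np.asarray(init, dtype=float)
        if z.shape != (n, G):
            raise ValueError(f"init responsibilities must have shape {(n, G)}")
        return z / z.sum(axis=1, keepdims=True)
    if G == 1:
        return np.ones((n, 1))
    if init == "kmeans":
        km = KMeans(
            n_clusters=G,
            init="k-means++",
            n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        labels = km.fit_predict(X)
        z = np.zeros((n, G))
        z[np.arange(n), labels] = 1.0
        return z
    if init == "random":
        z = rng.random((n, G)) + 1e-3
        return z / z.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown init spec {init!r}")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _decompose(covs):
    """lambda_g, D_g, A_g (diag, det 1) from each covariance matrix."""
    G, p, _ = covs.shape
    volumes = np.empty(G)
    orientations = np.empty((G, p, p))
    shapes = np.empty((G, p))
    for g in range(G):
        vals, vecs = np.linalg.eigh(covs[g])
        lam = np.prod(vals) ** (1.0 / p)
        volumes[g] = lam
        orientations[g] = vecs
        shapes[g] = vals / lam
    return volumes, orientations, shapes


def _run_em(X, G, model_name, z0, tol, max_iter, floor):
    state: dict = {}
    z = z0
    trace = []
    prev_ll = -np.inf
    weights = means = covs = None
    regularized = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        m = _m_step(X, z, model_name, floor, state)
        if m is None:
            return None  # collapsed component
        weights, means, covs, touched = m
        regularized = regularized or touched
        try:
            ll, z = _e_step(X, weights, means, covs)
        except np.linalg.LinAlgError:
            return None
        trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
            converged = True
            break
        prev_ll = ll
    return weights, means, covs, z, trace, converged, regularized, it


def fit_gpcm(
    profiles: np.ndarray,
    G: int,
    model_name: str = "VVV",
    init="kmeans",
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_starts: int = 10,
) -> GPCMFit:
    """Fit a G-component GPCM mixture to an (n, p) profile matrix by EM.

    ``init`` is either ``"kmeans"`` (k-means++ hard assignment, ``n_starts``
    restarts), ``"random"``, or an explicit (n, G) responsibility matrix (in
    which case a single run is performed).  The best restart by log-likelihood
    is returned.  Covariance eigenvalues are floored at 1e-6 times the data
    variance; a fit that needed flooring is flagged ``regularized``.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValueError("profiles must be a 2-d array (genes x conditions)")
    n, p = X.shape
    if G < 1:
        raise ValueError("G must be >= 1")
    if n <= G:
        raise ValueError(f"need n > G (got n={n}, G={G})")
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unsupported model {model_name!r}; expected one of {MODEL_NAMES}")

    floor = 1e-6 * float(np.var(X)) if np.var(X) > 0 else 1e-12
    rng = np.random.default_rng(seed)
    explicit = isinstance(init, np.ndarray) or G == 1
    starts = 1 if explicit else n_starts

    best = None
    for _ in range(starts):
        z0 = _init_responsibilities(X, G, init, rng)
        out = _run_em(X, G, model_name, z0, tol, max_iter, floor)
        if out is None:
            continue
        if best is None or out[4][-1] > best[4][-1]:
            best = out
    if best is None:
        raise DegenerateFitError(
            f"all {starts} restart(s) degenerate for model {model_name}, G={G}, n={n}"
        )
    weights, means, covs, z, trace, converged, regularized, n_iter = best
    ll = trace[-1]
    m = n_free_params(model_name, G, p)
    volumes, orientations, shapes = _decompose(covs)
    return GPCMFit(
        G=G,
        model_name=model_name,
        weights=weights,
        means=means,
        covariances=covs,
        volumes=volumes,
        orientations=orientations,
        shapes=shapes,
        responsibilities=z,
        log_likelihood=ll,
        n_params=m,
        bic=2.0 * ll - m * np.log(n),
        n_iter=n_iter,
        converged=converged,
        regularized=regularized,
        loglik_trace=np.asarray(trace),
    )


def bic_of(fit: GPCMFit, n: int) -> float:
    """BIC = 2*loglik - m*log(n) (maximized; larger is better)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 2.0 * fit.log_likelihood - fit.n_params * np.log(n)


def predict_labels(fit: GPCMFit) -> np.ndarray:
    """Hard labels by maximum responsibility; ties go to the lowest index."""
    return np.argmax(fit.responsibilities, axis=1)


def select_model(
    profiles: np.ndarray,
    G_range=range(1, 10),
    model_set=MODEL_NAMES,
    seed: int | None = None,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[GPCMFit, pd.DataFrame]:
    """Fit every (G, model) pair and return the BIC-maximizing fit plus the grid.

    Infeasible cells (n < G*(p+1)) are flagged ``unfitted``; degenerate cells
    are flagged ``degenerate``.  Ties in BIC are broken toward smaller G, then
    toward the simpler model (the order of ``MODEL_NAMES``).
    """
    X = np.asarray(profiles, dtype=float)
    n, p = X.shape
    G_range = list(G_range)
    if not G_range:
        raise ValueError("G_range must be non-empty")
    for mname in model_set:
        n_covariance_params(mname, 1, p)  # validates names early

    rows = []
    fits: dict[tuple[int, str], GPCMFit] = {}
    ss = np.random.SeedSequence(seed)
    for G in G_range:
        for mname in model_set:
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
            if n < G * (p + 1) or n <= G:
                rows.append({"G": G, "model": mname, "status": "unfitted",
                             "loglik": np.nan, "n_params": np.nan, "bic": np.nan})
                continue
            try:
                fit = fit_gpcm(X, G, mname, seed=sub_seed, tol=tol,
                               max_iter=max_iter, n_starts=n_starts)
            except DegenerateFitError:
                rows.append({"G": G, "model": mname, "status": "degenerate",
                             "loglik": np.nan, "n_params": np.nan, "bic": np.nan})
                continue
            fits[(G, mname)] = fit
            rows.append({"G": G, "model": mname, "status": "ok",
                         "loglik": fit.log_likelihood, "n_params": fit.n_params,
                         "bic": fit.bic})
    grid = pd.DataFrame(rows)
    if not fits:
        raise DegenerateFitError(f"no (G, model) cell could be fitted; grid:\n{grid}")
    best_key = min(
        fits,
        key=lambda k: (-fits[k].bic, k[0], MODEL_NAMES.index(k[1])),
    )
    return fits[best_key], grid
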