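"""Two-step clustering of 4-condition expression profiles.

Step 1 clusters the (LDSN, LDLN, HDSN, HDLN) mean profiles of the
density-specific gene set with a mixture model (GPCM or PGMM engine, BIC
selection), grouping genes that follow a similar overall trend.  Step 2 splits
each component's profiles by planting density into two 2-dimensional data sets
— the (SN, LN) pair under high density and the (SN, LN) pair under low density
— and clusters each with k = 2 (k-means, or a G = 2 GPCM).  A gene whose
nitrogen-response sub-cluster differs between the two densities is flagged
*discordant*: its response to nitrogen follows one trend under low density and
a different trend under high density.

The two step-2 solutions carry arbitrary label indices, so sub-clusters are
matched across densities by the nitrogen trend of their centers (the LN - SN
coordinate difference), which is directly comparable between densities and
stays well defined even when half the genes are discordant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import gpcm as _gpcm
from . import pgmm as _pgmm
from .datamodel import CONDITIONS

STRATEGIES = ("gpcm-kmeans", "pgmm-kmeans", "gpcm-gpcm", "pgmm-gpcm")

_I_LDSN, _I_LDLN, _I_HDSN, _I_HDLN = (CONDITIONS.index(c) for c in CONDITIONS)


def split_by_density(profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split (n, 4) condition profiles into HD and LD (SN, LN) pairs.

    Returns (hd_pairs, ld_pairs), each (n, 2) with columns (SN, LN).
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(CONDITIONS):
        raise ValueError(f"profiles must be (n, {len(CONDITIONS)})")
    hd = X[:, [_I_HDSN, _I_HDLN]]
    ld = X[:, [_I_LDSN, _I_LDLN]]
    return hd, ld


def kmeans2(points: np.ndarray, seed: int | None = None, n_starts: int = 10
            ) -> tuple[np.ndarray, np.ndarray]:
    """2-means on an (n, 2) matrix: best of ``n_starts`` k-means++ runs.

    Returns (labels in {0, 1}, centers (2, 2)).  When all points coincide the
    split is degenerate: every point gets label 0 and both centers equal the
    common point (documented convention).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need an (n, 2) matrix with n >= 2")
    if np.all(pts == pts[0]):
        return np.zeros(len(pts), dtype=int), np.tile(pts[0], (2, 1))
    # canonical point order makes the seeded result independent of row order
    order = np.lexsort(pts.T[::-1])
    km = KMeans(n_clusters=2, init="k-means++", n_init=n_starts,
                random_state=None if seed is None else int(seed))
    sorted_labels = km.fit_predict(pts[order])
    labels = np.empty(len(pts), dtype=int)
    labels[order] = sorted_labels
    return labels, km.cluster_centers_


def _gpcm2(points: np.ndarray, seed, n_starts: int,
           model_set=_gpcm.MODEL_NAMES) -> tuple[np.ndarray, np.ndarray]:
    """G = 2 GPCM on an (n, 2) matrix; best covariance model by BIC."""
    pts = np.asarray(points, dtype=float)
    if np.all(pts == pts[0]):
        return np.zeros(len(pts), dtype=int), np.tile(pts[0], (2, 1))
    order = np.lexsort(pts.T[::-1])
    fit, _ = _gpcm.select_model(pts[order], G_range=[2], model_set=model_set,
                                seed=seed, n_starts=n_starts)
    labels = np.empty(len(pts), dtype=int)
    labels[order] = _gpcm.predict_labels(fit)
    return labels, fit.means


def match_labels(hd_labels, hd_centers, ld_labels, ld_centers
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Relabel the HD sub-clusters to align with the LD sub-clusters.

    Candidate pairings are scored by the total mismatch of center nitrogen
    trends (LN - SN); the identity pairing wins ties.  Returns the HD labels
    and centers after relabeling.
    """
    hd_trend = hd_centers[:, 1] - hd_centers[:, 0]
    ld_trend = ld_centers[:, 1] - ld_centers[:, 0]
    ident = abs(hd_trend[0] - ld_trend[0]) + abs(hd_trend[1] - ld_trend[1])
    swap = abs(hd_trend[1] - ld_trend[0]) + abs(hd_trend[0] - ld_trend[1])
    if swap < ident:
        return 1 - np.asarray(hd_labels), hd_centers[::-1].copy()
    return np.asarray(hd_labels), hd_centers


def step2_component(
    profiles: np.ndarray,
    method: str = "kmeans",
    seed: int | None = None,
    n_starts: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Density-split 2-cluster analysis of one component's (n, 4) profiles.

    Runs the k = 2 (or G = 2 GPCM) clustering on the HD and LD (SN, LN) pairs,
    matches the sub-clusters across densities by center nitrogen trend, and
    returns (hd_labels, ld_labels, hd_centers, ld_centers, discordant).
    """
    if method not in ("kmeans", "gpcm"):
        raise ValueError("method must be 'kmeans' or 'gpcm'")
    hd, ld = split_by_density(profiles)
    ss = np.random.SeedSequence(seed)
    s_hd, s_ld = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2))
    cluster = kmeans2 if method == "kmeans" else _gpcm2
    hd_labels, hd_centers = cluster(hd, s_hd, n_starts)
    ld_labels, ld_centers = cluster(ld, s_ld, n_starts)
    hd_labels, hd_centers = match_labels(hd_labels, hd_centers, ld_labels, ld_centers)
    return hd_labels, ld_labels, hd_centers, ld_centers, hd_labels != ld_labels


@dataclass
class ComponentSplit:
    """Step-2 result for one step-1 component."""

    gene_ids: list[str]
    hd_labels: np.ndarray | None   # aligned to LD labels
    ld_labels: np.ndarray | None
    hd_centers: np.ndarray | None
    ld_centers: np.ndarray | None
    discordant: np.ndarray | None  # bool per gene; None when skipped
    skipped: bool = False


@dataclass
class TwoStepResult:
    strategy: str
    step1_fit: object
    step1_labels: np.ndarray
    gene_ids: list[str]
    components: dict[int, ComponentSplit] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per gene: component, sub-labels (1-based), discordance."""
        rows = []
        for comp, cs in self.components.items():
            for i, gid in enumerate(cs.gene_ids):
                rows.append({
                    "gene_id": gid,
                    "component": comp,
                    "hd_sublabel": None if cs.skipped else int(cs.hd_labels[i]) + 1,
                    "ld_sublabel": None if cs.skipped else int(cs.ld_labels[i]) + 1,
                    "discordant": None if cs.skipped else bool(cs.discordant[i]),
                })
        return pd.DataFrame(rows)

    def discordance_flags(self) -> dict[str, bool]:
        """gene_id -> discordant, omitting genes in skipped components."""
        out = {}
        for cs in self.components.values():
            if cs.skipped:
                continue
            for gid, d in zip(cs.gene_ids, cs.discordant):
                out[gid] = bool(d)
        return out


def run_two_step(
    gene_ids: Sequence[str],
    profiles: np.ndarray,
    strategy: str = "gpcm-kmeans",
    seed: int | None = None,
    G_range=range(1, 10),
    model_set=_gpcm.MODEL_NAMES,
    q_range=(1,),
    constraints=("UUU",),
    n_starts: int = 10,
    step2_density: str = "both",
) -> TwoStepResult:
    """Run the full two-step strategy on (n, 4) condition-mean profiles.

    ``strategy`` picks the step-1 engine and step-2 method from
    ``gpcm-kmeans``, ``pgmm-kmeans``, ``gpcm-gpcm``, ``pgmm-gpcm``.  Step 2 is
    run per step-1 component on the HD and LD (SN, LN) pairs independently and
    the two 2-cluster solutions are matched to flag discordant genes.
    Components with fewer than 4 genes (2 x k) skip step 2.
    ``step2_density`` may restrict step 2 to one density ("HD" or "LD"), in
    which case discordance is undefined and left None.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if step2_density not in ("both", "HD", "LD"):
        raise ValueError("step2_density must be 'both', 'HD' or 'LD'")
    X = np.asarray(profiles, dtype=float)
    gene_ids = list(gene_ids)
    if len(gene_ids) != len(X):
        raise ValueError("gene_ids and profiles disagree in length")

    ss = np.random.SeedSequence(seed)
    s1_seed, s2_seed = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2))

    engine = strategy.split("-")[0]
    if engine == "gpcm":
        fit, _ = _gpcm.select_model(X, G_range=G_range, model_set=model_set,
                                    seed=s1_seed, n_starts=n_starts)
        labels = _gpcm.predict_labels(fit)
    else:
        fit, _ = _pgmm.select_pgmm(X, G_range=G_range, q_range=q_range,
                                   constraints=constraints, seed=s1_seed,
                                   n_starts=n_starts)
        labels = _pgmm.predict_labels(fit)

    step2 = strategy.split("-")[1]
    result = TwoStepResult(strategy=strategy, step1_fit=fit,
                           step1_labels=labels, gene_ids=gene_ids)
    s2_ss = np.random.SeedSequence(s2_seed)
    for comp in range(fit.G):
        idx = np.flatnonzero(labels == comp)
        ids = [gene_ids[i] for i in idx]
        if idx.size < 4:  # < 2*k genes: sub-clustering is meaningless
            result.components[comp] = ComponentSplit(
                gene_ids=ids, hd_labels=None, ld_labels=None,
                hd_centers=None, ld_centers=None, discordant=None, skipped=True)
            continue
        comp_seed = int(s2_ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
        hd_labels = ld_labels = None
        hd_centers = ld_centers = None
        discordant = None
        if step2_density == "both":
            hd_labels, ld_labels, hd_centers, ld_centers, discordant = step2_component(
                X[idx], method=step2, seed=comp_seed, n_starts=n_starts)
        else:
            hd, ld = split_by_density(X[idx])
            pts = hd if step2_density == "HD" else ld
            cluster = kmeans2 if step2 == "kmeans" else _gpcm2
            labs, cents = cluster(pts, comp_seed, n_starts)
            if step2_density == "HD":
                hd_labels, hd_centers = labs, cents
            else:
                ld_labels, ld_centers = labs, cents
        result.components[comp] = ComponentSplit(
            gene_ids=ids, hd_labels=hd_labels, ld_labels=ld_labels,
            hd_centers=hd_centers, ld_centers=ld_centers,
            discordant=discordant, skipped=False)
    return result
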