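"""Synthetic expression, qPCR and GC-MS fixtures.

Generators that invert the pipeline's own models so every stage can be tested
without any download: expression profiles drawn from a Gaussian mixture over
4-condition mean profiles (the model the clustering assumes), Ct tables built
by inverting the 2^-ddCt relation at perfect doubling efficiency, and
component-area tables built by inverting internal-standard normalization.

Defaults emulate the structure of the study data this pipeline targets:
~21,179 genes, 4 density x nitrogen conditions, 3 replicates, 2 timepoints
(21 d and 31 d), with ~5% of genes carrying structured condition responses
grouped into 8 mean profiles and the rest flat.  Replicate noise is Gaussian
on the log2 scale (SD 0.25, a typical array replicate SD).  All generators
are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    CONDITIONS,
    CtTable,
    ExpressionMatrix,
    MetaboliteTable,
    SampleMeta,
)
from .gpcm import MODEL_NAMES

#: 8 default cluster mean profiles over (LDSN, LDLN, HDSN, HDLN), log2 units.
#: Effects are ~2 log2 (4-fold): HD up/down, LN up/down under both densities,
#: additive combined stress, combined-only, and an opposed HD-up/LN-down class.
DEFAULT_PROFILE_MEANS = np.array(
    [
        [8.0, 8.0, 10.0, 10.0],   # enhanced by high density
        [8.0, 8.0, 6.0, 6.0],     # suppressed by high density
        [8.0, 10.0, 8.0, 10.0],   # enhanced by nitrogen limitation
        [8.0, 6.0, 8.0, 6.0],     # suppressed by nitrogen limitation
        [8.0, 10.0, 10.0, 12.0],  # enhanced by both, additive
        [8.0, 6.0, 6.0, 4.0],     # suppressed by both, additive
        [8.0, 8.0, 8.0, 10.0],    # combined-stress specific
        [8.0, 6.0, 10.0, 8.0],    # HD-enhanced, LN-suppressed
    ]
)


@dataclass
class SimConfig:
    """Parameters of the expression-matrix generator."""

    n_genes: int = 21179
    n_replicates: int = 3
    timepoints: tuple[int, ...] = (21, 31)
    K_true: int = 8
    profile_means: np.ndarray = field(default_factory=lambda: DEFAULT_PROFILE_MEANS.copy())
    covariance_model: str = "EII"
    covariance_params: dict = field(default_factory=lambda: {"volume": 0.0625})
    frac_null: float = 0.95
    frac_discordant: float = 0.1
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.profile_means = np.asarray(self.profile_means, dtype=float)
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if self.profile_means.shape != (self.K_true, len(CONDITIONS)):
            raise ValueError(
                f"profile_means must have shape ({self.K_true}, {len(CONDITIONS)})"
            )
        if not (0.0 <= self.frac_null <= 1.0 and 0.0 <= self.frac_discordant <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.covariance_model not in MODEL_NAMES:
            raise ValueError(f"covariance_model must be one of {MODEL_NAMES}")
        if self.n_genes < 0 or self.n_replicates < 1:
            raise ValueError("n_genes must be >= 0 and n_replicates >= 1")


def component_covariances(cfg: SimConfig) -> np.ndarray:
    """Build the (K, 4, 4) component covariances from model + parameters.

    Parameter keys by model: volume (scalar) or volumes (length K); shape
    (length 4 diagonal, normalized to unit determinant) or shapes (K x 4);
    cov (4 x 4) or covs (K x 4 x 4) for the full-covariance models.
    """
    K, p = cfg.K_true, len(CONDITIONS)
    prm = cfg.covariance_params
    model = cfg.covariance_model

    def volumes():
        if "volumes" in prm:
            v = np.asarray(prm["volumes"], dtype=float)
            if v.shape != (K,):
                raise ValueError(f"volumes must have length {K}")
            return v
        return np.full(K, float(prm.get("volume", 0.0625)))

    def shapes():
        if "shapes" in prm:
            a = np.asarray(prm["shapes"], dtype=float)
        elif "shape" in prm:
            a = np.tile(np.asarray(prm["shape"], dtype=float), (K, 1))
        else:
            a = np.ones((K, p))
        a = a / np.prod(a, axis=1, keepdims=True) ** (1.0 / p)
        return a

    if model in ("EII", "VII"):
        v = volumes()
        if model == "EII" and not np.allclose(v, v[0]):
            raise ValueError("EII requires a common volume")
        return np.array([lv * np.eye(p) for lv in v])
    if model in ("EEI", "VEI", "EVI", "VVI"):
        v, a = volumes(), shapes()
        if model in ("EEI", "EVI") and not np.allclose(v, v[0]):
            raise ValueError(f"{model} requires a common volume")
        if model in ("EEI", "VEI") and not np.allclose(a, a[0]):
            raise ValueError(f"{model} requires a common shape")
        return np.array([np.diag(v[k] * a[k]) for k in range(K)])
    # EEE / VVV
    if "covs" in prm:
        c = np.asarray(prm["covs"], dtype=float)
        if c.shape != (K, p, p):
            raise ValueError(f"covs must have shape ({K}, {p}, {p})")
        return c
    c = np.asarray(prm.get("cov", 0.0625 * np.eye(p)), dtype=float)
    return np.tile(c, (K, 1, 1))


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Draw an expression matrix from the planted mixture.

    Returns (matrix, true_labels, true_discordance): labels are -1 for flat
    (null) genes and 0..K-1 for clustered genes; the discordance flag marks
    clustered genes whose nitrogen offset was planted under only one density.
    Replicate observations are the gene's latent condition value plus
    independent N(0, noise_sd^2) noise, independently at each timepoint.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    p = len(CONDITIONS)
    samples = [
        SampleMeta(
            sample_id=f"{cond}_t{tp}_r{r}",
            density=cond[:2], nitrogen=cond[2:], timepoint=tp, replicate=r,
        )
        for tp in cfg.timepoints
        for cond in CONDITIONS
        for r in range(1, cfg.n_replicates + 1)
    ]
    if n == 0:
        empty = np.empty((0, len(samples)))
        m = ExpressionMatrix(gene_ids=[], samples=samples, values=empty)
        return m, np.empty(0, dtype=int), np.empty(0, dtype=bool)

    n_null = int(round(cfg.frac_null * n))
    n_struct = n - n_null
    if n_struct > 0 and cfg.K_true > n_struct:
        raise ValueError(
            f"K_true={cfg.K_true} exceeds the {n_struct} genes left after null allocation"
        )

    labels = np.full(n, -1, dtype=int)
    if n_struct > 0:
        assign = np.arange(n_struct) % cfg.K_true  # balanced, then shuffled
        rng.shuffle(assign)
        struct_idx = rng.choice(n, size=n_struct, replace=False)
        labels[struct_idx] = assign

    latent = np.empty((n, p))
    null_mask = labels == -1
    base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=int(null_mask.sum()))
    latent[null_mask] = base[:, None]
    covs = component_covariances(cfg)
    for k in range(cfg.K_true):
        idx = np.flatnonzero(labels == k)
        if idx.size:
            latent[idx] = rng.multivariate_normal(cfg.profile_means[k], covs[k], size=idx.size)

    # plant discordance: remove the gene's nitrogen offset under one density
    i_ldsn, i_ldln, i_hdsn, i_hdln = (CONDITIONS.index(c) for c in CONDITIONS)
    discordant = np.zeros(n, dtype=bool)
    if n_struct > 0 and cfg.frac_discordant > 0:
        off_ld = np.abs(cfg.profile_means[:, i_ldln] - cfg.profile_means[:, i_ldsn])
        off_hd = np.abs(cfg.profile_means[:, i_hdln] - cfg.profile_means[:, i_hdsn])
        eligible_k = (off_ld > 1e-9) | (off_hd > 1e-9)
        candidates = np.flatnonzero((labels >= 0) & eligible_k[np.maximum(labels, 0)])
        n_disc = int(round(cfg.frac_discordant * n_struct))
        n_disc = min(n_disc, candidates.size)
        chosen = rng.choice(candidates, size=n_disc, replace=False)
        for i in chosen:
            k = labels[i]
            options = []
            if off_ld[k] > 1e-9:
                options.append("LD")
            if off_hd[k] > 1e-9:
                options.append("HD")
            which = options[int(rng.integers(len(options)))]
            if which == "LD":
                latent[i, i_ldln] = latent[i, i_ldsn]
            else:
                latent[i, i_hdln] = latent[i, i_hdsn]
            discordant[i] = True

    cond_col = np.array([CONDITIONS.index(s.condition) for s in samples])
    values = latent[:, cond_col] + rng.normal(0.0, cfg.noise_sd, size=(n, len(samples)))
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    m = ExpressionMatrix(gene_ids=gene_ids, samples=samples, values=values)
    return m, labels, discordant


def simulate_ct(
    fold_changes: Mapping[str, Mapping[str, float]],
    base_ct: float = 25.0,
    ref_ct: float = 18.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    calibrator: str = "LDSN",
    reference_gene: str = "actin2",
) -> CtTable:
    """Build a Ct table by inverting the 2^-ddCt relation.

    ``fold_changes[gene][condition]`` is the true relative abundance versus the
    calibrator (whose fold is taken as 1).  With perfect doubling efficiency,
    Ct_target = base_ct - log2(fold) + noise; the reference gene sits at
    ``ref_ct`` in every sample up to the same noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    conditions: set[str] = {calibrator}
    for gene, folds in fold_changes.items():
        for cond, f in folds.items():
            if f <= 0:
                raise ValueError(f"fold change must be positive (gene {gene!r}, {cond})")
            conditions.add(cond)
    for gene, folds in fold_changes.items():
        for cond in sorted(conditions):
            fold = float(folds.get(cond, 1.0))
            for r in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append({
                    "gene": gene, "condition": cond, "replicate": r,
                    "ct": base_ct - np.log2(fold) + noise,
                })
    for cond in sorted(conditions):
        for r in range(1, n_replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({
                "gene": reference_gene, "condition": cond, "replicate": r,
                "ct": ref_ct + noise,
            })
    return CtTable(data=pd.DataFrame(rows), reference_gene=reference_gene)


def simulate_metabolites(
    true_concentrations: Mapping[str, Mapping[str, float]],
    ribitol_area: float = 500.0,
    snr_range: tuple[float, float] = (5.0, 50.0),
    noise_cv: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    internal_standard: str = "ribitol",
) -> MetaboliteTable:
    """Build a component-area table by inverting ribitol normalization.

    Component area = true concentration x the sample's internal-standard area
    x multiplicative log-normal noise (sigma = noise_cv on the log scale);
    per-component S/N is drawn uniformly from ``snr_range``.
    """
    if ribitol_area <= 0:
        raise ValueError("ribitol_area must be positive")
    lo, hi = snr_range
    if lo <= 0 or hi < lo:
        raise ValueError("snr_range must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    conditions: set[str] = set()
    for comp, conc in true_concentrations.items():
        for cond, c in conc.items():
            if c < 0:
                raise ValueError(f"negative concentration for {comp!r} in {cond}")
            conditions.add(cond)
    rows = []
    samples = [(cond, r) for cond in sorted(conditions) for r in range(1, n_replicates + 1)]
    std_area = {
        s: ribitol_area * (float(np.exp(rng.normal(0.0, noise_cv))) if noise_cv > 0 else 1.0)
        for s in samples
    }
    snr_of = {
        comp: float(rng.uniform(lo, hi)) for comp in sorted(true_concentrations)
    }
    for comp in sorted(true_concentrations):
        conc = true_concentrations[comp]
        for cond, r in samples:
            mult = float(np.exp(rng.normal(0.0, noise_cv))) if noise_cv > 0 else 1.0
            rows.append({
                "component_id": comp, "condition": cond, "replicate": r,
                "area": float(conc.get(cond, 0.0)) * std_area[(cond, r)] * mult,
                "snr": snr_of[comp],
            })
    std_snr = float(rng.uniform(lo, hi))
    for cond, r in samples:
        rows.append({
            "component_id": internal_standard, "condition": cond, "replicate": r,
            "area": std_area[(cond, r)], "snr": std_snr,
        })
    return MetaboliteTable(data=pd.DataFrame(rows), internal_standard=internal_standard)
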