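"""qPCR relative quantification and GC-MS component normalization.

The 2^-ddCt method expresses a target gene relative to a reference gene
(actin2) and a calibrator condition (LDSN, the optimal control): per replicate
dCt = Ct_target - Ct_reference, ddCt = dCt - mean dCt of the calibrator, and
fold = 2^-ddCt, assuming perfect doubling per cycle.  GC-MS component areas
are filtered at signal-to-noise >= 5 and normalized to the ribitol internal
standard of the same sample.  Group comparisons use one-way ANOVA with
Fisher's LSD at alpha = 5% (optionally on square-root transformed values),
with Tukey's HSD and Shapiro-Wilk reported alongside from standard routines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datamodel import CtTable, MetaboliteTable, ValidationError
from .de import two_sample_ttest


@dataclass(frozen=True)
class DdctResult:
    gene: str
    condition: str
    delta_ct: float          # mean Ct_target - Ct_reference (cycles)
    delta_delta_ct: float    # vs calibrator mean dCt (cycles)
    fold: float              # mean of per-replicate 2^-ddCt
    replicate_folds: tuple[float, ...]
    p_vs_calibrator: float | None  # pooled t on replicate dCt; None at calibrator


@dataclass(frozen=True)
class NormalizedComponent:
    component_id: str
    condition: str
    replicate: int
    normalized_area: float   # area / same-sample ribitol area
    snr: float
    quantifiable: bool


def ddct_folds(ct: CtTable, calibrator: str = "LDSN") -> list[DdctResult]:
    """2^-ddCt fold changes of every target gene versus the calibrator.

    ddCt is formed against the calibrator's *mean* dCt; per-replicate folds
    feed the condition mean and a pooled t-test of replicate dCt values
    against the calibrator's.
    """
    df = ct.data
    ref = df[df["gene"] == ct.reference_gene].set_index(["condition", "replicate"])["ct"]
    targets = sorted(set(df["gene"]) - {ct.reference_gene})
    results: list[DdctResult] = []
    for gene in targets:
        sub = df[df["gene"] == gene]
        if calibrator not in set(sub["condition"]):
            raise ValidationError(f"gene {gene!r} has no measurement at calibrator {calibrator!r}")
        dct: dict[str, np.ndarray] = {}
        for cond, grp in sub.groupby("condition"):
            vals = []
            for _, row in grp.iterrows():
                key = (cond, row["replicate"])
                if key not in ref.index:
                    raise ValidationError(
                        f"reference {ct.reference_gene!r} missing for condition "
                        f"{cond!r} replicate {row['replicate']}"
                    )
                vals.append(row["ct"] - ref.loc[key])
            dct[cond] = np.asarray(vals, dtype=float)
        cal_mean = dct[calibrator].mean()
        for cond in sorted(dct):
            ddct = dct[cond] - cal_mean
            folds = 2.0 ** (-ddct)
            if cond == calibrator:
                p = None
            elif len(dct[cond]) >= 2 and len(dct[calibrator]) >= 2:
                _, p = two_sample_ttest(dct[cond], dct[calibrator], variant="pooled")
            else:
                p = None
            results.append(DdctResult(
                gene=gene, condition=cond,
                delta_ct=float(dct[cond].mean()),
                delta_delta_ct=float(ddct.mean()),
                fold=float(folds.mean()),
                replicate_folds=tuple(float(f) for f in folds),
                p_vs_calibrator=p,
            ))
    return results


def sn_filter(tbl: MetaboliteTable, threshold: float = 5.0) -> MetaboliteTable:
    """Keep components whose signal-to-noise ratio is >= threshold (inclusive)."""
    keep = tbl.data["snr"] >= threshold
    return MetaboliteTable(data=tbl.data[keep].reset_index(drop=True),
                           internal_standard=tbl.internal_standard)


def ribitol_normalize(tbl: MetaboliteTable, quant_threshold: float = 5.0
                      ) -> list[NormalizedComponent]:
    """Divide each component area by its sample's internal-standard area.

    The internal standard itself normalizes to 1.  Components below the
    quantifiability S/N threshold are carried with ``quantifiable=False``
    ("ND": detectable but below quantifiable amount), never imputed as zero.
    """
    df = tbl.data
    std = df[df["component_id"] == tbl.internal_standard]
    std_area = std.set_index(["condition", "replicate"])["area"]
    out = []
    for _, row in df.iterrows():
        key = (row["condition"], row["replicate"])
        if key not in std_area.index:
            raise ValidationError(
                f"internal standard {tbl.internal_standard!r} missing for sample "
                f"condition {key[0]!r} replicate {key[1]}"
            )
        denom = float(std_area.loc[key])
        if denom <= 0:
            raise ValidationError(
                f"internal standard area non-positive in sample condition "
                f"{key[0]!r} replicate {key[1]}"
            )
        out.append(NormalizedComponent(
            component_id=row["component_id"], condition=row["condition"],
            replicate=int(row["replicate"]),
            normalized_area=float(row["area"]) / denom,
            snr=float(row["snr"]),
            quantifiable=bool(row["snr"] >= quant_threshold),
        ))
    return out


@dataclass(frozen=True)
class AnovaLsdResult:
    f_statistic: float
    p_value: float
    lsd: float | None              # balanced-design LSD; None when unbalanced
    pairwise_significant: np.ndarray  # (k, k) bool, |mean_i - mean_j| > LSD_ij
    omnibus_significant: bool
    tukey_summary: str
    shapiro_p: float | None


def anova_lsd(groups, alpha: float = 0.05, sqrt_transform: bool = False) -> AnovaLsdResult:
    """One-way ANOVA with Fisher's least-significant-difference post hoc.

    LSD = t(1 - alpha/2, df_error) * sqrt(2 * MSE / n) for balanced groups;
    unbalanced pairs use the harmonic-mean n of the pair.  Pairwise flags are
    reported regardless of the omnibus result (which is flagged separately).
    Tukey's HSD and a Shapiro-Wilk residual-normality p accompany the result
    via standard library routines.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    if sqrt_transform:
        if any((g < 0).any() for g in gs):
            raise ValueError("square-root transform requires non-negative values")
        gs = [np.sqrt(g) for g in gs]

    k = len(gs)
    ns = np.array([len(g) for g in gs])
    means = np.array([g.mean() for g in gs])
    n_tot = int(ns.sum())
    df_err = n_tot - k
    sse = sum(((g - g.mean()) ** 2).sum() for g in gs)
    mse = sse / df_err
    if mse == 0.0:
        # all groups internally constant: F is 0/0 (p = 1) or infinite
        if np.allclose(means, means[0]):
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
    else:
        f, p = stats.f_oneway(*gs)
        f, p = float(f), float(p)
        if not np.isfinite(f):  # identical groups: SSB = SSE = 0
            f, p = 0.0, 1.0

    tcrit = stats.t.ppf(1 - alpha / 2, df_err)
    balanced = bool(np.all(ns == ns[0]))
    lsd = float(tcrit * np.sqrt(2.0 * mse / ns[0])) if balanced else None
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            nh = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])  # harmonic-mean pair size
            lsd_ij = tcrit * np.sqrt(2.0 * mse / nh)
            sig[i, j] = abs(means[i] - means[j]) > lsd_ij

    values = np.concatenate(gs)
    labels = np.concatenate([[f"g{i}"] * len(g) for i, g in enumerate(gs)])
    try:
        tukey = str(pairwise_tukeyhsd(values, labels, alpha=alpha))
    except Exception:  # degenerate spread
        tukey = "unavailable (degenerate data)"
    resid = np.concatenate([g - g.mean() for g in gs])
    if len(resid) >= 3 and np.ptp(resid) > 0:
        shapiro_p = float(stats.shapiro(resid).pvalue)
    else:
        shapiro_p = None
    return AnovaLsdResult(
        f_statistic=f, p_value=p, lsd=lsd, pairwise_significant=sig,
        omnibus_significant=bool(p < alpha), tukey_summary=tukey,
        shapiro_p=shapiro_p,
    )


def normalized_to_frame(comps: list[NormalizedComponent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "component_id": c.component_id, "condition": c.condition,
        "replicate": c.replicate, "normalized_area": c.normalized_area,
        "snr": c.snr, "quantifiable": c.quantifiable,
    } for c in comps])


def ddct_to_frame(results: list[DdctResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene, "condition": r.condition, "delta_ct": r.delta_ct,
        "delta_delta_ct": r.delta_delta_ct, "fold": r.fold,
        "p_vs_calibrator": r.p_vs_calibrator,
    } for r in results])
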