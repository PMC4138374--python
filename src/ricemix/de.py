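"""Responsive-gene calling, BH adjustment, and Venn partitioning.

Each gene is tested in three contrasts against the optimal-control condition
LDSN: HD (HDSN vs LDSN), LN (LDLN vs LDSN) and HDLN (HDLN vs LDSN).  A gene is
called *responsive* in a contrast when the linear fold change between condition
means passes the cutoff (default 2, both directions) AND the
Benjamini-Hochberg adjusted p-value of a two-sample t-test on the replicate
log2 values is below alpha (default 0.05).  Responsive sets feed a three-way
Venn partition; the clustering input set is the genes responsive to high
density but not to nitrogen limitation at a stricter 3-fold cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionMatrix

#: contrast name -> treatment condition (all against LDSN)
CONTRASTS = {"HD": "HDSN", "LN": "LDLN", "HDLN": "HDLN"}
CONTROL = "LDSN"


@dataclass(frozen=True)
class ContrastCall:
    fold_change: float      # linear scale, treatment / control
    log2_fc: float
    p_raw: float
    q_bh: float
    responsive: bool
    direction: str          # enhanced | suppressed | none


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    contrasts: dict[str, ContrastCall]


@dataclass(frozen=True)
class VennPartition:
    """The 7 disjoint regions over the (HD, LN, HDLN) responsive sets."""

    regions: dict[str, frozenset]

    REGION_KEYS = (
        "HD_only", "LN_only", "HDLN_only",
        "HD_LN", "HD_HDLN", "LN_HDLN", "HD_LN_HDLN",
    )

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def union(self) -> frozenset:
        out: frozenset = frozenset()
        for v in self.regions.values():
            out = out | v
        return out


def two_sample_ttest(x, y, variant: str = "pooled") -> tuple[float, float]:
    """Two-sided two-sample t-test.

    ``variant`` is ``"pooled"`` (Student, equal variances — the default for
    triplicate arrays) or ``"welch"``.  When both groups have zero variance,
    p = 1 if the means are equal (no evidence) and p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(t), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _vector_ttest(X: np.ndarray, Y: np.ndarray, variant: str) -> np.ndarray:
    """Row-wise two-sided t-test p-values for (genes x reps) matrices."""
    res = stats.ttest_ind(X, Y, axis=1, equal_var=(variant == "pooled"))
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: p = 1 when means agree, else 0
    nan = ~np.isfinite(p)
    if np.any(nan):
        equal = np.isclose(X[nan].mean(axis=1), Y[nan].mean(axis=1))
        p[nan] = np.where(equal, 1.0, 0.0)
    return p


def contrast_table(
    m: ExpressionMatrix,
    timepoint: int,
    test: str = "pooled",
) -> pd.DataFrame:
    """Per-gene log2 fold changes and raw p-values for the three contrasts.

    Long-format frame with columns gene_id, contrast, log2_fc, p_raw.
    """
    if test not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {test!r}")
    ctrl_idx = m.sample_index(timepoint=timepoint, condition=CONTROL)
    if ctrl_idx.size < 2:
        raise ValueError(f"need >= 2 {CONTROL} replicates at timepoint {timepoint}")
    Y = m.values[:, ctrl_idx]
    frames = []
    for name, cond in CONTRASTS.items():
        idx = m.sample_index(timepoint=timepoint, condition=cond)
        if idx.size < 2:
            raise ValueError(f"need >= 2 {cond} replicates at timepoint {timepoint}")
        X = m.values[:, idx]
        log2_fc = X.mean(axis=1) - Y.mean(axis=1)
        p = _vector_ttest(X, Y, test)
        frames.append(pd.DataFrame({
            "gene_id": m.gene_ids, "contrast": name,
            "log2_fc": log2_fc, "p_raw": p,
        }))
    return pd.concat(frames, ignore_index=True)


def call_responsive(
    m: ExpressionMatrix,
    timepoint: int,
    fold_cutoff: float = 2.0,
    alpha: float = 0.05,
    test: str = "pooled",
    apply_bh: bool = True,
) -> list[DEResult]:
    """Call genes responsive per contrast: fold cutoff AND BH-adjusted p < alpha.

    BH is applied per contrast across all genes.  ``apply_bh=False`` drops the
    significance criterion and keeps the fold filter alone.
    """
    if fold_cutoff <= 1:
        raise ValueError("fold_cutoff must exceed 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    tbl = contrast_table(m, timepoint, test=test)
    tbl["q_bh"] = np.concatenate([
        bh_adjust(tbl.loc[tbl["contrast"] == c, "p_raw"].to_numpy())
        for c in CONTRASTS
    ])
    log_cut = np.log2(fold_cutoff)
    passes_fold = np.abs(tbl["log2_fc"]) >= log_cut
    passes_sig = (tbl["q_bh"] < alpha) if apply_bh else True
    tbl["responsive"] = passes_fold & passes_sig

    # contrast frames were concatenated in CONTRASTS order, each in gene order
    cols = {}
    for k, c in enumerate(CONTRASTS):
        block = tbl.iloc[k * m.n_genes:(k + 1) * m.n_genes]
        cols[c] = (
            block["log2_fc"].to_numpy(), block["p_raw"].to_numpy(),
            block["q_bh"].to_numpy(), block["responsive"].to_numpy(),
        )
    results = []
    for i, gid in enumerate(m.gene_ids):
        calls = {}
        for c in CONTRASTS:
            lfc_a, p_a, q_a, r_a = cols[c]
            lfc = float(lfc_a[i])
            resp = bool(r_a[i])
            direction = "none" if not resp else ("enhanced" if lfc > 0 else "suppressed")
            calls[c] = ContrastCall(
                fold_change=float(2.0 ** lfc), log2_fc=lfc,
                p_raw=float(p_a[i]), q_bh=float(q_a[i]),
                responsive=resp, direction=direction,
            )
        results.append(DEResult(gene_id=gid, contrasts=calls))
    return results


def responsive_sets(de: list[DEResult]) -> dict[str, frozenset]:
    return {
        c: frozenset(r.gene_id for r in de if r.contrasts[c].responsive)
        for c in CONTRASTS
    }


def venn_partition(de: list[DEResult]) -> VennPartition:
    """Partition the three responsive sets into the 7 disjoint Venn regions."""
    s = responsive_sets(de)
    hd, ln, both = s["HD"], s["LN"], s["HDLN"]
    regions = {
        "HD_only": hd - ln - both,
        "LN_only": ln - hd - both,
        "HDLN_only": both - hd - ln,
        "HD_LN": (hd & ln) - both,
        "HD_HDLN": (hd & both) - ln,
        "LN_HDLN": (ln & both) - hd,
        "HD_LN_HDLN": hd & ln & both,
    }
    return VennPartition(regions={k: frozenset(v) for k, v in regions.items()})


def overlap_fraction(de: list[DEResult], denominator: str = "HD") -> float | None:
    """Fraction of HD-responsive genes that are also LN-responsive.

    ``denominator="union"`` uses |HD u LN| instead of |HD|.  Returns None when
    the denominator set is empty (the fraction is undefined).
    """
    s = responsive_sets(de)
    inter = s["HD"] & s["LN"]
    denom = s["HD"] if denominator == "HD" else s["HD"] | s["LN"]
    if not denom:
        return None
    return len(inter) / len(denom)


def select_density_specific(de: list[DEResult]) -> frozenset:
    """Genes responsive to high density but not to nitrogen limitation.

    Expects DE results computed at the stricter clustering cutoff (3-fold by
    convention); selection itself only reads the responsive flags.
    """
    s = responsive_sets(de)
    return frozenset(s["HD"] - s["LN"])


def density_specific_genes(
    m: ExpressionMatrix,
    timepoint: int,
    fold_cutoff: float = 3.0,
    alpha: float = 0.05,
    test: str = "pooled",
    apply_bh: bool = True,
) -> frozenset:
    """Recompute DE at ``fold_cutoff`` (default 3) and select HD-not-LN genes."""
    de = call_responsive(m, timepoint, fold_cutoff=fold_cutoff, alpha=alpha,
                         test=test, apply_bh=apply_bh)
    return select_density_specific(de)
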