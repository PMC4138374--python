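"""Core data types and TSV readers/writers.

The pipeline works on four table kinds: a log2 expression matrix with sample
metadata (density x nitrogen condition, timepoint, replicate), per-gene
condition-mean profiles, qPCR Ct tables, and GC-MS component-area tables with
an internal standard.  Expression values are assumed already normalized
(log2 scale); missing values are rejected, never imputed.

Condition labels combine planting density (HD/LD) and nitrogen supply (SN/LN).
The fixed condition order (LDSN, LDLN, HDSN, HDLN) is used everywhere; LDSN is
the optimal control condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Fixed condition order used by every profile-shaped array in the package.
CONDITIONS: tuple[str, ...] = ("LDSN", "LDLN", "HDSN", "HDLN")

DENSITIES = ("HD", "LD")
NITROGENS = ("SN", "LN")
TIMEPOINTS = (21, 31)


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


def condition_label(density: str, nitrogen: str) -> str:
    if density not in DENSITIES:
        raise ValidationError(f"unknown density {density!r}; expected one of {DENSITIES}")
    if nitrogen not in NITROGENS:
        raise ValidationError(f"unknown nitrogen level {nitrogen!r}; expected one of {NITROGENS}")
    return density + nitrogen


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one array sample (one replicate of one condition/timepoint)."""

    sample_id: str
    density: str
    nitrogen: str
    timepoint: int
    replicate: int

    def __post_init__(self) -> None:
        condition_label(self.density, self.nitrogen)  # validates
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: timepoint {self.timepoint} not in {TIMEPOINTS}"
            )
        if self.replicate < 1:
            raise ValidationError(f"sample {self.sample_id!r}: replicate must be >= 1")

    @property
    def condition(self) -> str:
        return self.density + self.nitrogen


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2-scale expression values."""

    gene_ids: list[str]
    samples: list[SampleMeta]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValidationError(f"duplicate gene ids: {sorted(dup)}")
        dup = _duplicates([s.sample_id for s in self.samples])
        if dup:
            raise ValidationError(f"duplicate sample ids: {sorted(dup)}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.samples[bad[1]].sample_id!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, timepoint: int | None = None, condition: str | None = None) -> np.ndarray:
        """Column indices of samples matching the given timepoint/condition."""
        idx = []
        for j, s in enumerate(self.samples):
            if timepoint is not None and s.timepoint != int(timepoint):
                continue
            if condition is not None and s.condition != condition:
                continue
            idx.append(j)
        return np.asarray(idx, dtype=int)

    def timepoints(self) -> list[int]:
        return sorted({s.timepoint for s in self.samples})


@dataclass(frozen=True)
class ConditionProfile:
    """Per-gene 4-vector of log2 condition means at one timepoint.

    Means are ordered (LDSN, LDLN, HDSN, HDLN).
    """

    gene_id: str
    means: tuple[float, float, float, float]
    timepoint: int

    def __post_init__(self) -> None:
        if len(self.means) != len(CONDITIONS):
            raise ValidationError(f"profile for {self.gene_id!r} must have {len(CONDITIONS)} means")
        if not all(np.isfinite(self.means)):
            raise ValidationError(f"non-finite condition mean for gene {self.gene_id!r}")


@dataclass
class CtTable:
    """qPCR cycle-threshold table.

    One row per (gene, condition, replicate); ``reference_gene`` (default
    actin2) must be measured in every (condition, replicate) that has a target
    measurement.
    """

    data: pd.DataFrame  # columns: gene, condition, replicate, ct
    reference_gene: str = "actin2"

    REQUIRED = ("gene", "condition", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"Ct table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        if len(self.data) and (self.data["ct"] <= 0).any():
            bad = self.data.loc[self.data["ct"] <= 0].iloc[0]
            raise ValidationError(
                f"non-positive Ct for gene {bad['gene']!r}, condition {bad['condition']!r}"
            )
        unknown = set(self.data["condition"]) - set(CONDITIONS)
        if unknown:
            raise ValidationError(f"unknown condition labels in Ct table: {sorted(unknown)}")
        ref = self.data[self.data["gene"] == self.reference_gene]
        ref_keys = set(zip(ref["condition"], ref["replicate"]))
        targets = self.data[self.data["gene"] != self.reference_gene]
        for cond, rep in sorted(set(zip(targets["condition"], targets["replicate"]))):
            if (cond, rep) not in ref_keys:
                raise ValidationError(
                    f"reference gene {self.reference_gene!r} missing for "
                    f"condition {cond!r} replicate {rep}"
                )


@dataclass
class MetaboliteTable:
    """GC-MS component-area table with a ribitol internal-standard row.

    One row per (component_id, condition, replicate); ``snr`` is the per-
    component signal-to-noise ratio used by the quantifiability filter.
    """

    data: pd.DataFrame  # columns: component_id, condition, replicate, area, snr
    internal_standard: str = "ribitol"

    REQUIRED = ("component_id", "condition", "replicate", "area", "snr")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"metabolite table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        if len(self.data) and (self.data["area"] < 0).any():
            raise ValidationError("negative component area")
        std = self.data[self.data["component_id"] == self.internal_standard]
        samples = set(zip(self.data["condition"], self.data["replicate"]))
        std_ok = set(zip(std.loc[std["area"] > 0, "condition"], std.loc[std["area"] > 0, "replicate"]))
        for cond, rep in sorted(samples - std_ok):
            raise ValidationError(
                f"internal standard {self.internal_standard!r} absent or zero in "
                f"sample condition {cond!r} replicate {rep}"
            )


# ---------------------------------------------------------------------------
# readers / writers (tab-separated, UTF-8, header row)
# ---------------------------------------------------------------------------

def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_expression(path_values: str, path_meta: str) -> ExpressionMatrix:
    """Read an expression matrix and its sample-metadata table.

    The values file is tab-separated with a ``gene_id`` first column and one
    column per sample; the metadata file has one row per sample with columns
    sample_id, density, nitrogen, timepoint, replicate.  Sample order is taken
    from the metadata file.
    """
    meta = pd.read_csv(path_meta, sep="\t", dtype=str)
    required = ["sample_id", "density", "nitrogen", "timepoint", "replicate"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata file missing columns: {missing}")
    samples = [
        SampleMeta(
            sample_id=row.sample_id,
            density=row.density,
            nitrogen=row.nitrogen,
            timepoint=int(row.timepoint),
            replicate=int(row.replicate),
        )
        for row in meta.itertuples()
    ]

    vals = pd.read_csv(path_values, sep="\t", dtype={0: str})
    gene_col = vals.columns[0]
    gene_ids = vals[gene_col].tolist()
    absent = [s.sample_id for s in samples if s.sample_id not in vals.columns]
    if absent:
        raise ValidationError(f"samples in metadata but absent from values file: {absent}")
    matrix = np.empty((len(gene_ids), len(samples)), dtype=float)
    for j, s in enumerate(samples):
        col = pd.to_numeric(vals[s.sample_id], errors="coerce")
        if col.isna().any():
            i = int(col.isna().idxmax())
            raise ValidationError(
                f"non-numeric or missing value for gene {gene_ids[i]!r} in sample {s.sample_id!r}"
            )
        matrix[:, j] = col.to_numpy()
    return ExpressionMatrix(gene_ids=gene_ids, samples=samples, values=matrix)


def write_expression(m: ExpressionMatrix, path_values: str, path_meta: str) -> None:
    """Write an ExpressionMatrix back to the two-file TSV dialect."""
    vals = pd.DataFrame(m.values, columns=[s.sample_id for s in m.samples])
    vals.insert(0, "gene_id", m.gene_ids)
    vals.to_csv(path_values, sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in m.samples],
            "density": [s.density for s in m.samples],
            "nitrogen": [s.nitrogen for s in m.samples],
            "timepoint": [s.timepoint for s in m.samples],
            "replicate": [s.replicate for s in m.samples],
        }
    )
    meta.to_csv(path_meta, sep="\t", index=False)


def read_ct(path: str, reference_gene: str = "actin2") -> CtTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "condition": str})
    return CtTable(data=df, reference_gene=reference_gene)


def write_ct(tbl: CtTable, path: str) -> None:
    tbl.data.to_csv(path, sep="\t", index=False)


def read_metabolites(path: str, internal_standard: str = "ribitol") -> MetaboliteTable:
    df = pd.read_csv(path, sep="\t", dtype={"component_id": str, "condition": str})
    return MetaboliteTable(data=df, internal_standard=internal_standard)


def write_metabolites(tbl: MetaboliteTable, path: str) -> None:
    tbl.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# condition means
# ---------------------------------------------------------------------------

def condition_means(m: ExpressionMatrix, timepoint: int) -> list[ConditionProfile]:
    """Average log2 replicate values within each condition at one timepoint.

    Returns one profile per gene with means in the fixed order
    (LDSN, LDLN, HDSN, HDLN).
    """
    timepoint = int(timepoint)
    cols = {c: m.sample_index(timepoint=timepoint, condition=c) for c in CONDITIONS}
    for c, idx in cols.items():
        if idx.size == 0:
            raise ValidationError(f"no replicate of condition {c} at timepoint {timepoint}")
    means = np.column_stack([m.values[:, cols[c]].mean(axis=1) for c in CONDITIONS])
    return [
        ConditionProfile(gene_id=g, means=tuple(means[i]), timepoint=timepoint)
        for i, g in enumerate(m.gene_ids)
    ]


def profiles_to_matrix(profiles: Sequence[ConditionProfile]) -> tuple[list[str], np.ndarray]:
    """Stack ConditionProfiles into (gene_ids, n x 4 array)."""
    ids = [p.gene_id for p in profiles]
    arr = np.array([p.means for p in profiles], dtype=float).reshape(len(profiles), len(CONDITIONS))
    return ids, arr
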