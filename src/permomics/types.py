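"""Core containers shared across the pipeline.

A quantification matrix is a features x samples table of non-negative
abundances (raw scale) or log2 values, with NaN marking missing entries.
Zeros are data (a measured zero count or intensity), not missingness;
below-LOD metabolite values arrive as missing and are tracked separately
through a detection table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LAYERS = ("peptide", "protein", "gene", "metabolite", "lipid", "cell_gene")
SCALES = ("raw", "log2")

#: layer -> (pt_max, pf_max) defaults for the threshold rule
DEFAULT_PT_PF = {
    "peptide": (0.05, 0.10),
    "protein": (0.05, 0.10),
    "gene": (0.05, 0.10),
    "cell_gene": (0.10, 0.20),
    "metabolite": (0.05, 0.10),
    "lipid": (0.05, 0.10),
}
DEFAULT_PCOM_MAX = 0.05
#: layers whose Pt/Pf are combined into Pcom
COMBINE_LAYERS = ("metabolite", "lipid")


class FormatError(ValueError):
    """Malformed external file (ragged rows, bad header, bad GMT line)."""


class ValidationError(ValueError):
    """Well-formed input that violates a contract (duplicate ids, mismatched dims)."""


@dataclass
class QuantMatrix:
    """One omics layer: features x samples with optional missing values."""

    data: pd.DataFrame  # float values, index = feature ids, columns = sample ids
    layer: str
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        self.data = self.data.astype(float)
        if self.scale == "raw":
            vals = self.data.to_numpy()
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError("raw-scale values must be >= 0 where present")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def to_raw(self) -> np.ndarray:
        """Values on the raw scale (2**x when stored as log2)."""
        v = self.data.to_numpy()
        return np.power(2.0, v) if self.scale == "log2" else v

    def to_log2(self) -> np.ndarray:
        """Values on the log2 scale; non-positive raw values become NaN."""
        v = self.data.to_numpy()
        if self.scale == "log2":
            return v
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(v > 0, np.log2(np.where(v > 0, v, 1.0)), np.nan)
        return out


@dataclass
class GroupDesign:
    """Two-group design: every sample is either case or control."""

    case_ids: list[str]
    ctrl_ids: list[str]

    def __post_init__(self) -> None:
        if not self.case_ids or not self.ctrl_ids:
            raise ValidationError("both groups must be non-empty")
        overlap = set(self.case_ids) & set(self.ctrl_ids)
        if overlap:
            raise ValidationError(f"samples assigned to both groups: {sorted(overlap)}")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GroupDesign":
        """Build from a two-column table (sample_id, group in {case, control})."""
        bad = set(table["group"]) - {"case", "control"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        return cls(
            case_ids=table.loc[table["group"] == "case", "sample_id"].tolist(),
            ctrl_ids=table.loc[table["group"] == "control", "sample_id"].tolist(),
        )

    @property
    def sample_ids(self) -> list[str]:
        return self.case_ids + self.ctrl_ids

    def group_of(self, sample_id: str) -> str:
        if sample_id in self.case_ids:
            return "case"
        if sample_id in self.ctrl_ids:
            return "control"
        raise KeyError(sample_id)

    def indices(self, sample_order: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
        """Column positions of case and control samples in a matrix column order."""
        order = list(sample_order)
        missing = [s for s in self.sample_ids if s not in order]
        if missing:
            raise ValidationError(f"design samples absent from matrix: {missing}")
        case = np.array([order.index(s) for s in self.case_ids], dtype=int)
        ctrl = np.array([order.index(s) for s in self.ctrl_ids], dtype=int)
        return case, ctrl


@dataclass
class PeptideProteinMap:
    """peptide -> (protein, gene symbol); one protein per peptide."""

    table: pd.DataFrame  # columns: peptide_id, protein_id, gene_symbol

    def __post_init__(self) -> None:
        t = self.table
        required = {"peptide_id", "protein_id", "gene_symbol"}
        if not required.issubset(t.columns):
            raise ValidationError(f"map table needs columns {sorted(required)}")
        if t["peptide_id"].duplicated().any():
            dup = t.loc[t["peptide_id"].duplicated(), "peptide_id"].tolist()
            raise ValidationError(f"peptides mapped to multiple proteins: {dup}")
        genes_per_protein = t.groupby("protein_id")["gene_symbol"].nunique()
        bad = genes_per_protein[genes_per_protein > 1].index.tolist()
        if bad:
            raise ValidationError(f"inconsistent protein->gene mapping for: {bad}")

    def protein_of(self, peptide_id: str) -> str:
        row = self.table.loc[self.table["peptide_id"] == peptide_id]
        if row.empty:
            raise ValidationError(f"unmapped peptide: {peptide_id}")
        return row["protein_id"].iloc[0]

    def as_dict(self) -> dict[str, tuple[str, str]]:
        return {
            r.peptide_id: (r.protein_id, r.gene_symbol)
            for r in self.table.itertuples(index=False)
        }


@dataclass
class RunConfig:
    """Knobs for the permutation test and layer calling.

    Thresholds are per layer; the defaults are the canonical ones
    (peptide/gene Pt<=0.05 & Pf<=0.10, single-cell Pt<=0.10 & Pf<=0.20,
    metabolite/lipid Pcom<=0.05).
    """

    n_perm: int = 1000
    seed: int = 0
    pt_max: dict = field(default_factory=lambda: {k: v[0] for k, v in DEFAULT_PT_PF.items()})
    pf_max: dict = field(default_factory=lambda: {k: v[1] for k, v in DEFAULT_PT_PF.items()})
    pcom_max: float = DEFAULT_PCOM_MAX
    min_depeptides: int = 2
    clamp_eps: float = 1e-12
    null_mode: str = "pooled_ecdf"  # or "pooled_kde"
    log_transform: dict = field(
        default_factory=lambda: {k: True for k in LAYERS}
    )
    t_flavor: str = "welch"  # or "student"
    dependence_correction: bool = True
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.min_depeptides < 1:
            raise ValidationError("min_depeptides must be >= 1")
        for name, d in (("pt_max", self.pt_max), ("pf_max", self.pf_max)):
            for layer, p in d.items():
                if not (0 < p < 1):
                    raise ValidationError(f"{name}[{layer}] must be in (0,1)")
        if not (0 < self.pcom_max < 1):
            raise ValidationError("pcom_max must be in (0,1)")
        if self.null_mode not in ("pooled_ecdf", "pooled_kde"):
            raise ValidationError(f"unknown null_mode {self.null_mode!r}")
        if self.t_flavor not in ("welch", "student"):
            raise ValidationError(f"unknown t_flavor {self.t_flavor!r}")

    def thresholds_for(self, layer: str) -> tuple[float, float]:
        return self.pt_max[layer], self.pf_max[layer]
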