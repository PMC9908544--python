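"""Readers and writers for the external formats.

Matrices, designs, maps and result tables are TSV; cell x gene counts are
Matrix Market triplets with line-aligned gene/cell label files; gene sets
are GMT. Missing values are written as "NA" and read from "NA" or an empty
cell. Floats are written with 6 significant digits so identical runs give
byte-identical tables.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .types import (
    FormatError,
    GroupDesign,
    PeptideProteinMap,
    QuantMatrix,
    RunConfig,
    ValidationError,
)

log = logging.getLogger("permomics")

_MISSING = {"", "NA", "NaN", "nan"}


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def read_quant_matrix(path, layer: str, scale: str = "raw",
                      uppercase_ids: bool | None = None) -> QuantMatrix:
    """Read a feature x sample TSV (first column = feature id, header = sample ids).

    Gene-layer feature ids are uppercased by default so mouse and human
    symbols ("Vamp2" vs "VAMP2") meet on one key downstream.
    """
    path = Path(path)
    if uppercase_ids is None:
        uppercase_ids = layer == "gene"
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if len(header) < 2:
            raise FormatError(f"{path}: header must name at least one sample column")
        sample_ids = header[1:]
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            fid = row[0].upper() if uppercase_ids else row[0]
            feature_ids.append(fid)
            vals = []
            for cell in row[1:]:
                cell = cell.strip()
                if cell in _MISSING:
                    vals.append(np.nan)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise FormatError(
                            f"{path}:{lineno}: non-numeric value {cell!r}"
                        ) from None
            rows.append(vals)
    seen: set[str] = set()
    for fid in feature_ids:
        if fid in seen:
            raise ValidationError(f"{path}: duplicate feature id {fid!r}")
        seen.add(fid)
    data = pd.DataFrame(rows, index=feature_ids, columns=sample_ids, dtype=float)
    return QuantMatrix(data=data, layer=layer, scale=scale)


def write_quant_matrix(matrix: QuantMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["feature_id", *matrix.sample_ids])
        for fid, row in zip(matrix.feature_ids, matrix.values):
            w.writerow([fid, *[_fmt(v) for v in row]])


def read_design(path) -> GroupDesign:
    t = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(t.columns):
        raise FormatError(f"{path}: design needs columns sample_id, group")
    return GroupDesign.from_table(t)


def write_design(design: GroupDesign, path) -> None:
    rows = [(s, "case") for s in design.case_ids] + [(s, "control") for s in design.ctrl_ids]
    pd.DataFrame(rows, columns=["sample_id", "group"]).to_csv(path, sep="\t", index=False)


def read_peptide_map(path) -> PeptideProteinMap:
    t = pd.read_csv(path, sep="\t", dtype=str)
    return PeptideProteinMap(table=t)


def write_peptide_map(pmap: PeptideProteinMap, path) -> None:
    pmap.table.to_csv(path, sep="\t", index=False)


def read_cell_matrix(mtx_path, genes_path, cells_path, labels_path) -> ad.AnnData:
    """Read an MTX bundle into an AnnData (cells x genes).

    The MTX stores cells as rows and genes as columns; the gene and cell
    files are one id per line, aligned with the matrix dimensions; the
    labels TSV (header: cell_id, cluster, condition) is aligned with the
    cell file. All-zero genes are retained.
    """
    m = scipy.io.mmread(mtx_path)
    m = sp.csr_matrix(m)
    genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    cells = [ln.strip() for ln in Path(cells_path).read_text().splitlines() if ln.strip()]
    if m.shape[0] != len(cells):
        raise ValidationError(
            f"matrix has {m.shape[0]} cell rows but cell file lists {len(cells)}"
        )
    if m.shape[1] != len(genes):
        raise ValidationError(
            f"matrix has {m.shape[1]} gene columns but gene file lists {len(genes)}"
        )
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if not {"cell_id", "cluster", "condition"}.issubset(labels.columns):
        raise FormatError(f"{labels_path}: needs columns cell_id, cluster, condition")
    if len(labels) != len(cells):
        raise ValidationError(
            f"labels file has {len(labels)} rows for {len(cells)} cells"
        )
    if list(labels["cell_id"]) != cells:
        raise ValidationError("labels file cell_id order does not match cell file")
    bad = set(labels["condition"]) - {"case", "control"}
    if bad:
        raise ValidationError(f"unknown condition labels: {sorted(bad)}")
    adata = ad.AnnData(
        X=m,
        obs=pd.DataFrame(
            {"cluster": labels["cluster"].values, "condition": labels["condition"].values},
            index=cells,
        ),
        var=pd.DataFrame(index=genes),
    )
    return adata


def write_cell_matrix(adata: ad.AnnData, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X)
    scipy.io.mmwrite(out / "matrix.mtx", X, field="integer" if np.issubdtype(X.dtype, np.integer) else "real")
    (out / "genes.txt").write_text("\n".join(adata.var_names) + "\n")
    (out / "cells.txt").write_text("\n".join(adata.obs_names) + "\n")
    pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "cluster": adata.obs["cluster"].values,
            "condition": adata.obs["condition"].values,
        }
    ).to_csv(out / "labels.tsv", sep="\t", index=False)


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> member ids. Ids uppercased."""
    sets: dict[str, set[str]] = {}
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        log.warning("gene-set file %s is empty", path)
        return sets
    for lineno, ln in enumerate(lines, start=1):
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
        name = fields[0]
        members = {m.strip().upper() for m in fields[2:] if m.strip()}
        sets[name] = members
    return sets


def write_gene_sets(sets: dict[str, set[str]], path, descriptions=None) -> None:
    with Path(path).open("w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(sets[name])]) + "\n")


def read_id_list(path) -> list[str]:
    """One id per line, case-normalized to uppercase."""
    return [
        ln.strip().upper()
        for ln in Path(path).read_text().splitlines()
        if ln.strip()
    ]


def read_level_map(path) -> pd.DataFrame:
    """set_name, level, parent_category TSV used by the level-proportion summary."""
    t = pd.read_csv(path, sep="\t", dtype={"set_name": str, "parent_category": str})
    if not {"set_name", "level"}.issubset(t.columns):
        raise FormatError(f"{path}: level map needs columns set_name, level")
    t["level"] = t["level"].astype(int)
    if (t["level"] < 1).any():
        raise ValidationError("levels must be >= 1")
    return t


def read_config(path) -> RunConfig:
    """Flat key-value config; nested thresholds use dotted keys (pt_max.peptide)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    for key, val in raw.items():
        if "." in key:
            field_name, layer = key.split(".", 1)
            d = getattr(cfg, field_name)
            if not isinstance(d, dict):
                raise ValidationError(f"config key {key!r} does not address a per-layer field")
            d[layer] = val
        else:
            if not hasattr(cfg, key):
                raise ValidationError(f"unknown config key {key!r}")
            setattr(cfg, key, val)
    cfg.__post_init__()
    return cfg


def write_result_table(df: pd.DataFrame, path, float_cols=None) -> None:
    """TSV with fixed column order and 6-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    cols = float_cols if float_cols is not None else [
        c for c in out.columns if pd.api.types.is_float_dtype(out[c])
    ]
    for c in cols:
        out[c] = out[c].map(_fmt)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
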