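"""Layer-specific significance rules.

Feature calls are long-format tables with columns
(feature_id, layer, significant, direction, rule, support):

* peptides / bulk genes — Pt and Pf both under their layer thresholds
  (boundaries inclusive);
* proteins — a roll-up of peptide calls: a protein is differential when it
  has at least ``min_depeptides`` differential peptides all sharing one
  direction; mixed-direction proteins are excluded outright;
* metabolites / lipids — Pcom under threshold, or detection in only one of
  the two groups (the unique-to-group rule for below-LOD censoring);
* single-cell genes — the same dual test run within each cell-type cluster
  with cells as replicate units, at looser thresholds.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd

from .permtest import dual_stat_test
from .types import GroupDesign, PeptideProteinMap, QuantMatrix, RunConfig, ValidationError

log = logging.getLogger("permomics")

CALL_COLUMNS = ["feature_id", "layer", "significant", "direction", "rule", "support"]


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(columns=CALL_COLUMNS)


def quantified_filter(matrix: QuantMatrix) -> list[str]:
    """Features quantified in at least one sample, input order preserved."""
    obs = ~np.isnan(matrix.values)
    keep = obs.any(axis=1)
    if not keep.any():
        log.warning("no feature has any observed value")
    return [fid for fid, k in zip(matrix.feature_ids, keep) if k]


def detection_table(matrix: QuantMatrix) -> pd.DataFrame:
    """Boolean detected flags: False wherever the value is missing."""
    return pd.DataFrame(
        ~np.isnan(matrix.values), index=matrix.feature_ids, columns=matrix.sample_ids
    )


def call_threshold(
    results: pd.DataFrame, pt_max: float, pf_max: float, layer: str
) -> pd.DataFrame:
    """Dual-threshold rule: significant iff Pt <= pt_max and Pf <= pf_max."""
    sig = (results["Pt"] <= pt_max) & (results["Pf"] <= pf_max)
    sig = sig.fillna(False) & (results["direction"] != "none")
    out = pd.DataFrame(
        {
            "feature_id": results["feature_id"],
            "layer": layer,
            "significant": sig.to_numpy(),
            "direction": np.where(sig, results["direction"], "none"),
            "rule": np.where(sig, "threshold", ""),
            "support": "",
        }
    )
    return out


def rollup_proteins(
    depeptide_calls: pd.DataFrame,
    pep_map: PeptideProteinMap,
    min_depeptides: int = 2,
) -> pd.DataFrame:
    """Summarize differential peptides into protein calls.

    A protein is called when it has >= ``min_depeptides`` differential
    peptides and they all share one direction; proteins whose differential
    peptides go both up and down are excluded. ``support`` lists the
    contributing peptide ids.
    """
    sig = depeptide_calls.loc[depeptide_calls["significant"].astype(bool)]
    mapping = pep_map.as_dict()
    unmapped = [p for p in sig["feature_id"] if p not in mapping]
    if unmapped:
        raise ValidationError(f"differential peptides missing from map: {unmapped}")
    rows = []
    by_protein: dict[str, list[tuple[str, str]]] = {}
    for pep, direction in zip(sig["feature_id"], sig["direction"]):
        prot = mapping[pep][0]
        by_protein.setdefault(prot, []).append((pep, direction))
    for prot in sorted(by_protein):
        peps = by_protein[prot]
        dirs = {d for _, d in peps}
        if len(peps) >= min_depeptides and len(dirs) == 1:
            rows.append(
                {
                    "feature_id": prot,
                    "layer": "protein",
                    "significant": True,
                    "direction": next(iter(dirs)),
                    "rule": "rollup",
                    "support": ",".join(sorted(p for p, _ in peps)),
                }
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS) if rows else _empty_calls()


def call_dems(
    results: pd.DataFrame,
    detection: pd.DataFrame,
    design: GroupDesign,
    pcom_max: float = 0.05,
    layer: str = "metabolite",
    min_detect: int = 1,
) -> pd.DataFrame:
    """Metabolite/lipid rule: Pcom <= pcom_max OR detected in only one group.

    The unique-to-group branch requires >= ``min_detect`` detected samples in
    the focal group and zero in the other; its direction is up for case-only
    features, down for control-only. When both branches apply the rule field
    records "threshold".
    """
    missing = set(results["feature_id"]) - set(detection.index)
    if missing:
        raise ValidationError(f"detection table does not cover: {sorted(missing)}")
    det = detection.loc[results["feature_id"]]
    n_case = det[design.case_ids].sum(axis=1).to_numpy()
    n_ctrl = det[design.ctrl_ids].sum(axis=1).to_numpy()
    unique_up = (n_case >= min_detect) & (n_ctrl == 0)
    unique_down = (n_ctrl >= min_detect) & (n_case == 0)
    thresh = (results["Pcom"] <= pcom_max).fillna(False).to_numpy() & (
        results["direction"] != "none"
    ).to_numpy()

    sig = thresh | unique_up | unique_down
    rule = np.where(thresh, "threshold", np.where(unique_up | unique_down, "unique_to_group", ""))
    direction = np.where(
        thresh,
        results["direction"],
        np.where(unique_up, "up", np.where(unique_down, "down", "none")),
    )
    return pd.DataFrame(
        {
            "feature_id": results["feature_id"],
            "layer": layer,
            "significant": sig,
            "direction": direction,
            "rule": rule,
            "support": "",
        }
    )


# ---------------------------------------------------------------------------
# single cell


def call_cluster_degs(
    adata: ad.AnnData,
    config: RunConfig | None = None,
    clusters: list[str] | None = None,
    aggregate_by: str | None = None,
) -> pd.DataFrame:
    """Cell-type-cluster-wise differential expression.

    Within each cluster, cells are the replicate units: the dual permutation
    test compares case vs control cells gene by gene (values log2(x+1) for
    the t statistic, raw counts for the median ratio; relabelings capped at
    ``config.n_perm``). Calls use the single-cell thresholds (default
    Pt <= 0.10 and Pf <= 0.20). Clusters with fewer than two cells in either
    condition are skipped with a warning. With ``aggregate_by`` set to an
    ``obs`` column, cells are mean-pooled per that unit first (pseudobulk).

    Returns a long table with a ``cluster`` column plus the call columns.
    """
    config = config or RunConfig()
    all_clusters = list(pd.unique(adata.obs["cluster"]))
    if clusters is None:
        clusters = all_clusters
    unknown = set(clusters) - set(all_clusters)
    if unknown:
        raise ValidationError(f"unknown cluster labels: {sorted(unknown)}")
    pt_max, pf_max = config.thresholds_for("cell_gene")
    frames = []
    for cl in clusters:
        sub = adata[adata.obs["cluster"] == cl]
        X = sub.X
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
        obs = sub.obs
        if aggregate_by is not None:
            units = obs.groupby([aggregate_by, "condition"], observed=True).indices
            cols, names, conds = [], [], []
            for (unit, cond), idx in units.items():
                cols.append(X[idx].mean(axis=0))
                names.append(f"{unit}")
                conds.append(cond)
            X = np.column_stack(cols)
            sample_ids, conditions = names, conds
        else:
            X = X.T  # genes x cells
            sample_ids = list(sub.obs_names)
            conditions = list(obs["condition"])
        case = [s for s, c in zip(sample_ids, conditions) if c == "case"]
        ctrl = [s for s, c in zip(sample_ids, conditions) if c == "control"]
        if len(case) < 2 or len(ctrl) < 2:
            log.warning("cluster %s skipped: <2 cells per condition", cl)
            continue
        qm = QuantMatrix(
            data=pd.DataFrame(X, index=list(adata.var_names), columns=sample_ids),
            layer="cell_gene",
            scale="raw",
        )
        design = GroupDesign(case_ids=case, ctrl_ids=ctrl)
        res = dual_stat_test(qm, design, config, combine=False)
        calls = call_threshold(res, pt_max, pf_max, layer="cell_gene")
        calls.insert(0, "cluster", cl)
        frames.append(calls)
    if not frames:
        return pd.DataFrame(columns=["cluster", *CALL_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def dotplot_stats(adata: ad.AnnData, gene_ids: list[str]) -> pd.DataFrame:
    """Per (cluster, gene): fraction of cells expressing (> 0) and mean expression.

    The mean includes non-expressing cells. Empty clusters report zeros with
    ``empty_cluster`` set.
    """
    missing = [g for g in gene_ids if g not in set(adata.var_names)]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing}")
    rows = []
    clusters = list(pd.unique(adata.obs["cluster"]))
    for cl in clusters:
        sub = adata[adata.obs["cluster"] == cl, gene_ids]
        X = sub.X
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
        n_cells = X.shape[0]
        for j, g in enumerate(gene_ids):
            if n_cells == 0:
                rows.append(
                    {"cluster": cl, "gene": g, "prop_expressing": 0.0,
                     "mean_expr": 0.0, "empty_cluster": True}
                )
            else:
                col = X[:, j]
                rows.append(
                    {
                        "cluster": cl,
                        "gene": g,
                        "prop_expressing": float((col > 0).mean()),
                        "mean_expr": float(col.mean()),
                        "empty_cluster": False,
                    }
                )
    return pd.DataFrame(rows)
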