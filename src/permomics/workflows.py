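"""End-to-end convenience workflows chaining simulate -> test -> call ->
rollup -> concord, with recovery metrics against the planted truth."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import calling, concordance, permtest, synthetic
from .types import RunConfig


def _recall_fdp(called: set[str], truth_positive: set[str]) -> tuple[float, float]:
    tp = len(called & truth_positive)
    recall = tp / len(truth_positive) if truth_positive else float("nan")
    fdp = (len(called) - tp) / len(called) if called else 0.0
    return recall, fdp


def proteome_concordance_recovery(spec: synthetic.SynthSpec, n_perm: int = 300) -> dict:
    """Simulate a mouse peptide layer and a paired human gene layer, run the
    full differential pipeline on both, and score recovery of the planted
    peptide effects and of the planted cross-layer concordant features."""
    cfg = RunConfig(n_perm=n_perm, seed=spec.seed)

    pep, pmap, truth = synthetic.gen_proteome(spec)
    design = synthetic.default_design(spec)
    res = permtest.dual_stat_test(pep, design, cfg)
    pt_max, pf_max = cfg.thresholds_for("peptide")
    pep_calls = calling.call_threshold(res, pt_max, pf_max, "peptide")

    pep_truth = truth.loc[truth["layer"] == "peptide"]
    truth_pos = set(pep_truth.loc[pep_truth["is_de"], "feature_id"])
    called = set(pep_calls.loc[pep_calls["significant"], "feature_id"])
    pep_recall, pep_fdp = _recall_fdp(called, truth_pos)

    prot_calls = calling.rollup_proteins(pep_calls, pmap, cfg.min_depeptides)
    sym = pmap.table.drop_duplicates("protein_id").set_index("protein_id")["gene_symbol"]
    prot_gene_calls = prot_calls.copy()
    prot_gene_calls["feature_id"] = prot_gene_calls["feature_id"].map(sym)

    human, human_truth = synthetic.gen_paired_human_layer(spec, truth)
    hres = permtest.dual_stat_test(human, synthetic.human_design(spec), cfg)
    hcalls = calling.call_threshold(hres, *cfg.thresholds_for("gene"), "gene")

    mouse_universe = sorted(set(sym))
    human_universe = list(human.feature_ids)
    matched = concordance.harmonize_genes(mouse_universe, human_universe)
    pivot = concordance.direction_pivot(
        prot_gene_calls, mouse_universe, hcalls, human_universe, matched
    )
    conc = concordance.concordant_features(pivot)

    prot_truth = truth.loc[truth["layer"] == "protein"].reset_index(drop=True)
    hum_truth = human_truth.reset_index(drop=True)
    same = (
        prot_truth["is_de"].to_numpy()
        & (prot_truth["planted_log2fc"].to_numpy() == hum_truth["planted_log2fc"].to_numpy())
        & (prot_truth["planted_log2fc"].to_numpy() != 0)
    )
    truth_conc = set(
        sym.loc[prot_truth.loc[same, "feature_id"]].str.upper()
    )
    called_conc = set(conc["feature_id"].str.upper())
    conc_recall, conc_fdp = _recall_fdp(called_conc, truth_conc)

    return {
        "depeptide_recall": pep_recall,
        "depeptide_fdp": pep_fdp,
        "n_depeptides_called": len(called),
        "n_deps": len(prot_calls),
        "concordant_recall": conc_recall,
        "concordant_fdp": conc_fdp,
        "n_concordant": len(called_conc),
        "n_matched": pivot.total,
    }


def average_recovery(
    base_spec: synthetic.SynthSpec, seeds: list[int], n_perm: int = 300
) -> dict:
    """Recovery metrics averaged over replicate simulations."""
    runs = [
        proteome_concordance_recovery(dataclasses.replace(base_spec, seed=s), n_perm)
        for s in seeds
    ]
    keys = ("depeptide_recall", "depeptide_fdp", "concordant_recall", "concordant_fdp")
    out = {k: float(np.mean([r[k] for r in runs])) for k in keys}
    out["n_seeds"] = len(seeds)
    return out


def constructed_dem_study():
    """A deterministic targeted-panel fixture exercising both DEM branches.

    Five metabolites carry an eight-fold case shift (driving Pcom under any
    sensible threshold), three are detected in only one group (two
    case-only, one control-only), and forty null metabolites have exactly
    equal case and control value multisets, so their observed statistics
    are identically zero. Returns (QuantMatrix, DetectionTable, design).
    """
    from .types import GroupDesign, QuantMatrix

    case_ids = [f"KO{i}" for i in range(1, 6)]
    ctrl_ids = [f"WT{i}" for i in range(1, 6)]
    base = np.array([10.0, 11.0, 12.0, 13.0, 9.0])
    rows, ids = [], []
    for i in range(5):  # strong fold changes
        ctrl = base * (1 + i / 7.0)
        rows.append(np.concatenate([8.0 * ctrl, ctrl]))
        ids.append(f"FOLD{i}")
    for i in range(2):  # case-only
        vals = np.concatenate([base * (2 + i), [np.nan] * 5])
        rows.append(vals)
        ids.append(f"CASEONLY{i}")
    rows.append(np.concatenate([[np.nan] * 5, base * 3.0]))  # control-only
    ids.append("CTRLONLY0")
    for i in range(40):  # exact null: identical group multisets
        g = base * (1 + i / 11.0)
        rows.append(np.concatenate([g, g]))
        ids.append(f"NULL{i}")
    data = pd.DataFrame(rows, index=ids, columns=case_ids + ctrl_ids)
    qm = QuantMatrix(data=data, layer="metabolite", scale="raw")
    design = GroupDesign(case_ids=case_ids, ctrl_ids=ctrl_ids)
    return qm, calling.detection_table(qm), design
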