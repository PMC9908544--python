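"""Seeded generators for every input layer, with planted ground truth.

The generators emulate a small-n two-group neuro-multi-omics study: a
TMT-style peptide matrix rolled out from protein-level effects, a targeted
metabolite panel with below-LOD censoring that creates group-unique
features, a paired "human" expression layer whose planted effects agree in
direction with the "mouse" layer with a set probability, negative-binomial
single-cell counts with effects confined to designated cell clusters, and
gene-set collections with one set deliberately loaded with differential
features. Truth tables are first-class outputs so recovery is measured
against what was planted, never re-derived.

All randomness flows from ``SynthSpec.seed`` through one Generator per
generator call; identical specs give byte-identical outputs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd

from .types import GroupDesign, PeptideProteinMap, QuantMatrix

TRUTH_COLUMNS = ["feature_id", "layer", "is_de", "direction", "planted_log2fc", "mechanism"]


@dataclass
class SynthSpec:
    """Study-shaped simulation parameters.

    Defaults mirror the design the pipeline targets: five cases vs five
    controls, log-normal abundances with sigma = 0.25 on log2, a two-fold
    planted effect in 10% of features, 2-6 peptides per protein, and an 80%
    chance that a planted effect replicates with the same direction in the
    paired layer.
    """

    n_case: int = 5
    n_ctrl: int = 5
    n_features: int = 1000
    frac_de: float = 0.10
    effect_log2fc: float = 1.0
    noise_sigma: float = 0.25
    peptides_per_protein: tuple[int, int] = (2, 6)
    lod_quantile: float = 0.15
    n_group_unique: int = 3
    concordance_rho: float = 0.8
    n_clusters: int = 3
    cells_per_cluster: int = 100
    n_genes_sc: int = 150
    de_clusters: tuple[str, ...] = ("Ex",)
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "lod_quantile"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if not (0.0 <= self.concordance_rho <= 1.0):
            raise ValueError("concordance_rho must be in [0,1]")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        for name in ("n_case", "n_ctrl", "n_features", "n_clusters",
                     "cells_per_cluster", "n_genes_sc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def default_design(spec: SynthSpec) -> GroupDesign:
    return GroupDesign(
        case_ids=[f"KO{i+1}" for i in range(spec.n_case)],
        ctrl_ids=[f"WT{i+1}" for i in range(spec.n_ctrl)],
    )


def _plant_effects(n: int, frac_de: float, effect: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Choose round(frac_de * n) features and give each a signed log2 effect."""
    n_de = round(frac_de * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effects = np.zeros(n)
    effects[de_idx] = signs * effect
    return effects, np.sort(de_idx)


def _truth_frame(ids, layer, effects, mechanism=None) -> pd.DataFrame:
    is_de = effects != 0
    direction = np.where(effects > 0, "up", np.where(effects < 0, "down", "none"))
    t = pd.DataFrame(
        {
            "feature_id": ids,
            "layer": layer,
            "is_de": is_de,
            "direction": direction,
            "planted_log2fc": effects,
            "mechanism": np.where(is_de, "fold", "none"),
        }
    )
    if mechanism is not None:
        t["mechanism"] = mechanism
    return t


def gen_proteome(spec: SynthSpec):
    """Peptide-level raw intensity matrix with protein-level planted effects.

    Protein baselines are Normal(20, 2) on log2; each protein spawns a
    uniform number of peptides in ``peptides_per_protein``, every peptide
    inheriting the protein's effect plus its own baseline offset; per-cell
    noise is Normal(0, noise_sigma) on log2. Returns
    (peptide QuantMatrix, PeptideProteinMap, SynthTruth).
    """
    rng = np.random.default_rng(spec.seed)
    n_prot = spec.n_features
    n_samp = spec.n_case + spec.n_ctrl
    prot_ids = [f"PROT{i:05d}" for i in range(n_prot)]
    gene_ids = [f"GENE{i:05d}" for i in range(n_prot)]
    baselines = rng.normal(20.0, 2.0, size=n_prot)
    effects, _ = _plant_effects(n_prot, spec.frac_de, spec.effect_log2fc, rng)

    lo, hi = spec.peptides_per_protein
    n_peps = rng.integers(lo, hi + 1, size=n_prot)
    pep_rows, map_rows, pep_effects, pep_base = [], [], [], []
    for i, prot in enumerate(prot_ids):
        for j in range(n_peps[i]):
            pid = f"PEP{i:05d}_{j}"
            pep_rows.append(pid)
            map_rows.append((pid, prot, gene_ids[i]))
            pep_effects.append(effects[i])
            # peptides of one protein differ in ionization efficiency
            pep_base.append(baselines[i] + rng.normal(0.0, 1.0))
    pep_effects = np.asarray(pep_effects)
    pep_base = np.asarray(pep_base)

    design = default_design(spec)
    shift = np.zeros((len(pep_rows), n_samp))
    shift[:, : spec.n_case] = pep_effects[:, None]
    log2 = (
        pep_base[:, None]
        + shift
        + rng.normal(0.0, spec.noise_sigma, size=(len(pep_rows), n_samp))
    )
    data = pd.DataFrame(2.0 ** log2, index=pep_rows, columns=design.sample_ids)
    matrix = QuantMatrix(data=data, layer="peptide", scale="raw")
    pmap = PeptideProteinMap(
        table=pd.DataFrame(map_rows, columns=["peptide_id", "protein_id", "gene_symbol"])
    )
    truth = pd.concat(
        [
            _truth_frame(pep_rows, "peptide", pep_effects),
            _truth_frame(prot_ids, "protein", effects),
        ],
        ignore_index=True,
    )
    return matrix, pmap, truth


def gen_metabolome(spec: SynthSpec):
    """Targeted metabolite panel with LOD censoring and group-unique features.

    Concentrations are log-normal (log2 baseline Normal(3, 1.5), noise
    ``noise_sigma``); every value below its feature's ``lod_quantile``
    theoretical quantile is censored to missing. ``n_group_unique``
    additional features are forced all-censored in one group and observed
    in the other, exercising the unique-to-group rule. Returns
    (QuantMatrix, DetectionTable, SynthTruth).
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_features
    n_samp = spec.n_case + spec.n_ctrl
    ids = [f"MET{i:04d}" for i in range(n)]
    base = rng.normal(3.0, 1.5, size=n)
    effects, _ = _plant_effects(n, spec.frac_de, spec.effect_log2fc, rng)

    design = default_design(spec)
    shift = np.zeros((n, n_samp))
    shift[:, : spec.n_case] = effects[:, None]
    log2 = base[:, None] + shift + rng.normal(0.0, spec.noise_sigma, size=(n, n_samp))

    # censor below the per-feature LOD = quantile of the null generating law
    from scipy.stats import norm

    lod = base + spec.noise_sigma * norm.ppf(spec.lod_quantile) if spec.lod_quantile > 0 else None
    vals = 2.0 ** log2
    if lod is not None:
        vals[log2 < lod[:, None]] = np.nan

    mechanism = np.where(effects != 0, "fold", "none").astype(object)
    # force group-unique features among the non-DE ones
    non_de = np.flatnonzero(effects == 0)
    n_uni = min(spec.n_group_unique, non_de.size)
    uni_idx = rng.choice(non_de, size=n_uni, replace=False) if n_uni else np.array([], int)
    directions = np.where(effects > 0, "up", np.where(effects < 0, "down", "none")).astype(object)
    for k, i in enumerate(uni_idx):
        case_only = k % 2 == 0
        floor = 2.0 ** (base[i] + 1.0)  # safely above any LOD
        if case_only:
            vals[i, : spec.n_case] = np.where(
                np.isnan(vals[i, : spec.n_case]), floor, np.maximum(vals[i, : spec.n_case], floor)
            )
            vals[i, spec.n_case:] = np.nan
            directions[i] = "up"
        else:
            vals[i, spec.n_case:] = np.where(
                np.isnan(vals[i, spec.n_case:]), floor, np.maximum(vals[i, spec.n_case:], floor)
            )
            vals[i, : spec.n_case] = np.nan
            directions[i] = "down"
        mechanism[i] = "unique"

    data = pd.DataFrame(vals, index=ids, columns=design.sample_ids)
    matrix = QuantMatrix(data=data, layer="metabolite", scale="raw")
    detection = pd.DataFrame(~np.isnan(vals), index=ids, columns=design.sample_ids)
    truth = pd.DataFrame(
        {
            "feature_id": ids,
            "layer": "metabolite",
            "is_de": (effects != 0) | (mechanism == "unique"),
            "direction": directions,
            "planted_log2fc": effects,
            "mechanism": mechanism,
        }
    )
    return matrix, detection, truth


def gen_paired_human_layer(spec: SynthSpec, mouse_truth: pd.DataFrame):
    """A "human" expression layer paired to the mouse protein truth.

    For each mouse-differential protein, the human gene carries the
    same-direction effect with probability ``concordance_rho``, the opposite
    direction with (1 - rho)/2, and no effect with (1 - rho)/2. Identifiers
    are emitted in human-style uppercase to exercise symbol harmonization.
    Returns (QuantMatrix, SynthTruth).
    """
    rng = np.random.default_rng(spec.seed + 2)
    prot = mouse_truth.loc[mouse_truth["layer"] == "protein"].reset_index(drop=True)
    # human symbols: uppercase of the mouse gene-style id
    ids = [f"GENE{i:05d}".upper() for i in range(len(prot))]
    n = len(ids)
    n_samp = spec.n_case + spec.n_ctrl

    effects = np.zeros(n)
    for i, r in enumerate(prot.itertuples(index=False)):
        if not r.is_de:
            continue
        u = rng.random()
        if u < spec.concordance_rho:
            effects[i] = r.planted_log2fc
        elif u < spec.concordance_rho + (1 - spec.concordance_rho) / 2:
            effects[i] = -r.planted_log2fc
        # else: effect dies out in the human layer
    base = rng.normal(10.0, 2.0, size=n)
    shift = np.zeros((n, n_samp))
    shift[:, : spec.n_case] = effects[:, None]
    log2 = base[:, None] + shift + rng.normal(0.0, spec.noise_sigma, size=(n, n_samp))
    cols = [f"ASD{i+1}" for i in range(spec.n_case)] + [f"CTL{i+1}" for i in range(spec.n_ctrl)]
    data = pd.DataFrame(2.0 ** log2, index=ids, columns=cols)
    matrix = QuantMatrix(data=data, layer="gene", scale="raw")
    truth = _truth_frame(ids, "gene", effects)
    return matrix, truth


def human_design(spec: SynthSpec) -> GroupDesign:
    return GroupDesign(
        case_ids=[f"ASD{i+1}" for i in range(spec.n_case)],
        ctrl_ids=[f"CTL{i+1}" for i in range(spec.n_ctrl)],
    )


def gen_single_cell(spec: SynthSpec):
    """Negative-binomial cell x gene counts with cluster-confined effects.

    Clusters get distinct mean profiles; condition effects (2^effect fold on
    the mean in case cells) are planted only in ``de_clusters``; cell
    library sizes are log-normal. Returns (AnnData, SynthTruth) where the
    truth carries a ``cluster`` column for the differential genes.
    """
    rng = np.random.default_rng(spec.seed + 3)
    G = spec.n_genes_sc
    genes = [f"SCG{i:04d}" for i in range(G)]
    cluster_names = ["Ex", "In", "Prog", "Astro", "OPC"][: spec.n_clusters]
    if len(cluster_names) < spec.n_clusters:
        cluster_names += [f"C{i}" for i in range(len(cluster_names), spec.n_clusters)]
    unknown = set(spec.de_clusters) - set(cluster_names)
    if unknown:
        raise ValueError(f"de_clusters not among generated clusters: {sorted(unknown)}")

    base_mean = 2.0 ** rng.normal(2.0, 1.0, size=G)  # counts-scale means, ~4 median
    # cluster identity: a random subset of genes scaled up per cluster
    cluster_scale = np.ones((spec.n_clusters, G))
    for c in range(spec.n_clusters):
        marker = rng.choice(G, size=max(1, G // 10), replace=False)
        cluster_scale[c, marker] = 4.0

    effects, _ = _plant_effects(G, spec.frac_de, spec.effect_log2fc, rng)

    X = np.zeros((spec.n_clusters * spec.cells_per_cluster, G), dtype=np.int64)
    obs_rows = []
    r = spec.nb_dispersion
    row = 0
    for c, cname in enumerate(cluster_names):
        planted = cname in spec.de_clusters
        for j in range(spec.cells_per_cluster):
            cond = "case" if j < spec.cells_per_cluster // 2 else "control"
            lib = 2.0 ** rng.normal(0.0, 0.3)
            mu = base_mean * cluster_scale[c] * lib
            if planted and cond == "case":
                mu = mu * 2.0 ** effects
            p = r / (r + mu)
            X[row] = rng.negative_binomial(r, p)
            obs_rows.append((f"CELL{row:05d}", cname, cond))
            row += 1
    obs = pd.DataFrame(obs_rows, columns=["cell_id", "cluster", "condition"]).set_index("cell_id")
    var = pd.DataFrame({"base_mean": base_mean}, index=genes)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["cluster_scale"] = pd.DataFrame(cluster_scale, index=cluster_names, columns=genes)

    frames = []
    for cname in cluster_names:
        eff = effects if cname in spec.de_clusters else np.zeros(G)
        t = _truth_frame(genes, "cell_gene", eff)
        t.insert(0, "cluster", cname)
        frames.append(t)
    truth = pd.concat(frames, ignore_index=True)
    return adata, truth


def gen_gene_sets(
    spec: SynthSpec,
    universe: list[str],
    de_ids: list[str],
    n_sets: int = 10,
    set_size: int = 20,
    loaded_overlap: float = 0.7,
):
    """Random gene sets plus one deliberately loaded with differential ids.

    The loaded set draws ``loaded_overlap`` of its members from ``de_ids``
    (the rest from the remaining universe), so over-representation recovery
    is testable. Also emits a level map assigning sets to levels 1-2.
    Returns (sets dict, level_map DataFrame, loaded set name).
    """
    rng = np.random.default_rng(spec.seed + 4)
    uni = [u.upper() for u in universe]
    de = [d.upper() for d in de_ids]
    rest = sorted(set(uni) - set(de))
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        name = f"SET_{string.ascii_uppercase[i % 26]}{i}"
        sets[name] = set(rng.choice(uni, size=min(set_size, len(uni)), replace=False))
    n_de_members = min(round(loaded_overlap * set_size), len(de))
    loaded = set(rng.choice(de, size=n_de_members, replace=False))
    if set_size - n_de_members > 0 and rest:
        loaded |= set(rng.choice(rest, size=min(set_size - n_de_members, len(rest)), replace=False))
    loaded_name = "SET_LOADED"
    sets[loaded_name] = loaded
    level_map = pd.DataFrame(
        {
            "set_name": list(sets),
            "level": [1 if i < max(1, len(sets) // 2) else 2 for i in range(len(sets))],
            "parent_category": "root",
        }
    )
    return sets, level_map, loaded_name
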