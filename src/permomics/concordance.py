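"""Cross-dataset integration: identifier harmonization, direction pivots,
concordant-feature extraction and annotation flagging.

Two layers (e.g. a mouse cortex proteome and a public human cortex
transcriptome) are matched feature-by-feature — by case-normalized symbol,
by an explicit ortholog map, or by canonicalized lipid name — and their
differential calls are cross-tabulated into a 3x3 direction pivot over
{up, down, unchanged}. The concordant set ("same trend") is the union of
the (up, up) and (down, down) cells.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ValidationError

DIRECTIONS = ("up", "down", "unchanged")


def harmonize_genes(
    ids_a: list[str], ids_b: list[str], ortholog_map: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Match two identifier lists 1:1.

    Default: uppercase-symbol equality (mouse "Vamp2" meets human "VAMP2").
    With an ortholog map (columns id_a, id_b), map-defined pairs take
    precedence over symbol equality; many-to-many map rows are rejected.
    Returns a table (id_a, id_b, canonical_id); unmatched ids are simply
    absent.
    """
    up_a = {i.upper(): i for i in ids_a}
    up_b = {i.upper(): i for i in ids_b}
    if len(up_a) != len(ids_a) or len(up_b) != len(ids_b):
        raise ValidationError("identifier lists collide after case normalization")
    rows = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    if ortholog_map is not None:
        m = ortholog_map
        if m["id_a"].duplicated().any() or m["id_b"].duplicated().any():
            bad = pd.concat(
                [m.loc[m["id_a"].duplicated(keep=False), "id_a"],
                 m.loc[m["id_b"].duplicated(keep=False), "id_b"]]
            ).unique().tolist()
            raise ValidationError(f"ortholog map is not 1:1; offenders: {bad}")
        for r in m.itertuples(index=False):
            ua, ub = r.id_a.upper(), r.id_b.upper()
            if ua in up_a and ub in up_b:
                rows.append((up_a[ua], up_b[ub], ub))
                used_a.add(ua)
                used_b.add(ub)
    for ua in up_a:
        if ua in used_a:
            continue
        if ua in up_b and ua not in used_b:
            rows.append((up_a[ua], up_b[ua], ua))
            used_b.add(ua)
    out = pd.DataFrame(rows, columns=["id_a", "id_b", "canonical_id"])
    if out["canonical_id"].duplicated().any():
        raise ValidationError("canonical ids collide in matched table")
    return out


_LIPID_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)\((.*)\)$")


def canonicalize_lipid_name(name: str) -> str:
    """Collapse print variants of a lipid name to one canonical string.

    Whitespace is stripped and the class token uppercased, so "pc (38:0)"
    and "PC(38:0)" collapse; chain descriptors inside the parentheses are
    kept verbatim apart from normalizing the ether prefix, preserving
    sphingoid notation like "d18:1/". Names that do not look like
    CLASS(chains) pass through after whitespace/case normalization.
    """
    s = re.sub(r"\s+", "", name)
    m = _LIPID_RE.match(s)
    if not m:
        return s.upper()
    cls, chains = m.groups()
    chains = re.sub(r"(?<![A-Za-z0-9])o-", "O-", chains)
    return f"{cls.upper()}({chains})"


@dataclass
class ConcordancePivot:
    """3x3 direction cross-tabulation between two layers on matched features."""

    counts: pd.DataFrame  # index = layer-A direction, columns = layer-B direction
    cells: dict = field(default_factory=dict)  # (dir_a, dir_b) -> list of canonical ids
    matched: pd.DataFrame | None = None

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def _direction_lookup(calls: pd.DataFrame) -> dict[str, str]:
    sig = calls.loc[calls["significant"].astype(bool)]
    return {f.upper(): d for f, d in zip(sig["feature_id"], sig["direction"])}


def direction_pivot(
    calls_a: pd.DataFrame,
    universe_a: list[str],
    calls_b: pd.DataFrame,
    universe_b: list[str],
    matched: pd.DataFrame,
) -> ConcordancePivot:
    """Cross-tabulate matched features by their direction in each layer.

    Non-significant features count as "unchanged". Every matched feature
    must belong to both tested universes. Cell lists are disjoint and the
    grand total equals the number of matched features.
    """
    ua = {u.upper() for u in universe_a}
    ub = {u.upper() for u in universe_b}
    dir_a = _direction_lookup(calls_a)
    dir_b = _direction_lookup(calls_b)
    counts = pd.DataFrame(0, index=list(DIRECTIONS), columns=list(DIRECTIONS))
    cells: dict[tuple[str, str], list[str]] = {
        (a, b): [] for a in DIRECTIONS for b in DIRECTIONS
    }
    for r in matched.itertuples(index=False):
        ka, kb = r.id_a.upper(), r.id_b.upper()
        if ka not in ua:
            raise ValidationError(f"matched feature {r.id_a!r} absent from layer-A universe")
        if kb not in ub:
            raise ValidationError(f"matched feature {r.id_b!r} absent from layer-B universe")
        da = dir_a.get(ka, "unchanged")
        db = dir_b.get(kb, "unchanged")
        da = da if da in ("up", "down") else "unchanged"
        db = db if db in ("up", "down") else "unchanged"
        counts.loc[da, db] += 1
        cells[(da, db)].append(r.canonical_id)
    return ConcordancePivot(counts=counts, cells=cells, matched=matched)


def concordant_features(pivot: ConcordancePivot) -> pd.DataFrame:
    """Features significant in both layers with the same direction."""
    rows = [
        {"feature_id": f, "direction": d}
        for d in ("up", "down")
        for f in pivot.cells.get((d, d), [])
    ]
    return pd.DataFrame(rows, columns=["feature_id", "direction"])


def annotate(features: list[str], annotation_list: list[str], label: str) -> pd.DataFrame:
    """Flag features present in a curated list (case-normalized membership)."""
    members = {a.upper() for a in annotation_list}
    return pd.DataFrame(
        {"feature_id": features, label: [f.upper() in members for f in features]}
    )
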