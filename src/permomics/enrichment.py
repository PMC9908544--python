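"""Gene-set over-representation and category proportion summaries.

Over-representation is the one-sided hypergeometric upper tail: for a query
of n features drawn from a universe of M, a set with K members in the
universe and k of them in the query scores

    p = P(X >= k),  X ~ Hypergeom(M, K, n),

with Benjamini-Hochberg adjustment across the tested sets. Category
proportion summaries (pie-chart style) attribute a feature annotated to k
categories at a level 1/k to each, so proportions sum to one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ValidationError

log = logging.getLogger("permomics")


def hypergeom_enrich(
    query: set[str] | list[str],
    sets: dict[str, set[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH correction.

    Query ids outside the universe are dropped (logged); each set is
    intersected with the universe before testing. Results are sorted by p
    with ties broken by set name.
    """
    uni = {u.upper() for u in universe}
    if not uni:
        raise ValidationError("empty universe")
    q = {x.upper() for x in query}
    dropped = q - uni
    if dropped:
        log.info("dropped %d query ids outside the universe", len(dropped))
    q &= uni
    rows = []
    for name in sorted(sets):
        members = {m.upper() for m in sets[name]} & uni
        k = len(q & members)
        M, K, n = len(uni), len(members), len(q)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": M,
                "p": min(p, 1.0),
                "overlap_ids": ",".join(sorted(q & members)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["q"] = np.maximum(out["q"], out["p"])
        out = out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
        out = out[
            ["set_name", "overlap", "set_size", "query_size", "universe_size",
             "p", "q", "overlap_ids"]
        ]
    return out


def level_proportions(
    calls: pd.DataFrame,
    sets: dict[str, set[str]],
    level_map: pd.DataFrame,
    level: int,
) -> pd.DataFrame:
    """Relative proportion of called features per category at one level.

    A feature annotated to k categories at the level contributes 1/k to
    each (fractional attribution, so proportions sum to 1); set
    ``fractional=False`` behavior is available through ``full_counts``.
    """
    return _level_proportions(calls, sets, level_map, level, fractional=True)


def level_counts(
    calls: pd.DataFrame,
    sets: dict[str, set[str]],
    level_map: pd.DataFrame,
    level: int,
) -> pd.DataFrame:
    """Full-count variant: a feature counts once in every category it hits."""
    return _level_proportions(calls, sets, level_map, level, fractional=False)


def _level_proportions(calls, sets, level_map, level, fractional):
    at_level = level_map.loc[level_map["level"] == level, "set_name"].tolist()
    if not at_level:
        raise ValidationError(f"no categories at level {level}")
    sig = calls.loc[calls["significant"].astype(bool), "feature_id"]
    feats = [f.upper() for f in sig]
    cat_members = {c: {m.upper() for m in sets.get(c, set())} for c in at_level}
    weights: dict[str, float] = {c: 0.0 for c in at_level}
    n_attributed = 0
    for f in feats:
        hits = [c for c in at_level if f in cat_members[c]]
        if not hits:
            continue
        n_attributed += 1
        w = 1.0 / len(hits) if fractional else 1.0
        for c in hits:
            weights[c] += w
    if n_attributed == 0:
        log.warning("no called feature annotated at level %d", level)
        return pd.DataFrame(columns=["category", "weight", "proportion"])
    total = sum(weights.values())
    rows = [
        {"category": c, "weight": weights[c], "proportion": weights[c] / total}
        for c in at_level
        if weights[c] > 0
    ]
    return pd.DataFrame(rows).sort_values("proportion", ascending=False).reset_index(drop=True)
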