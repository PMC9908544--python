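"""Permutation-based dual-statistic differential expression.

Each feature gets two statistics from the same two-group comparison:

* ``t``   — Welch's two-sample t on log2 values (configurable to Student's),
* ``f``   — the log2 ratio of group medians on the raw scale.

Both are referred to a single empirical null obtained by relabeling the
samples: statistics from every feature and every relabeling are pooled,
because per-feature nulls at n = 5 vs 5 are far too small to resolve small
p-values. The observed labeling is excluded from the null. Two-tailed
empirical p-values Pt and Pf use the pseudocount estimator

    p = (1 + #{|null| >= |observed|}) / (1 + N),

which can never return 0. For layers measured on targeted panels
(metabolites, lipids) Pt and Pf are combined into a single Pcom with
Stouffer's z-score method. Because the two statistics are computed from the
same handful of samples they are positively dependent and the textbook
independent combination is anti-conservative; by default the observed
combined score z1 + z2 is therefore referred to its own permutation null —
the combined scores realized by the relabelings — so Pcom inherits the
calibration of Pt and Pf. The independence closed form
(1 - Phi((z1 + z2)/sqrt(2))) is available via
``RunConfig.dependence_correction = False`` and as ``stouffer_combine``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .types import COMBINE_LAYERS, GroupDesign, QuantMatrix, RunConfig, ValidationError

log = logging.getLogger("permomics")


# ---------------------------------------------------------------------------
# scalar statistics


def welch_t(case_values, ctrl_values) -> float:
    """Welch's t: mean difference (case - control) over the unpooled SE.

    Returns NaN (feature untestable) when either group has fewer than two
    non-missing values.
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(ctrl_values, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return float("nan")
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if se2 == 0.0:
        return 0.0 if a.mean() == b.mean() else math.copysign(math.inf, a.mean() - b.mean())
    return float((a.mean() - b.mean()) / math.sqrt(se2))


def student_t(case_values, ctrl_values) -> float:
    """Pooled-variance two-sample t (alternative flavor)."""
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(ctrl_values, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return float("nan")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    se2 = sp2 * (1 / a.size + 1 / b.size)
    if se2 == 0.0:
        return 0.0 if a.mean() == b.mean() else math.copysign(math.inf, a.mean() - b.mean())
    return float((a.mean() - b.mean()) / math.sqrt(se2))


def median_log_ratio(case_values, ctrl_values) -> float:
    """log2(median(case) / median(control)) on the raw scale.

    Even-length groups use the midpoint of the two central order statistics.
    Returns NaN (untestable; candidate for the unique-to-group rule) when a
    group has no observed value or a group median is zero.
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(ctrl_values, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return float("nan")
    ma, mb = float(np.median(a)), float(np.median(b))
    if mb == 0.0 or ma == 0.0:
        return float("nan")
    return math.log2(ma / mb)


# ---------------------------------------------------------------------------
# vectorized statistics over a features x samples array


def _row_t(values: np.ndarray, case_idx, ctrl_idx, flavor: str = "welch") -> np.ndarray:
    """Per-row two-sample t; NaN-aware; rows with <2 obs per group get NaN."""
    a = values[:, case_idx]
    b = values[:, ctrl_idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        na = np.sum(~np.isnan(a), axis=1)
        nb = np.sum(~np.isnan(b), axis=1)
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
        if flavor == "welch":
            se2 = va / na + vb / nb
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se2 = sp2 * (1 / na + 1 / nb)
        t = (ma - mb) / np.sqrt(se2)
        t = np.where((na >= 2) & (nb >= 2), t, np.nan)
        # zero spread in both groups: identical groups give t = 0
        zero_se = se2 == 0
        t = np.where(zero_se & (ma == mb), 0.0, t)
    return t


def _row_f(values_raw: np.ndarray, case_idx, ctrl_idx) -> np.ndarray:
    """Per-row log2 median ratio on the raw scale; NaN where undefined."""
    a = values_raw[:, case_idx]
    b = values_raw[:, ctrl_idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmedian(a, axis=1)
        mb = np.nanmedian(b, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.log2(ma / mb)
    f = np.where((ma > 0) & (mb > 0), f, np.nan)
    return f


# ---------------------------------------------------------------------------
# relabelings


def _all_relabelings(n: int, k: int):
    return combinations(range(n), k)


def sample_relabelings(
    n_samples: int, n_case: int, observed: tuple[int, ...], n_perm: int, seed: int
) -> tuple[list[tuple[int, ...]], bool]:
    """Distinct case/control relabelings, excluding the observed one.

    Enumerates exhaustively when the space fits within ``n_perm``; otherwise
    draws ``n_perm`` distinct relabelings uniformly without replacement.
    Returns (relabelings, exhaustive).
    """
    total = math.comb(n_samples, n_case)
    if total < 2:
        raise ValidationError("fewer than 2 distinct relabelings possible")
    observed = tuple(sorted(observed))
    if total - 1 <= n_perm:
        labs = [c for c in _all_relabelings(n_samples, n_case) if c != observed]
        return labs, True
    rng = np.random.default_rng(seed)
    if total <= 200_000:
        pool = [c for c in _all_relabelings(n_samples, n_case) if c != observed]
        pick = rng.choice(len(pool), size=n_perm, replace=False)
        return [pool[i] for i in sorted(pick)], False
    # space too large to enumerate: rejection-sample distinct subsets
    chosen: set[tuple[int, ...]] = set()
    labs: list[tuple[int, ...]] = []
    while len(labs) < n_perm:
        c = tuple(sorted(rng.choice(n_samples, size=n_case, replace=False).tolist()))
        if c == observed or c in chosen:
            continue
        chosen.add(c)
        labs.append(c)
    return labs, False


# ---------------------------------------------------------------------------
# null distribution and empirical p-values


@dataclass
class NullDistribution:
    """Pooled permutation null for one statistic."""

    statistic: str  # "t" or "f"
    values: np.ndarray  # pooled across features and relabelings
    n_perm_used: int
    exhaustive: bool

    def __post_init__(self) -> None:
        if self.values.size == 0:
            raise ValidationError("empty null distribution")
        self._abs_sorted = np.sort(np.abs(self.values))

    @property
    def degenerate(self) -> bool:
        return bool(np.all(self.values == 0))


def empirical_pvalue(observed: float, null: NullDistribution) -> float:
    """Two-tailed pseudocount p-value of one observation against the pooled null."""
    return float(empirical_pvalues(np.asarray([observed]), null)[0])


def empirical_pvalues(observed: np.ndarray, null: NullDistribution) -> np.ndarray:
    s = null._abs_sorted
    n = s.size
    ge = n - np.searchsorted(s, np.abs(observed), side="left")
    p = (1.0 + ge) / (1.0 + n)
    return np.where(np.isnan(observed), np.nan, p)


def kde_pvalues(observed: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Smoothed tail probability from a Gaussian KDE (Silverman bandwidth) on |null|."""
    absnull = np.abs(null.values)
    if np.all(absnull == absnull[0]):
        return empirical_pvalues(observed, null)
    kde = stats.gaussian_kde(absnull, bw_method="silverman")
    out = np.empty_like(observed, dtype=float)
    hi = float(absnull.max() + 10 * absnull.std())
    for i, o in enumerate(np.abs(observed)):
        if np.isnan(o):
            out[i] = np.nan
        else:
            out[i] = min(1.0, max(kde.integrate_box_1d(o, hi), 1.0 / (1 + absnull.size)))
    return out


def build_null(
    matrix: QuantMatrix,
    design: GroupDesign,
    statistic: str,
    n_perm: int,
    seed: int,
    t_flavor: str = "welch",
    log_transform: bool = True,
) -> NullDistribution:
    """Pooled permutation null for one statistic over all testable features."""
    if statistic not in ("t", "f"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    case_idx, ctrl_idx = design.indices(matrix.sample_ids)
    observed = tuple(sorted(case_idx.tolist()))
    labs, exhaustive = sample_relabelings(
        len(matrix.sample_ids), len(case_idx), observed, n_perm, seed
    )
    if statistic == "t":
        vals = matrix.to_log2() if log_transform else matrix.values
        testable = (
            np.sum(~np.isnan(vals[:, case_idx]), axis=1) >= 2
        ) & (np.sum(~np.isnan(vals[:, ctrl_idx]), axis=1) >= 2)
    else:
        vals = matrix.to_raw()
        testable = ~np.isnan(_row_f(vals, case_idx, ctrl_idx))
    all_idx = np.arange(len(matrix.sample_ids))
    pooled = []
    sub = vals[testable]
    for c in labs:
        ci = np.asarray(c)
        gi = np.setdiff1d(all_idx, ci, assume_unique=True)
        if statistic == "t":
            row = _row_t(sub, ci, gi, t_flavor)
        else:
            row = _row_f(sub, ci, gi)
        pooled.append(row[~np.isnan(row)])
    values = np.concatenate(pooled) if pooled else np.empty(0)
    return NullDistribution(
        statistic=statistic, values=values, n_perm_used=len(labs), exhaustive=exhaustive
    )


# ---------------------------------------------------------------------------
# Stouffer combination


def stouffer_combine(p1: float, p2: float, clamp_eps: float = 1e-12) -> float:
    """Combine two p-values with Stouffer's z-score method (independence form).

    z_k = Phi^-1(1 - p_k); Pcom = 1 - Phi((z1 + z2) / sqrt(2)). Inputs are
    clamped into [clamp_eps, 1 - clamp_eps] before inversion. Monotone
    non-decreasing in each argument.
    """
    p1 = min(max(p1, clamp_eps), 1.0 - clamp_eps)
    p2 = min(max(p2, clamp_eps), 1.0 - clamp_eps)
    z = stats.norm.isf(p1) + stats.norm.isf(p2)
    return float(stats.norm.sf(z / math.sqrt(2.0)))


def stouffer_combine_dependent(
    p1: np.ndarray, p2: np.ndarray, rho: float, clamp_eps: float = 1e-12
) -> np.ndarray:
    """Stouffer combination of two dependent p-values.

    The sum z1 + z2 of two standard-normal scores with correlation ``rho``
    has variance 2 + 2*rho, so the combined score is scaled accordingly;
    rho = 0 recovers the independence form.
    """
    p1 = np.clip(np.asarray(p1, dtype=float), clamp_eps, 1 - clamp_eps)
    p2 = np.clip(np.asarray(p2, dtype=float), clamp_eps, 1 - clamp_eps)
    z = stats.norm.isf(p1) + stats.norm.isf(p2)
    return stats.norm.sf(z / math.sqrt(2.0 + 2.0 * rho))


def null_z_correlation(
    null_t_pairs: np.ndarray,
    null_f_pairs: np.ndarray,
    null_t: NullDistribution,
    null_f: NullDistribution,
    clamp_eps: float = 1e-12,
) -> float:
    """Correlation of the two statistics' z-scores, estimated under the null.

    Both arrays hold the aligned (relabeling, feature) statistic pairs; each
    is converted to a two-tailed empirical p against its own pooled null and
    then to a normal score. The correlation of these scores is what inflates
    the naive Stouffer sum.
    """
    ok = ~np.isnan(null_t_pairs) & ~np.isnan(null_f_pairs)
    if ok.sum() < 100:
        return 0.0
    pt = empirical_pvalues(null_t_pairs[ok], null_t)
    pf = empirical_pvalues(null_f_pairs[ok], null_f)
    zt = stats.norm.isf(np.clip(pt, clamp_eps, 1 - clamp_eps))
    zf = stats.norm.isf(np.clip(pf, clamp_eps, 1 - clamp_eps))
    rho = float(np.corrcoef(zt, zf)[0, 1])
    if not np.isfinite(rho):
        return 0.0
    return float(np.clip(rho, 0.0, 0.95))


# ---------------------------------------------------------------------------
# the full dual test


def dual_stat_test(
    matrix: QuantMatrix,
    design: GroupDesign,
    config: RunConfig | None = None,
    combine: bool | None = None,
) -> pd.DataFrame:
    """Per-feature t and median-ratio statistics with permutation p-values.

    Returns one row per feature with columns feature_id, n_case_obs,
    n_ctrl_obs, t_stat, f_stat, Pt, Pf, Pcom, direction. Features failing a
    statistic's testability precondition carry NaN for that p-value and do
    not contribute to its pooled null. Pcom is filled when ``combine`` is
    true (default: layers measured on targeted panels). Diagnostics
    (exhaustive, n_perm_used, rho, degenerate flags) are attached in
    ``DataFrame.attrs``.
    """
    config = config or RunConfig()
    if combine is None:
        combine = matrix.layer in COMBINE_LAYERS
    case_idx, ctrl_idx = design.indices(matrix.sample_ids)
    n = len(matrix.sample_ids)
    observed = tuple(sorted(case_idx.tolist()))

    raw = matrix.to_raw()
    log_t = config.log_transform.get(matrix.layer, True)
    tvals = matrix.to_log2() if log_t else matrix.values

    obs_t = _row_t(tvals, case_idx, ctrl_idx, config.t_flavor)
    obs_f = _row_f(raw, case_idx, ctrl_idx)
    testable_t = ~np.isnan(obs_t)
    testable_f = ~np.isnan(obs_f)
    if not testable_t.any() and not testable_f.any():
        raise ValidationError("all features untestable for both statistics")

    labs, exhaustive = sample_relabelings(n, len(case_idx), observed, config.n_perm, config.seed)
    all_idx = np.arange(n)
    n_feat = matrix.n_features
    perm_t = np.empty((len(labs), n_feat))
    perm_f = np.empty((len(labs), n_feat))
    for j, c in enumerate(labs):
        ci = np.asarray(c)
        gi = np.setdiff1d(all_idx, ci, assume_unique=True)
        perm_t[j] = _row_t(tvals, ci, gi, config.t_flavor)
        perm_f[j] = _row_f(raw, ci, gi)

    pool_t = perm_t[:, testable_t].ravel()
    pool_t = pool_t[~np.isnan(pool_t)]
    pool_f = perm_f[:, testable_f].ravel()
    pool_f = pool_f[~np.isnan(pool_f)]

    pt = np.full(n_feat, np.nan)
    pf = np.full(n_feat, np.nan)
    null_t = null_f = None
    if pool_t.size:
        null_t = NullDistribution("t", pool_t, len(labs), exhaustive)
        est = kde_pvalues if config.null_mode == "pooled_kde" else empirical_pvalues
        pt[testable_t] = est(obs_t[testable_t], null_t)
    if pool_f.size:
        null_f = NullDistribution("f", pool_f, len(labs), exhaustive)
        est = kde_pvalues if config.null_mode == "pooled_kde" else empirical_pvalues
        pf[testable_f] = est(obs_f[testable_f], null_f)

    pcom = np.full(n_feat, np.nan)
    rho = 0.0
    if combine and null_t is not None and null_f is not None:
        ok = ~np.isnan(pt) & ~np.isnan(pf)
        if config.dependence_correction:
            # combined z referred to its own permutation null: the sum of
            # dependent z-scores is compared with the sums realized under
            # relabeling, so Pcom inherits the calibration of Pt and Pf
            both = testable_t & testable_f
            tp = perm_t[:, both].ravel()
            fp = perm_f[:, both].ravel()
            pair_ok = ~np.isnan(tp) & ~np.isnan(fp)
            zt_null = stats.norm.isf(
                np.clip(empirical_pvalues(tp[pair_ok], null_t), config.clamp_eps, 1 - config.clamp_eps)
            )
            zf_null = stats.norm.isf(
                np.clip(empirical_pvalues(fp[pair_ok], null_f), config.clamp_eps, 1 - config.clamp_eps)
            )
            rho = float(np.clip(np.corrcoef(zt_null, zf_null)[0, 1], 0.0, 0.95))
            zsum_null = np.sort(zt_null + zf_null)
            zsum_obs = stats.norm.isf(
                np.clip(pt[ok], config.clamp_eps, 1 - config.clamp_eps)
            ) + stats.norm.isf(np.clip(pf[ok], config.clamp_eps, 1 - config.clamp_eps))
            n_null = zsum_null.size
            ge = n_null - np.searchsorted(zsum_null, zsum_obs, side="left")
            pcom[ok] = (1.0 + ge) / (1.0 + n_null)
        else:
            pcom[ok] = stouffer_combine_dependent(pt[ok], pf[ok], 0.0, config.clamp_eps)

    direction = np.where(
        np.isnan(obs_f) | (obs_f == 0), "none", np.where(obs_f > 0, "up", "down")
    )
    out = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "n_case_obs": np.sum(~np.isnan(raw[:, case_idx]), axis=1).astype(int),
            "n_ctrl_obs": np.sum(~np.isnan(raw[:, ctrl_idx]), axis=1).astype(int),
            "t_stat": obs_t,
            "f_stat": obs_f,
            "Pt": pt,
            "Pf": pf,
            "Pcom": pcom,
            "direction": direction,
        }
    )
    if config.bh_correct:
        from statsmodels.stats.multitest import multipletests

        for col in ("Pt", "Pf", "Pcom"):
            mask = ~out[col].isna()
            if mask.any():
                out.loc[mask, col + "_bh"] = multipletests(
                    out.loc[mask, col], method="fdr_bh"
                )[1]
    out.attrs.update(
        {
            "layer": matrix.layer,
            "exhaustive": exhaustive,
            "n_perm_used": len(labs),
            "rho": rho,
            "degenerate_t": bool(null_t is not None and null_t.degenerate),
            "degenerate_f": bool(null_f is not None and null_f.degenerate),
        }
    )
    return out
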