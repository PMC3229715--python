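"""Two-group differential expression with permutation-based multiplicity
control.

Per assay, a pooled-variance two-sample t-test gives the nominal p-value.
Family-wise error is controlled by the Westfall-Young step-down min-P
procedure: group labels are permuted B times (or all distinct label
assignments are enumerated when that is cheaper), permutation p-values
are computed per assay, and the ordered observed p-values are compared
against successive minima of the permutation p-value vectors.  The
"overall P" is the single-step global min-P — the probability, under
label permutation, that the smallest p-value in the family is at least
as small as the one observed.  Empirical q-values are estimated from the
same permutation null.

Sign convention: lower Ct = higher expression, so a candidate with
negative mean Ct difference (group1 - group2) is reported "up" in
group 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .ct_io import CtMatrix, GroupDesign
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass
class DiffExpParams:
    """Permutation-test settings."""

    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    variance_mode: str = "pooled"  # or "welch"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.variance_mode not in ("pooled", "welch"):
            raise ConfigError("variance_mode must be 'pooled' or 'welch'")


@dataclass
class DiffExpResult:
    """Per-assay inference plus the family-level overall P."""

    table: pd.DataFrame  # indexed by assay_id
    overall_p: float
    n_perm: int
    exhaustive: bool
    perm_p_matrix: np.ndarray = field(repr=False, default=None)  # assays x permutations


def two_sample_t(
    values_g1: np.ndarray, values_g2: np.ndarray, variance_mode: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, p, df).

    Pooled-variance Student t by default, Welch optional.  With zero
    pooled variance the statistic is degenerate: equal means give
    (0, 1), unequal means give a signed infinite t with p = 0, flagged
    in the log.
    """
    x = np.asarray(values_g1, dtype=float)
    y = np.asarray(values_g2, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise DataError(f"need >= 2 values per group, got {n1} and {n2}")
    d = x.mean() - y.mean()
    if variance_mode == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        v1, v2 = x.var(ddof=1) / n1, y.var(ddof=1) / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)) if se > 0 else n1 + n2 - 2
    if se == 0:
        if d == 0:
            return 0.0, 1.0, float(df)
        logger.warning("zero pooled variance with unequal means; degenerate t")
        return math.copysign(math.inf, d), 0.0, float(df)
    t = d / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), float(df)


def _group_indices(
    matrix: CtMatrix, design: GroupDesign
) -> tuple[np.ndarray, np.ndarray]:
    design.check_covers(matrix.sample_ids)
    groups = [design.group_of(s) for s in matrix.sample_ids]
    present = set(groups)
    if len(present) != 2:
        raise DataError(f"exactly two groups required, found {sorted(present)}")
    # the mutation-carrier group is always group 1
    labels = ["PGRN+", "PGRN-"] if present == {"PGRN+", "PGRN-"} else sorted(present)
    g1 = np.array([i for i, g in enumerate(groups) if g == labels[0]])
    g2 = np.array([i for i, g in enumerate(groups) if g == labels[1]])
    return g1, g2


def _t_statistics(
    vals: np.ndarray, g1: np.ndarray, g2: np.ndarray, mode: str = "pooled"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample t statistics and df for one labelling."""
    x, y = vals[:, g1], vals[:, g2]
    n1, n2 = len(g1), len(g2)
    d = x.mean(axis=1) - y.mean(axis=1)
    if mode == "pooled":
        sp2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / (
            n1 + n2 - 2
        )
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = np.full(vals.shape[0], float(n1 + n2 - 2))
    else:
        v1, v2 = x.var(axis=1, ddof=1) / n1, y.var(axis=1, ddof=1) / n2
        se = np.sqrt(v1 + v2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        df[~np.isfinite(df)] = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d / se
    t[(se == 0) & (d == 0)] = 0.0
    t[(se == 0) & (d != 0)] = np.inf * np.sign(d[(se == 0) & (d != 0)])
    return t, df


def _analytic_p(abs_t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Two-sided p from the t distribution, column-broadcast over df."""
    return 2.0 * stats.t.sf(abs_t, df if np.ndim(df) == np.ndim(abs_t) else df[:, None])


def _permutation_assignments(
    n: int, n1: int, params: DiffExpParams
) -> tuple[np.ndarray, bool]:
    """Indices of group-1 members per permutation (rows), plus a flag
    marking exhaustive enumeration.

    Random mode draws ``n_perm`` label shuffles from a seeded generator;
    when ``n_perm`` meets or exceeds the number of distinct assignments
    C(n, n1), all of them are enumerated instead.
    """
    n_distinct = math.comb(n, n1)
    if params.n_perm >= n_distinct:
        logger.info(
            "n_perm=%d >= %d distinct assignments; enumerating exhaustively",
            params.n_perm,
            n_distinct,
        )
        return np.array(list(combinations(range(n), n1)), dtype=int), True
    rng = np.random.default_rng(params.seed)
    picks = np.empty((params.n_perm, n1), dtype=int)
    for b in range(params.n_perm):
        picks[b] = rng.permutation(n)[:n1]
    return picks, False


def westfall_young_minp(
    matrix: CtMatrix, design: GroupDesign, params: DiffExpParams | None = None
) -> DiffExpResult:
    """Step-down min-P adjusted p-values, overall P and empirical q-values.

    For each relabelling of the samples (B seeded shuffles, or every
    distinct assignment when that is cheaper) the full vector of
    per-assay t-test p-values is computed from the t distribution —
    the continuous within-assay standardization that makes min-P
    workable when B is modest relative to the number of assays.  Assays
    are ordered by nominal p ascending (ties broken by assay id) and
    adjusted via the step-down successive-minima construction: p-adj(i)
    is the share of relabellings whose minimum p over ranks i..m is at
    or below the observed p(i), monotonized to be non-decreasing.  The
    observed (identity) labelling is always part of the reference set —
    it is one of the enumerated assignments in exhaustive mode and is
    prepended to the shuffles otherwise — so no adjusted p can be 0 and
    observed and permuted quantities share one scale.  overall_p is the
    adjusted p of the top-ranked assay, i.e. the single-step global
    min-P test.
    """
    params = params or DiffExpParams()
    vals = matrix.data.to_numpy()
    assay_ids = np.array(matrix.assay_ids)
    nan_rows = np.isnan(vals).any(axis=1)
    if nan_rows.any():
        logger.warning(
            "dropping %d assay(s) with missing cells from permutation analysis",
            int(nan_rows.sum()),
        )
        vals = vals[~nan_rows]
        assay_ids = assay_ids[~nan_rows]
    if len(assay_ids) == 0:
        raise DataError("no complete assays available for differential expression")

    g1, g2 = _group_indices(matrix, design)
    n, n1 = len(g1) + len(g2), len(g1)
    mean1, mean2 = vals[:, g1].mean(axis=1), vals[:, g2].mean(axis=1)

    # Nominal (analytic) t-test per assay.
    t_obs = np.empty(len(assay_ids))
    p_raw = np.empty(len(assay_ids))
    for i in range(len(assay_ids)):
        t_obs[i], p_raw[i], _ = two_sample_t(
            vals[i, g1], vals[i, g2], params.variance_mode
        )

    picks, exhaustive = _permutation_assignments(n, n1, params)
    g1_sorted = np.sort(g1)
    if exhaustive:
        obs_col = next(
            b for b in range(picks.shape[0]) if np.array_equal(np.sort(picks[b]), g1_sorted)
        )
    else:
        picks = np.vstack([g1_sorted[None, :], picks])
        obs_col = 0
    n_cols = picks.shape[0]
    all_idx = np.arange(n)
    p_full = np.empty((len(assay_ids), n_cols))
    for b in range(n_cols):
        sel = picks[b]
        rest = np.setdiff1d(all_idx, sel)
        t_b, df_b = _t_statistics(vals, sel, rest, params.variance_mode)
        p_full[:, b] = _analytic_p(np.abs(t_b), df_b)

    # share of relabellings (identity included) at or below the observed p
    p_perm_obs = (p_full <= p_raw[:, None] + 1e-15).sum(axis=1) / n_cols

    # Step-down ordering: nominal p ascending, ties by assay id.
    order = np.lexsort((assay_ids, p_raw))
    p_cmp = p_raw[order]
    q = np.minimum.accumulate(p_full[order][::-1], axis=0)[::-1]  # successive minima
    counts = (q <= p_cmp[:, None] + 1e-15).sum(axis=1)
    p_adj_ordered = counts / n_cols
    p_adj_ordered = np.maximum.accumulate(p_adj_ordered)  # enforce monotonicity
    p_wy = np.empty(len(assay_ids))
    p_wy[order] = p_adj_ordered
    overall_p = float(p_adj_ordered[0])

    null_cols = np.delete(np.arange(n_cols), obs_col)
    p_perm_b = p_full[:, null_cols]
    q_emp = empirical_qvalues(p_raw, p_perm_b)

    diff = mean1 - mean2
    table = pd.DataFrame(
        {
            "mean_g1": mean1,
            "mean_g2": mean2,
            "diff": diff,
            "t": t_obs,
            "p_raw": p_raw,
            "p_perm": p_perm_obs,
            "p_wy": p_wy,
            "q_emp": q_emp,
            "direction": np.where(diff < 0, "up", np.where(diff > 0, "down", "none")),
        },
        index=pd.Index(assay_ids, name="assay_id"),
    )
    return DiffExpResult(
        table=table,
        overall_p=overall_p,
        n_perm=n_cols if exhaustive else n_cols - 1,
        exhaustive=exhaustive,
        perm_p_matrix=p_perm_b,
    )


def empirical_qvalues(
    raw_p_observed: np.ndarray, permutation_p_matrix: np.ndarray
) -> np.ndarray:
    """Empirical q-values from a permutation null p-value matrix.

    For each observed p_i the numerator is the mean, over permutations,
    of null p-values at or below p_i (the expected false-positive count
    with pi0 fixed at 1) and the denominator the observed count at or
    below p_i; the ratio is capped at 1 and monotonized by a cumulative
    minimum from the largest observed p downward.
    """
    p_obs = np.asarray(raw_p_observed, dtype=float)
    null_p = np.asarray(permutation_p_matrix, dtype=float)
    if null_p.size == 0:
        raise DataError("empty permutation p-value matrix")
    m = len(p_obs)
    null_flat = np.sort(null_p.ravel())
    B = null_p.shape[1]
    p_sorted = np.sort(p_obs)
    q = np.empty(m)
    order = np.argsort(p_obs, kind="stable")
    for i in order:
        pi = p_obs[i]
        expected_fp = np.searchsorted(null_flat, pi, side="right") / B
        observed = np.searchsorted(p_sorted, pi, side="right")
        q[i] = min(1.0, expected_fp / observed)
    # monotonize: largest p first, cumulative minimum downward
    q_ord = q[order]
    q_ord = np.minimum.accumulate(q_ord[::-1])[::-1]
    q[order] = q_ord
    return q


def rank_candidates(result: DiffExpResult, alpha: float = 0.05) -> pd.DataFrame:
    """Assays with nominal p < alpha, ordered by p, with direction labels.

    Direction is relative to group 1: "up" means higher expression in
    group 1, i.e. a lower mean Ct there.
    """
    tab = result.table.reset_index()
    cand = tab[tab["p_raw"] < alpha].sort_values(["p_raw", "assay_id"], kind="stable")
    return cand.set_index("assay_id")
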