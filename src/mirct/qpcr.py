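"""qRT-PCR validation statistics.

Duplicate wells are reconciled (mean if they agree within 2 cycles,
otherwise the well farther from the assay-wide median is dropped), Ct
values are referenced against the endogenous control (RNU48) to give
delta-Ct, and the negated delta-Ct — a log2 expression proxy under
perfect probe efficiency — is compared between groups with pooled
two-sample t-tests.  Group mean differences and their 95% confidence
intervals are exponentiated base 2 into fold changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ct_io import GroupDesign, QpcrWellTable
from .errors import ConfigError, DataError
from .diffexp import two_sample_t

logger = logging.getLogger(__name__)


@dataclass
class QpcrParams:
    """Validation-arm thresholds."""

    dup_diff_threshold: float = 2.0
    control_assay_id: str = "RNU48"
    ci_level: float = 0.95
    min_ct_detect: float = 35.0

    def __post_init__(self) -> None:
        if self.dup_diff_threshold <= 0:
            raise ConfigError("dup_diff_threshold must be > 0")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must lie in (0, 1)")


def reconcile_duplicates(
    wells: QpcrWellTable, params: QpcrParams | None = None
) -> pd.DataFrame:
    """Collapse duplicate wells to one Ct per assay x sample.

    If the two wells differ by more than the threshold (strictly more
    than 2 cycles by default), the well farther — in absolute distance —
    from the assay's center (median of all that assay's wells across all
    samples) is deleted and the other kept.  Otherwise the mean is used.
    A lone well is kept as-is; a fully missing pair yields a missing
    cell.

    Returns a DataFrame indexed by assay_id with sample ids as columns.
    """
    params = params or QpcrParams()
    df = wells.wells
    centers = df.groupby("assay_id")["ct"].median()
    assay_ids = sorted(df["assay_id"].unique())
    sample_ids = sorted(df["sample_id"].unique())
    out = pd.DataFrame(np.nan, index=assay_ids, columns=sample_ids)
    for (assay, sample), grp in df.groupby(["assay_id", "sample_id"]):
        cts = grp["ct"].dropna().to_numpy()
        if cts.size == 0:
            continue
        if cts.size == 1:
            out.loc[assay, sample] = cts[0]
            continue
        a, b = float(cts[0]), float(cts[1])
        if abs(a - b) > params.dup_diff_threshold:
            center = centers[assay]
            kept = a if abs(a - center) <= abs(b - center) else b
            out.loc[assay, sample] = kept
        else:
            out.loc[assay, sample] = (a + b) / 2.0
    out.index.name = "assay_id"
    return out


def delta_ct(
    reconciled: pd.DataFrame, params: QpcrParams | None = None
) -> pd.DataFrame:
    """Minus-delta-Ct table: control Ct minus target Ct, per sample.

    delta-Ct = Ct_target - Ct_control; the returned values are its
    negation, interpretable as log2 relative expression.  Samples whose
    control is missing are excluded for all assays (and logged); the
    control row itself is dropped from the output.
    """
    params = params or QpcrParams()
    if params.control_assay_id not in reconciled.index:
        raise DataError(f"control assay {params.control_assay_id!r} not in reconciled table")
    control = reconciled.loc[params.control_assay_id]
    usable = control.notna()
    if not usable.all():
        logger.warning(
            "control missing for sample(s) %s; excluded from all assays",
            list(control.index[~usable]),
        )
    targets = reconciled.drop(index=params.control_assay_id)
    minus_dct = -(targets.loc[:, usable] - control[usable])
    return minus_dct


@dataclass
class QpcrAssayResult:
    """Group comparison on the minus-delta-Ct scale for every assay."""

    table: pd.DataFrame  # assay_id x {n_g1, n_g2, diff_log2, fc, ci_lo, ci_hi, t, p}
    ci_level: float


def group_fold_change(
    minus_dcts: pd.DataFrame, design: GroupDesign, params: QpcrParams | None = None
) -> QpcrAssayResult:
    """Fold changes of group 1 (PGRN+) over group 2 with pooled-t CIs.

    d = mean(minus-dCt | group1) - mean(minus-dCt | group2); FC = 2^d and
    the CI is 2^(d +/- t_crit * SE) with the pooled standard error.  By
    construction log2(FC) equals d exactly.
    """
    params = params or QpcrParams()
    design.check_covers(minus_dcts.columns)
    g1 = [s for s in minus_dcts.columns if design.group_of(s) == "PGRN+"]
    g2 = [s for s in minus_dcts.columns if design.group_of(s) == "PGRN-"]
    rows = []
    for assay, row in minus_dcts.iterrows():
        x = row[g1].dropna().to_numpy(dtype=float)
        y = row[g2].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise DataError(f"assay {assay!r}: need >= 2 samples per group")
        d = x.mean() - y.mean()
        t, p, df = two_sample_t(x, y, "pooled")
        se = _pooled_se(x, y)
        if math.isinf(t):
            logger.warning("assay %r: degenerate (zero) variance", assay)
        tcrit = stats.t.ppf(1 - (1 - params.ci_level) / 2, df)
        lo, hi = d - tcrit * se, d + tcrit * se
        rows.append(
            {
                "assay_id": assay,
                "n_g1": len(x),
                "n_g2": len(y),
                "diff_log2": d,
                "fc": 2.0**d,
                "ci_lo": 2.0**lo,
                "ci_hi": 2.0**hi,
                "t": t,
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("assay_id")
    return QpcrAssayResult(table=table, ci_level=params.ci_level)


def _pooled_se(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    return math.sqrt(sp2 * (1 / n1 + 1 / n2))


def detectability_check(
    reconciled: pd.DataFrame, params: QpcrParams | None = None
) -> pd.Series:
    """Flag assays with insufficient detection.

    An assay is undetectable when its median reconciled Ct exceeds the
    detection limit (low abundance crosses the threshold late) or more
    than half its samples are missing.
    """
    params = params or QpcrParams()
    med = reconciled.median(axis=1, skipna=True)
    frac_missing = reconciled.isna().mean(axis=1)
    undetectable = (med > params.min_ct_detect) | (frac_missing > 0.5) | med.isna()
    flags = ~undetectable
    flags.name = "detectable"
    return flags


def validate_assays(
    wells: QpcrWellTable, design: GroupDesign, params: QpcrParams | None = None
) -> pd.DataFrame:
    """Full validation arm: reconcile, reference, test, flag.

    Returns one row per target assay with sample counts, fold change,
    CI bounds, p-value and the detectability flag.
    """
    params = params or QpcrParams(control_assay_id=wells.control_assay_id)
    reconciled = reconcile_duplicates(wells, params)
    flags = detectability_check(reconciled.drop(index=params.control_assay_id), params)
    minus_dcts = delta_ct(reconciled, params)
    result = group_fold_change(minus_dcts, design, params)
    out = result.table.join(flags)
    return out
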