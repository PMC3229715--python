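"""Array preprocessing: detection filter, lowess normalization, KNN
imputation, and robust shrinkage of extremes — applied in that order.

The detection filter drops assays where >= 20% of samples are missing or
above 35 Ct; surviving cells above 35 Ct are censored to missing and
later imputed.  Normalization removes per-sample intensity trends by
lowess-smoothing each sample's deviation from a median pseudo-reference
profile.  Imputation follows the K-nearest-neighbour scheme of the SAM
lineage: a missing cell is filled with the unweighted mean of the K
assays closest in Euclidean profile distance that are observed in that
sample.  Finally, per-assay extremes beyond +/- c robust z-units
(median +/- c * 1.4826 * MAD) are winsorized to the bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .ct_io import CtMatrix
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Minimum observed values a sample needs for a lowess fit.
MIN_OBS_FOR_LOWESS = 10


@dataclass
class PreprocessParams:
    """Tunable thresholds for the four preprocessing steps."""

    max_ct: float = 35.0
    max_missing_frac: float = 0.20
    knn_k: int = 10
    lowess_span: float = 2.0 / 3.0
    shrink_c: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.max_missing_frac <= 1:
            raise ConfigError("max_missing_frac must lie in (0, 1]")
        if self.knn_k < 1:
            raise ConfigError("knn_k must be >= 1")
        if not 0 < self.lowess_span <= 1:
            raise ConfigError("lowess_span must lie in (0, 1]")
        if self.shrink_c <= 0:
            raise ConfigError("shrink_c must be > 0")


def detection_filter(
    matrix: CtMatrix, params: PreprocessParams | None = None
) -> tuple[CtMatrix, list[str]]:
    """Drop minimally expressed assays; censor late-Ct cells to missing.

    An assay is excluded iff the fraction of samples with a missing Ct or
    Ct > ``max_ct`` is >= ``max_missing_frac`` ("20% or more", so the
    boundary excludes).  In retained assays, cells above ``max_ct`` are
    set to missing so imputation can replace them.

    Returns the filtered matrix and the excluded assay ids (input order).
    """
    params = params or PreprocessParams()
    if matrix.n_assays == 0 or matrix.n_samples == 0:
        raise DataError("cannot filter an empty matrix")
    vals = matrix.data.to_numpy()
    bad = np.isnan(vals) | (vals > params.max_ct)
    frac_bad = bad.mean(axis=1)
    keep = frac_bad < params.max_missing_frac
    excluded = [a for a, k in zip(matrix.assay_ids, keep) if not k]
    out = matrix.data.loc[keep].copy()
    censored = int((out.to_numpy() > params.max_ct).sum())
    out = out.mask(out > params.max_ct)
    if censored:
        logger.info(
            "detection filter: censored %d retained cell(s) with Ct > %.3g to missing",
            censored,
            params.max_ct,
        )
    logger.info(
        "detection filter: retained %d/%d assays", int(keep.sum()), matrix.n_assays
    )
    return matrix.advance(out, "filtered"), excluded


def reference_profile(matrix: CtMatrix) -> pd.Series:
    """Per-assay median across samples (the normalization pseudo-reference)."""
    return matrix.data.median(axis=1, skipna=True)


def lowess_normalize(
    matrix: CtMatrix, params: PreprocessParams | None = None
) -> CtMatrix:
    """Remove each sample's smooth intensity trend against the reference.

    For every sample, fit a lowess curve of (sample Ct - reference Ct)
    against reference Ct over the non-missing pairs and subtract the
    fitted deviation from the sample's values.  Missing cells remain
    missing.  A sample with fewer than 10 observed values cannot support
    a fit and raises :class:`DataError`.
    """
    params = params or PreprocessParams()
    ref = reference_profile(matrix)
    out = matrix.data.copy()
    for sample in matrix.sample_ids:
        col = matrix.data[sample]
        obs = col.notna() & ref.notna()
        n_obs = int(obs.sum())
        if n_obs < MIN_OBS_FOR_LOWESS:
            raise DataError(
                f"sample {sample!r}: only {n_obs} non-missing values; "
                f"need >= {MIN_OBS_FOR_LOWESS} to fit the normalization curve"
            )
        x = ref[obs].to_numpy()
        y = (col[obs] - ref[obs]).to_numpy()
        fitted = sm_lowess(y, x, frac=params.lowess_span, return_sorted=False)
        out.loc[obs, sample] = col[obs].to_numpy() - fitted
    return matrix.advance(out, "normalized")


def _profile_distances(vals: np.ndarray, target_row: int) -> np.ndarray:
    """Mean-squared-difference distance from one assay to every other.

    Distance over samples where both assays are observed, scaled by the
    shared-sample count: ``sqrt(sum(d^2) / n_shared)``.  Assays sharing
    no samples with the target get distance ``inf``.
    """
    target = vals[target_row]
    diff = vals - target[None, :]
    shared = ~np.isnan(diff)
    n_shared = shared.sum(axis=1)
    sq = np.where(shared, diff, 0.0) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(sq.sum(axis=1) / n_shared)
    dist[n_shared == 0] = np.inf
    return dist


def knn_impute(matrix: CtMatrix, params: PreprocessParams | None = None) -> CtMatrix:
    """Fill missing cells from the K nearest assay profiles.

    A missing cell (assay a, sample s) becomes the unweighted mean over
    the ``knn_k`` assays nearest to a — among assays observed in s — of
    their values in s.  Ties in distance break by row order for
    determinism.  Observed cells are never touched.
    """
    params = params or PreprocessParams()
    orig = matrix.data.to_numpy()  # read-only source: fills never feed fills
    missing = np.isnan(orig)
    out = orig.copy()
    if not missing.any():
        return matrix.advance(matrix.data.copy(), "imputed")
    for i in np.flatnonzero(missing.any(axis=1)):
        dist = _profile_distances(orig, i)
        dist[i] = np.inf  # never self
        for j in np.flatnonzero(missing[i]):
            eligible = np.flatnonzero(~missing[:, j] & np.isfinite(dist))
            if eligible.size == 0:
                raise DataError(
                    f"assay {matrix.assay_ids[i]!r}, sample {matrix.sample_ids[j]!r}: "
                    "no eligible neighbour to impute from"
                )
            if eligible.size < params.knn_k:
                logger.warning(
                    "assay %r, sample %r: only %d eligible neighbours (k=%d); using all",
                    matrix.assay_ids[i],
                    matrix.sample_ids[j],
                    eligible.size,
                    params.knn_k,
                )
                chosen = eligible
            else:
                order = np.argsort(dist[eligible], kind="stable")
                chosen = eligible[order[: params.knn_k]]
            out[i, j] = orig[chosen, j].mean()
    frame = pd.DataFrame(out, index=matrix.assay_ids, columns=matrix.sample_ids)
    return matrix.advance(frame, "imputed")


def shrink_extremes(
    matrix: CtMatrix, params: PreprocessParams | None = None
) -> CtMatrix:
    """Winsorize per-assay extremes to median +/- c * 1.4826 * MAD.

    Assays whose MAD is zero (majority-constant rows) are left unchanged
    rather than collapsed onto the median.
    """
    params = params or PreprocessParams()
    vals = matrix.data.to_numpy().copy()
    med = np.nanmedian(vals, axis=1)
    mad = np.nanmedian(np.abs(vals - med[:, None]), axis=1)
    sigma = 1.4826 * mad
    has_scale = sigma > 0
    lo = med - params.shrink_c * sigma
    hi = med + params.shrink_c * sigma
    rows = has_scale[:, None]
    vals = np.where(rows, np.clip(vals, lo[:, None], hi[:, None]), vals)
    out = pd.DataFrame(vals, index=matrix.assay_ids, columns=matrix.sample_ids)
    return matrix.advance(out, "shrunk")


def preprocess_pipeline(
    matrix: CtMatrix, params: PreprocessParams | None = None
) -> tuple[CtMatrix, dict]:
    """Run filter -> lowess -> KNN imputation -> shrinkage, in order.

    Returns the analysis-ready matrix and a stage report with assay /
    missing-cell counts after each step.
    """
    params = params or PreprocessParams()
    report: dict = {
        "input": {"n_assays": matrix.n_assays, "n_samples": matrix.n_samples,
                  "n_missing": int(matrix.data.isna().sum().sum())},
    }
    filtered, excluded = detection_filter(matrix, params)
    report["filtered"] = {
        "n_assays": filtered.n_assays,
        "n_excluded": len(excluded),
        "excluded_assay_ids": excluded,
        "n_missing": int(filtered.data.isna().sum().sum()),
    }
    normalized = lowess_normalize(filtered, params)
    report["normalized"] = {"n_assays": normalized.n_assays,
                            "n_missing": int(normalized.data.isna().sum().sum())}
    imputed = knn_impute(normalized, params)
    report["imputed"] = {"n_assays": imputed.n_assays,
                         "n_imputed": report["normalized"]["n_missing"],
                         "n_missing": int(imputed.data.isna().sum().sum())}
    shrunk = shrink_extremes(imputed, params)
    n_shrunk = int((shrunk.data.to_numpy() != imputed.data.to_numpy()).sum())
    report["shrunk"] = {"n_assays": shrunk.n_assays, "n_cells_winsorized": n_shrunk}
    return shrunk, report
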