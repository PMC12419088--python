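"""Normalization, reference-class batch correction and validity filtering.

The abundance container throughout is a pandas DataFrame of log2 relative
abundances with proteins as rows and samples as columns; missing values are
NaN.  Estimator classes follow scikit-learn conventions (samples are rows of
``X``); the module-level functions wrap them in the proteins-by-samples
orientation used by the rest of the pipeline.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

LAYER_BLOCKS = {"E14.5": 4, "E18.5": 9}  # superficial block ends here


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        raise ValueError("duplicate protein ids")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids")


class MedianNormalizer(BaseEstimator, TransformerMixin):
    """Subtract the per-sample median of observed values.

    ``X`` is samples x features.  With ``assume_log2=False`` values must be
    strictly positive and are log2-transformed first.  Stateless; ``fit`` is
    a no-op kept for pipeline compatibility.
    """

    def __init__(self, assume_log2: bool = True):
        self.assume_log2 = assume_log2

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        values = np.asarray(X, dtype=float)
        if not self.assume_log2:
            if np.nanmin(values) <= 0:
                raise ValueError("values must be > 0 before log2 transform")
            values = np.log2(values)
        n_obs = np.sum(~np.isnan(values), axis=1)
        if np.any(n_obs == 0):
            bad = np.flatnonzero(n_obs == 0)
            names = (list(np.asarray(X.index)[bad]) if isinstance(X, pd.DataFrame)
                     else bad.tolist())
            raise ValueError(f"samples with no observed values: {names}")
        med = np.nanmedian(values, axis=1, keepdims=True)
        out = values - med
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


class ValidityFilter(BaseEstimator, TransformerMixin):
    """Keep features observed in at least ``min_fraction`` of the samples.

    The threshold uses >= semantics on the observed count, i.e. a feature is
    kept iff count >= ceil(min_fraction * n_samples).
    """

    def __init__(self, min_fraction: float = 0.7):
        self.min_fraction = min_fraction

    def fit(self, X, y=None):
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in (0, 1]")
        values = np.asarray(X, dtype=float)
        n = values.shape[0]
        if n == 0:
            raise ValueError("no samples in scope")
        need = math.ceil(self.min_fraction * n - 1e-9)
        counts = np.sum(~np.isnan(values), axis=0)
        self.n_samples_ = n
        self.support_ = counts >= need
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]


def normalize_median(matrix: pd.DataFrame, assume_log2: bool = True) -> pd.DataFrame:
    """Median-center every sample column of a proteins x samples matrix."""
    _check_matrix(matrix)
    return MedianNormalizer(assume_log2=assume_log2).fit_transform(matrix.T).T


def filter_by_validity(matrix: pd.DataFrame, min_fraction: float,
                       scope: Iterable[str] | None = None) -> pd.DataFrame:
    """Keep proteins observed in >= ``min_fraction`` of the ``scope`` samples.

    ``scope`` defaults to all columns; the returned matrix keeps all columns
    but only the passing proteins, in their original order.
    """
    _check_matrix(matrix)
    scope = list(matrix.columns) if scope is None else list(scope)
    flt = ValidityFilter(min_fraction=min_fraction).fit(matrix[scope].T)
    return matrix.loc[flt.support_]


def default_reference_classes(manifest: pd.DataFrame) -> pd.Series:
    """Model x layer-block reference classes (e.g. ``CTRL E14.5 L1-4``).

    The superficial block covers layers 1..4 at E14.5 and 1..9 at E18.5; the
    deep block the remainder.  Excluded samples get no class.
    """
    keep = manifest[~manifest["excluded"]]
    cut = keep["timepoint"].map(LAYER_BLOCKS)
    n_layers = keep.groupby("timepoint")["layer_index"].transform("max")
    block = np.where(keep["layer_index"] <= cut,
                     "L1-" + cut.astype(str),
                     "L" + (cut + 1).astype(str) + "-" + n_layers.astype(str))
    labels = keep["model"] + " " + keep["timepoint"] + " " + block
    return pd.Series(labels.to_numpy(), index=keep["sample_id"].to_numpy())


class BatchCorrector(BaseEstimator, TransformerMixin):
    """Reference-class location adjustment of additive batch effects.

    Per feature and batch, the batch effect is the mean class-mean-centered
    residual over the reference samples of the batch; it is subtracted from
    every sample of the batch.  Estimation and subtraction are iterated to a
    fixed point so that re-estimating effects on the corrected data returns
    ~0 even for unbalanced designs.  Reference classes observed in fewer
    than two batches are skipped for estimation.

    ``fit`` requires per-sample ``batch`` labels and ``classes`` labels
    (samples without a class are corrected but do not inform estimation).
    ``transform`` applies the stored effects to the fitted samples.
    """

    def __init__(self, adjust_scale: bool = False, max_iter: int = 25,
                 tol: float = 1e-10):
        self.adjust_scale = adjust_scale
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None, *, batch, classes):
        values = np.asarray(X, dtype=float)  # samples x features
        batch = pd.Series(np.asarray(batch, dtype=object))
        classes = pd.Series(np.asarray(classes, dtype=object))
        counts = batch.value_counts()
        if (counts < 2).any():
            small = list(counts.index[counts < 2])
            raise ValueError(f"batches with fewer than 2 samples: {small}")

        # classes usable for estimation must span >= 2 batches
        ref = classes.notna()
        span = pd.crosstab(classes[ref], batch[ref]).gt(0).sum(axis=1)
        usable = set(span.index[span >= 2])
        skipped = set(span.index[span < 2])
        if skipped:
            logger.warning("reference classes present in a single batch "
                           "skipped for estimation: %s", sorted(skipped))
        est = ref & classes.isin(usable)

        batches = list(pd.unique(batch))
        total = np.zeros((len(batches), values.shape[1]))
        work = values.copy()
        for _ in range(self.max_iter):
            resid = np.full_like(work, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                for cls in usable:
                    rows = (classes == cls) & est
                    cmean = np.nanmean(work[rows.to_numpy()], axis=0)
                    resid[rows.to_numpy()] = work[rows.to_numpy()] - cmean
                step = np.zeros_like(total)
                for bi, b in enumerate(batches):
                    rows = (batch == b) & est
                    if rows.any():
                        eff = np.nanmean(resid[rows.to_numpy()], axis=0)
                        step[bi] = np.where(np.isfinite(eff), eff, 0.0)
            if not np.any(np.abs(step) > self.tol):
                break
            total += step
            for bi, b in enumerate(batches):
                work[(batch == b).to_numpy()] -= step[bi]

        self.batches_ = batches
        self.effects_ = total
        self.batch_ = batch
        if self.adjust_scale:
            scales = np.ones_like(total)
            pooled = np.nanstd(work, axis=0, ddof=1)
            for bi, b in enumerate(batches):
                rows = (batch == b) & est
                if rows.sum() >= 3:
                    s = np.nanstd(work[rows.to_numpy()], axis=0, ddof=1)
                    ok = np.isfinite(s) & (s > 0) & np.isfinite(pooled) & (pooled > 0)
                    scales[bi, ok] = s[ok] / pooled[ok]
            self.scales_ = scales
        return self

    def transform(self, X):
        values = np.asarray(X, dtype=float).copy()
        for bi, b in enumerate(self.batches_):
            rows = (self.batch_ == b).to_numpy()
            values[rows] -= self.effects_[bi]
            if self.adjust_scale:
                values[rows] /= self.scales_[bi]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(values, index=X.index, columns=X.columns)
        return values


def batch_correct(matrix: pd.DataFrame, manifest: pd.DataFrame, batch_key: str,
                  references: Mapping[str, str] | pd.Series | None = None,
                  adjust_scale: bool = False) -> pd.DataFrame:
    """Remove additive batch effects from a proteins x samples matrix.

    ``batch_key`` is ``la_batch`` or ``m_batch``.  With ``references`` given
    (sample_id -> class), only those samples inform the per-batch location
    estimates; with ``references=None`` every sample participates, labelled
    by the default model x layer-block classes.  The missing pattern and the
    matrix shape are unchanged.
    """
    _check_matrix(matrix)
    if batch_key not in ("la_batch", "m_batch"):
        raise ValueError("batch_key must be 'la_batch' or 'm_batch'")
    meta = manifest.set_index("sample_id").loc[list(matrix.columns)]
    batch = meta[batch_key]
    if batch.nunique() == 1:
        return matrix.copy()

    all_classes = default_reference_classes(manifest)
    if references is None:
        classes = all_classes.reindex(matrix.columns)
    else:
        references = pd.Series(dict(references)) if not isinstance(references, pd.Series) else references
        classes = references.reindex(matrix.columns)

    corrector = BatchCorrector(adjust_scale=adjust_scale)
    corrector.fit(matrix.T, batch=batch.to_numpy(), classes=classes.to_numpy())
    return corrector.transform(matrix.T).T


def estimate_batch_effects(matrix: pd.DataFrame, manifest: pd.DataFrame,
                           batch_key: str,
                           references: Mapping[str, str] | pd.Series | None = None
                           ) -> pd.DataFrame:
    """One-pass per-(batch, protein) location estimates (diagnostic).

    Returns a batches x proteins frame of mean class-centered residuals;
    ~0 everywhere after a successful correction.
    """
    meta = manifest.set_index("sample_id").loc[list(matrix.columns)]
    batch = meta[batch_key]
    if references is None:
        classes = default_reference_classes(manifest).reindex(matrix.columns)
    else:
        references = pd.Series(dict(references)) if not isinstance(references, pd.Series) else references
        classes = references.reindex(matrix.columns)
    corrector = BatchCorrector(max_iter=1)
    corrector.fit(matrix.T, batch=batch.to_numpy(), classes=classes.to_numpy())
    return pd.DataFrame(corrector.effects_, index=corrector.batches_,
                        columns=matrix.index)
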