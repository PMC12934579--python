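"""Bulk RNA-seq count preparation: filtering, normalization, batch
correction, and iterative PCA/Mahalanobis outlier removal.

Module-level functions operate on gene x sample count matrices (genes as
rows, the layout count files use). The sklearn-style transformers at the
bottom operate on samples x genes arrays (samples as rows, the sklearn
convention) and compose with :class:`sklearn.pipeline.Pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "NormalizedMatrix",
    "OutlierReport",
    "filter_low_counts",
    "size_factors_median_of_ratios",
    "stabilize",
    "remove_batch",
    "mahalanobis_outliers",
    "LowCountFilter",
    "MedianRatiosNormalizer",
    "BatchEffectRemover",
    "MahalanobisOutlierFilter",
]


@dataclass
class NormalizedMatrix:
    """Normalized expression (genes x samples) plus provenance."""

    values: pd.DataFrame
    size_factors: pd.Series
    transform: str = "none"  # "none" | "log-stabilized"
    batch_removed: bool = False


@dataclass
class OutlierRound:
    removed: list[str]
    distances: dict[str, float]  # squared Mahalanobis distance per sample
    cutoff: float
    n_pcs: int


@dataclass
class OutlierReport:
    rounds: list[OutlierRound] = field(default_factory=list)

    @property
    def removed_samples(self) -> list[str]:
        return [s for r in self.rounds for s in r.removed]


def filter_low_counts(
    counts: pd.DataFrame, min_total: int = 40, per_sample: bool = False
) -> pd.DataFrame:
    """Drop weakly expressed genes.

    Default: keep genes whose total count across all samples is at least
    ``min_total`` (a gene totalling 39 is removed, 40 retained). With
    ``per_sample=True`` the threshold applies to the per-sample maximum
    instead.
    """
    if per_sample:
        keep = counts.max(axis=1) >= min_total
    else:
        keep = counts.sum(axis=1) >= min_total
    if not keep.any():
        raise ValueError("low-count filter removed every gene")
    return counts.loc[keep]


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization).

    For genes expressed in every sample, each sample's factor is the median
    ratio of its counts to the per-gene geometric mean; factors are then
    rescaled to geometric mean 1 so normalized values sit on the scale of a
    typical library.
    """
    c = counts.to_numpy(dtype=float)
    all_pos = (c > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios is "
            "undefined (consider a pseudo-reference fallback upstream)"
        )
    sub = c[all_pos]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def stabilize(counts: pd.DataFrame, factors: pd.Series) -> NormalizedMatrix:
    """Variance-stabilizing transform: log2(count / size_factor + 1)."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    vals = np.log2(counts.to_numpy(dtype=float) / factors.to_numpy()[None, :] + 1.0)
    return NormalizedMatrix(
        pd.DataFrame(vals, index=counts.index, columns=counts.columns),
        size_factors=factors,
        transform="log-stabilized",
    )


def _design_matrices(meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Condition design (intercept + treatment dummies) and sum-to-zero batch
    dummies, aligned to meta's row order."""
    cond = pd.get_dummies(meta["condition"], drop_first=True, dtype=float)
    x_cond = np.column_stack([np.ones(len(meta)), cond.to_numpy()])
    levels = sorted(meta["batch"].unique())
    # sum-to-zero coding: correction averages to zero over batches
    x_batch = np.zeros((len(meta), len(levels) - 1))
    for j, lvl in enumerate(levels[1:]):
        x_batch[(meta["batch"] == lvl).to_numpy(), j] = 1.0
        x_batch[(meta["batch"] == levels[0]).to_numpy(), j] = -1.0
    return x_cond, x_batch


def remove_batch(norm: NormalizedMatrix, meta: pd.DataFrame) -> NormalizedMatrix:
    """Subtract additive batch effects on the stabilized scale.

    Per gene, a least-squares fit on condition plus batch indicators is
    computed and only the fitted batch component is subtracted, so condition
    effects pass through untouched. Requires batches to span more than one
    condition (otherwise batch and condition are confounded).
    """
    meta = meta.loc[norm.values.columns]
    if meta["batch"].nunique() <= 1:
        out = NormalizedMatrix(
            norm.values.copy(), norm.size_factors, norm.transform, batch_removed=True
        )
        return out
    tab = pd.crosstab(meta["batch"], meta["condition"])
    confounded = tab.index[(tab > 0).sum(axis=1) < 2].tolist()
    if confounded and meta["condition"].nunique() > 1:
        raise ValueError(
            f"batch(es) {confounded} contain a single condition; batch and "
            "condition are confounded and the batch effect is not estimable"
        )
    x_cond, x_batch = _design_matrices(meta)
    design = np.column_stack([x_cond, x_batch])
    y = norm.values.to_numpy().T  # samples x genes
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    batch_beta = beta[x_cond.shape[1] :]
    corrected = (y - x_batch @ batch_beta).T
    return NormalizedMatrix(
        pd.DataFrame(corrected, index=norm.values.index, columns=norm.values.columns),
        norm.size_factors,
        norm.transform,
        batch_removed=True,
    )


def mahalanobis_outliers(
    norm: NormalizedMatrix,
    n_pcs: int = 2,
    conf: float = 0.95,
    max_rounds: int = 2,
) -> tuple[NormalizedMatrix, OutlierReport]:
    """Iterative sample-outlier removal in PCA space.

    Each round: PCA on the gene-standardized matrix; squared Mahalanobis
    distance of every sample's first ``n_pcs`` scores to their mean and
    covariance; samples beyond the chi-square(``n_pcs``) quantile at
    ``conf`` (the confidence ellipse) are removed and PCA is re-evaluated.
    Stops after a round removing nothing, or after ``max_rounds``.
    """
    vals = norm.values
    report = OutlierReport()
    cutoff = float(stats.chi2.ppf(conf, df=n_pcs))
    for _ in range(max_rounds):
        if vals.shape[1] <= n_pcs + 2:
            raise ValueError("too few samples for the requested number of PCs")
        x = vals.to_numpy(dtype=float)
        sd = x.std(axis=1)
        keep = sd > 0
        z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
        scores = PCA(n_components=n_pcs, svd_solver="full").fit_transform(z.T)
        center = scores.mean(axis=0)
        cov = np.cov(scores, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        if np.linalg.matrix_rank(cov) < n_pcs:
            raise ValueError(
                "singular PC covariance; use more samples or fewer PCs"
            )
        diff = scores - center
        d2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
        distances = dict(zip(vals.columns, map(float, d2)))
        removed = [s for s, d in distances.items() if d > cutoff]
        report.rounds.append(OutlierRound(removed, distances, cutoff, n_pcs))
        if not removed:
            break
        vals = vals.drop(columns=removed)
    out = NormalizedMatrix(
        vals, norm.size_factors.loc[vals.columns], norm.transform, norm.batch_removed
    )
    return out, report


# ---------------------------------------------------------------------------
# sklearn-style transformers (samples x genes)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(
        X,
        index=[f"s{i}" for i in range(X.shape[0])],
        columns=[f"g{j}" for j in range(X.shape[1])],
    )


class LowCountFilter(TransformerMixin, BaseEstimator):
    """Drop genes (columns) whose total count falls below ``min_total``."""

    def __init__(self, min_total: int = 40):
        self.min_total = min_total

    def fit(self, X, y=None):
        X = _as_frame(X)
        filtered = filter_low_counts(X.T, min_total=self.min_total)
        self.keep_genes_ = filtered.index
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_frame(X)
        return X.loc[:, self.keep_genes_]


class MedianRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios normalization with optional log2(x+1) stabilization.

    ``fit`` stores the per-gene log geometric mean of the training counts as
    the pseudo-reference; ``transform`` computes each sample's size factor
    against that reference, divides, and (by default) log-stabilizes.
    """

    def __init__(self, log_transform: bool = True):
        self.log_transform = log_transform

    def fit(self, X, y=None):
        X = _as_frame(X)
        c = X.to_numpy(dtype=float)
        all_pos = (c > 0).all(axis=0)
        if not all_pos.any():
            raise ValueError("no gene expressed in every training sample")
        self.reference_genes_ = X.columns[all_pos]
        self.log_geomean_ = pd.Series(
            np.log(c[:, all_pos]).mean(axis=0), index=self.reference_genes_
        )
        # rescale constant making the training factors' geometric mean 1
        raw = self._raw_factors(X)
        self.rescale_ = float(np.exp(np.mean(np.log(raw))))
        self.size_factors_ = pd.Series(raw / self.rescale_, index=X.index)
        self.n_features_in_ = X.shape[1]
        return self

    def _raw_factors(self, X: pd.DataFrame) -> np.ndarray:
        sub = X.loc[:, self.reference_genes_].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            logratio = np.log(sub) - self.log_geomean_.to_numpy()[None, :]
        return np.exp(np.nanmedian(np.where(np.isfinite(logratio), logratio, np.nan), axis=1))

    def transform(self, X):
        X = _as_frame(X)
        factors = self._raw_factors(X) / self.rescale_
        vals = X.to_numpy(dtype=float) / factors[:, None]
        if self.log_transform:
            vals = np.log2(vals + 1.0)
        return pd.DataFrame(vals, index=X.index, columns=X.columns)


class BatchEffectRemover(TransformerMixin, BaseEstimator):
    """Remove additive batch effects while preserving condition effects.

    Transductive: ``fit`` takes the per-sample ``condition`` and ``batch``
    labels of the matrix it will correct; ``transform`` must be called with
    (a subset of) the same samples.
    """

    def fit(self, X, y=None, *, condition, batch):
        X = _as_frame(X)
        meta = pd.DataFrame({"condition": list(condition), "batch": list(batch)}, index=X.index)
        norm = NormalizedMatrix(X.T, pd.Series(1.0, index=X.index), "log-stabilized")
        corrected = remove_batch(norm, meta)
        self.corrected_ = corrected.values.T
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_frame(X)
        return self.corrected_.loc[X.index]

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


class MahalanobisOutlierFilter(TransformerMixin, BaseEstimator):
    """Drop outlying samples (rows) via iterative PCA-space Mahalanobis
    screening against the chi-square confidence ellipse."""

    def __init__(self, n_pcs: int = 2, conf: float = 0.95, max_rounds: int = 2):
        self.n_pcs = n_pcs
        self.conf = conf
        self.max_rounds = max_rounds

    def fit(self, X, y=None):
        X = _as_frame(X)
        norm = NormalizedMatrix(X.T, pd.Series(1.0, index=X.index), "log-stabilized")
        _, report = mahalanobis_outliers(
            norm, n_pcs=self.n_pcs, conf=self.conf, max_rounds=self.max_rounds
        )
        self.report_ = report
        self.outlier_ids_ = report.removed_samples
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_frame(X)
        return X.drop(index=[s for s in self.outlier_ids_ if s in X.index])

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)
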