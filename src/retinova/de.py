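"""Negative-binomial differential expression with Wald tests.

Per gene, counts are modeled as NB(mu, alpha) with Var = mu + alpha*mu^2,
log mu = X beta + log(size factor). Dispersions are method-of-moments
estimates shrunk toward a mean-dispersion trend; coefficients are fit by
iteratively reweighted least squares and contrasts tested with a Wald z.
Differentially expressed genes (DEGs) are called at BH-adjusted p < 0.05
and |log2 fold change| > 0.32 (both strict), and DEG sets from two
contrasts can be compared for shared / contra-regulated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "DEGSet",
    "estimate_dispersion",
    "nb_wald",
    "bh_adjust",
    "call_degs",
    "deg_overlap",
    "NegativeBinomialDE",
]

LN2 = np.log(2.0)
MIN_ALPHA = 1e-8


@dataclass
class DEGSet:
    """Up/down-regulated gene sets at fixed thresholds."""

    up: set
    down: set
    padj_max: float = 0.05
    abs_lfc_min: float = 0.32

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def _group_indicator(conditions: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = list(pd.unique(conditions))
    x = np.zeros((len(conditions), len(levels)))
    for j, lvl in enumerate(levels):
        x[(conditions == lvl).to_numpy(), j] = 1.0
    return x, levels


def build_design(
    meta: pd.DataFrame, include_batch: bool = True
) -> tuple[np.ndarray, list[str]]:
    """One-hot condition design (no intercept) plus optional batch dummies.

    The cell-means coding makes a contrast between two conditions a simple
    difference of coefficients.
    """
    x, levels = _group_indicator(meta["condition"])
    names = [f"condition[{lvl}]" for lvl in levels]
    if include_batch and "batch" in meta and meta["batch"].nunique() > 1:
        b = pd.get_dummies(meta["batch"], drop_first=True, dtype=float)
        x = np.column_stack([x, b.to_numpy()])
        names += [f"batch[{c}]" for c in b.columns]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is not full rank (confounded factors?)")
    return x, names


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    meta: pd.DataFrame,
    shrink: bool = True,
    n_bins: int = 20,
) -> pd.Series:
    """Per-gene NB dispersion alpha (Var = mu + alpha*mu^2).

    Method of moments on size-factor-normalized counts: with q = k/s,
    Var(q) ~= mu * mean(1/s) + alpha * mu^2, so
    alpha_raw = (v - m * mean(1/s)) / m^2 using the within-condition pooled
    variance v and overall mean m, floored at 1e-8. When ``shrink`` is on,
    raw estimates are averaged with a log-mean binned median trend using
    weight w = min(1, 20/df) on the trend (small-sample estimates lean on
    the trend, large-sample ones stand alone).
    """
    groups = meta.loc[counts.columns, "condition"]
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("every condition needs >= 2 samples to estimate dispersion")
    q = counts.to_numpy(dtype=float) / factors.loc[counts.columns].to_numpy()[None, :]
    m = q.mean(axis=1)
    n = q.shape[1]
    n_groups = groups.nunique()
    df = n - n_groups
    # pooled within-condition variance (removes condition means from v)
    ss = np.zeros(q.shape[0])
    for lvl in groups.unique():
        sel = (groups == lvl).to_numpy()
        sub = q[:, sel]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    v = ss / max(df, 1)
    inv_s = float((1.0 / factors.loc[counts.columns]).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - m * inv_s) / np.where(m > 0, m * m, np.nan)
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.maximum(raw, MIN_ALPHA)

    if not shrink:
        return pd.Series(raw, index=counts.index, name="alpha")

    # trend: median raw dispersion in log-mean bins, interpolated
    ok = m > 0
    logm = np.log10(np.where(ok, m, 1.0))
    edges = np.quantile(logm[ok], np.linspace(0, 1, n_bins + 1)) if ok.sum() > n_bins else None
    trend = np.full_like(raw, np.median(raw[ok]) if ok.any() else MIN_ALPHA)
    if edges is not None and np.unique(edges).size > 2:
        idx = np.clip(np.searchsorted(edges, logm, side="right") - 1, 0, n_bins - 1)
        centers, medians = [], []
        for b in range(n_bins):
            sel = ok & (idx == b)
            if sel.sum() >= 5:
                centers.append(logm[sel].mean())
                medians.append(np.median(raw[sel]))
        if len(centers) >= 2:
            trend = np.interp(logm, centers, medians)
    w = min(1.0, 20.0 / max(df, 1))
    alpha = w * trend + (1.0 - w) * raw
    return pd.Series(np.maximum(alpha, MIN_ALPHA), index=counts.index, name="alpha")


def _irls_nb(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: float, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit one NB log-linear GLM; returns (beta, cov(beta), converged)."""
    n, p = x.shape
    # initialize from log normalized counts
    z0 = np.log(np.maximum(y * np.exp(-offset), 0.5))
    beta, *_ = np.linalg.lstsq(x, z0, rcond=None)
    converged = False
    xtwx = np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(x @ beta + offset, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = x.T * w
        xtwx = xtw @ x
        try:
            new = np.linalg.solve(xtwx + 1e-10 * np.eye(p), xtw @ z)
        except np.linalg.LinAlgError:
            return beta, np.full((p, p), np.nan), False
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            converged = True
            break
        beta = new
    try:
        cov = np.linalg.inv(xtwx + 1e-10 * np.eye(p))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged


def nb_wald(
    counts: pd.DataFrame,
    factors: pd.Series,
    alpha: pd.Series,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    include_batch: bool = True,
) -> pd.DataFrame:
    """Per-gene Wald test of ``contrast = (group, reference)``.

    Returns a DataFrame indexed by gene with columns baseMean, log2FC, SE,
    stat, pvalue, converged. log2FC is the contrast-group coefficient minus
    the reference coefficient on the log2 scale; genes with all-zero counts
    across the two contrasted groups get NaN p-values (and are excluded
    from the BH denominator downstream).
    """
    meta = meta.loc[counts.columns]
    x, names = build_design(meta, include_batch=include_batch)
    grp, ref = contrast
    try:
        j_grp = names.index(f"condition[{grp}]")
        j_ref = names.index(f"condition[{ref}]")
    except ValueError as e:
        raise ValueError(f"contrast level missing from design: {e}") from e
    c = np.zeros(x.shape[1])
    c[j_grp], c[j_ref] = 1.0, -1.0

    offset = np.log(factors.loc[counts.columns].to_numpy())
    in_contrast = meta["condition"].isin(contrast).to_numpy()
    y_all = counts.to_numpy(dtype=float)
    a_all = alpha.loc[counts.index].to_numpy()

    base_mean = (y_all / np.exp(offset)[None, :]).mean(axis=1)
    rows = []
    for g in range(y_all.shape[0]):
        y = y_all[g]
        if y[in_contrast].sum() == 0:
            rows.append((np.nan, np.nan, np.nan, np.nan, False))
            continue
        beta, cov, converged = _irls_nb(y, x, offset, float(a_all[g]))
        est = float(c @ beta)
        var = float(c @ cov @ c)
        if not converged or not np.isfinite(var) or var <= 0:
            rows.append((est / LN2, np.nan, np.nan, np.nan, False))
            continue
        se = np.sqrt(var)
        z = est / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((est / LN2, se / LN2, z, p, True))
    out = pd.DataFrame(
        rows, index=counts.index, columns=["log2FC", "SE", "stat", "pvalue", "converged"]
    )
    out.insert(0, "baseMean", base_mean)
    out["alpha"] = a_all
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are preserved and excluded from the number of tests m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def call_degs(
    results: pd.DataFrame, padj_max: float = 0.05, abs_lfc_min: float = 0.32
) -> DEGSet:
    """Call DEGs at strict thresholds: padj < padj_max and |log2FC| > abs_lfc_min."""
    r = results.copy()
    if "padj" not in r:
        r["padj"] = bh_adjust(r["pvalue"].to_numpy())
    sig = (r["padj"] < padj_max) & r["padj"].notna()
    up = set(r.index[sig & (r["log2FC"] > abs_lfc_min)])
    down = set(r.index[sig & (r["log2FC"] < -abs_lfc_min)])
    return DEGSet(up, down, padj_max, abs_lfc_min)


def deg_overlap(a: DEGSet, b: DEGSet) -> dict:
    """Set algebra between two DEG calls.

    Shared genes keep direction (a.up & b.up, a.down & b.down);
    contra-regulated genes flip it. ``percent_shared`` is the co-directional
    overlap as a percent of all DEGs in ``a``.
    """
    shared_up = a.up & b.up
    shared_down = a.down & b.down
    contra = (a.up & b.down) | (a.down & b.up)
    n_a = len(a)
    return {
        "shared_up": len(shared_up),
        "shared_down": len(shared_down),
        "contra": len(contra),
        "unique_to_a": n_a - len(shared_up) - len(shared_down) - len(contra),
        "unique_to_b": len(b) - len(shared_up) - len(shared_down) - len(contra),
        "percent_shared": 100.0 * (len(shared_up) + len(shared_down)) / n_a if n_a else 0.0,
        "shared_up_genes": sorted(shared_up),
        "shared_down_genes": sorted(shared_down),
    }


class NegativeBinomialDE(BaseEstimator):
    """sklearn-style estimator wrapping the NB Wald workflow.

    ``fit`` takes a samples x genes count matrix plus per-sample condition
    (and optional batch) labels, estimates size factors and dispersions,
    and caches the design; ``results`` fits the per-gene GLM for a contrast
    and returns the annotated table with BH-adjusted p-values.
    """

    def __init__(
        self,
        padj_max: float = 0.05,
        abs_lfc_min: float = 0.32,
        include_batch: bool = True,
        shrink_dispersion: bool = True,
    ):
        self.padj_max = padj_max
        self.abs_lfc_min = abs_lfc_min
        self.include_batch = include_batch
        self.shrink_dispersion = shrink_dispersion

    def fit(self, X, y, *, batch=None, size_factors=None):
        from .qc import size_factors_median_of_ratios

        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        counts = X.T  # genes x samples
        meta = pd.DataFrame({"condition": list(y)}, index=X.index)
        if batch is not None:
            meta["batch"] = list(batch)
        if size_factors is None:
            size_factors = size_factors_median_of_ratios(counts)
        else:
            size_factors = pd.Series(size_factors, index=X.index)
        self.counts_ = counts
        self.meta_ = meta
        self.size_factors_ = size_factors
        self.dispersion_ = estimate_dispersion(
            counts, size_factors, meta, shrink=self.shrink_dispersion
        )
        self.n_features_in_ = X.shape[1]
        return self

    def results(self, contrast: tuple[str, str]) -> pd.DataFrame:
        res = nb_wald(
            self.counts_,
            self.size_factors_,
            self.dispersion_,
            self.meta_,
            contrast,
            include_batch=self.include_batch and "batch" in self.meta_,
        )
        res["padj"] = bh_adjust(res["pvalue"].to_numpy())
        return res

    def degs(self, contrast: tuple[str, str]) -> DEGSet:
        return call_degs(self.results(contrast), self.padj_max, self.abs_lfc_min)
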