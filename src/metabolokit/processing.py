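"""Transformation, normalization, QC-LOESS drift correction and PCA.

Sample-based normalization removes between-sample technical variance
(total-signal, metadata such as dry mass, per-batch reference medians, or
a locally weighted regression on pooled quality-control samples across the
injection sequence).  Feature-based scaling (auto / Pareto / range) makes
variables comparable in total variance.  The conventional pipeline order
is transform -> sample normalization -> feature scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_data import BATCH_COL, Dataset, ORDER_COL, TYPE_COL

__all__ = [
    "NormalizationSpec",
    "transform_values",
    "normalize_samples",
    "qc_loess_normalize",
    "scale_features",
    "pca_overview",
    "apply_pipeline",
]

DEFAULT_SPAN_GRID = tuple(np.round(np.arange(0.3, 1.01, 0.1), 2))


class ProcessingError(ValueError):
    pass


@dataclass
class NormalizationSpec:
    """Declarative processing recipe mirrored by the CLI/config layer."""

    transform: str = "none"            # none | log2 | log10 | ln | power
    power_exponent: float = 0.5
    sample_method: str = "none"        # none | sum | metadata | batch_median | qc_loess
    sample_params: dict = field(default_factory=dict)
    feature_method: str = "none"       # none | auto | pareto | range
    span_grid: tuple = DEFAULT_SPAN_GRID
    loess_degree: int = 2

    def __post_init__(self) -> None:
        if self.power_exponent <= 0:
            raise ProcessingError("power_exponent must be positive")
        if any(not (0 < s <= 1) for s in self.span_grid):
            raise ProcessingError("span grid values must lie in (0, 1]")


# ---------------------------------------------------------------------------
# transformation


def transform_values(d: Dataset, method: str, exponent: float = 0.5) -> Dataset:
    """Elementwise variable transformation; missing values stay missing."""
    x = d.intensities
    if method == "none":
        return d.copy()
    if method in ("log2", "log10", "ln"):
        bad = (x <= 0).to_numpy() & x.notna().to_numpy()
        if bad.any():
            fi, si = np.argwhere(bad)[0]
            raise ProcessingError(
                f"{method} transform requires positive intensities; "
                f"feature {x.index[fi]!r}, sample {x.columns[si]!r} is "
                f"{x.iat[fi, si]}"
            )
        fn = {"log2": np.log2, "log10": np.log10, "ln": np.log}[method]
        return d.with_intensities(fn(x))
    if method == "power":
        if exponent <= 0:
            raise ProcessingError("power exponent must be positive")
        return d.with_intensities(x ** exponent)
    raise ProcessingError(f"unknown transform {method!r}")


# ---------------------------------------------------------------------------
# sample-based normalization


def normalize_samples(d: Dataset, method: str, **params) -> Dataset:
    """Sample-based normalization.

    ``sum``
        Each sample is divided by its total signal and rescaled by the
        median of all sample totals, keeping intensities on the original
        scale.
    ``metadata``
        Division by a positive numeric per-sample metadata column
        (``column=``, e.g. dry mass), rescaled by the column median.
    ``batch_median``
        Per batch, each sample is divided feature-wise by the median
        vector of designated reference samples
        (``reference_type="qc"`` by default).
    """
    x = d.intensities
    if method == "sum":
        totals = x.sum(axis=0, skipna=True)
        if (totals == 0).any():
            zero = totals.index[totals == 0].tolist()
            raise ProcessingError(f"zero total signal for sample(s) {zero}")
        scale = totals.median() / totals
        return d.with_intensities(x * scale)
    if method == "metadata":
        col = params.get("column")
        if col is None or col not in d.sample_meta.columns:
            raise ProcessingError("metadata normalization needs a sample-meta 'column'")
        m = pd.to_numeric(d.sample_meta[col])
        if (m <= 0).any() or m.isna().any():
            raise ProcessingError(f"metadata column {col!r} must be positive for all samples")
        return d.with_intensities(x * (m.median() / m))
    if method == "batch_median":
        ref_type = params.get("reference_type", "qc")
        if BATCH_COL not in d.sample_meta.columns:
            raise ProcessingError("batch_median normalization requires batch labels")
        stypes = d.sample_types()
        out = x.copy()
        for batch, cols in x.columns.groupby(d.sample_meta[BATCH_COL]).items():
            ref = [c for c in cols if stypes[c] == ref_type]
            if not ref:
                raise ProcessingError(f"no {ref_type!r} reference samples in batch {batch!r}")
            med = x[ref].median(axis=1)
            if (med == 0).any():
                raise ProcessingError(f"zero reference median in batch {batch!r}")
            out[list(cols)] = x[list(cols)].div(med, axis=0)
        return d.with_intensities(out)
    raise ProcessingError(f"unknown sample normalization {method!r}")


# ---------------------------------------------------------------------------
# QC-LOESS drift correction


def _loess_predict(x_train, y_train, x_eval, span, degree):
    """Local polynomial regression with tricube weights.

    For each evaluation point the ``span`` fraction of nearest training
    points (at least degree+2) is fitted by weighted least squares.
    """
    n = len(x_train)
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        dist = np.abs(x_train - x0)
        idx = np.argsort(dist, kind="stable")[:k]
        h = dist[idx].max()
        if h == 0:
            out[i] = float(np.mean(y_train[idx]))
            continue
        w = (1 - (dist[idx] / h) ** 3) ** 3
        w = np.clip(w, 1e-12, None)
        deg = min(degree, len(idx) - 1)
        xc = x_train[idx] - x0  # center for conditioning
        X = np.vander(xc, deg + 1, increasing=True)
        W = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * W[:, None], y_train[idx] * W, rcond=None)
        out[i] = beta[0]
    return out


def _choose_span(x, y, span_grid, degree):
    """Leave-one-out cross-validation over the span grid (min MSE)."""
    best_span, best_err = None, np.inf
    for span in span_grid:
        errs = []
        for i in range(len(x)):
            mask = np.ones(len(x), bool)
            mask[i] = False
            pred = _loess_predict(x[mask], y[mask], [x[i]], span, degree)[0]
            errs.append((pred - y[i]) ** 2)
        err = float(np.mean(errs))
        if err < best_err - 1e-15:
            best_err, best_span = err, span
    return best_span


def qc_loess_normalize(
    d: Dataset,
    span_grid=DEFAULT_SPAN_GRID,
    degree: int = 2,
    min_qc: int = 4,
) -> tuple[Dataset, pd.DataFrame]:
    """Correct within-batch signal drift using pooled QC samples.

    Per feature and per batch a locally weighted polynomial regression of
    QC intensity on injection order is fitted, with the span chosen from
    ``span_grid`` by leave-one-out cross-validation on the QC samples.
    Every sample's intensity is divided by the fitted drift curve at its
    injection order and rescaled to the across-batch QC median, which also
    aligns batches to a common level (batch effect correction).

    Returns the corrected dataset and a table of chosen spans
    (feature x batch).
    """
    if ORDER_COL not in d.sample_meta.columns:
        raise ProcessingError("qc_loess requires an injection_order column")
    stypes = d.sample_types()
    batches = (
        d.sample_meta[BATCH_COL]
        if BATCH_COL in d.sample_meta.columns
        else pd.Series("batch1", index=d.intensities.columns)
    )
    order = pd.to_numeric(d.sample_meta[ORDER_COL])

    qc_cols = stypes == "qc"
    for batch in batches.unique():
        n_qc = int((qc_cols & (batches == batch)).sum())
        if n_qc < min_qc:
            raise ProcessingError(
                f"batch {batch!r} has {n_qc} QC samples; at least {min_qc} required"
            )

    x = d.intensities
    out = x.copy()
    spans = pd.DataFrame(index=x.index, columns=pd.unique(batches), dtype=float)
    global_qc_median = x.loc[:, qc_cols.to_numpy()].median(axis=1)

    for feat in x.index:
        row = x.loc[feat]
        for batch in spans.columns:
            in_batch = (batches == batch).to_numpy()
            bcols = x.columns[in_batch]
            qc_in_batch = bcols[(qc_cols[bcols]).to_numpy()]
            xq = order[qc_in_batch].to_numpy(dtype=float)
            yq = row[qc_in_batch].to_numpy(dtype=float)
            ok = ~np.isnan(yq)
            if ok.sum() < min_qc:
                warnings.warn(
                    f"feature {feat!r} has <{min_qc} non-missing QC values in "
                    f"batch {batch!r}; passed through uncorrected"
                )
                continue
            xq, yq = xq[ok], yq[ok]
            span = _choose_span(xq, yq, span_grid, degree)
            spans.loc[feat, batch] = span
            fitted = _loess_predict(
                xq, yq, order[bcols].to_numpy(dtype=float), span, degree
            )
            fitted = np.where(fitted <= 0, np.nan, fitted)
            target = global_qc_median[feat]
            out.loc[feat, bcols] = row[bcols].to_numpy() / fitted * target
    return d.with_intensities(out), spans


# ---------------------------------------------------------------------------
# feature-based scaling


def scale_features(d: Dataset, method: str) -> Dataset:
    """Per-feature scaling: auto (unit variance), Pareto (sqrt sd), range.

    All three first mean-center.  Standard deviation uses the n-1 sample
    estimator.  Constant features are set to 0 with a warning rather than
    dividing by zero.
    """
    if method not in ("auto", "pareto", "range"):
        raise ProcessingError(f"unknown feature scaling {method!r}")
    x = d.intensities
    n_ok = x.notna().sum(axis=1)
    if (n_ok < 2).any():
        bad = x.index[n_ok < 2].tolist()
        raise ProcessingError(f"features with <2 non-missing values: {bad}")
    mean = x.mean(axis=1)
    centered = x.sub(mean, axis=0)
    if method == "range":
        denom = x.max(axis=1) - x.min(axis=1)
    else:
        sd = x.std(axis=1, ddof=1)
        denom = sd if method == "auto" else np.sqrt(sd)
    const = denom == 0
    if const.any():
        warnings.warn(f"constant feature(s) scaled to 0: {x.index[const].tolist()}")
        denom = denom.replace(0, np.nan)
    scaled = centered.div(denom, axis=0)
    scaled.loc[const] = scaled.loc[const].where(x.loc[const].isna(), 0.0)
    return d.with_intensities(scaled)


# ---------------------------------------------------------------------------
# PCA overview


def pca_overview(d: Dataset, n_components: int = 2):
    """PCA of samples on centered features.

    Returns ``(scores, loadings, explained_variance_fractions)`` where
    scores is samples x components and loadings features x components.
    Missing values are not handled here: impute or subset first.
    """
    x = d.intensities.to_numpy(dtype=float).T  # samples x features
    if np.isnan(x).any():
        raise ProcessingError(
            "PCA requires complete data; impute or drop missing values first"
        )
    n_components = min(n_components, min(x.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    comps = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=d.intensities.columns, columns=comps),
        pd.DataFrame(pca.components_.T, index=d.intensities.index, columns=comps),
        pd.Series(pca.explained_variance_ratio_, index=comps),
    )


# ---------------------------------------------------------------------------
# pipeline


def apply_pipeline(d: Dataset, spec: NormalizationSpec) -> tuple[Dataset, dict]:
    """Run transform -> sample normalization -> feature scaling.

    Returns the processed dataset and a dict of stage reports (chosen
    LOESS spans when applicable).
    """
    report: dict = {}
    if spec.transform != "none":
        d = transform_values(d, spec.transform, spec.power_exponent)
    if spec.sample_method == "qc_loess":
        d, spans = qc_loess_normalize(d, spec.span_grid, spec.loess_degree)
        report["loess_spans"] = spans
    elif spec.sample_method != "none":
        d = normalize_samples(d, spec.sample_method, **spec.sample_params)
    if spec.feature_method != "none":
        d = scale_features(d, spec.feature_method)
    return d, report
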