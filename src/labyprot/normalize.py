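"""Variance stabilization and batch correction for reporter-intensity matrices.

``GlogNormalizer`` performs a VSN-style normalization: each sample is first
calibrated by a median-of-ratios scale factor against a geometric-mean
reference profile, then passed through the generalized logarithm

    y = log2( (x + sqrt(x^2 + c^2)) / 2 ),

which behaves like log2(x) for x >> c but stays finite (and roughly linear)
near zero, so replicate variance no longer explodes at low intensity.  The
offset ``c`` is taken from a low quantile of the calibrated intensities.

``BatchCorrector`` removes additive and multiplicative replicate-batch
effects by parametric empirical-Bayes shrinkage while protecting the
timepoint means — the same two-way decomposition ComBat uses: standardize
per protein, estimate per-(batch, protein) location/scale on the residuals,
shrink them toward batch-level priors, remove, and restore the protected
means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfoundedDesignError, ValidationError
from .io import IntensityMatrix


def glog(x: np.ndarray, c: float) -> np.ndarray:
    """Generalized log2; monotone in x, = log2(c/2) at x = 0."""
    return np.log2((x + np.sqrt(x * x + c * c)) / 2.0)


class GlogNormalizer(BaseEstimator, TransformerMixin):
    """Median-ratio calibration followed by a generalized-log2 transform.

    Follows the sklearn transformer protocol with samples in rows and
    proteins in columns.  ``fit`` learns the geometric-mean reference
    profile over proteins complete in every training sample and the glog
    offset ``c``; ``transform`` scales each sample to the reference and
    applies the glog.

    Parameters
    ----------
    offset_quantile : float
        Quantile of the calibrated training intensities used as the glog
        offset ``c`` (default 0.05, i.e. the 5th percentile).
    min_finite : int
        Minimum quantified proteins a sample must carry (default 3).

    Attributes
    ----------
    reference_ : ndarray of shape (n_proteins,)
        Geometric-mean reference profile (NaN where no complete row exists).
    offset_ : float
        The glog offset ``c``.
    scale_factors_ : ndarray
        Median-of-ratios factor per training sample.
    """

    def __init__(self, offset_quantile: float = 0.05, min_finite: int = 3):
        self.offset_quantile = offset_quantile
        self.min_finite = min_finite

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("expected a 2-D samples x proteins array")
        n_finite = np.isfinite(X).sum(axis=1)
        if (n_finite < self.min_finite).any():
            bad = int(np.argmin(n_finite))
            raise ValidationError(
                f"sample {bad} has {int(n_finite[bad])} finite values (< {self.min_finite})"
            )
        with np.errstate(invalid="ignore"):
            if np.any(X[np.isfinite(X)] <= 0):
                raise ValidationError("raw intensities must be positive")
        return X

    def _factors(self, X: np.ndarray) -> np.ndarray:
        ratios = X / self.reference_[None, :]
        return np.array([np.nanmedian(r[np.isfinite(r)]) if np.isfinite(r).any() else 1.0
                         for r in ratios])

    def fit(self, X, y=None):
        X = self._check(X)
        complete = np.isfinite(X).all(axis=0)
        if not complete.any():
            # fall back to per-protein geometric mean over available samples
            ref = np.exp(np.nanmean(np.log(X), axis=0))
        else:
            ref = np.full(X.shape[1], np.nan)
            ref[complete] = np.exp(np.mean(np.log(X[:, complete]), axis=0))
            # proteins with missing cells still need a reference for calibration ratios
            incomplete = ~complete
            if incomplete.any():
                ref[incomplete] = np.exp(np.nanmean(np.log(X[:, incomplete]), axis=0))
        self.reference_ = ref
        factors = self._factors(X)
        calibrated = X / factors[:, None]
        self.scale_factors_ = factors
        self.offset_ = float(np.nanquantile(calibrated, self.offset_quantile))
        return self

    def transform(self, X):
        X = self._check(X)
        factors = self._factors(X)
        return glog(X / factors[:, None], self.offset_)


def glog_normalize(m: IntensityMatrix, offset_quantile: float = 0.05) -> IntensityMatrix:
    """Normalize a raw IntensityMatrix; returns a matrix with scale_tag='glog'."""
    if m.scale_tag != "raw":
        raise ValidationError(f"glog_normalize expects raw scale, got {m.scale_tag!r}")
    est = GlogNormalizer(offset_quantile=offset_quantile)
    out = est.fit_transform(m.values.to_numpy().T).T
    return m.with_values(pd.DataFrame(out, index=m.values.index, columns=m.values.columns), "glog")


# ---------------------------------------------------------------------------
# batch correction


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = np.mean(delta_hat), np.var(delta_hat, ddof=1) if delta_hat.size > 1 else 0.0
    if s2 <= 0:
        return np.inf
    return (2 * s2 + m * m) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = np.mean(delta_hat), np.var(delta_hat, ddof=1) if delta_hat.size > 1 else 0.0
    if s2 <= 0:
        return np.inf
    return (m * s2 + m ** 3) / s2


class BatchCorrector(BaseEstimator, TransformerMixin):
    """ComBat-style parametric empirical-Bayes batch correction.

    ``fit_transform(X, batch=..., group=...)`` with X samples x proteins.
    ``group`` (the timepoint label per sample) is protected: its per-protein
    means are fitted first and restored after correction.  With a single
    batch the transform is the identity.

    Attributes
    ----------
    gamma_star_ : dict batch -> shrunken additive effect per protein
    delta_star_ : dict batch -> shrunken scale effect per protein
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol

    def fit_transform(self, X, y=None, *, batch, group):
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        group = np.asarray(group)
        if not (len(batch) == len(group) == X.shape[0]):
            raise ValidationError("batch/group labels must match the number of samples")
        batches = pd.unique(batch)
        self.batches_ = list(batches)
        if len(batches) < 2:
            self.gamma_star_, self.delta_star_ = {}, {}
            return X.copy()
        for b in batches:
            if len(np.unique(group[batch == b])) < 2:
                raise ConfoundedDesignError(
                    f"batch {b!r} is nested within a single group; batch and "
                    "group effects are confounded"
                )

        # protected group (timepoint) means per protein
        fitted = np.full_like(X, np.nan)
        for g in pd.unique(group):
            sel = group == g
            fitted[sel] = np.nanmean(X[sel], axis=0)[None, :]
        resid = X - fitted

        # pooled residual scale per protein; proteins whose residuals are at
        # float-rounding level (noise-free data) carry no batch information
        sigma = np.sqrt(np.nanmean(resid ** 2, axis=0))
        floor = 1e-8 * max(1.0, float(np.nanmax(np.abs(X))))
        degenerate = ~np.isfinite(sigma) | (sigma <= floor)
        sigma[degenerate] = 1.0
        Z = resid / sigma[None, :]
        Z[:, degenerate] = 0.0

        self.gamma_star_, self.delta_star_ = {}, {}
        correction = np.zeros_like(X)
        for b in batches:
            sel = batch == b
            Zb = Z[sel]
            n_b = np.isfinite(Zb).sum(axis=0).astype(float)
            gamma_hat = np.nanmean(Zb, axis=0)
            with np.errstate(invalid="ignore"):
                delta_hat = np.nanvar(Zb, axis=0, ddof=1)
            delta_hat = np.where(np.isfinite(delta_hat) & (delta_hat > 0), delta_hat, 1.0)

            gamma_bar = float(np.nanmean(gamma_hat))
            # prior variance of the true batch effects: spread of the observed
            # per-protein batch means minus their average sampling variance,
            # so a batch shift shared by all proteins shrinks fully to the
            # batch-level mean and no per-protein noise is removed
            raw_var = float(np.nanvar(gamma_hat, ddof=1)) if gamma_hat.size > 1 else 0.0
            sampling_var = float(np.nanmean(delta_hat / np.maximum(n_b, 1.0)))
            tau2 = max(raw_var - sampling_var, 0.0)
            a, bp = _aprior(delta_hat), _bprior(delta_hat)

            # same logic for the scale: only keep per-protein scale factors if
            # their spread exceeds the chi-square sampling spread
            delta_excess = (float(np.nanvar(delta_hat, ddof=1)) if delta_hat.size > 1 else 0.0) \
                - float(np.nanmean(2.0 * delta_hat ** 2 / np.maximum(n_b - 1.0, 1.0)))

            g_star = np.full_like(gamma_hat, gamma_bar)
            d_star = np.full_like(delta_hat, float(np.nanmean(delta_hat)))
            if delta_excess > 0 and np.isfinite(a) and np.isfinite(bp):
                ssq0 = np.nansum((Zb - g_star[None, :]) ** 2, axis=0)
                d_star = (0.5 * ssq0 + bp) / (n_b / 2.0 + a - 1.0)
            if tau2 > 0 and np.isfinite(a) and np.isfinite(bp):
                g_star = gamma_hat.copy()
                d_star = delta_hat.copy()
                for _ in range(self.max_iter):
                    g_new = (n_b * tau2 * gamma_hat + d_star * gamma_bar) / (n_b * tau2 + d_star)
                    ssq = np.nansum((Zb - g_new[None, :]) ** 2, axis=0)
                    d_new = (0.5 * ssq + bp) / (n_b / 2.0 + a - 1.0)
                    change = max(np.nanmax(np.abs(g_new - g_star)), np.nanmax(np.abs(d_new - d_star)))
                    g_star, d_star = g_new, d_new
                    if change < self.tol:
                        break
            self.gamma_star_[b] = g_star
            self.delta_star_[b] = d_star
            correction[sel] = (Z[sel] - g_star[None, :]) / np.sqrt(d_star)[None, :]

        return correction * sigma[None, :] + fitted

    def fit(self, X, y=None, **kw):  # pragma: no cover - fit_transform is the API
        self.fit_transform(X, y, **kw)
        return self


def batch_correct(m: IntensityMatrix) -> IntensityMatrix:
    """Remove replicate-batch effects from a glog-scale matrix."""
    if m.scale_tag != "glog":
        raise ValidationError(f"batch_correct expects glog scale, got {m.scale_tag!r}")
    d = m.design.frame.loc[list(m.values.columns)]
    est = BatchCorrector()
    out = est.fit_transform(
        m.values.to_numpy().T, batch=d["batch"].to_numpy(), group=d["timepoint"].to_numpy()
    ).T
    return m.with_values(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), "batch_corrected"
    )
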