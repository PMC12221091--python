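"""Per-timepoint differential abundance with empirical-Bayes moderated
t-statistics.

Model: for each protein g, glog-scale abundances are fitted by ordinary
least squares on timepoint means.  The residual variance s_g^2 (d_g degrees
of freedom) is shrunk toward a prior (d0, s0^2) estimated by moment-matching
the distribution of log s_g^2 — the scaled inverse-chi-square hierarchy of
limma's eBayes:

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t for contrast Tk vs the reference timepoint is

    t_gk = log2fc_gk / (s~_g * sqrt(1/n_gk + 1/n_g0)),   df = d0 + d_g.

Significance calls follow the two-part rule: Benjamini-Hochberg adjusted
p below ``alpha`` AND fold change outside [fc_down, fc_up].  By default
``alpha`` is applied to the ADJUSTED p (the DEP convention) and BH runs
within each contrast separately; both are switchable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import polygamma, psi
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import IntensityMatrix

# reason codes for missing statistics
TOO_FEW_REF = "too_few_replicates_at_reference"
TOO_FEW_CONTRAST = "too_few_replicates_at_contrast"
NO_RESIDUAL_DF = "no_residual_df"


@dataclass
class SignificanceThresholds:
    """Two-part significance rule: adjusted-p cutoff and fold-change bounds."""

    alpha: float = 0.1
    fc_up: float = 1.0001
    adjust_method: str = "BH"
    use_adjusted_p: bool = True
    pool_contrasts: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.fc_up <= 1:
            raise ValidationError("fc_up must exceed 1")

    @property
    def fc_down(self) -> float:
        return 1.0 / self.fc_up

    @property
    def log2_fc_up(self) -> float:
        return math.log2(self.fc_up)


# ---------------------------------------------------------------------------
# hyperparameter estimation (limma's fitFDist by moment matching)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate (d0, s0^2) from observed residual variances and their df.

    Moment-matches the distribution of e_g = log s_g^2 - psi(d_g/2) +
    log(d_g/2): under the hierarchy its mean is log s0^2 - psi(d0/2) +
    log(d0/2) and its excess variance over trigamma(d_g/2) is
    trigamma(d0/2).  Returns d0 = inf when the observed spread does not
    exceed the chi-square sampling spread (e.g. all variances identical).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 >= 0) & np.isfinite(df) & (df > 0)
    if ok.sum() < 2:
        raise ValidationError("need >=2 residual variances to estimate the prior")
    if np.ptp(s2[ok]) == 0:
        # all variances identical (possibly 0): no excess spread to shrink
        return np.inf, float(s2[ok][0])
    pos = ok & (s2 > 0)
    if pos.sum() < 2:
        raise ValidationError("need >=2 positive residual variances to estimate the prior")
    s2, df = s2[pos], df[pos]
    z = np.log(s2)
    e = z - psi(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, df / 2.0)))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + psi(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def posterior_variance(s2: np.ndarray, df: np.ndarray, d0: float, s0_sq: float) -> np.ndarray:
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


@dataclass
class ModeratedFitParams:
    """Empirical-Bayes variance hyperparameters and per-protein posteriors."""

    d0: float
    s0_sq: float
    resid_df: pd.Series
    posterior_s2: pd.Series


# ---------------------------------------------------------------------------
# the estimator


class ModeratedDE(BaseEstimator):
    """Empirical-Bayes moderated t-statistics for timepoint contrasts.

    sklearn-style estimator: ``fit(X, timepoint=...)`` with X samples x
    proteins (glog scale, NaN = missing) computes per-protein timepoint
    means, residual variances, the shrinkage prior and one contrast per
    non-reference timepoint.

    Parameters
    ----------
    reference_timepoint : int
        The baseline condition (default 0, the zoospore stage).
    min_replicates : int
        Minimum quantified replicates a timepoint needs for a contrast
        (default 2); below it the statistic is set missing with a reason code.

    Attributes
    ----------
    prior_df_ : float               (d0; np.inf in the degenerate equal-variance case)
    prior_var_ : float              (s0^2)
    resid_df_ : ndarray             per-protein residual df
    posterior_var_ : ndarray        shrunken variances s~_g^2
    results_ : DataFrame            long table protein x contrast with log2fc,
                                    moderated_t, p_raw and a reason column
    """

    def __init__(self, reference_timepoint: int = 0, min_replicates: int = 2):
        self.reference_timepoint = reference_timepoint
        self.min_replicates = min_replicates

    def fit(self, X, y=None, *, timepoint, protein_ids=None):
        X = np.asarray(X, dtype=float)
        timepoint = np.asarray(timepoint)
        if X.ndim != 2 or len(timepoint) != X.shape[0]:
            raise ValidationError("X must be samples x proteins with one timepoint per sample")
        tps = sorted(pd.unique(timepoint).tolist())
        if self.reference_timepoint not in tps:
            raise ValidationError(f"reference timepoint {self.reference_timepoint} absent")
        if protein_ids is None:
            protein_ids = [f"p{i}" for i in range(X.shape[1])]

        n_prot = X.shape[1]
        finite = np.isfinite(X)
        means = np.full((len(tps), n_prot), np.nan)
        counts = np.zeros((len(tps), n_prot))
        rss = np.zeros(n_prot)
        for i, t in enumerate(tps):
            sel = timepoint == t
            block = X[sel]
            counts[i] = np.isfinite(block).sum(axis=0)
            with np.errstate(invalid="ignore"):
                means[i] = np.where(counts[i] > 0, np.nanmean(block, axis=0), np.nan)
            resid = block - means[i][None, :]
            rss += np.nansum(resid * resid, axis=0)

        n_obs = finite.sum(axis=0).astype(float)
        n_groups = (counts > 0).sum(axis=0).astype(float)
        dg = n_obs - n_groups
        with np.errstate(divide="ignore", invalid="ignore"):
            s2 = np.where(dg > 0, rss / np.where(dg > 0, dg, 1.0), np.nan)

        d0, s0_sq = estimate_variance_prior(s2, dg)
        s2_post = posterior_variance(np.where(np.isfinite(s2), s2, s0_sq), dg, d0, s0_sq)

        ref_i = tps.index(self.reference_timepoint)
        rows = []
        for i, t in enumerate(tps):
            if t == self.reference_timepoint:
                continue
            log2fc = means[i] - means[ref_i]
            vk = 1.0 / np.maximum(counts[i], 1) + 1.0 / np.maximum(counts[ref_i], 1)
            se = np.sqrt(s2_post * vk)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = np.where((se == 0) & (log2fc == 0), 0.0, log2fc / se)
            df_total = np.where(np.isinf(d0), np.inf, d0 + dg)
            p = np.where(
                np.isinf(df_total),
                2.0 * t_dist.sf(np.abs(tstat), 1e12),
                2.0 * t_dist.sf(np.abs(tstat), np.where(df_total > 0, df_total, 1.0)),
            )
            reason = np.full(n_prot, "", dtype=object)
            bad_ref = counts[ref_i] < self.min_replicates
            bad_con = counts[i] < self.min_replicates
            bad_df = (dg <= 0) & ~np.isinf(d0)
            reason[bad_df] = NO_RESIDUAL_DF
            reason[bad_con] = TOO_FEW_CONTRAST
            reason[bad_ref] = TOO_FEW_REF
            drop = bad_ref | bad_con | bad_df
            log2fc = np.where(drop, np.nan, log2fc)
            tstat = np.where(drop, np.nan, tstat)
            p = np.where(drop, np.nan, p)
            rows.append(pd.DataFrame({
                "protein_id": protein_ids,
                "contrast": f"T{t}",
                "log2fc": log2fc,
                "moderated_t": tstat,
                "p_raw": np.clip(p, 0.0, 1.0),
                "reason": reason,
            }))

        self.prior_df_ = d0
        self.prior_var_ = s0_sq
        self.resid_df_ = dg
        self.sample_var_ = s2
        self.posterior_var_ = s2_post
        self.timepoints_ = tps
        self.results_ = pd.concat(rows, ignore_index=True)
        return self


def fit_moderated(m: IntensityMatrix, reference_timepoint: int = 0,
                  min_replicates: int = 2) -> tuple[ModeratedFitParams, pd.DataFrame]:
    """Moderated-t contrasts of every timepoint against the reference."""
    if m.scale_tag == "raw":
        raise ValidationError("fit_moderated expects glog or batch_corrected scale")
    est = ModeratedDE(reference_timepoint=reference_timepoint, min_replicates=min_replicates)
    tp = m.design.frame.loc[list(m.values.columns), "timepoint"].to_numpy()
    est.fit(m.values.to_numpy().T, timepoint=tp, protein_ids=m.protein_ids)
    params = ModeratedFitParams(
        d0=est.prior_df_,
        s0_sq=est.prior_var_,
        resid_df=pd.Series(est.resid_df_, index=m.protein_ids),
        posterior_s2=pd.Series(est.posterior_var_, index=m.protein_ids),
    )
    return params, est.results_


# ---------------------------------------------------------------------------
# multiple testing and calls


def adjust_and_call(table: pd.DataFrame,
                    thresholds: SignificanceThresholds | None = None) -> pd.DataFrame:
    """Add BH-adjusted p-values, significance calls and directions.

    BH runs within each contrast separately by default
    (``thresholds.pool_contrasts`` pools the four families).  A protein is
    significant iff its (adjusted or raw, per ``use_adjusted_p``) p is below
    ``alpha`` and |log2fc| exceeds log2(fc_up).
    """
    thr = thresholds or SignificanceThresholds()
    out = table.copy()
    out["p_adj"] = np.nan
    groups = [out.index] if thr.pool_contrasts else [
        out.index[out["contrast"] == c] for c in out["contrast"].unique()
    ]
    for idx in groups:
        p = out.loc[idx, "p_raw"]
        ok = p.notna()
        if ok.any():
            out.loc[idx[ok.to_numpy()], "p_adj"] = multipletests(
                p[ok].to_numpy(), method="fdr_bh")[1]
    p_for_call = out["p_adj"] if thr.use_adjusted_p else out["p_raw"]
    lfc = out["log2fc"]
    up = (p_for_call < thr.alpha) & (lfc > thr.log2_fc_up)
    down = (p_for_call < thr.alpha) & (lfc < -thr.log2_fc_up)
    out["significant"] = (up | down).fillna(False)
    out["direction"] = np.select([up.fillna(False), down.fillna(False)], ["up", "down"], "none")
    return out


@dataclass
class DESummary:
    """Per-protein and global accounting of significance calls."""

    up_timepoints: dict[str, set[str]]
    down_timepoints: dict[str, set[str]]
    n_up: int
    n_down: int
    n_unique_de: int
    n_both_directions: int
    per_timepoint_up: dict[str, int]
    per_timepoint_down: dict[str, int]
    exclusively_up_at: dict[str, int] = field(default_factory=dict)
    down_at_all: int = 0
    up_at_all: int = 0

    def upregulated_at(self, protein_id: str) -> set[str]:
        return self.up_timepoints.get(protein_id, set())


def summarize_de(table: pd.DataFrame) -> DESummary:
    """Collapse per-contrast calls into per-protein direction sets and the
    global pattern counts (n up/down at >=1 timepoint, exclusively-up-at-Tk,
    down-at-all-timepoints, per-timepoint totals)."""
    contrasts = list(table["contrast"].unique())
    up_tp: dict[str, set[str]] = {}
    down_tp: dict[str, set[str]] = {}
    sig = table[table["significant"]]
    for _, row in sig.iterrows():
        d = up_tp if row["direction"] == "up" else down_tp
        d.setdefault(row["protein_id"], set()).add(row["contrast"])
    up_set, down_set = set(up_tp), set(down_tp)
    per_up = {c: int(((sig["contrast"] == c) & (sig["direction"] == "up")).sum())
              for c in contrasts}
    per_down = {c: int(((sig["contrast"] == c) & (sig["direction"] == "down")).sum())
                for c in contrasts}
    exclusively_up = {
        c: sum(1 for p, s in up_tp.items() if s == {c} and p not in down_set)
        for c in contrasts
    }
    all_c = set(contrasts)
    return DESummary(
        up_timepoints=up_tp,
        down_timepoints=down_tp,
        n_up=len(up_set),
        n_down=len(down_set),
        n_unique_de=len(up_set | down_set),
        n_both_directions=len(up_set & down_set),
        per_timepoint_up=per_up,
        per_timepoint_down=per_down,
        exclusively_up_at=exclusively_up,
        down_at_all=sum(1 for s in down_tp.values() if s == all_c),
        up_at_all=sum(1 for s in up_tp.values() if s == all_c),
    )
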