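import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from labyprot.de import (ModeratedDE, SignificanceThresholds, adjust_and_call,
                         estimate_variance_prior, fit_moderated, posterior_variance,
                         summarize_de, TOO_FEW_CONTRAST, TOO_FEW_REF)
from labyprot.errors import ValidationError
from tests.conftest import make_matrix


def _limma_fixture():
    """Heteroskedastic 60-protein x 15-sample matrix; regenerated bit-for-bit
    from the seed that produced the frozen external reference values."""
    rng = np.random.default_rng(20250930)
    n, reps, tps = 60, 3, [0, 2, 4, 6, 8]
    base = rng.uniform(14, 20, size=n)
    sig = np.sqrt(0.5 * 4 / rng.chisquare(4, size=n))
    X = np.empty((n, len(tps) * reps))
    cols = []
    j = 0
    for t in tps:
        for r in range(reps):
            X[:, j] = base + 0 * rng.binomial(1, 0, size=n) + rng.normal(0, sig)
            cols.append(f"T{t}_{r + 1}")
            j += 1
    for j, c in enumerate(cols):
        if int(c.split("_")[0][1:]) >= 6:
            X[:5, j] += 0.8
    return pd.DataFrame(X, index=[f"P{i:03d}" for i in range(n)], columns=cols)


# reference values computed once with Bioconductor limma (lmFit + eBayes,
# group-means design, contrasts Tk - T0) on the fixture above
LIMMA_D0 = 3.04996081
LIMMA_S0SQ = 0.434249666
LIMMA_T = {
    "P000": [1.566455782, -0.5491372499, 3.556939281, 2.009311385],
    "P003": [1.253587311, 1.095915535, 0.559610775, 1.193154958],
    "P017": [0.5230301636, -1.32955444, -0.4615607916, 0.828530748],
    "P042": [-0.3148783016, -2.330014222, -0.2103070516, -1.030531723],
}
LIMMA_P = {
    "P000": [0.1411611156, 0.5921839163, 0.003490068035, 0.06565144311],
    "P042": [0.7578321412, 0.03649296528, 0.8366760755, 0.3214825171],
}


@pytest.fixture(scope="module")
def fit():
    X = _limma_fixture()
    tp = [int(c.split("_")[0][1:]) for c in X.columns]
    return ModeratedDE().fit(X.to_numpy().T, timepoint=tp,
                             protein_ids=list(X.index))


class TestModeratedFitAgainstLimma:

    def test_hyperparameters(self, fit):
        assert fit.prior_df_ == pytest.approx(LIMMA_D0, abs=5e-7)
        assert fit.prior_var_ == pytest.approx(LIMMA_S0SQ, abs=5e-8)

    @pytest.mark.parametrize("pid", list(LIMMA_T))
    def test_moderated_t(self, fit, pid):
        r = fit.results_[fit.results_["protein_id"] == pid]
        assert np.allclose(r["moderated_t"], LIMMA_T[pid], atol=5e-7)

    @pytest.mark.parametrize("pid", list(LIMMA_P))
    def test_p_values(self, fit, pid):
        r = fit.results_[fit.results_["protein_id"] == pid]
        assert np.allclose(r["p_raw"], LIMMA_P[pid], atol=5e-9)


class TestVariancePrior:
    def test_identical_variances_collapse_to_infinite_prior_df(self):
        d0, s0 = estimate_variance_prior(np.full(30, 1.7), np.full(30, 10.0))
        assert np.isinf(d0) and s0 == pytest.approx(1.7)
        post = posterior_variance(np.full(30, 1.7), np.full(30, 10.0), d0, s0)
        assert np.allclose(post, 1.7)

    def test_recovers_planted_hyperparameters(self):
        """Scaled inverse-chi-square simulation with d0=4, s0^2=2."""
        rng = np.random.default_rng(5)
        d0_true, s0_true, dg, n = 4.0, 2.0, 10, 2000
        sig2 = d0_true * s0_true / chi2.rvs(d0_true, size=n, random_state=rng)
        s2 = sig2 * chi2.rvs(dg, size=n, random_state=rng) / dg
        d0, s0 = estimate_variance_prior(s2, np.full(n, dg))
        assert abs(d0 - d0_true) / d0_true < 0.2
        assert abs(s0 - s0_true) / s0_true < 0.1

    def test_posterior_between_sample_and_prior(self):
        rng = np.random.default_rng(7)
        s2 = rng.uniform(0.1, 5.0, size=200)
        dg = np.full(200, 8.0)
        d0, s0 = estimate_variance_prior(s2, dg)
        post = posterior_variance(s2, dg, d0, s0)
        lo, hi = np.minimum(s2, s0), np.maximum(s2, s0)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_infinite_prior_limit_equals_pooled_variance_t(self):
        """As d0 -> inf every posterior variance equals s0^2 exactly."""
        rng = np.random.default_rng(9)
        s2 = rng.uniform(0.5, 2.0, size=50)
        dg = np.full(50, 10.0)
        post = posterior_variance(s2, dg, np.inf, 1.23)
        assert np.allclose(post, 1.23, atol=1e-10)


class TestContrasts:
    def test_zero_effect_protein_has_t0_p1(self):
        # identical means at every timepoint; other proteins supply variance
        rng = np.random.default_rng(3)
        X = rng.normal(16, 0.5, size=(20, 15))
        X[0] = np.tile([15.0, 16.0, 17.0], 5)  # same triple at every timepoint
        m = make_matrix(X)
        _, table = fit_moderated(m)
        r0 = table[table["protein_id"] == "P0"]
        assert np.allclose(r0["log2fc"], 0.0, atol=1e-12)
        assert np.allclose(r0["moderated_t"], 0.0, atol=1e-12)
        assert np.allclose(r0["p_raw"], 1.0)

    def test_too_few_replicates_flagged_not_crashed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(16, 0.5, size=(10, 15))
        m = make_matrix(X)
        m.values.iloc[0, [0, 1]] = np.nan           # reference timepoint thinned
        m.values.iloc[1, [3, 4]] = np.nan           # T2 thinned
        _, table = fit_moderated(m)
        r0 = table[(table["protein_id"] == "P0")]
        assert (r0["reason"] == TOO_FEW_REF).all()
        assert r0["p_raw"].isna().all()
        r1 = table[(table["protein_id"] == "P1") & (table["contrast"] == "T2")]
        assert (r1["reason"] == TOO_FEW_CONTRAST).all()

    def test_reference_must_be_present(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(16, 0.5, size=(10, 15)))
        with pytest.raises(ValidationError, match="reference"):
            fit_moderated(m, reference_timepoint=99)


class TestAdjustAndCall:
    @staticmethod
    def _table(p_values, log2fc=None, contrast="T2"):
        n = len(p_values)
        return pd.DataFrame({
            "protein_id": [f"p{i}" for i in range(n)],
            "contrast": contrast,
            "log2fc": log2fc if log2fc is not None else np.ones(n),
            "moderated_t": np.ones(n),
            "p_raw": p_values,
            "reason": "",
        })

    def test_bh_step_up_by_hand(self):
        out = adjust_and_call(self._table([0.01, 0.02, 0.03]))
        assert np.allclose(out["p_adj"], [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        out = adjust_and_call(self._table([0.2]))
        assert out["p_adj"].iloc[0] == pytest.approx(0.2)

    def test_zero_fold_change_never_significant(self):
        out = adjust_and_call(self._table([1e-8], log2fc=[0.0]))
        assert not out["significant"].iloc[0]
        assert out["direction"].iloc[0] == "none"

    def test_direction_tracks_sign(self):
        out = adjust_and_call(self._table([1e-4, 1e-4], log2fc=[2.0, -2.0]))
        assert out["direction"].tolist() == ["up", "down"]

    def test_fc_bounds_are_reciprocal(self):
        thr = SignificanceThresholds(fc_up=1.5)
        assert thr.fc_down == pytest.approx(1 / 1.5, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40))
    def test_bh_monotone_in_raw_p(self, ps):
        out = adjust_and_call(self._table(ps))
        s = out.sort_values("p_raw")
        assert np.all(np.diff(s["p_adj"]) >= -1e-12)


class TestSummarize:
    @staticmethod
    def _calls(rows):
        return pd.DataFrame(rows, columns=["protein_id", "contrast", "log2fc",
                                           "significant", "direction"])

    def test_exclusive_up_at_t2_definition(self):
        calls = self._calls([
            ("a", "T2", 1.0, True, "up"), ("a", "T4", 0.1, False, "none"),
            ("b", "T2", 1.0, True, "up"), ("b", "T6", 1.0, True, "up"),
        ])
        s = summarize_de(calls)
        assert s.exclusively_up_at["T2"] == 1
        assert s.n_up == 2

    def test_no_calls_all_zero(self):
        calls = self._calls([("a", "T2", 0.0, False, "none")])
        s = summarize_de(calls)
        assert (s.n_up, s.n_down, s.n_unique_de, s.down_at_all) == (0, 0, 0, 0)

    def test_counts_match_bruteforce_on_random_calls(self):
        rng = np.random.default_rng(11)
        rows = []
        proteins = [f"p{i}" for i in range(40)]
        for p in proteins:
            for c in ("T2", "T4", "T6", "T8"):
                sig = bool(rng.uniform() < 0.3)
                direction = rng.choice(["up", "down"]) if sig else "none"
                rows.append((p, c, 1.0 if direction == "up" else -1.0, sig, direction))
        s = summarize_de(self._calls(rows))
        # brute-force recount straight from the rows
        by = {}
        for p, c, _, sig, d in rows:
            if sig:
                by.setdefault(p, {}).setdefault(d, set()).add(c)
        n_up = sum(1 for v in by.values() if "up" in v)
        n_down = sum(1 for v in by.values() if "down" in v)
        down_all = sum(1 for v in by.values() if v.get("down") == {"T2", "T4", "T6", "T8"})
        assert s.n_up == n_up and s.n_down == n_down
        assert s.n_unique_de == len(by)
        assert s.down_at_all == down_all
        assert s.n_both_directions == sum(1 for v in by.values() if len(v) == 2)
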