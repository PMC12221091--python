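import numpy as np
import pandas as pd
import pytest

from labyprot.de import DESummary, adjust_and_call, fit_moderated, summarize_de
from labyprot.errors import ValidationError
from labyprot.normalize import batch_correct, glog_normalize
from labyprot.screen import (BINS, LineageCall, ScreenConfig, bin_deltas,
                             classify_lineage, combine_candidates,
                             concordance_crosstab, orthogroup_filter,
                             select_top_hits)
from labyprot.simulate import SimulationConfig, simulate_all
from tests.test_merge import hit_rows


def classed(rows):
    """rows: (query, subject, taxon_class, bitscore, evalue, pident)"""
    out = hit_rows([(q, s, b, e, p) for q, s, _, b, e, p in rows])
    out["taxon_class"] = [r[2] for r in rows]
    return out


def summary_up(up: dict[str, set]) -> DESummary:
    return DESummary(up_timepoints=up, down_timepoints={}, n_up=len(up), n_down=0,
                     n_unique_de=len(up), n_both_directions=0,
                     per_timepoint_up={}, per_timepoint_down={})


class TestSelectTopHits:
    def test_keeps_five_smallest_evalues(self):
        rows = [("q", f"s{i}", 100 - i, 10.0 ** -(60 - i), 80) for i in range(7)]
        top = select_top_hits(hit_rows(rows), 5)
        assert len(top) == 5
        assert set(top["subject"]) == {f"s{i}" for i in range(5)}

    def test_evalue_tie_prefers_higher_pident(self):
        rows = [("q", "lo", 50, 1e-10, 70), ("q", "hi", 50, 1e-10, 95)]
        top = select_top_hits(hit_rows(rows), 1)
        assert top["subject"].tolist() == ["hi"]

    def test_matches_sort_then_truncate_oracle(self):
        rng = np.random.default_rng(41)
        rows = [(f"q{rng.integers(6)}", f"s{i}", float(rng.integers(30, 200)),
                 10.0 ** -float(rng.integers(3, 50)), float(rng.integers(20, 99)))
                for i in range(200)]
        hits = hit_rows(rows)
        top = select_top_hits(hits, 5)
        oracle = (hits.sort_values(["evalue", "pident", "bitscore", "subject"],
                                   ascending=[True, False, False, True])
                  .groupby("query").head(5))
        for q in hits["query"].unique():
            got = top[top["query"] == q]["subject"].tolist()
            want = oracle[oracle["query"] == q]["subject"].tolist()
            assert sorted(got) == sorted(want)


class TestClassifyLineage:
    def test_absent_query_is_aurli_only(self):
        calls = classify_lineage(classed([]), ["ghost"])
        assert calls[0].group == "aurli_only"

    def test_only_hondaea_hits_is_laby_only(self):
        hits = classed([("q", "h1", "laby_hondaea", 100, 1e-30, 80)])
        assert classify_lineage(hits, ["q"])[0].group == "laby_only"

    def test_only_other_hits_is_stramenopile_group(self):
        hits = classed([("q", f"o{i}", "other_stramenopile", 100 + i, 1e-30, 80)
                        for i in range(5)])
        assert classify_lineage(hits, ["q"])[0].group == "stramenopile_not_hondaea"

    def test_both_with_delta_arithmetic(self):
        hits = classed([
            ("q", "h1", "laby_hondaea", 120, 1e-40, 85),
            ("q", "o1", "other_stramenopile", 90, 1e-25, 60),
        ])
        call = classify_lineage(hits, ["q"])[0]
        assert call.group == "both"
        assert call.delta_bitscore == pytest.approx(30.0)
        assert call.delta_pident == pytest.approx(25.0)
        assert call.delta_log10_evalue == pytest.approx(40 - 25)

    def test_unknown_taxon_class_rejected(self):
        hits = classed([("q", "x", "martian", 10, 1e-3, 50)])
        with pytest.raises(ValidationError, match="martian"):
            classify_lineage(hits, ["q"])

    def test_partition_covers_every_query_once(self):
        rng = np.random.default_rng(43)
        rows = []
        queries = [f"q{i}" for i in range(60)]
        for q in queries:
            for j in range(rng.integers(0, 6)):
                cls = rng.choice(["laby_hondaea", "other_stramenopile"])
                rows.append((q, f"{q}s{j}", cls, float(rng.integers(30, 200)),
                             10.0 ** -float(rng.integers(3, 50)), 70.0))
        hits = classed(rows) if rows else classed([])
        calls = classify_lineage(select_top_hits(hits, 5), queries)
        assert len(calls) == len(queries)
        assert {c.query for c in calls} == set(queries)
        assert all(c.group in ("aurli_only", "laby_only",
                               "stramenopile_not_hondaea", "both") for c in calls)


class TestBinDeltas:
    @staticmethod
    def _both(deltas):
        return [LineageCall(f"q{i}", "both", delta_bitscore=float(d))
                for i, d in enumerate(deltas)]

    def test_top_bin_boundary_on_1_to_100(self):
        calls = bin_deltas(self._both(range(1, 101)))
        by_delta = {c.delta_bitscore: c.quantile_bin for c in calls}
        assert by_delta[99.0] == "Q975_100" and by_delta[100.0] == "Q975_100"
        assert by_delta[97.0] == "Q95_975"
        assert by_delta[85.0] == "Q0_85"
        assert by_delta[1.0] == "Q0_85"

    def test_single_delta_is_its_own_maximum(self):
        calls = bin_deltas(self._both([7.5]))
        assert calls[0].quantile_bin == "Q975_100"

    def test_all_equal_is_degenerate_and_warned(self):
        with pytest.warns(UserWarning, match="degenerate"):
            calls = bin_deltas(self._both([3.0, 3.0, 3.0]))
        assert len({c.quantile_bin for c in calls}) == 1

    def test_no_both_calls_warns_and_passes_through(self):
        calls = [LineageCall("q", "laby_only")]
        with pytest.warns(UserWarning, match="nothing to bin"):
            out = bin_deltas(calls)
        assert out[0].quantile_bin is None

    def test_bin_monotone_in_delta(self):
        rng = np.random.default_rng(47)
        calls = bin_deltas(self._both(rng.normal(0, 20, size=200)))
        rank = {b: i for i, b in enumerate(BINS)}
        s = sorted(calls, key=lambda c: c.delta_bitscore)
        bins = [rank[c.quantile_bin] for c in s]
        assert all(b2 >= b1 for b1, b2 in zip(bins, bins[1:]))


class TestOrthogroupFilter:
    @staticmethod
    def _table(rows):
        """rows: og -> {genome: [ids]}"""
        from labyprot.io import OrthogroupTable
        lineages = {"Aurli": "labyrinthulomycota", "Honfer": "labyrinthulomycota",
                    "Aplke": "labyrinthulomycota", "Sacce": "other", "Phatri": "other"}
        members = {og: {g: tuple(v) for g, v in per.items()} for og, per in rows.items()}
        counts = pd.DataFrame.from_dict(
            {og: {g: len(v) for g, v in per.items()} for og, per in rows.items()},
            orient="index").reindex(columns=list(lineages), fill_value=0).fillna(0).astype(int)
        return OrthogroupTable(counts, members, lineages)

    def test_passing_protein(self):
        og = self._table({"OG1": {"Aurli": ["a1"], "Honfer": ["h1"]}})
        flags = orthogroup_filter(og, summary_up({"a1": {"T6"}}), ScreenConfig(), ["a1"])
        assert flags["a1"]["passed"]
        assert all(flags["a1"][f"cond{i}_{n}"] for i, n in
                   [(1, "min_laby"), (2, "max_nonlaby"), (3, "upregulated"), (4, "hondaea_copy")])

    def test_two_nonlaby_genomes_fail_condition2_only(self):
        og = self._table({"OG1": {"Aurli": ["a1"], "Honfer": ["h1"],
                                  "Sacce": ["s1"], "Phatri": ["p1"]}})
        flags = orthogroup_filter(og, summary_up({"a1": {"T6"}}), ScreenConfig(), ["a1"])
        f = flags["a1"]
        assert not f["passed"] and not f["cond2_max_nonlaby"]
        assert f["cond1_min_laby"] and f["cond3_upregulated"] and f["cond4_hondaea_copy"]

    def test_up_at_t2_only_fails_condition3_only(self):
        og = self._table({"OG1": {"Aurli": ["a1"], "Honfer": ["h1"]}})
        flags = orthogroup_filter(og, summary_up({"a1": {"T2"}}), ScreenConfig(), ["a1"])
        f = flags["a1"]
        assert not f["passed"] and not f["cond3_upregulated"]
        assert f["cond1_min_laby"] and f["cond2_max_nonlaby"] and f["cond4_hondaea_copy"]

    def test_no_orthogroup_fails_presence_conditions(self):
        og = self._table({})
        flags = orthogroup_filter(og, summary_up({"a1": {"T6"}}), ScreenConfig(), ["a1"])
        assert not flags["a1"]["passed"] and not flags["a1"]["cond1_min_laby"]

    def test_conservation_flag_needs_three_laby_genomes(self):
        og = self._table({"OG1": {"Aurli": ["a1"], "Honfer": ["h1"], "Aplke": ["x1"]},
                          "OG2": {"Aurli": ["a2"], "Honfer": ["h2"]}})
        flags = orthogroup_filter(og, summary_up({}), ScreenConfig(), ["a1", "a2"])
        assert flags["a1"]["conserved"] and not flags["a2"]["conserved"]


class TestCombineCandidates:
    def test_orthogroup_only_route(self):
        calls = [LineageCall("a1", "both", delta_bitscore=0.0, quantile_bin="Q0_85")]
        og_flags = {"a1": {"passed": True}}
        recs = combine_candidates(calls, og_flags, summary_up({"a1": {"T6"}}),
                                  ScreenConfig())
        assert len(recs) == 1 and recs[0].passed_orthogroup and not recs[0].passed_blast

    def test_laby_only_blast_route(self):
        calls = [LineageCall("a1", "laby_only")]
        recs = combine_candidates(calls, {}, summary_up({"a1": {"T6"}}), ScreenConfig())
        assert len(recs) == 1 and recs[0].passed_blast

    def test_not_upregulated_is_never_candidate(self):
        calls = [LineageCall("a1", "laby_only")]
        assert combine_candidates(calls, {"a1": {"passed": True}},
                                  summary_up({"a1": {"T2"}}), ScreenConfig()) == []

    def test_aurli_only_excluded_by_default_switchable(self):
        calls = [LineageCall("a1", "aurli_only")]
        up = summary_up({"a1": {"T8"}})
        assert combine_candidates(calls, {}, up, ScreenConfig()) == []
        cfg = ScreenConfig(include_aurli_only=True)
        assert len(combine_candidates(calls, {}, up, cfg)) == 1


class TestConcordance:
    def test_identical_calls_on_diagonal(self):
        calls = {"g1": "up", "g2": "down", "g3": "up"}
        tab = concordance_crosstab(calls, calls)
        assert tab.loc["up", "up"] == 2 and tab.loc["down", "down"] == 1
        assert tab.loc["up", "down"] == 0 and tab.loc["down", "up"] == 0

    def test_toy_fixture_hand_count(self):
        prot = {"g1": "up", "g2": "up", "g3": "down", "g4": "down", "g5": "up", "g6": "down"}
        trans = {"g1": "up", "g2": "down", "g3": "down", "g4": "up", "g5": "up", "g7": "up"}
        tab = concordance_crosstab(prot, trans)
        assert tab.to_numpy().sum() == 5  # g6 and g7 are not shared
        assert tab.loc["up", "up"] == 2
        assert tab.loc["up", "down"] == 1
        assert tab.loc["down", "up"] == 1
        assert tab.loc["down", "down"] == 1

    def test_empty_intersection_all_zero(self):
        tab = concordance_crosstab({"a": "up"}, {"b": "down"})
        assert (tab.to_numpy() == 0).all()

    def test_bad_direction_rejected(self):
        with pytest.raises(ValidationError):
            concordance_crosstab({"a": "sideways"}, {"a": "up"})


class TestEndToEndScreen:
    @staticmethod
    def _run(noise_sd, bit_noise, seed):
        cfg = SimulationConfig(n_proteins=700, noise_sd_log2=noise_sd,
                               bitscore_noise_sd=bit_noise, missing_rate=0.0,
                               seed=seed)
        m, truth, hits, og, _, _ = simulate_all(cfg)
        calls = adjust_and_call(fit_moderated(batch_correct(glog_normalize(m)))[1])
        summary = summarize_de(calls)
        sc = ScreenConfig()
        sh = hits.screen_hits.copy()
        sh["taxon_class"] = sh["subject"].map(hits.taxon_map)
        lineage_calls = bin_deltas(classify_lineage(select_top_hits(sh, sc.top_n),
                                                    m.protein_ids, sc.top_n))
        flags = orthogroup_filter(og, summary, sc, m.protein_ids)
        recs = combine_candidates(lineage_calls, flags, summary, sc)
        return truth, {r.protein_id for r in recs}

    def test_noise_free_precision_and_recall_are_one(self):
        truth, got = self._run(0.0, 0.0, 51)
        assert got == set(truth.planted_candidates())

    def test_score_noise_keeps_sensitivity_and_blocks_decoys(self):
        sens = []
        for seed in range(6):
            truth, got = self._run(0.25, 5.0, 60 + seed)
            planted = set(truth.planted_candidates())
            sens.append(len(got & planted) / len(planted))
            tf = truth.frame
            decoys = set(tf.index[(tf["lineage_class"] == "broad")
                                  & tf["archetype"].isin(("C3", "C4"))])
            assert not (got & decoys)
        assert np.mean(sens) >= 0.95
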