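import numpy as np
import pandas as pd
import pytest

import hwr_community.selection as sel
from hwr_community.linkage import quintile_matrix
from hwr_community.models import belsley_diagnostics, quintile_design
from hwr_community.selection import (
    SelectionConfig,
    eliminate_collinear,
    fit_final_model,
    sequential_domain_selection,
)


class _CannedFit:
    """Stand-in model fit returning scripted adjusted R² per variable set."""

    def __init__(self, r2_table, variables):
        self.adjusted_r2 = r2_table[frozenset(variables)]
        self.r2 = self.adjusted_r2
        self.variables = variables

    def wald_p(self, variable):
        return 0.5


class TestSequentialRule:
    def _run_with_canned_r2(self, monkeypatch, r2_table, importance):
        domain_of = pd.Series("d1", index=importance.index)
        quintiles = pd.DataFrame(
            {v: pd.array([1, 2, 3, 4, 5] * 4, dtype="Int64") for v in importance.index}
        )
        outcome = pd.Series(np.zeros(20), name="y")
        weights = pd.Series(1.0, index=quintiles.index)
        monkeypatch.setattr(
            sel, "fit_weighted_quintile_model",
            lambda q, variables, o, w: _CannedFit(r2_table, list(variables)),
        )
        return sequential_domain_selection(
            "d1", importance, domain_of, quintiles, outcome, weights
        )

    def test_worked_relative_ten_percent_example(self, monkeypatch):
        # seed model R²=0.10; +B → 0.12 (gain 0.20, keep); +C on {top,B} →
        # 0.121 (gain 0.00833, drop)
        importance = pd.Series({"top": 0.5, "B": 0.3, "C": 0.2})
        r2 = {
            frozenset(["top"]): 0.10,
            frozenset(["top", "B"]): 0.12,
            frozenset(["top", "B", "C"]): 0.121,
        }
        trace = self._run_with_canned_r2(monkeypatch, r2, importance)
        assert trace.retained == ["top", "B"]
        steps = trace.steps.set_index("variable")
        assert steps.loc["B", "relative_gain"] == pytest.approx(0.20)
        assert steps.loc["B", "decision"] == "kept"
        assert steps.loc["C", "relative_gain"] == pytest.approx(0.121 / 0.12 - 1)
        assert steps.loc["C", "decision"] == "dropped"

    def test_rejected_candidates_do_not_change_the_baseline(self, monkeypatch):
        importance = pd.Series({"top": 0.5, "B": 0.3, "C": 0.2})
        r2 = {
            frozenset(["top"]): 0.10,
            frozenset(["top", "B"]): 0.105,  # gain 0.05 < 0.10 → drop
            frozenset(["top", "C"]): 0.12,  # evaluated against 0.10, kept
        }
        trace = self._run_with_canned_r2(monkeypatch, r2, importance)
        assert trace.retained == ["top", "C"]

    def test_single_variable_domain_returns_seed_only(self, small_pipeline):
        res = small_pipeline
        importance = res.importance
        dom = pd.Series(
            {v: ("solo" if i == 0 else "other") for i, v in enumerate(importance.index)}
        )
        trace = sequential_domain_selection(
            "solo", importance, dom, res.quintiles,
            res.srr["combined_log_srr"], res.srr["total_volume"].astype(float),
        )
        assert trace.retained == [importance.index[0]]
        assert (trace.steps["decision"] == "seed").all()

    def test_empty_domain_rejected(self, small_pipeline):
        res = small_pipeline
        dom = pd.Series("other", index=res.importance.index)
        with pytest.raises(ValueError, match="no candidate"):
            sequential_domain_selection(
                "ghost", res.importance, dom, res.quintiles,
                res.srr["combined_log_srr"], res.srr["total_volume"].astype(float),
            )


class TestTraceAudit:
    def test_recorded_r2_reproducible_by_independent_refit(self, small_pipeline):
        """Every step's r2_after must re-derive from the recorded prefix."""
        res = small_pipeline
        outcome = res.srr[res.config.outcome_name]
        weights = res.srr["total_volume"].astype(float)
        for trace in res.traces.values():
            retained = []
            for _, step in trace.steps.iterrows():
                if step["decision"] == "skipped":
                    continue
                trial = retained + [step["variable"]]
                fit = sel.fit_weighted_quintile_model(
                    res.quintiles, trial, outcome, weights
                )
                assert fit.adjusted_r2 == pytest.approx(
                    step["r2_after"], abs=1e-10
                )
                if step["decision"] in ("seed", "kept"):
                    retained.append(step["variable"])
            assert retained == trace.retained


def _quintiles_with_duplicate(rng, n=80):
    raw = pd.DataFrame(
        rng.standard_normal((n, 3)), columns=["a", "c", "d"],
        index=[f"H{i:03d}" for i in range(n)],
    )
    raw["b"] = raw["a"] + 1e-6 * rng.standard_normal(n)  # same quintiles as a
    return quintile_matrix(raw)


class TestEliminateCollinear:
    def test_clean_design_is_identity(self, rng):
        raw = pd.DataFrame(
            rng.standard_normal((100, 4)), columns=list("abcd"),
            index=[f"H{i:03d}" for i in range(100)],
        )
        q = quintile_matrix(raw)
        imp = pd.Series({"a": 0.4, "b": 0.3, "c": 0.2, "d": 0.1})
        final, log = eliminate_collinear(["a", "b", "c", "d"], imp, q)
        assert final == ["a", "b", "c", "d"]
        assert log == []

    def test_lower_importance_member_of_duplicate_pair_dropped(self, rng):
        q = _quintiles_with_duplicate(rng)
        imp = pd.Series({"a": 0.5, "b": 0.2, "c": 0.2, "d": 0.1})
        final, log = eliminate_collinear(["a", "b", "c", "d"], imp, q)
        assert "b" not in final and "a" in final
        assert log[0]["dropped"] == "b"

    def test_post_elimination_rediagnosis_is_flag_free(self, rng):
        q = _quintiles_with_duplicate(rng)
        imp = pd.Series({"a": 0.5, "b": 0.2, "c": 0.2, "d": 0.1})
        final, _ = eliminate_collinear(["a", "b", "c", "d"], imp, q)
        X, _ = quintile_design(q, final)
        assert belsley_diagnostics(X).flags == []

    def test_three_way_dependency_terminates_flag_free(self, rng):
        n = 80
        raw = pd.DataFrame(
            rng.standard_normal((n, 2)), columns=["a", "b"],
            index=[f"H{i:03d}" for i in range(n)],
        )
        raw["c"] = raw["a"] + 1e-6 * rng.standard_normal(n)
        raw["d"] = raw["b"] + 1e-6 * rng.standard_normal(n)
        raw["e"] = raw["a"] + 2e-6 * rng.standard_normal(n)
        q = quintile_matrix(raw)
        imp = pd.Series({"a": 0.4, "b": 0.3, "c": 0.1, "d": 0.1, "e": 0.1})
        final, log = eliminate_collinear(list("abcde"), imp, q)
        X, _ = quintile_design(q, final)
        assert belsley_diagnostics(X).flags == []
        assert {"a", "b"} <= set(final)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            eliminate_collinear([], pd.Series(dtype=float), pd.DataFrame())


class TestPipeline:
    def test_artifact_shapes_and_traces(self, small_pipeline):
        res = small_pipeline
        assert len(res.traces) == 6  # one per populated domain
        assert set(res.final_variables) <= set(res.retained_union)
        report = res.final_report()
        # one Q1 reference row plus Q2–Q5 per final variable
        assert len(report) == 5 * len(res.final_variables)
        assert (report[report["quintile"] == "Q1"]["coefficient"] == 0).all()

    def test_final_r2_at_least_best_domain_when_superset(self, small_pipeline):
        res = small_pipeline
        for dom, trace in res.traces.items():
            if set(trace.retained) <= set(res.final_variables):
                assert res.final_fit.r2 >= res.domain_r2[dom] - 1e-10

    def test_signal_variable_survives_to_final_model(self, small_pipeline):
        res = small_pipeline
        assert "Population estimate" in res.final_variables

    def test_quintile_means_monotone_for_signal_variable(self, small_pipeline):
        from hwr_community.linkage import quintile_summary
        from scipy.stats import spearmanr

        res = small_pipeline
        summ = quintile_summary(
            res.quintiles[["Population estimate"]],
            res.srr["combined_log_srr"],
            res.srr["total_volume"].astype(float),
        )
        rho, _ = spearmanr(summ["quintile"], summ["mean"])
        assert rho > 0

    def test_write_emits_all_tables(self, small_pipeline, tmp_path):
        small_pipeline.write(tmp_path)
        for name in ("geography.csv", "community.csv", "hospitals.csv",
                     "discharges.csv", "srr.csv", "exposures.csv",
                     "quintiles.csv", "importance.csv", "forest_meta.csv",
                     "model_fit.csv", "summary.csv", "params.yaml"):
            assert (tmp_path / name).exists(), name
        assert len(list(tmp_path.glob("trace_*.csv"))) == 6

    def test_config_roundtrip_from_dict(self):
        cfg = sel.config_from_dict(
            {"seed": 3, "n_hospitals": 55,
             "selection": {"rule": "pvalue", "pvalue_threshold": 0.2},
             "gamma": {"age_per_year": 0.01}}
        )
        assert cfg.seed == 3
        assert cfg.selection.rule == "pvalue"
        assert cfg.gamma.age_per_year == 0.01
        with pytest.raises(ValueError, match="unknown config"):
            sel.config_from_dict({"bogus": 1})

    def test_invalid_selection_config_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(rule="magic")
        with pytest.raises(ValueError):
            SelectionConfig(relative_r2_threshold=0.0)

    def test_final_model_requires_variables(self, small_pipeline):
        res = small_pipeline
        with pytest.raises(ValueError):
            fit_final_model([], res.quintiles, res.srr["combined_log_srr"],
                            res.srr["total_volume"].astype(float))

    def test_pvalue_rule_runs(self, small_pipeline):
        res = small_pipeline
        cfg = SelectionConfig(rule="pvalue")
        dom_of = pd.Series("d", index=res.importance.index)
        trace = sequential_domain_selection(
            "d", res.importance.head(6), dom_of, res.quintiles,
            res.srr["combined_log_srr"], res.srr["total_volume"].astype(float),
            cfg,
        )
        assert trace.rule == "pvalue"
        kept = trace.steps[trace.steps["decision"] == "kept"]
        assert (kept["wald_p"] < cfg.pvalue_threshold).all()
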