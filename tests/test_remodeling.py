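"""Remodeling modules, PRi/PAi indices, classification and validation."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spcpipe import (
    align_runs,
    classify_remodeling,
    compute_modules,
    pai,
    pri,
    remodeling_table,
    validate_anova_tukey,
)
from spcpipe._errors import UnsupportedDesignError, ValidationError
from tests.conftest import make_run


def matrix_from_profiles(tiny_design, profiles: dict[str, tuple[int, int, int]]):
    """Build an aligned matrix whose condition-level SpC* equal ``profiles``."""
    conditions = ("native", "preEVLP", "postEVLP")
    counts_per_run = {}
    for run_id, (cond, _a, _r) in tiny_design.run_map.items():
        c_idx = conditions.index(cond)
        counts_per_run[run_id] = {
            acc: prof[c_idx] for acc, prof in profiles.items() if prof[c_idx] > 0
        }
    runs = [make_run(run_id, c) for run_id, c in counts_per_run.items()]
    return align_runs(runs, tiny_design)


class TestModules:
    def test_worked_example(self, tiny_design):
        matrix = matrix_from_profiles(tiny_design, {"P1": (10, 20, 10)})
        modules = compute_modules(matrix)
        row = modules.loc["P1"]
        assert row.m_perturbation == pytest.approx(-2 / 3)
        assert row.m_treatment == pytest.approx(+2 / 3)
        assert row.m_baseline == pytest.approx(0.0)

    def test_constant_protein_all_zero(self, tiny_design):
        matrix = matrix_from_profiles(tiny_design, {"P1": (5, 5, 5)})
        assert (compute_modules(matrix).loc["P1",
                ["m_perturbation", "m_treatment", "m_baseline"]] == 0).all()

    def test_ln_fold_change_metric(self, tiny_design):
        matrix = matrix_from_profiles(tiny_design, {"P1": (10, 20, 10)})
        modules = compute_modules(matrix, metric="lnfc")
        assert modules.loc["P1", "m_perturbation"] == pytest.approx(math.log(0.5))

    def test_ln_metric_pseudocount_for_zeros(self, tiny_design):
        matrix = matrix_from_profiles(tiny_design, {"P1": (10, 0, 10)})
        modules = compute_modules(matrix, metric="lnfc")
        assert modules.loc["P1", "m_perturbation"] == pytest.approx(math.log(10 / 0.5))

    def test_unknown_metric_rejected(self, tiny_design):
        matrix = matrix_from_profiles(tiny_design, {"P1": (1, 1, 1)})
        with pytest.raises(ValidationError):
            compute_modules(matrix, metric="zscore")

    def test_requires_three_conditions(self, tiny_matrix):
        from spcpipe import StudyDesign

        design = StudyDesign(("a", "b"), {"r1": ("a", "x", 1), "r2": ("b", "y", 1)})
        runs = [make_run("r1", {"P1": 1}), make_run("r2", {"P1": 2})]
        two_cond = align_runs(runs, design)
        with pytest.raises(UnsupportedDesignError):
            compute_modules(two_cond)


class TestIndices:
    @pytest.mark.parametrize(
        "m_pert, m_treat, expected",
        [(0.4, -0.4, -1.0), (0.3, -0.2, -1.5), (0.0, 0.5, 0.0)],
    )
    def test_pri_values(self, m_pert, m_treat, expected):
        assert pri(m_pert, m_treat) == pytest.approx(expected)

    def test_pri_undefined_for_zero_treatment(self):
        assert math.isnan(pri(0.3, 0.0))

    @pytest.mark.parametrize(
        "m_base, m_treat, expected",
        [(-0.5, 0.5, -1.0), (-0.6, 0.4, -1.5), (0.0, 0.4, 0.0)],
    )
    def test_pai_values(self, m_base, m_treat, expected):
        assert pai(m_base, m_treat) == pytest.approx(expected)

    def test_pai_undefined_for_zero_treatment(self):
        assert math.isnan(pai(0.3, 0.0))


class TestClassification:
    def test_recovered_activated_excluded_examples(self, tiny_design):
        matrix = matrix_from_profiles(
            tiny_design,
            {
                "REC": (20, 40, 20),   # up in perturbed, back at baseline
                "ACT": (10, 10, 30),   # responds to treatment only
                "LOW": (1, 2, 1),      # noise-level counts
                "FLAT": (8, 8, 8),
            },
        )
        result = classify_remodeling(compute_modules(matrix))
        assert result.loc["REC", "remodel_class"] == "recovered"
        assert result.loc["REC", "pri"] == pytest.approx(-1.0)
        assert result.loc["ACT", "remodel_class"] == "activated"
        assert result.loc["ACT", "pai"] == pytest.approx(-1.0)
        assert result.loc["LOW", "dci_excluded"]
        assert result.loc["LOW", "remodel_class"] == "none"
        assert result.loc["FLAT", "remodel_class"] == "none"

    def test_inhibited_direction(self, tiny_design):
        matrix = matrix_from_profiles(tiny_design, {"INH": (30, 30, 10)})
        result = classify_remodeling(compute_modules(matrix))
        assert result.loc["INH", "remodel_class"] == "inhibited"

    def test_exact_recovery_identity(self, tiny_design):
        # baseline = treated != perturbed forces PRi = -1 exactly
        rng = np.random.default_rng(41)
        profiles = {}
        for i in range(20):
            base = int(rng.integers(5, 50))
            pert = int(rng.integers(5, 50))
            if pert == base:
                pert += 1
            profiles[f"P{i}"] = (base, pert, base)
        matrix = matrix_from_profiles(tiny_design, profiles)
        result = classify_remodeling(compute_modules(matrix))
        passing = ~result["dci_excluded"]
        assert passing.any()
        np.testing.assert_allclose(result.loc[passing, "pri"], -1.0, atol=1e-12)
        assert (result.loc[passing, "remodel_class"] == "recovered").all()

    def test_pure_activation_identity(self, tiny_design):
        matrix = matrix_from_profiles(tiny_design, {"A": (12, 12, 40)})
        result = classify_remodeling(compute_modules(matrix))
        assert result.loc["A", "pai"] == pytest.approx(-1.0)

    def test_order_invariance(self, tiny_design):
        profiles = {"A": (20, 40, 20), "B": (10, 10, 30), "C": (5, 5, 5)}
        matrix = matrix_from_profiles(tiny_design, profiles)
        modules = compute_modules(matrix)
        forward = classify_remodeling(modules)["remodel_class"]
        backward = classify_remodeling(modules.iloc[::-1])["remodel_class"]
        pd.testing.assert_series_equal(forward.sort_index(), backward.sort_index())

    def test_dci_any_rule_stricter(self, tiny_design):
        matrix = matrix_from_profiles(tiny_design, {"REC": (20, 40, 20)})
        modules = compute_modules(matrix)
        permissive = classify_remodeling(modules, dci_rule="all")
        strict = classify_remodeling(modules, dci_rule="any")
        # the baseline module of a perfectly recovered protein has DCI 0
        assert permissive.loc["REC", "remodel_class"] == "recovered"
        assert strict.loc["REC", "dci_excluded"]


class TestValidation:
    def test_planted_effect_detected(self):
        rng = np.random.default_rng(42)
        conditions = ("native", "preEVLP", "postEVLP")
        run_map = {
            f"{c}_A{a}_r1": (c, f"{c}-A{a}", 1)
            for c in conditions
            for a in range(1, 6)
        }
        from spcpipe import StudyDesign

        design = StudyDesign(conditions, run_map)
        lam = {"native": 20, "preEVLP": 40, "postEVLP": 20}
        runs = [
            make_run(run_id, {"CAND": int(rng.poisson(lam[cond])) + 1})
            for run_id, (cond, _a, _r) in design.run_map.items()
        ]
        matrix = align_runs(runs, design)
        summary, tukeys = validate_anova_tukey(matrix, ["CAND"])
        assert summary.at["CAND", "anova_p"] < 0.05
        result = tukeys["CAND"]
        by_pair = dict(zip(result.pairs, result.reject))
        assert by_pair[(0, 1)] and by_pair[(1, 2)]  # native-pre and pre-post

    def test_constant_candidate_degenerate(self, tiny_design):
        matrix = matrix_from_profiles(tiny_design, {"P1": (5, 5, 5)})
        summary, _ = validate_anova_tukey(matrix, ["P1"])
        assert summary.at["P1", "anova_p"] == 1.0
        assert summary.at["P1", "degenerate"]

    def test_anova_matches_oracle_on_study(self, small_study):
        _config, matrix, _truth = small_study
        candidates = list(matrix.proteins[:20])
        summary, _ = validate_anova_tukey(matrix, candidates)
        for acc in candidates:
            groups = [
                matrix.spc_star_animal.loc[
                    acc, [(c, a) for a in matrix.design.animals(c)]
                ].to_numpy(dtype=float)
                for c in matrix.conditions
            ]
            if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
                continue
            f_ref, p_ref = sps.f_oneway(*groups)
            assert summary.at[acc, "anova_p"] == pytest.approx(float(p_ref), abs=1e-10)

    def test_remodeling_table_composes(self, small_study):
        _config, matrix, _truth = small_study
        table = remodeling_table(matrix)
        assert {"pri", "pai", "remodel_class", "anova_p", "significant"} <= set(
            table.columns
        )
        candidates = table["remodel_class"] != "none"
        assert table.loc[candidates, "anova_p"].notna().all()
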