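"""Alignment, averaging, Venn partitioning, repeatability and the MW/pI map."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from spcpipe import (
    align_runs,
    compute_pi_mw,
    generate_venn_fixture,
    group_by_gene,
    normalize_total,
    overlap_stats,
    repeatability,
    scattered_proteins,
    venn_from_sets,
    venn_partition,
    virtual_map,
)
from spcpipe._errors import (
    InsufficientDataError,
    UnsupportedDesignError,
    ValidationError,
)
from tests.conftest import make_run


class TestAlignRuns:
    def test_technical_replicates_averaged(self, tiny_matrix):
        # P1 counted 4 and 6 in the native animal's two runs
        assert tiny_matrix.spc_star_animal.loc["P1", ("native", "native-A1")] == 5.0

    def test_absent_protein_is_zero(self, tiny_matrix):
        assert tiny_matrix.spc_star_condition.at["P3", "postEVLP"] == 0.0
        assert tiny_matrix.id_frequency.at["P3", "postEVLP"] == 0.0

    def test_id_frequency_counts_detected_runs(self, tiny_matrix):
        assert tiny_matrix.id_frequency.at["P1", "native"] == 1.0
        assert tiny_matrix.id_frequency.at["P3", "native"] == 1.0

    def test_condition_star_is_mean_over_animals(self, tiny_matrix):
        expected = tiny_matrix.spc_star_animal["native"].mean(axis=1)
        pd.testing.assert_series_equal(
            tiny_matrix.spc_star_condition["native"], expected, check_names=False
        )

    def test_permutation_invariant(self, tiny_design, tiny_matrix):
        counts = {
            run_id: {
                acc: int(spc)
                for acc, spc in tiny_matrix.spc[run_id].items()
                if spc > 0
            }
            for run_id in tiny_matrix.spc.columns
        }
        runs = [make_run(r, c) for r, c in counts.items()][::-1]
        shuffled = align_runs(runs, tiny_design)
        pd.testing.assert_frame_equal(shuffled.spc, tiny_matrix.spc)

    def test_missing_run_table_reported(self, tiny_design):
        runs = [make_run("native_A1_r1", {"P1": 1})]
        with pytest.raises(ValidationError, match="native_A1_r2"):
            align_runs(runs, tiny_design)


class TestGroupByGene:
    def test_isoforms_summed(self, tiny_design):
        genes = {"P1a": "Myh9", "P1b": "Myh9", "P2": "Actb"}
        runs = [
            make_run(run_id, {"P1a": 3, "P1b": 7, "P2": 1}, genes=genes)
            for run_id in tiny_design.run_ids
        ]
        grouped = group_by_gene(align_runs(runs, tiny_design))
        assert len(grouped.proteins) == 2
        assert grouped.spc.loc["P1a"].eq(10).all()

    def test_distinct_symbols_identity(self, small_study):
        _config, matrix, _truth = small_study
        again = group_by_gene(matrix)
        pd.testing.assert_frame_equal(again.spc, matrix.spc)


class TestVenn:
    PAPER_REGIONS = (1160, 205, 75, 39, 184, 176, 56)

    def test_worked_example(self):
        sets = generate_venn_fixture(self.PAPER_REGIONS, labels=("n", "pre", "post"))
        part = venn_from_sets(sets)
        assert part.union_size == 1895
        assert part.marginal("n") == 1588
        assert part.marginal("pre") == 1616
        assert part.marginal("post") == 1330

    def test_identical_sets_all_triple(self):
        base = {f"P{i}" for i in range(37)}
        part = venn_from_sets({"a": set(base), "b": set(base), "c": set(base)})
        sizes = part.sizes()
        assert sizes[frozenset({"a", "b", "c"})] == 37
        assert sum(sizes.values()) == 37

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.lists(hst.tuples(hst.booleans(), hst.booleans(), hst.booleans()),
                     max_size=40))
    def test_regions_partition_union(self, membership):
        sets = {"a": set(), "b": set(), "c": set()}
        for i, (in_a, in_b, in_c) in enumerate(membership):
            for label, member in zip("abc", (in_a, in_b, in_c)):
                if member:
                    sets[label].add(f"x{i}")
        part = venn_from_sets(sets)
        union = sets["a"] | sets["b"] | sets["c"]
        regions = list(part.regions.values())
        assert part.union_size == len(union)
        assert set().union(*regions) == union
        for i, r1 in enumerate(regions):
            for r2 in regions[i + 1:]:
                assert not (r1 & r2)
        # brute-force membership enumeration agrees region by region
        for key, members in part.regions.items():
            for acc in union:
                expected = frozenset(lab for lab in "abc" if acc in sets[lab])
                assert (acc in members) == (expected == key)

    def test_matrix_partition(self, tiny_matrix):
        part = venn_partition(tiny_matrix)
        sizes = part.sizes()
        assert sizes[frozenset({"native", "preEVLP", "postEVLP"})] == 2  # P1, P2
        assert sizes[frozenset({"native", "preEVLP"})] == 1  # P3

    def test_requires_three_conditions(self):
        with pytest.raises(UnsupportedDesignError):
            venn_from_sets({"a": set(), "b": set()})


class TestRepeatability:
    def test_identity(self):
        x = pd.Series([3.0, 5, 8], index=["P1", "P2", "P3"])
        result = repeatability(x, x.copy())
        assert result.r_squared == pytest.approx(1.0)
        assert result.slope == pytest.approx(1.0)
        assert result.n_points == 3

    def test_exact_scaling(self):
        x = pd.Series([3.0, 5, 8], index=["P1", "P2", "P3"])
        result = repeatability(x, 2 * x)
        assert result.slope == pytest.approx(2.0)
        assert result.r_squared == pytest.approx(1.0)

    def test_r_squared_symmetric(self):
        x = pd.Series([3.0, 5, 8, 1], index=list("abcd"))
        y = pd.Series([2.0, 6, 7, 2], index=list("abcd"))
        assert repeatability(x, y).r_squared == pytest.approx(
            repeatability(y, x).r_squared
        )

    def test_poisson_replicates_correlate(self):
        # paired Poisson draws from a shared abundance law behave like
        # technical replicates: strong correlation, slope near 1
        rng = np.random.default_rng(21)
        lam = rng.lognormal(1.6, 1.0, 600)
        idx = [f"P{i}" for i in range(600)]
        x = pd.Series(rng.poisson(lam).astype(float), index=idx)
        y = pd.Series(rng.poisson(lam).astype(float), index=idx)
        result = repeatability(x, y)
        assert result.r_squared > 0.8
        assert result.slope == pytest.approx(1.0, abs=0.15)

    def test_degenerate_flagged(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert repeatability(x, y).degenerate


class TestScattered:
    def test_identical_vectors_give_empty_list(self):
        x = pd.Series(np.arange(1.0, 21.0), index=[f"P{i}" for i in range(20)])
        assert scattered_proteins(x, x.copy()) == []

    def test_infinite_threshold_gives_empty_list(self):
        rng = np.random.default_rng(2)
        idx = [f"P{i}" for i in range(50)]
        x = pd.Series(rng.poisson(10, 50).astype(float), index=idx)
        y = pd.Series(rng.poisson(10, 50).astype(float), index=idx)
        assert scattered_proteins(x, y, threshold_sd=np.inf) == []

    def test_planted_contaminants_recovered(self):
        rng = np.random.default_rng(3)
        n = 600
        idx = [f"P{i}" for i in range(n)]
        lam = rng.lognormal(1.6, 1.0, n)
        peer = pd.Series(lam, index=idx)
        sample_lam = lam.copy()
        planted = [f"P{i}" for i in rng.choice(np.where(lam > np.median(lam))[0], 20,
                                               replace=False)]
        sample_lam[[int(p[1:]) for p in planted]] *= 10
        sample = pd.Series(rng.poisson(sample_lam).astype(float), index=idx)
        flagged = scattered_proteins(sample, peer)
        assert len(set(planted) & set(flagged)) >= 16  # >= 80% of the planted set
        # removing the flagged proteins improves the correlation
        keep = [i for i in idx if i not in flagged]
        before = repeatability(sample, peer).r_squared
        after = repeatability(sample[keep], peer[keep]).r_squared
        assert after >= before

    def test_too_few_common_proteins(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(InsufficientDataError):
            scattered_proteins(x, x)


class TestNormalizeAndOverlap:
    def test_scale_factors(self):
        a = pd.Series([60.0, 40.0])
        b = pd.Series([120.0, 80.0])
        a2, b2 = normalize_total(a, b)
        assert a2.sum() == pytest.approx(150.0)
        assert b2.sum() == pytest.approx(150.0)
        pd.testing.assert_series_equal(a2, a * 1.5)
        pd.testing.assert_series_equal(b2, b * 0.75)

    def test_identity_and_rank_preserved(self):
        rng = np.random.default_rng(4)
        a = pd.Series(rng.uniform(0, 10, 30))
        a2, a3 = normalize_total(a, a.copy())
        pd.testing.assert_series_equal(a2, a)
        b = pd.Series(rng.uniform(0, 10, 30))
        a4, b4 = normalize_total(a, b)
        assert (a4.rank() == a.rank()).all()
        assert (b4.rank() == b.rank()).all()

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            normalize_total(pd.Series([0.0]), pd.Series([1.0]))

    def test_overlap_stats(self):
        reference = {f"P{i}" for i in range(100)}
        query = {f"P{i}" for i in range(60, 160)}
        stats = overlap_stats(reference, query)
        assert stats["n_shared"] == 40
        assert stats["confirmation_pct"] == pytest.approx(40.0)


class TestVirtualMap:
    def test_coordinates_passed_through(self, tiny_design):
        from spcpipe import RunTable

        runs = [
            RunTable(
                run_id,
                pd.DataFrame(
                    {"score": [200.0], "spc": [5], "mw": [50000.0], "pi": [6.1]},
                    index=pd.Index(["P1"], name="accession"),
                ),
            )
            for run_id in tiny_design.run_ids
        ]
        matrix = align_runs(runs, tiny_design)
        points = virtual_map(matrix, score_cut=100.0)
        assert len(points) == 1
        row = points.iloc[0]
        assert (row.mw, row.pi, row.confidence_code) == (50000.0, 6.1, "high")

    def test_missing_coordinates_skipped_with_warning(self, tiny_matrix):
        with pytest.warns(UserWarning, match="skipped"):
            points = virtual_map(tiny_matrix)
        assert points.empty

    def test_generated_study_points_in_range(self, small_study):
        _config, matrix, _truth = small_study
        points = virtual_map(matrix)
        assert len(points) == len(matrix.proteins)
        assert points["pi"].between(0, 14).all()
        assert (points["mw"] > 0).all()


class TestPiMw:
    def test_glycine_mass(self):
        _pi, mw = compute_pi_mw("G")
        assert mw == pytest.approx(75.07, abs=0.01)

    def test_basic_vs_acidic_ordering(self):
        pi_k, _ = compute_pi_mw("K" * 10)
        pi_d, _ = compute_pi_mw("D" * 10)
        assert pi_k > pi_d
        assert 0 <= pi_d <= 14 and 0 <= pi_k <= 14

    def test_invalid_residue_names_position(self):
        with pytest.raises(ValidationError, match="position 3"):
            compute_pi_mw("GGXG")
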