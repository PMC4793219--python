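import math

import numpy as np
import pytest

from editscan.cohort_analysis import (
    DifferentialResult,
    GeneDirectionSummary,
    ValidationRule,
    bh_fdr,
    classify_site_direction,
    differential_editing,
    paired_t_test,
    recurrence_distribution,
    summarize_gene_directions,
    validate_against_cohort,
)
from editscan.core_model.types import EditingMatrix, EditingSite
from editscan.synthetic_data import CohortPlan, simulate_editing_cohort

SITE = EditingSite("chr1", 100)


def matrix_from(depths, levels, samples=None):
    depths = np.asarray(depths)
    samples = samples or [f"s{j}" for j in range(depths.shape[1])]
    keys = [f"chr1:{i}:A>G" for i in range(depths.shape[0])]
    return EditingMatrix(keys, samples, depths, np.asarray(levels))


class TestRecurrence:
    def test_counts_nonzero_levels(self):
        m = matrix_from([[25, 30, 22]], [[0.1, 0.2, 0.05]])
        assert recurrence_distribution(m) == {"chr1:0:A>G": 3}

    def test_depth_19_excludes_site(self):
        m = matrix_from([[25, 19, 22]], [[0.1, 0.2, 0.05]])
        assert recurrence_distribution(m) == {}

    def test_zero_levels_counted_as_absent(self):
        m = matrix_from([[25, 30, 22]], [[0.0, 0.0, 0.3]])
        assert recurrence_distribution(m)["chr1:0:A>G"] == 1

    def test_column_order_invariance(self):
        depths = [[25, 30, 22], [40, 50, 60]]
        levels = [[0.1, 0.0, 0.2], [0.0, 0.1, 0.0]]
        m1 = recurrence_distribution(matrix_from(depths, levels))
        perm = [2, 0, 1]
        m2 = recurrence_distribution(matrix_from(
            np.array(depths)[:, perm], np.array(levels)[:, perm]))
        assert m1 == m2


class TestValidation:
    def test_real(self):
        cells = [(50, 5, 0.1)] * 3 + [(50, 0, 0.0)] * 13
        assert validate_against_cohort(SITE, cells) == "real"

    def test_likely(self):
        cells = [(50, 5, 0.1)] + [(50, 0, 0.0)] * 15
        assert validate_against_cohort(SITE, cells) == "likely"

    def test_insufficient(self):
        cells = [(9, 1, 0.1)] * 16
        assert validate_against_cohort(SITE, cells) == "insufficient"

    def test_unsupported(self):
        cells = [(50, 0, 0.0)] * 16
        assert validate_against_cohort(SITE, cells) == "unsupported"

    def test_boundary_cell_supports(self):
        # depth 10, alt 1, af exactly 0.01: inclusive everywhere
        cells = [(10, 1, 0.01), (10, 1, 0.01)]
        assert validate_against_cohort(SITE, cells) == "real"

    def test_empty_cohort_insufficient(self):
        assert validate_against_cohort(SITE, []) == "insufficient"


class TestPairedT:
    def test_closed_form_example(self):
        # differences (1, 2, 3): t = mean/(sd/sqrt(3)) = 2*sqrt(3)
        t, p = paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * math.sqrt(3))
        assert p == pytest.approx(0.07418, abs=1e-4)

    def test_identical_vectors(self):
        t, p = paired_t_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert (t, p) == (0.0, 1.0)

    def test_degenerate_constant_difference(self):
        with pytest.warns(UserWarning):
            t, p = paired_t_test([1.1, 2.1, 3.1], [1.0, 2.0, 3.0])
        assert math.isinf(t) and p == 0.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [0.5])

    def test_type_one_error_calibrated(self):
        # smaller-scale version of the acceptance check
        rng = np.random.default_rng(3)
        plan = CohortPlan(n_sites=2000, n_pairs=30, n_differential=0,
                          depth_mean=50, overdispersion=0.01)
        mat, _pairs, _truth = simulate_editing_cohort(plan, rng)
        fp = sum(paired_t_test(mat.level[i, :30], mat.level[i, 30:])[1] <= 0.05
                 for i in range(plan.n_sites))
        assert 0.03 <= fp / plan.n_sites <= 0.07


class TestBhFdr:
    def test_hand_worked_example(self):
        # p*m/rank then cumulative min from the largest p
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_constant_p(self):
        assert np.allclose(bh_fdr([0.5] * 7), 0.5)

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty(self):
        assert bh_fdr([]).size == 0

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestDifferentialEditing:
    def test_planted_effects_recovered(self):
        rng = np.random.default_rng(11)
        plan = CohortPlan(n_sites=400, n_pairs=40, n_differential=30,
                          delta=0.15, depth_mean=100, overdispersion=0.01)
        mat, pairs, truth = simulate_editing_cohort(plan, rng)
        res = differential_editing(mat, pairs, "SIM")
        sig = {r.site_key for r in res if r.significant()}
        planted = {k for k, (f, _d) in truth.differential.items() if f}
        assert len(sig & planted) / len(planted) >= 0.9
        false = sig - planted
        assert len(false) <= max(3, 0.1 * len(sig))

    def test_identical_pair_not_significant(self):
        depths = np.full((1, 22), 50)
        levels = np.tile(np.linspace(0.1, 0.5, 11), (1, 2))
        m = matrix_from(depths, levels,
                        samples=[f"T{i}" for i in range(11)]
                        + [f"N{i}" for i in range(11)])
        pairs = [(f"T{i}", f"N{i}") for i in range(11)]
        res = differential_editing(m, pairs, "X", min_pairs=5)
        assert len(res) == 1
        assert not res[0].significant()

    def test_min_pairs_floor(self):
        depths = np.full((1, 10), 50)
        levels = np.random.default_rng(0).random((1, 10))
        m = matrix_from(depths, levels,
                        samples=[f"T{i}" for i in range(5)]
                        + [f"N{i}" for i in range(5)])
        pairs = [(f"T{i}", f"N{i}") for i in range(5)]
        with pytest.warns(UserWarning):
            assert differential_editing(m, pairs, "X") == []

    def test_missing_pairs_dropped(self):
        rng = np.random.default_rng(2)
        depths = np.full((1, 30), 60)
        depths[0, 0] = -1  # tumor 0 missing
        levels = rng.random((1, 30))
        m = matrix_from(depths, levels,
                        samples=[f"T{i}" for i in range(15)]
                        + [f"N{i}" for i in range(15)])
        pairs = [(f"T{i}", f"N{i}") for i in range(15)]
        (res,) = differential_editing(m, pairs, "X")
        assert res.n_pairs == 14


class TestDirectionCalls:
    def test_two_up_no_down(self):
        entries = [(True, "up"), (True, "up"), (False, "down")]
        assert classify_site_direction(entries) == "up"

    def test_two_up_one_down(self):
        entries = [(True, "up"), (True, "up"), (True, "down")]
        assert classify_site_direction(entries) == "up"

    def test_two_up_two_down_not_called(self):
        entries = [(True, "up")] * 2 + [(True, "down")] * 2
        assert classify_site_direction(entries) == "not_called"

    def test_symmetry_under_label_swap(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            entries = [(bool(rng.integers(2)),
                        "up" if rng.integers(2) else "down")
                       for _ in range(rng.integers(0, 8))]
            swapped = [(s, "down" if d == "up" else "up")
                       for s, d in entries]
            a = classify_site_direction(entries)
            b = classify_site_direction(swapped)
            flip = {"up": "down", "down": "up", "not_called": "not_called"}
            assert b == flip[a]


class TestGeneSummary:
    @staticmethod
    def calls_for(counts):
        """(gene -> (n_up, n_down)) -> site_calls + site_to_gene maps."""
        site_calls, site_to_gene = {}, {}
        for gene, (up, down) in counts.items():
            for i in range(up):
                key = f"{gene}_u{i}"
                site_calls[key] = "up"
                site_to_gene[key] = gene
            for i in range(down):
                key = f"{gene}_d{i}"
                site_calls[key] = "down"
                site_to_gene[key] = gene
        return site_calls, site_to_gene

    def test_consistent_flag(self):
        calls, genes = self.calls_for({"G1": (22, 0), "G2": (24, 15)})
        out = {s.gene: s for s in summarize_gene_directions(calls, genes)}
        assert out["G1"].consistent
        assert not out["G2"].consistent

    def test_min_sites_filter(self):
        calls, genes = self.calls_for({"G1": (1, 0), "G2": (2, 0)})
        out = summarize_gene_directions(calls, genes)
        assert [s.gene for s in out] == ["G2"]

    def test_gene_filter(self):
        calls, genes = self.calls_for({"G1": (3, 0), "G2": (2, 0)})
        out = summarize_gene_directions(calls, genes, gene_filter={"G2"})
        assert [s.gene for s in out] == ["G2"]
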