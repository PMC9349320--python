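from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from mmclonal.errors import DomainError
from mmclonal.stats import (
    ContingencyTable2x2,
    associate_pattern_features,
    fisher_exact,
    gep70_score,
    mann_whitney,
)
from mmclonal.types import ClinicalRecord


def fisher_oracle(a, b, c, d):
    """Independent oracle: full hypergeometric enumeration, point-probability
    two-sided convention."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    probs = sps.hypergeom.pmf(ks, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    return float(np.clip(probs[probs <= p_obs * (1 + 1e-12)].sum(), 0, 1))


def mw_oracle(x, y):
    """Independent oracle: enumerate all assignments; two-sided deviation
    counting on the U statistic."""
    pooled = list(x) + list(y)
    n = len(x)
    mu = n * len(y) / 2

    def u_of(ix):
        xs = [pooled[i] for i in ix]
        ys = [pooled[i] for i in range(len(pooled)) if i not in ix]
        return sum(
            sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for yi in ys)
            for xi in xs
        )

    u_obs = u_of(range(n))
    hits = total = 0
    for ix in combinations(range(len(pooled)), n):
        total += 1
        if abs(u_of(set(ix)) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[0, 11], [7, 3]], 0.0010319917440660474),  # frozen from the oracle
            ([[5, 5], [5, 5]], 1.0),
            ([[2, 0], [0, 2]], 1 / 3),
        ],
    )
    def test_frozen_values(self, table, expected):
        (a, b), (c, d) = table
        assert fisher_oracle(a, b, c, d) == pytest.approx(expected, rel=1e-9)
        assert fisher_exact(table) == pytest.approx(expected, rel=1e-9)

    def test_matches_oracle_on_exhaustive_small_tables(self):
        for total in range(1, 13):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                            fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12
                        )

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestMannWhitney:
    def test_frozen_small_examples(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        assert mann_whitney([1], [1]) == pytest.approx(1.0)
        assert mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]) == pytest.approx(2 / 252)

    def test_matches_enumeration_oracle_on_random_small_inputs(self):
        rng = np.random.default_rng(31)
        for _ in range(120):
            n = int(rng.integers(1, 6))
            m = int(rng.integers(1, min(7, 13 - n)))
            # integer draws so ties occur frequently
            x = rng.integers(0, 6, size=n).tolist()
            y = rng.integers(0, 6, size=m).tolist()
            assert mann_whitney(x, y) == pytest.approx(mw_oracle(x, y), abs=1e-12)

    def test_matches_scipy_exact_distribution_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            perm = rng.permutation(100)  # distinct values -> tie-free
            x = perm[:5].tolist()
            y = perm[5:11].tolist()
            expected = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert mann_whitney(x, y) == pytest.approx(expected.pvalue, abs=1e-12)

    def test_large_sample_path_close_to_exact_enumeration(self):
        x = [1, 3, 5, 7, 9, 11, 13.5]
        y = [2, 4, 6, 8, 10, 12, 14]
        # combined n = 14 exceeds the exact cutoff -> normal approximation
        p_approx = mann_whitney(x, y)
        assert p_approx == pytest.approx(mw_oracle(x, y), abs=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney([], [1])


class TestGep70:
    UP = [f"UP{i}" for i in range(51)]
    DOWN = [f"DN{i}" for i in range(19)]

    def _expr(self, up_val, down_val):
        expr = {g: up_val for g in self.UP}
        expr.update({g: down_val for g in self.DOWN})
        return expr

    def test_flat_expression_scores_zero_low_risk(self):
        score, risk = gep70_score(self._expr(8.0, 8.0), self.UP, self.DOWN)
        assert score == 0.0 and risk == "low"

    def test_unit_difference_scores_one_high_risk(self):
        score, risk = gep70_score(self._expr(8.0, 7.0), self.UP, self.DOWN)
        assert score == pytest.approx(1.0) and risk == "high"

    def test_score_exactly_at_cutoff_is_high_risk(self):
        # single-gene sets make the means (and hence the boundary) bit-exact
        score, risk = gep70_score({"U": 0.66, "D": 0.0}, ["U"], ["D"])
        assert score == 0.66 and risk == "high"
        score, risk = gep70_score(
            {"U": np.nextafter(0.66, 0.0), "D": 0.0}, ["U"], ["D"]
        )
        assert risk == "low"

    def test_invariant_to_other_genes_and_common_shifts(self):
        expr = self._expr(8.0, 7.5)
        score0, _ = gep70_score(expr, self.UP, self.DOWN)
        expr_extra = dict(expr, OTHER=99.0)
        assert gep70_score(expr_extra, self.UP, self.DOWN)[0] == score0
        shifted = {g: v + 2.5 for g, v in expr.items()}
        assert gep70_score(shifted, self.UP, self.DOWN)[0] == pytest.approx(score0)

    def test_refuses_when_too_many_genes_missing(self):
        expr = self._expr(8.0, 7.0)
        for g in self.DOWN[:5]:  # 5/19 > 20%
            del expr[g]
        with pytest.raises(DomainError, match="missing"):
            gep70_score(expr, self.UP, self.DOWN)
        # <= 20% missing: mean over available genes
        expr = self._expr(8.0, 7.0)
        for g in self.DOWN[:3]:
            del expr[g]
        score, _ = gep70_score(expr, self.UP, self.DOWN)
        assert score == pytest.approx(1.0)


def _clinical(pid, fl, response):
    return ClinicalRecord(patient_id=pid, pet_fl_count=fl, best_response=response)


class TestAssociations:
    def test_reconstructed_cohort_reproduces_the_printed_association(self):
        # 21 patients: 11 with >=3 lesions (all multi-branch),
        # 10 with <3 lesions of which 7 single-cell expansions
        patterns = {}
        clinical = {}
        for i in range(11):
            pid = f"M{i}"
            patterns[pid] = "coexisting_subclones"
            clinical[pid] = _clinical(pid, 5, "PR")
        for i in range(7):
            pid = f"S{i}"
            patterns[pid] = "single_cell_expansion"
            clinical[pid] = _clinical(pid, 1, "CR")
        for i in range(3):
            pid = f"X{i}"
            patterns[pid] = "alternating_spatial_dominance"
            clinical[pid] = _clinical(pid, 2, "CR")
        results = associate_pattern_features(patterns, clinical)
        lesions = results[0]
        assert lesions.table.as_array().tolist() == [[0, 11], [7, 3]]
        assert lesions.p_value < 0.01
        assert lesions.p_value == pytest.approx(fisher_oracle(0, 11, 7, 3), rel=1e-9)

    def test_unmatched_patients_reported(self):
        patterns = {"P1": "single_cell_expansion", "P2": "coexisting_subclones"}
        clinical = {"P1": _clinical("P1", 1, "CR"), "P3": _clinical("P3", 5, "PR")}
        results = associate_pattern_features(patterns, clinical)
        assert set(results[0].unmatched_patients) == {"P2", "P3"}

    def test_empty_join_gives_explicit_empty_results(self):
        results = associate_pattern_features({"P1": "single_cell_expansion"}, {})
        assert all(r.p_value is None and r.table is None for r in results)
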