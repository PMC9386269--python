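"""Spearman validation statistics, strength labels, cohort summaries, folds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tremorkit import (
    classify_correlation,
    cohort_summary,
    correlation_matrix,
    fold_ratio,
    spearman,
)
from tremorkit.errors import StatsError


def _oracle_spearman(x, y):
    """Independent rank-then-Pearson computation with explicit mean ranks."""

    def mean_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = mean_ranks(x), mean_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10, dtype=float)
        assert spearman(x, x**3).r_s == pytest.approx(1.0)

    def test_perfect_antitone(self):
        x = np.arange(10, dtype=float)
        assert spearman(x, -x).r_s == pytest.approx(-1.0)

    def test_mean_rank_tie_handling_matches_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([10.0, 20.0, 30.0, 40.0])
        res = spearman(x, y)
        assert res.r_s == pytest.approx(_oracle_spearman(x, y), abs=1e-12)

    def test_random_vectors_with_ties_match_oracle_and_scipy(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n).round(1)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            r = spearman(x, y).r_s
            assert r == pytest.approx(_oracle_spearman(x, y), abs=1e-12)
            assert r == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_invariant_under_strictly_monotone_transform(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman(x, y).r_s
        assert spearman(np.exp(x), y).r_s == pytest.approx(base, abs=1e-12)
        assert spearman(x, 3 * y + 7).r_s == pytest.approx(base, abs=1e-12)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert spearman(x, y).r_s == pytest.approx(spearman(y, x).r_s, abs=1e-15)

    def test_t_and_permutation_p_agree_at_n10(self, rng):
        diffs = []
        for _ in range(10):
            x, y = rng.normal(size=10), rng.normal(size=10)
            pt = spearman(x, y, p_method="t").p_two_tailed
            pp = spearman(x, y, p_method="permutation", seed=3,
                          n_permutations=20_000).p_two_tailed
            diffs.append(abs(pt - pp))
        assert max(diffs) < 0.02

    def test_exhaustive_permutation_at_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        res = spearman(x, y)  # n=6 -> exhaustive over 720 orderings
        # oracle: fraction of the 720 orderings with |r| >= r_obs
        import itertools

        robs = abs(_oracle_spearman(x, y))
        hits = sum(
            abs(_oracle_spearman(x, np.array(p))) >= robs - 1e-12
            for p in itertools.permutations(y)
        )
        assert res.p_two_tailed == pytest.approx(hits / 720)

    def test_ci_bounds_bracket_r(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        res = spearman(x, y)
        assert -1 <= res.ci_low <= res.r_s <= res.ci_high <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError):
            spearman(np.ones(10), np.arange(10.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatsError):
            spearman(np.arange(5.0), np.arange(6.0))


class TestClassify:
    @pytest.mark.parametrize(
        "r,label",
        [
            (0.489, "moderate"),
            (0.601, "strong"),
            (0.1, "weak"),
            (-0.75, "strong"),
            (0.4, "moderate"),
            (0.5756, "moderate"),
        ],
    )
    def test_thresholds(self, r, label):
        assert classify_correlation(r) == label

    def test_monotone_in_magnitude(self):
        order = {"weak": 0, "moderate": 1, "strong": 2}
        labels = [order[classify_correlation(r)] for r in np.linspace(0, 1, 101)]
        assert labels == sorted(labels)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            classify_correlation(1.2)


class TestCohortSummary:
    def test_mean_and_sd_with_n_minus_one(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "position": ["wing", "wing"],
                "total_power": [1.0, 3.0],
            }
        )
        out = cohort_summary(df)
        assert out.loc["wing", "total_power_mean"] == pytest.approx(2.0)
        assert out.loc["wing", "total_power_std"] == pytest.approx(np.sqrt(2))

    def test_identical_subjects_have_zero_sd(self):
        df = pd.DataFrame(
            {
                "subject_id": list("abc"),
                "position": ["rest"] * 3,
                "total_power": [0.5] * 3,
            }
        )
        assert cohort_summary(df).loc["rest", "total_power_std"] == 0.0

    def test_single_subject_rejected(self):
        df = pd.DataFrame(
            {"subject_id": ["a"], "position": ["rest"], "total_power": [1.0]}
        )
        with pytest.raises(StatsError, match="single subject"):
            cohort_summary(df)


class TestFoldRatio:
    def test_patient_vs_control_action_power(self):
        assert fold_ratio(1.88, 0.09) == pytest.approx(20.9, abs=0.05)

    def test_wing_vs_posture_peak_power(self):
        assert fold_ratio(8.37, 1.58) == pytest.approx(5.30, abs=0.005)

    def test_identity(self):
        assert fold_ratio(2.5, 2.5) == 1.0

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(StatsError):
            fold_ratio(1.0, 0.0)


class TestCorrelationMatrix:
    def _crst(self, n, rng):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "rest": rng.integers(0, 5, n),
                "posture": rng.integers(0, 5, n),
                "action": rng.integers(0, 5, n),
            }
        )

    def test_self_correlation_diagonal_is_one(self, rng):
        crst = self._crst(12, rng)
        rows = []
        for pos in ("rest", "posture", "action"):
            for i in range(12):
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "position": pos,
                        "total_power": float(crst.loc[i, pos]),
                    }
                )
        table = correlation_matrix(crst, pd.DataFrame(rows))
        diag = table[(table.crst_condition == table.position)]
        assert (diag.r_s > 0.999).all()

    def test_monotone_link_gives_strong_diagonal(self, rng):
        n = 25
        crst = self._crst(n, rng)
        rows = []
        for pos in ("rest", "posture", "action"):
            noise = rng.normal(0, 0.3, n)
            for i in range(n):
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "position": pos,
                        "total_power": float(np.exp(crst.loc[i, pos] + noise[i])),
                    }
                )
        table = correlation_matrix(crst, pd.DataFrame(rows))
        diag = table[
            (table.crst_condition == table.position)
            & (table.crst_condition != "total")
        ]
        assert (diag.p < 0.05).all()
        assert (diag.strength == "strong").all()

    def test_grid_includes_wing_column_when_present(self, rng):
        crst = self._crst(10, rng)
        rows = []
        for pos in ("rest", "wing"):
            for i in range(10):
                rows.append(
                    {"subject_id": f"s{i}", "position": pos,
                     "total_power": float(rng.uniform())}
                )
        table = correlation_matrix(crst, pd.DataFrame(rows))
        assert "wing" in set(table.position)

    def test_pipeline_position_names_are_canonicalised(self, rng):
        crst = self._crst(10, rng)
        rows = [
            {"subject_id": f"s{i}", "position": "posture_unimanual_dominant",
             "total_power": float(rng.uniform())}
            for i in range(10)
        ]
        table = correlation_matrix(crst, pd.DataFrame(rows))
        assert set(table.position) == {"posture"}

    def test_too_few_joined_subjects_rejected(self, rng):
        crst = self._crst(3, rng)
        rows = [
            {"subject_id": f"s{i}", "position": "rest", "total_power": 1.0 * i}
            for i in range(3)
        ]
        with pytest.raises(StatsError, match="need >= 4"):
            correlation_matrix(crst, pd.DataFrame(rows))

    def test_shuffled_ids_look_null(self, rng):
        # under the null, roughly 5% of cells reach p < 0.05
        n = 25
        flags = []
        for rep in range(30):
            crst = self._crst(n, rng)
            rows = [
                {"subject_id": f"s{i}", "position": "posture",
                 "total_power": float(rng.normal())}
                for i in range(n)
            ]
            table = correlation_matrix(crst, pd.DataFrame(rows))
            flags.extend((table.p < 0.05).tolist())
        assert np.mean(flags) < 0.15
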