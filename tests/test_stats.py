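"""Group inference: cutoff split, assumption checks, mixed ANOVA against
brute-force and pingouin oracles, simple effects, Mann-Whitney against
exhaustive enumeration, and the power/sample-size utilities."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import linalg
from scipy import stats as sps

from emoroc.design import EMOTIONS
from emoroc.stats import (
    GroupSplit,
    eta2_to_f,
    f_to_eta2,
    interaction_power,
    mann_whitney,
    mauchly_sphericity,
    mixed_anova,
    normality_tests,
    required_sample_size,
    simple_main_effects,
    split_by_cutoff,
)


def make_table(y, groups):
    df = pd.DataFrame(np.asarray(y, float), columns=list(EMOTIONS))
    df.index = [f"s{i:02d}" for i in range(len(df))]
    df["group"] = list(groups)
    return df


class TestSplit:
    def test_rule_application(self):
        split = split_by_cutoff({"a": 33, "b": 38, "c": 39, "d": 40, "e": 47})
        assert split.low_ids == ("a", "b", "c")
        assert split.high_ids == ("d", "e")

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="Low"):
            split_by_cutoff({"a": 40, "b": 41})
        with pytest.raises(ValueError, match="High"):
            split_by_cutoff({"a": 30})

    def test_study_like_cohort_sizes(self, rng):
        traits = {f"P{i}": int(rng.integers(33, 40)) for i in range(15)}
        traits.update({f"Q{i}": int(rng.integers(40, 48)) for i in range(13)})
        split = split_by_cutoff(traits)
        assert (len(split.low_ids), len(split.high_ids)) == (15, 13)


class TestNormality:
    def test_null_calibration(self, rng):
        res = normality_tests(rng.standard_normal(200), "lilliefors")
        assert res.p > 0.05 and res.passed

    def test_uniform_rejected_by_lilliefors(self, rng):
        rejections = sum(
            not normality_tests(rng.random(500), "lilliefors").passed for _ in range(5)
        )
        assert rejections == 5

    def test_ks_matches_scipy_statistic(self, rng):
        x = rng.standard_normal(50)
        res = normality_tests(x, "ks")
        d, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        assert res.statistic == pytest.approx(d) and res.p == pytest.approx(p)

    def test_too_small_and_constant(self):
        with pytest.raises(ValueError):
            normality_tests([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="constant"):
            normality_tests([2.0] * 10)


class TestMauchly:
    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.standard_normal((28, 4)) + 0.5 * rng.standard_normal((28, 1))
        res = mauchly_sphericity(x)
        df = pd.DataFrame(x, columns=list("ABCD"))
        df["subj"] = range(28)
        long = df.melt(id_vars="subj", var_name="cond", value_name="y")
        ref = pg.sphericity(long, dv="y", subject="subj", within="cond")
        assert res.W == pytest.approx(ref.W, abs=1e-10)
        assert res.chi2 == pytest.approx(ref.chi2, abs=1e-9)
        assert res.p == pytest.approx(ref.pval, abs=5e-3)

    def test_eigenvalue_identity(self, rng):
        """W equals prod(lambda) / mean(lambda)^(k-1) of the contrast
        covariance, computed here from scratch."""
        x = rng.standard_normal((20, 4))
        res = mauchly_sphericity(x)
        c = linalg.helmert(4)
        lam = np.linalg.eigvalsh(c @ np.cov(x, rowvar=False) @ c.T)
        expected = np.prod(lam) / np.mean(lam) ** 3
        assert res.W == pytest.approx(expected, abs=1e-12)

    def test_compound_symmetry_near_one(self, rng):
        x = rng.standard_normal((40, 4)) + 2.0 * rng.standard_normal((40, 1))
        res = mauchly_sphericity(x)
        assert res.W > 0.8 and res.passed

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError):
            mauchly_sphericity(rng.standard_normal((4, 4)))


def brute_force_mixed_ss(y, groups):
    """Unweighted-means split-plot sums of squares from first principles:
    explicit loops over cells, no linear algebra shared with the
    implementation."""
    y = np.asarray(y, float)
    n, m = y.shape
    labels = sorted(set(groups))
    g = len(labels)
    members = {lab: [i for i, gi in enumerate(groups) if gi == lab] for lab in labels}
    n_h = g / sum(1 / len(members[lab]) for lab in labels)
    cell = {(lab, j): np.mean([y[i, j] for i in members[lab]]) for lab in labels for j in range(m)}
    row = {lab: np.mean([cell[(lab, j)] for j in range(m)]) for lab in labels}
    col = {j: np.mean([cell[(lab, j)] for lab in labels]) for j in range(m)}
    grand = np.mean(list(cell.values()))
    ss_a = m * n_h * sum((row[lab] - grand) ** 2 for lab in labels)
    ss_b = g * n_h * sum((col[j] - grand) ** 2 for j in range(m))
    ss_ab = n_h * sum(
        (cell[(lab, j)] - row[lab] - col[j] + grand) ** 2 for lab in labels for j in range(m)
    )
    ss_subj = m * sum(
        (np.mean(y[i]) - np.mean([np.mean(y[i2]) for i2 in members[lab]])) ** 2
        for lab in labels
        for i in members[lab]
    )
    ss_resid = sum(
        (
            y[i, j]
            - np.mean(y[i])
            - cell[(lab, j)]
            + np.mean([np.mean(y[i2]) for i2 in members[lab]])
        )
        ** 2
        for lab in labels
        for i in members[lab]
        for j in range(m)
    )
    return ss_a, ss_b, ss_ab, ss_subj, ss_resid


class TestMixedAnova:
    def test_interaction_df_study_design(self, rng):
        y = rng.standard_normal((28, 4))
        res = mixed_anova(make_table(y, ["Low"] * 15 + ["High"] * 13))
        assert (res.interaction.df_num, res.interaction.df_den) == (3, 78)
        assert res.effects["group"].df_den == 26

    def test_brute_force_oracle_small(self, rng):
        y = rng.standard_normal((6, 4))
        groups = ["A", "A", "A", "B", "B", "B"]
        res = mixed_anova(make_table(y, groups))
        ss_a, ss_b, ss_ab, ss_subj, ss_resid = brute_force_mixed_ss(y, groups)
        assert res.effects["group"].ss == pytest.approx(ss_a, abs=1e-10)
        assert res.effects["emotion"].ss == pytest.approx(ss_b, abs=1e-10)
        assert res.interaction.ss == pytest.approx(ss_ab, abs=1e-10)
        assert res.ss_subject_error == pytest.approx(ss_subj, abs=1e-10)
        assert res.ss_within_error == pytest.approx(ss_resid, abs=1e-10)

    def test_brute_force_oracle_unbalanced(self, rng):
        y = rng.standard_normal((11, 4))
        groups = ["A"] * 6 + ["B"] * 5
        res = mixed_anova(make_table(y, groups))
        ss_a, ss_b, ss_ab, *_ = brute_force_mixed_ss(y, groups)
        assert res.effects["group"].ss == pytest.approx(ss_a, abs=1e-10)
        assert res.effects["emotion"].ss == pytest.approx(ss_b, abs=1e-10)
        assert res.interaction.ss == pytest.approx(ss_ab, abs=1e-10)

    def test_matches_pingouin_balanced(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.standard_normal((16, 4)) + np.array([0.2, 0.0, -0.1, 0.3])
        y[:8] += 0.4
        table = make_table(y, ["A"] * 8 + ["B"] * 8)
        res = mixed_anova(table)
        long = table.reset_index().melt(
            id_vars=["index", "group"], var_name="emotion", value_name="y"
        )
        ref = pg.mixed_anova(
            long, dv="y", within="emotion", between="group", subject="index"
        ).set_index("Source")
        assert res.interaction.F == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)
        assert res.effects["group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert res.effects["emotion"].F == pytest.approx(ref.loc["emotion", "F"], rel=1e-9)
        assert res.interaction.p == pytest.approx(ref.loc["Interaction", "p_unc"], rel=1e-9)
        assert res.interaction.partial_eta2 == pytest.approx(ref.loc["Interaction", "np2"], rel=1e-9)

    def test_subject_decomposition_invariant(self, rng):
        """SS_total = SS_between_subjects + SS_within_subjects always."""
        for n1, n2 in ((5, 4), (15, 13), (3, 9)):
            y = rng.standard_normal((n1 + n2, 4)) * rng.uniform(0.5, 2)
            res = mixed_anova(make_table(y, ["A"] * n1 + ["B"] * n2))
            assert res.ss_total == pytest.approx(
                res.ss_between_subjects + res.ss_within_subjects, rel=1e-9
            )

    def test_degenerate_data_errors(self):
        y = np.tile([0.5, 0.6, 0.7, 0.8], (8, 1))
        with pytest.raises(ValueError, match="error variance"):
            mixed_anova(make_table(y, ["A"] * 4 + ["B"] * 4))

    def test_missing_group_label_errors(self, rng):
        table = make_table(rng.standard_normal((6, 4)), ["A"] * 3 + ["B"] * 3)
        with pytest.raises(ValueError, match="missing group"):
            mixed_anova(table.drop(columns="group"), groups={"s00": "A"})


class TestSimpleEffects:
    @staticmethod
    def split_for(table):
        return GroupSplit(
            low_ids=tuple(table.index[table["group"] == "Low"]),
            high_ids=tuple(table.index[table["group"] == "High"]),
        )

    def test_identical_groups_zero_diff(self, rng):
        half = rng.standard_normal((6, 4))
        table = make_table(np.vstack([half, half]), ["Low"] * 6 + ["High"] * 6)
        for res in simple_main_effects(table, self.split_for(table)):
            assert res.mean_diff == pytest.approx(0.0, abs=1e-12)

    def test_single_emotion_separation(self, rng):
        y = rng.standard_normal((40, 4)) * 0.1
        y[:20, 2] += 1.0  # Low group advantage in FE only
        table = make_table(y, ["Low"] * 20 + ["High"] * 20)
        results = {r.emotion: r for r in simple_main_effects(table, self.split_for(table))}
        assert results["FE"].p_bonferroni < 0.05
        for emo in ("HA", "NE", "DI"):
            assert results[emo].p_bonferroni > 0.5

    def test_hand_computed_contrast(self):
        low = np.array([[0.7, 0.6, 0.8, 0.7]] * 2) + np.array([[0.0], [0.1]])
        high = np.array([[0.6, 0.6, 0.6, 0.6]] * 2) + np.array([[0.0], [0.2]])
        table = make_table(np.vstack([low, high]), ["Low"] * 2 + ["High"] * 2)
        res = {r.emotion: r for r in simple_main_effects(table, self.split_for(table))}
        assert res["HA"].mean_diff == pytest.approx(0.75 - 0.70, abs=1e-12)
        pooled = ((0.1**2 / 2) + (0.2**2 / 2)) / 2  # two one-df variances
        assert res["HA"].sem == pytest.approx(math.sqrt(pooled * (1 / 2 + 1 / 2)), abs=1e-12)
        assert res["HA"].p_bonferroni == min(1.0, 4 * res["HA"].p_uncorrected)


def enumerate_exact_p(x, y):
    """Exhaustive permutation oracle: two-tailed P(|U - mu| >= |u - mu|)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_small(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.exact and res.p == pytest.approx(0.1, abs=1e-12)
        assert res.r_rank_biserial == pytest.approx(1.0)

    def test_identical_samples(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.z == 0.0
        assert res.r_rank_biserial == pytest.approx(0.0)

    def test_study_separation_z(self, rng):
        """Fully separated groups of 15 and 13: |z| = 97.5/sqrt(15*13*29/12)."""
        low = rng.uniform(33, 39.4, 15)
        high = rng.uniform(40, 47, 13)
        res = mann_whitney(low, high)
        assert abs(res.z) == pytest.approx(97.5 / math.sqrt(15 * 13 * 29 / 12), abs=1e-12)
        assert abs(res.z) == pytest.approx(4.49, abs=0.01)
        assert res.r_rank_biserial == pytest.approx(1.0)
        assert res.r_z == pytest.approx(abs(res.z) / math.sqrt(28), abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (3, 6), (5, 5)])
    def test_exact_p_matches_enumeration(self, rng, n1, n2):
        for _ in range(5):
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2)
            res = mann_whitney(x, y)
            assert res.exact
            assert res.p == pytest.approx(enumerate_exact_p(x, y), abs=1e-12)

    def test_tie_corrected_variance(self):
        """With ties, z uses the midrank tie correction (checked against the
        explicit formula)."""
        x = [1, 2, 2, 3]
        y = [2, 3, 3, 4]
        res = mann_whitney(x, y)
        ranks = sps.rankdata(x + y)
        u = ranks[:4].sum() - 10
        _, t = np.unique(x + y, return_counts=True)
        var = 16 / 12 * (9 - (t**3 - t).sum() / (8 * 7))
        assert res.z == pytest.approx((u - 8) / math.sqrt(var), abs=1e-12)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestEffectSizeAndPower:
    def test_eta2_conversions(self):
        assert eta2_to_f(0.5) == pytest.approx(1.0)
        assert eta2_to_f(0.40) == pytest.approx(0.8165, abs=1e-4)
        # the eta^2 that corresponds to f = 0.441
        assert f_to_eta2(0.441) == pytest.approx(0.1628, abs=1e-3)
        with pytest.raises(ValueError):
            eta2_to_f(1.0)

    def test_minimality_certificate(self):
        for f in (0.3, 0.44, 0.8165):
            n = required_sample_size(f)
            assert interaction_power(n, f) >= 0.8
            assert interaction_power(n - 1, f) < 0.8

    def test_saturation_at_large_effect(self):
        assert required_sample_size(2.0) == 4  # two groups of two

    def test_monte_carlo_power_oracle(self, rng):
        """Analytic interaction power vs simulation of the generative model
        (equicorrelated within-subject errors, unit total variance)."""
        f, rho, reps = 0.5, 0.5, 600
        n_total = required_sample_size(f, rho=rho)
        n1 = n_total // 2
        delta = f * np.array([[1, -1, 1, -1], [-1, 1, -1, 1]], float)
        rej = 0
        for _ in range(reps):
            rows = []
            for gi, n in ((0, n1), (1, n_total - n1)):
                b = rng.standard_normal((n, 1))
                e = rng.standard_normal((n, 4))
                rows.append(delta[gi] + np.sqrt(rho) * b + np.sqrt(1 - rho) * e)
            table = make_table(np.vstack(rows), ["A"] * n1 + ["B"] * (n_total - n1))
            rej += mixed_anova(table).interaction.p < 0.05
        analytic = interaction_power(n_total, f, rho=rho)
        se = math.sqrt(analytic * (1 - analytic) / reps)
        assert rej / reps == pytest.approx(analytic, abs=3.5 * se)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            required_sample_size(0.0)
        with pytest.raises(ValueError):
            required_sample_size(0.5, alpha=1.5)
        with pytest.raises(ValueError):
            required_sample_size(0.5, epsilon=0.0)
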