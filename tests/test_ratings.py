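"""Composite scores, Spearman checks, split-plot ANOVA, Bonferroni post-hocs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bodylines.ratings import (
    bonferroni_posthoc,
    composite_beauty,
    mixed_anova,
    spearman_by_stimulus,
    validate_ratings,
)


def long_table(values, genders=None):
    """Build a composite-style table from a (participants x stimuli) array."""
    values = np.asarray(values, float)
    n, k = values.shape
    genders = genders or ["woman" if i % 2 == 0 else "man" for i in range(n)]
    rows = [
        {"participant": f"p{i:03d}", "gender": genders[i], "stimulus": s + 1,
         "beauty": values[i, s]}
        for i in range(n)
        for s in range(k)
    ]
    return pd.DataFrame(rows)


def rating_rows(participant, gender, stimulus, short, long_):
    return [
        {"participant": participant, "gender": gender, "stimulus": stimulus,
         "context": "short_term", "direction": "none", "rating": short},
        {"participant": participant, "gender": gender, "stimulus": stimulus,
         "context": "long_term", "direction": "none", "rating": long_},
    ]


def definitional_split_plot(values, genders):
    """Brute-force sums of squares for a balanced split-plot design.

    Classical textbook decomposition from cell and marginal means; valid for
    equal group sizes and complete within data.  Returns a dict of SS.
    """
    values = np.asarray(values, float)
    genders = np.asarray(genders)
    n, k = values.shape
    grand = values.mean()
    groups = np.unique(genders)
    ss = {}
    # between stratum
    subj_means = values.mean(axis=1)
    ss["between_groups"] = k * sum(
        np.sum(genders == g) * (subj_means[genders == g].mean() - grand) ** 2
        for g in groups
    )
    ss["subjects_within"] = k * sum(
        np.sum((subj_means[genders == g] - subj_means[genders == g].mean()) ** 2)
        for g in groups
    )
    # within stratum
    col_means = values.mean(axis=0)
    ss["within_factor"] = n * np.sum((col_means - grand) ** 2)
    inter = 0.0
    for g in groups:
        sel = genders == g
        cell = values[sel].mean(axis=0)
        inter += np.sum(sel) * np.sum(
            (cell - col_means - subj_means[sel].mean() + grand) ** 2
        )
    ss["interaction"] = inter
    ss["total"] = np.sum((values - grand) ** 2)
    ss["within_error"] = (
        ss["total"] - ss["between_groups"] - ss["subjects_within"]
        - ss["within_factor"] - ss["interaction"]
    )
    return ss


class TestCompositeBeauty:
    def test_mean_of_contexts(self):
        rows = rating_rows("p1", "woman", 1, 6.0, 8.0) + rating_rows(
            "p1", "woman", 2, 5.0, 5.0
        )
        comp, excl = composite_beauty(pd.DataFrame(rows))
        assert excl.empty
        got = comp.set_index("stimulus")["beauty"]
        assert got[1] == 7.0 and got[2] == 5.0

    def test_identical_contexts_identity(self, rng):
        rows = []
        for i in range(5):
            for s in (1, 2, 3):
                r = float(rng.uniform(0, 10))
                rows += rating_rows(f"p{i}", "man", s, r, r)
        df = pd.DataFrame(rows)
        comp, _ = composite_beauty(df)
        short = df[df.context == "short_term"].set_index(["participant", "stimulus"])
        for _, row in comp.iterrows():
            assert row["beauty"] == short.loc[(row["participant"], row["stimulus"]), "rating"]

    def test_missing_context_excluded_and_reported(self):
        rows = rating_rows("p1", "woman", 1, 6.0, 8.0)
        rows.append({"participant": "p1", "gender": "woman", "stimulus": 2,
                     "context": "short_term", "direction": "none", "rating": 4.0})
        comp, excl = composite_beauty(pd.DataFrame(rows))
        assert len(comp) == 1
        assert list(excl.itertuples(index=False)) == [("p1", 2)]

    def test_duplicate_rows_rejected(self):
        rows = rating_rows("p1", "woman", 1, 6.0, 8.0) * 2
        with pytest.raises(ValueError, match="duplicate"):
            validate_ratings(pd.DataFrame(rows))


class TestSpearman:
    def test_perfect_agreement(self, rng):
        rows = []
        for i in range(12):
            r = float(rng.uniform(0, 10))
            rows += rating_rows(f"p{i}", "man", 1, r, r)
        out = spearman_by_stimulus(pd.DataFrame(rows))
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_reversed_ranks(self, rng):
        rows = []
        for i in range(12):
            r = float(rng.uniform(1, 9))
            rows += rating_rows(f"p{i}", "man", 1, r, 10.0 - r)
        out = spearman_by_stimulus(pd.DataFrame(rows))
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle_with_ties(self):
        short = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 7.0, 8.0, 9.0])
        long_ = np.array([2.0, 1.0, 3.0, 3.0, 4.0, 6.0, 5.0, 8.0, 7.0, 9.0])
        rows = []
        for i, (s, l) in enumerate(zip(short, long_)):
            rows += rating_rows(f"p{i}", "man", 1, s, l)
        out = spearman_by_stimulus(pd.DataFrame(rows))

        # oracle: Pearson correlation of average ranks (handles ties exactly)
        def avg_ranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x))
            sx = x[order]
            i = 0
            while i < len(x):
                j = i
                while j < len(x) and sx[j] == sx[i]:
                    j += 1
                ranks[order[i:j]] = (i + j - 1) / 2.0 + 1.0
                i = j
            return ranks
        ra, rb = avg_ranks(short), avg_ranks(long_)
        rho_oracle = np.corrcoef(ra, rb)[0, 1]
        assert out.loc[0, "rho"] == pytest.approx(rho_oracle, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        rows = rating_rows("p1", "man", 1, 1, 2) + rating_rows("p2", "man", 1, 3, 4)
        with pytest.raises(ValueError, match="< 3"):
            spearman_by_stimulus(pd.DataFrame(rows))


class TestMixedAnova:
    def test_toy_design_matches_definitional_oracle(self):
        values = np.array([[3.0, 5.0], [4.0, 7.0], [6.0, 6.0], [8.0, 9.0]])
        genders = ["woman", "woman", "man", "man"]
        table = long_table(values, genders)
        rep = mixed_anova(table, between="gender")
        oracle = definitional_split_plot(values, genders)
        got = rep.table.set_index("effect")["ss"]
        assert got["gender"] == pytest.approx(oracle["between_groups"], abs=1e-10)
        assert got["stimulus"] == pytest.approx(oracle["within_factor"], abs=1e-10)
        assert got["stimulus x gender"] == pytest.approx(oracle["interaction"], abs=1e-10)
        assert rep.error_ss["between_error"] == pytest.approx(
            oracle["subjects_within"], abs=1e-10
        )
        assert rep.error_ss["within_error"] == pytest.approx(
            oracle["within_error"], abs=1e-10
        )

    @pytest.mark.parametrize("n_per_group,k,seed", [(2, 3, 1), (4, 2, 2), (3, 3, 3)])
    def test_small_designs_match_oracle_F(self, n_per_group, k, seed):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_group
        values = rng.uniform(0, 10, size=(n, k))
        genders = ["woman"] * n_per_group + ["man"] * n_per_group
        rep = mixed_anova(long_table(values, genders), between="gender")
        oracle = definitional_split_plot(values, genders)
        n_groups = 2
        f_within = (oracle["within_factor"] / (k - 1)) / (
            oracle["within_error"] / ((n - n_groups) * (k - 1))
        )
        f_between = (oracle["between_groups"] / 1) / (
            oracle["subjects_within"] / (n - n_groups)
        )
        got = rep.table.set_index("effect")
        assert got.loc["stimulus", "F"] == pytest.approx(f_within, rel=1e-10)
        assert got.loc["gender", "F"] == pytest.approx(f_between, rel=1e-10)

    def test_ss_conservation_balanced(self):
        for seed in range(4):
            rng = np.random.default_rng(seed)
            values = rng.uniform(0, 10, size=(8, 4))
            rep = mixed_anova(long_table(values), between="gender")
            total = rep.error_ss["total"]
            parts = (
                rep.table["ss"].sum()
                + rep.error_ss["between_error"]
                + rep.error_ss["within_error"]
            )
            assert parts == pytest.approx(total, rel=1e-8)

    def test_zero_variance_gives_zero_F(self):
        values = np.full((6, 3), 5.0)
        rep = mixed_anova(long_table(values), between="gender")
        assert np.all(rep.table["F"].to_numpy() == 0.0)
        assert np.all(rep.table["p"].to_numpy() == 1.0)
        assert rep.epsilon == 1.0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 10, size=(10, 4))
        t1 = long_table(values)
        t2 = long_table(3.5 * values + 2.0)
        r1 = mixed_anova(t1, between="gender")
        r2 = mixed_anova(t2, between="gender")
        for col in ("F", "p", "ges"):
            assert np.allclose(
                r1.table[col].to_numpy(), r2.table[col].to_numpy(),
                rtol=1e-9, atol=1e-12,
            )
        assert r1.epsilon == pytest.approx(r2.epsilon, rel=1e-9)

    def test_greenhouse_geisser_epsilon_compound_symmetry(self):
        # compound-symmetric covariance (shared subject effect + iid noise)
        # is spherical, so epsilon should be near 1 at n = 200
        rng = np.random.default_rng(11)
        n, k = 200, 5
        values = rng.normal(0, 2, n)[:, None] + rng.normal(0, 1, (n, k))
        rep = mixed_anova(long_table(values), between="gender")
        assert rep.epsilon == pytest.approx(1.0, abs=0.05)
        assert rep.table["df1_corr"].max() <= rep.table["df1"].max()

    def test_matches_pingouin_one_between(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        n, k = 40, 5  # balanced groups: conventions coincide exactly
        effect = np.linspace(0, 1.5, k)
        values = (
            effect[None, :]
            + rng.normal(0, 1.0, n)[:, None]
            + rng.normal(0, 0.8, (n, k))
        )
        genders = ["woman"] * (n // 2) + ["man"] * (n // 2)
        values[np.array(genders) == "woman"] += 1.0
        table = long_table(values, genders)
        ours = mixed_anova(table, between="gender").table.set_index("effect")
        theirs = pg.mixed_anova(
            data=table, dv="beauty", within="stimulus", subject="participant",
            between="gender", correction=True,
        ).set_index("Source")
        assert ours.loc["gender", "F"] == pytest.approx(
            theirs.loc["gender", "F"], rel=1e-8
        )
        assert ours.loc["stimulus", "F"] == pytest.approx(
            theirs.loc["stimulus", "F"], rel=1e-8
        )
        assert ours.loc["stimulus x gender", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-8
        )
        # epsilon conventions differ slightly: we pool the within-group
        # covariance (sphericity is a within-group assumption in a split
        # plot), pingouin uses the total covariance
        assert ours.loc["stimulus", "epsilon"] == pytest.approx(
            theirs.loc["stimulus", "eps"], rel=1e-2
        )

    def test_two_between_factors_supported(self):
        rng = np.random.default_rng(9)
        rows = []
        for g in ("woman", "man"):
            for d in ("left", "right"):
                for i in range(5):
                    pid = f"{g}-{d}-{i}"
                    for s in range(1, 4):
                        rows.append(
                            {"participant": pid, "gender": g, "direction": d,
                             "stimulus": s, "beauty": float(rng.uniform(0, 10))}
                        )
        rep = mixed_anova(pd.DataFrame(rows), between=["gender", "direction"])
        effects = set(rep.table["effect"])
        assert {
            "gender", "direction", "gender x direction", "stimulus",
            "stimulus x gender", "stimulus x direction",
            "stimulus x gender x direction",
        } <= effects

    def test_incomplete_participants_dropped_and_reported(self):
        values = np.random.default_rng(0).uniform(0, 10, size=(6, 3))
        table = long_table(values)
        table = table[~((table.participant == "p000") & (table.stimulus == 2))]
        rep = mixed_anova(table, between="gender")
        assert rep.dropped_participants == ("p000",)

    def test_small_between_cell_rejected(self):
        values = np.random.default_rng(0).uniform(0, 10, size=(3, 3))
        with pytest.raises(ValueError, match="< 2"):
            mixed_anova(long_table(values, ["woman", "man", "man"]), between="gender")


class TestBonferroniPosthoc:
    def test_identical_columns(self):
        values = np.tile(np.random.default_rng(0).uniform(0, 10, 8)[:, None], (1, 3))
        out = bonferroni_posthoc(long_table(values))
        assert np.all(out["t"] == 0.0)
        assert np.all(out["p_adj"] == 1.0)

    def test_multiplication_rule_and_df(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 10, size=(15, 5))
        out = bonferroni_posthoc(long_table(values))
        m = len(out)
        assert m == 10
        assert np.allclose(out["p_adj"], np.minimum(1.0, out["p"] * m))
        assert np.all(out["df"] == 14)

    def test_bonferroni_dominance_and_monotonicity(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 10, size=(12, 4)) + np.arange(4) * 0.8
        out = bonferroni_posthoc(long_table(values))
        assert np.all(out["p_adj"] >= out["p"] - 1e-15)
        srt = out.sort_values("p")
        assert np.all(np.diff(srt["p_adj"].to_numpy()) >= -1e-15)

    def test_single_level_rejected(self):
        values = np.random.default_rng(0).uniform(0, 10, size=(6, 1))
        with pytest.raises(ValueError):
            bonferroni_posthoc(long_table(values))
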