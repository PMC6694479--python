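"""Feature ranking, kernel screening, gene-set kernels, survival cutoffs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from multikernel import (
    GeneSetCollection,
    KernelSpec,
    compute_gram,
    dichotomize_survival,
    geneset_kernel_specs,
    median_heuristic_sigma,
    ovarian_preset,
    rank_features,
    screen_kernels,
    select_top_features,
)
from multikernel.prioritization import PrioritizationError


def expression_table(rng, n=40, p=30, n_inf=3, effect=2.0):
    y = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    X = rng.normal(size=(n, p))
    X[:, :n_inf] += (effect / 2) * y[:, None]
    df = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                      columns=[f"g{j}" for j in range(p)])
    return df, y


class TestRankFeatures:
    @pytest.mark.parametrize("method", ["t", "wilcoxon"])
    def test_perfectly_separating_feature_ranks_first(self, rng, method):
        n = 30
        y = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        X = pd.DataFrame(
            {"perfect": 2.0 * y, "noise": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)],
        )
        ranking = rank_features(X, y, method)
        assert ranking.ordered_features[0] == "perfect"
        assert ranking.pvalues["perfect"] < 1e-6

    def test_constant_feature_flagged_with_p_one(self, rng):
        n = 20
        y = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        X = pd.DataFrame(
            {"const": np.ones(n), "ok": rng.normal(size=n) + y},
            index=[f"s{i}" for i in range(n)],
        )
        ranking = rank_features(X, y, "t")
        assert ranking.pvalues["const"] == 1.0
        assert bool(ranking.table.loc["const", "flagged"])
        assert "const" in ranking.ordered_features  # not silently dropped

    def test_informative_recall_in_top_ranks(self):
        """5 informative among 500 nulls, shift 1.5 sd, n = 100."""
        recalls = []
        for seed in range(8):
            r = np.random.default_rng(seed)
            n, p = 100, 500
            y = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
            X = r.normal(size=(n, p))
            X[:, :5] += 0.75 * y[:, None]  # 1.5 sd between-group shift
            df = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                              columns=[f"g{j}" for j in range(p)])
            top10 = select_top_features(rank_features(df, y, "t"), 10)
            recalls.append(len(set(top10) & {f"g{j}" for j in range(5)}) / 5)
        assert np.mean(recalls) >= 0.8

    def test_ranking_requires_two_groups(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)), index=[f"s{i}" for i in range(10)])
        with pytest.raises(PrioritizationError):
            rank_features(X, np.ones(10), "t")
        with pytest.raises(PrioritizationError):
            rank_features(X, np.r_[np.ones(9), [-1.0]], "bogus")


class TestSelectTop:
    def test_prefix_consistency(self, rng):
        df, y = expression_table(rng, p=50)
        ranking = rank_features(df, y, "t")
        top10 = select_top_features(ranking, 10)
        top25 = select_top_features(ranking, 25)
        assert top25[:10] == top10
        assert select_top_features(ranking, 50) == ranking.ordered_features

    def test_invalid_k(self, rng):
        df, y = expression_table(rng)
        ranking = rank_features(df, y, "t")
        for k in (0, -1, df.shape[1] + 1):
            with pytest.raises(PrioritizationError):
                select_top_features(ranking, k)

    def test_selection_depends_on_rows_used(self, rng):
        """Selecting on train+test rows changes the list: leakage is real."""
        df, y = expression_table(rng, n=60, effect=0.8)
        train = df.index[:40]
        r_train = rank_features(df.loc[train], y[:40], "t")
        r_all = rank_features(df, y, "t")
        assert select_top_features(r_train, 5) != select_top_features(r_all, 5)


class TestScreening:
    @staticmethod
    def _screening_problem(seed, n=160, p_noise=20, frac_pos=0.65):
        rng = np.random.default_rng(seed)
        n_pos = int(round(n * frac_pos))
        y = np.r_[np.ones(n_pos), -np.ones(n - n_pos)]
        X = pd.DataFrame(
            rng.normal(size=(n, p_noise + 2)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"f{j}" for j in range(p_noise + 2)],
        )
        X[["f0", "f1"]] = X[["f0", "f1"]].to_numpy() + 1.0 * y[:, None]
        noise_cols = tuple(f"f{j}" for j in range(2, p_noise + 2))
        specs = [
            KernelSpec("radial", sigma=median_heuristic_sigma(X[list(noise_cols)]),
                       feature_subset=noise_cols, name="noise"),
            KernelSpec("radial", sigma=median_heuristic_sigma(X[["f0", "f1"]]),
                       feature_subset=("f0", "f1"), name="informative"),
        ]
        return X, y, specs

    def test_noise_eliminated_informative_kept(self):
        noise_out = inf_in = 0
        for seed in range(5):
            X, y, specs = self._screening_problem(seed)
            res = screen_kernels(X, y, specs, folds=10, seed=seed)
            names = [s.name for s in res.survivors]
            noise_out += "noise" not in names
            inf_in += "informative" in names
        assert inf_in == 5
        assert noise_out >= 4

    def test_survivors_carry_best_hyperparameters(self):
        X, y, specs = self._screening_problem(0)
        res = screen_kernels(X, y, specs, folds=5, seed=0)
        assert len(res.survivor_C) == len(res.survivors)
        assert all(c in (0.01, 0.1, 1.0, 10.0, 100.0) for c in res.survivor_C)

    def test_all_eliminated_raises(self):
        rng = np.random.default_rng(0)
        n = 100
        y = np.r_[np.ones(65), -np.ones(35)]
        X = pd.DataFrame(rng.normal(size=(n, 10)),
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"f{j}" for j in range(10)])
        spec = KernelSpec("radial", sigma=0.02, name="noise")
        with pytest.raises(PrioritizationError, match="no surviving"):
            screen_kernels(X, y, [spec], folds=10, seed=0)

    def test_accuracy_equal_to_nir_is_eliminated(self):
        """Majority-class collapse scores exactly NIR and must not survive."""
        rng = np.random.default_rng(1)
        n = 100
        y = np.r_[np.ones(70), -np.ones(30)]
        X = pd.DataFrame(rng.normal(size=(n, 5)) * 1e-8,  # effectively constant
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"f{j}" for j in range(5)])
        spec = KernelSpec("radial", sigma=1.0, name="flat")
        with pytest.raises(PrioritizationError):
            screen_kernels(X, y, [spec], folds=10, seed=1)


class TestGeneSets:
    def test_gmt_round_trip(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text(
            "SET_A\tfirst set\tg1\tg2\tg3\n"
            "SET_B\tsecond set\tg2\tg4\n"
        )
        coll = GeneSetCollection.from_gmt(gmt)
        assert len(coll) == 2
        assert coll.sets["SET_A"] == ("g1", "g2", "g3")
        assert coll.descriptions["SET_B"] == "second set"

    def test_malformed_gmt_rejected(self, tmp_path):
        bad = tmp_path / "bad.gmt"
        bad.write_text("ONLY_NAME\tdesc\n")
        with pytest.raises(PrioritizationError, match="malformed"):
            GeneSetCollection.from_gmt(bad)
        dup = tmp_path / "dup.gmt"
        dup.write_text("S\td\tg1\nS\td\tg2\n")
        with pytest.raises(PrioritizationError, match="duplicate"):
            GeneSetCollection.from_gmt(dup)

    def test_one_spec_per_intersecting_set(self):
        coll = GeneSetCollection(
            sets={"A": ("g1", "g2"), "B": ("g3", "gX"), "EMPTY": ("gZ",)}
        )
        specs = geneset_kernel_specs(["g1", "g2", "g3"], coll, KernelSpec("linear"))
        by_name = {s.name: s for s in specs}
        assert set(by_name) == {"A", "B"}  # EMPTY dropped with a warning
        assert by_name["A"].feature_subset == ("g1", "g2")
        assert by_name["B"].feature_subset == ("g3",)

    def test_all_empty_raises(self):
        coll = GeneSetCollection(sets={"A": ("gX",)})
        with pytest.raises(PrioritizationError):
            geneset_kernel_specs(["g1"], coll, KernelSpec("linear"))

    def test_restricted_specs_match_projected_tables(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)),
                          index=[f"s{i}" for i in range(10)],
                          columns=["g1", "g2", "g3", "g4"])
        coll = GeneSetCollection(sets={"A": ("g2", "g4")})
        (spec,) = geneset_kernel_specs(list(df.columns), coll, KernelSpec("linear"))
        full = compute_gram(df, df, spec).values
        proj = compute_gram(df[["g2", "g4"]], df[["g2", "g4"]], KernelSpec("linear")).values
        np.testing.assert_allclose(full, proj)


class TestDichotomize:
    def test_textbook_example(self):
        times = np.arange(1.0, 11.0)
        labels, cutoff, kept = dichotomize_survival(times, np.ones(10, dtype=int))
        assert cutoff == pytest.approx(5.5)
        assert np.mean(labels > 0) == pytest.approx(0.5)
        assert len(kept) == 10

    def test_censored_patients_excluded(self):
        times = np.arange(1.0, 11.0)
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1, 0, 1])
        labels, _, kept = dichotomize_survival(times, event, min_kept=5)
        assert len(kept) == 7
        assert labels.size == 7

    def test_identical_event_times_fail(self):
        with pytest.raises(PrioritizationError):
            dichotomize_survival(np.full(20, 3.0), np.ones(20, dtype=int))

    def test_infeasible_band_fails_explicitly(self):
        # tied event times: the only cutoff splits 15/5, outside 40-60%
        times = np.r_[np.full(15, 1.0), np.full(5, 2.0)]
        with pytest.raises(PrioritizationError, match="no cutoff"):
            dichotomize_survival(times, np.ones(20, dtype=int))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_success_implies_proportion_in_band(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(12, 60))
        times = r.lognormal(3.0, 1.0, size=n)
        event = (r.random(n) < 0.8).astype(int)
        try:
            labels, cutoff, kept = dichotomize_survival(times, event, min_kept=5)
        except PrioritizationError:
            return  # explicit failure is acceptable
        prop = float(np.mean(labels > 0))
        assert 0.4 <= prop <= 0.6
        assert np.all((labels > 0) == (times[np.asarray(event) != 0] > cutoff))


def test_median_heuristic_and_preset(rng):
    X = pd.DataFrame(rng.normal(size=(30, 4)))
    sigma = median_heuristic_sigma(X)
    assert sigma > 0
    preset = ovarian_preset([f"g{j}" for j in range(5)], "stage", "age",
                            n_stage_levels=4, age_sigma=sigma)
    assert len(preset["expression"]) == 4  # linear + 3 radial widths
    assert {s.kind for s in preset["clinical"]} == {"clinical_ordinal", "radial"}
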