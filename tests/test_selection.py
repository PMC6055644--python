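"""BIC scoring, all-subsets search, VIF computation and pruning."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ch4pred import all_subsets, bic_score, prune_collinear, vif_scores


def toy_frame(n=200, seed=0, collinear=False):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0, 1, n)
    x2 = rng.normal(0, 1, n)
    x3 = 0.8 * x1 + 0.5 * x2 + rng.normal(0, 0.3, n)
    df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3,
                       "y": 2 * x1 + rng.normal(0, 1, n),
                       "group_id": "g1",
                       "study_id": np.repeat([f"s{i}" for i in range(4)],
                                             n // 4)})
    if collinear:
        df["x1_copy"] = df["x1"]
    return df


class TestBic:
    def test_worked_value(self):
        assert bic_score(100, 100, 2) == pytest.approx(9.2103, abs=5e-4)

    def test_closed_form_when_sse_equals_n(self):
        for n, p in [(10, 1), (500, 3), (2566, 6)]:
            assert bic_score(n, n, p) == pytest.approx(p * math.log(n))

    def test_penalty_per_coefficient(self):
        base = bic_score(50.0, 300, 2)
        assert bic_score(50.0, 300, 3) - base == pytest.approx(math.log(300))

    def test_nonpositive_sse_rejected(self):
        with pytest.raises(ValueError):
            bic_score(0.0, 10, 1)


class TestVif:
    def test_orthogonal_predictors(self):
        n = 64
        df = pd.DataFrame({"a": np.tile([1.0, -1.0], n // 2),
                           "b": np.repeat([1.0, -1.0], n // 2)})
        vifs = vif_scores(df, ["a", "b"])
        assert vifs["a"] == pytest.approx(1.0, abs=1e-9)
        assert vifs["b"] == pytest.approx(1.0, abs=1e-9)

    def test_exact_duplicate_is_inf(self):
        df = toy_frame(collinear=True)
        vifs = vif_scores(df, ["x1", "x1_copy", "x2"])
        assert math.isinf(vifs["x1"]) and math.isinf(vifs["x1_copy"])
        assert math.isfinite(vifs["x2"])

    def test_matches_auxiliary_regressions(self):
        df = toy_frame(seed=3)
        preds = ["x1", "x2", "x3"]
        vifs = vif_scores(df, preds)
        for j, name in enumerate(preds):
            others = [p for p in preds if p != name]
            X = np.column_stack([np.ones(len(df))]
                                + [df[p].to_numpy() for p in others])
            yj = df[name].to_numpy()
            beta, *_ = np.linalg.lstsq(X, yj, rcond=None)
            resid = yj - X @ beta
            r2 = 1 - resid @ resid / ((yj - yj.mean()) @ (yj - yj.mean()))
            assert vifs[name] == pytest.approx(1 / (1 - r2), rel=1e-8)


class TestPrune:
    def test_all_below_threshold_untouched(self):
        df = toy_frame()
        retained, removed = prune_collinear(df, ["x1", "x2"], threshold=5)
        assert retained == ["x1", "x2"] and removed == []

    def test_duplicate_removed_first_kept(self):
        df = toy_frame(collinear=True)
        retained, removed = prune_collinear(df, ["x1", "x1_copy", "x2"])
        assert retained == ["x1", "x2"]
        assert removed[0][0] == "x1_copy" and math.isinf(removed[0][1])

    def test_removal_order_matches_stepwise_oracle(self):
        rng = np.random.default_rng(8)
        n = 150
        base = rng.normal(0, 1, n)
        df = pd.DataFrame({
            "a": base + rng.normal(0, 0.1, n),
            "b": base + rng.normal(0, 0.1, n),
            "c": base + rng.normal(0, 0.15, n),
            "d": rng.normal(0, 1, n),
        })
        preds = ["a", "b", "c", "d"]
        retained, removed = prune_collinear(df, preds, threshold=5)
        # oracle: recompute at each step
        cur = list(preds)
        expected = []
        while len(cur) >= 2:
            vifs = vif_scores(df, cur)
            worst = max(vifs.values())
            if worst <= 5:
                break
            victim = [p for p in cur if vifs[p] == worst][-1]
            cur.remove(victim)
            expected.append(victim)
        assert [p for p, _ in removed] == expected
        assert retained == cur

    def test_terminates_within_bound(self):
        df = toy_frame(collinear=True)
        df["x1_copy2"] = df["x1"]
        retained, removed = prune_collinear(df, ["x1", "x1_copy", "x1_copy2"])
        assert len(removed) <= 3 and len(retained) >= 1


class TestAllSubsets:
    def test_single_candidate(self):
        df = toy_frame()
        res = all_subsets(df, ["x1"], "y")
        assert res.best == ("x1",)

    def test_ranked_list_is_complete(self):
        df = toy_frame()
        res = all_subsets(df, ["x1", "x2", "x3"], "y", vif_order="none")
        assert len(res.candidates) == 2 ** 3 - 1
        bics = [b for _, b in res.candidates]
        assert bics == sorted(bics)

    def test_recovers_sparse_truth(self):
        df = toy_frame(n=2000, seed=1)
        res = all_subsets(df, ["x1", "x2"], "y")
        assert res.best == ("x1",)

    def test_permutation_invariant_best(self):
        df = toy_frame(seed=5)
        best = None
        for perm in itertools.permutations(["x1", "x2", "x3"]):
            res = all_subsets(df, list(perm), "y", vif_order="none")
            if best is None:
                best = set(res.best)
            assert set(res.best) == best

    def test_noise_predictor_raises_bic(self):
        rng = np.random.default_rng(12)
        n = 5000
        df = pd.DataFrame({"x1": rng.normal(0, 1, n),
                           "noise": rng.normal(0, 1, n)})
        df["y"] = 2 * df["x1"] + rng.normal(0, 1, n)
        res = all_subsets(df, ["x1", "noise"], "y", vif_order="none")
        scores = dict(res.candidates)
        assert scores[("x1",)] < scores[("x1", "noise")]
        assert res.best == ("x1",)

    def test_lmm_engine_runs(self, sim_small_frame):
        df, _ = sim_small_frame
        res = all_subsets(df, ["dmi", "ndf"], "ch4", engine="lmm",
                          vif_order="none")
        assert len(res.candidates) == 3
        assert "dmi" in res.best

    def test_too_many_candidates_rejected(self):
        df = toy_frame()
        with pytest.raises(ValueError, match="prune"):
            all_subsets(df, [f"c{i}" for i in range(13)], "y")

    def test_vif_prune_before_search(self):
        df = toy_frame(collinear=True)
        res = all_subsets(df, ["x1", "x1_copy", "x2"], "y")
        assert res.removed_collinear[0][0] == "x1_copy"
        assert all("x1_copy" not in s for s, _ in res.candidates)
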