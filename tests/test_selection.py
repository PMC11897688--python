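"""Factor-subset enumeration, the model sweep and hierarchical selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import laiproj as lp
from laiproj import ArgumentError
from laiproj.io_preprocess import extract_region_frame
from laiproj.metrics import DisoScore
from laiproj.selection import (
    EvaluatedModel,
    FactorCombination,
    ModelSpec,
    best_per_combo,
    best_per_combo_algo,
    enumerate_combinations,
    evaluate_all,
    select_optimum,
)


class TestEnumeration:
    def test_five_factors_give_31_combinations(self):
        combos = enumerate_combinations(lp.FACTORS)
        assert len(combos) == 31
        assert [c.index for c in combos] == list(range(1, 32))

    def test_canonical_ordering(self):
        combos = enumerate_combinations(lp.FACTORS)
        # singletons 1-5 in factor order, first pair ET+SM, last the quintuple
        assert [c.members for c in combos[:5]] == [(f,) for f in lp.FACTORS]
        assert combos[5].members == ("ET", "SM")
        assert combos[30].members == lp.FACTORS
        sizes = [len(c.members) for c in combos]
        assert sizes == sorted(sizes)

    def test_single_factor(self):
        assert len(enumerate_combinations(["SM"])) == 1

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_powerset_oracle(self, k):
        factors = lp.FACTORS[:k]
        combos = enumerate_combinations(factors)
        oracle = set()
        for r in range(1, k + 1):
            oracle |= set(itertools.combinations(factors, r))
        assert {c.members for c in combos} == oracle
        assert len(combos) == 2**k - 1

    def test_empty_list_rejected(self):
        with pytest.raises(ArgumentError):
            enumerate_combinations([])

    def test_duplicate_members_rejected(self):
        with pytest.raises(ArgumentError):
            FactorCombination(members=("SM", "SM"), index=1)


def _fake_models(rng, n_combos=4, datasets=("A", "B", "C"), algos=("LR", "SVR")):
    combos = enumerate_combinations(lp.FACTORS[:2])[:n_combos]
    out = []
    for combo in combos:
        for algo in algos:
            for ds in datasets:
                out.append(
                    EvaluatedModel(
                        spec=ModelSpec("R", ds, combo, algo),
                        model=None,
                        score=DisoScore(float(rng.uniform(0.1, 2.0))),
                    )
                )
    return out, combos


class TestHierarchicalSelection:
    def test_best_per_combo_algo_matches_groupby_oracle(self, rng):
        models, combos = _fake_models(rng)
        table = best_per_combo_algo(models, dataset_order=("A", "B", "C"))
        assert len(table) == len(combos) * 2
        for em in table:
            peers = [m for m in models
                     if m.spec.combination.index == em.spec.combination.index
                     and m.spec.algorithm_id == em.spec.algorithm_id]
            assert em.score.value == min(p.score.value for p in peers)

    def test_best_per_combo_matches_groupby_oracle(self, rng):
        models, combos = _fake_models(rng)
        t186 = best_per_combo_algo(models, dataset_order=("A", "B", "C"))
        t31 = best_per_combo(t186)
        assert len(t31) == len(combos)
        for em in t31:
            peers = [m for m in t186
                     if m.spec.combination.index == em.spec.combination.index]
            assert em.score.value == min(p.score.value for p in peers)

    def test_optimum_is_global_minimum(self, rng):
        models, _ = _fake_models(rng)
        opt = select_optimum(models, dataset_order=("A", "B", "C"))
        assert opt.score.value == min(m.score.value for m in models)

    def test_tie_prefers_fewer_factors(self):
        short = EvaluatedModel(
            ModelSpec("R", "A", FactorCombination(("SM", "CO2"), 12), "LR"),
            None, DisoScore(0.5))
        long = EvaluatedModel(
            ModelSpec("R", "A", FactorCombination(("ET", "SM", "Pre", "Tmp"), 26), "LR"),
            None, DisoScore(0.5))
        assert select_optimum([long, short]).spec.combination.members == ("SM", "CO2")

    def test_dataset_tie_breaks_by_order(self):
        combo = FactorCombination(("SM",), 2)
        a = EvaluatedModel(ModelSpec("R", "CanESM5", combo, "LR"), None, DisoScore(0.4))
        b = EvaluatedModel(ModelSpec("R", "MME", combo, "LR"), None, DisoScore(0.4))
        table = best_per_combo_algo([b, a], dataset_order=("CanESM5", "MME"))
        assert table[0].spec.dataset_id == "CanESM5"

    def test_empty_table_rejected(self):
        with pytest.raises(ArgumentError):
            select_optimum([])


def _toy_obs_and_frames(rng, n=120):
    idx = pd.date_range("2000-01-01", periods=n, freq="MS")
    frames = {}
    for ds, noise in (("A", 0.05), ("B", 0.2)):
        frames[ds] = pd.DataFrame(
            {f: rng.standard_normal(n) for f in lp.FACTORS}, index=idx
        )
    truth = frames["A"]
    obs = pd.Series(
        2 + truth["SM"] + truth["CO2"] + 0.05 * rng.standard_normal(n),
        index=idx,
    )
    return obs, frames


class TestEvaluateAll:
    def test_count_identity(self, rng):
        obs, frames = _toy_obs_and_frames(rng)
        combos = enumerate_combinations(lp.FACTORS[:2])  # 3 combos
        models, failures = evaluate_all(
            obs, frames, algorithms=["LR", "SVR"], combinations=combos,
            master_seed=1,
        )
        assert len(models) == 3 * 2 * 2
        assert failures == 0

    def test_degenerate_single_model_sweep(self, rng):
        obs, frames = _toy_obs_and_frames(rng)
        combos = [enumerate_combinations(lp.FACTORS)[0]]
        models, _ = evaluate_all(obs, {"A": frames["A"]}, algorithms=["LR"],
                                 combinations=combos, master_seed=1)
        assert len(models) == 1
        assert math.isfinite(models[0].score.value)

    def test_deterministic_under_fixed_seed(self, rng):
        obs, frames = _toy_obs_and_frames(rng)
        combos = enumerate_combinations(lp.FACTORS[:2])
        m1, _ = evaluate_all(obs, frames, algorithms=["LR", "RF"],
                             combinations=combos, master_seed=7)
        m2, _ = evaluate_all(obs, frames, algorithms=["LR", "RF"],
                             combinations=combos, master_seed=7)
        assert [m.score.value for m in m1] == [m.score.value for m in m2]

    def test_fit_failure_scores_infinity_not_abort(self, rng):
        idx = pd.date_range("2000-01-01", periods=9, freq="MS")
        obs = pd.Series(rng.standard_normal(9), index=idx)
        frames = {"A": pd.DataFrame({f: rng.standard_normal(9) for f in lp.FACTORS},
                                    index=idx)}
        combos = [enumerate_combinations(lp.FACTORS)[-1]]  # 5 factors, needs 10
        models, failures = evaluate_all(obs, frames, algorithms=["LR"],
                                        combinations=combos, master_seed=1)
        assert failures == 1
        assert math.isinf(models[0].score.value)

    def test_misaligned_dataset_rejected(self, rng):
        obs, frames = _toy_obs_and_frames(rng)
        bad = frames["A"].iloc[:-6]
        with pytest.raises(ArgumentError):
            evaluate_all(obs, {"A": bad}, algorithms=["LR"],
                         combinations=[enumerate_combinations(lp.FACTORS)[0]])

    def test_removing_a_dataset_never_improves_optimum(self, rng):
        obs, frames = _toy_obs_and_frames(rng)
        combos = enumerate_combinations(lp.FACTORS[:3])
        full, _ = evaluate_all(obs, frames, algorithms=["LR"],
                               combinations=combos, master_seed=3)
        sub, _ = evaluate_all(obs, {"A": frames["A"]}, algorithms=["LR"],
                              combinations=combos, master_seed=3)
        assert (min(m.score.value for m in sub)
                >= min(m.score.value for m in full) - 1e-12)


class TestProjection:
    def test_lr_optimum_extrapolates_linearly(self, rng):
        idx = pd.date_range("2000-01-01", periods=60, freq="MS")
        t = np.arange(60, dtype=float)
        frame = pd.DataFrame({"SM": t, "CO2": 2 * t}, index=idx)
        obs = pd.Series(1.0 + 0.5 * frame["SM"] + 0.25 * frame["CO2"], index=idx)
        combo = FactorCombination(("SM", "CO2"), 12)
        models, _ = evaluate_all(obs, {"A": frame}, algorithms=["LR"],
                                 combinations=[combo], master_seed=0)
        fut_idx = pd.date_range("2005-01-01", periods=24, freq="MS")
        tf = np.arange(60, 84, dtype=float)
        future = pd.DataFrame({"SM": tf, "CO2": 2 * tf}, index=fut_idx)
        series = lp.project(models[0], future)
        np.testing.assert_allclose(series.to_numpy(), 1.0 + 0.5 * tf + 0.5 * tf,
                                   atol=1e-6)
        assert len(series) == 24

    def test_missing_factor_in_scenario_rejected(self, rng):
        obs, frames = _toy_obs_and_frames(rng)
        combo = FactorCombination(("SM", "CO2"), 12)
        models, _ = evaluate_all(obs, {"A": frames["A"]}, algorithms=["LR"],
                                 combinations=[combo], master_seed=0)
        bad = frames["A"][["SM"]]
        with pytest.raises(lp.ContractError):
            lp.project(models[0], bad)


class TestRunRegion:
    def test_region_specific_truth_recovered(self):
        """Different generating combos per latitude band are found per region."""
        cfg = lp.SynthConfig(
            seed=5,
            region_combos={"N-High": ("Tmp",), "Trop": ("Pre", "CO2"),
                           "default": ("SM", "CO2")},
        )
        clim = lp.simulate_factor_bundles(cfg)
        lai, gt = lp.simulate_lai(clim)
        for rname, truth in (("N-High", {"Tmp"}), ("Trop", {"Pre", "CO2"})):
            region = lp.REGIONS_BY_NAME[rname]
            obs = lp.extract_region(lai, region)
            esm = {b.dataset_id: extract_region_frame(b, region)
                   for b in clim.historical}
            out = lp.run_region(rname, obs, esm, algorithms=["LR"], master_seed=5)
            members = set(out.selection.optimum.spec.combination.members)
            assert truth <= members

    def test_projections_cover_every_scenario(self):
        cfg = lp.SynthConfig(seed=9)
        clim = lp.simulate_factor_bundles(cfg)
        lai, _ = lp.simulate_lai(clim)
        region = lp.REGIONS_BY_NAME["Global"]
        obs = lp.extract_region(lai, region)
        esm = {b.dataset_id: extract_region_frame(b, region)
               for b in clim.historical}
        scen = {s: {b.dataset_id: extract_region_frame(b, region) for b in bl}
                for s, bl in clim.scenarios.items()}
        out = lp.run_region("Global", obs, esm, scenario_frames=scen,
                            algorithms=["LR"], master_seed=9)
        assert set(out.projections) == set(cfg.scenarios)
        for series in out.projections.values():
            assert len(series) == 1032
            assert np.isfinite(series.to_numpy()).all()

    def test_identical_seeds_give_identical_selection(self):
        cfg = lp.SynthConfig(seed=3)
        clim = lp.simulate_factor_bundles(cfg)
        lai, _ = lp.simulate_lai(clim)
        region = lp.REGIONS_BY_NAME["Global"]
        obs = lp.extract_region(lai, region)
        esm = {b.dataset_id: extract_region_frame(b, region)
               for b in clim.historical}
        o1 = lp.run_region("Global", obs, esm, algorithms=["LR", "SVR"],
                           master_seed=4)
        o2 = lp.run_region("Global", obs, esm, algorithms=["LR", "SVR"],
                           master_seed=4)
        assert ([m.score.value for m in o1.selection.all_models]
                == [m.score.value for m in o2.selection.all_models])
        assert (o1.selection.optimum.spec == o2.selection.optimum.spec)
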