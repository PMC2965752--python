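"""Generator behavior: Mendelian ratios, survival arithmetic, seed
determinism, and type invariants."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from smnmod.simulate import (
    ConfigurationError,
    LethalityCounts,
    ModifierEffect,
    PumpingTrial,
    SimulationConfig,
    events_to_frame,
    simulate_boutons,
    simulate_brood,
    simulate_lethality,
    simulate_pumping,
    simulate_screen,
)


def _frame(events):
    return events_to_frame(events)


class TestBrood:
    def test_mendelian_heterozygote_fraction(self):
        # balancer homozygotes die as embryos: survivors are 1:2 homo:het
        cfg = SimulationConfig(
            n_broods=1, brood_size=12_000, day=1, debris_rate=0.0,
            mortality_hazard={"heterozygous": 0.0, "homozygous": 0.0},
        )
        df = _frame(simulate_brood(cfg, seed=42))
        animals = df[df["true_genotype"] != "debris"]
        het = (animals["true_genotype"] == "heterozygous").mean()
        assert het == pytest.approx(2 / 3, abs=0.02)

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_broods=2, brood_size=50, day=4)
        a = simulate_brood(cfg, seed=7)
        b = simulate_brood(cfg, seed=7)
        assert a == b
        c = simulate_brood(cfg, seed=8)
        assert a != c

    def test_survival_closed_form(self):
        # homozygote hazard 0.5/day switched on after day 2, assayed day 4:
        # homozygote survival 0.5^2, so homozygotes are
        # (1/3)(1/4) / ((1/3)(1/4) + 2/3) = 1/9 of survivors
        cfg = SimulationConfig(
            n_broods=1, brood_size=20_000, day=4, debris_rate=0.0,
            maternal_depletion_day=2,
            mortality_hazard={"heterozygous": 0.0, "homozygous": 0.5},
        )
        df = _frame(simulate_brood(cfg, seed=3))
        frac = (df["true_genotype"] == "homozygous").mean()
        assert frac == pytest.approx(1 / 9, abs=0.01)

    def test_event_invariants(self):
        cfg = SimulationConfig(n_broods=4, brood_size=60)
        df = _frame(simulate_brood(cfg, seed=5))
        assert (df["tof_length"] > 0).all()
        assert (df["gfp_intensity"] >= 0).all()
        assert set(df["true_genotype"]) <= {"homozygous", "heterozygous", "debris"}

    def test_debris_rate(self):
        cfg = SimulationConfig(n_broods=1, brood_size=20_000, day=1,
                               debris_rate=0.1)
        df = _frame(simulate_brood(cfg, seed=9))
        n_debris = (df["true_genotype"] == "debris").sum()
        # binomial on progeny slots
        assert n_debris == pytest.approx(2000, abs=150)

    def test_event_table_schema(self):
        cfg = SimulationConfig(n_broods=1, brood_size=20, day=2)
        df = _frame(simulate_brood(cfg, seed=1))
        assert list(df.columns) == [
            "plate_id", "well_id", "replicate_id", "clone_id",
            "tof_length", "gfp_intensity", "true_genotype",
        ]

    def test_config_file_round_trip(self, tmp_path):
        cfg = SimulationConfig(
            n_broods=3, brood_size=25, day=5,
            modifier_effect={"c0001": ModifierEffect(growth_mult=0.5)},
        )
        payload = {
            "n_broods": 3, "brood_size": 25, "day": 5,
            "modifier_effect": {"c0001": {"growth_mult": 0.5}},
        }
        import json

        p_json = tmp_path / "cfg.json"
        p_json.write_text(json.dumps(payload))
        loaded = SimulationConfig.from_file(p_json)
        assert loaded.modifier_effect == cfg.modifier_effect
        assert loaded.day == 5

        import yaml

        p_yaml = tmp_path / "cfg.yaml"
        p_yaml.write_text(yaml.safe_dump(payload))
        assert SimulationConfig.from_file(p_yaml) == loaded

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(debris_rate=1.5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(brood_size=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(genotype_growth_rate={"heterozygous": 1.2,
                                                   "homozygous": 0.3})
        with pytest.raises(ConfigurationError):
            ModifierEffect(growth_mult=-1.0).validate()


class TestScreenDataset:
    def test_layout_and_exchangeability(self):
        cfg = SimulationConfig(n_broods=2, brood_size=30)
        ds = simulate_screen(cfg, 1, 96, {}, n_trials=1, seed=1)
        assert ds.layout.shape == (96, 3)
        assert ds.events.groupby("clone_id", observed=True).size().size == 96

    def test_planted_clone_must_exist(self):
        cfg = SimulationConfig(n_broods=1, brood_size=10)
        with pytest.raises(ConfigurationError, match="planted"):
            simulate_screen(cfg, 1, 8, {"nope": ModifierEffect()}, 1, seed=1)

    def test_retest_trial_ids_extend(self):
        cfg = SimulationConfig(n_broods=1, brood_size=30)
        ds = simulate_screen(cfg, 1, 8, {}, n_trials=2, seed=2)
        full = ds.with_additional_trials(cfg, 4, seed=3)
        assert full.trial_ids == [1, 2, 3, 4, 5, 6]
        # retest draws are independent of the primary draws
        t12 = full.events[full.events["replicate_id"] <= 2]
        pd.testing.assert_frame_equal(
            t12.reset_index(drop=True), ds.events.reset_index(drop=True)
        )

    def test_planted_enhancer_depresses_homozygote_large_fraction(self):
        # a mortality-tripling homozygote effect keeps that clone's
        # large fraction below the plate median in nearly every trial
        cfg = SimulationConfig(n_broods=16)
        eff = ModifierEffect(mortality_mult=3.0)
        below = 0
        n_rep = 200
        for s in range(n_rep):
            ds = simulate_screen(cfg, 1, 24, {"c0001": eff}, 1, seed=100 + s)
            ev = ds.events
            homo = ev[ev["true_genotype"] == "homozygous"]
            frac = homo.groupby("clone_id", observed=True)["tof_length"].apply(
                lambda x: (x >= 300.0).mean()
            )
            below += frac["c0001"] < frac.median()
        assert below >= 0.95 * n_rep

    def test_bulk_matches_single_brood_distribution(self):
        # the screen's bulk path and simulate_brood share one core model
        cfg = SimulationConfig(n_broods=4, brood_size=50)
        ds = simulate_screen(cfg, 1, 50, {}, n_trials=1, seed=11)
        pooled = []
        for s in range(50):
            pooled.append(_frame(simulate_brood(cfg, seed=1000 + s)))
        brood_df = pd.concat(pooled)
        bulk = ds.events
        for col in ("tof_length",):
            m1, m2 = brood_df[col].mean(), bulk[col].mean()
            assert m1 == pytest.approx(m2, rel=0.05)
        f1 = (brood_df["true_genotype"] == "homozygous").mean()
        f2 = (bulk["true_genotype"] == "homozygous").mean()
        assert f1 == pytest.approx(f2, abs=0.02)


class TestPumping:
    def test_control_mean_rate(self):
        cfg = SimulationConfig()
        trials = simulate_pumping(cfg, ["control"], {"empty": 1.0}, 1000, 1,
                                  seed=4, day=1)
        counts = np.array(trials[0].pump_counts)
        assert counts.mean() == pytest.approx(250 / 6, abs=1.0)

    def test_seed_determinism(self):
        cfg = SimulationConfig()
        a = simulate_pumping(cfg, ["homozygous"], {"empty": 1.0}, 10, 3, seed=5)
        b = simulate_pumping(cfg, ["homozygous"], {"empty": 1.0}, 10, 3, seed=5)
        assert a == b

    def test_homozygote_day_course_declines(self):
        cfg = SimulationConfig()
        means = []
        for day in (1, 2, 3, 4):
            t = simulate_pumping(cfg, ["homozygous"], {"empty": 1.0}, 2000, 1,
                                 seed=6, day=day)
            means.append(np.mean(t[0].pump_counts))
        assert means[0] == pytest.approx(means[1], rel=0.05)  # maternal rescue
        assert means[2] < 0.6 * means[1]
        assert means[3] < means[2]

    def test_unknown_genotype_rejected(self):
        cfg = SimulationConfig()
        with pytest.raises(ConfigurationError):
            simulate_pumping(cfg, ["mystery"], {"empty": 1.0}, 5, 1, seed=1)

    def test_counts_nonnegative_integers(self):
        cfg = SimulationConfig()
        trials = simulate_pumping(cfg, ["homozygous", "heterozygous"],
                                  {"empty": 1.0, "x": 0.5}, 25, 2, seed=8)
        for t in trials:
            assert all(isinstance(c, int) and c >= 0 for c in t.pump_counts)

    def test_trial_type_invariants(self):
        with pytest.raises(ConfigurationError):
            PumpingTrial(1, "homozygous", "empty", 3, ())
        with pytest.raises(ConfigurationError):
            PumpingTrial(1, "homozygous", "empty", 3, (5,), window_s=0)


class TestLethality:
    def test_reference_parameterization(self):
        out = simulate_lethality(0.44, 0.56, 100, seed=1)
        assert out.total == 100
        assert out.n_eclosed == 0

    def test_all_eclose(self):
        out = simulate_lethality(0.0, 0.0, 50, seed=2)
        assert out.n_eclosed == 50

    def test_binomial_convergence(self):
        out = simulate_lethality(0.3, 0.2, 10_000, seed=3)
        assert out.n_early_pupal / out.total == pytest.approx(0.3, abs=0.01)

    def test_simplex_enforced(self):
        with pytest.raises(ConfigurationError):
            simulate_lethality(0.7, 0.5, 10, seed=1)
        with pytest.raises(ConfigurationError):
            LethalityCounts("x", 0, 0, 0)


class TestBoutons:
    def test_poisson_mean(self):
        recs = simulate_boutons({"wt": 60.0}, (0.0, 0.0), 10_000, seed=1)
        counts = [r.bouton_count for r in recs]
        assert np.mean(counts) == pytest.approx(60.0, abs=1.0)
        assert all(r.muscle_area == pytest.approx(1.0) for r in recs)

    def test_seed_determinism(self):
        a = simulate_boutons({"wt": 60.0, "mut": 30.0}, (0.0, 0.2), 12, seed=9)
        b = simulate_boutons({"wt": 60.0, "mut": 30.0}, (0.0, 0.2), 12, seed=9)
        assert a == b

    def test_mean_scales_with_area(self):
        recs = simulate_boutons({"wt": 60.0}, (0.0, 0.4), 20_000, seed=2)
        df = pd.DataFrame([dataclasses.asdict(r) for r in recs])
        big = df[df["muscle_area"] > df["muscle_area"].median()]
        small = df[df["muscle_area"] <= df["muscle_area"].median()]
        assert big["bouton_count"].mean() > 1.2 * small["bouton_count"].mean()

    def test_invalid_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_boutons({"wt": -5.0}, (0.0, 0.1), 5, seed=1)
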