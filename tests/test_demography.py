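"""Cohort-component engine: single-step update, multi-year projection, W(t)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pretermcast import (
    AgeStructuredPopulation,
    FertilityFeedbackSpec,
    MigrationSchedule,
    SurvivalSchedule,
    age_advance,
    project_population,
    women_of_reproductive_age,
)


def uniform_pop(year=2024, a_max=100, per_age=100.0):
    return AgeStructuredPopulation(year=year, counts=np.full(a_max + 1, per_age))


def identity_surv(a_max=100):
    return SurvivalSchedule(probabilities=np.ones(a_max + 1))


class TestAgeAdvance:
    def test_identity_survival_shifts_cohorts_unchanged(self):
        pop = uniform_pop(per_age=100.0)
        nxt = age_advance(pop, identity_surv(), MigrationSchedule.zeros(), 0.0)
        assert nxt.year == pop.year + 1
        assert nxt.counts[0] == 0.0
        assert np.allclose(nxt.counts[1:-1], 100.0)
        # open top interval keeps its own survivors plus arrivals from below
        assert nxt.counts[-1] == pytest.approx(200.0)

    def test_survival_and_migration_arithmetic(self):
        counts = np.zeros(101)
        counts[30] = 1000.0
        pop = AgeStructuredPopulation(year=2024, counts=counts)
        surv = SurvivalSchedule(probabilities=np.full(101, 0.999))
        mig_vec = np.zeros(101)
        mig_vec[31] = 50.0
        nxt = age_advance(pop, surv, MigrationSchedule.from_vector(mig_vec), 0.0)
        assert nxt.counts[31] == pytest.approx(1000 * 0.999 + 50)  # 1049

    def test_out_migration_floored_at_zero(self, caplog):
        counts = np.zeros(101)
        counts[20] = 100.0
        pop = AgeStructuredPopulation(year=2024, counts=counts)
        mig_vec = np.zeros(101)
        mig_vec[21] = -150.0
        with caplog.at_level("WARNING"):
            nxt = age_advance(pop, identity_surv(), MigrationSchedule.from_vector(mig_vec))
        assert nxt.counts[21] == 0.0
        assert any("floored" in rec.message for rec in caplog.records)

    def test_newborns_enter_age_zero_with_migration(self):
        pop = uniform_pop()
        mig_vec = np.zeros(101)
        mig_vec[0] = 7.0
        nxt = age_advance(pop, identity_surv(), MigrationSchedule.from_vector(mig_vec), 30.0)
        assert nxt.counts[0] == pytest.approx(37.0)

    def test_length_mismatch_rejected(self):
        pop = uniform_pop(a_max=50)
        with pytest.raises(ValueError, match="length"):
            age_advance(pop, identity_surv(a_max=100), MigrationSchedule.zeros(50))
        with pytest.raises(ValueError, match="length"):
            age_advance(pop, identity_surv(a_max=50), MigrationSchedule.zeros(100))

    def test_negative_newborns_rejected(self):
        with pytest.raises(ValueError):
            age_advance(uniform_pop(), identity_surv(), MigrationSchedule.zeros(), -1.0)

    def test_non_integer_year_rejected(self):
        with pytest.raises(TypeError):
            AgeStructuredPopulation(year=2024.5, counts=np.ones(101))


class TestProjectPopulation:
    def test_conservation_under_identity_survival(self):
        rng = np.random.default_rng(0)
        counts = rng.uniform(50, 150, size=101)
        pop = AgeStructuredPopulation(year=2024, counts=counts)
        traj = project_population(
            pop, identity_surv(), MigrationSchedule.zeros(), end_year=2029
        )
        final = traj[-1]
        # cohorts aged 0..94 at start occupy ages 5..99 five years later;
        # ages 95+ are absorbed into the open top interval; nothing is lost
        assert final.counts[5:100].sum() == pytest.approx(counts[:95].sum())
        assert final.counts[-1] == pytest.approx(counts[95:].sum())
        assert final.total() == pytest.approx(pop.total())

    def test_geometric_decay_closed_form(self):
        pop = uniform_pop(per_age=1000.0)
        surv = SurvivalSchedule(probabilities=np.full(101, 0.99))
        traj = project_population(pop, surv, MigrationSchedule.zeros(), end_year=2027)
        for k, snapshot in enumerate(traj):
            # interior cohorts (away from the newborn and open-top edges)
            assert np.allclose(snapshot.counts[k + 1 : 99], 1000.0 * 0.99**k)

    def test_feedback_requires_births_for_every_year(self):
        pop = uniform_pop()
        with pytest.raises(KeyError, match="2025"):
            project_population(
                pop,
                identity_surv(),
                MigrationSchedule.zeros(),
                feedback=FertilityFeedbackSpec(),
                births_by_year={2024: 1000.0},
                end_year=2026,
            )

    def test_end_year_must_follow_baseline(self):
        with pytest.raises(ValueError):
            project_population(
                uniform_pop(year=2024), identity_surv(), MigrationSchedule.zeros(),
                end_year=2024,
            )

    def test_matches_manual_single_step_loop_on_synthetic_bundle(self, bundle_seed1):
        b = bundle_seed1
        traj = project_population(
            b.baseline_population, b.survival, b.migration, end_year=b.baseline_population.year + 27
        )
        pop = b.baseline_population
        for snapshot in traj[1:]:
            pop = age_advance(pop, b.survival, b.migration, 0.0)
            assert snapshot.year == pop.year
            np.testing.assert_array_equal(snapshot.counts, pop.counts)


class TestWomenOfReproductiveAge:
    def test_uniform_pyramid(self):
        assert women_of_reproductive_age(uniform_pop(per_age=100.0)) == 3500.0

    def test_all_zero_pyramid(self):
        pop = AgeStructuredPopulation(year=2024, counts=np.zeros(101))
        assert women_of_reproductive_age(pop) == 0.0

    def test_matches_stored_csv_rows(self, bundle_seed1, tmp_path):
        path = tmp_path / "pyramid.csv"
        bundle_seed1.baseline_population.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        expected = df[(df["age"] >= 15) & (df["age"] <= 49)]["count"].sum()
        assert women_of_reproductive_age(bundle_seed1.baseline_population) == pytest.approx(expected)

    def test_bounds_outside_pyramid_rejected(self):
        with pytest.raises(ValueError):
            women_of_reproductive_age(uniform_pop(a_max=40), 15, 49)
        with pytest.raises(ValueError):
            women_of_reproductive_age(uniform_pop(), 30, 20)


small_pyramids = st.lists(
    st.floats(0, 1e5, allow_nan=False), min_size=6, max_size=12
)
survival_lists = st.lists(st.floats(0, 1, allow_nan=False), min_size=12, max_size=12)


class TestProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.floats(0, 1e5), min_size=12, max_size=12),
        probs=survival_lists,
        mig=st.lists(st.floats(-100, 100), min_size=12, max_size=12),
        steps=st.integers(1, 6),
    )
    def test_multi_year_projection_equals_repeated_single_steps(
        self, counts, probs, mig, steps
    ):
        pop = AgeStructuredPopulation(year=2000, counts=np.array(counts))
        surv = SurvivalSchedule(probabilities=np.array(probs))
        sched = MigrationSchedule.from_vector(mig)
        traj = project_population(pop, surv, sched, end_year=2000 + steps)
        manual = pop
        for snapshot in traj[1:]:
            manual = age_advance(manual, surv, sched, 0.0)
            np.testing.assert_array_equal(snapshot.counts, manual.counts)
        assert all(np.all(s.counts >= 0) for s in traj)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.floats(0, 1e5), min_size=12, max_size=12),
        probs=survival_lists,
        age=st.integers(0, 11),
        drop=st.floats(0.01, 1.0),
        steps=st.integers(1, 5),
    )
    def test_lowering_survival_never_raises_any_later_count(
        self, counts, probs, age, drop, steps
    ):
        pop = AgeStructuredPopulation(year=2000, counts=np.array(counts))
        sched = MigrationSchedule.zeros(11)
        hi = SurvivalSchedule(probabilities=np.array(probs))
        lowered = np.array(probs)
        lowered[age] = max(0.0, lowered[age] - drop)
        lo = SurvivalSchedule(probabilities=lowered)
        t_hi = project_population(pop, hi, sched, end_year=2000 + steps)
        t_lo = project_population(pop, lo, sched, end_year=2000 + steps)
        for a, b in zip(t_hi, t_lo):
            assert np.all(b.counts <= a.counts + 1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(counts=st.lists(st.floats(0, 1e6), min_size=50, max_size=60))
    def test_reproductive_sum_equals_brute_force(self, counts):
        pop = AgeStructuredPopulation(year=2010, counts=np.array(counts))
        brute = sum(counts[15:50])
        assert women_of_reproductive_age(pop) == pytest.approx(brute)


class TestCsvRoundTrips:
    def test_pyramid_survival_migration_round_trip(self, bundle_seed1, tmp_path):
        b = bundle_seed1
        b.baseline_population.to_csv(tmp_path / "p.csv")
        b.survival.to_csv(tmp_path / "s.csv")
        b.migration.to_csv(tmp_path / "m.csv")
        pop = AgeStructuredPopulation.from_csv(tmp_path / "p.csv", year=b.baseline_population.year)
        np.testing.assert_allclose(pop.counts, b.baseline_population.counts)
        surv = SurvivalSchedule.from_csv(tmp_path / "s.csv")
        np.testing.assert_allclose(surv.probabilities, b.survival.probabilities)
        mig = MigrationSchedule.from_csv(tmp_path / "m.csv")
        np.testing.assert_allclose(mig.default, b.migration.default)

    def test_year_varying_migration_dialect(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"age": [0, 1, 0, 1], "year": [2024, 2024, 2025, 2025],
             "net_migration": [5.0, -2.0, 1.0, 0.5]}
        )
        df.to_csv(tmp_path / "m.csv", index=False)
        mig = MigrationSchedule.from_csv(tmp_path / "m.csv")
        np.testing.assert_allclose(mig.net_for(2024), [5.0, -2.0])
        np.testing.assert_allclose(mig.net_for(2025), [1.0, 0.5])
        np.testing.assert_allclose(mig.net_for(2030), [0.0, 0.0])
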