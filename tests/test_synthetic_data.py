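"""Generator statistics: hypoexponential draws, event histories, traces."""

import numpy as np
import pytest

from arakin.step_model import hypoexp_cdf, hypoexp_pdf
from arakin.synthetic_data import (PopulationParams, default_geometry,
                                   events_to_trace, make_mask,
                                   population_traces, sample_hypoexp,
                                   simulate_cell_events)
from oracles import renewal_mean


class TestSampleHypoexp:
    def test_mean_is_sum_of_step_means(self):
        x = sample_hypoexp([1 / 1000, 1 / 500], n=200_000, seed=1)
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - 1500.0) < 3 * se

    def test_erlang_squared_cv_is_one_over_d(self):
        r = 1 / 480.0
        x = sample_hypoexp([r, r, r], n=200_000, seed=2)
        cv2 = x.var() / x.mean() ** 2
        assert cv2 == pytest.approx(1 / 3, abs=0.01)

    def test_erlang3_mean_within_three_se(self):
        x = sample_hypoexp([1 / 480] * 3, n=100_000, seed=3)
        se = np.sqrt(3 * 480**2 / x.size)   # closed-form Erlang variance
        assert abs(x.mean() - 1440.0) < 3 * se

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_hypoexp([1 / 100, 0.0], n=10)
        with pytest.raises(ValueError):
            sample_hypoexp([], n=10)


class TestSimulateCellEvents:
    def test_first_production_mean_adds_intake_and_initiation(self):
        # intake mean 1444 s + one initiation interval mean 1440.6 s ~ 2885 s
        params = PopulationParams(n_cells=3000, t_total=36_000, seed=4,
                                  spurious_rna_mean=0.0)
        events = simulate_cell_events(params)
        first = np.array([e.production_times[0] for e in events
                          if e.production_times.size])
        sd = np.sqrt(2 * 722**2 + 1440.6**2 / 3)
        assert first.size == 3000
        assert abs(first.mean() - 2884.6) < 3 * sd / np.sqrt(first.size)

    def test_empty_intake_means_instant_activation(self):
        params = PopulationParams(n_cells=50, intake_rates=(), seed=5)
        events = simulate_cell_events(params)
        assert all(e.intake_completion_time == 0.0 for e in events)

    def test_interval_squared_cv_matches_erlang_oracle(self):
        params = PopulationParams(n_cells=600, t_total=72_000, seed=6,
                                  intake_rates=())
        events = simulate_cell_events(params)
        dts = np.concatenate([np.diff(e.production_times) for e in events])
        cv2 = dts.var() / dts.mean() ** 2
        assert dts.size > 20_000
        assert cv2 == pytest.approx(1 / 3, abs=0.02)

    def test_event_ordering_invariants(self):
        params = PopulationParams(n_cells=100, seed=7)
        for e in simulate_cell_events(params):
            assert (np.diff(e.production_times) > 0).all()
            assert (e.production_times >= e.intake_completion_time).all()
            assert (e.production_times <= params.t_total).all()

    def test_renewal_count_matches_volterra_oracle(self):
        rates = (3 / 1440.6,) * 3
        params = PopulationParams(n_cells=4000, t_total=7200, seed=8,
                                  intake_rates=(), initiation_rates=rates)
        events = simulate_cell_events(params)
        for t in (2000.0, 4000.0, 7200.0):
            counts = np.array([(e.production_times <= t).sum() for e in events])
            m_hat = counts.mean()
            se = counts.std(ddof=1) / np.sqrt(counts.size)
            (m_oracle,) = renewal_mean(lambda s: hypoexp_pdf(rates, s),
                                       lambda s: hypoexp_cdf(rates, s),
                                       np.array([t]))
            assert abs(m_hat - m_oracle) < 3 * se

    def test_same_seed_identical_different_seed_distinct(self):
        params = PopulationParams(n_cells=20, seed=9)
        a = simulate_cell_events(params)
        b = simulate_cell_events(params)
        c = simulate_cell_events(params, seed=10)
        for ea, eb in zip(a, b):
            assert ea.intake_completion_time == eb.intake_completion_time
            np.testing.assert_array_equal(ea.production_times, eb.production_times)
        assert any(ea.intake_completion_time != ec.intake_completion_time
                   for ea, ec in zip(a, c))

    def test_spurious_rna_poisson_mean(self):
        params = PopulationParams(n_cells=5000, seed=11)
        n0 = np.array([e.initial_rna_count
                       for e in simulate_cell_events(params)])
        assert n0.mean() == pytest.approx(0.2, abs=3 * np.sqrt(0.2 / 5000))


class TestEventsToTrace:
    def test_no_events_no_noise_gives_zero_trace(self):
        from arakin.synthetic_data import TrueEvents

        params = PopulationParams(n_cells=1, noise_sd=0.0)
        ev = TrueEvents(0, 0.0, np.array([]), 0)
        tr = events_to_trace(ev, params, seed=0)
        assert (tr.intensities == 0).all()

    def test_staircase_levels_and_step_frames(self):
        from arakin.synthetic_data import TrueEvents

        params = PopulationParams(n_cells=1, noise_sd=0.0)
        ev = TrueEvents(0, 0.0, np.array([600.0, 1800.0]), 0)
        tr = events_to_trace(ev, params, seed=0)
        assert tr.intensities[9] == 0.0
        assert tr.intensities[10] == 100.0   # frame at 600 s includes the event
        assert tr.intensities[29] == 100.0
        assert tr.intensities[30] == 200.0
        assert tr.intensities[-1] == 200.0

    def test_trace_noise_sd_recovered(self):
        from arakin.synthetic_data import TrueEvents

        params = PopulationParams(n_cells=1, noise_sd=10.0, t_total=60_000)
        ev = TrueEvents(0, 0.0, np.array([]), 0)
        tr = events_to_trace(ev, params, seed=12)
        sd = tr.intensities.std(ddof=1)
        n = tr.intensities.size
        se = 10.0 / np.sqrt(2 * (n - 1))
        assert abs(sd - 10.0) < 3 * se


class TestGeometry:
    def test_overlapping_boxes_rejected(self):
        from arakin.synthetic_data import ImageGeometry

        with pytest.raises(ValueError, match="overlap"):
            ImageGeometry(shape=(40, 40),
                          cell_boxes=((0, 0, 20, 20), (10, 10, 30, 30)))

    def test_mask_labels_cells_one_based(self):
        geom = default_geometry(4)
        mask = make_mask(geom)
        assert set(np.unique(mask)) == {0, 1, 2, 3, 4}
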