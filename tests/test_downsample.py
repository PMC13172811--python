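import math

import numpy as np
import pandas as pd
import pytest

from probemine.downsample import (ErrorDecayModel, ExtractionObservation,
                                  LinearModel, analyze_counts, back_calculate,
                                  fit_error_decay, fit_linear,
                                  invert_error_decay, observations_from_counts,
                                  relative_error)


def obs(x, c_x, c_100):
    return ExtractionObservation(x=x, c_x=c_x, c_100=c_100)


class TestFitLinear:
    def test_perfect_proportionality(self):
        points = [obs(x, x * 10, 1000) for x in (1, 10, 25, 50)]  # y == x
        model = fit_linear(points)
        assert model.slope == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_two_points_equal_closed_form_line(self):
        points = [obs(10, 80, 1000), obs(50, 520, 1000)]
        model = fit_linear(points)
        slope = (52.0 - 8.0) / (50 - 10)
        assert model.slope == pytest.approx(slope)
        assert model.intercept == pytest.approx(8.0 - slope * 10)

    def test_recovers_known_coefficients_under_noise(self):
        rng = np.random.default_rng(77)
        xs = rng.choice([1, 10, 25, 50], size=200)
        points = []
        for x in xs:
            y = 1.004 * x - 0.557 + rng.normal(0, 0.5)
            c_100 = 10_000
            points.append(obs(float(x), max(0, round(y * c_100 / 100)), c_100))
        model = fit_linear(points)
        assert model.slope == pytest.approx(1.004, abs=0.01)
        assert model.intercept == pytest.approx(-0.557, abs=0.3)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([obs(10, 5, 100)])
        with pytest.raises(ValueError):
            fit_linear([obs(10, 5, 100), obs(10, 7, 100)])


class TestBackCalculate:
    def test_exact_halving_inverted(self):
        assert back_calculate(500, 50, LinearModel(1.0, 0.0)) == pytest.approx(1000)

    def test_with_fitted_calibration(self):
        model = LinearModel(slope=1.004, intercept=-0.5570)
        assert back_calculate(500, 50, model) == pytest.approx(100 * 500 / 49.643,
                                                               rel=1e-6)

    def test_identity_at_full_extraction(self):
        assert back_calculate(7, 100, LinearModel(1.0, 0.0)) == pytest.approx(7)

    def test_non_positive_prediction_rejected(self):
        with pytest.raises(ValueError):
            back_calculate(10, 1, LinearModel(0.1, -1.0))


class TestRelativeError:
    @pytest.mark.parametrize("estimate,actual,expected", [
        (1000, 1000, 0.0), (1100, 1000, 10.0), (900, 1000, 10.0),
    ])
    def test_examples(self, estimate, actual, expected):
        assert relative_error(estimate, actual) == pytest.approx(expected)

    def test_zero_actual_rejected(self):
        with pytest.raises(ValueError):
            relative_error(10, 0)


class TestErrorDecay:
    def test_exact_linearization_recovery(self):
        truth = ErrorDecayModel(amplitude=100.0, decay=1.5)
        points = [(m, truth.predict(m)) for m in (10, 100, 1000)]
        fitted = fit_error_decay(points)
        assert fitted.amplitude == pytest.approx(100.0)
        assert fitted.decay == pytest.approx(1.5)

    def test_amplitude_is_error_at_m_equal_one(self):
        model = ErrorDecayModel(amplitude=42.0, decay=0.9)
        assert model.predict(1) == pytest.approx(42.0)

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(5)
        truth = ErrorDecayModel(amplitude=120.0, decay=1.2)
        ms = np.exp(rng.uniform(math.log(5), math.log(50_000), size=100))
        points = [(m, truth.predict(m) * rng.lognormal(0, 0.1)) for m in ms]
        fitted = fit_error_decay(points)
        assert fitted.amplitude == pytest.approx(truth.amplitude, rel=0.05)
        assert fitted.decay == pytest.approx(truth.decay, rel=0.05)

    def test_invalid_points_rejected(self):
        with pytest.raises(ValueError):
            fit_error_decay([(0, 10), (10, 5)])
        with pytest.raises(ValueError):
            fit_error_decay([(10, 5)])


class TestInvertErrorDecay:
    def test_inversion_round_trips_prediction(self):
        model = ErrorDecayModel(amplitude=99.44, decay=1.527)
        for err in (1, 5, 10, 20):
            m = invert_error_decay(model, err)
            assert model.predict(m) == pytest.approx(err, rel=0.05)

    def test_threshold_equal_to_amplitude_gives_one_read(self):
        model = ErrorDecayModel(amplitude=80.0, decay=2.0)
        assert invert_error_decay(model, 80.0) == 1

    def test_threshold_above_amplitude_rejected(self):
        with pytest.raises(ValueError):
            invert_error_decay(ErrorDecayModel(amplitude=50.0, decay=1.0), 60)


def simulated_counts(seed=123, n_total=100_000):
    """Hypergeometric downsampling of a grid of true abundances."""
    rng = np.random.default_rng(seed)
    rows = []
    abundances = [30, 100, 300, 1000, 3000, 10_000]
    for i, c100 in enumerate(abundances):
        for rep in range(8):
            name = f"file_{i}_{rep}"
            rows.append({"probe": "p", "file": name,
                         "extraction_pct": 100, "matched": c100})
            for x in (1, 10, 25, 50):
                drawn = rng.hypergeometric(c100, n_total - c100,
                                           int(n_total * x / 100))
                rows.append({"probe": "p", "file": name,
                             "extraction_pct": x, "matched": int(drawn)})
    return pd.DataFrame(rows)


class TestAnalyzeCounts:
    def test_observation_builder_drops_zero_references(self):
        counts = pd.DataFrame([
            {"probe": "p", "file": "f", "extraction_pct": 100, "matched": 0},
            {"probe": "p", "file": "f", "extraction_pct": 10, "matched": 0},
            {"probe": "q", "file": "f", "extraction_pct": 100, "matched": 50},
            {"probe": "q", "file": "f", "extraction_pct": 10, "matched": 4},
        ])
        observations = observations_from_counts(counts)
        assert len(observations) == 1
        assert observations[0].y == pytest.approx(8.0)

    def test_proportional_downsampling_recovers_identity_line(self):
        calibration, back, models, thresholds = analyze_counts(simulated_counts())
        assert calibration.slope == pytest.approx(1.0, abs=0.05)
        assert calibration.intercept == pytest.approx(0.0, abs=1.0)
        # error decays with abundance: each extraction's decay rate is positive
        assert models and all(m.decay > 0 for m in models.values())
        # relative error shrinks as the full-data count grows
        for x, sub in back.groupby("extraction_pct"):
            low = sub[sub["reference_100pct"] <= 300]["relative_error_pct"].mean()
            high = sub[sub["reference_100pct"] >= 3000]["relative_error_pct"].mean()
            assert high < low
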