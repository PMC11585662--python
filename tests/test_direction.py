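import numpy as np
import pytest

from meaconn import (
    AnalysisConfig,
    DirectionalityField,
    PairwiseResult,
    Recording,
    SpikeTrain,
    accept_pair,
    assembloid_directionality,
    connection_established,
    maturation_trajectory,
    pair_vector,
    pairwise_table,
)
from meaconn.direction import electrode_vector
from meaconn.simulate import fixture_config, simulate_assembloid


def _result(e1, e2, sttc=0.5, significant=True, delay=0.002, grid=None):
    d_pitch = grid.distance_pitch(e1, e2) if grid else 1.0
    d_m = grid.distance_m(e1, e2) if grid else 300e-6
    return PairwiseResult(
        e1=e1, e2=e2, sttc=sttc, significant=significant, delay_s=delay,
        distance_pitch=d_pitch, distance_m=d_m, speed_mps=None,
    )


class TestAcceptPair:
    def test_accepted(self):
        assert accept_pair(_result("a", "b", sttc=0.45, significant=True))

    def test_sttc_below_cutoff(self):
        assert not accept_pair(_result("a", "b", sttc=0.29, significant=True))

    def test_not_significant_high_sttc(self):
        assert not accept_pair(_result("a", "b", sttc=0.9, significant=False))

    def test_cutoff_inclusive(self):
        assert accept_pair(_result("a", "b", sttc=0.3, significant=True))


class TestPairVector:
    def test_down_column(self, grid):
        assert pair_vector(grid, "R2C3", "R6C3") == (0.0, 4.0)

    def test_reversed(self, grid):
        assert pair_vector(grid, "R6C3", "R2C3") == (0.0, -4.0)

    def test_diagonal(self, grid):
        assert pair_vector(grid, "R2C3", "R5C6") == (3.0, 3.0)

    def test_identical_rejected(self, grid):
        with pytest.raises(ValueError):
            pair_vector(grid, "R2C3", "R2C3")

    def test_magnitude_equals_distance(self, grid, rng):
        ids = grid.electrode_ids
        for _ in range(20):
            a, b = rng.choice(ids, 2, replace=False)
            x, y = pair_vector(grid, a, b)
            assert np.hypot(x, y) == pytest.approx(grid.distance_pitch(a, b))


class TestElectrodeVector:
    def test_cancellation(self):
        att = {"e": [(0.0, 4.0), (0.0, -4.0)]}
        assert electrode_vector("e", att) == (0.0, 0.0)

    def test_single(self):
        assert electrode_vector("e", {"e": [(3.0, 3.0)]}) == (3.0, 3.0)

    def test_no_pairs(self):
        assert electrode_vector("e", {}) == (0.0, 0.0)


class TestEstablishment:
    def test_y_two_established(self):
        assert connection_established(2.0, threshold=2.0)

    def test_negative_three_established(self):
        assert connection_established(-3.0, threshold=2.0)

    def test_below_threshold_not(self):
        assert not connection_established(1.9, threshold=2.0)

    def test_monotone_in_threshold(self, rng):
        for _ in range(50):
            y = rng.normal(0, 3)
            t1, t2 = sorted(rng.uniform(0.5, 5.0, 2))
            if connection_established(y, t2):
                assert connection_established(y, t1)


def _recording_with_counts(grid, codes, duration=60.0):
    trains = {}
    for e in grid.electrode_ids:
        n = 30 if e in codes else 0
        trains[e] = SpikeTrain(e, np.linspace(1, duration - 1, n), 0.0, duration)
    return Recording(trains=trains, grid=grid)


class TestAssembloidDirectionality:
    def test_empty_table_zero_field(self, grid):
        rec = _recording_with_counts(grid, [])
        field = assembloid_directionality(rec, [])
        assert field.assembloid_vector == (0.0, 0.0)
        assert not field.established
        assert field.vertical_y == 0.0

    def test_double_entry_bookkeeping(self, grid):
        # assembloid vector == sum over electrodes == 2 x sum over pairs
        results = [
            _result("R2C3", "R6C3", delay=0.002, grid=grid),   # lead R2C3: (0,+4)
            _result("R3C5", "R6C2", delay=-0.001, grid=grid),  # lead R6C2: (+3,-3)
        ]
        rec = _recording_with_counts(grid, ["R2C3", "R6C3", "R3C5", "R6C2"])
        field = assembloid_directionality(rec, results)
        total = np.sum(list(field.electrode_vectors.values()), axis=0)
        assert tuple(total) == field.assembloid_vector
        assert field.assembloid_vector == (2 * 3.0, 2 * 1.0)
        assert field.vertical_y == pytest.approx(1.0)
        assert field.lateral_abs_x == pytest.approx(3.0)

    def test_lead_attachment_option(self, grid):
        results = [_result("R2C3", "R6C3", delay=0.002, grid=grid)]
        rec = _recording_with_counts(grid, ["R2C3", "R6C3"])
        cfg = AnalysisConfig(attachment="lead")
        field = assembloid_directionality(rec, results, cfg)
        assert field.electrode_vectors["R2C3"] == (0.0, 4.0)
        assert field.electrode_vectors["R6C3"] == (0.0, 0.0)
        assert field.vertical_y == pytest.approx(4.0)

    def test_attachment_rule_leaves_verdict_invariant(self, grid):
        results = [_result("R2C3", "R6C3", delay=0.002, grid=grid)]
        rec = _recording_with_counts(grid, ["R2C3", "R6C3"])
        f_both = assembloid_directionality(rec, results, AnalysisConfig(attachment="both"))
        f_lead = assembloid_directionality(rec, results, AnalysisConfig(attachment="lead"))
        assert f_both.vertical_y == pytest.approx(f_lead.vertical_y)
        assert f_both.established == f_lead.established

    def test_rotation_negates_vector(self, grid):
        # 180 degree rotation: R r C c -> R (9-r) C (9-c)
        rot = lambda e: f"R{9 - int(e[1])}C{9 - int(e[3])}"
        results = [
            _result("R2C3", "R6C3", delay=0.002, grid=grid),
            _result("R3C5", "R6C2", delay=-0.001, grid=grid),
        ]
        rotated = [
            _result(rot(r.e1), rot(r.e2), delay=r.delay_s, grid=grid) for r in results
        ]
        codes = ["R2C3", "R6C3", "R3C5", "R6C2"]
        rec = _recording_with_counts(grid, codes)
        rec_rot = _recording_with_counts(grid, [rot(c) for c in codes])
        f = assembloid_directionality(rec, results)
        f_rot = assembloid_directionality(rec_rot, rotated)
        assert f_rot.assembloid_vector[0] == pytest.approx(-f.assembloid_vector[0])
        assert f_rot.assembloid_vector[1] == pytest.approx(-f.assembloid_vector[1])

    def test_zero_delay_pair_contributes_nothing(self, grid):
        results = [_result("R2C3", "R6C3", delay=0.0, grid=grid)]
        rec = _recording_with_counts(grid, ["R2C3", "R6C3"])
        field = assembloid_directionality(rec, results)
        assert field.assembloid_vector == (0.0, 0.0)

    def test_mean_firing_rate(self, grid):
        rec = _recording_with_counts(grid, ["R1C1", "R2C2"], duration=60.0)
        field = assembloid_directionality(rec, [])
        assert field.mean_firing_rate == pytest.approx(60 / (64 * 60.0))


class TestSimulationRecovery:
    def test_forward_fixture_positive_established(self):
        rec, truth = simulate_assembloid(fixture_config("forward", seed=4))
        field = assembloid_directionality(rec, pairwise_table(rec))
        assert truth.net_direction_sign == 1
        assert field.vertical_y > 0
        assert field.established

    def test_backward_fixture_negative(self):
        rec, truth = simulate_assembloid(fixture_config("backward", seed=4))
        field = assembloid_directionality(rec, pairwise_table(rec))
        assert truth.net_direction_sign == -1
        assert field.vertical_y < 0

    def test_null_fixture_small_field(self):
        rec, _ = simulate_assembloid(fixture_config("null", seed=4))
        field = assembloid_directionality(rec, pairwise_table(rec))
        assert abs(field.vertical_y) < 2.0

    def test_symmetric_transmission_mean_y_near_zero(self):
        # equal forward/backward transmission: mean y consistent with 0
        # (run count scaled down for runtime; assertion uses the sample SE)
        from meaconn.simulate import Connection, SimulationConfig

        conns = [
            Connection("R2C4", "R7C4", 0.5),
            Connection("R7C3", "R2C3", 0.5),
        ]
        ys = []
        for seed in range(40):
            cfg = SimulationConfig(duration=60.0, connections=conns)
            rec, _ = simulate_assembloid(cfg, seed=seed)
            ys.append(assembloid_directionality(rec, pairwise_table(rec)).vertical_y)
        se = np.std(ys, ddof=1) / np.sqrt(len(ys))
        assert abs(np.mean(ys)) <= max(3 * se, 0.5)

    def test_mirrored_recording_flips_y(self):
        # relabel rows r -> 9-r: same spikes, swapped compartment labels
        rec, _ = simulate_assembloid(fixture_config("forward", seed=4))
        flip = lambda e: f"R{9 - int(e[1])}C{e[3]}"
        trains = {
            flip(e): SpikeTrain(flip(e), tr.times, tr.t_start, tr.t_stop)
            for e, tr in rec.trains.items()
        }
        rec_m = Recording(trains=trains, grid=rec.grid)
        f = assembloid_directionality(rec, pairwise_table(rec))
        f_m = assembloid_directionality(rec_m, pairwise_table(rec_m))
        assert f_m.vertical_y == pytest.approx(-f.vertical_y)
        assert f_m.lateral_abs_x == pytest.approx(f.lateral_abs_x)


def _field(y, absx=0.0):
    return DirectionalityField(
        electrode_vectors={}, assembloid_vector=(absx, y), vertical_y=y,
        lateral_abs_x=absx, established=abs(y) >= 2, mean_firing_rate=1.0,
        threshold=2.0,
    )


class TestMaturationTrajectory:
    def test_identical_values_h_zero(self):
        stages = {
            "D4": [_field(1.0), _field(1.0)],
            "D40": [_field(1.0), _field(1.0)],
        }
        out = maturation_trajectory(stages)
        assert out["kruskal_wallis"]["vertical_y"]["H"] == 0.0
        assert out["kruskal_wallis"]["vertical_y"]["p"] == 1.0

    def test_two_stage_hand_computed_h(self):
        stages = {
            "early": [_field(1.0), _field(2.0), _field(3.0)],
            "late": [_field(10.0), _field(11.0), _field(12.0)],
        }
        out = maturation_trajectory(stages)
        # rank formula: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1) = 27/7
        assert out["kruskal_wallis"]["vertical_y"]["H"] == pytest.approx(27 / 7, abs=1e-9)

    def test_small_stage_excluded(self, caplog):
        stages = {
            "a": [_field(1.0), _field(2.0)],
            "b": [_field(3.0), _field(4.0)],
            "tiny": [_field(9.0)],
        }
        with caplog.at_level("WARNING", logger="meaconn"):
            out = maturation_trajectory(stages)
        assert "tiny" not in out["stages"]
        assert "excluded" in caplog.text

    def test_needs_two_stages(self):
        with pytest.raises(ValueError):
            maturation_trajectory({"only": [_field(1.0), _field(2.0)]})

    def test_stage_summaries(self):
        stages = {
            "a": [_field(1.0, 2.0), _field(3.0, 4.0)],
            "b": [_field(5.0, 6.0), _field(7.0, 8.0)],
        }
        out = maturation_trajectory(stages)
        assert out["stages"]["a"]["vertical_y_mean"] == pytest.approx(2.0)
        assert out["stages"]["a"]["lateral_abs_x_mean"] == pytest.approx(3.0)
        assert out["stages"]["b"]["vertical_y_sd"] == pytest.approx(np.std([5, 7], ddof=1))

    def test_transmission_gradient_recovers_monotone_x(self):
        # cohorts with stronger planted transmission show larger mean |x|
        from meaconn.core import AnalysisConfig
        from meaconn.simulate import SimulationConfig, Connection

        def cohort(prob, seeds):
            fields = []
            conns = [
                Connection("R4C2", "R5C5", prob),
                Connection("R3C6", "R6C3", prob),
            ]
            for s in seeds:
                cfg = SimulationConfig(duration=120.0, connections=conns)
                rec, _ = simulate_assembloid(cfg, seed=s)
                fields.append(assembloid_directionality(rec, pairwise_table(rec)))
            return fields

        stages = {
            "weak": cohort(0.1, [1, 2]),
            "strong": cohort(0.9, [3, 4]),
        }
        out = maturation_trajectory(stages)
        assert (
            out["stages"]["strong"]["lateral_abs_x_mean"]
            > out["stages"]["weak"]["lateral_abs_x_mean"]
        )
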