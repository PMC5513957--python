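"""Grid enumeration, cell runners, seeding, and the power bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from snarcpower import (
    CellOutcome,
    GridSpec,
    SimulationParams,
    cell_seed_sequence,
    enumerate_grid,
    generate_sample,
    power_estimate,
    run_cell_one_group,
    run_cell_two_group,
    run_grid,
    sample_slopes,
    one_sample_snarc_test,
)
from snarcpower.sweep import _simulate_slope_matrix, alpha_column


class TestEnumerateGrid:
    def test_core_design_has_256_cells(self):
        assert len(enumerate_grid(GridSpec())) == 256

    def test_single_cell(self):
        spec = GridSpec(effects=(-5.0,), ns=(20,), ks=(20,), sdrs=(75.0,))
        assert len(enumerate_grid(spec)) == 1

    def test_extended_plot_grid_cardinality(self):
        spec = GridSpec(
            ks=tuple(range(10, 121, 10)),
            ns=(10, 12, 14, 16, 18, 20, 30, 40, 50),
        )
        assert len(enumerate_grid(spec)) == 12 * 9 * 4 * 4

    def test_deterministic_order(self):
        cells = enumerate_grid(GridSpec())
        assert [c.index for c in cells] == list(range(256))
        assert cells == enumerate_grid(GridSpec())


class TestCellRunners:
    def test_vectorised_matches_subject_by_subject(self):
        """The cell kernel consumes the identical random stream as looping
        generate_subject and applying the dRT regression per subject."""
        params = SimulationParams(slope=-4.0, n=6, k=8, sdr=120.0)
        reps = 5
        vec = _simulate_slope_matrix(params, reps, np.random.default_rng(42))
        rng = np.random.default_rng(42)
        loop = np.array(
            [sample_slopes(generate_sample(params, rng)).slopes for _ in range(reps)]
        )
        assert np.allclose(vec, loop, rtol=1e-10, atol=1e-10)

    def test_one_group_outcome_matches_explicit_tests(self):
        params = SimulationParams(slope=-5.0, n=8, k=10, sdr=150.0)
        reps = 20
        out = run_cell_one_group(params, reps, seed=3)
        rng = np.random.default_rng(3)
        for i in range(reps):
            ss = sample_slopes(generate_sample(params, rng))
            r = one_sample_snarc_test(ss)
            assert out.sig[0.05][i] == r.sig[0.05]

    def test_fixed_seed_reproduces(self):
        params = SimulationParams(slope=-3.0, n=10, k=10, sdr=150.0)
        a = run_cell_one_group(params, 50, seed=9)
        b = run_cell_one_group(params, 50, seed=9)
        for alpha in a.sig:
            assert np.array_equal(a.sig[alpha], b.sig[alpha])

    def test_two_group_requires_equal_n(self):
        pa = SimulationParams(slope=-2.0, n=10, k=10, sdr=75.0)
        pb = SimulationParams(slope=2.0, n=12, k=10, sdr=75.0)
        with pytest.raises(Exception):
            run_cell_two_group(pa, pb, 10)

    def test_two_group_location_invariance(self):
        """Only the slope difference matters: (-2,+2) and (-6,-2) give the
        same power up to Monte Carlo error."""
        reps = 800
        common = dict(n=15, k=15, sdr=150.0)
        o1 = run_cell_two_group(
            SimulationParams(slope=-2.0, **common),
            SimulationParams(slope=2.0, **common),
            reps,
            seed=21,
        )
        o2 = run_cell_two_group(
            SimulationParams(slope=-6.0, **common),
            SimulationParams(slope=-2.0, **common),
            reps,
            seed=22,
        )
        p1, se1 = power_estimate(o1, 0.05)
        p2, se2 = power_estimate(o2, 0.05)
        assert abs(p1 - p2) < 3 * np.hypot(se1, se2)


class TestPowerEstimate:
    def test_all_significant(self):
        out = CellOutcome(None, 4, {0.05: np.ones(4, dtype=np.uint8)})
        assert power_estimate(out, 0.05) == (1.0, 0.0)

    def test_binomial_se(self):
        sig = np.array([1, 0] * 500, dtype=np.uint8)
        out = CellOutcome(None, 1000, {0.05: sig})
        p, se = power_estimate(out, 0.05)
        assert p == 0.5
        assert se == pytest.approx(np.sqrt(0.25 / 1000))

    def test_small_example(self):
        out = CellOutcome(None, 5, {0.05: np.array([1, 0, 1, 0, 1], dtype=np.uint8)})
        assert power_estimate(out, 0.05)[0] == pytest.approx(0.6)


@pytest.fixture(scope="module")
def tiny_grid():
    spec = GridSpec(
        effects=(-5.0, -1.0),
        ns=(5, 10),
        ks=(5,),
        sdrs=(75.0, 300.0),
        replications=30,
        seed=77,
    )
    return spec, run_grid(spec)


class TestRunGrid:
    def test_table_shapes(self, tiny_grid):
        spec, (power, long) = tiny_grid
        assert len(power) == spec.n_cells * len(spec.alphas)
        assert len(long) == spec.n_cells * spec.replications
        assert set(power.columns) == {
            "mode", "slope_or_sld", "n", "k", "sdR",
            "alpha", "replications", "power", "mc_se",
        }
        for a in spec.alphas:
            assert alpha_column(a) in long.columns

    def test_master_seed_fixes_everything(self, tiny_grid):
        spec, (power, long) = tiny_grid
        power2, long2 = run_grid(spec)
        pd.testing.assert_frame_equal(power, power2)
        pd.testing.assert_frame_equal(long, long2)

    def test_cell_isolated_rerun_matches_grid(self, tiny_grid):
        spec, (power, long) = tiny_grid
        cells = enumerate_grid(spec)
        cell = cells[3]
        params = SimulationParams(
            slope=cell.effect, n=cell.n, k=cell.k, sdr=cell.sdr
        )
        out = run_cell_one_group(
            params, spec.replications, spec.alphas,
            seed=cell_seed_sequence(spec.seed, cell.index),
        )
        mask = (
            (long["slope_or_sld"] == cell.effect)
            & (long["n"] == cell.n)
            & (long["k"] == cell.k)
            & (long["sdR"] == cell.sdr)
        )
        assert np.array_equal(
            long.loc[mask, alpha_column(0.05)].to_numpy(), out.sig[0.05]
        )

    def test_power_columns_consistent(self, tiny_grid):
        _, (power, _) = tiny_grid
        assert ((power["power"] >= 0) & (power["power"] <= 1)).all()
        expected_se = np.sqrt(
            power["power"] * (1 - power["power"]) / power["replications"]
        )
        assert np.allclose(power["mc_se"], expected_se)


def test_alpha_column_names():
    assert alpha_column(0.05) == "sig_05"
    assert alpha_column(0.01) == "sig_01"
    assert alpha_column(0.001) == "sig_001"
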