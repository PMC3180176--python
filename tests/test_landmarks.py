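import numpy as np
import pytest

from curvereg import (
    Curve,
    CurvePair,
    OptimizerParams,
    add_landmark,
    arclength_point,
    collect,
    cost,
    curvature,
    generate,
    init_chain,
    max_curvature,
    relax,
)
from curvereg.landmarks import _cost_at, read_landmarks_csv, write_landmarks_csv

from conftest import bumpy_pair, line_curve, sine_curve


def line_pair(length=100.0, n=101):
    return CurvePair(line_curve(length, n), line_curve(length, n), id="line")


def eq1_oracle(chain, i, lam):
    """Straight-line reimplementation of the cost: normalized curvature
    difference plus weighted normalized displacements."""
    src, tgt = chain.pair.source, chain.pair.target
    t1 = abs(
        curvature(src, chain.s_source[i])
        / max_curvature(src, chain.s_source[i - 1], chain.s_source[i + 1])
        - curvature(tgt, chain.s_target[i])
        / max_curvature(tgt, chain.s_target[i - 1], chain.s_target[i + 1])
    )
    ls = (chain.seg_source[i, 1] - chain.seg_source[i, 0]) * src.length
    lt = (chain.seg_target[i, 1] - chain.seg_target[i, 0]) * tgt.length
    ds = abs(chain.s_source[i] - chain.s_source_init[i]) * src.length
    dt = abs(chain.s_target[i] - chain.s_target_init[i]) * tgt.length
    return t1 + lam * (ds / ls + dt / lt)


class TestInitChain:
    def test_endpoints_only(self):
        ch = init_chain(line_pair())
        np.testing.assert_array_equal(ch.s_source, [0.0, 1.0])
        np.testing.assert_array_equal(ch.s_target, [0.0, 1.0])
        assert ch.n_placed == 2

    def test_endpoints_map_to_curve_ends(self):
        pair = bumpy_pair(0)
        ch = init_chain(pair)
        np.testing.assert_allclose(ch.source_points()[0], pair.source.points[0])
        np.testing.assert_allclose(ch.source_points()[-1], pair.source.points[-1])


class TestAddLandmark:
    def test_midpoint_of_straight_curve(self):
        ch = add_landmark(init_chain(line_pair()))
        assert ch.s_source[1] == pytest.approx(0.5)
        np.testing.assert_allclose(
            arclength_point(ch.pair.source, ch.s_source[1]), [50.0, 0.0]
        )

    def test_tie_breaks_toward_lower_s(self):
        ch = add_landmark(add_landmark(init_chain(line_pair())))
        # two equal 50-px segments: the second landmark goes into the first
        assert ch.s_source[1] == pytest.approx(0.25)

    def test_unequal_segments_hand_computed(self):
        # landmarks at 0, 30, 100 px on a 100-px curve: longest segment is
        # [30, 100], midpoint at 65; homologue at fraction 0.5 of the
        # corresponding target segment
        ch = init_chain(line_pair())
        ch.s_source = np.array([0.0, 0.3, 1.0])
        ch.s_target = np.array([0.0, 0.4, 1.0])
        ch.s_source_init = ch.s_source.copy()
        ch.s_target_init = ch.s_target.copy()
        ch.seg_source = np.vstack([ch.seg_source, [np.nan, np.nan]])
        ch.seg_target = np.vstack([ch.seg_target, [np.nan, np.nan]])
        out = add_landmark(ch)
        assert out.s_source[2] == pytest.approx(0.65)
        assert out.s_target[2] == pytest.approx(0.7)  # fraction 0.5 of [0.4, 1]

    def test_records_initial_position_and_segment(self):
        out = add_landmark(init_chain(bumpy_pair(1)))
        assert out.s_source_init[1] == out.s_source[1]
        np.testing.assert_array_equal(out.seg_source[1], [0.0, 1.0])


class TestCost:
    def test_identical_curves_zero(self):
        pair = CurvePair(sine_curve(), sine_curve(), id="same")
        ch = add_landmark(init_chain(pair))
        assert cost(ch, 1, 0.25) == 0.0

    def test_zero_displacement_curvature_term_only(self):
        pair = CurvePair(sine_curve(), line_curve(n_points=200), id="mixed")
        ch = add_landmark(init_chain(pair))
        expected = abs(
            curvature(pair.source, 0.5) / max_curvature(pair.source, 0.0, 1.0)
            - curvature(pair.target, 0.5) / max_curvature(pair.target, 0.0, 1.0)
        )
        assert cost(ch, 1, 0.25) == pytest.approx(expected, abs=1e-12)

    def test_matches_independent_reimplementation(self):
        pair = CurvePair(sine_curve(), sine_curve(mirror=True), id="mirror")
        ch = add_landmark(init_chain(pair))
        # slide both sides by 0.1 of the segment length
        ch.s_source[1] += 0.1
        ch.s_target[1] += 0.1
        assert cost(ch, 1, 0.25) == pytest.approx(eq1_oracle(ch, 1, 0.25), abs=1e-12)

    def test_endpoint_index_rejected(self):
        ch = add_landmark(init_chain(line_pair()))
        for i in (0, 2, 5):
            with pytest.raises(IndexError):
                cost(ch, i, 0.25)


class TestRelax:
    def test_identical_curves_stay_put(self):
        pair = CurvePair(sine_curve(), sine_curve(), id="same")
        ch = add_landmark(init_chain(pair))
        out = relax(ch, 1, OptimizerParams())
        assert out.s_source[1] == ch.s_source[1]
        assert out.s_target[1] == ch.s_target[1]

    @pytest.mark.parametrize("seed", range(3))
    def test_attains_brute_force_grid_minimum(self, seed):
        pair = bumpy_pair(seed)
        ch = add_landmark(init_chain(pair))
        params = OptimizerParams()
        out = relax(ch, 1, params)
        got = cost(out, 1, params.lam)
        grid = np.linspace(0.01, 0.99, 101)
        brute = min(
            _cost_at(ch, 1, s, t, params.lam) for s in grid for t in grid
        )
        assert got <= brute + 1e-3

    def test_large_lambda_restricts_displacement(self):
        pair = bumpy_pair(3)
        ch = add_landmark(init_chain(pair))
        out = relax(ch, 1, OptimizerParams(lam=1e3))
        assert abs(out.s_source[1] - ch.s_source[1]) < 1e-3
        assert abs(out.s_target[1] - ch.s_target[1]) < 1e-3

    @pytest.mark.parametrize("seed", range(4))
    def test_never_increases_cost(self, seed):
        pair = bumpy_pair(seed + 10)
        params = OptimizerParams()
        ch = add_landmark(init_chain(pair))
        before = cost(ch, 1, params.lam)
        after = cost(relax(ch, 1, params), 1, params.lam)
        assert after <= before + 1e-12


class TestGenerate:
    def test_n2_endpoints_only(self):
        opt, non = generate(bumpy_pair(0), OptimizerParams(n_landmarks=2))
        assert opt.n_placed == non.n_placed == 2
        np.testing.assert_array_equal(opt.s_source, [0.0, 1.0])

    def test_identical_pair_opt_equals_non(self):
        pair = CurvePair(sine_curve(), sine_curve(), id="same")
        opt, non = generate(pair, OptimizerParams(n_landmarks=5))
        np.testing.assert_allclose(opt.s_source, non.s_source, atol=1e-12)
        np.testing.assert_allclose(opt.s_target, non.s_target, atol=1e-12)

    def test_optimized_cost_not_above_nonoptimized(self):
        pair = bumpy_pair(7)
        params = OptimizerParams(n_landmarks=8)
        opt, non = generate(pair, params)
        for i in range(1, opt.n_placed - 1):
            assert cost(opt, i, params.lam) <= cost(non, i, params.lam) + 1e-9

    @pytest.mark.parametrize("reoptimize_all", [False, True])
    def test_order_preserved_and_invariants_hold(self, reoptimize_all):
        pair = bumpy_pair(4)
        opt, non = generate(
            pair, OptimizerParams(n_landmarks=9, reoptimize_all=reoptimize_all)
        )
        for ch in (opt, non):
            assert ch.n_placed == 9
            assert np.all(np.diff(ch.s_source) > 0)
            assert np.all(np.diff(ch.s_target) > 0)
            assert ch.s_source[0] == 0.0 and ch.s_source[-1] == 1.0

    def test_bit_reproducible(self):
        pair = bumpy_pair(5)
        params = OptimizerParams(n_landmarks=7)
        a, _ = generate(pair, params)
        b, _ = generate(pair, params)
        np.testing.assert_array_equal(a.s_source, b.s_source)
        np.testing.assert_array_equal(a.s_target, b.s_target)

    def test_lambda_monotone_displacement(self):
        # stronger displacement weighting never increases mean sliding
        pairs = [bumpy_pair(s) for s in (20, 21, 22)]
        means = []
        for lam in (0.05, 0.25, 1.0, 10.0):
            disp = []
            for pair in pairs:
                opt, _ = generate(pair, OptimizerParams(lam=lam, n_landmarks=6))
                disp.extend(
                    np.abs(opt.s_source - opt.s_source_init) * pair.source.length
                )
                disp.extend(
                    np.abs(opt.s_target - opt.s_target_init) * pair.target.length
                )
            means.append(np.mean(disp))
        assert all(b <= a + 1e-9 for a, b in zip(means, means[1:]))


class TestCollect:
    def test_single_chain_counts(self):
        opt, _ = generate(bumpy_pair(0), OptimizerParams(n_landmarks=4))
        src, tgt = collect([opt])
        assert src.shape == tgt.shape == (4, 2)

    def test_shared_endpoint_deduplicated(self):
        # two curves sharing one endpoint: 2x4 landmarks -> 7 pairs
        x1 = np.linspace(0.0, 50.0, 60)
        x2 = np.linspace(50.0, 100.0, 60)
        mk = lambda x: Curve(np.column_stack([x, 0.1 * x]), id=str(x[0]))
        pa = CurvePair(mk(x1), mk(x1), id="a")
        pb = CurvePair(mk(x2), mk(x2), id="b")
        chains = [generate(p, OptimizerParams(n_landmarks=4))[0] for p in (pa, pb)]
        src, tgt = collect(chains)
        assert len(src) == 7

    def test_deterministic_order(self):
        chains = [
            generate(bumpy_pair(s), OptimizerParams(n_landmarks=4))[0]
            for s in (31, 30)
        ]
        a, _ = collect(chains)
        b, _ = collect(list(reversed(chains)))
        np.testing.assert_array_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            collect([])


class TestLandmarkIO:
    def test_csv_roundtrip(self, tmp_path):
        opt, _ = generate(bumpy_pair(2), OptimizerParams(n_landmarks=5))
        path = tmp_path / "landmarks.csv"
        write_landmarks_csv([opt], path, optimized=True)
        src, tgt = read_landmarks_csv(path)
        np.testing.assert_allclose(src, opt.source_points(), atol=1e-12)
        np.testing.assert_allclose(tgt, opt.target_points(), atol=1e-12)
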