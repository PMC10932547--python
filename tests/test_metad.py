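"""HILLS parsing, bias summation, PMF reconstruction and energetics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from unbind import metad


def hills_frame(cv, sigma=0.05, height=0.3, t0=0.2, biasf=35.0):
    cv = np.atleast_1d(np.asarray(cv, dtype=float))
    return pd.DataFrame({
        "time": t0 * (1 + np.arange(cv.size)),
        "cv": cv,
        "sigma": sigma,
        "height": height,
        "biasf": biasf,
    })


class TestParseHills:
    def test_empty_body_gives_empty_table(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("#! FIELDS time cv sigma height biasf\n")
        assert len(metad.parse_hills(p)) == 0

    def test_hand_written_fixture_exact_values(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text(
            "#! FIELDS time cv sigma height biasf\n"
            "# comment line\n"
            "0.2 -0.95 0.05 0.3 35\n"
            "0.4 -0.90 0.05 0.29 35\n"
            "0.6 -0.85 0.05 0.28 35\n"
        )
        df = metad.parse_hills(p)
        assert len(df) == 3
        assert df["cv"].tolist() == [-0.95, -0.90, -0.85]
        assert df["height"].tolist() == [0.3, 0.29, 0.28]

    def test_plumed_style_column_names(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text(
            "#! FIELDS time xi sigma_xi height biasf\n"
            "0.2 1.5 0.05 0.3 35\n"
        )
        df = metad.parse_hills(p)
        assert df["cv"].iloc[0] == 1.5

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("#! FIELDS time cv sigma\n0.2 1.0 0.05\n")
        with pytest.raises(ValueError, match="height"):
            metad.parse_hills(p)

    def test_non_monotone_time_warns(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("#! FIELDS time cv sigma height biasf\n"
                     "0.4 0 0.05 0.3 35\n0.2 0 0.05 0.3 35\n")
        with pytest.warns(RuntimeWarning, match="monotone"):
            metad.parse_hills(p)

    def test_generator_output_round_trips(self, tmp_path):
        from unbind.synthetic import WTMetadParams, simulate_wtmetad

        run = simulate_wtmetad(
            WTMetadParams(n_walkers=2, t_per_walker_ps=5.0, seed=5))
        paths = run.write_hills(tmp_path)
        for path, original in zip(paths, run.hills):
            parsed = metad.parse_hills(path)
            np.testing.assert_allclose(parsed["cv"], original["cv"],
                                       atol=1e-9)
            np.testing.assert_allclose(parsed["height"], original["height"],
                                       atol=1e-9)
            # write(parse(x)) is byte-identical to write(x)
            rewritten = metad.write_hills(parsed, tmp_path / "rt")
            assert rewritten.read_text() == path.read_text()


class TestMergeWalkers:
    def test_single_walker_identity(self):
        h = hills_frame([0.1, 0.2, 0.3])
        merged = metad.merge_walkers([h])
        pd.testing.assert_frame_equal(
            merged.drop(columns="walker"), h)

    def test_interleaved_walkers_sorted_by_time(self):
        h1 = hills_frame([0.0, 0.1], t0=0.2)
        h2 = hills_frame([1.0, 1.1], t0=0.3)
        merged = metad.merge_walkers([h1, h2])
        assert (np.diff(merged["time"]) >= 0).all()

    def test_count_conserved_over_24_walkers(self):
        walkers = [hills_frame(np.full(10, i * 0.1)) for i in range(24)]
        merged = metad.merge_walkers(walkers)
        assert len(merged) == 240

    def test_ties_broken_by_walker_index(self):
        h1 = hills_frame([5.0], t0=1.0)
        h2 = hills_frame([7.0], t0=1.0)
        merged = metad.merge_walkers([h2, h1])  # walker 0 holds cv=7
        assert merged["cv"].tolist() == [7.0, 5.0]


class TestBiasOnGrid:
    def test_single_hill_at_centre(self):
        v = metad.bias_on_grid(hills_frame([0.5], height=0.3),
                               np.array([0.5]))
        assert v[0] == pytest.approx(0.3)

    def test_single_hill_one_sigma_away(self):
        v = metad.bias_on_grid(hills_frame([0.0], sigma=0.1, height=1.0),
                               np.array([0.1]))
        assert v[0] == pytest.approx(np.exp(-0.5))

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(14)
        n = 10_000
        hills = pd.DataFrame({
            "time": np.arange(n) * 0.2,
            "cv": rng.uniform(-2, 2, n),
            "sigma": rng.uniform(0.03, 0.1, n),
            "height": rng.uniform(0.05, 0.3, n),
            "biasf": 35.0,
        })
        grid = np.linspace(-2, 2, 512)
        v = metad.bias_on_grid(hills, grid)
        oracle = np.zeros_like(grid)
        c = hills["cv"].to_numpy()
        s = hills["sigma"].to_numpy()
        h = hills["height"].to_numpy()
        for j, x in enumerate(grid):
            acc = 0.0
            for i in range(n):
                acc += h[i] * np.exp(-0.5 * ((x - c[i]) / s[i]) ** 2)
            oracle[j] = acc
        np.testing.assert_allclose(v, oracle, rtol=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-2, 2), min_size=2, max_size=12),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, centres, rnd):
        hills = hills_frame(centres)
        grid = np.linspace(-3, 3, 61)
        v1 = metad.bias_on_grid(hills, grid)
        perm = list(range(len(centres)))
        rnd.shuffle(perm)
        v2 = metad.bias_on_grid(hills.iloc[perm].reset_index(drop=True), grid)
        np.testing.assert_allclose(v1, v2, rtol=1e-12, atol=1e-12)


class TestPmf:
    def test_zero_hills_identically_zero(self):
        grid = np.linspace(-1, 1, 11)
        prof = metad.pmf(hills_frame([]).iloc[:0], grid, 35.0)
        assert np.all(prof.F_kcal == 0.0)

    def test_infinite_gamma_equals_minus_bias(self):
        hills = hills_frame([0.0, 0.5], height=2.0, sigma=0.2)
        grid = np.linspace(-1, 1, 101)
        prof = metad.pmf(hills, grid, np.inf)
        v = metad.bias_on_grid(hills, grid) / metad.KCAL_TO_KJ
        expected = -v - (-v).min()
        np.testing.assert_allclose(prof.F_kcal, expected, atol=1e-12)

    def test_wt_factor_scales_profile(self):
        hills = hills_frame([0.0], height=4.184)  # 1 kcal/mol at centre
        grid = np.array([-1.0, 0.0])
        prof = metad.pmf(hills, grid, gamma=35.0)
        # F(-1) - F(0) = (35/34) * 1 kcal/mol up to the far tail
        diff = prof.F_kcal[0] - prof.F_kcal[1]
        assert diff == pytest.approx(35 / 34, abs=1e-8)

    def test_gamma_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            metad.pmf(hills_frame([0.0]), np.array([0.0, 1.0]), 1.0)

    def test_grid_refinement_stable_barrier(self):
        """Halving the grid spacing moves the barrier < 0.05 kcal/mol."""
        rng = np.random.default_rng(3)
        centres = np.concatenate([rng.normal(-1, 0.15, 400),
                                  rng.normal(1, 0.15, 400)])
        hills = hills_frame(centres, sigma=0.1, height=0.25)
        barriers = []
        for n in (301, 601):
            grid = np.linspace(-1.8, 1.8, n)
            prof = metad.pmf(hills, grid, 35.0)
            b, _ = metad.barrier_and_dg(prof, (-1.4, -0.6), (0.6, 1.4))
            barriers.append(b)
        assert abs(barriers[1] - barriers[0]) < 0.05


class TestConvergence:
    def test_single_checkpoint_equals_full_pmf(self):
        hills = hills_frame(np.linspace(-1, 1, 50))
        grid = np.linspace(-2, 2, 101)
        profiles, dev = metad.convergence_series(hills, grid, [len(hills)])
        full = metad.pmf(hills, grid, 35.0)
        np.testing.assert_allclose(profiles[0].F_kcal, full.F_kcal)
        assert dev[-1] == 0.0

    def test_converged_synthetic_run_levels_off(self):
        from unbind.synthetic import WTMetadParams, simulate_wtmetad

        run = simulate_wtmetad(
            WTMetadParams(n_walkers=8, t_per_walker_ps=150.0, seed=2))
        merged = metad.merge_walkers(run.hills)
        # basin region; the steep walls are rarely revisited late in a run
        grid = np.linspace(-1.2, 1.2, 201)
        n = len(merged)
        _, dev = metad.convergence_series(
            merged, grid, [n // 4, n // 2, int(0.9 * n), n], gamma=35.0)
        assert dev[-1] == 0.0
        assert dev[-2] <= 0.5  # late-stage profiles agree within 0.5 kcal/mol

    def test_non_increasing_checkpoints_rejected(self):
        with pytest.raises(ValueError):
            metad.convergence_series(hills_frame([0.0]),
                                     np.linspace(-1, 1, 5), [3, 2])


class TestBarrierAndDg:
    def test_triangle_profile(self):
        grid = np.linspace(-1, 1, 201)
        # piecewise linear 0 -> 3 -> -4
        f = np.interp(grid, [-1, 0, 1], [0.0, 3.0, -4.0])
        prof = metad.FreeEnergyProfile(grid, f)
        b, dg = metad.barrier_and_dg(prof, (-1.0, -0.8), (0.8, 1.0))
        assert b == pytest.approx(3.0, abs=1e-9)
        assert dg == pytest.approx(-4.0, abs=1e-9)

    def test_symmetric_double_well_zero_reaction_free_energy(self):
        grid = np.linspace(-1.5, 1.5, 301)
        f = 4.0 * ((grid ** 2 - 1) ** 2)
        prof = metad.FreeEnergyProfile(grid, f)
        b, dg = metad.barrier_and_dg(prof, (-1.2, -0.8), (0.8, 1.2))
        assert dg == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(4.0, rel=1e-6)

    def test_analytic_quartic_extrema(self):
        a, bh = 1.3, 2.5
        grid = np.linspace(-2, 2, 4001)
        f = bh * ((grid / a) ** 2 - 1) ** 2
        prof = metad.FreeEnergyProfile(grid, f)
        b, dg = metad.barrier_and_dg(prof, (-1.5, -1.1), (1.1, 1.5))
        assert b == pytest.approx(bh, rel=1e-4)
        assert dg == pytest.approx(0.0, abs=1e-9)

    def test_monotone_profile_has_no_barrier(self):
        grid = np.linspace(0, 1, 101)
        prof = metad.FreeEnergyProfile(grid, 5 * grid)
        with pytest.raises(ValueError, match="maximum"):
            metad.barrier_and_dg(prof, (0.0, 0.1), (0.9, 1.0))


class TestReplicaMeanSem:
    def test_identical_replicas_zero_sem(self):
        grid = np.linspace(-1, 1, 51)
        f = (grid ** 2 - 1) ** 2
        reps = [metad.FreeEnergyProfile(grid, f.copy()) for _ in range(3)]
        prof = metad.replica_mean_sem(reps)
        np.testing.assert_allclose(prof.sem_kcal, 0.0, atol=1e-14)

    def test_constant_offsets_removed_by_alignment(self):
        grid = np.linspace(-1, 1, 51)
        f = (grid ** 2 - 1) ** 2
        reps = [metad.FreeEnergyProfile(grid, f + c) for c in (0.0, 2.0)]
        prof = metad.replica_mean_sem(reps)
        np.testing.assert_allclose(prof.sem_kcal, 0.0, atol=1e-12)

    def test_sem_matches_direct_formula(self, rng):
        grid = np.linspace(-1, 1, 31)
        base = (grid ** 2 - 1) ** 2
        noisy = [base + 0.05 * rng.standard_normal(grid.size)
                 for _ in range(3)]
        reps = [metad.FreeEnergyProfile(grid, f) for f in noisy]
        prof = metad.replica_mean_sem(reps)
        aligned = np.vstack([f - f.min() for f in noisy])
        sem = aligned.std(axis=0, ddof=1) / np.sqrt(3)
        np.testing.assert_allclose(prof.sem_kcal, sem, atol=1e-12)

    def test_mismatched_grids_interpolated_with_warning(self):
        g1 = np.linspace(-1, 1, 51)
        g2 = np.linspace(-1, 1, 71)
        reps = [metad.FreeEnergyProfile(g1, (g1 ** 2 - 1) ** 2),
                metad.FreeEnergyProfile(g2, (g2 ** 2 - 1) ** 2)]
        with pytest.warns(RuntimeWarning, match="interpolating"):
            prof = metad.replica_mean_sem(reps)
        assert prof.grid.size == 51


class TestAntisymCv:
    def test_equidistant_gives_zero(self):
        xi, *_ = metad.antisym_cv((0, 1, 0), (1, 0, 0), (-1, 0, 0))
        assert xi == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        xi, r_cs, r_cn = metad.antisym_cv((0, 0, 2), (0, 0, 0), (0, 0, 5))
        assert (xi, r_cs, r_cn) == pytest.approx((-1.0, 2.0, 3.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=9, max_size=9))
    def test_matches_norm_oracle(self, coords):
        ce, sd, n6 = (np.array(coords[i:i + 3]) for i in (0, 3, 6))
        if np.allclose(ce, sd) or np.allclose(ce, n6):
            return
        xi, r_cs, r_cn = metad.antisym_cv(ce, sd, n6)
        assert r_cs == pytest.approx(np.sqrt(((ce - sd) ** 2).sum()))
        assert r_cn == pytest.approx(np.sqrt(((ce - n6) ** 2).sum()))
        assert xi == pytest.approx(r_cs - r_cn)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            metad.antisym_cv((0, 0, 0), (0, 0, 0), (1, 0, 0))
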