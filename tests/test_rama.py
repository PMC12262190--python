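"""Free-energy surfaces, region classification and population statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mucinppii as m
from mucinppii.ensemble import KB_KCAL
from mucinppii.rama import COIL, label_codes
from conftest import region_masses_by_quadrature, weighted_spec


def _degenerate_traj(phi=-75.0, psi=145.0, n_frames=50, n_res=2):
    return m.DihedralTrajectory(
        np.full((n_frames, n_res), phi), np.full((n_frames, n_res), psi),
        np.arange(1, n_res + 1), ["T"] * n_res, [False] * n_res)


class TestHistogram2d:
    def test_single_point_mass(self):
        p, pe, se = m.histogram2d(_degenerate_traj(), 36)
        assert p.max() == 1.0 and p.sum() == pytest.approx(1.0)

    def test_normalisation(self, stationary_trajectory):
        p, _, _ = m.histogram2d(stationary_trajectory, 72)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_sampling_flat(self):
        rng = np.random.default_rng(0)
        n = 100000
        traj = m.DihedralTrajectory(
            rng.uniform(-180, 180, (n, 1)).clip(None, np.nextafter(180, 0)),
            rng.uniform(-180, 180, (n, 1)).clip(None, np.nextafter(180, 0)),
            [1], ["A"], [False])
        p, _, _ = m.histogram2d(traj, 36)
        mean = 1.0 / 36 ** 2
        se = np.sqrt(mean * (1 - mean) / n)
        assert p.max() < mean + 5 * se

    def test_residue_filter(self, stationary_trajectory):
        p, _, _ = m.histogram2d(stationary_trajectory, 36, residues=[393])
        assert p.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        traj = _degenerate_traj(n_frames=1)
        traj.phi[:] = np.nan
        with pytest.raises(ValueError):
            m.histogram2d(traj, 36)


class TestFreeEnergySurface:
    def test_modal_bin_zero_and_nonnegative(self, stationary_trajectory):
        fes = m.surface_from_trajectory(stationary_trajectory, 72, 300.0)
        defined = np.isfinite(fes.delta_g)
        assert fes.delta_g[defined].min() == 0.0
        assert fes.delta_g[np.unravel_index(
            np.argmax(fes.probability), fes.probability.shape)] == 0.0

    def test_half_max_bin_closed_form(self):
        p = np.array([[0.5, 0.25], [0.25, 0.0]])
        fes = m.free_energy_surface(p, [0, 1, 2], [0, 1, 2], 300.0)
        expected = KB_KCAL * 300.0 * np.log(2.0)   # ~0.4132 kcal/mol
        assert fes.delta_g[0, 1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4132, abs=5e-5)
        assert np.isinf(fes.delta_g[1, 1])

    def test_linear_in_temperature(self):
        p = np.array([[0.5, 0.25], [0.25, 0.0]])
        f300 = m.free_energy_surface(p, [0, 1, 2], [0, 1, 2], 300.0)
        f600 = m.free_energy_surface(p, [0, 1, 2], [0, 1, 2], 600.0)
        defined = np.isfinite(f300.delta_g)
        assert np.allclose(f600.delta_g[defined], 2.0 * f300.delta_g[defined])

    def test_inverse_recovers_probability(self, stationary_trajectory):
        fes = m.surface_from_trajectory(stationary_trajectory, 72, 300.0)
        defined = np.isfinite(fes.delta_g)
        recovered = np.exp(-fes.delta_g[defined] /
                           (KB_KCAL * fes.temperature)) * fes.p_max
        assert np.abs(recovered - fes.probability[defined]).max() < 1e-12

    def test_duplicate_frames_leave_surface_unchanged(self):
        traj = _degenerate_traj()
        rng = np.random.default_rng(1)
        traj.phi += rng.uniform(-30, 30, traj.phi.shape)
        traj.psi += rng.uniform(-30, 30, traj.psi.shape)
        doubled = m.DihedralTrajectory(
            np.vstack([traj.phi, traj.phi]), np.vstack([traj.psi, traj.psi]),
            traj.residue_numbers, traj.residue_types, traj.glycosylated)
        f1 = m.surface_from_trajectory(traj, 36)
        f2 = m.surface_from_trajectory(doubled, 36)
        assert np.array_equal(f1.delta_g, f2.delta_g)

    def test_unnormalised_grid_rejected(self):
        with pytest.raises(ValueError, match="normalised"):
            m.free_energy_surface(np.array([[0.5, 0.2], [0.2, 0.0]]),
                                  [0, 1, 2], [0, 1, 2])

    def test_tsv_and_json_export(self, tmp_path, stationary_trajectory):
        fes = m.surface_from_trajectory(stationary_trajectory, 36)
        fes.write_tsv(tmp_path / "fes.tsv")
        fes.write_json(tmp_path / "fes.json")
        df = pd.read_csv(tmp_path / "fes.tsv", sep="\t")
        assert list(df.columns) == ["phi_lo", "phi_hi", "psi_lo", "psi_hi",
                                    "P", "dG"]
        assert len(df) == 36 * 36
        assert df["P"].sum() == pytest.approx(1.0, abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize("phi,psi,expected", [
        (-75.0, 145.0, "PPII"),
        (60.0, 45.0, "alphaL"),
        (0.0, 0.0, COIL),
        (-100.0, -170.0, "beta"),   # psi wraps: -170 = 190 in (50, 240)
        (-63.0, -80.0, "alphaR"),
        (-120.0, 140.0, "beta"),
        (-75.0, -150.0, "PPII"),    # psi wraps for PPII too
    ])
    def test_examples(self, phi, psi, expected):
        assert m.classify(phi, psi) == expected

    def test_boundary_angles_fall_to_coil(self):
        # strict inequalities: exact printed bounds belong to no region
        assert m.classify(-90.0, 145.0) == COIL
        assert m.classify(30.0, 40.0) == COIL

    def test_total_and_single_valued_on_degree_grid(self):
        """Exhaustive 1-degree torus scan: every point has exactly one
        label, and named regions never overlap."""
        regions = m.RegionSet()
        assert regions.check_disjoint(step=1.0)
        grid = np.arange(-180.0, 180.0, 1.0)
        phi, psi = np.meshgrid(grid, grid, indexing="ij")
        labels = m.classify(phi, psi, regions)
        assert set(np.unique(labels)) <= set(regions.labels)

    @given(st.floats(-180.0, 179.999), st.floats(-180.0, 179.999))
    @settings(max_examples=200, derandomize=True)
    def test_total_on_arbitrary_angles(self, phi, psi):
        assert m.classify(phi, psi) in m.RegionSet().labels

    def test_undefined_angles_get_none(self):
        assert m.classify(np.nan, 0.0) is None


class TestResiduePopulations:
    def test_degenerate_ppii_ensemble(self):
        pops = m.residue_populations(_degenerate_traj())
        ppii = pops[pops.region == "PPII"]
        assert (ppii["fraction"] == 1.0).all()
        zero = pops[pops.region != "PPII"]
        assert (zero["fraction"] == 0.0).all()

    def test_fractions_sum_to_one(self, stationary_trajectory):
        pops = m.residue_populations(stationary_trajectory)
        sums = pops.groupby("residue_number")["fraction"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_matches_frame_average_of_classify(self):
        """Population fractions equal the time average of per-frame labels
        (direct oracle equivalence on a small trajectory)."""
        rng = np.random.default_rng(7)
        traj = m.DihedralTrajectory(
            rng.uniform(-180, 179, (200, 3)), rng.uniform(-180, 179, (200, 3)),
            [1, 2, 3], ["A", "T", "P"], [False] * 3)
        pops = m.residue_populations(traj)
        for r in range(3):
            labels = [m.classify(traj.phi[f, r], traj.psi[f, r])
                      for f in range(200)]
            for region in m.RegionSet().labels:
                expected = np.mean([lab == region for lab in labels])
                got = pops[(pops.residue_number == r + 1)
                           & (pops.region == region)]["fraction"].iloc[0]
                assert got == pytest.approx(expected, abs=1e-12)


class TestPopulationCi:
    def test_degenerate_ensemble_unit_interval(self):
        table = m.population_ci(_degenerate_traj(n_frames=500),
                                block_length=5, n_boot=200, seed=0)
        ppii = table[table.region == "PPII"]
        assert (ppii["ci_low"] == 1.0).all() and (ppii["ci_high"] == 1.0).all()

    def test_deterministic_given_seed(self, stationary_trajectory):
        traj = stationary_trajectory.select_frames(slice(0, 2000))
        a = m.population_ci(traj, block_length=5, n_boot=300, seed=11)
        b = m.population_ci(traj, block_length=5, n_boot=300, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_ci_brackets_fraction(self, stationary_trajectory):
        traj = stationary_trajectory.select_frames(slice(0, 2000))
        t = m.population_ci(traj, block_length=5, n_boot=300, seed=1)
        assert (t["ci_low"] <= t["fraction"] + 1e-12).all()
        assert (t["ci_high"] >= t["fraction"] - 1e-12).all()

    def test_width_shrinks_like_sqrt_n(self):
        spec = weighted_spec({"PPII": 0.7, "alphaR": 0.3}, kappa=100.0)
        widths = []
        for n, seed in ((1000, 0), (4000, 1)):
            traj = m.sample_ensemble([spec], n, seed=seed)
            t = m.population_ci(traj, block_length=1, n_boot=500, seed=2)
            row = t[t.region == "PPII"].iloc[0]
            widths.append(row["ci_high"] - row["ci_low"])
        ratio = widths[0] / widths[1]
        assert 1.5 < ratio < 2.7      # ~2 expected for 4x the frames

    def test_block_length_validation(self):
        traj = _degenerate_traj(n_frames=50)
        with pytest.raises(ValueError, match="block_length"):
            m.population_ci(traj, block_length=50, n_boot=200)

    def test_n_boot_validation(self):
        with pytest.raises(ValueError, match="n_boot"):
            m.population_ci(_degenerate_traj(), n_boot=50)


class TestComparePopulations:
    def test_identical_trajectories_not_significant(
            self, stationary_trajectory):
        traj = stationary_trajectory.select_frames(slice(0, 2000))
        out = m.compare_populations(traj, traj, n_boot=300, seed=0)
        assert not out["significant"].any()

    def test_constructed_shift_detected(self):
        """A 0.3 alphaR -> PPII weight shift is flagged significant with
        the right directions."""
        base = weighted_spec({"PPII": 0.4, "alphaR": 0.4, "beta": 0.2},
                             kappa=100.0)
        shifted = weighted_spec({"PPII": 0.4, "alphaR": 0.4, "beta": 0.2},
                                kappa=100.0, glycosylated=True,
                                glyco_weight_shift=0.3)
        a = m.sample_ensemble([base, base], 20000, seed=5)
        b = m.sample_ensemble([shifted, base], 20000, seed=6)
        out = m.compare_populations(a, b, n_boot=400, seed=7)
        r1 = out[out.residue_number == 1].set_index("region")
        assert r1.loc["PPII", "significant"] and r1.loc["PPII", "delta"] > 0
        assert r1.loc["alphaR", "significant"] and \
            r1.loc["alphaR", "delta"] < 0
        # the unshifted residue shows no PPII/alphaR calls
        r2 = out[out.residue_number == 2].set_index("region")
        assert not r2.loc["PPII", "significant"]
        assert not r2.loc["alphaR", "significant"]

    def test_null_false_positive_rate_near_alpha(self):
        """Under the null (same spec, different seeds) the per-cell
        significance rate is close to alpha = 0.05."""
        spec = weighted_spec({"PPII": 0.6, "alphaR": 0.4}, kappa=100.0)
        calls = []
        rng_seed = 0
        for rep in range(40):
            a = m.sample_ensemble([spec, spec], 1500, seed=rng_seed)
            b = m.sample_ensemble([spec, spec], 1500, seed=rng_seed + 1)
            rng_seed += 2
            out = m.compare_populations(a, b, block_length=1, n_boot=200,
                                        seed=rep)
            live = out[out.region.isin(["PPII", "alphaR"])]
            calls.extend(live["significant"].tolist())
        rate = np.mean(calls)
        # 160 (correlated) calls; generous 3-sigma band around 0.05
        assert 0.0 <= rate < 0.13

    def test_mismatched_residues_rejected(self, stationary_trajectory):
        other = _degenerate_traj(n_res=2)
        with pytest.raises(ValueError, match="numbering"):
            m.compare_populations(stationary_trajectory, other)


def test_label_codes_match_classify(stationary_trajectory):
    traj = stationary_trajectory.select_frames(slice(0, 20))
    codes, labels = label_codes(traj)
    names = m.classify(traj.phi, traj.psi)
    for i, lab in enumerate(labels):
        assert np.array_equal(codes == i, names == lab)
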