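"""Region-set validation, classification, densities and fraction tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polyconf as pc
from polyconf.regions import BUILTIN_REGION_SETS, RegionOverlapError


class TestBuiltinSets:
    @pytest.mark.parametrize("name", BUILTIN_REGION_SETS)
    def test_partition_holds_on_one_degree_grid(self, name):
        # construction runs validate_partition; re-run explicitly
        pc.builtin_region_set(name).validate_partition(grid_step=1.0)

    def test_alpha_r_box_bounds(self, standard_regions):
        box = standard_regions.region_for("alphaR").boxes[0]
        assert box.phi == (-90, -30) and box.psi == (-90, 0)

    def test_ppii_box_bounds(self, standard_regions):
        box = standard_regions.region_for("PPII").boxes[0]
        assert box.phi == (-104, -46) and box.psi == (116, 174)

    def test_beta_psi_clause_read_as_104_to_180(self, standard_regions):
        assert pc.classify(-150, 150, standard_regions) == "beta"
        assert pc.classify(-150, 104, standard_regions) == "beta"
        assert pc.classify(-150, 103.9, standard_regions) == "other"

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            pc.builtin_region_set("charmm99_typo")

    def test_overlapping_user_set_rejected(self):
        a = pc.Region("a", (pc.AngularBox((-90, -30), (-90, 0)),))
        b = pc.Region("b", (pc.AngularBox((-60, 0), (-30, 30)),))
        with pytest.raises(RegionOverlapError):
            pc.RegionSet("bad", (a, b))

    def test_yaml_round_trip(self, tmp_path, standard_regions):
        p = tmp_path / "regions.yaml"
        standard_regions.to_yaml(p)
        back = pc.RegionSet.from_yaml(p)
        grid = np.arange(-179.5, 180, 7.0)
        pp, ss = np.meshgrid(grid, grid)
        np.testing.assert_array_equal(back.classify_array(pp, ss),
                                      standard_regions.classify_array(pp, ss))

    def test_integration_sets_have_area_indices(self):
        for name in ("charmm_integration", "amber99_integration"):
            rs = pc.builtin_region_set(name)
            assert sorted(r.area_index for r in rs.regions) == [0, 1, 2, 3, 4]
        assert "3.10" in pc.builtin_region_set("charmm_integration").labels
        assert "additional_screw" in pc.builtin_region_set("amber99_integration").labels


class TestClassify:
    @pytest.mark.parametrize("phi, psi, label", [
        (-60, -45, "alphaR"),
        (60, 45, "alphaL"),
        (-75, 145, "PPII"),
        (-150, 150, "beta"),
        (0, 0, "other"),
    ])
    def test_examples(self, standard_regions, phi, psi, label):
        assert pc.classify(phi, psi, standard_regions) == label

    def test_wrap_equivalence_example(self, standard_regions):
        assert pc.classify(300, 45, standard_regions) == \
            pc.classify(-60, 45, standard_regions)

    # dyadic angles keep phi + 360k exactly representable
    _angles = st.integers(-1440, 1440).map(lambda n: n * 0.125)

    @given(_angles, _angles, st.integers(-2, 2), st.integers(-2, 2))
    @settings(deadline=None, max_examples=200)
    def test_wrap_equivalence_property(self, phi, psi, k, m):
        rs = pc.builtin_region_set("standard_literature")
        assert pc.classify(phi + 360 * k, psi + 360 * m, rs) == \
            pc.classify(phi, psi, rs)

    def test_boundary_convention(self, standard_regions):
        # printed closed bounds: alphaR includes all four edges
        assert pc.classify(-90, -90, standard_regions) == "alphaR"
        assert pc.classify(-30, 0, standard_regions) == "alphaR"
        # beta phi upper bound is open at -104 (PPII takes over in psi >= 116)
        assert pc.classify(-104, 150, standard_regions) == "PPII"
        assert pc.classify(-104.0001, 150, standard_regions) == "beta"


class TestClassifyTrajectory:
    def test_termini_excluded(self, emitted_trajectory, standard_regions):
        states = pc.classify_trajectory(emitted_trajectory, standard_regions)
        assert states.n_analyzed_monomers == emitted_trajectory.chain_length - 2

    def test_constant_alpha_r(self, standard_regions):
        traj = pc.DihedralTrajectory(
            times=np.arange(5.0), residue_ids=np.arange(1, 33),
            phi=np.full((5, 32), -60.0), psi=np.full((5, 32), -45.0))
        states = pc.classify_trajectory(traj, standard_regions)
        assert (states.labels() == "alphaR").all()
        assert states.codes.shape == (5, 30)

    def test_empty_trajectory_raises(self, standard_regions):
        traj = pc.DihedralTrajectory(times=np.empty(0), residue_ids=np.arange(1, 33),
                                     phi=np.empty((0, 32)), psi=np.empty((0, 32)))
        with pytest.raises(ValueError, match="no frames"):
            pc.classify_trajectory(traj, standard_regions)


class TestDensity:
    def test_single_sample_single_bin(self, standard_regions):
        traj = pc.DihedralTrajectory(times=[0.0], residue_ids=[1, 2, 3],
                                     phi=[[np.nan, -60.0, np.nan]],
                                     psi=[[np.nan, -45.0, np.nan]])
        dens = pc.ramachandran_density(traj, bin_width=10.0)
        assert dens.weights.max() == pytest.approx(1.0)
        assert (dens.weights > 0).sum() == 1

    def test_bad_bin_width_rejected(self, emitted_trajectory):
        with pytest.raises(ValueError, match="divide"):
            pc.ramachandran_density(emitted_trajectory, bin_width=7.0)

    def test_weights_sum_to_one(self, emitted_trajectory):
        dens = pc.ramachandran_density(emitted_trajectory, bin_width=5.0)
        assert dens.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_sampling_multinomial_bound(self, rng):
        n = 1_000_000
        traj = pc.DihedralTrajectory(
            times=np.arange(float(n)), residue_ids=[1],
            phi=rng.uniform(-180, 180, (n, 1)).clip(-179.999, 180),
            psi=rng.uniform(-180, 180, (n, 1)).clip(-179.999, 180))
        dens = pc.ramachandran_density(traj, bin_width=10.0, exclude_termini=False)
        p = 1.0 / 1296
        sd = np.sqrt(p * (1 - p) / n)
        assert np.abs(dens.weights - p).max() < 5 * sd


class TestIntegration:
    def test_all_alpha_r_density(self, standard_regions):
        traj = pc.DihedralTrajectory(
            times=np.arange(3.0), residue_ids=np.arange(1, 6),
            phi=np.full((3, 5), -60.0), psi=np.full((3, 5), -45.0))
        dens = pc.ramachandran_density(traj, bin_width=10.0)
        table = pc.integrate_regions(dens, standard_regions)
        assert table.fractions["alphaR"] == pytest.approx(1.0)

    def test_uniform_density_area_ratio(self, standard_regions):
        n_bins = 360
        w = np.full((n_bins, n_bins), 1.0 / n_bins**2)
        edges = np.linspace(-180, 180, n_bins + 1)
        dens = pc.Density2D(phi_edges=edges, psi_edges=edges, weights=w)
        table = pc.integrate_regions(dens, standard_regions)
        assert table.fractions["alphaR"] == pytest.approx(60 * 90 / 360**2, abs=1e-12)

    def test_matches_direct_classification_on_aligned_bins(
            self, emitted_trajectory, standard_regions):
        # all standard bounds are even degrees, so 2-degree bins align exactly
        dens = pc.ramachandran_density(emitted_trajectory, bin_width=2.0)
        integrated = pc.integrate_regions(dens, standard_regions)
        states = pc.classify_trajectory(emitted_trajectory, standard_regions)
        direct = pc.state_fractions(states)
        for label in standard_regions.alphabet:
            assert integrated.fractions[label] == pytest.approx(
                direct.fractions[label], abs=1e-12)


class TestStateFractions:
    def test_constant_input(self, standard_regions):
        traj = pc.DihedralTrajectory(
            times=np.arange(10.0), residue_ids=np.arange(1, 33),
            phi=np.full((10, 32), -60.0), psi=np.full((10, 32), -45.0))
        states = pc.classify_trajectory(traj, standard_regions)
        table = pc.state_fractions(states, n_blocks=5)
        assert table.fractions["alphaR"] == 1.0
        assert table.errors["alphaR"] == 0.0

    def test_fractions_sum_to_one(self, markov_states):
        table = pc.state_fractions(markov_states)
        assert sum(table.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_markov_stationary_recovered_within_three_block_sd(
            self, markov_states, three_state_spec):
        exact = pc.stationary_law(pc.transition_matrix(three_state_spec))
        table = pc.state_fractions(markov_states, n_blocks=5)
        for k, label in enumerate(three_state_spec.labels):
            frac, sd = table[label]
            assert abs(frac - exact[k]) < 3 * max(sd, 1e-3)

    def test_too_few_frames(self, markov_states):
        small = pc.StateTrajectory(times=markov_states.times[:3],
                                   codes=markov_states.codes[:3],
                                   alphabet=markov_states.alphabet)
        with pytest.raises(ValueError, match="too few frames"):
            pc.state_fractions(small, n_blocks=5)

    def test_tsv_export(self, tmp_path, markov_states):
        table = pc.state_fractions(markov_states)
        p = tmp_path / "frac.tsv"
        table.to_tsv(p)
        lines = p.read_text().strip().split("\n")
        assert lines[0] == "state\tfraction\tsd"
        assert len(lines) == 1 + len(markov_states.alphabet)
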