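"""Synthetic generators: Markov states, emissions, chains, bridges, ACFs."""

import numpy as np
import pytest

import polyconf as pc


class TestMarkovGenerator:
    def test_single_state_constant(self):
        spec = pc.GeneratorSpec(states={"alphaR": (1.0, 1.0)}, n_frames=50,
                                n_residues=4, seed=0)
        st = pc.markov_state_trajectory(spec)
        assert (st.codes == 0).all()

    def test_stay_probability_formula(self):
        spec = pc.GeneratorSpec(states={"A": (0.5, 1.0), "B": (0.5, 1.0)},
                                n_frames=10, dt=0.1)
        T = pc.transition_matrix(spec)
        assert T[0, 0] == pytest.approx(np.exp(-0.1), abs=1e-12)
        assert T[1, 1] == pytest.approx(np.exp(-0.1), abs=1e-12)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_rows_sum_to_one_generic(self):
        spec = pc.GeneratorSpec(
            states={"a": (0.5, 0.3), "b": (0.3, 2.0), "c": (0.2, 7.0)},
            n_frames=10, dt=0.1)
        T = pc.transition_matrix(spec)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_stationary_law_is_eigenvector(self, three_state_spec):
        T = pc.transition_matrix(three_state_spec)
        pi = pc.stationary_law(T)
        np.testing.assert_allclose(pi @ T, pi, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empirical_fractions_match_exact_law(self):
        spec = pc.GeneratorSpec(
            states={"A": (0.5, 0.5), "B": (0.3, 1.0), "C": (0.2, 2.0)},
            n_frames=20000, n_residues=10, dt=0.1, seed=11)
        st = pc.markov_state_trajectory(spec)
        pi = pc.stationary_law(pc.transition_matrix(spec))
        n = st.codes.size
        for k in range(3):
            emp = (st.codes == k).mean()
            se = np.sqrt(pi[k] * (1 - pi[k]) / n)
            # residue-frames are temporally correlated: widen by the
            # integrated correlation (lifetime / dt)
            corr = np.sqrt(2 * spec.states[list(spec.states)[k]][1] / spec.dt)
            assert abs(emp - pi[k]) < 3 * se * corr + 0.005

    def test_seed_determinism(self, three_state_spec):
        a = pc.markov_state_trajectory(three_state_spec)
        b = pc.markov_state_trajectory(three_state_spec)
        np.testing.assert_array_equal(a.codes, b.codes)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            pc.GeneratorSpec(states={"A": (0.7, 1.0), "B": (0.7, 1.0)})
        with pytest.raises(ValueError):
            pc.GeneratorSpec(states={"A": (1.0, -1.0)})


class TestEmission:
    def test_zero_jitter_hits_centroids(self, standard_regions):
        spec = pc.GeneratorSpec(states={"alphaR": (0.6, 1.0), "PPII": (0.4, 1.0)},
                                n_frames=20, n_residues=4, emission_jitter=0.0,
                                seed=2)
        st = pc.markov_state_trajectory(spec)
        traj = pc.emit_dihedrals(st, standard_regions, spec)
        alpha_box = standard_regions.region_for("alphaR").boxes[0]
        mask = st.codes == 0
        assert np.allclose(traj.phi[mask], alpha_box.centroid[0])
        assert np.allclose(traj.psi[mask], alpha_box.centroid[1])

    def test_classification_closure(self, markov_states, emitted_trajectory,
                                    standard_regions):
        states = pc.classify_trajectory(emitted_trajectory, standard_regions,
                                        exclude_termini=False)
        np.testing.assert_array_equal(states.labels(), markov_states.labels())

    def test_round_trip_fractions_identical(self, markov_states,
                                            emitted_trajectory, standard_regions):
        reclassified = pc.classify_trajectory(emitted_trajectory, standard_regions,
                                              exclude_termini=False)
        emp = {lab: (markov_states.labels() == lab).mean()
               for lab in markov_states.alphabet}
        table = pc.state_fractions(reclassified)
        for lab, frac in emp.items():
            assert table.fractions[lab] == pytest.approx(frac, abs=1e-12)

    def test_oversized_jitter_errors(self, standard_regions):
        spec = pc.GeneratorSpec(states={"alphaR": (1.0, 1.0)}, n_frames=20,
                                n_residues=3, emission_jitter=1e7, seed=0)
        st = pc.markov_state_trajectory(spec)
        with pytest.raises(RuntimeError, match="jitter"):
            pc.emit_dihedrals(st, standard_regions, spec)

    def test_seed_determinism(self, markov_states, standard_regions,
                              three_state_spec):
        a = pc.emit_dihedrals(markov_states, standard_regions, three_state_spec)
        b = pc.emit_dihedrals(markov_states, standard_regions, three_state_spec)
        np.testing.assert_array_equal(a.phi, b.phi)


class TestSyntheticChain:
    @staticmethod
    def _states(label, n_frames=3, n_res=12):
        return pc.StateTrajectory(times=0.1 * np.arange(n_frames),
                                  codes=np.zeros((n_frames, n_res), dtype=int),
                                  alphabet=(label,))

    def test_straight_chain_when_bend_zero(self):
        st = self._states("beta")
        coords = pc.synthetic_chain(st, geometry_map={"beta": (0.38, 0.0)})
        e2e = pc.end_to_end_series(coords)
        assert e2e == pytest.approx([11 * 0.38] * 3, abs=1e-9)

    def test_screw_chain_more_compact(self):
        stretched = pc.synthetic_chain(self._states("beta", n_res=24),
                                       geometry_map={"beta": (0.38, 5.0)}, seed=4)
        coiled = pc.synthetic_chain(self._states("alphaR", n_res=24),
                                    geometry_map={"alphaR": (0.38, 80.0)}, seed=4)
        rg_s = pc.rg_series(stretched).mean()
        rg_c = pc.rg_series(coiled).mean()
        assert rg_c < rg_s

    def test_seed_determinism(self, markov_states):
        a = pc.synthetic_chain(markov_states, seed=9)
        b = pc.synthetic_chain(markov_states, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_missing_geometry_entry(self, markov_states):
        with pytest.raises(KeyError):
            pc.synthetic_chain(markov_states, geometry_map={"alphaR": (0.38, 10.0)})


class TestBridgeFixture:
    def test_programmed_pairs_exact(self):
        fx = pc.bridge_fixture(32, [(3, 10)])
        found = pc.detect_bridges(fx, 0)
        assert {(b.residue_a, b.residue_b) for b in found} == {(3, 10)}
        assert pc.bridge_fraction(fx).fraction == pytest.approx(2 / 32)

    def test_empty_pairs(self):
        fx = pc.bridge_fixture(16, [], n_free_ions=3)
        assert pc.detect_bridges(fx, 0) == frozenset()

    def test_duplicate_residue_rejected(self):
        with pytest.raises(ValueError, match="at most one"):
            pc.bridge_fixture(32, [(3, 10), (10, 20)])

    def test_free_ions_stay_clear(self):
        fx = pc.bridge_fixture(16, [(2, 12)], n_free_ions=5)
        found = pc.detect_bridges(fx, 0)
        assert {(b.residue_a, b.residue_b) for b in found} == {(2, 12)}


class TestPairedBlocks:
    def test_block_b_mirrors_block_a_runs(self, markov_states):
        paired = pc.pair_state_blocks(markov_states, slice(0, 4), slice(10, 14),
                                      "beta")
        code = markov_states.alphabet.index("beta")
        full_a = (markov_states.codes[:, 0:4] == code).all(axis=1)
        assert (paired.codes[full_a][:, 10:14] == code).all()
        # unpaired frames keep their original dynamics
        np.testing.assert_array_equal(paired.codes[~full_a],
                                      markov_states.codes[~full_a])


class TestSyntheticACF:
    def test_first_lag_value(self):
        acf = pc.synthetic_acf(amplitude=1.0, tau=0.1, beta=1.0, noise_sd=0.0,
                               n_lags=50, dt=0.1)
        assert acf.values[1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_seed_determinism(self):
        a = pc.synthetic_acf(noise_sd=0.05, seed=42)
        b = pc.synthetic_acf(noise_sd=0.05, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_zero_at_origin_forced(self):
        acf = pc.synthetic_acf(amplitude=0.8, noise_sd=0.02, seed=1)
        assert acf.values[0] == 1.0
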