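"""Synthetic trajectory generation for pipeline testing and calibration.

Every analysis stage gets an input generator with known ground truth:
residue-wise Markov switching among conformational states (prescribed
stationary fractions and mean lifetimes), dihedral emissions truncated to
region boxes (classification closure by construction), bead-chain
coordinates whose bend geometry follows the state sequence, ion placements
that realize programmed bridge sets, and noisy stretched-exponential series
for fit-recovery experiments.  No physical realism is attempted — the
generators target the statistical structure the analyses assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .geometry import BridgeSpec
from .io import CoordinateTrajectory, DihedralTrajectory
from .regions import RegionSet, StateTrajectory
from .relaxation import AutocorrelationSeries, kww

__all__ = [
    "GeneratorSpec",
    "transition_matrix",
    "stationary_law",
    "markov_state_trajectory",
    "emit_dihedrals",
    "synthetic_chain",
    "bridge_fixture",
    "pair_state_blocks",
    "synthetic_acf",
    "write_fixture_pdb",
]


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic 32-residue anionic peptide.

    ``states`` maps label -> (stationary fraction π_s, mean lifetime λ_s in
    ns).  Frame spacing defaults to the 0.1 ns trajectory sampling step.
    """

    states: Mapping[str, tuple[float, float]]
    n_frames: int = 1000
    n_residues: int = 32
    dt: float = 0.1
    emission_jitter: float = 10.0    # degrees, SD about the box center
    seed: int = 0

    def __post_init__(self) -> None:
        pis = np.array([p for p, _ in self.states.values()], dtype=float)
        lams = np.array([l for _, l in self.states.values()], dtype=float)
        if np.any(pis <= 0) or abs(pis.sum() - 1.0) > 1e-9:
            raise ValueError("stationary fractions must be positive and sum to 1")
        if np.any(lams <= 0):
            raise ValueError("mean lifetimes must be positive")
        if self.emission_jitter < 0:
            raise ValueError("jitter must be >= 0")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.states)


def transition_matrix(spec: GeneratorSpec) -> np.ndarray:
    """Discrete-time transition matrix of the per-residue state chain.

    Stay probability q_s = exp(-dt/λ_s); transitions s -> s' are split
    proportionally to the target fractions π_{s'} over s' != s, so rows sum
    to 1 exactly.
    """
    labels = spec.labels
    pis = np.array([spec.states[s][0] for s in labels])
    lams = np.array([spec.states[s][1] for s in labels])
    k = len(labels)
    T = np.zeros((k, k))
    if k == 1:
        return np.ones((1, 1))
    q = np.exp(-spec.dt / lams)
    for i in range(k):
        off = pis.copy()
        off[i] = 0.0
        T[i] = (1.0 - q[i]) * off / off.sum()
        T[i, i] = q[i]
    return T


def stationary_law(T: np.ndarray) -> np.ndarray:
    """Exact stationary distribution of a transition matrix (left eigenvector).

    The proportional-attraction construction only approximates the target
    fractions; tests and calibration compare against this exact law.
    """
    w, v = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def markov_state_trajectory(spec: GeneratorSpec) -> StateTrajectory:
    """Simulate independent per-residue Markov chains of conformational states.

    Chains are initialized from the exact stationary law of the constructed
    transition matrix and evolve synchronously; seed-reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    T = transition_matrix(spec)
    pi0 = stationary_law(T)
    k = T.shape[0]
    cum_T = np.cumsum(T, axis=1)
    codes = np.empty((spec.n_frames, spec.n_residues), dtype=np.int16)
    codes[0] = rng.choice(k, size=spec.n_residues, p=pi0)
    for f in range(1, spec.n_frames):
        u = rng.random(spec.n_residues)
        rows = cum_T[codes[f - 1]]
        codes[f] = (u[:, None] > rows).sum(axis=1)
    times = spec.dt * np.arange(spec.n_frames)
    return StateTrajectory(times=times, codes=codes, alphabet=spec.labels)


def emit_dihedrals(states: StateTrajectory, regions: RegionSet,
                   spec: GeneratorSpec) -> DihedralTrajectory:
    """Emit (Φ, Ψ) angles consistent with a state trajectory.

    Angles are drawn from a Gaussian about the centroid of each state's
    widest box with SD = ``emission_jitter``, rejection-truncated to the
    box, so classification under the same region set returns the emitting
    state exactly.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_frames, n_res = states.codes.shape
    phi = np.empty((n_frames, n_res))
    psi = np.empty((n_frames, n_res))
    for code, label in enumerate(states.alphabet):
        mask = states.codes == code
        count = int(mask.sum())
        if count == 0:
            continue
        box = regions.region_for(label).widest_box()
        (c_phi, c_psi) = box.centroid
        samples = np.empty((count, 2))
        filled = 0
        for _ in range(10_000):
            need = count - filled
            if need == 0:
                break
            cand = rng.normal([c_phi, c_psi], spec.emission_jitter, size=(need, 2))
            ok = box.contains(cand[:, 0], cand[:, 1])
            got = cand[ok]
            samples[filled:filled + len(got)] = got
            filled += len(got)
        if filled < count:
            raise RuntimeError(
                f"emission for state {label!r} rejected too often; "
                f"reduce emission_jitter (currently {spec.emission_jitter} deg)")
        phi[mask] = samples[:, 0]
        psi[mask] = samples[:, 1]
    return DihedralTrajectory(times=states.times,
                              residue_ids=np.arange(1, n_res + 1),
                              phi=phi, psi=psi)


#: Default virtual-bond geometry per conformational family: stretched
#: states walk nearly straight, screw states turn sharply.
DEFAULT_GEOMETRY: Mapping[str, tuple[float, float]] = {
    "PPII": (0.38, 25.0),
    "beta": (0.38, 10.0),
    "alphaR": (0.38, 80.0),
    "alphaL": (0.38, 80.0),
    "3.10": (0.38, 75.0),
    "additional_screw": (0.38, 70.0),
    "other": (0.38, 45.0),
}


def synthetic_chain(states: StateTrajectory,
                    geometry_map: Mapping[str, tuple[float, float]] | None = None,
                    seed: int = 0) -> CoordinateTrajectory:
    """Bead (CA-only) chain whose local bending follows the state sequence.

    ``geometry_map``: label -> (virtual bond length nm, bend angle deg).
    Beads are placed sequentially; each step rotates the previous direction
    by the state's bend angle about a random perpendicular axis.
    Deterministic under ``seed``.
    """
    geometry_map = dict(DEFAULT_GEOMETRY if geometry_map is None else geometry_map)
    missing = set(states.alphabet) - set(geometry_map)
    if missing:
        raise KeyError(f"geometry_map lacks states {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n_frames, n_res = states.codes.shape
    bonds = np.array([geometry_map[s][0] for s in states.alphabet])
    bends = np.radians([geometry_map[s][1] for s in states.alphabet])
    positions = np.zeros((n_frames, n_res, 3))
    for f in range(n_frames):
        direction = np.array([1.0, 0.0, 0.0])
        point = np.zeros(3)
        for r in range(1, n_res):
            code = states.codes[f, r]
            theta = bends[code]
            if theta > 0:
                # random axis perpendicular to the current direction
                raw = rng.normal(size=3)
                axis = raw - raw.dot(direction) * direction
                norm = np.linalg.norm(axis)
                if norm < 1e-12:
                    axis = np.array([0.0, 1.0, 0.0])
                else:
                    axis /= norm
                direction = (np.cos(theta) * direction
                             + np.sin(theta) * np.cross(axis, direction))
                direction /= np.linalg.norm(direction)
            point = point + bonds[code] * direction
            positions[f, r] = point
    resids = np.arange(1, n_res + 1)
    return CoordinateTrajectory(
        times=states.times,
        positions=positions,
        resids=resids,
        backbone_role=np.array(["CA"] * n_res, dtype=object),
        carboxylate_resid=np.full(n_res, -1),
        ion_species=np.array([""] * n_res, dtype=object),
        masses=np.ones(n_res),
    )


def bridge_fixture(n_residues: int = 32,
                   bridged_pairs: Sequence[tuple[int, int]] = (),
                   n_frames: int = 1,
                   n_free_ions: int = 0,
                   ion_species: str = "NA",
                   dt: float = 0.1,
                   ion_active: np.ndarray | None = None,
                   ) -> CoordinateTrajectory:
    """Coordinate fixture realizing an exactly known bridge set.

    Each residue carries a CA bead and two carboxylate oxygens.  For every
    requested pair one oxygen of each member is moved to a shared meeting
    point with the bridging ion 0.20 nm from both; free ions and inactive
    frames park ions >= 0.6 nm from every oxygen.  A residue may appear in
    at most one pair.  ``ion_active`` (n_frames,) toggles the bridge ions
    per frame.
    """
    flat = [r for pair in bridged_pairs for r in pair]
    if len(set(flat)) != len(flat):
        raise ValueError("a residue may appear in at most one bridged pair")
    for a, b in bridged_pairs:
        if not (1 <= a <= n_residues and 1 <= b <= n_residues) or a == b:
            raise ValueError(f"invalid pair ({a}, {b})")
    if ion_active is None:
        ion_active = np.ones(n_frames, dtype=bool)
    ion_active = np.asarray(ion_active, dtype=bool)
    if len(ion_active) != n_frames:
        raise ValueError("ion_active length must equal n_frames")

    spacing = 0.5
    atoms = []   # (resid, role, carbox_resid, ion_species, xyz)
    for r in range(1, n_residues + 1):
        x = spacing * (r - 1)
        atoms.append((r, "CA", -1, "", np.array([x, 0.0, 0.0])))
        atoms.append((r, "", r, "", np.array([x, 0.30, 0.05])))
        atoms.append((r, "", r, "", np.array([x, 0.30, -0.05])))

    meeting_y = 2.0
    ion_home = []      # rest position of each bridge ion
    ion_far = []       # parking position when inactive
    for k, (a, b) in enumerate(sorted(tuple(sorted(p)) for p in bridged_pairs)):
        p = np.array([spacing * (a - 1), meeting_y + 1.5 * k, 0.0])
        # second oxygen of each member meets the ion at +/- 0.20 nm
        atoms[3 * (a - 1) + 2] = (a, "", a, "", p + np.array([0.20, 0.0, 0.0]))
        atoms[3 * (b - 1) + 2] = (b, "", b, "", p - np.array([0.20, 0.0, 0.0]))
        ion_resid = n_residues + 1 + k
        atoms.append((ion_resid, "", -1, ion_species, p.copy()))
        ion_home.append(p.copy())
        ion_far.append(p + np.array([0.0, 50.0, 0.0]))
    for k in range(n_free_ions):
        ion_resid = n_residues + 1 + len(bridged_pairs) + k
        atoms.append((ion_resid, "", -1, ion_species,
                      np.array([spacing * k, -10.0, 0.0])))

    base = np.array([a[4] for a in atoms])
    positions = np.repeat(base[None], n_frames, axis=0)
    n_pep_atoms = 3 * n_residues
    for f in range(n_frames):
        if not ion_active[f]:
            for k in range(len(bridged_pairs)):
                positions[f, n_pep_atoms + k] = ion_far[k]
    return CoordinateTrajectory(
        times=dt * np.arange(n_frames),
        positions=positions,
        resids=np.array([a[0] for a in atoms]),
        backbone_role=np.array([a[1] for a in atoms], dtype=object),
        carboxylate_resid=np.array([a[2] for a in atoms]),
        ion_species=np.array([a[3] for a in atoms], dtype=object),
        masses=np.ones(len(atoms)),
    )


def pair_state_blocks(states: StateTrajectory, block_a: slice, block_b: slice,
                      label: str) -> StateTrajectory:
    """Correlate two residue blocks' runs of one state (paired sequences).

    Frames where every residue of ``block_a`` sits in ``label`` get
    ``block_b`` forced into the same state, emulating ion-paired
    antiparallel sequences for timeline illustrations.  Off the paired
    frames both blocks keep their original dynamics.
    """
    if label not in states.alphabet:
        raise KeyError(label)
    code = states.alphabet.index(label)
    codes = states.codes.copy()
    paired = (codes[:, block_a] == code).all(axis=1)
    codes[np.ix_(paired, range(*block_b.indices(codes.shape[1])))] = code
    return StateTrajectory(times=states.times, codes=codes,
                           alphabet=states.alphabet,
                           residue_ids=states.residue_ids)


def synthetic_acf(amplitude: float = 1.0, tau: float = 10.0, beta: float = 1.0,
                  noise_sd: float = 0.0, n_lags: int = 200, dt: float = 0.1,
                  seed: int = 0) -> AutocorrelationSeries:
    """Noisy stretched-exponential series for fit-recovery experiments.

    C(t_k) = A exp(-(t_k/τ)^β) + ε_k with Gaussian ε; C(0) forced to 1.
    """
    rng = np.random.default_rng(seed)
    lags = dt * np.arange(n_lags)
    values = kww(lags, amplitude, tau, beta)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_lags)
    values[0] = 1.0
    return AutocorrelationSeries(lags=lags, values=values, kind="distance",
                                 normalization="synthetic")


def write_fixture_pdb(traj: CoordinateTrajectory, path: str | Path) -> None:
    """Write a coordinate fixture as a multi-model PDB via MDAnalysis.

    Peptide residues are written as GLU with OE1/OE2 carboxylate oxygens so
    the default role selection reads the file back unchanged.
    """
    import warnings

    import MDAnalysis as mda

    n_atoms = traj.positions.shape[1]
    resids = np.asarray(traj.resids)
    species = np.asarray(traj.ion_species)
    role = np.asarray(traj.backbone_role)
    carbox = np.asarray(traj.carboxylate_resid)

    names, resnames = [], []
    ox_seen: dict[int, int] = {}
    for i in range(n_atoms):
        if species[i]:
            names.append(str(species[i]))
            resnames.append(str(species[i]))
        elif role[i]:
            names.append(str(role[i]))
            resnames.append("GLU")
        elif carbox[i] >= 0:
            nth = ox_seen.get(int(carbox[i]), 0)
            ox_seen[int(carbox[i])] = nth + 1
            names.append("OE1" if nth == 0 else "OE2")
            resnames.append("GLU")
        else:
            names.append("X")
            resnames.append("UNK")

    _, res_index = np.unique(resids, return_inverse=True)
    n_res = res_index.max() + 1
    u = mda.Universe.empty(n_atoms, n_residues=n_res,
                           atom_resindex=res_index,
                           residue_segindex=np.zeros(n_res, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames",
                       [resnames[np.flatnonzero(res_index == r)[0]]
                        for r in range(n_res)])
    u.add_TopologyAttr("resids", np.unique(resids))
    u.load_new(traj.positions * 10.0, format="memory", dt=1.0)  # nm -> Å
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        with mda.Writer(str(path), n_atoms, multiframe=True) as writer:
            for ts in u.trajectory:
                writer.write(u.atoms)
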