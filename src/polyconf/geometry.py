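"""Chain-size observables and counterion-bridge accounting.

Radius of gyration and end-to-end distance characterize overall chain
dimensions; bridge detection finds counterions simultaneously coordinating
carboxylate oxygens of two sequence-separated residues (the contact-distance
criterion, cutoffs at typical first RDF minima for Na+/K+ against
carboxylate oxygen).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .io import CoordinateTrajectory

__all__ = [
    "BridgeSpec",
    "Bridge",
    "BridgeReport",
    "radius_of_gyration",
    "end_to_end_distance",
    "rg_series",
    "end_to_end_series",
    "detect_bridges",
    "bridge_fraction",
]

log = logging.getLogger(__name__)


def radius_of_gyration(positions, masses=None) -> float:
    """Mass-weighted RMS distance of atoms from their center of mass (nm).

    ``positions`` is (n_atoms, 3); ``masses`` defaults to unit masses.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        raise ValueError("need >= 2 atoms")
    m = np.ones(len(pos)) if masses is None else np.asarray(masses, dtype=float)
    if np.any(m < 0) or m.sum() <= 0:
        raise ValueError("masses must be positive with nonzero total")
    com = (m[:, None] * pos).sum(axis=0) / m.sum()
    sq = ((pos - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * sq).sum() / m.sum()))


def end_to_end_distance(positions) -> float:
    """Euclidean distance between the first and last point of a chain (nm).

    No minimum image is applied: the chain is whole by construction.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        raise ValueError("need an ordered chain of >= 2 points")
    return float(np.linalg.norm(pos[-1] - pos[0]))


def _ca_indices(traj: CoordinateTrajectory) -> np.ndarray:
    role = np.asarray(traj.backbone_role)
    ca = np.flatnonzero(role == "CA")
    if len(ca) == 0:
        raise ValueError("no CA atoms annotated; cannot build the chain axis")
    order = np.argsort(np.asarray(traj.resids)[ca], kind="stable")
    return ca[order]


def rg_series(traj: CoordinateTrajectory) -> np.ndarray:
    """Per-frame radius of gyration of the peptide atoms (nm)."""
    peptide = np.asarray(traj.ion_species) == ""
    m = None if traj.masses is None else traj.masses[peptide]
    return np.array([radius_of_gyration(frame[peptide], m)
                     for frame in traj.positions])


def end_to_end_series(traj: CoordinateTrajectory) -> np.ndarray:
    """Per-frame CA(1)-CA(n) distance (nm)."""
    ca = _ca_indices(traj)
    if len(ca) < 2:
        raise ValueError("need CA atoms of at least two residues")
    d = traj.positions[:, ca[-1]] - traj.positions[:, ca[0]]
    return np.linalg.norm(d, axis=1)


@dataclass(frozen=True)
class BridgeSpec:
    """Geometric criterion for a counterion bridge.

    An ion bridges residues a and b when it lies within ``cutoffs_nm`` of at
    least one carboxylate oxygen of each, with ``|a - b| >=
    min_residue_separation`` ("distant" groups, excluding nearest-neighbour
    contacts).
    """

    cutoffs_nm: dict = field(default_factory=lambda: {"NA": 0.32, "K": 0.36})
    min_residue_separation: int = 3

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.cutoffs_nm.values()):
            raise ValueError("cutoffs must be positive")
        if self.min_residue_separation < 1:
            raise ValueError("min_residue_separation must be >= 1")


@dataclass(frozen=True)
class Bridge:
    ion_index: int       # atom index of the bridging ion
    residue_a: int
    residue_b: int       # residue_a < residue_b


@dataclass
class BridgeReport:
    """Per-frame bridges plus the time-averaged bridged-carboxyl fraction."""

    bridges_per_frame: list        # list of frozenset[Bridge]
    fraction: float                # mean fraction of carboxyls in >= 1 bridge
    error: float                   # SD of per-block fractions
    per_frame_fraction: np.ndarray
    spec: BridgeSpec

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


def _min_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def detect_bridges(traj: CoordinateTrajectory, frame: int,
                   spec: BridgeSpec | None = None) -> frozenset:
    """Bridges present in one frame under the contact-distance criterion.

    An ion near carboxylate oxygens of three residues yields every
    qualifying pair.  Minimum-image distances are used when the trajectory
    carries an orthorhombic box.
    """
    spec = spec or BridgeSpec()
    species = np.asarray(traj.ion_species)
    ox_resid = np.asarray(traj.carboxylate_resid)
    ox_idx = np.flatnonzero(ox_resid >= 0)
    if len(ox_idx) == 0:
        raise ValueError("no carboxylate oxygens annotated")
    ion_idx = np.flatnonzero(species != "")
    if len(ion_idx) == 0:
        log.warning("no ions present; bridge set is empty")
        return frozenset()
    pos = traj.positions[frame]
    box = None if traj.box is None else traj.box[frame]
    bridges = set()
    ox_pos = pos[ox_idx]
    ox_owner = ox_resid[ox_idx]
    for ai in ion_idx:
        cutoff = spec.cutoffs_nm.get(str(species[ai]))
        if cutoff is None:
            continue
        d = _min_image(ox_pos - pos[ai], box)
        near = np.linalg.norm(d, axis=1) <= cutoff
        residues = np.unique(ox_owner[near])
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                a, b = int(residues[i]), int(residues[j])
                if b - a >= spec.min_residue_separation:
                    bridges.add(Bridge(int(ai), a, b))
    return frozenset(bridges)


def bridge_fraction(traj: CoordinateTrajectory, spec: BridgeSpec | None = None,
                    n_blocks: int = 5) -> BridgeReport:
    """Time-averaged fraction of carboxyl groups engaged in >= 1 bridge.

    Per frame the fraction is (residues appearing in any bridge) / (all
    carboxylate-bearing residues); the error is the SD of per-block means
    over ``n_blocks`` contiguous equal-length blocks (0 when the trajectory
    is shorter than the block count).
    """
    spec = spec or BridgeSpec()
    n_carboxyl = len(traj.carboxylate_residues())
    if n_carboxyl == 0:
        raise ValueError("no carboxylate oxygens annotated")
    per_frame = []
    fracs = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        bridges = detect_bridges(traj, f, spec)
        per_frame.append(bridges)
        bridged = {b.residue_a for b in bridges} | {b.residue_b for b in bridges}
        fracs[f] = len(bridged) / n_carboxyl
    if traj.n_frames >= n_blocks and n_blocks >= 2:
        block_len = traj.n_frames // n_blocks
        blocks = fracs[:n_blocks * block_len].reshape(n_blocks, block_len)
        error = float(blocks.mean(axis=1).std(ddof=1))
    else:
        error = 0.0
    return BridgeReport(bridges_per_frame=per_frame, fraction=float(fracs.mean()),
                        error=error, per_frame_fraction=fracs, spec=spec)


def write_series_tsv(times: np.ndarray, values: np.ndarray, path: str | Path,
                     name: str = "value") -> None:
    """Export a per-frame observable as TSV (time_ns, value)."""
    lines = [f"time_ns\t{name}"]
    for t, v in zip(times, values):
        lines.append(f"{t:.10g}\t{v:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
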