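"""Trajectory input/output and basic preprocessing.

Dihedral time series live in :class:`DihedralTrajectory` (degrees, canonical
domain ``(-180, 180]``); coordinate frames with role annotations live in
:class:`CoordinateTrajectory` (nm, ns).  Coordinate reading delegates to
MDAnalysis; dihedral tables are plain delimited text with a header row.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "wrap_degrees",
    "DihedralTrajectory",
    "CoordinateTrajectory",
    "AnalysisConfig",
    "read_dihedral_table",
    "write_dihedral_table",
    "read_coordinate_trajectory",
    "compute_backbone_dihedrals",
    "discard_equilibration",
]

#: Column names of the on-disk dihedral table format.
DIHEDRAL_COLUMNS = ("time_ns", "residue", "phi_deg", "psi_deg")


def wrap_degrees(angle):
    """Wrap angles (degrees) into the canonical domain ``(-180, 180]``.

    Idempotent; NaN passes through (used as the undefined-angle marker for
    terminal residues).
    """
    a = np.asarray(angle, dtype=float)
    wrapped = a - 360.0 * np.ceil((a - 180.0) / 360.0)
    return wrapped if wrapped.ndim else float(wrapped)


class TrajectoryError(ValueError):
    """Raised for malformed trajectory inputs."""


def _check_uniform_times(times: np.ndarray) -> float:
    if len(times) < 2:
        return float("nan")
    steps = np.diff(times)
    dt = float(steps[0])
    if dt <= 0:
        raise TrajectoryError(f"non-positive frame spacing dt={dt}")
    if not np.allclose(steps, dt, rtol=1e-9, atol=0.0):
        raise TrajectoryError("frame times are not uniformly spaced")
    return dt


@dataclass
class DihedralTrajectory:
    """Per-frame, per-residue backbone (Φ, Ψ) angles in degrees.

    ``phi`` and ``psi`` have shape ``(n_frames, n_residues)``; terminal
    residues that lack a neighbour carry NaN for the undefined angle.
    """

    times: np.ndarray          # (n_frames,), ns
    residue_ids: np.ndarray    # (n_residues,), 1-based, strictly increasing
    phi: np.ndarray            # degrees, (-180, 180]
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape:
            raise TrajectoryError("phi and psi shapes differ")
        if self.phi.shape != (len(self.times), len(self.residue_ids)):
            raise TrajectoryError(
                f"angle matrices {self.phi.shape} do not match "
                f"{len(self.times)} frames x {len(self.residue_ids)} residues"
            )
        if np.any(np.diff(self.residue_ids) <= 0):
            raise TrajectoryError("residue_ids must be strictly increasing")
        for name, arr in (("phi", self.phi), ("psi", self.psi)):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() <= -180.0 or finite.max() > 180.0):
                raise TrajectoryError(f"{name} outside (-180, 180]; wrap first")
        _check_uniform_times(self.times)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def chain_length(self) -> int:
        return len(self.residue_ids)

    @property
    def dt(self) -> float:
        """Frame spacing in ns (NaN for single-frame trajectories)."""
        return _check_uniform_times(self.times)


@dataclass
class CoordinateTrajectory:
    """Coordinate frames (nm) with per-atom role annotations.

    Roles drive the downstream geometry analyses: ``backbone_role`` marks
    N/CA/C atoms (empty string otherwise), ``carboxylate_resid`` maps each
    side-chain carboxylate oxygen to its owning residue id (-1 otherwise)
    and ``ion_species`` tags counterions by species name.
    """

    times: np.ndarray                # (n_frames,), ns
    positions: np.ndarray            # (n_frames, n_atoms, 3), nm
    resids: np.ndarray               # (n_atoms,), 1-based residue id
    backbone_role: np.ndarray        # (n_atoms,), '' | 'N' | 'CA' | 'C'
    carboxylate_resid: np.ndarray    # (n_atoms,), residue id or -1
    ion_species: np.ndarray          # (n_atoms,), '' or species name
    masses: np.ndarray | None = None # (n_atoms,), amu
    box: np.ndarray | None = None    # (n_frames, 3) orthorhombic edges, nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        n_frames, n_atoms = self.positions.shape[:2]
        if len(self.times) != n_frames:
            raise TrajectoryError("times length does not match frames")
        for name in ("resids", "backbone_role", "carboxylate_resid", "ion_species"):
            if len(getattr(self, name)) != n_atoms:
                raise TrajectoryError(f"{name} length does not match atom count")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (n_frames, 3):
                raise TrajectoryError("box must be (n_frames, 3) orthorhombic edges")
            if np.any(self.box <= 0):
                raise TrajectoryError("box dimensions must be strictly positive")
        _check_uniform_times(self.times)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted ids of peptide residues (atoms not tagged as ions)."""
        mask = np.asarray(self.ion_species) == ""
        return np.unique(np.asarray(self.resids)[mask])

    def carboxylate_residues(self) -> np.ndarray:
        ox = np.asarray(self.carboxylate_resid)
        return np.unique(ox[ox >= 0])


@dataclass
class AnalysisConfig:
    """Analysis thresholds and conventions shared across the pipeline."""

    equilibration_fraction: float = 0.1
    region_set: str = "standard_literature"
    min_run_length: int = 4
    n_analyzed_monomers: int | None = None   # default chain_length - 2
    bridge_cutoffs_nm: dict = field(default_factory=lambda: {"NA": 0.32, "K": 0.36})
    min_residue_separation: int = 3
    acf_fit_floor: float = 0.02
    n_blocks: int = 5
    stride: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration_fraction must be in [0, 1)")
        if self.min_run_length < 2:
            raise ValueError("min_run_length must be >= 2")
        if self.n_blocks < 2:
            raise ValueError("block count must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Dihedral tables


def read_dihedral_table(path: str | Path, delimiter: str | None = None) -> DihedralTrajectory:
    """Read a delimited dihedral table into a wrapped, validated trajectory.

    The file must have a header ``time_ns,residue,phi_deg,psi_deg`` (comma or
    tab; auto-detected when ``delimiter`` is None) and a complete
    frame x residue grid; rows may appear in any order.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c",
                     dtype=str, skipinitialspace=True)
    missing = [c for c in DIHEDRAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"missing columns {missing} in {path}")
    for col in DIHEDRAL_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrajectoryError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col} "
                f"at line {row + 2} of {path}"
            )
        df[col] = converted
    times = np.sort(df["time_ns"].unique())
    resids = np.sort(df["residue"].unique().astype(int))
    phi = df.pivot_table(index="time_ns", columns="residue", values="phi_deg")
    psi = df.pivot_table(index="time_ns", columns="residue", values="psi_deg")
    phi = phi.reindex(index=times, columns=resids)
    psi = psi.reindex(index=times, columns=resids)
    # NaN from reindexing = missing cell (input NaN is legal: undefined termini)
    counts = df.groupby(["time_ns", "residue"]).size()
    expected = len(times) * len(resids)
    if len(counts) != expected:
        grid = pd.MultiIndex.from_product([times, resids], names=["time_ns", "residue"])
        gap = grid.difference(counts.index)[0]
        raise TrajectoryError(
            f"incomplete grid: missing (frame t={gap[0]}, residue {gap[1]}) in {path}"
        )
    return DihedralTrajectory(
        times=times,
        residue_ids=resids,
        phi=wrap_degrees(phi.to_numpy()),
        psi=wrap_degrees(psi.to_numpy()),
    )


def write_dihedral_table(traj: DihedralTrajectory, path: str | Path,
                         delimiter: str = ",") -> None:
    """Write the long-format delimited table read by :func:`read_dihedral_table`."""
    n_f, n_r = traj.phi.shape
    df = pd.DataFrame({
        "time_ns": np.repeat(traj.times, n_r),
        "residue": np.tile(traj.residue_ids, n_f),
        "phi_deg": traj.phi.ravel(),
        "psi_deg": traj.psi.ravel(),
    })
    df.to_csv(path, sep=delimiter, index=False, float_format="%.8f")


# ---------------------------------------------------------------------------
# Coordinates

#: Default role selection: GROMACS/CHARMM-style atom and residue names for
#: fully deprotonated Asp/Glu chains with monovalent counterions.
DEFAULT_SELECTION: Mapping[str, str | Mapping[str, str]] = {
    "backbone": "name N CA C",
    "carboxylate_oxygens": "name OD1 OD2 OE1 OE2",
    "ions": {"NA": "resname NA SOD", "K": "resname K POT"},
}


def read_coordinate_trajectory(topology: str | Path,
                               trajectory: str | Path | None = None,
                               selection: Mapping | None = None,
                               ) -> CoordinateTrajectory:
    """Load coordinates through MDAnalysis and annotate atom roles.

    ``selection`` maps roles to MDAnalysis selection strings (see
    ``DEFAULT_SELECTION``).  Positions are converted Å → nm and times
    ps → ns.  Ions are optional; an empty backbone selection is an error.
    """
    import warnings

    import MDAnalysis as mda

    sel = dict(DEFAULT_SELECTION)
    if selection:
        sel.update(selection)
    with warnings.catch_warnings():
        # benign format chatter (placeholder CRYST1, guessed elements, no dt)
        warnings.simplefilter("ignore", UserWarning)
        u = mda.Universe(str(topology)) if trajectory is None else mda.Universe(
            str(topology), str(trajectory))
    n_atoms = len(u.atoms)

    backbone = u.select_atoms(str(sel["backbone"]))
    if len(backbone) == 0:
        raise TrajectoryError("backbone selection matched no atoms")
    backbone_role = np.full(n_atoms, "", dtype=object)
    backbone_role[backbone.indices] = [a.name for a in backbone]

    carbox = u.select_atoms(str(sel["carboxylate_oxygens"]))
    carboxylate_resid = np.full(n_atoms, -1, dtype=int)
    carboxylate_resid[carbox.indices] = carbox.resids

    ion_species = np.full(n_atoms, "", dtype=object)
    for species, ion_sel in dict(sel.get("ions", {})).items():
        grp = u.select_atoms(str(ion_sel))
        ion_species[grp.indices] = species

    positions, times, boxes = [], [], []
    have_box = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for ts in u.trajectory:
            positions.append(ts.positions.copy() / 10.0)   # Å -> nm
            times.append(ts.time / 1000.0)                 # ps -> ns
            if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
                have_box = False
            else:
                boxes.append(ts.dimensions[:3].copy() / 10.0)
    times = np.asarray(times)
    if len(times) > 1 and np.allclose(times, times[0]):
        # Multi-model PDBs carry no time axis; synthesize unit spacing.
        times = np.arange(len(times), dtype=float)
    try:
        masses = u.atoms.masses.copy()
    except Exception:
        masses = None
    return CoordinateTrajectory(
        times=times,
        positions=np.asarray(positions),
        resids=u.atoms.resids.copy(),
        backbone_role=backbone_role,
        carboxylate_resid=carboxylate_resid,
        ion_species=ion_species,
        masses=masses,
        box=np.asarray(boxes) if have_box and boxes else None,
    )


def dihedral_angle(p0, p1, p2, p3):
    """Torsion angle (degrees, IUPAC sign) for atom quadruples.

    Accepts arrays broadcastable to ``(..., 3)``.  cis = 0°, trans = 180°
    (canonicalized from -180°); clockwise rotation of the far bond viewed
    along the near bond is negative.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


def compute_backbone_dihedrals(coords: CoordinateTrajectory) -> DihedralTrajectory:
    """Extract Φ/Ψ backbone torsions from annotated coordinates.

    Φ(i) = C(i-1)–N(i)–CA(i)–C(i); Ψ(i) = N(i)–CA(i)–C(i)–N(i+1).  Terminal
    residues lacking a neighbour get NaN for the undefined angle.
    """
    role = np.asarray(coords.backbone_role)
    resids_all = np.asarray(coords.resids)
    peptide = coords.residue_ids
    idx = {}
    for name in ("N", "CA", "C"):
        for rid in peptide:
            match = np.flatnonzero((role == name) & (resids_all == rid))
            if len(match) == 0:
                raise TrajectoryError(f"missing backbone atom {name} for residue {rid}")
            idx[(name, rid)] = int(match[0])

    pos = coords.positions
    n_frames, n_res = coords.n_frames, len(peptide)
    phi = np.full((n_frames, n_res), np.nan)
    psi = np.full((n_frames, n_res), np.nan)
    N = np.stack([pos[:, idx[("N", r)]] for r in peptide], axis=1)
    CA = np.stack([pos[:, idx[("CA", r)]] for r in peptide], axis=1)
    C = np.stack([pos[:, idx[("C", r)]] for r in peptide], axis=1)
    if n_res >= 2:
        phi[:, 1:] = dihedral_angle(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])
        psi[:, :-1] = dihedral_angle(N[:, :-1], CA[:, :-1], C[:, :-1], N[:, 1:])
    return DihedralTrajectory(times=coords.times, residue_ids=peptide, phi=phi, psi=psi)


def discard_equilibration(traj, fraction: float | None = None,
                          time_ns: float | None = None):
    """Drop the initial equilibration period of a trajectory.

    By fraction of frames (``ceil(fraction * n_frames)`` frames removed) or
    by absolute time.  Returns the same trajectory type with dt unchanged.
    """
    if (fraction is None) == (time_ns is None):
        raise ValueError("give exactly one of fraction or time_ns")
    n = traj.n_frames
    if fraction is not None:
        if not 0.0 <= fraction < 1.0:
            raise ValueError("fraction must be in [0, 1)")
        n_drop = math.ceil(fraction * n)
    else:
        n_drop = int(np.searchsorted(traj.times, traj.times[0] + time_ns))
    if isinstance(traj, DihedralTrajectory):
        return DihedralTrajectory(
            times=traj.times[n_drop:], residue_ids=traj.residue_ids,
            phi=traj.phi[n_drop:], psi=traj.psi[n_drop:])
    if isinstance(traj, CoordinateTrajectory):
        return CoordinateTrajectory(
            times=traj.times[n_drop:], positions=traj.positions[n_drop:],
            resids=traj.resids, backbone_role=traj.backbone_role,
            carboxylate_resid=traj.carboxylate_resid, ion_species=traj.ion_species,
            masses=traj.masses,
            box=None if traj.box is None else traj.box[n_drop:])
    raise TypeError(f"unsupported trajectory type {type(traj)!r}")
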