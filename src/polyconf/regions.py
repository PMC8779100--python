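"""Ramachandran region sets, conformer classification and fraction tables.

A :class:`RegionSet` partitions the (Φ, Ψ) torus into named conformational
states via angular boxes; everything unassigned is the ``other`` complement.
Classification, 2-D dihedral densities and region integration all operate on
the canonical angle domain ``(-180, 180]`` degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .io import DihedralTrajectory, wrap_degrees

__all__ = [
    "AngularBox",
    "Region",
    "RegionSet",
    "StateTrajectory",
    "FractionTable",
    "Density2D",
    "builtin_region_set",
    "BUILTIN_REGION_SETS",
    "classify",
    "classify_trajectory",
    "ramachandran_density",
    "integrate_regions",
    "state_fractions",
]

OTHER = "other"


@dataclass(frozen=True)
class AngularBox:
    """Rectangle on the (Φ, Ψ) torus with per-edge open/closed flags.

    Bounds are degrees; a box may be specified with bounds outside
    (-180, 180] to express wrapping (membership is tested modulo 360°).
    """

    phi: tuple[float, float]
    psi: tuple[float, float]
    closed_phi: tuple[bool, bool] = (True, True)
    closed_psi: tuple[bool, bool] = (True, True)

    def _axis_contains(self, x, lo, hi, closed_lo, closed_hi):
        x = np.asarray(x, dtype=float)
        hit = np.zeros(x.shape, dtype=bool)
        for shift in (-360.0, 0.0, 360.0):
            v = x + shift
            lo_ok = (v >= lo) if closed_lo else (v > lo)
            hi_ok = (v <= hi) if closed_hi else (v < hi)
            hit |= lo_ok & hi_ok
        return hit

    def contains(self, phi, psi) -> np.ndarray:
        return (self._axis_contains(phi, *self.phi, *self.closed_phi)
                & self._axis_contains(psi, *self.psi, *self.closed_psi))

    @property
    def centroid(self) -> tuple[float, float]:
        return (wrap_degrees(0.5 * (self.phi[0] + self.phi[1])),
                wrap_degrees(0.5 * (self.psi[0] + self.psi[1])))

    @property
    def area(self) -> float:
        return abs((self.phi[1] - self.phi[0]) * (self.psi[1] - self.psi[0]))


@dataclass(frozen=True)
class Region:
    """A named conformational state covering one or more angular boxes."""

    label: str
    boxes: tuple[AngularBox, ...]
    area_index: int | None = None     # integration-area tag (0-4) when applicable
    approximate: bool = False         # bounds reconstructed, not printed values

    def contains(self, phi, psi) -> np.ndarray:
        hit = np.zeros(np.broadcast(np.asarray(phi), np.asarray(psi)).shape, dtype=bool)
        for box in self.boxes:
            hit |= box.contains(phi, psi)
        return hit

    def widest_box(self) -> AngularBox:
        return max(self.boxes, key=lambda b: b.area)


class RegionOverlapError(ValueError):
    """Two labeled regions claim the same torus point."""


@dataclass
class RegionSet:
    """Validated partition of the Ramachandran torus into labeled states.

    Points covered by no region belong to the ``other`` complement; the
    full label alphabet is ``labels + ('other',)``.
    """

    name: str
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate region labels in {self.name}")
        if OTHER in labels:
            raise ValueError(f"'{OTHER}' is reserved for the complement")
        self.validate_partition()

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.regions)

    @property
    def alphabet(self) -> tuple[str, ...]:
        return self.labels + (OTHER,)

    def validate_partition(self, grid_step: float = 1.0) -> None:
        """Assert no two labeled regions overlap on a 1° torus grid."""
        grid = np.arange(-180.0 + grid_step, 180.0 + grid_step / 2, grid_step)
        pp, ss = np.meshgrid(grid, grid, indexing="ij")
        coverage = np.zeros(pp.shape, dtype=int)
        for region in self.regions:
            coverage += region.contains(pp, ss)
        if coverage.max() > 1:
            i, j = np.argwhere(coverage > 1)[0]
            raise RegionOverlapError(
                f"region set {self.name!r}: grid point "
                f"(phi={grid[i]:g}, psi={grid[j]:g}) claimed by multiple regions")

    def classify_array(self, phi, psi) -> np.ndarray:
        """Vectorized classification to label codes (index into alphabet).

        NaN angles (undefined termini) map to -1.
        """
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        codes = np.full(np.broadcast(phi, psi).shape, len(self.regions), dtype=np.int16)
        unresolved = np.ones_like(codes, dtype=bool)
        for k, region in enumerate(self.regions):
            hit = unresolved & region.contains(phi, psi)
            codes[hit] = k
            unresolved &= ~hit
        codes[~(np.isfinite(phi) & np.isfinite(psi))] = -1
        return codes

    def region_for(self, label: str) -> Region:
        for region in self.regions:
            if region.label == label:
                return region
        raise KeyError(label)

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = {"name": self.name, "regions": []}
        for r in self.regions:
            data["regions"].append({
                "label": r.label,
                "area_index": r.area_index,
                "approximate": r.approximate,
                "boxes": [{
                    "phi": list(b.phi), "psi": list(b.psi),
                    "closed_phi": list(b.closed_phi), "closed_psi": list(b.closed_psi),
                } for b in r.boxes],
            })
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionSet":
        data = yaml.safe_load(Path(path).read_text())
        regions = []
        for r in data["regions"]:
            boxes = tuple(AngularBox(
                phi=tuple(b["phi"]), psi=tuple(b["psi"]),
                closed_phi=tuple(b.get("closed_phi", [True, True])),
                closed_psi=tuple(b.get("closed_psi", [True, True])),
            ) for b in r["boxes"])
            regions.append(Region(label=r["label"], boxes=boxes,
                                  area_index=r.get("area_index"),
                                  approximate=bool(r.get("approximate", False))))
        return cls(name=data["name"], regions=tuple(regions))


# ---------------------------------------------------------------------------
# Builtin region sets


def _standard_literature_regions(include_zeta_gamma: bool = False) -> tuple[Region, ...]:
    # Literature bounds for deprotonated Asp/Glu backbone basins.  The
    # beta-sheet psi clause is the interval [104, 180]; phi is half-open at
    # -104 so beta and PPII do not overlap.
    regions = [
        Region("alphaR", (AngularBox((-90, -30), (-90, 0)),), area_index=0),
        Region("alphaL", (AngularBox((30, 90), (0, 90)),), area_index=4),
        Region("PPII", (AngularBox((-104, -46), (116, 174)),), area_index=2),
        Region("beta", (AngularBox((-180, -104), (104, 180),
                                   closed_phi=(True, False)),), area_index=3),
    ]
    if include_zeta_gamma:
        # 30-degree boxes about the zeta (-135, 60) and gamma' (-80, 80)
        # centers, trimmed at phi = -110 so the two stay disjoint.
        regions.append(Region("zeta", (AngularBox(
            (-165, -110), (30, 90), closed_phi=(True, False)),), approximate=True))
        regions.append(Region("gamma_prime", (AngularBox(
            (-110, -50), (50, 104), closed_psi=(True, False)),), approximate=True))
    return tuple(regions)


def _screw_complement_boxes() -> tuple[AngularBox, ...]:
    # Complement of the canonical alphaR box inside the enclosing screw box
    # phi [-160, -30] x psi [-90, 50], decomposed into disjoint rectangles.
    return (
        AngularBox((-160, -90), (-90, 50), closed_phi=(True, False)),
        AngularBox((-90, -30), (0, 50), closed_psi=(False, True)),
    )


def _integration_regions(screw_label: str) -> tuple[Region, ...]:
    # Integration-area topology: 0 = alphaR, 1 = second screw area,
    # 2 = PPII, 3 = beta, 4 = alphaL.  Bounds beyond the printed alphaR box
    # are reconstructions of the figure areas and are flagged approximate.
    return (
        Region("alphaR", (AngularBox((-90, -30), (-90, 0)),), area_index=0),
        Region(screw_label, _screw_complement_boxes(), area_index=1, approximate=True),
        Region("PPII", (AngularBox((-104, -46), (116, 174)),), area_index=2,
               approximate=True),
        Region("beta", (AngularBox((-180, -104), (104, 180),
                                   closed_phi=(True, False)),), area_index=3,
               approximate=True),
        Region("alphaL", (AngularBox((30, 90), (0, 90)),), area_index=4,
               approximate=True),
    )


def _build_builtin(name: str) -> RegionSet:
    if name == "standard_literature":
        return RegionSet(name, _standard_literature_regions())
    if name == "standard_literature_extended":
        return RegionSet(name, _standard_literature_regions(include_zeta_gamma=True))
    if name == "charmm_integration":
        # C27-style maps separate alphaR from the 3.10 area.
        return RegionSet(name, _integration_regions("3.10"))
    if name in ("amber99_integration", "opls_integration"):
        # AMBER/OPLS maps merge alphaR and 3.10 into area 0; area 1 holds
        # the population outside canonical basins ("additional screw").
        return RegionSet(name, _integration_regions("additional_screw"))
    raise KeyError(f"unknown builtin region set {name!r}")


BUILTIN_REGION_SETS = (
    "standard_literature",
    "standard_literature_extended",
    "charmm_integration",
    "amber99_integration",
    "opls_integration",
)


def builtin_region_set(name: str) -> RegionSet:
    """Return a shipped, validated region set by name."""
    if name not in BUILTIN_REGION_SETS:
        raise KeyError(
            f"unknown region set {name!r}; available: {BUILTIN_REGION_SETS}")
    return _build_builtin(name)


# ---------------------------------------------------------------------------
# Classification


def classify(phi: float, psi: float, regions: RegionSet) -> str:
    """Label a single (Φ, Ψ) pair; angles are wrapped internally."""
    code = regions.classify_array(wrap_degrees(phi), wrap_degrees(psi))
    return regions.alphabet[int(code)]


@dataclass
class StateTrajectory:
    """Discrete per-frame, per-residue conformational-state labels.

    ``codes`` indexes into ``alphabet``; shape (n_frames, n_analyzed_monomers).
    """

    times: np.ndarray
    codes: np.ndarray
    alphabet: tuple[str, ...]
    residue_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be (n_frames, n_residues)")
        if len(self.times) != self.codes.shape[0]:
            raise ValueError("times length does not match frames")
        if self.codes.size and (self.codes.min() < 0
                                or self.codes.max() >= len(self.alphabet)):
            raise ValueError("codes outside alphabet range")

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    @property
    def n_analyzed_monomers(self) -> int:
        return self.codes.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else float("nan")

    def labels(self) -> np.ndarray:
        """Labels as a string array (convenience view of codes)."""
        return np.asarray(self.alphabet, dtype=object)[self.codes]


def classify_trajectory(traj: DihedralTrajectory, regions: RegionSet,
                        exclude_termini: bool = True) -> StateTrajectory:
    """Classify every residue-frame of a dihedral trajectory.

    With ``exclude_termini`` (default) the first and last residues are
    dropped, leaving chain_length - 2 analyzed monomers.
    """
    if traj.n_frames == 0:
        raise ValueError("no frames to classify (empty trajectory)")
    phi, psi, resids = traj.phi, traj.psi, traj.residue_ids
    if exclude_termini and traj.chain_length >= 3:
        phi, psi, resids = phi[:, 1:-1], psi[:, 1:-1], resids[1:-1]
    codes = regions.classify_array(phi, psi)
    if np.any(codes < 0):
        raise ValueError("undefined (NaN) angles among analyzed residues; "
                         "exclude termini or clean the input")
    return StateTrajectory(times=traj.times, codes=codes,
                           alphabet=regions.alphabet, residue_ids=resids)


# ---------------------------------------------------------------------------
# Densities, integration, fractions


@dataclass
class Density2D:
    """Normalized 2-D histogram of (Φ, Ψ) over residue-frames."""

    phi_edges: np.ndarray
    psi_edges: np.ndarray
    weights: np.ndarray       # (n_phi_bins, n_psi_bins), sums to 1

    def __post_init__(self) -> None:
        self.phi_edges = np.asarray(self.phi_edges, dtype=float)
        self.psi_edges = np.asarray(self.psi_edges, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("density weights must sum to 1")
        for edges in (self.phi_edges, self.psi_edges):
            if abs(edges[0] + 180.0) > 1e-9 or abs(edges[-1] - 180.0) > 1e-9:
                raise ValueError("bins must cover the full torus [-180, 180]")

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (0.5 * (self.phi_edges[:-1] + self.phi_edges[1:]),
                0.5 * (self.psi_edges[:-1] + self.psi_edges[1:]))


def ramachandran_density(traj: DihedralTrajectory, bin_width: float = 10.0,
                         exclude_termini: bool = True) -> Density2D:
    """Normalized (Φ, Ψ) histogram over all analyzed residue-frames."""
    if abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 360")
    phi, psi = traj.phi, traj.psi
    if exclude_termini and traj.chain_length >= 3:
        phi, psi = phi[:, 1:-1], psi[:, 1:-1]
    mask = np.isfinite(phi) & np.isfinite(psi)
    edges = np.linspace(-180.0, 180.0, int(round(360.0 / bin_width)) + 1)
    hist, _, _ = np.histogram2d(phi[mask].ravel(), psi[mask].ravel(),
                                bins=[edges, edges])
    total = hist.sum()
    if total == 0:
        raise ValueError("no finite residue-frames to histogram")
    return Density2D(phi_edges=edges, psi_edges=edges, weights=hist / total)


@dataclass
class FractionTable:
    """Per-state population fractions with block-SD errors."""

    fractions: dict          # label -> fraction in [0, 1]
    errors: dict             # label -> SD across blocks (0 when n_blocks unused)
    region_set: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")
        if any(e < 0 for e in self.errors.values()):
            raise ValueError("errors must be >= 0")

    def __getitem__(self, label: str) -> tuple[float, float]:
        return self.fractions[label], self.errors.get(label, 0.0)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["state\tfraction\tsd"]
        for label, frac in self.fractions.items():
            lines.append(f"{label}\t{frac:.10g}\t{self.errors.get(label, 0.0):.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


def integrate_regions(density: Density2D, regions: RegionSet) -> FractionTable:
    """Integrate a dihedral density over each region of a set.

    Bins are assigned to regions by bin-center membership; when every box
    bound lies on a bin edge this equals direct per-sample classification.
    """
    pc, sc = density.bin_centers()
    pp, ss = np.meshgrid(pc, sc, indexing="ij")
    codes = regions.classify_array(pp, ss)
    fractions = {}
    for k, label in enumerate(regions.alphabet):
        fractions[label] = float(density.weights[codes == k].sum())
    return FractionTable(fractions=fractions,
                         errors={label: 0.0 for label in regions.alphabet},
                         region_set=regions.name,
                         metadata={"method": "integration"})


def state_fractions(states: StateTrajectory, n_blocks: int = 5) -> FractionTable:
    """Population fraction of each state with SD over contiguous time blocks.

    The fraction is the mean over all residue-frames; the error is the SD of
    per-block fractions over ``n_blocks`` equal-length contiguous blocks
    (trailing remainder frames contribute to the fraction but not the SD).
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if states.n_frames < n_blocks:
        raise ValueError(f"too few frames ({states.n_frames}) for {n_blocks} blocks")
    n_states = len(states.alphabet)
    n_frames, n_res = states.codes.shape
    counts = np.zeros((n_frames, n_states), dtype=np.int64)
    rows = np.repeat(np.arange(n_frames), n_res)
    np.add.at(counts, (rows, states.codes.ravel()), 1)
    totals = counts.sum(axis=0)
    fractions = totals / totals.sum()
    block_len = states.n_frames // n_blocks
    block_fracs = np.empty((n_blocks, n_states))
    for b in range(n_blocks):
        chunk = counts[b * block_len:(b + 1) * block_len]
        block_fracs[b] = chunk.sum(axis=0) / chunk.sum()
    errors = block_fracs.std(axis=0, ddof=1)
    return FractionTable(
        fractions={lab: float(fractions[k]) for k, lab in enumerate(states.alphabet)},
        errors={lab: float(errors[k]) for k, lab in enumerate(states.alphabet)},
        metadata={"n_blocks": n_blocks, "method": "classification"})
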