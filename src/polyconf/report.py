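"""Pipeline orchestration, conformation timelines and JSON reporting.

``run_pipeline`` chains the stages — equilibration discard, classification,
fraction tables, sequence statistics, chain geometry (when coordinates are
available) and relaxation analysis — and writes a deterministic JSON report
plus TSV artifacts, each stamped with a hash of the configuration and the
seed.  ``conformation_timeline`` renders the per-monomer state evolution as
a raster with the conventional color semantics (PPII green, β red, 3.10
yellow, αR pink, αL blue).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import sequences as seqmod
from .geometry import BridgeSpec, bridge_fraction, end_to_end_series, rg_series
from .io import AnalysisConfig, CoordinateTrajectory, DihedralTrajectory, \
    discard_equilibration, read_dihedral_table
from .reference import compare_to_reference
from .regions import StateTrajectory, builtin_region_set, classify_trajectory, \
    state_fractions
from .relaxation import dihedral_autocorrelation, distance_autocorrelation, \
    fit_stretched_exponential

__all__ = ["conformation_timeline", "timeline_to_tsv", "timeline_to_png",
           "run_pipeline", "STATE_COLORS"]

log = logging.getLogger(__name__)

#: Timeline color semantics.
STATE_COLORS = {
    "PPII": "#2ca02c",              # green
    "beta": "#d62728",              # red
    "3.10": "#ffdf00",              # yellow
    "additional_screw": "#ff7f0e",  # orange
    "alphaR": "#f7a8b8",            # pink
    "alphaL": "#1f77b4",            # blue
    "zeta": "#9467bd",
    "gamma_prime": "#8c564b",
    "other": "#c7c7c7",             # grey
}


def conformation_timeline(states: StateTrajectory, pixel_dt: float) -> np.ndarray:
    """Raster of modal state codes per (monomer, time pixel).

    Each pixel covers ``pixel_dt`` ns and takes the modal state of its
    window; ties go to the state of the window's first frame.  Width is
    ``ceil(total_time / pixel_dt)``.
    """
    dt = states.dt
    if not np.isfinite(dt):
        dt = pixel_dt
    if pixel_dt < dt - 1e-12:
        raise ValueError(f"pixel_dt {pixel_dt} shorter than frame spacing {dt}")
    frames_per_px = max(1, int(round(pixel_dt / dt)))
    n_frames, n_mono = states.codes.shape
    n_px = int(np.ceil(n_frames / frames_per_px))
    n_states = len(states.alphabet)
    raster = np.empty((n_mono, n_px), dtype=np.int16)
    for p in range(n_px):
        window = states.codes[p * frames_per_px:(p + 1) * frames_per_px]
        for m in range(n_mono):
            counts = np.bincount(window[:, m], minlength=n_states)
            top = counts.max()
            candidates = np.flatnonzero(counts == top)
            first = window[0, m]
            raster[m, p] = first if first in candidates else candidates[0]
    return raster


def timeline_to_tsv(raster: np.ndarray, states: StateTrajectory,
                    path: str | Path) -> None:
    """Write the timeline raster as a TSV label matrix (rows = monomers)."""
    labels = np.asarray(states.alphabet, dtype=object)[raster]
    lines = ["\t".join(row) for row in labels]
    Path(path).write_text("\n".join(lines) + "\n")


def timeline_to_png(raster: np.ndarray, states: StateTrajectory,
                    path: str | Path, pixel_dt: float) -> None:
    """Render the timeline raster as an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    colors = [STATE_COLORS.get(lab, "#000000") for lab in states.alphabet]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.imshow(raster, aspect="auto", interpolation="nearest",
              cmap=ListedColormap(colors), vmin=-0.5,
              vmax=len(states.alphabet) - 0.5,
              extent=(0, raster.shape[1] * pixel_dt, raster.shape[0] + 0.5, 0.5))
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("monomer")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: AnalysisConfig,
                 dihedrals: DihedralTrajectory | str | Path,
                 coordinates: CoordinateTrajectory | None = None,
                 out_dir: str | Path = ".",
                 molecule: str | None = None,
                 sequence_targets: tuple[str, ...] = ("alphaR", "beta"),
                 ) -> dict:
    """Run the full analysis chain and write the JSON report + TSV artifacts.

    Returns the report dict; the report is deterministic for a fixed config
    and seed (no timestamps).  ``molecule`` enables comparison against the
    packaged experimental reference table.
    """
    if config.region_set is None:
        raise ValueError("config must name a region set")
    regions = builtin_region_set(config.region_set)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if isinstance(dihedrals, (str, Path)):
        dihedrals = read_dihedral_table(dihedrals)
    log.info("discarding equilibration fraction %.3f", config.equilibration_fraction)
    traj = discard_equilibration(dihedrals, fraction=config.equilibration_fraction)
    if config.stride > 1:
        traj = DihedralTrajectory(times=traj.times[::config.stride],
                                  residue_ids=traj.residue_ids,
                                  phi=traj.phi[::config.stride],
                                  psi=traj.psi[::config.stride])

    states = classify_trajectory(traj, regions, exclude_termini=True)
    fractions = state_fractions(states, n_blocks=config.n_blocks)
    fractions.to_tsv(out_dir / "fractions.tsv")

    report: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "region_set": regions.name,
        "n_frames_analyzed": states.n_frames,
        "n_analyzed_monomers": states.n_analyzed_monomers,
        "fractions": {lab: {"fraction": fractions.fractions[lab],
                            "sd": fractions.errors[lab]}
                      for lab in states.alphabet},
        "sequences": {},
        "relaxation": {},
    }

    for target in sequence_targets:
        if target not in states.alphabet:
            continue
        record = seqmod.run_lengths(states, target)
        frac = seqmod.sequence_fraction(record, min_len=config.min_run_length)
        seqmod.write_length_histogram(
            record, out_dir / f"run_lengths_{target.replace('.', '')}.tsv")
        report["sequences"][target] = {
            "min_run_length": config.min_run_length,
            "fraction_in_sequences": frac,
        }

    # Dihedral relaxation of the psi angle (phi motion is typically much
    # more restricted); skipped for trajectories too short to window a fit.
    try:
        acf = dihedral_autocorrelation(traj.psi[:, 1:-1], traj.dt, kind="dihedral-psi")
        acf.to_tsv(out_dir / "acf_psi.tsv")
        fit = fit_stretched_exponential(acf, floor=config.acf_fit_floor)
        report["relaxation"]["psi"] = fit.to_dict()
    except (ValueError, RuntimeError) as exc:
        log.warning("psi relaxation skipped: %s", exc)
        report["relaxation"]["psi"] = None

    if coordinates is not None:
        coords = discard_equilibration(coordinates,
                                       fraction=config.equilibration_fraction)
        rg = rg_series(coords)
        report["geometry"] = {"rg_mean_nm": float(rg.mean()),
                              "rg_sd_nm": float(rg.std(ddof=1)) if len(rg) > 1 else 0.0}
        try:
            e2e = end_to_end_series(coords)
            report["geometry"]["end_to_end_mean_nm"] = float(e2e.mean())
            if len(e2e) >= 20:
                acf_d = distance_autocorrelation(e2e, coords.times[1] - coords.times[0])
                acf_d.to_tsv(out_dir / "acf_end_to_end.tsv")
                fit_d = fit_stretched_exponential(acf_d, floor=config.acf_fit_floor)
                report["relaxation"]["end_to_end"] = fit_d.to_dict()
        except (ValueError, RuntimeError) as exc:
            log.warning("end-to-end analysis skipped: %s", exc)
        if len(coords.carboxylate_residues()):
            spec = BridgeSpec(cutoffs_nm=config.bridge_cutoffs_nm,
                              min_residue_separation=config.min_residue_separation)
            br = bridge_fraction(coords, spec, n_blocks=config.n_blocks)
            report["geometry"]["bridge_fraction"] = br.fraction
            report["geometry"]["bridge_fraction_sd"] = br.error

    if molecule is not None:
        comparison = compare_to_reference(fractions, molecule)
        report["reference_comparison"] = comparison.to_dict()

    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
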