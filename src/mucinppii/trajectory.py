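"""Conformational trajectory containers and per-frame observables.

Two central containers: :class:`DihedralTrajectory` (frames x residues of
backbone (phi, psi) pairs, the pipeline's main exchange object) and
:class:`BackboneTrajectory` (per-frame N/CA/C/O coordinates).  Observables:
backbone dihedrals and the mass-weighted radius of gyration

    Rg = sqrt[ (1/M) * sum_i m_i (r_i - R)^2 ],

with R the mass-weighted centroid — the compactness measure used for
sampling-convergence checks.

File formats: multi-model PDB (read via Biopython) and a tab-separated
dihedral table (one row per frame x residue) that round-trips exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import wrap_degrees
from .peptide import BACKBONE_ATOMS, BackboneGeometry, THREE_TO_ONE
from .peptide import measure_dihedrals as _measure

log = logging.getLogger(__name__)

TABLE_COLUMNS = ["frame", "time_ns", "residue_number", "residue_type",
                 "glycosylated", "phi", "psi"]


@dataclass
class DihedralTrajectory:
    """Backbone (phi, psi) angles for every frame and residue.

    Angles are degrees in [-180, 180); undefined terminal angles are NaN.
    """

    phi: np.ndarray                     # (n_frames, n_residues)
    psi: np.ndarray                     # (n_frames, n_residues)
    residue_numbers: np.ndarray
    residue_types: list[str]
    glycosylated: np.ndarray            # bool per residue
    time_ns: np.ndarray | None = None   # per-frame, strictly increasing

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape or self.phi.ndim != 2:
            raise ValueError("phi and psi must be matching 2-D arrays")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.glycosylated = np.asarray(self.glycosylated, dtype=bool)
        n_res = self.phi.shape[1]
        if not (len(self.residue_numbers) == len(self.residue_types)
                == len(self.glycosylated) == n_res):
            raise ValueError("residue metadata length mismatch")
        for arr in (self.phi, self.psi):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < -180.0 or finite.max() >= 180.0):
                raise ValueError("angles must lie in [-180, 180)")
        if self.time_ns is not None:
            self.time_ns = np.asarray(self.time_ns, dtype=float)
            if len(self.time_ns) != self.n_frames:
                raise ValueError("time_ns length mismatch")
            if self.n_frames > 1 and not np.all(np.diff(self.time_ns) > 0):
                raise ValueError("time_ns must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]

    def select_frames(self, idx) -> "DihedralTrajectory":
        return DihedralTrajectory(
            self.phi[idx], self.psi[idx], self.residue_numbers,
            list(self.residue_types), self.glycosylated,
            None if self.time_ns is None else self.time_ns[idx])

    def discard_burn_in(self, fraction: float) -> "DihedralTrajectory":
        """Drop the initial ``fraction`` of frames (e.g. 0.5: keep the
        second half of the run for analysis)."""
        if not 0.0 <= fraction < 1.0:
            raise ValueError("burn-in fraction must be in [0, 1)")
        start = int(round(fraction * self.n_frames))
        return self.select_frames(slice(start, None))


@dataclass
class BackboneTrajectory:
    """Per-frame backbone heavy-atom coordinates (N, CA, C, O per residue)."""

    coords: np.ndarray                  # (n_frames, n_residues, 4, 3), angstrom
    atom_masses: np.ndarray = field(
        default_factory=lambda: BackboneGeometry().atom_masses)
    residue_numbers: np.ndarray | None = None
    residue_types: list[str] | None = None
    time_ns: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[2:] != (4, 3):
            raise ValueError("coords must be (n_frames, n_residues, 4, 3)")
        self.atom_masses = np.asarray(self.atom_masses, dtype=float)
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(1, self.coords.shape[1] + 1)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


def read_pdb_models(path) -> BackboneTrajectory:
    """Read a multi-model PDB into a backbone trajectory (one frame per
    MODEL record).  Non-backbone atoms are ignored with a logged count;
    a residue missing any of N/CA/C/O raises a parse error naming the
    model and residue.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", path)
    models = list(structure)
    if not models:
        raise ValueError(f"no MODEL records found in {path}")
    frames = []
    ignored = 0
    res_numbers, res_types = None, None
    for model in models:
        residues = [r for chain in model for r in chain
                    if r.id[0] == " "]
        frame = np.empty((len(residues), 4, 3))
        numbers, types = [], []
        for ri, res in enumerate(residues):
            for ai, name in enumerate(BACKBONE_ATOMS):
                if name not in res:
                    raise ValueError(
                        f"model {model.id + 1}, residue {res.id[1]} "
                        f"({res.resname}): missing backbone atom {name}")
                frame[ri, ai] = res[name].coord
            ignored += sum(1 for a in res if a.get_name() not in BACKBONE_ATOMS)
            numbers.append(res.id[1])
            types.append(THREE_TO_ONE.get(res.resname, "X"))
        if res_numbers is None:
            res_numbers, res_types = numbers, types
        elif numbers != res_numbers:
            raise ValueError("inconsistent residue numbering across models")
        frames.append(frame)
    if ignored:
        log.info("ignored %d non-backbone atoms in %s", ignored, path)
    return BackboneTrajectory(np.stack(frames),
                              residue_numbers=np.asarray(res_numbers),
                              residue_types=res_types)


def compute_dihedrals(traj: BackboneTrajectory,
                      glycosylated=None) -> DihedralTrajectory:
    """Backbone dihedrals from coordinates.

    phi(i) is the C(i-1)-N(i)-CA(i)-C(i) torsion and psi(i) the
    N(i)-CA(i)-C(i)-N(i+1) torsion; chain termini lacking a neighbour get
    NaN entries, which downstream histograms and classifiers skip.
    """
    if traj.n_residues < 2:
        raise ValueError("need at least 2 residues for backbone dihedrals")
    phi, psi = _measure(traj.coords)
    types = traj.residue_types or ["X"] * traj.n_residues
    if glycosylated is None:
        glycosylated = np.zeros(traj.n_residues, dtype=bool)
    return DihedralTrajectory(phi, psi, traj.residue_numbers, list(types),
                              glycosylated, traj.time_ns)


def radius_of_gyration(coords, masses) -> np.ndarray:
    """Mass-weighted radius of gyration (angstrom).

    ``coords`` is (..., n_atoms, 3); ``masses`` (n_atoms,).  Returns one
    Rg per leading frame (scalar for a single frame).
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.shape[-2] < 2:
        raise ValueError("radius of gyration needs at least 2 atoms")
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    w = masses / total
    center = np.einsum("...ij,i->...j", coords, w)
    sq = np.sum((coords - center[..., None, :]) ** 2, axis=-1)
    return np.sqrt(np.einsum("...i,i->...", sq, w))


def trajectory_rg(traj: BackboneTrajectory) -> np.ndarray:
    """Per-frame Rg over all backbone heavy atoms."""
    flat = traj.coords.reshape(traj.n_frames, -1, 3)
    masses = np.tile(traj.atom_masses, traj.n_residues)
    return radius_of_gyration(flat, masses)


def write_dihedral_table(path, traj: DihedralTrajectory) -> None:
    """Write the tab-separated dihedral-trajectory table (one row per
    frame x residue; header mandatory; exact round trip)."""
    n_f, n_r = traj.n_frames, traj.n_residues
    frames = np.repeat(np.arange(n_f), n_r)
    times = (np.repeat(traj.time_ns, n_r) if traj.time_ns is not None
             else np.full(n_f * n_r, np.nan))
    df = pd.DataFrame({
        "frame": frames,
        "time_ns": times,
        "residue_number": np.tile(traj.residue_numbers, n_f),
        "residue_type": np.tile(np.asarray(traj.residue_types), n_f),
        "glycosylated": np.tile(traj.glycosylated.astype(int), n_f),
        "phi": traj.phi.ravel(),
        "psi": traj.psi.ravel(),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    log.info("wrote %d frames x %d residues to %s", n_f, n_r, path)


def read_dihedral_table(path) -> DihedralTrajectory:
    """Read the tab-separated dihedral table written by
    :func:`write_dihedral_table`.  Angles are wrapped into [-180, 180)
    on read; malformed rows raise with a line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed dihedral table {path}: {exc}") from exc
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("frame", "residue_number", "phi", "psi"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                       & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: malformed value in column {col!r} at line "
                f"{bad[0] + 2}")  # +2: header line and 1-based numbering
    frames = np.sort(df["frame"].unique())
    first = df[df["frame"] == frames[0]].sort_values("residue_number")
    res_numbers = first["residue_number"].to_numpy()
    res_types = first["residue_type"].astype(str).tolist()
    glyco = first["glycosylated"].astype(bool).to_numpy()
    n_r = len(res_numbers)
    df = df.sort_values(["frame", "residue_number"])
    if len(df) != len(frames) * n_r:
        raise ValueError(f"{path}: ragged table (frames x residues mismatch)")
    def _wrap_outside(values):
        # wrap only out-of-range entries so in-range values round-trip
        # bit-exactly through the text format
        inside = (values >= -180.0) & (values < 180.0)
        return np.where(inside | ~np.isfinite(values), values,
                        wrap_degrees(values))

    phi = _wrap_outside(df["phi"].to_numpy()).reshape(len(frames), n_r)
    psi = _wrap_outside(df["psi"].to_numpy()).reshape(len(frames), n_r)
    times = df.groupby("frame", sort=True)["time_ns"].first().to_numpy()
    time_ns = None if np.isnan(times).all() else times
    return DihedralTrajectory(phi, psi, res_numbers, res_types, glyco, time_ns)
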