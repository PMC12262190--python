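"""Model peptides of the lubricin mucin domain.

The mucin domain of lubricin (PRG4) is built from KEPAPTTP-like tandem
repeats whose threonines carry O-linked GalNAc-Gal glycans.  This module
constructs model peptides of that domain: sequence handling, O-glycosylation
site assignment (with explicit exclusions such as the one unglycosylated
threonine in the two-repeat model peptide), ideal-geometry backbone
coordinates from (phi, psi, omega) dihedrals, helix-parameter measurement,
and multi-model PDB output.

Glycans are represented purely as per-residue site flags; no glycan atoms
are ever built.  Coordinates use ideal (Engh-Huber-style) bond lengths and
angles, which is sufficient for dihedral-level and radius-of-gyration
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import dihedral_angle, helix_fit, place_atom

log = logging.getLogger(__name__)

#: Default two-tandem-repeat mucin-domain model peptide (PRG4 residues 393-410).
MUCIN_PEPTIDE_SEQUENCE = "PKEPAPTTTKEPAPTTPK"
MUCIN_PEPTIDE_FIRST_RESIDUE = 393
#: The third threonine of the model peptide (Thr401) is not glycosylated.
MUCIN_PEPTIDE_EXCLUDED_SITES = frozenset({401})

#: Canonical polyproline-II backbone dihedrals (degrees).
PPII_PHI_PSI = (-75.0, 145.0)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Residue types with high intrinsic polyproline-II propensity: proline,
#: alanine, and long-linear-sidechain residues such as lysine.
HIGH_PPII_PROPENSITY = frozenset({"P", "A", "K"})

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class BackboneGeometry:
    """Ideal backbone internal coordinates (Engh-Huber-style values).

    Lengths in angstrom, angles in degrees, masses in dalton.
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    n_ca_c: float = 111.2
    ca_c_n: float = 116.2
    c_n_ca: float = 121.7
    ca_c_o: float = 120.8
    mass_n: float = 14.007
    mass_ca: float = 12.011
    mass_c: float = 12.011
    mass_o: float = 15.999

    def __post_init__(self):
        for name in ("n_ca", "ca_c", "c_n", "c_o"):
            if not 1.0 < getattr(self, name) < 2.0:
                raise ValueError(f"bond length {name} outside (1.0, 2.0) A")
        for name in ("n_ca_c", "ca_c_n", "c_n_ca", "ca_c_o"):
            if not 90.0 < getattr(self, name) < 140.0:
                raise ValueError(f"bond angle {name} outside (90, 140) degrees")

    @property
    def atom_masses(self) -> np.ndarray:
        """Masses for the (N, CA, C, O) backbone atoms of one residue."""
        return np.array([self.mass_n, self.mass_ca, self.mass_c, self.mass_o])


def assign_glyco_sites(sequence: str, first_residue_number: int,
                       excluded_residue_numbers=()) -> set[int]:
    """Residue numbers of O-glycosylated threonines.

    Every threonine in ``sequence`` is assigned a glycan site except those
    listed in ``excluded_residue_numbers`` (e.g. Thr401 of the two-repeat
    mucin model peptide, which is not glycosylated in lubricin).

    Raises
    ------
    ValueError
        If an exclusion lies outside the peptide's numbering range or does
        not point at a threonine.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    _validate_sequence(sequence)
    last = first_residue_number + len(sequence) - 1
    excluded = set(excluded_residue_numbers)
    for num in excluded:
        if not first_residue_number <= num <= last:
            raise ValueError(
                f"excluded residue {num} outside numbering range "
                f"[{first_residue_number}, {last}]")
        if sequence[num - first_residue_number] != "T":
            raise ValueError(f"excluded residue {num} is not a threonine")
    return {first_residue_number + i
            for i, aa in enumerate(sequence)
            if aa == "T" and first_residue_number + i not in excluded}


def count_high_ppii_residues(sequence: str,
                             high_propensity_set=HIGH_PPII_PROPENSITY) -> int:
    """Count residues with high intrinsic PPII propensity.

    With the default set {P, A, K}, five of the eight residues of the
    KEPAPTTP mucin tandem repeat qualify.
    """
    _validate_sequence(sequence)
    return sum(1 for aa in sequence if aa in high_propensity_set)


def _validate_sequence(sequence: str) -> None:
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"unknown residue letters: {sorted(bad)}")


@dataclass
class PeptideModel:
    """A mucin-domain model peptide.

    Attributes
    ----------
    sequence : one-letter amino-acid string.
    first_residue_number : number of the first residue (e.g. 393).
    glyco_sites : residue numbers flagged as carrying an O-linked glycan.
    dihedral_assignment : (n_residues, 3) array of (phi, psi, omega) in
        degrees; defaults to the canonical PPII conformation with trans
        (omega = 180) peptide bonds.
    """

    sequence: str
    first_residue_number: int = 1
    glyco_sites: set[int] = field(default_factory=set)
    dihedral_assignment: np.ndarray | None = None

    def __post_init__(self):
        _validate_sequence(self.sequence)
        last = self.first_residue_number + len(self.sequence) - 1
        for num in self.glyco_sites:
            if not self.first_residue_number <= num <= last:
                raise ValueError(f"glyco site {num} outside residue range")
            if self.sequence[num - self.first_residue_number] not in "TS":
                raise ValueError(
                    f"glyco site {num} is not a threonine or serine")
        if self.dihedral_assignment is None:
            phi, psi = PPII_PHI_PSI
            self.dihedral_assignment = np.tile(
                [phi, psi, 180.0], (len(self.sequence), 1))
        self.dihedral_assignment = np.asarray(
            self.dihedral_assignment, dtype=float)
        if self.dihedral_assignment.shape != (len(self.sequence), 3):
            raise ValueError("dihedral_assignment must be (n_residues, 3)")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.arange(self.first_residue_number,
                         self.first_residue_number + len(self.sequence))

    @property
    def glycosylated_mask(self) -> np.ndarray:
        return np.isin(self.residue_numbers, sorted(self.glyco_sites))

    @classmethod
    def mucin_model_peptide(cls, glycosylated: bool = True) -> "PeptideModel":
        """The two-tandem-repeat model peptide (residues 393-410), with
        glycans on every threonine except Thr401 when ``glycosylated``."""
        sites = assign_glyco_sites(
            MUCIN_PEPTIDE_SEQUENCE, MUCIN_PEPTIDE_FIRST_RESIDUE,
            MUCIN_PEPTIDE_EXCLUDED_SITES) if glycosylated else set()
        return cls(MUCIN_PEPTIDE_SEQUENCE, MUCIN_PEPTIDE_FIRST_RESIDUE, sites)


def build_backbone_frames(phi, psi, omega=None,
                          geometry: BackboneGeometry | None = None) -> np.ndarray:
    """Build backbone Cartesian coordinates from dihedrals, batched over frames.

    Chain extension by sequential internal-coordinate (NeRF) placement: the
    first residue seeds an arbitrary rigid-body frame, then each peptide unit
    is appended using the ideal bond lengths/angles and the assigned psi(i),
    omega(i+1), phi(i+1) torsions.  phi of the first residue and psi of the
    last influence nothing except the terminal carbonyl-oxygen placement.

    Parameters
    ----------
    phi, psi : (n_frames, n_residues) or (n_residues,) arrays, degrees.
    omega : like phi; defaults to 180 (trans) everywhere.

    Returns
    -------
    (n_frames, n_residues, 4, 3) array of N, CA, C, O coordinates (angstrom);
    the leading axis is squeezed away for unbatched input.
    """
    geometry = geometry or BackboneGeometry()
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    squeeze = np.asarray(phi).ndim == 2 and np.asarray(psi).shape == phi.shape
    if omega is None:
        omega = np.full_like(phi, 180.0)
    else:
        omega = np.atleast_2d(np.asarray(omega, dtype=float))
    if not phi.shape == psi.shape == omega.shape:
        raise ValueError("phi, psi, omega must have matching shapes")
    n_frames, n_res = phi.shape
    if n_res < 1:
        raise ValueError("need at least one residue")

    g = geometry
    coords = np.zeros((n_frames, n_res, 4, 3))
    # seed frame: N at origin, CA on +x, C in the xy-plane
    theta = np.radians(g.n_ca_c)
    coords[:, 0, 0] = [0.0, 0.0, 0.0]
    coords[:, 0, 1] = [g.n_ca, 0.0, 0.0]
    coords[:, 0, 2] = coords[:, 0, 1] + g.ca_c * np.array(
        [-np.cos(theta), np.sin(theta), 0.0])

    for i in range(n_res - 1):
        n_i, ca_i, c_i = coords[:, i, 0], coords[:, i, 1], coords[:, i, 2]
        n_next = place_atom(n_i, ca_i, c_i, g.c_n, g.ca_c_n, psi[:, i])
        ca_next = place_atom(ca_i, c_i, n_next, g.n_ca, g.c_n_ca,
                             omega[:, i + 1])
        c_next = place_atom(c_i, n_next, ca_next, g.ca_c, g.n_ca_c,
                            phi[:, i + 1])
        coords[:, i + 1, 0] = n_next
        coords[:, i + 1, 1] = ca_next
        coords[:, i + 1, 2] = c_next

    # carbonyl oxygens: anti to the following amide nitrogen (torsion psi+180)
    for i in range(n_res):
        coords[:, i, 3] = place_atom(
            coords[:, i, 0], coords[:, i, 1], coords[:, i, 2],
            g.c_o, g.ca_c_o, psi[:, i] + 180.0)
    return coords


def build_backbone(model: PeptideModel,
                   geometry: BackboneGeometry | None = None) -> np.ndarray:
    """Backbone coordinates (n_residues, 4, 3) for a single conformation.

    Re-measuring dihedrals from the output reproduces the model's
    ``dihedral_assignment`` at interior residues to better than 1e-6 degrees.
    """
    d = model.dihedral_assignment
    coords = build_backbone_frames(d[:, 0], d[:, 1], d[:, 2], geometry)
    log.info("built backbone for %d-residue peptide starting at %d",
             model.n_residues, model.first_residue_number)
    return coords[0]


def measure_dihedrals(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) in degrees from backbone coordinates.

    ``coords`` is (..., n_residues, 4, 3) with atoms ordered N, CA, C, O.
    phi is NaN at the first residue, psi NaN at the last.
    """
    coords = np.asarray(coords, dtype=float)
    n_res = coords.shape[-3]
    shape = coords.shape[:-3] + (n_res,)
    phi = np.full(shape, np.nan)
    psi = np.full(shape, np.nan)
    n, ca, c = coords[..., 0, :], coords[..., 1, :], coords[..., 2, :]
    if n_res >= 2:
        phi[..., 1:] = dihedral_angle(c[..., :-1, :], n[..., 1:, :],
                                      ca[..., 1:, :], c[..., 1:, :])
        psi[..., :-1] = dihedral_angle(n[..., :-1, :], ca[..., :-1, :],
                                       c[..., :-1, :], n[..., 1:, :])
    return phi, psi


def helix_parameters(backbone_coords: np.ndarray):
    """Twist (deg/residue), rise (A/residue) and residues per turn from a
    backbone conformation's consecutive CA atoms.

    Negative twist denotes a left-handed helix; the canonical PPII
    conformation gives roughly -120 deg/residue, i.e. three residues per
    turn, left-handed.
    """
    coords = np.asarray(backbone_coords, dtype=float)
    if coords.ndim == 3 and coords.shape[-2] == 4:
        ca = coords[:, 1, :]
    else:
        ca = coords
    return helix_fit(ca)


def write_pdb(path, coords, model: PeptideModel,
              geometry: BackboneGeometry | None = None) -> None:
    """Write one or more backbone conformations as a multi-model PDB file.

    ``coords`` is (n_residues, 4, 3) or (n_frames, n_residues, 4, 3).
    Glycosylation sites are recorded in REMARK 999 lines only; no glycan
    atoms are written.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 3:
        coords = coords[None]
    if coords.shape[1:] != (model.n_residues, 4, 3):
        raise ValueError("coordinate shape does not match the peptide model")
    elements = ("N", "C", "C", "O")
    res_numbers = model.residue_numbers
    res_names = [ONE_TO_THREE[aa] for aa in model.sequence]
    lines = ["REMARK 999 MUCIN-DOMAIN MODEL PEPTIDE (BACKBONE ONLY)"]
    if model.glyco_sites:
        sites = " ".join(str(s) for s in sorted(model.glyco_sites))
        lines.append(f"REMARK 999 O-GLYCOSYLATION SITES (NO GLYCAN ATOMS): {sites}")
    for frame_idx, frame in enumerate(coords, start=1):
        lines.append(f"MODEL     {frame_idx:4d}")
        serial = 1
        for r in range(model.n_residues):
            for a, atom_name in enumerate(BACKBONE_ATOMS):
                x, y, z = frame[r, a]
                lines.append(
                    f"ATOM  {serial:5d} {atom_name:^4s}{res_names[r]:>3s} A"
                    f"{res_numbers[r]:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00          {elements[a]:>2s}")
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    log.info("wrote %d model(s) to %s", coords.shape[0], path)


ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}
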