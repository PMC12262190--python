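"""Low-level backbone geometry: angle wrapping, torsion measurement,
internal-coordinate atom placement (NeRF) and helical-axis fitting.

All angles cross this module's API in degrees; the convention throughout
the package is the IUPAC torsion sign with values in [-180, 180).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def wrap_degrees(angle):
    """Map angles (degrees, any real) onto [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def dihedral_angle(p0, p1, p2, p3):
    """Torsion angle p0-p1-p2-p3 in degrees, in [-180, 180).

    Accepts arrays broadcastable to (..., 3); returns shape (...).
    Positive sign follows the IUPAC convention (clockwise rotation of the
    far bond when sighting down p1->p2).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    # components of b0/b2 perpendicular to b1
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond_length, bond_angle_deg, torsion_deg):
    """Place atom d from internal coordinates relative to atoms a, b, c.

    d is positioned so that |c-d| = bond_length, the angle b-c-d equals
    bond_angle_deg and the torsion a-b-c-d equals torsion_deg.  Inputs
    broadcast over leading axes (batched placement across frames).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(np.asarray(bond_angle_deg, dtype=float))[..., None]
    tau = np.radians(np.asarray(torsion_deg, dtype=float))[..., None]
    r = np.asarray(bond_length, dtype=float)

    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d = -np.cos(theta) * bc + np.sin(theta) * (np.cos(tau) * m + np.sin(tau) * n)
    return c + np.asarray(r)[..., None] * d


class HelixFitError(ValueError):
    """Raised when CA positions do not define a helical screw motion."""


def helix_fit(ca_coords):
    """Fit a helical screw motion through consecutive CA positions.

    Finds the rigid transform (Kabsch rotation + translation) best mapping
    CA[i] onto CA[i+1]; for an ideal regular helix this is exact and its
    rotation angle is the per-residue twist.  Returns
    ``(twist_deg, rise_per_residue, residues_per_turn)`` where a negative
    twist denotes a left-handed helix (rotation opposed to the right-hand
    rule about the direction of advance).

    Parameters
    ----------
    ca_coords : (n, 3) array with n >= 6.
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3 or ca.shape[0] < 6:
        raise HelixFitError("helix fit needs at least 6 CA positions")
    a = ca[:-1]
    b = ca[1:]
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    # collinear or coincident points carry no rotational information
    if np.linalg.matrix_rank(a_c, tol=1e-8) < 2:
        raise HelixFitError("CA positions are collinear; no helical axis defined")
    rot, _ = Rotation.align_vectors(b_c, a_c)
    rotvec = rot.as_rotvec()
    angle = np.linalg.norm(rotvec)
    if angle < 1e-10:
        raise HelixFitError("no net twist between consecutive residues")
    axis = rotvec / angle
    translation = b.mean(axis=0) - rot.apply(a.mean(axis=0))
    rise = float(np.dot(translation, axis))
    # orient the axis along the direction of advance; the rotation is then
    # right-handed (positive twist) or left-handed (negative twist)
    twist = np.degrees(angle) if rise >= 0 else -np.degrees(angle)
    residues_per_turn = 360.0 / np.degrees(angle)
    return float(twist), abs(rise), float(residues_per_turn)
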