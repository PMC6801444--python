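"""Helix-frame geometry for membrane-adsorbed amphipathic peptides.

The analysis views the helical peptide as an oriented cylinder lying on a
bilayer whose normal is the laboratory z axis.  Everything here is built
from three ingredients:

* the helix axis (first principal direction of the C-alpha cloud, oriented
  from the N- to the C-terminus),
* the membrane normal ``+z``,
* atom positions expressed in nm.

From these we derive the rotation angle ``theta`` of the helix about its own
axis (the dihedral spanned by the axis, the Trp CG atom and ``+z``), the
descending/ascending side classification of nearby lipids, and the
orientation statistic ``t . l`` of the Trp indole relative to the nonpolar
surface fragment it sits on.

Angle conventions
-----------------
``theta`` is the signed angle, measured about the *oriented* helix axis with
the right-hand rule, from the half-plane containing ``+z`` to the half-plane
containing the Trp CG atom, wrapped to ``[0, 360)`` degrees.  A mirror image
of the system (one coordinate negated through the plane spanned by the axis
and z) maps ``theta -> 360 - theta``.

During adsorption the L enantiomer rotates so that ``theta`` decreases
(clockwise seen along the axis) while the D enantiomer rotates with
``theta`` increasing.  The *descending* side of the cylinder is the half
whose surface velocity under that rotation sense points into the membrane
(negative z); the other half is *ascending*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Z_AXIS = np.array([0.0, 0.0, 1.0])

DESCENDING = "des"
ASCENDING = "asc"


class GeometryError(ValueError):
    """Raised when a geometric construction is undefined for the input."""


class UndefinedAngleError(GeometryError):
    """Rotation angle undefined (reference atom projects onto the axis)."""


class SideUndefinedError(GeometryError):
    """Side classification undefined (helix axis nearly parallel to z)."""


@dataclass
class HelixFrame:
    """Oriented helix axis and centroid, plus a degeneracy flag.

    ``ambiguous`` is set when the top two singular values of the centered
    C-alpha cloud are nearly equal, i.e. the principal direction is not well
    separated from the second one.
    """

    axis: np.ndarray
    centroid: np.ndarray
    ambiguous: bool = False
    singular_values: np.ndarray = field(default=None, repr=False)

    def in_plane_basis(self, reference: np.ndarray = Z_AXIS):
        """Orthonormal pair (e1, e2) perpendicular to the axis.

        e1 is the reference vector (default +z) projected off the axis and
        normalized; e2 = axis x e1 completes a right-handed triad, so an
        angle increasing from e1 towards e2 is a right-hand rotation about
        the oriented axis.
        """
        a = self.axis
        ref = np.asarray(reference, dtype=float)
        perp = ref - np.dot(ref, a) * a
        norm = np.linalg.norm(perp)
        if norm < 1e-12:
            raise SideUndefinedError(
                "helix axis is parallel to the reference direction; "
                "the in-plane frame is undefined"
            )
        e1 = perp / norm
        e2 = np.cross(a, e1)
        return e1, e2


def helix_axis(ca_coordinates: np.ndarray, ambiguity_ratio: float = 0.05) -> HelixFrame:
    """Oriented helix axis from ordered C-alpha positions.

    The axis is the first principal direction of the centered point cloud,
    with its sign fixed so that ``axis . (ca[-1] - ca[0]) > 0`` (N- to
    C-terminus).  Requires at least 4 points.

    Parameters
    ----------
    ca_coordinates
        ``(n, 3)`` array of C-alpha positions in nm, in residue order.
    ambiguity_ratio
        If the relative gap between the two leading singular values is
        below this value the returned frame is flagged ``ambiguous``.
    """
    ca = np.asarray(ca_coordinates, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3 or ca.shape[0] < 4:
        raise GeometryError("helix_axis needs an (n>=4, 3) array of CA positions")
    centroid = ca.mean(axis=0)
    centered = ca - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    span = ca[-1] - ca[0]
    if np.dot(axis, span) < 0:
        axis = -axis
    ambiguous = bool(s[0] > 0 and (s[0] - s[1]) / s[0] < ambiguity_ratio)
    return HelixFrame(axis=axis, centroid=centroid, ambiguous=ambiguous, singular_values=s)


def signed_angle_about_axis(frame: HelixFrame, point: np.ndarray,
                            reference: np.ndarray = Z_AXIS) -> float:
    """Signed angle (degrees, in [0, 360)) of ``point`` about the helix axis.

    Measured from the half-plane spanned by the axis and ``reference``
    (default +z) to the half-plane containing ``point``, right-hand rule
    about the oriented axis.
    """
    e1, e2 = frame.in_plane_basis(reference)
    v = np.asarray(point, dtype=float) - frame.centroid
    v = v - np.dot(v, frame.axis) * frame.axis
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise UndefinedAngleError(
            "point projects onto the helix axis; the angle is undefined"
        )
    ang = np.degrees(np.arctan2(np.dot(v, e2), np.dot(v, e1)))
    return float(np.mod(ang, 360.0))


def rotation_angle(peptide, helix: HelixFrame | None = None) -> float:
    """Rotation angle theta of the helix about its own axis, in degrees.

    theta is the dihedral composed of the helix axis, the Trp side chain
    (atom CG) and the positive z direction: the signed angle about the
    oriented axis from the +z half-plane to the half-plane of CG, wrapped
    to [0, 360).

    ``peptide`` must expose ``trp_index`` and ``coords_of(atom, residue)``
    (see :class:`chiralmem.synthetic.PeptideModel`).
    """
    if getattr(peptide, "trp_index", None) is None:
        raise GeometryError("peptide has no Trp residue; rotation angle undefined")
    if helix is None:
        helix = helix_axis(peptide.ca_coords())
    cg = peptide.coords_of("CG", peptide.trp_index)
    return signed_angle_about_axis(helix, cg)


def descending_sign(chirality: str) -> int:
    """Sign of ``(r - centroid) . e2`` on the descending side.

    A surface point at angle ``phi`` about the axis (in the e1/e2 frame,
    e1 the projected +z) has vertical velocity proportional to
    ``-omega * sin(phi)`` with ``omega = d(theta)/dt``.  The L enantiomer
    rotates with theta decreasing (omega < 0), so its descending half
    (velocity pointing into the membrane, v_z < 0) is ``sin(phi) < 0``,
    i.e. negative e2 component; for D (omega > 0) it is the positive-e2
    half.
    """
    if chirality == "L":
        return -1
    if chirality == "D":
        return 1
    raise ValueError(f"unknown chirality {chirality!r}; expected 'L' or 'D'")


def classify_sides(c2_positions: np.ndarray, helix: HelixFrame, chirality: str,
                   max_vertical_angle: float = 1.0):
    """Descending/ascending label for each lipid reference point.

    The vertical plane containing the helix axis and z splits space in two.
    Each lipid is labeled by the side on which its reference point (the
    chiral C2 carbon, or the lipid center of mass) falls; the chirality
    fixes which side is descending (see :func:`descending_sign`).

    Parameters
    ----------
    c2_positions
        ``(m, 3)`` reference points in nm.
    max_vertical_angle
        If the helix axis is within this many degrees of +-z the dividing
        plane is undefined and :class:`SideUndefinedError` is raised.

    Returns
    -------
    labels : ndarray of {"des", "asc"} strings, shape (m,)
    ties : boolean ndarray, True where the point lies exactly in the
        dividing plane (deterministically labeled ascending).
    """
    tilt = np.degrees(np.arccos(np.clip(abs(float(np.dot(helix.axis, Z_AXIS))), 0.0, 1.0)))
    if tilt < max_vertical_angle:
        raise SideUndefinedError(
            f"helix axis within {max_vertical_angle} deg of vertical; sides undefined"
        )
    _, e2 = helix.in_plane_basis()
    pts = np.atleast_2d(np.asarray(c2_positions, dtype=float))
    s2 = (pts - helix.centroid) @ e2
    sign = descending_sign(chirality)
    labels = np.where(sign * s2 > 0, DESCENDING, ASCENDING)
    ties = s2 == 0.0
    # measure-zero tie: deterministic ascending
    labels[ties] = ASCENDING
    return labels, ties


@dataclass
class TrpOrientation:
    """Orientation of the Trp indole relative to its surface fragment.

    ``t`` is the unit tangent of the nonpolar helix fragment containing
    Trp, evaluated at Trp; ``l`` is the unit vector along the indole long
    axis CD1 -> CH2; ``dot = t . l`` lies in [-1, 1].  Values near +1 are
    the cis ("well-orientated") arrangement in which the indole runs along
    the surface groove; values near 0 / -1 are perpendicular / trans
    ("bad-orientated").
    """

    t: np.ndarray
    l: np.ndarray
    dot: float


def fragment_tangent(cb_positions: np.ndarray, member_index: int) -> np.ndarray:
    """Unit tangent of a surface fragment at one of its member residues.

    The fragment is the ordered list of C-beta positions of its residues.
    For three or more members a quadratic arc is fitted through the points
    (per coordinate, against the member ordinal) and differentiated at the
    requested member; for exactly two members the tangent is the chord.
    The tangent points from the N- to the C-terminal end of the fragment.
    """
    cb = np.asarray(cb_positions, dtype=float)
    m = cb.shape[0]
    if m < 2:
        raise GeometryError("fragment tangent needs at least 2 member residues")
    if m == 2:
        tangent = cb[1] - cb[0]
    else:
        s = np.arange(m, dtype=float)
        coeffs = np.polyfit(s, cb, deg=2)  # (3, 3): per-coordinate quadratic
        # derivative 2*a*s + b at the member position
        tangent = 2.0 * coeffs[0] * s[member_index] + coeffs[1]
    norm = np.linalg.norm(tangent)
    if norm < 1e-12:
        raise GeometryError("degenerate fragment: zero tangent")
    return tangent / norm


def trp_orientation(peptide, helix: HelixFrame | None = None) -> TrpOrientation:
    """Dot product ``t . l`` between fragment tangent and indole long axis.

    Requires the peptide to carry a Trp with pseudo-atoms CD1 and CH2 and a
    fragment assignment placing Trp on a nonpolar surface fragment with at
    least two members.
    """
    trp = getattr(peptide, "trp_index", None)
    if trp is None:
        raise GeometryError("peptide has no Trp residue")
    frag_id = peptide.fragment_assignment.get(trp)
    if frag_id is None:
        raise GeometryError("Trp is not assigned to a surface fragment")
    members = sorted(r for r, f in peptide.fragment_assignment.items() if f == frag_id)
    if len(members) < 2:
        raise GeometryError("Trp fragment has fewer than 2 member residues")
    cb = np.array([peptide.coords_of("CB", r) for r in members])
    t = fragment_tangent(cb, members.index(trp))
    try:
        cd1 = peptide.coords_of("CD1", trp)
        ch2 = peptide.coords_of("CH2", trp)
    except KeyError as exc:
        raise GeometryError(f"missing Trp indole atom: {exc}") from exc
    l = ch2 - cd1
    norm = np.linalg.norm(l)
    if norm < 1e-12:
        raise GeometryError("degenerate indole axis (CD1 == CH2)")
    l = l / norm
    return TrpOrientation(t=t, l=l, dot=float(np.dot(t, l)))


def rotate_about_axis(coords: np.ndarray, frame: HelixFrame, angle_deg: float) -> np.ndarray:
    """Rotate coordinates about the helix axis through its centroid.

    Positive angles follow the right-hand rule about the oriented axis,
    which *increases* theta by the same amount.  To rotate in an
    enantiomer's adsorption sense (L: theta decreasing, D: increasing) use
    :func:`rotate_in_adsorption_sense`.
    """
    a = frame.axis
    ang = np.radians(angle_deg)
    c, s = np.cos(ang), np.sin(ang)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    rot = np.eye(3) + s * k + (1 - c) * (k @ k)  # Rodrigues
    rel = np.asarray(coords, dtype=float) - frame.centroid
    return rel @ rot.T + frame.centroid


def rotate_in_adsorption_sense(coords: np.ndarray, frame: HelixFrame, chirality: str,
                               angle_deg: float) -> np.ndarray:
    """Rotate by ``angle_deg`` in the chirality's adsorption rotation sense."""
    sense = -1.0 if chirality == "L" else 1.0
    if chirality not in ("L", "D"):
        raise ValueError(f"unknown chirality {chirality!r}")
    return rotate_about_axis(coords, frame, sense * angle_deg)
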