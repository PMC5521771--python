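"""Rigid-monomer geometry for the one-site-per-monomer chain model.

Each pyranose monomer is treated as a rigid body in the ideal ⁴C₁ chair.
The only atoms retained are those needed to define the two glycosidic
dihedrals of a (1→4) link plus the ring atoms used to place the single
coarse-grained interaction site (the ring geometric center):

* ring atoms C1, C2, C3, C4, C5, O5 on an ideal chair,
* the exocyclic glycosidic oxygen attached equatorially at C1,
* the equatorial attachment direction for the incoming glycosidic
  oxygen at C4.

Dihedral convention (heavy-atom IUPAC-style for a (1→4) link between
monomer i and monomer i+1):

    phi = O5(i)  - C1(i) - O - C4(i+1)
    psi = C1(i)  - O     - C4(i+1) - C5(i+1)

All bond lengths, bond angles and ring torsions are constants of this
module; the virtual-bond length ``l`` between successive ring centers is
*derived* from forward reconstruction, never set independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

# bond lengths in nm; angles in radians
RING_BOND_LENGTH = 0.1513       # mean endocyclic C-C / C-O bond
RING_BOND_ANGLE = np.deg2rad(111.0)
C1_O_BOND = 0.1414              # anomeric C1 - glycosidic O
O_C4_BOND = 0.1426              # glycosidic O - C4'
GLYCOSIDIC_ANGLE = np.deg2rad(116.0)   # C1 - O - C4'
EXOCYCLIC_ANGLE = np.deg2rad(109.5)    # ring-C - C - O substituent

RING_ATOMS = ("C1", "C2", "C3", "C4", "C5", "O5")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _cross3(a, b):
    """3-vector cross product without numpy's generic-axis overhead."""
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _unit3(v):
    n = np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    return v / n


def _chair_ring(bond: float, angle: float) -> np.ndarray:
    """Ideal chair: six atoms alternating above/below a hexagonal ring.

    Atom k sits at (R cos 60k°, R sin 60k°, ±h); R and h are solved so
    adjacent atoms are ``bond`` apart and the internal angle is ``angle``.
    """

    def ring(h: float) -> np.ndarray:
        r2 = bond * bond - 4.0 * h * h
        radius = np.sqrt(max(r2, 1e-12))
        th = np.deg2rad(60.0 * np.arange(6))
        pts = np.column_stack(
            [radius * np.cos(th), radius * np.sin(th), h * (-1.0) ** np.arange(6)]
        )
        return pts

    def angle_err(h: float) -> float:
        pts = ring(h)
        v1 = pts[0] - pts[1]
        v2 = pts[2] - pts[1]
        cosa = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return np.arccos(cosa) - angle

    h = brentq(angle_err, 1e-6, bond / 2 - 1e-6)
    return ring(h)


def _substituent_direction(
    center: np.ndarray, nb1: np.ndarray, nb2: np.ndarray, angle: float
) -> np.ndarray:
    """Unit vector from ``center`` making ``angle`` with both ring bonds.

    Two solutions exist (axial and equatorial); the equatorial one —
    smaller out-of-ring-plane component — is returned, as appropriate for
    the 1e,4e substituents of a β-D-pyranose.
    """
    u = _unit(nb1 - center)
    v = _unit(nb2 - center)
    c = np.cos(angle)
    uv = u @ v
    # w = a u + b v ± c3 n  with  w·u = w·v = cos(angle)
    a = b = c / (1.0 + uv)
    n = _unit(np.cross(u, v))
    planar = a * u + b * v
    c3sq = 1.0 - planar @ planar
    c3 = np.sqrt(max(c3sq, 0.0))
    w_plus = planar + c3 * n
    w_minus = planar - c3 * n
    # equatorial: smaller |z| (ring axis is z in the template frame)
    return w_plus if abs(w_plus[2]) < abs(w_minus[2]) else w_minus


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom D from A, B, C so that |CD| = bond, angle(B,C,D) = angle
    and dihedral(A,B,C,D) = torsion (natural-extension reference frame)."""
    bc = _unit3(c - b)
    n = _unit3(_cross3(b - a, bc))
    m = _cross3(n, bc)
    x = -bond * np.cos(angle)
    y = -bond * np.sin(angle) * np.cos(torsion)
    z = -bond * np.sin(angle) * np.sin(torsion)
    return c + x * bc + y * m + z * n


def dihedral_angle(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Signed dihedral of the four points, wrapped to [0, 2π)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = _unit(b1)
    v = b0 - (b0 @ b1u) * b1u
    w = b2 - (b2 @ b1u) * b1u
    x = v @ w
    y = np.cross(b1u, v) @ w
    return float(np.arctan2(y, x) % (2.0 * np.pi))


def _frame_from_points(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray):
    """Orthonormal frame (3x3 columns) + origin from three points."""
    e1 = _unit3(p2 - p1)
    d = p3 - p1
    e2 = _unit3(d - (d @ e1) * e1)
    e3 = _cross3(e1, e2)
    out = np.empty((3, 3))
    out[:, 0] = e1
    out[:, 1] = e2
    out[:, 2] = e3
    return out, p1


def superpose(template_pts: np.ndarray, world_pts: np.ndarray):
    """Proper rigid transform (R, t) taking 3 template points to 3 world
    points with matching internal geometry: x_world = R @ x_templ + t."""
    ft, ot = _frame_from_points(*template_pts)
    fw, ow = _frame_from_points(*world_pts)
    rot = fw @ ft.T
    return rot, ow - rot @ ot


@dataclass(frozen=True)
class GeometryParams:
    """Template coordinates of the retained atoms (monomer body frame).

    ``atoms`` maps atom name -> position (nm); ``o_glyc`` is the exocyclic
    glycosidic oxygen bonded to C1, ``o4_attach`` the position the incoming
    glycosidic oxygen occupies relative to C4. ``ring_center`` is the mean
    of the six ring atoms and is the coarse-grained interaction site.
    """

    atoms: dict = field(default_factory=dict)
    o_glyc: np.ndarray = None
    o4_attach: np.ndarray = None
    ring_center: np.ndarray = None
    # link internals derived from the template
    theta_o_c4_c5: float = 0.0

    @classmethod
    def ideal_pyranose(cls) -> "GeometryParams":
        ring = _chair_ring(RING_BOND_LENGTH, RING_BOND_ANGLE)
        atoms = {name: ring[i] for i, name in enumerate(RING_ATOMS)}
        # exocyclic O at C1 (ring neighbors O5 and C2)
        w1 = _substituent_direction(
            atoms["C1"], atoms["O5"], atoms["C2"], EXOCYCLIC_ANGLE
        )
        o_glyc = atoms["C1"] + C1_O_BOND * w1
        # incoming glycosidic O attachment at C4 (ring neighbors C3 and C5)
        w4 = _substituent_direction(
            atoms["C4"], atoms["C3"], atoms["C5"], EXOCYCLIC_ANGLE
        )
        o4 = atoms["C4"] + O_C4_BOND * w4
        center = ring.mean(axis=0)
        theta = float(
            np.arccos(
                _unit(o4 - atoms["C4"]) @ _unit(atoms["C5"] - atoms["C4"])
            )
        )
        self = cls(
            atoms=atoms,
            o_glyc=o_glyc,
            o4_attach=o4,
            ring_center=center,
            theta_o_c4_c5=theta,
        )
        return self

    def __post_init__(self):
        if not self.atoms:
            return
        # cached pieces of the per-link kinematic step
        up = np.column_stack(
            [self.atoms["O5"], self.atoms["C1"], self.o_glyc]
        )
        object.__setattr__(self, "_upstream_templ", up)
        object.__setattr__(
            self,
            "_downstream_frame",
            _frame_from_points(
                self.o4_attach, self.atoms["C4"], self.atoms["C5"]
            ),
        )

    def next_frame(
        self,
        rot: np.ndarray,
        trans: np.ndarray,
        phi: float,
        psi: float,
    ):
        """Frame of monomer i+1 given monomer i's frame and the link dihedrals."""
        upstream = rot @ self._upstream_templ + trans[:, None]
        o5, c1, o = upstream[:, 0], upstream[:, 1], upstream[:, 2]
        c4 = place_atom(o5, c1, o, O_C4_BOND, GLYCOSIDIC_ANGLE, phi)
        c5 = place_atom(
            c1, o, c4, RING_BOND_LENGTH, self.theta_o_c4_c5, psi
        )
        ft, ot = self._downstream_frame
        fw, ow = _frame_from_points(o, c4, c5)
        new_rot = fw @ ft.T
        return new_rot, ow - new_rot @ ot

    def link_dihedrals(self, rot_i, trans_i, rot_j, trans_j):
        """Measure (phi, psi) of the link between two placed monomers."""
        o5 = rot_i @ self.atoms["O5"] + trans_i
        c1 = rot_i @ self.atoms["C1"] + trans_i
        o = rot_i @ self.o_glyc + trans_i
        c4 = rot_j @ self.atoms["C4"] + trans_j
        c5 = rot_j @ self.atoms["C5"] + trans_j
        return dihedral_angle(o5, c1, o, c4), dihedral_angle(c1, o, c4, c5)
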