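"""Monomer sequences and rigid-geometry chain conformations.

A chitosan chain of DP monomers is an ordered sequence of GlcNAc
(acetylated, never charged) and GlcN (titratable: neutral GlcNH2 or
protonated GlcNH3+) units.  The geometry of every monomer is the rigid
ideal pyranose of :mod:`chitosim.geometry`; the chain's only degrees of
freedom are the DP−1 glycosidic dihedral pairs (φ_i, ψ_i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import GeometryParams
from .pmf_maps import GLCNAC, GLCNH2, GLCNH3

TWO_PI = 2.0 * math.pi

KIND_GLCNAC = "GlcNAc"
KIND_GLCN = "GlcN"


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class MonomerState:
    kind: str
    z: int
    index: int

    def __post_init__(self):
        if self.kind == KIND_GLCNAC and self.z != 0:
            raise ValueError("GlcNAc cannot carry charge")
        if self.z not in (0, 1):
            raise ValueError("charge must be 0 or 1")


def state_label(kind: str, z: int) -> str:
    """Map (kind, charge) to the three-state monomer label."""
    if kind == KIND_GLCNAC:
        return GLCNAC
    return GLCNH3 if z else GLCNH2


@dataclass
class PolymerSequence:
    """Ordered monomer kinds plus live charge states.

    ``is_glcn[i]`` marks titratable monomers; ``charges[i]`` is z_i
    (GlcNAc entries are always 0).
    """

    is_glcn: np.ndarray
    charges: np.ndarray
    pattern: str
    dd: float
    seed: int | None = None

    @property
    def dp(self) -> int:
        return self.is_glcn.size

    @property
    def n_t(self) -> int:
        return int(self.is_glcn.sum())

    @property
    def titratable_indices(self) -> np.ndarray:
        return np.nonzero(self.is_glcn)[0]

    def monomer(self, i: int) -> MonomerState:
        kind = KIND_GLCN if self.is_glcn[i] else KIND_GLCNAC
        return MonomerState(kind, int(self.charges[i]), i)

    def label(self, i: int) -> str:
        if not self.is_glcn[i]:
            return GLCNAC
        return GLCNH3 if self.charges[i] else GLCNH2

    def link_key(self, i: int) -> tuple:
        """Link i joins monomers i (C1 side) and i+1 (C4 side)."""
        return (self.label(i), self.label(i + 1))

    def kind_string(self) -> str:
        return "".join("A" if g else "D" for g in self.is_glcn)

    def copy(self) -> "PolymerSequence":
        return PolymerSequence(
            self.is_glcn.copy(), self.charges.copy(), self.pattern, self.dd, self.seed
        )


def build_sequence(
    dp: int, dd: float, pattern: str = "random", seed: int | None = None
) -> PolymerSequence:
    """Build a sequence of ``dp`` monomers with deacetylation ``dd``.

    Patterns: ``random`` (GlcNAc positions drawn uniformly without
    replacement, count = round((1−DD)·DP, half-up)), ``alternating``
    ([GlcN, GlcNAc] tiling), ``block<k>`` (k GlcN then k GlcNAc,
    repeated), or an explicit string of A (GlcN) / D (GlcNAc).
    Deterministic given the seed.  Charges start at zero.
    """
    if dp < 2:
        raise ValueError("DP must be at least 2")
    if not 0.0 <= dd <= 1.0:
        raise ValueError("DD must lie in [0, 1]")

    if pattern and set(pattern) <= {"A", "D"}:
        if len(pattern) != dp:
            raise ValueError("explicit pattern length must equal DP")
        is_glcn = np.array([c == "A" for c in pattern])
        dd_eff = is_glcn.mean()
        return PolymerSequence(is_glcn, np.zeros(dp, dtype=np.int8), "explicit", dd_eff, seed)

    n_ac = round_half_up((1.0 - dd) * dp)
    if pattern == "random":
        rng = np.random.default_rng(seed)
        is_glcn = np.ones(dp, dtype=bool)
        if n_ac:
            pos = rng.choice(dp, size=n_ac, replace=False)
            is_glcn[pos] = False
    elif pattern == "alternating" or pattern.startswith("block"):
        k = 1 if pattern == "alternating" else int(pattern[5:] or 1)
        if k < 1:
            raise ValueError("block size must be >= 1")
        tile = np.concatenate([np.ones(k, dtype=bool), np.zeros(k, dtype=bool)])
        is_glcn = np.resize(tile, dp)
        n_ac_tiled = int((~is_glcn).sum())
        if n_ac_tiled != n_ac:
            nearest = 1.0 - n_ac_tiled / dp
            raise ValueError(
                f"DD={dd} not representable by {pattern} tiling at DP={dp}; "
                f"nearest representable DD is {nearest:.4f}"
            )
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return PolymerSequence(is_glcn, np.zeros(dp, dtype=np.int8), pattern, dd, seed)


# ---------------------------------------------------------------------------
# Conformation
# ---------------------------------------------------------------------------

def _orthonormalize(a: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) (Gram-Schmidt on the columns).

    The downstream-segment rotation of a pivot move is composed from the
    old and new link frames; without this projection their rounding
    errors feed back into later compositions and grow geometrically.
    """
    from .geometry import _cross3, _unit3

    u0 = _unit3(a[:, 0])
    v1 = a[:, 1] - (a[:, 1] @ u0) * u0
    u1 = _unit3(v1)
    out = np.empty((3, 3))
    out[:, 0] = u0
    out[:, 1] = u1
    out[:, 2] = _cross3(u0, u1)
    return out

class Conformation:
    """Chain coordinates as a deterministic function of the dihedrals.

    Maintains per-monomer rigid frames (rotation ``rots[i]``, origin
    ``trans[i]``), the coarse-grained site positions (ring centers) and
    the dihedral list.  ``pivot_update`` applies the downstream rigid
    rotation of a pivot move in O(DP − i) vectorized work and is exactly
    equivalent to a full rebuild.
    """

    def __init__(
        self,
        dp: int,
        dihedrals: np.ndarray,
        geometry: GeometryParams | None = None,
    ):
        if dihedrals.shape != (dp - 1, 2):
            raise ValueError("need one (phi, psi) pair per link")
        self.dp = dp
        self.geometry = geometry or GeometryParams.ideal_pyranose()
        self.dihedrals = np.mod(np.asarray(dihedrals, dtype=float), TWO_PI)
        self.rots = np.empty((dp, 3, 3))
        self.trans = np.empty((dp, 3))
        self.sites = np.empty((dp, 3))
        self.rebuild()

    # -- construction --------------------------------------------------------
    def rebuild(self, from_link: int = 0):
        geo = self.geometry
        if from_link == 0:
            self.rots[0] = np.eye(3)
            self.trans[0] = 0.0
            self.sites[0] = geo.ring_center
        for i in range(from_link, self.dp - 1):
            phi, psi = self.dihedrals[i]
            rot, tr = geo.next_frame(self.rots[i], self.trans[i], phi, psi)
            self.rots[i + 1] = rot
            self.trans[i + 1] = tr
            self.sites[i + 1] = rot @ geo.ring_center + tr

    def pivot_update(self, link: int, phi: float, psi: float):
        """Set link ``link`` to (phi, psi), rigidly moving the downstream
        segment; monomers 0..link are untouched."""
        if not 0 <= link < self.dp - 1:
            raise IndexError("link index out of range")
        geo = self.geometry
        j = link + 1
        old_rot = self.rots[j].copy()
        old_tr = self.trans[j].copy()
        new_rot, new_tr = geo.next_frame(
            self.rots[link], self.trans[link], phi % TWO_PI, psi % TWO_PI
        )
        a = _orthonormalize(new_rot @ old_rot.T)
        self.rots[j:] = np.einsum("ab,nbc->nac", a, self.rots[j:])
        self.trans[j:] = (self.trans[j:] - old_tr) @ a.T + new_tr
        self.sites[j:] = (self.sites[j:] - old_tr) @ a.T + new_tr
        self.dihedrals[link] = (phi % TWO_PI, psi % TWO_PI)

    def copy(self) -> "Conformation":
        c = object.__new__(Conformation)
        c.dp = self.dp
        c.geometry = self.geometry
        c.dihedrals = self.dihedrals.copy()
        c.rots = self.rots.copy()
        c.trans = self.trans.copy()
        c.sites = self.sites.copy()
        return c

    # -- measurement ---------------------------------------------------------
    def atom_positions(self):
        """World positions of the retained atoms, one dict per monomer."""
        geo = self.geometry
        out = []
        for i in range(self.dp):
            d = {
                name: self.rots[i] @ pos + self.trans[i]
                for name, pos in geo.atoms.items()
            }
            d["O1"] = self.rots[i] @ geo.o_glyc + self.trans[i]
            out.append(d)
        return out

    def measured_dihedrals(self) -> np.ndarray:
        geo = self.geometry
        out = np.empty((self.dp - 1, 2))
        for i in range(self.dp - 1):
            out[i] = geo.link_dihedrals(
                self.rots[i], self.trans[i], self.rots[i + 1], self.trans[i + 1]
            )
        return out

    def bond_vectors(self) -> np.ndarray:
        """Virtual bonds between successive ring-center sites."""
        return np.diff(self.sites, axis=0)

    @property
    def bond_length(self) -> float:
        return float(np.linalg.norm(self.bond_vectors(), axis=1).mean())

    @property
    def contour_length(self) -> float:
        return (self.dp - 1) * self.bond_length

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.sites[-1] - self.sites[0]))


def minimum_energy_conformation(sequence, library, geometry=None) -> Conformation:
    """All links at their map's global minimum (the initial MC state)."""
    from .pmf_maps import find_minima

    dih = np.empty((sequence.dp - 1, 2))
    cache = {}
    for i in range(sequence.dp - 1):
        key = sequence.link_key(i)
        if key not in cache:
            mins = find_minima(library.map_for_link(*key))
            cache[key] = mins[0][:2] if mins else (0.0, 0.0)
        dih[i] = cache[key]
    return Conformation(sequence.dp, dih, geometry)
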