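"""Glycosidic (φ, ψ) free-energy maps.

A chitosan chain has three monomer states — acetylated GlcNAc, neutral
GlcNH2 and protonated GlcNH3+ — so a glycosidic link comes in nine
flavours keyed by the ordered pair of monomer states at its two ends
(first label: the monomer contributing its anomeric C1; second: the
monomer contributing C4).  Each flavour carries a two-dimensional free
energy surface over the link dihedrals, periodic on [0, 2π)², stored on
a regular grid of cell-centered bins in units of k_BT and normalized so
the global minimum is exactly zero.

Maps can be loaded from text files (3-column ``phi psi G`` triples or a
dense matrix with a one-line header) or generated synthetically from
well positions/depths; the bundled nine-map library is synthesized from
the published map-feature statistics (main-minimum position, depth gap
ΔG₂ to the second minimum, accessible-area fractions) with basin widths
calibrated numerically to reproduce the printed area fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq

TWO_PI = 2.0 * np.pi

GLCNAC = "GlcNAc"
GLCNH2 = "GlcNH2"
GLCNH3 = "GlcNH3+"
MONOMER_STATES = (GLCNAC, GLCNH2, GLCNH3)

DEFAULT_GRID = 200
DEFAULT_CUTOFF = 7.0  # k_BT restriction for pivot proposals

#: Published per-link map features used to parameterize the synthetic
#: library: (area ≤ 12 k_BT %, area < 1 k_BT %, φ_min rad, ψ_min rad,
#: ΔG₂ k_BT).  Keys are (C1-side state, C4-side state).
MAP_FEATURE_TABLE = {
    (GLCNAC, GLCNAC): (29.8, 0.61, 4.956, 2.180, 2.4),
    (GLCNAC, GLCNH2): (27.4, 0.50, 4.933, 2.198, 3.0),
    (GLCNAC, GLCNH3): (21.7, 0.53, 4.9747, 2.214, 3.7),
    (GLCNH2, GLCNAC): (28.0, 0.87, 4.953, 2.05, 2.6),
    (GLCNH2, GLCNH2): (28.4, 0.55, 4.997, 2.188, 4.0),
    (GLCNH2, GLCNH3): (26.6, 0.68, 5.037, 2.209, 3.4),
    (GLCNH3, GLCNAC): (25.6, 0.54, 5.11, 2.216, 1.35),
    (GLCNH3, GLCNH2): (25.2, 0.49, 5.1287, 2.1736, 2.2),
    (GLCNH3, GLCNH3): (19.3, 0.60, 5.12, 2.186, 3.6),
}

KBT_KJMOL_298 = 2.4790  # k_B * 298 K, for converting kJ/mol map files


class MapFormatError(ValueError):
    """Raised for malformed or structurally inconsistent map files."""


# ---------------------------------------------------------------------------
# DihedralMap
# ---------------------------------------------------------------------------

@dataclass
class DihedralMap:
    """Periodic free-energy grid over (φ, ψ) for one link type.

    ``grid[i, j]`` is the free energy (k_BT) at the center of the cell
    φ ∈ [iΔ, (i+1)Δ), ψ ∈ [jΔ', (j+1)Δ'); the map is normalized so
    ``grid.min() == 0`` and ``offset`` records the subtracted constant.
    """

    grid: np.ndarray
    link_key: tuple | None = None
    offset: float = 0.0
    interpolation: str = "bilinear"  # or "nearest" (piecewise constant)
    _interp: RegularGridInterpolator | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2:
            raise MapFormatError("map grid must be 2-D")
        if not np.all(np.isfinite(g)):
            raise MapFormatError("map grid contains non-finite energies")
        gmin = g.min()
        self.offset = float(self.offset + gmin)
        self.grid = g - gmin
        self._interp = None

    # -- geometry of the grid ------------------------------------------------
    @property
    def n_phi(self) -> int:
        return self.grid.shape[0]

    @property
    def n_psi(self) -> int:
        return self.grid.shape[1]

    @property
    def bin_widths(self) -> tuple:
        return TWO_PI / self.n_phi, TWO_PI / self.n_psi

    def bin_centers(self):
        dphi, dpsi = self.bin_widths
        return (
            (np.arange(self.n_phi) + 0.5) * dphi,
            (np.arange(self.n_psi) + 0.5) * dpsi,
        )

    # -- evaluation ----------------------------------------------------------
    def _build_interp(self):
        # ghost-pad one cell on each side so bilinear interpolation wraps
        dphi, dpsi = self.bin_widths
        phi_c, psi_c = self.bin_centers()
        phi_ext = np.concatenate([[phi_c[0] - dphi], phi_c, [phi_c[-1] + dphi]])
        psi_ext = np.concatenate([[psi_c[0] - dpsi], psi_c, [psi_c[-1] + dpsi]])
        g = np.pad(self.grid, 1, mode="wrap")
        self._interp = RegularGridInterpolator(
            (phi_ext, psi_ext), g, method="linear", bounds_error=True
        )

    def energy(self, phi, psi):
        """Interpolated free energy (k_BT) at continuous angles (periodic)."""
        phi = np.mod(phi, TWO_PI)
        psi = np.mod(psi, TWO_PI)
        if self.interpolation == "nearest":
            i = np.minimum((phi / self.bin_widths[0]).astype(int), self.n_phi - 1)
            j = np.minimum((psi / self.bin_widths[1]).astype(int), self.n_psi - 1)
            return self.grid[i, j]
        if self._interp is None:
            self._build_interp()
        pts = np.stack(np.broadcast_arrays(phi, psi), axis=-1)
        out = self._interp(pts)
        return out if out.ndim else float(out)

    def energy_scalar(self, phi: float, psi: float) -> float:
        """Fast scalar periodic bilinear lookup (hot path of the MC loop)."""
        if self.interpolation == "nearest":
            i = int((phi % TWO_PI) / TWO_PI * self.n_phi) % self.n_phi
            j = int((psi % TWO_PI) / TWO_PI * self.n_psi) % self.n_psi
            return float(self.grid[i, j])
        n, m = self.n_phi, self.n_psi
        x = (phi % TWO_PI) / TWO_PI * n - 0.5
        y = (psi % TWO_PI) / TWO_PI * m - 0.5
        i0 = math.floor(x)
        j0 = math.floor(y)
        fx = x - i0
        fy = y - j0
        i0 %= n
        j0 %= m
        i1 = (i0 + 1) % n
        j1 = (j0 + 1) % m
        g = self.grid
        return float(
            (1 - fx) * ((1 - fy) * g[i0, j0] + fy * g[i0, j1])
            + fx * ((1 - fy) * g[i1, j0] + fy * g[i1, j1])
        )


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------

def _parse_triples(lines, path):
    rows = []
    for ln, line in lines:
        parts = line.replace(",", " ").split()
        if len(parts) != 3:
            raise MapFormatError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise MapFormatError(f"{path}:{ln}: malformed row: {line!r}") from exc
    arr = np.array(rows)
    phis = np.unique(arr[:, 0])
    psis = np.unique(arr[:, 1])
    if phis.size * psis.size != arr.shape[0]:
        raise MapFormatError(f"{path}: (phi, psi) points do not form a rectangular grid")
    grid = np.full((phis.size, psis.size), np.nan)
    iph = np.searchsorted(phis, arr[:, 0])
    ips = np.searchsorted(psis, arr[:, 1])
    grid[iph, ips] = arr[:, 2]
    if np.isnan(grid).any():
        raise MapFormatError(f"{path}: duplicate or missing grid points")
    return phis, psis, grid


def _resample_periodic(phis, psis, grid, n_out):
    """Periodic bilinear resampling onto the canonical cell-centered grid."""
    src = DihedralMap(grid, interpolation="bilinear")
    # source axes may be arbitrary within one period: build interpolator in
    # the source's own coordinates, with wrap padding
    dphi = phis[1] - phis[0] if phis.size > 1 else TWO_PI
    dpsi = psis[1] - psis[0] if psis.size > 1 else TWO_PI
    phi_ext = np.concatenate([[phis[0] - dphi], phis, [phis[-1] + dphi]])
    psi_ext = np.concatenate([[psis[0] - dpsi], psis, [psis[-1] + dpsi]])
    g = np.pad(grid, 1, mode="wrap")
    interp = RegularGridInterpolator(
        (phi_ext, psi_ext), g, method="linear", bounds_error=False, fill_value=None
    )
    out_phi = (np.arange(n_out) + 0.5) * TWO_PI / n_out
    out_psi = (np.arange(n_out) + 0.5) * TWO_PI / n_out
    # shift target angles into the source window [phis[0]-dphi/?, ...+period)
    p0 = phis[0]
    q0 = psis[0]
    op = np.mod(out_phi - p0, TWO_PI) + p0
    oq = np.mod(out_psi - q0, TWO_PI) + q0
    pp, qq = np.meshgrid(op, oq, indexing="ij")
    del src
    return interp(np.stack([pp, qq], axis=-1))


def load_map(path, link_key=None, grid_spec=DEFAULT_GRID) -> DihedralMap:
    """Read a map file (auto-detected dialect) onto the canonical grid.

    Dialects: 3-column whitespace/comma-separated ``phi psi G`` triples in
    radians, or a dense matrix preceded by a one-line header
    ``# phi <lo> <hi> psi <lo> <hi> [kJ/mol]``.  Angles on [−π, π) are
    shifted to [0, 2π); energies declared in kJ/mol are converted to k_BT
    at 298 K.
    """
    with open(path) as fh:
        raw = fh.readlines()

    unit_kjmol = False
    header = None
    data_lines = []
    for ln, line in enumerate(raw, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if "kJ/mol" in s:
                unit_kjmol = True
            if header is None and ("phi" in s and "psi" in s):
                toks = s.lstrip("#").split()
                try:  # a dense-matrix header carries numeric axis ranges
                    ip, iq = toks.index("phi"), toks.index("psi")
                    float(toks[ip + 1]), float(toks[ip + 2])
                    float(toks[iq + 1]), float(toks[iq + 2])
                    header = s
                except (ValueError, IndexError):
                    pass
            continue
        data_lines.append((ln, s))
    if not data_lines:
        raise MapFormatError(f"{path}: no data rows")

    first_cols = len(data_lines[0][1].replace(",", " ").split())
    if first_cols == 3 and header is None:
        phis, psis, grid = _parse_triples(data_lines, path)
    else:
        if header is None:
            raise MapFormatError(
                f"{path}: dense-matrix dialect requires a '# phi lo hi psi lo hi' header"
            )
        toks = header.lstrip("#").split()
        try:
            ip = toks.index("phi")
            iq = toks.index("psi")
            phi_lo, phi_hi = float(toks[ip + 1]), float(toks[ip + 2])
            psi_lo, psi_hi = float(toks[iq + 1]), float(toks[iq + 2])
        except (ValueError, IndexError) as exc:
            raise MapFormatError(f"{path}: unparseable header {header!r}") from exc
        rows = []
        width = None
        for ln, s in data_lines:
            parts = s.replace(",", " ").split()
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise MapFormatError(f"{path}:{ln}: ragged matrix row")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise MapFormatError(f"{path}:{ln}: malformed row") from exc
        grid = np.array(rows)
        n_phi, n_psi = grid.shape
        phis = phi_lo + (np.arange(n_phi) + 0.5) * (phi_hi - phi_lo) / n_phi
        psis = psi_lo + (np.arange(n_psi) + 0.5) * (psi_hi - psi_lo) / n_psi

    if unit_kjmol:
        grid = grid / KBT_KJMOL_298

    # shift a [-pi, pi) axis convention to [0, 2pi)
    if phis.min() < 0 or psis.min() < 0:
        order_p = np.argsort(np.mod(phis, TWO_PI))
        order_q = np.argsort(np.mod(psis, TWO_PI))
        phis = np.mod(phis, TWO_PI)[order_p]
        psis = np.mod(psis, TWO_PI)[order_q]
        grid = grid[np.ix_(order_p, order_q)]

    if grid.shape != (grid_spec, grid_spec):
        grid = _resample_periodic(phis, psis, grid, grid_spec)
    return DihedralMap(grid, link_key=link_key)


def write_map(path, dmap: DihedralMap):
    """Write a map as 3-column triples (round-trips through load_map)."""
    phi_c, psi_c = dmap.bin_centers()
    with open(path, "w") as fh:
        fh.write("# phi(rad) psi(rad) G(kBT)\n")
        for i, p in enumerate(phi_c):
            for j, q in enumerate(psi_c):
                fh.write(f"{p:.10f} {q:.10f} {dmap.grid[i, j]:.8f}\n")


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Well:
    """A periodic Gaussian basin: bottom at ``background - depth``."""

    phi: float
    psi: float
    depth: float
    width_phi: float
    width_psi: float


def _angdiff(a, b):
    return (a - b + np.pi) % TWO_PI - np.pi


def synthesize_map(
    wells, background: float, grid_spec: int = DEFAULT_GRID, link_key=None
) -> DihedralMap:
    """Compose periodic Gaussian basins on a flat background.

    The surface is a soft minimum,
    ``G = -ln( e^{-B} + Σ_w e^{-(B - depth_w) - d_w²/2} )``,
    where d_w is the periodic Mahalanobis distance to well w, so each well
    bottom sits ``depth_w`` below the background plateau B.  The result is
    normalized to min = 0.
    """
    wells = [w if isinstance(w, Well) else Well(*w) for w in wells]
    if not wells:
        raise ValueError("at least one well is required")
    for w in wells:
        if w.depth <= 0 or w.width_phi <= 0 or w.width_psi <= 0:
            raise ValueError("well depths and widths must be positive")
        if background < w.depth:
            raise ValueError("background must be >= the deepest well")
    dphi = TWO_PI / grid_spec
    phi_c = (np.arange(grid_spec) + 0.5) * dphi
    psi_c = (np.arange(grid_spec) + 0.5) * dphi
    pp, qq = np.meshgrid(phi_c, psi_c, indexing="ij")
    boltz = np.full_like(pp, np.exp(-background))
    for w in wells:
        d2 = (
            (_angdiff(pp, w.phi) / w.width_phi) ** 2
            + (_angdiff(qq, w.psi) / w.width_psi) ** 2
        )
        boltz += np.exp(-(background - w.depth) - 0.5 * d2)
    dmap = DihedralMap(-np.log(boltz), link_key=link_key)
    centers = {(round(w.phi, 6), round(w.psi, 6)) for w in wells}
    if len(find_minima(dmap)) < len(centers):
        warnings.warn("overlapping wells merged into a single minimum", stacklevel=2)
    return dmap


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

@dataclass
class MapFeatures:
    minima: list
    delta_g2: float | None
    area_12kt: float
    area_1kt: float


def find_minima(dmap: DihedralMap):
    """Local minima (strictly below all 8 periodic neighbours).

    Positions are refined below bin resolution by a separable quadratic
    fit through the minimum bin and its axial neighbours.  A flat map has
    no strict minimum and yields an empty list.
    """
    g = dmap.grid
    if np.ptp(g) == 0.0:
        warnings.warn("flat map: no minima", stacklevel=2)
        return []
    is_min = np.ones_like(g, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_min &= g < np.roll(np.roll(g, di, axis=0), dj, axis=1)
    out = []
    dphi, dpsi = dmap.bin_widths
    phi_c, psi_c = dmap.bin_centers()
    for i, j in zip(*np.nonzero(is_min)):
        gm = g[i, j]
        gl = g[(i - 1) % dmap.n_phi, j]
        gr = g[(i + 1) % dmap.n_phi, j]
        gd = g[i, (j - 1) % dmap.n_psi]
        gu = g[i, (j + 1) % dmap.n_psi]
        di_ = 0.5 * (gl - gr) / (gl - 2 * gm + gr) if gl - 2 * gm + gr > 0 else 0.0
        dj_ = 0.5 * (gd - gu) / (gd - 2 * gm + gu) if gd - 2 * gm + gu > 0 else 0.0
        phi = (phi_c[i] + di_ * dphi) % TWO_PI
        psi = (psi_c[j] + dj_ * dpsi) % TWO_PI
        g_ref = gm
        if gl - 2 * gm + gr > 0:
            g_ref -= 0.125 * (gl - gr) ** 2 / (gl - 2 * gm + gr)
        if gd - 2 * gm + gu > 0:
            g_ref -= 0.125 * (gd - gu) ** 2 / (gd - 2 * gm + gu)
        out.append((float(phi), float(psi), float(g_ref)))
    out.sort(key=lambda t: t[2])
    return out


def _merge_levels(dmap: DihedralMap, minima_bins):
    """Watershed merge level of each local-minimum bin (union-find over
    bins sorted by energy); used to decide whether two minima are distinct."""
    g = dmap.grid
    n, m = g.shape
    order = np.argsort(g, axis=None, kind="stable")
    parent = np.full(n * m, -1, dtype=np.int64)
    comp_min = {}
    merge_level = {}
    min_set = {i * m + j for i, j in minima_bins}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    flat_g = g.ravel()
    for idx in order:
        i, j = divmod(int(idx), m)
        parent[idx] = idx
        comp_min[idx] = idx
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nb = ((i + di) % n) * m + ((j + dj) % m)
            if parent[nb] == -1:
                continue
            ra, rb = find(idx), find(nb)
            if ra == rb:
                continue
            # keep the deeper component's minimum
            if flat_g[comp_min[ra]] > flat_g[comp_min[rb]]:
                ra, rb = rb, ra
            # rb's minimum dies here
            dead = comp_min[rb]
            if dead in min_set and dead not in merge_level:
                merge_level[dead] = flat_g[idx]
            parent[rb] = ra
    return merge_level


def distinct_minima(dmap: DihedralMap, min_saddle: float | None = None):
    """Minima separated by a saddle at least ``min_saddle`` above both
    (default: one bin-level of energy resolution, suppressing grid noise)."""
    minima = find_minima(dmap)
    if len(minima) < 2:
        return minima
    g = dmap.grid
    phi_c, psi_c = dmap.bin_centers()
    dphi, dpsi = dmap.bin_widths
    bins = [
        (int(round(p / dphi - 0.5)) % dmap.n_phi, int(round(q / dpsi - 0.5)) % dmap.n_psi)
        for p, q, _ in minima
    ]
    if min_saddle is None:
        # one-bin energy scale: median absolute neighbour difference
        diff = np.abs(np.diff(g, axis=0))
        min_saddle = max(float(np.median(diff)), 1e-9)
    levels = _merge_levels(dmap, bins)
    m = dmap.n_psi
    kept = []
    for (p, q, gv), (bi, bj) in zip(minima, bins):
        flat = bi * m + bj
        lvl = levels.get(flat)
        if lvl is None:  # global minimum's component never dies
            kept.append((p, q, gv))
        elif lvl - g[bi, bj] >= min_saddle:
            kept.append((p, q, gv))
    kept.sort(key=lambda t: t[2])
    return kept


def delta_g2(dmap: DihedralMap, min_saddle: float | None = None):
    """Free-energy gap to the second distinct minimum; None if single-welled."""
    mins = distinct_minima(dmap, min_saddle)
    if len(mins) < 2:
        return None
    return mins[1][2] - mins[0][2]


def accessible_area_fraction(dmap: DihedralMap, threshold: float, strict: bool = False):
    """Fraction of grid bins with G ≤ threshold (or strictly < if requested)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if strict:
        return float(np.mean(dmap.grid < threshold))
    return float(np.mean(dmap.grid <= threshold))


def map_features(dmap: DihedralMap) -> MapFeatures:
    return MapFeatures(
        minima=distinct_minima(dmap),
        delta_g2=delta_g2(dmap),
        area_12kt=accessible_area_fraction(dmap, 12.0),
        area_1kt=accessible_area_fraction(dmap, 1.0, strict=True),
    )


# ---------------------------------------------------------------------------
# Restriction & sampling
# ---------------------------------------------------------------------------

@dataclass
class RestrictedRegion:
    """Bins of a map with G ≤ cutoff, with a uniform continuous sampler."""

    parent: tuple | None
    cutoff: float
    allowed_flat: np.ndarray
    shape: tuple
    bin_widths: tuple

    @property
    def bin_count(self) -> int:
        return int(self.allowed_flat.size)

    def sample(self, rng, size=None):
        """Uniform over allowed bins, jittered uniformly within each bin."""
        dphi, dpsi = self.bin_widths
        if size is None:
            pick = int(self.allowed_flat[rng.integers(0, self.allowed_flat.size)])
            i, j = divmod(pick, self.shape[1])
            return (i + rng.random()) * dphi, (j + rng.random()) * dpsi
        pick = self.allowed_flat[rng.integers(0, self.allowed_flat.size, size)]
        i, j = np.divmod(pick, self.shape[1])
        return (i + rng.random(size)) * dphi, (j + rng.random(size)) * dpsi

    def contains_bin(self, phi, psi):
        dphi, dpsi = self.bin_widths
        i = int(np.mod(phi, TWO_PI) / dphi) % self.shape[0]
        j = int(np.mod(psi, TWO_PI) / dpsi) % self.shape[1]
        return bool(np.isin(i * self.shape[1] + j, self.allowed_flat))


def restrict(dmap: DihedralMap, cutoff: float = DEFAULT_CUTOFF) -> RestrictedRegion:
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    allowed = np.nonzero(dmap.grid.ravel() <= cutoff)[0]
    return RestrictedRegion(
        parent=dmap.link_key,
        cutoff=cutoff,
        allowed_flat=allowed,
        shape=dmap.grid.shape,
        bin_widths=dmap.bin_widths,
    )


# ---------------------------------------------------------------------------
# Nine-map library
# ---------------------------------------------------------------------------

class MapLibraryError(KeyError):
    pass


_SYNTHETIC_MEMO: dict = {}


@dataclass
class MapLibrary:
    """The nine maps keyed by ordered (C1-side, C4-side) monomer states."""

    maps: dict
    cutoff: float = DEFAULT_CUTOFF
    _regions: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        shapes = {m.grid.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise MapFormatError(f"maps have inconsistent grid shapes: {shapes}")

    def validate_complete(self):
        missing = [
            k
            for k in (
                (a, b) for a in MONOMER_STATES for b in MONOMER_STATES
            )
            if k not in self.maps
        ]
        if missing:
            raise MapLibraryError(f"missing link maps: {missing}")

    def map_for_link(self, left_state: str, right_state: str) -> DihedralMap:
        for s in (left_state, right_state):
            if s not in MONOMER_STATES:
                raise MapLibraryError(f"unknown monomer state {s!r}")
        key = (left_state, right_state)
        try:
            return self.maps[key]
        except KeyError:
            raise MapLibraryError(f"missing link map {key}") from None

    def region_for_link(self, left_state: str, right_state: str) -> RestrictedRegion:
        key = (left_state, right_state)
        if key not in self._regions:
            self._regions[key] = restrict(self.map_for_link(*key), self.cutoff)
        return self._regions[key]

    @classmethod
    def from_manifest(cls, path, cutoff=DEFAULT_CUTOFF, grid_spec=DEFAULT_GRID):
        """Manifest: lines ``<left-state> <right-state> <map-file-path>``."""
        import os

        maps = {}
        base = os.path.dirname(os.path.abspath(path))
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                parts = s.split()
                if len(parts) != 3:
                    raise MapFormatError(f"{path}:{ln}: expected 'left right file'")
                left, right, fname = parts
                if not os.path.isabs(fname):
                    fname = os.path.join(base, fname)
                maps[(left, right)] = load_map(fname, (left, right), grid_spec)
        return cls(maps=maps, cutoff=cutoff)

    @classmethod
    def synthetic(
        cls,
        cutoff=DEFAULT_CUTOFF,
        grid_spec=DEFAULT_GRID,
        background=14.0,
        shoulder=6.0,
    ) -> "MapLibrary":
        """Nine-map library synthesized from the published feature table.

        Each map is two basins — the main minimum at the printed (φ, ψ)
        and a secondary anti-ψ basin ΔG₂ above it at (φ, ψ−π) — each a
        narrow core plus a broad shoulder ``shoulder`` k_BT up.  The core
        and shoulder widths are calibrated per link so the map reproduces
        the printed <1 k_BT and ≤12 k_BT area fractions.
        """
        memo_key = (grid_spec, background, shoulder)
        if memo_key not in _SYNTHETIC_MEMO:
            maps = {}
            for key, (a12, a1, phi0, psi0, dg2) in MAP_FEATURE_TABLE.items():
                maps[key] = _calibrated_map(
                    phi0, psi0, dg2, a12 / 100.0, a1 / 100.0,
                    background, shoulder, grid_spec, key,
                )
            _SYNTHETIC_MEMO[memo_key] = maps
        lib = cls(maps=dict(_SYNTHETIC_MEMO[memo_key]), cutoff=cutoff)
        lib.validate_complete()
        return lib


def _two_basin_map(phi0, psi0, dg2, w_core, w_broad, background, shoulder,
                   grid_spec, key=None):
    psi2 = (psi0 - np.pi) % TWO_PI
    wells = [
        Well(phi0, psi0, background, w_core, w_core),
        Well(phi0, psi0, background - shoulder, w_broad, w_broad),
        Well(phi0, psi2, background - dg2, w_core, w_core),
        Well(phi0, psi2, background - dg2 - shoulder, w_broad, w_broad),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthesize_map(wells, background, grid_spec, link_key=key)


def _calibrated_map(phi0, psi0, dg2, a12, a1, background, shoulder,
                    grid_spec, key):
    """Solve (w_core, w_broad) so the two printed area fractions match."""
    w_broad = 0.45

    def a1_err(w_core, wb):
        m = _two_basin_map(phi0, psi0, dg2, w_core, wb, background, shoulder,
                           grid_spec)
        return accessible_area_fraction(m, 1.0, strict=True) - a1

    def a12_err(wb, wc):
        m = _two_basin_map(phi0, psi0, dg2, wc, wb, background, shoulder,
                           grid_spec)
        return accessible_area_fraction(m, 12.0) - a12

    w_core = 0.2
    for _ in range(3):
        w_core = brentq(a1_err, 0.02, 0.8, args=(w_broad,), xtol=1e-4)
        w_broad = brentq(a12_err, 0.05, 1.5, args=(w_core,), xtol=1e-4)
    return _two_basin_map(phi0, psi0, dg2, w_core, w_broad, background,
                          shoulder, grid_spec, key)
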