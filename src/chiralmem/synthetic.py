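"""Ground-truth-known synthetic systems for the adsorption analysis.

Real data for this analysis would be all-atom trajectories of an
amphipathic helix (the 18-residue Arg/Leu/Trp peptide
Ac-RLLRLLLRLWRRLLRLLR-NH2, "C6", as L or D enantiomer) adsorbing onto a
POPC bilayer.  This module replaces those with generators whose ground
truth is known exactly:

* ideal alpha-helix peptide models with pseudo side chains and a rigid
  3-atom indole proxy (CG, CD1, CH2) for Trp,
* coarse pseudo-POPC bilayers (head / chiral-C2 / tail pseudo-atoms on a
  jittered lattice, two leaflets),
* analytic 2D reference free-energy surfaces over (dz, theta) with
  configurable basins and a theta-gated barrier ridge, calibrated by dense
  grid search so the minimax saddle height is exact,
* overdamped Langevin (Euler-Maruyama) kinetic traces on those surfaces,
* Metropolis-sampled harmonic umbrella windows along dz,
* frame ensembles with a Poisson-distributed number of lipid head groups
  in contact with the Trp residue (placement verified geometrically).

Units: nm, ns, degrees; energies in kBT at the surface temperature
(303.15 K default).  Every generator is seeded and bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry
from .contacts import Frame
from .kinetics import KineticTrace, TraceError
from .pmf import (DEFAULT_TEMPERATURE, UmbrellaWindow, UmbrellaWindowSet,
                  _check_overlap, minimax_on_grid)

C6_SEQUENCE = "RLLRLLLRLWRRLLRLLR"

POLAR_CHARGED = "polar_charged"
NONPOLAR = "nonpolar"

# ideal alpha-helix geometry (nm / degrees per residue)
HELIX_RISE = 0.15
HELIX_TWIST = 100.0
R_CA = 0.23
R_CB = 0.34
R_CG = 0.45
INDOLE_LENGTH = 0.55  # CD1 -> CH2 distance of the rigid indole proxy

_RESIDUE_NAMES = {"R": "ARG", "L": "LEU", "W": "TRP"}
_POLARITY = {"R": POLAR_CHARGED, "L": NONPOLAR, "W": NONPOLAR}


class UnknownResidueError(ValueError):
    """Sequence contains a residue code outside {R, L, W}."""


# ---------------------------------------------------------------------------
# peptide


@dataclass
class PeptideModel:
    """Pseudo-atomic model of an ideal helical peptide.

    Atoms are CA/CB per residue plus CG, CD1, CH2 for the single Trp; all
    atoms are heavy.  Coordinates in nm; the helix axis of a freshly built
    model runs along +x with the membrane normal along z.
    """

    sequence: str
    chirality: str
    atom_names: list
    atom_residues: np.ndarray  # 1-based residue index per atom
    elements: list
    coords: np.ndarray  # (n_atoms, 3)
    polarity_class: dict  # residue index -> POLAR_CHARGED | NONPOLAR
    trp_index: int | None
    fragment_assignment: dict  # nonpolar residue index -> fragment id

    def residue_indices(self):
        return range(1, len(self.sequence) + 1)

    def residue_name(self, residue: int) -> str:
        return _RESIDUE_NAMES[self.sequence[residue - 1]]

    def coords_of(self, atom_name: str, residue: int) -> np.ndarray:
        for i, (name, res) in enumerate(zip(self.atom_names, self.atom_residues)):
            if name == atom_name and res == residue:
                return self.coords[i]
        raise KeyError(f"atom {atom_name} of residue {residue} not present")

    def ca_coords(self) -> np.ndarray:
        sel = [i for i, n in enumerate(self.atom_names) if n == "CA"]
        order = np.argsort(self.atom_residues[sel], kind="stable")
        return self.coords[np.asarray(sel)[order]]

    def residue_heavy_coords(self, residue: int) -> np.ndarray:
        sel = self.atom_residues == residue
        return self.coords[sel]

    def heavy_coords(self) -> np.ndarray:
        return self.coords

    def com(self) -> np.ndarray:
        """Center of mass with unit pseudo-atom masses."""
        return self.coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray) -> "PeptideModel":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def translated(self, shift) -> "PeptideModel":
        return self.with_coords(self.coords + np.asarray(shift, dtype=float))

    def mirrored(self) -> "PeptideModel":
        """Mirror image through the xz plane; chirality tag flips."""
        coords = self.coords.copy()
        coords[:, 1] *= -1.0
        return replace(self, coords=coords,
                       chirality="D" if self.chirality == "L" else "L")


def wheel_angle(residue: int, twist: float = HELIX_TWIST) -> float:
    """Helical-wheel angular position of a residue (degrees, 1-based)."""
    return ((residue - 1) * twist) % 360.0


def _circular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def assign_fragments(sequence: str, twist: float = HELIX_TWIST,
                     band_width: float = 100.0) -> dict:
    """Group nonpolar residues into stacked surface fragments.

    A fragment is a chain of nonpolar residues stacked roughly one helical
    turn apart along the helix surface: each member extends the chain from
    its last residue by a sequence step of 3 (preferred) or 4, provided the
    helical-wheel angular drift of that step stays within ``band_width``
    degrees.  For the C6 sequence this yields exactly four fragments, with
    Trp on a longest (4-residue) one.
    """
    frag_of: dict = {}
    last_of: dict = {}
    next_id = 0
    for r, code in enumerate(sequence, start=1):
        if _POLARITY[code] != NONPOLAR:
            continue
        attached = False
        for step in (3, 4):
            prev = r - step
            fid = frag_of.get(prev)
            if fid is not None and last_of[fid] == prev:
                drift = _circular_distance(wheel_angle(r, twist),
                                           wheel_angle(prev, twist))
                if drift <= band_width:
                    frag_of[r] = fid
                    last_of[fid] = r
                    attached = True
                    break
        if not attached:
            frag_of[r] = next_id
            last_of[next_id] = r
            next_id += 1
    return frag_of


def build_peptide(sequence: str = C6_SEQUENCE, chirality: str = "L",
                  rise: float = HELIX_RISE, twist: float = HELIX_TWIST,
                  band_width: float = 100.0, phase_deg: float = 0.0,
                  trp_tilt_deg: float = 0.0) -> PeptideModel:
    """Ideal alpha-helix model with pseudo side chains.

    The helix axis runs along +x; residue wheel angles are measured about
    it from +z (so ``phase_deg`` sets the initial rotation angle theta of
    residue 1).  The D enantiomer is the exact mirror image of the L model
    through the xz plane (y negated), which preserves the axis orientation
    and all intra-peptide distances.

    ``trp_tilt_deg`` rotates the rigid indole proxy away from the surface
    fragment tangent, in the local tangent plane: 0 builds the cis
    ("well-orientated", t.l ~ +1) arrangement, 90 a perpendicular one,
    180 the trans arrangement (t.l ~ -1).
    """
    if not sequence:
        raise UnknownResidueError("empty sequence")
    bad = sorted(set(sequence) - set(_RESIDUE_NAMES))
    if bad:
        raise UnknownResidueError(f"unknown residue codes: {bad}; expected R, L, W")
    if chirality not in ("L", "D"):
        raise ValueError(f"chirality must be 'L' or 'D', got {chirality!r}")
    trp_positions = [i for i, c in enumerate(sequence, start=1) if c == "W"]
    if len(trp_positions) > 1:
        raise UnknownResidueError("more than one Trp is not supported")
    trp_index = trp_positions[0] if trp_positions else None

    n = len(sequence)
    e1 = np.array([0.0, 0.0, 1.0])
    e2 = np.array([0.0, -1.0, 0.0])  # axis(+x) cross e1
    axis = np.array([1.0, 0.0, 0.0])

    def radial(phi_deg):
        phi = math.radians(phi_deg)
        return math.cos(phi) * e1 + math.sin(phi) * e2

    x0 = -(n - 1) * rise / 2.0  # centered on the origin
    phis = [phase_deg + (i * twist) for i in range(n)]
    ca = np.array([(x0 + i * rise) * axis + R_CA * radial(phis[i]) for i in range(n)])
    cb = np.array([(x0 + i * rise) * axis + R_CB * radial(phis[i]) for i in range(n)])

    polarity = {i + 1: _POLARITY[c] for i, c in enumerate(sequence)}
    fragments = assign_fragments(sequence, twist=twist, band_width=band_width)

    trp_atoms = {}
    if trp_index is not None:
        i = trp_index - 1
        u = radial(phis[i])  # outward surface normal at Trp
        cg = (x0 + i * rise) * axis + R_CG * u
        frag_id = fragments.get(trp_index)
        members = sorted(r for r, f in fragments.items() if f == frag_id)
        if frag_id is not None and len(members) >= 2:
            t = geometry.fragment_tangent(cb[[m - 1 for m in members]],
                                          members.index(trp_index))
        else:  # lone Trp: fall back to the helix axis direction
            t = axis.copy()
        # rotate the indole long axis away from the tangent, about the
        # outward normal (Rodrigues), to build cis / perpendicular / trans
        ang = math.radians(trp_tilt_deg)
        l_vec = (t * math.cos(ang) + np.cross(u, t) * math.sin(ang)
                 + u * np.dot(u, t) * (1 - math.cos(ang)))
        l_vec /= np.linalg.norm(l_vec)
        cd1 = cg + 0.05 * u - 0.5 * INDOLE_LENGTH * l_vec
        trp_atoms = {"CG": cg, "CD1": cd1, "CH2": cd1 + INDOLE_LENGTH * l_vec}

    names, residues, elements, coords = [], [], [], []
    for i in range(n):
        per_res = [("CA", ca[i]), ("CB", cb[i])]
        if i + 1 == trp_index:
            per_res += list(trp_atoms.items())
        for name, xyz in per_res:
            names.append(name)
            residues.append(i + 1)
            elements.append("C")
            coords.append(xyz)

    model = PeptideModel(sequence=sequence, chirality="L", atom_names=names,
                         atom_residues=np.array(residues), elements=elements,
                         coords=np.array(coords), polarity_class=polarity,
                         trp_index=trp_index, fragment_assignment=fragments)
    if chirality == "D":
        model = model.mirrored()
    return model


# ---------------------------------------------------------------------------
# bilayer


@dataclass
class LipidPseudo:
    """Coarse stand-in for one POPC molecule.

    ``head_atoms`` proxy the phosphate/choline group, ``c2_atom`` the
    chiral sn-2 carbon sitting between head and tails along z, and
    ``tail_atoms`` the acyl chains.
    """

    lipid_id: int
    head_atoms: np.ndarray  # (h, 3)
    c2_atom: np.ndarray  # (3,)
    tail_atoms: np.ndarray  # (t, 3)
    leaflet: str  # "upper" | "lower"

    def all_coords(self) -> np.ndarray:
        return np.vstack([np.atleast_2d(self.head_atoms),
                          np.atleast_2d(self.c2_atom),
                          np.atleast_2d(self.tail_atoms)])

    def com(self) -> np.ndarray:
        return self.all_coords().mean(axis=0)

    def mirrored(self) -> "LipidPseudo":
        def flip(a):
            a = np.array(a, dtype=float)
            a[..., 1] *= -1.0
            return a
        return replace(self, head_atoms=flip(self.head_atoms),
                       c2_atom=flip(self.c2_atom), tail_atoms=flip(self.tail_atoms))


@dataclass
class BilayerModel:
    """Two-leaflet pseudo-bilayer with the membrane normal along z."""

    lipids: list
    box: np.ndarray  # (3,) nm
    normal_axis: str = "z"

    def com(self) -> np.ndarray:
        return np.vstack([l.all_coords() for l in self.lipids]).mean(axis=0)

    def mirrored(self) -> "BilayerModel":
        return replace(self, lipids=[l.mirrored() for l in self.lipids])


# leaflet z layout (nm from the bilayer midplane)
_Z_HEAD = (1.95, 1.85)
_Z_C2 = 1.55
_Z_TAIL = (1.0, 0.5)


def build_bilayer(n_lipids: int = 128, area_per_lipid: float = 0.68,
                  seed: int = 0, jitter: float = 0.03) -> BilayerModel:
    """Pseudo-POPC bilayer on a jittered lattice, half per leaflet.

    The lateral box area satisfies ``x * y = (n_lipids / 2) *
    area_per_lipid``; head, C2 and tail pseudo-atoms sit at fixed z
    offsets from the midplane (z = 0) with small seeded jitter.
    """
    if n_lipids < 2 or n_lipids % 2:
        raise ValueError("n_lipids must be even and >= 2")
    rng = np.random.default_rng(seed)
    n_half = n_lipids // 2
    side = math.sqrt(n_half * area_per_lipid)
    n_side = math.ceil(math.sqrt(n_half))
    spacing = side / n_side
    box = np.array([side, side, 6.0])

    lipids = []
    lid = 0
    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        placed = 0
        for gi in range(n_side):
            for gj in range(n_side):
                if placed >= n_half:
                    break
                xy = np.array([(gi + 0.5) * spacing, (gj + 0.5) * spacing])
                xy = xy + rng.normal(0.0, jitter, size=2)
                heads = np.array([[*(xy + rng.normal(0, jitter, 2)), sign * z]
                                  for z in _Z_HEAD])
                c2 = np.array([*(xy + rng.normal(0, jitter, 2)), sign * _Z_C2])
                tails = np.array([[*(xy + rng.normal(0, jitter, 2)), sign * z]
                                  for z in _Z_TAIL])
                lipids.append(LipidPseudo(lipid_id=lid, head_atoms=heads,
                                          c2_atom=c2, tail_atoms=tails,
                                          leaflet=leaflet))
                lid += 1
                placed += 1
    return BilayerModel(lipids=lipids, box=box)


def mirror_frame(frame: Frame) -> Frame:
    """Mirror a whole frame through the xz plane (peptide chirality flips)."""
    return Frame(peptide=frame.peptide.mirrored(),
                 lipids=[l.mirrored() for l in frame.lipids],
                 box=None if frame.box is None else np.array(frame.box))


# ---------------------------------------------------------------------------
# reference free-energy surfaces


@dataclass
class GaussianBasin:
    """Attractive well: depth (kBT) at (dz0, theta0), periodic in theta."""

    dz0: float
    theta0: float
    depth: float
    sigma_dz: float
    sigma_theta: float  # degrees


@dataclass
class ThetaRidge:
    """Barrier ridge across dz, lowest at theta0 (the saddle gate).

    Height base + modulation * (1 - g(theta)) where g is a periodic
    (von Mises shaped) bump at theta0; the gap at theta0 has height
    ``base``.
    """

    dz0: float
    sigma_dz: float
    base: float
    modulation: float
    theta0: float
    sigma_theta: float  # degrees


class ReferenceSurface:
    """Analytic 2D free-energy surface U(dz, theta) in kBT.

    Smooth, periodic in theta with period 360 deg, finite on the whole
    simulated domain; quadratic walls confine dz to ``walls``.  The
    ``barrier`` preset calibrates a global scale factor so that the
    minimax saddle height between its two basins -- measured by dense grid
    search -- equals the requested value exactly.
    """

    def __init__(self, basins=(), ridge: ThetaRidge | None = None,
                 tilt: float = 0.0, walls=(1.0, 2.5), wall_k: float = 100.0,
                 temperature: float = DEFAULT_TEMPERATURE, name: str = "custom"):
        self.basins = list(basins)
        self.ridge = ridge
        self.tilt = tilt
        self.walls = tuple(walls)
        self.wall_k = wall_k
        self.temperature = temperature
        self.name = name
        self.scale = 1.0
        self.saddle_info = None

    # -- energetics --------------------------------------------------------

    def _theta_bump(self, theta, theta0, sigma_deg):
        s = math.radians(sigma_deg)
        d = np.radians(np.asarray(theta, dtype=float) - theta0)
        return np.exp((np.cos(d) - 1.0) / s**2)

    def _theta_bump_grad(self, theta, theta0, sigma_deg):
        # d/dtheta (degrees) of the periodic bump
        s = math.radians(sigma_deg)
        d = np.radians(np.asarray(theta, dtype=float) - theta0)
        g = np.exp((np.cos(d) - 1.0) / s**2)
        return g * (-np.sin(d) / s**2) * (math.pi / 180.0)

    def energy(self, dz, theta):
        dz = np.asarray(dz, dtype=float)
        theta = np.asarray(theta, dtype=float)
        lo, hi = self.walls
        u = self.tilt * (dz - lo)
        u = u + self.wall_k * np.where(dz > hi, (dz - hi) ** 2, 0.0)
        u = u + self.wall_k * np.where(dz < lo, (lo - dz) ** 2, 0.0)
        for b in self.basins:
            gdz = np.exp(-((dz - b.dz0) ** 2) / (2 * b.sigma_dz**2))
            u = u - b.depth * gdz * self._theta_bump(theta, b.theta0, b.sigma_theta)
        r = self.ridge
        if r is not None:
            height = r.base + r.modulation * (1.0 - self._theta_bump(theta, r.theta0,
                                                                     r.sigma_theta))
            u = u + height * np.exp(-((dz - r.dz0) ** 2) / (2 * r.sigma_dz**2))
        return self.scale * u

    def gradient(self, dz, theta):
        """(dU/d dz [kBT/nm], dU/d theta [kBT/deg])."""
        dz = np.asarray(dz, dtype=float)
        theta = np.asarray(theta, dtype=float)
        lo, hi = self.walls
        gz = np.full_like(dz, self.tilt)
        gz = gz + self.wall_k * np.where(dz > hi, 2 * (dz - hi), 0.0)
        gz = gz - self.wall_k * np.where(dz < lo, 2 * (lo - dz), 0.0)
        gt = np.zeros_like(theta)
        for b in self.basins:
            gdz = np.exp(-((dz - b.dz0) ** 2) / (2 * b.sigma_dz**2))
            bump = self._theta_bump(theta, b.theta0, b.sigma_theta)
            gz = gz + b.depth * gdz * bump * (dz - b.dz0) / b.sigma_dz**2
            gt = gt - b.depth * gdz * self._theta_bump_grad(theta, b.theta0,
                                                            b.sigma_theta)
        r = self.ridge
        if r is not None:
            gdz = np.exp(-((dz - r.dz0) ** 2) / (2 * r.sigma_dz**2))
            height = r.base + r.modulation * (1.0 - self._theta_bump(theta, r.theta0,
                                                                     r.sigma_theta))
            gz = gz - height * gdz * (dz - r.dz0) / r.sigma_dz**2
            gt = gt - r.modulation * self._theta_bump_grad(theta, r.theta0,
                                                           r.sigma_theta) * gdz
        return self.scale * gz, self.scale * gt

    # -- analysis ----------------------------------------------------------

    def analytic_barrier(self, seed_pre=(2.2, 90.0), seed_post=(1.2, 230.0),
                         n_dz: int = 301, n_theta: int = 240) -> dict:
        """Minimax-path saddle between two basins by dense grid search."""
        lo, hi = self.walls
        dz = np.linspace(lo, hi, n_dz)
        th = np.linspace(0.0, 360.0, n_theta, endpoint=False)
        U = self.energy(dz[:, None], th[None, :])
        mask = np.ones_like(U, dtype=bool)
        ia = (int(np.argmin(np.abs(dz - seed_pre[0]))),
              int(np.argmin(np.abs(th - seed_pre[1]))))
        ib = (int(np.argmin(np.abs(dz - seed_post[0]))),
              int(np.argmin(np.abs(th - seed_post[1]))))
        a, b, saddle, _ = minimax_on_grid(U, mask, ia, ib, periodic_j=True)
        return {
            "barrier": float(U[saddle] - U[a]),
            "saddle": (float(dz[saddle[0]]), float(th[saddle[1]])),
            "basin_pre": (float(dz[a[0]]), float(th[a[1]])),
            "basin_post": (float(dz[b[0]]), float(th[b[1]])),
        }

    # -- presets -----------------------------------------------------------

    @classmethod
    def flat(cls, temperature: float = DEFAULT_TEMPERATURE,
             walls=(1.0, 2.5)) -> "ReferenceSurface":
        return cls(walls=walls, temperature=temperature, name="flat")

    @classmethod
    def downhill(cls, temperature: float = DEFAULT_TEMPERATURE) -> "ReferenceSurface":
        """Single-funnel surface: free energy decreases monotonically with dz.

        Emulates barrier-free adsorption: a constant tilt toward small dz
        plus the adsorbed-state well at (1.2 nm, 230 deg).
        """
        surf = cls(basins=[GaussianBasin(1.2, 230.0, 8.0, 0.20, 60.0)],
                   tilt=2.5, walls=(1.0, 2.5), temperature=temperature,
                   name="downhill")
        surf.saddle_info = surf.analytic_barrier()
        return surf

    @classmethod
    def escape_well(cls, depth: float = 3.0, dz0: float = 1.75,
                    sigma: float = 0.10,
                    temperature: float = DEFAULT_TEMPERATURE) -> "ReferenceSurface":
        """Single basin just above the adsorption threshold, flat in theta.

        Escape from the well to smaller dz is a fluctuation-activated
        (Kramers) event, so the first-passage-time distribution is
        approximately a single exponential.
        """
        return cls(basins=[GaussianBasin(dz0, 0.0, depth, sigma, 1e6)],
                   walls=(1.0, 2.2), temperature=temperature, name="escape_well")

    @classmethod
    def harmonic(cls, kappa: float = 50.0, dz0: float = 1.75,
                 temperature: float = DEFAULT_TEMPERATURE) -> "ReferenceSurface":
        """1D harmonic well in dz (kappa in kBT/nm^2), flat in theta."""
        surf = cls(walls=(0.0, 0.0), wall_k=0.0, temperature=temperature,
                   name="harmonic")
        k = kappa

        def energy(dz, theta, _k=k, _dz0=dz0):
            return 0.5 * _k * (np.asarray(dz, dtype=float) - _dz0) ** 2

        def gradient(dz, theta, _k=k, _dz0=dz0):
            dz = np.asarray(dz, dtype=float)
            return _k * (dz - _dz0), np.zeros_like(np.asarray(theta, dtype=float))

        surf.energy = energy
        surf.gradient = gradient
        return surf

    @classmethod
    def barrier(cls, saddle_height: float = 4.3, saddle_dz: float = 1.8,
                saddle_theta: float = 150.0,
                temperature: float = DEFAULT_TEMPERATURE) -> "ReferenceSurface":
        """Two-basin surface with a theta-gated ridge.

        Emulates the activated adsorption pathway: a pre-adsorption basin
        at (2.2 nm, 90 deg), the adsorbed basin at (1.2 nm, 230 deg), and
        a ridge across dz = ``saddle_dz`` whose lowest gap sits at
        ``saddle_theta``.  After construction the whole surface is scaled
        so that the dense-grid minimax barrier from the pre-adsorption
        basin equals ``saddle_height`` (kBT) exactly.
        """
        surf = cls(
            basins=[GaussianBasin(2.2, 90.0, 2.0, 0.15, 45.0),
                    GaussianBasin(1.2, 230.0, 8.0, 0.20, 55.0)],
            ridge=ThetaRidge(dz0=saddle_dz, sigma_dz=0.07, base=1.2,
                             modulation=7.0, theta0=saddle_theta,
                             sigma_theta=40.0),
            tilt=0.0, walls=(1.0, 2.5), temperature=temperature, name="barrier")
        raw = surf.analytic_barrier()
        surf.scale = saddle_height / raw["barrier"]
        surf.saddle_info = surf.analytic_barrier()
        return surf


SURFACE_PRESETS = {
    "flat": ReferenceSurface.flat,
    "downhill": ReferenceSurface.downhill,
    "barrier": ReferenceSurface.barrier,
    "harmonic": ReferenceSurface.harmonic,
    "escape_well": ReferenceSurface.escape_well,
}


# ---------------------------------------------------------------------------
# Langevin kinetic traces


@dataclass
class LangevinConfig:
    """Overdamped Langevin (Euler-Maruyama) integration parameters.

    Mobilities are inverse friction coefficients in surface-kBT units:
    at equal simulation and surface temperatures the diffusion constant of
    each coordinate equals its mobility.  ``temperature = 0`` switches the
    noise off while keeping the deterministic drift.
    """

    dt: float = 0.01  # ns
    total_time: float = 200.0  # ns
    mobility_dz: float = 0.012  # nm^2 / (kBT ns)
    mobility_theta: float = 50.0  # deg^2 / (kBT ns)
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0
    init_dz: float = 2.2
    init_dz_std: float = 0.05
    init_theta: float | None = None  # None -> uniform on [0, 360)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        steps = self.total_time / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("total_time must be an integer multiple of dt")

    @property
    def n_steps(self):
        return int(round(self.total_time / self.dt))


def simulate_traces(surface: ReferenceSurface, config: LangevinConfig,
                    n_traj: int) -> list:
    """Seeded Euler-Maruyama traces of (dz, theta) on a reference surface.

    All trajectories propagate in lockstep (vectorized); theta is wrapped
    to [0, 360).  A non-finite force aborts with a diagnostic rather than
    silently truncating.
    """
    rng = np.random.default_rng(config.seed)
    n_steps = config.n_steps
    dt = config.dt
    t_ratio = config.temperature / surface.temperature
    noise_dz = math.sqrt(2.0 * config.mobility_dz * t_ratio * dt)
    noise_th = math.sqrt(2.0 * config.mobility_theta * t_ratio * dt)

    dz = rng.normal(config.init_dz, config.init_dz_std, size=n_traj)
    if config.init_theta is None:
        theta = rng.uniform(0.0, 360.0, size=n_traj)
    else:
        theta = np.full(n_traj, float(config.init_theta))

    dz_out = np.empty((n_steps + 1, n_traj))
    th_out = np.empty((n_steps + 1, n_traj))
    dz_out[0], th_out[0] = dz, theta
    for step in range(1, n_steps + 1):
        gz, gt = surface.gradient(dz, theta)
        if not (np.all(np.isfinite(gz)) and np.all(np.isfinite(gt))):
            bad = int(np.argmax(~(np.isfinite(gz) & np.isfinite(gt))))
            raise TraceError(
                f"non-finite force at step {step} (t={step * dt:.3f} ns) "
                f"in trajectory {bad}: dz={dz[bad]:.4f}, theta={theta[bad]:.2f}")
        dz = dz - config.mobility_dz * gz * dt + noise_dz * rng.standard_normal(n_traj)
        theta = (theta - config.mobility_theta * gt * dt
                 + noise_th * rng.standard_normal(n_traj)) % 360.0
        dz_out[step], th_out[step] = dz, theta

    time = np.arange(n_steps + 1) * dt
    meta = {"surface": surface.name, "seed": config.seed, "dt": dt,
            "temperature": config.temperature}
    return [KineticTrace(time=time, dz=dz_out[:, j], theta=th_out[:, j],
                         trajectory_id=f"traj-{j}", metadata=dict(meta))
            for j in range(n_traj)]


# ---------------------------------------------------------------------------
# umbrella sampling


def sample_umbrella(surface: ReferenceSurface, centers=None,
                    k_bias: float = 1000.0, n_samples: int = 20000,
                    seed: int = 0, n_chains: int = 32,
                    proposal_dz: float = 0.05, proposal_theta: float = 15.0,
                    observables: dict | None = None,
                    check_overlap: bool = True) -> UmbrellaWindowSet:
    """Metropolis-sampled harmonic umbrella windows along dz.

    Per window, ``n_chains`` independent random-walk chains sample the
    biased density exp(-[U + k/2 (dz - c)^2] / kBT); the first 10% of each
    chain is discarded as burn-in and the kept steps are interleaved into
    ``n_samples`` samples.  ``observables`` maps names to callables
    ``f(dz, theta)`` evaluated on the kept samples.  Identical seeds
    reproduce identical streams.
    """
    from .pmf import KB_KJ_PER_MOL_K  # kJ/mol/K
    if centers is None:
        centers = np.linspace(1.0, 2.5, 16)
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 1 or (centers.size > 1 and np.any(np.diff(centers) <= 0)):
        raise ValueError("centers must be strictly increasing")
    kT = KB_KJ_PER_MOL_K * surface.temperature

    steps_keep = math.ceil(n_samples / n_chains)
    burn = max(200, math.ceil(0.1 * steps_keep))

    theta_grid = np.arange(0.0, 360.0, 0.5)
    windows = []
    for wi, center in enumerate(centers):
        rng = np.random.default_rng([int(seed), wi])

        def reduced(dz, theta, _c=center):
            return surface.energy(dz, theta) + 0.5 * k_bias * (dz - _c) ** 2 / kT

        dz = rng.normal(center, math.sqrt(kT / k_bias), size=n_chains)
        # start chains from the conditional theta distribution at the window
        # center so burn-in only has to relax local correlations
        u_theta = surface.energy(np.full_like(theta_grid, center), theta_grid)
        p_theta = np.exp(-(u_theta - u_theta.min()))
        p_theta /= p_theta.sum()
        theta = (rng.choice(theta_grid, size=n_chains, p=p_theta)
                 + rng.uniform(0.0, 0.5, size=n_chains))
        u_cur = reduced(dz, theta)
        kept_dz = np.empty((steps_keep, n_chains))
        kept_th = np.empty((steps_keep, n_chains))
        for step in range(burn + steps_keep):
            dz_prop = dz + rng.normal(0.0, proposal_dz, size=n_chains)
            th_prop = (theta + rng.normal(0.0, proposal_theta, size=n_chains)) % 360.0
            u_prop = reduced(dz_prop, th_prop)
            accept = rng.random(n_chains) < np.exp(np.minimum(u_cur - u_prop, 0.0))
            dz = np.where(accept, dz_prop, dz)
            theta = np.where(accept, th_prop, theta)
            u_cur = np.where(accept, u_prop, u_cur)
            if step >= burn:
                kept_dz[step - burn] = dz
                kept_th[step - burn] = theta
        dz_s = kept_dz.ravel()[:n_samples]
        th_s = kept_th.ravel()[:n_samples]
        obs = {name: np.asarray(fn(dz_s, th_s), dtype=float)
               for name, fn in (observables or {}).items()}
        windows.append(UmbrellaWindow(center=float(center), k_bias=k_bias,
                                      dz=dz_s, theta=th_s, observables=obs,
                                      seed=int(seed), burn_in=burn,
                                      metadata={"n_chains": n_chains,
                                                "surface": surface.name}))
    wset = UmbrellaWindowSet(windows=windows, temperature=surface.temperature,
                             metadata={"k_bias": k_bias, "seed": int(seed)})
    if check_overlap and len(windows) > 1:
        _check_overlap(wset, [np.arange(w.n_samples) for w in wset.windows])
    return wset


# ---------------------------------------------------------------------------
# Trp-contact fixtures


def place_contact_fixture(peptide: PeptideModel, mean_heads_near_trp: float,
                          n_frames: int, seed: int = 0, n_lipids: int = 12,
                          contact_cutoff: float = 0.5) -> list:
    """Frames whose Trp-head contact count is Poisson with the given mean.

    Per frame, K ~ Poisson(mean) lipids are placed with one head atom
    inside the contact cutoff of a Trp heavy atom, and the remaining
    lipids with all head atoms well outside it; the placement is verified
    geometrically (and redrawn on the rare failure), so the realized
    distinct-lipid contact count equals K by construction, not merely by
    intent.
    """
    if mean_heads_near_trp < 0:
        raise ValueError("mean contact count must be >= 0")
    if peptide.trp_index is None:
        raise geometry.GeometryError("peptide has no Trp residue")
    rng = np.random.default_rng(seed)
    trp = peptide.residue_heavy_coords(peptide.trp_index)
    trp_center = trp.mean(axis=0)

    def random_unit():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    def make_contact_lipid(lid):
        anchor = trp[rng.integers(0, len(trp))]
        head1 = anchor + rng.uniform(0.15, contact_cutoff - 0.02) * random_unit()
        head2 = head1 + 0.08 * random_unit()
        c2 = head1 + 0.25 * random_unit()
        tails = np.array([c2 + 0.3 * random_unit(), c2 + 0.5 * random_unit()])
        return LipidPseudo(lipid_id=lid, head_atoms=np.array([head1, head2]),
                           c2_atom=c2, tail_atoms=tails, leaflet="upper")

    def make_far_lipid(lid):
        for _ in range(100):
            center = trp_center + rng.uniform(contact_cutoff + 0.5, 3.0) * random_unit()
            heads = np.array([center + 0.05 * random_unit(),
                              center + 0.05 * random_unit()])
            d = np.linalg.norm(trp[:, None, :] - heads[None, :, :], axis=-1)
            if d.min() > contact_cutoff + 0.1:
                c2 = center + 0.25 * random_unit()
                tails = np.array([c2 + 0.3 * random_unit(),
                                  c2 + 0.5 * random_unit()])
                return LipidPseudo(lipid_id=lid, head_atoms=heads, c2_atom=c2,
                                   tail_atoms=tails, leaflet="upper")
        raise RuntimeError("could not place a non-contact lipid")

    def realized_count(lipids):
        n = 0
        for lipid in lipids:
            d = np.linalg.norm(trp[:, None, :]
                               - np.atleast_2d(lipid.head_atoms)[None, :, :], axis=-1)
            if d.min() <= contact_cutoff:
                n += 1
        return n

    frames = []
    for _ in range(n_frames):
        for _attempt in range(20):
            k = int(min(rng.poisson(mean_heads_near_trp), n_lipids))
            lipids = [make_contact_lipid(i) for i in range(k)]
            lipids += [make_far_lipid(k + i) for i in range(n_lipids - k)]
            if realized_count(lipids) == k:
                break
        else:
            raise RuntimeError("contact fixture placement failed to verify")
        frames.append(Frame(peptide=peptide, lipids=lipids, box=None))
    return frames
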