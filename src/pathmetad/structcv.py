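"""Structural collective variables of base-pair geometry.

Computes, from atomic coordinates, the CVs that characterize the
Watson-Crick-Franklin (WCF) vs Hoogsteen (HG) state of an A.T base pair:

* chi      -- glycosidic torsion O4'-C1'-N9-C4 of the purine;
* chi'     -- the base-rolling pseudo-dihedral over four centers of mass, a
              less locally dependent replacement for chi that avoids biasing
              sugar rotation (group definitions are configurable; the shipped
              default uses sugar, glycosidic-end and six-ring COM points);
* theta    -- the base-opening pseudo-dihedral over four centers of mass
              (flanking-pair bases and the flipping nucleotide); negative
              values mean opening toward the major groove;
* d_WCF    -- A:N1 - T:N3 hydrogen-bond distance (characteristic of WCF);
* d_HG     -- A:N7 - T:N3 (characteristic of HG);
* d_HB     -- A:N6 - T:O4 (conserved in both pairings);
* d_CC     -- C1'-C1' distance (~10.6 A in WCF, ~9.1 A in HG);
* d_NB     -- distance between the COMs of the two bases flanking the
              rolling purine;
* N_water  -- water oxygens within a cutoff (default 6 A) of A:N6.

A deterministic fixture generator builds synthetic idealized three-base-pair
duplex fragments (WCF, HG, mid-rotated, flipped) with correct atom naming;
the HG fixture is obtained by rotating the adenine base 180 degrees about its
glycosidic axis and re-closing the pair on the N7 side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError, SelectionError

__all__ = [
    "StructureFrame",
    "AtomGroupSpec",
    "CVRecord",
    "dihedral",
    "com_pseudo_dihedral",
    "pair_distances",
    "n_water",
    "classify_state",
    "make_fixture",
    "compute_cvs",
    "write_cv_table",
    "default_chi_spec",
    "default_chi_prime_spec",
    "default_theta_spec",
    "atomic_mass",
]

# masses inferred from the leading letters of PDB atom names, with overrides
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}


def atomic_mass(atom_name: str, overrides: dict | None = None) -> float:
    """Mass from the first alphabetic character of a PDB atom name."""
    if overrides and atom_name in overrides:
        return overrides[atom_name]
    m = re.search(r"[A-Za-z]", atom_name)
    if m is None:
        raise SelectionError(f"cannot infer element from atom name {atom_name!r}")
    el = m.group(0).upper()
    if el not in _MASSES:
        raise SelectionError(f"no mass for element {el!r} (atom {atom_name!r})")
    return _MASSES[el]


class StructureFrame:
    """Atoms (name, residue id/name, chain, coordinates in Angstrom).

    Keys (chain, residue id, atom name) are unique; coordinates are finite.
    An optional orthorhombic box enables minimum-image distances.
    """

    def __init__(self, chain, res_id, res_name, name, coord, box=None, serial=None):
        self.chain = np.asarray(chain, dtype=object)
        self.res_id = np.asarray(res_id, dtype=int)
        self.res_name = np.asarray(res_name, dtype=object)
        self.name = np.asarray(name, dtype=object)
        self.coord = np.asarray(coord, dtype=float)
        self.box = None if box is None else np.asarray(box, dtype=float)
        n = self.coord.shape[0]
        self.serial = (np.arange(1, n + 1) if serial is None
                       else np.asarray(serial, dtype=int))
        if not np.all(np.isfinite(self.coord)):
            raise ParameterError("coordinates must be finite")
        keys = list(zip(self.chain, self.res_id, self.name))
        if len(set(keys)) != n:
            raise ParameterError("duplicate (chain, residue, atom-name) keys")
        self._index = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return self.coord.shape[0]

    # -- selection --------------------------------------------------------
    def index_of(self, chain, res_id, name) -> int:
        try:
            return self._index[(chain, int(res_id), name)]
        except KeyError:
            raise SelectionError(
                f"no atom ({chain!r}, {res_id}, {name!r}) in frame"
            ) from None

    def position(self, chain, res_id, name) -> np.ndarray:
        return self.coord[self.index_of(chain, res_id, name)]

    def com(self, selectors, mass_overrides: dict | None = None) -> np.ndarray:
        """Mass-weighted center of a list of (chain, res_id, name) selectors."""
        idx = [self.index_of(*sel) for sel in selectors]
        m = np.array([atomic_mass(self.name[i], mass_overrides) for i in idx])
        return (self.coord[idx] * m[:, None]).sum(axis=0) / m.sum()

    def residue_atoms(self, chain, res_id, names=None):
        mask = (self.chain == chain) & (self.res_id == int(res_id))
        if names is not None:
            mask &= np.isin(self.name, list(names))
        return np.flatnonzero(mask)

    def transformed(self, rotation=None, translation=None) -> "StructureFrame":
        c = self.coord
        if rotation is not None:
            c = c @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            c = c + np.asarray(translation, dtype=float)
        return StructureFrame(self.chain, self.res_id, self.res_name,
                              self.name, c, self.box, self.serial)

    # -- PDB I/O (via biotite) --------------------------------------------
    def to_pdb(self, filename) -> None:
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        arr = struc.AtomArray(len(self))
        arr.coord = self.coord.astype(np.float32)
        arr.chain_id = self.chain.astype("U4")
        arr.res_id = self.res_id
        arr.res_name = self.res_name.astype("U5")
        arr.atom_name = self.name.astype("U6")
        arr.set_annotation("element", np.array(
            [re.search(r"[A-Za-z]", n).group(0).upper() for n in self.name], dtype="U2"))
        arr.set_annotation("hetero", np.array(
            [rn in ("HOH", "WAT") for rn in self.res_name]))
        pdb = PDBFile()
        pdb.set_structure(arr)
        pdb.write(filename)

    @classmethod
    def from_pdb(cls, filename, box=None) -> "StructureFrame":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(filename)
        arr = pdb.get_structure(model=1)
        return cls(arr.chain_id, arr.res_id, arr.res_name, arr.atom_name,
                   np.asarray(arr.coord, dtype=float), box=box)


@dataclass(frozen=True)
class AtomGroupSpec:
    """Four pseudo-dihedral points, each one atom or a COM of a group.

    ``groups`` is a tuple of four tuples of (chain, res_id, atom_name)
    selectors; a length-1 group is a single atom.
    """

    groups: tuple

    def __post_init__(self) -> None:
        if len(self.groups) != 4:
            raise ParameterError("a pseudo-dihedral needs exactly four points")
        if any(len(g) == 0 for g in self.groups):
            raise ParameterError("empty atom group in pseudo-dihedral spec")


@dataclass
class CVRecord:
    """One set of structural CVs (angles in rad, distances in Angstrom)."""

    chi: float | None = None
    chi_prime: float | None = None
    theta: float | None = None
    d_wcf: float | None = None
    d_hg: float | None = None
    d_hb: float | None = None
    d_cc: float | None = None
    d_nb: float | None = None
    n_water: int | None = None


# ---------------------------------------------------------------------------
# geometry


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in (-pi, pi] by the standard atan2 construction."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-10:
            raise GeometryError("coincident consecutive points in torsion")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear triple: torsion undefined")
    ang = float(np.arctan2(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)),
                           n1 @ n2))
    return np.pi if ang == -np.pi else ang


def com_pseudo_dihedral(frame: StructureFrame, spec: AtomGroupSpec,
                        mass_overrides: dict | None = None) -> float:
    """Torsion over the four mass-weighted centers of the spec's groups."""
    pts = [frame.com(g, mass_overrides) for g in spec.groups]
    return dihedral(*pts)


# shipped default group conventions (three-bp fragment around a rolling
# purine at (chain, res) with 5'/3' flanking pairs; see make_fixture layout)

SIX_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
BASE_ATOMS = {
    "DA": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "DG": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "DT": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"),
    "DC": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
}


def default_chi_spec(chain="A", res=16) -> AtomGroupSpec:
    """Glycosidic torsion O4'-C1'-N9-C4 of the rolling purine."""
    return AtomGroupSpec((
        ((chain, res, "O4'"),),
        ((chain, res, "C1'"),),
        ((chain, res, "N9"),),
        ((chain, res, "C4"),),
    ))


def default_chi_prime_spec(chain="A", res=16) -> AtomGroupSpec:
    """Base-rolling pseudo-dihedral over centers of mass.

    Shipped convention: sugar COM (O4', C4') / C1' / glycosidic-end base COM
    (N9, C4, C8) / six-ring COM.  The COM points give longer torsion arms
    than the single-atom glycosidic torsion, so the angle reports base
    rolling with little sensitivity to local (e.g. sugar-pucker) noise; the
    third point lies on the glycosidic axis, so a rotation of the base about
    that axis shifts chi' by almost exactly the rotation angle.
    """
    ring = tuple((chain, res, a) for a in SIX_RING)
    return AtomGroupSpec((
        ((chain, res, "O4'"), (chain, res, "C4'")),
        ((chain, res, "C1'"),),
        ((chain, res, "N9"), (chain, res, "C4"), (chain, res, "C8")),
        ring,
    ))


def default_theta_spec(frame: StructureFrame, chain="A", res=16) -> AtomGroupSpec:
    """Base-opening pseudo-dihedral: 5' pair bases / 3' pair bases / sugar /
    6-ring COM of the flipping purine.

    The flanking-pair groups collect the base atoms of the residues pairing
    with res-1 and res+1 (both strands), located by residue proximity.
    """

    def pair_group(res_a):
        sels = []
        for i in range(len(frame)):
            if frame.name[i] in BASE_ATOMS.get(frame.res_name[i], ()):
                if frame.chain[i] == chain and frame.res_id[i] == res_a:
                    sels.append((frame.chain[i], int(frame.res_id[i]), frame.name[i]))
        # partner residue on the other strand: nearest base COM
        best = None
        ref = frame.com(sels) if sels else None
        for ch in set(frame.chain):
            if ch == chain:
                continue
            for rid in set(frame.res_id[frame.chain == ch]):
                rn = frame.res_name[frame.residue_atoms(ch, rid)[0]]
                if rn not in BASE_ATOMS:
                    continue
                g = [(ch, int(rid), a) for a in BASE_ATOMS[rn]
                     if (ch, int(rid), a) in frame._index]
                if not g:
                    continue
                dist = np.linalg.norm(frame.com(g) - ref)
                if best is None or dist < best[0]:
                    best = (dist, g)
        if best is not None:
            sels += best[1]
        return tuple(sels)

    ring = tuple((chain, res, a) for a in SIX_RING)
    sugar = tuple((chain, res, a) for a in ("C1'", "C2'", "C3'", "C4'", "O4'"))
    return AtomGroupSpec((pair_group(res - 1), pair_group(res + 1), sugar, ring))


# ---------------------------------------------------------------------------
# distances and solvation


@dataclass(frozen=True)
class PairSpec:
    """Identifies the rolling purine, its pyrimidine partner and neighbors."""

    purine: tuple = ("A", 16)
    pyrimidine: tuple = ("B", 9)
    neighbor_5p: tuple = ("A", 15)
    neighbor_3p: tuple = ("A", 17)


def pair_distances(frame: StructureFrame, spec: PairSpec | None = None):
    """(d_WCF, d_HG, d_HB, d_CC, d_NB) in Angstrom.

    d_WCF = A:N1-T:N3, d_HG = A:N7-T:N3, d_HB = A:N6-T:O4,
    d_CC = C1'(A)-C1'(T), d_NB = COM-COM distance of the two bases flanking
    the rolling purine.
    """
    spec = spec or PairSpec()
    ca, ra = spec.purine
    ct, rt = spec.pyrimidine

    def dist(a, b):
        return float(np.linalg.norm(a - b))

    n1 = frame.position(ca, ra, "N1")
    n7 = frame.position(ca, ra, "N7")
    n6 = frame.position(ca, ra, "N6")
    n3 = frame.position(ct, rt, "N3")
    o4 = frame.position(ct, rt, "O4")
    c1a = frame.position(ca, ra, "C1'")
    c1t = frame.position(ct, rt, "C1'")

    def base_com(chain, rid):
        idx0 = frame.residue_atoms(chain, rid)
        if idx0.size == 0:
            raise SelectionError(f"no residue ({chain!r}, {rid})")
        rn = frame.res_name[idx0[0]]
        names = BASE_ATOMS.get(rn)
        if names is None:
            raise SelectionError(f"residue {rn!r} has no base definition")
        sels = [(chain, rid, a) for a in names if (chain, rid, a) in frame._index]
        return frame.com(sels)

    nb5 = base_com(*spec.neighbor_5p)
    nb3 = base_com(*spec.neighbor_3p)
    return (dist(n1, n3), dist(n7, n3), dist(n6, o4), dist(c1a, c1t), dist(nb5, nb3))


def n_water(frame: StructureFrame, center=("A", 16, "N6"), cutoff: float = 6.0) -> int:
    """Water oxygens within ``cutoff`` of the center atom (minimum image if a
    box is present)."""
    if not cutoff > 0:
        raise ParameterError("cutoff must be > 0")
    c = frame.position(*center)
    mask = np.isin(frame.res_name, ("HOH", "WAT")) & np.isin(frame.name, ("O", "OW"))
    if not mask.any():
        return 0
    d = frame.coord[mask] - c
    if frame.box is not None:
        d = d - frame.box * np.round(d / frame.box)
    return int(np.count_nonzero(np.einsum("ij,ij->i", d, d) <= cutoff**2))


# ---------------------------------------------------------------------------
# classification


def classify_state(cv: CVRecord) -> str:
    """WCF / HG / intermediate from chi' (and pairing distances if given).

    WCF: |chi' - 1.5| < 0.6 rad and, when available, d_WCF < 3.5 A.
    HG:  |chi' + 1.5| < 0.6 rad and, when available, d_HG < 3.5 A.
    """
    if cv.chi_prime is None:
        raise ParameterError("chi' is required for classification")
    chip = float(cv.chi_prime)

    def near(target):
        return abs((chip - target + np.pi) % (2 * np.pi) - np.pi) < 0.6

    if near(1.5) and (cv.d_wcf is None or cv.d_wcf < 3.5):
        return "WCF"
    if near(-1.5) and (cv.d_hg is None or cv.d_hg < 3.5):
        return "HG"
    return "intermediate"


# ---------------------------------------------------------------------------
# synthetic fixtures
#
# Idealized base geometries in the standard base reference frame (x, y in the
# base plane, C1' at upper left); the complementary base of an ideal pair is
# placed by the 180-degree rotation about the x axis (y -> -y, z -> -z).

_BASE_FRAME = {
    "DA": {
        "C1'": (-2.479, 5.346, 0.0), "N9": (-1.291, 4.498, 0.0),
        "C8": (0.024, 4.897, 0.0), "N7": (0.877, 3.902, 0.0),
        "C5": (0.071, 2.771, 0.0), "C6": (0.369, 1.398, 0.0),
        "N6": (1.611, 0.909, 0.0), "N1": (-0.668, 0.532, 0.0),
        "C2": (-1.912, 1.023, 0.0), "N3": (-2.320, 2.290, 0.0),
        "C4": (-1.267, 3.124, 0.0),
    },
    "DG": {
        "C1'": (-2.477, 5.399, 0.0), "N9": (-1.289, 4.551, 0.0),
        "C8": (0.023, 4.962, 0.0), "N7": (0.870, 3.969, 0.0),
        "C5": (0.071, 2.833, 0.0), "C6": (0.424, 1.460, 0.0),
        "O6": (1.554, 0.955, 0.0), "N1": (-0.700, 0.641, 0.0),
        "C2": (-1.999, 1.087, 0.0), "N2": (-2.949, 0.139, 0.0),
        "N3": (-2.342, 2.364, 0.0), "C4": (-1.265, 3.177, 0.0),
    },
    "DC": {
        "C1'": (-2.477, 5.402, 0.0), "N1": (-1.285, 4.542, 0.0),
        "C2": (-1.472, 3.158, 0.0), "O2": (-2.628, 2.709, 0.0),
        "N3": (-0.391, 2.344, 0.0), "C4": (0.837, 2.868, 0.0),
        "N4": (1.875, 2.027, 0.0), "C5": (1.056, 4.275, 0.0),
        "C6": (-0.023, 5.068, 0.0),
    },
    "DT": {
        "C1'": (-2.481, 5.354, 0.0), "N1": (-1.284, 4.500, 0.0),
        "C2": (-1.462, 3.135, 0.0), "O2": (-2.562, 2.608, 0.0),
        "N3": (-0.298, 2.407, 0.0), "C4": (0.994, 2.897, 0.0),
        "O4": (1.944, 2.119, 0.0), "C5": (1.106, 4.338, 0.0),
        "C7": (2.466, 4.961, 0.0), "C6": (-0.024, 5.057, 0.0),
    },
}

_FLIP_X = np.diag([1.0, -1.0, -1.0])  # complement placement in an ideal pair
_RISE = 3.4  # Angstrom per base-pair step
_TWIST = np.deg2rad(36.0)


def _rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


_SUGAR_NAMES = ("C2'", "C3'", "C4'", "O4'")


def _sugar_ring(c1p: np.ndarray, glyco_atom: np.ndarray, torsion_probe,
                chi_prime_target: float | None):
    """Place a planar furanose ring (C1', C2', C3', C4', O4') at C1'.

    The ring is a regular pentagon (bond 1.45 A) whose plane contains the
    glycosidic axis; its azimuth about that axis is solved, when a target is
    given, so that ``torsion_probe(ring_atoms)`` -- the chi' convention --
    equals the target.
    """
    a = glyco_atom - c1p
    a = a / np.linalg.norm(a)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(a @ ref) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    R = 1.45 / (2.0 * np.sin(np.pi / 5.0))
    gamma0 = np.deg2rad(115.0)

    def ring_at(phi):
        u = np.cos(phi) * e1 + np.sin(phi) * e2
        f1, f2 = -a, u
        center = c1p + R * (np.cos(gamma0) * f1 + np.sin(gamma0) * f2)
        out = {}
        for k, name in enumerate(_SUGAR_NAMES, start=1):
            psi = gamma0 + np.pi + k * 2.0 * np.pi / 5.0
            out[name] = center + R * (np.cos(psi) * f1 + np.sin(psi) * f2)
        return out

    if chi_prime_target is None:
        return ring_at(0.0)

    def wrap(x):
        return (x + np.pi) % (2.0 * np.pi) - np.pi

    # the torsion is almost exactly linear in the ring azimuth with slope
    # +/-1; a short fixed-point iteration absorbs the residual nonlinearity
    t0 = torsion_probe(ring_at(0.0))
    slope = np.sign(wrap(torsion_probe(ring_at(0.1)) - t0)) or 1.0
    phi = slope * wrap(chi_prime_target - t0)
    for _ in range(20):
        err = wrap(torsion_probe(ring_at(phi)) - chi_prime_target)
        if abs(err) < 1e-12:
            break
        phi -= slope * err
    return ring_at(phi)


def _pair_coords(purine_name: str, pyr_name: str):
    """Ideal pair: purine in the standard frame, pyrimidine x-flipped."""
    pur = {k: np.array(v) for k, v in _BASE_FRAME[purine_name].items()}
    pyr = {k: _FLIP_X @ np.array(v) for k, v in _BASE_FRAME[pyr_name].items()}
    return pur, pyr


def _solve_pyrimidine_placement(pyr, targets, init=(0.0, 0.0, 0.0)):
    """In-plane rigid transform of the pyrimidine satisfying distance targets.

    ``targets`` is a list of (pyr_atom_name, reference_point, distance).
    Solved with scipy least squares (3 dof: rotation + translation in z=0).
    """
    from scipy.optimize import least_squares

    names = [t[0] for t in targets]
    refs = np.array([t[1] for t in targets])
    dists = np.array([t[2] for t in targets])
    pts = np.array([pyr[n] for n in names])

    def residual(x):
        phi, tx, ty = x
        R = _rotation_z(phi)
        moved = pts @ R.T + np.array([tx, ty, 0.0])
        return np.linalg.norm(moved - refs, axis=1) - dists

    sol = least_squares(residual, np.asarray(init, dtype=float), xtol=1e-14, ftol=1e-14)
    phi, tx, ty = sol.x
    R = _rotation_z(phi)
    return {k: R @ v + np.array([tx, ty, 0.0]) for k, v in pyr.items()}, sol


def _mass_com(coords: dict, names) -> np.ndarray:
    m = np.array([atomic_mass(n) for n in names])
    pts = np.array([coords[n] for n in names])
    return (pts * m[:, None]).sum(axis=0) / m.sum()


def _chi_prime_of(coords: dict) -> float:
    """chi' of a purine coordinate dict by the shipped default convention."""
    p1 = _mass_com(coords, ("O4'", "C4'"))
    p2 = coords["C1'"]
    p3 = _mass_com(coords, ("N9", "C4", "C8"))
    p4 = _mass_com(coords, SIX_RING)
    return dihedral(p1, p2, p3, p4)


def make_fixture(kind: str = "WCF", noise: float = 0.0, seed: int = 0,
                 n_waters: int = 0, water_box: float | None = None) -> StructureFrame:
    """Synthetic idealized three-base-pair duplex fragment.

    Layout: chain A carries C15 - A16 - A17 (A16 is the rolling adenine),
    chain B the complementary G10 - T9 - T8.  Base pairs are stacked with a
    3.4 A rise and 36 degree twist about the z axis.  ``kind`` selects the
    state of the central A16.T9 pair:

    * ``"WCF"``         -- ideal pair (chi' = +1.5 rad, d_WCF = 2.82 A,
                           d_CC = 10.6 A);
    * ``"HG"``          -- adenine base rotated 180 degrees about the
                           glycosidic (C1'-N9) axis, pair re-closed on the
                           N7 side (d_HG = 2.9 A, d_CC = 9.1 A);
    * ``"mid-rotated"`` -- adenine base rotated 90 degrees (chi' ~ 0);
    * ``"flipped"``     -- whole A16 nucleotide swung out of the helix
                           toward the major groove (theta < -pi/4).

    ``noise`` is the per-atom root-mean-square Gaussian displacement in
    Angstrom (sigma = noise / sqrt(3) per coordinate), drawn from a
    deterministic seeded generator.  ``n_waters`` places water oxygens
    uniformly in a cube of side ``water_box`` (default 25 A) centered on the
    duplex.
    """
    if kind not in ("WCF", "HG", "mid-rotated", "flipped"):
        raise ParameterError(f"unknown fixture kind {kind!r}")
    rng = np.random.default_rng(seed)

    apur, tpyr = _pair_coords("DA", "DT")

    glyco_angle = {"WCF": 0.0, "HG": np.pi, "mid-rotated": np.pi / 2,
                   "flipped": 0.0}[kind]
    if glyco_angle != 0.0:
        axis = apur["N9"] - apur["C1'"]
        R = _rotation_about_axis(axis, glyco_angle)
        origin = apur["C1'"]
        for a in [a for a in apur if a != "C1'"]:
            apur[a] = origin + R @ (apur[a] - origin)

    # pyrimidine placed to exact pairing targets
    if kind == "HG":
        tpyr, _ = _solve_pyrimidine_placement(
            tpyr,
            [("N3", apur["N7"], 2.9),
             ("O4", apur["N6"], 3.0),
             ("C1'", apur["C1'"], 9.1)],
            init=(0.6, 1.0, 1.0),
        )
    else:
        tpyr, _ = _solve_pyrimidine_placement(
            tpyr,
            [("N3", apur["N1"], 2.82),
             ("O4", apur["N6"], 2.95),
             ("C1'", apur["C1'"], 10.6)],
            init=(0.0, 0.0, 0.0),
        )

    # A16 sugar ring, azimuth solved so chi' hits the state's target value
    # (the glycosidic rotation shifts chi' by almost exactly its angle)
    target = (1.5 - glyco_angle + np.pi) % (2 * np.pi) - np.pi

    def probe(ring, apur=apur):
        return _chi_prime_of({**apur, **ring})

    apur.update(_sugar_ring(apur["C1'"], apur["N9"], probe, target))

    atoms = []  # (chain, res_id, res_name, atom_name, xyz)

    def emit(chain, rid, rname, coords, transform=None):
        for aname, xyz in coords.items():
            p = np.asarray(xyz, dtype=float)
            if transform is not None:
                p = transform(p)
            atoms.append((chain, rid, rname, aname, p))

    # central pair at z = 0
    emit("A", 16, "DA", apur)
    tpyr = dict(tpyr)
    tpyr.update(_sugar_ring(tpyr["C1'"], tpyr["N1"], None, None))
    emit("B", 9, "DT", tpyr)

    # flanking pairs: C15.G10 below (5'), A17.T8 above (3')
    for (rid_a, rname_a, rid_b, rname_b, level) in (
        (15, "DC", 10, "DG", -1),
        (17, "DA", 8, "DT", +1),
    ):
        if rname_a == "DC":
            pur, pyr = _pair_coords("DG", "DC")
            a_coords, b_coords = pyr, pur  # cytosine on chain A, guanine on B
            a_anchor, b_anchor = "N1", "N9"
        else:
            pur, pyr = _pair_coords("DA", "DT")
            a_coords, b_coords = pur, pyr
            a_anchor, b_anchor = "N9", "N1"
        Rz = _rotation_z(level * _TWIST)
        shift = np.array([0.0, 0.0, level * _RISE])

        def tf(p, Rz=Rz, shift=shift):
            return Rz @ p + shift

        for coords, chain, rid, rname, anchor in (
            (a_coords, "A", rid_a, rname_a, a_anchor),
            (b_coords, "B", rid_b, rname_b, b_anchor),
        ):
            coords = dict(coords)
            coords.update(_sugar_ring(coords["C1'"], coords[anchor], None, None))
            emit(chain, rid, rname, coords, tf)

    frame_arrays = list(zip(*[(c, r, rn, an) for c, r, rn, an, _ in atoms]))
    coords = np.array([p for *_, p in atoms])

    if kind == "flipped":
        # swing the whole A16 nucleotide about the vertical axis through its
        # C1' toward the major groove (sign chosen so theta < 0)
        c1 = apur["C1'"]
        R = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), 2.0 * np.pi / 3.0)
        sel = [i for i, (c, r, *_rest) in enumerate(atoms)
               if c == "A" and r == 16]
        coords[sel] = (coords[sel] - c1) @ R.T + c1

    if noise > 0:
        coords = coords + rng.normal(0.0, noise / np.sqrt(3.0), coords.shape)

    chain, res_id, res_name, name = frame_arrays
    chain = list(chain)
    res_id = list(res_id)
    res_name = list(res_name)
    name = list(name)

    box = None
    if n_waters > 0:
        side = water_box or 25.0
        center = coords.mean(axis=0)
        wpos = center + rng.uniform(-side / 2, side / 2, (n_waters, 3))
        for i, p in enumerate(wpos):
            chain.append("W")
            res_id.append(100 + i)
            res_name.append("HOH")
            name.append("O")
        coords = np.vstack([coords, wpos])
        box = np.array([side, side, side])

    return StructureFrame(chain, res_id, res_name, name, coords, box=box)


def write_cv_table(records, filename) -> None:
    """COLVAR-style plain-text table: frame index, then one column per CV."""
    cols = ("chi", "chi_prime", "theta", "d_wcf", "d_hg", "d_hb",
            "d_cc", "d_nb", "n_water")
    with open(filename, "w") as fh:
        fh.write("# frame " + " ".join(cols) + "\n")
        for i, rec in enumerate(records):
            vals = [getattr(rec, c) for c in cols]
            fh.write(str(i) + " " + " ".join(
                "nan" if v is None else f"{v:.10g}" for v in vals) + "\n")


def compute_cvs(frame: StructureFrame, pair: PairSpec | None = None,
                water_cutoff: float = 6.0) -> CVRecord:
    """All structural CVs of a frame with the shipped default conventions."""
    pair = pair or PairSpec()
    ca, ra = pair.purine
    chi = com_pseudo_dihedral(frame, default_chi_spec(ca, ra))
    chip = com_pseudo_dihedral(frame, default_chi_prime_spec(ca, ra))
    theta = com_pseudo_dihedral(frame, default_theta_spec(frame, ca, ra))
    d_wcf, d_hg, d_hb, d_cc, d_nb = pair_distances(frame, pair)
    nw = n_water(frame, (ca, ra, "N6"), water_cutoff)
    return CVRecord(chi, chip, theta, d_wcf, d_hg, d_hb, d_cc, d_nb, nw)
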