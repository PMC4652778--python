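"""Reaction coordinates from atomic coordinates.

Two collective variables describe the Watson-Crick -> Hoogsteen switch of a
purine base in duplex DNA:

* chi — the glycosidic dihedral O4'-C1'-N9-C4 of the purine nucleotide.
  anti (WC-like) conformers lie in [-180, -90) degrees, syn (HG-like)
  conformers in [-90, 90].
* CPDb — a pseudodihedral P1-P2-P3-P4 of four centers of mass: the flanking
  base pairs (P1), two backbone phosphate groups (P2, P3) and the
  five-membered ring of the flipping purine (P4).  Flipping into the major
  groove gives CPDb > 0, into the minor groove CPDb < 0 (the sign depends on
  the P2/P3 order; swapping them negates the angle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .umbrella import wrap_angle

# CODATA-style standard atomic weights (amu) for elements common in nucleic
# acids; extend as needed.
ATOMIC_WEIGHTS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "MG": 24.305, "K": 39.098, "CL": 35.45,
    "F": 18.998, "BR": 79.904, "I": 126.904, "FE": 55.845, "ZN": 65.38,
}

PURINE_RING5_ATOMS = ("N9", "C8", "N7", "C5", "C4")
PHOSPHATE_ATOMS = ("P", "OP1", "OP2", "O1P", "O2P", "O5'", "O3'")


class DegenerateGeometryError(ValueError):
    """Raised when a dihedral is undefined (collinear/coincident points)."""


class SelectionError(KeyError):
    """Raised when an atom selection does not resolve in a frame."""


def mass_of(element):
    try:
        return ATOMIC_WEIGHTS[element.upper()]
    except KeyError:
        raise SelectionError(f"no standard atomic weight for element {element!r}")


@dataclass
class StructureFrame:
    """One frame of atomic coordinates.

    Column arrays over atoms: residue ids, residue names, atom names,
    element symbols, masses (amu) and Cartesian positions (Angstrom).
    """

    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.res_ids)
        if not (len(self.atom_names) == len(self.masses) == n
                and self.coords.shape == (n, 3)):
            raise ValueError("inconsistent frame column lengths")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in frame")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be > 0")
        # atom names must be unique within a residue
        seen = set()
        for rid, name in zip(self.res_ids, self.atom_names):
            key = (int(rid), str(name))
            if key in seen:
                raise ValueError(f"duplicate atom {name!r} in residue {rid}")
            seen.add(key)

    def __len__(self):
        return len(self.res_ids)

    @classmethod
    def from_atoms(cls, atoms):
        """Build from (res_id, res_name, atom_name, element, mass, xyz) tuples."""
        rid, rname, aname, elem, mass, xyz = zip(*atoms)
        return cls(np.array(rid), np.array(rname, dtype=object),
                   np.array(aname, dtype=object), np.array(elem, dtype=object),
                   np.array(mass, dtype=float), np.array(xyz, dtype=float))

    def select(self, res_id, atom_name):
        """Indices of atoms matching (residue id, atom name).

        PDB prime/star aliases are accepted: O4' matches O4*.
        """
        name = str(atom_name)
        alias = name.replace("'", "*") if "'" in name else name.replace("*", "'")
        mask = (self.res_ids == int(res_id)) & (
            (self.atom_names == name) | (self.atom_names == alias))
        return np.nonzero(mask)[0]

    def atom_position(self, res_id, atom_name):
        idx = self.select(res_id, atom_name)
        if len(idx) == 0:
            raise SelectionError(
                f"atom {atom_name!r} not found in residue {res_id}")
        return self.coords[idx[0]]

    def residue_atoms(self, res_id, heavy_only=True):
        mask = self.res_ids == int(res_id)
        if heavy_only:
            mask &= np.array([str(e).upper() != "H" for e in self.elements])
        return np.nonzero(mask)[0]


def frames_from_pdb(path, heavy_only=False):
    """Read a (possibly multi-MODEL) PDB file into a list of StructureFrame.

    Keeps altloc 'A' or blank; masses are resolved from element symbols.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdbfile = pdb.PDBFile.read(str(path))
    stack = pdbfile.get_structure(model=None, altloc="first")
    if stack.stack_depth() == 0:
        raise ValueError(f"no models in {path}")
    frames = []
    for model in stack:
        arr = model
        elements = np.array([e if e else "C" for e in arr.element], dtype=object)
        if heavy_only:
            keep = np.array([str(e).upper() != "H" for e in elements])
            arr = arr[keep]
            elements = elements[keep]
        masses = np.array([mass_of(str(e)) for e in elements])
        frames.append(StructureFrame(
            res_ids=np.asarray(arr.res_id, dtype=int),
            res_names=np.array(arr.res_name, dtype=object),
            atom_names=np.array(arr.atom_name, dtype=object),
            elements=elements,
            masses=masses,
            coords=np.asarray(arr.coord, dtype=float),
        ))
    return frames


def dihedral(a, b, c, d):
    """Signed IUPAC dihedral a-b-c-d in degrees, range [-180, 180).

    Sign follows the right-hand rule about the b->c axis; the planar-cis
    (eclipsed) arrangement is 0 and planar-trans is represented as -180.
    Raises DegenerateGeometryError for collinear/coincident defining points.
    """
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    axis = c - b
    n2 = np.linalg.norm(axis)
    if n2 < 1e-12:
        raise DegenerateGeometryError(f"central atoms coincide: b={b}, c={c}")
    axis = axis / n2
    u = a - b
    w = d - c
    v1 = u - np.dot(u, axis) * axis
    v2 = w - np.dot(w, axis) * axis
    if np.linalg.norm(v1) < 1e-10 or np.linalg.norm(v2) < 1e-10:
        raise DegenerateGeometryError(
            f"collinear points leave the dihedral undefined: {a}, {b}, {c}, {d}")
    x = np.dot(v1, v2)
    y = np.dot(np.cross(v1, v2), axis)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def center_of_mass(masses, positions=None):
    """Mass-weighted mean position.

    Accepts either (masses, positions) arrays or a single iterable of
    (mass, position) pairs.
    """
    if positions is None:
        pairs = list(masses)
        if not pairs:
            raise SelectionError("empty selection has no center of mass")
        masses = np.array([m for m, _ in pairs], dtype=float)
        positions = np.array([p for _, p in pairs], dtype=float)
    else:
        masses = np.asarray(masses, dtype=float)
        positions = np.asarray(positions, dtype=float)
        if masses.size == 0:
            raise SelectionError("empty selection has no center of mass")
    if np.any(masses <= 0):
        raise ValueError("masses must be > 0")
    return (masses[:, None] * positions).sum(axis=0) / masses.sum()


@dataclass(frozen=True)
class PseudoatomSpec:
    """The four pseudoatom selections defining the base-flip pseudodihedral.

    Each group is a tuple of (residue id, atom name) pairs; P1 is typically
    the heavy atoms of the base pairs flanking the flipping base, P2/P3 the
    two phosphate groups bracketing it along the backbone, and P4 the
    five-membered ring of the flipping purine.
    """

    p1_atoms: tuple
    p2_atoms: tuple
    p3_atoms: tuple
    p4_atoms: tuple

    def __post_init__(self):
        for name in ("p1_atoms", "p2_atoms", "p3_atoms", "p4_atoms"):
            sel = tuple((int(r), str(a)) for r, a in getattr(self, name))
            if not sel:
                raise ValueError(f"{name} selection is empty")
            object.__setattr__(self, name, sel)

    @property
    def groups(self):
        return (self.p1_atoms, self.p2_atoms, self.p3_atoms, self.p4_atoms)


def flip_spec_for_duplex(frame, target_res, flank_residues, phosphate_residues,
                         heavy_only=True):
    """Construct the default PseudoatomSpec for a flipping purine.

    P1 collects the (heavy) atoms of the base pairs above and below the
    target pair, P2/P3 the phosphate groups of the two given residues, and
    P4 the purine five-membered ring of the target residue.  This is a
    documented default — the exact flanking/phosphate membership is a
    modelling choice, and all four groups remain fully configurable.
    """
    p1 = []
    for rid in flank_residues:
        for i in frame.residue_atoms(rid, heavy_only=heavy_only):
            p1.append((int(frame.res_ids[i]), str(frame.atom_names[i])))
    def phosphate(rid):
        sel = [(rid, a) for a in PHOSPHATE_ATOMS if len(frame.select(rid, a))]
        if not sel:
            raise SelectionError(f"no phosphate atoms found in residue {rid}")
        return sel
    p2 = phosphate(phosphate_residues[0])
    p3 = phosphate(phosphate_residues[1])
    p4 = [(target_res, a) for a in PURINE_RING5_ATOMS
          if len(frame.select(target_res, a))]
    return PseudoatomSpec(tuple(p1), tuple(p2), tuple(p3), tuple(p4))


def _resolve_group(frame, group):
    idx = []
    missing = []
    for rid, aname in group:
        hits = frame.select(rid, aname)
        if len(hits) == 0:
            missing.append((rid, aname))
        else:
            idx.extend(hits.tolist())
    if missing:
        raise SelectionError(f"unresolved pseudoatom selections: {missing}")
    return np.array(idx, dtype=int)


def chi_angle(frame, residue):
    """Glycosidic dihedral O4'-C1'-N9-C4 (degrees) of a purine residue."""
    points = []
    for aname in ("O4'", "C1'", "N9", "C4"):
        idx = frame.select(residue, aname)
        if len(idx) == 0:
            raise SelectionError(
                f"chi angle of residue {residue}: atom {aname} is missing")
        points.append(frame.coords[idx[0]])
    return dihedral(*points)


def cpdb_angle(frame, spec):
    """Base-flip pseudodihedral (degrees): dihedral of the four group COMs."""
    centers = []
    for group in spec.groups:
        idx = _resolve_group(frame, group)
        centers.append(center_of_mass(frame.masses[idx], frame.coords[idx]))
    return dihedral(*centers)


def classify_chi(chi):
    """Label a glycosidic angle as 'anti', 'syn' or 'other'.

    anti: [-180, -90); syn: [-90, 90]; other: (90, 180).  The boundary at
    -90 belongs to syn.  The input is wrapped internally, so the three
    labels partition the full circle.
    """
    x = float(wrap_angle(chi))
    if -180.0 <= x < -90.0:
        return "anti"
    if -90.0 <= x <= 90.0:
        return "syn"
    return "other"


@dataclass
class TorsionSeries:
    """Per-frame (time, CPDb, chi) observables; angles in [-180, 180)."""

    times: np.ndarray
    cpdb: np.ndarray
    chi: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cpdb = np.asarray(wrap_angle(self.cpdb), dtype=float)
        self.chi = np.asarray(wrap_angle(self.chi), dtype=float)
        if not (len(self.times) == len(self.cpdb) == len(self.chi)):
            raise ValueError("times, cpdb and chi must have equal lengths")

    def __len__(self):
        return len(self.times)


def extract_timeseries(frames, chi_residue, cpdb_spec, times=None, dt=1.0):
    """Compute one (time, CPDb, chi) row per frame, order preserved."""
    frames = list(frames)
    if times is None:
        times = dt * np.arange(len(frames))
    cpdbs, chis = [], []
    for i, fr in enumerate(frames):
        try:
            cpdbs.append(cpdb_angle(fr, cpdb_spec))
            chis.append(chi_angle(fr, chi_residue))
        except (SelectionError, DegenerateGeometryError) as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
    return TorsionSeries(np.asarray(times, dtype=float),
                         np.array(cpdbs), np.array(chis))
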