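"""Rigid domains, flexible pseudo-linkers, spin-label sites and conformers.

Two independently folded domains are treated as rigid bodies: the
*stationary* body defines the world frame, the *moving* body is placed by
a rotation plus a translation that is derived from a flexible pseudo-linker
chain so the two domains always stay covalently connected.  The linker is
a chain of fixed-length virtual bonds (one per linker residue) with free
pseudo-torsions and bounded pseudo-bend angles; it reproduces the reach
constraint of the real flexible residues at a fraction of the cost of full
backbone torsions.

Spin labels are virtual point sites (optionally weighted point clouds) in
their body's local frame; inter-label distances are plain Euclidean
distances between the effective (weighted-mean) positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

__all__ = [
    "RigidBody",
    "LabelSite",
    "Linker",
    "Conformer",
    "Placement",
    "TwoBodySystem",
    "load_rigid_body",
    "build_linker_chain",
    "place_conformer",
    "label_distance",
    "steric_score",
    "write_ensemble_pdb",
    "wrap_angle",
    "ELEMENT_RADII",
    "COARSE_RADIUS",
]

# soft-sphere contact radii (Angstrom); coarse mode uses one sphere per residue
ELEMENT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
COARSE_RADIUS = 3.0
DEFAULT_BOND_LENGTH = 3.8  # pseudo Calpha-Calpha virtual bond


def wrap_angle(deg):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    wrapped = -((-np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0)
    return float(wrapped) if np.ndim(deg) == 0 else wrapped


@dataclass(frozen=True)
class RigidBody:
    """A rigid domain in a body-local frame.

    ``coords`` are Angstrom positions translated so the geometric centre
    of the rigid-range atoms sits at the origin.  Internal geometry never
    changes: conformers only rotate and translate the body as a whole.
    """

    atom_names: tuple[str, ...]
    residue_ids: np.ndarray  # int, per atom
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3)
    rigid_ranges: tuple[tuple[int, int], ...]
    role: str  # "stationary" | "moving"
    name: str = "body"
    # three non-collinear body-frame points seeding the linker construction
    # frame (inner reference, outer reference, attachment point)
    anchor_triad: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.role not in ("stationary", "moving"):
            raise ValueError(f"role must be stationary|moving, got {self.role!r}")
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_ids", np.asarray(self.residue_ids, dtype=int))
        if self.anchor_triad is not None:
            tri = np.asarray(self.anchor_triad, dtype=float)
            if tri.shape != (3, 3):
                raise ValueError("anchor_triad must be three xyz points")
            object.__setattr__(self, "anchor_triad", tri)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def anchor(self) -> np.ndarray:
        """Attachment point of the linker in the body frame."""
        if self.anchor_triad is None:
            raise ValueError(f"body {self.name!r} has no anchor defined")
        return self.anchor_triad[2]

    def rigid_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_atoms, dtype=bool)
        for lo, hi in self.rigid_ranges:
            mask |= (self.residue_ids >= lo) & (self.residue_ids <= hi)
        return mask

    def calpha_coords(self) -> np.ndarray:
        """Per-residue representative coordinates (CA atoms, coarse steric mode)."""
        idx = [i for i, n in enumerate(self.atom_names) if n == "CA"]
        if not idx:  # point-cloud bodies: every atom is a residue centre
            return self.coords
        return self.coords[idx]

    def radius_of_gyration(self) -> float:
        c = self.coords[self.rigid_mask()]
        centre = c.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum((c - centre) ** 2, axis=1))))


@dataclass(frozen=True)
class LabelSite:
    """A virtual spin-label site attached to one body.

    ``position`` is the effective point in the body frame (by convention
    the centre of the label's terminal N-O bond).  An optional weighted
    ``cloud`` of alternative positions collapses to its weighted mean for
    distance evaluation.
    """

    body_role: str
    residue: int
    position: np.ndarray
    cloud: tuple[tuple[np.ndarray, float], ...] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.cloud is not None:
            cloud = tuple((np.asarray(xyz, dtype=float), float(w)) for xyz, w in self.cloud)
            wsum = sum(w for _, w in cloud)
            if abs(wsum - 1.0) > 1e-9:
                raise ValueError(f"cloud weights sum to {wsum}, expected 1")
            object.__setattr__(self, "cloud", cloud)

    def effective_position(self) -> np.ndarray:
        if self.cloud is None:
            return self.position
        return np.sum([w * xyz for xyz, w in self.cloud], axis=0)


@dataclass(frozen=True)
class Linker:
    """Pseudo-bond chain tethering the moving body to the stationary one."""

    n_residues: int
    bond_length: float = DEFAULT_BOND_LENGTH
    max_bend: float = 100.0  # max deviation (deg) from a straight continuation

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("linker needs at least one residue")

    @property
    def n_torsions(self) -> int:
        return self.n_residues

    @property
    def max_reach(self) -> float:
        return self.n_residues * self.bond_length

    def clip_bends(self, bends) -> np.ndarray:
        return np.clip(np.asarray(bends, dtype=float), 0.0, self.max_bend)


@dataclass
class Conformer:
    """One placement of the moving body: orientation plus linker angles.

    The translation is derived (the moving body's anchor coincides with
    the linker chain end) so the chain is closed by construction.
    """

    quaternion: np.ndarray  # (x, y, z, w), unit norm
    translation: np.ndarray  # derived, world frame
    linker_torsions: np.ndarray  # degrees, (-180, 180]
    linker_bends: np.ndarray  # degrees, [0, max_bend]
    pair_distances: dict[str, float] = field(default_factory=dict)
    target_value: float = np.inf
    relative_probability: float | None = None

    def __post_init__(self) -> None:
        self.quaternion = np.asarray(self.quaternion, dtype=float)
        norm = np.linalg.norm(self.quaternion)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"quaternion norm {norm} != 1")
        self.quaternion = self.quaternion / norm
        self.translation = np.asarray(self.translation, dtype=float)
        self.linker_torsions = wrap_angle(np.asarray(self.linker_torsions, dtype=float))
        self.linker_bends = np.asarray(self.linker_bends, dtype=float)

    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)


@dataclass(frozen=True)
class Placement:
    """World coordinates of a placed conformer."""

    stationary_coords: np.ndarray
    moving_coords: np.ndarray
    linker_points: np.ndarray
    rotation_matrix: np.ndarray
    translation: np.ndarray


def load_rigid_body(pdb_path, chain: str, rigid_ranges, role: str,
                    name: str | None = None, anchor_residue: int | None = None) -> RigidBody:
    """Load one chain of a PDB file as a rigid body.

    Only ATOM records of the first model are used; for alternate locations
    altloc 'A' (or blank) is preferred.  Coordinates are shifted so the
    geometric centre of the rigid-range atoms is at the origin.  Raises if
    any residue declared rigid is absent from the file.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("body", str(pdb_path))
    model = next(iter(structure))
    if chain not in model:
        raise ValueError(f"chain {chain!r} not found in {pdb_path}")
    names, resids, elements, xyz = [], [], [], []
    for residue in model[chain]:
        if residue.id[0] != " ":  # skip HETATM / waters
            continue
        for atom in residue:
            if atom.get_altloc() not in (" ", "A"):
                continue
            names.append(atom.get_name())
            resids.append(residue.id[1])
            elements.append(atom.element if atom.element else atom.get_name()[0])
            xyz.append(atom.get_coord())
    if not xyz:
        raise ValueError(f"no ATOM records for chain {chain!r} in {pdb_path}")
    resids = np.array(resids, dtype=int)
    coords = np.array(xyz, dtype=float)
    ranges = tuple((int(lo), int(hi)) for lo, hi in rigid_ranges)
    present = set(resids.tolist())
    missing = [i for lo, hi in ranges for i in range(lo, hi + 1) if i not in present]
    if missing:
        raise ValueError(f"{pdb_path}: residues declared rigid but missing: {missing}")

    mask = np.zeros(len(coords), dtype=bool)
    for lo, hi in ranges:
        mask |= (resids >= lo) & (resids <= hi)
    coords = coords - coords[mask].mean(axis=0)

    triad = None
    if anchor_residue is not None:
        anchor_idx = _calpha_index(names, resids, anchor_residue)
        triad = _default_triad(coords, coords[anchor_idx])
    return RigidBody(atom_names=tuple(names), residue_ids=resids,
                     elements=tuple(elements), coords=coords,
                     rigid_ranges=ranges, role=role,
                     name=name or f"{pdb_path}:{chain}", anchor_triad=triad)


def _calpha_index(names, resids, residue: int) -> int:
    for i, (n, rid) in enumerate(zip(names, resids)):
        if rid == residue and n == "CA":
            return i
    raise ValueError(f"no CA atom for residue {residue}")


def _default_triad(coords: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Seed a construction frame: body centre, a point offset towards the
    anchor, and the anchor itself (guaranteed non-collinear by the offset)."""
    centre = coords.mean(axis=0)
    direction = anchor - centre
    nrm = np.linalg.norm(direction)
    if nrm < 1e-9:
        direction, nrm = np.array([1.0, 0.0, 0.0]), 1.0
    direction = direction / nrm
    perp = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(direction, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    mid = anchor - 3.8 * direction + 1.0 * perp
    return np.stack([centre, mid, anchor])


def build_linker_chain(triad: np.ndarray, linker: Linker,
                       bends_deg: np.ndarray, torsions_deg: np.ndarray) -> np.ndarray:
    """Grow the pseudo-bond chain from the stationary anchor.

    ``triad`` gives three seed points (world frame) ending at the
    attachment point; each new point is placed at the fixed bond length,
    deviating from the straight continuation by the bend angle and rotated
    about the previous bond by the torsion.  Returns the chain points
    beyond the anchor, shape ``(n_residues, 3)``.
    """
    from math import cos, sin, sqrt

    bends = np.deg2rad(linker.clip_bends(bends_deg))
    torsions = np.deg2rad(np.asarray(torsions_deg, dtype=float))
    if len(bends) != linker.n_residues or len(torsions) != linker.n_residues:
        raise ValueError("need one bend and one torsion per linker residue")
    # scalar arithmetic: this is the hot inner loop of the sampler
    ax, ay, az = triad[0]
    bx, by, bz = triad[1]
    cx, cy, cz = triad[2]
    bond = linker.bond_length
    points = np.empty((linker.n_residues, 3))
    for i in range(linker.n_residues):
        ux, uy, uz = cx - bx, cy - by, cz - bz
        inv = 1.0 / sqrt(ux * ux + uy * uy + uz * uz)
        ux, uy, uz = ux * inv, uy * inv, uz * inv
        vx, vy, vz = bx - ax, by - ay, bz - az
        nx = vy * uz - vz * uy
        ny = vz * ux - vx * uz
        nz = vx * uy - vy * ux
        nn = sqrt(nx * nx + ny * ny + nz * nz)
        if nn < 1e-12:  # collinear history: pick any perpendicular
            nx, ny, nz = uy, -ux, 0.0
            nn = sqrt(nx * nx + ny * ny)
            if nn < 1e-6:
                nx, ny, nz = uz, 0.0, -ux
                nn = sqrt(nx * nx + nz * nz)
        inv = 1.0 / nn
        nx, ny, nz = nx * inv, ny * inv, nz * inv
        mx = ny * uz - nz * uy
        my = nz * ux - nx * uz
        mz = nx * uy - ny * ux
        ct, st = cos(bends[i]), sin(bends[i])
        cp, sp = cos(torsions[i]), sin(torsions[i])
        dx = ct * ux + st * (cp * mx + sp * nx)
        dy = ct * uy + st * (cp * my + sp * ny)
        dz = ct * uz + st * (cp * mz + sp * nz)
        new_x, new_y, new_z = cx + bond * dx, cy + bond * dy, cz + bond * dz
        points[i, 0], points[i, 1], points[i, 2] = new_x, new_y, new_z
        ax, ay, az = bx, by, bz
        bx, by, bz = cx, cy, cz
        cx, cy, cz = new_x, new_y, new_z
    return points


def place_conformer(stationary: RigidBody, moving: RigidBody,
                    conformer: Conformer, linker: Linker) -> Placement:
    """Compute world coordinates for a conformer.

    The stationary body defines the world frame (its coordinates are
    returned unchanged).  The linker chain is grown from the stationary
    anchor; the moving body is rotated by the conformer quaternion and
    translated so its anchor point lands on the chain end.
    """
    chain = build_linker_chain(stationary.anchor_triad, linker,
                               conformer.linker_bends, conformer.linker_torsions)
    R = conformer.rotation().as_matrix()
    t = chain[-1] - R @ moving.anchor
    moving_coords = moving.coords @ R.T + t
    conformer.translation = t
    return Placement(stationary_coords=stationary.coords,
                     moving_coords=moving_coords,
                     linker_points=chain, rotation_matrix=R, translation=t)


def default_label_position(body: RigidBody, residue: int, offset: float = 7.0) -> np.ndarray:
    """Virtual-label position for a residue: ``offset`` Angstrom from the CA
    along the CA->CB direction, approximating the nitroxide N-O bond centre.
    Falls back to the radially-outward direction for CA-only models."""
    idx = {name: i for i, (name, rid) in
           enumerate(zip(body.atom_names, body.residue_ids)) if rid == residue}
    if "CA" not in idx:
        raise ValueError(f"residue {residue} has no CA atom in body {body.name!r}")
    ca = body.coords[idx["CA"]]
    if "CB" in idx:
        direction = body.coords[idx["CB"]] - ca
    else:
        direction = ca - body.coords[body.rigid_mask()].mean(axis=0)
    nrm = np.linalg.norm(direction)
    if nrm < 1e-9:
        direction, nrm = np.array([1.0, 0.0, 0.0]), 1.0
    return ca + offset * direction / nrm


def label_world_position(placement: Placement, site: LabelSite) -> np.ndarray:
    pos = site.effective_position()
    if site.body_role == "stationary":
        return pos
    return placement.rotation_matrix @ pos + placement.translation


def label_distance(placement: Placement, a: LabelSite, b: LabelSite) -> float:
    """Euclidean distance (Angstrom) between two label sites."""
    return float(np.linalg.norm(label_world_position(placement, a)
                                - label_world_position(placement, b)))


def steric_score(placement: Placement, stationary: RigidBody, moving: RigidBody,
                 mode: str = "coarse", stiffness: float = 1.0) -> float:
    """Soft-sphere inter-body clash score: sum of k*max(0, d_min - d)^2.

    ``coarse`` mode uses one sphere per residue at the CA position with a
    3 Angstrom radius; ``atomic`` mode uses per-element contact radii.
    Zero iff no inter-body pair is closer than contact distance.
    """
    if mode == "coarse":
        sc = placement.stationary_coords[_coarse_index(stationary)]
        mc = placement.moving_coords[_coarse_index(moving)]
        dmin = 2.0 * COARSE_RADIUS
        d = cdist(sc, mc)
        overlap = dmin - d
    elif mode == "atomic":
        rs = np.array([ELEMENT_RADII.get(e, 1.7) for e in stationary.elements])
        rm = np.array([ELEMENT_RADII.get(e, 1.7) for e in moving.elements])
        d = cdist(placement.stationary_coords, placement.moving_coords)
        overlap = rs[:, None] + rm[None, :] - d
    else:
        raise ValueError(f"unknown steric mode {mode!r}")
    np.clip(overlap, 0.0, None, out=overlap)
    return float(stiffness * np.sum(overlap * overlap))


def _coarse_index(body: RigidBody) -> np.ndarray:
    idx = [i for i, n in enumerate(body.atom_names) if n == "CA"]
    return np.asarray(idx if idx else range(body.n_atoms), dtype=int)


@dataclass(frozen=True)
class TwoBodySystem:
    """A stationary body, a moving body, their linker, and the label sites."""

    stationary: RigidBody
    moving: RigidBody
    linker: Linker
    labels: dict[str, LabelSite]
    # restraint label -> (site name on stationary, site name on moving)
    pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, (sa, sb) in self.pairs.items():
            ra = self.labels[sa].body_role
            rb = self.labels[sb].body_role
            if ra == rb:
                raise ValueError(f"restraint {pair!r} links two sites on the same body")

    def place(self, conformer: Conformer) -> Placement:
        return place_conformer(self.stationary, self.moving, conformer, self.linker)

    def pair_distances(self, placement: Placement) -> dict[str, float]:
        return {pair: label_distance(placement, self.labels[sa], self.labels[sb])
                for pair, (sa, sb) in self.pairs.items()}


def write_ensemble_pdb(path, system: TwoBodySystem, conformers,
                       max_models: int | None = None) -> None:
    """Write the ensemble as a multi-model PDB (stationary body superposed).

    The stationary body keeps chain A, the linker pseudo-atoms chain L and
    the moving body chain B; loadable by PyMOL/ChimeraX next to the volume
    map so both share a frame.
    """
    conformers = list(conformers)
    if max_models is not None:
        conformers = conformers[:max_models]
    with open(path, "w") as fh:
        fh.write("REMARK   generated by confspace: ensemble in stationary-body frame\n")
        for imodel, conf in enumerate(conformers, 1):
            placement = system.place(conf)
            fh.write(f"MODEL     {imodel:4d}\n")
            serial = 1
            serial = _write_body(fh, system.stationary, placement.stationary_coords, "A", serial)
            for j, pt in enumerate(placement.linker_points, 1):
                fh.write(_atom_record(serial, "CA", "GLY", "L", j, pt, "C"))
                serial += 1
            _write_body(fh, system.moving, placement.moving_coords, "B", serial)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_body_pdb(path, body: RigidBody, chain: str = "A") -> None:
    """Write one body (in its body-local frame) as a single-model PDB."""
    with open(path, "w") as fh:
        fh.write(f"REMARK   confspace rigid body {body.name} ({body.role})\n")
        _write_body(fh, body, body.coords, chain, 1)
        fh.write("END\n")


def _write_body(fh, body: RigidBody, coords: np.ndarray, chain: str, serial: int) -> int:
    for name, rid, elem, xyz in zip(body.atom_names, body.residue_ids, body.elements, coords):
        fh.write(_atom_record(serial, name, "ALA", chain, int(rid), xyz, elem))
        serial += 1
    return serial


def _atom_record(serial, name, resname, chain, resid, xyz, element) -> str:
    name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"ATOM  {serial % 100000:5d} {name_f}{'':1s}{resname:<3s} {chain}"
            f"{resid % 10000:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}\n")
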