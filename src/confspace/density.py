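"""Volumetric rendering of the sampled conformation space.

Every conformer of the (superposed, weighted) ensemble contributes an
isotropic 3D Gaussian centred at its moving body's geometric centre, with
peak amplitude equal to the conformer's relative probability, truncated
beyond a few standard deviations.  Contributions are merged by taking the
*maximum* at each grid point of an evenly spaced grid (1 A default), so
the map encodes "the most probable conformer covering this point" rather
than a summed density.  The grid is written as CCP4/MRC (mode 2) or
OpenDX text, both loadable by PyMOL/ChimeraX alongside the superposed
multi-model PDB.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .structure import RigidBody, TwoBodySystem

__all__ = [
    "DensityGrid",
    "superpose_transform",
    "superpose_on_stationary",
    "moving_centres",
    "build_density_grid",
    "write_volume",
    "read_volume",
    "iso_volume",
]


@dataclass(frozen=True)
class DensityGrid:
    """Regular scalar field; ``values[ix, iy, iz]`` at
    ``origin + (ix, iy, iz) * spacing``."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def superpose_transform(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid transform (R, t) mapping ``mobile`` onto
    ``reference`` (Kabsch)."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def superpose_on_stationary(placements, stationary: RigidBody):
    """Map each placement into the stationary body's reference frame.

    Each conformer's stationary-part coordinates are superposed onto the
    reference body by a least-squares rigid fit and the same transform is
    applied to the moving body and linker.  Returns new placements; the
    post-fit stationary RMSD is exact to numerical precision because the
    rigid bodies are identical.
    """
    from .structure import Placement

    mask = stationary.rigid_mask()
    ref = stationary.coords[mask]
    out = []
    for pl in placements:
        R, t = superpose_transform(pl.stationary_coords[mask], ref)
        out.append(Placement(
            stationary_coords=pl.stationary_coords @ R.T + t,
            moving_coords=pl.moving_coords @ R.T + t,
            linker_points=pl.linker_points @ R.T + t,
            rotation_matrix=R @ pl.rotation_matrix,
            translation=R @ pl.translation + t))
    return out


def moving_centres(system: TwoBodySystem, ensemble) -> np.ndarray:
    """Geometric centre of the moving body's rigid part for every conformer."""
    mask = system.moving.rigid_mask()
    local_centre = system.moving.coords[mask].mean(axis=0)
    centres = np.empty((len(ensemble.conformers), 3))
    for i, conf in enumerate(ensemble.conformers):
        R = conf.rotation().as_matrix()
        centres[i] = R @ local_centre + conf.translation
    return centres


def build_density_grid(centres: np.ndarray, relatives: np.ndarray,
                       spacing: float = 1.0, sigma_density: float = 10.0,
                       truncation: float = 3.0) -> DensityGrid:
    """Max-merged grid of probability-scaled Gaussians.

    ``centres`` are Gaussian centres (one or more per conformer),
    ``relatives`` the matching peak amplitudes in [0, 1].  Each Gaussian
    is evaluated only within ``truncation * sigma_density`` of its centre;
    the grid box covers every centre plus the truncation radius plus one
    voxel of padding.
    """
    if sigma_density <= 0:
        raise ValueError("sigma_density must be positive")
    centres = np.atleast_2d(np.asarray(centres, dtype=float))
    relatives = np.atleast_1d(np.asarray(relatives, dtype=float))
    if len(centres) != len(relatives):
        raise ValueError("one amplitude per Gaussian centre required")
    pad = truncation * sigma_density + spacing
    lo = centres.min(axis=0) - pad
    hi = centres.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    values = np.zeros(shape)
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    r_trunc = truncation * sigma_density
    inv2s2 = 1.0 / (2.0 * sigma_density ** 2)
    for centre, amp in zip(centres, relatives):
        if amp <= 0.0:
            continue
        sl = []
        for k in range(3):
            i0 = max(int(np.floor((centre[k] - r_trunc - lo[k]) / spacing)), 0)
            i1 = min(int(np.ceil((centre[k] + r_trunc - lo[k]) / spacing)) + 1, shape[k])
            sl.append((i0, i1))
        gx = axes[0][sl[0][0]:sl[0][1]] - centre[0]
        gy = axes[1][sl[1][0]:sl[1][1]] - centre[1]
        gz = axes[2][sl[2][0]:sl[2][1]] - centre[2]
        r2 = (gx[:, None, None] ** 2 + gy[None, :, None] ** 2
              + gz[None, None, :] ** 2)
        contrib = amp * np.exp(-r2 * inv2s2)
        contrib[r2 > r_trunc * r_trunc] = 0.0
        block = values[sl[0][0]:sl[0][1], sl[1][0]:sl[1][1], sl[2][0]:sl[2][1]]
        np.maximum(block, contrib, out=block)
    return DensityGrid(origin=lo, spacing=spacing, values=values)


def density_centres_per_residue(system: TwoBodySystem, ensemble):
    """Centres and amplitudes for the per-residue Gaussian mode
    (one Gaussian per moving-body residue, all at the conformer's weight)."""
    from .structure import _coarse_index

    idx = _coarse_index(system.moving)
    local = system.moving.coords[idx]
    centres, amps = [], []
    for conf in ensemble.conformers:
        R = conf.rotation().as_matrix()
        centres.append(local @ R.T + conf.translation)
        rel = conf.relative_probability if conf.relative_probability is not None else 1.0
        amps.extend([rel] * len(local))
    return np.concatenate(centres, axis=0), np.asarray(amps)


def iso_volume(grid: DensityGrid, level: float) -> float:
    """Volume (A^3) of the region with values above ``level``."""
    return float(np.sum(grid.values > level)) * grid.spacing ** 3


# ---------------------------------------------------------------------------
# volume file I/O (CCP4/MRC mode-2 float maps and OpenDX scalar fields)

def write_volume(grid: DensityGrid, path, format: str = "mrc") -> None:
    """Write the grid as a CCP4/MRC 2000 map or an OpenDX text field."""
    if format == "mrc":
        _write_mrc(grid, path)
    elif format == "dx":
        _write_dx(grid, path)
    else:
        raise ValueError(f"unknown volume format {format!r}")


def read_volume(path, format: str = "mrc") -> DensityGrid:
    if format == "mrc":
        return _read_mrc(path)
    if format == "dx":
        return _read_dx(path)
    raise ValueError(f"unknown volume format {format!r}")


def _write_mrc(grid: DensityGrid, path) -> None:
    nx, ny, nz = grid.shape
    data = np.ascontiguousarray(np.transpose(grid.values, (2, 1, 0)),
                                dtype="<f4")  # x fastest on disk
    vals = grid.values
    header = bytearray(1024)
    struct.pack_into("<10i", header, 0,
                     nx, ny, nz,  # NC NR NS
                     2,           # MODE: 32-bit float
                     0, 0, 0,     # start indices
                     nx, ny, nz)  # sampling along cell axes
    struct.pack_into("<6f", header, 40,
                     nx * grid.spacing, ny * grid.spacing, nz * grid.spacing,
                     90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order x, y, z
    struct.pack_into("<3f", header, 76,
                     float(vals.min()), float(vals.max()), float(vals.mean()))
    struct.pack_into("<2i", header, 88, 1, 0)  # ISPG=1, NSYMBT=0
    struct.pack_into("<3f", header, 196, *grid.origin)  # ORIGIN
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian MACHST
    struct.pack_into("<f", header, 216, float(vals.std()))
    struct.pack_into("<i", header, 220, 0)  # NLABL
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data.tobytes())


def _read_mrc(path) -> DensityGrid:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        if mode != 2:
            raise ValueError(f"unsupported MRC mode {mode}")
        cell = struct.unpack_from("<3f", header, 40)
        origin = struct.unpack_from("<3f", header, 196)
        data = np.frombuffer(fh.read(4 * nx * ny * nz), dtype="<f4")
    values = np.transpose(data.reshape(nz, ny, nx), (2, 1, 0)).astype(float)
    spacing = cell[0] / nx
    return DensityGrid(origin=np.array(origin), spacing=float(spacing), values=values)


def _write_dx(grid: DensityGrid, path) -> None:
    nx, ny, nz = grid.shape
    flat = grid.values.reshape(-1)  # z fastest, per OpenDX convention
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing:.6f} 0 0\n")
        fh.write(f"delta 0 {grid.spacing:.6f} 0\n")
        fh.write(f"delta 0 0 {grid.spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {flat.size} data follows\n")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def _read_dx(path) -> DensityGrid:
    shape = origin = spacing = None
    data: list[float] = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("object 1"):
                shape = tuple(int(x) for x in s.split()[-3:])
            elif s.startswith("origin"):
                origin = np.array([float(x) for x in s.split()[1:4]])
            elif s.startswith("delta") and spacing is None:
                spacing = float(s.split()[1])
            elif s and s[0] in "-+0123456789" and shape is not None:
                data.extend(float(x) for x in s.split())
    values = np.array(data).reshape(shape)
    return DensityGrid(origin=origin, spacing=spacing, values=values)
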