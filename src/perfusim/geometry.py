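"""Meshes, masks, vessel maps, observation upscaling and region partitions.

The computational domain is a regular Cartesian cell grid in which selected
cells are inactive, mapping out the tissue geometry (e.g. an organ outline).
Cells carry a vessel label (tissue / artery / vein); flow is driven by
Dirichlet pressures on designated inlet (artery) and outlet (vein) cells on
the domain boundary, with no-flow conditions on all other external faces.

Coordinate convention: 0-based cell indices, x is the first array axis and
y the second; cell (i, j) has its center at ((i + 0.5) h, (j + 0.5) h).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# vessel label codes
TISSUE = 0
ARTERY = 1
VEIN = 2

# grayscale mask dialect: 0 = inactive, 255 = tissue, 200 = artery, 100 = vein
GRAY_INACTIVE = 0
GRAY_TISSUE = 255
GRAY_ARTERY = 200
GRAY_VEIN = 100


class ConfigurationError(ValueError):
    """Raised when a mesh or boundary specification is inconsistent."""


@dataclass
class BoundaryConditions:
    """Dirichlet pressures: arterial inlet p_a0 and venous outlet p_v0 (Pa)."""

    p_a0: float
    p_v0: float

    def __post_init__(self) -> None:
        if not self.p_a0 > self.p_v0:
            raise ConfigurationError(
                f"inlet pressure p_a0={self.p_a0} must exceed outlet p_v0={self.p_v0}"
            )


@dataclass
class Mesh:
    """Regular Cartesian cell grid with an active mask and vessel labels.

    Attributes
    ----------
    nx, ny : int
        Cell counts along x (first axis) and y (second axis).
    cell_size : float
        Cell edge length h in meters (square cells).
    active : (nx, ny) bool array
        True for cells inside the tissue domain.
    vessel_label : (nx, ny) int array
        TISSUE / ARTERY / VEIN per cell.
    inlet_cells, outlet_cells : list of (i, j)
        Boundary cells carrying Dirichlet arterial / venous pressure.
    vessel_diameter : (nx, ny) float array or None
        Vessel diameter (m) in labeled cells, used for the Hagen-Poiseuille
        transmissibility override T = D^2 / (32 mu).
    """

    nx: int
    ny: int
    cell_size: float
    active: np.ndarray
    vessel_label: np.ndarray
    inlet_cells: list = field(default_factory=list)
    outlet_cells: list = field(default_factory=list)
    vessel_diameter: np.ndarray | None = None

    # --- derived helpers -------------------------------------------------
    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def n_inactive(self) -> int:
        return self.nx * self.ny - self.n_active

    @property
    def cell_index(self) -> np.ndarray:
        """(nx, ny) int array: dense index of each active cell, -1 if inactive."""
        idx = -np.ones((self.nx, self.ny), dtype=np.int64)
        idx[self.active] = np.arange(self.n_active)
        return idx

    @property
    def active_ij(self) -> np.ndarray:
        """(n_active, 2) array of (i, j) indices in row-major order."""
        return np.argwhere(self.active)

    def is_boundary(self, i: int, j: int) -> bool:
        return i in (0, self.nx - 1) or j in (0, self.ny - 1)


def build_mesh(
    nx: int,
    ny: int,
    cell_size: float,
    active_mask: np.ndarray | None = None,
    vessel_label: np.ndarray | None = None,
    inlet_cells=(),
    outlet_cells=(),
    vessel_diameter: np.ndarray | None = None,
) -> Mesh:
    """Assemble and validate a :class:`Mesh`.

    Inlet cells must be active artery cells and outlet cells active vein
    cells, both on the domain boundary; at least one of each is required.
    """
    if nx < 1 or ny < 1:
        raise ConfigurationError("nx and ny must be >= 1")
    if cell_size <= 0:
        raise ConfigurationError("cell_size must be positive")
    if active_mask is None:
        active_mask = np.ones((nx, ny), dtype=bool)
    active_mask = np.asarray(active_mask, dtype=bool)
    if vessel_label is None:
        vessel_label = np.zeros((nx, ny), dtype=np.int8)
    vessel_label = np.asarray(vessel_label)
    if active_mask.shape != (nx, ny) or vessel_label.shape != (nx, ny):
        raise ConfigurationError(
            f"mask/label shape must be ({nx}, {ny}), got {active_mask.shape} and {vessel_label.shape}"
        )
    inlet_cells = [tuple(c) for c in inlet_cells]
    outlet_cells = [tuple(c) for c in outlet_cells]
    if not inlet_cells:
        raise ConfigurationError("at least one inlet cell is required")
    if not outlet_cells:
        raise ConfigurationError("at least one outlet cell is required")
    mesh = Mesh(nx, ny, float(cell_size), active_mask, vessel_label,
                inlet_cells, outlet_cells, vessel_diameter)
    for (i, j) in inlet_cells:
        if not active_mask[i, j]:
            raise ConfigurationError(f"inlet cell {(i, j)} is inactive")
        if vessel_label[i, j] != ARTERY:
            raise ConfigurationError(f"inlet cell {(i, j)} is not an artery cell")
        if not mesh.is_boundary(i, j):
            raise ConfigurationError(f"inlet cell {(i, j)} is not on the domain boundary")
    for (i, j) in outlet_cells:
        if not active_mask[i, j]:
            raise ConfigurationError(f"outlet cell {(i, j)} is inactive")
        if vessel_label[i, j] != VEIN:
            raise ConfigurationError(f"outlet cell {(i, j)} is not a vein cell")
        if not mesh.is_boundary(i, j):
            raise ConfigurationError(f"outlet cell {(i, j)} is not on the domain boundary")
    return mesh


def vessel_transmissibility(diameter: float, viscosity: float) -> float:
    """Hagen-Poiseuille-equivalent Darcy transmissibility T = D^2 / (32 mu).

    Obtained by matching the Darcy equation (porosity 1) with Poiseuille flow
    through a vessel of diameter ``D``; units m^2/(Pa s).
    """
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    if diameter < 0:
        raise ValueError("diameter must be nonnegative")
    return diameter**2 / (32.0 * viscosity)


def coarsen_field(field2d: np.ndarray, factor: int,
                  active: np.ndarray | None = None):
    """Block-average a single 2D field; returns (coarse, coarse_active).

    Each coarse value is the arithmetic mean of its factor x factor block
    restricted to active fine cells.  Trailing partial blocks are averaged
    over the available cells.  Blocks with no active cells are marked
    inactive (value 0).
    """
    if factor < 1:
        raise ValueError("coarsening factor must be >= 1")
    nx, ny = field2d.shape
    if active is None:
        active = np.ones((nx, ny), dtype=bool)
    cnx = -(-nx // factor)
    cny = -(-ny // factor)
    vals = np.where(active, field2d, 0.0)
    coarse = np.zeros((cnx, cny))
    counts = np.zeros((cnx, cny))
    # pad to full blocks, then block-sum
    pnx, pny = cnx * factor, cny * factor
    vp = np.zeros((pnx, pny))
    cp = np.zeros((pnx, pny))
    vp[:nx, :ny] = vals
    cp[:nx, :ny] = active
    coarse = vp.reshape(cnx, factor, cny, factor).sum(axis=(1, 3))
    counts = cp.reshape(cnx, factor, cny, factor).sum(axis=(1, 3))
    coarse_active = counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        coarse = np.where(coarse_active, coarse / np.maximum(counts, 1), 0.0)
    return coarse, coarse_active


def coarsen_series(series: np.ndarray, factor: int,
                   active: np.ndarray | None = None):
    """Coarsen an (nt, nx, ny) time series of fields; see :func:`coarsen_field`.

    Returns (coarse series of shape (nt, cnx, cny), coarse_active).
    """
    series = np.asarray(series)
    if series.ndim == 2:
        return coarsen_field(series, factor, active)
    out = []
    coarse_active = None
    for t in range(series.shape[0]):
        c, coarse_active = coarsen_field(series[t], factor, active)
        out.append(c)
    return np.stack(out), coarse_active


@dataclass
class RegionPartition:
    """Rectangular tiling of a mesh into (rows x cols) regions of interest.

    ``region_id`` is an (nx, ny) int array giving each active cell's region
    (row-major over tiles); inactive cells hold -1.
    """

    level: tuple
    region_id: np.ndarray
    n_regions: int

    def region_cells(self, r: int) -> np.ndarray:
        return np.argwhere(self.region_id == r)


def partition_regions(mesh: Mesh, rows: int, cols: int) -> RegionPartition:
    """Tile the mesh bounding box into rows x cols regions.

    Tiles are as equal as possible; trailing tiles absorb remainders.  Every
    active cell belongs to exactly one region.
    """
    if not (1 <= rows <= mesh.nx) or not (1 <= cols <= mesh.ny):
        raise ValueError("partition level must satisfy 1 <= rows <= nx, 1 <= cols <= ny")
    xi = np.minimum((np.arange(mesh.nx) * rows) // mesh.nx, rows - 1)
    yj = np.minimum((np.arange(mesh.ny) * cols) // mesh.ny, cols - 1)
    rid = xi[:, None] * cols + yj[None, :]
    rid = np.where(mesh.active, rid, -1)
    return RegionPartition((rows, cols), rid, rows * cols)


# ---------------------------------------------------------------------------
# mask / label readers

def read_label_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an active mask and vessel labels from a grayscale raster or text matrix.

    Grayscale dialect: 0 = inactive, 255 = tissue, 200 = artery, 100 = vein.
    Delimited text matrices may either use the grayscale codes or the label
    codes {-1: inactive, 0: tissue, 1: artery, 2: vein} directly.

    Returns (active, vessel_label).
    """
    path = str(path)
    if path.endswith((".png", ".tif", ".tiff")):
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"), dtype=np.int16).T
    else:
        arr = np.loadtxt(path, delimiter=None if path.endswith(".txt") else ",",
                         dtype=np.int16)
    if arr.max() > 2:  # grayscale dialect
        active = arr != GRAY_INACTIVE
        label = np.zeros(arr.shape, dtype=np.int8)
        label[arr == GRAY_ARTERY] = ARTERY
        label[arr == GRAY_VEIN] = VEIN
    else:
        active = arr >= 0
        label = np.maximum(arr, 0).astype(np.int8)
    return active, label


def save_mesh(h5group, mesh: Mesh) -> None:
    """Write mesh arrays into an open h5py group."""
    h5group.attrs["nx"] = mesh.nx
    h5group.attrs["ny"] = mesh.ny
    h5group.attrs["cell_size"] = mesh.cell_size
    h5group.create_dataset("active", data=mesh.active)
    h5group.create_dataset("vessel_label", data=mesh.vessel_label)
    h5group.create_dataset("inlet_cells", data=np.asarray(mesh.inlet_cells, dtype=np.int64))
    h5group.create_dataset("outlet_cells", data=np.asarray(mesh.outlet_cells, dtype=np.int64))
    if mesh.vessel_diameter is not None:
        h5group.create_dataset("vessel_diameter", data=mesh.vessel_diameter)


def load_mesh(h5group) -> Mesh:
    vd = h5group["vessel_diameter"][...] if "vessel_diameter" in h5group else None
    return Mesh(
        int(h5group.attrs["nx"]),
        int(h5group.attrs["ny"]),
        float(h5group.attrs["cell_size"]),
        h5group["active"][...].astype(bool),
        h5group["vessel_label"][...],
        [tuple(c) for c in h5group["inlet_cells"][...]],
        [tuple(c) for c in h5group["outlet_cells"][...]],
        vd,
    )
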