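"""Grid-based electrostatic-potential models and RMSE/RRMSE metrics.

A model potential is a sum of per-atom terms evaluated at off-nucleus
points (in hartree/e):

* ``charges``:       q_A / r
* ``atomic_dipoles``:  mu_A . (r - r_A) / |r - r_A|^3
* ``cloud_penetration``: N_cloud * exp(-b r) (1/r + b/2), the potential of
  the neutral pair {+N_cloud point, diffuse exponential electron cloud
  rho(r) = a exp(-b r), N_cloud = 8 pi a / b^3}.  A positive test charge
  penetrating the cloud sees less enclosed negative charge, so the
  correction is positive and decays exponentially.

For 3D-periodic cells the charge term is an Ewald sum in the tinfoil
(zero-average) gauge; dipole and cloud terms are real-space sums converged
by cutoff.  Periodic potentials carry an arbitrary constant, so metric
evaluation offers mean-offset alignment (default on for periodic grids).

Model quality is scored over *valid* grid points only: electron density
below 1e-4 e/bohr^3, farther than 2 A from every atom, and within 5 A of
at least one atom.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import erfc

from .constants import ANGSTROM_TO_BOHR, HARTREE_TO_KCAL_PER_MOL, element_symbol
from .errors import SchemaError, UnsupportedOperationError, ValidationError
from .partition import StockholderPartition

DEFAULT_RHO_MAX = 1.0e-4  # e / bohr^3
DEFAULT_INNER_ANGSTROM = 2.0
DEFAULT_OUTER_ANGSTROM = 5.0

ESP_TERMS = ("charges", "atomic_dipoles", "cloud_penetration")


@dataclass
class PotentialGrid:
    """Volumetric scalar field on a regular (possibly sheared) grid.

    ``origin`` (bohr), ``axes`` (3 step vectors, bohr, rows), ``values`` of
    shape ``shape``; ``kind`` is "esp" (hartree/e) or "density" (e/bohr^3).
    """

    origin: np.ndarray
    axes: np.ndarray
    values: np.ndarray
    kind: str = "esp"
    periodic: bool = False

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValidationError("grid values must be a 3D array")
        if abs(np.linalg.det(self.axes)) < 1e-14:
            raise ValidationError("grid axes are linearly dependent")
        if self.kind not in ("esp", "density"):
            raise ValidationError(f"unknown grid kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def points(self) -> np.ndarray:
        """All grid-point positions, shape (n_points, 3), C order."""
        n1, n2, n3 = self.shape
        idx = np.stack(
            np.meshgrid(np.arange(n1), np.arange(n2), np.arange(n3), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return self.origin + idx @ self.axes


@dataclass
class ValidMask:
    mask: np.ndarray

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def flat(self) -> np.ndarray:
        return self.mask.reshape(-1)


@dataclass
class EspMetrics:
    rmse: float  # kcal mol^-1 e^-1
    rrmse: float
    r_squared: float
    n_valid: int

    @property
    def rmse_au(self) -> float:
        return self.rmse / HARTREE_TO_KCAL_PER_MOL


# ---------------------------------------------------------------------------
# Gaussian cube I/O
# ---------------------------------------------------------------------------

def write_cube(grid: PotentialGrid, partition: StockholderPartition, path) -> None:
    """Write a Gaussian cube file (bohr units, positive atom count)."""
    lines = [f"qdrcharges {grid.kind} grid", "generated by qdrcharges"]
    n = partition.n_atoms
    lines.append(
        f"{n:5d} {grid.origin[0]:12.6f} {grid.origin[1]:12.6f} {grid.origin[2]:12.6f}"
    )
    for i in range(3):
        ax = grid.axes[i]
        lines.append(
            f"{grid.shape[i]:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}"
        )
    for a in partition.atoms:
        p = a.position
        lines.append(
            f"{a.element:5d} {float(a.charge):12.6f} {p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f}"
        )
    flat = grid.values.reshape(grid.shape[0] * grid.shape[1], grid.shape[2])
    for row in flat:
        for start in range(0, len(row), 6):
            lines.append(" ".join(f"{v: .5E}" for v in row[start : start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path, kind: str = "esp") -> tuple[PotentialGrid, np.ndarray, np.ndarray]:
    """Read a Gaussian cube file; returns (grid, elements, positions_bohr)."""
    tokens_lines = Path(path).read_text().splitlines()
    try:
        hdr = tokens_lines[2].split()
        n_atoms = int(hdr[0])
        origin = np.array([float(v) for v in hdr[1:4]])
        shape = []
        axes = []
        for i in range(3):
            t = tokens_lines[3 + i].split()
            shape.append(int(t[0]))
            axes.append([float(v) for v in t[1:4]])
        elements = np.zeros(abs(n_atoms), dtype=int)
        positions = np.zeros((abs(n_atoms), 3))
        for i in range(abs(n_atoms)):
            t = tokens_lines[6 + i].split()
            elements[i] = int(t[0])
            positions[i] = [float(v) for v in t[2:5]]
        data = []
        for ln in tokens_lines[6 + abs(n_atoms):]:
            data.extend(float(v) for v in ln.split())
        values = np.array(data).reshape(shape)
    except (IndexError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed cube file ({exc})") from exc
    grid = PotentialGrid(origin=origin, axes=np.array(axes), values=values, kind=kind)
    return grid, elements, positions


# ---------------------------------------------------------------------------
# valid-point selection
# ---------------------------------------------------------------------------

def _min_atom_distances(
    points: np.ndarray, partition: StockholderPartition, reach: float
) -> np.ndarray:
    """Distance from each point to the nearest atom (or periodic image)."""
    pos = partition.positions
    cell = partition.cell
    if cell.is_periodic:
        shifts = []
        for i in range(3):
            if cell.periodic_flags[i]:
                n = int(np.ceil(reach / np.linalg.norm(cell.lattice[i]))) + 1
                shifts.append(range(-n, n + 1))
            else:
                shifts.append(range(0, 1))
        images = np.concatenate(
            [
                pos + np.array([i, j, k], dtype=float) @ cell.lattice
                for i in shifts[0]
                for j in shifts[1]
                for k in shifts[2]
            ]
        )
    else:
        images = pos
    d, _ = cKDTree(images).query(points, k=1)
    return d


def valid_grid_mask(
    density: PotentialGrid,
    partition: StockholderPartition,
    rho_max: float = DEFAULT_RHO_MAX,
    inner_angstrom: float = DEFAULT_INNER_ANGSTROM,
    outer_angstrom: float = DEFAULT_OUTER_ANGSTROM,
) -> ValidMask:
    """Mask of valid grid points: rho < rho_max, distance-to-nearest-atom
    in (inner, outer]."""
    if density.kind != "density":
        raise ValidationError("valid_grid_mask needs a density grid")
    inner = inner_angstrom * ANGSTROM_TO_BOHR
    outer = outer_angstrom * ANGSTROM_TO_BOHR
    pts = density.points()
    d = _min_atom_distances(pts, partition, reach=outer + 2.0)
    mask = (
        (density.values.reshape(-1) < rho_max) & (d > inner) & (d <= outer)
    ).reshape(density.shape)
    vm = ValidMask(mask=mask)
    if vm.n_valid == 0:
        raise ValidationError(
            "no valid grid points; check that the grid and geometry are in the "
            "same frame and that the grid extends 2-5 A beyond the atoms"
        )
    return vm


# ---------------------------------------------------------------------------
# model potential
# ---------------------------------------------------------------------------

def _cloud_counts(partition: StockholderPartition) -> np.ndarray:
    n = np.zeros(partition.n_atoms)
    for i, a in enumerate(partition.atoms):
        if a.cloud_a is None or a.cloud_b is None:
            raise ValidationError(
                f"atom {i}: cloud_penetration term requires cloud_a/cloud_b"
            )
        n[i] = 8.0 * np.pi * a.cloud_a / a.cloud_b**3
    return n


def _real_space_images(partition: StockholderPartition, reach: float) -> np.ndarray:
    """Atom-image index/shift table covering a real-space cutoff."""
    cell = partition.cell
    shifts = []
    for i in range(3):
        if cell.periodic_flags[i]:
            n = int(np.ceil(reach / np.linalg.norm(cell.lattice[i]))) + 1
            shifts.append(range(-n, n + 1))
        else:
            shifts.append(range(0, 1))
    return np.array(
        [[i, j, k] for i in shifts[0] for j in shifts[1] for k in shifts[2]],
        dtype=float,
    )


def _ewald_charge_potential(
    partition: StockholderPartition, points: np.ndarray, accuracy: float = 1e-10
) -> np.ndarray:
    """Ewald potential of the point charges for a 3D-periodic cell,
    tinfoil (zero-average) gauge."""
    cell = partition.cell
    if cell.n_periodic != 3:
        raise UnsupportedOperationError(
            "periodic ESP evaluation implemented for 3D-periodic cells only"
        )
    lat = cell.lattice
    vol = cell.volume()
    q = partition.charges
    pos = partition.positions

    alpha = (len(q) * np.pi**3 / vol**2) ** (1.0 / 6.0)
    rcut = np.sqrt(-np.log(accuracy)) / alpha
    kcut = 2.0 * alpha * np.sqrt(-np.log(accuracy))

    v = np.zeros(len(points))
    # real-space part
    shifts = _real_space_images(partition, rcut)
    for shift in shifts:
        disp = points[:, None, :] - (pos + shift @ lat)[None, :, :]
        d = np.linalg.norm(disp, axis=2)
        v += (q[None, :] * erfc(alpha * d) / d).sum(axis=1)
    # reciprocal part
    rec = 2.0 * np.pi * np.linalg.inv(lat).T
    nmax = [int(np.ceil(kcut / np.linalg.norm(rec[i]))) + 1 for i in range(3)]
    for n1 in range(-nmax[0], nmax[0] + 1):
        for n2 in range(-nmax[1], nmax[1] + 1):
            for n3 in range(-nmax[2], nmax[2] + 1):
                if n1 == n2 == n3 == 0:
                    continue
                k = n1 * rec[0] + n2 * rec[1] + n3 * rec[2]
                k2 = k @ k
                if k2 > kcut * kcut:
                    continue
                sk = np.sum(q * np.exp(-1j * (pos @ k)))
                v += (
                    4.0 * np.pi / (vol * k2)
                    * np.exp(-k2 / (4.0 * alpha**2))
                    * np.real(sk * np.exp(1j * (points @ k)))
                )
    # charged-background term (zero for neutral cells)
    v -= np.pi * np.sum(q) / (alpha**2 * vol)
    return v


def model_potential(
    partition: StockholderPartition,
    points: np.ndarray,
    terms=("charges",),
    real_space_cutoff_angstrom: float = 25.0,
    units: str = "au",
) -> np.ndarray:
    """Model electrostatic potential at the given points (bohr).

    ``terms`` selects the contributions; ``units`` is "au" (hartree/e) or
    "kcal/mol/e".  Points must not coincide with nuclei.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    for t in terms:
        if t not in ESP_TERMS:
            raise ValidationError(f"unknown potential term {t!r}")
    pos = partition.positions
    q = partition.charges
    mu = partition.dipoles
    periodic = partition.cell.is_periodic
    v = np.zeros(len(points))

    if "charges" in terms:
        if periodic:
            v += _ewald_charge_potential(partition, points)
        else:
            disp = points[:, None, :] - pos[None, :, :]
            d = np.linalg.norm(disp, axis=2)
            if np.any(d < 1e-10):
                raise ValidationError("evaluation point coincides with a nucleus")
            v += (q[None, :] / d).sum(axis=1)

    short_terms = [t for t in terms if t != "charges"]
    if short_terms:
        reach = real_space_cutoff_angstrom * ANGSTROM_TO_BOHR
        shifts = _real_space_images(partition, reach) if periodic else np.zeros((1, 3))
        n_cloud = _cloud_counts(partition) if "cloud_penetration" in short_terms else None
        b = (
            np.array([a.cloud_b for a in partition.atoms])
            if n_cloud is not None
            else None
        )
        for shift in shifts:
            disp = points[:, None, :] - (pos + shift @ partition.cell.lattice)[None, :, :]
            d = np.linalg.norm(disp, axis=2)
            if np.any(d < 1e-10):
                raise ValidationError("evaluation point coincides with a nucleus")
            if periodic:
                far = d > reach
            else:
                far = np.zeros_like(d, dtype=bool)
            if "atomic_dipoles" in short_terms:
                contrib = np.einsum("pai,ai->pa", disp, mu) / d**3
                contrib[far] = 0.0
                v += contrib.sum(axis=1)
            if n_cloud is not None:
                contrib = n_cloud[None, :] * np.exp(-b[None, :] * d) * (
                    1.0 / d + b[None, :] / 2.0
                )
                contrib[far] = 0.0
                v += contrib.sum(axis=1)

    if units == "kcal/mol/e":
        v = v * HARTREE_TO_KCAL_PER_MOL
    elif units != "au":
        raise ValidationError(f"unknown units {units!r}")
    return v


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def esp_metrics(
    model_values: np.ndarray,
    qm_values: np.ndarray,
    mask: ValidMask | np.ndarray,
    align_offset: bool = False,
    input_units: str = "au",
) -> EspMetrics:
    """RMSE/RRMSE/R^2 of a model potential against the reference.

    The null model sets every atomic charge to zero, i.e. predicts zero
    potential everywhere, so RMSE_null is the rms reference potential over
    the mask.  ``align_offset`` removes the mean model-reference difference
    first (and the reference mean from the null), appropriate for periodic
    potentials which carry an arbitrary constant.
    """
    m = np.asarray(mask.flat if isinstance(mask, ValidMask) else mask, dtype=bool).reshape(-1)
    mv = np.asarray(model_values, dtype=float).reshape(-1)[m]
    qv = np.asarray(qm_values, dtype=float).reshape(-1)[m]
    if len(mv) == 0:
        raise ValidationError("empty valid mask")
    diff = mv - qv
    null = qv.copy()
    if align_offset:
        diff = diff - np.mean(diff)
        null = null - np.mean(null)
    rmse = float(np.sqrt(np.mean(diff**2)))
    rmse_null = float(np.sqrt(np.mean(null**2)))
    if rmse_null == 0.0:
        raise ValidationError("reference potential vanishes on mask; RRMSE undefined")
    rrmse = rmse / rmse_null
    scale = HARTREE_TO_KCAL_PER_MOL if input_units == "au" else 1.0
    return EspMetrics(
        rmse=rmse * scale,
        rrmse=rrmse,
        r_squared=1.0 - rrmse**2,
        n_valid=len(mv),
    )
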