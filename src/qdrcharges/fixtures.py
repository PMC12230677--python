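"""Synthetic stockholder partitions, conformational ensembles, and oracle
potential/density grids.

Every other module is testable from these generators alone: they emulate
(i) the per-atom charge/dipole/quadrupole + overlap-population exchange
data a stockholder partitioning code would produce, (ii) volumetric
"reference" ESP and density grids whose ground truth is a known multipole
model, and (iii) per-method, per-conformation charge ensembles with
controlled correlation structure.  Identical specs and seeds reproduce
identical fixtures bitwise.

The water-like fixture uses published starting magnitudes for a gas-phase
water molecule (H charge 0.388, |mu_H| 0.042, |Theta_H| 0.053; O charge
-0.776, |mu_O| 0.136, |Theta_O| 0.384, all a.u.); the orientations of the
dipoles and quadrupole principal axes are generator-defined C2v-symmetric
choices, so only the magnitudes are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_BOHR
from .errors import ValidationError
from .esp import PotentialGrid, model_potential
from .partition import AtomSite, Cell, StockholderPartition, enumerate_pairs
from .ensembles import EnsembleChargeTable

FIXTURE_KINDS = (
    "diatomic",
    "homodiatomic",
    "water_like",
    "chain",
    "rocksalt",
    "ring_tube",
    "random",
)

# default cloud parameters: rho = a exp(-b r) with the 1e-4 e/bohr^3
# isosurface at ~2.65 A, between the 2 A and 5 A mask cutoffs
DEFAULT_CLOUD_A = 2.2
DEFAULT_CLOUD_B = 2.0


@dataclass
class FixtureSpec:
    kind: str = "random"
    seed: int = 0
    size: int = 8
    op_scale: float = 0.5
    dipole_scale: float = 0.1
    quadrupole_scale: float = 0.1
    net_charge: float = 0.0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValidationError(f"unknown fixture kind {self.kind!r}")


def _axial_quadrupole(axis: np.ndarray, frobenius_norm: float) -> np.ndarray:
    """Traceless axially symmetric tensor s (u u^T - I/3) with the given
    Frobenius norm (|| u u^T - I/3 ||_F = sqrt(2/3))."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    s = frobenius_norm / np.sqrt(2.0 / 3.0)
    return s * (np.outer(u, u) - np.eye(3) / 3.0)


def _finalize(
    atoms: list[AtomSite],
    cell: Cell,
    op_table: dict,
    method_name: str,
    net_charge: float,
) -> StockholderPartition:
    for a in atoms:
        a.n_electrons = a.element - a.charge
        if a.cloud_a is None:
            a.cloud_a = DEFAULT_CLOUD_A
            a.cloud_b = DEFAULT_CLOUD_B
    pairs = enumerate_pairs(atoms, cell, op_table=op_table)
    part = StockholderPartition(
        atoms=atoms, cell=cell, pairs=pairs, method_name=method_name,
        net_charge=net_charge,
    )
    part.validate()
    return part


def _make_diatomic(spec: FixtureSpec, hetero: bool) -> StockholderPartition:
    r = 1.5 * ANGSTROM_TO_BOHR
    x = np.array([1.0, 0.0, 0.0])
    if hetero:
        charges = (0.3, -0.3)
        elements = (1, 9)
        dipoles = (spec.dipole_scale * x, spec.dipole_scale * x)
    else:
        charges = (0.0, 0.0)
        elements = (7, 7)
        dipoles = (spec.dipole_scale * x, -spec.dipole_scale * x)
    quad = _axial_quadrupole(x, spec.quadrupole_scale)
    atoms = [
        AtomSite(index=0, element=elements[0], position=np.zeros(3),
                 charge=charges[0], dipole=dipoles[0], quadrupole=quad.copy()),
        AtomSite(index=1, element=elements[1], position=r * x,
                 charge=charges[1], dipole=dipoles[1], quadrupole=quad.copy()),
    ]
    op = {(0, 1, (0, 0, 0)): spec.op_scale}
    name = "synthetic-diatomic" if hetero else "synthetic-homodiatomic"
    return _finalize(atoms, Cell(), op, name, 0.0)


def _make_water_like(spec: FixtureSpec) -> StockholderPartition:
    r_oh = 0.9572 * ANGSTROM_TO_BOHR
    half = np.deg2rad(104.52 / 2.0)
    h1_dir = np.array([np.sin(half), 0.0, np.cos(half)])
    h2_dir = np.array([-np.sin(half), 0.0, np.cos(half)])
    z = np.array([0.0, 0.0, 1.0])
    atoms = [
        AtomSite(index=0, element=8, position=np.zeros(3), charge=-0.776,
                 dipole=-0.136 * z, quadrupole=_axial_quadrupole(z, 0.384)),
        AtomSite(index=1, element=1, position=r_oh * h1_dir, charge=0.388,
                 dipole=-0.042 * h1_dir, quadrupole=_axial_quadrupole(h1_dir, 0.053)),
        AtomSite(index=2, element=1, position=r_oh * h2_dir, charge=0.388,
                 dipole=-0.042 * h2_dir, quadrupole=_axial_quadrupole(h2_dir, 0.053)),
    ]
    op = {
        (0, 1, (0, 0, 0)): spec.op_scale,
        (0, 2, (0, 0, 0)): spec.op_scale,
        (1, 2, (0, 0, 0)): 0.02,
    }
    return _finalize(atoms, Cell(), op, "synthetic-water-like", 0.0)


def _make_chain(spec: FixtureSpec) -> StockholderPartition:
    if spec.size < 2:
        raise ValidationError("chain fixture needs size >= 2")
    rng = np.random.default_rng(spec.seed)
    spacing = 1.5 * ANGSTROM_TO_BOHR
    x = np.array([1.0, 0.0, 0.0])
    atoms = []
    for i in range(spec.size):
        mu = spec.dipole_scale * rng.standard_normal(3)
        qraw = rng.standard_normal((3, 3))
        quad = (qraw + qraw.T) / 2.0
        quad -= np.trace(quad) / 3.0 * np.eye(3)
        norm = np.linalg.norm(quad)
        quad = spec.quadrupole_scale * quad / norm if norm > 0 else quad
        atoms.append(
            AtomSite(index=i, element=6, position=i * spacing * x, charge=0.0,
                     dipole=mu, quadrupole=quad)
        )
    op = {(i, i + 1, (0, 0, 0)): spec.op_scale for i in range(spec.size - 1)}
    return _finalize(atoms, Cell(), op, "synthetic-chain", 0.0)


def _make_rocksalt(spec: FixtureSpec) -> StockholderPartition:
    """3D-periodic rocksalt supercell; every atom sits on an inversion
    center, so all atomic dipoles and quadrupoles vanish by symmetry."""
    if spec.size % 2 == 1:
        raise ValidationError("rocksalt fixture needs an even atom count")
    k = round((spec.size / 8) ** (1.0 / 3.0))
    if 8 * k**3 != spec.size:
        raise ValidationError(
            "rocksalt fixture size must be 8*k^3 (conventional-cell replication)"
        )
    a0 = 5.64 * ANGSTROM_TO_BOHR
    basis = [
        (11, np.array([0.0, 0.0, 0.0])),
        (11, np.array([0.5, 0.5, 0.0])),
        (11, np.array([0.5, 0.0, 0.5])),
        (11, np.array([0.0, 0.5, 0.5])),
        (17, np.array([0.5, 0.0, 0.0])),
        (17, np.array([0.0, 0.5, 0.0])),
        (17, np.array([0.0, 0.0, 0.5])),
        (17, np.array([0.5, 0.5, 0.5])),
    ]
    atoms = []
    idx = 0
    for i in range(k):
        for j in range(k):
            for m in range(k):
                for elem, frac in basis:
                    pos = (frac + np.array([i, j, m], dtype=float)) * a0
                    charge = 0.858 if elem == 11 else -0.858
                    atoms.append(
                        AtomSite(index=idx, element=elem, position=pos, charge=charge)
                    )
                    idx += 1
    cell = Cell(lattice=np.eye(3) * (k * a0), periodic_flags=(True, True, True))
    # nearest-neighbor overlap populations at distance a0/2
    probe = enumerate_pairs(atoms, cell, op_table={}, cutoff_sum=a0 / 2 * 1.05)
    op = {}
    for p in range(len(probe)):
        key = (int(probe.atom_a[p]), int(probe.atom_b[p]),
               tuple(int(t) for t in probe.translation[p]))
        op[key] = spec.op_scale * 0.2
    return _finalize(atoms, cell, op, "synthetic-rocksalt", 0.0)


def _make_ring_tube(spec: FixtureSpec) -> StockholderPartition:
    """Ring of alternating +/- charges with coherent outward radial dipoles.

    A toy stand-in for tubular materials whose radially aligned atomic
    dipoles shift the potential between the inside and outside of the tube
    in a way no atom-centered point-charge-only model can reproduce.
    """
    n = spec.size
    if n < 4 or n % 2 == 1:
        raise ValidationError("ring_tube fixture needs an even atom count >= 4")
    bond = 1.45 * ANGSTROM_TO_BOHR
    radius = bond / (2.0 * np.sin(np.pi / n))
    atoms = []
    for i in range(n):
        phi = 2.0 * np.pi * i / n
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        charge = 0.4 if i % 2 == 0 else -0.4
        elem = 5 if i % 2 == 0 else 7
        atoms.append(
            AtomSite(index=i, element=elem, position=radius * radial, charge=charge,
                     dipole=spec.dipole_scale * radial,
                     quadrupole=_axial_quadrupole(radial, spec.quadrupole_scale))
        )
    op = {(i, (i + 1) % n, (0, 0, 0)): spec.op_scale for i in range(n)}
    return _finalize(atoms, Cell(), op, "synthetic-ring-tube", 0.0)


def _make_random(spec: FixtureSpec) -> StockholderPartition:
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    if n < 2:
        raise ValidationError("random fixture needs size >= 2")
    box = 2.2 * n ** (1.0 / 3.0)  # angstrom
    min_sep = 1.3
    pos_ang = []
    attempts = 0
    while len(pos_ang) < n:
        cand = rng.uniform(0, box, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in pos_ang):
            pos_ang.append(cand)
        attempts += 1
        if attempts > 20000:
            raise ValidationError("could not place atoms with minimum separation")
    pos = np.array(pos_ang) * ANGSTROM_TO_BOHR

    charges = rng.normal(0.0, 0.3, size=n)
    charges += (spec.net_charge - charges.sum()) / n
    atoms = []
    for i in range(n):
        mu = spec.dipole_scale * rng.standard_normal(3)
        qraw = rng.standard_normal((3, 3))
        quad = (qraw + qraw.T) / 2.0
        quad -= np.trace(quad) / 3.0 * np.eye(3)
        norm = np.linalg.norm(quad)
        quad = spec.quadrupole_scale * quad / norm if norm > 0 else quad
        atoms.append(
            AtomSite(index=i, element=6, position=pos[i], charge=float(charges[i]),
                     dipole=mu, quadrupole=quad)
        )
    op = {}
    for i in range(n):
        for j in range(i + 1, n):
            d_ang = np.linalg.norm(pos[i] - pos[j]) / ANGSTROM_TO_BOHR
            if d_ang < 4.0:
                op[(i, j, (0, 0, 0))] = spec.op_scale * float(np.exp(-2.0 * (d_ang - 1.3)))
    return _finalize(atoms, Cell(), op, "synthetic-random", spec.net_charge)


def make_fixture(spec: FixtureSpec) -> StockholderPartition:
    """Generate a synthetic stockholder partition from a spec."""
    builders = {
        "diatomic": lambda s: _make_diatomic(s, hetero=True),
        "homodiatomic": lambda s: _make_diatomic(s, hetero=False),
        "water_like": _make_water_like,
        "chain": _make_chain,
        "rocksalt": _make_rocksalt,
        "ring_tube": _make_ring_tube,
        "random": _make_random,
    }
    return builders[spec.kind](spec)


def make_oracle_grids(
    partition: StockholderPartition,
    spacing_angstrom: float = 0.5,
    padding_angstrom: float = 6.0,
    terms=("charges",),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[PotentialGrid, PotentialGrid]:
    """Synthetic reference ESP grid (ground truth = the chosen multipole
    terms of the partition, plus optional seeded Gaussian noise) and a
    matching electron-density grid built from the atoms' exponential
    clouds, so the density-threshold mask rule is exercised."""
    if spacing_angstrom <= 0 or padding_angstrom <= 0:
        raise ValidationError("spacing and padding must be positive")
    spacing = spacing_angstrom * ANGSTROM_TO_BOHR
    if partition.cell.is_periodic:
        if partition.cell.n_periodic != 3:
            raise ValidationError("oracle grids support nonperiodic or 3D-periodic cells")
        lat = partition.cell.lattice
        shape = [max(2, int(np.ceil(np.linalg.norm(lat[i]) / spacing))) for i in range(3)]
        axes = np.array([lat[i] / shape[i] for i in range(3)])
        origin = np.zeros(3)
        periodic = True
    else:
        pos = partition.positions
        lo = pos.min(axis=0) - padding_angstrom * ANGSTROM_TO_BOHR
        hi = pos.max(axis=0) + padding_angstrom * ANGSTROM_TO_BOHR
        shape = [int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3)]
        axes = np.eye(3) * spacing
        origin = lo
        periodic = False

    proto = PotentialGrid(
        origin=origin, axes=axes, values=np.zeros(shape), kind="esp", periodic=periodic
    )
    points = proto.points()
    esp_vals = model_potential(partition, points, terms=terms)
    if noise_sd > 0:
        esp_vals = esp_vals + np.random.default_rng(seed).normal(0, noise_sd, len(esp_vals))

    # density: sum of atom-centered exponential clouds over nearby images
    dens = np.zeros(len(points))
    cell = partition.cell
    if periodic:
        shifts = [
            np.array([i, j, k], dtype=float) @ cell.lattice
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        ]
    else:
        shifts = [np.zeros(3)]
    for a in partition.atoms:
        ca = a.cloud_a if a.cloud_a is not None else DEFAULT_CLOUD_A
        cb = a.cloud_b if a.cloud_b is not None else DEFAULT_CLOUD_B
        for sh in shifts:
            d = np.linalg.norm(points - (a.position + sh), axis=1)
            dens += ca * np.exp(-cb * d)

    esp = PotentialGrid(origin=origin, axes=axes, values=esp_vals.reshape(shape),
                        kind="esp", periodic=periodic)
    density = PotentialGrid(origin=origin, axes=axes, values=dens.reshape(shape),
                            kind="density", periodic=periodic)
    return esp, density


def make_ensemble(
    n_atoms: int = 50,
    n_conformations: int = 21,
    n_methods: int = 4,
    perturbation: float = 0.02,
    method_spread: float = 0.05,
    seed: int = 0,
) -> EnsembleChargeTable:
    """Synthetic per-method, per-conformation charge table.

    Methods share a common base charge profile plus method-specific offsets
    of rms ``method_spread`` (controlling inter-method correlation);
    conformations add i.i.d. jitter of sd ``perturbation``, so the expected
    conformational sensitivity is ``perturbation``.
    """
    if n_conformations < 1:
        raise ValidationError("need at least one conformation")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 0.4, size=n_atoms)
    values = np.zeros((n_methods, n_conformations, n_atoms))
    for m in range(n_methods):
        profile = base + rng.normal(0.0, method_spread, size=n_atoms)
        jitter = rng.normal(0.0, perturbation, size=(n_conformations, n_atoms)) \
            if perturbation > 0 else np.zeros((n_conformations, n_atoms))
        values[m] = profile[None, :] + jitter
    return EnsembleChargeTable(
        methods=[f"method_{m}" for m in range(n_methods)],
        conformations=[f"conf_{c}" for c in range(n_conformations)],
        values=values,
    )
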