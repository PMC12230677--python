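"""System multipole moments and molecular multipole error statistics.

The traceless quadrupole tensor is stored in the detraced-second-moment
convention

    Theta_ij = sum q (x_i x_j - r^2 delta_ij / 3)             (point charges)

which is the convention the atomic tensors use throughout the package.
The Buckingham convention differs by a factor 3/2 and is available via
:func:`to_buckingham`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ATOMIC_WEIGHTS
from .errors import UnsupportedOperationError, ValidationError
from .partition import StockholderPartition

MODEL_KINDS = ("charges_only", "charges_plus_dipoles", "charges_dipoles_quadrupoles")


@dataclass
class MultipoleSummary:
    origin_kind: str
    origin: np.ndarray
    dipole: np.ndarray
    quadrupole: np.ndarray
    model: str


def center_of_mass(partition: StockholderPartition) -> np.ndarray:
    w = ATOMIC_WEIGHTS[partition.elements]
    return (w[:, None] * partition.positions).sum(axis=0) / w.sum()


def center_of_nuclear_charge(partition: StockholderPartition) -> np.ndarray:
    z = partition.elements.astype(float)
    return (z[:, None] * partition.positions).sum(axis=0) / z.sum()


def _resolve_origin(partition: StockholderPartition, origin) -> tuple[str, np.ndarray]:
    if isinstance(origin, str):
        if origin == "center_of_mass":
            return origin, center_of_mass(partition)
        if origin == "center_of_nuclear_charge":
            return origin, center_of_nuclear_charge(partition)
        raise ValidationError(f"unknown origin kind {origin!r}")
    return "explicit", np.asarray(origin, dtype=float).reshape(3)


def detrace(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return t - np.trace(t) / 3.0 * np.eye(3)


def system_multipoles(
    partition: StockholderPartition,
    model: str = "charges_dipoles_quadrupoles",
    origin="center_of_mass",
) -> MultipoleSummary:
    """Total dipole and traceless quadrupole of a nonperiodic system.

    ``model`` selects which atomic moments contribute: point charges only,
    charges + atomic dipoles, or charges + dipoles + atomic quadrupoles.
    Including the atomic dipoles reproduces the partition's own total
    dipole exactly; including the quadrupoles also reproduces the total
    traceless quadrupole exactly (a property of the atom-centered
    polyatomic multipole expansion).
    """
    if partition.cell.is_periodic:
        raise UnsupportedOperationError(
            "system multipoles are origin-dependent and unbounded for periodic cells"
        )
    if model not in MODEL_KINDS:
        raise ValidationError(f"unknown model kind {model!r}")
    kind, o = _resolve_origin(partition, origin)
    r = partition.positions - o
    q = partition.charges

    dip = (q[:, None] * r).sum(axis=0)
    r2 = np.einsum("ai,ai->a", r, r)
    quad = np.einsum("a,ai,aj->ij", q, r, r) - np.eye(3) * (q @ r2) / 3.0

    if model in ("charges_plus_dipoles", "charges_dipoles_quadrupoles"):
        mu = partition.dipoles
        dip = dip + mu.sum(axis=0)
        cross = np.einsum("ai,aj->ij", r, mu)
        quad = quad + cross + cross.T - (2.0 / 3.0) * np.eye(3) * np.einsum("ai,ai->", r, mu)
    if model == "charges_dipoles_quadrupoles":
        quad = quad + partition.quadrupoles.sum(axis=0)

    return MultipoleSummary(
        origin_kind=kind, origin=o, dipole=dip, quadrupole=detrace(quad), model=model
    )


def to_buckingham(quadrupole: np.ndarray) -> np.ndarray:
    """Rescale a traceless quadrupole tensor to the Buckingham convention."""
    return 1.5 * np.asarray(quadrupole, dtype=float)


def from_buckingham(quadrupole: np.ndarray) -> np.ndarray:
    return np.asarray(quadrupole, dtype=float) / 1.5


@dataclass
class ErrorStats:
    """Dataset-level molecular multipole error statistics.

    Relative measures divide by the null model (all atomic charges zero),
    whose RRMSE is 1 by construction.
    """

    me: float
    rme: float
    rmse_dipole_mag: float
    rmse_dipole_vec: float
    rmse_quadrupole: float
    rrmse_dipole_mag: float
    rrmse_dipole_vec: float
    rrmse_quadrupole: float
    rms_atomic_dipole: float | None = None
    rms_atomic_quadrupole: float | None = None

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def rms_atomic_moments(partitions: list[StockholderPartition]) -> tuple[float, float]:
    """Root-mean-square atomic dipole and quadrupole magnitudes over all atoms."""
    mus = np.concatenate([p.dipoles for p in partitions])
    thetas = np.concatenate([p.quadrupoles for p in partitions])
    rms_mu = float(np.sqrt(np.mean(np.sum(mus**2, axis=1))))
    rms_q = float(np.sqrt(np.mean(np.sum(thetas**2, axis=(1, 2)))))
    return rms_mu, rms_q


def multipole_error_stats(
    models: list[MultipoleSummary],
    references: list[MultipoleSummary | tuple],
    partitions: list[StockholderPartition] | None = None,
) -> ErrorStats:
    """Error statistics of model multipoles against reference multipoles.

    ``references`` holds per-molecule reference (dipole, quadrupole) pairs
    or :class:`MultipoleSummary` objects.  The null model for the relative
    measures predicts zero dipole and zero quadrupole for every molecule.
    """
    if len(models) == 0 or len(models) != len(references):
        raise ValidationError("need equally many model and reference molecules")

    def _unpack(x):
        if isinstance(x, MultipoleSummary):
            return x.dipole, x.quadrupole
        return np.asarray(x[0], dtype=float), np.asarray(x[1], dtype=float)

    md = np.array([_unpack(m)[0] for m in models])
    mq = np.array([_unpack(m)[1] for m in models])
    rd = np.array([_unpack(r)[0] for r in references])
    rq = np.array([_unpack(r)[1] for r in references])

    mag_m = np.linalg.norm(md, axis=1)
    mag_r = np.linalg.norm(rd, axis=1)
    me = float(np.mean(mag_m - mag_r))
    avg = float(np.mean(mag_r))
    rme = me / avg if avg > 0 else np.nan

    rmse_mag = float(np.sqrt(np.mean((mag_m - mag_r) ** 2)))
    rmse_vec = float(np.sqrt(np.mean(np.sum((md - rd) ** 2, axis=1))))
    rmse_quad = float(np.sqrt(np.mean(np.sum((mq - rq) ** 2, axis=(1, 2)))))

    null_mag = float(np.sqrt(np.mean(mag_r**2)))
    null_vec = null_mag
    null_quad = float(np.sqrt(np.mean(np.sum(rq**2, axis=(1, 2)))))

    rms_mu = rms_q = None
    if partitions is not None:
        rms_mu, rms_q = rms_atomic_moments(partitions)

    def _ratio(a, b):
        return a / b if b > 0 else np.nan

    return ErrorStats(
        me=me,
        rme=rme,
        rmse_dipole_mag=rmse_mag,
        rmse_dipole_vec=rmse_vec,
        rmse_quadrupole=rmse_quad,
        rrmse_dipole_mag=_ratio(rmse_mag, null_mag),
        rrmse_dipole_vec=_ratio(rmse_vec, null_vec),
        rrmse_quadrupole=_ratio(rmse_quad, null_quad),
        rms_atomic_dipole=rms_mu,
        rms_atomic_quadrupole=rms_q,
    )
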