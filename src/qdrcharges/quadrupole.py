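"""Quadrupole resorption (QR): move part of each atom-in-material traceless
quadrupole into the point charges, compensating locally so the total
charge, dipole, and traceless quadrupole are preserved about any origin.

For a directed pair (A, b), a charge q_Ab flows from image b to atom A.
The bookkeeping that closes each pair's conservation triple is entirely
local to atom A:

* a compensating dipole +q_Ab R_Ab Rhat_Ab is placed on atom A (cancelling
  the point-charge dipole change exactly);
* the quadrupole generated by the shift is removed from atom A's tensor:
  Theta'_A = Theta_A + q_Ab R_Ab^2 (Rhat Rhat^T - I/3).

Quadrupole (and dipole) changes are therefore confined to the self atom;
only the charges touch first neighbors.  The transfers minimize

    L_QR = sum_{A,b} (q_Ab R_Ab^2 / w_Ab)^2
         + sum_A || Theta_A + sum_b q_Ab R_Ab^2 D_b ||_F^2

with D_b = Rhat_b Rhat_b^T - I/3, solved per atom in the scaled unknowns
S_Ab = q_Ab R_Ab^2 / w_Ab with rhs V_Ab = -w_Ab (Rhat . Theta_A . Rhat)
(the trace term drops because Theta_A is traceless).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import AtomBlock, cg_solve, DEFAULT_CG_TOL
from .dipole import TransferSet
from .errors import SolverError, ValidationError
from .partition import StockholderPartition

QUAD_TRACE_TOL = 1.0e-8


@dataclass
class QrUpdate:
    """Solved QR transfers plus the per-atom compensating dipoles and
    traceless tensors removed from each atomic quadrupole."""

    transfers: TransferSet
    comp_dipoles: np.ndarray  # (N, 3), e*bohr
    quad_deltas: np.ndarray  # (N, 3, 3), traceless, added to Theta_A

    def to_frame(self, partition: StockholderPartition) -> pd.DataFrame:
        return self.transfers.to_frame(partition)


def qr_block(partition: StockholderPartition, atom: int) -> AtomBlock:
    ps = partition.pairs
    slots = ps.slots_of[atom]
    return AtomBlock(
        atom=atom,
        kind="QR",
        directions=ps.direction[slots].reshape(-1, 3),
        weights=ps.weights[slots],
        pair_slots=slots,
    )


def build_qr_rhs(partition: StockholderPartition, atom: int) -> np.ndarray:
    """Right-hand side V^(A): slot b carries -w_Ab (Rhat_b . Theta_A . Rhat_b)."""
    theta = partition.atoms[atom].quadrupole
    if abs(np.trace(theta)) > QUAD_TRACE_TOL:
        raise ValidationError(
            f"atom {atom}: quadrupole trace {np.trace(theta):.3e} beyond tolerance"
        )
    block = qr_block(partition, atom)
    u = block.directions
    return -block.weights * np.einsum("bi,ij,bj->b", u, theta, u)


def solve_qr(
    partition: StockholderPartition, tol: float = DEFAULT_CG_TOL
) -> QrUpdate:
    """Solve the QR system block by block; returns the unique minimizer."""
    if partition.pairs is None:
        raise ValidationError("partition has no enumerated pairs")
    ps = partition.pairs
    n = partition.n_atoms
    q = np.zeros(len(ps))
    reports = []
    for atom in range(n):
        block = qr_block(partition, atom)
        if block.dim == 0:
            continue
        rhs = build_qr_rhs(partition, atom)
        try:
            s, report = cg_solve(block, rhs, tol=tol)
        except SolverError as exc:
            raise SolverError(f"QR solve failed on atom {atom}: {exc}", exc.report) from exc
        reports.append(report)
        # S_Ab = q_Ab R_Ab^2 / w_Ab  ->  q_Ab = w_Ab S_Ab / R_Ab^2
        d = ps.distance[block.pair_slots]
        q[block.pair_slots] = block.weights * s / (d * d)
    transfers = TransferSet(q=q, kind="QR", reports=reports)

    comp = np.zeros((n, 3))
    deltas = np.zeros((n, 3, 3))
    rvec = ps.rvec()
    for p in range(len(ps)):
        a = ps.atom_a[p]
        comp[a] += q[p] * rvec[p]
        u = ps.direction[p]
        deltas[a] += q[p] * ps.distance[p] ** 2 * (np.outer(u, u) - np.eye(3) / 3.0)
    return QrUpdate(transfers=transfers, comp_dipoles=comp, quad_deltas=deltas)


def apply_qr(partition: StockholderPartition, update: QrUpdate) -> StockholderPartition:
    """Apply a QR update, returning a new partition.

    Charges move between pair partners; compensating dipoles and quadrupole
    deltas land only on the self atoms, keeping the conservation triple
    exact about any origin and tracelessness exact.
    """
    if update.transfers.kind != "QR":
        raise ValidationError("apply_qr requires QR transfers")
    out = partition.copy()
    ps = partition.pairs
    charges = out.charges
    for p in range(len(ps)):
        charges[ps.atom_a[p]] += update.transfers.q[p]
        charges[ps.atom_b[p]] -= update.transfers.q[p]
    out.charges = charges
    out.dipoles = partition.dipoles + update.comp_dipoles
    out.quadrupoles = partition.quadrupoles + update.quad_deltas
    return out
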