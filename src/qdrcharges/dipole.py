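"""Dipole resorption (DR): move part of each atom-in-material dipole into
the point charges of the atom and its bonded neighbors.

For every directed pair (A, b) an unknown charge q_Ab flows from image b
to atom A.  The charge shift carries the point-charge dipole -q_Ab R_Ab
Rhat_Ab; to keep the total dipole *and* the total traceless quadrupole
about any origin unchanged, half of the balancing shift dipole
+q_Ab R_Ab Rhat_Ab is placed on atom A and half on image b.  Atomic
quadrupole tensors are untouched by DR.

The transfers minimize the convex loss

    L_DR = sum_{A,b} (q_Ab R_Ab / w_Ab)^2
         + sum_A || mu_A + sum_b q_Ab R_Ab Rhat_Ab ||^2

whose normal equations decouple into one SPD block per atom (see
:mod:`qdrcharges.blocks`) in the scaled unknowns X_Ab = q_Ab R_Ab / w_Ab
with right-hand side T_Ab = -w_Ab (mu_A . Rhat_Ab).  The first term turns
transfers off as OP_Ab -> 0; the second drives the residual (unresorbed)
atomic dipoles toward zero.  Each atom's residual in the loss is modeled
with that atom's own outgoing transfers (mirrored transfers live in the
neighbor's block), which is what makes the system block diagonal; the
apply step then uses the exactly conservative half/half split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import AtomBlock, BlockSolveReport, cg_solve, DEFAULT_CG_TOL
from .errors import SolverError, ValidationError
from .partition import StockholderPartition


@dataclass
class TransferSet:
    """Per-directed-pair charge transfers q_Ab (e), aligned with the
    partition's pair arrays.  Mirrored entries are solved independently in
    their own atom blocks; no symmetry is imposed between them."""

    q: np.ndarray
    kind: str
    reports: list[BlockSolveReport]

    @property
    def total_matvecs(self) -> int:
        return sum(r.matvec_count for r in self.reports)

    def to_frame(self, partition: StockholderPartition) -> pd.DataFrame:
        """Audit table (atom_a, atom_b, translation, q_ab)."""
        ps = partition.pairs
        return pd.DataFrame(
            {
                "atom_a": ps.atom_a,
                "atom_b": ps.atom_b,
                "l1": ps.translation[:, 0],
                "l2": ps.translation[:, 1],
                "l3": ps.translation[:, 2],
                "q_ab": self.q,
            }
        )


def dr_block(partition: StockholderPartition, atom: int) -> AtomBlock:
    ps = partition.pairs
    slots = ps.slots_of[atom]
    return AtomBlock(
        atom=atom,
        kind="DR",
        directions=ps.direction[slots].reshape(-1, 3),
        weights=ps.weights[slots],
        pair_slots=slots,
    )


def build_dr_rhs(partition: StockholderPartition, atom: int) -> np.ndarray:
    """Right-hand side T^(A): slot b carries -w_Ab (mu_A . Rhat_Ab)."""
    block = dr_block(partition, atom)
    mu = partition.atoms[atom].dipole
    return -block.weights * (block.directions @ mu)


def solve_dr(
    partition: StockholderPartition, tol: float = DEFAULT_CG_TOL
) -> TransferSet:
    """Solve the DR system block by block; returns the unique minimizer."""
    if partition.pairs is None:
        raise ValidationError("partition has no enumerated pairs")
    ps = partition.pairs
    q = np.zeros(len(ps))
    reports = []
    for atom in range(partition.n_atoms):
        block = dr_block(partition, atom)
        if block.dim == 0:
            continue
        rhs = -block.weights * (block.directions @ partition.atoms[atom].dipole)
        try:
            x, report = cg_solve(block, rhs, tol=tol)
        except SolverError as exc:
            raise SolverError(f"DR solve failed on atom {atom}: {exc}", exc.report) from exc
        reports.append(report)
        # X_Ab = q_Ab R_Ab / w_Ab  ->  q_Ab = w_Ab X_Ab / R_Ab
        q[block.pair_slots] = block.weights * x / ps.distance[block.pair_slots]
    return TransferSet(q=q, kind="DR", reports=reports)


def apply_dr(
    partition: StockholderPartition, transfers: TransferSet
) -> StockholderPartition:
    """Apply DR transfers, returning a new partition.

    Each directed transfer moves q_Ab onto atom A (and off image b's parent
    atom) and splits the shift dipole +q_Ab R_Ab Rhat_Ab half/half between
    the two atoms.  Net charge, total dipole, and total traceless
    quadrupole about any fixed origin are preserved; quadrupole tensors are
    unchanged bitwise.
    """
    if transfers.kind != "DR":
        raise ValidationError("apply_dr requires DR transfers")
    out = partition.copy()
    ps = partition.pairs
    charges = out.charges
    dipoles = out.dipoles
    shift = transfers.q[:, None] * ps.rvec()  # q_Ab * Rvec_Ab per pair
    for p in range(len(ps)):
        a = ps.atom_a[p]
        b = ps.atom_b[p]
        charges[a] += transfers.q[p]
        charges[b] -= transfers.q[p]
        dipoles[a] += 0.5 * shift[p]
        dipoles[b] += 0.5 * shift[p]
    out.charges = charges
    out.dipoles = dipoles
    return out
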