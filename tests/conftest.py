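"""Shared test helpers: independent dense oracles and conservation checks.

Everything here is deliberately written from the defining formulas (loops,
elementwise construction, generic quadratic minimization) rather than
through the package's matrix-free code paths, so it can serve as an
independent cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from qdrcharges import FixtureSpec, make_fixture
from qdrcharges.blocks import AtomBlock


def random_directions(rng, n):
    d = rng.standard_normal((n, 3))
    return d / np.linalg.norm(d, axis=1)[:, None]


def random_block(rng, kind, n, op_low=0.05, op_high=1.5):
    ops = rng.uniform(op_low, op_high, n)
    return AtomBlock(
        atom=0,
        kind=kind,
        directions=random_directions(rng, n),
        weights=2.0 * np.tanh(2.0 * ops),
        pair_slots=np.arange(n),
    )


def dense_dr_oracle(block):
    """Dense DR matrix built elementwise: diagonal 1 + w_b^2, off-diagonal
    w_b w_d (u_b . u_d)."""
    n = block.dim
    m = np.zeros((n, n))
    for b in range(n):
        for d in range(n):
            if b == d:
                m[b, d] = 1.0 + block.weights[b] ** 2
            else:
                m[b, d] = (
                    block.weights[b]
                    * block.weights[d]
                    * float(block.directions[b] @ block.directions[d])
                )
    return m


def dense_qr_oracle(block):
    """Dense QR matrix built elementwise: diagonal 1 + (2/3) w_b^2,
    off-diagonal w_b w_d ((u_b . u_d)^2 - 1/3)."""
    n = block.dim
    c = np.zeros((n, n))
    for b in range(n):
        for d in range(n):
            dot = float(block.directions[b] @ block.directions[d])
            if b == d:
                c[b, d] = 1.0 + (2.0 / 3.0) * block.weights[b] ** 2
            else:
                c[b, d] = block.weights[b] * block.weights[d] * (dot * dot - 1.0 / 3.0)
    return c


def quad_minimize(loss, n):
    """Generic dense minimizer of a quadratic loss from point evaluations.

    For a quadratic L(x) = c + g.x + x.H.x/2, unit-step central differences
    recover g exactly and second differences recover H exactly.
    """
    e = np.eye(n)
    l0 = loss(np.zeros(n))
    g = np.array([(loss(e[i]) - loss(-e[i])) / 2.0 for i in range(n)])
    h = np.zeros((n, n))
    for i in range(n):
        h[i, i] = loss(e[i]) + loss(-e[i]) - 2.0 * l0
        for j in range(i + 1, n):
            h[i, j] = h[j, i] = (
                loss(e[i] + e[j]) - loss(e[i]) - loss(e[j]) + l0
            )
    return np.linalg.solve(h, -g)


def dr_loss_in_q(part):
    """The dipole-resorption loss over the active (nonzero-overlap) pair
    transfers, written directly from its definition.

    Pairs with OP = 0 carry an infinite first-term penalty, so their
    transfers are identically zero; they are excluded from the variables.
    Returns (loss over active transfers, active-pair mask).
    """
    ps = part.pairs
    w = 2.0 * np.tanh(2.0 * ps.op)
    active = np.flatnonzero(ps.op > 0)

    def loss(x):
        qvec = np.zeros(len(ps))
        qvec[active] = x
        total = 0.0
        for p in active:
            total += (qvec[p] * ps.distance[p] / w[p]) ** 2
        for a in range(part.n_atoms):
            resid = part.atoms[a].dipole.copy()
            for p in ps.slots_of[a]:
                resid = resid + qvec[p] * ps.distance[p] * ps.direction[p]
            total += float(resid @ resid)
        return total

    return loss, active


def qr_loss_in_q(part):
    """The quadrupole-resorption loss over active pair transfers; see
    :func:`dr_loss_in_q` for the zero-overlap convention."""
    ps = part.pairs
    w = 2.0 * np.tanh(2.0 * ps.op)
    active = np.flatnonzero(ps.op > 0)

    def loss(x):
        qvec = np.zeros(len(ps))
        qvec[active] = x
        total = 0.0
        for p in active:
            total += (qvec[p] * ps.distance[p] ** 2 / w[p]) ** 2
        for a in range(part.n_atoms):
            resid = part.atoms[a].quadrupole.copy()
            for p in ps.slots_of[a]:
                u = ps.direction[p]
                resid = resid + qvec[p] * ps.distance[p] ** 2 * (
                    np.outer(u, u) - np.eye(3) / 3.0
                )
            total += float(np.sum(resid * resid))
        return total

    return loss, active


def totals_about(part, origin):
    """Independent net charge / total dipole / total traceless quadrupole
    (detraced second-moment convention) of a nonperiodic partition."""
    origin = np.asarray(origin, dtype=float)
    q_tot = 0.0
    mu_tot = np.zeros(3)
    th_tot = np.zeros((3, 3))
    for a in part.atoms:
        r = a.position - origin
        q_tot += a.charge
        mu_tot += a.charge * r + a.dipole
        th_tot += a.charge * (np.outer(r, r) - np.eye(3) * (r @ r) / 3.0)
        th_tot += (
            np.outer(r, a.dipole)
            + np.outer(a.dipole, r)
            - (2.0 / 3.0) * np.eye(3) * float(r @ a.dipole)
        )
        th_tot += a.quadrupole
    return q_tot, mu_tot, th_tot


TEST_ORIGINS = [
    np.zeros(3),
    np.array([1.7, -2.3, 0.9]),
    np.array([-10.0, 4.0, 6.5]),
]


def assert_conservation(before, after, tol=1e-10):
    for origin in TEST_ORIGINS:
        q0, m0, t0 = totals_about(before, origin)
        q1, m1, t1 = totals_about(after, origin)
        assert abs(q1 - q0) <= tol
        assert np.max(np.abs(m1 - m0)) <= tol
        assert np.max(np.abs(t1 - t0)) <= tol


@pytest.fixture
def water():
    return make_fixture(FixtureSpec(kind="water_like"))


@pytest.fixture
def random_partition():
    return make_fixture(FixtureSpec(kind="random", seed=11, size=6))
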