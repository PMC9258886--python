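"""Per-cohort cell-density balance on the deforming tissue.

The balance is solved in referential (material) form on the fixed
reference mesh.  With referential density ``c0 = J c`` the flux pulls
back to ``Q = J F^-1 q`` and the source to ``F^c = J f^c``, giving

    d(c0)/dt = J f^c + Div Q,
    Q = -c0 H(c) vhat(r) F^-1 nhat  +  D J C^-1 Grad(c0 / J),

where ``nhat = F N / |F N|`` is the current glial-fiber direction,
``vhat(r)`` the signed migration speed at referential radius ``r`` and
``H`` the density-activation switch.  Zero cell flux is prescribed on
all boundaries, so with consistent-mass Galerkin elements the total
referential cell number changes exactly by the integrated source.

Time stepping is backward Euler with the geometric factors (``F``, ``J``)
and the activation ``H`` frozen at the step start (staggered coupling).
An artificial streamline-diffusion flux ``-nu (w x w) Grad c0`` with
``nu = stab * |W| h / 2 * (coth Pe - 1/Pe)`` is added in conservative
form; the Peclet limiter makes it vanish in diffusion-dominated cells
and approach first-order upwinding where advection dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import params as prm
from .fem import EquilibriumSolver

__all__ = ["TransportSolver", "CohortDensityField", "cohort_flux",
           "total_density", "TransportError"]


class TransportError(RuntimeError):
    """Linear solve failed; the caller should reduce the time step."""


@dataclass
class CohortDensityField:
    """Nodal referential densities per cohort plus bookkeeping."""

    c0: np.ndarray                   # (n_cohorts, n_nodes) referential [um^-3]
    clipped_mass: float = 0.0        # cumulative mass removed by clipping
    total_mass0: float = 0.0         # reference for the clipping budget

    def copy(self):
        return CohortDensityField(self.c0.copy(), self.clipped_mass,
                                  self.total_mass0)


def total_density(c_per_cohort: np.ndarray) -> np.ndarray:
    """Total cell density: pointwise sum over the cohort axis."""
    c = np.asarray(c_per_cohort, float)
    return c.sum(axis=0) if c.ndim > 1 else c


def cohort_flux(c_i, grad_c_i, F, N, r, cohort, params: prm.ModelParameters):
    """Spatial cell flux ``q_i`` [um^-2 d^-1] at one material point.

    Advective part ``-c H(c) vhat(r) n/|n|`` along the deformed fiber,
    plus isotropic Fickian part ``D grad c``.
    """
    n = np.asarray(F, float) @ np.asarray(N, float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValueError("degenerate fiber direction: |F N| = 0")
    H = prm.migration_activation(c_i, params)
    vhat = prm.velocity_magnitude(r, cohort, params)
    return -c_i * H * vhat * n / nn + params.D * np.asarray(grad_c_i, float)


def _tridiag_solve(conn, Ee, rhs, n):
    """Assemble 2-node-element operators into banded form and solve."""
    from scipy.linalg import solve_banded

    diag = np.zeros(n)
    np.add.at(diag, conn[:, 0], Ee[:, 0, 0])
    np.add.at(diag, conn[:, 1], Ee[:, 1, 1])
    upper = np.zeros(n)
    lower = np.zeros(n)
    np.add.at(upper, conn[:, 1], Ee[:, 0, 1])    # col index = right node
    np.add.at(lower, conn[:, 0], Ee[:, 1, 0])    # col index = left node
    ab = np.zeros((3, n))
    ab[1] = diag
    ab[0] = upper
    ab[2] = lower
    return solve_banded((1, 1), ab, rhs)


class TransportSolver:
    """Backward-Euler advection-diffusion update for all cohorts."""

    def __init__(self, solver: EquilibriumSolver, stab: float = 1.0):
        self.fe = solver
        self.params = solver.params
        self.mesh = solver.mesh
        self.stab = float(stab)
        self._build_static()

    def _build_static(self):
        fe = self.fe
        n = self.mesh.n_nodes
        # consistent mass matrix
        Me = np.einsum("eq,qa,qb->eab", fe.wdetJ, fe.shapeN, fe.shapeN)
        self.Me_el = Me
        rows = np.repeat(self.mesh.elements, fe.n_en, axis=1).ravel()
        cols = np.tile(self.mesh.elements, (1, fe.n_en)).ravel()
        self._scatter = (rows, cols)
        self.M = sp.coo_matrix((Me.ravel(), (rows, cols)),
                               shape=(n, n)).tocsr()
        self.mass_vector = np.asarray(self.M.sum(axis=1)).ravel()
        # element size for stabilization
        if self.mesh.kind == "bar1d":
            self.h_el = (self.mesh.nodes[self.mesh.elements[:, 1], 0]
                         - self.mesh.nodes[self.mesh.elements[:, 0], 0])
        else:
            area = fe.wdetJ.sum(axis=1)
            self.h_el = np.sqrt(area)
        # per-cohort velocity magnitude at qps (function of referential r)
        p = self.params
        self.vhat_qp = np.stack(
            [np.asarray(prm.velocity_magnitude(fe.r_qp, i + 1, p))
             for i in range(p.n_cohorts)])
        self.Gx_qp = np.asarray(prm.neurogenesis_spatial(fe.r_qp, p))

    # ------------------------------------------------------------------
    def initial_field(self) -> CohortDensityField:
        c0 = np.zeros((self.params.n_cohorts, self.mesh.n_nodes))
        return CohortDensityField(c0=c0)

    def total_referential_mass(self, c0_nodal: np.ndarray) -> float:
        """Quadrature-exact ``int c0 dV`` for one cohort field."""
        return float(self.mass_vector @ np.asarray(c0_nodal))

    # ------------------------------------------------------------------
    def advance(self, field: CohortDensityField, t: float, dt: float,
                F_qp: np.ndarray, J_qp: np.ndarray,
                J_nodal: np.ndarray) -> CohortDensityField:
        """Advance all cohorts from ``t`` to ``t + dt`` (implicit Euler).

        ``F_qp``/``J_qp`` describe the frozen deformation over the step;
        ``J_nodal`` is the nodal projection of ``J`` used to convert the
        diffusing quantity ``c = c0/J``.
        """
        fe, p = self.fe, self.params
        mesh = self.mesh
        if dt <= 0:
            raise ValueError("dt must be > 0")
        Finv = np.linalg.inv(F_qp)
        Cinv = np.einsum("eqiK,eqjK->eqij", Finv, Finv)   # (F^-1)(F^-1)^T
        # current fiber direction at qps
        n_cur = np.einsum("eqij,eqj->eqi", F_qp, fe.N_qp)
        n_nrm = np.linalg.norm(n_cur, axis=-1, keepdims=True)
        if np.any(n_nrm == 0):
            raise ValueError("degenerate fiber direction")
        nhat = n_cur / n_nrm
        # referential diffusivity tensor D * J * C^-1 (dim x dim block)
        d = mesh.dim
        Kdiff_qp = p.D * J_qp[..., None, None] * Cinv[..., :3, :3]

        new = field.copy()
        grad = fe.dNdX                                    # (e, q, a, dim)
        for i in range(p.n_cohorts):
            c_sp_qp = fe.interp_to_qp(field.c0[i]) / J_qp
            H_qp = prm.migration_activation(c_sp_qp, p)
            # referential advection velocity W = H vhat F^-1 nhat
            W = (H_qp * self.vhat_qp[i])[..., None] * \
                np.einsum("eqiK,eqi->eqK", Finv, nhat)    # (e, q, 3)
            W = W[..., :d]
            # advection: + int (grad w . W) c0
            Ae = np.einsum("eq,eqaK,eqK,qb->eab", fe.wdetJ, grad, W,
                           fe.shapeN)
            # diffusion on c = c0/J: K_ab acting on c0_b / J_b
            Ke = np.einsum("eq,eqaK,eqKL,eqbL->eab", fe.wdetJ, grad,
                           Kdiff_qp[..., :d, :d], grad)
            # streamline artificial diffusion on c0 (conservative),
            # Peclet-limited so it vanishes in diffusion-dominated cells
            Wn = np.linalg.norm(W, axis=-1)
            what = W / np.where(Wn[..., None] > 0, Wn[..., None], 1.0)
            kappa = np.einsum("eqK,eqKL,eqL->eq", what,
                              Kdiff_qp[..., :d, :d], what) / J_qp
            pe = 0.5 * Wn * self.h_el[:, None] / np.maximum(kappa, 1e-300)
            zeta = np.where(pe > 1e-4, 1.0 / np.tanh(np.maximum(pe, 1e-4))
                            - 1.0 / np.maximum(pe, 1e-4), pe / 3.0)
            nu = self.stab * 0.5 * Wn * self.h_el[:, None] * zeta
            Se = np.einsum("eq,eq,eqa,eqb->eab", fe.wdetJ, nu,
                           np.einsum("eqaK,eqK->eqa", grad, what),
                           np.einsum("eqbK,eqK->eqb", grad, what))
            n = mesh.n_nodes
            # source at end of step
            Gt = prm.neurogenesis_temporal(t + dt, i + 1, p)
            src_qp = J_qp * p.Gc * self.Gx_qp * Gt
            b_src = np.zeros(n)
            np.add.at(b_src, mesh.elements,
                      np.einsum("eq,qa->ea", fe.wdetJ * src_qp, fe.shapeN))
            rhs = self.M @ field.c0[i] / dt + b_src
            # element operator: M/dt - A + K diag(1/J) + S
            Jinv_col = 1.0 / np.asarray(J_nodal)[mesh.elements]   # (e, en)
            Ee = (self.Me_el / dt - Ae + Se
                  + Ke * Jinv_col[:, None, :])
            try:
                if mesh.kind == "bar1d":
                    c_new = _tridiag_solve(mesh.elements, Ee, rhs, n)
                else:
                    rows, cols = self._scatter
                    lhs = sp.coo_matrix((Ee.ravel(), (rows, cols)),
                                        shape=(n, n)).tocsc()
                    c_new = spla.spsolve(lhs, rhs)
            except Exception as exc:  # pragma: no cover - solver failure path
                raise TransportError(str(exc)) from exc
            if not np.all(np.isfinite(c_new)):
                raise TransportError("non-finite transport solution")
            neg = c_new < 0
            if np.any(neg):
                new.clipped_mass += -float(
                    self.mass_vector[neg] @ c_new[neg])
                c_new = np.maximum(c_new, 0.0)
            new.c0[i] = c_new
        return new
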