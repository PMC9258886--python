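"""Quasi-static finite-element equilibrium with growth-prescribed ``Fg``.

Standard displacement elements (two-node lines for the bar, bilinear
quadrilaterals in plane strain for the half disc) with full Newton
iteration on the total-Lagrangian residual

    R_a = int_B  dN_a/dX_J  P_iJ(F; Fg)  dV  = 0,

where ``P`` is the first Piola-Kirchhoff stress of the neo-Hookean
morphoelastic material.  The consistent tangent is assembled from the
analytic ``dP/dF``.  Out-of-plane kinematics: the bar carries
``F = diag(1 + u', 1, 1)`` (lateral roller symmetry) and the plane
strain elements fix ``F_33 = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as cst
from . import params as prm
from .mesh import Mesh

__all__ = ["EquilibriumSolver", "MechanicalState", "NonConvergenceError"]

_GP1 = np.array([-1.0, 1.0]) / np.sqrt(3.0)


class NonConvergenceError(RuntimeError):
    """Newton failed to converge; the caller should cut the load step."""


@dataclass
class MechanicalState:
    """Converged displacement field and per-quadrature-point state."""

    u: np.ndarray            # (n_nodes, dim)
    F: np.ndarray            # (n_el, n_qp, 3, 3)
    Fg: np.ndarray
    Fe: np.ndarray
    T: np.ndarray            # Cauchy stress (n_el, n_qp, 3, 3)
    J: np.ndarray            # (n_el, n_qp)
    Je: np.ndarray
    residual: float
    n_iter: int


def _quad_shape(xi, eta):
    N = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                         (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
    dN = 0.25 * np.array([[-(1 - eta), -(1 - xi)],
                          [+(1 - eta), -(1 + xi)],
                          [+(1 + eta), +(1 + xi)],
                          [-(1 + eta), +(1 - xi)]])
    return N, dN


class EquilibriumSolver:
    """Assembles and solves ``div T = 0`` on a fixed reference mesh."""

    def __init__(self, mesh: Mesh, params: prm.ModelParameters):
        self.mesh = mesh
        self.params = params
        self._precompute()
        self._material()
        self._dirichlet()

    # ------------------------------------------------------------------
    def _precompute(self):
        mesh = self.mesh
        conn = mesh.elements
        if mesh.kind == "bar1d":
            h = np.diff(mesh.nodes[:, 0])[conn[:, 0] // 1]  # uniform anyway
            h = (mesh.nodes[conn[:, 1], 0] - mesh.nodes[conn[:, 0], 0])
            n_qp = 2
            self.shapeN = np.stack([np.array([(1 - xi) / 2, (1 + xi) / 2])
                                    for xi in _GP1])           # (qp, en)
            dNdX = np.empty((mesh.n_elements, n_qp, 2, 1))
            for q in range(n_qp):
                dNdX[:, q, 0, 0] = -1.0 / h
                dNdX[:, q, 1, 0] = +1.0 / h
            self.dNdX = dNdX
            self.wdetJ = np.repeat((h / 2)[:, None], n_qp, axis=1)
            self.n_qp, self.n_en, self.dof_per_node = n_qp, 2, 1
        elif mesh.kind == "quad4":
            pts = [(xi, eta) for eta in _GP1 for xi in _GP1]
            n_qp = 4
            X = mesh.nodes[conn]                               # (el, 4, 2)
            self.shapeN = np.empty((n_qp, 4))
            self.dNdX = np.empty((mesh.n_elements, n_qp, 4, 2))
            self.wdetJ = np.empty((mesh.n_elements, n_qp))
            for q, (xi, eta) in enumerate(pts):
                N, dN = _quad_shape(xi, eta)
                self.shapeN[q] = N
                # Jmap[k, i] = d x_i / d xi_k, so (Jmap^-1)[i, k] = d xi_k / d x_i
                Jmap = np.einsum("ak,eai->eki", dN, X)         # (el, 2, 2)
                detJ = np.linalg.det(Jmap)
                if np.any(detJ <= 0):
                    raise ValueError("non-positive element Jacobian in mesh")
                Jinv = np.linalg.inv(Jmap)
                self.dNdX[:, q] = np.einsum("ak,eik->eai", dN, Jinv)
                self.wdetJ[:, q] = detJ  # unit gauss weights
            self.n_qp, self.n_en, self.dof_per_node = n_qp, 4, 2
        else:
            raise ValueError(f"unsupported mesh kind {mesh.kind!r}")

        # quadrature-point referential positions and radii
        self.X_qp = np.einsum("qa,eai->eqi", self.shapeN, mesh.nodes[conn])
        if mesh.dim == 1:
            self.r_qp = self.X_qp[..., 0]
        else:
            self.r_qp = np.linalg.norm(self.X_qp, axis=-1)
        self.N_qp = np.repeat(mesh.fiber[:, None, :], self.n_qp, axis=1)

        # scatter indices
        d = self.dof_per_node
        edof = (conn[:, :, None] * d + np.arange(d)[None, None, :])
        self.edof = edof.reshape(mesh.n_elements, self.n_en * d)
        self.rows = np.repeat(self.edof, self.n_en * d, axis=1).ravel()
        self.cols = np.tile(self.edof, (1, self.n_en * d)).ravel()
        self.n_dof = mesh.n_nodes * d

    def _material(self):
        p = self.params
        self.mu_qp = np.asarray(prm.shear_modulus(self.r_qp, p))
        self.L_qp = np.asarray(prm.lame_L(self.r_qp, p))

    def _dirichlet(self):
        mesh, d = self.mesh, self.dof_per_node
        fixed = []
        if mesh.kind == "bar1d":
            fixed += list(mesh.node_sets["fixed"])
        else:
            fixed += [int(n) * d + 1 for n in mesh.node_sets["symmetry"]]
            fixed += [int(n) * d + 0 for n in mesh.node_sets["origin"]]
        self.fixed_dofs = np.unique(np.asarray(fixed, int))
        free = np.ones(self.n_dof, bool)
        free[self.fixed_dofs] = False
        self.free = np.where(free)[0]

    # ------------------------------------------------------------------
    def deformation_gradient(self, u: np.ndarray,
                             F33_qp: np.ndarray | None = None) -> np.ndarray:
        """Full 3x3 deformation gradient at every quadrature point.

        For plane-strain elements the through-thickness stretch is the
        kinematic constraint ``Fe_33 = 1``: out-of-plane growth is
        absorbed stress-free, so ``F_33 = Fg_33`` (supplied via
        ``F33_qp``; defaults to 1).  The bar's lateral faces are roller
        supported, hence lateral total stretches are exactly 1.
        """
        mesh = self.mesh
        u_el = u.reshape(mesh.n_nodes, self.dof_per_node)[mesh.elements]
        F = np.tile(np.eye(3), (mesh.n_elements, self.n_qp, 1, 1))
        if mesh.kind == "bar1d":
            F[..., 0, 0] += np.einsum("ea,eqa->eq", u_el[..., 0],
                                      self.dNdX[..., 0])
        else:
            grad = np.einsum("eai,eqaJ->eqiJ", u_el, self.dNdX)
            F[..., :2, :2] += grad
            if F33_qp is not None:
                F[..., 2, 2] = F33_qp
        return F

    def interp_to_qp(self, nodal: np.ndarray) -> np.ndarray:
        """Interpolate a nodal scalar field to quadrature points."""
        vals = np.asarray(nodal)[self.mesh.elements]      # (el, en)
        return np.einsum("qa,ea->eq", self.shapeN, vals)

    def project_to_nodes(self, qp_field: np.ndarray) -> np.ndarray:
        """Mass-lumped projection of a per-qp scalar field to nodes."""
        num = np.zeros(self.mesh.n_nodes)
        den = np.zeros(self.mesh.n_nodes)
        w = self.wdetJ
        contrib = np.einsum("eq,qa->ea", w * qp_field, self.shapeN)
        wsum = np.einsum("eq,qa->ea", w, self.shapeN)
        np.add.at(num, self.mesh.elements, contrib)
        np.add.at(den, self.mesh.elements, wsum)
        return num / den

    # ------------------------------------------------------------------
    def _internal_force(self, F):
        P = cst.first_pk_stress(F, self._Fg, self.mu_qp, self.L_qp)
        fint = np.zeros(self.n_dof)
        if self.mesh.kind == "bar1d":
            fe = np.einsum("eq,eq,eqa->ea", self.wdetJ, P[..., 0, 0],
                           self.dNdX[..., 0])
        else:
            fe = np.einsum("eq,eqiJ,eqaJ->eai", self.wdetJ,
                           P[..., :2, :2], self.dNdX)
        np.add.at(fint, self.edof, fe.reshape(self.mesh.n_elements, -1))
        return fint

    def _stiffness(self, F):
        A = cst.material_tangent(F, self._Fg, self.mu_qp, self.L_qp)
        if self.mesh.kind == "bar1d":
            Ke = np.einsum("eq,eq,eqa,eqb->eab", self.wdetJ,
                           A[..., 0, 0, 0, 0], self.dNdX[..., 0],
                           self.dNdX[..., 0])
        else:
            Ke = np.einsum("eq,eqaJ,eqiJkL,eqbL->eaikb", self.wdetJ,
                           self.dNdX, A[..., :2, :2, :2, :2], self.dNdX)
            # order dofs node-major: (a,i),(b,k)
            Ke = np.einsum("eaikb->eaibk", Ke)
            n = self.n_en * self.dof_per_node
            Ke = Ke.reshape(self.mesh.n_elements, n, n)
        K = sp.coo_matrix((Ke.ravel(), (self.rows, self.cols)),
                          shape=(self.n_dof, self.n_dof)).tocsr()
        return K

    def solve(self, Fg_qp: np.ndarray, u0: np.ndarray | None = None,
              rtol: float = 1e-8, max_iter: int = 25) -> MechanicalState:
        """Newton-solve equilibrium for the given growth tensor field.

        ``Fg_qp``: (n_el, n_qp, 3, 3) with positive determinant.
        Raises :class:`NonConvergenceError` if the iteration stalls; the
        caller is expected to reduce its (pseudo-)time step.
        """
        self._Fg = np.asarray(Fg_qp, float)
        if np.any(np.linalg.det(self._Fg) <= 0):
            raise cst.DegenerateGrowthError("Fg field has non-positive det")
        if self.mesh.kind == "bar1d":
            return self._solve_bar(u0, rtol, max_iter)
        F33 = self._Fg[..., 2, 2] if self.mesh.kind == "quad4" else None
        # fixed dofs keep their u0 values (zero when u0 is None), so
        # inhomogeneous Dirichlet data can be imposed through u0
        u = np.zeros(self.n_dof) if u0 is None else np.array(u0, float).ravel().copy()

        def residual(uvec):
            F = self.deformation_gradient(uvec, F33)
            if np.any(np.linalg.det(F) <= 0):
                return None, None
            return self._internal_force(F), F

        fint, F = residual(u)
        if fint is None:
            raise NonConvergenceError("inverted element at initial guess")
        scale = max(1.0, float(np.linalg.norm(fint[self.free])))
        for it in range(max_iter):
            rnorm = float(np.linalg.norm(fint[self.free]))
            scale = max(scale, float(np.linalg.norm(fint[self.free])), 1.0)
            if rnorm <= rtol * scale:
                return self._finalize(u, F, rnorm, it)
            K = self._stiffness(F)
            Kff = K[self.free][:, self.free]
            du = spla.spsolve(Kff.tocsc(), -fint[self.free])
            if not np.all(np.isfinite(du)):
                raise NonConvergenceError("singular tangent")
            # backtracking on residual growth or element inversion
            step = 1.0
            for _ in range(6):
                u_try = u.copy()
                u_try[self.free] += step * du
                fint_try, F_try = residual(u_try)
                if fint_try is not None and (
                        np.linalg.norm(fint_try[self.free]) < rnorm
                        or step < 0.2):
                    break
                step *= 0.5
            else:
                raise NonConvergenceError("line search failed")
            u, fint, F = u_try, fint_try, F_try
        rnorm = float(np.linalg.norm(fint[self.free]))
        if rnorm <= 100 * rtol * scale:   # accept near-converged state
            return self._finalize(u, F, rnorm, max_iter)
        raise NonConvergenceError(
            f"Newton did not converge: |R| = {rnorm:.3e} (scale {scale:.3e})")

    # ------------------------------------------------------------------
    def _solve_bar(self, u0, rtol, max_iter):
        """Fast Newton path for the bar: diagonal kinematics, banded solve.

        ``Fg = diag(tp, tt, tt)`` and ``F = diag(lam, 1, 1)`` with the
        lateral roller constraint, so the residual reduces to a scalar
        axial stress per quadrature point and the tangent is tridiagonal.
        """
        from scipy.linalg import solve_banded

        mesh = self.mesh
        n = mesh.n_nodes
        conn = mesh.elements
        h = mesh.nodes[conn[:, 1], 0] - mesh.nodes[conn[:, 0], 0]
        tp = self._Fg[..., 0, 0]
        tt = self._Fg[..., 1, 1]
        Jg = tp * tt * tt
        mu, L = self.mu_qp, self.L_qp
        w = self.wdetJ

        def P_and_dP(lam_el):
            f = lam_el[:, None] / tp
            Je = f / (tt * tt)
            lnJe = np.log(Je)
            Pe = mu * f + (L * lnJe - mu) / f
            P = Jg * Pe / tp
            dP = (Jg / tp ** 2) * (mu + (L + mu - L * lnJe) / f ** 2)
            # quadrature-average over the element (lam constant per elem)
            return (w * P).sum(1) / h, (w * dP).sum(1) / h

        u = np.zeros(n) if u0 is None else np.array(u0, float).ravel().copy()
        u[0] = 0.0

        def assemble(uvec):
            lam = 1.0 + (uvec[conn[:, 1]] - uvec[conn[:, 0]]) / h
            if np.any(lam <= 0):
                return None, None, None
            P, dP = P_and_dP(lam)
            R = np.zeros(n)
            np.add.at(R, conn[:, 0], -P)
            np.add.at(R, conn[:, 1], +P)
            return R, dP / h, lam

        R, k_el, lam = assemble(u)
        if R is None:
            raise NonConvergenceError("inverted element at initial guess")
        scale = max(1.0, float(np.linalg.norm(R[1:])))
        for it in range(max_iter):
            rnorm = float(np.linalg.norm(R[1:]))
            scale = max(scale, rnorm)
            if rnorm <= rtol * scale:
                return self._finalize_bar(u, lam, tp, tt)
            # tridiagonal system on free nodes 1..n-1
            diag = np.zeros(n)
            np.add.at(diag, conn[:, 0], k_el)
            np.add.at(diag, conn[:, 1], k_el)
            ab = np.zeros((3, n - 1))
            ab[1] = diag[1:]
            ab[0, 1:] = -k_el[1:]
            ab[2, :-1] = -k_el[1:]
            du = solve_banded((1, 1), ab, -R[1:])
            step = 1.0
            for _ in range(6):
                u_try = u.copy()
                u_try[1:] += step * du
                R_try, k_try, lam_try = assemble(u_try)
                if R_try is not None and (
                        np.linalg.norm(R_try[1:]) < rnorm or step < 0.2):
                    break
                step *= 0.5
            else:
                raise NonConvergenceError("bar line search failed")
            u, R, k_el, lam = u_try, R_try, k_try, lam_try
        rnorm = float(np.linalg.norm(R[1:]))
        if rnorm <= 100 * rtol * scale:
            return self._finalize_bar(u, lam, tp, tt)
        raise NonConvergenceError(
            f"bar Newton did not converge: |R| = {rnorm:.3e}")

    def _finalize_bar(self, u, lam_el, tp, tt):
        ne, nq = self.mesh.n_elements, self.n_qp
        F = np.tile(np.eye(3), (ne, nq, 1, 1))
        F[..., 0, 0] = lam_el[:, None]
        Fe = np.tile(np.eye(3), (ne, nq, 1, 1))
        Fe[..., 0, 0] = lam_el[:, None] / tp
        Fe[..., 1, 1] = 1.0 / tt
        Fe[..., 2, 2] = 1.0 / tt
        T = cst.cauchy_stress(Fe, self.mu_qp, self.L_qp)
        rnorm = 0.0
        return MechanicalState(
            u=u.reshape(self.mesh.n_nodes, 1), F=F, Fg=self._Fg.copy(),
            Fe=Fe, T=T, J=np.linalg.det(F), Je=np.linalg.det(Fe),
            residual=rnorm, n_iter=0)

    def _finalize(self, u, F, rnorm, n_iter):
        Fgi = np.linalg.inv(self._Fg)
        Fe = F @ Fgi
        T = cst.cauchy_stress(Fe, self.mu_qp, self.L_qp)
        return MechanicalState(
            u=u.reshape(self.mesh.n_nodes, self.dof_per_node),
            F=F, Fg=self._Fg.copy(), Fe=Fe, T=T,
            J=np.linalg.det(F), Je=np.linalg.det(Fe),
            residual=rnorm, n_iter=n_iter)
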