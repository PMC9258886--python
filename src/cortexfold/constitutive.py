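"""Pointwise morphoelastic kinematics and neo-Hookean elasticity.

The total deformation gradient factors multiplicatively, ``F = Fe . Fg``:
``Fg`` is the stress-free shape change produced by the accumulated cell
density (transversely isotropic about the radial glial fiber direction
``N``), and only the elastic part ``Fe`` generates Cauchy stress through
a compressible neo-Hookean free energy

    psi(Ce, Je) = mu/2 [tr(Ce) - 3 - 2 ln Je] + L/2 ln^2(Je).

All tensors are stored as full 3x3 arrays regardless of the spatial
dimension of the enclosing finite-element problem; reduced-dimension
runs impose their kinematic constraints on ``F`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DeformationState",
    "DegenerateGrowthError",
    "growth_tensor",
    "elastic_decomposition",
    "strain_energy",
    "cauchy_stress",
    "first_pk_stress",
    "material_tangent",
]

I3 = np.eye(3)


class DegenerateGrowthError(ValueError):
    """Growth stretch 1 + k*c dropped to zero or below."""


@dataclass
class DeformationState:
    """Kinematic state at a material point."""

    F: np.ndarray
    Fg: np.ndarray
    Fe: np.ndarray
    J: float
    Jg: float
    Je: float
    Be: np.ndarray
    Ce: np.ndarray


def growth_tensor(c_total, k_par, k_perp, N):
    """Growth tensor ``Fg = (1 + k_par c) N@N + (1 + k_perp c)(1 - N@N)``.

    ``c_total`` is the total (summed over cohorts) spatial cell density.
    Stretch ``1 + k_par c`` acts along the fiber direction ``N`` and the
    double eigenvalue ``1 + k_perp c`` acts in the transverse plane.

    Broadcasts: ``c_total`` may have shape ``(...,)``, ``N`` shape
    ``(..., 3)``; the result has shape ``(..., 3, 3)``.
    """
    c = np.asarray(c_total, float)
    N = np.asarray(N, float)
    nrm = np.linalg.norm(N, axis=-1)
    if not np.allclose(nrm, 1.0, atol=1e-8):
        raise ValueError("fiber direction N must be a unit vector")
    th_par = 1.0 + np.asarray(k_par) * c
    th_perp = 1.0 + np.asarray(k_perp) * c
    if np.any(th_par <= 0) or np.any(th_perp <= 0):
        raise DegenerateGrowthError("growth stretch 1 + k*c must stay > 0")
    NN = N[..., :, None] * N[..., None, :]
    return (th_par[..., None, None] * NN
            + th_perp[..., None, None] * (I3 - NN))


def elastic_decomposition(F, Fg) -> DeformationState:
    """Split ``F`` into elastic and growth parts, ``Fe = F . Fg^-1``."""
    F = np.asarray(F, float)
    Fg = np.asarray(Fg, float)
    J = float(np.linalg.det(F))
    Jg = float(np.linalg.det(Fg))
    if J <= 0:
        raise ValueError(f"det F must be > 0, got {J}")
    if Jg <= 0:
        raise DegenerateGrowthError(f"det Fg must be > 0, got {Jg}")
    Fe = F @ np.linalg.inv(Fg)
    Je = float(np.linalg.det(Fe))
    return DeformationState(F=F, Fg=Fg, Fe=Fe, J=J, Jg=Jg, Je=Je,
                            Be=Fe @ Fe.T, Ce=Fe.T @ Fe)


def strain_energy(Ce, Je, mu, L):
    """Referential free energy density [kPa]; zero at the relaxed state."""
    Je = np.asarray(Je, float)
    if np.any(Je <= 0):
        raise ValueError("Je must be > 0")
    trCe = np.trace(np.asarray(Ce, float), axis1=-2, axis2=-1)
    lnJe = np.log(Je)
    out = 0.5 * mu * (trCe - 3.0 - 2.0 * lnJe) + 0.5 * L * lnJe ** 2
    return out if np.ndim(out) else float(out)


def cauchy_stress(Fe, mu, L):
    """Cauchy stress ``T = [mu Be + (L ln Je - mu) 1] / Je`` [kPa].

    Symmetric; identically zero when ``Fe`` is the identity (and hence
    whenever ``F = Fg``: only elastic deformation induces stress).
    Broadcasts over leading axes of ``Fe`` (shape ``(..., 3, 3)``).
    """
    Fe = np.asarray(Fe, float)
    Je = np.linalg.det(Fe)
    if np.any(Je <= 0):
        raise ValueError("det Fe must be > 0")
    Be = Fe @ np.swapaxes(Fe, -1, -2)
    mu = np.asarray(mu, float)[..., None, None] if np.ndim(mu) else mu
    L = np.asarray(L, float)[..., None, None] if np.ndim(L) else L
    lnJe = np.log(Je)[..., None, None]
    Je_ = Je[..., None, None]
    return (mu * Be + (L * lnJe - mu) * I3) / Je_


def first_pk_stress(F, Fg, mu, L):
    """First Piola-Kirchhoff stress wrt the reference configuration.

    With stored energy per unit reference volume ``W(F) = Jg psi(Fe)``,
    ``P = dW/dF = Jg Pe Fg^-T`` where ``Pe = mu Fe + (L ln Je - mu) Fe^-T``.
    Broadcasts over leading axes.
    """
    F = np.asarray(F, float)
    Fg = np.asarray(Fg, float)
    Fgi = np.linalg.inv(Fg)
    Fe = F @ Fgi
    Je = np.linalg.det(Fe)
    if np.any(Je <= 0):
        raise ValueError("det Fe must be > 0")
    Jg = np.linalg.det(Fg)
    FeiT = np.swapaxes(np.linalg.inv(Fe), -1, -2)
    mu_ = np.asarray(mu, float)[..., None, None] if np.ndim(mu) else mu
    L_ = np.asarray(L, float)[..., None, None] if np.ndim(L) else L
    lnJe = np.log(Je)[..., None, None]
    Pe = mu_ * Fe + (L_ * lnJe - mu_) * FeiT
    return Jg[..., None, None] * Pe @ np.swapaxes(Fgi, -1, -2)


def material_tangent(F, Fg, mu, L):
    """Consistent tangent ``A_iJkL = dP_iJ / dF_kL`` (reference frame).

    Built from the elastic tangent
    ``dPe_iM/dFe_kN = mu d_ik d_MN + L Fe^-T_iM Fe^-T_kN
    - (L ln Je - mu) Fe^-1_Mk Fe^-1_Ni``
    pulled back through the fixed growth map.  Broadcasts over leading
    axes; returns shape ``(..., 3, 3, 3, 3)``.
    """
    F = np.asarray(F, float)
    Fg = np.asarray(Fg, float)
    Fgi = np.linalg.inv(Fg)
    Fe = F @ Fgi
    Je = np.linalg.det(Fe)
    if np.any(Je <= 0):
        raise ValueError("det Fe must be > 0")
    Jg = np.linalg.det(Fg)
    Fei = np.linalg.inv(Fe)
    FeiT = np.swapaxes(Fei, -1, -2)
    mu_ = np.asarray(mu, float)
    L_ = np.asarray(L, float)
    lnJe = np.log(Je)
    d = I3
    # elastic tangent dPe_iM/dFe_kN
    t1 = np.einsum("ik,MN->iMkN", d, d) * mu_[..., None, None, None, None] \
        if np.ndim(mu_) else mu_ * np.einsum("ik,MN->iMkN", d, d)
    t2 = np.einsum("...iM,...kN->...iMkN", FeiT, FeiT)
    t3 = np.einsum("...Mk,...Ni->...iMkN", Fei, Fei)
    coef = (L_ * lnJe - mu_)
    Ae = t1 + L_[..., None, None, None, None] * t2 if np.ndim(L_) else t1 + L_ * t2
    Ae = Ae - (coef[..., None, None, None, None] * t3 if np.ndim(coef)
               else coef * t3)
    # pull back: A_iJkL = Jg * Ae_iMkN Fgi_JM Fgi_LN
    A = np.einsum("...iMkN,...JM,...LN->...iJkL", Ae, Fgi, Fgi)
    return A * (Jg[..., None, None, None, None] if np.ndim(Jg) else Jg)
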