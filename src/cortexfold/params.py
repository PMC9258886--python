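"""Model parameters and smooth spatial/temporal property profiles.

The developing brain domain is parameterised by a single radial material
coordinate ``r`` (distance from the ventricular surface in the reference
configuration, in micrometres).  Every spatially varying property --
neurogenesis region, migration velocity, growth coefficients, elastic
moduli -- is a smoothed-step profile built from the logistic function
``H(x; alpha) = e^{alpha x} / (1 + e^{alpha x})``, so the domain splits
into an inner (subcortical) and an outer (cortical) plateau with a smooth
transition whose width is ``~1/alpha``.

Units convention: lengths in um, time in days, densities in um^-3,
stresses in kPa.  Smoothing parameters ``alpha_G/alpha_v/alpha_k/alpha_mu``
act on micrometre arguments (um^-1); ``alpha_c`` acts on the dimensionless
normalized density excess ``(c - c0)/c0``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "ParameterError",
    "smoothed_heaviside",
    "migration_activation",
    "neurogenesis_spatial",
    "neurogenesis_temporal",
    "velocity_magnitude",
    "growth_coefficients",
    "shear_modulus",
    "lame_L",
]


class ParameterError(ValueError):
    """Raised for invalid or inconsistent model parameters."""


@dataclass
class ModelParameters:
    """Material and model constants (defaults: ferret calibration values).

    The three neuron cohorts are labelled by in-utero electroporation day
    ``delta_it`` (simulation days, day 0 = E31) and by their terminal
    radial destination ``delta_iv`` in the cortical plate.
    """

    # -- transport / activation
    c0: float = 1.0e-6             # threshold cell density [um^-3]
    alpha_c: float = 0.1           # activation sensitivity on (c-c0)/c0 [-]
    # -- geometry / neurogenesis
    R0: float = 239.0              # initial radius / bar length [um]
    delta_x: float = 0.2 * 239.0   # ventricular-zone extent [um]
    alpha_G: float = 0.05          # neurogenesis smoothing [um^-1]
    delta_it: tuple = (0.0, 3.0, 6.0)  # electroporation days per cohort [d]
    epsilon: float = 2.0           # temporal smoothing of the birth pulse [d]
    # -- migration
    alpha_v: float = 0.05          # velocity smoothing [um^-1]
    v_base: float = 1472.2         # baseline migration speed, shared v_i [um/d]
    delta_iv: tuple = (191.6, 210.7, 222.7)  # cohort destinations [um]
    D: float = 31612.6             # diffusion coefficient [um^2/d]
    # -- growth
    k_s: float = 202950.0          # subcortical growth parameter [um^3]
    beta_k: float = 1.0            # tangential/radial growth ratio [-]
    delta_k: float = 0.93 * 239.0  # growth-mode transition radius [um]
    alpha_k: float = 1.0           # growth smoothing [um^-1]
    Gc: float = 1.41e-5            # baseline division rate [um^-3 d^-1]
    # -- elasticity
    mu_s: float = 1.0              # subcortical shear modulus [kPa]
    nu: float = 0.45               # Poisson ratio [-]
    L_s: float = 9.3               # subcortical second Lame constant [kPa]
    beta_mu: float = 3.0           # cortex/subcortex stiffness ratio [-]
    delta_mu: float = 0.93 * 239.0  # stiffness transition radius [um]
    alpha_mu: float = 1.0          # stiffness smoothing [um^-1]
    # -- schedule
    tau: float = 27.0              # total simulated duration [d]
    # Orientation of the neurogenesis region G^x: "svz" places proliferation
    # outside the ventricular zone (r > delta_x), where the intermediate
    # progenitors divide; "ventricular" confines it to r < delta_x.
    neurogenesis_profile: str = "svz"

    def __post_init__(self):
        self.delta_it = tuple(float(v) for v in np.atleast_1d(self.delta_it))
        self.delta_iv = tuple(float(v) for v in np.atleast_1d(self.delta_iv))
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        positive = dict(
            c0=self.c0, alpha_c=self.alpha_c, R0=self.R0, delta_x=self.delta_x,
            alpha_G=self.alpha_G, epsilon=self.epsilon, alpha_v=self.alpha_v,
            v_base=self.v_base, D=self.D, k_s=self.k_s, delta_k=self.delta_k,
            alpha_k=self.alpha_k, Gc=self.Gc, mu_s=self.mu_s, L_s=self.L_s,
            delta_mu=self.delta_mu, alpha_mu=self.alpha_mu, tau=self.tau,
        )
        for name, val in positive.items():
            if not val > 0:
                raise ParameterError(f"{name} must be > 0, got {val!r}")
        if not 0 < self.nu < 0.5:
            raise ParameterError(f"nu must lie in (0, 0.5), got {self.nu!r}")
        if self.beta_mu < 1 or self.beta_k < 1:
            raise ParameterError("beta_mu and beta_k must be >= 1")
        if len(self.delta_it) != len(self.delta_iv):
            raise ParameterError("delta_it and delta_iv must have equal length")
        if any(b < a for a, b in zip(self.delta_it, self.delta_it[1:])):
            raise ParameterError("delta_it must be nondecreasing")
        if any(b <= a for a, b in zip(self.delta_iv, self.delta_iv[1:])):
            raise ParameterError("delta_iv must be strictly increasing")
        if any(v <= 0 for v in self.delta_iv):
            raise ParameterError("delta_iv entries must be > 0")
        if self.neurogenesis_profile not in ("svz", "ventricular"):
            raise ParameterError(
                "neurogenesis_profile must be 'svz' or 'ventricular', "
                f"got {self.neurogenesis_profile!r}")

    @property
    def n_cohorts(self) -> int:
        return len(self.delta_it)

    # ------------------------------------------------------------------
    # config-file round trip
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["delta_it"] = list(self.delta_it)
        d["delta_iv"] = list(self.delta_iv)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config {path} must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)


# ----------------------------------------------------------------------
# profile functions


def smoothed_heaviside(x, alpha):
    """Logistic step ``e^{alpha x} / (1 + e^{alpha x})``.

    Strictly increasing in ``x`` with plateaus 0 and 1 and value 1/2 at
    ``x = 0``; ``alpha`` sets the transition sharpness and must be > 0.
    """
    if not np.all(np.asarray(alpha) > 0):
        raise ParameterError(f"alpha must be > 0, got {alpha!r}")
    from scipy.special import expit

    out = expit(np.multiply(alpha, x))
    return out if np.ndim(out) else float(out)


def migration_activation(c_i, params: ModelParameters):
    """Fraction of the cohort actively migrating at spatial density ``c_i``.

    Migration is half activated at the threshold density ``c0``; the
    logistic argument is the normalized excess ``(c_i - c0)/c0`` scaled by
    ``alpha_c`` (equivalently, the raw excess measured in units of c0).
    """
    return smoothed_heaviside((np.asarray(c_i, float) - params.c0) / params.c0,
                              params.alpha_c)


def neurogenesis_spatial(r, params: ModelParameters):
    """Spatial neurogenesis window ``G^x(r)`` in [0, 1].

    With the default ``svz`` orientation the source is ~0 inside the
    ventricular zone (r < delta_x) and ~1 beyond it, where intermediate
    progenitor cells proliferate; ``ventricular`` flips the window.
    """
    if params.neurogenesis_profile == "svz":
        return smoothed_heaviside(np.asarray(r, float) - params.delta_x,
                                  params.alpha_G)
    return smoothed_heaviside(params.delta_x - np.asarray(r, float),
                              params.alpha_G)


def neurogenesis_temporal(t, cohort: int, params: ModelParameters):
    """Temporal birth pulse ``G^t_i(t)`` for cohort ``cohort`` (1-based).

    A Cauchy-type bump of height 1 centred on the cohort's
    electroporation day with half-width ``epsilon``.
    """
    delta = params.delta_it[_cohort_index(cohort, params)]
    e2 = params.epsilon ** 2
    out = e2 / ((np.asarray(t, float) - delta) ** 2 + e2)
    return out if out.ndim else float(out)


def velocity_magnitude(r, cohort: int, params: ModelParameters):
    """Signed migration speed profile ``v_i(r)`` [um/d].

    ``+0.5 v_base`` well inside the cohort destination ``delta_iv``,
    exactly zero at the destination, and ``-0.5 v_base`` beyond it (the
    vertical shift pins the zero crossing at the destination; the negative
    branch confines cells that overshoot).
    """
    delta = params.delta_iv[_cohort_index(cohort, params)]
    H = smoothed_heaviside(delta - np.asarray(r, float), params.alpha_v)
    out = params.v_base * H - 0.5 * params.v_base
    return out if np.ndim(out) else float(out)


def growth_coefficients(r, params: ModelParameters):
    """Radial/tangential growth coefficients ``(k_par, k_perp)`` [um^3].

    Both equal ``k_s`` in the subcortex; past the transition radius
    ``delta_k`` radial growth is reduced to ``k_s/beta_k`` while
    tangential growth is amplified to ``k_s * beta_k``.
    """
    H = smoothed_heaviside(np.asarray(r, float) - params.delta_k,
                           params.alpha_k)
    k_par = params.k_s * (1.0 + (1.0 / params.beta_k - 1.0) * H)
    k_perp = params.k_s * (1.0 + (params.beta_k - 1.0) * H)
    return k_par, k_perp


def shear_modulus(r, params: ModelParameters):
    """Shear modulus profile [kPa]: ``mu_s`` inner, ``beta_mu*mu_s`` outer."""
    H = smoothed_heaviside(np.asarray(r, float) - params.delta_mu,
                           params.alpha_mu)
    out = params.mu_s * (1.0 + (params.beta_mu - 1.0) * H)
    return out if np.ndim(out) else float(out)


def lame_L(r, params: ModelParameters):
    """Second Lame constant profile [kPa], scaled with the shear modulus.

    The Poisson ratio is spatially uniform, so ``L(r) = L_s * mu(r)/mu_s``.
    """
    out = params.L_s * np.asarray(shear_modulus(r, params)) / params.mu_s
    return out if np.ndim(out) else float(out)


def _cohort_index(cohort: int, params: ModelParameters) -> int:
    if not 1 <= int(cohort) <= params.n_cohorts:
        raise ParameterError(
            f"cohort must be in 1..{params.n_cohorts}, got {cohort!r}")
    return int(cohort) - 1
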