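"""Coupled growth-transport-equilibrium time loop.

Staggered scheme per time step (day 0 = E31 through day 27 = P16):

1. advance the per-cohort referential densities over [t, t + dt] with
   the deformation frozen at the step start;
2. rebuild the growth tensor from the total spatial density;
3. re-solve quasi-static mechanical equilibrium.

On solver failure the step is retried with a halved dt (down to a
floor), after which the run aborts with a diagnostic frame.  Runs are
deterministic given the configuration and seed (the seed only feeds the
initial surface imperfection of the 2-D geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constitutive as cst
from . import params as prm
from .fem import EquilibriumSolver, NonConvergenceError
from .mesh import Mesh, make_bar_mesh, make_halfcircle_mesh
from .profiles import DensityProfile
from .transport import TransportSolver, TransportError

__all__ = ["SimulationConfig", "SimulationFrame", "TimepointMap",
           "run_simulation", "measure_length", "sample_profile",
           "SimulationError"]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TimepointMap:
    """Simulation days for the three experimental preparation times.

    E39-40 (midpoint E39.5), P5-6 and P16 with birth at E42 map to days
    8.5, 16.5 and 27 after the day-0 electroporation at E31.
    """

    t1: float = 8.5
    t2: float = 16.5
    t3: float = 27.0

    def as_tuple(self):
        return (self.t1, self.t2, self.t3)


@dataclass
class SimulationFrame:
    """State snapshot at one output time."""

    t: float
    nodes_ref: np.ndarray           # (n_nodes, dim)
    u: np.ndarray                   # (n_nodes, dim)
    c_spatial: np.ndarray           # (n_cohorts, n_nodes) [um^-3]
    c_referential: np.ndarray       # (n_cohorts, n_nodes) [um^-3 ref]
    J_nodal: np.ndarray
    fiber_n: np.ndarray             # (n_el, 3) deformed fiber (unnormalized)
    fiber_N: np.ndarray             # (n_el, 3) referential fiber direction
    ln_lambda: np.ndarray           # (n_el,) log max principal stretch of F
    geometry: str = "bar"
    R0: float = 0.0
    surface: np.ndarray | None = None   # (n_surf, 2) deformed outer polyline
    diverged: bool = False              # last frame before a failed step

    @property
    def nodes_current(self) -> np.ndarray:
        return self.nodes_ref + self.u


@dataclass
class SimulationConfig:
    """Run configuration for :func:`run_simulation`."""

    params: prm.ModelParameters = field(default_factory=prm.ModelParameters)
    geometry: str = "bar"              # "bar" | "halfcircle"
    n_elems: int | None = None         # default 60 (bar) / 1147 (half disc)
    dt: float = 0.05                   # base time step [d]
    out_every: float = 0.5             # output cadence [d]
    seed: int = 0
    perturb_amplitude: float = 1e-3    # outer-surface imperfection, x R0
    stab: float = 1.0                  # streamline stabilization factor
    bar_tangential_growth: bool = False
    stop_time: float | None = None     # early stop (defaults to params.tau)
    timepoints: TimepointMap = field(default_factory=TimepointMap)
    newton_rtol: float = 1e-8
    min_dt_factor: float = 1.0 / 64.0
    # return the frames accumulated so far (flagging the last one) if a
    # step fails at the dt floor, instead of raising; used by the sweep,
    # where post-onset non-convergence (creasing without contact) is an
    # expected end of the meaningful simulation window
    partial_ok: bool = False


def _implicit_spatial_density(c0_qp, Je_qp, k_par, k_perp, c_init=None):
    """Solve ``c * Je * (1 + k_par c)(1 + k_perp c)^2 = c0`` per point.

    The spatial density and the growth dilution it causes are mutually
    dependent (``c = c0 / J`` with ``J = Je * Jg(c)``); lagging ``J`` a
    whole step is an unstable fixed-point iteration once the growth
    stretch exceeds ~2, so the local nonlinearity is solved exactly with
    a monotone Newton iteration, lagging only the elastic ``Je``.
    """
    c0 = np.maximum(np.asarray(c0_qp, float), 0.0)
    c = np.array(c_init, float) if c_init is not None else c0.copy()
    c = np.maximum(c, 0.0)
    for _ in range(60):
        tp = 1.0 + k_par * c
        tt = 1.0 + k_perp * c
        f = c * Je_qp * tp * tt ** 2 - c0
        df = Je_qp * (tp * tt ** 2
                      + c * (k_par * tt ** 2 + 2.0 * k_perp * tp * tt))
        step = f / df
        c = np.maximum(c - step, 0.0)
        if np.all(np.abs(f) <= 1e-12 * np.maximum(c0, 1e-30)):
            break
    return c


def _build_mesh(cfg: SimulationConfig) -> Mesh:
    p = cfg.params
    if cfg.geometry == "bar":
        return make_bar_mesh(p.R0, cfg.n_elems or 60)
    if cfg.geometry == "halfcircle":
        mesh = make_halfcircle_mesh(p.R0, cfg.n_elems or 1147)
        # deterministic radial white-noise imperfection on the pial surface
        rng = np.random.default_rng(cfg.seed)
        surf = mesh.node_sets["outer_surface"]
        wiggle = rng.uniform(-1.0, 1.0, size=surf.size)
        rhat = mesh.nodes[surf] / np.linalg.norm(mesh.nodes[surf], axis=1,
                                                 keepdims=True)
        mesh.nodes[surf] += (cfg.perturb_amplitude * p.R0
                             * wiggle[:, None] * rhat)
        return mesh
    raise ValueError(f"unknown geometry {cfg.geometry!r}")


def run_simulation(cfg: SimulationConfig):
    """Run the coupled model; returns the list of output frames."""
    p = cfg.params
    mesh = _build_mesh(cfg)
    solver = EquilibriumSolver(mesh, p)
    transport = TransportSolver(solver, stab=cfg.stab)

    k_par, k_perp = prm.growth_coefficients(solver.r_qp, p)
    k_par = np.asarray(k_par, float)
    k_perp = np.asarray(k_perp, float)
    if cfg.geometry == "bar" and not cfg.bar_tangential_growth:
        k_perp = np.zeros_like(k_perp)

    t_end = cfg.stop_time if cfg.stop_time is not None else p.tau
    out_times = set(np.round(np.arange(0.0, t_end + 1e-9, cfg.out_every), 9))
    for tt in cfg.timepoints.as_tuple():
        if tt <= t_end + 1e-9:
            out_times.add(round(tt, 9))
    out_times.add(round(t_end, 9))
    events = sorted(out_times)

    u = np.zeros((mesh.n_nodes, solver.dof_per_node))
    field = transport.initial_field()
    # deformation state carried across the staggered loop (F includes the
    # stress-free out-of-plane growth stretch in plane strain)
    F_prev = np.tile(np.eye(3), (mesh.n_elements, solver.n_qp, 1, 1))
    mech = None
    c_qp_prev = None
    frames = []

    def record(t):
        F_qp = F_prev
        J_qp = np.linalg.det(F_qp)
        J_nod = np.maximum(solver.project_to_nodes(J_qp), 1e-12)
        c_sp = field.c0 / J_nod[None, :]
        n_def = np.einsum("eqij,eqj->eqi", F_qp, solver.N_qp).mean(axis=1)
        C = np.einsum("eqki,eqkj->eqij", F_qp, F_qp)
        lam_max = np.sqrt(np.linalg.eigvalsh(C)[..., -1]).mean(axis=1)
        surface = None
        if cfg.geometry == "halfcircle":
            surf = mesh.node_sets["outer_surface"]
            cur = mesh.nodes[surf] + u[surf]
            ang = np.arctan2(mesh.nodes[surf][:, 1], mesh.nodes[surf][:, 0])
            order = np.argsort(ang)
            surface = cur[order]
        frames.append(SimulationFrame(
            t=t, nodes_ref=mesh.nodes.copy(), u=u.copy(),
            c_spatial=c_sp, c_referential=field.c0.copy(),
            J_nodal=J_nod, fiber_n=n_def, fiber_N=mesh.fiber.copy(),
            ln_lambda=np.log(lam_max),
            geometry=cfg.geometry, R0=p.R0, surface=surface))

    t = 0.0
    record(t)
    dt_min = cfg.dt * cfg.min_dt_factor
    for t_next in events:
        if t_next <= 1e-12:
            continue
        while t < t_next - 1e-9:
            dt_try = min(cfg.dt, t_next - t)
            while True:
                try:
                    J_qp = np.linalg.det(F_prev)
                    J_nod = np.maximum(solver.project_to_nodes(J_qp), 1e-12)
                    field_new = transport.advance(field, t, dt_try, F_prev,
                                                  J_qp, J_nod)
                    c0_qp = sum(solver.interp_to_qp(field_new.c0[i])
                                for i in range(p.n_cohorts))
                    Je_qp = (np.linalg.det(mech.Fe) if mech is not None
                             else np.ones_like(J_qp))
                    c_qp = _implicit_spatial_density(c0_qp, Je_qp, k_par,
                                                     k_perp, c_init=c_qp_prev)
                    Fg = cst.growth_tensor(c_qp, k_par, k_perp, solver.N_qp)
                    mech = solver.solve(Fg, u0=u.ravel(),
                                        rtol=cfg.newton_rtol)
                    break
                except (NonConvergenceError, TransportError,
                        cst.DegenerateGrowthError) as exc:
                    dt_try *= 0.5
                    if dt_try < dt_min:
                        record(t)
                        if cfg.partial_ok:
                            frames[-1].diverged = True
                            return frames
                        raise SimulationError(
                            f"step failed at t = {t:.4f} d even at the dt "
                            f"floor ({dt_min:.3g} d): {exc}") from exc
            t += dt_try
            u = mech.u
            F_prev = mech.F
            c_qp_prev = c_qp
            field = field_new
        record(round(t, 9))
    return frames


def measure_length(frame: SimulationFrame) -> float:
    """Current bar length: fixed end to free end [um]."""
    if frame.geometry != "bar":
        raise ValueError("measure_length is defined for the bar geometry")
    x = frame.nodes_current[:, 0]
    return float(x[-1] - x[0])


def sample_profile(frame: SimulationFrame, n_points: int,
                   cohort: int, timepoint: int = 0) -> DensityProfile:
    """Cohort density at equispaced normalized positions along the bar."""
    if frame.geometry != "bar":
        raise ValueError("sample_profile is defined for the bar geometry")
    x = frame.nodes_current[:, 0]
    length = float(x[-1] - x[0])
    xi = np.linspace(0.0, 1.0, n_points)
    dens = np.interp(x[0] + xi * length, x, frame.c_spatial[cohort - 1])
    return DensityProfile(normalized_position=xi, density=dens,
                          length=length, cohort=cohort, timepoint=timepoint)
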