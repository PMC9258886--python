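"""Genetic-algorithm calibration of the migration/growth parameters.

Seven parameters are estimated from the eight cohort density profiles
and three domain lengths: the baseline division rate ``Gc``, shared
migration speed ``v_base``, the three cohort destinations ``delta_iv``,
the diffusion coefficient ``D`` and the subcortical growth parameter
``k_s``.  The objective balances relative density-vector errors (weight
``w1 = 11/8``) against relative length errors (``w2 = 11/3``).

The optimizer is a small real-coded GA: elitism of one, tournament
selection (size 2), blend (BLX-alpha) crossover and per-gene Gaussian
mutation with bounds clipping, all driven by a single seeded RNG so
calibrations are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import params as prm
from .profiles import (DensityProfile, ExperimentalDataset, PROFILE_KEYS,
                       resample_profile)
from .simulation import (SimulationConfig, TimepointMap, run_simulation,
                         measure_length, sample_profile, SimulationError)

__all__ = ["GAConfig", "Genome", "CalibrationRecord", "objective",
           "evolve", "calibrate", "sensitivity_scan", "forward_profiles",
           "W1", "W2", "default_bounds"]

W1 = 11.0 / 8.0
W2 = 11.0 / 3.0

#: profile keys present in single-cohort mode (summed densities)
SINGLE_KEYS = ((1, 1), (1, 2), (1, 3))
PENALTY = 1.0e9


@dataclass
class GAConfig:
    pop_size: int = 10
    n_generations: int = 40
    # evolution strategy: "de" (differential evolution, rand/1/bin with
    # greedy slot replacement — keeps diversity in a 10-member
    # population and follows the objective's curved valley) or
    # "tournament" (elitism + tournament + BLX + Gaussian mutation)
    strategy: str = "de"
    de_weight: tuple = (0.5, 1.0)    # range of the differential weight
    de_crossover: float = 0.9        # binomial crossover rate
    de_best_frac: float = 0.7        # final fraction of mutants anchored
    #   at the incumbent best (best/1 vs rand/1); ramped linearly from 0
    #   so early generations explore and late generations exploit
    elitism: int = 1
    tournament: int = 2
    crossover_prob: float = 0.9
    blx_alpha: float = 0.5
    mutation_prob: float = 0.2
    mutation_sigma: float = 0.1      # initial fraction of each gene's range
    mutation_sigma_final: float = 0.005  # annealed-to fraction at last gen
    diff_move_prob: float = 0.3      # differential (population-vector) move
    convergence_tol: float = 1e-3    # plateau rule on the best objective
    convergence_window: int = 10
    refine_fraction: float = 0.0     # if in (0, 1): fraction of budget
    refine_sigma: float = 0.02       # before a restart around the best
    bounds_expand: float = 0.0       # fractional widening of initial ranges
    n_elems: int = 60
    dt: float = 0.05
    n_points: int = 60


@dataclass
class Genome:
    """Parameter vector with names and box bounds."""

    names: tuple
    values: np.ndarray
    bounds: np.ndarray               # (n, 2)

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


@dataclass
class CalibrationRecord:
    mode: str
    best_genome: Genome
    best_objective: float
    best_trace: list                 # best-so-far objective per generation
    generations: list                # per-generation (values array, fitness)
    n_evaluations: int = 0
    failures: int = 0


def default_bounds(mode: str, params: prm.ModelParameters) -> dict:
    """Search ranges: literature ranges where available, wide brackets
    otherwise (destinations within the domain, k_s within a factor ~2)."""
    b = {
        "Gc": (1.0e-6, 1.5e-5),
        "v_base": (230.0, 4752.0),
        "D": (25000.0, 35000.0),
        "k_s": (1.0e5, 3.0e5),
    }
    dest = (0.4 * params.R0, 0.999 * params.R0)
    if mode == "single_cohort":
        b["delta_v"] = dest
    else:
        b["delta_1v"] = dest
        b["delta_2v"] = dest
        b["delta_3v"] = dest
    return b


def _genome_names(mode: str):
    if mode == "single_cohort":
        return ("Gc", "v_base", "delta_v", "D", "k_s")
    return ("Gc", "v_base", "delta_1v", "delta_2v", "delta_3v", "D", "k_s")


def _apply_genome(params: prm.ModelParameters, names, values,
                  mode: str) -> prm.ModelParameters:
    d = dict(zip(names, values))
    kw = dict(Gc=d["Gc"], v_base=d["v_base"], D=d["D"], k_s=d["k_s"])
    if mode == "single_cohort":
        kw["delta_it"] = (0.0,)
        kw["delta_iv"] = (d["delta_v"],)
    else:
        dv = sorted((d["delta_1v"], d["delta_2v"], d["delta_3v"]))
        # enforce strict ordering for the parameter invariant
        for i in range(1, 3):
            if dv[i] <= dv[i - 1]:
                dv[i] = dv[i - 1] * (1 + 1e-9) + 1e-9
        kw["delta_iv"] = tuple(dv)
    return params.replace(**kw)


# ----------------------------------------------------------------------
def objective(sim_profiles: dict, sim_lengths: dict,
              exp: ExperimentalDataset, w1: float = W1, w2: float = W2,
              n_points: int = 60, keys=None) -> float:
    """Weighted relative density + length misfit.

    ``w1 * sum_k ||c_sim - c_exp|| / ||c_exp|| + w2 * sum_t |l_sim -
    l_exp| / l_exp`` over the profile keys and timepoints present in
    the experimental dataset (restrict with ``keys``).
    """
    keys = tuple(keys) if keys is not None else tuple(sorted(exp.profiles))
    total = 0.0
    for key in keys:
        ce = resample_profile(exp.profiles[key], n_points)
        cs = resample_profile(sim_profiles[key], n_points)
        norm = np.linalg.norm(ce)
        if norm == 0:
            raise ValueError(f"degenerate dataset: zero density norm {key}")
        total += w1 * np.linalg.norm(cs - ce) / norm
    for tp, le in sorted(exp.lengths.items()):
        if keys and all(k[1] != tp for k in keys):
            continue
        total += w2 * abs(sim_lengths[tp] - le) / le
    return float(total)


def forward_profiles(params: prm.ModelParameters, ga: GAConfig,
                     keys=PROFILE_KEYS,
                     timepoints: TimepointMap = TimepointMap()):
    """Run the bar model and sample the keyed profiles and lengths."""
    cfg = SimulationConfig(params=params, geometry="bar",
                           n_elems=ga.n_elems, dt=ga.dt,
                           timepoints=timepoints, out_every=max(
                               timepoints.as_tuple()))
    frames = run_simulation(cfg)
    tp_times = timepoints.as_tuple()
    profiles, lengths = {}, {}
    for tp, tt in enumerate(tp_times, start=1):
        frame = next(f for f in frames if abs(f.t - tt) < 1e-6)
        lengths[tp] = measure_length(frame)
        for cohort, tpk in keys:
            if tpk == tp:
                profiles[(cohort, tp)] = sample_profile(
                    frame, ga.n_points, cohort, timepoint=tp)
    return profiles, lengths


# ----------------------------------------------------------------------
def evolve(population: np.ndarray, fitness: np.ndarray, ga: GAConfig,
           bounds: np.ndarray, rng: np.random.Generator,
           sigma: float | None = None) -> np.ndarray:
    """One GA generation: elitism + tournament + BLX + Gaussian mutation.

    ``sigma`` overrides the mutation width (fraction of each gene's
    range); :func:`calibrate` anneals it geometrically from
    ``mutation_sigma`` to ``mutation_sigma_final`` so late generations
    refine rather than re-explore.
    """
    pop = np.asarray(population, float)
    fit = np.asarray(fitness, float)
    if pop.size == 0:
        raise ValueError("empty population")
    n, g = pop.shape
    order = np.argsort(fit)
    nxt = [pop[order[i]].copy() for i in range(min(ga.elitism, n))]

    def pick():
        idx = rng.integers(0, n, size=ga.tournament)
        return pop[idx[np.argmin(fit[idx])]]

    span = bounds[:, 1] - bounds[:, 0]
    while len(nxt) < n:
        p1, p2 = pick().copy(), pick().copy()
        if rng.random() < ga.crossover_prob:
            lo = np.minimum(p1, p2)
            hi = np.maximum(p1, p2)
            d = hi - lo
            child = rng.uniform(lo - ga.blx_alpha * d,
                                hi + ga.blx_alpha * d)
        else:
            child = p1
        mut = rng.random(g) < ga.mutation_prob
        s = ga.mutation_sigma if sigma is None else sigma
        child = np.where(mut, child + rng.standard_normal(g) * s * span,
                         child)
        if rng.random() < ga.diff_move_prob and n >= 2:
            # differential move anchored at the incumbent best: follows
            # the ridge directions that isotropic mutation explores poorly
            ia, ib = rng.choice(n, size=2, replace=False)
            child = child + rng.uniform(0.4, 1.0) * (pop[ia] - pop[ib])
        nxt.append(np.clip(child, bounds[:, 0], bounds[:, 1]))
    return np.asarray(nxt[:n])


def calibrate(dataset: ExperimentalDataset, mode: str = "three_cohort",
              ga: GAConfig | None = None,
              base_params: prm.ModelParameters | None = None,
              seed: int = 0,
              timepoints: TimepointMap = TimepointMap()) -> CalibrationRecord:
    """GA search for the genome minimizing the profile + length misfit.

    Modes: ``three_cohort`` (full dataset), ``leave_out_t3`` (fit on the
    first two timepoints only, for validation against the third) and
    ``single_cohort`` (one cohort fitted to summed densities).
    """
    if mode not in ("three_cohort", "leave_out_t3", "single_cohort"):
        raise ValueError(f"unknown calibration mode {mode!r}")
    ga = ga or GAConfig()
    base = base_params or prm.ModelParameters()
    rng = np.random.default_rng(seed)
    names = _genome_names(mode)
    bnds = default_bounds(mode, base)
    bounds = np.array([bnds[k] for k in names], float)
    if ga.bounds_expand:
        mid = bounds.mean(axis=1)
        half = 0.5 * (bounds[:, 1] - bounds[:, 0]) * (1 + ga.bounds_expand)
        bounds = np.column_stack([np.maximum(mid - half, 1e-12), mid + half])

    if mode == "single_cohort":
        exp = _summed_dataset(dataset)
        keys = SINGLE_KEYS
        fkeys = SINGLE_KEYS
    elif mode == "leave_out_t3":
        exp = dataset
        keys = tuple(k for k in sorted(dataset.profiles) if k[1] != 3)
        fkeys = PROFILE_KEYS
    else:
        exp = dataset
        keys = tuple(sorted(dataset.profiles))
        fkeys = PROFILE_KEYS

    cache: dict = {}
    failures = 0
    evals = 0

    def fitness_of(vec):
        nonlocal failures, evals
        key = tuple(np.round(vec, 9))
        if key in cache:
            return cache[key]
        p = _apply_genome(base, names, vec, mode)
        try:
            prof, lens = forward_profiles(p, ga, keys=fkeys,
                                          timepoints=timepoints)
            val = objective(prof, lens, exp, n_points=ga.n_points, keys=keys)
        except (SimulationError, prm.ParameterError, ValueError):
            failures += 1
            val = PENALTY
        evals += 1
        cache[key] = val
        return val

    n, g = ga.pop_size, len(names)
    pop = rng.uniform(bounds[:, 0], bounds[:, 1], size=(n, g))
    fit = np.array([fitness_of(v) for v in pop])
    record = CalibrationRecord(mode=mode, best_genome=None,
                               best_objective=np.inf, best_trace=[],
                               generations=[])

    def bookkeep():
        best = int(np.argmin(fit))
        if fit[best] < record.best_objective:
            record.best_objective = float(fit[best])
            record.best_genome = Genome(names=names,
                                        values=pop[best].copy(),
                                        bounds=bounds.copy())
        record.best_trace.append(record.best_objective)
        record.generations.append((pop.copy(), fit.copy()))
        if ga.strategy == "de":
            # greedy slot replacement makes the best-trace piecewise
            # flat; a plateau rule would truncate systematically, so DE
            # runs to the generation cap
            return False
        w = ga.convergence_window
        return (len(record.best_trace) > w and
                record.best_trace[-w - 1] - record.best_trace[-1]
                < ga.convergence_tol)

    bookkeep()
    for gen in range(1, ga.n_generations):
        if ga.strategy == "de":
            best_frac = ga.de_best_frac * gen / max(ga.n_generations - 1, 1)
            for i in range(n):
                r1, r2, r3 = rng.choice(
                    [j for j in range(n) if j != i], size=3, replace=False)
                Fw = rng.uniform(*ga.de_weight)
                anchor = (pop[int(np.argmin(fit))]
                          if rng.random() < best_frac else pop[r1])
                mutant = anchor + Fw * (pop[r2] - pop[r3])
                mask = rng.random(g) < ga.de_crossover
                mask[rng.integers(g)] = True
                child = np.clip(np.where(mask, mutant, pop[i]),
                                bounds[:, 0], bounds[:, 1])
                cf = fitness_of(child)
                if cf <= fit[i]:
                    pop[i], fit[i] = child, cf
        else:
            frac = gen / max(ga.n_generations - 1, 1)
            sigma = ga.mutation_sigma * (
                ga.mutation_sigma_final / ga.mutation_sigma) ** frac
            if (0.0 < ga.refine_fraction < 1.0 and
                    gen == int(ga.refine_fraction * ga.n_generations)):
                # restart tightly around the incumbent best: the first
                # half locates the basin, the second half refines
                span = bounds[:, 1] - bounds[:, 0]
                best_vec = record.best_genome.values
                pop = best_vec + ga.refine_sigma * span \
                    * rng.standard_normal((n, g))
                pop = np.clip(pop, bounds[:, 0], bounds[:, 1])
                pop[0] = best_vec
            else:
                pop = evolve(pop, fit, ga, bounds, rng, sigma=sigma)
            fit = np.array([fitness_of(v) for v in pop])
        if bookkeep():
            break
    record.n_evaluations = evals
    record.failures = failures
    return record


def _summed_dataset(dataset: ExperimentalDataset) -> ExperimentalDataset:
    """Sum cohort densities per timepoint (single-cohort target data)."""
    out = ExperimentalDataset(lengths=dict(dataset.lengths))
    for tp in sorted({k[1] for k in dataset.profiles}):
        profs = [p for (c, t), p in dataset.profiles.items() if t == tp]
        grid = profs[0].normalized_position
        total = np.zeros_like(grid)
        for p in profs:
            total += np.interp(grid, p.normalized_position, p.density)
        out.profiles[(1, tp)] = DensityProfile(
            normalized_position=grid, density=total,
            length=profs[0].length, cohort=1, timepoint=tp)
    return out


# ----------------------------------------------------------------------
def sensitivity_scan(dataset: ExperimentalDataset,
                     center: prm.ModelParameters,
                     pairs=(("Gc", "D"), ("v_base", "k_s")),
                     rel_range: float = 0.2, n_grid: int = 5,
                     ga: GAConfig | None = None,
                     timepoints: TimepointMap = TimepointMap()) -> pd.DataFrame:
    """Objective surface on 2-D grids around a calibrated point."""
    ga = ga or GAConfig()
    rows = []
    keys = tuple(sorted(dataset.profiles))
    for p1, p2 in pairs:
        v1c = getattr(center, p1)
        v2c = getattr(center, p2)
        for f1 in np.linspace(1 - rel_range, 1 + rel_range, n_grid):
            for f2 in np.linspace(1 - rel_range, 1 + rel_range, n_grid):
                p = center.replace(**{p1: v1c * f1, p2: v2c * f2})
                try:
                    prof, lens = forward_profiles(p, ga,
                                                  timepoints=timepoints)
                    val = objective(prof, lens, dataset,
                                    n_points=ga.n_points, keys=keys)
                except (SimulationError, ValueError):
                    val = np.nan
                rows.append((p1, v1c * f1, p2, v2c * f2, val))
    return pd.DataFrame(rows, columns=["param1", "value1", "param2",
                                       "value2", "f_obj"])
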