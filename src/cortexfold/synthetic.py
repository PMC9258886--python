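"""Synthetic experiment-like datasets with known ground truth.

The generator runs the calibrated forward bar model and emulates the
imaging pipeline's outputs: eight cohort density profiles (cohort 3 is
not imaged at the first timepoint) plus the three domain lengths, with
optional counting noise.  Because the generating parameters are known,
these datasets exercise the calibration and profiling machinery without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import params as prm
from .profiles import DensityProfile, ExperimentalDataset, PROFILE_KEYS
from .simulation import (SimulationConfig, TimepointMap, run_simulation,
                         measure_length, sample_profile)

__all__ = ["SyntheticConfig", "generate_profile_dataset",
           "generate_neuron_table", "NeuronTable"]


@dataclass
class NeuronTable:
    """Neuron coordinates inside a rectangular ROI of W x L um."""

    x: np.ndarray              # [um], 0 <= x <= W
    y: np.ndarray              # [um], 0 <= y <= L
    width: float               # ROI width W [um]
    length: float              # ROI length L [um]
    thickness: float = 50.0    # assumed section depth [um]
    cohort: int = 0
    timepoint: int = 0

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class SyntheticConfig:
    """Noise model and imaging-geometry settings for dataset generation."""

    params: prm.ModelParameters = field(default_factory=prm.ModelParameters)
    n_points: int = 60           # samples per profile
    noise: str = "poisson"       # "none" | "poisson" | "gaussian"
    sigma: float = 0.0           # multiplicative std for gaussian noise
    roi_width: float = 500.0     # W [um]
    depth: float = 50.0          # dz [um]
    seed: int = 0
    n_elems: int = 60
    dt: float = 0.05
    timepoints: TimepointMap = field(default_factory=TimepointMap)

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.noise not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def generate_profile_dataset(cfg: SyntheticConfig):
    """Run the forward bar model and emit a noisy calibration dataset.

    Returns ``(dataset, truth)`` where ``truth`` is a manifest dict with
    the generating genome and run settings.
    """
    p = cfg.params
    if max(cfg.timepoints.as_tuple()) > p.tau + 1e-9:
        raise ValueError(
            f"imaging timepoints {cfg.timepoints.as_tuple()} exceed the "
            f"simulated duration tau = {p.tau} d")
    sim_cfg = SimulationConfig(params=p, geometry="bar", n_elems=cfg.n_elems,
                               dt=cfg.dt, timepoints=cfg.timepoints,
                               seed=cfg.seed)
    frames = run_simulation(sim_cfg)
    rng = np.random.default_rng(cfg.seed)
    tp_times = cfg.timepoints.as_tuple()
    dataset = ExperimentalDataset()
    for tp, tt in enumerate(tp_times, start=1):
        frame = next(f for f in frames if abs(f.t - tt) < 1e-6)
        dataset.lengths[tp] = measure_length(frame)
    for cohort, tp in PROFILE_KEYS:
        tt = tp_times[tp - 1]
        frame = next(f for f in frames if abs(f.t - tt) < 1e-6)
        prof = sample_profile(frame, cfg.n_points, cohort, timepoint=tp)
        dens = _apply_noise(prof, cfg, rng)
        dataset.profiles[(cohort, tp)] = DensityProfile(
            normalized_position=prof.normalized_position, density=dens,
            length=prof.length, cohort=cohort, timepoint=tp)
    dataset.validate()
    truth = {
        "genome": {
            "Gc": p.Gc, "v_base": p.v_base,
            "delta_iv": list(p.delta_iv), "D": p.D, "k_s": p.k_s,
        },
        "noise": cfg.noise, "sigma": cfg.sigma, "seed": cfg.seed,
        "n_points": cfg.n_points, "n_elems": cfg.n_elems, "dt": cfg.dt,
        "timepoints": list(tp_times),
    }
    return dataset, truth


def _apply_noise(prof: DensityProfile, cfg: SyntheticConfig, rng):
    dens = prof.density.copy()
    if cfg.noise == "poisson":
        # counting noise: expected neurons per sampling bin of the ROI
        bin_len = prof.length * np.mean(np.diff(prof.normalized_position))
        vol = cfg.roi_width * cfg.depth * bin_len
        dens = rng.poisson(np.maximum(dens * vol, 0.0)) / vol
    elif cfg.noise == "gaussian" and cfg.sigma > 0:
        dens = np.maximum(
            dens * (1.0 + cfg.sigma * rng.standard_normal(dens.shape)), 0.0)
    return dens


def generate_neuron_table(profile: DensityProfile, W: float, dz: float,
                          seed: int = 0) -> NeuronTable:
    """Inhomogeneous Poisson point sample consistent with a profile.

    Expected neuron count per unit ROI length is ``density(y) * W * dz``;
    x-coordinates are uniform across the ROI width.
    """
    rng = np.random.default_rng(seed)
    L = profile.length
    y_edges = np.concatenate([[0.0],
                              0.5 * (profile.normalized_position[1:]
                                     + profile.normalized_position[:-1]) * L,
                              [L]])
    seg_len = np.diff(y_edges)
    lam = profile.density * W * dz * seg_len
    counts = rng.poisson(np.maximum(lam, 0.0))
    ys, xs = [], []
    for lo, hi, n in zip(y_edges[:-1], y_edges[1:], counts):
        if n:
            ys.append(rng.uniform(lo, hi, n))
            xs.append(rng.uniform(0.0, W, n))
    y = np.concatenate(ys) if ys else np.empty(0)
    x = np.concatenate(xs) if xs else np.empty(0)
    return NeuronTable(x=x, y=y, width=W, length=L, thickness=dz,
                       cohort=profile.cohort, timepoint=profile.timepoint)
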