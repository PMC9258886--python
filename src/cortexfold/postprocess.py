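"""Folding metrics: buckling onset, wavelength, strain and fiber fields.

Onset is detected from the outer-surface radius ``r(theta)``: the RMS
deviation from a running circumferential mean (window default pi/4)
is tracked over time and onset is the first frame where it exceeds a
fraction (default 1%) of the initial radius.  The fold wavelength is
the dominant nonzero cosine mode of ``r(theta)`` on the half circle,
converted to an arc length per fold and normalized by ``R0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as prm
from .simulation import SimulationConfig, SimulationFrame, run_simulation

__all__ = ["FoldingMetrics", "surface_deviation", "detect_onset",
           "measure_wavelength", "fiber_field", "folding_metrics",
           "run_sweep", "FOLDING_PROFILE"]

#: neurogenesis orientation used for the 2-D folding studies: the
#: proliferative region must stay spatially confined for the disc
#: geometry (the outward-open profile makes the source volume feedback
#: unbounded in 2-D); see docs/methods.md.
FOLDING_PROFILE = "ventricular"


@dataclass
class FoldingMetrics:
    onset_time: float | None          # [d]; None if never buckles
    normalized_wavelength: float | None   # fold arc length / R0
    deviation_trace: np.ndarray       # (n_frames,) RMS surface deviation [um]
    times: np.ndarray                 # (n_frames,) [d]
    fiber_angle_std_final: float = np.nan   # [rad]


def _radius_vs_angle(surface: np.ndarray, n: int = 256):
    ang = np.arctan2(surface[:, 1], surface[:, 0])
    order = np.argsort(ang)
    th, r = ang[order], np.linalg.norm(surface, axis=1)[order]
    grid = np.linspace(0.0, np.pi, n)
    return grid, np.interp(grid, th, r)


def surface_deviation(surface: np.ndarray, window: float = np.pi / 4) -> float:
    """RMS deviation of the outer radius from its running mean [um]."""
    th, r = _radius_vs_angle(surface)
    half = window / 2
    run = np.array([r[(th >= t - half) & (th <= t + half)].mean()
                    for t in th])
    return float(np.sqrt(np.mean((r - run) ** 2)))


def detect_onset(times, deviation_trace, R0: float,
                 threshold: float = 0.01) -> float | None:
    """First time the surface deviation exceeds ``threshold * R0``."""
    times = np.asarray(times, float)
    dev = np.asarray(deviation_trace, float)
    if times.size < 3:
        raise ValueError("need at least three frames to detect onset")
    above = dev > threshold * R0
    if not np.any(above):
        return None
    return float(times[np.argmax(above)])


def measure_wavelength(surface: np.ndarray, R0: float,
                       k_max: int = 40) -> float:
    """Dominant-fold arc length normalized by ``R0``.

    Decomposes ``r(theta)`` on the half circle into cosine modes
    (symmetry about both cut ends), picks the dominant nonzero mode
    ``k*`` and returns ``(arc length) / k* / R0``.
    """
    th, r = _radius_vs_angle(surface)
    amps = np.array([np.trapezoid(r * np.cos(k * th), th) * 2 / np.pi
                     for k in range(1, k_max + 1)])
    if np.max(np.abs(amps)) < 1e-12 * max(np.max(r), 1.0):
        raise ValueError("flat surface: no dominant circumferential mode")
    k_star = int(np.argmax(np.abs(amps))) + 1
    dr = np.gradient(r, th)
    arc = np.trapezoid(np.sqrt(r ** 2 + dr ** 2), th)
    return float(arc / k_star / R0)


def fiber_field(frame: SimulationFrame,
                fiber_ref: np.ndarray | None = None) -> np.ndarray:
    """Angle between the deformed fiber ``n = F N`` and the referential
    radial direction ``N``, per element [rad].

    The reference directions default to the ones stored in the frame
    (``N`` is radial by construction); an undeformed frame gives zeros.
    """
    Nr = fiber_ref if fiber_ref is not None else frame.fiber_N
    n = frame.fiber_n
    nn = n / np.linalg.norm(n, axis=1, keepdims=True)
    Nr = Nr / np.linalg.norm(Nr, axis=1, keepdims=True)
    cosang = np.clip(np.abs((nn * Nr).sum(axis=1)), 0.0, 1.0)
    return np.arccos(cosang)


def folding_metrics(frames, fiber_ref: np.ndarray | None = None,
                    threshold: float = 0.01,
                    window: float = np.pi / 4) -> FoldingMetrics:
    """Onset, wavelength and fiber statistics for a 2-D run."""
    times = np.array([f.t for f in frames])
    dev = np.array([surface_deviation(f.surface, window) for f in frames])
    R0 = frames[0].R0
    onset = detect_onset(times, dev, R0, threshold)
    wavelength = None
    if onset is not None:
        fr = next(f for f in frames if f.t >= onset)
        try:
            wavelength = measure_wavelength(fr.surface, R0)
        except ValueError:
            wavelength = None
    ang_std = float(np.std(fiber_field(frames[-1], fiber_ref)))
    return FoldingMetrics(onset_time=onset,
                          normalized_wavelength=wavelength,
                          deviation_trace=dev, times=times,
                          fiber_angle_std_final=ang_std)


def run_sweep(base_params: prm.ModelParameters | None = None,
              beta_mu_values=(3.0, 5.0, 7.0, 9.0),
              beta_k_values=(1.0, 1.5, 2.0),
              n_elems: int = 300, dt: float = 0.05, seed: int = 1,
              out_every: float = 0.25,
              stop_time: float | None = None) -> pd.DataFrame:
    """Folding metrics over the stiffness-ratio x growth-ratio grid.

    Individual run failures are recorded (``status`` column) and the
    sweep continues.  Runs use the spatially confined neurogenesis
    profile (see :data:`FOLDING_PROFILE`).
    """
    base = base_params or prm.ModelParameters()
    rows = []
    for bmu in beta_mu_values:
        for bk in beta_k_values:
            p = base.replace(beta_mu=float(bmu), beta_k=float(bk),
                             neurogenesis_profile=FOLDING_PROFILE)
            cfg = SimulationConfig(params=p, geometry="halfcircle",
                                   n_elems=n_elems, dt=dt, seed=seed,
                                   out_every=out_every,
                                   stop_time=stop_time, partial_ok=True)
            try:
                frames = run_simulation(cfg)
                m = folding_metrics(frames)
                status = ("ok" if not frames[-1].diverged
                          else f"partial(t_end={frames[-1].t:.2f})")
                rows.append((bmu, bk, m.onset_time,
                             m.normalized_wavelength, status))
            except Exception as exc:   # keep sweeping on cell failure
                rows.append((bmu, bk, None, None, f"failed: {exc}"))
    return pd.DataFrame(rows, columns=["beta_mu", "beta_k", "onset_time",
                                       "normalized_wavelength", "status"])
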