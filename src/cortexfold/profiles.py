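"""Density-profile containers shared by simulation, profiling and calibration.

A :class:`DensityProfile` is the unit of comparison throughout: cell
density (per um^3) of one cohort sampled along the normalized radial
position of a domain of known length.  An :class:`ExperimentalDataset`
bundles the eight (cohort, timepoint) profiles used for calibration --
cohort 3 is absent at the first timepoint, mirroring the imaging layout
-- together with the three domain lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DensityProfile", "ExperimentalDataset", "PROFILE_KEYS",
           "resample_profile"]

#: the (cohort, timepoint) pairs present in the calibration dataset
PROFILE_KEYS = ((1, 1), (2, 1), (1, 2), (2, 2), (3, 2), (1, 3), (2, 3), (3, 3))


@dataclass
class DensityProfile:
    """1-D cohort density vs normalized radial position."""

    normalized_position: np.ndarray   # values in [0, 1], strictly increasing
    density: np.ndarray               # [um^-3], >= 0
    length: float                     # source domain length [um]
    cohort: int = 0
    timepoint: int = 0

    def __post_init__(self):
        self.normalized_position = np.asarray(self.normalized_position, float)
        self.density = np.asarray(self.density, float)
        if self.normalized_position.shape != self.density.shape:
            raise ValueError("position and density shapes differ")
        if np.any(np.diff(self.normalized_position) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")


def resample_profile(profile: DensityProfile, n_points: int) -> np.ndarray:
    """Linear resampling of the density onto a uniform [0, 1] grid."""
    grid = np.linspace(0.0, 1.0, n_points)
    return np.interp(grid, profile.normalized_position, profile.density)


@dataclass
class ExperimentalDataset:
    """Eight keyed profiles plus per-timepoint domain lengths."""

    profiles: dict = field(default_factory=dict)  # (cohort, tp) -> profile
    lengths: dict = field(default_factory=dict)   # tp -> length [um]

    def validate(self, keys=PROFILE_KEYS) -> None:
        missing = [k for k in keys if k not in self.profiles]
        if missing:
            raise ValueError(f"dataset missing profile keys: {missing}")
        tps = sorted(self.lengths)
        if not tps:
            raise ValueError("dataset has no lengths")
        vals = [self.lengths[t] for t in tps]
        if any(v <= 0 for v in vals) or any(b <= a for a, b in
                                            zip(vals, vals[1:])):
            raise ValueError("lengths must be positive and increasing")

    # ------------------------------------------------------------------
    def to_frames(self):
        rows = []
        for (cohort, tp), prof in sorted(self.profiles.items()):
            for xi, c in zip(prof.normalized_position, prof.density):
                rows.append((cohort, tp, xi, c))
        prof_df = pd.DataFrame(
            rows, columns=["cohort", "timepoint", "normalized_position",
                           "density_um3"])
        len_df = pd.DataFrame(
            sorted(self.lengths.items()), columns=["timepoint", "length_um"])
        return prof_df, len_df

    def to_csv(self, profiles_path, lengths_path) -> None:
        prof_df, len_df = self.to_frames()
        prof_df.to_csv(profiles_path, index=False)
        len_df.to_csv(lengths_path, index=False)

    @classmethod
    def from_csv(cls, profiles_path, lengths_path) -> "ExperimentalDataset":
        prof_df = pd.read_csv(profiles_path)
        len_df = pd.read_csv(lengths_path)
        lengths = {int(r.timepoint): float(r.length_um)
                   for r in len_df.itertuples()}
        profiles = {}
        for (cohort, tp), grp in prof_df.groupby(["cohort", "timepoint"]):
            grp = grp.sort_values("normalized_position")
            profiles[(int(cohort), int(tp))] = DensityProfile(
                normalized_position=grp.normalized_position.to_numpy(),
                density=grp.density_um3.to_numpy(),
                length=lengths.get(int(tp), np.nan),
                cohort=int(cohort), timepoint=int(tp))
        return cls(profiles=profiles, lengths=lengths)
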