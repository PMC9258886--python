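"""From neuron coordinates to 1-D radial cell-density profiles.

Mirrors the imaging workflow: a rectangular ROI spanning the radial
extent of the developing cortex is divided into subcells (default
45.1 x 49.3 x 50 um), neurons are counted per subcell, densities are
averaged across the ROI width, and positions are normalized by the
ROI length (averaged within each imaging group).
"""

from __future__ import annotations

import numpy as np

from .profiles import DensityProfile
from .synthetic import NeuronTable

__all__ = ["DEFAULT_SUBCELL", "bin_neurons", "profile_from_counts",
           "group_normalize", "neurons_from_mask"]

#: subcell dimensions (dx, dy, dz) in um used by the counting workflow
DEFAULT_SUBCELL = (45.1, 49.3, 50.0)


def bin_neurons(table: NeuronTable, subcell=DEFAULT_SUBCELL) -> np.ndarray:
    """Count neurons on an (x-bin, y-bin) grid of subcells.

    Bins are half-open ``[lo, hi)`` with the trailing (possibly
    partial) bin closed so boundary neurons are kept.  Raises if any
    coordinate falls outside the ROI.
    """
    dx, dy, dz = subcell
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("subcell dimensions must be > 0")
    bad = ((table.x < 0) | (table.x > table.width)
           | (table.y < 0) | (table.y > table.length))
    if np.any(bad):
        idx = np.where(bad)[0]
        raise ValueError(
            f"{idx.size} neuron(s) outside the ROI, first offenders: "
            f"{[(float(table.x[i]), float(table.y[i])) for i in idx[:5]]}")
    nx = max(int(np.ceil(table.width / dx)), 1)
    ny = max(int(np.ceil(table.length / dy)), 1)
    ix = np.minimum((table.x / dx).astype(int), nx - 1)
    iy = np.minimum((table.y / dy).astype(int), ny - 1)
    grid = np.zeros((nx, ny), dtype=float)
    np.add.at(grid, (ix, iy), 1.0)
    return grid


def profile_from_counts(grid: np.ndarray, subcell=DEFAULT_SUBCELL,
                        L: float = None, cohort: int = 0,
                        timepoint: int = 0) -> DensityProfile:
    """Average subcell densities across the ROI width into a profile.

    ``density(y) = mean_x count / (dx dy dz)``; a partial trailing
    subcell (ROI length not a multiple of dy) is volume-corrected.
    Positions are y-bin centers normalized by the ROI length ``L``.
    """
    if L is None or L <= 0:
        raise ValueError("ROI length L must be > 0")
    dx, dy, dz = subcell
    grid = np.asarray(grid, float)
    ny = grid.shape[1]
    dy_eff = np.full(ny, dy)
    if ny * dy > L:                       # trailing partial subcell
        dy_eff[-1] = L - (ny - 1) * dy
    centers = np.cumsum(dy_eff) - 0.5 * dy_eff
    dens = grid.mean(axis=0) / (dx * dy_eff * dz)
    return DensityProfile(normalized_position=centers / L, density=dens,
                          length=float(L), cohort=cohort,
                          timepoint=timepoint)


def group_normalize(profiles) -> tuple:
    """Re-normalize profiles by the mean ROI length of each timepoint.

    Returns ``(profiles, group_lengths)`` where each profile's
    positions are rescaled from its own length to the group mean and
    its ``length`` attribute is replaced by the group mean.
    """
    groups: dict = {}
    for p in profiles:
        groups.setdefault(p.timepoint, []).append(p)
    if any(len(v) == 0 for v in groups.values()) or not groups:
        raise ValueError("every timepoint group needs at least one profile")
    group_lengths = {tp: float(np.mean([p.length for p in ps]))
                     for tp, ps in groups.items()}
    out = []
    for p in profiles:
        Lg = group_lengths[p.timepoint]
        out.append(DensityProfile(
            normalized_position=p.normalized_position * (p.length / Lg),
            density=p.density, length=Lg, cohort=p.cohort,
            timepoint=p.timepoint))
    return out, group_lengths


def neurons_from_mask(mask: np.ndarray, pixel_size: float,
                      thickness: float = 50.0, cohort: int = 0,
                      timepoint: int = 0) -> NeuronTable:
    """Optional image front-end: centroids of connected components.

    ``mask`` is a binary (thresholded) image with axis 0 = y (radial)
    and axis 1 = x; ``pixel_size`` is um per pixel.
    """
    from scipy import ndimage

    labels, n = ndimage.label(np.asarray(mask) > 0)
    if n == 0:
        cy = cx = np.empty(0)
    else:
        cents = np.asarray(ndimage.center_of_mass(mask, labels,
                                                  np.arange(1, n + 1)))
        cy, cx = cents[:, 0], cents[:, 1]
    return NeuronTable(x=cx * pixel_size, y=cy * pixel_size,
                       width=mask.shape[1] * pixel_size,
                       length=mask.shape[0] * pixel_size,
                       thickness=thickness, cohort=cohort,
                       timepoint=timepoint)
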