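"""Umbrella-window grids and the harmonic bias model.

A 2D umbrella-sampling run biases the base-flipping pseudodihedral (CPDb)
and the glycosidic angle (chi) toward a rectangular grid of window centers.
The bias at window (i, j) is

    U_ij(CPDb, chi) = k_CPDb * (CPDb - CPDb0_i)^2 + k_chi * (chi - chi0_j)^2

with force constants in kcal/mol/rad^2 and angle differences taken as
minimal-image wrapped differences (chi is periodic; CPDb is wrapped too,
although the sampled range never spans the seam).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEG2RAD = np.pi / 180.0


def wrap_angle(x):
    """Wrap an angle (degrees) into the canonical range [-180, 180).

    +180 maps to -180 so every angle has exactly one representation;
    works elementwise on arrays.
    """
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


def angle_diff(a, b):
    """Minimal-image difference a - b in degrees, in [-180, 180)."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class UmbrellaWindow:
    """One harmonic bias window centered at (cpdb0, chi0).

    Force constants are kcal/mol/rad^2; centers are degrees, wrapped to
    [-180, 180) on construction.
    """

    id: int
    cpdb0: float
    chi0: float
    k_cpdb: float
    k_chi: float

    def __post_init__(self):
        if self.k_cpdb < 0 or self.k_chi < 0:
            raise ValueError("force constants must be >= 0")
        object.__setattr__(self, "cpdb0", float(wrap_angle(self.cpdb0)))
        object.__setattr__(self, "chi0", float(wrap_angle(self.chi0)))


@dataclass(frozen=True)
class WindowGrid:
    """Rectangular grid of umbrella windows, row-major (CPDb outer, chi inner)."""

    windows: tuple
    n_cpdb: int
    n_chi: int
    cpdb_range: tuple
    chi_range: tuple

    def __len__(self):
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i):
        return self.windows[i]


class GridSpecificationError(ValueError):
    """Raised when a window grid has duplicate wrapped centers."""


def build_window_grid(n_cpdb, cpdb_range, n_chi, chi_range,
                      k_cpdb=100.0, k_chi=50.0):
    """Build the rectangular window grid.

    CPDb centers include both range endpoints (spacing (max-min)/(n-1) for
    n > 1).  chi centers are treated as periodic: spacing span/n starting at
    the lower bound, so a full [-180, 180] range with n windows covers both
    endpoints without duplicating the wrapped seam point.

    The reference setup (13 CPDb windows over [-100, 100] x 24 chi windows
    over [-180, 180]) yields 312 windows.
    """
    if n_cpdb < 1 or n_chi < 1:
        raise ValueError("window counts must be >= 1")
    clo, chi_ = float(cpdb_range[0]), float(cpdb_range[1])
    xlo, xhi = float(chi_range[0]), float(chi_range[1])
    if clo >= chi_ or xlo >= xhi:
        raise ValueError("ranges must be non-degenerate (lo < hi)")

    if n_cpdb == 1:
        cpdb_centers = np.array([clo])
    else:
        cpdb_centers = np.linspace(clo, chi_, n_cpdb)
    chi_centers = xlo + (xhi - xlo) / n_chi * np.arange(n_chi)

    windows = []
    seen = set()
    wid = 0
    for c0 in cpdb_centers:
        for x0 in chi_centers:
            w = UmbrellaWindow(wid, c0, x0, k_cpdb, k_chi)
            key = (round(w.cpdb0, 9), round(w.chi0, 9))
            if key in seen:
                raise GridSpecificationError(
                    f"duplicate wrapped window center {key}")
            seen.add(key)
            windows.append(w)
            wid += 1
    return WindowGrid(tuple(windows), n_cpdb, n_chi,
                      (clo, chi_), (xlo, xhi))


def bias_energy(window, cpdb, chi, half_k=False, per_deg2=False):
    """Harmonic bias energy (kcal/mol) of a window at (cpdb, chi) degrees.

    Differences are minimal-image wrapped, converted to radians unless
    ``per_deg2`` declares the force constants as kcal/mol/deg^2.  ``half_k``
    switches to the U = (k/2) dx^2 convention used by some bias engines.
    """
    dc = angle_diff(cpdb, window.cpdb0)
    dx = angle_diff(chi, window.chi0)
    if not per_deg2:
        dc = dc * DEG2RAD
        dx = dx * DEG2RAD
    u = window.k_cpdb * dc ** 2 + window.k_chi * dx ** 2
    if half_k:
        u = 0.5 * u
    return u
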