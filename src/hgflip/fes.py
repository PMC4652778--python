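"""Reweighting biased window ensembles into a 2D free-energy surface.

The estimator is the self-consistent weighted-histogram method (WHAM): for
histogram bins l with total counts n_l and windows i with N_i samples and
bias Boltzmann factors c_il, the unbiased bin probabilities and window
shifts satisfy

    p_l = n_l / sum_i N_i exp(beta f_i) c_il
    exp(-beta f_i) = sum_l c_il p_l

The fixed point is found by minimizing the equivalent convex likelihood
function (L-BFGS) and polishing with direct fixed-point sweeps until the
self-consistency residual drops below tolerance.  The glycosidic angle axis
is periodic throughout; bias factors are evaluated at bin centers by
default (``n_quad`` switches to a per-bin Gauss-Legendre average of
exp(-beta U), which pairs with the piecewise-constant density model less
favorably for stiff restraints and is off by default).

F is reported in kcal/mol, referenced so the lowest sampled bin is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .umbrella import DEG2RAD, angle_diff

#: gas constant in kcal/mol/K
R_KCAL = 1.9872041e-3
DEFAULT_TEMPERATURE = 300.0


class DegenerateInputError(ValueError):
    pass


@dataclass
class BiasedEnsemble:
    """Samples of (cpdb, chi) degrees collected under one umbrella window.

    ``bias_offset`` is an optional constant (kcal/mol) added to the
    window's bias energy, for engines whose restraints carry one; the
    estimated surface is invariant when the same constant is added to
    every window.
    """

    window: object
    samples: np.ndarray
    bias_offset: float = 0.0

    def __post_init__(self):
        from .umbrella import wrap_angle
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 1:
            raise ValueError("samples must be a non-empty (n, 2) array")
        self.samples = wrap_angle(s)

    @property
    def n(self):
        return self.samples.shape[0]

    @property
    def cpdb(self):
        return self.samples[:, 0]

    @property
    def chi(self):
        return self.samples[:, 1]


@dataclass
class FESGrid:
    """Binned 2D free-energy surface F(CPDb, chi) in kcal/mol.

    F has shape (n_cpdb_bins, n_chi_bins); unsampled bins are masked out
    (NaN in F).  The minimum over sampled bins is 0.
    """

    cpdb_edges: np.ndarray
    chi_edges: np.ndarray
    F: np.ndarray
    sampled_mask: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.cpdb_edges = np.asarray(self.cpdb_edges, dtype=float)
        self.chi_edges = np.asarray(self.chi_edges, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.sampled_mask = np.asarray(self.sampled_mask, dtype=bool)
        shape = (len(self.cpdb_edges) - 1, len(self.chi_edges) - 1)
        if self.F.shape != shape or self.sampled_mask.shape != shape:
            raise ValueError("F/sampled_mask shape does not match bin edges")

    @property
    def cpdb_centers(self):
        return 0.5 * (self.cpdb_edges[:-1] + self.cpdb_edges[1:])

    @property
    def chi_centers(self):
        return 0.5 * (self.chi_edges[:-1] + self.chi_edges[1:])

    @property
    def chi_periodic(self):
        span = self.chi_edges[-1] - self.chi_edges[0]
        return abs(span - 360.0) < 1e-9

    def locate(self, cpdb, chi):
        """Indices (i, j) of the bin whose center is nearest to (cpdb, chi)."""
        i = int(np.argmin(np.abs(self.cpdb_centers - cpdb)))
        j = int(np.argmin(np.abs(angle_diff(self.chi_centers, chi))))
        return i, j


@dataclass
class WhamResult:
    """Per-window free-energy shifts f_i (kcal/mol) and solver diagnostics."""

    window_shifts: np.ndarray
    iterations: int
    converged: bool
    residual: float


@dataclass
class Marginal1D:
    """A 1D free-energy profile along chi or CPDb, min-referenced to 0."""

    axis: str
    centers: np.ndarray
    F: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.F)
        self.mask = np.asarray(self.mask, dtype=bool)


def bin_edges(lo, hi, width):
    """Evenly spaced bin edges covering [lo, hi] with bins of ~width degrees."""
    n = max(1, int(round((hi - lo) / width)))
    return np.linspace(lo, hi, n + 1)


def _log_bias_factors(ensembles, cpdb_edges, chi_edges, beta, n_quad):
    """log c_il per window i and 2D bin l = (ci, xi).

    The harmonic bias is separable in the two angles, so the bin-averaged
    Boltzmann factor factorizes into per-axis quadratures.
    """
    if n_quad > 1:
        nodes, wts = np.polynomial.legendre.leggauss(n_quad)
        wts = wts / wts.sum()
    else:
        nodes, wts = np.array([0.0]), np.array([1.0])

    def axis_log(edges, centers0, k, periodic):
        lo, hi = edges[:-1], edges[1:]
        mid = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo)
        pts = mid[:, None] + half[:, None] * nodes[None, :]   # (nbin, nq)
        d = angle_diff(pts[None, :, :], centers0[:, None, None]) * DEG2RAD
        loga = -beta * k[:, None, None] * d ** 2
        return logsumexp(loga, axis=2, b=wts[None, None, :])  # (nwin, nbin)

    k_c = np.array([e.window.k_cpdb for e in ensembles], dtype=float)
    k_x = np.array([e.window.k_chi for e in ensembles], dtype=float)
    c0 = np.array([e.window.cpdb0 for e in ensembles], dtype=float)
    x0 = np.array([e.window.chi0 for e in ensembles], dtype=float)
    log_a = axis_log(cpdb_edges, c0, k_c, False)
    log_b = axis_log(chi_edges, x0, k_x, True)
    return log_a, log_b


def wham2d(ensembles, cpdb_edges=None, chi_edges=None,
           temperature=DEFAULT_TEMPERATURE, tol=1e-7, max_iter=100_000,
           bin_width=5.0, n_quad=1):
    """Estimate the unbiased 2D free-energy surface from biased ensembles.

    Parameters
    ----------
    ensembles : list of BiasedEnsemble
    cpdb_edges, chi_edges : bin edges in degrees; by default chi covers the
        full circle in `bin_width` bins and cpdb covers the sample range
        rounded out to whole bins.
    tol : convergence tolerance (kcal/mol) on the maximum change of the
        window shifts under one self-consistency sweep.

    Returns
    -------
    (FESGrid, WhamResult)
    """
    ensembles = list(ensembles)
    if not ensembles:
        raise DegenerateInputError("need at least one biased ensemble")
    all_c = np.concatenate([e.cpdb for e in ensembles])
    all_x = np.concatenate([e.chi for e in ensembles])
    if chi_edges is None:
        chi_edges = bin_edges(-180.0, 180.0, bin_width)
    if cpdb_edges is None:
        lo = np.floor(all_c.min() / bin_width) * bin_width
        hi = np.ceil(all_c.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        cpdb_edges = bin_edges(lo, hi, bin_width)
    cpdb_edges = np.asarray(cpdb_edges, dtype=float)
    chi_edges = np.asarray(chi_edges, dtype=float)
    eps = 1e-9
    if (all_c.min() < cpdb_edges[0] - eps or all_c.max() > cpdb_edges[-1] + eps
            or all_x.min() < chi_edges[0] - eps
            or all_x.max() > chi_edges[-1] + eps):
        raise ValueError("bin edges do not cover all samples")

    beta = 1.0 / (R_KCAL * temperature)
    nwin = len(ensembles)
    N = np.array([e.n for e in ensembles], dtype=float)

    counts = np.zeros((len(cpdb_edges) - 1, len(chi_edges) - 1))
    for e in ensembles:
        h, _, _ = np.histogram2d(
            np.clip(e.cpdb, cpdb_edges[0], cpdb_edges[-1] - 1e-12),
            np.clip(e.chi, chi_edges[0], chi_edges[-1] - 1e-12),
            bins=(cpdb_edges, chi_edges))
        counts += h
    sampled = counts > 0
    if not sampled.any():
        raise DegenerateInputError("all histogram bins are empty")

    ci, xi = np.nonzero(sampled)
    n_l = counts[ci, xi]
    log_a, log_b = _log_bias_factors(ensembles, cpdb_edges, chi_edges,
                                     beta, n_quad)
    log_c = log_a[:, ci] + log_b[:, xi]          # (nwin, L)
    offsets = np.array([e.bias_offset for e in ensembles], dtype=float)
    log_c = log_c - beta * offsets[:, None]
    logN = np.log(N)
    log_nl = np.log(n_l)

    def log_denom(g):
        return logsumexp(logN[:, None] + g[:, None] + log_c, axis=0)

    def objective(g_free):
        g = np.concatenate([[0.0], g_free])
        logD = log_denom(g)
        obj = -(N * g).sum() + (n_l * logD).sum()
        t = np.exp(logN[:, None] + g[:, None] + log_c - logD[None, :])
        grad = -N + (t * n_l[None, :]).sum(axis=1)
        return obj, grad[1:]

    g = np.zeros(nwin)
    iters = 0
    if nwin > 1:
        res = minimize(objective, g[1:], jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
        g = np.concatenate([[0.0], res.x])
        iters += int(res.nit)

    # polish with direct self-consistency sweeps until the fixed-point
    # residual (max shift change, kcal/mol) is below tol
    kT = 1.0 / beta
    residual = np.inf
    converged = False
    for _ in range(max_iter):
        logD = log_denom(g)
        logp = log_nl - logD
        g_new = -logsumexp(logp[None, :] + log_c, axis=1)
        g_new = g_new - g_new[0]
        residual = kT * float(np.max(np.abs(g_new - g)))
        iters += 1
        g = g_new
        if residual <= tol:
            converged = True
            break

    logD = log_denom(g)
    logp = log_nl - logD
    F = np.full(counts.shape, np.nan)
    F[ci, xi] = -kT * logp
    F[ci, xi] -= np.nanmin(F[ci, xi])
    fes = FESGrid(cpdb_edges, chi_edges, F, sampled, temperature)
    result = WhamResult(window_shifts=kT * g, iterations=iters,
                        converged=converged, residual=residual)
    return fes, result


def _profile_from_logp(axis, centers, logw, has_data, temperature):
    F = np.full(len(centers), np.nan)
    F[has_data] = -R_KCAL * temperature * logw[has_data]
    if has_data.any():
        F[has_data] -= np.nanmin(F[has_data])
    return Marginal1D(axis=axis, centers=centers, F=F, mask=has_data)


def marginal(fes, axis):
    """Effective 1D profile F(axis) = -RT ln of the integrated probability.

    The 2D probability P = exp(-F/RT) (0 on masked bins) is integrated over
    the other axis by bin-width quadrature; the result is min-referenced to
    0.  Centers whose entire row/column is masked are masked in the output.
    """
    RT = R_KCAL * fes.temperature
    logP = np.where(fes.sampled_mask, -fes.F / RT, -np.inf)
    if axis == "chi":
        widths = np.diff(fes.cpdb_edges)
        logw = logsumexp(logP, axis=0, b=widths[:, None])
        centers = fes.chi_centers
        has = fes.sampled_mask.any(axis=0)
    elif axis == "cpdb":
        widths = np.diff(fes.chi_edges)
        logw = logsumexp(logP, axis=1, b=widths[None, :])
        centers = fes.cpdb_centers
        has = fes.sampled_mask.any(axis=1)
    else:
        raise ValueError("axis must be 'chi' or 'cpdb'")
    return _profile_from_logp(axis, centers, logw, has, fes.temperature)


class MaskedRowError(ValueError):
    pass


def slice_profile(fes, cpdb=0.0):
    """1D profile of chi at fixed CPDb (nearest bin row), min-referenced."""
    i = int(np.argmin(np.abs(fes.cpdb_centers - cpdb)))
    row_mask = fes.sampled_mask[i]
    if not row_mask.any():
        raise MaskedRowError(
            f"CPDb row at {fes.cpdb_centers[i]:.1f} deg is entirely unsampled")
    F = np.where(row_mask, fes.F[i], np.nan)
    F = F - np.nanmin(F)
    return Marginal1D(axis="chi", centers=fes.chi_centers, F=F, mask=row_mask)


def min_path_profile(fes, axis):
    """Lowest-F 1D profile: min of F over the other axis, per bin center."""
    Fm = np.where(fes.sampled_mask, fes.F, np.inf)
    if axis == "chi":
        F = np.min(Fm, axis=0)
        centers = fes.chi_centers
        has = fes.sampled_mask.any(axis=0)
    elif axis == "cpdb":
        F = np.min(Fm, axis=1)
        centers = fes.cpdb_centers
        has = fes.sampled_mask.any(axis=1)
    else:
        raise ValueError("axis must be 'chi' or 'cpdb'")
    F = np.where(has, F, np.nan)
    if has.any():
        F = F - np.nanmin(F[has])
    return Marginal1D(axis=axis, centers=centers, F=F, mask=has)
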