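"""Synthetic study inputs: a model landscape, biased samplers, aggregation data.

The analytic model surface emulates the qualitative topography of the
WC -> HG switching landscape so that every downstream stage (reweighting,
basin/pathway analysis, convergence checks) can be exercised with known
ground truth.  Its default parameters encode the designed landscape:

* WC basin (anti chi, CPDb ~ 0) at F = 0; HG basin (syn chi) 4.4 kcal/mol
  above it (calibrated exactly at construction);
* a locally stable intermediate near (CPDb, chi) = (-57.3, 51.2) in the
  minor groove;
* small-flip routes (|CPDb| <= 20) with the lowest barriers (~10-11
  kcal/mol), major/minor-groove opening routes higher (~13-14 kcal/mol),
  every route saddle falling at syn chi;
* base-opening profiles of ~8.0 (major) / 8.4 (minor) kcal/mol;
* steep walls beyond |CPDb| ~ 120 deg.

These are design targets of the generator, not claims about real DNA.

The window sampler is a Metropolis Monte Carlo chain directly in
collective-variable space: the generator produces exactly the statistical
object the reweighting stage consumes (biased samples of (CPDb, chi)) and
is bit-reproducible for fixed seeds.  A toy well-tempered metadynamics
walker with bias factor gamma = (T + dT)/T is provided for coverage studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .aggregation import ComFrame, OsmoticPoint, predict_phi
from .fes import R_KCAL, BiasedEnsemble, FESGrid
from .umbrella import DEG2RAD, angle_diff, bias_energy, wrap_angle

# ---------------------------------------------------------------------------
# analytic model surface


@dataclass(frozen=True)
class ModelSurfaceSpec:
    """Parameters of the analytic (CPDb, chi) landscape.

    chi_profile: (chi_deg, kcal/mol) control points of the periodic
    glycosidic rotation profile W(chi) at CPDb = 0 (cubic periodic spline).
    flip_profile: control points of the base-flipping profile V(CPDb) at the
    WC chi value.  coupling_floor/width shape the factor h(CPDb) multiplying
    W: rotation is cheaper once the base has flipped out
    (h = floor + (1 - floor) exp(-(CPDb/width)^2)).  basins are extra
    Gaussian wells (center, depth, (sigma_cpdb, sigma_chi)), used for the
    minor-groove intermediate.  wall_onset/wall_k add a quadratic wall
    beyond the physically sampled flipping range.
    """

    chi_profile: tuple = (
        (-180.0, 8.5), (-150.0, 5.5), (-115.0, 0.0), (-75.0, 5.0),
        (-35.0, 11.0), (0.0, 7.5), (55.0, 4.4), (78.0, 10.8),
        (100.0, 9.9), (140.0, 8.9),
    )
    flip_profile: tuple = (
        (-130.0, 30.0), (-110.0, 14.0), (-90.0, 7.0), (-70.0, 6.6),
        (-57.0, 6.2), (-45.0, 8.4), (-25.0, 4.0), (0.0, 0.0),
        (25.0, 3.8), (45.0, 8.0), (70.0, 6.5), (90.0, 6.8),
        (110.0, 14.0), (130.0, 30.0),
    )
    coupling_floor: float = 0.6
    coupling_width: float = 35.0
    basins: tuple = (((-57.3, 51.2), 2.5, (12.0, 15.0)),)
    wall_onset: float = 120.0
    wall_k: float = 0.05           # kcal/mol/deg^2 beyond the onset
    delta_g_target: float = 4.4    # designed F(HG) - F(WC), kcal/mol

    def __post_init__(self):
        if len(self.basins) + 2 < 2:
            raise ValueError("surface needs at least the two rotation basins")


class ModelSurface:
    """Evaluable F_true(cpdb, chi); smooth, chi-periodic, min-shifted to 0."""

    def __init__(self, spec, _hg_adjust=0.0, _shift=0.0):
        self.spec = spec
        xs = np.array([p[0] for p in spec.chi_profile], dtype=float)
        ys = np.array([p[1] for p in spec.chi_profile], dtype=float)
        order = np.argsort(xs)
        xs, ys = xs[order], ys[order]
        # apply the HG-well calibration to the knot nearest the HG basin
        hg_knot = int(np.argmin(np.abs(xs - 55.0)))
        ys = ys.copy()
        ys[hg_knot] += _hg_adjust
        self._chi_spline = CubicSpline(
            np.append(xs, xs[0] + 360.0), np.append(ys, ys[0]),
            bc_type="periodic")
        self._chi_x0 = xs[0]
        cs = np.array([p[0] for p in spec.flip_profile], dtype=float)
        vs = np.array([p[1] for p in spec.flip_profile], dtype=float)
        order = np.argsort(cs)
        self._flip_spline = CubicSpline(cs[order], vs[order])
        self._flip_lo, self._flip_hi = cs.min(), cs.max()
        self._hg_adjust = _hg_adjust
        self._shift = _shift

    def _w(self, chi):
        x = self._chi_x0 + np.mod(np.asarray(chi, dtype=float) - self._chi_x0,
                                  360.0)
        return self._chi_spline(x)

    def _vflip(self, cpdb):
        c = np.asarray(cpdb, dtype=float)
        v = self._flip_spline(np.clip(c, self._flip_lo, self._flip_hi))
        over = np.maximum(np.abs(c) - self.spec.wall_onset, 0.0)
        return v + self.spec.wall_k * over ** 2

    def _h(self, cpdb):
        s = self.spec
        c = np.asarray(cpdb, dtype=float)
        return s.coupling_floor + (1.0 - s.coupling_floor) * np.exp(
            -(c / s.coupling_width) ** 2)

    def __call__(self, cpdb, chi):
        c = np.asarray(cpdb, dtype=float)
        x = np.asarray(chi, dtype=float)
        F = self._vflip(c) + self._h(c) * self._w(x)
        for (bc, bx), depth, (sc, sx) in self.spec.basins:
            dx = angle_diff(x, bx)
            F = F - depth * np.exp(-0.5 * ((c - bc) / sc) ** 2
                                   - 0.5 * (dx / sx) ** 2)
        return F - self._shift

    # -- designed landmarks -------------------------------------------------

    def _fine_grid(self, dc=1.0, dx=1.0, c_extent=120.0):
        c = np.arange(-c_extent, c_extent + dc / 2, dc)
        x = np.arange(-180.0, 180.0, dx)
        return c, x, self(c[:, None], x[None, :])

    def basin_minima(self):
        """(WC, HG) minima as ((cpdb, chi), F): the lowest local minimum of
        the fine-grid surface with anti / syn chi at small |CPDb|."""
        c, x, F = self._fine_grid()
        local = np.ones_like(F, dtype=bool)
        for dc in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dc == 0 and dx == 0:
                    continue
                nb = np.roll(F, (dc, dx), axis=(0, 1))
                if dc == -1:
                    nb[-1, :] = np.inf      # CPDb axis is not periodic
                elif dc == 1:
                    nb[0, :] = np.inf
                local &= F < nb
        small = np.abs(c) <= 20.0
        anti = (x >= -180.0) & (x < -90.0)
        syn = (x >= -90.0) & (x <= 90.0)
        out = []
        for m in (anti, syn):
            region = local & small[:, None] & m[None, :]
            if not region.any():
                raise ValueError("surface has no local minimum in a basin "
                                 "region; check the profile control points")
            masked = np.where(region, F, np.inf)
            i, j = np.unravel_index(np.argmin(masked), masked.shape)
            out.append(((float(c[i]), float(x[j])), float(F[i, j])))
        return tuple(out)

    @property
    def delta_g(self):
        (_, f_wc), (_, f_hg) = self.basin_minima()
        return f_hg - f_wc

    def true_grid(self, cpdb_edges, chi_edges, temperature=300.0):
        """FESGrid of the exact surface at bin centers (all bins sampled)."""
        ce = np.asarray(cpdb_edges, dtype=float)
        xe = np.asarray(chi_edges, dtype=float)
        cc = 0.5 * (ce[:-1] + ce[1:])
        xc = 0.5 * (xe[:-1] + xe[1:])
        F = self(cc[:, None], xc[None, :])
        F = F - F.min()
        return FESGrid(ce, xe, F, np.ones_like(F, dtype=bool), temperature)


def model_surface(spec=None, calibrate=True, tol=0.02, max_rounds=12):
    """Build the model surface, calibrating F(HG) - F(WC) to the design target.

    The HG-well depth is adjusted iteratively until the fine-grid basin
    difference matches ``spec.delta_g_target`` within ``tol`` kcal/mol, and
    the global minimum is shifted to 0.
    """
    spec = spec or ModelSurfaceSpec()
    adjust = 0.0
    surf = ModelSurface(spec, _hg_adjust=adjust)
    if calibrate:
        for _ in range(max_rounds):
            err = surf.delta_g - spec.delta_g_target
            if abs(err) <= tol:
                break
            adjust -= err
            surf = ModelSurface(spec, _hg_adjust=adjust)
    _, _, F = surf._fine_grid()
    (_, f_wc), _ = surf.basin_minima()
    shift = min(float(F.min()), f_wc)
    return ModelSurface(spec, _hg_adjust=adjust, _shift=shift)


def default_surface():
    """The calibrated default landscape (module-level cache)."""
    global _DEFAULT_SURFACE
    try:
        return _DEFAULT_SURFACE
    except NameError:
        _DEFAULT_SURFACE = model_surface()
        return _DEFAULT_SURFACE


# ---------------------------------------------------------------------------
# Metropolis window sampler


@dataclass(frozen=True)
class MCParams:
    """Metropolis chain settings for one umbrella window.

    n_steps counts total Markov steps; samples are taken every ``thin``
    steps after ``n_equil`` equilibration steps, so each window yields
    (n_steps - n_equil) // thin samples.
    """

    temperature: float = 300.0
    step_cpdb: float = 4.0       # proposal s.d., degrees
    step_chi: float = 5.0
    n_steps: int = 16_000
    n_equil: int = 1_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.n_steps > self.n_equil >= 0:
            raise ValueError("need n_steps > n_equil >= 0")
        if self.step_cpdb <= 0 or self.step_chi <= 0:
            raise ValueError("step sizes must be > 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_samples(self):
        return (self.n_steps - self.n_equil) // self.thin


class StepSizeError(RuntimeError):
    pass


def _window_seed(master_seed, window_id):
    """Deterministic, platform-stable per-window seed material."""
    return [int(master_seed) & 0x7FFFFFFF, int(window_id)]


def _sample_windows_batched(F_true, windows, params, master_seed=None):
    """Advance one Metropolis chain per window, vectorized across windows.

    Each window consumes its own pre-drawn random stream (seeded from
    (master seed, window id) when a master seed is given, else from
    params.seed and the window id), so results are identical whether
    windows are sampled singly or as a batch.
    """
    windows = list(windows)
    nw = len(windows)
    n = params.n_steps
    beta = 1.0 / (R_KCAL * params.temperature)
    prop = np.empty((nw, n, 2))
    unif = np.empty((nw, n))
    for k, w in enumerate(windows):
        seed = _window_seed(master_seed if master_seed is not None
                            else params.seed, w.id)
        rng = np.random.default_rng(seed)
        prop[k, :, 0] = rng.normal(0.0, params.step_cpdb, size=n)
        prop[k, :, 1] = rng.normal(0.0, params.step_chi, size=n)
        unif[k] = rng.random(n)

    c0 = np.array([w.cpdb0 for w in windows])
    x0 = np.array([w.chi0 for w in windows])
    kc = np.array([w.k_cpdb for w in windows])
    kx = np.array([w.k_chi for w in windows])

    def energy(c, x):
        dc = angle_diff(c, c0) * DEG2RAD
        dx = angle_diff(x, x0) * DEG2RAD
        return F_true(c, x) + kc * dc ** 2 + kx * dx ** 2

    c, x = c0.copy(), x0.copy()
    e = energy(c, x)
    n_keep = params.n_samples
    out = np.empty((nw, n_keep, 2))
    accepted_equil = np.zeros(nw, dtype=int)
    accepted_prod = np.zeros(nw, dtype=int)
    kidx = 0
    for step in range(n):
        cn = wrap_angle(c + prop[:, step, 0])
        xn = wrap_angle(x + prop[:, step, 1])
        en = energy(cn, xn)
        acc = unif[:, step] < np.exp(np.minimum(0.0, -beta * (en - e)))
        c = np.where(acc, cn, c)
        x = np.where(acc, xn, x)
        e = np.where(acc, en, e)
        if step < params.n_equil:
            accepted_equil += acc
        else:
            accepted_prod += acc
            if (step - params.n_equil) % params.thin == 0 and kidx < n_keep:
                out[:, kidx, 0] = c
                out[:, kidx, 1] = x
                kidx += 1
    if params.n_equil > 0:
        dead = np.nonzero(accepted_equil == 0)[0]
        if len(dead):
            raise StepSizeError(
                f"zero acceptance during equilibration for windows "
                f"{[windows[i].id for i in dead]}; reduce the step sizes")
    ensembles = []
    n_prod = n - params.n_equil
    for k, w in enumerate(windows):
        ens = BiasedEnsemble(w, out[k, :kidx])
        ens.acceptance_rate = accepted_prod[k] / n_prod
        ensembles.append(ens)
    return ensembles


def sample_window_mc(F_true, window, params):
    """Metropolis samples of one biased window; deterministic for a seed."""
    return _sample_windows_batched(F_true, [window], params)[0]


def make_window_suite(F_true, grid, params, master_seed=0, colvar_dir=None):
    """One biased ensemble per window of the grid.

    Per-window seeds are derived deterministically from
    (master_seed, window id).  When ``colvar_dir`` is given, each ensemble
    is also written as a COLVAR-style text file ``window_<id>.colvar``.
    """
    ensembles = _sample_windows_batched(F_true, list(grid), params,
                                        master_seed=master_seed)
    if colvar_dir is not None:
        from pathlib import Path

        from .geometry import TorsionSeries
        from .io import write_colvar
        d = Path(colvar_dir)
        d.mkdir(parents=True, exist_ok=True)
        for e in ensembles:
            ts = TorsionSeries(np.arange(e.n, dtype=float),
                               e.cpdb, e.chi)
            write_colvar(d / f"window_{e.window.id:04d}.colvar", ts)
    return ensembles


# ---------------------------------------------------------------------------
# toy well-tempered metadynamics


@dataclass(frozen=True)
class MetadParams:
    """Well-tempered hill deposition settings.

    gamma = (T + delta_T)/T > 1 is the bias factor; the deposited hill
    height decays as w0 * exp(-V_bias/(kB * delta_T)) at the current point.
    """

    hill_height: float = 1.0          # w0, kcal/mol
    deposition_stride: int = 50       # MC steps between hills
    hill_width_cpdb: float = 10.0     # degrees
    hill_width_chi: float = 10.0
    gamma: float = 15.0
    temperature: float = 300.0
    step_cpdb: float = 8.0
    step_chi: float = 10.0

    def __post_init__(self):
        if not self.gamma > 1:
            raise ValueError("bias factor gamma must be > 1")
        if self.hill_height <= 0:
            raise ValueError("hill height must be > 0")

    @property
    def delta_T(self):
        if math.isinf(self.gamma):
            return math.inf
        return (self.gamma - 1.0) * self.temperature


class _BiasGrid:
    """Accumulated Gaussian bias on a (CPDb, chi) grid, chi periodic."""

    def __init__(self, c_extent=130.0, spacing=2.5):
        self.c = np.arange(-c_extent, c_extent + spacing / 2, spacing)
        self.x = np.arange(-180.0, 180.0, spacing)
        self.V = np.zeros((len(self.c), len(self.x)))

    def add_hill(self, c0, x0, height, sc, sx):
        gc = np.exp(-0.5 * ((self.c - c0) / sc) ** 2)
        gx = np.exp(-0.5 * (angle_diff(self.x, x0) / sx) ** 2)
        self.V += height * np.outer(gc, gx)

    def value(self, c, x):
        # nearest-node lookup is adequate for this deposition bookkeeping toy
        i = int(np.argmin(np.abs(self.c - c)))
        j = int(np.argmin(np.abs(angle_diff(self.x, x))))
        return float(self.V[i, j])


def sample_wt_metadynamics(F_true, params, n_steps, seed=0):
    """Run the well-tempered walker; returns (trajectory, hill history).

    trajectory: (n_steps, 2) visited (cpdb, chi); hills: list of
    (step, cpdb, chi, height).  In the gamma -> infinity limit the hill
    heights stay constant at w0.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 777])
    beta = 1.0 / (R_KCAL * params.temperature)
    bias = _BiasGrid()
    kB_dT = R_KCAL * params.delta_T
    c, x = 0.0, -115.0
    e = float(F_true(c, x)) + bias.value(c, x)
    traj = np.empty((n_steps, 2))
    hills = []
    for step in range(n_steps):
        cn = float(wrap_angle(c + params.step_cpdb * rng.normal()))
        xn = float(wrap_angle(x + params.step_chi * rng.normal()))
        en = float(F_true(cn, xn)) + bias.value(cn, xn)
        if rng.random() < math.exp(min(0.0, -beta * (en - e))):
            c, x, e = cn, xn, en
        traj[step] = (c, x)
        if (step + 1) % params.deposition_stride == 0:
            v_here = bias.value(c, x)
            if math.isinf(params.gamma):
                h = params.hill_height
            else:
                h = params.hill_height * math.exp(-v_here / kB_dT)
            bias.add_hill(c, x, h, params.hill_width_cpdb,
                          params.hill_width_chi)
            hills.append((step, c, x, h))
            e = float(F_true(c, x)) + bias.value(c, x)
    return traj, hills


def window_coverage(traj, grid):
    """Fraction of window cells visited by a trajectory.

    A cell is the rectangle of half the window spacing around each center
    (chi periodic); mirrors the visual check that a walker touches nearly
    every window region.
    """
    traj = np.asarray(traj, dtype=float)
    c0 = np.array([w.cpdb0 for w in grid])
    x0 = np.array([w.chi0 for w in grid])
    dc = (grid.cpdb_range[1] - grid.cpdb_range[0]) / max(grid.n_cpdb - 1, 1)
    dx = 360.0 / grid.n_chi
    hit = 0
    for k in range(len(grid)):
        in_c = np.abs(traj[:, 0] - c0[k]) <= dc / 2
        in_x = np.abs(angle_diff(traj[:, 1], x0[k])) <= dx / 2
        if np.any(in_c & in_x):
            hit += 1
    return hit / len(grid)


# ---------------------------------------------------------------------------
# aggregation-data generator

DA_MOLALITIES = (0.0450, 0.0375, 0.0300)   # deoxyadenosine set, mol/kg
DT_MOLALITIES = (0.20, 0.15, 0.10)         # deoxythymidine set, mol/kg


def _draw_cluster_sizes(rng, x, n_molecules):
    """Sample i-mer sizes from the equal-K geometric distribution.

    Cluster sizes are i.i.d. geometric with success probability (1 - x),
    x = K_A * [monomer]; whole clusters are drawn until the frame holds at
    least ``n_molecules`` molecules (the last cluster is kept intact, so a
    frame can slightly exceed the target count).  Keeping clusters whole
    makes the pooled clusters-to-molecules ratio an unbiased estimate of
    the osmotic coefficient (Wald's identity).
    """
    sizes = []
    total = 0
    while total < n_molecules:
        s = 1 if x <= 0 else int(rng.geometric(1.0 - x))
        sizes.append(s)
        total += s
    return sizes


def _frame_from_sizes(rng, sizes, box, member_radius=1.2):
    """Place the drawn clusters in a periodic box, well separated.

    Cluster seeds sit on a jittered cubic lattice with spacing far above
    the contact cutoff; members scatter within ``member_radius`` of the
    seed, so the geometric cluster criterion reproduces the drawn sizes.
    """
    n_sites = int(np.ceil(len(sizes) ** (1 / 3)))
    spacing = box / max(n_sites, 1)
    sites = []
    for a in range(n_sites):
        for b in range(n_sites):
            for c in range(n_sites):
                sites.append((a, b, c))
    rng.shuffle(sites)
    pos = []
    for size, site in zip(sizes, sites):
        seed = (np.array(site) + 0.5) * spacing
        seed = seed + rng.uniform(-1.0, 1.0, 3)
        pos.append(seed)
        for _ in range(size - 1):
            prev = pos[-1]
            step = rng.normal(size=3)
            step = member_radius * step / np.linalg.norm(step)
            pos.append(prev + step)
    return ComFrame(np.array(pos), box=np.array([box, box, box]))


def make_aggregation_points(K_A, m_T_list=DA_MOLALITIES, n_frames=200,
                            seed=0, n_molecules=16, geometric=False,
                            box=80.0):
    """Synthetic (m_T, phi) observations for a known association constant.

    Per-frame cluster counts are drawn from the equal-K equilibrium
    distribution at each molality and converted to phi as cluster/molecule
    count ratios.  With ``geometric=True`` a ComFrame realization of every
    frame is also returned, constructed so the 3.5-Angstrom cluster
    criterion reproduces the drawn distribution.
    """
    points = []
    frames = []
    for im, m_T in enumerate(m_T_list):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 1000 + im])
        phi_eq = predict_phi(K_A, m_T)
        x = 1.0 - phi_eq
        n_clusters = n_mols = 0
        for _ in range(n_frames):
            sizes = _draw_cluster_sizes(rng, x, n_molecules)
            n_clusters += len(sizes)
            n_mols += sum(sizes)
            if geometric:
                frames.append(_frame_from_sizes(rng, sizes, box))
        points.append(OsmoticPoint(m_T=float(m_T), phi=n_clusters / n_mols))
    if geometric:
        return points, frames
    return points
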