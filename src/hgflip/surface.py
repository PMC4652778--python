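"""Critical-point and pathway analysis of a 2D free-energy surface.

Basins (Watson-Crick, Hoogsteen, the minor-groove locally stable
intermediate) are local minima of the binned surface; transition states are
located by minimax (lowest-saddle) paths on the 8-connected bin graph with
the glycosidic axis periodic.  The six-route taxonomy — clockwise (R) vs
counterclockwise (L) glycosidic rotation crossed with small base flipping
(|CPDb| <= 20 deg), major-groove opening (CPDb >= +60) and minor-groove
opening (CPDb <= -60) — is operationalized as region constraints on the
minimax search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .fes import R_KCAL, wham2d
from .geometry import classify_chi
from .umbrella import angle_diff, wrap_angle


class NoPathError(ValueError):
    pass


@dataclass(frozen=True)
class CriticalPoint:
    kind: str                    # 'minimum' or 'transition_state'
    cpdb: float
    chi: float
    F: float
    ij: tuple = None             # bin indices on the source grid


@dataclass(frozen=True)
class BasinLabel:
    label: str                   # 'WC', 'HG', 'LS' or 'other'
    point: CriticalPoint


@dataclass
class TransitionPath:
    """Grid path between two labeled basins with its transition state(s)."""

    points: list                 # ordered (cpdb, chi) bin centers
    start: BasinLabel
    end: BasinLabel
    ts: CriticalPoint
    forward_barrier: float
    reverse_barrier: float
    klass: str = "unclassified"
    sub_ts: tuple = ()


@dataclass
class ConvergenceReport:
    fractions: list
    rms_error: list              # kcal/mol per fraction vs final surface
    threshold: float             # k_B T at the run temperature


def _neighbors(i, j, nc, nx, periodic_chi):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ni, nj = i + di, j + dj
            if ni < 0 or ni >= nc:
                continue
            if periodic_chi:
                nj %= nx
            elif nj < 0 or nj >= nx:
                continue
            yield ni, nj


def find_minima(fes):
    """Local minima of the sampled surface (strict over 8-neighbors).

    Minima within one bin of each other are merged (keeping the lower one;
    ties broken by lexicographically lower (cpdb, chi) center).  Returned
    sorted by F.
    """
    F, mask = fes.F, fes.sampled_mask
    nc, nx = F.shape
    per = fes.chi_periodic
    cand = []
    for i, j in zip(*np.nonzero(mask)):
        f0 = F[i, j]
        is_min = True
        for ni, nj in _neighbors(i, j, nc, nx, per):
            if mask[ni, nj] and F[ni, nj] <= f0:
                is_min = False
                break
        if is_min:
            cand.append((f0, fes.cpdb_centers[i], fes.chi_centers[j], (i, j)))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    kept = []
    for f0, c, x, ij in cand:
        close = False
        for k in kept:
            di = abs(ij[0] - k.ij[0])
            dj = abs(ij[1] - k.ij[1])
            if per:
                dj = min(dj, nx - dj)
            if di <= 1 and dj <= 1:
                close = True
                break
        if not close:
            kept.append(CriticalPoint("minimum", float(c), float(x),
                                      float(f0), ij))
    return kept


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _minimax_threshold(fes, start, end, allowed=None):
    """Minimax path start->end: lowest F threshold connecting the two bins.

    Bins are inserted in order of increasing F (union-find); the threshold
    is reached when start and end join the same component.  The returned
    path is a shortest path on the sub-grid with F <= threshold.
    """
    F, mask = fes.F, fes.sampled_mask
    nc, nx = F.shape
    per = fes.chi_periodic
    ok = mask if allowed is None else (mask & allowed)
    if not (ok[start] and ok[end]):
        raise NoPathError("an endpoint lies outside the allowed sampled region")
    flat = lambda i, j: i * nx + j
    order = sorted(zip(*np.nonzero(ok)), key=lambda ij: F[ij])
    uf = _UnionFind(nc * nx)
    added = np.zeros((nc, nx), dtype=bool)
    threshold = None
    for i, j in order:
        added[i, j] = True
        for ni, nj in _neighbors(i, j, nc, nx, per):
            if added[ni, nj]:
                uf.union(flat(i, j), flat(ni, nj))
        if (added[start] and added[end]
                and uf.find(flat(*start)) == uf.find(flat(*end))):
            threshold = F[i, j]
            break
    if threshold is None:
        raise NoPathError("basins are not connected on the sampled grid")
    # BFS on the threshold sub-grid
    sub = ok & (F <= threshold + 1e-9)
    prev = {start: None}
    queue = [start]
    while queue:
        nxt = []
        for node in queue:
            if node == end:
                queue = []
                break
            for nb in _neighbors(*node, nc, nx, per):
                if sub[nb] and nb not in prev:
                    prev[nb] = node
                    nxt.append(nb)
        else:
            queue = nxt
            continue
        break
    if end not in prev:
        raise NoPathError("threshold sub-grid lost connectivity (unexpected)")
    path = []
    node = end
    while node is not None:
        path.append(node)
        node = prev[node]
    path.reverse()
    return path, threshold


def find_ts(fes, a, b, allowed=None):
    """Transition state between two minima: highest bin on the minimax path."""
    ia = a.ij if a.ij is not None else fes.locate(a.cpdb, a.chi)
    ib = b.ij if b.ij is not None else fes.locate(b.cpdb, b.chi)
    path, threshold = _minimax_threshold(fes, tuple(ia), tuple(ib), allowed)
    k = int(np.argmax([fes.F[ij] for ij in path]))
    i, j = path[k]
    return CriticalPoint("transition_state", float(fes.cpdb_centers[i]),
                         float(fes.chi_centers[j]), float(fes.F[i, j]), (i, j))


def label_basins(minima, chi_classifier=classify_chi,
                 flip_threshold_small=20.0, ls_threshold=40.0):
    """Assign WC / HG / LS / other labels to located minima.

    WC is the lowest anti minimum with |CPDb| <= flip_threshold_small, HG
    the lowest syn minimum in the same flip band; LS is any syn minimum
    flipped into the minor groove (CPDb < -ls_threshold).
    """
    labels = []
    wc = hg = None
    for m in sorted(minima, key=lambda m: m.F):
        cls = chi_classifier(m.chi)
        if cls == "anti" and abs(m.cpdb) <= flip_threshold_small and wc is None:
            wc = m
            labels.append(BasinLabel("WC", m))
        elif cls == "syn" and abs(m.cpdb) <= flip_threshold_small and hg is None:
            hg = m
            labels.append(BasinLabel("HG", m))
        elif cls == "syn" and m.cpdb < -ls_threshold:
            labels.append(BasinLabel("LS", m))
        else:
            labels.append(BasinLabel("other", m))
    if wc is None:
        warnings.warn("no anti minimum found: surface has no WC basin",
                      stacklevel=2)
    return labels


def classify_path(path, small_cutoff=20.0, large_cutoff=60.0):
    """Route label from path geometry: R/L x {1: small, 2: major, 3: minor}."""
    pts = np.asarray(path.points, dtype=float)
    if len(pts) < 2:
        return "unclassified"
    dchi = angle_diff(pts[1:, 1], pts[:-1, 1]).sum()
    side = "R" if dchi < 0 else "L"     # clockwise = decreasing chi travel
    c = pts[:, 0]
    if np.max(np.abs(c)) <= small_cutoff + 1e-9:
        size = "1"
    elif np.max(c) >= large_cutoff - 1e-9:
        size = "2"
    elif np.min(c) <= -large_cutoff + 1e-9:
        size = "3"
    else:
        return "unclassified"
    return side + size


def _path_to_transition(fes, path_idx, start, end, min_prominence=0.5):
    profile = np.array([fes.F[ij] for ij in path_idx])
    k = int(np.argmax(profile))
    i, j = path_idx[k]
    ts = CriticalPoint("transition_state", float(fes.cpdb_centers[i]),
                       float(fes.chi_centers[j]), float(profile[k]), (i, j))
    peaks, _ = find_peaks(profile, prominence=min_prominence)
    if k not in peaks:
        peaks = np.sort(np.append(peaks, k))
    sub = tuple(
        CriticalPoint("transition_state",
                      float(fes.cpdb_centers[path_idx[p][0]]),
                      float(fes.chi_centers[path_idx[p][1]]),
                      float(profile[p]), tuple(path_idx[p]))
        for p in peaks)
    points = [(float(fes.cpdb_centers[i]), float(fes.chi_centers[j]))
              for i, j in path_idx]
    tp = TransitionPath(points=points, start=start, end=end, ts=ts,
                        forward_barrier=float(ts.F - start.point.F),
                        reverse_barrier=float(ts.F - end.point.F),
                        sub_ts=sub)
    tp.klass = classify_path(tp)
    return tp


def _direction_mask(fes, wc_chi, hg_chi, direction):
    """Block the chi column bisecting the opposite rotation corridor."""
    d_ccw = (hg_chi - wc_chi) % 360.0
    if direction == "cw":
        cut = wrap_angle(wc_chi + d_ccw / 2.0)
    else:
        cut = wrap_angle(wc_chi - (360.0 - d_ccw) / 2.0)
    j = int(np.argmin(np.abs(angle_diff(fes.chi_centers, cut))))
    allowed = np.ones(fes.F.shape, dtype=bool)
    allowed[:, j] = False
    return allowed


def extract_paths(fes, wc, hg, small_cutoff=20.0, large_cutoff=60.0,
                  basin_chi_halfwidth=25.0, min_prominence=0.5):
    """The six WC<->HG routes: {cw, ccw} x {small flip, major, minor opening}.

    Small-flip routes are minimax paths confined to |CPDb| <= small_cutoff.
    Opening routes must perform the glycosidic rotation in the flipped-out
    state: outside chi corridors of +-basin_chi_halfwidth around the WC and
    HG basins, only bins with CPDb >= +large_cutoff (major groove) or
    CPDb <= -large_cutoff (minor groove) are allowed, so the path climbs out
    near the basin chi, traverses chi while open, and re-closes.  Routes
    whose constraint set is disconnected are omitted.  All local maxima of
    the path profile are reported as sub-transition states (minor-groove
    openings typically carry two, flanking the LS intermediate).
    """
    a_ij = wc.point.ij if wc.point.ij else fes.locate(wc.point.cpdb, wc.point.chi)
    b_ij = hg.point.ij if hg.point.ij else fes.locate(hg.point.cpdb, hg.point.chi)
    a_ij, b_ij = tuple(a_ij), tuple(b_ij)
    cc = fes.cpdb_centers[:, None]
    xc = fes.chi_centers[None, :]
    chi_near_basin = (
        (np.abs(angle_diff(xc, wc.point.chi)) <= basin_chi_halfwidth)
        | (np.abs(angle_diff(xc, hg.point.chi)) <= basin_chi_halfwidth))
    paths = []
    for direction in ("cw", "ccw"):
        dmask = _direction_mask(fes, wc.point.chi, hg.point.chi, direction)
        families = (
            dmask & (np.abs(cc) <= small_cutoff + 1e-9),        # small flip
            dmask & (chi_near_basin | (cc >= large_cutoff - 1e-9)),   # major
            dmask & (chi_near_basin | (cc <= -large_cutoff + 1e-9)),  # minor
        )
        for allowed in families:
            try:
                p, _ = _minimax_threshold(fes, a_ij, b_ij, allowed)
            except NoPathError:
                continue
            paths.append(_path_to_transition(fes, p, wc, hg, min_prominence))
    return paths


def delta_g(fes, a, b):
    """Free-energy difference F(b) - F(a) between two labeled basin minima."""
    return float(b.point.F - a.point.F)


def convergence_report(ensembles, fractions, temperature=None,
                       wham_kwargs=None):
    """Cumulative-data convergence: RMS error of partial-data surfaces.

    For each fraction f the surface is re-estimated from the first
    ceil(f*n) samples of every window and compared with the full-data
    surface (RMS over bins sampled in both, after aligning by the mean over
    common bins).  The reported threshold is k_B*T.
    """
    fractions = list(fractions)
    if any(f2 < f1 for f1, f2 in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be ascending")
    if not math.isclose(fractions[-1], 1.0):
        raise ValueError("the final fraction must be 1.0")
    kw = dict(wham_kwargs or {})
    if temperature is not None:
        kw["temperature"] = temperature
    full_fes, _ = wham2d(ensembles, **kw)
    kw.setdefault("cpdb_edges", full_fes.cpdb_edges)
    kw.setdefault("chi_edges", full_fes.chi_edges)
    T = full_fes.temperature
    rms_list = []
    from .fes import BiasedEnsemble
    for f in fractions:
        if f >= 1.0:
            rms_list.append(0.0)
            continue
        truncated = []
        for e in ensembles:
            m = math.ceil(f * e.n)
            if m < 1:
                raise ValueError(
                    f"fraction {f} leaves window {e.window.id} empty")
            truncated.append(BiasedEnsemble(e.window, e.samples[:m]))
        part, _ = wham2d(truncated, **kw)
        common = part.sampled_mask & full_fes.sampled_mask
        diff = part.F[common] - full_fes.F[common]
        diff -= diff.mean()
        rms_list.append(float(np.sqrt(np.mean(diff ** 2))))
    return ConvergenceReport(fractions=fractions, rms_error=rms_list,
                             threshold=R_KCAL * T)
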