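import numpy as np
import pytest

from hgflip.fes import BiasedEnsemble, FESGrid, R_KCAL, bin_edges
from hgflip.surface import (BasinLabel, CriticalPoint, NoPathError,
                            TransitionPath, classify_path,
                            convergence_report, delta_g, extract_paths,
                            find_minima, find_ts, label_basins)
from hgflip.umbrella import UmbrellaWindow

from _oracles import minimax_value_dijkstra, minimax_value_exhaustive


def grid_from_array(F, periodic=True, cpdb_span=(-60, 60)):
    F = np.asarray(F, dtype=float)
    nc, nx = F.shape
    ce = np.linspace(*cpdb_span, nc + 1)
    xe = np.linspace(-180, 180, nx + 1) if periodic else \
        np.linspace(0, 90, nx + 1)
    return FESGrid(ce, xe, F, np.ones_like(F, dtype=bool), 300.0)


class TestFindMinima:
    def test_single_paraboloid_has_one_minimum(self):
        c = np.linspace(-1, 1, 11)
        F = c[:, None] ** 2 + c[None, :] ** 2
        fes = grid_from_array(F, periodic=False)
        minima = find_minima(fes)
        assert len(minima) == 1
        assert minima[0].ij == (5, 5)

    def test_two_separated_paraboloids(self):
        c = np.arange(12, dtype=float)
        F = np.minimum((c[:, None] - 2) ** 2 + (c[None, :] - 2) ** 2,
                       (c[:, None] - 9) ** 2 + (c[None, :] - 9) ** 2)
        minima = find_minima(grid_from_array(F, periodic=False))
        assert len(minima) == 2

    def test_chi_periodicity_joins_seam_neighbors(self):
        # a single well centered on the seam must not split in two
        x = np.linspace(-177.5, 177.5, 72)
        c = np.linspace(-0.5, 0.5, 5)
        F = (1 - np.cos(np.radians(x - 178.0)))[None, :] + c[:, None] ** 2
        minima = find_minima(grid_from_array(F))
        assert len(minima) == 1
        assert minima[0].chi == pytest.approx(177.5)

    def test_default_surface_minima_near_designed_centers(self, true_grid):
        minima = find_minima(true_grid)
        labels = {lab.label: lab for lab in label_basins(minima)}
        ls = labels["LS"].point
        assert abs(ls.cpdb - (-57.3)) <= 5.0
        assert abs(ls.chi - 51.2) <= 5.0


class TestFindTs:
    def test_three_bin_ridge(self):
        F = np.array([[0.0, 5.0, 1.0]]).T   # three CPDb bins, one chi bin
        fes = grid_from_array(F, periodic=False)
        minima = find_minima(fes)
        assert len(minima) == 2
        ts = find_ts(fes, minima[0], minima[1])
        assert ts.F == 5.0
        assert ts.F - minima[0].F == pytest.approx(5.0)

    def test_symmetric_double_well_saddle(self):
        c = np.linspace(-1, 1, 21)
        y = np.linspace(-0.2, 0.2, 5)
        F = ((c ** 2 - 0.5) ** 2)[:, None] + y[None, :] ** 2
        fes = grid_from_array(F, periodic=False)
        minima = find_minima(fes)
        ts = find_ts(fes, minima[0], minima[1])
        assert ts.ij[0] == 10   # the central ridge bin
        assert ts.F == pytest.approx(0.25)

    def test_disconnected_basins_raise(self):
        F = np.zeros((5, 4))
        mask = np.ones_like(F, dtype=bool)
        mask[2, :] = False
        fes = FESGrid(np.linspace(-60, 60, 6), np.linspace(0, 90, 5),
                      F, mask, 300.0)
        a = CriticalPoint("minimum", -48, 11.25, 0.0, (0, 0))
        b = CriticalPoint("minimum", 48, 78.75, 0.0, (4, 3))
        with pytest.raises(NoPathError):
            find_ts(fes, a, b)

    @pytest.mark.parametrize("periodic", [True, False])
    def test_matches_dijkstra_minimax_oracle_on_random_grids(self, periodic):
        rng = np.random.default_rng(17)
        for _ in range(40):
            F = rng.uniform(0, 10, size=(10, 12))
            fes = grid_from_array(F, periodic=periodic)
            ij_a = (int(rng.integers(10)), int(rng.integers(12)))
            ij_b = (int(rng.integers(10)), int(rng.integers(12)))
            if ij_a == ij_b:
                continue
            a = CriticalPoint("minimum", 0, 0, F[ij_a], ij_a)
            b = CriticalPoint("minimum", 0, 0, F[ij_b], ij_b)
            ts = find_ts(fes, a, b)
            oracle = minimax_value_dijkstra(F, np.ones_like(F, bool),
                                            ij_a, ij_b, periodic)
            assert ts.F == pytest.approx(oracle)

    def test_matches_exhaustive_enumeration_on_tiny_grids(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            F = rng.uniform(0, 10, size=(3, 4))
            fes = grid_from_array(F, periodic=False)
            a = CriticalPoint("minimum", 0, 0, F[0, 0], (0, 0))
            b = CriticalPoint("minimum", 0, 0, F[2, 3], (2, 3))
            ts = find_ts(fes, a, b)
            assert ts.F == pytest.approx(
                minimax_value_exhaustive(F, (0, 0), (2, 3), False))


def make_min(cpdb, chi, F):
    return CriticalPoint("minimum", cpdb, chi, F, None)


class TestLabelBasins:
    def test_reference_labels(self):
        labs = label_basins([make_min(0, -105, 0.0), make_min(0, 55, 4.4)])
        assert [l.label for l in labs] == ["WC", "HG"]

    def test_minor_groove_intermediate(self):
        labs = label_basins([make_min(0, -105, 0.0), make_min(0, 55, 4.4),
                             make_min(-57, 51, 6.5)])
        assert [l.label for l in labs] == ["WC", "HG", "LS"]

    def test_single_anti_minimum_gives_wc_only(self):
        labs = label_basins([make_min(0, -120, 0.0)])
        assert [l.label for l in labs] == ["WC"]

    def test_missing_anti_minimum_warns_but_labels(self):
        with pytest.warns(UserWarning, match="WC"):
            labs = label_basins([make_min(0, 30, 0.0)])
        assert labs[0].label == "HG"

    def test_flipped_anti_minimum_is_other(self):
        labs = label_basins([make_min(0, -105, 0.0), make_min(75, -110, 5.0)])
        assert [l.label for l in labs] == ["WC", "other"]


def path_of(points, start_F=0.0, end_F=4.4):
    start = BasinLabel("WC", make_min(*points[0], start_F))
    end = BasinLabel("HG", make_min(*points[-1], end_F))
    ts = make_min(*max(points, key=lambda p: 0), 10.0)
    return TransitionPath(points=points, start=start, end=end, ts=ts,
                          forward_barrier=10.0, reverse_barrier=5.6)


class TestClassifyPath:
    def test_small_clockwise_is_r1(self):
        # decreasing chi through the seam at small flip
        pts = [(0, -115), (5, -160), (-5, 170), (0, 120), (5, 85), (0, 55)]
        assert classify_path(path_of(pts)) == "R1"

    def test_minor_groove_counterclockwise_is_l3(self):
        pts = [(0, -115), (-40, -100), (-75, -60), (-70, 0), (-40, 40),
               (0, 55)]
        assert classify_path(path_of(pts)) == "L3"

    def test_major_groove_clockwise_is_r2(self):
        pts = [(0, -115), (40, -160), (75, 160), (70, 85), (0, 55)]
        assert classify_path(path_of(pts)) == "R2"

    def test_intermediate_flip_is_unclassified(self):
        pts = [(0, -115), (40, -60), (0, 55)]
        assert classify_path(path_of(pts)) == "unclassified"


class TestExtractPaths:
    def test_six_routes_with_small_opening_lowest(self, true_grid):
        labels = {l.label: l for l in label_basins(find_minima(true_grid))}
        paths = extract_paths(true_grid, labels["WC"], labels["HG"])
        classes = {p.klass: p for p in paths}
        assert set(classes) == {"R1", "R2", "R3", "L1", "L2", "L3"}
        small = max(classes["R1"].forward_barrier,
                    classes["L1"].forward_barrier)
        for large in ("R2", "R3", "L2", "L3"):
            assert classes[large].forward_barrier > small

    def test_minor_routes_carry_two_transition_states(self, true_grid):
        labels = {l.label: l for l in label_basins(find_minima(true_grid))}
        paths = extract_paths(true_grid, labels["WC"], labels["HG"])
        for p in paths:
            if p.klass in ("R3", "L3"):
                assert len(p.sub_ts) >= 2

    def test_barriers_bound_delta_g(self, true_grid):
        labels = {l.label: l for l in label_basins(find_minima(true_grid))}
        dg = delta_g(true_grid, labels["WC"], labels["HG"])
        for p in extract_paths(true_grid, labels["WC"], labels["HG"]):
            assert p.forward_barrier >= dg - 1e-9
            assert p.forward_barrier >= 0

    def test_chi_mirror_swaps_rotation_direction(self, true_grid):
        labels = {l.label: l for l in label_basins(find_minima(true_grid))}
        wc_chi = labels["WC"].point.chi
        xc = true_grid.chi_centers
        # mirror chi about the WC basin center; 5-degree grid maps onto itself
        from hgflip.umbrella import wrap_angle
        target = wrap_angle(2 * wc_chi - xc)
        perm = [int(np.argmin(np.abs(wrap_angle(target[j] - xc))))
                for j in range(len(xc))]
        Fm = true_grid.F[:, perm]
        mirrored = FESGrid(true_grid.cpdb_edges, true_grid.chi_edges, Fm,
                           np.ones_like(Fm, bool), true_grid.temperature)
        # map the original basin labels through the mirror (anti/syn naming
        # is not mirror-symmetric, so labels are carried over, not re-derived)
        def mirror_label(lab):
            chi_m = float(wrap_angle(2 * wc_chi - lab.point.chi))
            j = int(np.argmin(np.abs(wrap_angle(xc - chi_m))))
            pt = CriticalPoint("minimum", lab.point.cpdb, chi_m,
                               lab.point.F, (lab.point.ij[0], j))
            return BasinLabel(lab.label, pt)
        orig = {p.klass: p.forward_barrier
                for p in extract_paths(true_grid, labels["WC"], labels["HG"])}
        mirr = {p.klass: p.forward_barrier
                for p in extract_paths(mirrored, mirror_label(labels["WC"]),
                                       mirror_label(labels["HG"]))}
        for a, b in (("R1", "L1"), ("L1", "R1"), ("R2", "L2"), ("L3", "R3"),
                     ("R3", "L3"), ("L2", "R2")):
            assert orig[a] == pytest.approx(mirr[b], abs=1e-9)


class TestDeltaG:
    def test_identical_basins_zero_and_antisymmetry(self, true_grid):
        labels = {l.label: l for l in label_basins(find_minima(true_grid))}
        wc, hg = labels["WC"], labels["HG"]
        assert delta_g(true_grid, wc, wc) == 0.0
        assert delta_g(true_grid, wc, hg) == -delta_g(true_grid, hg, wc)

    def test_invariant_to_additive_reference(self, true_grid):
        shifted = FESGrid(true_grid.cpdb_edges, true_grid.chi_edges,
                          true_grid.F + 3.0, true_grid.sampled_mask,
                          true_grid.temperature)
        labels = {l.label: l for l in label_basins(find_minima(true_grid))}
        slabels = {l.label: l for l in label_basins(find_minima(shifted))}
        assert delta_g(shifted, slabels["WC"], slabels["HG"]) == \
            pytest.approx(delta_g(true_grid, labels["WC"], labels["HG"]))


class TestConvergence:
    def _tiny_suite(self, duplicate=False):
        rng = np.random.default_rng(9)
        ens = []
        for i, x0 in enumerate(np.arange(-150.0, 180.0, 30.0)):
            w = UmbrellaWindow(i, 0.0, x0, 5.0, 5.0)
            s = np.column_stack([rng.normal(0, 15, 400),
                                 rng.normal(x0, 20, 400)])
            if duplicate:
                s = np.vstack([s, s])
            ens.append(BiasedEnsemble(w, s))
        return ens

    def test_final_fraction_has_zero_rms(self):
        rep = convergence_report(self._tiny_suite(), [1.0],
                                 wham_kwargs={"bin_width": 15.0})
        assert rep.rms_error == [0.0]
        assert rep.threshold == pytest.approx(R_KCAL * 300.0)

    def test_duplicated_samples_give_zero_rms_at_half(self):
        rep = convergence_report(self._tiny_suite(duplicate=True),
                                 [0.5, 1.0],
                                 wham_kwargs={"bin_width": 15.0})
        assert rep.rms_error[0] == pytest.approx(0.0, abs=1e-5)

    def test_fraction_ordering_enforced(self):
        with pytest.raises(ValueError):
            convergence_report(self._tiny_suite(), [0.5, 0.25, 1.0])
        with pytest.raises(ValueError):
            convergence_report(self._tiny_suite(), [0.25, 0.5])
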