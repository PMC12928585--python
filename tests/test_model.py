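"""Tissue construction: seeding, domain assignment, boundaries, mutants."""

import copy

import numpy as np
import pytest

from pcpotts import lattice as L
from pcpotts.lattice import CompartmentRegistry, Lattice
from pcpotts.model import (BoundaryConfig, DomainFractions, build_boundary,
                           build_single_cell, build_tissue,
                           domain_site_counts, initialize_seed_tissue,
                           make_mutant_patch, assign_pcp_domains)
from pcpotts import metrics


class TestDomainFractions:
    def test_default_counts_at_144(self):
        counts = domain_site_counts(144, DomainFractions())
        assert counts == {"proximal": 22, "distal": 22, "lateral": 28,
                          "cytoplasm": 72}
        assert sum(counts.values()) == 144

    @pytest.mark.parametrize("volume", [36, 64, 100, 144, 288])
    def test_counts_conserve_volume_and_stay_near_fractions(self, volume):
        counts = domain_site_counts(volume, DomainFractions())
        assert sum(counts.values()) == volume
        assert counts["proximal"] == counts["distal"]
        for role, frac in [("proximal", 0.15), ("distal", 0.15),
                           ("lateral", 0.20), ("cytoplasm", 0.50)]:
            assert abs(counts[role] - frac * volume) <= 1.5

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ValueError):
            domain_site_counts(144, DomainFractions(1.0, 0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            DomainFractions(0.5, 0.3, 0.3, 0.2)  # sums to 1.3


class TestSeedTissue:
    def test_packing_fills_interior_exactly(self):
        t = initialize_seed_tissue(4, 4, relax_mcs=300, seed=1)
        reg = t.registry
        assert reg.volume[0] == 0  # no medium holes
        seed_vols = [reg.volume[c] for c in t._seed_comps.values()]
        assert sum(seed_vols) == 16 * 144
        assert min(seed_vols) > 0

    def test_identical_seed_identical_packing(self):
        a = initialize_seed_tissue(3, 3, relax_mcs=200, seed=7)
        b = initialize_seed_tissue(3, 3, relax_mcs=200, seed=7)
        assert np.array_equal(a.lattice.sites, b.lattice.sites)

    def test_packing_is_irregular(self):
        # relaxed seed cells should not be rectangles: most cells underfill
        # their bounding box
        t = initialize_seed_tissue(4, 4, relax_mcs=1500, seed=3)
        fills = []
        for cid in t._seed_comps.values():
            sites = np.flatnonzero(t.lattice.sites == cid)
            x, y = t.lattice.coords(sites)
            # bounding box under torus: use extent of sorted gaps
            fills.append(sites.size / ((np.ptp(x) + 1) * (np.ptp(y) + 1)))
        assert np.mean([f < 0.98 for f in fills]) > 0.5


class TestAssignDomains:
    def test_counts_and_conservation(self):
        t = build_tissue(3, 3, relax_mcs=200, seed=2)
        reg = t.registry
        total = 0
        for cell in t.cells.values():
            vols = {r: int(reg.volume[c]) for r, c in cell.comps.items()}
            assert vols["proximal"] == vols["distal"]
            # relaxed seed volumes fluctuate a little around the 144 target
            assert abs(sum(vols.values()) - 144) <= 15
            total += sum(vols.values())
        assert total == 9 * 144  # conservation
        assert reg.volume[0] == 0

    def test_random_assignment_has_no_prepattern(self):
        """Initial phi matches the random-walk null E|sum nu|/N."""
        base = initialize_seed_tissue(4, 4, relax_mcs=300, seed=5)
        phis = []
        for k in range(60):
            t = copy.deepcopy(base)
            t.noise.rng = np.random.default_rng(1000 + k)
            assign_pcp_domains(t)
            phis.append(metrics.tissue_global_order(t))
        n = 16
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n))  # E[phi], uniform angles
        assert abs(np.mean(phis) - expected) < 0.06

    def test_prepolarized_starts_ordered(self):
        t = build_tissue(3, 3, relax_mcs=1000, seed=4, prepolarized=True)
        assert metrics.tissue_global_order(t) > 0.99
        df = metrics.tissue_polarity(t)
        # x-axis convention: proximal band left => nu points in -x
        assert np.all(np.abs(np.abs(df.angle) - 180) < 25)
        assert abs(abs(metrics.circular_mean_deg(df.angle.to_numpy())) - 180) < 10

    def test_prepolarized_vertical_axis(self):
        t = initialize_seed_tissue(3, 3, relax_mcs=1000, seed=4)
        from pcpotts.model import assign_prepolarized_domains
        assign_prepolarized_domains(t, axis="y")
        df = metrics.tissue_polarity(t)
        assert metrics.tissue_global_order(t) > 0.99
        assert np.all(np.abs(np.abs(df.angle) - 90) < 25)
        assert abs(abs(metrics.circular_mean_deg(df.angle.to_numpy())) - 90) < 15


class TestBoundary:
    def test_left_distal_wall_layout(self):
        t = build_tissue(3, 3, relax_mcs=200, seed=1,
                         boundary=BoundaryConfig("left_distal_wall"))
        assert len(t.walls) == 1
        wid = t.walls[0]
        grid = t.lattice.grid()
        assert np.all(grid[:, :3] == wid)
        assert t.registry.frozen[wid]
        assert t.registry.ctype[wid] == L.DIST
        assert t.registry.volume[0] > 0  # open medium on the right

    def test_lateral_wall_type_and_double_wall(self):
        t = build_tissue(3, 3, relax_mcs=200, seed=1,
                         boundary=BoundaryConfig("left_lateral_wall"))
        assert t.registry.ctype[t.walls[0]] == L.LAT
        t2 = build_tissue(3, 3, relax_mcs=200, seed=1,
                          boundary=BoundaryConfig("double_wall"))
        assert len(t2.walls) == 2
        types = sorted(int(t2.registry.ctype[w]) for w in t2.walls)
        assert types == [L.PROX, L.DIST]

    def test_periodic_has_no_walls(self):
        t = build_tissue(3, 3, relax_mcs=200, seed=1)
        assert t.walls == [] and t.registry.volume[0] == 0

    def test_wall_overlap_rejected(self):
        lat = Lattice(30, 24)
        reg = CompartmentRegistry()
        c = reg.new_compartment(L.CYTO, 0, 10, 2.0)
        lat.sites[:] = c
        with pytest.raises(ValueError):
            build_boundary(lat, reg, BoundaryConfig("left_distal_wall"), 10)


class TestMutants:
    def test_fz_like_keeps_only_proximal_surface(self):
        t = build_tissue(3, 3, relax_mcs=200, seed=6, prepolarized=True)
        target = list(t.cells)[4]
        prox_before = int(t.registry.volume[t.cells[target].comps["proximal"]])
        dist_before = int(t.registry.volume[t.cells[target].comps["distal"]])
        make_mutant_patch(t, [target], "fz_like")
        cell = t.cells[target]
        assert cell.mutant == "fz_like"
        assert "distal" not in cell.comps
        assert int(t.registry.volume[cell.comps["proximal"]]) == \
            prox_before + dist_before
        # excluded from polarity aggregates
        assert len(metrics.tissue_polarity(t)) == 8
        assert metrics.polarity_vector(t, cell) is None

    def test_vang_like_is_mirror(self):
        t = build_tissue(3, 3, relax_mcs=200, seed=6, prepolarized=True)
        target = list(t.cells)[4]
        make_mutant_patch(t, [target], "vang_like")
        assert "proximal" not in t.cells[target].comps
        assert "distal" in t.cells[target].comps

    @pytest.mark.parametrize("kind,affected", [("fz_like", "distal"),
                                               ("vang_like", "proximal")])
    def test_domineering_non_autonomy_is_one_sided(self, kind, affected):
        """Wild-type cells on one specific side of a mutant clone reorient:
        the distal side for fz-like clones, the proximal side for
        vang-like, while the opposite side keeps the tissue polarity."""
        from pcpotts.experiments import select_cells_in_rect
        flipped, intact = [], []
        for s in (1, 2):
            t = build_tissue(6, 3, seed=s, relax_mcs=2000, prepolarized=True,
                             boundary=BoundaryConfig("left_distal_wall"))
            sel = select_cells_in_rect(t, (3, 4), (0, 3))  # middle column
            make_mutant_patch(t, sel, kind)
            t.run(20_000)
            df = metrics.tissue_polarity(t)
            col = ((df.com_x - t.wall_face_x()) // t.cell_diameter).astype(int)
            right = df.nu_x[col == 4].mean()  # distal side of the clone
            left = df.nu_x[col == 2].mean()  # proximal side of the clone
            if kind == "fz_like":
                flipped.append(right)
                intact.append(left)
            else:
                flipped.append(left)
                intact.append(right)
        # background polarity has nu_x ~ -1 (proximal domains face the
        # wall); the affected side reverses toward the clone
        assert np.mean(flipped) > 0.0
        assert np.mean(intact) < -0.8

    def test_empty_selection_warns_noop(self):
        t = build_tissue(3, 3, relax_mcs=200, seed=6)
        with pytest.warns(UserWarning):
            make_mutant_patch(t, [], "fz_like")


class TestSingleCell:
    def test_isolated_cell_setup(self):
        t = build_single_cell(seed=0)
        reg = t.registry
        cell = t.cells[0]
        assert sum(int(reg.volume[c]) for c in cell.comps.values()) == 144
        assert int(reg.volume[cell.comps["proximal"]]) == 22

    def test_autonomous_cell_segregates_nonautonomous_does_not(self):
        """Regime contrast: interface closes only in the autonomous cell."""
        ifs = {}
        for regime in ("autonomous", "non_autonomous"):
            vals = []
            for s in range(3):
                t = build_single_cell(seed=s, regime=regime)
                t.run(150)
                for _ in range(20):
                    t.run(5)
                    vals.append(metrics.separation_trace(t, t.cells[0])[1])
            ifs[regime] = np.mean(vals)
        assert ifs["autonomous"] < 1.0
        assert ifs["non_autonomous"] > 3.0
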