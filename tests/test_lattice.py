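"""Potts engine: neighbourhoods, energies, Metropolis dynamics."""

import math

import numpy as np
import pytest

from pcpotts import lattice as L
from pcpotts.lattice import (CompartmentRegistry, ContactEnergyModel, Lattice,
                             NoiseModel, contact_energy_pair, delta_H,
                             metropolis_step, neighbor_offsets, run_mcs,
                             total_energy)


class TestNeighborOffsets:
    @pytest.mark.parametrize("order,count", [(1, 4), (2, 8), (3, 12), (4, 20)])
    def test_cumulative_shell_counts(self, order, count):
        offs = neighbor_offsets(order)
        assert len(offs) == count
        assert len(set(offs)) == count

    def test_shells_match_squared_distance_enumeration(self):
        # order 4 = all offsets with squared distance <= 5, origin excluded
        expected = {(dx, dy) for dx in range(-2, 3) for dy in range(-2, 3)
                    if 0 < dx * dx + dy * dy <= 5}
        assert set(neighbor_offsets(4)) == expected
        assert (2, 0) in neighbor_offsets(3)
        assert all(not (abs(dx) == 2 and abs(dy) == 2)
                   for dx, dy in neighbor_offsets(4))

    @pytest.mark.parametrize("bad", [0, 5, -1])
    def test_invalid_order_rejected(self, bad):
        with pytest.raises(ValueError):
            neighbor_offsets(bad)


class TestContactEnergies:
    def test_cross_cell_uses_external_matrix(self, model):
        reg = CompartmentRegistry()
        p1 = reg.new_compartment(L.PROX, 0, 10, 2.0)
        d2 = reg.new_compartment(L.DIST, 1, 10, 2.0)
        assert contact_energy_pair(p1, d2, model, reg) == 7  # pd affinity

    def test_same_cell_uses_internal_matrix(self, model):
        reg = CompartmentRegistry()
        p = reg.new_compartment(L.PROX, 0, 10, 2.0)
        d = reg.new_compartment(L.DIST, 0, 10, 2.0)
        c = reg.new_compartment(L.CYTO, 0, 10, 2.0)
        assert contact_energy_pair(p, d, model, reg) == 30  # pd exclusion
        assert contact_energy_pair(p, c, model, reg) == 1

    def test_medium_and_self_pairs(self, model):
        reg = CompartmentRegistry()
        p = reg.new_compartment(L.PROX, 0, 10, 2.0)
        assert contact_energy_pair(0, 0, model, reg) == 0  # medium-medium
        assert contact_energy_pair(p, p, model, reg) == 0  # same compartment
        assert contact_energy_pair(p, 0, model, reg) == 10

    def test_unknown_id_raises(self, model):
        reg = CompartmentRegistry()
        with pytest.raises(KeyError):
            contact_energy_pair(0, 99, model, reg)

    def test_asymmetric_matrix_rejected(self):
        j = np.ones((L.N_TYPES, L.N_TYPES))
        bad = j.copy()
        bad[1, 2] = 5
        with pytest.raises(ValueError):
            ContactEnergyModel(bad, j)

    def test_non_autonomous_internal_all_negative(self):
        m = ContactEnergyModel.non_autonomous()
        live = [L.PROX, L.DIST, L.LAT, L.CYTO]
        assert all(m.internal_j[a, b] < 0 for a in live for b in live)
        # external matrix unchanged between regimes
        assert np.array_equal(m.external_J,
                              ContactEnergyModel.autonomous().external_J)


class TestTotalEnergy:
    def test_volume_term_zero_at_target(self, model):
        lat = Lattice(12, 12)
        reg = CompartmentRegistry()
        c = reg.new_compartment(L.CYTO, 0, 144.0, 2.0)
        lat.sites[:] = c  # fills the torus: no contacts, V = Vt
        lat.recount_volumes(reg)
        assert total_energy(lat, reg, model) == 0.0

    def test_volume_term_arithmetic(self, model):
        # lambda (V - Vt)^2 = 2 * 3^2 = 18 with no contact contribution
        lat = Lattice(12, 12)
        reg = CompartmentRegistry()
        c = reg.new_compartment(L.CYTO, 0, 141.0, 2.0)
        lat.sites[:] = c
        lat.recount_volumes(reg)
        assert total_energy(lat, reg, model) == pytest.approx(18.0)


class TestDeltaH:
    def test_same_compartment_is_zero(self, random_lattice, model):
        lat, reg = random_lattice(seed=1)
        idx = np.flatnonzero(lat.sites == lat.sites[0])
        assert delta_H(int(idx[0]), int(idx[0]), lat, reg, model) == 0.0

    def test_matches_brute_force_on_random_proposals(self, random_lattice, model):
        """Incremental dH == total_energy(after) - total_energy(before)."""
        lat, reg = random_lattice(seed=2)
        rng = np.random.default_rng(0)
        h = total_energy(lat, reg, model)
        checked = 0
        while checked < 300:
            j = int(rng.integers(lat.n_sites))
            i = int(lat.nbr3[j, rng.integers(12)])
            si, sj = int(lat.sites[i]), int(lat.sites[j])
            if si == sj:
                continue
            dh = delta_H(i, j, lat, reg, model)
            lat.sites[j] = si
            reg.volume[si] += 1
            reg.volume[sj] -= 1
            h_new = total_energy(lat, reg, model)
            assert h_new - h == pytest.approx(dh, abs=1e-9)
            h = h_new
            checked += 1

    def test_pure_volume_flip_algebra(self, model):
        # isolated flip between two over/under-target compartments
        lat = Lattice(12, 12)
        reg = CompartmentRegistry()
        a = reg.new_compartment(L.CYTO, 0, 72.0, 2.0)
        b = reg.new_compartment(L.CYTO, 1, 72.0, 2.0)
        lat.grid()[:6, :] = a
        lat.grid()[6:, :] = b
        lat.recount_volumes(reg)  # both exactly at target
        j = lat.index(0, 6)  # b site adjacent to a
        i = lat.index(0, 5)
        dh = delta_H(int(i), int(j), lat, reg, model)
        dh_vol = 2.0 * ((72 + 1 - 72) ** 2 + (72 - 1 - 72) ** 2)  # = 4
        h0 = total_energy(lat, reg, model)
        lat.sites[j] = a
        reg.volume[a] += 1
        reg.volume[b] -= 1
        assert dh == pytest.approx(total_energy(lat, reg, model) - h0)
        # contact change accounted separately from the volume algebra
        assert dh - dh_vol == pytest.approx(
            (total_energy(lat, reg, model) - h0) - dh_vol)


class TestMetropolis:
    def test_downhill_moves_drive_growth_to_target(self, model):
        # a far-under-target compartment invades medium: dH strongly negative
        lat = Lattice(20, 20)
        reg = CompartmentRegistry()
        p = reg.new_compartment(L.PROX, 0, 150.0, 2.0)
        lat.grid()[8:12, 8:12] = p  # V = 16 << Vt = 150
        lat.recount_volumes(reg)
        noise = NoiseModel(10.0, 0)
        accepted = 0
        for _ in range(20_000):
            accepted += metropolis_step(lat, reg, model, noise)
        assert accepted > 0
        assert abs(reg.volume[p] - 150) < 20  # grew to ~target

    def test_acceptance_law_exp_minus_dh_over_t(self, random_lattice, model):
        """Empirical acceptance at fixed positive dH matches exp(-dH/T)."""
        lat, reg = random_lattice(seed=3)
        noise = NoiseModel(20.0, 1)
        rng = noise.rng
        trials: dict[float, list[int]] = {}
        for _ in range(120_000):
            j = int(rng.integers(lat.n_sites))
            i = int(lat.nbr3[j, rng.integers(12)])
            si, sj = int(lat.sites[i]), int(lat.sites[j])
            if si == sj or (sj != 0 and reg.volume[sj] <= 1):
                continue
            dh = delta_H(i, j, lat, reg, model)
            if dh <= 0:
                continue
            acc = rng.random() < math.exp(-dh / noise.temperature)
            trials.setdefault(dh, []).append(acc)
            # do not apply: keeps the proposal distribution stationary
        checked = 0
        for dh, accs in trials.items():
            n = len(accs)
            p = math.exp(-dh / noise.temperature)
            if n < 150 or p < 1e-3:
                continue
            se = math.sqrt(p * (1 - p) / n)
            assert abs(np.mean(accs) - p) < 3 * se + 1e-9
            checked += 1
        assert checked >= 3

    def test_mcs_attempt_count_and_determinism(self, random_lattice, model):
        lat1, reg1 = random_lattice(seed=4)
        log = run_mcs(lat1, reg1, model, NoiseModel(10.0, 9), 5)
        assert log.total_attempts == 5 * 400  # N attempts per MCS
        lat2, reg2 = random_lattice(seed=4)
        run_mcs(lat2, reg2, model, NoiseModel(10.0, 9), 5)
        assert np.array_equal(lat1.sites, lat2.sites)
        lat3, reg3 = random_lattice(seed=4)
        run_mcs(lat3, reg3, model, NoiseModel(10.0, 10), 5)
        assert not np.array_equal(lat1.sites, lat3.sites)

    def test_zero_mcs_is_identity(self, random_lattice, model, noise):
        lat, reg = random_lattice(seed=5)
        before = lat.sites.copy()
        log = run_mcs(lat, reg, model, noise, 0)
        assert np.array_equal(before, lat.sites)
        assert log.total_attempts == 0

    def test_volume_bookkeeping_after_run(self, random_lattice, model, noise):
        lat, reg = random_lattice(seed=6)
        run_mcs(lat, reg, model, noise, 20)
        counts = np.bincount(lat.sites, minlength=reg.n)
        assert np.array_equal(counts, reg.volume[: reg.n])
        assert reg.volume[1:reg.n].sum() == np.count_nonzero(lat.sites)

    def test_kernel_energy_consistency(self, random_lattice, model, noise):
        """H0 + sum of accepted kernel dH equals brute-force final energy."""
        lat, reg = random_lattice(seed=7)
        h0 = total_energy(lat, reg, model)
        log = run_mcs(lat, reg, model, noise, 30)
        assert total_energy(lat, reg, model) == pytest.approx(
            h0 + sum(log.dh), abs=1e-6)

    def test_frozen_compartments_never_change(self, model):
        lat = Lattice(20, 20)
        reg = CompartmentRegistry()
        wall = reg.new_compartment(L.DIST, 99, 0.0, 0.0, frozen=True)
        lat.grid()[:, :3] = wall
        cell = reg.new_compartment(L.CYTO, 0, 300.0, 2.0)
        lat.grid()[:, 3:8] = cell
        lat.recount_volumes(reg)
        wall_sites = np.flatnonzero(lat.sites == wall)
        run_mcs(lat, reg, model, NoiseModel(20.0, 3), 100)
        assert np.array_equal(wall_sites, np.flatnonzero(lat.sites == wall))

    def test_extinction_guard_keeps_compartments_alive(self, model):
        # a 1-site compartment squeezed by a dominant neighbour survives
        lat = Lattice(10, 10)
        reg = CompartmentRegistry()
        big = reg.new_compartment(L.CYTO, 0, 200.0, 2.0)
        tiny = reg.new_compartment(L.PROX, 1, 1.0, 2.0)
        lat.sites[:] = big
        lat.sites[55] = tiny
        lat.recount_volumes(reg)
        run_mcs(lat, reg, model, NoiseModel(30.0, 5), 200)
        assert reg.volume[tiny] >= 1
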