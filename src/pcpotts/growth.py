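"""Cell growth scheduling, division with domain inheritance, cascade activation.

Growth raises a cell's total target volume at a fixed rate (default 0.001
sites/MCS, a 1.44e5 MCS doubling time for 144-site cells).  Membrane-domain
targets (proximal/distal/lateral) scale with the square root of the total
target — an isoperimetric proxy that keeps the membrane band thickness and
the 15:15:20 ratios fixed as the cell grows — while the cytoplasm absorbs
the remainder.  When a cell's realized volume doubles its birth volume it
divides through its centre of mass along the chosen principal axis; each
daughter inherits half of every domain but the domain positions are
re-randomized, so daughters lose their polarity and must re-polarize from
their neighbours.  After division a cell waits a uniformly random fraction
of the refractory time t_r before growing again.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .lattice import neighbor_offsets
from .model import TAU, Cell, Tissue, _MEMBRANE, set_cell_active
from . import metrics

log = logging.getLogger(__name__)


@dataclass
class GrowthPolicy:
    """Growth/division protocol parameters."""

    mode: str = "uniform"  # none | front_only | uniform
    rate: float = 0.001  # target-volume increment per MCS (whole cell)
    refractory_time: float = 10_000.0  # t_r, MCS
    division_axis: str = "minor"  # minor | major

    def __post_init__(self):
        if self.mode not in ("none", "front_only", "uniform"):
            raise ValueError(f"unknown growth mode {self.mode!r}")
        if self.division_axis not in ("minor", "major"):
            raise ValueError(f"division axis must be minor or major")
        if self.rate < 0 or self.refractory_time < 0:
            raise ValueError("rate and refractory time must be >= 0")


def front_cells(tissue: Tissue) -> set[int]:
    """Clusters with at least one site order-1 adjacent to open medium."""
    lat = tissue.lattice
    grid = lat.grid()
    cl = tissue.registry.cluster[: tissue.registry.n][grid]
    touches = np.zeros_like(grid, dtype=bool)
    for dx, dy in neighbor_offsets(1):
        touches |= np.roll(np.roll(grid, dy, axis=0), dx, axis=1) == 0
    out = set(np.unique(cl[(grid != 0) & touches]).tolist())
    return {c for c in out if c in tissue.cells}


def schedule_growth(tissue: Tissue, policy: GrowthPolicy,
                    now: float | None = None) -> None:
    """Assign wake times: uniform mode wakes every cell at now + U[0, t_r];
    front_only marks only the open-boundary cells as growing."""
    if policy.mode == "none":
        return
    now = tissue.time if now is None else now
    rng = tissue.noise.rng
    front = front_cells(tissue) if policy.mode == "front_only" else None
    for cell in tissue.cells.values():
        if front is not None and cell.cluster_id not in front:
            cell.phase = "waiting"
            cell.wake_time = math.inf
            continue
        cell.phase = "waiting"
        cell.wake_time = now + rng.uniform(0.0, policy.refractory_time)


def grow_step(tissue: Tissue, cell: Cell, policy: GrowthPolicy,
              dt_mcs: float) -> None:
    """Advance one growing cell's target volumes by dt_mcs of growth."""
    reg = tissue.registry
    cell.vt_total += policy.rate * dt_mcs
    scale = math.sqrt(cell.vt_total / cell.v_ref)
    mem_sum = 0.0
    for role, ref in cell.mem_ref.items():
        t = ref * scale
        reg.target[cell.comps[role]] = t
        mem_sum += t
    reg.target[cell.comps["cytoplasm"]] = cell.vt_total - mem_sum


def _principal_axes(dx: np.ndarray, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(major, minor) unit eigenvectors of the site second-moment tensor."""
    cov = np.cov(np.stack([dx, dy]))
    w, v = np.linalg.eigh(cov)
    return v[:, 1], v[:, 0]  # eigh sorts ascending


def _allocate_counts(n: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n sites proportional to weights,
    at least one site per type, cytoplasm absorbs rounding residue."""
    tot = sum(weights.values())
    quota = {r: n * w / tot for r, w in weights.items()}
    counts = {r: max(1, math.floor(q)) for r, q in quota.items()}
    rem = n - sum(counts.values())
    order = sorted(weights, key=lambda r: quota[r] - math.floor(quota[r]),
                   reverse=True)
    i = 0
    while rem > 0:
        counts[order[i % len(order)]] += 1
        rem -= 1
        i += 1
    while rem < 0:  # possible only via the max(1, .) floor
        big = max(counts, key=lambda r: counts[r])
        counts[big] -= 1
        rem += 1
    return counts


def check_and_divide(tissue: Tissue, cell: Cell, policy: GrowthPolicy,
                     now: float | None = None) -> tuple[Cell, Cell] | None:
    """Divide the cell if its realized volume has doubled its birth volume.

    The cleavage line passes through the COM along the chosen principal
    axis (minor-axis division splits the cell across its long dimension).
    Each daughter's sites are relabeled uniformly at random with half the
    parent's volume in every domain (largest remainder), so daughters start
    unpolarized.  Returns the daughters, or None if no division."""
    reg = tissue.registry
    lat = tissue.lattice
    now = tissue.time if now is None else now
    vol = int(sum(reg.volume[c] for c in cell.compartment_ids))
    if vol < 2 * cell.birth_volume:
        return None
    sites = tissue.sites_of_cluster(cell.cluster_id)
    x, y = lat.coords(sites)
    cx = metrics._axis_com(x, lat.width, lat.boundary_mode_x == "periodic")
    cy = metrics._axis_com(y, lat.height, lat.boundary_mode_y == "periodic")
    dx = metrics._min_image_arr(x - cx, lat.width,
                                lat.boundary_mode_x == "periodic")
    dy = metrics._min_image_arr(y - cy, lat.height,
                                lat.boundary_mode_y == "periodic")
    if np.ptp(dx) < 1e-9 or np.ptp(dy) < 1e-9:
        log.warning("degenerate (collinear) cell %d: coordinate-axis cleavage",
                    cell.cluster_id)
        axis_vec = np.array([1.0, 0.0]) if np.ptp(dx) >= np.ptp(dy) \
            else np.array([0.0, 1.0])
    else:
        major, minor = _principal_axes(dx, dy)
        axis_vec = major if policy.division_axis == "minor" else minor
    side = dx * axis_vec[0] + dy * axis_vec[1]
    mask_a = side < 0  # sites exactly on the cleavage line join daughter A
    if mask_a.all() or (~mask_a).all():  # pathological; split by median rank
        mask_a = np.argsort(side, kind="stable") < sites.size // 2

    parent_per_type = {r: float(reg.volume[cid])
                       for r, cid in cell.comps.items()}
    rng = tissue.noise.rng
    daughters = []
    for mask in (mask_a, ~mask_a):
        dsites = sites[mask]
        counts = _allocate_counts(dsites.size, parent_per_type)
        cluster = tissue.next_cluster
        tissue.next_cluster += 1
        comps = {}
        lam = reg.lam[cell.comps["cytoplasm"]]
        for role in cell.comps:
            comps[role] = reg.new_compartment(
                reg.ctype[cell.comps[role]], cluster,
                float(reg.target[cell.comps[role]]) / 2.0, lam)
        labels = np.concatenate([
            np.full(counts[r], comps[r], dtype=np.int32) for r in comps])
        rng.shuffle(labels)
        lat.sites[dsites] = labels
        vt = cell.vt_total / 2.0
        d = Cell(cluster_id=cluster, comps=comps, mutant=cell.mutant,
                 active=cell.active, phase="waiting",
                 wake_time=now + rng.uniform(0.0, policy.refractory_time),
                 birth_volume=int(dsites.size), vt_total=vt, v_ref=vt,
                 mem_ref={r: float(reg.target[comps[r]])
                          for r in comps if r in _MEMBRANE})
        daughters.append(d)
        tissue.cells[cluster] = d
    for cid in cell.compartment_ids:
        reg.target[cid] = 0.0
        reg.lam[cid] = 0.0
    del tissue.cells[cell.cluster_id]
    lat.recount_volumes(reg)
    return daughters[0], daughters[1]


@dataclass
class DivisionEvent:
    mcs: float
    parent: int
    daughters: tuple[int, int]
    axis: str
    com: tuple[float, float]


class GrowthEngine:
    """run_mcs callback advancing growth and divisions between kernel chunks."""

    def __init__(self, tissue: Tissue, policy: GrowthPolicy):
        self.tissue = tissue
        self.policy = policy
        self.events: list[DivisionEvent] = []
        self._last = tissue.time
        schedule_growth(tissue, policy)

    def __call__(self, mcs_done: float) -> None:
        t = self.tissue
        now = t.time + mcs_done  # tissue.time updated after run() returns
        dt = now - self._last
        self._last = now
        if self.policy.mode == "none" or dt <= 0:
            return
        divided = False
        for cell in list(t.cells.values()):
            if cell.phase == "waiting" and now >= cell.wake_time:
                cell.phase = "growing"
            if cell.phase != "growing":
                continue
            grow_step(t, cell, self.policy, dt)
            pair = check_and_divide(t, cell, self.policy, now)
            if pair is not None:
                divided = True
                x, y = t.lattice.coords(t.sites_of_cluster(pair[0].cluster_id))
                self.events.append(DivisionEvent(
                    now, cell.cluster_id,
                    (pair[0].cluster_id, pair[1].cluster_id),
                    self.policy.division_axis,
                    (float(x.mean()), float(y.mean()))))
        if divided and self.policy.mode == "front_only":
            front = front_cells(t)
            for cell in t.cells.values():
                if cell.phase == "waiting" and cell.cluster_id in front \
                        and not math.isfinite(cell.wake_time):
                    cell.wake_time = now + t.noise.rng.uniform(
                        0.0, self.policy.refractory_time)


def run_with_growth(tissue: Tissue, policy: GrowthPolicy, n_mcs: int, *,
                    update_every: int = 50, sample_every: int | None = None,
                    sample_fn=None) -> GrowthEngine:
    """Run n_mcs MCS with growth/division updates every ``update_every`` MCS.

    ``sample_fn(tissue)`` is additionally invoked every ``sample_every`` MCS.
    """
    engine = GrowthEngine(tissue, policy)
    next_sample = sample_every

    def cb(mcs_done):
        nonlocal next_sample
        engine(mcs_done)
        if sample_every is not None and mcs_done >= next_sample:
            t_saved = tissue.time
            tissue.time = t_saved + mcs_done
            try:
                sample_fn(tissue)
            finally:
                tissue.time = t_saved
            next_sample += sample_every

    tissue.run(n_mcs, callback=cb, callback_every=update_every)
    return engine


# ---------------------------------------------------------------------------
# cascade activation


class CascadeActivation:
    """Column-by-column PCP activation from the left boundary.

    All cells start with inactive (non-sorting) energetics except column 0.
    Column k+1 switches on once column k's mean local order has exceeded
    ``threshold`` continuously for ``dwell_mcs``."""

    def __init__(self, tissue: Tissue, threshold: float = 0.9,
                 dwell_mcs: float = 10 * TAU, check_every: int = 20):
        self.tissue = tissue
        self.threshold = threshold
        self.dwell = dwell_mcs
        self.check_every = check_every
        self.activation_times: dict[int, float] = {}
        self._dwell_acc = 0.0
        cols = self.column_of_cells()
        self.n_cols = max(cols.values()) + 1 if cols else 0
        if threshold <= 0:
            for c in tissue.cells.values():
                set_cell_active(tissue, c.cluster_id, True)
            self.current = self.n_cols
            for k in range(self.n_cols):
                self.activation_times[k] = tissue.time
            return
        for c in tissue.cells.values():
            set_cell_active(tissue, c.cluster_id, cols[c.cluster_id] == 0)
        self.current = 0
        self.activation_times[0] = tissue.time

    def column_of_cells(self) -> dict[int, int]:
        df = metrics.tissue_polarity(self.tissue)
        x0 = self.tissue.wall_face_x()
        d = self.tissue.cell_diameter
        return {int(r.cluster): min(self.tissue.grid_shape[0] - 1,
                                    max(0, int((r.com_x - x0) // d)))
                for r in df.itertuples()}

    def column_order(self, col: int) -> float:
        cols = self.column_of_cells()
        df = metrics.tissue_polarity(self.tissue)
        sel = df[df.cluster.map(cols) == col]
        if len(sel) == 0:
            return 0.0
        return metrics.global_order(sel[["nu_x", "nu_y"]].to_numpy())

    def __call__(self, mcs_done: float) -> None:
        if self.current >= self.n_cols - 1:
            return
        if self.column_order(self.current) >= self.threshold:
            self._dwell_acc += self.check_every
        else:
            self._dwell_acc = 0.0
        if self._dwell_acc >= self.dwell:
            self.current += 1
            self._dwell_acc = 0.0
            cols = self.column_of_cells()
            for cl, k in cols.items():
                if k == self.current:
                    set_cell_active(self.tissue, cl, True)
            self.activation_times[self.current] = self.tissue.time + mcs_done


def cascade_activation(tissue: Tissue, *, threshold: float = 0.9,
                       dwell_mcs: float = 10 * TAU, budget_mcs: int = 100_000,
                       check_every: int = 20) -> dict[int, float]:
    """Run the staged activation protocol; returns column -> activation MCS.

    Columns whose activation was not reached within the budget are absent
    from the result (partial result on a stalled cascade)."""
    ctrl = CascadeActivation(tissue, threshold, dwell_mcs, check_every)
    done = 0
    while done < budget_mcs and ctrl.current < ctrl.n_cols - 1:
        tissue.run(check_every, callback=ctrl, callback_every=check_every)
        done += check_every
    return ctrl.activation_times
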