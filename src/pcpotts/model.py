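"""PCP tissue construction on top of the Potts engine.

A biological cell is a *cluster* of four compartments — proximal, distal,
lateral, cytoplasm — occupying 15/15/20/50 % of its volume.  Internal contact
energies sort proximal and distal domains to opposite ends of each cell
(autonomous regime) and the cross-cell proximal-distal affinity couples the
orientation of neighbouring cells.  Tissues are initialized from transient
single-compartment "seed" cells that grow from random positions until they
fill the interior, producing an irregular epithelial packing; PCP domains
are then assigned at random positions inside each cell so that no spatial
pre-pattern is imposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lattice import (
    CYTO, DIST, ICYTO, IDIST, ILAT, IPROX, LAT, PROX, SEED,
    CompartmentRegistry, ContactEnergyModel, Lattice, NoiseModel, com_1d,
    min_image, run_mcs,
)

# Calibrated defaults (see scripts/calibrate.py and docs/methods.md):
# 144-site cells (12x12), volume-constraint weight 2, temperature 15.
# T was chosen by scanning for maximal cell-autonomous polarization of
# small (4x4) tissues while keeping the single-cell polarization time
# near 20 MCS — the same criterion that fixes the contact energies.
DEFAULT_CELL_AREA = 144
DEFAULT_LAMBDA_V = 2.0
DEFAULT_TEMPERATURE = 15.0
#: single-cell polarization time in MCS; the natural time unit of the model
TAU = 20.0

_MEMBRANE = ("proximal", "distal", "lateral")
_TYPE_OF = {"proximal": PROX, "distal": DIST, "lateral": LAT, "cytoplasm": CYTO}
_INACTIVE_OF = {PROX: IPROX, DIST: IDIST, LAT: ILAT, CYTO: ICYTO}
_ACTIVE_OF = {v: k for k, v in _INACTIVE_OF.items()}


@dataclass
class DomainFractions:
    """Volume fractions of the four compartments (must sum to 1)."""

    cytoplasm: float = 0.50
    proximal: float = 0.15
    distal: float = 0.15
    lateral: float = 0.20

    def __post_init__(self):
        tot = self.cytoplasm + self.proximal + self.distal + self.lateral
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("domain fractions must sum to 1")


def domain_site_counts(volume: int, fractions: DomainFractions) -> dict[str, int]:
    """Integer site allocation for one cell.

    Proximal/distal rounded half-up, lateral floored, cytoplasm absorbs the
    residual; every compartment must get at least one site.
    """
    n_p = math.floor(fractions.proximal * volume + 0.5)
    n_d = math.floor(fractions.distal * volume + 0.5)
    n_l = math.floor(fractions.lateral * volume)
    n_c = volume - n_p - n_d - n_l
    counts = {"proximal": n_p, "distal": n_d, "lateral": n_l, "cytoplasm": n_c}
    if min(counts.values()) < 1:
        raise ValueError(
            f"cell of {volume} sites cannot hold all four domains at "
            f"fractions {fractions} (got {counts})")
    return counts


@dataclass
class Cell:
    """One biological cell: a cluster of compartments plus cycle state."""

    cluster_id: int
    comps: dict[str, int]  # role -> compartment ID
    mutant: str = "wildtype"  # wildtype | fz_like | vang_like
    active: bool = True
    # cell-cycle state (used by the growth module)
    phase: str = "waiting"  # waiting | growing
    wake_time: float = 0.0
    birth_volume: int = 0
    vt_total: float = 0.0  # current total target volume
    v_ref: float = 0.0  # reference volume for membrane sqrt-scaling
    mem_ref: dict = field(default_factory=dict)  # role -> target at v_ref

    @property
    def compartment_ids(self) -> list[int]:
        return list(self.comps.values())


@dataclass
class BoundaryConfig:
    """Signalling-boundary layout.

    modes: ``periodic`` (torus, no walls), ``left_distal_wall`` (frozen
    distal-typed wall on the left — the directional cue — with open medium on
    the right), ``left_lateral_wall`` (control wall with lateral contact
    properties), ``double_wall`` (distal wall left + proximal wall right),
    ``none`` (open medium all around is not supported; equals periodic).
    """

    mode: str = "periodic"
    wall_width: int = 3  # >= order-4 reach so cells never see past a wall
    open_margin: int = 12  # sites of open medium on the right, when open

    def __post_init__(self):
        if self.mode not in ("periodic", "none", "left_distal_wall",
                             "left_lateral_wall", "double_wall"):
            raise ValueError(f"unknown boundary mode {self.mode!r}")
        if self.wall_width < 3:
            raise ValueError("wall_width below the order-4 contact reach")

    @property
    def has_left_wall(self) -> bool:
        return self.mode in ("left_distal_wall", "left_lateral_wall", "double_wall")


@dataclass
class Tissue:
    """A full simulation state: lattice + registry + cells + protocol bits."""

    lattice: Lattice
    registry: CompartmentRegistry
    contact: ContactEnergyModel
    noise: NoiseModel
    cell_area: int
    boundary: BoundaryConfig
    cells: dict[int, Cell] = field(default_factory=dict)
    walls: list[int] = field(default_factory=list)
    wall_types: dict[int, int] = field(default_factory=dict)
    blocker: int | None = None
    time: float = 0.0
    next_cluster: int = 0
    grid_shape: tuple[int, int] = (0, 0)  # (n_cols, n_rows) of the seeded grid
    _seed_comps: dict[int, int] = field(default_factory=dict)

    @property
    def cell_diameter(self) -> float:
        return math.sqrt(self.cell_area)

    def wall_face_x(self) -> float:
        """x coordinate of the inner face of the left wall (0 if none)."""
        return float(self.boundary.wall_width) if self.boundary.has_left_wall else 0.0

    def cluster_of_sites(self) -> np.ndarray:
        return self.registry.cluster[: self.registry.n][self.lattice.sites]

    def sites_of_cluster(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_of_sites() == cluster_id)

    def run(self, n_mcs: int, **kw):
        log = run_mcs(self.lattice, self.registry, self.contact, self.noise,
                      n_mcs, **kw)
        self.time += n_mcs
        return log

    def valid_cells(self) -> list[Cell]:
        """Cells that carry a defined polarity vector (non-mutant)."""
        return [c for c in self.cells.values()
                if "proximal" in c.comps and "distal" in c.comps]


def regime_contact_model(name: str) -> ContactEnergyModel:
    if name == "autonomous":
        return ContactEnergyModel.autonomous()
    if name == "non_autonomous":
        return ContactEnergyModel.non_autonomous()
    raise ValueError(f"unknown parameter regime {name!r}")


# ---------------------------------------------------------------------------
# boundary walls


def build_boundary(lattice: Lattice, registry: CompartmentRegistry,
                   config: BoundaryConfig, cluster_start: int) -> list[int]:
    """Create frozen wall compartments per the boundary config.

    Walls are ordinary compartments with their own cluster IDs (so cells
    interact with them through the external J row of the wall's type), no
    volume constraint, and the frozen flag set.  Returns the wall IDs.
    """
    walls: list[int] = []
    grid = lattice.grid()
    if not config.has_left_wall:
        return walls
    if np.any(grid[:, : config.wall_width] != 0):
        raise ValueError("left wall region overlaps existing compartments")
    wtype = LAT if config.mode == "left_lateral_wall" else DIST
    wid = registry.new_compartment(wtype, cluster_start, 0.0, 0.0, frozen=True)
    grid[:, : config.wall_width] = wid
    walls.append(wid)
    if config.mode == "double_wall":
        if np.any(grid[:, -config.wall_width:] != 0):
            raise ValueError("right wall region overlaps existing compartments")
        pid = registry.new_compartment(PROX, cluster_start + 1, 0.0, 0.0,
                                       frozen=True)
        grid[:, -config.wall_width:] = pid
        walls.append(pid)
    lattice.boundary_mode_x = "fixed"
    lattice.recount_volumes(registry)
    return walls


def plan_lattice(n_cols: int, n_rows: int, cell_area: int,
                 boundary: BoundaryConfig,
                 extra_margin: int = 0) -> tuple[int, int, tuple[int, int]]:
    """Lattice dimensions and the x-extent [x0, x1) of the tissue interior."""
    s = int(round(math.sqrt(cell_area)))
    if s * s != cell_area:
        raise ValueError("cell_area must be a perfect square")
    height = n_rows * s
    tissue_w = n_cols * s
    if boundary.mode in ("periodic", "none"):
        return tissue_w, height, (0, tissue_w)
    w = boundary.wall_width
    if boundary.mode == "double_wall":
        return 2 * w + tissue_w, height, (w, w + tissue_w)
    width = w + tissue_w + boundary.open_margin + extra_margin
    return width, height, (w, w + tissue_w)


# ---------------------------------------------------------------------------
# seed-cell initialization


def initialize_seed_tissue(n_cols: int, n_rows: int, *,
                           cell_area: int = DEFAULT_CELL_AREA,
                           boundary: BoundaryConfig | None = None,
                           regime: str = "autonomous",
                           seed: int = 0,
                           temperature: float = DEFAULT_TEMPERATURE,
                           lambda_v: float = DEFAULT_LAMBDA_V,
                           relax_mcs: int = 10_000,
                           fill_budget_mcs: int = 20_000,
                           extra_margin: int = 0) -> Tissue:
    """Pack ``n_cols x n_rows`` seed cells into the lattice interior.

    Seeds are placed at random sites and grow under their volume constraint
    until no medium is left inside the tissue region, then boundaries relax
    for ``relax_mcs``.  Open margins are blocked by a frozen medium-typed
    compartment during this phase (energetically identical to medium) so
    that cells pack against the intended tissue box.
    """
    boundary = boundary or BoundaryConfig()
    width, height, (x0, x1) = plan_lattice(n_cols, n_rows, cell_area, boundary,
                                           extra_margin)
    lattice = Lattice(width, height)
    registry = CompartmentRegistry()
    contact = regime_contact_model(regime)
    noise = NoiseModel(temperature, seed)
    n_cells = n_cols * n_rows
    tissue = Tissue(lattice, registry, contact, noise, cell_area, boundary,
                    next_cluster=n_cells, grid_shape=(n_cols, n_rows))
    tissue.walls = build_boundary(lattice, registry, boundary, n_cells)
    tissue.next_cluster += len(tissue.walls)
    # walls are contact-neutral (seed-typed) while the tissue packs; their
    # signalling type switches on together with the PCP domains — otherwise
    # a medium film sticks to the wall (medium-distal adhesion is cheaper
    # than seed-distal) and the interior never fills
    for wid in tissue.walls:
        tissue.wall_types[wid] = int(registry.ctype[wid])
        registry.ctype[wid] = SEED

    # block any open medium so seeds pack the tissue box exactly
    grid = lattice.grid()
    open_cols = np.flatnonzero((np.arange(width) >= x1)
                               & (grid == 0).all(axis=0))
    if open_cols.size:
        # seed-typed so its contacts are neutral: a medium-typed blocker
        # attracts a stable medium film (medium-medium contact is free)
        bid = registry.new_compartment(SEED, tissue.next_cluster, 0.0, 0.0,
                                       frozen=True)
        tissue.next_cluster += 1
        grid[:, open_cols] = bid
        tissue.blocker = bid

    # drop seeds at distinct random interior sites
    rng = noise.rng
    interior = np.flatnonzero(lattice.sites == 0)
    pos = rng.choice(interior, size=n_cells, replace=False)
    for k in range(n_cells):
        cid = registry.new_compartment(SEED, k, float(cell_area), lambda_v)
        lattice.sites[pos[k]] = cid
        tissue._seed_comps[k] = cid
    lattice.recount_volumes(registry)

    # Grow until the interior is completely filled.  A Potts cell's
    # equilibrium volume sits a little below its target (boundary contact
    # cost), so targets are inflated by the per-cell share of the remaining
    # medium while filling; once the medium is extinct (it has no sites to
    # copy from, so it never returns) targets revert to the exact area.
    seed_ids = np.array(list(tissue._seed_comps.values()))
    done = 0
    while registry.volume[0] > 0:
        if done >= fill_budget_mcs:
            raise RuntimeError(
                f"seed cells failed to fill the lattice within "
                f"{fill_budget_mcs} MCS ({registry.volume[0]} medium sites left)")
        bump = min(0.3 * cell_area, float(registry.volume[0]) / n_cells)
        registry.target[seed_ids] = cell_area + bump
        tissue.run(50)
        done += 50
    registry.target[seed_ids] = float(cell_area)
    if relax_mcs > 0:
        tissue.run(relax_mcs)
    return tissue


def _arm_walls(tissue: Tissue) -> None:
    for wid, wtype in tissue.wall_types.items():
        tissue.registry.ctype[wid] = wtype
    tissue.wall_types = {}


def _melt_blocker(tissue: Tissue) -> None:
    if tissue.blocker is None:
        return
    bid = tissue.blocker
    mask = tissue.lattice.sites == bid
    tissue.lattice.sites[mask] = 0
    tissue.registry.frozen[bid] = False
    tissue.registry.volume[bid] = 0
    tissue.registry.volume[0] += int(mask.sum())
    tissue.blocker = None


# ---------------------------------------------------------------------------
# PCP domain assignment


def _new_cell_compartments(tissue: Tissue, cluster: int,
                           counts: dict[str, int], active: bool) -> Cell:
    reg = tissue.registry
    comps = {}
    for role in ("proximal", "distal", "lateral", "cytoplasm"):
        t = _TYPE_OF[role]
        if not active:
            t = _INACTIVE_OF[t]
        comps[role] = reg.new_compartment(t, cluster, float(counts[role]),
                                          reg.lam[tissue._seed_comps[cluster]]
                                          if cluster in tissue._seed_comps
                                          else DEFAULT_LAMBDA_V)
    total = sum(counts.values())
    return Cell(cluster_id=cluster, comps=comps, active=active,
                birth_volume=total, vt_total=float(total), v_ref=float(total),
                mem_ref={r: float(counts[r]) for r in _MEMBRANE})


def assign_pcp_domains(tissue: Tissue,
                       fractions: DomainFractions | None = None,
                       active: bool = True) -> Tissue:
    """Replace each seed cell by four PCP compartments at random positions.

    Sites are relabeled uniformly at random at the given fractions (exact
    per-cell counts, documented rounding), so the initial tissue carries no
    polarity pre-pattern.
    """
    fractions = fractions or DomainFractions()
    if not tissue._seed_comps:
        raise ValueError("tissue has no seed cells to compartmentalize")
    rng = tissue.noise.rng
    reg = tissue.registry
    for cluster, seed_id in sorted(tissue._seed_comps.items()):
        sites = np.flatnonzero(tissue.lattice.sites == seed_id)
        counts = domain_site_counts(sites.size, fractions)
        cell = _new_cell_compartments(tissue, cluster, counts, active)
        labels = np.concatenate([
            np.full(counts[r], cell.comps[r], dtype=np.int32)
            for r in ("proximal", "distal", "lateral", "cytoplasm")])
        rng.shuffle(labels)
        tissue.lattice.sites[sites] = labels
        reg.target[seed_id] = 0.0
        reg.lam[seed_id] = 0.0
        tissue.cells[cluster] = cell
    tissue._seed_comps = {}
    tissue.lattice.recount_volumes(reg)
    _arm_walls(tissue)
    _melt_blocker(tissue)
    return tissue


def assign_prepolarized_domains(tissue: Tissue,
                                fractions: DomainFractions | None = None,
                                axis: str = "x") -> Tissue:
    """Assign domains in bands so every cell starts perfectly polarized.

    For x-axis polarity the proximal sites occupy each cell's extreme-left
    band and distal its extreme-right band; lateral splits into top/bottom
    bands of the remainder and cytoplasm fills the centre.  Global order is
    ~1 by construction.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    fractions = fractions or DomainFractions()
    if not tissue._seed_comps:
        raise ValueError("tissue has no seed cells to compartmentalize")
    lat = tissue.lattice
    reg = tissue.registry
    for cluster, seed_id in sorted(tissue._seed_comps.items()):
        sites = np.flatnonzero(lat.sites == seed_id)
        counts = domain_site_counts(sites.size, fractions)
        cell = _new_cell_compartments(tissue, cluster, counts, True)
        x, y = lat.coords(sites)
        # band positions relative to the cell's own (periodic-aware) COM so
        # that cells straddling the torus seam band correctly
        px = lat.boundary_mode_x == "periodic"
        py = lat.boundary_mode_y == "periodic"
        xr = min_image(x - com_1d(x, lat.width, px), lat.width, px)
        yr = min_image(y - com_1d(y, lat.height, py), lat.height, py)
        main, ortho = (xr, yr) if axis == "x" else (yr, xr)
        order = np.lexsort((ortho, main))  # ascending along the polarity axis
        sites = sites[order]
        ortho = ortho[order]
        n_p, n_d = counts["proximal"], counts["distal"]
        lat.sites[sites[:n_p]] = cell.comps["proximal"]
        lat.sites[sites[sites.size - n_d:]] = cell.comps["distal"]
        middle = sites[n_p: sites.size - n_d]
        mo = np.argsort(ortho[n_p: sites.size - n_d], kind="stable")
        middle = middle[mo]
        n_l = counts["lateral"]
        half = n_l // 2
        lat.sites[middle[:half]] = cell.comps["lateral"]
        lat.sites[middle[middle.size - (n_l - half):]] = cell.comps["lateral"]
        lat.sites[middle[half: middle.size - (n_l - half)]] = cell.comps["cytoplasm"]
        reg.target[seed_id] = 0.0
        reg.lam[seed_id] = 0.0
        tissue.cells[cluster] = cell
    tissue._seed_comps = {}
    lat.recount_volumes(reg)
    _arm_walls(tissue)
    _melt_blocker(tissue)
    return tissue


# ---------------------------------------------------------------------------
# mutant clones and cascade activation


def make_mutant_patch(tissue: Tissue, cell_ids, kind: str) -> Tissue:
    """Convert selected wild-type cells into single-surface-domain mutants.

    ``fz_like`` cells keep only proximal surface domains (distal relabeled
    proximal, 30 % of volume in one type); ``vang_like`` is the mirror case.
    Mutant cells have no polarity vector and are excluded from all order
    parameters, but interact energetically like any other cell.
    """
    if kind not in ("fz_like", "vang_like"):
        raise ValueError(f"unknown mutant kind {kind!r}")
    cell_ids = list(cell_ids)
    if not cell_ids:
        import warnings
        warnings.warn("empty mutant selection: no-op")
        return tissue
    lose, keep = (("distal", "proximal") if kind == "fz_like"
                  else ("proximal", "distal"))
    reg = tissue.registry
    for cl in cell_ids:
        cell = tissue.cells[cl]
        if cell.mutant != "wildtype":
            raise ValueError(f"cell {cl} is already mutant")
        gone = cell.comps.pop(lose)
        kept = cell.comps[keep]
        tissue.lattice.sites[tissue.lattice.sites == gone] = kept
        reg.volume[kept] += reg.volume[gone]
        reg.target[kept] += reg.target[gone]
        reg.volume[gone] = 0
        reg.target[gone] = 0.0
        reg.lam[gone] = 0.0
        cell.mutant = kind
        cell.mem_ref = {keep: float(reg.target[kept]),
                        "lateral": cell.mem_ref["lateral"]}
    return tissue


def set_cell_active(tissue: Tissue, cluster_id: int, active: bool) -> None:
    """Toggle a cell between inactive (mixed) and active PCP energetics.

    Implemented as a registry type flip — no lattice rewrite."""
    cell = tissue.cells[cluster_id]
    reg = tissue.registry
    for cid in cell.compartment_ids:
        t = int(reg.ctype[cid])
        if active and t in _ACTIVE_OF:
            reg.ctype[cid] = _ACTIVE_OF[t]
        elif not active and t in _INACTIVE_OF:
            reg.ctype[cid] = _INACTIVE_OF[t]
    cell.active = active


# ---------------------------------------------------------------------------
# single-cell fixture


def build_single_cell(*, cell_area: int = DEFAULT_CELL_AREA,
                      regime: str = "autonomous", seed: int = 0,
                      temperature: float = DEFAULT_TEMPERATURE,
                      lambda_v: float = DEFAULT_LAMBDA_V,
                      fractions: DomainFractions | None = None,
                      margin: int = 6) -> Tissue:
    """An isolated cell with randomly mixed domains in a sea of medium.

    The canonical setup for the single-cell segregation experiments: the
    square cell block is labeled uniformly at random at the standard
    fractions; whether it sorts depends on the parameter regime.
    """
    fractions = fractions or DomainFractions()
    s = int(round(math.sqrt(cell_area)))
    size = s + 2 * margin
    lattice = Lattice(size, size)
    registry = CompartmentRegistry()
    contact = regime_contact_model(regime)
    noise = NoiseModel(temperature, seed)
    tissue = Tissue(lattice, registry, contact, noise, cell_area,
                    BoundaryConfig("periodic"), next_cluster=1,
                    grid_shape=(1, 1))
    counts = domain_site_counts(cell_area, fractions)
    tissue._seed_comps = {}
    cell = _new_cell_compartments(tissue, 0, counts, True)
    for role in cell.comps:
        registry.lam[cell.comps[role]] = lambda_v
    labels = np.concatenate([
        np.full(counts[r], cell.comps[r], dtype=np.int32)
        for r in ("proximal", "distal", "lateral", "cytoplasm")])
    noise.rng.shuffle(labels)
    tissue.lattice.grid()[margin: margin + s, margin: margin + s] = \
        labels.reshape(s, s)
    lattice.recount_volumes(registry)
    tissue.cells[0] = cell
    return tissue


def build_tissue(n_cols: int, n_rows: int, *,
                 boundary: BoundaryConfig | None = None,
                 regime: str = "autonomous",
                 cell_area: int = DEFAULT_CELL_AREA,
                 seed: int = 0,
                 temperature: float = DEFAULT_TEMPERATURE,
                 lambda_v: float = DEFAULT_LAMBDA_V,
                 relax_mcs: int = 10_000,
                 prepolarized: bool = False,
                 active: bool = True,
                 extra_margin: int = 0,
                 fractions: DomainFractions | None = None) -> Tissue:
    """Seed, pack, relax and compartmentalize a full tissue in one call."""
    tissue = initialize_seed_tissue(
        n_cols, n_rows, cell_area=cell_area, boundary=boundary, regime=regime,
        seed=seed, temperature=temperature, lambda_v=lambda_v,
        relax_mcs=relax_mcs, extra_margin=extra_margin)
    if prepolarized:
        assign_prepolarized_domains(tissue, fractions)
    else:
        assign_pcp_domains(tissue, fractions, active=active)
    return tissue
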