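"""Named, reproducible experiment protocols and their runner.

Each figure-level experiment protocol is encoded as an ExperimentSpec:
tissue geometry, parameter regime, boundary signal, growth policy, optional
mutant patch / maintenance / cascade protocol, MCS budget, sampling cadence
and replicate count.  Replicate k of a spec is a pure function of
``base_seed + k``.  Every spec also carries a "desk" profile — a reduced
variant (fewer replicates, shorter runs, sometimes smaller tissues) sized
for interactive use; ensemble means at desk scale carry correspondingly
larger Monte-Carlo error and, for runs cut before the plateau, lower phi.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .growth import GrowthPolicy, cascade_activation, run_with_growth
from .lattice import SEED, CompartmentRegistry, Lattice, NoiseModel
from .model import (
    DEFAULT_CELL_AREA, DEFAULT_LAMBDA_V, DEFAULT_TEMPERATURE,
    BoundaryConfig, Tissue, assign_pcp_domains,
    assign_prepolarized_domains, build_tissue, make_mutant_patch,
    regime_contact_model,
)
from . import metrics


@dataclass
class ExperimentSpec:
    """A fully serializable experiment protocol."""

    name: str
    n_cols: int = 8
    n_rows: int = 8
    regime: str = "autonomous"
    boundary_mode: str = "periodic"
    cell_area: int = DEFAULT_CELL_AREA
    mcs: int = 500_000
    sample_every: int = 2_000
    replicates: int = 100
    base_seed: int = 1000
    relax_mcs: int = 10_000
    prepolarized: bool = False
    hex_packing: bool = False
    mutant: dict | None = None  # {"kind": ..., "cols": [c0, c1], "rows": [r0, r1]}
    transient_wall_mcs: float | None = None
    growth: dict | None = None  # GrowthPolicy fields
    growth_target_cells: int | None = None  # sizes the open margin
    cascade: dict | None = None  # {"threshold": ..., "dwell_mcs": ...}
    desk: dict = field(default_factory=dict)  # field overrides at desk scale

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSpec":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentSpec":
        return cls.from_dict(yaml.safe_load(text))

    def spec_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def at_desk_scale(self) -> "ExperimentSpec":
        d = self.to_dict()
        overrides = d.pop("desk")
        d.update(overrides)
        d["desk"] = {}
        return ExperimentSpec(**d)

    # -- pieces -------------------------------------------------------------
    def boundary(self) -> BoundaryConfig:
        margin = 12
        if self.growth_target_cells:
            s = int(round(math.sqrt(self.cell_area)))
            need_cols = math.ceil(self.growth_target_cells / self.n_rows) + 2
            margin = max(margin, (need_cols - self.n_cols) * s + s)
        return BoundaryConfig(self.boundary_mode, open_margin=margin)

    def growth_policy(self) -> GrowthPolicy | None:
        return GrowthPolicy(**self.growth) if self.growth else None


# ---------------------------------------------------------------------------
# hexagonal fixture


def generate_hex_fixture(rows: int, cols: int,
                         cell_area: int = DEFAULT_CELL_AREA, *,
                         seed: int = 0,
                         temperature: float = DEFAULT_TEMPERATURE,
                         lambda_v: float = DEFAULT_LAMBDA_V,
                         regime: str = "autonomous") -> Tissue:
    """Perfectly hexagonally packed tissue of (near-)equal-area cells.

    Cell centres form offset rows (triangular lattice); each site joins its
    nearest centre under torus distance, which rasterizes a hexagonal tiling
    on the square site lattice.  Interior cells have exactly six neighbours.
    """
    a = int(round(math.sqrt(cell_area / (math.sqrt(3) / 2))))
    dy = int(round(a * math.sqrt(3) / 2))
    if a < 4 or dy < 4:
        raise ValueError("cell_area too small for a hexagonal tiling")
    if rows % 2:
        raise ValueError("rows must be even for periodic hexagonal packing")
    W, H = a * cols, dy * rows
    # the +0.25 offsets break site-to-center distance ties, which would
    # otherwise all fall to the lowest-index cell at the wrap seam
    cx = np.array([[(c + 0.5 * (r % 2)) * a + 0.25 for c in range(cols)]
                   for r in range(rows)], float).ravel()
    cy = np.array([[(r + 0.5) * dy + 0.25 for c in range(cols)]
                   for r in range(rows)], float).ravel()
    lattice = Lattice(W, H)
    registry = CompartmentRegistry()
    noise = NoiseModel(temperature, seed)
    tissue = Tissue(lattice, registry, regime_contact_model(regime), noise,
                    cell_area, BoundaryConfig("periodic"),
                    next_cluster=rows * cols, grid_shape=(cols, rows))
    idx = np.arange(lattice.n_sites)
    x, y = (idx % W) + 0.5, (idx // W) + 0.5
    dx = (x[:, None] - cx[None, :] + W / 2) % W - W / 2
    dyv = (y[:, None] - cy[None, :] + H / 2) % H - H / 2
    nearest = np.argmin(dx * dx + dyv * dyv, axis=1)
    for k in range(rows * cols):
        cid = registry.new_compartment(SEED, k, 0.0, lambda_v)
        tissue._seed_comps[k] = cid
        lattice.sites[nearest == k] = cid
    lattice.recount_volumes(registry)
    registry.target[1:registry.n] = registry.volume[1:registry.n].astype(float)
    return tissue


def cluster_adjacency(tissue: Tissue) -> dict[int, set[int]]:
    """Cluster -> set of order-1 adjacent clusters (walls/medium excluded)."""
    grid = tissue.lattice.grid()
    cl = tissue.registry.cluster[: tissue.registry.n][grid]
    adj: dict[int, set[int]] = {c: set() for c in tissue.cells} or {
        c: set() for c in np.unique(cl) if c >= 0}
    for shifted in (np.roll(cl, 1, 0), np.roll(cl, 1, 1)):
        pairs = np.stack([cl.ravel(), shifted.ravel()], 1)
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        for a, b in np.unique(pairs, axis=0):
            if a in adj and b in adj:
                adj[int(a)].add(int(b))
                adj[int(b)].add(int(a))
    return adj


# ---------------------------------------------------------------------------
# runner


@dataclass
class ReplicateResult:
    replicate: int
    seed: int
    phi: pd.DataFrame  # mcs, phi, n_cells
    final_cells: pd.DataFrame
    divisions: pd.DataFrame | None = None
    activation: dict | None = None
    tissue: Tissue | None = None


@dataclass
class ResultBundle:
    spec: ExperimentSpec
    replicates: list[ReplicateResult]

    @property
    def phi(self) -> pd.DataFrame:
        out = []
        for r in self.replicates:
            df = r.phi.copy()
            df.insert(0, "replicate", r.replicate)
            out.append(df)
        return pd.concat(out, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        g = self.phi.groupby("mcs")["phi"]
        return pd.DataFrame({"phi_mean": g.mean(),
                             "phi_se": g.sem(),
                             "n": g.size()}).reset_index()

    def final_phi(self) -> np.ndarray:
        return np.array([r.phi["phi"].iloc[-1] for r in self.replicates])

    def save(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"spec": self.spec.to_dict(), "hash": self.spec.spec_hash()}
        (out / "config.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
        self.phi.to_csv(out / "phi_series.csv", index=False)
        self.summary().to_csv(out / "phi_summary.csv", index=False)
        cells = []
        for r in self.replicates:
            df = r.final_cells.copy()
            df.insert(0, "replicate", r.replicate)
            cells.append(df)
        pd.concat(cells, ignore_index=True).to_csv(
            out / "cells_final.csv", index=False)
        div = [r.divisions.assign(replicate=r.replicate)
               for r in self.replicates if r.divisions is not None]
        if div:
            pd.concat(div, ignore_index=True).to_csv(
                out / "divisions.csv", index=False)


def _grid_position(tissue: Tissue, com_x: float, com_y: float) -> tuple[int, int]:
    d = tissue.cell_diameter
    col = int((com_x - tissue.wall_face_x()) // d)
    row = int(com_y // d)
    return (min(max(col, 0), tissue.grid_shape[0] - 1),
            min(max(row, 0), tissue.grid_shape[1] - 1))


def select_cells_in_rect(tissue: Tissue, cols: tuple[int, int],
                         rows: tuple[int, int]) -> list[int]:
    """Cluster IDs of cells whose COM falls in the half-open cell-grid
    rectangle [cols[0], cols[1]) x [rows[0], rows[1])."""
    out = []
    for r in metrics.tissue_polarity(tissue).itertuples():
        c, rw = _grid_position(tissue, r.com_x, r.com_y)
        if cols[0] <= c < cols[1] and rows[0] <= rw < rows[1]:
            out.append(int(r.cluster))
    return out


def remove_left_wall(tissue: Tissue) -> None:
    """Convert the (transient) left wall to open medium."""
    reg = tissue.registry
    for wid in tissue.walls:
        mask = tissue.lattice.sites == wid
        tissue.lattice.sites[mask] = 0
        reg.frozen[wid] = False
        reg.volume[0] += int(mask.sum())
        reg.volume[wid] = 0
    tissue.walls = []


def _build_for_spec(spec: ExperimentSpec, seed: int) -> Tissue:
    if spec.hex_packing:
        tissue = generate_hex_fixture(spec.n_rows, spec.n_cols,
                                      spec.cell_area, seed=seed,
                                      regime=spec.regime)
        if spec.prepolarized:
            assign_prepolarized_domains(tissue)
        else:
            assign_pcp_domains(tissue)
        return tissue
    return build_tissue(
        spec.n_cols, spec.n_rows, boundary=spec.boundary(),
        regime=spec.regime, cell_area=spec.cell_area, seed=seed,
        relax_mcs=spec.relax_mcs, prepolarized=spec.prepolarized,
        active=spec.cascade is None)


def run_replicate(spec: ExperimentSpec, k: int,
                  keep_tissue: bool = False) -> ReplicateResult:
    """Run replicate k of a spec (seed = base_seed + k)."""
    seed = spec.base_seed + k
    tissue = _build_for_spec(spec, seed)
    if spec.mutant:
        sel = select_cells_in_rect(tissue, tuple(spec.mutant["cols"]),
                                   tuple(spec.mutant["rows"]))
        make_mutant_patch(tissue, sel, spec.mutant["kind"])
    rows = []

    def sample(t: Tissue):
        df = metrics.tissue_polarity(t)
        phi = metrics.global_order(df[["nu_x", "nu_y"]].to_numpy()) \
            if len(df) else float("nan")
        rows.append({"mcs": t.time, "phi": phi, "n_cells": len(df)})

    policy = spec.growth_policy()
    divisions = None
    activation = None
    if spec.cascade is not None:
        activation = cascade_activation(tissue, budget_mcs=spec.mcs,
                                        **spec.cascade)
        sample(tissue)
    elif policy is not None:
        wall_end = spec.transient_wall_mcs
        engine = run_with_growth(tissue, policy, spec.mcs,
                                 sample_every=spec.sample_every,
                                 sample_fn=sample)
        divisions = pd.DataFrame([dataclasses.asdict(e) for e in engine.events])
        if wall_end is not None and tissue.time >= wall_end:
            remove_left_wall(tissue)
    else:
        done = 0
        while done < spec.mcs:
            step = min(spec.sample_every, spec.mcs - done)
            tissue.run(step)
            done += step
            if spec.transient_wall_mcs is not None and tissue.walls \
                    and tissue.time >= spec.transient_wall_mcs:
                remove_left_wall(tissue)
            sample(tissue)
    final = metrics.tissue_polarity(tissue)
    return ReplicateResult(k, seed, pd.DataFrame(rows), final, divisions,
                           activation, tissue if keep_tissue else None)


def run_experiment(spec: ExperimentSpec, *, desk: bool = False,
                   replicates: int | None = None, base_seed: int | None = None,
                   keep_tissues: bool = False, progress=None) -> ResultBundle:
    """Execute all replicates of a spec.  Replicate k depends only on
    base_seed + k, so any subset reproduces bit-identically."""
    if desk:
        spec = spec.at_desk_scale()
    if replicates is not None or base_seed is not None:
        d = spec.to_dict()
        if replicates is not None:
            d["replicates"] = replicates
        if base_seed is not None:
            d["base_seed"] = base_seed
        spec = ExperimentSpec(**d)
    results = []
    for k in range(spec.replicates):
        results.append(run_replicate(spec, k, keep_tissue=keep_tissues))
        if progress:
            progress(k + 1, spec.replicates)
    return ResultBundle(spec, results)


# ---------------------------------------------------------------------------
# the catalog


def builtin_specs() -> dict[str, ExperimentSpec]:
    """Named protocols for every figure-level experiment."""
    desk_small = {"replicates": 5, "mcs": 60_000, "relax_mcs": 2_000}
    specs = [
        ExperimentSpec("fig2_periodic_8x8", 8, 8, mcs=1_000_000,
                       desk=desk_small),
        ExperimentSpec("fig2_left_wall_8x8", 8, 8,
                       boundary_mode="left_distal_wall", mcs=1_000_000,
                       desk=desk_small),
        ExperimentSpec("fig2_lateral_wall_8x8", 8, 8,
                       boundary_mode="left_lateral_wall", mcs=1_000_000,
                       desk=desk_small),
        ExperimentSpec("fig2_mutant_fz", 12, 8,
                       boundary_mode="left_distal_wall", prepolarized=True,
                       mutant={"kind": "fz_like", "cols": [5, 7],
                               "rows": [3, 5]},
                       transient_wall_mcs=100_000.0, mcs=300_000,
                       desk={"replicates": 3, "mcs": 30_000,
                             "relax_mcs": 2_000,
                             "transient_wall_mcs": 10_000.0}),
        ExperimentSpec("fig2_mutant_vang", 12, 8,
                       boundary_mode="left_distal_wall", prepolarized=True,
                       mutant={"kind": "vang_like", "cols": [5, 7],
                               "rows": [3, 5]},
                       transient_wall_mcs=100_000.0, mcs=300_000,
                       desk={"replicates": 3, "mcs": 30_000,
                             "relax_mcs": 2_000,
                             "transient_wall_mcs": 10_000.0}),
        ExperimentSpec("fig3_periodic_30x30", 30, 30, mcs=1_000_000,
                       desk={"n_cols": 12, "n_rows": 12, "replicates": 3,
                             "mcs": 60_000, "relax_mcs": 2_000}),
        ExperimentSpec("fig3_wall_30x30", 30, 30,
                       boundary_mode="left_distal_wall", mcs=1_000_000,
                       desk={"n_cols": 12, "n_rows": 12, "replicates": 3,
                             "mcs": 60_000, "relax_mcs": 2_000}),
        ExperimentSpec("fig4_no_growth_20x10", 20, 10,
                       boundary_mode="left_distal_wall", mcs=1_000_000,
                       desk={"n_cols": 8, "n_rows": 4, "replicates": 3,
                             "mcs": 60_000, "relax_mcs": 2_000}),
        ExperimentSpec("fig4_front_growth", 4, 10,
                       boundary_mode="left_distal_wall", prepolarized=True,
                       growth={"mode": "front_only"},
                       growth_target_cells=900, mcs=4_000_000,
                       desk={"n_cols": 4, "n_rows": 4, "cell_area": 36,
                             "growth_target_cells": 60, "replicates": 2,
                             "mcs": 120_000, "relax_mcs": 1_000}),
        ExperimentSpec("fig4_uniform_growth", 4, 10,
                       boundary_mode="left_distal_wall", prepolarized=True,
                       growth={"mode": "uniform"},
                       growth_target_cells=900, mcs=4_000_000,
                       desk={"n_cols": 4, "n_rows": 4, "cell_area": 36,
                             "growth_target_cells": 60, "replicates": 2,
                             "mcs": 120_000, "relax_mcs": 1_000}),
        ExperimentSpec("s8_fast_growth", 4, 10,
                       boundary_mode="left_distal_wall", prepolarized=True,
                       growth={"mode": "uniform", "rate": 0.01},
                       growth_target_cells=900, mcs=600_000,
                       desk={"n_cols": 4, "n_rows": 4, "cell_area": 36,
                             "growth_target_cells": 60, "replicates": 2,
                             "mcs": 60_000, "relax_mcs": 1_000}),
        ExperimentSpec("s9_short_refractory", 4, 10,
                       boundary_mode="left_distal_wall", prepolarized=True,
                       growth={"mode": "uniform", "refractory_time": 1_000.0},
                       growth_target_cells=900, mcs=4_000_000,
                       desk={"n_cols": 4, "n_rows": 4, "cell_area": 36,
                             "growth_target_cells": 60, "replicates": 2,
                             "mcs": 120_000, "relax_mcs": 1_000}),
        ExperimentSpec("s11_major_axis_uniform", 4, 10,
                       boundary_mode="left_distal_wall", prepolarized=True,
                       growth={"mode": "uniform", "division_axis": "major"},
                       growth_target_cells=900, mcs=4_000_000,
                       desk={"n_cols": 4, "n_rows": 4, "cell_area": 36,
                             "growth_target_cells": 60, "replicates": 2,
                             "mcs": 120_000, "relax_mcs": 1_000}),
        ExperimentSpec("fig5_nonauto_periodic_30x30", 30, 30,
                       regime="non_autonomous", mcs=1_000_000,
                       desk={"n_cols": 8, "n_rows": 8, "replicates": 3,
                             "mcs": 60_000, "relax_mcs": 2_000}),
        ExperimentSpec("fig5_nonauto_wall_30x30", 30, 30,
                       regime="non_autonomous",
                       boundary_mode="left_distal_wall", mcs=1_000_000,
                       desk={"n_cols": 8, "n_rows": 8, "replicates": 3,
                             "mcs": 60_000, "relax_mcs": 2_000}),
        ExperimentSpec("s13_first_passage_10x10", 10, 10, mcs=1_000_000,
                       sample_every=1_000,
                       desk={"n_cols": 6, "n_rows": 6, "replicates": 3,
                             "mcs": 60_000, "relax_mcs": 2_000}),
        ExperimentSpec("s14_maintenance_10x10", 10, 10,
                       boundary_mode="left_distal_wall", prepolarized=True,
                       mcs=1_000_000,
                       desk={"replicates": 3, "mcs": 60_000,
                             "relax_mcs": 2_000}),
        ExperimentSpec("s15_hex_maintenance", 10, 10, hex_packing=True,
                       prepolarized=True, mcs=1_000_000,
                       desk={"n_cols": 6, "n_rows": 6, "replicates": 3,
                             "mcs": 60_000}),
        ExperimentSpec("s16_double_wall_10x10", 10, 10,
                       boundary_mode="double_wall", mcs=1_000_000,
                       desk={"n_cols": 8, "n_rows": 8, "replicates": 3,
                             "mcs": 60_000, "relax_mcs": 2_000}),
        ExperimentSpec("s16_cascade", 6, 6,
                       boundary_mode="left_distal_wall",
                       cascade={"threshold": 0.9, "dwell_mcs": 200.0},
                       mcs=500_000,
                       desk={"n_cols": 4, "n_rows": 4, "replicates": 2,
                             "mcs": 60_000, "relax_mcs": 2_000}),
    ]
    return {s.name: s for s in specs}
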