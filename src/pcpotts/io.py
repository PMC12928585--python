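"""Snapshot serialization and vector-field rendering.

Snapshots are compressed ``.npz`` containers holding the integer site map
plus the compartment table (id, type, cluster, V, V_t, lambda, frozen) and
metadata; the compartment table is also exportable as plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import CompartmentRegistry, Lattice, NoiseModel, TYPE_NAMES
from .model import BoundaryConfig, Cell, Tissue, regime_contact_model


def compartment_table(tissue: Tissue) -> pd.DataFrame:
    reg = tissue.registry
    n = reg.n
    return pd.DataFrame({
        "id": np.arange(n),
        "type": [TYPE_NAMES[int(t)] for t in reg.ctype[:n]],
        "cluster": reg.cluster[:n],
        "volume": reg.volume[:n],
        "target_volume": reg.target[:n],
        "lambda_v": reg.lam[:n],
        "frozen": reg.frozen[:n],
    })


def save_snapshot(tissue: Tissue, path, regime: str = "autonomous") -> None:
    reg = tissue.registry
    n = reg.n
    cells_meta = {
        str(c.cluster_id): {"comps": c.comps, "mutant": c.mutant,
                            "active": c.active}
        for c in tissue.cells.values()}
    meta = {
        "width": tissue.lattice.width, "height": tissue.lattice.height,
        "boundary_mode_x": tissue.lattice.boundary_mode_x,
        "boundary_mode_y": tissue.lattice.boundary_mode_y,
        "boundary": tissue.boundary.mode,
        "wall_width": tissue.boundary.wall_width,
        "cell_area": tissue.cell_area, "time": tissue.time,
        "temperature": tissue.noise.temperature,
        "regime": regime, "grid_shape": list(tissue.grid_shape),
        "walls": tissue.walls, "next_cluster": tissue.next_cluster,
        "cells": cells_meta,
    }
    np.savez_compressed(
        Path(path), sites=tissue.lattice.sites,
        ctype=reg.ctype[:n], cluster=reg.cluster[:n], volume=reg.volume[:n],
        target=reg.target[:n], lam=reg.lam[:n], frozen=reg.frozen[:n],
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_snapshot(path) -> Tissue:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        lattice = Lattice(meta["width"], meta["height"],
                          meta["boundary_mode_x"], meta["boundary_mode_y"])
        lattice.sites = z["sites"].astype(np.int32)
        reg = CompartmentRegistry()
        n = len(z["ctype"])
        while reg.ctype.size < n:
            reg._grow()
        reg.n = n
        reg.ctype[:n] = z["ctype"]
        reg.cluster[:n] = z["cluster"]
        reg.volume[:n] = z["volume"]
        reg.target[:n] = z["target"]
        reg.lam[:n] = z["lam"]
        reg.frozen[:n] = z["frozen"]
    tissue = Tissue(lattice, reg, regime_contact_model(meta["regime"]),
                    NoiseModel(meta["temperature"], 0), meta["cell_area"],
                    BoundaryConfig(meta["boundary"],
                                   wall_width=meta["wall_width"]),
                    time=meta["time"], next_cluster=meta["next_cluster"],
                    grid_shape=tuple(meta["grid_shape"]),
                    walls=list(meta["walls"]))
    for cid_s, c in meta["cells"].items():
        tissue.cells[int(cid_s)] = Cell(
            cluster_id=int(cid_s), comps=dict(c["comps"]),
            mutant=c["mutant"], active=c["active"])
    return tissue


def render_vector_field(tissue: Tissue, path=None, ax=None):
    """Polarity vector-field plot (one arrow per cell over the site map)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from . import metrics
    df = metrics.tissue_polarity(tissue)
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(6, 6))
    cl = tissue.registry.cluster[: tissue.registry.n][tissue.lattice.grid()]
    ax.imshow(np.where(cl >= 0, cl % 13, np.nan), cmap="Pastel1",
              interpolation="nearest", origin="upper")
    d = tissue.cell_diameter * 0.45
    ax.quiver(df.com_x, df.com_y, df.nu_x * d, df.nu_y * d, angles="xy",
              scale_units="xy", scale=1, width=0.004, color="k")
    ax.set_xticks([]), ax.set_yticks([])
    ax.set_title(f"t = {tissue.time:.0f} MCS")
    if own_fig and path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
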