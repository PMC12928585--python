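"""Polarity quantification: per-cell vectors, order parameters, timings.

Every cell gets a unit polarity vector nu = (r_prox - r_dist)/|.| from the
centres of mass of its proximal and distal compartments (periodic-aware).
The global order parameter is phi = |sum nu| / N in [0, 1]; phi_R(r) averages
alignment inside neighbourhoods of radius r (in cell diameters) and phi_B(r)
is the cumulative order of all cells within distance r of the signalling
wall.  Mutant cells and walls are excluded everywhere.

Sign convention: nu points from the distal toward the proximal compartment.
With a distal-typed wall on the left, proximal domains face the wall, so nu
points in -x while the tissue is conventionally drawn as polarized "to the
right"; all order parameters are invariant under this global sign choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import com_1d, min_image
from .model import TAU, Tissue

# ---------------------------------------------------------------------------
# centres of mass

_axis_com = com_1d


def compartment_com(tissue: Tissue, comp_id: int) -> tuple[float, float]:
    """Centre of mass of a compartment, circular-mean averaged on periodic axes."""
    lat = tissue.lattice
    sites = np.flatnonzero(lat.sites == comp_id)
    x, y = lat.coords(sites)
    return (_axis_com(x, lat.width, lat.boundary_mode_x == "periodic"),
            _axis_com(y, lat.height, lat.boundary_mode_y == "periodic"))


_min_image = min_image
_min_image_arr = min_image


@dataclass
class PolarityVector:
    cluster_id: int
    nu: tuple[float, float]
    angle: float  # degrees in (-180, 180]


def polarity_vector(tissue: Tissue, cell) -> PolarityVector | None:
    """Unit vector from the distal COM toward the proximal COM.

    None (undefined) for mutant cells or coincident COMs."""
    if "proximal" not in cell.comps or "distal" not in cell.comps:
        return None
    lat = tissue.lattice
    px, py = compartment_com(tissue, cell.comps["proximal"])
    dx_, dy_ = compartment_com(tissue, cell.comps["distal"])
    if any(math.isnan(v) for v in (px, py, dx_, dy_)):
        return None
    vx = _min_image(px - dx_, lat.width, lat.boundary_mode_x == "periodic")
    vy = _min_image(py - dy_, lat.height, lat.boundary_mode_y == "periodic")
    norm = math.hypot(vx, vy)
    if norm == 0.0:
        return None
    vx, vy = vx / norm, vy / norm
    ang = math.degrees(math.atan2(vy, vx))
    if ang <= -180.0:
        ang += 360.0
    return PolarityVector(cell.cluster_id, (vx, vy), ang)


def _all_compartment_coms(tissue: Tissue) -> tuple[np.ndarray, np.ndarray,
                                                   np.ndarray]:
    """(com_x, com_y, volume) arrays indexed by compartment ID, computed in
    one pass over the lattice (circular mean on periodic axes)."""
    lat = tissue.lattice
    n = tissue.registry.n
    sites = lat.sites
    counts = np.bincount(sites, minlength=n)[:n].astype(float)
    idx = np.arange(lat.n_sites)
    out = []
    for coords, extent, periodic in (
            (idx % lat.width, lat.width, lat.boundary_mode_x == "periodic"),
            (idx // lat.width, lat.height, lat.boundary_mode_y == "periodic")):
        with np.errstate(invalid="ignore"):
            if periodic:
                theta = coords * (2.0 * math.pi / extent)
                c = np.bincount(sites, weights=np.cos(theta), minlength=n)[:n]
                s = np.bincount(sites, weights=np.sin(theta), minlength=n)[:n]
                com = (np.arctan2(s, c) / (2.0 * math.pi) % 1.0) * extent
                com[counts == 0] = math.nan
            else:
                tot = np.bincount(sites, weights=coords, minlength=n)[:n]
                com = np.where(counts > 0, tot / np.maximum(counts, 1),
                               math.nan)
        out.append(com)
    return out[0], out[1], counts


def tissue_polarity(tissue: Tissue) -> pd.DataFrame:
    """Per-cell polarity table: cluster, nu_x, nu_y, angle, COM coordinates.

    Mutant cells and cells with coincident proximal/distal COMs are
    excluded."""
    lat = tissue.lattice
    comx, comy, vols = _all_compartment_coms(tissue)
    px = lat.boundary_mode_x == "periodic"
    py = lat.boundary_mode_y == "periodic"
    rows = []
    for cell in tissue.cells.values():
        if "proximal" not in cell.comps or "distal" not in cell.comps:
            continue
        p, d = cell.comps["proximal"], cell.comps["distal"]
        if vols[p] == 0 or vols[d] == 0:
            continue
        vx = _min_image(comx[p] - comx[d], lat.width, px)
        vy = _min_image(comy[p] - comy[d], lat.height, py)
        norm = math.hypot(vx, vy)
        if norm == 0.0 or math.isnan(norm):
            continue
        vx, vy = vx / norm, vy / norm
        ang = math.degrees(math.atan2(vy, vx))
        if ang <= -180.0:
            ang += 360.0
        ids = cell.compartment_ids
        w = vols[ids]
        if px:
            th = np.array([comx[i] for i in ids]) * (2 * math.pi / lat.width)
            cx = (math.atan2((w * np.sin(th)).sum(), (w * np.cos(th)).sum())
                  / (2 * math.pi) % 1.0) * lat.width
        else:
            cx = float((w * np.array([comx[i] for i in ids])).sum() / w.sum())
        if py:
            th = np.array([comy[i] for i in ids]) * (2 * math.pi / lat.height)
            cy = (math.atan2((w * np.sin(th)).sum(), (w * np.cos(th)).sum())
                  / (2 * math.pi) % 1.0) * lat.height
        else:
            cy = float((w * np.array([comy[i] for i in ids])).sum() / w.sum())
        rows.append({"cluster": cell.cluster_id, "nu_x": vx, "nu_y": vy,
                     "angle": ang, "com_x": cx, "com_y": cy})
    return pd.DataFrame(rows, columns=["cluster", "nu_x", "nu_y", "angle",
                                       "com_x", "com_y"])


# ---------------------------------------------------------------------------
# order parameters


def global_order(nu: np.ndarray) -> float:
    """phi = |sum nu| / N over an (N, 2) array of unit vectors."""
    nu = np.asarray(nu, dtype=float)
    if nu.ndim != 2 or nu.shape[0] == 0:
        raise ValueError("global order needs at least one polarity vector")
    return float(np.hypot(*nu.sum(axis=0)) / nu.shape[0])


def tissue_global_order(tissue: Tissue) -> float:
    df = tissue_polarity(tissue)
    return global_order(df[["nu_x", "nu_y"]].to_numpy())


def _pair_distances(com: np.ndarray, W: int, H: int,
                    periodic_x: bool, periodic_y: bool) -> np.ndarray:
    dx = com[:, None, 0] - com[None, :, 0]
    dy = com[:, None, 1] - com[None, :, 1]
    if periodic_x:
        dx = (dx + W / 2.0) % W - W / 2.0
    if periodic_y:
        dy = (dy + H / 2.0) % H - H / 2.0
    return np.hypot(dx, dy)


def radial_local_order(com: np.ndarray, nu: np.ndarray, r: float,
                       diameter: float, W: int, H: int,
                       periodic_x: bool = True,
                       periodic_y: bool = True) -> float:
    """phi_R(r): mean over reference cells of the alignment of all cells
    within r cell diameters (reference included; a neighbourless reference
    contributes 1)."""
    if r <= 0:
        raise ValueError("r must be positive")
    d = _pair_distances(np.asarray(com, float), W, H, periodic_x, periodic_y)
    within = d < r * diameter
    nu = np.asarray(nu, float)
    sums = within @ nu  # (N, 2) neighbourhood vector sums
    counts = within.sum(axis=1)
    return float(np.mean(np.hypot(sums[:, 0], sums[:, 1]) / counts))


def tissue_radial_order(tissue: Tissue, r: float) -> float:
    df = tissue_polarity(tissue)
    lat = tissue.lattice
    return radial_local_order(
        df[["com_x", "com_y"]].to_numpy(), df[["nu_x", "nu_y"]].to_numpy(),
        r, tissue.cell_diameter, lat.width, lat.height,
        lat.boundary_mode_x == "periodic", lat.boundary_mode_y == "periodic")


def boundary_local_order(com_x: np.ndarray, nu: np.ndarray, r: float,
                         wall_x: float, diameter: float) -> float:
    """phi_B(r): cumulative order of cells whose centres lie within r cell
    diameters of the wall's inner face."""
    if r <= 0:
        raise ValueError("r must be positive")
    sel = (np.asarray(com_x, float) - wall_x) < r * diameter
    if not sel.any():
        raise ValueError(f"no cells within {r} diameters of the boundary")
    return global_order(np.asarray(nu, float)[sel])


def tissue_boundary_order(tissue: Tissue, r: float) -> float:
    df = tissue_polarity(tissue)
    return boundary_local_order(
        df["com_x"].to_numpy(), df[["nu_x", "nu_y"]].to_numpy(),
        r, tissue.wall_face_x(), tissue.cell_diameter)


# ---------------------------------------------------------------------------
# time series statistics


def polarization_time(times: np.ndarray, phi: np.ndarray,
                      bin_width: float = 1000.0,
                      tol: float = 1.05) -> float | None:
    """Stabilization time of a phi(t) series.

    The series is cut into bins of ``bin_width`` MCS; the result is the left
    edge of the first bin whose within-bin variance is within ``tol`` of the
    minimum over bins.  None if no complete bin exists."""
    times = np.asarray(times, float)
    phi = np.asarray(phi, float)
    idx = np.floor(times / bin_width).astype(int)
    variances = {}
    for b in np.unique(idx):
        vals = phi[idx == b]
        if vals.size >= 2:
            variances[b] = float(vals.var())
    if not variances:
        return None
    vmin = min(variances.values())
    for b in sorted(variances):
        if variances[b] <= tol * vmin + 1e-15:
            return float(b * bin_width)
    return None


def first_passage_time(times: np.ndarray, phi: np.ndarray,
                       level: float = 0.5) -> float | None:
    """First time phi reaches ``level``; None if never."""
    hits = np.flatnonzero(np.asarray(phi, float) >= level)
    return float(np.asarray(times, float)[hits[0]]) if hits.size else None


def to_tau(mcs: float) -> float:
    return mcs / TAU


# ---------------------------------------------------------------------------
# compartment separation diagnostics


def separation_trace(tissue: Tissue, cell) -> tuple[float, int]:
    """(proximal-distal COM distance in cell diameters, shared interface).

    The interface counts order-1 adjacent site pairs between the cell's
    proximal and distal compartments (each unordered pair once)."""
    lat = tissue.lattice
    pid, did = cell.comps["proximal"], cell.comps["distal"]
    px, py = compartment_com(tissue, pid)
    dx_, dy_ = compartment_com(tissue, did)
    vx = _min_image(px - dx_, lat.width, lat.boundary_mode_x == "periodic")
    vy = _min_image(py - dy_, lat.height, lat.boundary_mode_y == "periodic")
    dist = math.hypot(vx, vy) / tissue.cell_diameter
    grid = lat.grid()
    interface = 0
    for shifted in (np.roll(grid, 1, axis=0), np.roll(grid, 1, axis=1)):
        interface += int(np.sum((grid == pid) & (shifted == did)))
        interface += int(np.sum((grid == did) & (shifted == pid)))
    return dist, interface


def segregation_time(tissue: Tissue, cell, *, max_mcs: int = 500,
                     plateau_window: int = 200, frac: float = 0.5,
                     settle: int = 15) -> float | None:
    """Single-cell domain-segregation (polarization) time in MCS.

    The cell counts as segregated from the first MCS at which the
    proximal-distal interface is closed and the COM separation has reached
    ``frac`` of its plateau (mean separation over the trailing
    ``plateau_window`` MCS), sustained for ``settle`` consecutive MCS.
    Calibrated operational definition; see docs/methods.md.  None if not
    reached within ``max_mcs``."""
    seps = np.empty(max_mcs)
    ifs = np.empty(max_mcs, dtype=int)
    for t in range(max_mcs):
        tissue.run(1)
        seps[t], ifs[t] = separation_trace(tissue, cell)
    plateau = seps[-plateau_window:].mean()
    run_zero = 0
    for t in range(max_mcs):
        if ifs[t] == 0 and seps[t] >= frac * plateau:
            run_zero += 1
            if run_zero == settle:
                return float(t + 2 - settle)
        else:
            run_zero = 0
    return None


# ---------------------------------------------------------------------------
# angle statistics


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.radians(np.asarray(angles_deg, float))
    m = math.degrees(math.atan2(np.sin(a).mean(), np.cos(a).mean()))
    return m + 360.0 if m <= -180.0 else m


@dataclass
class AngleStatistics:
    histogram: np.ndarray  # counts per bin
    bin_edges: np.ndarray  # degrees
    circular_mean: float  # degrees
    mean_positive: float | None  # split means (up/down populations)
    mean_negative: float | None


def angle_statistics(angles_deg: np.ndarray, n_bins: int = 24) -> AngleStatistics:
    angles = np.asarray(angles_deg, float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    hist, _ = np.histogram(angles, bins=edges)
    pos = angles[angles > 0]
    neg = angles[angles < 0]
    return AngleStatistics(
        histogram=hist, bin_edges=edges,
        circular_mean=circular_mean_deg(angles),
        mean_positive=circular_mean_deg(pos) if pos.size else None,
        mean_negative=circular_mean_deg(neg) if neg.size else None,
    )
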