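"""Square-lattice Potts engine with sub-cellular compartments.

State is a flat integer site map (site -> compartment ID, 0 = medium) plus a
registry of per-compartment attributes (type, cluster, volume, target volume,
volume-constraint weight, frozen flag).  The effective energy is

    H = sum_c lambda_c (V_c - Vt_c)^2  +  sum_{unordered pairs (i,j), d<=4th order} J(s_i, s_j)

where J is zero between sites of the same compartment, looked up in the
*internal* matrix for compartments sharing a cluster (the same biological
cell) and in the *external* matrix otherwise (medium has its own row).
Dynamics are Metropolis site-copy attempts: a random target site j, a random
source i among j's 3rd-order neighbours; accept if dH <= 0, else with
probability exp(-dH / T).

The contact sum counts each unordered site pair once.  This is a fixed
convention (the alternative, ordered counting, rescales every contact energy
by 2 and leaves the dynamics unchanged up to a redefinition of T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernel import pack_contact_tables, run_attempts_kernel

# ---------------------------------------------------------------------------
# compartment types

MEDIUM = 0
PROX = 1
DIST = 2
LAT = 3
CYTO = 4
SEED = 5
# "inactive" variants used by the cascade-activation protocol: same geometry,
# no sorting drive until the cell is switched on.
IPROX = 6
IDIST = 7
ILAT = 8
ICYTO = 9
N_TYPES = 10

TYPE_NAMES = {
    MEDIUM: "medium", PROX: "proximal", DIST: "distal", LAT: "lateral",
    CYTO: "cytoplasm", SEED: "seed", IPROX: "inactive_proximal",
    IDIST: "inactive_distal", ILAT: "inactive_lateral",
    ICYTO: "inactive_cytoplasm",
}

# ---------------------------------------------------------------------------
# neighbourhoods

_SHELLS = {
    1: [(1, 0), (-1, 0), (0, 1), (0, -1)],
    2: [(1, 1), (1, -1), (-1, 1), (-1, -1)],
    3: [(2, 0), (-2, 0), (0, 2), (0, -2)],
    4: [(2, 1), (2, -1), (-2, 1), (-2, -1), (1, 2), (1, -2), (-1, 2), (-1, -2)],
}


def neighbor_offsets(order: int) -> list[tuple[int, int]]:
    """Cumulative square-lattice neighbour shells.

    order 1 -> 4 offsets (von Neumann), 2 -> 8 (Moore), 3 -> 12, 4 -> 20.
    Enumeration order is fixed for reproducibility.
    """
    if order not in (1, 2, 3, 4):
        raise ValueError(f"neighbour order must be in 1..4, got {order!r}")
    out: list[tuple[int, int]] = []
    for k in range(1, order + 1):
        out.extend(_SHELLS[k])
    return out


# ---------------------------------------------------------------------------
# periodic geometry helpers


def com_1d(coords: np.ndarray, extent: int, periodic: bool) -> float:
    """Centre of mass along one axis; circular mean if the axis wraps."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        return math.nan
    if not periodic:
        return float(coords.mean())
    theta = coords * (2.0 * math.pi / extent)
    ang = math.atan2(np.sin(theta).mean(), np.cos(theta).mean())
    return (ang / (2.0 * math.pi) % 1.0) * extent


def min_image(d, extent: int, periodic: bool):
    """Minimum-image displacement(s) along one axis."""
    if periodic:
        return (d + extent / 2.0) % extent - extent / 2.0
    return d


# ---------------------------------------------------------------------------
# domain types


class ContactEnergyModel:
    """Internal (same-cell) and external (cross-cell + medium) contact matrices.

    Both are (N_TYPES x N_TYPES) symmetric float arrays indexed by compartment
    type; medium uses row/column 0 of the external matrix.
    """

    def __init__(self, internal_j: np.ndarray, external_J: np.ndarray):
        internal_j = np.asarray(internal_j, dtype=np.float64)
        external_J = np.asarray(external_J, dtype=np.float64)
        if internal_j.shape != (N_TYPES, N_TYPES) or external_J.shape != (N_TYPES, N_TYPES):
            raise ValueError("contact matrices must be (N_TYPES, N_TYPES)")
        if not np.allclose(internal_j, internal_j.T) or not np.allclose(external_J, external_J.T):
            raise ValueError("contact matrices must be symmetric")
        self.internal_j = internal_j
        self.external_J = external_J
        self._packed: np.ndarray | None = None

    def packed_table(self) -> np.ndarray:
        if self._packed is None:
            self._packed = pack_contact_tables(self.internal_j, self.external_J)
        return self._packed

    @staticmethod
    def _base_external() -> np.ndarray:
        J = np.zeros((N_TYPES, N_TYPES))

        def s(a, b, v):
            J[a, b] = J[b, a] = v

        s(PROX, PROX, 12); s(PROX, DIST, 7); s(PROX, LAT, 12); s(PROX, CYTO, 30)
        s(DIST, DIST, 12); s(DIST, LAT, 12); s(DIST, CYTO, 30)
        s(LAT, LAT, 14); s(LAT, CYTO, 30)
        s(CYTO, CYTO, 50)
        s(MEDIUM, PROX, 10); s(MEDIUM, DIST, 10); s(MEDIUM, LAT, 14)
        s(MEDIUM, CYTO, 30); s(MEDIUM, MEDIUM, 0)
        # transient seed cells: lateral-like neutral adhesion
        for t in range(N_TYPES):
            s(SEED, t, 14)
        s(SEED, SEED, 14)
        # inactive compartments mirror their active counterparts but carry no
        # proximal-distal cross-cell affinity (the pd value 7 becomes the
        # like-type value 12)
        mirror = {IPROX: PROX, IDIST: DIST, ILAT: LAT, ICYTO: CYTO}
        for it, at in mirror.items():
            for t in range(N_TYPES):
                src = mirror.get(t, t)
                v = J[at, src]
                if {at, src} == {PROX, DIST}:
                    v = 12.0
                s(it, t, v)
            s(it, MEDIUM, J[at, MEDIUM])
        s(SEED, IPROX, 14); s(SEED, IDIST, 14); s(SEED, ILAT, 14); s(SEED, ICYTO, 14)
        return J

    @classmethod
    def autonomous(cls) -> "ContactEnergyModel":
        """Fly-like regime: a lone cell sorts its own domains (j_pd = 30)."""
        j = np.ones((N_TYPES, N_TYPES))
        j[PROX, DIST] = j[DIST, PROX] = 30
        j[MEDIUM, :] = j[:, MEDIUM] = 0
        return cls(j, cls._base_external())

    @classmethod
    def non_autonomous(cls, internal: float = -1.0) -> "ContactEnergyModel":
        """Mouse-like regime: all internal contact energies negative, so
        domains stay mixed in an isolated cell and segregate only through
        neighbour coupling."""
        if internal >= 0:
            raise ValueError("non-autonomous internal energies must be negative")
        j = np.full((N_TYPES, N_TYPES), float(internal))
        j[MEDIUM, :] = j[:, MEDIUM] = 0
        return cls(j, cls._base_external())

    def pair_energy(self, a: int, b: int, registry: "CompartmentRegistry") -> float:
        """Contact energy of one unordered adjacent site pair with IDs a, b."""
        if a == b:
            return 0.0
        ta, tb = registry.ctype[a], registry.ctype[b]
        if a != 0 and b != 0 and registry.cluster[a] == registry.cluster[b]:
            return float(self.internal_j[ta, tb])
        return float(self.external_J[ta, tb])


def contact_energy_pair(a: int, b: int, model: ContactEnergyModel,
                        registry: "CompartmentRegistry") -> float:
    if a < 0 or a >= registry.n or b < 0 or b >= registry.n:
        raise KeyError(f"unknown compartment ID in pair ({a}, {b})")
    return model.pair_energy(a, b, registry)


@dataclass
class NoiseModel:
    """Metropolis temperature and the master RNG for a simulation."""

    temperature: float = 10.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        self.rng = np.random.default_rng(self.rng_seed)

    def kernel_seed(self) -> int:
        return int(self.rng.integers(1, 2**31 - 1))


class CompartmentRegistry:
    """Column store of per-compartment attributes, indexed by compartment ID.

    ID 0 is the medium (type MEDIUM, no volume constraint, cluster -1).
    """

    _CAP0 = 64

    def __init__(self):
        n = self._CAP0
        self.ctype = np.zeros(n, dtype=np.int8)
        self.cluster = np.full(n, -1, dtype=np.int64)
        self.volume = np.zeros(n, dtype=np.int64)
        self.target = np.zeros(n, dtype=np.float64)
        self.lam = np.zeros(n, dtype=np.float64)
        self.frozen = np.zeros(n, dtype=np.bool_)
        self.n = 1  # medium preallocated as ID 0

    def _grow(self):
        for name in ("ctype", "cluster", "volume", "target", "lam", "frozen"):
            arr = getattr(self, name)
            new = np.zeros(arr.size * 2, dtype=arr.dtype)
            if name == "cluster":
                new[:] = -1
            new[: arr.size] = arr
            setattr(self, name, new)

    def new_compartment(self, ctype: int, cluster: int, target: float,
                        lam: float, frozen: bool = False) -> int:
        if self.n == self.ctype.size:
            self._grow()
        cid = self.n
        self.n += 1
        self.ctype[cid] = ctype
        self.cluster[cid] = cluster
        self.volume[cid] = 0
        self.target[cid] = target
        self.lam[cid] = lam
        self.frozen[cid] = frozen
        return cid

    def views(self):
        """Trimmed array views handed to the update kernel."""
        n = self.n
        return (self.ctype[:n], self.cluster[:n], self.volume[:n],
                self.target[:n], self.lam[:n], self.frozen[:n])


class Lattice:
    """2D site grid mapping each site to a compartment ID.

    The update kernel always wraps (torus); non-periodic behaviour is realized
    by frozen wall compartments and medium rims.  ``boundary_mode_x/_y``
    record the *physical* boundary so that metrics know which axes wrap.
    """

    def __init__(self, width: int, height: int,
                 boundary_mode_x: str = "periodic",
                 boundary_mode_y: str = "periodic"):
        if width < 5 or height < 5:
            raise ValueError("lattice must be at least 5x5 for 4th-order contacts")
        for m in (boundary_mode_x, boundary_mode_y):
            if m not in ("periodic", "fixed"):
                raise ValueError(f"unknown boundary mode {m!r}")
        self.width = width
        self.height = height
        self.boundary_mode_x = boundary_mode_x
        self.boundary_mode_y = boundary_mode_y
        self.sites = np.zeros(width * height, dtype=np.int32)
        self._nbr3: np.ndarray | None = None
        self._nbr4: np.ndarray | None = None

    # -- geometry helpers ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.width * self.height

    def index(self, x, y):
        return (np.asarray(y) % self.height) * self.width + (np.asarray(x) % self.width)

    def coords(self, idx):
        idx = np.asarray(idx)
        return idx % self.width, idx // self.width

    def grid(self) -> np.ndarray:
        """Site map as a (height, width) array."""
        return self.sites.reshape(self.height, self.width)

    def _build_table(self, offsets) -> np.ndarray:
        W, H = self.width, self.height
        idx = np.arange(self.n_sites)
        x, y = idx % W, idx // W
        cols = [((y + dy) % H) * W + (x + dx) % W for dx, dy in offsets]
        return np.stack(cols, axis=1).astype(np.int32)

    @property
    def nbr3(self) -> np.ndarray:
        if self._nbr3 is None:
            self._nbr3 = self._build_table(neighbor_offsets(3))
        return self._nbr3

    @property
    def nbr4(self) -> np.ndarray:
        if self._nbr4 is None:
            self._nbr4 = self._build_table(neighbor_offsets(4))
        return self._nbr4

    def recount_volumes(self, registry: CompartmentRegistry) -> None:
        counts = np.bincount(self.sites, minlength=registry.n)
        registry.volume[: registry.n] = counts[: registry.n]


# ---------------------------------------------------------------------------
# energies


def total_energy(lattice: Lattice, registry: CompartmentRegistry,
                 model: ContactEnergyModel) -> float:
    """Brute-force H = H_V + H_C.  Oracle / diagnostic only (O(20 N))."""
    n = registry.n
    vols = registry.volume[:n].astype(np.float64)
    hv = float(np.sum(registry.lam[1:n] * (vols[1:] - registry.target[1:n]) ** 2))

    # each unordered pair once: half of the 20 order-4 offsets
    half = [(dx, dy) for dx, dy in neighbor_offsets(4)
            if (dy > 0) or (dy == 0 and dx > 0)]
    sites = lattice.sites
    W, H = lattice.width, lattice.height
    idx = np.arange(lattice.n_sites)
    x, y = idx % W, idx // W
    ct = registry.ctype[:n].astype(np.int64)
    cl = registry.cluster[:n]
    hc = 0.0
    for dx, dy in half:
        other = sites[((y + dy) % H) * W + (x + dx) % W]
        a, b = sites, other
        diff = a != b
        ta, tb = ct[a[diff]], ct[b[diff]]
        same_cell = (cl[a[diff]] == cl[b[diff]]) & (a[diff] != 0) & (b[diff] != 0)
        e = np.where(same_cell, model.internal_j[ta, tb], model.external_J[ta, tb])
        hc += float(e.sum())
    return hv + hc


def delta_H(site_i: int, site_j: int, lattice: Lattice,
            registry: CompartmentRegistry, model: ContactEnergyModel) -> float:
    """Incremental energy change of copying site i's ID over site j.

    Pure computation (no state change); exactly equals the brute-force
    total_energy difference.
    """
    si = int(lattice.sites[site_i])
    sj = int(lattice.sites[site_j])
    if si == sj:
        return 0.0
    dh = 0.0
    # volume terms of the two affected compartments
    if si != 0:
        v, t, lam = registry.volume[si], registry.target[si], registry.lam[si]
        dh += lam * ((v + 1 - t) ** 2 - (v - t) ** 2)
    if sj != 0:
        v, t, lam = registry.volume[sj], registry.target[sj], registry.lam[sj]
        dh += lam * ((v - 1 - t) ** 2 - (v - t) ** 2)
    # contact terms around j
    for k in lattice.nbr4[site_j]:
        sk = int(lattice.sites[k])
        dh += model.pair_energy(si, sk, registry) - model.pair_energy(sj, sk, registry)
    return float(dh)


# ---------------------------------------------------------------------------
# Metropolis dynamics


def metropolis_step(lattice: Lattice, registry: CompartmentRegistry,
                    model: ContactEnergyModel, noise: NoiseModel) -> bool:
    """One site-copy attempt (reference implementation; the MCS loop uses the
    compiled kernel).  Returns True if a flip was accepted."""
    rng = noise.rng
    j = int(rng.integers(lattice.n_sites))
    i = int(lattice.nbr3[j, rng.integers(12)])
    si, sj = int(lattice.sites[i]), int(lattice.sites[j])
    if si == sj:
        return False
    if registry.frozen[si] or registry.frozen[sj]:
        return False
    if sj != 0 and registry.volume[sj] <= 1:  # extinction guard
        return False
    dh = delta_H(i, j, lattice, registry, model)
    if dh > 0 and rng.random() >= math.exp(-dh / noise.temperature):
        return False
    lattice.sites[j] = si
    registry.volume[si] += 1
    registry.volume[sj] -= 1
    return True


@dataclass
class StepLog:
    """Per-chunk record of the MCS loop."""

    mcs: list = field(default_factory=list)
    attempts: list = field(default_factory=list)
    accepted: list = field(default_factory=list)
    dh: list = field(default_factory=list)

    @property
    def total_attempts(self) -> int:
        return int(sum(self.attempts))

    @property
    def total_accepted(self) -> int:
        return int(sum(self.accepted))

    def to_dataframe(self):
        """Tidy per-chunk table: mcs, attempts, accepted, acceptance_rate,
        cumulative energy change."""
        import pandas as pd

        df = pd.DataFrame({"mcs": self.mcs, "attempts": self.attempts,
                           "accepted": self.accepted, "delta_h": self.dh})
        df["acceptance_rate"] = df.accepted / df.attempts
        df["cumulative_delta_h"] = df.delta_h.cumsum()
        return df


def run_mcs(lattice: Lattice, registry: CompartmentRegistry,
            model: ContactEnergyModel, noise: NoiseModel, n_mcs: int, *,
            callback=None, callback_every: int = 100,
            log: StepLog | None = None) -> StepLog:
    """Run ``n_mcs`` Monte-Carlo steps (1 MCS = width*height copy attempts).

    ``callback(mcs_done)`` is invoked every ``callback_every`` MCS (and at the
    end); it may mutate targets / perform divisions between kernel chunks.
    Fully reproducible from the NoiseModel seed.
    """
    if n_mcs < 0:
        raise ValueError("n_mcs must be >= 0")
    log = log or StepLog()
    N = lattice.n_sites
    done = 0
    while done < n_mcs:
        chunk = min(callback_every, n_mcs - done) if callback else (n_mcs - done)
        attempts = chunk * N
        ct, cl, vol, tgt, lam, frz = registry.views()
        acc, dh = run_attempts_kernel(
            lattice.sites, lattice.nbr3, lattice.nbr4,
            ct, cl, vol, tgt, lam, frz,
            model.packed_table(),
            float(noise.temperature), attempts, noise.kernel_seed())
        done += chunk
        log.mcs.append(done)
        log.attempts.append(attempts)
        log.accepted.append(int(acc))
        log.dh.append(float(dh))
        if callback is not None:
            callback(done)
    return log
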