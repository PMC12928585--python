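# Methods

## Model

`pcpotts` implements a compartmental (sub-cellular) Cellular Potts /
Glazier–Graner–Hogeweg model of planar cell polarity (PCP).  Each epithelial
cell is a *cluster* of four compartments on a 2D square lattice — proximal,
distal, lateral and cytoplasm, at 15/15/20/50 % of cell volume — standing in
for the asymmetrically localized PCP protein complexes (Vang–Pk and
Fz–Dsh–Dgo in the fly nomenclature) and the rest of the cell.

The effective energy is

    H = Σ_c λ_V (V_c − V_t,c)²  +  Σ_{⟨i,j⟩ ≤ 4th order} J(σ_i, σ_j)

with each unordered site pair counted once (the ordered-pair alternative
rescales all contact energies by 2 and is dynamically equivalent).  `J` is
zero between sites of the same compartment, looked up in the *internal*
matrix `j` when the compartments share a cluster and in the *external*
matrix `J` otherwise; the medium (ID 0) has its own row.  Dynamics are
Metropolis site-copy attempts: a uniformly random target site, a uniformly
random source among its 12 third-order neighbours; accept if ΔH ≤ 0, else
with probability exp(−ΔH/T).  One Monte-Carlo step (MCS) is N attempts,
N = lattice site count.

Contact energies (autonomous regime): internal j_pd = 30, all other internal
pairs 1 — proximal and distal exclude each other inside a cell, with the
lateral domain buffering between them.  External: J_pd = 7 (the cross-cell
proximal–distal affinity that couples neighbour orientations), J_pp = J_dd =
J_pl = J_dl = 12, J_ll = 14, cytoplasm 30 against everything and 50 against
itself (keeps cytoplasm interior), medium row 10/10/14/30 and 0 with itself
(the open boundary has no proximal/distal preference).  The non-autonomous
regime sets every internal energy to −1 (all internal pairs like to mix), so
an isolated cell cannot sort its own domains and polarity arises only
through neighbour coupling.

### Parameters and calibration

| parameter | default | units | note |
|---|---|---|---|
| cell target area | 144 | sites | 12×12; consistent with the 0.001 sites/MCS growth rate ≡ 1.44·10⁵ MCS doubling |
| λ_V | 2 | energy/site² | volume-constraint weight |
| T | 15 | energy | Metropolis temperature |
| τ | ≈ 20 | MCS | single-cell polarization time; the model's time unit |
| growth rate | 0.001 | sites/MCS | per cell, total target volume |
| refractory time t_r | 10⁴ | MCS | max random delay before (re)growth |
| wall width | 3 | sites | ≥ 4th-order contact reach |

λ_V and T have no canonical values; they were calibrated with
`scripts/calibrate.py` in two stages.  (1) The single-cell polarization time
τ — operationally, the first MCS at which the proximal–distal interface is
closed and the COM separation exceeds half its plateau, sustained for 15
consecutive MCS — is ≈ 20 MCS; τ turns out to be only weakly sensitive to
(T, λ_V) in the scanned range, so this stage mostly fixes the operational
definition.  (2) T was then chosen to maximize the final polarization of
small (4×4, periodic) cell-autonomous tissues — the same optimization
criterion behind the contact-energy defaults.  T = 10 leaves small tissues permanently
trapped in antiparallel configurations; T = 15 anneals them reliably.
At this temperature 8×8 periodic tissues show a broad outcome spread on
10⁵-MCS horizons — some runs anneal to a ≈0.95 plateau while others linger
in swirled multi-domain states — so small-ensemble plateau means are noisy;
the operating point is therefore a property of this calibration, and we
report what the calibrated model computes.

### Initialization

Tissues start as single-compartment *seed* cells dropped at random lattice
sites, growing under their volume constraint until the tissue box contains
no medium, then relaxing (default 10⁴ MCS) into an irregular packing.  Two
devices make the fill robust: (i) open margins are blocked by a frozen,
contact-neutral compartment that is dissolved to medium when PCP starts, so
cells pack against the intended box; (ii) because a Potts cell's equilibrium
volume sits slightly below target (boundary contact cost), fill-phase
targets are inflated by the per-cell share of the remaining medium and
reset to the exact area once the medium is extinct (the medium cannot
re-nucleate: with zero sites it is never a copy source).  Walls are
contact-neutral during packing and acquire their signalling type (distal /
lateral / proximal) when PCP domains are assigned — otherwise a stable
medium film coats the wall and the interior never fills.

PCP domains are then assigned by relabeling each cell's sites uniformly at
random at exact per-cell counts (prox/dist rounded half-up, lateral floored,
cytoplasm the residual: 22/22/28/72 at 144 sites), imposing no pre-pattern;
the maintenance experiments instead band the compartments (proximal band on
the left of each cell, etc., computed in wrap-aware cell-local coordinates)
giving global order ≥ 0.99 by construction.

### Polarity sign convention

The polarity vector is ν = (r_prox − r_dist)/|·|, periodic-aware.  With a
distal-typed left wall, proximal domains adhere to the wall, so ν points in
−x while such tissues are conventionally drawn as polarized "to the right";
plots that follow that convention should draw −ν.  Every order parameter
(ϕ, ϕ_R, ϕ_B) is invariant under this global sign choice.  ϕ_R(r) includes
the reference cell in its own neighbourhood (a neighbourless reference
contributes 1); ϕ_B(r) bins from the inner wall face in one-cell-diameter
units; the cell diameter is √(target area) = 12 sites.

### Growth and division

Growing cells raise their total target volume at `rate` sites/MCS;
membrane-domain targets scale with √(total target) — an isoperimetric proxy
keeping the membrane band thickness and the 15:15:20 ratios constant —
and the cytoplasm absorbs the remainder.  A cell divides when its realized
volume reaches twice its birth volume: the cleavage line passes through the
COM along a principal axis of the site second-moment tensor ("minor-axis"
division splits the cell across its long dimension), each daughter receives
half of every domain (largest-remainder, ±1 site) at uniformly random
positions — daughters lose polarity and re-polarize from their neighbours —
and waits a uniform random fraction of t_r before growing again.
Degenerate (collinear) cells fall back to a coordinate-axis cleavage and are
logged.  Division bookkeeping runs between kernel chunks (default every 50
MCS), so realized division volumes can overshoot the threshold by the
growth accrued within a chunk (≪ 1 site at default rates).

### Cascade activation

For the staged-activation protocol, cells can be built with "inactive"
compartment types: internal energies all 1 (no sorting drive) and external
energies equal to the active ones except that the proximal–distal affinity
7 is replaced by the like-type value 12 (no coupling bias).  Activation
flips the compartment types in the registry — an O(1) switch with no
lattice rewrite.  Column k+1 activates after column k's mean local order
has exceeded a threshold (default 0.9) continuously for a dwell time
(default 10 τ); threshold and dwell are protocol constants exposed in the
config.

## Engine and numerics

The Metropolis loop is a single Numba kernel (~10⁷ attempts/s/core):
neighbour lookups via precomputed torus tables, both contact matrices packed
into one flat (same-cluster, type, type) table, xorshift64* RNG seeded per
chunk from the master `numpy` generator — trajectories are bit-reproducible
from (config, seed).  "Fixed" boundaries are realized physically (frozen
walls + medium rims) on the torus tables; metrics treat an axis as
non-periodic when walls occupy it.  Proposals into or out of frozen
compartments are rejected, as are proposals that would drop a live
compartment to zero volume (losing a surface domain would silently change
the model class; mutants are created explicitly instead).  Incremental ΔH
is exact: the test suite checks it against a brute-force total-energy
oracle proposal by proposal, and each kernel chunk returns Σ(accepted ΔH),
which must match the brute-force energy difference of the chunk.

No compartment-connectivity constraint is enforced; fragmented compartments
are legal and all COM-based metrics handle them.

## Mutant clones

`fz_like` cells have their distal compartment merged into the proximal one
(single surface type at 30 % of volume); `vang_like` is the mirror.  Mutant
cells carry no polarity vector and are excluded from every aggregate, but
interact energetically like any cell.  Wild-type cells on the distal side
of an fz-like clone re-orient toward it (domineering non-autonomy), on the
proximal side of a vang-like clone away from it.

## What the synthetic tissues do and do not emulate

All inputs are generated internally: there is no external data.  The
simulated tissues reproduce irregular epithelial packing, intercellular PCP
coupling, boundary cues, proliferation and clonal mosaics, but not cell
mechanics (stress, shear, vertex-style rearrangement), molecular pathway
dynamics, or 3D structure.  Passing tests therefore validate the patterning
logic of the compartment model, not quantitative biology of any specific
epithelium.

## Desk scales

Full-scale protocols (100 replicates, 10⁶–10⁷ MCS, up to 30×30 cells) are
encoded in the experiment catalog; the default test-suite and acceptance
runs use reduced "desk" profiles chosen so a complete pass takes tens of
minutes on one core: ensembles of 2–4 seeds, 4×10⁴–10⁵ MCS for 8×8
tissues (plateau means taken from the detected stabilization time onward),
30–80 seeds for single-cell statistics, and growth runs of 18 → ≥36 cells
at the default rate rather than 40 → 900.  Cell area cannot be scaled below
~100 sites: with ≤6-site membrane domains the polarity vector decorrelates
and pre-established order collapses, so desk growth runs keep 144-site
cells and scale the cell count instead.  Desk-scale ensemble means carry
larger Monte-Carlo error than the full protocols; expected deviations are
noted per experiment in the catalog.

## Known limitations

- T (and with it the coarsening speed and plateau height) is set by
  calibration, with the residual freedom described above.
- Stabilization detection (first bin whose variance is within 5 % of the
  minimal within-bin variance, 10³-MCS bins) is sensitive to bin width for
  short series.
- The hexagonal fixture rasterizes hexagons on the square site lattice from
  the integer-rounded triangular-lattice pitch, so its cell area is the
  nearest realizable value to the request (e.g. 143 for 144), equal across
  cells by construction.
- Lattices are allocated with their full growth margin up front; there is
  no dynamic re-allocation.
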