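"""Calibration of the Potts temperature and volume-constraint weight.

Reproduces how the package defaults (T = 15, lambda_V = 2) were fixed:

1. single-cell stage — scan (T, lambda_V) and report the mean single-cell
   polarization time tau (first sustained closure of the proximal-distal
   interface with COM separation above half its plateau); the model's time
   unit is defined by tau ~= 20 MCS;
2. tissue stage — scan T on small (4x4, periodic) tissues and report the
   mean final global polarization after 3e4 MCS; the production T maximizes
   small-tissue cell-autonomous polarization, mirroring how the published
   contact energies were chosen.

Usage: python scripts/calibrate.py [--seeds N] [--quick]
"""

import argparse

import numpy as np

from pcpotts.metrics import segregation_time, separation_trace, tissue_global_order
from pcpotts.model import build_single_cell, build_tissue


def single_cell_tau(T, lam, seeds, max_mcs=500):
    taus, seps = [], []
    for s in range(seeds):
        t = build_single_cell(seed=100 + s, temperature=T, lambda_v=lam)
        tau = segregation_time(t, t.cells[0], max_mcs=max_mcs)
        if tau is not None:
            taus.append(tau)
        seps.append(separation_trace(t, t.cells[0])[0])
    return (np.mean(taus) if taus else np.nan, len(taus),
            float(np.mean(seps)))


def tissue_phi(T, seeds, mcs=30_000):
    phis = []
    for s in range(seeds):
        t = build_tissue(4, 4, seed=1 + s, temperature=T, relax_mcs=2_000)
        t.run(mcs)
        phis.append(tissue_global_order(t))
    return float(np.mean(phis)), float(np.std(phis))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, default=20)
    ap.add_argument("--quick", action="store_true",
                    help="fewer seeds / shorter runs")
    args = ap.parse_args()
    seeds = 6 if args.quick else args.seeds
    mcs = 10_000 if args.quick else 30_000

    print("== single-cell polarization time (target ~20 MCS) ==")
    for T in (8.0, 10.0, 12.0, 15.0, 20.0):
        for lam in (1.0, 2.0):
            tau, n, sep = single_cell_tau(T, lam, seeds)
            print(f"T={T:5.1f} lambda={lam}: tau = {tau:6.1f} MCS "
                  f"(n={n}/{seeds}), plateau separation {sep:.2f} diam")

    print("== 4x4 tissue polarization (pick T maximizing phi) ==")
    for T in (10.0, 15.0, 20.0, 25.0):
        m, s = tissue_phi(T, max(3, seeds // 3), mcs)
        print(f"T={T:5.1f}: final phi = {m:.3f} +- {s:.3f}")


if __name__ == "__main__":
    main()
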