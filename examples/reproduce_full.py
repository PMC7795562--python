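"""Full-length reproduction protocol (overnight; hours per state point).

The published state points use extended starts, equilibrations of 1-12
million MC steps (drift-checked on Nc, Ic, Mc) and productions of 10^7
steps.  This script runs that protocol for a chosen set of state points;
each takes hours on one core, so points are run one at a time and every
run writes its complete output directory (time series, profiles, 2D
surface, snapshot, metadata).

    python examples/reproduce_full.py --point warm_c22 --out scratch/full

Desk-scale variants of the same pipeline live in the test suite and in
scripts/acceptance.py.
"""

import argparse

from hydrofold.experiment import run_experiment

STATE_POINTS = {
    # folded regime, warm water, low concentration
    "warm_c4.5": dict(scale=0, T_star=0.4, Np=2),
    # slight unfolding: minimum of F*(Nc) near 0.94
    "warm_c22": dict(scale=0, T_star=0.4, Np=10),
    # aggregation onset at ambient T: shallow F*(Ic) minimum near 0.1
    "ambient_c27": dict(scale=0, T_star=0.3, Np=12),
    # weakened hydrophobic-shell couplings at c = 11%
    "ambient_c11_s1": dict(scale=1, T_star=0.3, Np=5, steps_equil=12_000_000),
    "ambient_c11_s2": dict(scale=2, T_star=0.3, Np=5, steps_equil=12_000_000),
    "warm_c11_s1": dict(scale=1, T_star=0.4, Np=5, steps_equil=12_000_000),
    "warm_c11_s2": dict(scale=2, T_star=0.4, Np=5, steps_equil=12_000_000),
}

BASE = dict(
    L=40,
    P_star=0.0,
    start="extended",
    steps_water_anneal=10_000,
    steps_equil=2_000_000,
    steps_prod=10_000_000,
    record_stride=100,
    equil_window=2_000,
    seed=1,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--point", choices=sorted(STATE_POINTS), required=True)
    ap.add_argument("--out", default="scratch/full")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = {**BASE, **STATE_POINTS[args.point], "seed": args.seed}
    meta = run_experiment(cfg, f"{args.out}/{args.point}")
    print("equilibrated:", meta["equilibrated"])
    print("profile minima:", meta["profile_minima"])


if __name__ == "__main__":
    main()
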