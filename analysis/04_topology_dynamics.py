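#!/usr/bin/env python
"""Topology of early- vs late-regime time-point networks.

Computes the six per-network measures (out/in degree, clustering
coefficient, average path length, betweenness, reachability), compares each
network against 300 size-matched random sub-networks of the static network
(same per-type node counts, same backtrack + wiring), and runs the
hub-removal perturbation: early-regime networks should be more
interconnected and more robust, late ones modular and hub-fragile.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from retnetdyn import SimConfig, simulate_irn, simulate_regimes
from retnetdyn.network import summarize
from retnetdyn.topology import network_metrics, perturb_hubs, random_subnetwork_null


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-rand", type=int, default=300)
    ap.add_argument("--perturb-depth", type=int, default=10)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed)
    irn, _ = simulate_irn(cfg)
    subnets, manifest = simulate_regimes(cfg)

    payload = {}
    for i, sn in enumerate(subnets):
        regime = manifest["regimes"][sn.timepoint]
        rep = network_metrics(sn.subnet)
        s = summarize(sn.subnet)
        null = random_subnetwork_null(irn, s.n_tf, s.n_mirna, s.n_gene,
                                      n_rand=args.n_rand, seed=args.seed * 100 + i)
        curve = perturb_hubs(sn.subnet, args.perturb_depth)
        payload[sn.timepoint] = {
            "regime": regime,
            "metrics": rep.metrics(),
            "null_mean": null.mean,
            "null_sd": null.sd,
            "singletons": curve.singletons(),
        }
        print(f"{sn.timepoint:6s} [{regime:5s}] cc={rep.cc_mean:.3f} apl={rep.apl:.2f} "
              f"bw={rep.bw_mean:.1f} reach={rep.reach_mean:.3f} "
              f"singletons@{args.perturb_depth}={curve.singletons()[-1]}")

    early = [tp for tp, r in manifest["regimes"].items() if r == "early"]
    late = [tp for tp, r in manifest["regimes"].items() if r == "late"]
    cc = {tp: payload[tp]["metrics"]["cc_mean"] for tp in payload}
    print(f"mean clustering: early {np.mean([cc[t] for t in early]):.3f} "
          f"vs late {np.mean([cc[t] for t in late]):.3f} "
          f"(early > late: interconnected -> modular transition)")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "topology_dynamics.json").write_text(json.dumps(payload, indent=2) + "\n")


if __name__ == "__main__":
    main()
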