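#!/usr/bin/env python
"""Ca²⁺ transient analysis: representative P4 response plus recovery stats.

Generates a Fluo-3-style transient at the normozoospermic DGC medians
(ΔP4 1.9, τ-up 3.3 s, τ-down 17.7 s), extracts the descriptors, and measures
recovery error over 100 traces at 3% amplitude noise. Writes under
results/calcium/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from spermfx.calcium_kinetics import extract_kinetics, normalize_trace
from spermfx.synthetic_data import P4TraceTruth, make_p4_trace, p4_trace_spec
from spermfx.trace_io import write_trace


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", default="results/calcium")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    truth = P4TraceTruth(delta_p4=1.9, tau_up=3.3, tau_down=17.7,
                         iono_level=260.0, mn_level=40.0,
                         p4_time=10.0, iono_time=80.0, mn_time=90.0)
    amplitude = truth.delta_p4 * (100.0 - truth.mn_level)
    spec = p4_trace_spec(truth, noise_sd=0.03 * amplitude)
    trace = make_p4_trace(truth, spec, seed=args.seed)
    write_trace(trace, out / "representative_p4_trace.tsv")
    kin = extract_kinetics(normalize_trace(trace))
    print(f"ΔP4 = {kin.delta_p4:.2f} (truth 1.9), τ-up = {kin.tau_up:.2f} s "
          f"(truth 3.3), τ-down = {kin.tau_down:.2f} s (truth 17.7), "
          f"recovered = {kin.recovered}")

    seeds = np.random.SeedSequence(args.seed).generate_state(100) % (2**31)
    rel = []
    for s in seeds:
        k = extract_kinetics(normalize_trace(make_p4_trace(truth, spec, seed=int(s))))
        rel.append([abs(k.delta_p4 - 1.9) / 1.9, abs(k.tau_up - 3.3) / 3.3,
                    abs(k.tau_down - 17.7) / 17.7])
    med = np.median(rel, axis=0)
    print(f"median relative error over 100 traces (3% noise): "
          f"ΔP4 {med[0]:.1%}, τ-up {med[1]:.1%}, τ-down {med[2]:.1%}")
    (out / "ca_report.json").write_text(json.dumps({
        "delta_p4": kin.delta_p4, "tau_up_s": kin.tau_up,
        "tau_down_s": kin.tau_down, "recovered": kin.recovered,
        "recovery_median_rel_error": dict(zip(("delta_p4", "tau_up", "tau_down"),
                                              map(float, med))),
    }, indent=2))


if __name__ == "__main__":
    main()
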