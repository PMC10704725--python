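#!/usr/bin/env python
"""Donor-adjusted differential expression for every stimulation contrast.

Reads the simulated experiment written by 01_simulate_experiment.py,
computes size factors and trend-shrunk dispersions once, then runs the NB
Wald test of each condition against control.  The qualitative pattern the
analysis expects: many genes respond to IL-6, more to IL-6 + sIL-6Ra,
none to sIL-6Ra alone, none under Olamkicept (full trans blockade) and
almost none under Tocilizumab.
"""

import argparse
from pathlib import Path

import transsig as ts

CONTRASTS = ["il6", "sil6r", "il6_sil6r", "il6_sil6r_olamkicept",
             "il6_sil6r_tocilizumab"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", type=Path, default=Path("results/experiment"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/de"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    exp = ts.read_counts(args.in_dir / "counts.tsv",
                         metadata_path=args.in_dir / "metadata.csv")
    factors = ts.size_factors(exp)
    disp = ts.estimate_dispersion(exp, factors)
    for cond in CONTRASTS:
        de = ts.fit_de(exp, (cond, "control"), disp, factors)
        out = args.out_dir / f"de_{cond}_vs_control.tsv"
        ts.write_table(de.reset_index(), out)
        n_sig = int((de["q"] < 0.05).sum())
        n_up = int(((de["q"] < 0.05) & (de["log2fc"] > 0)).sum())
        print(f"{cond:>24} vs control: {n_sig:5d} DEGs (q<0.05), {n_up} up")


if __name__ == "__main__":
    main()
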