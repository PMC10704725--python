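#!/usr/bin/env python
"""Derive the trans-signaling signature through the three filters.

Runs the derivation on the packaged fixture, in which exactly five genes
satisfy every filter and four decoys each violate one: a low-baseline gene
(quartile filter), a sub-top-5% gene (fold-change filter), a gene that is
not core-enriched in the second validation dataset (GSEA filter), and an
IL-4/IL-13-sensitive gene (Th2 filter).  Writes the signature GMT and the
per-candidate provenance table.
"""

import argparse
from pathlib import Path

import transsig as ts


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/signature"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    de, baseline, datasets, th2, expected = ts.make_signature_fixture(args.seed)
    sig = ts.derive_signature(de, datasets=datasets, th2=th2,
                              baseline=baseline, seed=args.seed)
    ts.write_gmt(ts.GeneSetCollection(sets=[ts.GeneSet(
        name="IL6_TRANS_SIGNATURE",
        description="trans-signaling epithelial response signature",
        genes=sig.genes)]), args.out_dir / "signature.gmt")
    ts.write_table(sig.provenance.reset_index(),
                   args.out_dir / "provenance.tsv")
    print(f"signature ({len(sig.genes)} genes): {', '.join(sig.genes)}")
    print(f"planted truth recovered exactly: {sig.genes == expected}")
    dropped = sig.provenance.index[~sig.provenance['final']]
    print(f"candidates excluded by the filters: {', '.join(dropped)}")


if __name__ == "__main__":
    main()
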