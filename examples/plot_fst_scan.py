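#!/usr/bin/env python
"""Manhattan-style plot of a per-site FST scan TSV.

Usage: python examples/plot_fst_scan.py scan.tsv scan.png [--highlight 0.2]

Reads the TSV written by `zwscan fst-scan` and draws theta per SNP, colouring
loci above the highlight threshold. Requires matplotlib (not a package
dependency).
"""

import argparse

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("scan_tsv")
    ap.add_argument("out_png")
    ap.add_argument("--highlight", type=float, default=0.2)
    args = ap.parse_args()

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scan = pd.read_csv(args.scan_tsv, sep="\t")
    scan = scan.dropna(subset=["THETA"]).reset_index(drop=True)
    x = range(len(scan))
    hot = scan["THETA"] > args.highlight

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.scatter([i for i in x if not hot[i]], scan.loc[~hot, "THETA"], s=4, c="grey")
    ax.scatter([i for i in x if hot[i]], scan.loc[hot, "THETA"], s=10, c="red")
    # chromosome boundaries
    for _, group in scan.groupby("CHROM", sort=False):
        ax.axvline(group.index[-1] + 0.5, lw=0.3, c="lightgrey")
    ax.set_xlabel("SNP (ordered by chromosome, position)")
    ax.set_ylabel(r"$\theta$ (Weir–Cockerham)")
    ax.set_ylim(min(-0.1, scan["THETA"].min()), 1.05)
    fig.tight_layout()
    fig.savefig(args.out_png, dpi=150)
    print(f"wrote {args.out_png}: {int(hot.sum())} loci above {args.highlight}")


if __name__ == "__main__":
    main()
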