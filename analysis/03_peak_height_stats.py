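#!/usr/bin/env python
"""Compare FPKM heights of adjacent-FBE peaks to all peaks.

Mirrors the occupancy analysis: mean height of peaks with adjacent
elements vs all peaks (pooled-variance t-test), plus the Y479A
partnership-dependence split when category labels are present.
Writes results/stats/height_stats.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from fbekit.peak_stats import categorize_y479, mean_height, pooled_t_test


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pairs", type=Path, default=Path("results/scan/pairs.tsv"))
    ap.add_argument("--peaks", type=Path, default=Path("results/synthetic/peaks.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()

    peaks = pd.read_csv(args.peaks, sep="\t")
    pairs = pd.read_csv(args.pairs, sep="\t")
    adjacent = peaks[peaks.peak_id.isin(set(pairs.peak_id))]

    cmp_all = pooled_t_test(
        adjacent.height_wt, peaks.height_wt, "adjacent", "all"
    )
    rows = [
        {
            "comparison": "adjacent_vs_all",
            "mean_adjacent": cmp_all.mean_a,
            "mean_all": cmp_all.mean_b,
            "n_adjacent": cmp_all.n_a,
            "n_all": cmp_all.n_b,
            "t": cmp_all.t_statistic,
            "p": cmp_all.format_p(),
        }
    ]
    print(
        f"adjacent peaks: mean {cmp_all.mean_a:.0f} FPKM (n={cmp_all.n_a}) vs "
        f"all peaks {cmp_all.mean_b:.0f} FPKM (n={cmp_all.n_b}), "
        f"p = {cmp_all.format_p()}"
    )

    if "height_mut" in peaks.columns and peaks.height_mut.notna().any():
        adj = adjacent.dropna(subset=["height_mut"]).copy()
        adj["category"] = [
            categorize_y479(wt, mut) for wt, mut in zip(adj.height_wt, adj.height_mut)
        ]
        lower = adj[adj.category == "lower"].height_wt
        rest = adj[adj.category != "lower"].height_wt
        if len(lower) >= 2 and len(rest) >= 2:
            c = pooled_t_test(lower, rest, "lower", "not_lower")
            rows.append(
                {
                    "comparison": "y479a_lower_vs_rest",
                    "mean_adjacent": c.mean_a,
                    "mean_all": c.mean_b,
                    "n_adjacent": c.n_a,
                    "n_all": c.n_b,
                    "t": c.t_statistic,
                    "p": c.format_p(),
                }
            )
            print(
                f"partnership-dependent (lower in Y479A) peaks: mean "
                f"{c.mean_a:.0f} vs {c.mean_b:.0f} FPKM, p = {c.format_p()}"
            )

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out / "height_stats.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
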