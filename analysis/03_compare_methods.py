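#!/usr/bin/env python
"""Compare the automated endpoints to the clinical standard.

Produces the descriptive per-method summaries, paired
method-minus-clinical difference statistics (negative = automated date
earlier), agreement-within-window fractions, the Kruskal-Wallis omnibus
test over complete cases, and six Bonferroni-adjusted Wilcoxon
signed-rank pairwise tests.  Writes summary.json and a boxplot/scatter
figure of PFS by method.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from ehrpfs.compare import aggregate
from ehrpfs.io import read_cohort, read_results
from ehrpfs.pipeline import battery_to_jsonable, comparison_battery


def _plot(results, clinical_col, out_path):
    wide = aggregate(results)
    order = ["clinical", "steroid", "nlp", "volumetric"]
    cols = [c for c in order if c in wide.columns]
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    axes[0].boxplot(
        [wide[c].dropna() for c in cols], tick_labels=cols, showfliers=True
    )
    axes[0].set_ylabel("PFS (months from CRT end)")
    axes[0].set_title("PFS by derivation method")
    for c in cols:
        if c == clinical_col:
            continue
        paired = wide[[clinical_col, c]].dropna()
        axes[1].scatter(paired[clinical_col], paired[c], s=12, alpha=0.6, label=c)
    lim = wide.max().max()
    axes[1].plot([0, lim], [0, lim], color="darkgreen", lw=1)
    axes[1].set_xlabel("clinical-standard PFS (months)")
    axes[1].set_ylabel("automated PFS (months)")
    axes[1].legend()
    axes[1].set_title("automated vs clinical dates")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results/results.csv"))
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--window", type=float, default=2.0)
    parser.add_argument("--bonferroni-m", type=int, default=6)
    parser.add_argument("--out", type=Path, default=Path("results/summary.json"))
    parser.add_argument(
        "--plot", type=Path, default=Path("results/pfs_by_method.png")
    )
    args = parser.parse_args()

    results = read_results(args.results)
    cohort_n = len(read_cohort(args.cohort).patients)
    battery = comparison_battery(
        results, cohort_n, window_months=args.window, bonferroni_m=args.bonferroni_m
    )
    payload = battery_to_jsonable(battery)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(payload, indent=2) + "\n")
    _plot(results, "clinical", args.plot)

    print(f"wrote {args.out} and {args.plot}")
    for method, s in payload["summaries"].items():
        med = "-" if s["median_pfs"] is None else f"{s['median_pfs']:.1f}"
        mean = "-" if s["mean_pfs"] is None else f"{s['mean_pfs']:.1f}"
        print(
            f"  {method:>10}: {s['percent_progressed']}% progressed, "
            f"mean {mean} / median {med} months"
        )
    for method, d in payload["differences"].items():
        side = "later" if d["mean_diff"] > 0 else "earlier"
        print(
            f"  {method:>10} vs clinical: mean {d['mean_diff']:+.1f} months "
            f"({side}), n={d['n_pairs']}"
        )
    if payload["omnibus"]:
        o = payload["omnibus"]
        print(
            f"  omnibus: H={o['statistic']:.1f}, df={o['df']}, p={o['p_value']:.3g} "
            f"(complete cases n={payload['n_complete_cases']})"
        )
    for t in payload["pairwise"]:
        if t["degenerate"]:
            continue
        print(
            f"  {t['method_a']} vs {t['method_b']}: W={t['statistic']:.1f}, "
            f"p={t['p_value']:.3g}, adj={t['p_adjusted']:.3g}, n={t['n_pairs']}"
        )


if __name__ == "__main__":
    main()
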