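"""Partial correlations between fitted rate constants.

Loads the multistart fits written by 02_fit_schemes.py, relabels lobes for
lobe-structured schemes (lower first-binding K_D -> C lobe), and computes
the partial-correlation matrix with per-pair p-values.  Writes coefficient
and p-value CSVs and a heatmap per scheme.
"""

import argparse
import json
import pathlib

import pandas as pd

from camkin.nlme import theta_param_names
from camkin.param_analysis import (
    partial_correlation_matrix,
    plot_heatmap,
    relabel_lobes,
    significant_pairs,
)
from camkin.schemes import build_scheme


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fits", default="results/fits/S5")
    ap.add_argument("--schemes", nargs="+", default=["S5"])
    ap.add_argument("--method", default="pearson",
                    choices=["pearson", "spearman"])
    ap.add_argument("--out", default="results/correlations")
    args = ap.parse_args()

    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    for sid in args.schemes:
        spec = build_scheme(sid)
        payload = json.loads(
            (pathlib.Path(args.fits) / f"{sid}_fits.json").read_text())
        names = list(theta_param_names(spec))
        ensemble = pd.DataFrame([f["theta"] for f in payload["fits"]])[names]
        if sid in ("S4", "S5", "S6"):
            ensemble = relabel_lobes(ensemble, sid)
        if len(ensemble) < len(names) + 2:
            print(f"{sid}: only {len(ensemble)} fits for {len(names)} "
                  f"parameters - skipping (need >= p + 2 rows)")
            continue
        coef, pval = partial_correlation_matrix(ensemble, method=args.method)
        coef.to_csv(out / f"{sid}_partial_corr.csv")
        pval.to_csv(out / f"{sid}_pvalues.csv")
        sig = significant_pairs(coef, pval)
        print(f"{sid}: {len(sig)} of {len(names) * (len(names) - 1) // 2} "
              f"parameter pairs significantly partially correlated (p < 0.05)")
        for a, b in sig:
            print(f"    {a} ~ {b}: r = {coef.loc[a, b]:+.2f}")
        ax = plot_heatmap(coef, pval)
        ax.figure.savefig(out / f"{sid}_heatmap.png", dpi=120)


if __name__ == "__main__":
    main()
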