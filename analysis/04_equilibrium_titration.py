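"""Equilibrium titration curves for every scheme and parameter source.

Computes mean Ca2+ ions bound per calmodulin against clamped free Ca2+
over the experimentally probed range and writes results/titration.csv
plus a comparison figure.
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

from camkin.protocols import titration_curve
from camkin.schemes import available_rate_sets, build_scheme, load_rate_set


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    ap.add_argument("--points", type=int, default=60)
    args = ap.parse_args()

    grid = np.geomspace(1e-8, 1e-3, args.points)
    rows = []
    for sid, sources in available_rate_sets().items():
        spec = build_scheme(sid)
        for source in sources:
            rates = load_rate_set(sid, source)
            for p in titration_curve(spec, rates, grid):
                rows.append({"scheme": sid, "source": source,
                             "free_ca_M": p.free_ca,
                             "ca_per_cam": p.ca_per_cam})
    df = pd.DataFrame(rows)
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "titration.csv", index=False)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharex=True, sharey=True)
    for ax, sid in zip(axes.ravel(), sorted(available_rate_sets())):
        sub = df[df.scheme == sid]
        for source, curve in sub.groupby("source"):
            ax.semilogx(curve.free_ca_M, curve.ca_per_cam, label=source)
        ax.set_title(sid)
        ax.legend(fontsize=6)
    fig.supxlabel("free Ca (M)")
    fig.supylabel("Ca per CaM")
    fig.tight_layout()
    fig.savefig(out / "titration.png", dpi=120)
    print(f"wrote {len(df)} titration rows for "
          f"{df.groupby(['scheme', 'source']).ngroups} scheme/source "
          f"combinations to {out / 'titration.csv'}")
    half = df[(df.scheme == "S3") & (df.source == "shifman")]
    mid = half.iloc[(half.ca_per_cam - 2.0).abs().argmin()]
    print(f"e.g. the sequential scheme with published K_Ds reaches "
          f"2 Ca/CaM at free Ca ~ {mid.free_ca_M:.2e} M")


if __name__ == "__main__":
    main()
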