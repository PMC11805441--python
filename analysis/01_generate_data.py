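"""Generate a synthetic flash-uncaging + equilibrium data set.

Writes the recordings (long CSV + composition CSV), the equilibrium
titration CSV, and the ground truth JSON under results/data/<scheme>/.
"""

import argparse
import json
import pathlib

from camkin.fitting import preprocess_recordings
from camkin.forward_model import equilibrium_points_to_frame, recordings_to_frames
from camkin.synthetic import (
    GroundTruth,
    generate_equilibrium_dataset,
    generate_uncaging_dataset,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scheme", default="S5")
    ap.add_argument("--groups", type=int, default=7)
    ap.add_argument("--flashes", type=int, default=4)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/data")
    args = ap.parse_args()

    truth = GroundTruth.default(args.scheme, seed=args.seed)
    recordings, truth = generate_uncaging_dataset(truth, args.groups, args.flashes)
    recordings = preprocess_recordings(recordings)
    eq_points = generate_equilibrium_dataset(truth)

    out = pathlib.Path(args.out) / args.scheme
    out.mkdir(parents=True, exist_ok=True)
    traces, comps = recordings_to_frames(recordings)
    traces.to_csv(out / "traces.csv", index=False)
    comps.to_csv(out / "compositions.csv", index=False)
    equilibrium_points_to_frame(eq_points).to_csv(out / "equilibrium.csv",
                                                  index=False)
    (out / "truth.json").write_text(json.dumps({
        "scheme_id": truth.scheme_id,
        "rates": truth.rates.to_json_dict(),
        "mu": truth.mu, "omega": truth.omega,
        "sigma_dyn": truth.sigma_dyn, "sigma_eq": truth.sigma_eq,
        "seed": truth.seed, "eta": truth.eta,
    }, indent=2))

    peaks = [float(r.observed.max()) for r in recordings]
    print(f"wrote {len(recordings)} recordings "
          f"({args.groups} groups x {args.flashes} flashes) and "
          f"{len(eq_points)} equilibrium points to {out}")
    print(f"fluorescence-ratio peaks span {min(peaks):.2f} .. {max(peaks):.2f}; "
          f"flash strengths eta in "
          f"[{min(truth.eta.values()):.2f}, {max(truth.eta.values()):.2f}]")


if __name__ == "__main__":
    main()
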