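"""Compare fitted and published rate sets via test RMSE, AIC and Cohen's d.

For each requested scheme this script evaluates (a) the fits written by
02_fit_schemes.py and (b) the packaged published rate sets on the test
split of the data written by 01_generate_data.py, computing per-recording
RMSE, the Laplace-marginal AIC, the Welch t-test and Cohen's d between
fitted and published RMSE samples.  Writes results/comparison/<scheme>.csv.
"""

import argparse
import json
import pathlib

import pandas as pd

from camkin.compare import ComparisonTable, aic, parameter_count, relative_likelihood
from camkin.fitting import estimate_etas, split_data
from camkin.forward_model import ODESettings, equilibrium_points_from_frame, recordings_from_frames
from camkin.nlme import FixedEffects, NLMEProblem, rates_from_vector, theta_param_names
from camkin.schemes import BufferParams, available_rate_sets, build_scheme, load_rate_set
from camkin.synthetic import default_truth_rates

import numpy as np


def rmse_samples(spec, buffers, recordings, fixed, settings):
    from camkin.compare import rmse
    from camkin.nlme import NLMEProblem as P

    etas = estimate_etas(spec, buffers, recordings, fixed, settings)
    prob = P(spec, buffers, recordings, [], settings)
    preflash = prob.preflash_states(fixed.rates)
    out = []
    for i, rec in enumerate(recordings):
        pred = prob.predict_recording(fixed.rates, etas[rec.recording_id], i,
                                      preflash)
        out.append(rmse(rec.observed, pred))
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data/S5")
    ap.add_argument("--fits", default="results/fits/S5")
    ap.add_argument("--schemes", nargs="+", default=["S5"])
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/comparison")
    args = ap.parse_args()

    data = pathlib.Path(args.data)
    recordings = recordings_from_frames(pd.read_csv(data / "traces.csv"),
                                        pd.read_csv(data / "compositions.csv"))
    eq_points = equilibrium_points_from_frame(pd.read_csv(data / "equilibrium.csv"))
    plan = split_data(recordings, seed=args.seed, fractions=(0.6, 0.2, 0.2))
    test = plan.select(recordings, "test")
    buffers = BufferParams()
    settings = ODESettings(rtol=1e-6, atol=1e-12)

    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table = ComparisonTable()
    for sid in args.schemes:
        spec = build_scheme(sid)
        k = parameter_count(spec)
        fit_file = pathlib.Path(args.fits) / f"{sid}_fits.json"
        payload = json.loads(fit_file.read_text())
        names = theta_param_names(spec)
        rmses, aics = [], []
        for f in payload["fits"]:
            vec = np.array([f["theta"][n] for n in names])
            fixed = FixedEffects(
                rates=rates_from_vector(spec, vec, default_truth_rates(sid)),
                mu=f["mu"], omega=f["omega"], sigma_dyn=f["sigma_dyn"],
                sigma_eq=f["sigma_eq"])
            rmses.extend(rmse_samples(spec, buffers, test, fixed, settings))
            prob = NLMEProblem(spec, buffers, test, eq_points, settings)
            aics.append(aic(k, prob.laplace_marginal_loglik(fixed)))
        table.add(sid, "our fits", rmses, aics, k)

        for source in available_rate_sets().get(sid, []):
            if source == "our_fits":
                continue
            rates = load_rate_set(sid, source)
            fixed = FixedEffects(rates=rates, mu=0.0, omega=1.0,
                                 sigma_dyn=float(np.median([f["sigma_dyn"] for f in payload["fits"]])),
                                 sigma_eq=float(np.median([f["sigma_eq"] for f in payload["fits"]])))
            r = rmse_samples(spec, buffers, test, fixed, settings)
            prob = NLMEProblem(spec, buffers, test, eq_points, settings)
            a = aic(k, prob.laplace_marginal_loglik(fixed))
            table.add(sid, rates.source_label, r, [a], k)

    df = table.to_frame(reference_source="our fits")
    df.to_csv(out / "comparison.csv", index=False)
    print(df.to_string(index=False))
    for sid in args.schemes:
        rows = df[df.scheme == sid]
        ref = rows[rows.source == "our fits"]["aic_median"].iloc[0]
        for _, row in rows.iterrows():
            if row.source != "our fits":
                rl = relative_likelihood(ref, row.aic_median)
                print(f"{sid}: relative likelihood of '{row.source}' vs fitted "
                      f"rates = {rl:.3g}")


if __name__ == "__main__":
    main()
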