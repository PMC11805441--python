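"""Model-comparison statistics: RMSE, Welch's t, Cohen's d, AIC and
relative likelihoods, plus assembly of per-scheme comparison tables."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error, sqrt(mean((y - y_hat)^2))."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("y and y_hat must be equal-length and non-empty")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def welch_ttest(r1, r2) -> tuple[float, float]:
    """Two-sided two-sample t-test assuming unequal variances
    (Satterthwaite degrees of freedom)."""
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    if min(r1.size, r2.size) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(r1) == 0 and np.var(r2) == 0:
        if np.mean(r1) == np.mean(r2):
            return 0.0, 1.0
        return math.inf if np.mean(r1) > np.mean(r2) else -math.inf, 0.0
    t, p = stats.ttest_ind(r1, r2, equal_var=False)
    return float(t), float(p)


def cohens_d(r1, r2) -> float:
    """Absolute standardized mean difference with the pooled SD."""
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    n1, n2 = r1.size, r2.size
    if min(n1, n2) < 2:
        raise ValueError("each sample needs at least 2 values")
    s_pooled = math.sqrt(((n1 - 1) * np.var(r1, ddof=1)
                          + (n2 - 1) * np.var(r2, ddof=1)) / (n1 + n2 - 2))
    if s_pooled == 0:
        return 0.0 if np.mean(r1) == np.mean(r2) else math.inf
    return float(abs(np.mean(r1) - np.mean(r2)) / s_pooled)


def aic(k: int, marginal_loglik: float) -> float:
    """Akaike information criterion, 2k - 2L."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * marginal_loglik


def parameter_count(spec) -> int:
    """k for AIC: the scheme's rate parameters plus the noise SD of the
    evaluated observable and the random-effect prior parameters mu and
    omega (sigma counted once per observable present; test evaluations use
    the dynamical observable only, hence + 3)."""
    return len(spec.forward_slots) + len(spec.kd_names) + 3


def relative_likelihood(aic_ref: float, aic_other: float) -> float:
    """exp((AIC_ref - AIC_other) / 2), clipped to (0, 1] when the other
    model is no better than the reference."""
    r = math.exp((aic_ref - aic_other) / 2.0)
    return min(r, 1.0) if aic_other >= aic_ref else r


@dataclass
class ComparisonTable:
    """Per-(scheme, parameter-source) samples of test RMSE and AIC across
    seeds, with effect sizes against a designated reference source."""

    rows: dict[tuple[str, str], dict] = field(default_factory=dict)

    def add(self, scheme_id: str, source_label: str, rmse_samples, aic_samples,
            k: int):
        self.rows[(scheme_id, source_label)] = {
            "rmse": np.asarray(rmse_samples, float),
            "aic": np.asarray(aic_samples, float),
            "k": int(k),
        }

    def to_frame(self, reference_source: str = "our fits") -> pd.DataFrame:
        out = []
        for (scheme, source), row in self.rows.items():
            ref = self.rows.get((scheme, reference_source))
            d = t = p = math.nan
            if ref is not None and source != reference_source:
                try:
                    d = cohens_d(row["rmse"], ref["rmse"])
                    t, p = welch_ttest(row["rmse"], ref["rmse"])
                except ValueError:  # too few samples for an effect size
                    pass
            out.append({
                "scheme": scheme,
                "source": source,
                "k": row["k"],
                "rmse_mean": float(np.mean(row["rmse"])),
                "rmse_sd": float(np.std(row["rmse"], ddof=1))
                if row["rmse"].size > 1 else math.nan,
                "aic_median": float(np.median(row["aic"])),
                "cohens_d_vs_ref": d,
                "t_stat": t,
                "t_pvalue": p,
            })
        return pd.DataFrame(out)
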