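"""Post-fit parameter analysis: lobe relabeling and partial correlations.

Multistart/multiseed fits of the lobe-structured schemes are only
identified up to a swap of the two lobes, so before any across-fit
statistic the lobe carrying the lower first-binding dissociation constant
is relabeled as the C lobe (the physiological high-affinity lobe).
Partial correlations between the log10 parameters then diagnose sloppy,
mutually compensating parameter combinations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: per-scheme parameter blocks belonging to each structural lobe, and the
#: K_D(s) whose (summed log10) value defines the lobe's first-binding
#: affinity used for the relabeling comparison
_LOBE_BLOCKS = {
    "S4": {
        "C": ("k1", "KD1", "k3", "KD2"),
        "N": ("k5", "KD3", "k7", "KD4"),
        "affinity": {"C": ("KD1", "KD2"), "N": ("KD3", "KD4")},  # lumped K_D
    },
    "S5": {
        "C": ("k1", "KD1", "k3", "KD2"),
        "N": ("k5", "KD3", "k7", "KD4"),
        "affinity": {"C": ("KD1",), "N": ("KD3",)},
    },
    "S6": {
        "C": ("k1c", "KD1c", "k3c", "KD2c", "k5c", "KD3c", "k7c", "KD4c"),
        "N": ("k1n", "KD1n", "k3n", "KD2n", "k5n", "KD3n", "k7n", "KD4n"),
        "affinity": {"C": ("KD1c",), "N": ("KD1n",)},
    },
}


def relabel_lobes(ensemble: pd.DataFrame, scheme_id: str) -> pd.DataFrame:
    """Swap lobe parameter blocks row-wise so K_D(C) <= K_D(N).

    ``ensemble`` holds one fit per row, log10 parameters in columns named
    by slot.  Idempotent; schemes without independent lobes are rejected."""
    if scheme_id not in _LOBE_BLOCKS:
        raise ValueError("lobe relabeling applies to S4, S5 and S6 only")
    blocks = _LOBE_BLOCKS[scheme_id]
    out = ensemble.copy()
    for i in out.index:
        kd_c = sum(out.loc[i, k] for k in blocks["affinity"]["C"])
        kd_n = sum(out.loc[i, k] for k in blocks["affinity"]["N"])
        if kd_c > kd_n:
            c_vals = [out.loc[i, k] for k in blocks["C"]]
            n_vals = [out.loc[i, k] for k in blocks["N"]]
            for k, v in zip(blocks["C"], n_vals):
                out.loc[i, k] = v
            for k, v in zip(blocks["N"], c_vals):
                out.loc[i, k] = v
    return out


def partial_correlation_matrix(ensemble: pd.DataFrame, method: str = "pearson",
                               ridge: float = 1e-8,
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise partial correlations controlling for all other columns.

    Computed from the inverse of the column correlation matrix (precision
    matrix), with a ridge fallback when the correlation matrix is close to
    singular.  ``method='spearman'`` rank-transforms columns first (partial
    rank correlation).  p-values are two-sided t with n - p degrees of
    freedom (n rows, p columns, p - 2 controls per pair)."""
    x = ensemble.to_numpy(float)
    n, p = x.shape
    if n < p + 2:
        raise ValueError("need at least p + 2 rows for the partial-corr t-test")
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 0, x)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = np.corrcoef(x, rowvar=False)

    def _pc_from(c):
        try:
            prec = np.linalg.inv(c)
        except np.linalg.LinAlgError:
            return None
        d = np.diag(prec)
        if np.any(d <= 0) or not np.all(np.isfinite(prec)):
            return None
        out = -prec / np.sqrt(np.outer(d, d))
        np.fill_diagonal(out, 1.0)
        if not np.all(np.isfinite(out)) or np.any(np.abs(out) > 1 + 1e-8):
            return None
        return np.clip(out, -1.0, 1.0)

    pc = _pc_from(corr)
    r = ridge
    while pc is None and r <= 1e-2:
        pc = _pc_from(corr + r * np.eye(p))
        r *= 10.0
    if pc is None:
        raise RuntimeError("correlation matrix singular even with ridge")
    df = n - p  # n - 2 - (p - 2) controls
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = pc * np.sqrt(df / np.clip(1.0 - pc ** 2, 1e-300, None))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    np.fill_diagonal(pvals, 0.0)
    cols = ensemble.columns
    return (pd.DataFrame(pc, index=cols, columns=cols),
            pd.DataFrame(pvals, index=cols, columns=cols))


def significant_pairs(coefficients: pd.DataFrame, p_values: pd.DataFrame,
                      alpha: float = 0.05,
                      correction: str | None = None) -> list[tuple[str, str]]:
    """Upper-triangle pairs with p < alpha.

    ``correction='bh'`` applies Benjamini-Hochberg across the upper
    triangle; the default (no correction) marks raw p-values."""
    if coefficients.shape != p_values.shape:
        raise ValueError("matrices must be conformable")
    cols = list(coefficients.columns)
    iu = np.triu_indices(len(cols), k=1)
    pv = p_values.to_numpy()[iu]
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(pv, alpha=alpha, method="fdr_bh")
    elif correction is None:
        reject = pv < alpha
    else:
        raise ValueError("correction must be None or 'bh'")
    return [(cols[i], cols[j]) for i, j, r in zip(iu[0], iu[1], reject) if r]


def ensemble_from_fits(fits, spec) -> pd.DataFrame:
    """Stack the fitted log10 parameters of converged fits into a
    (fits x parameters) frame."""
    from .nlme import theta_param_names, theta_vector

    rows = []
    for f in fits:
        rows.append(theta_vector(f.theta_star, spec))
    return pd.DataFrame(rows, columns=list(theta_param_names(spec)))


def plot_heatmap(coefficients: pd.DataFrame, p_values: pd.DataFrame | None = None,
                 alpha: float = 0.05, ax=None):
    """Correlation heatmap with significance stars (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(coefficients.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(coefficients.columns)),
                  coefficients.columns, rotation=90)
    ax.set_yticks(range(len(coefficients.index)), coefficients.index)
    if p_values is not None:
        pv = p_values.to_numpy()
        for i in range(pv.shape[0]):
            for j in range(pv.shape[1]):
                if i != j and pv[i, j] < alpha:
                    ax.text(j, i, "*", ha="center", va="center")
    ax.figure.colorbar(im, ax=ax, label="partial correlation")
    return ax
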