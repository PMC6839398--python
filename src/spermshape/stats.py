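"""Statistical procedures for the sex-ratio-drive analyses.

Proportion standard errors and Z-tests, exact binomial tests, Holm and
Bonferroni corrections, Wilcoxon rank-sum and Kolmogorov-Smirnov tests, and
the beta regression of swim-up X proportions (logit link, precision
parameter) with likelihood-ratio testing between nested fits.

Counted sex ratios are modelled as proportions p-hat = k/n with
SE = sqrt(p(1-p)/n). The swim-up model explains the per-slide X proportion
by strain, live/dead state and fraction index ("segment"); the segment
enters numerically by default, so the headline quantity is a logit-scale
trend per fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.othermod.betareg import BetaModel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "se_proportion", "two_proportion_ztest", "one_sample_ztest",
    "binomial_test_two_tailed", "holm_bonferroni", "wilcoxon_ranksum",
    "ks_two_sample", "BetaRegResult", "betareg_fit", "likelihood_ratio_test",
    "swimup_report",
]


def se_proportion(k: int, n: int) -> float:
    """Standard error of a counted proportion: sqrt(p(1-p)/n), p = k/n."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = k / n
    return float(np.sqrt(p * (1.0 - p) / n))


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int,
                         continuity: bool = True) -> tuple[float, float]:
    """Two-tailed pooled two-proportions Z-test.

    With ``continuity`` (default) the Yates correction
    (1/n1 + 1/n2)/2 is subtracted from |p1 - p2| and floored at zero.
    A pooled proportion of exactly 0 or 1 has no sampling variance; the
    test returns (0, 1) with a warning in that degenerate case.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("invalid counts")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        warnings.warn("degenerate two-proportion test (zero pooled variance)")
        return 0.0, 1.0
    diff = abs(p1 - p2)
    if continuity:
        diff = max(0.0, diff - (1 / n1 + 1 / n2) / 2.0)
    z = diff / np.sqrt(var)
    z = float(np.sign(p1 - p2) * z)
    p = 2.0 * sps.norm.sf(abs(z))
    return z, float(p)


def one_sample_ztest(k: int, n: int, p0: float) -> tuple[float, float]:
    """One-sample Z-test of a proportion against ``p0``, two-tailed."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly in (0, 1)")
    p_hat = k / n
    z = (p_hat - p0) / np.sqrt(p0 * (1 - p0) / n)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def binomial_test_two_tailed(k: int, n: int, p0: float = 0.5,
                             method: str = "minlike") -> float:
    """Exact two-tailed binomial test.

    ``minlike`` (default) sums all outcomes no more likely than the
    observed one; ``doubled`` doubles the smaller one-sided tail (capped
    at 1).
    """
    if not 0 <= k <= n or n <= 0:
        raise ValueError("invalid counts")
    if method == "minlike":
        return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)
    if method == "doubled":
        lo = sps.binom.cdf(k, n, p0)
        hi = sps.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lo, hi)))
    raise ValueError(f"unknown method {method!r}")


def holm_bonferroni(pvalues, alpha: float = 0.05
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm adjustment; returns (adjusted p-values, reject flags)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(pvalues, alpha=alpha, method="holm")
    return adjusted, reject


def wilcoxon_ranksum(a, b) -> tuple[float, float]:
    """Two-tailed Wilcoxon rank-sum test; returns (W, p) with W the rank
    sum of the first sample.

    Exact enumeration for small tie-free samples (<= 20 combined values),
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if np.ptp(pooled) == 0:
        # all values identical: no evidence either way
        w = a.size * (pooled.size + 1) / 2.0
        return float(w), 1.0
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic + a.size * (a.size + 1) / 2.0)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return w, p


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample two-tailed Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# beta regression

@dataclass
class BetaRegResult:
    """Fitted beta regression of X proportions (logit mean link)."""

    coefficients: pd.Series
    phi: float
    llf: float
    n_params: int
    fitted: np.ndarray = field(repr=False)
    formula: str = ""
    converged: bool = True
    model_result: object = field(default=None, repr=False)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.model_result.conf_int(alpha)
        if not isinstance(ci, pd.DataFrame):
            ci = pd.DataFrame(ci, index=self.model_result.params.index)
        return ci


def _shrink_boundaries(y: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Move exact 0/1 proportions to the interior via (y(n-1)+0.5)/n."""
    y = y.astype(float).copy()
    at_bound = (y <= 0.0) | (y >= 1.0)
    if at_bound.any():
        y[at_bound] = (y[at_bound] * (n[at_bound] - 1) + 0.5) / n[at_bound]
    return y


def prepare_swimup(table: pd.DataFrame,
                   segment_numeric: bool = True) -> pd.DataFrame:
    """Attach the analysis columns (x_prop, total, segment) to a swim-up
    count table with male_id/genotype/state/fraction/x_count/y_count."""
    required = {"genotype", "state", "fraction", "x_count", "y_count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"swim-up table missing columns: {sorted(missing)}")
    df = table.copy()
    df["total"] = df["x_count"] + df["y_count"]
    if (df["total"] <= 0).any():
        raise ValueError("each analyzed row needs x_count + y_count > 0")
    df["x_prop"] = _shrink_boundaries(
        (df["x_count"] / df["total"]).to_numpy(), df["total"].to_numpy())
    df["segment"] = (df["fraction"].astype(float) if segment_numeric
                     else df["fraction"].astype(str))
    return df


def betareg_fit(table: pd.DataFrame,
                formula: str = "x_prop ~ C(genotype) * C(state) * segment",
                segment_numeric: bool = True,
                maxiter: int = 500) -> BetaRegResult:
    """Maximum-likelihood beta regression of the X proportion.

    The mean follows a logit link on the model formula (by default the
    full strain x state x segment interaction, segment numeric); a single
    precision parameter phi is estimated on the log scale. Proportions at
    the 0/1 boundary are shrunk inward before fitting because the beta
    likelihood is undefined there.
    """
    df = prepare_swimup(table, segment_numeric=segment_numeric)
    model = BetaModel.from_formula(formula, df)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise ValueError(
            f"rank-deficient design matrix ({rank} < {model.exog.shape[1]}); "
            "check for aliased factor combinations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=maxiter, disp=False)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(
            f"beta regression did not converge in {maxiter} iterations; "
            f"last log-likelihood {res.llf:.4f}")
    params = res.params
    phi = float(np.exp(params.iloc[-1]))  # precision fitted on log scale
    return BetaRegResult(coefficients=params, phi=phi, llf=float(res.llf),
                         n_params=len(params),
                         fitted=np.asarray(res.fittedvalues, dtype=float),
                         formula=formula, converged=True, model_result=res)


def likelihood_ratio_test(full: BetaRegResult, reduced: BetaRegResult,
                          tol: float = 1e-6) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square test of nested beta regressions."""
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than reduced")
    chi2 = 2.0 * (full.llf - reduced.llf)
    if chi2 < -tol:
        raise RuntimeError(
            "full-model log-likelihood below reduced model: optimizer failure")
    chi2 = max(chi2, 0.0)
    return float(chi2), int(df), float(sps.chi2.sf(chi2, df))


def swimup_report(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per genotype x state x fraction pooled X proportion with one-sample
    Z-tests against 0.5, Holm-corrected within each genotype x state series
    (the per-fraction enrichment calls of the swim-up figure)."""
    df = prepare_swimup(table)
    grouped = (df.groupby(["genotype", "state", "fraction"])
                 [["x_count", "total"]].sum().reset_index())
    grouped["x_proportion"] = grouped["x_count"] / grouped["total"]
    grouped["se"] = [se_proportion(int(k), int(n)) for k, n in
                     zip(grouped["x_count"], grouped["total"])]
    pvals = [one_sample_ztest(int(k), int(n), 0.5)[1]
             for k, n in zip(grouped["x_count"], grouped["total"])]
    grouped["p"] = pvals
    parts = []
    for _, sub in grouped.groupby(["genotype", "state"]):
        adj, rej = holm_bonferroni(sub["p"].to_numpy(), alpha=alpha)
        sub = sub.copy()
        sub["p_holm"] = adj
        sub["enriched"] = rej
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)
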