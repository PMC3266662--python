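"""Per-gene correlation with SPPR, Storey q-value FDR, and moderated
differential expression between conditions.

Correlation significance uses the exact t transform of the Pearson
coefficient, t = r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2 degrees of
freedom. The false discovery rate is estimated with Storey q-values:
pi0 is estimated on a lambda grid with a cubic-spline smoother evaluated at
the largest lambda, and q_(i) = min_{j >= i} pi0 * m * p_(j) / j.

Differential expression between conditions uses a per-gene linear model
with empirical-Bayes variance moderation: the per-gene residual variances
are shrunk toward a prior variance s0^2 with prior degrees of freedom d0,
both estimated by method of moments on the log-variance scale (mean and
trigamma-inverted spread), and moderated t statistics are referred to a
t distribution with d0 + d_g degrees of freedom. P-values are adjusted per
contrast with Benjamini-Hochberg; genes are called significant at
adjusted p < 0.05 and |log2 fold change| > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, special, stats


class CorrelationError(ValueError):
    """Invalid input to the correlation / DE analysis."""


# ---------------------------------------------------------------------------
# Pearson correlation to SPPR


def correlate_to_sppr(
    expr: pd.DataFrame,
    sppr: pd.Series,
    tail: str = "two-sided",
    log_sppr: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of every gene's expression with SPPR.

    Returns a DataFrame indexed by gene id with columns r, p, n. Genes with
    zero expression variance have undefined correlation; they are returned
    with NaN r/p and must be excluded before q-value estimation
    (:func:`estimate_qvalues` rejects NaN input).

    tail: 'two-sided' (default), 'greater' (H1: r > 0) or 'less'
    (H1: r < 0) — the one-sided forms feed the per-tail network analyses.
    """
    if expr.shape[1] < 3:
        raise CorrelationError("need at least 3 samples")
    if set(expr.columns) != set(sppr.index):
        raise CorrelationError("sample ids of expression and SPPR do not match")
    y = sppr.reindex(expr.columns).to_numpy(dtype=float)
    if log_sppr:
        y = np.log(y)
    x = expr.to_numpy(dtype=float)
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.where(sx == 0, np.nan, np.clip(r, -1.0, 1.0))
    p = correlation_pvalue(r, n, tail=tail)
    return pd.DataFrame({"r": r, "p": p, "n": n}, index=expr.index)


def correlation_pvalue(r, n: int, tail: str = "two-sided"):
    """P-value of a Pearson correlation via the exact t transform."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)
    if tail == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    elif tail == "greater":
        p = stats.t.sf(t, df=n - 2)
    elif tail == "less":
        p = stats.t.cdf(t, df=n - 2)
    else:
        raise CorrelationError(f"unknown tail {tail!r}")
    return np.where(np.isnan(r), np.nan, np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Storey q-values


def estimate_pi0(
    pvals: np.ndarray, lambdas: np.ndarray | None = None, method: str = "smoother"
) -> float:
    """Estimate the null proportion pi0.

    'smoother': pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) over the
    grid lambda in {0.05, ..., 0.95}, cubic-spline smoothed, evaluated at
    the largest lambda and clipped to (0, 1]. 'fixed': single-lambda
    estimate at lambdas[0].
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if method == "fixed" or lambdas.size < 4:
        pi0 = pi0_l[0] if lambdas.size == 1 else pi0_l[-1]
    elif method == "smoother":
        spline = interpolate.UnivariateSpline(lambdas, pi0_l, k=3)
        pi0 = float(spline(lambdas.max()))
    else:
        raise CorrelationError(f"unknown pi0 method {method!r}")
    return float(min(max(pi0, 1.0 / m), 1.0))


def estimate_qvalues(
    pvals, lambdas=None, pi0_method: str = "smoother"
) -> tuple[np.ndarray, float]:
    """Storey q-values; returns (q array in input order, pi0 estimate)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise CorrelationError("empty p-value list")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise CorrelationError("p-values must lie in [0, 1] and be non-missing")
    m = p.size
    pi0 = estimate_pi0(p, lambdas=lambdas, method=pi0_method)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def add_qvalues(records: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Attach a q column to a correlate_to_sppr result table.

    Zero-variance genes (NaN p) are excluded from the q-value computation
    and keep NaN q.
    """
    out = records.copy()
    valid = records["p"].notna()
    q = np.full(len(records), np.nan)
    if valid.any():
        q[valid.to_numpy()], pi0 = estimate_qvalues(
            records.loc[valid, "p"].to_numpy(), **kwargs
        )
        out.attrs["pi0"] = pi0
    out["q"] = q
    return out


# ---------------------------------------------------------------------------
# Significance selection and sensitivity to sample exclusion


@dataclass
class SelectionResult:
    positive: list[str]
    negative: list[str]
    achieved_fdr: float  # max q among selected genes (NaN if none selected)
    r_cut: float

    @property
    def n_selected(self) -> int:
        return len(self.positive) + len(self.negative)


def select_significant(records: pd.DataFrame, r_cut: float = 0.8) -> SelectionResult:
    """Partition genes at |r| > r_cut into positive/negative sets.

    The achieved FDR at the cut is the largest q-value among the selected
    genes (the q-value of the least significant selection).
    """
    if records.empty:
        raise CorrelationError("empty correlation table")
    if not 0 < r_cut < 1:
        raise CorrelationError("r_cut must lie strictly inside (0, 1)")
    sel = records[records["r"].abs() > r_cut]
    pos = sel.index[sel["r"] > 0].tolist()
    neg = sel.index[sel["r"] < 0].tolist()
    if "q" in records.columns and len(sel):
        fdr = float(sel["q"].max())
    else:
        fdr = float("nan")
    return SelectionResult(positive=pos, negative=neg, achieved_fdr=fdr, r_cut=r_cut)


@dataclass
class ExclusionResult:
    sample_id: str
    n_before: int
    n_after: int

    @property
    def relative_change(self) -> float:
        if self.n_before == 0:
            return float("nan")
        return (self.n_after - self.n_before) / self.n_before


def exclusion_sensitivity(
    expr: pd.DataFrame, sppr: pd.Series, sample_id: str, r_cut: float = 0.8
) -> ExclusionResult:
    """Count of |r| > r_cut genes before and after dropping one sample."""
    if sample_id not in expr.columns:
        raise CorrelationError(f"unknown sample id {sample_id!r}")
    if expr.shape[1] - 1 < 3:
        raise CorrelationError("exclusion would leave fewer than 3 samples")
    before = correlate_to_sppr(expr, sppr)
    after = correlate_to_sppr(expr.drop(columns=[sample_id]), sppr.drop(sample_id))
    n_before = int((before["r"].abs() > r_cut).sum())
    n_after = int((after["r"].abs() > r_cut).sum())
    return ExclusionResult(sample_id=sample_id, n_before=n_before, n_after=n_after)


# ---------------------------------------------------------------------------
# Moderated differential expression


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    On the log scale, e_g = log s2_g - digamma(df/2) + log(df/2) has mean
    log s0^2 - digamma(d0/2) + log(d0/2) and variance trigamma(df/2) +
    trigamma(d0/2); matching the observed mean and variance and inverting
    the trigamma gives (d0, s0^2). Returns d0 = inf when the observed
    spread is no larger than expected under a single common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-300)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) if e.size > 1 else 0.0
    target = e_var - special.polygamma(1, df / 2.0)
    if target <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        # solve trigamma(d0/2) = target for d0
        sol = optimize.brentq(
            lambda x: special.polygamma(1, x / 2.0) - target, 1e-3, 1e8
        )
        d0 = float(sol)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def differential_expression(
    expr: pd.DataFrame,
    condition_map: pd.Series,
    contrasts: list[tuple[str, str]],
    p_cut: float = 0.05,
    lfc_cut: float = 0.5,
) -> pd.DataFrame:
    """Moderated per-gene two-group comparisons for each contrast (a, b).

    log2FC is mean(a) - mean(b). Returns one row per gene and contrast with
    columns gene_id, contrast, log2fc, t, p, p_adj, significant.
    """
    results = []
    for a, b in contrasts:
        cols_a = condition_map.index[condition_map == a]
        cols_b = condition_map.index[condition_map == b]
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise CorrelationError(
                f"contrast {a} vs {b}: need >=2 replicates per condition"
            )
        xa = expr[cols_a].to_numpy(dtype=float)
        xb = expr[cols_b].to_numpy(dtype=float)
        na, nb = xa.shape[1], xb.shape[1]
        lfc = xa.mean(axis=1) - xb.mean(axis=1)
        df_g = na + nb - 2
        s2 = (
            ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            + ((xb - xb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        ) / df_g
        d0, s0_2 = _fit_variance_prior(s2, df_g)
        if np.isinf(d0):
            s2_mod = np.full_like(s2, s0_2)
            df_mod = np.inf
        else:
            s2_mod = (d0 * s0_2 + df_g * s2) / (d0 + df_g)
            df_mod = d0 + df_g
        se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / se
        if np.isinf(df_mod):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df=df_mod)
        p_adj = _benjamini_hochberg(p)
        results.append(
            pd.DataFrame(
                {
                    "gene_id": expr.index,
                    "contrast": f"{a}v{b}",
                    "log2fc": lfc,
                    "t": t,
                    "p": p,
                    "p_adj": p_adj,
                    "significant": (p_adj < p_cut) & (np.abs(lfc) > lfc_cut),
                }
            )
        )
    return pd.concat(results, ignore_index=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def unmoderated_ttest(
    expr: pd.DataFrame, condition_map: pd.Series, a: str, b: str
) -> pd.DataFrame:
    """Plain pooled-variance two-sample t per gene (reference, no shrinkage)."""
    cols_a = condition_map.index[condition_map == a]
    cols_b = condition_map.index[condition_map == b]
    t, p = stats.ttest_ind(
        expr[cols_a].to_numpy(dtype=float),
        expr[cols_b].to_numpy(dtype=float),
        axis=1,
        equal_var=True,
    )
    return pd.DataFrame(
        {
            "log2fc": expr[cols_a].mean(axis=1) - expr[cols_b].mean(axis=1),
            "t": t,
            "p": p,
        },
        index=expr.index,
    )
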