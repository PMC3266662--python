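"""TRAC-vs-array cross-platform calibration and functional-category
enrichment tests.

Calibration compares three nested ordinary-least-squares models of paired
signals (array_ij is the microarray signal of gene j in sample i, trac_ij
the corresponding TRAC signal):

* m0: array = alpha + beta * trac              (single intercept and slope)
* m1: array = alpha_j + beta * trac            (gene-specific intercepts)
* m2: array = alpha_j + beta_j * trac          (gene-specific slopes too)

The models are ranked with the Gaussian-likelihood AIC in the OLS form
AIC = n * ln(RSS / n) + 2 * n_params, with the same constant convention
across models so differences are comparable; ties go to the model with
fewer parameters.

Enrichment of functional categories in a gene set against a background uses
one-sided over-representation tests: hypergeometric for computationally
derived annotations, Fisher's exact test for manual ones (the two agree on
2x2 tables). '% of expressed' is the share of the query set carrying the
category, '% of annotated' the share of the category's background members
found in the query set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class CalibrationError(ValueError):
    """Invalid input to the calibration / enrichment analysis."""


@dataclass
class TracModelFit:
    model: str  # m0 / m1 / m2
    n_params: int
    rss: float
    aic: float
    sigma: float  # degrees-of-freedom-corrected residual SD
    slope: float | None  # global slope (m0/m1); None for m2
    intercepts: dict[str, float] = field(default_factory=dict)
    slopes: dict[str, float] = field(default_factory=dict)  # m2 only
    r_squared: float = float("nan")


@dataclass
class TracModelSelection:
    fits: dict[str, TracModelFit]
    selected: str

    @property
    def best(self) -> TracModelFit:
        return self.fits[self.selected]


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss = float(((y - x @ beta) ** 2).sum())
    return beta, rss


def fit_trac_models(table: pd.DataFrame) -> TracModelSelection:
    """Fit m0/m1/m2 to a paired table and select the lowest-AIC model.

    *table* has columns gene_id, trac_signal, array_signal. With a single
    gene m1 collapses to m0 (identical fit, more bookkeeping parameters),
    so m0 wins the AIC tie by parsimony. m2 requires >= 2 observations per
    gene, otherwise a per-gene slope is undetermined.
    """
    for col in ("gene_id", "trac_signal", "array_signal"):
        if col not in table.columns:
            raise CalibrationError(f"paired table missing column {col!r}")
    genes = sorted(table["gene_id"].unique())
    g_index = {g: i for i, g in enumerate(genes)}
    n = len(table)
    G = len(genes)
    y = table["array_signal"].to_numpy(dtype=float)
    trac = table["trac_signal"].to_numpy(dtype=float)
    g_col = np.array([g_index[g] for g in table["gene_id"]])
    counts = np.bincount(g_col, minlength=G)
    if counts.min() < 2:
        raise CalibrationError("need >= 2 observations per gene")
    if n <= 2:
        raise CalibrationError("need more than 2 observations overall")
    for g in genes:
        if np.ptp(trac[g_col == g_index[g]]) == 0:
            raise CalibrationError(f"gene {g}: degenerate TRAC signal")
    tss = float(((y - y.mean()) ** 2).sum())

    def aic(rss: float, k: int) -> float:
        return n * np.log(rss / n) + 2 * k

    # m0: common intercept and slope
    x0 = np.column_stack([np.ones(n), trac])
    b0, rss0 = _ols(x0, y)
    fit0 = TracModelFit(
        model="m0",
        n_params=2,
        rss=rss0,
        aic=aic(rss0, 2),
        sigma=float(np.sqrt(rss0 / (n - 2))),
        slope=float(b0[1]),
        intercepts={g: float(b0[0]) for g in genes},
        r_squared=1.0 - rss0 / tss,
    )
    # m1: gene-specific intercepts, shared slope
    x1 = np.zeros((n, G + 1))
    x1[np.arange(n), g_col] = 1.0
    x1[:, G] = trac
    b1, rss1 = _ols(x1, y)
    k1 = G + 1
    fit1 = TracModelFit(
        model="m1",
        n_params=k1,
        rss=rss1,
        aic=aic(rss1, k1),
        sigma=float(np.sqrt(rss1 / max(n - k1, 1))),
        slope=float(b1[G]),
        intercepts={g: float(b1[g_index[g]]) for g in genes},
        r_squared=1.0 - rss1 / tss,
    )
    # m2: gene-specific intercepts and slopes (independent per-gene OLS)
    rss2 = 0.0
    intercepts2: dict[str, float] = {}
    slopes2: dict[str, float] = {}
    for g in genes:
        m = g_col == g_index[g]
        xg = np.column_stack([np.ones(m.sum()), trac[m]])
        if np.ptp(trac[m]) == 0:
            raise CalibrationError(f"gene {g}: degenerate TRAC signal for m2")
        bg, rg = _ols(xg, y[m])
        rss2 += rg
        intercepts2[g] = float(bg[0])
        slopes2[g] = float(bg[1])
    k2 = 2 * G
    fit2 = TracModelFit(
        model="m2",
        n_params=k2,
        rss=rss2,
        aic=aic(rss2, k2),
        sigma=float(np.sqrt(rss2 / max(n - k2, 1))),
        slope=None,
        intercepts=intercepts2,
        slopes=slopes2,
        r_squared=1.0 - rss2 / tss,
    )
    fits = {"m0": fit0, "m1": fit1, "m2": fit2}
    # lowest AIC wins; ties (within float noise) go to fewer parameters
    selected = min(fits.values(), key=lambda f: (round(f.aic, 9), f.n_params)).model
    return TracModelSelection(fits=fits, selected=selected)


@dataclass
class EnrichmentResult:
    category: str
    hits: int
    set_size: int
    category_size: int
    background_size: int
    pct_of_expressed: float
    pct_of_annotated: float
    p: float


def enrichment_test(
    gene_set: Iterable[str],
    background: Iterable[str],
    category_map: Mapping[str, Sequence[str]] | pd.DataFrame,
    mode: str = "hypergeometric",
    p_cut: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided over-representation test per category.

    *category_map* is either a mapping gene -> categories or a DataFrame
    with columns gene_id, category. Only categories with at least one hit
    are tested; results with p < p_cut are returned sorted by p. No
    multiple-testing correction is applied (raw p cut-off).
    """
    genes = set(gene_set)
    bg = set(background)
    if not genes:
        raise CalibrationError("empty gene set")
    if not genes <= bg:
        raise CalibrationError("gene set is not a subset of the background")
    if mode not in ("hypergeometric", "fisher"):
        raise CalibrationError(f"unknown mode {mode!r}")
    if isinstance(category_map, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for g, c in category_map[["gene_id", "category"]].itertuples(index=False):
            mapping.setdefault(str(g), set()).add(str(c))
    else:
        mapping = {g: set(cs) for g, cs in category_map.items()}
    by_cat: dict[str, set[str]] = {}
    for g in bg:
        for c in mapping.get(g, ()):
            by_cat.setdefault(c, set()).add(g)
    N, n = len(bg), len(genes)
    results = []
    for cat, members in sorted(by_cat.items()):
        K = len(members)
        k = len(members & genes)
        if k == 0:
            continue
        if mode == "hypergeometric":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="greater")[1])
        if p < p_cut:
            results.append(
                EnrichmentResult(
                    category=cat,
                    hits=k,
                    set_size=n,
                    category_size=K,
                    background_size=N,
                    pct_of_expressed=100.0 * k / n,
                    pct_of_annotated=100.0 * k / K,
                    p=p,
                )
            )
    results.sort(key=lambda r: (r.p, r.category))
    return results


def enrichment_to_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "hits": r.hits,
                "set_size": r.set_size,
                "category_size": r.category_size,
                "background_size": r.background_size,
                "pct_of_expressed": r.pct_of_expressed,
                "pct_of_annotated": r.pct_of_annotated,
                "p": r.p,
            }
            for r in results
        ],
        columns=[
            "category",
            "hits",
            "set_size",
            "category_size",
            "background_size",
            "pct_of_expressed",
            "pct_of_annotated",
            "p",
        ],
    )
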