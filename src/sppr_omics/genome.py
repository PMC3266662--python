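"""Genome structure of the SPPR response: adjacent co-correlated gene pairs,
their permutation null, chromosomal cluster detection, promoter sharing,
and per-gene characteristic comparisons.

A qualifying pair is two chromosomally consecutive genes on the same
scaffold whose correlations to SPPR both exceed the cut in absolute value
and share a sign. A cluster is seeded by three consecutive qualifying genes
of the same sign and extended over flanking genes while the sign of the
correlation does not change (the extension requires only the sign by
default; magnitude-thresholded extension is available). Genes with r
exactly 0 terminate extension and never seed.

The permutation null keeps gene positions (and hence scaffold gene counts)
fixed and shuffles the correlation values over positions; the statistic is
the number of genes belonging to at least one qualifying pair, and the
p-value uses the add-one estimator p = (1 + #{perm >= obs}) / (1 + n_perm)
so that p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


class GenomeStructureError(ValueError):
    """Invalid input to the genome-structure analysis."""


def _per_scaffold(annotation: pd.DataFrame, correlations: pd.DataFrame):
    """Yield (scaffold_id, ordered gene ids, r values) per scaffold."""
    missing = set(correlations.index) - set(annotation["gene_id"])
    if missing:
        raise GenomeStructureError(
            f"genes in correlation table missing from annotation: {sorted(missing)[:5]}"
        )
    r_map = correlations["r"]
    for sc, sub in annotation.groupby("scaffold_id", sort=True):
        sub = sub.sort_values("start")
        genes = sub["gene_id"].to_numpy()
        r = r_map.reindex(genes).to_numpy(dtype=float)
        yield sc, genes, r


def _qualifying_pair_mask(r: np.ndarray, r_cut: float) -> np.ndarray:
    """Boolean mask over consecutive positions i: (i, i+1) is a qualifying pair."""
    with np.errstate(invalid="ignore"):
        ok = np.abs(r) > r_cut
    same_sign = np.sign(r[:-1]) * np.sign(r[1:]) > 0
    return ok[:-1] & ok[1:] & same_sign


def adjacent_qualifying_pairs(
    annotation: pd.DataFrame, correlations: pd.DataFrame, r_cut: float = 0.7
) -> pd.DataFrame:
    """Consecutive same-scaffold gene pairs with |r| > r_cut and equal sign."""
    rows = []
    for sc, genes, r in _per_scaffold(annotation, correlations):
        mask = _qualifying_pair_mask(r, r_cut)
        for i in np.flatnonzero(mask):
            rows.append(
                {
                    "scaffold_id": sc,
                    "gene1": genes[i],
                    "gene2": genes[i + 1],
                    "r1": r[i],
                    "r2": r[i + 1],
                    "sign": "+" if r[i] > 0 else "-",
                }
            )
    return pd.DataFrame(
        rows, columns=["scaffold_id", "gene1", "gene2", "r1", "r2", "sign"]
    )


def _genes_in_pairs_count(r_by_scaffold: list[np.ndarray], r_cut: float, sign) -> int:
    """Number of genes in >=1 qualifying pair (optionally restricted to a sign)."""
    total = 0
    for r in r_by_scaffold:
        mask = _qualifying_pair_mask(r, r_cut)
        if sign is not None:
            mask = mask & (np.sign(r[:-1]) == sign)
        in_pair = np.zeros(len(r), dtype=bool)
        idx = np.flatnonzero(mask)
        in_pair[idx] = True
        in_pair[idx + 1] = True
        total += int(in_pair.sum())
    return total


@dataclass
class PermutationResult:
    observed: int
    p: float
    n_perm: int
    null_mean: float
    null_sd: float


def pair_permutation_test(
    annotation: pd.DataFrame,
    correlations: pd.DataFrame,
    r_cut: float = 0.7,
    n_perm: int = 10_000,
    seed: int = 0,
    sign: int | None = None,
) -> PermutationResult:
    """Permutation p-value for the count of genes in qualifying pairs.

    sign: +1 / -1 restricts the statistic to pairs of that correlation sign;
    None counts both signs together.
    """
    if n_perm < 1:
        raise GenomeStructureError("n_perm must be >= 1")
    scaffolds = [r for _, _, r in _per_scaffold(annotation, correlations)]
    observed = _genes_in_pairs_count(scaffolds, r_cut, sign)
    rng = np.random.default_rng(seed)
    all_r = np.concatenate(scaffolds)
    sizes = [len(r) for r in scaffolds]
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(all_r)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        null[i] = _genes_in_pairs_count(parts, r_cut, sign)
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return PermutationResult(
        observed=observed,
        p=float(p),
        n_perm=n_perm,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
    )


@dataclass
class ChromosomalCluster:
    scaffold_id: str
    gene_ids: list[str]
    sign: str  # '+' or '-'
    seed_triplet: list[str]

    def validate(self, r_map: pd.Series, r_cut: float) -> None:
        assert set(self.seed_triplet) <= set(self.gene_ids)
        s = 1.0 if self.sign == "+" else -1.0
        seed_r = r_map.reindex(self.seed_triplet).to_numpy(dtype=float)
        assert np.all(np.abs(seed_r) > r_cut) and np.all(np.sign(seed_r) == s)
        r = r_map.reindex(self.gene_ids).to_numpy(dtype=float)
        assert np.all(np.sign(r) == s)


def detect_clusters(
    annotation: pd.DataFrame,
    correlations: pd.DataFrame,
    r_cut: float = 0.7,
    extend_requires_cut: bool = False,
) -> list[ChromosomalCluster]:
    """Chromosomal clusters of consecutive co-correlated genes.

    Each maximal same-sign run of consecutive genes that contains a seed
    triplet (three consecutive genes all |r| > r_cut, same sign) is reported
    once; the run's full extent is the cluster because extension stops only
    at a sign change (or at genes below the cut if extend_requires_cut).
    """
    clusters: list[ChromosomalCluster] = []
    for sc, genes, r in _per_scaffold(annotation, correlations):
        signs = np.sign(np.nan_to_num(r, nan=0.0))
        if extend_requires_cut:
            with np.errstate(invalid="ignore"):
                signs = np.where(np.abs(np.nan_to_num(r, nan=0.0)) > r_cut, signs, 0.0)
        i = 0
        n = len(genes)
        while i < n:
            if signs[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < n and signs[j + 1] == signs[i]:
                j += 1
            run = slice(i, j + 1)
            with np.errstate(invalid="ignore"):
                strong = np.abs(r[run]) > r_cut
            seed_at = None
            for k in range(len(strong) - 2):
                if strong[k] and strong[k + 1] and strong[k + 2]:
                    seed_at = i + k
                    break
            if seed_at is not None:
                clusters.append(
                    ChromosomalCluster(
                        scaffold_id=sc,
                        gene_ids=list(genes[run]),
                        sign="+" if signs[i] > 0 else "-",
                        seed_triplet=list(genes[seed_at : seed_at + 3]),
                    )
                )
            i = j + 1
    return clusters


def clusters_to_table(
    clusters: list[ChromosomalCluster], annotation: pd.DataFrame
) -> pd.DataFrame:
    """BED-like summary: scaffold, min start, max end, sign, gene list."""
    ann = annotation.set_index("gene_id")
    rows = []
    for c in clusters:
        sub = ann.loc[c.gene_ids]
        rows.append(
            {
                "scaffold_id": c.scaffold_id,
                "start": int(sub["start"].min()),
                "end": int(sub["end"].max()),
                "sign": c.sign,
                "n_genes": len(c.gene_ids),
                "genes": ",".join(c.gene_ids),
            }
        )
    return pd.DataFrame(
        rows, columns=["scaffold_id", "start", "end", "sign", "n_genes", "genes"]
    )


@dataclass
class PromoterSharingResult:
    divergent_pairs: int
    within_gap: int
    max_gap: int
    table: pd.DataFrame


def promoter_sharing(
    pairs: pd.DataFrame, annotation: pd.DataFrame, max_gap: int = 1000
) -> PromoterSharingResult:
    """Divergently transcribed adjacent pairs that could share a promoter.

    A pair (upstream by coordinate, downstream) is potentially
    promoter-sharing iff the upstream gene is on the minus strand and the
    downstream gene on the plus strand, so their transcription starts face
    each other. Separation is the distance between the two transcription
    start positions (the end coordinate for minus-strand genes).
    """
    ann = annotation.set_index("gene_id")
    if ann["strand"].isna().any() or (~ann["strand"].isin(["+", "-"])).any():
        raise GenomeStructureError("annotation strand missing or invalid")
    rows = []
    for _, pr in pairs.iterrows():
        g1, g2 = pr["gene1"], pr["gene2"]
        a, b = ann.loc[g1], ann.loc[g2]
        divergent = a["strand"] == "-" and b["strand"] == "+"
        tss1 = a["end"] if a["strand"] == "-" else a["start"]
        tss2 = b["end"] if b["strand"] == "-" else b["start"]
        sep = int(abs(tss2 - tss1))
        rows.append(
            {
                "gene1": g1,
                "gene2": g2,
                "divergent": divergent,
                "separation": sep,
                "within_gap": divergent and sep < max_gap,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene1", "gene2", "divergent", "separation", "within_gap"]
    )
    return PromoterSharingResult(
        divergent_pairs=int(table["divergent"].sum()) if len(table) else 0,
        within_gap=int(table["within_gap"].sum()) if len(table) else 0,
        max_gap=max_gap,
        table=table,
    )


def gene_characteristics(
    annotation: pd.DataFrame,
    expr: pd.DataFrame,
    condition_map: pd.Series,
    contrasts: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-gene characteristic table: max expression, max |log2FC| over the
    condition contrasts, GC%, distance to scaffold end, and length.

    Genes without expression data are excluded (flagged via the returned
    table's attrs['excluded']).
    """
    ann = annotation.set_index("gene_id")
    has_expr = ann.index.isin(expr.index)
    excluded = list(ann.index[~has_expr])
    ann = ann[has_expr]
    x = expr.reindex(ann.index)
    max_expr = x.max(axis=1)
    fcs = []
    for a, b in contrasts:
        cols_a = condition_map.index[condition_map == a]
        cols_b = condition_map.index[condition_map == b]
        fcs.append((x[cols_a].mean(axis=1) - x[cols_b].mean(axis=1)).abs())
    max_fc = pd.concat(fcs, axis=1).max(axis=1) if fcs else pd.Series(0.0, index=ann.index)
    table = pd.DataFrame(
        {
            "max_expr": max_expr,
            "max_abs_log2fc": max_fc,
            "gc": ann["gc"],
            "dist_to_end": ann["dist_to_end"],
            "length": ann["length"],
        }
    )
    table.attrs["excluded"] = excluded
    return table


@dataclass
class CharacteristicComparison:
    characteristic: str
    coefficient: float  # mean(setA) - mean(setB) from the linear model
    p: float
    n_a: int
    n_b: int


def compare_characteristics(
    table: pd.DataFrame,
    set_a: list[str],
    set_b: list[str],
    characteristic: str,
) -> CharacteristicComparison:
    """Linear-model comparison of a characteristic between two gene sets.

    Fits characteristic ~ 1 + indicator(set A) by OLS over the union of the
    two (disjoint) sets and reports the group coefficient and its two-sided
    p-value.
    """
    if not set_a or not set_b:
        raise GenomeStructureError("both gene sets must be non-empty")
    overlap = set(set_a) & set(set_b)
    if overlap:
        raise GenomeStructureError(f"gene sets overlap: {sorted(overlap)[:5]}")
    if len(set_a) < 2 or len(set_b) < 2:
        raise GenomeStructureError("need >=2 genes per set (no residual df otherwise)")
    ya = table.loc[table.index.intersection(set_a), characteristic].to_numpy(dtype=float)
    yb = table.loc[table.index.intersection(set_b), characteristic].to_numpy(dtype=float)
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.ones(len(ya)), np.zeros(len(yb))])
    fit = sm.OLS(y, sm.add_constant(g)).fit()
    return CharacteristicComparison(
        characteristic=characteristic,
        coefficient=float(fit.params[1]),
        p=float(fit.pvalues[1]),
        n_a=len(ya),
        n_b=len(yb),
    )
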