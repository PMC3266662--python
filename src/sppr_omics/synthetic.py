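"""Synthetic inputs with planted, recoverable structure.

The generators emulate the study design the pipeline expects: nine chemostat
samples in three conditions (triplicates of D03, D06 and HD), a scaffold-based
genome annotation, a log2 expression matrix with per-gene correlations to the
specific extracellular protein production rate (SPPR) planted by construction,
adjacent-gene clusters on scaffolds, a bipartite gene-metabolite network with
planted reporter metabolites and a planted high-scoring path, protein
fold changes derived from transcript fold changes with controlled
translational control efficiency ratios (TCEr), and paired TRAC/array signals
from a gene-specific-intercept linear model.

Every generator is deterministic under a fixed seed. For a planted target
correlation r the expression of a gene is

    x_is = a_g + b * SPPR_s + eps_is,   eps ~ N(0, noise_sd^2),

with the slope b = sign(r) * noise_sd * |r| / (sd(SPPR) * sqrt(1 - r^2)),
which makes the population Pearson correlation between x and SPPR equal to r
(|r| = 1 is generated as an exact noise-free linear relation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .physiology import CultivationRecord

TAXONOMY_CLASSES = ("Fungi", "Pezizomycotina", "Trichoderma")

#: Default per-sample SPPR values (mg protein / g biomass / h), three
#: triplicate conditions ordered D03, D06, HD. D03 cultivations have the
#: highest and HD the lowest protein production rate.
DEFAULT_SPPR = (3.0, 3.2, 2.5, 1.5, 1.6, 1.4, 0.8, 0.9, 0.85)

DEFAULT_GC_MEANS = {"Fungi": 58.2, "Pezizomycotina": 57.5, "Trichoderma": 55.5}

_CATEGORY_POOL = (
    "metabolism",
    "protein synthesis",
    "protein secretion",
    "secreted protein",
    "transporter",
    "secondary metabolism",
    "regulation",
    "unknown",
)

_DOMAIN_POOL = tuple(f"IPR{100000 + 137 * i:06d}" for i in range(60))


class SyntheticSpecError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    planted_corr maps gene ids (see :func:`gene_id` for the deterministic
    naming scheme) to target Pearson correlations with SPPR in [-1, 1].
    planted_clusters are (scaffold index, start gene rank, length, sign)
    tuples, 1-based; their genes are planted at ``sign * cluster_corr``.
    """

    n_scaffolds: int = 10
    genes_per_scaffold: int = 100
    n_samples: int = 9
    conditions: tuple[str, ...] = ("D03", "D06", "HD")
    sppr_values: tuple[float, ...] = DEFAULT_SPPR
    planted_corr: dict[str, float] = field(default_factory=dict)
    planted_clusters: list[tuple[int, int, int, int]] = field(default_factory=list)
    cluster_corr: float = 0.85
    noise_sd: float = 0.25
    gc_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GC_MEANS))
    gc_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_scaffolds <= 0 or self.genes_per_scaffold <= 0:
            raise SyntheticSpecError("scaffold and gene counts must be positive")
        if self.n_samples <= 0 or self.n_samples % len(self.conditions):
            raise SyntheticSpecError(
                "n_samples must be a positive multiple of the condition count"
            )
        if len(self.sppr_values) != self.n_samples:
            raise SyntheticSpecError("sppr_values length must equal n_samples")
        if any(v <= 0 for v in self.sppr_values):
            raise SyntheticSpecError("SPPR values must be positive")
        if self.noise_sd <= 0:
            raise SyntheticSpecError("noise_sd must be > 0")
        for g, r in self.planted_corr.items():
            if abs(r) > 1:
                raise SyntheticSpecError(f"planted correlation for {g} outside [-1,1]")
        if not 0 < self.cluster_corr <= 1:
            raise SyntheticSpecError("cluster_corr must be in (0,1]")
        for sc, start, length, sign in self.planted_clusters:
            if not 1 <= sc <= self.n_scaffolds:
                raise SyntheticSpecError(f"cluster scaffold {sc} out of range")
            if start < 1 or start + length - 1 > self.genes_per_scaffold:
                raise SyntheticSpecError(
                    f"cluster [{start}, {start + length - 1}] outside scaffold {sc}"
                )
            if sign not in (-1, 1):
                raise SyntheticSpecError("cluster sign must be +1 or -1")
        for cls, m in self.gc_means.items():
            if not 0 <= m <= 100:
                raise SyntheticSpecError(f"GC mean for {cls} outside [0,100]")

    @property
    def sample_ids(self) -> list[str]:
        reps = self.n_samples // len(self.conditions)
        return [f"{c}_{i + 1}" for c in self.conditions for i in range(reps)]

    @property
    def condition_map(self) -> pd.Series:
        reps = self.n_samples // len(self.conditions)
        return pd.Series(
            [c for c in self.conditions for _ in range(reps)],
            index=self.sample_ids,
            name="condition",
        )

    @property
    def sppr(self) -> pd.Series:
        return pd.Series(list(self.sppr_values), index=self.sample_ids, name="sppr")


def gene_id(scaffold: int, rank: int) -> str:
    """Deterministic gene identifier for 1-based scaffold and gene rank."""
    return f"g{scaffold:02d}_{rank:03d}"


def effective_planted(spec: SyntheticSpec) -> dict[str, float]:
    """Planted correlation targets: explicit map plus cluster genes."""
    planted = dict(spec.planted_corr)
    for sc, start, length, sign in spec.planted_clusters:
        for rank in range(start, start + length):
            planted.setdefault(gene_id(sc, rank), sign * spec.cluster_corr)
    return planted


def generate_genome(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate a scaffold-ordered gene annotation table.

    Columns: gene_id, scaffold_id, start, end, strand, length, gc,
    dist_to_end, scaffold_length, taxonomy, categories, domains (categories
    and domains are ';'-joined strings). Coordinates are 1-based inclusive
    and non-overlapping within each scaffold.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for sc in range(1, spec.n_scaffolds + 1):
        pos = 1
        sc_rows = []
        for rank in range(1, spec.genes_per_scaffold + 1):
            gap = int(rng.integers(200, 2000))
            length = int(np.clip(rng.lognormal(np.log(1300.0), 0.5), 150, 15000))
            start = pos + gap
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            taxonomy = TAXONOMY_CLASSES[
                rng.choice(3, p=[0.60, 0.25, 0.15])
            ]
            gc = float(
                np.clip(
                    rng.normal(spec.gc_means.get(taxonomy, 57.0), spec.gc_sd), 0, 100
                )
            )
            n_cat = int(rng.integers(1, 3))
            cats = sorted(rng.choice(_CATEGORY_POOL, size=n_cat, replace=False))
            # lineage-specific genes frequently lack any known domain
            p_nodomain = {"Fungi": 0.1, "Pezizomycotina": 0.35, "Trichoderma": 0.6}
            if rng.random() < p_nodomain[taxonomy]:
                doms: list[str] = []
            else:
                doms = sorted(
                    rng.choice(_DOMAIN_POOL, size=int(rng.integers(1, 4)), replace=False)
                )
            sc_rows.append(
                {
                    "gene_id": gene_id(sc, rank),
                    "scaffold_id": f"scaffold_{sc}",
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "length": length,
                    "gc": gc,
                    "taxonomy": taxonomy,
                    "categories": ";".join(cats),
                    "domains": ";".join(doms),
                }
            )
            pos = end
        scaffold_length = pos + int(rng.integers(200, 2000))
        for row in sc_rows:
            row["scaffold_length"] = scaffold_length
            row["dist_to_end"] = min(row["start"] - 1, scaffold_length - row["end"])
        rows.extend(sc_rows)
    ann = pd.DataFrame(rows)
    return ann[
        [
            "gene_id",
            "scaffold_id",
            "start",
            "end",
            "strand",
            "length",
            "gc",
            "dist_to_end",
            "scaffold_length",
            "taxonomy",
            "categories",
            "domains",
        ]
    ]


def generate_expression(
    annotation: pd.DataFrame, spec: SyntheticSpec
) -> pd.DataFrame:
    """Generate the log2 expression matrix (genes x samples).

    Planted genes follow a linear SPPR response tuned so the population
    Pearson correlation equals the planted target; all other genes are
    independent N(baseline, noise_sd^2) noise.
    """
    spec.validate()
    planted = effective_planted(spec)
    missing = sorted(set(planted) - set(annotation["gene_id"]))
    if missing:
        raise SyntheticSpecError(f"planted gene ids absent from annotation: {missing}")
    rng = np.random.default_rng(spec.seed + 1)
    sppr = np.asarray(spec.sppr_values, dtype=float)
    sppr_c = sppr - sppr.mean()
    sd_sppr = sppr.std(ddof=0)
    genes = annotation["gene_id"].to_numpy()
    base = rng.normal(8.0, 1.5, size=len(genes))
    noise = rng.normal(0.0, spec.noise_sd, size=(len(genes), spec.n_samples))
    x = base[:, None] + noise
    for i, g in enumerate(genes):
        r = planted.get(g)
        if r is None or r == 0.0:
            continue
        if abs(r) >= 1.0:
            x[i] = base[i] + np.sign(r) * sppr_c  # exact, noise-free
        else:
            b = np.sign(r) * spec.noise_sd * abs(r) / (sd_sppr * np.sqrt(1 - r * r))
            x[i] = base[i] + b * sppr_c + noise[i]
    return pd.DataFrame(x, index=pd.Index(genes, name="gene_id"), columns=spec.sample_ids)


def generate_cultivations(spec: SyntheticSpec) -> list[CultivationRecord]:
    """Cultivation table whose steady-state balances reproduce spec SPPRs.

    Dilution rate is 0.03/h for D03 and HD, 0.06/h for D06; the HD feed
    carries 4x the substrate. Biomass follows the feed at a fixed yield, and
    protein is back-computed so SPPR = 1000 * D * P / X matches the spec.
    """
    spec.validate()
    d_by_cond = {"D03": 0.03, "D06": 0.06, "HD": 0.03}
    feed_by_cond = {"D03": 10.0, "D06": 10.0, "HD": 40.0}
    yield_xs = 0.5
    rng = np.random.default_rng(spec.seed + 2)
    records = []
    for sid, sppr in zip(spec.sample_ids, spec.sppr_values):
        cond = str(spec.condition_map[sid])
        d = d_by_cond.get(cond, 0.03)
        feed = feed_by_cond.get(cond, 10.0)
        x = feed * yield_xs * float(rng.uniform(0.95, 1.05))
        p = sppr * x / d / 1000.0
        records.append(
            CultivationRecord(
                sample_id=sid,
                condition=cond,
                dilution_rate=d,
                biomass=x,
                protein=p,
                substrate_feed=feed,
                substrate_residual=0.0,
            )
        )
    return records


@dataclass
class SyntheticNetwork:
    """Bipartite metabolic network plus the homology-search side tables."""

    edges: pd.DataFrame  # columns gene_id, metabolite_id
    similarity: pd.DataFrame  # columns query, subject, bitscore
    reactions: dict[str, list[str]]  # source-species gene -> reaction ids
    planted_reporters: list[str]
    planted_path: list[str]


def generate_network(
    annotation: pd.DataFrame,
    n_metabolites: int,
    planted_reporters: Sequence[str],
    planted_path: Sequence[str],
    spec: SyntheticSpec,
    mean_degree: float = 3.0,
    reporter_k: int = 4,
) -> SyntheticNetwork:
    """Generate the bipartite gene-metabolite network and similarity table.

    The planted path genes are chained through dedicated metabolites, so the
    gene-projection graph contains them as consecutive neighbors. Planted
    reporter metabolites attach to genes carrying planted correlations, so
    their neighborhood p-values are collectively small downstream. Metabolite
    background degree is 1 + Poisson(mean_degree - 1). The similarity table
    holds reciprocal best-hit bit scores (both directions) for a synthetic
    source species, used for metabolic-model transfer and edge weighting.
    """
    spec.validate()
    if mean_degree < 1:
        raise SyntheticSpecError("mean_degree must be >= 1")
    genes = list(annotation["gene_id"])
    gene_set = set(genes)
    for g in list(planted_path):
        if g not in gene_set:
            raise SyntheticSpecError(f"planted path gene {g} absent from annotation")
    n_dedicated = max(0, len(planted_path) - 1)
    if n_dedicated + len(planted_reporters) > n_metabolites:
        raise SyntheticSpecError(
            "planted path and reporters do not fit in the requested metabolite count"
        )
    rng = np.random.default_rng(spec.seed + 3)
    met_ids = [f"m{i + 1:04d}" for i in range(n_metabolites)]
    edges: list[tuple[str, str]] = []
    used = 0
    # chain the planted path through dedicated metabolites
    for i in range(n_dedicated):
        m = met_ids[used]
        used += 1
        edges.append((planted_path[i], m))
        edges.append((planted_path[i + 1], m))
    planted_genes = [g for g in effective_planted(spec) if g in gene_set]
    for name in planted_reporters:
        met_ids[used] = name  # reporter name replaces a pool metabolite id
        used += 1
        pool = planted_genes if len(planted_genes) >= reporter_k else genes
        for g in rng.choice(pool, size=min(reporter_k, len(pool)), replace=False):
            edges.append((str(g), name))
    for m in met_ids[used:]:
        k = 1 + int(rng.poisson(mean_degree - 1))
        for g in rng.choice(genes, size=min(k, len(genes)), replace=False):
            edges.append((str(g), m))
    edge_df = (
        pd.DataFrame(edges, columns=["gene_id", "metabolite_id"])
        .drop_duplicates()
        .reset_index(drop=True)
    )
    # reciprocal best-hit similarity scores for every gene in the network
    net_genes = sorted(edge_df["gene_id"].unique())
    sim_rows = []
    reactions: dict[str, list[str]] = {}
    for i, g in enumerate(net_genes):
        src = f"src_{g}"
        fwd = float(rng.uniform(60, 300))
        rev = fwd * float(rng.uniform(0.8, 1.2))
        sim_rows.append((src, g, fwd))
        sim_rows.append((g, src, rev))
        reactions[src] = [f"R{i + 1:04d}"]
    # low-scoring decoy hits that must never win a best-hit comparison
    for g in net_genes[:: max(1, len(net_genes) // 10)]:
        sim_rows.append((f"src_{g}", f"decoy_{g}", float(rng.uniform(20, 40))))
    similarity = pd.DataFrame(sim_rows, columns=["query", "subject", "bitscore"])
    return SyntheticNetwork(
        edges=edge_df,
        similarity=similarity,
        reactions=reactions,
        planted_reporters=list(planted_reporters),
        planted_path=list(planted_path),
    )


def generate_proteome(
    expression: pd.DataFrame,
    condition_map: pd.Series,
    comparisons: Sequence[tuple[str, str]],
    tcer_targets: Mapping[str, float],
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Protein/transcript fold-change pairs with controlled TCEr.

    For each gene and comparison (a, b), the transcript log2 fold change is
    the difference of condition means from *expression*, and the protein
    log2 fold change is transcript + log2(TCEr target) + N(0, noise_sd^2).
    """
    known = set(condition_map)
    for a, b in comparisons:
        if a not in known or b not in known:
            raise SyntheticSpecError(f"unknown condition in comparison {a} vs {b}")
    missing = sorted(set(tcer_targets) - set(expression.index))
    if missing:
        raise SyntheticSpecError(f"TCEr target genes absent from expression: {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    for g, tcer in tcer_targets.items():
        if tcer <= 0:
            raise SyntheticSpecError(f"TCEr target for {g} must be positive")
        for a, b in comparisons:
            t_fc = float(
                expression.loc[g, condition_map[condition_map == a].index].mean()
                - expression.loc[g, condition_map[condition_map == b].index].mean()
            )
            p_fc = t_fc + np.log2(tcer) + float(rng.normal(0.0, noise_sd))
            rows.append(
                {
                    "protein_id": f"sp_{g}",
                    "gene_id": g,
                    "comparison": f"{a}v{b}",
                    "protein_log2fc": p_fc,
                    "transcript_log2fc": t_fc,
                }
            )
    return pd.DataFrame(rows)


def generate_trac(
    gene_ids: Sequence[str],
    alphas: Sequence[float],
    beta: float,
    sigma: float,
    n_samples: int,
    seed: int = 0,
    trac_range: tuple[float, float] = (6.0, 14.0),
) -> pd.DataFrame:
    """Paired TRAC/array signals from the gene-specific-intercept model.

    array_ij = alpha_j + beta * trac_ij + eps_ij with eps ~ N(0, sigma^2);
    TRAC signals are uniform over *trac_range*.
    """
    if sigma <= 0:
        raise SyntheticSpecError("sigma must be > 0")
    if len(alphas) != len(gene_ids):
        raise SyntheticSpecError("alphas length must equal gene count")
    rng = np.random.default_rng(seed)
    rows = []
    for g, a in zip(gene_ids, alphas):
        trac = rng.uniform(*trac_range, size=n_samples)
        array = a + beta * trac + rng.normal(0.0, sigma, size=n_samples)
        for i in range(n_samples):
            rows.append(
                {
                    "gene_id": g,
                    "sample_id": f"s{i + 1}",
                    "trac_signal": float(trac[i]),
                    "array_signal": float(array[i]),
                }
            )
    return pd.DataFrame(rows)
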