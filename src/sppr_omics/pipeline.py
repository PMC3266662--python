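"""Pipeline driver: ties the analysis stages together and writes a
reproducible results directory with a run manifest.

The driver either generates a full synthetic study (default) or reads the
inputs named in the configuration, then runs: physiology -> SPPR
correlation with q-values -> significance selection -> adjacent pairs,
permutation test, cluster detection, promoter sharing -> gene
characteristics -> metabolic-model transfer, reporter metabolites, enriched
paths -> TRAC calibration -> transcript-protein integration -> enrichment.
All randomness is routed through per-stage seeds derived from the single
configured seed, so two runs with the same configuration are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, correlation, genome, integration, io, network, physiology
from . import synthetic as syn

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Thresholds, sizes and seeds for a pipeline run.

    File paths are optional; inputs without a path are generated by the
    synthetic module.
    """

    seed: int = 0
    # selection thresholds
    r_cut_select: float = 0.8
    r_cut_pairs: float = 0.7
    de_p_cut: float = 0.05
    de_lfc_cut: float = 0.5
    fc_hi: float = 0.6
    fc_lo: float = 0.3
    # resampling sizes
    n_perm: int = 2000
    n_shuffle: int = 2000
    n_background: int = 1000
    n_colorings: int = 300
    k_min: int = 3
    k_max: int = 6
    empath_p_cut: float = 0.025
    # behavior toggles for the documented design alternatives
    welch: bool = False
    spearman: bool = False
    log_sppr: bool = False
    extend_requires_cut: bool = False
    bbh_require_both: bool = False
    bbh_cutoff: float = 50.0
    empath_lambda: float = 0.0
    # synthetic-study shape
    synthetic: dict = field(default_factory=dict)
    # optional input paths (override synthetic generation)
    expression_path: str | None = None
    annotation_path: str | None = None
    network_path: str | None = None
    similarity_path: str | None = None
    cultivations_path: str | None = None
    pairs_path: str | None = None
    trac_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.r_cut_select < 1 or not 0 < self.r_cut_pairs < 1:
            raise PipelineError("correlation cut-offs must lie in (0, 1)")
        if self.n_perm < 1 or self.n_shuffle < 1 or self.n_background < 1:
            raise PipelineError("resampling sizes must be positive")
        if int(self.seed) != self.seed:
            raise PipelineError("seed must be an integer")


def default_synthetic_spec(config: PipelineConfig) -> syn.SyntheticSpec:
    """Synthetic study shape used when no input files are configured."""
    opts = dict(config.synthetic)
    opts.setdefault("n_scaffolds", 6)
    opts.setdefault("genes_per_scaffold", 80)
    opts.setdefault("seed", config.seed)
    if "planted_clusters" not in opts:
        n_sc, gps = opts["n_scaffolds"], opts["genes_per_scaffold"]
        wanted = [(1, 10, 5, 1), (2, 30, 4, -1), (4, 50, 6, 1)]
        opts["planted_clusters"] = [
            (sc, start, length, sign)
            for sc, start, length, sign in wanted
            if sc <= n_sc and start + length - 1 <= gps
        ]
    spec = syn.SyntheticSpec(**opts)
    if not spec.planted_corr:
        rng = np.random.default_rng(spec.seed + 7)
        total = spec.n_scaffolds * spec.genes_per_scaffold
        n_pos = n_neg = min(30, total // 8)
        free = [
            syn.gene_id(sc, rank)
            for sc in range(1, spec.n_scaffolds + 1)
            for rank in range(1, spec.genes_per_scaffold + 1)
        ]
        clustered = set(syn.effective_planted(spec))
        free = [g for g in free if g not in clustered]
        chosen = rng.choice(free, size=n_pos + n_neg, replace=False)
        spec.planted_corr = {
            **{g: 0.9 for g in chosen[:n_pos]},
            **{g: -0.9 for g in chosen[n_pos:]},
        }
    return spec


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write results plus manifest.json under *outdir*.

    Returns the manifest dictionary. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "sppr-omics",
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not k.endswith("_path")
        },
        "stages": {},
        "warnings": [],
    }
    state: dict = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3)
            }
            logger.info("stage %s done", name)

        return wrap

    @stage("inputs")
    def _inputs():
        spec = default_synthetic_spec(config)
        state["spec"] = spec
        if config.annotation_path:
            state["annotation"] = io.read_annotation(config.annotation_path)
        else:
            state["annotation"] = syn.generate_genome(spec)
        if config.expression_path:
            state["expression"] = io.read_expression(config.expression_path)
        else:
            state["expression"] = syn.generate_expression(state["annotation"], spec)
        state["condition_map"] = spec.condition_map
        if config.cultivations_path:
            state["cultivations"] = io.read_cultivations(config.cultivations_path)
        else:
            state["cultivations"] = syn.generate_cultivations(spec)
        if config.network_path:
            state["edges"] = io.read_network(config.network_path)
            state["similarity"] = (
                io.read_similarity(config.similarity_path)
                if config.similarity_path
                else None
            )
            state["reactions"] = {}
        else:
            planted = [g for g, r in syn.effective_planted(spec).items() if r < 0][:5]
            net = syn.generate_network(
                state["annotation"],
                n_metabolites=60,
                planted_reporters=["rep_met_1", "rep_met_2"],
                planted_path=planted,
                spec=spec,
            )
            state["edges"] = net.edges
            state["similarity"] = net.similarity
            state["reactions"] = net.reactions
        io.write_annotation(state["annotation"], outdir / "annotation.tsv")
        io.write_expression(state["expression"], outdir / "expression.tsv")
        io.write_network(state["edges"], outdir / "network.tsv")

    @stage("physiology")
    def _physiology():
        records = physiology.compute_rates_all(state["cultivations"])
        state["cultivations"] = records
        state["sppr"] = pd.Series(
            {r.sample_id: r.sppr for r in records}, name="sppr"
        ).reindex(state["expression"].columns)
        contrast = physiology.condition_contrast(
            records, "yield_xs", "HD", "D06", welch=config.welch
        )
        state["yield_contrast"] = contrast
        io.write_cultivations(records, outdir / "cultivations.tsv")

    @stage("correlation")
    def _correlation():
        recs = correlation.correlate_to_sppr(
            state["expression"], state["sppr"], log_sppr=config.log_sppr
        )
        recs = correlation.add_qvalues(recs)
        state["correlations"] = recs
        state["selection"] = correlation.select_significant(
            recs.dropna(subset=["r"]), r_cut=config.r_cut_select
        )
        recs.rename_axis("gene_id").to_csv(outdir / "correlations.tsv", sep="\t")

    @stage("differential_expression")
    def _de():
        conds = list(dict.fromkeys(state["condition_map"]))
        contrasts = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1 :]]
        state["contrasts"] = contrasts
        de = correlation.differential_expression(
            state["expression"],
            state["condition_map"],
            contrasts,
            p_cut=config.de_p_cut,
            lfc_cut=config.de_lfc_cut,
        )
        state["de"] = de
        de.to_csv(outdir / "differential_expression.tsv", sep="\t", index=False)

    @stage("genome_structure")
    def _genome():
        ann, corr = state["annotation"], state["correlations"]
        pairs = genome.adjacent_qualifying_pairs(ann, corr, r_cut=config.r_cut_pairs)
        perm = genome.pair_permutation_test(
            ann,
            corr,
            r_cut=config.r_cut_pairs,
            n_perm=config.n_perm,
            seed=config.seed + 11,
        )
        clusters = genome.detect_clusters(
            ann,
            corr,
            r_cut=config.r_cut_pairs,
            extend_requires_cut=config.extend_requires_cut,
        )
        sharing = genome.promoter_sharing(pairs, ann)
        chars = genome.gene_characteristics(
            ann, state["expression"], state["condition_map"], state["contrasts"]
        )
        state.update(
            pairs=pairs, permutation=perm, clusters=clusters, characteristics=chars
        )
        state["promoter_sharing"] = sharing
        pairs.to_csv(outdir / "adjacent_pairs.tsv", sep="\t", index=False)
        io.write_clusters_bed(
            genome.clusters_to_table(clusters, ann), outdir / "clusters.bed.tsv"
        )
        chars.rename_axis("gene_id").to_csv(outdir / "characteristics.tsv", sep="\t")

    @stage("metabolic_network")
    def _network():
        if state.get("similarity") is not None and state["reactions"]:
            bbh = network.bbh_transfer(
                state["similarity"],
                state["reactions"],
                cutoff=config.bbh_cutoff,
                require_both=config.bbh_require_both,
            )
            state["bbh"] = bbh
            gene_scores = network.bidirectional_scores(bbh.mapping)
        else:
            gene_scores = None
        results = {}
        for tail, name in (("greater", "positive"), ("less", "negative")):
            one_sided = correlation.correlate_to_sppr(
                state["expression"], state["sppr"], tail=tail
            )["p"].dropna()
            reporters = network.reporter_metabolites(
                state["edges"],
                one_sided,
                n_background=config.n_background,
                seed=config.seed + 13,
            )
            graph = network.gene_projection(state["edges"], gene_scores)
            pvals = {g: float(one_sided.get(g, 1.0)) for g in graph.nodes}
            paths = network.empath(
                graph,
                pvals,
                k_min=config.k_min,
                k_max=config.k_max,
                n_shuffle=config.n_shuffle,
                n_colorings=config.n_colorings,
                seed=config.seed + 17,
                p_cut=config.empath_p_cut,
                lam=config.empath_lambda,
            )
            results[name] = {"reporters": reporters, "empath": paths}
            reporters.to_csv(
                outdir / f"reporter_metabolites.{name}.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                [
                    {
                        "k": p.k,
                        "score": p.score,
                        "p": p.p,
                        "genes": ",".join(p.gene_ids),
                    }
                    for p in paths.paths
                ]
            ).to_csv(outdir / f"empath.{name}.tsv", sep="\t", index=False)
        state["network_results"] = results

    @stage("trac_calibration")
    def _trac():
        if config.trac_path:
            table = io.read_trac(config.trac_path)
        else:
            rng = np.random.default_rng(config.seed + 19)
            gene_ids = [f"trac_g{i:02d}" for i in range(31)]
            alphas = rng.uniform(1.0, 3.0, size=31)
            table = syn.generate_trac(
                gene_ids, alphas, beta=0.52, sigma=0.25, n_samples=9,
                seed=config.seed + 19,
            )
        io.write_trac(table, outdir / "trac.tsv")
        state["trac_fit"] = calibration.fit_trac_models(table)

    @stage("integration")
    def _integration():
        if config.pairs_path:
            pairs = io.read_pairs(config.pairs_path)
        else:
            rng = np.random.default_rng(config.seed + 23)
            genes = list(state["expression"].index[:40])
            tcer_targets = {
                g: float(2.0 ** rng.normal(0.0, 0.8)) for g in genes
            }
            pairs = syn.generate_proteome(
                state["expression"],
                state["condition_map"],
                comparisons=[("D03", "D06"), ("D03", "HD")],
                tcer_targets=tcer_targets,
                seed=config.seed + 23,
            )
        classified = integration.classify_table(
            pairs, hi=config.fc_hi, lo=config.fc_lo
        )
        state["integration"] = classified
        state["fc_correlation"] = {
            comp: integration.fc_correlation(sub)
            for comp, sub in classified.groupby("comparison")
        }
        io.write_pairs(classified, outdir / "integration.tsv")

    @stage("enrichment")
    def _enrichment():
        ann = state["annotation"].set_index("gene_id")
        cat_map = {
            g: [c for c in str(cats).split(";") if c]
            for g, cats in ann["categories"].items()
        }
        background = list(ann.index)
        sel = state["selection"]
        results = {}
        for name, genes_ in (("positive", sel.positive), ("negative", sel.negative)):
            if genes_:
                res = calibration.enrichment_test(
                    genes_, background, cat_map, mode="hypergeometric"
                )
                calibration.enrichment_to_table(res).to_csv(
                    outdir / f"enrichment.{name}.tsv", sep="\t", index=False
                )
                results[name] = res
        state["enrichment"] = results

    sel = state["selection"]
    manifest["results"] = {
        "n_genes": int(len(state["expression"])),
        "n_positive_selected": len(sel.positive),
        "n_negative_selected": len(sel.negative),
        "achieved_fdr": sel.achieved_fdr,
        "pair_permutation_p": state["permutation"].p,
        "n_clusters_positive": sum(1 for c in state["clusters"] if c.sign == "+"),
        "n_clusters_negative": sum(1 for c in state["clusters"] if c.sign == "-"),
        "yield_contrast_p": state["yield_contrast"].p,
        "trac_selected_model": state["trac_fit"].selected,
        "trac_slope": state["trac_fit"].fits["m1"].slope,
        "trac_sigma": state["trac_fit"].fits["m1"].sigma,
        "fc_correlation": state["fc_correlation"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    state["manifest"] = manifest
    return manifest
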