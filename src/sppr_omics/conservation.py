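"""Conservation of chromosomal clusters across genomes by sliding-window
InterPro domain-content matching plus orthology verification.

Windows of w consecutive genes (default pairings w=16/step=2 and
w=30/step=5) slide along each scaffold of a target genome. A window matches
a query cluster when its pooled InterPro domain content shares at least
min_shared distinct domains with the cluster's domain content (default: all
of them). A match is homology-confirmed when every shared domain is carried
by a window gene that shares a protein-cluster (orthology group) with some
gene of the query cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_STEP = {16: 2, 30: 5}


class ConservationError(ValueError):
    """Invalid input to the conservation analysis."""


@dataclass
class Window:
    species_id: str
    scaffold_id: str
    gene_ids: tuple[str, ...]
    domains: frozenset[str]


@dataclass
class WindowMatch:
    species_id: str
    scaffold_id: str
    gene_ids: tuple[str, ...]
    shared_domains: frozenset[str]
    homology_confirmed: bool = False
    confirmed_genes: tuple[str, ...] = field(default_factory=tuple)


def enumerate_windows(
    order: pd.DataFrame, w: int = 16, step: int | None = None
) -> list[Window]:
    """Full-length windows of w consecutive genes per scaffold.

    *order* has columns species_id, scaffold_id, rank, gene_id, domains
    (';'-joined string, may be empty). Windows start at ranks 1, 1+step, ...
    and only complete windows are emitted; scaffolds shorter than w yield
    none.
    """
    if w <= 0:
        raise ConservationError("window length must be positive")
    if step is None:
        step = DEFAULT_STEP.get(w, 1)
    if step <= 0:
        raise ConservationError("step must be positive")
    windows: list[Window] = []
    for (species, scaffold), sub in order.groupby(
        ["species_id", "scaffold_id"], sort=True
    ):
        sub = sub.sort_values("rank")
        genes = sub["gene_id"].tolist()
        doms = [_parse_domains(d) for d in sub["domains"]]
        for start in range(0, len(genes) - w + 1, step):
            windows.append(
                Window(
                    species_id=str(species),
                    scaffold_id=str(scaffold),
                    gene_ids=tuple(genes[start : start + w]),
                    domains=frozenset().union(*doms[start : start + w]),
                )
            )
    return windows


def _parse_domains(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    parts = [p for p in str(value).split(";") if p]
    return frozenset(parts)


def match_cluster(
    cluster_domains: Iterable[str],
    windows: Iterable[Window],
    min_shared: int | None = None,
) -> list[WindowMatch]:
    """Windows whose domain content overlaps the cluster's domain content.

    min_shared defaults to all distinct cluster domains (strict overlap);
    duplicate domains count once. Matches are sorted by descending shared
    count.
    """
    cluster_set = frozenset(cluster_domains)
    if not cluster_set:
        raise ConservationError("cluster domain set is empty")
    if min_shared is None:
        min_shared = len(cluster_set)
    if min_shared > len(cluster_set):
        raise ConservationError("min_shared exceeds the cluster's domain count")
    if min_shared < 1:
        raise ConservationError("min_shared must be >= 1")
    matches = []
    for win in windows:
        shared = win.domains & cluster_set
        if len(shared) >= min_shared:
            matches.append(
                WindowMatch(
                    species_id=win.species_id,
                    scaffold_id=win.scaffold_id,
                    gene_ids=win.gene_ids,
                    shared_domains=shared,
                )
            )
    matches.sort(key=lambda m: (-len(m.shared_domains), m.species_id, m.scaffold_id))
    return matches


def verify_homology(
    matches: list[WindowMatch],
    cluster_genes: Iterable[str],
    orthogroup_of: Mapping[str, str],
    domains_of: Mapping[str, Iterable[str]],
) -> list[WindowMatch]:
    """Confirm matches via shared orthology groups.

    A match is confirmed iff every shared domain is carried by at least one
    window gene whose orthology group is also the orthology group of some
    query-cluster gene. Window genes without an orthology mapping leave the
    match unconfirmed (with a logged warning) rather than failing.
    """
    cluster_groups = set()
    for g in cluster_genes:
        grp = orthogroup_of.get(g)
        if grp is None:
            logger.warning("query cluster gene %s has no orthology group", g)
        else:
            cluster_groups.add(grp)
    out = []
    for m in matches:
        confirmed_genes = []
        ok = True
        for dom in m.shared_domains:
            carriers = [
                g
                for g in m.gene_ids
                if dom in frozenset(domains_of.get(g, ()))
            ]
            hom = [g for g in carriers if orthogroup_of.get(g) in cluster_groups]
            if not hom:
                if any(g not in orthogroup_of for g in carriers):
                    logger.warning(
                        "window %s/%s: no orthology mapping for carriers of %s",
                        m.species_id,
                        m.scaffold_id,
                        dom,
                    )
                ok = False
            else:
                confirmed_genes.extend(hom)
        out.append(
            WindowMatch(
                species_id=m.species_id,
                scaffold_id=m.scaffold_id,
                gene_ids=m.gene_ids,
                shared_domains=m.shared_domains,
                homology_confirmed=ok,
                confirmed_genes=tuple(sorted(set(confirmed_genes))),
            )
        )
    return out


def matches_to_table(matches: list[WindowMatch]) -> pd.DataFrame:
    rows = [
        {
            "species_id": m.species_id,
            "scaffold_id": m.scaffold_id,
            "genes": ",".join(m.gene_ids),
            "shared_domains": ";".join(sorted(m.shared_domains)),
            "n_shared": len(m.shared_domains),
            "homology_confirmed": m.homology_confirmed,
        }
        for m in matches
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "species_id",
            "scaffold_id",
            "genes",
            "shared_domains",
            "n_shared",
            "homology_confirmed",
        ],
    )
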