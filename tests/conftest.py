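import numpy as np
import pandas as pd
import pytest

from sppr_omics import synthetic as syn


@pytest.fixture
def small_spec():
    """Compact synthetic study: 3 scaffolds x 30 genes, one planted cluster."""
    return syn.SyntheticSpec(
        n_scaffolds=3,
        genes_per_scaffold=30,
        planted_corr={"g01_003": 0.9, "g02_005": -0.9},
        planted_clusters=[(1, 10, 5, 1)],
        seed=11,
    )


@pytest.fixture
def small_genome(small_spec):
    return syn.generate_genome(small_spec)


@pytest.fixture
def small_expression(small_spec, small_genome):
    return syn.generate_expression(small_genome, small_spec)


def make_annotation(r_values, scaffold="scaffold_1", spacing=2000, length=1000):
    """Minimal single-scaffold annotation with one gene per r value."""
    rows = []
    pos = 1
    for i, _ in enumerate(r_values):
        start = pos + 500
        end = start + length - 1
        rows.append(
            {
                "gene_id": f"g{i + 1}",
                "scaffold_id": scaffold,
                "start": start,
                "end": end,
                "strand": "+",
                "length": length,
                "gc": 55.0,
                "dist_to_end": 0,
                "scaffold_length": 10**6,
                "taxonomy": "Fungi",
                "categories": "",
                "domains": "",
            }
        )
        pos = start + spacing
    ann = pd.DataFrame(rows)
    corr = pd.DataFrame(
        {"r": np.asarray(r_values, dtype=float)},
        index=pd.Index(ann["gene_id"], name="gene_id"),
    )
    return ann, corr
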