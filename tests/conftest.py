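import numpy as np
import pandas as pd
import pytest

from sgcap.synthetic_data import (
    simulate_annotation,
    simulate_cell_image,
    simulate_three_contrast_counts,
)


@pytest.fixture(scope="session")
def annotation_fixture(tmp_path_factory):
    """Simulated GTF/FASTA/BED/TE files plus their ground truth."""
    out = tmp_path_factory.mktemp("annot")
    paths, truth = simulate_annotation(
        40, out, seed=17, extra_isoform_prob=0.25, te_missing_rate=0.1)
    return paths, truth


@pytest.fixture(scope="session")
def labeled_counts():
    """Small three-contrast labeling experiment with planted enrichment."""
    return simulate_three_contrast_counts(
        n_genes=300, n_enriched=30, n_depleted=10, log2fc=2.5,
        seed=17, dispersion=0.02)


@pytest.fixture(scope="session")
def clean_cell():
    """Noise-free synthetic two-channel cell image with truth."""
    return simulate_cell_image(n_puncta=50, inside_fraction=0.7, seed=17)


def make_contrast_table(enriched=(), depleted=(), other=(), fc=1.0, padj=1e-4):
    """Hand-built contrast table: enriched at +fc, depleted at -fc, rest null."""
    rows = []
    for g in enriched:
        rows.append((g, fc, padj))
    for g in depleted:
        rows.append((g, -fc, padj))
    for g in other:
        rows.append((g, 0.0, 1.0))
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])
    return df.set_index("gene_id")
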