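import numpy as np
import pandas as pd
import pytest

import orthoconserve as oc


@pytest.fixture(scope="session")
def small_bundle():
    """One small seeded two-species expression bundle shared across tests."""
    return oc.generate_paired_expression(
        n_genes=200,
        n_tissues=4,
        samples_per_tissue=20,
        n_modules=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def gwas_bundle():
    """Markers + annotation with a planted enriched gene set."""
    markers, annotation, truth = oc.generate_gwas_markers(
        n_markers=2_000, n_chroms=2, enriched_gene_set_size=10, enrichment_ratio=5.0, seed=7
    )
    return markers, annotation, truth


def toy_expression(values, tissues, species="toy", gene_prefix="g"):
    """Build an ExpressionMatrix from a plain array and tissue labels."""
    arr = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(arr.shape[0])]
    samples = [f"s{j}" for j in range(arr.shape[1])]
    return oc.ExpressionMatrix(
        species=species,
        values=pd.DataFrame(arr, index=genes, columns=samples),
        tissue_of_sample=pd.Series(list(tissues), index=samples),
    )
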