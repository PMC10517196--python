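import numpy as np
import pandas as pd
import pytest

from pathprs.io_formats import GenotypeMatrix, SummaryStatRecord


def make_genotypes(dosage, bps=None, chrom="1", sample_prefix="S", ref="A", alt="G"):
    """Build a GenotypeMatrix from a raw dosage array (rows = samples)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if bps is None:
        bps = [1000 * (j + 1) for j in range(m)]
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j + 1}" for j in range(m)],
            "chrom": chrom,
            "bp": bps,
            "ref": ref,
            "alt": alt,
        }
    )
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n)],
        variants=variants,
        dosage=dosage,
    )


def make_stats(G, betas=None, ps=None):
    """Summary-stat records matching G's variants (effect allele = alt)."""
    m = G.n_variants
    betas = [0.1] * m if betas is None else betas
    ps = [0.01] * m if ps is None else ps
    return [
        SummaryStatRecord(
            variant_id=row["variant_id"],
            chrom=row["chrom"],
            bp=int(row["bp"]),
            a1=row["alt"],
            a2=row["ref"],
            beta=float(betas[j]),
            p=float(ps[j]),
        )
        for j, row in G.variants.iterrows()
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
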