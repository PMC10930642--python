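import numpy as np
import pytest

from rohscan import GenotypeMatrix, MarkerMap


@pytest.fixture
def tiny_map():
    """Three markers on two chromosomes."""
    return MarkerMap(
        marker_id=np.array(["m1", "m2", "m3"], dtype=object),
        chrom=np.array(["1", "1", "2"], dtype=object),
        pos_bp=np.array([1000, 2000, 500]),
        allele_a=np.array(["A", "C", "G"], dtype=object),
        allele_b=np.array(["T", "G", "A"], dtype=object),
    )


def make_matrix(dosage, samples=None, n_alleles=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    if samples is None:
        samples = [f"s{i}" for i in range(dosage.shape[0])]
    return GenotypeMatrix(samples, dosage, n_alleles)


def uniform_map(n, chrom="1", spacing=50_000, start=1_000_000, prefix="m"):
    pos = start + spacing * np.arange(n)
    return MarkerMap(
        marker_id=np.array([f"{prefix}{i}" for i in range(n)], dtype=object),
        chrom=np.array([chrom] * n, dtype=object),
        pos_bp=pos,
        allele_a=np.array(["A"] * n, dtype=object),
        allele_b=np.array(["B"] * n, dtype=object),
    )
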