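import numpy as np
import pandas as pd
import pytest

from pathassoc.data_model import (
    Dataset,
    GenotypeMatrix,
    PathwayMap,
    SnpAnnotation,
    SubjectTable,
)


def make_dataset(
    dosages: np.ndarray,
    status: np.ndarray,
    snp_ids: list[str] | None = None,
    regions: list[str] | None = None,
    pathway_map: dict[str, set[str]] | None = None,
    sex: np.ndarray | None = None,
    birth_year: np.ndarray | None = None,
    age: np.ndarray | None = None,
) -> Dataset:
    """Assemble a small aligned Dataset from raw arrays for tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, k = dosages.shape
    snp_ids = snp_ids or [f"snp{j}" for j in range(k)]
    regions = regions or ["R1"] * k
    subject_ids = [f"s{i}" for i in range(n)]
    if sex is None:
        sex = np.where(np.arange(n) % 10 == 0, "M", "F")
    if birth_year is None:
        birth_year = 1940 + (np.arange(n) % 40)
    if age is None:
        age = 30 + (np.arange(n) % 40)
    subjects = pd.DataFrame(
        {"status": np.asarray(status, dtype=int), "sex": sex,
         "birth_year": birth_year, "age": age},
        index=pd.Index(subject_ids),
    )
    ann = pd.DataFrame({"gene_region": regions}, index=pd.Index(snp_ids))
    pmap = pathway_map or {r: {"P1"} for r in set(regions)}
    return Dataset(
        genotypes=GenotypeMatrix(pd.DataFrame(dosages, index=subject_ids, columns=snp_ids)),
        subjects=SubjectTable(subjects),
        annotation=SnpAnnotation(ann),
        pathways=PathwayMap({r: frozenset(p) for r, p in pmap.items()}),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def balanced_dataset(rng):
    """60 subjects, 4 SNPs in 2 regions, genotypes independent of status."""
    n = 60
    g = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
    status = np.array([1, 0] * (n // 2))
    return make_dataset(g, status, regions=["R1", "R1", "R2", "R2"],
                        pathway_map={"R1": {"P1", "P2"}, "R2": {"P2"}})
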