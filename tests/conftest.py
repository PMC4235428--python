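import numpy as np
import pandas as pd
import pytest

from pedphewas import phecodes
from pedphewas.genotypes import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20140401)


@pytest.fixture(scope="session")
def mini_map():
    return phecodes.load_mini_map()


@pytest.fixture
def toy_map():
    """Hand-built map: 6 ICD-9 codes -> 3 phecodes in 3 categories."""
    rows = [
        ("714.30", "714.1", "JRA", 714, 714.99, "musculoskeletal"),
        ("714.31", "714.1", "JRA", 714, 714.99, "musculoskeletal"),
        ("555.9", "555.1", "Crohn's", 555, 558.99, "digestive"),
        ("556.9", "555.2", "UC", 555, 558.99, "digestive"),
        ("493.90", "495", "Asthma", 490, 496.99, "respiratory"),
        ("477.9", "476", "Allergic rhinitis", 470, 478.99, "respiratory"),
    ]
    frame = pd.DataFrame(
        rows,
        columns=["icd9", "phecode", "description", "exclude_lo", "exclude_hi", "category"],
    )
    return phecodes.PhecodeMap.from_frame(frame)


def make_genotypes(dosages, pos=None, chrom=None, subjects=None):
    """Small GenotypeMatrix from a raw dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "id": [f"rs{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    subj = subjects if subjects is not None else np.array(
        [f"S{i:04d}" for i in range(n)], dtype=object
    )
    return GenotypeMatrix(subjects=subj, variants=variants, dosages=dosages)


@pytest.fixture
def make_G():
    return make_genotypes
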