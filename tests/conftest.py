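import numpy as np
import pytest

from famvar.pedigree import Individual, Pedigree
from famvar.phenotype_prep import inverse_normal_transform


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        [
            Individual("F", "fam1", None, None, "male"),
            Individual("M", "fam1", None, None, "female"),
            Individual("C", "fam1", "F", "M", "male"),
        ]
    )


@pytest.fixture
def sib_quartet() -> Pedigree:
    """Two founder parents with a son and a daughter."""
    return Pedigree(
        [
            Individual("F", "fam1", None, None, "male"),
            Individual("M", "fam1", None, None, "female"),
            Individual("S1", "fam1", "F", "M", "male"),
            Individual("S2", "fam1", "F", "M", "female"),
        ]
    )


def aligned(ds, column, transform=None) -> np.ndarray:
    """Phenotype column scattered into pedigree row order (NaN elsewhere)."""
    ped = ds.pedigree
    out = np.full(len(ped), np.nan)
    pos = {iid: k for k, iid in enumerate(ped.ids)}
    rows = np.array([pos[i] for i in ds.phenotypes["id"]], dtype=np.intp)
    vals = ds.phenotypes[column].to_numpy(dtype=float)
    out[rows] = transform(vals) if transform is not None else vals
    return out


def int_trait(ds, column) -> np.ndarray:
    return aligned(ds, column, inverse_normal_transform)


def basic_design(ds) -> np.ndarray:
    """Intercept + centred age + squared age + sex, aligned to the pedigree."""
    age = aligned(ds, "age")
    sex = ds.pedigree.sexes.astype(float)
    return np.column_stack(
        [np.ones(len(ds.pedigree)), age - 45.0, (age - 45.0) ** 2, sex]
    )
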