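import numpy as np
import pandas as pd
import pytest

from germcore import (
    PhenotypeMatrix,
    Trait,
    TraitSchema,
    default_collection_spec,
    generate_collection,
)


@pytest.fixture
def toy_schema() -> TraitSchema:
    return TraitSchema(
        [
            Trait("PH", "quantitative", units="cm"),
            Trait("SR", "qualitative", classes=("two", "six")),
        ]
    )


@pytest.fixture
def toy_matrix(toy_schema) -> PhenotypeMatrix:
    df = pd.DataFrame(
        {"PH": [100.0, 120.0, 140.0], "SR": ["two", "six", "six"]},
        index=pd.Index(["A1", "A2", "A3"], name="accession_id"),
    )
    return PhenotypeMatrix(df, toy_schema)


@pytest.fixture(scope="session")
def collection_300() -> PhenotypeMatrix:
    """Mid-size synthetic collection shared across tests (seeded)."""
    return generate_collection(default_collection_spec(n_accessions=300, seed=42))


@pytest.fixture(scope="session")
def gower_300(collection_300) -> np.ndarray:
    from germcore import gower_matrix

    return gower_matrix(collection_300)
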