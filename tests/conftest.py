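import numpy as np
import pandas as pd
import pytest

from cofactomics.annotations import AnnotationCatalog, AnnotationRecord
from cofactomics.tables_io import ConcentrationMatrix, SampleDesign


@pytest.fixture
def toy_matrix():
    """3 entities x 4 samples with one missing cell."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 4.0, 0.4],
            "s2": [2.0, np.nan, 0.8],
            "s3": [3.0, 6.0, 1.2],
            "s4": [4.0, 8.0, 1.6],
        },
        index=["m1", "m2", "m3"],
    )
    return ConcentrationMatrix(data=data, unit="umol_per_g", entity_kind="metabolite")


@pytest.fixture
def two_arm_design():
    rows = []
    for model in ("CRCA", "SEKI"):
        for arm, n in (("experimental", 3), ("control", 3)):
            for k in range(n):
                rows.append(
                    {
                        "sample_id": f"{model}_{arm[:3]}_{k}",
                        "model": model,
                        "arm": arm,
                        "tissue": "liver",
                        "sex": "F",
                    }
                )
    return SampleDesign(table=pd.DataFrame(rows))


def make_record(
    accession,
    ec=(),
    chebi=(),
    keywords=(),
    activity="",
    binding="",
    entry_name="",
):
    return AnnotationRecord(
        accession=accession,
        entry_name=entry_name or accession,
        ec_numbers=tuple(ec),
        catalytic_activity=activity,
        nucleotide_binding=binding,
        keyword_ids=frozenset(keywords),
        chebi_ids=frozenset(chebi),
    )


def random_catalog(rng, n=10):
    """Small random catalog for property tests."""
    chebis = ["CHEBI:57540", "CHEBI:597326", "CHEBI:57287", "CHEBI:30616"]
    records = []
    for i in range(n):
        ec = (f"1.1.1.{rng.integers(1, 9)}",) if rng.random() < 0.5 else ()
        cs = tuple(rng.choice(chebis, size=rng.integers(0, 3), replace=False))
        kws = ("KW-0560",) if rng.random() < 0.4 else ()
        records.append(make_record(f"P{i:04d}", ec=ec, chebi=cs, keywords=kws))
    return AnnotationCatalog(records=tuple(records))
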