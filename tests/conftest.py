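import pandas as pd
import pytest

from robseg.cohort import CohortTable
from robseg.karyotype import RobTranslocation


@pytest.fixture
def rob1314() -> RobTranslocation:
    return RobTranslocation(13, 14)


def make_cohort(rows) -> CohortTable:
    """Build a cohort from (embryo_id, arm, gender, age, translocation, karyotype)
    tuples; patient ids are derived from embryo ids."""
    df = pd.DataFrame(
        rows, columns=["embryo_id", "arm", "gender", "age", "translocation", "karyotype"]
    )
    df.insert(1, "patient_id", "P" + df["embryo_id"].astype(str))
    return CohortTable(df)


def carrier_rows(karyotypes, gender="female", age=30, translocation="rob(13;14)(q10;q10)",
                 prefix="E"):
    return [
        (f"{prefix}{i}", "carrier", gender, age, translocation, k)
        for i, k in enumerate(karyotypes)
    ]


def control_rows(karyotypes, gender="female", age=30, prefix="K"):
    return [(f"{prefix}{i}", "control", gender, age, "", k) for i, k in enumerate(karyotypes)]
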