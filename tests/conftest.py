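import numpy as np
import pandas as pd
import pytest

from bonepmi.synthetic import default_study_spec, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One draw of the default 25-sample study (seed 1)."""
    return generate_study(default_study_spec(seed=1))


@pytest.fixture(scope="session")
def tibia_late(default_study):
    """The 10-sample two-class tibia stratum of the default study."""
    from bonepmi.proteome_sets import subset_study
    table, meta = default_study
    return subset_study(table, meta, bone="tibia", pmi_classes=["PMI15", "PMI20"])


@pytest.fixture()
def tiny_table():
    """3 samples x 3 proteins with one explicit missing value."""
    return pd.DataFrame(
        {"p1": [5.0, 2.0, 1.0], "p2": [np.nan, 1.0, 4.0], "p3": [2.0, 3.0, 7.0]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"))
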