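import numpy as np
import pandas as pd
import pytest

from mrmediate.summary_io import SummaryTable, _coerce_dtypes


def make_table(name, rows, trait_type="quantitative"):
    """Build a SummaryTable from a list of dicts, filling sensible defaults."""
    defaults = {
        "chromosome": "1",
        "position": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pval": 1e-9,
        "n": 10_000,
    }
    if not rows:
        return SummaryTable(trait_name=name, trait_type=trait_type)
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults, variant_id=f"rs{i + 1}", position=1000 + i * 20_000_000)
        r.update(row)
        full.append(r)
    df = _coerce_dtypes(pd.DataFrame(full))
    return SummaryTable(trait_name=name, trait_type=trait_type, records=df)


@pytest.fixture(scope="session")
def valid_study():
    """One simulated study under the reference ('valid') conditions."""
    from mrmediate.simulate import scenario_battery, simulate_study

    return simulate_study(scenario_battery("valid"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
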