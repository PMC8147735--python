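import numpy as np
import pandas as pd
import pytest

from concindex.ranking import RankedSample, weighted_fractional_rank
from concindex.synthetic_data import CountryScenario


def make_sample(h, wealth=None, w=None, bounds=(0.0, 1.0), label="") -> RankedSample:
    """RankedSample from raw vectors: ranks on wealth (default: given order)."""
    h = np.asarray(h, dtype=float)
    wealth = np.arange(h.size) if wealth is None else np.asarray(wealth, float)
    w = np.ones(h.size) if w is None else np.asarray(w, float)
    r = weighted_fractional_rank(wealth, w)
    return RankedSample(h=h, r=r, w=w, bounds=bounds, label=label)


@pytest.fixture
def toy_sample() -> RankedSample:
    """Perfectly pro-rich binary indicator: poorest two 0, richest two 1."""
    return make_sample([0, 0, 1, 1])


@pytest.fixture
def respondent_csv(tmp_path):
    """Write a small standard-schema respondent CSV, return its path."""

    def _write(rows: list[dict], name: str = "resp.csv"):
        defaults = dict(
            country_code="AAA", program="MICS", year_label="2015",
            weight=1.0, wealth_index=1.0, age=20,
            heard_of_aids=1, k_condom=1, k_single_partner=1,
            k_mosquito=0, k_food=0, ever_tested=0, condom_last="NA",
        )
        df = pd.DataFrame([{**defaults, **row} for row in rows])
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path

    return _write


def tiny_scenario(code="AAA", n=500, b=0.3, a=0.3, **kw) -> CountryScenario:
    defaults = dict(
        country_code=code,
        n=n,
        pc_gdp_ppp=10_000.0,
        pop_share=1.0,
        gradients={
            "heard_of_aids": (a, b),
            "ever_tested": (0.4, 0.0),
            "condom_last": (0.2, 0.1),
        },
        wealth_law="uniform",
        weight_law="equal",
    )
    defaults.update(kw)
    return CountryScenario(**defaults)
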