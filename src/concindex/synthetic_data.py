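"""Synthetic multi-country survey generator with analytic ground truth.

Each synthetic country draws household wealth from a lognormal (or
uniform) law, sampling weights from a mean-one gamma (or equal) law, and
binary responses from a *linear-in-rank* probability model:

    P(h_j = 1 | r) = a_j + b_j * r,

where r is the respondent's true fractional position in the country's
wealth distribution. The linear model is chosen over a logistic one
because it admits an exact closed-form concentration index,

    CI = b / (6 mu),        mu = a + b/2,

(Wagstaff-normalized: b / (6 mu (1 - mu))), obtained from
CI = (2/mu) * ∫ r (a + b r) dr − 1 with r uniform on (0,1). That gives
every estimator in the package an analytic target. Missingness is
applied completely at random; real surveys' informative missingness and
cluster-sampling geometry are deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ranking import weighted_fractional_rank
from .survey_data import INDICATOR_COLUMNS, KNOWLEDGE_ITEMS, STANDARD_COLUMNS

__all__ = [
    "CountryScenario",
    "generate_country_survey",
    "generate_multicountry",
    "true_ci_linear_model",
    "default_scenarios",
    "scenario_truth",
]

#: Binary indicators drawn directly from a (a, b) gradient.
GRADIENT_INDICATORS = ["heard_of_aids", "ever_tested", "condom_last"]


@dataclass(frozen=True)
class CountryScenario:
    """Generating parameters for one synthetic country survey.

    ``gradients`` maps each of heard_of_aids / ever_tested / condom_last
    to its (intercept a, slope b); ``knowledge_items`` holds four such
    pairs for the knowledge questions. Validity requires 0 < a < 1 and
    0 < a + b < 1 (slopes may be negative). ``missing_rate`` is the
    MCAR missingness probability applied per indicator.
    """

    country_code: str
    n: int
    pc_gdp_ppp: float
    pop_share: float
    gradients: dict[str, tuple[float, float]]
    knowledge_items: tuple[tuple[float, float], ...] = (
        (0.6, 0.2), (0.55, 0.2), (0.4, 0.25), (0.45, 0.25),
    )
    wealth_law: str = "lognormal"
    wealth_sigma: float = 0.6
    weight_law: str = "gamma"
    weight_shape: float = 2.0
    missing_rate: float = 0.0
    program: str = "MICS"
    year_label: str = "2015"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("scenario needs n ≥ 2")
        if self.pc_gdp_ppp <= 0:
            raise ValidationError("pc_gdp_ppp must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.wealth_law not in ("lognormal", "uniform"):
            raise ValidationError(f"unknown wealth_law {self.wealth_law!r}")
        if self.weight_law not in ("equal", "gamma"):
            raise ValidationError(f"unknown weight_law {self.weight_law!r}")
        missing = [k for k in GRADIENT_INDICATORS if k not in self.gradients]
        if missing:
            raise ValidationError(f"gradients missing for {missing}")
        if len(self.knowledge_items) != 4:
            raise ValidationError("knowledge_items must hold four (a, b) pairs")
        for name, (a, b) in {**self.gradients,
                             **{f"k{i}": ab for i, ab in
                                enumerate(self.knowledge_items)}}.items():
            if not (0 < a < 1 and 0 < a + b < 1):
                raise ValidationError(
                    f"indicator {name!r}: need 0 < a < 1 and 0 < a+b < 1, "
                    f"got (a, b) = ({a}, {b})"
                )


def true_ci_linear_model(a: float, b: float, normalized: bool = False) -> float:
    """Exact concentration index of the linear-in-rank Bernoulli model.

    For P(h=1|r) = a + b·r with r ~ Uniform(0,1): CI = b/(6 mu) with
    mu = a + b/2; the Wagstaff-normalized value divides by (1 − mu).
    """
    mu = a + b / 2.0
    if mu <= 0 or mu >= 1:
        raise ValidationError(f"degenerate model: mean {mu!r} not in (0,1)")
    ci = b / (6.0 * mu)
    return ci / (1.0 - mu) if normalized else ci


def generate_country_survey(scenario: CountryScenario, seed: int) -> pd.DataFrame:
    """Draw one country's respondent table (standard schema, no missing
    weights or wealth) reproducibly from ``seed``."""
    rng = np.random.default_rng(seed)
    n = scenario.n

    if scenario.wealth_law == "lognormal":
        wealth = rng.lognormal(mean=0.0, sigma=scenario.wealth_sigma, size=n)
    else:
        wealth = rng.uniform(0.0, 1.0, size=n)
    if scenario.weight_law == "equal":
        weight = np.ones(n)
    else:
        weight = rng.gamma(scenario.weight_shape, 1.0 / scenario.weight_shape, n)
        weight = np.maximum(weight, 1e-6)

    # True fractional position in the country's wealth distribution.
    r = weighted_fractional_rank(wealth, np.ones(n))

    df = pd.DataFrame(
        {
            "country_code": scenario.country_code,
            "program": scenario.program,
            "year_label": scenario.year_label,
            "weight": weight,
            "wealth_index": wealth,
            "age": rng.integers(15, 25, size=n),
        }
    )
    for name in GRADIENT_INDICATORS:
        a, b = scenario.gradients[name]
        df[name] = (rng.random(n) < a + b * r).astype(float)
    for item, (a, b) in zip(KNOWLEDGE_ITEMS, scenario.knowledge_items):
        df[item] = (rng.random(n) < a + b * r).astype(float)

    if scenario.missing_rate > 0:
        for col in INDICATOR_COLUMNS:
            mask = rng.random(n) < scenario.missing_rate
            df.loc[mask, col] = np.nan
    return df.loc[:, STANDARD_COLUMNS]


def generate_multicountry(
    scenarios: list[CountryScenario],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate country surveys and build the matching metadata table.

    Country seeds are spawned deterministically from the master seed, so
    adding a country does not perturb the others' draws.
    """
    codes = [s.country_code for s in scenarios]
    if len(set(codes)) != len(codes):
        raise ValidationError(f"duplicate country codes in scenarios: {codes}")
    total = sum(s.pop_share for s in scenarios)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"pop_shares must sum to 1, got {total!r}")

    children = np.random.SeedSequence(seed).spawn(len(scenarios))
    frames = [
        generate_country_survey(s, int(child.generate_state(1)[0]))
        for s, child in zip(scenarios, children)
    ]
    records = pd.concat(frames, ignore_index=True)
    meta = pd.DataFrame(
        {
            "country_code": codes,
            "pc_gdp_ppp": [s.pc_gdp_ppp for s in scenarios],
            "pop_share": [s.pop_share for s in scenarios],
        }
    )
    return records, meta


def default_scenarios(n_per_country: int = 3000) -> list[CountryScenario]:
    """A six-country region emulating the study's structure at desk scale.

    Countries span a five-fold pc-GDP-PPP range; awareness, knowledge
    and condom-use prevalence rise with national income (a between-
    country gradient on top of the within-country slopes), while
    HIV-testing prevalence is unrelated to income — mirroring the
    qualitative pattern the method is meant to detect. Population
    shares are unequal so inter-mode weighting matters.
    """
    gdps = [5000.0, 8000.0, 12000.0, 16000.0, 20000.0, 25000.0]
    shares = [0.10, 0.15, 0.25, 0.20, 0.18, 0.12]
    heard_a = [0.55, 0.62, 0.70, 0.75, 0.80, 0.84]
    condom_a = [0.12, 0.16, 0.20, 0.25, 0.30, 0.34]
    tested_a = [0.40, 0.30, 0.45, 0.25, 0.35, 0.40]
    know_a = [0.30, 0.36, 0.44, 0.50, 0.56, 0.62]
    scenarios = []
    for i, code in enumerate(["ALP", "BRV", "CRD", "DLT", "EST", "FNX"]):
        scenarios.append(
            CountryScenario(
                country_code=code,
                n=n_per_country,
                pc_gdp_ppp=gdps[i],
                pop_share=shares[i],
                gradients={
                    "heard_of_aids": (heard_a[i], 0.12),
                    "ever_tested": (tested_a[i], 0.05),
                    "condom_last": (condom_a[i], 0.15),
                },
                knowledge_items=tuple(
                    (min(know_a[i] + d, 0.75), 0.15) for d in (0.0, 0.05, -0.05, 0.02)
                ),
                missing_rate=0.02,
            )
        )
    return scenarios


def scenario_truth(scenarios: list[CountryScenario]) -> dict:
    """Analytic within-country CIs implied by each scenario's gradients."""
    truth: dict = {}
    for s in scenarios:
        entry = {}
        for name, (a, b) in s.gradients.items():
            entry[name] = {
                "a": a,
                "b": b,
                "mu": a + b / 2.0,
                "ci_standard": true_ci_linear_model(a, b, normalized=False),
                "ci_wagstaff": true_ci_linear_model(a, b, normalized=True),
            }
        truth[s.country_code] = entry
    return truth
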