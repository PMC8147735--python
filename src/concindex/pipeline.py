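"""Full-analysis orchestration: descriptives, intra- and inter-country CIs.

Three products mirror the standard reporting shape of a multi-country
inequality study:

* a descriptive table of survey-weighted means with normal 95%
  intervals per country-survey and indicator;
* an intra-country matrix of Wagstaff-normalized concentration indices
  (one row per country, one column per indicator, ``NS`` where the
  estimate is not significantly different from zero, ``NA`` where the
  survey did not carry the indicator);
* an inter-country summary: one region-level CI per indicator from the
  pooled sample ranked on GDP-PPP-scaled wealth with population-share
  weights.

Every cell is reproducible in isolation by building the corresponding
:class:`~concindex.ranking.RankedSample` and calling
:func:`concindex.concentration.estimate`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concentration, ranking, survey_data
from .errors import ConfigError, MetadataError
from .ranking import RankedSample

logger = logging.getLogger(__name__)

#: Analysis indicators in reporting order, with theoretical bounds.
INDICATOR_BOUNDS: dict[str, tuple[float, float]] = {
    "heard_of_aids": (0.0, 1.0),
    "knowledge_score": (0.0, 4.0),
    "ever_tested": (0.0, 1.0),
    "condom_last": (0.0, 1.0),
}
DEFAULT_INDICATORS = list(INDICATOR_BOUNDS)

#: Indicators reported as percentages in the descriptive table.
_PERCENT_INDICATORS = {"heard_of_aids", "ever_tested", "condom_last"}

REGION_LABEL = "REGION"


@dataclass
class InequalityTable:
    """Country × indicator matrix of CI estimates with NS/NA markers.

    ``cells`` is the long-form record of every estimate; ``rendered()``
    pivots it into the familiar matrix, printing the point estimate to
    three decimals, ``NS`` when not significant at the stated level and
    ``NA`` where the indicator is absent from that country's survey.
    """

    cells: pd.DataFrame  # columns: country_code, indicator, n, mu, value, ...

    def rendered(self) -> pd.DataFrame:
        def fmt(row: pd.Series) -> str:
            if row["status"] == "NA":
                return "NA"
            if not row["significant"]:
                return "NS"
            return f"{row['value']:.3f}"

        out = self.cells.copy()
        out["cell"] = out.apply(fmt, axis=1)
        wide = out.pivot(index="country_code", columns="indicator", values="cell")
        cols = [c for c in DEFAULT_INDICATORS if c in wide.columns]
        wide = wide.loc[:, cols]
        if REGION_LABEL in wide.index:  # region row first, countries alphabetical
            order = [REGION_LABEL] + sorted(i for i in wide.index if i != REGION_LABEL)
            wide = wide.loc[order]
        return wide


def prepare_records(
    records: pd.DataFrame,
    *,
    never_heard_policy: str = "zero",
    missing_item_policy: str = "missing",
) -> pd.DataFrame:
    """Attach the derived 0-4 knowledge score to eligible respondents."""
    out = survey_data.filter_eligible(records)
    out = out.copy()
    out["knowledge_score"] = survey_data.build_knowledge_score(
        out,
        never_heard_policy=never_heard_policy,
        missing_item_policy=missing_item_policy,
    )
    return out


def _weighted_mean_se(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted mean and its linearized standard error.

    Uses the standard first-order approximation for a ratio-of-sums
    mean with sampling weights and an n/(n-1) small-sample factor; no
    design effects (clusters/strata) enter, matching intervals that may
    extend past a proportion's logical range.
    """
    wt = w / w.sum()
    mean = float(np.sum(wt * x))
    n = x.size
    if n < 2:
        return mean, float("nan")
    var = float(np.sum(wt**2 * (x - mean) ** 2)) * n / (n - 1)
    return mean, float(np.sqrt(var))


def descriptive_table(
    records: pd.DataFrame,
    indicators: list[str] | None = None,
) -> pd.DataFrame:
    """Survey-weighted means with 95% intervals per country-survey.

    Returns a long DataFrame (country_code, program, variable, n, mean,
    se, ci_low, ci_high). Age is always included; binary indicators are
    reported on the percent scale; each indicator uses its own
    complete cases, so Ns differ across columns. An indicator entirely
    missing for a country-survey yields an ``NA`` row (n = 0).
    """
    indicators = list(indicators or DEFAULT_INDICATORS)
    rows = []
    for (code, program), grp in records.groupby(
        ["country_code", "program"], sort=True
    ):
        w_all = grp["weight"].to_numpy(dtype=float)
        for var in ["age", *indicators]:
            x = grp[var].to_numpy(dtype=float)
            ok = ~np.isnan(x)
            scale = 100.0 if var in _PERCENT_INDICATORS else 1.0
            if ok.sum() == 0:
                rows.append(
                    dict(country_code=code, program=program, variable=var,
                         n=0, mean=np.nan, se=np.nan,
                         ci_low=np.nan, ci_high=np.nan)
                )
                continue
            mean, se = _weighted_mean_se(x[ok] * scale, w_all[ok])
            rows.append(
                dict(
                    country_code=code, program=program, variable=var,
                    n=int(ok.sum()), mean=mean, se=se,
                    ci_low=mean - 1.96 * se, ci_high=mean + 1.96 * se,
                )
            )
    return pd.DataFrame(rows)


def _complete_case_sample(
    grp: pd.DataFrame,
    indicator: str,
    ranking_values: np.ndarray,
    weights: np.ndarray,
    bounds: tuple[float, float],
    label: str,
) -> RankedSample | None:
    """Listwise-deleted RankedSample for one cell; None if < 2 cases.

    Ranks and weight totals are rebuilt on the complete cases so the
    rank mean stays exactly 1/2 for the analyzed subsample.
    """
    h = grp[indicator].to_numpy(dtype=float)
    ok = ~np.isnan(h)
    if ok.sum() < 2:
        return None
    r = ranking.weighted_fractional_rank(ranking_values[ok], weights[ok])
    return RankedSample(h=h[ok], r=r, w=weights[ok], bounds=bounds, label=label)


def intra_country_table(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    indicators: list[str] | None = None,
    *,
    normalize: bool = True,
    alpha: float = 0.05,
    relevance: float = concentration.RELEVANCE_THRESHOLD,
    wealth_normalization: str = "minmax",
) -> InequalityTable:
    """Within-country CI matrix, ranking on the household wealth index.

    MICS and DHS records pooled under one country are ranked together
    after min-max normalizing wealth within each survey (the two
    programs' asset indices are on unrelated scales); for a
    single-survey country that normalization is a monotone transform
    and leaves the CI untouched. Weights are intra-mode (mean one per
    country-survey). No GDP scaling enters here.
    """
    indicators = list(indicators or DEFAULT_INDICATORS)
    known = set(meta["country_code"])
    missing = sorted(set(records["country_code"]) - known)
    if missing:
        raise MetadataError(f"countries absent from metadata: {missing}")

    cells = []
    for code, grp in records.groupby("country_code", sort=True):
        grp = grp.reset_index(drop=True)
        wealth = grp["wealth_index"].to_numpy(dtype=float)
        if grp["program"].nunique() > 1:
            survey_key = (grp["country_code"] + "|" + grp["program"]).to_numpy()
            rank_var = ranking.normalize_wealth_within_country(
                wealth, survey_key, method=wealth_normalization
            )
        else:
            rank_var = wealth
        w = ranking.normalize_weights(grp, meta, mode="intra")
        for ind in indicators:
            sample = _complete_case_sample(
                grp, ind, rank_var, w, INDICATOR_BOUNDS[ind], f"{code}:{ind}"
            )
            if sample is None:
                cells.append(
                    dict(country_code=code, indicator=ind, status="NA",
                         n=0, mu=np.nan, value=np.nan, se=np.nan,
                         ci_low=np.nan, ci_high=np.nan,
                         significant=False, relevant=False, pro_rich=False)
                )
                continue
            est = concentration.estimate(
                sample, normalize=normalize, alpha=alpha, relevance=relevance
            )
            cells.append(_estimate_row(code, ind, est))
    return InequalityTable(cells=pd.DataFrame(cells))


def _estimate_row(code: str, ind: str, est: concentration.CIEstimate) -> dict:
    return dict(
        country_code=code, indicator=ind, status="OK", n=est.n, mu=est.mu,
        value=est.value, se=est.se, ci_low=est.ci95[0], ci_high=est.ci95[1],
        significant=est.significant, relevant=est.relevant,
        pro_rich=est.pro_rich,
    )


def inter_country_summary(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    indicators: list[str] | None = None,
    *,
    normalize: bool = True,
    alpha: float = 0.05,
    relevance: float = concentration.RELEVANCE_THRESHOLD,
    wealth_normalization: str = "minmax",
) -> list[concentration.CIEstimate]:
    """Region-level CI per indicator from the pooled multi-country sample.

    Respondents are ranked on within-country-normalized wealth scaled
    by pc-GDP-PPP; weights are inter-mode, so each country's total
    analysis weight equals its share of the region's female 15-24
    population. The same Wagstaff normalization as the intra-country
    estimates is applied.
    """
    indicators = list(indicators or DEFAULT_INDICATORS)
    grp = records.reset_index(drop=True)
    survey_key = (grp["country_code"] + "|" + grp["program"]).to_numpy()
    norm_wealth = ranking.normalize_wealth_within_country(
        grp["wealth_index"].to_numpy(dtype=float),
        survey_key,
        method=wealth_normalization,
    )
    if wealth_normalization == "minmax":
        scaled = ranking.intercountry_scaled_wealth(
            norm_wealth, grp["country_code"].to_numpy(), meta
        )
    else:  # additive shift keeps a monotone-in-GDP ordering for z-scores
        scaled = ranking.intercountry_scaled_wealth(
            (norm_wealth - norm_wealth.min())
            / (norm_wealth.max() - norm_wealth.min()),
            grp["country_code"].to_numpy(),
            meta,
        )
    w = ranking.normalize_weights(grp, meta, mode="inter")

    estimates = []
    for ind in indicators:
        sample = _complete_case_sample(
            grp, ind, scaled, w, INDICATOR_BOUNDS[ind], f"{REGION_LABEL}:{ind}"
        )
        if sample is None:
            continue
        estimates.append(
            concentration.estimate(
                sample, normalize=normalize, alpha=alpha, relevance=relevance
            )
        )
    return estimates


def inter_summary_frame(estimates: list[concentration.CIEstimate]) -> pd.DataFrame:
    rows = [
        _estimate_row(REGION_LABEL, est.label.split(":", 1)[-1], est)
        for est in estimates
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Config-driven runs
# ---------------------------------------------------------------------------

_REQUIRED_CONFIG_KEYS = {"inputs"}


def load_config(config_path: str | Path) -> dict:
    """Load and validate a YAML run configuration."""
    path = Path(config_path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    problems = []
    for key in _REQUIRED_CONFIG_KEYS:
        if key not in cfg:
            problems.append(f"missing key {key!r}")
    inputs = cfg.get("inputs", {})
    for key in ("respondents", "country_meta"):
        if key not in inputs:
            problems.append(f"missing key 'inputs.{key}'")
    ci_cfg = cfg.get("ci", {})
    if "alpha" in ci_cfg and not 0 < ci_cfg["alpha"] < 1:
        problems.append("'ci.alpha' must be in (0,1)")
    if ci_cfg.get("normalize", "wagstaff") not in ("wagstaff", "none"):
        problems.append("'ci.normalize' must be 'wagstaff' or 'none'")
    if cfg.get("ranking", {}).get("normalization", "minmax") not in (
        "minmax", "zscore",
    ):
        problems.append("'ranking.normalization' must be 'minmax' or 'zscore'")
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    cfg["_config_dir"] = str(path.parent)
    return cfg


def run_analysis(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Run the whole analysis from a config file; returns the output dir.

    Writes ``descriptives.csv``, ``intra_ci.csv``, ``inter_ci.csv``,
    ``intra_ci_matrix.csv`` (the rendered NS/NA matrix),
    ``validation.json`` and ``run.log``. Deterministic: identical
    inputs and config give byte-identical outputs.
    """
    cfg = load_config(config_path)
    base = Path(cfg["_config_dir"])

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    out = Path(out_dir) if out_dir else resolve(cfg.get("output", "out"))

    respondents_paths = cfg["inputs"]["respondents"]
    if isinstance(respondents_paths, str):
        respondents_paths = [respondents_paths]
    column_map = cfg.get("column_map") or {}

    frames, reports = [], {}
    for p in respondents_paths:
        df, report = survey_data.read_survey_table(resolve(p), column_map)
        frames.append(df)
        reports[str(p)] = json.loads(report.to_json())
    records = survey_data.pool_surveys(frames)
    meta = survey_data.read_country_meta(resolve(cfg["inputs"]["country_meta"]))

    know = cfg.get("knowledge", {})
    records = prepare_records(
        records,
        never_heard_policy=know.get("never_heard_policy", "zero"),
        missing_item_policy=know.get("missing_item_policy", "missing"),
    )

    ci_cfg = cfg.get("ci", {})
    kwargs = dict(
        normalize=ci_cfg.get("normalize", "wagstaff") == "wagstaff",
        alpha=ci_cfg.get("alpha", 0.05),
        relevance=ci_cfg.get("relevance_threshold",
                             concentration.RELEVANCE_THRESHOLD),
        wealth_normalization=cfg.get("ranking", {}).get("normalization", "minmax"),
    )
    indicators = cfg.get("indicators") or DEFAULT_INDICATORS

    desc = descriptive_table(records, indicators)
    intra = intra_country_table(records, meta, indicators, **kwargs)
    inter = inter_country_summary(records, meta, indicators, **kwargs)
    inter_df = inter_summary_frame(inter)

    out.mkdir(parents=True, exist_ok=True)
    desc.to_csv(out / "descriptives.csv", index=False)
    intra.cells.to_csv(out / "intra_ci.csv", index=False)
    inter_df.to_csv(out / "inter_ci.csv", index=False)
    matrix = InequalityTable(
        cells=pd.concat([inter_df, intra.cells], ignore_index=True)
    ).rendered()
    matrix.to_csv(out / "intra_ci_matrix.csv")
    (out / "validation.json").write_text(
        json.dumps(reports, indent=2, sort_keys=True), encoding="utf-8"
    )

    cfg_bytes = Path(config_path).read_bytes()
    log_lines = [
        f"config_sha256: {hashlib.sha256(cfg_bytes).hexdigest()}",
        f"respondents: {int(len(records))}",
        f"countries: {int(records['country_code'].nunique())}",
    ]
    for ind in indicators:
        log_lines.append(f"n_{ind}: {int(records[ind].notna().sum())}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    logger.info("analysis written to %s", out)
    return out
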