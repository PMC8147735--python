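"""Socioeconomic ranking variables and analysis weights.

The concentration index ranks respondents by a socioeconomic variable.
Intra-country estimation ranks on the survey's household wealth index
directly; inter-country estimation first min-max normalizes the wealth
index within each country (the index is on a survey-specific scale) and
multiplies by the country's per-capita GDP at purchasing-power parity,
so that a poor household in a rich country can out-rank a rich household
in a poor one. Analysis weights are the survey sampling weights,
rescaled to mean one within each country-survey (intra mode) or to sum
to the country's share of the region's female 15-24 population (inter
mode).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MetadataError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "RankedSample",
    "weighted_fractional_rank",
    "normalize_wealth_within_country",
    "intercountry_scaled_wealth",
    "normalize_weights",
]


@dataclass
class RankedSample:
    """Aligned vectors for one CI estimation run.

    Attributes
    ----------
    h : indicator values, one per respondent, inside ``bounds``.
    r : weighted fractional ranks in (0,1), weighted mean 1/2.
    w : positive analysis weights (any scale; the CI is scale-invariant).
    bounds : theoretical (min, max) of the indicator, used by the
        Wagstaff normalization (binary: (0,1); knowledge score: (0,4)).
    label : free-text description for tables and logs.
    """

    h: np.ndarray
    r: np.ndarray
    w: np.ndarray
    bounds: tuple[float, float] = (0.0, 1.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not (self.h.shape == self.r.shape == self.w.shape) or self.h.ndim != 1:
            raise ValidationError("h, r, w must be 1-d vectors of equal length")
        if self.h.size == 0:
            raise ValidationError("empty sample")
        if np.isnan(self.h).any() or np.isnan(self.r).any() or np.isnan(self.w).any():
            raise ValidationError("missing values are not allowed in a RankedSample")
        if (self.w <= 0).any():
            raise ValidationError("analysis weights must be positive")
        a, b = self.bounds
        if not a < b:
            raise ValidationError(f"bounds must satisfy a < b, got {self.bounds}")
        if (self.h < a - 1e-12).any() or (self.h > b + 1e-12).any():
            raise ValidationError("indicator values outside declared bounds")
        if (self.r <= 0).any() or (self.r >= 1).any():
            raise ValidationError("fractional ranks must lie strictly in (0,1)")
        rbar = float(np.average(self.r, weights=self.w))
        if abs(rbar - 0.5) > 1e-9:
            raise ValidationError(
                f"weighted mean of fractional ranks is {rbar!r}, expected 1/2"
            )

    @property
    def n(self) -> int:
        return int(self.h.size)

    @property
    def mu(self) -> float:
        """Weighted mean of the indicator."""
        return float(np.average(self.h, weights=self.w))


def weighted_fractional_rank(ranking_var, w) -> np.ndarray:
    """Weighted fractional ranks in (0,1), poorest to richest.

    After ordering by ``ranking_var`` ascending, respondent *i* receives

        r_i = (W_before + w_i / 2) / W_total,

    the weight-share of strictly poorer respondents plus half her own.
    Ties form a block and share the block's mean rank
    ``(W_before_block + W_block/2) / W_total``, which makes the rank —
    and every downstream CI — invariant to the input ordering. Ranks are
    returned in the original order and have weighted mean exactly 1/2.
    """
    x = np.asarray(ranking_var, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.ndim != 1 or x.shape != w.shape:
        raise ValidationError("ranking_var and w must be 1-d and equally long")
    if x.size == 0:
        raise ValidationError("cannot rank an empty sample")
    if np.isnan(x).any():
        raise ValidationError("ranking variable contains missing values")
    if (w <= 0).any() or np.isnan(w).any():
        raise ValidationError("weights must be positive and non-missing")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    ws = w[order]
    total = ws.sum()

    # Tie blocks: first index of each run of equal ranking values.
    block_start = np.r_[True, xs[1:] != xs[:-1]]
    block_id = np.cumsum(block_start) - 1
    block_w = np.bincount(block_id, weights=ws)
    cum_before = np.r_[0.0, np.cumsum(block_w)[:-1]]
    block_rank = (cum_before + block_w / 2.0) / total

    r_sorted = block_rank[block_id]
    r = np.empty_like(r_sorted)
    r[order] = r_sorted
    return r


def normalize_wealth_within_country(
    wealth,
    country,
    *,
    method: str = "minmax",
) -> np.ndarray:
    """Rescale the wealth index within each country group.

    ``minmax`` (default) maps each country's wealth onto [0,1]; a
    degenerate country (constant wealth) maps to 0.5 everywhere, with a
    warning. ``zscore`` standardizes to mean 0, sd 1 (degenerate: 0).
    Min-max is the default because it composes with the multiplicative
    GDP-PPP scaling: the product stays non-negative and monotone within
    country.
    """
    if method not in ("minmax", "zscore"):
        raise ValueError(f"unknown normalization method {method!r}")
    wealth = np.asarray(wealth, dtype=float)
    country = np.asarray(country)
    if wealth.shape != country.shape or wealth.ndim != 1:
        raise ValidationError("wealth and country must be 1-d and equally long")
    if np.isnan(wealth).any():
        raise ValidationError("wealth contains missing values among analysis rows")

    out = np.empty_like(wealth)
    for code in pd.unique(country):
        mask = country == code
        block = wealth[mask]
        lo, hi = block.min(), block.max()
        if method == "minmax":
            if hi == lo:
                warnings.warn(
                    f"country {code!r}: constant wealth index; using 0.5",
                    stacklevel=2,
                )
                out[mask] = 0.5
            else:
                out[mask] = (block - lo) / (hi - lo)
        else:
            sd = block.std(ddof=0)
            if sd == 0:
                warnings.warn(
                    f"country {code!r}: constant wealth index; using 0.0",
                    stacklevel=2,
                )
                out[mask] = 0.0
            else:
                out[mask] = (block - block.mean()) / sd
    return out


def intercountry_scaled_wealth(norm_wealth, country, meta: pd.DataFrame) -> np.ndarray:
    """Place country-normalized wealth on a common cross-country scale.

    Multiplies each respondent's normalized wealth (in [0,1]) by her
    country's pc-GDP-PPP. Only the induced ordering matters: the result
    is used solely as a ranking variable for the inter-country CI.
    """
    norm_wealth = np.asarray(norm_wealth, dtype=float)
    country = np.asarray(country)
    gdp = dict(zip(meta["country_code"], meta["pc_gdp_ppp"]))
    missing = [c for c in pd.unique(country) if c not in gdp or pd.isna(gdp[c])]
    if missing:
        raise MetadataError(f"pc_gdp_ppp missing for countries: {missing}")
    factors = np.array([gdp[c] for c in country], dtype=float)
    return norm_wealth * factors


def normalize_weights(
    records: pd.DataFrame,
    meta: pd.DataFrame | None,
    mode: str,
) -> np.ndarray:
    """Build analysis weights from the survey sampling weights.

    ``intra``: within each country-survey (``country_code`` ×
    ``program``), weights are rescaled to mean one, so a country's
    total weight equals its respondent count. The CI is invariant to
    weight scale; the rescaling only fixes reported effective Ns.

    ``inter``: weights are first rescaled to sum one within each
    country, then multiplied by the country's ``pop_share`` from
    ``meta``, so every country's total analysis weight equals its share
    of the region's female 15-24 population and the grand total is 1.
    A survey then speaks for its country's population size, not its
    sample size.
    """
    if mode not in ("intra", "inter"):
        raise ValueError(f"mode must be 'intra' or 'inter', got {mode!r}")
    w = records["weight"].to_numpy(dtype=float)
    if (w <= 0).any() or np.isnan(w).any():
        raise ValidationError("sampling weights must be positive")

    out = np.empty_like(w)
    if mode == "intra":
        groups = records.groupby(["country_code", "program"], sort=False).indices
        for _, idx in groups.items():
            out[idx] = w[idx] / w[idx].mean()
        return out

    if meta is None:
        raise MetadataError("inter-mode weights require country metadata")
    shares = dict(zip(meta["country_code"], meta["pop_share"]))
    groups = records.groupby("country_code", sort=False).indices
    for code, idx in groups.items():
        if code not in shares or pd.isna(shares[code]):
            raise MetadataError(f"pop_share missing for country {code!r}")
        out[idx] = w[idx] / w[idx].sum() * shares[code]
    return out
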