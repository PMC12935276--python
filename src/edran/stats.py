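"""Descriptive and correlational analyses of EDRan series, plus the
one-sample proportion power calculation used to judge dataset adequacy.

All outputs are tidy pandas frames so they can be written straight to CSV.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FEATURE_COLUMNS
from .event_data import MatchRecord


def _label_map(labels: Mapping[str, int] | Sequence[MatchRecord]) -> Mapping[str, int]:
    if isinstance(labels, Mapping):
        return labels
    return {rec.match_id: rec.result for rec in labels}


def winner_loser_curves(
    series: pd.DataFrame, labels: Mapping[str, int] | Sequence[MatchRecord]
) -> pd.DataFrame:
    """Mean ± sd EDRan of winners and losers per α and interval.

    The winner of a match is Team A when its label is 1, Team B otherwise
    (roles, not sides). Also returns the per-interval mean winner-minus-loser
    difference and its running (cumulative) sum over intervals.

    Returns a tidy frame: ``alpha, interval, winner_mean, winner_sd,
    loser_mean, loser_sd, mean_diff, cum_diff``.
    """
    labels = _label_map(labels)
    df = series.copy()
    df["label"] = df["match_id"].map(labels)
    if df["label"].isna().any():
        missing = df.loc[df["label"].isna(), "match_id"].unique()
        raise ValueError(f"missing result label for match(es): {list(missing)[:5]}")
    df["role"] = np.where(
        ((df["label"] == 1) & (df["team"] == "A")) | ((df["label"] == 0) & (df["team"] == "B")),
        "winner",
        "loser",
    )
    grouped = (
        df.groupby(["alpha", "interval", "role"])["H"].agg(["mean", "std"]).unstack("role")
    )
    out = pd.DataFrame(
        {
            "winner_mean": grouped[("mean", "winner")],
            "winner_sd": grouped[("std", "winner")],
            "loser_mean": grouped[("mean", "loser")],
            "loser_sd": grouped[("std", "loser")],
        }
    )
    out["mean_diff"] = out["winner_mean"] - out["loser_mean"]
    out = out.reset_index().sort_values(["alpha", "interval"]).reset_index(drop=True)
    out["cum_diff"] = out.groupby("alpha")["mean_diff"].cumsum()
    return out


def normality_gate(features: pd.DataFrame, alpha_level: float = 0.05) -> pd.DataFrame:
    """Shapiro–Wilk normality check per feature column.

    Returns ``feature, W, p_value, degenerate, rank_based_recommended``.
    A constant sample is reported as degenerate (p undefined). Rank-based
    methods are recommended whenever any non-degenerate feature rejects
    normality at ``alpha_level``.
    """
    cols = [c for c in features.columns if c in FEATURE_COLUMNS] or [
        c for c in features.columns if features[c].dtype.kind in "fc"
    ]
    rows = []
    for col in cols:
        x = np.asarray(features[col].dropna(), dtype=float)
        if x.size < 3:
            raise ValueError(f"feature {col}: need >= 3 observations, got {x.size}")
        if np.ptp(x) == 0:
            rows.append({"feature": col, "W": np.nan, "p_value": np.nan, "degenerate": True})
            continue
        w, p = sps.shapiro(x)
        rows.append({"feature": col, "W": w, "p_value": p, "degenerate": False})
    out = pd.DataFrame(rows)
    any_reject = bool((out.loc[~out["degenerate"], "p_value"] < alpha_level).any())
    out["rank_based_recommended"] = any_reject
    return out


def spearman_profile(features: pd.DataFrame) -> pd.DataFrame:
    """Spearman ρ between each ΔH_α(t_i) feature and the binary result.

    Average ranks handle ties (the label is binary, so ties dominate its
    ranks). A constant feature has undefined ρ and is reported as NaN.
    Returns ``feature, interval, rho, p_value, mean_rho`` where ``mean_rho``
    repeats the across-interval mean of the defined ρ values.
    """
    if "result" not in features.columns:
        raise ValueError("feature table must contain a 'result' column")
    y = np.asarray(features["result"], dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    rows = []
    for i, col in enumerate(FEATURE_COLUMNS, start=1):
        if col not in features.columns:
            continue
        x = np.asarray(features[col], dtype=float)
        if np.ptp(x) == 0:
            rows.append({"feature": col, "interval": i, "rho": np.nan, "p_value": np.nan})
            continue
        res = sps.spearmanr(x, y)
        rows.append({"feature": col, "interval": i, "rho": res.statistic, "p_value": res.pvalue})
    out = pd.DataFrame(rows)
    out["mean_rho"] = out["rho"].mean(skipna=True)
    return out


def proportion_power(
    n: int,
    p_obs: float,
    p0: float = 0.5,
    alpha_level: float = 0.05,
    method: str = "normal",
) -> float:
    """Post-hoc power of a two-sided one-sample proportion test.

    ``method="normal"`` (default) uses the unpooled normal approximation:
    critical bounds ``p0 ± z_{1-α/2}·SE0`` with ``SE0 = sqrt(p0(1-p0)/n)``,
    and the sampling distribution under the alternative uses
    ``SE1 = sqrt(p_obs(1-p_obs)/n)``; power is the probability (both tails)
    that the sample proportion falls outside the bounds. ``method="exact"``
    uses the binomial rejection region at nominal α/2 per tail.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < p_obs < 1:
        raise ValueError(f"p_obs must be in (0, 1), got {p_obs}")
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if method == "normal":
        z = sps.norm.ppf(1 - alpha_level / 2)
        se0 = math.sqrt(p0 * (1 - p0) / n)
        se1 = math.sqrt(p_obs * (1 - p_obs) / n)
        lo, hi = p0 - z * se0, p0 + z * se0
        return float(sps.norm.sf((hi - p_obs) / se1) + sps.norm.cdf((lo - p_obs) / se1))
    if method == "exact":
        k = np.arange(n + 1)
        cdf0 = sps.binom.cdf(k, n, p0)
        sf0 = sps.binom.sf(k - 1, n, p0)
        lower = k[cdf0 <= alpha_level / 2]
        upper = k[sf0 <= alpha_level / 2]
        power = 0.0
        if lower.size:
            power += float(sps.binom.cdf(lower.max(), n, p_obs))
        if upper.size:
            power += float(sps.binom.sf(upper.min() - 1, n, p_obs))
        return power
    raise ValueError(f"method must be 'normal' or 'exact', got {method!r}")
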