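"""Internode certainty (ICA) from quartet tallies, support-vs-depth
regression, and the species-accumulation extrapolation.

For a focal branch, the quartet jackknife yields counts over the three
mutually exclusive quartet resolutions (one consistent with the branch, two
conflicting). With frequencies p_i the magnitude is the complement of the
normalized Shannon entropy in base 3,

    M = 1 + sum_{p_i > 0} p_i * log3(p_i),

signed positive when the focal resolution is strictly the most frequent and
negative otherwise. M is 1 when one resolution absorbs every replicate, and 0
when all three occur equally often.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quartet_support import QuartetTally

__all__ = [
    "ICAResult",
    "RegressionResult",
    "ica_from_tally",
    "regress_support_vs_depth",
    "extrapolate_accumulation",
]


@dataclass(frozen=True)
class ICAResult:
    branch: str
    ica: float
    p_focal: float
    p_alt1: float
    p_alt2: float
    sign_basis: str  # "strictly-max" | "tied" | "minority"
    log_base: int = 3

    def __post_init__(self):
        if abs(self.ica) > 1 + 1e-12:
            raise ValueError(f"|ICA| = {abs(self.ica)} exceeds 1")


def _entropy_complement(freqs: np.ndarray, base: int = 3) -> float:
    nz = freqs[freqs > 0]
    return 1.0 + float(np.sum(nz * np.log(nz) / math.log(base)))


def ica_from_tally(tally: QuartetTally, exclude_uninformative: bool = False) -> ICAResult:
    """ICA score for one branch's quartet-replicate tally.

    The sign is positive only when the focal count strictly exceeds both
    alternatives; an exact tie with the best alternative is scored negative
    and flagged ``tied``. With ``exclude_uninformative`` the replicates that
    carried no usable data (and hence were resolved at random) are removed
    from the denominator before computing frequencies.
    """
    counts = np.array(tally.counts, dtype=float)
    if exclude_uninformative and tally.uninformative_counts is not None:
        counts = counts - np.array(tally.uninformative_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"branch {tally.branch!r}: no replicates to score")
    freqs = counts / total
    m = _entropy_complement(freqs)
    m = min(max(m, 0.0), 1.0)  # clamp tiny float excursions at the endpoints
    focal, alt1, alt2 = counts
    best_alt = max(alt1, alt2)
    if focal > best_alt:
        sign_basis = "strictly-max"
        ica = m
    elif focal == best_alt:
        sign_basis = "tied"
        ica = -m
    else:
        sign_basis = "minority"
        ica = -m
    if ica == 0.0:
        ica = 0.0  # normalize -0.0
    return ICAResult(
        branch=tally.branch,
        ica=ica,
        p_focal=float(freqs[0]),
        p_alt1=float(freqs[1]),
        p_alt2=float(freqs[2]),
        sign_basis=sign_basis,
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r2: float
    pvalue: float
    n: int
    lower_excl: float | None
    upper_excl: float | None
    per_count: pd.DataFrame  # columns: count, mean_ica, sd_ica, n


def regress_support_vs_depth(
    points,
    lower_excl: float | None = None,
    upper_excl: float | None = None,
) -> RegressionResult:
    """OLS of ICA on decisive-locus count, optionally restricted to counts
    strictly between the exclusive bounds. Also returns per-count means and
    standard deviations of ICA (the dots and error bars of the usual
    support-vs-depth plot)."""
    df = pd.DataFrame(points, columns=["count", "ica"]).astype(float)
    if lower_excl is not None:
        df = df[df["count"] > lower_excl]
    if upper_excl is not None:
        df = df[df["count"] < upper_excl]
    if len(df) < 3:
        raise ValueError(f"regression needs >= 3 points after filtering, got {len(df)}")
    if np.ptp(df["ica"].to_numpy()) == 0.0:
        # constant response: flat line, no association
        class fit:  # noqa: N801 - mimics the linregress result fields
            slope = 0.0
            intercept = float(df["ica"].iloc[0])
            rvalue = 0.0
            pvalue = 1.0
    else:
        fit = stats.linregress(df["count"], df["ica"])
    per_count = (
        df.groupby("count")["ica"]
        .agg(mean_ica="mean", sd_ica="std", n="size")
        .reset_index()
        .sort_values("count", ignore_index=True)
    )
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r2=float(fit.rvalue) ** 2,
        pvalue=float(fit.pvalue),
        n=len(df),
        lower_excl=lower_excl,
        upper_excl=upper_excl,
        per_count=per_count,
    )


def extrapolate_accumulation(
    current_species: int, goal: int, rate_per_year: float, base_year: int = 2012
) -> tuple[int, int]:
    """Years (ceiling) until a linear species-accumulation rate reaches the
    goal, and the corresponding calendar year."""
    if rate_per_year <= 0:
        raise ValueError("accumulation rate must be positive")
    if goal < current_species:
        raise ValueError("goal below current species count")
    years = math.ceil((goal - current_species) / rate_per_year)
    return years, base_year + years
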