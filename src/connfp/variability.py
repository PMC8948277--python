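"""Across-participant edge variability and its group statistics.

The separating marker proposed for the fingerprinting/prediction
dissociation is the standard deviation of an edge's connectivity across
participants: highly discriminatory edges sit in the upper tail of the SD
distribution, while behaviour-predictive edges show intermediate
variability.  This module computes per-edge SDs, their percentile-mask
overlap with the differential-power signature, and heteroscedastic group
comparisons (Welch ANOVA with an omega-squared effect size, Games–Howell
post hocs, FDR-corrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from statsmodels.stats.multitest import multipletests

from .connectome import ConnectomeSet
from .fingerprint import DPVector, threshold_percentile
from .overlap import OverlapResult, edge_overlap_test

__all__ = [
    "EdgeStats",
    "GroupComparison",
    "edge_sd",
    "sd_overlap",
    "welch_anova",
    "games_howell",
]


@dataclass
class EdgeStats:
    """Per-edge sample SD across participants (z-connectivity units)."""

    sd: np.ndarray
    n_subjects: int
    basis: str = "session_mean"


@dataclass
class GroupComparison:
    groups: dict[str, np.ndarray]
    welch_F: float
    df1: float
    df2: float
    p: float
    omega_sq: float
    posthoc: pd.DataFrame


def edge_sd(connectomes: ConnectomeSet, basis: str = "session_mean") -> EdgeStats:
    """Sample SD (ddof=1) of every edge across participants.

    ``basis`` selects what enters the SD for each subject: the mean of the
    two session matrices (default), a single session (``"session1"`` /
    ``"session2"``), or all session vectors pooled as observations
    (``"pooled"``).
    """
    if connectomes.n_subjects < 2:
        raise ValueError("edge SD needs at least 2 subjects")
    if basis == "session_mean":
        values = connectomes.session_mean()
    elif basis.startswith("session"):
        values = connectomes.session(int(basis.removeprefix("session")) - 1)
    elif basis == "pooled":
        values = connectomes.data.reshape(-1, connectomes.n_edges)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return EdgeStats(
        sd=values.std(axis=0, ddof=1),
        n_subjects=connectomes.n_subjects,
        basis=basis,
    )


def sd_overlap(
    dp: DPVector,
    stats: EdgeStats,
    pct: float = 99,
    n_perm: int = 1000,
    seed: int | None = None,
) -> OverlapResult:
    """Overlap between high-DP edges and high-SD edges at one percentile.

    Both vectors are thresholded at the same percentile; the degree-
    preserving null rewires the SD mask while the DP mask stays fixed.
    """
    if dp.values.size != stats.sd.size:
        raise ValueError("DP and SD vectors must share the edge indexing")
    mask_dp = threshold_percentile(dp.values, pct=pct)
    mask_sd = threshold_percentile(stats.sd, pct=pct)
    return edge_overlap_test(mask_dp, mask_sd, n_perm=n_perm, seed=seed)


def _check_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        if v.std(ddof=1) == 0:
            raise ValueError(f"group {name!r} has zero variance")
        out[name] = v
    return out


def _long_format(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "value": np.concatenate(list(groups.values())),
            "group": np.repeat(list(groups.keys()), [len(v) for v in groups.values()]),
        }
    )


def welch_anova(groups: dict[str, np.ndarray]) -> tuple[float, float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA with an omega-squared estimate.

    Returns ``(F, df1, df2, p, omega_sq)`` with Welch–Satterthwaite df2 and
    ``omega_sq = df1 (F - 1) / (df1 (F - 1) + N_total)`` (an approximation
    appropriate for the unequal-variance setting).
    """
    groups = _check_groups(groups)
    res = pg.welch_anova(data=_long_format(groups), dv="value", between="group")
    F = float(res.loc[0, "F"])
    df1 = float(res.loc[0, "ddof1"])
    df2 = float(res.loc[0, "ddof2"])
    p = float(res.loc[0, "p_unc"])
    n_total = sum(len(v) for v in groups.values())
    omega = df1 * (F - 1.0) / (df1 * (F - 1.0) + n_total)
    return F, df1, df2, p, max(0.0, omega)


def games_howell(groups: dict[str, np.ndarray], fdr: bool = True) -> pd.DataFrame:
    """Games–Howell pairwise post hocs, optionally Benjamini–Hochberg corrected.

    For each pair: Welch t on the mean difference, Welch–Satterthwaite df,
    two-sided p from the studentized-range distribution (q = t·sqrt(2),
    k = number of groups).  Returns a table with columns
    ``pair, mean_diff, t, df, p_raw, p_fdr``.
    """
    groups = _check_groups(groups)
    res = pg.pairwise_gameshowell(data=_long_format(groups), dv="value", between="group")
    table = pd.DataFrame(
        {
            "pair": [f"{a} vs {b}" for a, b in zip(res["A"], res["B"])],
            "mean_diff": res["diff"].to_numpy(float),
            "t": res["T"].to_numpy(float),
            "df": res["df"].to_numpy(float),
            "p_raw": res["pval"].to_numpy(float),
        }
    )
    if fdr:
        table["p_fdr"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    else:
        table["p_fdr"] = table["p_raw"]
    return table
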