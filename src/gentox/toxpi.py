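"""ToxPi-style weighted integration of endpoint potencies.

Each compound's per-endpoint benchmark concentrations are converted into
slice scores on [0, 1] and combined into a single prioritization score:

1. Missing, infinite, or above-top BMC confidence limits are substituted with
   10,000 uM (10 mM, the top-concentration cap).
2. BMCL and BMCU are each mapped to ``-log10(value in uM)`` and summed; the
   substitution-only baseline (two inactive limits) is shifted to 0 so
   inactive slices do not protrude from the origin.
3. Each slice is normalized by its maximum across compounds, giving 1 to the
   most potent compound on that slice (when any compound is active).
4. The overall score is the weighted sum of slice scores.  Default weights:
   the transcriptomic (TGx-DDI) BMC and the micronucleus BMC carry 1/3 each;
   the four DNA-damage biomarker BMCs (4H/24H p53, 4H/24H gamma-H2AX) carry
   1/12 each.

Confidence bands come from rescoring with all-BMCL (upper) and all-BMCU
(lower) inputs; profiles are ranked by overall score and clustered on their
slice-score vectors (Euclidean distance, average linkage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "SliceDefinition",
    "ToxPiProfile",
    "DEFAULT_SLICES",
    "SUBSTITUTION_UM",
    "score_profiles",
    "cluster_profiles",
    "profiles_frame",
]

SUBSTITUTION_UM = 10_000.0


@dataclass(frozen=True)
class SliceDefinition:
    """One pie slice: a named endpoint with a weight fraction."""

    name: str
    weight: float
    endpoint: str  # column prefix in the BMC table


DEFAULT_SLICES: tuple[SliceDefinition, ...] = (
    SliceDefinition("TGx-DDI", 1 / 3, "tgx_ddi"),
    SliceDefinition("MN", 1 / 3, "mn"),
    SliceDefinition("4H p53", 1 / 12, "p53_4h"),
    SliceDefinition("24H p53", 1 / 12, "p53_24h"),
    SliceDefinition("4H gH2AX", 1 / 12, "gh2ax_4h"),
    SliceDefinition("24H gH2AX", 1 / 12, "gh2ax_24h"),
)


@dataclass
class ToxPiProfile:
    """Per-compound weighted slice scores, overall score, CI, rank, cluster."""

    compound: str
    slice_scores: dict[str, float]
    overall: float
    ci_lower: float
    ci_upper: float
    rank: int | None = None
    cluster: int | None = None


def _substitute(value: float, top: float | None = None) -> float:
    """Apply the 10,000 uM substitution rule to one confidence limit."""
    if value is None or not np.isfinite(value) or value <= 0:
        return SUBSTITUTION_UM
    if top is not None and value > top:
        return SUBSTITUTION_UM
    return min(float(value), SUBSTITUTION_UM)


def _raw_slice_scores(
    bmc_table: pd.DataFrame,
    compounds: Sequence[str],
    slices: Sequence[SliceDefinition],
    top_conc: Mapping[str, float] | None,
    lower_col: str,
    upper_col: str,
    transform_each: bool,
) -> pd.DataFrame:
    baseline = (
        2.0 * -math.log10(SUBSTITUTION_UM)
        if transform_each
        else -math.log10(2.0 * SUBSTITUTION_UM)
    )
    rows = {}
    for compound in compounds:
        top = top_conc.get(compound) if top_conc else None
        rec = {}
        for sl in slices:
            key = (compound, sl.endpoint)
            if key in bmc_table.index:
                r = bmc_table.loc[key]
                lo = _substitute(r[lower_col], top)
                hi = _substitute(r[upper_col], top)
            else:
                lo = hi = SUBSTITUTION_UM
            if transform_each:
                raw = -math.log10(lo) + -math.log10(hi)
            else:
                raw = -math.log10(lo + hi)
            rec[sl.name] = raw - baseline
        rows[compound] = rec
    return pd.DataFrame(rows).T


def score_profiles(
    bmc_table: pd.DataFrame,
    slices: Sequence[SliceDefinition] = DEFAULT_SLICES,
    top_conc: Mapping[str, float] | None = None,
    transform_each: bool = True,
    compounds: Sequence[str] | None = None,
) -> list[ToxPiProfile]:
    """Score, rank, and band all compounds in a BMC table.

    Parameters
    ----------
    bmc_table : DataFrame
        Indexed by (compound, endpoint) with columns ``bmc``, ``bmcl``,
        ``bmcu`` in uM.  Missing endpoints are treated as inactive
        (substituted with 10,000 uM).
    slices : sequence of SliceDefinition
        Weights are re-normalized to sum to 1.
    top_conc : mapping, optional
        compound -> top tested concentration; BMC limits above it are
        substituted.
    transform_each : bool
        Transform-each-then-sum (``-log10 BMCL + -log10 BMCU``, default) or
        the alternative sum-then-transform reading.

    compounds : sequence of str, optional
        All compounds to score, including fully inactive ones absent from
        ``bmc_table`` (default: the compounds present in the table).

    Returns
    -------
    list of ToxPiProfile, ordered by rank (ties share a rank).
    """
    if compounds is None:
        compounds = list(bmc_table.index.get_level_values("compound").unique())
    if not compounds:
        raise ValueError("empty compound set")
    finite_bmcs = bmc_table[["bmcl", "bmcu"]].to_numpy(float)
    if np.any(finite_bmcs[np.isfinite(finite_bmcs)] < 0):
        raise ValueError("negative BMC limits are not meaningful")
    wsum = sum(sl.weight for sl in slices)
    if wsum <= 0:
        raise ValueError("slice weights must be positive")
    weights = {sl.name: sl.weight / wsum for sl in slices}

    def normalized(lower_col: str, upper_col: str) -> pd.DataFrame:
        raw = _raw_slice_scores(
            bmc_table, compounds, slices, top_conc, lower_col, upper_col,
            transform_each,
        )
        smax = raw.max(axis=0)
        norm = raw.copy()
        for col in raw.columns:
            norm[col] = raw[col] / smax[col] if smax[col] > 0 else 0.0
        return norm

    point = normalized("bmcl", "bmcu")
    upper = normalized("bmcl", "bmcl")  # all-lower-limit: most potent reading
    lower = normalized("bmcu", "bmcu")

    def overall(frame: pd.DataFrame) -> pd.Series:
        return sum(frame[name] * w for name, w in weights.items())

    ov = overall(point)
    ov_hi = overall(upper)
    ov_lo = overall(lower)

    order = ov.sort_values(ascending=False)
    ranks = order.rank(method="min", ascending=False).astype(int)

    profiles = []
    for compound in order.index:
        profiles.append(
            ToxPiProfile(
                compound=compound,
                slice_scores=point.loc[compound].to_dict(),
                overall=float(ov[compound]),
                ci_lower=float(min(ov_lo[compound], ov[compound])),
                ci_upper=float(max(ov_hi[compound], ov[compound])),
                rank=int(ranks[compound]),
            )
        )
    return profiles


def profiles_frame(profiles: Sequence[ToxPiProfile]) -> pd.DataFrame:
    """Tabular view of a profile set (one row per compound)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "compound": p.compound,
                **{f"slice:{k}": v for k, v in p.slice_scores.items()},
                "overall": p.overall,
                "ci_lower": p.ci_lower,
                "ci_upper": p.ci_upper,
                "rank": p.rank,
                "cluster": p.cluster,
            }
        )
    return pd.DataFrame(rows).set_index("compound")


def cluster_profiles(
    profiles: Sequence[ToxPiProfile], k: int = 2
) -> tuple[np.ndarray, dict[str, int]]:
    """Hierarchically cluster slice-score vectors; annotates ``cluster`` ids.

    Euclidean distance, average linkage; ids from cutting the tree into ``k``
    clusters (default 2).  Returns the scipy linkage matrix and the
    compound -> cluster-id mapping.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    names = [p.compound for p in profiles]
    keys = list(profiles[0].slice_scores)
    X = np.array([[p.slice_scores[k_] for k_ in keys] for p in profiles])
    Z = linkage(X, method="average", metric="euclidean")
    ids = fcluster(Z, t=k, criterion="maxclust")
    mapping = dict(zip(names, (int(i) for i in ids)))
    for p in profiles:
        p.cluster = mapping[p.compound]
    return Z, mapping


def plot_profiles(profiles: Sequence[ToxPiProfile], path: str) -> None:
    """Save a simple per-compound pie-profile figure (one wedge per slice)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(profiles)
    ncol = min(4, n)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow),
                             subplot_kw={"projection": "polar"})
    axes = np.atleast_1d(axes).ravel()
    for ax in axes[n:]:
        ax.set_visible(False)
    for ax, p in zip(axes, profiles):
        keys = list(p.slice_scores)
        widths = 2 * np.pi / len(keys)
        angles = np.arange(len(keys)) * widths
        ax.bar(angles, [p.slice_scores[k] for k in keys], width=widths,
               align="edge", alpha=0.7)
        ax.set_ylim(0, 1)
        ax.set_xticks(angles + widths / 2)
        ax.set_xticklabels(keys, fontsize=6)
        ax.set_yticklabels([])
        ax.set_title(f"{p.compound} ({p.overall:.2f})", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
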