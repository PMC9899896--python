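"""Micronucleus (MN) endpoint computation and positive/negative calling.

Well-level flow-cytometry summaries (MN events, nucleated events, %EMA-positive
nuclei, nuclei density) are reduced to per-concentration endpoints:

* ``%MN = 100 * MN events / nucleated events``
* ``fold MN`` — %MN relative to the plate-mean solvent control (control = 1)
* ``relative survival (RS) = 100 * treated nuclei/mL / mean control nuclei/mL``
* ``fold EMA`` — %apoptotic/necrotic (EMA-positive) relative to the control
  mean; a plain ratio, no percent scaling.

Concentrations with RS < 40 % (cytotoxicity) or fold-EMA > 4 (overt
apoptosis/necrosis) are gated out of the statistics.  A compound is called MN
positive when at least one non-gated concentration shows a >= 2.50-fold
increase in %MN together with a Holm-Sidak-adjusted Poisson-regression
p-value < 0.05 against the solvent controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WELL_COLUMNS",
    "MnCall",
    "compute_microflow_endpoints",
    "poisson_lrt_pvalue",
    "holm_sidak",
    "call_mn",
    "RS_GATE",
    "EMA_FOLD_GATE",
    "MN_FOLD_THRESHOLD",
]

WELL_COLUMNS = (
    "compound",
    "concentration",
    "replicate",
    "mn_events",
    "nucleated_events",
    "pct_ema_positive",
    "nuclei_per_ml",
    "is_control",
)

RS_GATE = 40.0  # % relative survival below which a concentration is gated
EMA_FOLD_GATE = 4.0  # fold-EMA above which a concentration is gated
MN_FOLD_THRESHOLD = 2.50


def _validate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    missing = set(WELL_COLUMNS) - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns: {sorted(missing)}")
    if (wells["nucleated_events"] <= 0).any():
        raise ValueError("zero nucleated events in at least one well")
    if (wells["mn_events"] < 0).any() or (
        wells["mn_events"] > wells["nucleated_events"]
    ).any():
        raise ValueError("mn_events must lie in [0, nucleated_events]")
    if not wells["is_control"].any():
        raise ValueError("no solvent-control wells present")
    if "plate" not in wells.columns:
        wells = wells.copy()
        wells["plate"] = 1
    return wells


def compute_microflow_endpoints(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-(compound, concentration) MN endpoints with gating flags.

    Returns a DataFrame indexed by (compound, concentration) with columns
    ``pct_mn``, ``fold_mn``, ``relative_survival``, ``fold_ema``, ``gated``
    and ``gate_reason``.  Gating (RS < 40 or fold-EMA > 4) is evaluated on
    the replicate-averaged endpoint, per the treatment-level exclusion rule.
    """
    wells = _validate_wells(wells)
    wells = wells.assign(
        pct_mn=100.0 * wells["mn_events"] / wells["nucleated_events"]
    )

    ctrl = wells[wells["is_control"]]
    ctrl_stats = ctrl.groupby("plate").agg(
        ctrl_density=("nuclei_per_ml", "mean"),
        ctrl_ema=("pct_ema_positive", "mean"),
        ctrl_pct_mn=("pct_mn", "mean"),
    )
    if (ctrl_stats["ctrl_density"] <= 0).any():
        raise ValueError("zero mean control nuclei density on a plate")

    treated = wells[~wells["is_control"]].merge(
        ctrl_stats, left_on="plate", right_index=True
    )
    rows = []
    for (compound, conc), grp in treated.groupby(
        ["compound", "concentration"], sort=True
    ):
        pct_mn = float(grp["pct_mn"].mean())
        fold_mn = pct_mn / float(grp["ctrl_pct_mn"].iloc[0]) if grp["ctrl_pct_mn"].iloc[0] > 0 else np.nan
        rs = 100.0 * float(grp["nuclei_per_ml"].mean()) / float(grp["ctrl_density"].iloc[0])
        ctrl_ema = float(grp["ctrl_ema"].iloc[0])
        fold_ema = float(grp["pct_ema_positive"].mean()) / ctrl_ema if ctrl_ema > 0 else np.nan
        reasons = []
        if rs < RS_GATE:
            reasons.append("cytotoxicity")
        if np.isfinite(fold_ema) and fold_ema > EMA_FOLD_GATE:
            reasons.append("ema")
        rows.append(
            {
                "compound": compound,
                "concentration": float(conc),
                "pct_mn": pct_mn,
                "fold_mn": fold_mn,
                "relative_survival": rs,
                "fold_ema": fold_ema,
                "gated": bool(reasons),
                "gate_reason": ";".join(reasons),
            }
        )
    out = pd.DataFrame(rows).set_index(["compound", "concentration"])
    return out


def poisson_lrt_pvalue(
    y_treated: np.ndarray,
    e_treated: np.ndarray,
    y_control: np.ndarray,
    e_control: np.ndarray,
) -> float:
    """Likelihood-ratio p-value for the treatment term in a Poisson log-linear
    model of event counts with a log-exposure offset.

    With a single treated-vs-control indicator the MLE rates are closed form
    (group events over group exposure), so the deviance reduces to
    ``2 * [y1 log r1 + y0 log r0 - (y1 + y0) log r_pool]``; the p-value is the
    chi-square(1) tail.
    """
    y1, e1 = float(np.sum(y_treated)), float(np.sum(e_treated))
    y0, e0 = float(np.sum(y_control)), float(np.sum(e_control))
    if e1 <= 0 or e0 <= 0:
        raise ValueError("non-positive exposure")
    r1, r0 = y1 / e1, y0 / e0
    rp = (y1 + y0) / (e1 + e0)

    def xlogy(a: float, b: float) -> float:
        return 0.0 if a == 0 else a * np.log(b)

    lrt = 2.0 * (xlogy(y1, r1) + xlogy(y0, r0) - xlogy(y1 + y0, rp))
    lrt = max(lrt, 0.0)
    return float(stats.chi2.sf(lrt, df=1))


def holm_sidak(pvalues: np.ndarray) -> np.ndarray:
    """Step-down Holm-Sidak adjustment.

    Raw p-values are ordered ascending and ``adj_i = max_{j<=i}
    1 - (1 - p_j)^(m - j + 1)`` (1-based j), capped at 1; returned in the
    original order.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        step = 1.0 - (1.0 - p[idx]) ** (m - i)
        running = max(running, step)
        adj_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class MnCall:
    """MN assay verdict for one compound.

    ``call`` is "positive", "negative", or "undetermined" (every concentration
    gated).  ``table`` holds the per-concentration evidence: fold MN, raw and
    Holm-Sidak-adjusted p-values, and gating flags.
    """

    compound: str
    call: str
    table: pd.DataFrame = field(repr=False, default=None)

    @property
    def positive(self) -> bool:
        return self.call == "positive"


def call_mn(
    wells: pd.DataFrame,
    summary: pd.DataFrame | None = None,
    alpha: float = 0.05,
    fold_threshold: float = MN_FOLD_THRESHOLD,
) -> dict[str, MnCall]:
    """Positive/negative MN calls per compound.

    Per non-gated concentration, MN event counts (offset: log nucleated
    events) are compared with the plate's solvent controls by a Poisson
    likelihood-ratio test; the per-concentration p-values of a compound are
    Holm-Sidak adjusted.  The compound is positive iff some non-gated
    concentration has fold MN >= ``fold_threshold`` and adjusted p < ``alpha``.
    """
    wells = _validate_wells(wells)
    if summary is None:
        summary = compute_microflow_endpoints(wells)
    ctrl = wells[wells["is_control"]]
    out: dict[str, MnCall] = {}
    for compound, comp_summary in summary.groupby(level="compound", sort=False):
        comp_summary = comp_summary.droplevel("compound")
        open_concs = comp_summary.index[~comp_summary["gated"]]
        if len(open_concs) == 0:
            out[compound] = MnCall(
                compound=compound, call="undetermined", table=comp_summary
            )
            continue
        pvals = []
        for conc in open_concs:
            grp = wells[
                (wells["compound"] == compound)
                & (wells["concentration"] == conc)
                & (~wells["is_control"])
            ]
            plates = grp["plate"].unique()
            ctrl_grp = ctrl[ctrl["plate"].isin(plates)]
            pvals.append(
                poisson_lrt_pvalue(
                    grp["mn_events"].to_numpy(float),
                    grp["nucleated_events"].to_numpy(float),
                    ctrl_grp["mn_events"].to_numpy(float),
                    ctrl_grp["nucleated_events"].to_numpy(float),
                )
            )
        adj = holm_sidak(np.array(pvals))
        table = comp_summary.copy()
        table["p_raw"] = np.nan
        table["p_adj"] = np.nan
        table.loc[open_concs, "p_raw"] = pvals
        table.loc[open_concs, "p_adj"] = adj
        hit = (
            (table.loc[open_concs, "fold_mn"] >= fold_threshold)
            & (table.loc[open_concs, "p_adj"] < alpha)
        ).any()
        out[compound] = MnCall(
            compound=compound,
            call="positive" if hit else "negative",
            table=table,
        )
    return out
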