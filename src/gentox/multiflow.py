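"""Multiplexed DNA-damage biomarker endpoints and mode-of-action (MoA) calls.

The assay multiplexes four biomarkers read at 4 h and 24 h post-exposure:

* **gamma-H2AX** (median fluorescence shift) — DNA double-strand breaks,
* **nuclear p53** (median fluorescence shift) — DNA-damage response,
* **phospho-histone H3 (p-H3)** (% positive events) — mitotic cells,
* **polyploidy** (% 8n events) — endoreduplication.

Each endpoint is expressed as a fold-change over the plate-mean solvent
control (control = 1).  Global Evaluation Factors (GEFs) — fold-change
thresholds calibrated on reference genotoxicants — define biologically
significant responses.  A clastogenic or aneugenic call requires at least two
of the four MoA-set biomarkers to meet or exceed their GEFs at two successive
non-gated concentrations ("robust"); two set biomarkers meeting their GEFs at
a single concentration gives a "weak" call.  Compounds meeting both set
criteria are pan-genotoxic; fewer than two biomarkers over GEF means
non-genotoxic.  Concentrations with > 80 % cytotoxicity (100 - relative
nuclei count at 24 h) are excluded from classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MULTIFLOW_WELL_COLUMNS",
    "GEFTable",
    "DEFAULT_GEF",
    "CLASTOGEN_BIOMARKERS",
    "ANEUGEN_BIOMARKERS",
    "MoACall",
    "compute_multiflow_endpoints",
    "call_moa",
    "CYTOTOXICITY_GATE",
]

MULTIFLOW_WELL_COLUMNS = (
    "compound",
    "concentration",
    "timepoint",
    "replicate",
    "mcf_gh2ax",
    "mcf_p53",
    "events_2n4n",
    "events_8n",
    "events_ph3_pos",
    "nuclei_per_ml",
    "is_control",
)

CYTOTOXICITY_GATE = 80.0  # % cytotoxicity (100 - RNC at 24H) above which gated

#: biomarker keys are "<timepoint> <endpoint>"
CLASTOGEN_BIOMARKERS = ("4H gh2ax", "24H gh2ax", "4H p53", "24H p53")
ANEUGEN_BIOMARKERS = ("4H ph3", "24H ph3", "24H polyploidy", "24H p53")


@dataclass(frozen=True)
class GEFTable:
    """Global Evaluation Factors: per-biomarker fold-change thresholds.

    The 24H p53 threshold belongs to both the clastogen and the aneugen sets.
    """

    thresholds: Mapping[str, float]

    def __post_init__(self) -> None:
        needed = set(CLASTOGEN_BIOMARKERS) | set(ANEUGEN_BIOMARKERS)
        missing = needed - set(self.thresholds)
        if missing:
            raise ValueError(f"GEF table missing biomarkers: {sorted(missing)}")
        if any(v <= 1.0 for v in self.thresholds.values()):
            raise ValueError("all GEF thresholds must exceed 1")

    def __getitem__(self, key: str) -> float:
        return self.thresholds[key]


DEFAULT_GEF = GEFTable(
    thresholds={
        "4H gh2ax": 1.51,
        "24H gh2ax": 2.11,
        "4H p53": 1.40,
        "24H p53": 1.45,
        "4H ph3": 1.71,
        "24H ph3": 1.52,
        "24H polyploidy": 5.86,
    }
)


def compute_multiflow_endpoints(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-(compound, concentration, timepoint) biomarker endpoints.

    Computes the gamma-H2AX and p53 shifts (treated MCF over mean control
    MCF), %polyploidy (``100 * 8n / (2n4n + 8n)``), %p-H3
    (``100 * pH3-positive / (2n4n + 8n)``), the relative nuclei count
    (``RNC = 100 * treated density / mean control density``), and every
    biomarker as a fold-change vs the control mean (control = 1).
    Cytotoxicity is ``100 - RNC`` at 24H; concentrations above the 80 %
    cytotoxicity gate are flagged ``gated``.
    """
    missing = set(MULTIFLOW_WELL_COLUMNS) - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns: {sorted(missing)}")
    if not wells["is_control"].any():
        raise ValueError("no solvent-control wells present")
    if (wells[["mcf_gh2ax", "mcf_p53"]] <= 0).any().any():
        raise ValueError("fluorescence intensities must be positive")
    wells = wells.copy()
    if "plate" not in wells.columns:
        wells["plate"] = 1

    total = wells["events_2n4n"] + wells["events_8n"]
    if (total <= 0).any():
        raise ValueError("zero total events in at least one well")
    wells["pct_polyploidy"] = 100.0 * wells["events_8n"] / total
    wells["pct_ph3"] = 100.0 * wells["events_ph3_pos"] / total

    ctrl = wells[wells["is_control"]]
    ctrl_stats = ctrl.groupby(["plate", "timepoint"]).agg(
        ctrl_gh2ax=("mcf_gh2ax", "mean"),
        ctrl_p53=("mcf_p53", "mean"),
        ctrl_poly=("pct_polyploidy", "mean"),
        ctrl_ph3=("pct_ph3", "mean"),
        ctrl_density=("nuclei_per_ml", "mean"),
    )
    if (ctrl_stats[["ctrl_gh2ax", "ctrl_p53", "ctrl_density"]] <= 0).any().any():
        raise ValueError("zero control MCF or density on a plate/timepoint")

    treated = wells[~wells["is_control"]].merge(
        ctrl_stats, left_on=["plate", "timepoint"], right_index=True
    )
    rows = []
    for (compound, conc, tp), grp in treated.groupby(
        ["compound", "concentration", "timepoint"], sort=True
    ):
        gh2ax_shift = float(grp["mcf_gh2ax"].mean() / grp["ctrl_gh2ax"].iloc[0])
        p53_shift = float(grp["mcf_p53"].mean() / grp["ctrl_p53"].iloc[0])
        pct_poly = float(grp["pct_polyploidy"].mean())
        pct_ph3 = float(grp["pct_ph3"].mean())
        rnc = 100.0 * float(grp["nuclei_per_ml"].mean() / grp["ctrl_density"].iloc[0])
        ctrl_poly = float(grp["ctrl_poly"].iloc[0])
        ctrl_ph3 = float(grp["ctrl_ph3"].iloc[0])
        rows.append(
            {
                "compound": compound,
                "concentration": float(conc),
                "timepoint": tp,
                "gh2ax_shift": gh2ax_shift,
                "p53_shift": p53_shift,
                "pct_polyploidy": pct_poly,
                "pct_ph3": pct_ph3,
                "rnc": rnc,
                "fold_gh2ax": gh2ax_shift,  # shifts are already fold-scale
                "fold_p53": p53_shift,
                "fold_polyploidy": pct_poly / ctrl_poly if ctrl_poly > 0 else np.nan,
                "fold_ph3": pct_ph3 / ctrl_ph3 if ctrl_ph3 > 0 else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index(["compound", "concentration", "timepoint"])

    # gate on 24H cytotoxicity; a concentration lacking a 24H record is kept
    cyto = 100.0 - out.xs("24H", level="timepoint")["rnc"]
    gated_concs = set(cyto.index[cyto > CYTOTOXICITY_GATE])
    out["cytotoxicity_24h"] = [
        float(cyto.loc[(c, x)]) if (c, x) in cyto.index else np.nan
        for c, x, _ in out.index
    ]
    out["gated"] = [(c, x) in gated_concs for c, x, _ in out.index]
    return out


def fold_table_from_endpoints(endpoints: pd.DataFrame, compound: str) -> pd.DataFrame:
    """Per-biomarker fold-changes over ordered concentrations for one compound.

    Rows: concentrations ascending (with the ``gated`` flag); columns: the
    seven GEF biomarkers keyed "<timepoint> <endpoint>".
    """
    sub = endpoints.xs(compound, level="compound")
    concs = sorted(sub.index.get_level_values("concentration").unique())
    rows = []
    for conc in concs:
        rec: dict[str, float | bool] = {"gated": False}
        for tp in ("4H", "24H"):
            key = (conc, tp)
            if key not in sub.index:
                continue
            r = sub.loc[key]
            rec[f"{tp} gh2ax"] = r["fold_gh2ax"]
            rec[f"{tp} p53"] = r["fold_p53"]
            rec[f"{tp} ph3"] = r["fold_ph3"]
            if tp == "24H":
                rec["24H polyploidy"] = r["fold_polyploidy"]
            rec["gated"] = rec["gated"] or bool(r["gated"])
        rows.append(pd.Series(rec, name=conc))
    return pd.DataFrame(rows)


@dataclass
class MoACall:
    """Mode-of-action verdict for one compound.

    ``call`` is clastogen, aneugen, pan-genotoxic, or non-genotoxic;
    ``strength`` is robust (two successive concentrations), weak
    (single-concentration evidence) or n/a.  ``support`` maps each positive
    MoA set to the (biomarker, concentration) pairs behind it.
    """

    call: str
    strength: str = "n/a"
    support: dict[str, list[tuple[str, float]]] = field(default_factory=dict)


def _set_evidence(
    hits: pd.DataFrame, biomarkers: tuple[str, ...], strict_consecutive: bool
) -> tuple[str | None, list[tuple[str, float]]]:
    """Evidence level for one MoA set over non-gated, ordered concentrations.

    Returns ("robust" | "weak" | None, supporting (biomarker, conc) pairs).
    Robust under the strict reading: the same >= 2 set biomarkers exceed
    their GEFs at two consecutive concentrations of the gated series; the
    looser reading accepts any >= 2 biomarkers robust anywhere with two
    consecutive concentrations each carrying >= 2 set hits.
    """
    cols = [b for b in biomarkers if b in hits.columns]
    sub = hits[cols]
    concs = list(sub.index)
    support: list[tuple[str, float]] = []

    if strict_consecutive:
        for i in range(len(concs) - 1):
            both = sub.iloc[i] & sub.iloc[i + 1]
            if int(both.sum()) >= 2:
                for b in sub.columns[both]:
                    support.extend([(b, concs[i]), (b, concs[i + 1])])
                return "robust", support
    else:
        per_conc = sub.sum(axis=1)
        for i in range(len(concs) - 1):
            if per_conc.iloc[i] >= 2 and per_conc.iloc[i + 1] >= 2:
                for j in (i, i + 1):
                    for b in sub.columns[sub.iloc[j]]:
                        support.append((b, concs[j]))
                return "robust", support

    # weak: >= 2 set biomarkers over GEF at one common concentration
    for i, conc in enumerate(concs):
        row = sub.iloc[i]
        if int(row.sum()) >= 2:
            support = [(b, conc) for b in sub.columns[row]]
            return "weak", support
    return None, []


def call_moa(
    fold_table: pd.DataFrame,
    gef: GEFTable = DEFAULT_GEF,
    strict_consecutive: bool = True,
) -> MoACall:
    """Classify a compound's MoA from its biomarker fold-change table.

    Parameters
    ----------
    fold_table : DataFrame
        Rows: concentrations ascending, columns: biomarker keys
        ("4H gh2ax", ..., "24H polyploidy") plus an optional boolean
        ``gated`` column; gated rows are removed before evaluating
        consecutiveness.
    gef : GEFTable
        Fold-change thresholds ("met or exceeded": >= counts as a hit).
    strict_consecutive : bool
        Strict reading of "two successive concentrations" (same biomarkers at
        both); the looser any-two-biomarkers reading when False.
    """
    if fold_table.empty:
        raise ValueError("empty fold table")
    table = fold_table.copy()
    if "gated" in table.columns:
        table = table[~table["gated"].astype(bool)].drop(columns="gated")
    if table.empty:
        return MoACall(call="non-genotoxic", strength="n/a")
    table = table.sort_index()

    hits = pd.DataFrame(index=table.index)
    for b in set(CLASTOGEN_BIOMARKERS) | set(ANEUGEN_BIOMARKERS):
        if b in table.columns:
            hits[b] = table[b].to_numpy(float) >= gef[b]

    clas_level, clas_support = _set_evidence(
        hits, CLASTOGEN_BIOMARKERS, strict_consecutive
    )
    aneu_level, aneu_support = _set_evidence(
        hits, ANEUGEN_BIOMARKERS, strict_consecutive
    )

    support: dict[str, list[tuple[str, float]]] = {}
    if clas_level:
        support["clastogen"] = clas_support
    if aneu_level:
        support["aneugen"] = aneu_support

    if clas_level and aneu_level:
        call = "pan-genotoxic"
    elif clas_level:
        call = "clastogen"
    elif aneu_level:
        call = "aneugen"
    else:
        return MoACall(call="non-genotoxic", strength="n/a")
    levels = [lv for lv in (clas_level, aneu_level) if lv]
    strength = "robust" if all(lv == "robust" for lv in levels) else "weak"
    return MoACall(call=call, strength=strength, support=support)
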