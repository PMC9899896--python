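"""End-to-end study orchestration and the integrated hazard-call rule.

The three assay verdicts for a compound — transcriptomic DDI call,
micronucleus (MN) call, and DNA-damage mode-of-action (MoA) call — are
combined into a single integrated category.  A compound positive in either
metabolic-activation (S9) condition of an assay counts as assay-positive
before the rule table applies:

=======  ====  ==============  ==============================
TGx-DDI  MN    MoA             integrated category
=======  ====  ==============  ==============================
pos      pos   clastogen       genotoxic-clastogen
pos      pos   aneugen         genotoxic-aneugen
pos      pos   pan-genotoxic   genotoxic-pan
neg      pos   non-genotoxic   likely-irrelevant-MN-positive
pos      pos   non-genotoxic   possibly-genotoxic-ambiguous
neg      neg   non-genotoxic   non-genotoxic
other combinations             possibly-genotoxic-ambiguous (noted)
=======  ====  ==============  ==============================

``run_study`` drives the full synthetic study: simulation, all three assay
callers, benchmark-concentration modeling, ToxPi integration, and the
integrated calls, writing tidy CSV outputs and a run log that records every
gate and filter decision.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import bmc as bmcmod
from . import microflow as mf
from . import multiflow as mflow
from . import simulate as sim
from . import toxpi as tp
from . import tgxddi

__all__ = ["IntegratedCall", "integrated_call", "collapse_s9", "run_study"]

logger = logging.getLogger("gentox")

CATEGORIES = (
    "genotoxic-clastogen",
    "genotoxic-aneugen",
    "genotoxic-pan",
    "likely-irrelevant-MN-positive",
    "possibly-genotoxic-ambiguous",
    "non-genotoxic",
)


@dataclass
class IntegratedCall:
    """Integrated hazard category for one compound, with the inputs behind it."""

    compound: str
    tgx: str  # "+" or "-"
    mn: str  # "+" or "-"
    moa: str  # clastogen | aneugen | pan-genotoxic | non-genotoxic
    category: str
    note: str = ""


def collapse_s9(calls: Mapping[str, bool] | bool) -> str:
    """Assay-positive ("+") if positive in any S9 condition."""
    if isinstance(calls, bool):
        return "+" if calls else "-"
    return "+" if any(calls.values()) else "-"


def integrated_call(
    compound: str, tgx: str, mn: str, moa: str | mflow.MoACall
) -> IntegratedCall:
    """Apply the integrated rule table to per-S9-collapsed assay calls."""
    if isinstance(moa, mflow.MoACall):
        moa = moa.call
    for name, v in (("tgx", tgx), ("mn", mn)):
        if v not in ("+", "-"):
            raise ValueError(f"{name} call must be '+' or '-', got {v!r}")
    if moa not in ("clastogen", "aneugen", "pan-genotoxic", "non-genotoxic"):
        raise ValueError(f"unknown MoA call {moa!r}")

    note = ""
    if (tgx, mn) == ("+", "+") and moa == "clastogen":
        cat = "genotoxic-clastogen"
    elif (tgx, mn) == ("+", "+") and moa == "aneugen":
        cat = "genotoxic-aneugen"
    elif (tgx, mn) == ("+", "+") and moa == "pan-genotoxic":
        cat = "genotoxic-pan"
    elif (tgx, mn) == ("-", "+") and moa == "non-genotoxic":
        cat = "likely-irrelevant-MN-positive"
    elif (tgx, mn) == ("+", "+") and moa == "non-genotoxic":
        cat = "possibly-genotoxic-ambiguous"
    elif (tgx, mn) == ("-", "-") and moa == "non-genotoxic":
        cat = "non-genotoxic"
    else:
        cat = "possibly-genotoxic-ambiguous"
        note = f"unmapped combination (tgx={tgx}, mn={mn}, moa={moa})"
        logger.info("compound %s: %s -> %s", compound, note, cat)
    return IntegratedCall(
        compound=compound, tgx=tgx, mn=mn, moa=moa, category=cat, note=note
    )


# --------------------------------------------------------------------------
# study driver
# --------------------------------------------------------------------------

_MULTIFLOW_TO_SLICE = {
    "4H p53": "p53_4h",
    "24H p53": "p53_24h",
    "4H gh2ax": "gh2ax_4h",
    "24H gh2ax": "gh2ax_24h",
}

DEFAULT_STUDY_CONFIG: dict = {
    "seed": 0,
    "simulation": {},  # overrides for SimulationConfig fields
    "bmc": {
        "n_perm": 100,
        "n_boot_gene": 40,
        "n_boot_median": 500,
        "n_boot_flow": 100,
    },
    "toxpi": {"k_clusters": 2},
}


def _load_config(config: str | Path | Mapping | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_STUDY_CONFIG.items()}
    if config is None:
        return merged
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    for key, value in dict(config).items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _simulation_config(cfg: dict, seed: int | None) -> sim.SimulationConfig:
    overrides = dict(cfg.get("simulation", {}))
    if "compounds" in overrides:
        overrides["compounds"] = tuple(
            sim.CompoundSpec(**c) for c in overrides["compounds"]
        )
    for key in ("concentrations", "flow_concentrations"):
        if key in overrides:
            overrides[key] = tuple(float(v) for v in overrides[key])
    if seed is not None:
        overrides["seed"] = int(seed)
    return sim.SimulationConfig(**overrides)


def _expression_gene_data(
    config: sim.SimulationConfig, compound: str
) -> dict[str, bmcmod.DoseResponseData]:
    """Per-gene replicate-level log2 responses for gene BMC modeling."""
    table = sim.simulate_expression_replicates(config)
    sub = table[table["compound"] == compound]
    out = {}
    for gene, grp in sub.groupby("gene", sort=False):
        out[gene] = bmcmod.DoseResponseData(
            concentrations=grp["concentration"].to_numpy(float),
            responses=grp["log2_expr"].to_numpy(float),
            endpoint_kind="log2-expression",
        )
    return out


def _flow_fold_data(
    wells: pd.DataFrame, value: pd.Series, compound: str
) -> bmcmod.DoseResponseData:
    """Replicate-level fold-change data (controls at x = 0, fold approx 1)."""
    mask = (wells["compound"] == compound) | wells["is_control"]
    sub = wells[mask & (wells["plate"] == compound)]
    ctrl_mean = value[sub.index[sub["is_control"]]].mean()
    folds = value[sub.index] / ctrl_mean
    return bmcmod.DoseResponseData(
        concentrations=sub["concentration"].to_numpy(float),
        responses=np.maximum(folds.to_numpy(float), 1e-9),
        endpoint_kind="fold-change",
    )


def run_study(
    config: str | Path | Mapping | None = None,
    outdir: str | Path = "results",
    seed: int | None = None,
) -> Path:
    """Simulate a study, run every assay caller, model BMCs, and integrate.

    Parameters
    ----------
    config : path, mapping or None
        YAML file or mapping with optional keys ``seed``, ``simulation``
        (SimulationConfig overrides), ``bmc`` (problem sizes), ``toxpi``.
    outdir : path
        Results directory (created; partial outputs removed on failure).
    seed : int, optional
        Overrides the config seed.

    Returns
    -------
    Path to the results directory.
    """
    outdir = Path(outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        cfg = _load_config(config)
        if seed is None:
            seed = int(cfg.get("seed", 0))
        simcfg = _simulation_config(cfg, seed)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(99,)))
        logger.info("seed=%d, %d compounds", seed, len(simcfg.compounds))

        # ---- simulate -------------------------------------------------
        training, samples, truth = sim.simulate_expression_study(simcfg)
        micro_wells, multi_wells = sim.simulate_flow_study(simcfg, truth)
        training.matrix.assign(label=training.labels).to_csv(outdir / "training_set.csv")
        samples.values.to_csv(outdir / "biomarker_matrix.csv")
        micro_wells.to_csv(outdir / "microflow_wells.csv", index=False)
        multi_wells.to_csv(outdir / "multiflow_wells.csv", index=False)

        # ---- TGx-DDI --------------------------------------------------
        clf = tgxddi.TgxDdiClassifier(training)
        logger.info("NSC shrinkage delta=%.4f (LOO CV)", clf.delta)
        tgx_table = clf.classify(samples)
        tgx_overall = clf.overall_calls(samples)
        tgx_table.to_csv(outdir / "tgx_concentration_calls.csv")
        tgx_overall.to_csv(outdir / "tgx_overall_calls.csv")

        # ---- MicroFlow ------------------------------------------------
        micro_summary = mf.compute_microflow_endpoints(micro_wells)
        for idx, row in micro_summary[micro_summary["gated"]].iterrows():
            logger.info("MN gate: %s excluded (%s)", idx, row["gate_reason"])
        mn_calls = mf.call_mn(micro_wells, micro_summary)
        micro_summary.to_csv(outdir / "microflow_endpoints.csv")
        pd.Series({k: v.call for k, v in mn_calls.items()}, name="mn_call").to_csv(
            outdir / "mn_calls.csv"
        )

        # ---- MultiFlow ------------------------------------------------
        multi_summary = mflow.compute_multiflow_endpoints(multi_wells)
        multi_summary.to_csv(outdir / "multiflow_endpoints.csv")
        moa_calls: dict[str, mflow.MoACall] = {}
        for spec in simcfg.compounds:
            fold_table = mflow.fold_table_from_endpoints(multi_summary, spec.name)
            for conc in fold_table.index[fold_table["gated"].astype(bool)]:
                logger.info("MoA gate: %s %.4g uM excluded (cytotoxicity > 80%%)",
                            spec.name, conc)
            moa_calls[spec.name] = mflow.call_moa(fold_table)
        pd.DataFrame(
            {k: {"moa_call": v.call, "strength": v.strength} for k, v in moa_calls.items()}
        ).T.to_csv(outdir / "moa_calls.csv")

        # ---- BMC modeling --------------------------------------------
        bmc_cfg = cfg["bmc"]
        bmc_rows = []
        positives = [
            s.name
            for s in simcfg.compounds
            if tgx_overall[s.name] == tgxddi.DDI
            or mn_calls[s.name].positive
            or moa_calls[s.name].call != "non-genotoxic"
        ]
        logger.info("BMC modeling for positive compounds: %s", positives)
        for name in positives:
            if tgx_overall[name] == tgxddi.DDI:
                gene_data = _expression_gene_data(simcfg, name)
                gs = bmcmod.gene_set_bmc(
                    gene_data,
                    n_perm=bmc_cfg["n_perm"],
                    n_boot=bmc_cfg["n_boot_median"],
                    n_boot_gene=bmc_cfg["n_boot_gene"],
                    sd=simcfg.noise_sd,
                    rng=rng,
                )
                logger.info("gene-set BMC %s: %s (filters %s)", name,
                            gs.median_bmc, gs.filter_counts)
                if not gs.empty:
                    bmc_rows.append((name, "tgx_ddi", gs.median_bmc,
                                     gs.ci_lower, gs.ci_upper))
            if mn_calls[name].positive:
                data = _flow_fold_data(micro_wells, 100.0 * micro_wells["mn_events"]
                                       / micro_wells["nucleated_events"], name)
                fit = bmcmod.fit_relative_bmc(data, ces=1.0,
                                              n_boot=bmc_cfg["n_boot_flow"], rng=rng)
                if fit.defined:
                    bmc_rows.append((name, "mn", fit.bmc, fit.bmcl, fit.bmcu))
            if moa_calls[name].call != "non-genotoxic":
                for biomarker, slice_name in _MULTIFLOW_TO_SLICE.items():
                    tp_, kind = biomarker.split(" ")
                    col = "mcf_gh2ax" if kind == "gh2ax" else "mcf_p53"
                    sub = multi_wells[multi_wells["timepoint"] == tp_]
                    data = _flow_fold_data(sub, sub[col], name)
                    fit = bmcmod.fit_relative_bmc(
                        data, ces=0.5, n_boot=bmc_cfg["n_boot_flow"], rng=rng
                    )
                    if fit.defined:
                        bmc_rows.append((name, slice_name, fit.bmc, fit.bmcl, fit.bmcu))
                    else:
                        logger.info("no %s BMC for %s (%s)", biomarker, name,
                                    ";".join(fit.flags))
        bmc_table = pd.DataFrame(
            bmc_rows, columns=["compound", "endpoint", "bmc", "bmcl", "bmcu"]
        ).set_index(["compound", "endpoint"])
        bmc_table.to_csv(outdir / "bmc_table.csv")

        # ---- ToxPi ----------------------------------------------------
        if len(bmc_table) and bmc_table.index.get_level_values("compound").nunique() >= 1:
            top_conc = {s.name: max(simcfg.flow_concentrations) for s in simcfg.compounds}
            profiles = tp.score_profiles(bmc_table, top_conc=top_conc)
            if len(profiles) >= 2:
                tp.cluster_profiles(profiles, k=min(cfg["toxpi"]["k_clusters"],
                                                    len(profiles)))
            tp.profiles_frame(profiles).to_csv(outdir / "toxpi_scores.csv")

        # ---- integrated calls ----------------------------------------
        rows = []
        for spec in simcfg.compounds:
            call = integrated_call(
                spec.name,
                collapse_s9(tgx_overall[spec.name] == tgxddi.DDI),
                collapse_s9(mn_calls[spec.name].positive),
                moa_calls[spec.name],
            )
            rows.append(vars(call))
        pd.DataFrame(rows).set_index("compound").to_csv(outdir / "integrated_calls.csv")
        logger.info("study complete")
        return outdir
    except Exception:
        logger.exception("study failed; removing partial outputs")
        for h in list(logger.handlers):
            logger.removeHandler(h)
            h.close()
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for f in outdir.glob("*.csv"):
                f.unlink()
        raise
    finally:
        if handler in logger.handlers:
            logger.removeHandler(handler)
            handler.close()
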