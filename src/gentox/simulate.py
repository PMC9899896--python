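"""Synthetic study generator with known ground truth.

Emulates the shape of an integrated in vitro genotoxicity screen on TK6
cells: a 28-chemical, two-class training set for the 64-gene transcriptomic
biomarker; test compounds profiled over a 6-point geometric concentration
series (70.71 % spacing) in duplicate; and 10-point flow-cytometry plates for
the micronucleus and DNA-damage biomarker assays, with solvent-control wells
on every plate.

Mean dose-response curves follow the 5-parameter exponential family
``fold(x) = c - (c - 1) * exp(-(x / b) ** d)`` (monotone for d >= 1) so every
generated compound has an analytically known benchmark concentration.  Noise
models: additive Gaussian on the log2 expression scale, Poisson counts for MN
events, binomial event counts for the ploidy/p-H3 fractions, and
multiplicative log-normal noise on fluorescence intensities (fold-changes are
scale-free and intensities stay positive).  The distributional forms are
modeling choices of this generator, not measured properties of the assays.

Randomness is split into one child stream per (sub-generator, compound) so
adding a compound never perturbs the data of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bmc import relative_bmc_from_params
from .design import build_series
from .tgxddi import DDI, NON_DDI, BiomarkerMatrix, TrainingSet

__all__ = [
    "EndpointCurve",
    "CompoundSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression_study",
    "simulate_flow_study",
    "expected_log2fc",
    "default_compounds",
    "MULTIFLOW_ENDPOINTS",
]

#: biomarker keys used for the DNA-damage plates
MULTIFLOW_ENDPOINTS = (
    "4H gh2ax",
    "24H gh2ax",
    "4H p53",
    "24H p53",
    "4H ph3",
    "24H ph3",
    "24H polyploidy",
)


@dataclass(frozen=True)
class EndpointCurve:
    """Monotone 5-parameter exponential fold-induction curve (control = 1)."""

    b: float  # concentration scale, uM
    c: float  # plateau fold
    d: float = 1.5  # shape; >= 1 keeps the curve monotone

    def fold(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = self.c - (self.c - 1.0) * np.exp(-np.power(x / self.b, self.d))
        return out if out.ndim else float(out)

    def true_bmc(self, ces: float) -> float:
        """Concentration of a ``ces`` relative increase over control, or nan."""
        return relative_bmc_from_params(self.b, self.c, self.d, ces)


_FLAT = EndpointCurve(b=1.0, c=1.0, d=1.0)

# plateau folds of the MoA-specific biomarker curves, chosen to clear the
# corresponding GEF thresholds with headroom at the top concentrations
_CLASTOGEN_FOLDS = {"4H gh2ax": 3.0, "24H gh2ax": 3.5, "4H p53": 2.5, "24H p53": 2.6}
_ANEUGEN_FOLDS = {"4H ph3": 3.2, "24H ph3": 3.0, "24H polyploidy": 9.0, "24H p53": 2.6}


@dataclass(frozen=True)
class CompoundSpec:
    """One simulated test compound.

    ``potency_b`` sets the concentration scale (uM) of all active endpoint
    curves; None leaves every endpoint flat.  ``effect_size`` overrides the
    study-wide expression effect size (0 allowed: an expression-inactive
    compound).  ``curves`` overrides individual biomarker curves.
    """

    name: str
    is_ddi: bool = False
    moa: str = "none"  # clastogen | aneugen | pan | none
    potency_b: float | None = None
    effect_size: float | None = None
    expression_d: float = 1.5
    mn_plateau_fold: float = 4.0
    viability_b: float | None = None  # RS/RNC decline scale; None = no decline
    viability_d: float = 2.0
    curves: Mapping[str, EndpointCurve] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.moa not in ("clastogen", "aneugen", "pan", "none"):
            raise ValueError(f"unknown moa {self.moa!r}")
        if self.effect_size is not None and self.effect_size < 0:
            raise ValueError("effect_size override must be >= 0")

    def multiflow_curve(self, biomarker: str) -> EndpointCurve:
        if biomarker in self.curves:
            return self.curves[biomarker]
        if self.potency_b is None:
            return _FLAT
        folds: dict[str, float] = {}
        if self.moa in ("clastogen", "pan"):
            folds.update(_CLASTOGEN_FOLDS)
        if self.moa in ("aneugen", "pan"):
            folds.update(_ANEUGEN_FOLDS)
        if biomarker not in folds:
            return _FLAT
        return EndpointCurve(b=self.potency_b, c=folds[biomarker])

    def mn_curve(self) -> EndpointCurve:
        if "mn" in self.curves:
            return self.curves["mn"]
        if self.potency_b is None or self.moa == "none":
            return _FLAT
        return EndpointCurve(b=self.potency_b, c=self.mn_plateau_fold)

    def survival(self, x: np.ndarray) -> np.ndarray:
        """Relative survival fraction in [0, 1] at concentrations ``x``."""
        x = np.asarray(x, dtype=float)
        if self.viability_b is None:
            return np.ones_like(x)
        return np.exp(-np.power(x / self.viability_b, self.viability_d))


def default_compounds(series_top: float = 100.0) -> tuple[CompoundSpec, ...]:
    """A small reference panel spanning the MoA classes.

    Potency scales sit mid-series so responses clear thresholds at the top
    concentrations while the low concentrations stay near control.
    """
    b = series_top / 5.0
    return (
        CompoundSpec("CLAST-1", is_ddi=True, moa="clastogen", potency_b=b),
        CompoundSpec("ANEU-1", is_ddi=False, moa="aneugen", potency_b=b),
        CompoundSpec("PAN-1", is_ddi=True, moa="pan", potency_b=b),
        CompoundSpec("NEG-1", is_ddi=False, moa="none", potency_b=None),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and generator parameters.

    Defaults mirror the screening design: 64 biomarker genes, a 28-chemical
    two-class training set, 6 concentrations at 70.71 % spacing in duplicate
    for expression, 10 concentrations for the flow plates, an analysis stop
    gate of 5,000 nucleated events per well, and a 0.7 % background MN
    frequency typical of solvent-control TK6 cells.  ``effect_size`` (mean
    |log2 FC| at the response plateau for responsive genes) and ``noise_sd``
    (replicate-level log2 SD) default to 1.0 and 0.25: a clear but not
    caricatured biomarker response four noise-SDs tall.
    """

    seed: int = 0
    n_biomarker_genes: int = 64
    n_training_chemicals: int = 28
    n_ddi_training: int = 14
    concentrations: tuple[float, ...] = build_series(100.0, 6).concentrations
    flow_concentrations: tuple[float, ...] = build_series(100.0, 10).concentrations
    n_replicates: int = 2
    effect_size: float = 1.0
    noise_sd: float = 0.25
    training_noise_sd: float = 0.25
    background_mn_rate: float = 0.007
    stop_gate: int = 5000
    n_control_wells: int = 6
    mcf_noise_sd: float = 0.05
    control_density: float = 1e6
    multiflow_total_events: int = 10_000
    base_ph3_fraction: float = 0.01
    base_polyploidy_fraction: float = 0.005
    base_pct_ema: float = 2.0
    compounds: tuple[CompoundSpec, ...] = field(default_factory=default_compounds)

    def __post_init__(self) -> None:
        if self.effect_size <= 0 or self.noise_sd <= 0:
            raise ValueError("effect_size and noise_sd must be positive")
        if not (0 < self.n_ddi_training < self.n_training_chemicals):
            raise ValueError("n_ddi_training must lie in (0, n_training_chemicals)")
        if self.n_ddi_training < 2 or self.n_training_chemicals - self.n_ddi_training < 2:
            raise ValueError("need >= 2 training chemicals per class")
        concs = np.asarray(self.concentrations)
        if np.any(concs <= 0) or np.any(np.diff(concs) >= 0):
            raise ValueError(
                "concentrations must be positive and strictly decreasing (top first)"
            )
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            raise ValueError("compound names must be unique")

    # -- deterministic substreams --------------------------------------
    def _rng(self, domain: int, index: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(domain, index))
        )

    def gene_directions(self) -> np.ndarray:
        """+1 for the first half of the genes, -1 for the second half.

        Mimics the two-block up/down structure of the DDI training heatmap
        and exercises centroid sign handling downstream.
        """
        g = self.n_biomarker_genes
        return np.where(np.arange(g) < g // 2, 1.0, -1.0)

    def gene_names(self) -> list[str]:
        return [f"G{i + 1:03d}" for i in range(self.n_biomarker_genes)]


@dataclass
class GroundTruth:
    """Known class, MoA, and per-endpoint true BMCs of the simulated compounds."""

    class_label: dict[str, str]
    moa_label: dict[str, str]
    true_bmc: dict[str, dict[str, float]]  # compound -> endpoint -> uM

    def __post_init__(self) -> None:
        if set(self.class_label) != set(self.moa_label):
            raise ValueError("class and MoA labels must cover the same compounds")


def _expression_rise(spec: CompoundSpec, x: np.ndarray) -> np.ndarray:
    """Saturating 0..1 rise of the expression response with concentration."""
    if spec.potency_b is None:
        return np.zeros_like(np.asarray(x, dtype=float))
    x = np.asarray(x, dtype=float)
    return 1.0 - np.exp(-np.power(x / spec.potency_b, spec.expression_d))


def expected_log2fc(
    config: SimulationConfig, spec: CompoundSpec, concentration: float
) -> np.ndarray:
    """Noiseless per-gene expected log2 fold-change at one concentration."""
    effect = config.effect_size if spec.effect_size is None else spec.effect_size
    if not spec.is_ddi or effect == 0:
        return np.zeros(config.n_biomarker_genes)
    rise = _expression_rise(spec, np.array([concentration]))[0]
    return config.gene_directions() * effect * rise


def true_expression_bmc(config: SimulationConfig, spec: CompoundSpec) -> float:
    """Concentration where the responsive-gene mean reaches one noise SD.

    Solves ``effect * (1 - exp(-(x/b)^d)) = noise_sd`` — the 1-SD benchmark
    response equation of the generator's mean function.
    """
    effect = config.effect_size if spec.effect_size is None else spec.effect_size
    if not spec.is_ddi or effect <= config.noise_sd or spec.potency_b is None:
        return float("nan")
    return float(
        spec.potency_b
        * (-math.log(1.0 - config.noise_sd / effect)) ** (1.0 / spec.expression_d)
    )


def _ground_truth(config: SimulationConfig) -> GroundTruth:
    class_label, moa_label, true_bmc = {}, {}, {}
    for spec in config.compounds:
        class_label[spec.name] = DDI if spec.is_ddi else NON_DDI
        moa_label[spec.name] = spec.moa
        per: dict[str, float] = {}
        b = true_expression_bmc(config, spec)
        if np.isfinite(b):
            per["expression"] = b
        mn = spec.mn_curve()
        if mn.c > 1.0:
            v = mn.true_bmc(ces=1.0)
            if np.isfinite(v):
                per["mn"] = v
        for biomarker in MULTIFLOW_ENDPOINTS:
            curve = spec.multiflow_curve(biomarker)
            if curve.c > 1.0:
                v = curve.true_bmc(ces=0.5)
                if np.isfinite(v):
                    per[biomarker] = v
        true_bmc[spec.name] = per
    return GroundTruth(class_label=class_label, moa_label=moa_label, true_bmc=true_bmc)


# --------------------------------------------------------------------------
# expression study
# --------------------------------------------------------------------------


def simulate_expression_study(
    config: SimulationConfig,
) -> tuple[TrainingSet, BiomarkerMatrix, GroundTruth]:
    """Training set, replicate-averaged test fold-changes, and ground truth.

    The DDI training class carries a class-specific mean shift of
    ``effect_size`` along the gene direction pattern; the non-DDI class is
    centred at zero.  DDI test compounds rise toward the DDI direction along
    their exponential dose-response; non-DDI compounds stay at zero mean.
    Replicate noise is additive Gaussian on the log2 scale.
    """
    g = config.n_biomarker_genes
    directions = config.gene_directions()
    genes = config.gene_names()

    rows, labels = {}, {}
    for i in range(config.n_training_chemicals):
        is_ddi = i < config.n_ddi_training
        rng = config._rng(domain=0, index=i)
        mean = directions * config.effect_size if is_ddi else np.zeros(g)
        name = f"TRAIN-{'DDI' if is_ddi else 'NON'}-{i + 1:02d}"
        rows[name] = mean + rng.normal(0.0, config.training_noise_sd, size=g)
        labels[name] = DDI if is_ddi else NON_DDI
    training = TrainingSet(
        matrix=pd.DataFrame(rows, index=genes).T, labels=pd.Series(labels)
    )

    sample_rows = {}
    for ci, spec in enumerate(config.compounds):
        rng = config._rng(domain=1, index=ci)
        for conc in config.concentrations:
            mean = expected_log2fc(config, spec, conc)
            reps = mean[None, :] + rng.normal(
                0.0, config.noise_sd, size=(config.n_replicates, g)
            )
            sample_rows[(spec.name, float(conc))] = reps.mean(axis=0)
    values = pd.DataFrame(sample_rows, index=genes).T
    values.index.names = ["compound", "concentration"]
    samples = BiomarkerMatrix(values=values)
    return training, samples, _ground_truth(config)


def gene_baselines(config: SimulationConfig) -> np.ndarray:
    """Per-gene baseline log2 expression, shared across compounds.

    Uniform on [6, 10]: mid-abundance transcripts on the log2 CPM scale.
    Drawn from a gene-keyed substream so the baselines do not move when
    compounds are added.
    """
    rng = config._rng(domain=5, index=0)
    return rng.uniform(6.0, 10.0, size=config.n_biomarker_genes)


def simulate_expression_replicates(config: SimulationConfig) -> pd.DataFrame:
    """Replicate-level per-gene log2 expression for BMC modeling.

    Long-format table (compound, gene, concentration, replicate, log2_expr)
    including solvent-control replicates at concentration 0.  Each gene sits
    at its baseline log2 expression and moves by the compound's expected
    log2 fold-change; replicate noise is additive Gaussian.  Drawn from an
    independent substream so the replicate-averaged classification matrix is
    unaffected.
    """
    rows = []
    genes = config.gene_names()
    baselines = gene_baselines(config)
    for ci, spec in enumerate(config.compounds):
        rng = config._rng(domain=4, index=ci)
        concs = [0.0] * config.n_control_wells + [
            c for c in config.concentrations for _ in range(config.n_replicates)
        ]
        reps = [r + 1 for r in range(config.n_control_wells)] + [
            r + 1 for _ in config.concentrations for r in range(config.n_replicates)
        ]
        for conc, rep in zip(concs, reps):
            shift = (
                np.zeros(config.n_biomarker_genes)
                if conc == 0.0
                else expected_log2fc(config, spec, conc)
            )
            vals = baselines + shift + rng.normal(0.0, config.noise_sd, size=len(genes))
            rows.extend(
                {
                    "compound": spec.name,
                    "gene": g,
                    "concentration": conc,
                    "replicate": rep,
                    "log2_expr": float(v),
                }
                for g, v in zip(genes, vals)
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# flow-cytometry plates
# --------------------------------------------------------------------------


def simulate_flow_study(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Well-level MicroFlow and MultiFlow plate tables.

    MN events are Poisson with rate ``background_mn_rate`` scaled by the
    compound's fold-induction curve at a fixed stop gate of nucleated events;
    fluorescence intensities are log-normal around the MoA-specific biomarker
    curves; ploidy and p-H3 positives are binomial; nuclei densities decline
    along each compound's survival curve so downstream gating is exercised.
    Solvent-control wells are present on every simulated plate (one plate per
    compound).
    """
    if truth is not None:
        missing = {s.name for s in config.compounds} - set(truth.class_label)
        if missing:
            raise ValueError(f"truth missing compounds: {sorted(missing)}")

    micro_rows: list[dict] = []
    multi_rows: list[dict] = []
    concs = np.asarray(config.flow_concentrations, dtype=float)

    for ci, spec in enumerate(config.compounds):
        rng_micro = config._rng(domain=2, index=ci)
        rng_multi = config._rng(domain=3, index=ci)
        plate = spec.name
        mn_curve = spec.mn_curve()
        surv = spec.survival(concs)

        # --- MicroFlow plate ------------------------------------------
        def micro_well(conc: float, fold: float, s: float, is_control: bool,
                       replicate: int) -> dict:
            rate = config.background_mn_rate * fold
            mn = int(min(rng_micro.poisson(rate * config.stop_gate), config.stop_gate))
            density = config.control_density * s * rng_micro.lognormal(0.0, 0.05)
            ema = config.base_pct_ema * rng_micro.lognormal(0.0, 0.1)
            return {
                "compound": "DMSO" if is_control else spec.name,
                "plate": plate,
                "concentration": 0.0 if is_control else float(conc),
                "replicate": replicate,
                "mn_events": mn,
                "nucleated_events": config.stop_gate,
                "pct_ema_positive": float(ema),
                "nuclei_per_ml": float(density),
                "is_control": is_control,
            }

        for r in range(config.n_control_wells):
            micro_rows.append(micro_well(0.0, 1.0, 1.0, True, r + 1))
        for j, conc in enumerate(concs):
            for r in range(config.n_replicates):
                micro_rows.append(
                    micro_well(conc, float(mn_curve.fold(conc)), float(surv[j]),
                               False, r + 1)
                )

        # --- MultiFlow plates (4H and 24H) ----------------------------
        folds = {
            bm: spec.multiflow_curve(bm).fold(concs) for bm in MULTIFLOW_ENDPOINTS
        }

        def multi_well(tp: str, conc: float, j: int | None, is_control: bool,
                       replicate: int) -> dict:
            def f(bm: str) -> float:
                return 1.0 if (is_control or j is None) else float(folds[bm][j])

            total = config.multiflow_total_events
            gh2ax = 100.0 * f(f"{tp} gh2ax") * rng_multi.lognormal(0.0, config.mcf_noise_sd)
            p53 = 150.0 * f(f"{tp} p53") * rng_multi.lognormal(0.0, config.mcf_noise_sd)
            poly_frac = config.base_polyploidy_fraction * (
                f("24H polyploidy") if tp == "24H" else 1.0
            )
            ph3_frac = config.base_ph3_fraction * f(f"{tp} ph3")
            n8 = int(rng_multi.binomial(total, min(poly_frac, 0.5)))
            nph3 = int(rng_multi.binomial(total, min(ph3_frac, 0.5)))
            s = 1.0 if is_control else float(surv[j])
            # survival losses accrue by 24H; 4H density barely moves
            density = config.control_density * (s if tp == "24H" else (0.5 + 0.5 * s))
            density *= rng_multi.lognormal(0.0, 0.05)
            return {
                "compound": "DMSO" if is_control else spec.name,
                "plate": plate,
                "concentration": 0.0 if is_control else float(conc),
                "timepoint": tp,
                "replicate": replicate,
                "mcf_gh2ax": float(gh2ax),
                "mcf_p53": float(p53),
                "events_2n4n": total - n8,
                "events_8n": n8,
                "events_ph3_pos": nph3,
                "nuclei_per_ml": float(density),
                "is_control": is_control,
            }

        for tp in ("4H", "24H"):
            for r in range(config.n_control_wells):
                multi_rows.append(multi_well(tp, 0.0, None, True, r + 1))
            for j, conc in enumerate(concs):
                for r in range(config.n_replicates):
                    multi_rows.append(multi_well(tp, float(conc), j, False, r + 1))

    return pd.DataFrame(micro_rows), pd.DataFrame(multi_rows)
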