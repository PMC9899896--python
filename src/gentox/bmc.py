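"""Benchmark-concentration (BMC) modeling of dose-response data.

Two flavours of potency estimation are provided:

* **SD-based gene BMCs** — each biomarker gene's log2 expression is fitted with
  a family of continuous dose-response models (Exponential 2/3/4/5, Linear,
  2nd-degree Polynomial, Restricted Power with exponent >= 1).  The best model
  (lowest AIC) defines the BMC as the concentration producing a change of
  ``bmr_sd`` residual standard deviations from the modeled control response.
  Genes are prefiltered with a permutation Williams trend test and a linear
  fold-change floor, fitted BMCs are screened with confidence-ratio quality
  filters, and the surviving per-gene BMCs are summarised by their median with
  a bootstrap confidence interval (the gene-set BMC).

* **Relative-increase (CES) BMCs** — flow-cytometry endpoints on a fold or
  percent scale are fitted with a single 5-parameter exponential model
  ``y = a * (c - (c - 1) * exp(-(x / b) ** d))`` and the BMC is the
  concentration at which the response exceeds control by a fixed relative
  increase (CES; 1.0 for micronucleus induction, 0.5 for the DNA-damage
  biomarkers).

The model interface follows the fit/results convention: ``DoseResponseModel``
holds the data and configuration, ``.fit()`` returns a results object carrying
estimates, confidence limits, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.optimize import isotonic_regression

__all__ = [
    "DoseResponseData",
    "ModelFit",
    "DoseResponseModel",
    "GeneSetBmc",
    "williams_trend_test",
    "fit_dose_response_family",
    "fit_relative_bmc",
    "lowest_bmc",
    "gene_set_bmc",
    "MODEL_FAMILY",
]


# --------------------------------------------------------------------------
# data container
# --------------------------------------------------------------------------


@dataclass
class DoseResponseData:
    """Replicate-level responses over a concentration series including controls.

    ``concentrations`` and ``responses`` are parallel arrays; controls are the
    entries with concentration 0.  At least two distinct positive
    concentrations plus a control group are required.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    endpoint_kind: str = "log2-expression"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.any(self.concentrations == 0):
            raise ValueError("a control group (concentration 0) is required")
        if len(set(self.concentrations[self.concentrations > 0])) < 2:
            raise ValueError("need >= 2 distinct positive concentrations")

    def groups(self) -> tuple[np.ndarray, list[np.ndarray]]:
        """Unique concentrations (ascending) and the response array of each."""
        levels = np.unique(self.concentrations)
        return levels, [self.responses[self.concentrations == lv] for lv in levels]


# --------------------------------------------------------------------------
# model family
# --------------------------------------------------------------------------


def _lin(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    return p[0] + p[1] * x


def _poly2(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    return p[0] + p[1] * x + p[2] * x * x


def _power(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    return p[0] + p[1] * np.power(x, p[2])


def _exp2(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    return p[0] * np.exp(np.clip(p[1] * x, -300, 300))


def _exp3(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    # p = (a, b, d, sign); sign is frozen to the adverse direction before fitting
    return p[0] * np.exp(np.clip(p[3] * np.power(p[1] * x, p[2]), -300, 300))


def _exp4(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    return p[0] * (p[2] - (p[2] - 1.0) * np.exp(-p[1] * x))


def _exp5(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    return p[0] * (p[2] - (p[2] - 1.0) * np.exp(-np.power(p[1] * x, p[3])))


def _safe_log(z: np.ndarray) -> np.ndarray:
    """log(z) with 0 where z <= 0 (those entries multiply a zero factor)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(z > 0, np.log(np.where(z > 0, z, 1.0)), 0.0)
    return out


def _jac_power(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    xg = np.power(x, p[2])
    return np.column_stack([np.ones_like(x), xg, p[1] * xg * _safe_log(x)])


def _jac_exp2(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    e = np.exp(np.clip(p[1] * x, -300, 300))
    return np.column_stack([e, p[0] * x * e])


def _jac_exp3(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    u = np.power(p[1] * x, p[2])
    f = p[0] * np.exp(np.clip(p[3] * u, -300, 300))
    return np.column_stack(
        [
            f / p[0],
            f * p[3] * p[2] * u / p[1],
            f * p[3] * u * _safe_log(p[1] * x),
            f * u,
        ]
    )


def _jac_exp4(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    e = np.exp(-p[1] * x)
    return np.column_stack(
        [
            p[2] - (p[2] - 1.0) * e,
            p[0] * (p[2] - 1.0) * x * e,
            p[0] * (1.0 - e),
        ]
    )


def _jac_exp5(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    u = np.power(p[1] * x, p[3])
    e = np.exp(-u)
    return np.column_stack(
        [
            p[2] - (p[2] - 1.0) * e,
            p[0] * (p[2] - 1.0) * e * p[3] * u / p[1],
            p[0] * (1.0 - e),
            p[0] * (p[2] - 1.0) * e * u * _safe_log(p[1] * x),
        ]
    )


@dataclass(frozen=True)
class _ModelSpec:
    name: str
    func: Callable[[np.ndarray, np.ndarray], np.ndarray]
    n_free: int  # free mean parameters (counts toward AIC)
    closed_form: bool = False
    jac: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None


MODEL_FAMILY: dict[str, _ModelSpec] = {
    "Linear": _ModelSpec("Linear", _lin, 2, closed_form=True),
    "Poly2": _ModelSpec("Poly2", _poly2, 3, closed_form=True),
    "Power": _ModelSpec("Power", _power, 3, jac=_jac_power),
    "Exp2": _ModelSpec("Exp2", _exp2, 2, jac=_jac_exp2),
    "Exp3": _ModelSpec("Exp3", _exp3, 3, jac=_jac_exp3),
    "Exp4": _ModelSpec("Exp4", _exp4, 3, jac=_jac_exp4),
    "Exp5": _ModelSpec("Exp5", _exp5, 4, jac=_jac_exp5),
}


def _initial_guesses(
    name: str, x: np.ndarray, y: np.ndarray
) -> list[tuple[np.ndarray, tuple]]:
    """Data-driven starting points and box bounds for each model."""
    xpos = x[x > 0]
    scale = 1.0 / np.median(xpos)
    y0 = float(np.mean(y[x == 0]))
    ytop = float(np.mean(y[x == x.max()]))
    direction = 1.0 if ytop >= y0 else -1.0
    a0 = y0 if abs(y0) > 1e-6 else (1e-6 if y0 >= 0 else -1e-6)
    span = ytop - y0

    inf = np.inf
    if name == "Power":
        return [
            (np.array([y0, span / (x.max() ** g or 1.0), g]),
             ([-inf, -inf, 1.0], [inf, inf, 18.0]))
            for g in (1.0, 2.0)
        ]
    if name == "Exp2":
        ratio = ytop / a0 if a0 != 0 else 2.0
        b0 = math.log(ratio) / x.max() if ratio > 0 else direction / x.max()
        return [(np.array([a0, b0]), ([-inf, -inf], [inf, inf]))]
    if name == "Exp3":
        # the exponent sign is pinned to the adverse direction via a
        # vanishingly small box (least_squares requires lb < ub strictly)
        return [
            (np.array([a0, scale, d, direction]),
             ([-inf, 1e-12, 1.0, direction - 1e-9],
              [inf, inf, 18.0, direction + 1e-9]))
            for d in (1.0, 2.0)
        ]
    if name == "Exp4":
        c0 = ytop / a0 if a0 != 0 else 2.0
        c0 = float(np.clip(c0, 1e-6, 1e6))
        return [(np.array([a0, scale, c0]),
                 ([-inf, 1e-12, 1e-9], [inf, inf, inf]))]
    if name == "Exp5":
        c0 = ytop / a0 if a0 != 0 else 2.0
        c0 = float(np.clip(c0, 1e-6, 1e6))
        return [
            (np.array([a0, scale, c0, d]),
             ([-inf, 1e-12, 1e-9, 1.0], [inf, inf, inf, 18.0]))
            for d in (1.0, 2.0)
        ]
    raise KeyError(name)


def _fit_one_model(
    name: str, x: np.ndarray, y: np.ndarray, start: np.ndarray | None = None
) -> tuple[np.ndarray, float] | None:
    """Least-squares fit of one family member; returns (params, rss) or None."""
    spec = MODEL_FAMILY[name]
    if spec.closed_form:
        deg = 1 if name == "Linear" else 2
        design = np.vander(x, deg + 1, increasing=True)
        params, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ params
        return params, float(resid @ resid)

    def resid_fn(p: np.ndarray) -> np.ndarray:
        return spec.func(x, p) - y

    best: tuple[np.ndarray, float] | None = None
    guesses = _initial_guesses(name, x, y)
    max_nfev = 120
    if start is not None:
        # warm start (bootstrap refits): the fitted params are close enough
        lo, hi = guesses[0][1]
        guesses = [(np.clip(start, lo, hi), (lo, hi))]
        max_nfev = 40
    for p0, bounds in guesses:
        lo, hi = (np.asarray(bounds[0], float), np.asarray(bounds[1], float))
        p0 = np.clip(p0, lo + 1e-12, hi - 1e-12 if np.all(np.isfinite(hi)) else hi)
        try:
            sol = optimize.least_squares(
                resid_fn, p0, bounds=(lo, hi), method="trf",
                jac=(lambda p, s=spec: s.jac(x, p)) if spec.jac else "2-point",
                xtol=1e-8, ftol=1e-8, x_scale="jac", max_nfev=max_nfev,
            )
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or rss < best[1]:
            best = (sol.x, rss)
    return best


def _gauss_loglik(rss: float, n: int) -> float:
    """Profile Gaussian log-likelihood with the ML variance (floored)."""
    sigma2 = max(rss / n, 1e-12)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


# --------------------------------------------------------------------------
# fit results
# --------------------------------------------------------------------------


@dataclass
class ModelFit:
    """A fitted dose-response model with its BMC and confidence limits.

    ``flags`` records quality issues: "no-crossing" (the fitted curve never
    reaches the benchmark response inside the searched range, BMC undefined),
    "above-top" (BMC beyond the highest tested concentration), "plateau"
    (relative model saturates below the CES target), "no-fit" (optimizer
    failed on every family member).
    """

    model: str
    params: dict[str, float]
    loglik: float
    aic: float
    fit_pvalue: float
    sigma: float
    bmc: float
    bmcl: float
    bmcu: float
    flags: tuple[str, ...] = ()
    n_obs: int = 0

    @property
    def defined(self) -> bool:
        return np.isfinite(self.bmc)

    def predict(self, x: np.ndarray) -> np.ndarray:
        spec = MODEL_FAMILY.get(self.model)
        if spec is None:
            raise ValueError(f"cannot predict for model {self.model!r}")
        return spec.func(np.asarray(x, float), np.array(list(self.params.values())))

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "model": self.model,
                **self.params,
                "loglik": self.loglik,
                "AIC": self.aic,
                "fit_p": self.fit_pvalue,
                "sigma": self.sigma,
                "BMC": self.bmc,
                "BMCL": self.bmcl,
                "BMCU": self.bmcu,
                "flags": ";".join(self.flags),
            }
        )


_PARAM_NAMES = {
    "Linear": ("a", "b"),
    "Poly2": ("a", "b", "c"),
    "Power": ("a", "b", "g"),
    "Exp2": ("a", "b"),
    "Exp3": ("a", "b", "d", "sign"),
    "Exp4": ("a", "b", "c"),
    "Exp5": ("a", "b", "c", "d"),
}


def _solve_bmc(
    f: Callable[[np.ndarray], np.ndarray], target: float, x_max: float
) -> float:
    """Smallest x in (0, x_max] with |f(x) - f(0)| = target, or nan."""
    f0 = float(f(np.array([0.0]))[0])
    grid = np.concatenate([[0.0], np.geomspace(x_max * 1e-6, x_max, 512)])
    dev = np.abs(f(grid) - f0) - target
    above = np.nonzero(dev > 0)[0]
    if len(above) == 0:
        return float("nan")
    i = above[0]
    if i == 0:
        return float("nan")
    lo, hi = grid[i - 1], grid[i]
    try:
        return float(
            optimize.brentq(lambda t: abs(float(f(np.array([t]))[0]) - f0) - target, lo, hi)
        )
    except ValueError:
        return float(hi)


def _lack_of_fit_p(
    x: np.ndarray, y: np.ndarray, rss_model: float, n_mean_params: int
) -> float:
    """Pure-error F test of the fitted curve against the group-means model."""
    levels = np.unique(x)
    rss_pe = 0.0
    for lv in levels:
        g = y[x == lv]
        rss_pe += float(np.sum((g - g.mean()) ** 2))
    df_pe = len(y) - len(levels)
    df_lof = len(levels) - n_mean_params
    if df_pe <= 0 or df_lof <= 0:
        return float("nan")
    num = max(rss_model - rss_pe, 0.0) / df_lof
    den = rss_pe / df_pe
    if den <= 0:
        return float("nan") if num <= 0 else 0.0
    return float(stats.f.sf(num / den, df_lof, df_pe))


class DoseResponseModel:
    """AIC-selected dose-response model family for a single endpoint.

    Parameters
    ----------
    data : DoseResponseData
    bmr_sd : float
        Benchmark response in residual-SD units (default 1).
    sd : float, optional
        Benchmark SD.  When given, the benchmark response is ``bmr_sd * sd``;
        otherwise the best model's own residual SD is used.  Supplying the
        assay's characteristic SD keeps the benchmark response fixed across
        endpoints and makes the BMC well defined even for near-noiseless data.
    models : sequence of str, optional
        Subset of ``MODEL_FAMILY`` to fit (default: all seven).
    """

    def __init__(
        self,
        data: DoseResponseData,
        bmr_sd: float = 1.0,
        sd: float | None = None,
        models: Sequence[str] | None = None,
    ) -> None:
        self.data = data
        self.bmr_sd = float(bmr_sd)
        self.sd = sd
        self.models = tuple(models) if models is not None else tuple(MODEL_FAMILY)
        unknown = set(self.models) - set(MODEL_FAMILY)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")

    def fit(
        self, n_boot: int = 250, rng: np.random.Generator | int | None = None
    ) -> ModelFit:
        """Fit every family member, select by AIC, solve and bootstrap the BMC."""
        rng = np.random.default_rng(rng)
        x, y = self.data.concentrations, self.data.responses
        n = len(y)
        fits: list[tuple[str, np.ndarray, float, float]] = []
        for name in self.models:
            res = _fit_one_model(name, x, y)
            if res is None:
                continue
            params, rss = res
            ll = _gauss_loglik(rss, n)
            aic = 2.0 * (MODEL_FAMILY[name].n_free + 1) - 2.0 * ll
            fits.append((name, params, rss, aic))
        if not fits:
            return ModelFit(
                model="none", params={}, loglik=float("nan"), aic=float("inf"),
                fit_pvalue=float("nan"), sigma=float("nan"),
                bmc=float("nan"), bmcl=float("nan"), bmcu=float("nan"),
                flags=("no-fit",), n_obs=n,
            )
        name, params, rss, aic = min(fits, key=lambda t: t[3])
        spec = MODEL_FAMILY[name]
        sigma_hat = math.sqrt(max(rss / n, 0.0))
        sigma_bmr = self.sd if self.sd is not None else sigma_hat
        target = self.bmr_sd * sigma_bmr
        fit_p = _lack_of_fit_p(x, y, rss, spec.n_free)

        def curve(params_: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
            return lambda t: spec.func(t, params_)

        x_max = float(x.max())
        bmc = _solve_bmc(curve(params), target, 10.0 * x_max)
        flags: list[str] = []
        if not np.isfinite(bmc):
            flags.append("no-crossing")
        elif bmc > x_max:
            flags.append("above-top")

        bmcl = bmcu = float("nan")
        if np.isfinite(bmc) and n_boot > 0:
            boot = self._bootstrap_bmcs(name, params, target, x_max, n_boot, rng)
            if len(boot) >= max(10, n_boot // 5):
                bmcl, bmcu = np.percentile(boot, [2.5, 97.5])
                bmcl, bmcu = min(bmcl, bmc), max(bmcu, bmc)

        return ModelFit(
            model=name,
            params=dict(zip(_PARAM_NAMES[name], params)),
            loglik=_gauss_loglik(rss, n),
            aic=aic,
            fit_pvalue=fit_p,
            sigma=sigma_hat,
            bmc=bmc,
            bmcl=float(bmcl),
            bmcu=float(bmcu),
            flags=tuple(flags),
            n_obs=n,
        )

    def _bootstrap_bmcs(
        self,
        name: str,
        params: np.ndarray,
        target: float,
        x_max: float,
        n_boot: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Nonparametric bootstrap: resample replicates within concentration."""
        x, y = self.data.concentrations, self.data.responses
        levels, groups = self.data.groups()
        spec = MODEL_FAMILY[name]
        out = []
        for _ in range(n_boot):
            yb = np.empty_like(y)
            xb = np.empty_like(x)
            pos = 0
            for lv, g in zip(levels, groups):
                k = len(g)
                yb[pos : pos + k] = rng.choice(g, size=k, replace=True)
                xb[pos : pos + k] = lv
                pos += k
            res = _fit_one_model(name, xb, yb, start=params)
            if res is None:
                continue
            pb, _ = res
            b = _solve_bmc(lambda t: spec.func(t, pb), target, 10.0 * x_max)
            if np.isfinite(b):
                out.append(b)
        return np.asarray(out)


def fit_dose_response_family(
    data: DoseResponseData,
    bmr_sd: float = 1.0,
    sd: float | None = None,
    n_boot: int = 250,
    models: Sequence[str] | None = None,
    rng: np.random.Generator | int | None = None,
) -> ModelFit:
    """Functional wrapper: AIC-best family fit with an SD-based BMC."""
    return DoseResponseModel(data, bmr_sd=bmr_sd, sd=sd, models=models).fit(
        n_boot=n_boot, rng=rng
    )


# --------------------------------------------------------------------------
# Williams trend test (permutation)
# --------------------------------------------------------------------------


def williams_trend_test(
    data: DoseResponseData,
    n_perm: int = 500,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation Williams-type trend test across the concentration groups.

    The statistic compares the isotonic (monotone-ordered) estimate of the
    highest-concentration group mean with the control mean, standardized by
    the pooled within-group variance; both monotone orientations are evaluated
    and the larger |t| is used.  The p-value is the permutation tail
    probability ``(1 + #{|t*| >= |t|}) / (1 + n_perm)`` under random
    reassignment of responses to groups.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    x, y = data.concentrations, data.responses
    levels = np.unique(x)
    group_idx = np.searchsorted(levels, x)
    counts = np.bincount(group_idx, minlength=len(levels)).astype(float)

    def tstat(yv: np.ndarray) -> float:
        sums = np.bincount(group_idx, weights=yv, minlength=len(levels))
        means = sums / counts
        sq = np.bincount(group_idx, weights=yv * yv, minlength=len(levels))
        ss_within = float(np.sum(sq - counts * means**2))
        df = len(yv) - len(levels)
        if df <= 0:
            raise ValueError("no within-group degrees of freedom")
        s2 = ss_within / df
        if s2 <= 0:
            raise ValueError("zero pooled within-group variance")
        se = math.sqrt(s2 * (1.0 / counts[-1] + 1.0 / counts[0]))
        up = isotonic_regression(means, weights=counts, increasing=True).x[-1]
        dn = isotonic_regression(means, weights=counts, increasing=False).x[-1]
        t_up = (up - means[0]) / se
        t_dn = (dn - means[0]) / se
        return t_up if abs(t_up) >= abs(t_dn) else t_dn

    t_obs = abs(tstat(y))
    hits = 0
    yp = y.copy()
    for _ in range(n_perm):
        rng.shuffle(yp)
        if abs(tstat(yp)) >= t_obs:
            hits += 1
    return (1 + hits) / (1 + n_perm)


# --------------------------------------------------------------------------
# gene-set BMC
# --------------------------------------------------------------------------


@dataclass
class GeneSetBmc:
    """Median BMC of the surviving biomarker genes with a bootstrap CI."""

    gene_bmcs: dict[str, float]
    median_bmc: float
    ci_lower: float
    ci_upper: float
    filter_counts: dict[str, int] = field(default_factory=dict)
    fits: dict[str, ModelFit] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.gene_bmcs

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "n_genes_passing": len(self.gene_bmcs),
                "median_BMC": self.median_bmc,
                "CI_lower": self.ci_lower,
                "CI_upper": self.ci_upper,
                **{f"removed_{k}": v for k, v in self.filter_counts.items()},
            }
        )


def _max_linear_fold(data: DoseResponseData) -> float:
    """Max over concentrations of the linear fold |2^(mean - control mean)|."""
    levels, groups = data.groups()
    ctrl = groups[0].mean()
    best = 1.0
    for lv, g in zip(levels[1:], groups[1:]):
        fold = 2.0 ** abs(g.mean() - ctrl)
        best = max(best, fold)
    return best


def bmc_quality_filter(fit: ModelFit) -> str | None:
    """Name of the quality rule that removes a gene BMC, or None if it passes.

    Rules, checked in order: undefined BMC ("no_bmc"); insufficient fit
    adequacy, p < 0.1 ("fit_p"); BMC/BMCL >= 20 ("bmc_bmcl_ratio");
    BMCU/BMC >= 20 ("bmcu_bmc_ratio"); BMCU/BMCL >= 40 ("bmcu_bmcl_ratio").
    """
    if not fit.defined:
        return "no_bmc"
    if np.isfinite(fit.fit_pvalue) and fit.fit_pvalue < 0.1:
        return "fit_p"
    bmcl, bmcu = fit.bmcl, fit.bmcu
    if np.isfinite(bmcl) and bmcl > 0 and fit.bmc / bmcl >= 20:
        return "bmc_bmcl_ratio"
    if np.isfinite(bmcu) and bmcu / fit.bmc >= 20:
        return "bmcu_bmc_ratio"
    if np.isfinite(bmcl) and np.isfinite(bmcu) and bmcl > 0 and bmcu / bmcl >= 40:
        return "bmcu_bmcl_ratio"
    return None


def gene_set_bmc(
    gene_data: Mapping[str, DoseResponseData],
    fold_change_floor: float = 1.5,
    williams_alpha: float = 0.05,
    n_perm: int = 500,
    n_boot: int = 2000,
    bmr_sd: float = 1.0,
    sd: float | None = None,
    n_boot_gene: int = 100,
    models: Sequence[str] | None = None,
    rng: np.random.Generator | int | None = None,
) -> GeneSetBmc:
    """Gene-set (median) BMC with trend prefiltering and quality filters.

    Genes pass the prefilter when the Williams permutation p-value is below
    ``williams_alpha`` and the maximum linear fold change reaches
    ``fold_change_floor``.  Fitted gene BMCs are removed when the fit-adequacy
    p-value is < 0.1 or the confidence-ratio filters fire (BMC/BMCL >= 20,
    BMCU/BMC >= 20, BMCU/BMCL >= 40).  The gene-set BMC is the median of the
    surviving BMCs; its CI holds the 2.5/97.5 percentiles of medians over
    ``n_boot`` resamples (with replacement) of the surviving BMC set.
    """
    if not gene_data:
        raise ValueError("gene_data is empty")
    rng = np.random.default_rng(rng)
    counts = {
        "prefilter": 0,
        "no_bmc": 0,
        "fit_p": 0,
        "bmc_bmcl_ratio": 0,
        "bmcu_bmc_ratio": 0,
        "bmcu_bmcl_ratio": 0,
    }
    surviving: dict[str, float] = {}
    fits: dict[str, ModelFit] = {}
    for gene, data in gene_data.items():
        p = williams_trend_test(data, n_perm=n_perm, rng=rng)
        if p >= williams_alpha or _max_linear_fold(data) < fold_change_floor:
            counts["prefilter"] += 1
            continue
        fit = fit_dose_response_family(
            data, bmr_sd=bmr_sd, sd=sd, n_boot=n_boot_gene, models=models, rng=rng
        )
        fits[gene] = fit
        removed = bmc_quality_filter(fit)
        if removed is not None:
            counts[removed] += 1
            continue
        surviving[gene] = fit.bmc

    if not surviving:
        return GeneSetBmc(
            gene_bmcs={}, median_bmc=float("nan"),
            ci_lower=float("nan"), ci_upper=float("nan"),
            filter_counts=counts, fits=fits,
        )
    values = np.array(list(surviving.values()))
    med = float(np.median(values))
    boots = np.median(
        values[rng.integers(0, len(values), size=(n_boot, len(values)))], axis=1
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return GeneSetBmc(
        gene_bmcs=surviving,
        median_bmc=med,
        ci_lower=float(min(lo, med)),
        ci_upper=float(max(hi, med)),
        filter_counts=counts,
        fits=fits,
    )


# --------------------------------------------------------------------------
# relative-increase (CES) BMC for flow endpoints
# --------------------------------------------------------------------------


def _exp5_rel(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    # y = a * (c - (c - 1) * exp(-(x / b) ** d))
    return p[0] * (p[2] - (p[2] - 1.0) * np.exp(-np.power(x / p[1], p[3])))


def _jac_exp5_rel(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    a, b, c, d = p
    v = np.power(x / b, d)
    e = np.exp(-v)
    return np.column_stack(
        [
            c - (c - 1.0) * e,
            -a * (c - 1.0) * e * d * v / b,
            a * (1.0 - e),
            a * (c - 1.0) * e * v * _safe_log(x / b),
        ]
    )


def relative_bmc_from_params(b: float, c: float, d: float, ces: float) -> float:
    """Closed-form CES BMC of the 5-parameter exponential, nan when saturated.

    Solves ``f(x)/f(0) - 1 = ces``:  x = b * (-ln((c - 1 - ces)/(c - 1)))**(1/d).
    """
    if c - 1.0 <= ces:
        return float("nan")
    return float(b * (-math.log((c - 1.0 - ces) / (c - 1.0))) ** (1.0 / d))


def fit_relative_bmc(
    data: DoseResponseData,
    ces: float,
    n_boot: int = 250,
    rng: np.random.Generator | int | None = None,
) -> ModelFit:
    """Fit the 5-parameter exponential and solve the relative-increase BMC.

    The model is ``y = a * (c - (c - 1) * exp(-(x / b) ** d))`` with a > 0,
    b > 0, c >= 1, d >= 1; the BMC is the concentration with
    ``f(BMC) / f(0) = 1 + ces``.  A fitted plateau below the CES target leaves
    the BMC undefined (flag "plateau").
    """
    if ces <= 0:
        raise ValueError(f"ces must be positive, got {ces}")
    if np.any(data.responses <= 0):
        raise ValueError("relative BMC modeling requires positive responses")
    rng = np.random.default_rng(rng)
    x, y = data.concentrations, data.responses
    n = len(y)

    def do_fit(xv: np.ndarray, yv: np.ndarray, start: np.ndarray | None = None):
        y0 = float(np.mean(yv[xv == 0]))
        ytop = float(np.mean(yv[xv == xv.max()]))
        a0 = max(y0, 1e-9)
        c0 = max(ytop / a0, 1.0 + 1e-6)
        xmed = float(np.median(xv[xv > 0]))
        lo = np.array([1e-12, 1e-12, 1.0, 1.0])
        hi = np.array([np.inf, np.inf, np.inf, 18.0])
        guesses = [np.array([a0, xmed, c0, d0]) for d0 in (1.0, 2.0)]
        if start is not None:
            guesses.insert(0, np.clip(start, lo + 1e-12, hi - 1e-9))
        best = None
        for p0 in guesses:
            try:
                sol = optimize.least_squares(
                    lambda p: _exp5_rel(xv, p) - yv, p0, bounds=(lo, hi),
                    jac=lambda p: _jac_exp5_rel(xv, p),
                    method="trf", xtol=1e-10, ftol=1e-10, x_scale="jac",
                    max_nfev=300,
                )
            except Exception:
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[1]:
                best = (sol.x, rss)
        return best

    res = do_fit(x, y)
    if res is None:
        return ModelFit(
            model="Exp5-rel", params={}, loglik=float("nan"), aic=float("inf"),
            fit_pvalue=float("nan"), sigma=float("nan"),
            bmc=float("nan"), bmcl=float("nan"), bmcu=float("nan"),
            flags=("no-fit",), n_obs=n,
        )
    params, rss = res
    a, b, c, d = params
    bmc = relative_bmc_from_params(b, c, d, ces)
    flags: list[str] = []
    if not np.isfinite(bmc):
        flags.append("plateau")
    elif bmc > x.max():
        flags.append("above-top")

    bmcl = bmcu = float("nan")
    if np.isfinite(bmc) and n_boot > 0:
        levels = np.unique(x)
        groups = [y[x == lv] for lv in levels]
        boot = []
        for _ in range(n_boot):
            yb = np.concatenate(
                [rng.choice(g, size=len(g), replace=True) for g in groups]
            )
            xb = np.concatenate([np.full(len(g), lv) for lv, g in zip(levels, groups)])
            rb = do_fit(xb, yb, start=params)
            if rb is None:
                continue
            bb = relative_bmc_from_params(rb[0][1], rb[0][2], rb[0][3], ces)
            if np.isfinite(bb):
                boot.append(bb)
        if len(boot) >= max(10, n_boot // 5):
            bmcl, bmcu = np.percentile(boot, [2.5, 97.5])
            bmcl, bmcu = min(bmcl, bmc), max(bmcu, bmc)

    return ModelFit(
        model="Exp5-rel",
        params={"a": a, "b": b, "c": c, "d": d},
        loglik=_gauss_loglik(rss, n),
        aic=2.0 * 5 - 2.0 * _gauss_loglik(rss, n),
        fit_pvalue=_lack_of_fit_p(x, y, rss, 4),
        sigma=math.sqrt(max(rss / n, 0.0)),
        bmc=bmc,
        bmcl=float(bmcl),
        bmcu=float(bmcu),
        flags=tuple(flags),
        n_obs=n,
    )


def lowest_bmc(fits: Mapping[str, ModelFit]) -> tuple[str | None, ModelFit | None]:
    """Pick the biomarker fit with the lowest defined BMC (overall endpoint BMC)."""
    defined = {k: f for k, f in fits.items() if f.defined}
    if not defined:
        return None, None
    key = min(defined, key=lambda k: defined[k].bmc)
    return key, defined[key]
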