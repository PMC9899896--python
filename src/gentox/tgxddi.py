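"""Transcriptomic DDI / non-DDI classification with a three-pronged ensemble.

A biomarker gene panel measured over a concentration series is compared with a
labeled reference (training) set of chemicals with known DNA damage-inducing
(DDI) and non-DDI mechanisms, using three independent statistical analyses:

1. **NSC-PA** — nearest shrunken centroids with posterior probabilities; a
   concentration is called DDI or non-DDI only when its class posterior
   exceeds 0.90, otherwise it is unclassifiable.
2. **PCA** — principal components are estimated on the training chemicals and
   the samples are projected with the training centering and loadings; the
   PC1 axis is oriented so the DDI training mean is negative, and a negative
   PC1 score yields a DDI call.
3. **2-DC** — two-way hierarchical clustering (Euclidean distance, average
   linkage) of training chemicals and sample conditions jointly; the tree is
   cut at its top split and a sample inherits the majority training label of
   its cluster, or is unclassifiable when the split does not separate the
   classes.

A compound's overall call is DDI if any method at any concentration returns
DDI; otherwise non-DDI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "TrainingSet",
    "BiomarkerMatrix",
    "NSCModel",
    "ConcentrationCall",
    "preprocess_expression",
    "fit_nsc",
    "classify_nsc",
    "choose_delta",
    "classify_pca",
    "classify_hclust",
    "overall_ddi_call",
    "TgxDdiClassifier",
]

DDI = "DDI"
NON_DDI = "nonDDI"
UNCLASSIFIABLE = "unclassifiable"
POSTERIOR_THRESHOLD = 0.90


@dataclass
class TrainingSet:
    """Labeled reference chemicals: log2 fold-change matrix plus class labels."""

    matrix: pd.DataFrame  # chemicals x genes
    labels: pd.Series  # chemical -> {DDI, nonDDI}

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.matrix.index)
        bad = set(self.labels.unique()) - {DDI, NON_DDI}
        if bad or self.labels.isna().any():
            raise ValueError(f"labels must be {DDI}/{NON_DDI} for every chemical")
        counts = self.labels.value_counts()
        if counts.get(DDI, 0) < 2 or counts.get(NON_DDI, 0) < 2:
            raise ValueError("need >= 2 chemicals per training class")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.columns


@dataclass
class BiomarkerMatrix:
    """Replicate-averaged log2 fold-changes, one row per (compound, concentration)."""

    values: pd.DataFrame  # rows: MultiIndex (compound, concentration); cols: genes

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("biomarker matrix contains missing values")

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    @property
    def conditions(self) -> pd.Index:
        return self.values.index


def preprocess_expression(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    probe_map: Mapping[str, str] | None = None,
    viability: Mapping[str, float] | None = None,
    viability_threshold: float = 40.0,
    min_depth: float | None = None,
) -> BiomarkerMatrix:
    """Counts to replicate-averaged log2 fold-changes vs solvent control.

    Parameters
    ----------
    counts : DataFrame
        Probes/genes (rows) x samples (columns), raw counts.
    design : DataFrame
        Indexed by sample id with columns ``compound``, ``concentration``,
        ``replicate`` and boolean ``is_control``.
    probe_map : mapping, optional
        probe id -> gene id; probes of the same gene are averaged on the
        log2(CPM + 1) scale.
    viability : mapping, optional
        (compound, concentration) or sample id -> % viability; conditions below
        ``viability_threshold`` are dropped.
    min_depth : float, optional
        Samples whose library size falls below this are dropped.

    Notes
    -----
    Counts are normalized to log2(CPM + 1) to absorb read-depth variability;
    replicates are averaged; fold-change is treated mean minus control mean
    per gene.
    """
    missing = set(counts.columns) - set(design.index)
    if missing:
        raise ValueError(f"samples absent from design: {sorted(missing)[:5]}")
    design = design.loc[list(counts.columns)]
    if not design["is_control"].any():
        raise ValueError("no control samples in design")

    lib = counts.sum(axis=0).astype(float)
    keep = lib > 0
    if min_depth is not None:
        keep &= lib >= min_depth
    counts = counts.loc[:, keep]
    design = design.loc[counts.columns]
    if not design["is_control"].any():
        raise ValueError("all control samples removed by depth filtering")

    cpm = counts.div(counts.sum(axis=0), axis=1) * 1e6
    logc = np.log2(cpm + 1.0)

    if probe_map is not None:
        genes = pd.Series({p: probe_map.get(p, p) for p in logc.index})
        logc = logc.groupby(genes).mean()

    ctrl_mean = logc.loc[:, design["is_control"]].mean(axis=1)
    treated = design.loc[~design["is_control"]]
    rows = {}
    for (compound, conc), grp in treated.groupby(["compound", "concentration"]):
        if viability is not None:
            v = viability.get((compound, conc))
            if v is not None and v < viability_threshold:
                continue
        rep_mean = logc.loc[:, grp.index].mean(axis=1)
        rows[(compound, float(conc))] = rep_mean - ctrl_mean
    if not rows:
        raise ValueError("no treated conditions survive preprocessing")
    values = pd.DataFrame(rows).T
    values.index.names = ["compound", "concentration"]
    return BiomarkerMatrix(values=values)


# --------------------------------------------------------------------------
# nearest shrunken centroids
# --------------------------------------------------------------------------


@dataclass
class NSCModel:
    """Fitted nearest-shrunken-centroid model.

    The standardized class deviation is ``d_kj = (xbar_kj - xbar_j) /
    (m_k * (s_j + s0))`` with ``m_k = sqrt(1/n_k + 1/n)`` and ``s0`` the
    median pooled within-class SD; soft-thresholding by ``delta`` shrinks the
    deviations toward zero and the shrunken centroids are reconstructed from
    the surviving deviations.
    """

    genes: pd.Index
    classes: tuple[str, ...]
    overall_centroid: np.ndarray
    shrunken_centroids: np.ndarray  # K x G
    s: np.ndarray
    s0: float
    delta: float
    priors: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")


def fit_nsc(training: TrainingSet, delta: float = 0.0) -> NSCModel:
    """Fit the shrunken-centroid summary of the training set."""
    X = training.matrix.to_numpy(dtype=float)
    y = training.labels.to_numpy()
    classes = (DDI, NON_DDI)
    n, _ = X.shape
    k = len(classes)
    overall = X.mean(axis=0)
    cent = np.vstack([X[y == c].mean(axis=0) for c in classes])
    nk = np.array([(y == c).sum() for c in classes])
    ss = np.zeros(X.shape[1])
    for i, c in enumerate(classes):
        ss += ((X[y == c] - cent[i]) ** 2).sum(axis=0)
    s = np.sqrt(ss / (n - k))
    if np.all(s == 0):
        raise ValueError("degenerate training set: zero within-class variance")
    s0 = float(np.median(s))
    m = np.sqrt(1.0 / nk + 1.0 / n)
    denom = m[:, None] * (s + s0)[None, :]
    d = (cent - overall) / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall[None, :] + denom * d_shrunk
    return NSCModel(
        genes=training.genes,
        classes=classes,
        overall_centroid=overall,
        shrunken_centroids=shrunken,
        s=s,
        s0=s0,
        delta=float(delta),
        priors=np.full(k, 1.0 / k),
    )


def classify_nsc(
    model: NSCModel, profile: np.ndarray | pd.Series
) -> tuple[dict[str, float], str]:
    """Posterior class probabilities and the >0.90-posterior call for a profile."""
    if isinstance(profile, pd.Series):
        if not profile.index.equals(model.genes):
            profile = profile.reindex(model.genes)
            if profile.isna().any():
                raise ValueError("profile gene set does not match model")
        profile = profile.to_numpy(dtype=float)
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (len(model.genes),):
        raise ValueError("profile gene set does not match model")
    scale = (model.s + model.s0) ** 2
    delta_k = ((profile[None, :] - model.shrunken_centroids) ** 2 / scale).sum(
        axis=1
    ) - 2.0 * np.log(model.priors)
    z = -0.5 * delta_k
    z -= z.max()
    post = np.exp(z)
    post /= post.sum()
    posteriors = dict(zip(model.classes, post))
    best = model.classes[int(np.argmax(post))]
    call = best if post.max() > POSTERIOR_THRESHOLD else UNCLASSIFIABLE
    return posteriors, call


def choose_delta(
    training: TrainingSet, deltas: Sequence[float] | None = None
) -> float:
    """Shrinkage by leave-one-chemical-out CV, smallest delta on tied accuracy."""
    if deltas is None:
        base = fit_nsc(training, delta=0.0)
        denom = np.sqrt(
            1.0 / np.array([(training.labels == c).sum() for c in base.classes])
            + 1.0 / len(training.labels)
        )
        d = np.abs(
            (
                np.vstack(
                    [
                        training.matrix[training.labels == c].mean(axis=0)
                        for c in base.classes
                    ]
                )
                - base.overall_centroid
            )
            / (denom[:, None] * (base.s + base.s0)[None, :])
        )
        deltas = np.linspace(0.0, float(d.max()), 15)
    best_delta, best_acc = 0.0, -1.0
    for delta in deltas:
        correct = 0
        n_eval = 0
        for chem in training.matrix.index:
            try:
                rest = TrainingSet(
                    matrix=training.matrix.drop(index=chem),
                    labels=training.labels.drop(index=chem),
                )
            except ValueError:  # dropping would empty a class of its pair
                continue
            model = fit_nsc(rest, delta=delta)
            post, _ = classify_nsc(model, training.matrix.loc[chem])
            pred = max(post, key=post.get)
            correct += pred == training.labels.loc[chem]
            n_eval += 1
        acc = correct / n_eval if n_eval else 0.0
        if acc > best_acc:  # strict: keeps the smallest delta on ties
            best_delta, best_acc = float(delta), acc
    return best_delta


# --------------------------------------------------------------------------
# PCA and hierarchical clustering prongs
# --------------------------------------------------------------------------


def _pca_axis(training: TrainingSet, scale: bool = False):
    X = training.matrix.to_numpy(dtype=float)
    center = X.mean(axis=0)
    Xc = X - center
    sd = np.ones(X.shape[1])
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    u, sv, vt = np.linalg.svd(Xc, full_matrices=False)
    if np.allclose(sv, 0):
        raise ValueError("zero-variance training matrix")
    axis = vt[0]
    train_scores = Xc @ axis
    ddi_mean = train_scores[(training.labels == DDI).to_numpy()].mean()
    if ddi_mean > 0:  # orient so the DDI training mean is negative
        axis = -axis
        train_scores = -train_scores
    return center, sd, axis, train_scores


def classify_pca(
    training: TrainingSet, samples: BiomarkerMatrix, scale: bool = False
) -> pd.DataFrame:
    """Project samples on the training PC1; negative scores are DDI.

    A score of exactly 0 is called non-DDI (strict inequality on the DDI
    side).  Returns a DataFrame indexed by condition with columns ``pc1`` and
    ``call``.
    """
    if not samples.genes.equals(training.genes):
        raise ValueError("sample gene set does not match training set")
    center, sd, axis, _ = _pca_axis(training, scale=scale)
    S = (samples.values.to_numpy(dtype=float) - center) / sd
    scores = S @ axis
    calls = np.where(scores < 0, DDI, NON_DDI)
    return pd.DataFrame({"pc1": scores, "call": calls}, index=samples.conditions)


def classify_hclust(
    training: TrainingSet, samples: BiomarkerMatrix
) -> pd.DataFrame:
    """Joint average-linkage clustering cut at the top split.

    Training chemicals and sample conditions are clustered together on their
    gene profiles (Euclidean distance, average linkage) and the dendrogram is
    cut into its two top clusters.  A cluster is the DDI (non-DDI) main
    cluster when the strict majority of its training chemicals is DDI
    (non-DDI); a sample inherits its cluster's identity, and is
    unclassifiable when its cluster holds no training chemicals or the top
    split fails to separate the classes by majority.
    """
    if not samples.genes.equals(training.genes):
        raise ValueError("sample gene set does not match training set")
    n_train = len(training.matrix)
    X = np.vstack(
        [training.matrix.to_numpy(dtype=float), samples.values.to_numpy(dtype=float)]
    )
    if len(X) < 2:
        raise ValueError("need at least two profiles to cluster")
    Z = linkage(X, method="average", metric="euclidean")
    assign = fcluster(Z, t=2, criterion="maxclust")
    labels = training.labels.to_numpy()

    identity: dict[int, str | None] = {}
    for cl in np.unique(assign):
        members = labels[assign[:n_train] == cl] if n_train else np.array([])
        n_ddi = int((members == DDI).sum())
        n_non = int((members == NON_DDI).sum())
        if len(members) == 0 or n_ddi == n_non:
            identity[cl] = None
        else:
            identity[cl] = DDI if n_ddi > n_non else NON_DDI

    separated = set(identity.values()) >= {DDI, NON_DDI}
    rows = []
    for i, cond in enumerate(samples.conditions):
        cl = int(assign[n_train + i])
        if not separated or identity.get(cl) is None:
            rows.append((cl, UNCLASSIFIABLE))
        else:
            rows.append((cl, identity[cl]))
    return pd.DataFrame(rows, columns=["branch", "call"], index=samples.conditions)


# --------------------------------------------------------------------------
# ensemble
# --------------------------------------------------------------------------


@dataclass
class ConcentrationCall:
    """One method's call for one (compound, concentration) condition."""

    condition: tuple
    method: str  # NSC | PCA | HC
    call: str  # DDI | nonDDI | unclassifiable
    posterior: float | None = None
    pc1: float | None = None
    branch: int | None = None


def overall_ddi_call(calls: Iterable[ConcentrationCall]) -> str:
    """DDI iff any method at any concentration returned DDI, else non-DDI."""
    calls = list(calls)
    if not calls:
        raise ValueError("empty call set")
    return DDI if any(c.call == DDI for c in calls) else NON_DDI


class TgxDdiClassifier:
    """Ensemble DDI classifier fitted on a labeled training set.

    Parameters
    ----------
    training : TrainingSet
    delta : float, optional
        NSC shrinkage; chosen by leave-one-chemical-out CV when omitted.
    pca_scale : bool
        Scale genes to unit variance in the PCA prong (default False:
        centering only).
    """

    def __init__(
        self,
        training: TrainingSet,
        delta: float | None = None,
        pca_scale: bool = False,
    ) -> None:
        self.training = training
        self.pca_scale = pca_scale
        self.delta = choose_delta(training) if delta is None else float(delta)
        self.nsc = fit_nsc(training, delta=self.delta)

    def classify(self, samples: BiomarkerMatrix) -> pd.DataFrame:
        """Per-condition calls from all three methods.

        Returns a DataFrame indexed by condition with columns
        ``nsc_posterior_ddi``, ``nsc_call``, ``pc1``, ``pca_call``,
        ``branch``, ``hc_call``.
        """
        pca = classify_pca(self.training, samples, scale=self.pca_scale)
        hc = classify_hclust(self.training, samples)
        nsc_rows = []
        for cond in samples.conditions:
            post, call = classify_nsc(self.nsc, samples.values.loc[cond])
            nsc_rows.append((post[DDI], call))
        nsc = pd.DataFrame(
            nsc_rows, columns=["nsc_posterior_ddi", "nsc_call"], index=samples.conditions
        )
        out = pd.concat(
            [nsc, pca.rename(columns={"call": "pca_call"}),
             hc.rename(columns={"call": "hc_call"})],
            axis=1,
        )
        return out

    def overall_calls(self, samples: BiomarkerMatrix) -> pd.Series:
        """Per-compound overall DDI/non-DDI calls (any positive anywhere)."""
        table = self.classify(samples)
        out = {}
        for compound, grp in table.groupby(level="compound", sort=False):
            calls = [
                ConcentrationCall(condition=idx, method=m, call=grp.loc[idx, col])
                for idx in grp.index
                for m, col in (("NSC", "nsc_call"), ("PCA", "pca_call"), ("HC", "hc_call"))
            ]
            out[compound] = overall_ddi_call(calls)
        return pd.Series(out, name="overall_call")
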