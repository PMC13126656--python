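"""Cosine-similarity network, 2D force-directed embedding, and LOOCV classifier.

The separability framework works on the selected feature vectors:

1. Each image's feature vector is L2-normalized; pairwise inner products give
   a symmetric cosine-similarity matrix (entries in [0, 1] for nonnegative
   features).
2. For visualization, the similarity network is embedded in 2D with a
   weighted force-directed (Fruchterman–Reingold) layout — higher-similarity
   pairs attract more strongly, all pairs repel — and an in-sample logistic
   boundary drawn on the coordinates summarizes separability.
3. For evaluation, a leave-one-out cross-validated logistic classifier is
   trained not on raw features but on four *similarity-summary attributes*
   per sample: mean and SD of its similarity to the normal/benign cluster and
   to the EC/EIN cluster.  A training sample's self-similarity (identically
   1) is excluded from its own cluster's statistics; the held-out sample's
   attributes use only its similarities to the training samples, so no fold
   ever sees the held-out data.

Per-fold logistic fits carry a small ridge penalty so that perfectly
separable folds still converge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .feature_selection import LABEL_COLUMN
from .rf_preprocessing import ValidationError
from .synthetic_data import LABEL_DISEASE, LABEL_NORMAL

__all__ = [
    "SimilarityMatrix",
    "Embedding2D",
    "BoundaryResult",
    "CVResult",
    "cosine_similarity",
    "force_layout",
    "boundary_2d",
    "similarity_summary",
    "loocv",
    "roc_auc",
    "confusion_at",
]

RIDGE_LAMBDA = 1e-6  # survives perfectly separated folds
ATTRIBUTE_NAMES = ("mean_sim_normal", "sd_sim_normal", "mean_sim_disease", "sd_sim_disease")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric unit-diagonal cosine similarities with sample ids and labels."""

    S: np.ndarray
    ids: list[str]
    labels: np.ndarray  # of LABEL_NORMAL / LABEL_DISEASE strings

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.S.shape != (n, n) or len(self.labels) != n:
            raise ValidationError("similarity matrix, ids and labels sizes differ")
        if not np.allclose(self.S, self.S.T, atol=1e-12):
            raise ValidationError("similarity matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Embedding2D:
    coords: np.ndarray  # (n, 2)
    seed: int
    n_iter: int
    final_energy: float


@dataclass(frozen=True)
class BoundaryResult:
    coef: np.ndarray  # (2,)
    intercept: float
    n_correct_side: int


@dataclass(frozen=True)
class CVResult:
    """Pooled out-of-fold predictions and their summary metrics."""

    probabilities: np.ndarray  # P(disease) per sample, out of fold
    labels: np.ndarray
    auc: float
    confusion: dict[str, float]
    fold_coefs: np.ndarray  # (n, 4) per-fold logistic coefficients
    fold_intercepts: np.ndarray


# ---------------------------------------------------------------------------
# Similarity matrix
# ---------------------------------------------------------------------------

def cosine_similarity(
    table: pd.DataFrame,
    feature_names: list[str] | None = None,
    label_column: str = LABEL_COLUMN,
    zscore: bool = False,
) -> SimilarityMatrix:
    """L2-normalize each row of the selected features; S = inner products.

    By default the raw (nonnegative) feature scales are kept — no per-column
    standardization — so all similarities land in [0, 1].  ``zscore=True``
    optionally standardizes columns first.  Rows with missing values in the
    selected columns are dropped with a warning; a zero-norm row is an error.
    """
    import warnings

    if feature_names is None:
        feature_names = [c for c in table.columns if c != label_column]
    x = table[feature_names].apply(pd.to_numeric, errors="coerce")
    ok = x.notna().all(axis=1)
    if not ok.all():
        dropped = list(table.index[~ok])
        warnings.warn(f"dropping rows with missing features: {dropped}", stacklevel=2)
    x = x[ok]
    labels = table.loc[ok, label_column].to_numpy()
    ids = [str(i) for i in table.index[ok]]
    arr = x.to_numpy(dtype=np.float64)
    if zscore:
        arr = (arr - arr.mean(axis=0)) / arr.std(axis=0, ddof=0)
    norms = np.linalg.norm(arr, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if zero.size:
        raise ValidationError(f"zero-norm feature vector for sample {ids[zero[0]]}")
    unit = arr / norms[:, None]
    S = unit @ unit.T
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S=S, ids=ids, labels=labels)


# ---------------------------------------------------------------------------
# Force-directed embedding and in-sample boundary
# ---------------------------------------------------------------------------

DEFAULT_WEIGHT_EXPONENT = 32.0
WEIGHT_LINEAR_MIX = 0.01


def force_layout(
    sim: SimilarityMatrix,
    seed: int = 42,
    n_iter: int = 500,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> Embedding2D:
    """Weighted Fruchterman–Reingold layout of the similarity network.

    Attraction between i and j scales with the edge weight
    (f_a = w * d^2 / k); every pair repels (f_r = k^2 / d) with
    k = 1/sqrt(n).  Displacements are capped by a linearly cooling
    temperature.  Coordinates are *not* rescaled afterwards, so equilibrium
    distances genuinely decrease with similarity.  Deterministic given seed.

    Edge weights are the cosine similarities raised to ``weight_exponent``,
    plus a small linear leak (``WEIGHT_LINEAR_MIX`` x similarity): nonnegative
    raw-scale feature vectors yield similarities concentrated near 1, and the
    monotone contrast stretch — which preserves the
    higher-similarity-attracts-more-strongly semantics — is what lets the
    near-uniform all-pairs similarity graph spread into visible structure,
    while the leak keeps every pair weakly attractive so equilibrium
    distances remain strictly decreasing in similarity.  Set the exponent to
    1 for untransformed weights.
    """
    n = len(sim)
    if n < 2:
        raise ValidationError("need at least 2 samples to lay out")
    if weight_exponent <= 0:
        raise ValidationError("weight_exponent must be positive")
    s_pos = np.clip(sim.S, 0.0, None)
    w = (s_pos**weight_exponent + WEIGHT_LINEAR_MIX * s_pos) / (1.0 + WEIGHT_LINEAR_MIX)
    np.fill_diagonal(w, 0.0)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-0.5, 0.5, size=(n, 2))
    k = 1.0 / math.sqrt(n)
    t0 = 0.1
    for it in range(n_iter):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=2)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        # net scalar force along the i<-j direction: repulsion - attraction
        coef = k * k / dist**2 - w * dist / k
        np.fill_diagonal(coef, 0.0)
        disp = (coef[:, :, None] * delta).sum(axis=1)
        step = np.linalg.norm(disp, axis=1, keepdims=True)
        t = t0 * (1.0 - it / n_iter) + 1e-3
        disp = np.where(step > t, disp / np.maximum(step, 1e-12) * t, disp)
        pos = pos + disp
    delta = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(delta, axis=2)
    iu = np.triu_indices(n, 1)
    d = np.maximum(dist[iu], 1e-12)
    energy = float((w[iu] * d**3 / (3 * k)).sum() - (k * k * np.log(d)).sum())
    return Embedding2D(coords=pos, seed=seed, n_iter=n_iter, final_energy=energy)


def _fit_logistic(x: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Maximum-likelihood logistic fit with a small ridge term.

    Class weights are balanced: with a 3:1 class imbalance, an unweighted
    intercept tracks the training base rate, which in leave-one-out folds
    shifts systematically with the held-out sample's own class and biases
    pooled out-of-fold AUC below chance under the null.
    """
    model = LogisticRegression(
        C=1.0 / RIDGE_LAMBDA, solver="lbfgs", max_iter=5000, tol=1e-8,
        class_weight="balanced",
    )
    model.fit(x, y)
    return model


def boundary_2d(emb: Embedding2D, labels: np.ndarray) -> BoundaryResult:
    """In-sample logistic boundary on the 2D coordinates.

    Returns the linear boundary (zero of coef . xy + intercept) and the number
    of samples lying on their own label's side.
    """
    labels = np.asarray(labels)
    if len(set(labels)) != 2:
        raise ValidationError("both classes must be present")
    y = (labels == LABEL_DISEASE).astype(int)
    model = _fit_logistic(emb.coords, y)
    score = emb.coords @ model.coef_[0] + model.intercept_[0]
    n_correct = int(((score > 0).astype(int) == y).sum())
    return BoundaryResult(
        coef=model.coef_[0].copy(),
        intercept=float(model.intercept_[0]),
        n_correct_side=n_correct,
    )


# ---------------------------------------------------------------------------
# Similarity-summary LOOCV classifier
# ---------------------------------------------------------------------------

def similarity_summary(
    sims: np.ndarray,
    labels: np.ndarray,
    exclude_index: int | None = None,
) -> np.ndarray:
    """Four summary attributes of one sample's similarities to a cluster set.

    Returns ``(mean_normal, sd_normal, mean_disease, sd_disease)`` over the
    samples labelled normal/benign resp. EC/EIN.  ``exclude_index`` removes
    one position first — used to drop a training sample's self-similarity
    from its own cluster.  Each cluster must keep >= 2 members so the SD is
    defined.
    """
    sims = np.asarray(sims, dtype=np.float64)
    labels = np.asarray(labels)
    keep = np.ones(len(sims), dtype=bool)
    if exclude_index is not None:
        keep[exclude_index] = False
    out = []
    for cluster in (LABEL_NORMAL, LABEL_DISEASE):
        vals = sims[keep & (labels == cluster)]
        if len(vals) < 2:
            raise ValidationError(
                f"cluster {cluster!r} has fewer than 2 members; SD undefined"
            )
        out.extend([vals.mean(), vals.std(ddof=1)])
    return np.array(out)


def _training_attributes(S_train: np.ndarray, labels_train: np.ndarray) -> np.ndarray:
    """(n_train, 4) attribute matrix; self-similarity excluded per row."""
    return np.vstack(
        [
            similarity_summary(S_train[j], labels_train, exclude_index=j)
            for j in range(len(labels_train))
        ]
    )


def fold_probability(
    S_train: np.ndarray,
    labels_train: np.ndarray,
    sims_test: np.ndarray,
) -> tuple[float, np.ndarray, float]:
    """One LOOCV fold as a pure function of training-only inputs.

    Fits the logistic model on the training attribute matrix and returns the
    held-out sample's predicted disease probability plus the fitted
    coefficients.  Exposed separately so leakage can be audited: the held-out
    sample's row/column appear nowhere in the arguments.
    """
    classes = set(labels_train)
    if classes != {LABEL_NORMAL, LABEL_DISEASE}:
        raise ValidationError("degenerate fold: training set must contain both classes")
    x_train = _training_attributes(S_train, labels_train)
    y_train = (labels_train == LABEL_DISEASE).astype(int)
    model = _fit_logistic(x_train, y_train)
    x_test = similarity_summary(sims_test, labels_train)
    prob = float(model.predict_proba(x_test[None, :])[0, model.classes_.tolist().index(1)])
    return prob, model.coef_[0].copy(), float(model.intercept_[0])


def loocv(sim: SimilarityMatrix, threshold: float = 0.5) -> CVResult:
    """Leave-one-out cross-validation of the similarity-summary classifier."""
    n = len(sim)
    labels = sim.labels
    if n < 6:
        raise ValidationError("need at least 6 samples for LOOCV")
    for cluster in (LABEL_NORMAL, LABEL_DISEASE):
        if (labels == cluster).sum() < 3:
            raise ValidationError(f"need >= 3 samples of class {cluster!r}")
    probs = np.empty(n)
    coefs = np.empty((n, 4))
    intercepts = np.empty(n)
    for i in range(n):
        train = np.arange(n) != i
        S_train = sim.S[np.ix_(train, train)]
        probs[i], coefs[i], intercepts[i] = fold_probability(
            S_train, labels[train], sim.S[i, train]
        )
    auc = roc_auc(probs, labels)
    confusion = confusion_at(probs, labels, threshold=threshold)
    return CVResult(
        probabilities=probs,
        labels=labels,
        auc=auc,
        confusion=confusion,
        fold_coefs=coefs,
        fold_intercepts=intercepts,
    )


# ---------------------------------------------------------------------------
# ROC / confusion
# ---------------------------------------------------------------------------

def roc_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann–Whitney rank statistic; ties count one half."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    pos = probs[labels == LABEL_DISEASE]
    neg = probs[labels == LABEL_NORMAL]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be present for ROC")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def confusion_at(
    probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Confusion counts at a probability threshold; EC/EIN is positive."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) != 2:
        raise ValidationError("both classes must be present")
    pred_pos = probs >= threshold
    is_pos = labels == LABEL_DISEASE
    tp = int((pred_pos & is_pos).sum())
    fn = int((~pred_pos & is_pos).sum())
    tn = int((~pred_pos & ~is_pos).sum())
    fp = int((pred_pos & ~is_pos).sum())
    return {
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / len(labels),
    }


def roc_curve_points(probs: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """FPR/TPR points swept over all observed thresholds (for plotting)."""
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(probs))[::-1]])
    rows = []
    is_pos = np.asarray(labels) == LABEL_DISEASE
    n_pos, n_neg = is_pos.sum(), (~is_pos).sum()
    for thr in thresholds:
        pred = probs >= thr
        rows.append(
            {
                "threshold": thr,
                "fpr": (pred & ~is_pos).sum() / n_neg,
                "tpr": (pred & is_pos).sum() / n_pos,
            }
        )
    return pd.DataFrame(rows)
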