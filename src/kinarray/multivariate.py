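"""PCA and partial least squares discriminant analysis with leave-one-out CV.

PLS-DA regresses a ±1 class code on the (mean-centered) peptide matrix by
sequential NIPALS extraction.  With a single response the NIPALS weight
update has a closed form per component:

    w_a ∝ X_a^T y_a / ‖X_a^T y_a‖        (unit weight vector)
    t_a = X_a w_a                        (score)
    p_a = X_a^T t_a / t_a^T t_a          (X loading)
    q_a = y_a^T t_a / t_a^T t_a          (y loading)
    X_{a+1} = X_a − t_a p_a^T,  y_{a+1} = y_a − q_a t_a

The regression vector b = W (P^T W)^{-1} q maps a centered sample profile
to its continuous *prediction score*; scores above 0 call the positive
class (BRAF(V600E) in the melanoma application), scores at or below 0 the
negative class (BRAF wild-type).  All linear algebra is deterministic — no
randomized initialization — so refits are bit-stable.

Leave-one-out cross-validation refits everything, including the column
centers, on the n−1 retained samples for every fold, so the held-out
profile never influences the model that scores it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import InhibitionProfile, SignalMatrix


def _as_matrix(mat) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(mat, SignalMatrix):
        df = mat.values
    elif isinstance(mat, InhibitionProfile):
        df = mat.lfc
    elif isinstance(mat, pd.DataFrame):
        df = mat
    else:
        arr = np.asarray(mat, dtype=float)
        return (
            arr,
            [f"s{i}" for i in range(arr.shape[0])],
            [f"p{j}" for j in range(arr.shape[1])],
        )
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray  # samples × components
    loadings: np.ndarray  # peptides × components, columns orthonormal
    explained_variance_fraction: np.ndarray
    sample_ids: list[str]
    peptide_ids: list[str]
    mean_: np.ndarray = field(repr=False, default=None)


def pca_fit(mat, n_components: int) -> PcaResult:
    """Column-mean-centered PCA via singular value decomposition.

    Sign convention: within each component, the loading element of largest
    magnitude is made positive, which fixes the otherwise arbitrary
    reflection and makes results reproducible across runs and libraries.
    """
    X, sample_ids, peptide_ids = _as_matrix(mat)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_rank = min(n - 1, p)
    if not (1 <= n_components <= max_rank):
        raise ValueError(
            f"n_components must be in 1..{max_rank}, got {n_components}"
        )
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")

    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic reflection: dominant loading entry positive
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    total_var = float((S**2).sum())
    evf = (S[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(
        n_components
    )
    return PcaResult(
        scores=U[:, :n_components] * S[:n_components],
        loadings=Vt[:n_components].T,
        explained_variance_fraction=evf,
        sample_ids=sample_ids,
        peptide_ids=peptide_ids,
        mean_=mean,
    )


# --------------------------------------------------------------------------
# PLS-DA
# --------------------------------------------------------------------------


@dataclass
class PlsdaModel:
    """Fitted two-class PLS-DA model (single ±1 response, NIPALS)."""

    x_means: np.ndarray
    x_scales: np.ndarray | None
    class_coding: dict[str, int]  # {negative_class: −1, positive_class: +1}
    weights: np.ndarray  # peptides × components (W)
    x_loadings: np.ndarray  # peptides × components (P)
    y_loadings: np.ndarray  # per-component q
    n_components: int
    regression_vector: np.ndarray
    y_mean: float
    training_scores: np.ndarray = field(repr=False, default=None)

    @property
    def negative_class(self) -> str:
        return next(c for c, v in self.class_coding.items() if v < 0)

    @property
    def positive_class(self) -> str:
        return next(c for c, v in self.class_coding.items() if v > 0)

    def classify(self, score: float) -> str:
        """Sign-threshold class call; a score of exactly 0 falls to the
        negative (reference) class."""
        return self.positive_class if score > 0 else self.negative_class


def encode_classes(
    y, classes: tuple[str, str] | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """Map a two-level label vector to −1/+1.

    ``classes = (negative, positive)``; if omitted the two labels are taken
    in sorted order, the first coded −1.
    """
    y = np.asarray(y)
    levels = sorted(set(map(str, y)))
    if classes is None:
        if len(levels) != 2:
            raise ValueError(f"need exactly two classes, got {levels}")
        classes = (levels[0], levels[1])
    coding = {classes[0]: -1, classes[1]: 1}
    unknown = set(map(str, y)) - set(coding)
    if unknown:
        raise ValueError(f"labels outside {classes}: {sorted(unknown)}")
    return np.array([coding[str(v)] for v in y], dtype=float), coding


def plsda_fit(
    X,
    y,
    n_components: int = 2,
    scale: bool = False,
    classes: tuple[str, str] | None = None,
) -> PlsdaModel:
    """Fit a two-class PLS-DA model by NIPALS on the full peptide panel.

    Parameters
    ----------
    X
        Samples × peptides matrix (array, DataFrame, SignalMatrix or
        InhibitionProfile).
    y
        Class label per sample (two levels), or a ±1 numeric vector.
    n_components
        Number of latent variables (default 2).
    scale
        Autoscale columns to unit variance inside the fit.  Off by
        default: log-fold-change profiles already share a common scale.
    classes
        ``(negative_class, positive_class)`` ordering for the ±1 coding.
    """
    Xarr, _, _ = _as_matrix(X)
    yarr = np.asarray(y)
    if yarr.dtype.kind in "ifb" and set(np.unique(yarr)) <= {-1.0, 1.0}:
        ycoded = yarr.astype(float)
        coding = {"-1": -1, "1": 1} if classes is None else {
            classes[0]: -1,
            classes[1]: 1,
        }
    else:
        ycoded, coding = encode_classes(yarr, classes)
    n, p = Xarr.shape
    if len(ycoded) != n:
        raise ValueError("X and y length mismatch")
    if len(set(ycoded)) < 2:
        raise ValueError("y must contain both classes")
    max_comp = min(n - 1, p)
    if not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must be in 1..{max_comp}")

    x_means = Xarr.mean(axis=0)
    Xc = Xarr - x_means
    if scale:
        x_scales = Xc.std(axis=0, ddof=1)
        x_scales[x_scales == 0] = 1.0
        Xc = Xc / x_scales
    else:
        x_scales = None
    if not np.any(Xc):
        raise ValueError("X has zero variance after centering")
    y_mean = float(ycoded.mean())
    yc = ycoded - y_mean

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(
                f"degenerate component {a + 1}: residual X'y vanished"
            )
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"degenerate component {a + 1}: zero score vector")
        pvec = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pvec)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a] = w, pvec, qa

    B = W @ np.linalg.solve(P.T @ W, q)
    model = PlsdaModel(
        x_means=x_means,
        x_scales=x_scales,
        class_coding=coding,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        n_components=n_components,
        regression_vector=B,
        y_mean=y_mean,
    )
    model.training_scores = plsda_predict(model, Xarr)
    return model


def plsda_predict(model: PlsdaModel, x) -> float | np.ndarray:
    """Continuous prediction score(s) for one profile or a stacked matrix.

    The score is the centered (and, if the model autoscaled, scaled)
    profile projected on the regression vector; the overall training mean
    maps to 0 by construction, making the sign threshold of the class rule
    a contrast against the pooled center.
    """
    arr = np.asarray(x, dtype=float) if not isinstance(x, pd.DataFrame) else x.to_numpy()
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != len(model.x_means):
        raise ValueError(
            f"profile length {arr.shape[1]} != panel size {len(model.x_means)}"
        )
    Z = arr - model.x_means
    if model.x_scales is not None:
        Z = Z / model.x_scales
    scores = Z @ model.regression_vector
    return float(scores[0]) if single else scores


# --------------------------------------------------------------------------
# Leave-one-out cross-validation
# --------------------------------------------------------------------------


@dataclass
class LoocvResult:
    sample_ids: list[str]
    prediction_scores: np.ndarray
    predicted_classes: list[str]
    true_classes: list[str]
    confusion: dict[tuple[str, str], int]  # (true, predicted) → count
    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    invalid_folds: list[str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "true_class": self.true_classes,
                "prediction_score": self.prediction_scores,
                "predicted_class": self.predicted_classes,
                "correct": [
                    t == p
                    for t, p in zip(self.true_classes, self.predicted_classes)
                ],
            }
        )


def loocv(
    X,
    y,
    n_components: int = 2,
    scale: bool = False,
    classes: tuple[str, str] | None = None,
) -> LoocvResult:
    """Leave-one-out cross-validated PLS-DA classification.

    Every fold refits centering (and scaling) and the PLS-DA decomposition
    on the retained n−1 samples only; the held-out sample is scored by that
    model and called by the sign rule.  Folds whose training set collapses
    to a single class are marked invalid and excluded from the accuracy
    denominators.
    """
    Xarr, sample_ids, _ = _as_matrix(X)
    y = np.asarray(y)
    n = Xarr.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    labels = [str(v) for v in y]
    if classes is None:
        levels = sorted(set(labels))
        if len(levels) != 2:
            raise ValueError(f"need exactly two classes, got {levels}")
        classes = (levels[0], levels[1])

    scores = np.full(n, np.nan)
    predicted: list[str] = []
    invalid: list[str] = []
    for i in range(n):
        keep = np.arange(n) != i
        y_train = [labels[j] for j in range(n) if j != i]
        if len(set(y_train)) < 2:
            invalid.append(sample_ids[i])
            predicted.append("invalid_fold")
            continue
        model = plsda_fit(
            Xarr[keep],
            y_train,
            n_components=min(n_components, n - 2),
            scale=scale,
            classes=classes,
        )
        s = plsda_predict(model, Xarr[i])
        scores[i] = s
        predicted.append(model.classify(s))

    valid = [i for i in range(n) if predicted[i] != "invalid_fold"]
    confusion: dict[tuple[str, str], int] = {}
    for i in valid:
        key = (labels[i], predicted[i])
        confusion[key] = confusion.get(key, 0) + 1
    correct = sum(1 for i in valid if labels[i] == predicted[i])
    overall = correct / len(valid) if valid else float("nan")
    per_class = {}
    for c in classes:
        idx = [i for i in valid if labels[i] == c]
        per_class[c] = (
            sum(1 for i in idx if predicted[i] == c) / len(idx)
            if idx
            else float("nan")
        )
    return LoocvResult(
        sample_ids=sample_ids,
        prediction_scores=scores,
        predicted_classes=predicted,
        true_classes=labels,
        confusion=confusion,
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        invalid_folds=invalid,
    )
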