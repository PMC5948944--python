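"""Pseudolinear discriminant classification of gait phases.

A linear discriminant with pooled within-class covariance whose inverse is
taken in the Moore–Penrose sense ("pseudolinear"), so that the routine
rank deficiency of 100+ correlated window features is handled without
regularization.  Each feature row is assigned

    argmax_c  x' S+ mu_c  -  1/2 mu_c' S+ mu_c  +  ln(prior_c)

with ties broken toward the lower phase number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import FeatureMatrix, NormalizationStats
from .io import LabelTrack


class FitError(ValueError):
    pass


@dataclass
class LDAModel:
    classes: np.ndarray              # sorted phase codes present in training
    means: np.ndarray                # (n_classes, n_features)
    pooled_cov: np.ndarray           # (n_features, n_features)
    pinv_cov: np.ndarray
    priors: np.ndarray
    norm_stats: NormalizationStats | None = None

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=int)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.pooled_cov = np.asarray(self.pooled_cov, dtype=float)
        self.pinv_cov = np.asarray(self.pinv_cov, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if np.any(self.priors < 0) or not np.isclose(self.priors.sum(), 1.0):
            raise FitError("priors must be nonnegative and sum to 1")

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.atleast_2d(np.asarray(X, dtype=float))


def _as_labels(y) -> np.ndarray:
    if isinstance(y, LabelTrack):
        return y.labels
    return np.asarray(y, dtype=int)


def fit(X, y, priors=None, norm_stats: NormalizationStats | None = None) -> LDAModel:
    """Fit the discriminant from feature rows ``X`` and phase labels ``y``.

    Pooled covariance uses the within-class scatter divided by ``n - C``.
    Default priors are the empirical class frequencies; pass a mapping
    ``{phase: weight}`` (renormalized) to override.
    """
    Xm, yv = _as_matrix(X), _as_labels(y)
    if Xm.shape[0] != yv.size:
        raise FitError(f"{Xm.shape[0]} feature rows but {yv.size} labels")
    classes = np.unique(yv)
    if classes.size < 2:
        raise FitError("need at least 2 classes to fit a discriminant")
    n, d = Xm.shape
    means = np.empty((classes.size, d))
    scatter = np.zeros((d, d))
    counts = np.empty(classes.size)
    for i, c in enumerate(classes):
        rows = Xm[yv == c]
        if rows.shape[0] < 2:
            raise FitError(f"class {c} has fewer than 2 training rows")
        counts[i] = rows.shape[0]
        means[i] = rows.mean(axis=0)
        centered = rows - means[i]
        scatter += centered.T @ centered
    pooled = scatter / (n - classes.size)
    pooled = (pooled + pooled.T) / 2.0
    pinv = np.linalg.pinv(pooled, hermitian=True)
    if priors is None:
        pr = counts / n
    else:
        pr = np.array([float(priors[int(c)]) for c in classes])
        pr = pr / pr.sum()
    return LDAModel(classes, means, pooled, pinv, pr, norm_stats)


def decision_scores(model: LDAModel, X) -> np.ndarray:
    """Linear discriminant scores, shape (n_rows, n_classes)."""
    Xm = _as_matrix(X)
    if Xm.shape[1] != model.n_features:
        raise FitError(
            f"feature dimension {Xm.shape[1]} != model dimension "
            f"{model.n_features}")
    W = model.pinv_cov @ model.means.T                      # (d, C)
    bias = -0.5 * np.einsum("cd,dc->c", model.means, W) + np.log(model.priors)
    return Xm @ W + bias


def predict(model: LDAModel, X) -> np.ndarray:
    """Phase code per row; ties go to the lower phase number."""
    scores = decision_scores(model, X)
    # classes are sorted ascending and argmax returns the first maximum
    return model.classes[np.argmax(scores, axis=1)]


def predict_track(model: LDAModel, X: FeatureMatrix) -> LabelTrack:
    return LabelTrack(predict(model, X), X.window_centers)


# ---------------------------------------------------------------------------
# Plain-text model serialization
# ---------------------------------------------------------------------------

def _write_block(fh, name: str, arr: np.ndarray) -> None:
    arr = np.atleast_2d(arr)
    fh.write(f"[{name}] {arr.shape[0]} {arr.shape[1]}\n")
    for row in arr:
        fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def save_model(model: LDAModel, path) -> None:
    """Write the model as self-describing key-value + matrix blocks."""
    with open(path, "w") as fh:
        fh.write("format fmgait-lda 1\n")
        fh.write("classes " + " ".join(map(str, model.classes.tolist())) + "\n")
        _write_block(fh, "priors", model.priors)
        _write_block(fh, "means", model.means)
        _write_block(fh, "pooled_cov", model.pooled_cov)
        if model.norm_stats is not None:
            _write_block(fh, "norm_min", model.norm_stats.col_min)
            _write_block(fh, "norm_max", model.norm_stats.col_max)


def load_model(path) -> LDAModel:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("format fmgait-lda"):
        raise FitError(f"{path}: not an fmgait LDA model file")
    classes = np.array(lines[1].split()[1:], dtype=int)
    blocks: dict[str, np.ndarray] = {}
    i = 2
    while i < len(lines):
        head = lines[i].split()
        name = head[0].strip("[]")
        r, c = int(head[1]), int(head[2])
        rows = [np.fromstring(lines[i + 1 + j], sep=" ") for j in range(r)]
        blocks[name] = np.vstack(rows).reshape(r, c)
        i += 1 + r
    pooled = blocks["pooled_cov"]
    stats = None
    if "norm_min" in blocks:
        stats = NormalizationStats(blocks["norm_min"].ravel(),
                                   blocks["norm_max"].ravel())
    return LDAModel(classes, blocks["means"], pooled,
                    np.linalg.pinv(pooled, hermitian=True),
                    blocks["priors"].ravel(), stats)
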