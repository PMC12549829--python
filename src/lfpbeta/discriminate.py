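"""SVD-LDA discrimination of neural activity states.

Beta-band Hilbert envelopes are cut into fixed-length non-overlapping
epochs; epochs are centred and projected onto their top-2 right singular
directions (SVD); a linear discriminant (Gaussian classes, pooled
covariance, empirical priors) separates the states.  Evaluation follows a
stratified 60/40 train/test split with 10-fold cross-validation on the
training portion, repeated over 30 independent random divisions; the mean
test accuracy over repetitions is the headline number, compared against
the 1/3 chance level of a balanced three-state problem by an exact
binomial test.

Both the SVD projection and its centring are fitted on training epochs
only and applied frozen to held-out data, so no test information leaks
into the feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError
from .io_preprocess import Recording

__all__ = [
    "EpochMatrix",
    "SvdProjection",
    "LdaModel",
    "DiscriminationResult",
    "build_epochs",
    "concat_epochs",
    "svd_project",
    "lda_fit",
    "lda_predict",
    "evaluate",
    "select_epoch_length",
    "significance_vs_chance",
    "channel_correlation",
]


@dataclass
class EpochMatrix:
    """Classifier input: one row per fixed-length envelope window."""

    X: np.ndarray  # (n_epochs, n_features)
    labels: np.ndarray  # (n_epochs,) state label per epoch
    epoch_len_s: float
    channel: str = "ch1"

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.X.shape[0] != self.labels.shape[0]:
            raise InvalidParameterError("one label per epoch required")
        if not np.isfinite(self.X).all():
            raise InvalidParameterError("epoch matrix contains non-finite values")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class SvdProjection:
    """Centering vector + top-k right singular directions, reusable on
    held-out data."""

    mean: np.ndarray  # (n_features,)
    components: np.ndarray  # (k, n_features)
    singular_values: np.ndarray  # (k,)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.components.T


@dataclass
class LdaModel:
    """Gaussian equal-covariance discriminant in the reduced space."""

    classes: np.ndarray
    class_means: np.ndarray  # (n_classes, k)
    pooled_covariance: np.ndarray  # (k, k)
    priors: np.ndarray  # (n_classes,)
    _coef: np.ndarray = field(init=False)
    _intercept: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        inv = np.linalg.inv(self.pooled_covariance)
        # linear discriminant: mu' S^-1 x - mu' S^-1 mu / 2 + log prior
        self._coef = self.class_means @ inv
        self._intercept = (
            -0.5 * np.einsum("ij,ij->i", self._coef, self.class_means)
            + np.log(self.priors)
        )


@dataclass
class DiscriminationResult:
    """Outcome of the repeated split protocol."""

    per_repetition_accuracy: np.ndarray  # (n_repetitions,)
    mean_accuracy: float
    confusion: np.ndarray  # class x class counts summed over test sets
    cv_accuracy: float  # mean 10-fold CV accuracy on the training sets
    classes: np.ndarray
    n_test_total: int
    n_correct_total: int
    p_vs_chance: float | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

def build_epochs(
    env: np.ndarray, fs: float, epoch_len_s: float, label: str, channel: str = "ch1"
) -> EpochMatrix:
    """Cut an envelope series into consecutive non-overlapping windows.

    The trailing partial window is dropped; each row holds one window's
    envelope samples.
    """
    env = np.asarray(env, dtype=float).ravel()
    n_per = int(round(epoch_len_s * fs))
    if n_per < 2:
        raise InvalidParameterError("epoch must span at least 2 samples")
    if env.size < n_per:
        raise InsufficientDataError(
            f"envelope of {env.size} samples shorter than one epoch ({n_per})"
        )
    n_epochs = env.size // n_per
    X = env[: n_epochs * n_per].reshape(n_epochs, n_per)
    return EpochMatrix(X, np.array([label] * n_epochs), epoch_len_s, channel)


def concat_epochs(parts: list[EpochMatrix]) -> EpochMatrix:
    """Stack per-state epoch matrices with a common epoch length."""
    if not parts:
        raise InvalidParameterError("no epoch matrices given")
    if len({p.epoch_len_s for p in parts}) != 1:
        raise InvalidParameterError("epoch lengths differ")
    if len({p.X.shape[1] for p in parts}) != 1:
        raise InvalidParameterError("feature counts differ")
    return EpochMatrix(
        np.vstack([p.X for p in parts]),
        np.concatenate([p.labels for p in parts]),
        parts[0].epoch_len_s,
        parts[0].channel,
    )


def combine_channels(parts: list[EpochMatrix]) -> EpochMatrix:
    """Concatenate features of channel-matched epochs (multi-channel model)."""
    if not parts:
        raise InvalidParameterError("no epoch matrices given")
    n = {p.X.shape[0] for p in parts}
    if len(n) != 1:
        raise InvalidParameterError("epoch counts differ across channels")
    for p in parts[1:]:
        if not np.array_equal(p.labels, parts[0].labels):
            raise InvalidParameterError("labels differ across channels")
    return EpochMatrix(
        np.hstack([p.X for p in parts]),
        parts[0].labels.copy(),
        parts[0].epoch_len_s,
        "+".join(p.channel for p in parts),
    )


# ---------------------------------------------------------------------------
# SVD feature reduction
# ---------------------------------------------------------------------------

def svd_project(X: np.ndarray, k: int = 2) -> tuple[np.ndarray, SvdProjection]:
    """Project column-centred epochs onto their top-k right singular
    directions.

    Returns ``(scores, projection)`` where ``scores`` is the epoch x k
    matrix and ``projection`` stores the centring mean and components for
    reuse on held-out data.  Component signs are fixed (largest-magnitude
    loading positive) for determinism.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if k > min(X.shape):
        raise InvalidParameterError(
            f"k={k} exceeds min(n_epochs, n_features)={min(X.shape)}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    comp = Vt[:k]
    sign = np.sign(comp[np.arange(k), np.argmax(np.abs(comp), axis=1)])
    sign[sign == 0] = 1.0
    comp = comp * sign[:, None]
    proj = SvdProjection(mean=mean, components=comp, singular_values=s[:k].copy())
    return proj.transform(X), proj


# ---------------------------------------------------------------------------
# Linear discriminant analysis
# ---------------------------------------------------------------------------

def lda_fit(scores: np.ndarray, labels: np.ndarray) -> LdaModel:
    """Fit the pooled-covariance Gaussian discriminant.

    A singular pooled covariance is regularised with a fixed ridge of
    1e-6 x mean diagonal.  Each class needs at least 2 epochs.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise InvalidParameterError("need >= 2 classes")
    if np.any(counts < 2):
        small = classes[counts < 2]
        raise InsufficientDataError(f"class {small[0]!r} has fewer than 2 epochs")
    k = scores.shape[1]
    means = np.vstack([scores[labels == c].mean(axis=0) for c in classes])
    pooled = np.zeros((k, k))
    for c, m in zip(classes, means):
        d = scores[labels == c] - m
        pooled += d.T @ d
    pooled /= scores.shape[0] - classes.size
    # regularize if singular / ill-conditioned
    try:
        cond_bad = np.linalg.cond(pooled) > 1e12
    except np.linalg.LinAlgError:  # pragma: no cover
        cond_bad = True
    if cond_bad or np.linalg.det(pooled) <= 0:
        ridge = 1e-6 * max(np.mean(np.diag(pooled)), np.finfo(float).tiny)
        pooled = pooled + ridge * np.eye(k)
        if np.linalg.det(pooled) <= 0:
            pooled = pooled + np.eye(k)  # degenerate all-zero case
    priors = counts / counts.sum()
    return LdaModel(classes, means, pooled, priors)


def lda_predict(model: LdaModel, scores: np.ndarray) -> np.ndarray:
    """Classify by largest linear discriminant score; ties break toward the
    lower class index (argmax order), for determinism."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    g = scores @ model._coef.T + model._intercept
    return model.classes[np.argmax(g, axis=1)]


# ---------------------------------------------------------------------------
# Evaluation protocol
# ---------------------------------------------------------------------------

def _stratified_split(
    labels: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _stratified_folds(
    labels: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    assignment = np.empty(labels.size, dtype=int)
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        assignment[idx] = np.arange(idx.size) % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def _fit_and_score(
    X_train: np.ndarray, y_train: np.ndarray,
    X_test: np.ndarray, y_test: np.ndarray, k: int,
) -> tuple[float, np.ndarray]:
    scores_train, proj = svd_project(X_train, k=k)
    model = lda_fit(scores_train, y_train)
    pred = lda_predict(model, proj.transform(X_test))
    acc = float(np.mean(pred == y_test))
    return acc, pred


def evaluate(
    epochs: EpochMatrix,
    split: float = 0.6,
    folds: int = 10,
    repetitions: int = 30,
    seed: int = 0,
    k: int = 2,
    chance: float | None = None,
) -> DiscriminationResult:
    """Run the repeated stratified split protocol.

    Per repetition: a stratified random ``split``/(1-``split``) division;
    ``folds``-fold cross-validated accuracy on the training portion (SVD and
    LDA refit within each fold); a final model refit on the full training
    set and scored on the held-out test set.  The mean test accuracy over
    ``repetitions`` divisions is reported, along with the summed confusion
    matrix and an exact binomial p-value against ``chance`` (default
    1/n_classes).
    """
    if not 0 < split < 1:
        raise InvalidParameterError("split must lie in (0, 1)")
    classes = epochs.classes
    if classes.size < 2:
        raise InvalidParameterError("need >= 2 classes to discriminate")
    for c in classes:
        n_c = int(np.sum(epochs.labels == c))
        if int(round(split * n_c)) < folds:
            raise InsufficientDataError(
                f"class {c!r}: {n_c} epochs leave fewer than {folds} "
                "training epochs for stratified folds"
            )
    chance = chance if chance is not None else 1.0 / classes.size
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5DA]))
    class_index = {c: i for i, c in enumerate(classes)}

    rep_acc = np.empty(repetitions)
    cv_accs = []
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    n_correct_total = 0
    n_test_total = 0
    for r in range(repetitions):
        train_idx, test_idx = _stratified_split(epochs.labels, split, rng)
        X_tr, y_tr = epochs.X[train_idx], epochs.labels[train_idx]
        X_te, y_te = epochs.X[test_idx], epochs.labels[test_idx]
        # 10-fold CV on the training set (model-quality estimate)
        fold_idx = _stratified_folds(y_tr, folds, rng)
        for f in range(folds):
            val = fold_idx[f]
            trn = np.concatenate([fold_idx[g] for g in range(folds) if g != f])
            acc, _ = _fit_and_score(X_tr[trn], y_tr[trn], X_tr[val], y_tr[val], k)
            cv_accs.append(acc)
        # final model on the full training set, scored on held-out data
        acc, pred = _fit_and_score(X_tr, y_tr, X_te, y_te, k)
        rep_acc[r] = acc
        n_test_total += y_te.size
        n_correct_total += int(round(acc * y_te.size))
        for yt, yp in zip(y_te, pred):
            confusion[class_index[yt], class_index[yp]] += 1

    result = DiscriminationResult(
        per_repetition_accuracy=rep_acc,
        mean_accuracy=float(rep_acc.mean()),
        confusion=confusion,
        cv_accuracy=float(np.mean(cv_accs)),
        classes=classes,
        n_test_total=n_test_total,
        n_correct_total=n_correct_total,
        seed=seed,
    )
    result.p_vs_chance = significance_vs_chance(result, chance=chance)
    return result


def select_epoch_length(
    envs_by_label: dict[str, np.ndarray],
    fs: float,
    candidates: tuple[float, ...] = (0.5, 1.0, 2.0),
    split: float = 0.6,
    folds: int = 10,
    seed: int = 0,
    k: int = 2,
) -> tuple[float, dict[float, float]]:
    """Pick the epoch length with the best training-set CV accuracy.

    For each candidate length the envelopes are epoched, a stratified
    train split is drawn, and the ``folds``-fold CV accuracy on the
    training portion is computed; the candidate with the highest CV
    accuracy wins (ties to the shorter epoch).  Returns
    ``(best_length, {length: cv_accuracy})``.
    """
    cv_by_len: dict[float, float] = {}
    for epoch_len in candidates:
        parts = [
            build_epochs(env, fs, epoch_len, label)
            for label, env in envs_by_label.items()
        ]
        epochs = concat_epochs(parts)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E1]))
        train_idx, _ = _stratified_split(epochs.labels, split, rng)
        X_tr, y_tr = epochs.X[train_idx], epochs.labels[train_idx]
        fold_idx = _stratified_folds(y_tr, folds, rng)
        accs = []
        for f in range(folds):
            val = fold_idx[f]
            trn = np.concatenate([fold_idx[g] for g in range(folds) if g != f])
            acc, _ = _fit_and_score(X_tr[trn], y_tr[trn], X_tr[val], y_tr[val], k)
            accs.append(acc)
        cv_by_len[epoch_len] = float(np.mean(accs))
    best = max(sorted(cv_by_len), key=lambda L: (cv_by_len[L], -L))
    return best, cv_by_len


def significance_vs_chance(
    result: DiscriminationResult,
    chance: float = 1.0 / 3.0,
    n_channels_tested: int = 1,
) -> float:
    """Exact binomial upper-tail probability of the pooled test-set
    correct count under the chance success rate, with a Bonferroni factor
    when several channels are evaluated together."""
    if not 0 < chance < 1:
        raise InvalidParameterError("chance must lie in (0, 1)")
    if result.n_test_total < 1:
        raise InsufficientDataError("no test classifications")
    # P(X >= observed) = sf(observed - 1)
    p = float(stats.binom.sf(result.n_correct_total - 1, result.n_test_total, chance))
    return float(min(1.0, p * n_channels_tested))


def channel_correlation(rec: Recording) -> np.ndarray:
    """Pearson correlation matrix across channels; zero-variance channels
    yield NaN rows/columns (flagged, not raised)."""
    if rec.n_channels < 2:
        raise InvalidParameterError("need >= 2 channels")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(rec.samples)
    np.fill_diagonal(r, 1.0)
    sd = rec.samples.std(axis=1)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    return r
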