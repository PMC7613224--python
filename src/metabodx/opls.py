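"""Orthogonal PLS discriminant analysis (single response) via NIPALS.

The discriminant core of the pipeline, written from scratch.  For a binary
response y in {-1, +1} and a column-scaled matrix X, the single-response
orthogonal projection is deterministic (no iteration loop is needed):

1. predictive weight  w = X'y / ||X'y||   (from the undeflated X);
2. for each orthogonal component, on the current X:
       t = Xw;  p = X't/(t't);  w_o = p - (w'p)w, normalised;
       t_o = Xw_o;  p_o = X't_o/(t_o't_o);  X <- X - t_o p_o';
3. predictive score t = Xw on the deflated X, with regression coefficient
   b = y't/(t't).

Because the orthogonal components are nested, one pass to ``max_ortho``
yields every candidate model along the way; the internal 7-fold Q²
selection exploits this.

The discriminant score reported for a sample is s = b * t.  Since t is
centred on the training data, b is unchanged whether y is centred or not,
and a row at the training mean scores exactly 0.  Cross-validated Q² is
computed on predictions yhat = ybar_train + s so that the mean predictor
scores Q² = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, NoSignalError, ValidationError

_EPS = 1e-12
MAX_ORTHO = 9


def encode_labels(y) -> tuple[np.ndarray, dict]:
    """Coerce class labels to the symmetric {-1, +1} coding.

    Accepts {-1, +1} (kept), {0, 1} (0 -> -1), or any two distinct values
    (sorted; the larger becomes +1).  Returns the coded vector and the
    encoding map.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(
            f"y must contain exactly two classes, found {classes.size}"
        )
    lo, hi = classes
    coded = np.where(y == hi, 1.0, -1.0)
    return coded, {float(lo) if np.isreal(lo) else lo: -1, float(hi) if np.isreal(hi) else hi: 1}


@dataclass
class OplsModel:
    """Fitted OPLS-DA parameters for one predictive component."""

    w: np.ndarray                 # unit predictive weight over buckets
    p: np.ndarray                 # predictive loading (on the deflated X)
    t: np.ndarray                 # training predictive scores
    b: float                      # regression coefficient of y on t
    W_o: np.ndarray               # (n_ortho, J) orthogonal weights
    P_o: np.ndarray               # (n_ortho, J) orthogonal loadings
    T_o: np.ndarray               # (n_ortho, n) orthogonal scores
    n_ortho: int
    y_mean: float                 # training mean of the +/-1 coded response
    r2y: float
    class_encoding: dict = field(default_factory=dict)
    q2: float | None = None

    @property
    def n_features(self) -> int:
        return self.w.size

    @property
    def fitted_scores(self) -> np.ndarray:
        """Training discriminant scores s = b * t."""
        return self.b * self.t


def _normalize(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _EPS:
        raise NoSignalError(f"{what} norm below {_EPS:g} (no signal)")
    return v / n


def _fit_stages(X: np.ndarray, y: np.ndarray, max_ortho: int):
    """One NIPALS pass recording every nested candidate model.

    Returns (w, W_o, P_o, T_o, t_by_stage, b_by_stage, y_mean) where stage c
    uses the first c orthogonal components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D")
    if y.ndim != 1 or y.size != X.shape[0]:
        raise ValidationError("y length must match rows of X")
    if np.ptp(y) == 0:
        raise ValidationError("y has zero variance")
    if not (0 <= max_ortho <= MAX_ORTHO):
        raise ValidationError(f"orthogonal component count must be in 0..{MAX_ORTHO}")

    w = _normalize(X.T @ y, "predictive weight")
    y_mean = float(y.mean())

    W_o, P_o, T_o, t_stage, b_stage = [], [], [], [], []

    def record(Xc):
        t = Xc @ w
        tt = float(t @ t)
        if tt < _EPS:
            raise NoSignalError("predictive score collapsed to zero")
        t_stage.append(t)
        b_stage.append(float(y @ t) / tt)

    Xc = X
    record(Xc)
    for _ in range(max_ortho):
        t = t_stage[-1]
        tt = float(t @ t)
        pvec = Xc.T @ t / tt
        w_o = pvec - float(w @ pvec) * w
        norm = np.linalg.norm(w_o)
        if norm < _EPS:
            # no orthogonal variation left; remaining candidates repeat
            w_o = np.zeros_like(w)
            t_o = np.zeros(X.shape[0])
            p_o = np.zeros_like(w)
        else:
            w_o = w_o / norm
            t_o = Xc @ w_o
            too = float(t_o @ t_o)
            if too < _EPS:
                t_o = np.zeros(X.shape[0])
                p_o = np.zeros_like(w)
            else:
                p_o = Xc.T @ t_o / too
                Xc = Xc - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
        record(Xc)

    J = X.shape[1]
    return (w,
            np.array(W_o).reshape(max_ortho, J) if max_ortho else np.zeros((0, J)),
            np.array(P_o).reshape(max_ortho, J) if max_ortho else np.zeros((0, J)),
            np.array(T_o).reshape(max_ortho, X.shape[0]) if max_ortho else np.zeros((0, X.shape[0])),
            t_stage, b_stage, y_mean, Xc)


def fit_opls(X: np.ndarray, y, n_ortho: int = 0) -> OplsModel:
    """Fit a single-response OPLS-DA model with ``n_ortho`` orthogonal
    components removed before the predictive fit.

    ``X`` must already be column-scaled (Pareto in this pipeline); ``y`` may
    be coded {-1,+1} or {0,1}.
    """
    coded, encoding = encode_labels(y)
    w, W_o, P_o, T_o, t_stage, b_stage, y_mean, X_def = _fit_stages(X, coded, n_ortho)
    t, b = t_stage[n_ortho], b_stage[n_ortho]
    resid = (coded - y_mean) - b * t
    ss = float(((coded - y_mean) ** 2).sum())
    r2y = 1.0 - float((resid ** 2).sum()) / ss if ss > 0 else 0.0
    return OplsModel(w=w, p=(X_def.T @ t) / float(t @ t),
                     t=t, b=b, W_o=W_o, P_o=P_o, T_o=T_o, n_ortho=n_ortho,
                     y_mean=y_mean, r2y=r2y, class_encoding=encoding)


def predict_scores(model: OplsModel, X_new: np.ndarray) -> np.ndarray:
    """Discriminant scores for new samples scaled with the training
    ScalingModel: deflate through the training orthogonal components in
    order, then s = (Xw) * b."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_features:
        raise ValidationError(
            f"feature count mismatch: model has {model.n_features}, X has {X_new.shape[1]}"
        )
    Xc = X_new
    for w_o, p_o in zip(model.W_o, model.P_o):
        t_o = Xc @ w_o
        Xc = Xc - np.outer(t_o, p_o)
    return (Xc @ model.w) * model.b


def _predict_stage_scores(w, W_o, P_o, b_stage, X_new):
    """Scores for every nested candidate (columns = 0..max_ortho)."""
    Xc = np.asarray(X_new, dtype=float)
    out = np.empty((Xc.shape[0], len(b_stage)))
    out[:, 0] = (Xc @ w) * b_stage[0]
    for c, (w_o, p_o) in enumerate(zip(W_o, P_o), start=1):
        t_o = Xc @ w_o
        Xc = Xc - np.outer(t_o, p_o)
        out[:, c] = (Xc @ w) * b_stage[c]
    return out


# ---------------------------------------------------------------------------
# internal cross-validation


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator,
                      require_both_in_train: bool = True,
                      max_attempts: int = 100):
    """Stratified k-fold assignment by per-class round robin.

    Redraws (up to ``max_attempts``) if any training fold would lose a
    class; raises :class:`DataError` when that cannot be satisfied.
    """
    y = np.asarray(y)
    n = y.size
    if n < k:
        raise ValidationError(f"need at least k={k} samples, have {n}")
    classes = np.unique(y)
    for _ in range(max_attempts):
        assign = np.empty(n, dtype=int)
        offset = 0
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            assign[idx] = (np.arange(idx.size) + offset) % k
            offset += idx.size  # stagger so small classes spread over folds
        folds = [np.flatnonzero(assign == f) for f in range(k)]
        if not require_both_in_train:
            return folds
        ok = True
        for f in range(k):
            train_mask = assign != f
            if np.unique(y[train_mask]).size < classes.size:
                ok = False
                break
        if ok:
            return folds
    raise DataError(
        f"could not build {k} stratified folds keeping every class in "
        f"every training set after {max_attempts} attempts"
    )


def q2_from_predictions(y, y_hat, y_bar=None) -> float:
    """Q2 = 1 - PRESS/SS with SS taken around the full-sample mean."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_bar is None:
        y_bar = y.mean()
    ss = float(((y - y_bar) ** 2).sum())
    if ss <= 0:
        raise ValidationError("y has zero variance")
    return 1.0 - float(((y - y_hat) ** 2).sum()) / ss


def _cv_stage_q2(X, y, max_ortho, k, seed):
    """Q2 for every candidate 0..max_ortho under one shared fold draw."""
    X = np.asarray(X, dtype=float)
    coded, _ = encode_labels(y)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    folds = _stratified_folds(coded, k, rng)
    y_hat = np.empty((coded.size, max_ortho + 1))
    for test_idx in folds:
        train_mask = np.ones(coded.size, dtype=bool)
        train_mask[test_idx] = False
        w, W_o, P_o, _, _, b_stage, y_mean, _ = _fit_stages(
            X[train_mask], coded[train_mask], max_ortho
        )
        y_hat[test_idx] = y_mean + _predict_stage_scores(
            w, W_o, P_o, b_stage, X[test_idx]
        )
    ss = float(((coded - coded.mean()) ** 2).sum())
    press = ((coded[:, None] - y_hat) ** 2).sum(axis=0)
    return 1.0 - press / ss


def q2_internal_cv(X, y, n_ortho: int, k: int = 7, seed: int = 0) -> float:
    """Stratified k-fold cross-validated Q2 for a fixed component count."""
    return float(_cv_stage_q2(X, y, n_ortho, k, seed)[n_ortho])


def select_n_orthogonal(X, y, max_ortho: int = MAX_ORTHO, k: int = 7,
                        seed: int = 0) -> tuple[int, np.ndarray]:
    """Pick the orthogonal-component count with the best internal-CV Q2.

    Candidates 0..max_ortho are evaluated on one shared stratified fold
    draw; ties break toward fewer components.  Returns (n_ortho, q2 per
    candidate).
    """
    q2s = _cv_stage_q2(X, y, max_ortho, k, seed)
    best = int(np.argmax(q2s))  # argmax returns the first (fewest) on ties
    return best, q2s


# ---------------------------------------------------------------------------
# VIP


@dataclass
class VipScores:
    """Variable importance of projection over the predictive component."""

    scores: np.ndarray
    threshold: float = 2.0

    @property
    def significant(self) -> np.ndarray:
        """Indices of buckets with VIP above the threshold."""
        return np.flatnonzero(self.scores > self.threshold)


def vip(model: OplsModel, threshold: float = 2.0) -> VipScores:
    """VIP_j = sqrt(J) * |w_j| for the single-predictive-component model.

    The orthogonal components carry no y-related variation by construction,
    so the VIP is computed on the predictive component alone; the mean
    squared VIP is exactly 1.
    """
    if model.w is None:
        raise ValidationError("model is not fitted")
    J = model.n_features
    return VipScores(scores=np.sqrt(J) * np.abs(model.w), threshold=threshold)
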