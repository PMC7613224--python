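"""External validation machinery: repeated stratified 10-fold CV,
permutation nulls, and Kolmogorov-Smirnov comparison of metric
distributions.

Everything that can leak information — Pareto scaling and the internal
Q2-based choice of orthogonal components — is refit inside every training
fold, so the classifier is genuinely blinded to each held-out fold.  The
default scheme of 100 repeats x 10 folds trains 1,000 models; both counts
are configuration knobs and the desk-scale runs in this repository use far
fewer (sizes are recorded in the scheme echo of every result).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError, NoSignalError, ValidationError
from .opls import (_stratified_folds, encode_labels, fit_opls, predict_scores,
                   select_n_orthogonal)


@dataclass
class CvDistribution:
    """Per-model held-out metrics from repeated external cross-validation.

    One entry per train/test split (length k x repeats); folds whose
    held-out portion lacks a class carry NaN for the undefined metric.
    """

    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray
    scheme: dict = field(default_factory=dict)
    oof_scores: np.ndarray | None = None      # (repeats, n) out-of-fold scores
    labels: np.ndarray | None = None          # 0/1 labels aligned to columns
    fold_assignments: np.ndarray | None = None  # (repeats, n) fold index
    fold_info: list | None = None             # per-fold training provenance

    @property
    def balanced_accuracy(self) -> np.ndarray:
        return 0.5 * (self.sensitivity + self.specificity)

    @property
    def mean_oof_scores(self) -> np.ndarray:
        """Per-sample discriminant score averaged over repeats."""
        if self.oof_scores is None:
            raise ValidationError("out-of-fold scores were not collected")
        return self.oof_scores.mean(axis=0)

    def concat(self, other: "CvDistribution") -> "CvDistribution":
        return CvDistribution(
            sensitivity=np.concatenate([self.sensitivity, other.sensitivity]),
            specificity=np.concatenate([self.specificity, other.specificity]),
            accuracy=np.concatenate([self.accuracy, other.accuracy]),
            scheme={"pooled": [self.scheme, other.scheme]},
        )


@dataclass
class KsResult:
    """Two-sample Kolmogorov-Smirnov comparison of two metric vectors."""

    d: float
    p_value: float
    sidedness: str = "two-sided"


def _pareto_fit_apply(X_train, X_test):
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=1)
    degen = sd <= 0
    scale = np.where(degen, 1.0, np.sqrt(np.where(degen, 1.0, sd)))
    A = (X_train - mean) / scale
    B = (X_test - mean) / scale
    A[:, degen] = 0.0
    B[:, degen] = 0.0
    return A, B


def _fold_metrics(y_true01, pred01):
    pos = y_true01 == 1
    neg = ~pos
    tp = int(np.sum(pred01[pos]))
    tn = int(np.sum(1 - pred01[neg]))
    sens = tp / pos.sum() if pos.sum() else np.nan
    spec = tn / neg.sum() if neg.sum() else np.nan
    acc = (tp + tn) / y_true01.size
    return sens, spec, acc


def external_cv(X, y, k: int = 10, repeats: int = 100, seed: int = 0,
                max_ortho: int = 9, internal_k: int = 7,
                repeat_indices=None, collect_fold_info: bool = False
                ) -> CvDistribution:
    """Repeated stratified k-fold external cross-validation.

    ``X`` is the *unscaled* bucket matrix: Pareto scaling and the internal
    7-fold selection of orthogonal components are refit on each training
    portion only.  Held-out samples are classified at discriminant score
    >= 0 and per-fold sensitivity/specificity/accuracy recorded.

    Repeat ``r`` draws its randomness from ``(seed, r)`` alone, so any
    single repeat is reproducible in isolation via ``repeat_indices=[r]``.
    If the smaller class has fewer members than ``k`` the stratification is
    relaxed (with a warning): some held-out folds will lack that class and
    carry NaN metrics.
    """
    X = np.asarray(X, dtype=float)
    coded, _ = encode_labels(y)
    y01 = (coded > 0).astype(int)
    n = y01.size
    counts = np.bincount(y01, minlength=2)
    if counts.min() < k:
        warnings.warn(
            f"smaller class has {counts.min()} members for k={k}: "
            "stratification relaxed; some held-out folds will lack it",
            stacklevel=2,
        )
    if repeat_indices is None:
        repeat_indices = range(repeats)
    repeat_indices = list(repeat_indices)
    sens_all, spec_all, acc_all = [], [], []
    oof = np.full((len(repeat_indices), n), np.nan)
    assign = np.full((len(repeat_indices), n), -1, dtype=int)
    info = [] if collect_fold_info else None
    no_signal_folds = 0

    for row, r in enumerate(repeat_indices):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(int(r),)))
        folds = _stratified_folds(y01, k, rng, require_both_in_train=False)
        for f, test_idx in enumerate(folds):
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            if np.unique(y01[train_mask]).size < 2:
                raise DataError(
                    f"class absent from the training portion of fold {f} (repeat {r})"
                )
            fold_seed = int(rng.integers(2 ** 31))
            Xtr, Xte = _pareto_fit_apply(X[train_mask], X[test_idx])
            ytr = y01[train_mask]
            try:
                n_ortho, _ = select_n_orthogonal(Xtr, ytr, max_ortho, internal_k,
                                                 seed=fold_seed)
                model = fit_opls(Xtr, ytr, n_ortho)
                scores = predict_scores(model, Xte)
                w_digest = hashlib.sha1(
                    model.w.tobytes() + np.float64(model.b).tobytes()
                ).hexdigest()
            except NoSignalError:
                scores = np.zeros(test_idx.size)
                w_digest = "no-signal"
                no_signal_folds += 1
            pred = (scores >= 0.0).astype(int)
            s, sp, a = _fold_metrics(y01[test_idx], pred)
            sens_all.append(s)
            spec_all.append(sp)
            acc_all.append(a)
            oof[row, test_idx] = scores
            assign[row, test_idx] = f
            if collect_fold_info:
                info.append({
                    "repeat": int(r), "fold": f,
                    "train_idx_digest": hashlib.sha1(
                        np.flatnonzero(train_mask).tobytes()).hexdigest(),
                    "model_digest": w_digest,
                })

    return CvDistribution(
        sensitivity=np.asarray(sens_all, dtype=float),
        specificity=np.asarray(spec_all, dtype=float),
        accuracy=np.asarray(acc_all, dtype=float),
        scheme={"k": k, "repeats": repeat_indices, "seed": seed,
                "max_ortho": max_ortho, "internal_k": internal_k,
                "no_signal_folds": no_signal_folds},
        oof_scores=oof,
        labels=y01,
        fold_assignments=assign,
        fold_info=info,
    )


def permutation_null(X, y, n_perm: int = 100, k: int = 10,
                     repeats_per_perm: int = 1, seed: int = 0) -> CvDistribution:
    """Null metric distribution from label-permuted reruns of external CV.

    Each permutation shuffles the labels once (seeded from ``(seed, perm)``)
    and contributes ``repeats_per_perm`` x k held-out models to the pool.
    """
    if n_perm < 20:
        raise ValidationError("n_perm must be >= 20 for a usable null")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    sens, spec, acc = [], [], []
    perm_log = []
    for p in range(n_perm):
        prng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(1_000_000 + p,))
        )
        y_perm = prng.permutation(y)
        sub_seed = int(prng.integers(2 ** 31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = external_cv(X, y_perm, k=k, repeats=repeats_per_perm,
                             seed=sub_seed)
        sens.append(cv.sensitivity)
        spec.append(cv.specificity)
        acc.append(cv.accuracy)
        perm_log.append({"perm": p, "sub_seed": sub_seed})
    return CvDistribution(
        sensitivity=np.concatenate(sens),
        specificity=np.concatenate(spec),
        accuracy=np.concatenate(acc),
        scheme={"n_perm": n_perm, "k": k, "repeats_per_perm": repeats_per_perm,
                "seed": seed, "permutations": perm_log},
    )


def ks_compare(real, null) -> KsResult:
    """Two-sided two-sample KS test between a real and a null metric vector.

    NaN entries (undefined fold metrics) are dropped first.  The exact
    two-sample distribution is used when both vectors have at most 10
    entries, the asymptotic Kolmogorov distribution otherwise.
    """
    real = np.asarray(real, dtype=float)
    null = np.asarray(null, dtype=float)
    real = real[np.isfinite(real)]
    null = null[np.isfinite(null)]
    if real.size < 2 or null.size < 2:
        raise ValidationError("both metric vectors need at least 2 finite entries")
    method = "exact" if (real.size <= 10 and null.size <= 10) else "asymp"
    res = stats.ks_2samp(real, null, alternative="two-sided", method=method)
    return KsResult(d=float(res.statistic), p_value=float(min(res.pvalue, 1.0)))
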