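"""Sequon-level glycosite classifier: feature assembly and SVM training.

The feature vector of a sequon window concatenates, in fixed order:

* 23 normalized gapped-dipeptide ratios (values in [0, 1]),
* a one-hot block per surface-accessibility region vocabulary,
* a one-hot block per secondary-structure region vocabulary

(156 dimensions with the reference vocabularies: 23 + 79 + 54).  The
classifier is an RBF-kernel support-vector machine tuned by k-fold
cross-validated grid search over C in {2^-5, 2^-3, ..., 2^15} and gamma in
{2^-15, 2^-13, ..., 2^3} (110 cells) on accuracy.  The decision threshold on
the probability score is chosen from [0.25, 0.75] by maximizing MCC on each
training fold, and the fold model with the highest test-fold MCC is kept for
prediction.

Featurizers (the GDR table and the pattern vocabularies) are fitted inside
each training fold only — they sit in front of the SVM in a Pipeline, so the
grid search refits them per fold and test-fold windows never contribute
counts.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedGroupKFold,
    StratifiedKFold,
)
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from . import patterns as pt
from .dipeptides import GappedDipeptideEncoder, gd_slots
from .evaluate import confusion, metrics
from .io import AnnotatedWindow, SequonWindow

C_GRID = tuple(2.0 ** k for k in range(-5, 17, 2))  # 11 values
GAMMA_GRID = tuple(2.0 ** k for k in range(-15, 5, 2))  # 10 values
THRESHOLD_GRID = tuple(np.round(np.arange(0.25, 0.7501, 0.01), 2))


@contextmanager
def _svc_probability_warnings():
    # Platt-style probability estimation mirrors libsvm's "-b 1"; newer
    # scikit-learn releases deprecate the flag in favour of an external
    # calibration wrapper, which would change the fitted object's layout.
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="The `probability` parameter", category=FutureWarning
        )
        yield


def _as_annotated(x) -> AnnotatedWindow:
    if isinstance(x, AnnotatedWindow):
        return x
    if isinstance(x, SequonWindow):
        return AnnotatedWindow(window=x)
    raise TypeError(f"expected AnnotatedWindow or SequonWindow, got {type(x)!r}")


class GlycositeFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer: annotated sequon windows -> numeric feature matrix.

    Fits the gapped-dipeptide-ratio table and, when enabled, the six pattern
    vocabularies (SA and SS, each over N-terminal / sequon / C-terminal
    regions, terminal pattern lengths selected by maximum APD_w).

    Parameters
    ----------
    l : window length, default 25.
    use_sa, use_ss : include the surface-accessibility / secondary-structure
        pattern blocks (requires the corresponding strings on every window).
    rare_threshold : pattern frequency floor as a fraction of training
        windows, default 0.01.
    pseudocount : GDR count smoothing, default 0.
    """

    def __init__(
        self,
        l: int = 25,
        use_gd: bool = True,
        use_sa: bool = True,
        use_ss: bool = True,
        rare_threshold: float = 0.01,
        pseudocount: float = 0.0,
    ):
        self.l = l
        self.use_gd = use_gd
        self.use_sa = use_sa
        self.use_ss = use_ss
        self.rare_threshold = rare_threshold
        self.pseudocount = pseudocount

    def fit(self, X: Sequence, y: Sequence[int]):
        anns = [_as_annotated(x) for x in X]
        y = np.asarray(y).astype(int)
        if not (self.use_gd or self.use_sa or self.use_ss):
            raise ValueError("at least one feature family must be enabled")
        if self.use_gd:
            self.gd_encoder_ = GappedDipeptideEncoder(
                l=self.l, pseudocount=self.pseudocount
            ).fit([a.window for a in anns], y)
        self.vocabs_ = {}
        self.w_star_ = {}
        for feature_type, enabled, attr in (
            (pt.SA, self.use_sa, "sa"),
            (pt.SS, self.use_ss, "ss"),
        ):
            if not enabled:
                continue
            strings = [getattr(a, attr) for a in anns]
            if any(s is None for s in strings):
                raise ValueError(
                    f"{feature_type} strings missing but use_{attr}=True"
                )
            for region in pt.REGIONS:
                w_star, vocab = pt.select_window_length(
                    strings, y, feature_type, region,
                    rare_threshold=self.rare_threshold, l=self.l,
                )
                self.vocabs_[(feature_type, region)] = vocab
                self.w_star_[(feature_type, region)] = w_star
        self.n_features_out_ = (
            (len(gd_slots(self.l)) if self.use_gd else 0)
            + sum(v.block_length for v in self.vocabs_.values())
        )
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        if not hasattr(self, "n_features_out_"):
            raise RuntimeError("GlycositeFeaturizer is not fitted")
        rows = []
        for x in X:
            a = _as_annotated(x)
            parts = []
            if self.use_gd:
                parts.append(self.gd_encoder_.table_.encode(a.window))
            if self.vocabs_:
                parts.append(
                    pt.encode_patterns(
                        a.sa if self.use_sa else None,
                        a.ss if self.use_ss else None,
                        self.vocabs_,
                        l=self.l,
                    )
                )
            rows.append(np.concatenate(parts))
        return np.vstack(rows)


def assemble_features(
    X: Sequence, featurizer: GlycositeFeaturizer
) -> np.ndarray:
    """Thin wrapper: encode windows with a fitted featurizer."""
    return featurizer.transform(X)


@dataclass
class FoldResult:
    fold: int
    threshold: float
    train_mcc: float
    test_mcc: float


class SequonClassifier(BaseEstimator, ClassifierMixin):
    """Second-stage glycosite classifier (featurizer + RBF SVM).

    ``fit(X, y, groups=...)`` runs the grid-search / threshold-selection
    protocol described in the module docstring.  Cross-validation folds are
    grouped by protein id by default (``fold_mode="protein"``) so sequons of
    one protein never straddle a train/test split; ``fold_mode="sequon"``
    restores plain stratified folds.

    Fitted attributes: ``C_``, ``gamma_`` (grid winners), ``threshold_`` (the
    kept fold's MCC-optimal score threshold), ``model_`` (the kept fold's
    fitted featurizer+SVM pipeline), ``fold_results_``, ``cv_results_``.
    """

    def __init__(
        self,
        l: int = 25,
        use_gd: bool = True,
        use_sa: bool = True,
        use_ss: bool = True,
        rare_threshold: float = 0.01,
        pseudocount: float = 0.0,
        C_grid: Sequence[float] = C_GRID,
        gamma_grid: Sequence[float] = GAMMA_GRID,
        threshold_grid: Sequence[float] = THRESHOLD_GRID,
        n_folds: int = 10,
        fold_mode: str = "protein",
        random_state: int | None = 0,
    ):
        self.l = l
        self.use_gd = use_gd
        self.use_sa = use_sa
        self.use_ss = use_ss
        self.rare_threshold = rare_threshold
        self.pseudocount = pseudocount
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.threshold_grid = threshold_grid
        self.n_folds = n_folds
        self.fold_mode = fold_mode
        self.random_state = random_state

    def _pipeline(self, probability: bool) -> Pipeline:
        featurizer = GlycositeFeaturizer(
            l=self.l, use_gd=self.use_gd, use_sa=self.use_sa, use_ss=self.use_ss,
            rare_threshold=self.rare_threshold, pseudocount=self.pseudocount,
        )
        svc = SVC(
            kernel="rbf", probability=probability, random_state=self.random_state
        )
        return Pipeline([("features", featurizer), ("svc", svc)])

    def _groups(self, X: Sequence, groups) -> np.ndarray | None:
        if self.fold_mode == "sequon":
            return None
        if self.fold_mode != "protein":
            raise ValueError(f"unknown fold_mode {self.fold_mode!r}")
        if groups is not None:
            return np.asarray(groups)
        ids = []
        for x in X:
            w = x.window if isinstance(x, AnnotatedWindow) else x
            ids.append(getattr(w, "protein_id", ""))
        ids = np.asarray(ids)
        if (ids == "").all():
            return None
        return ids

    def fit(self, X: Sequence, y: Sequence[int], groups: Sequence | None = None):
        X = list(X)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        if min((y == c).sum() for c in classes) < self.n_folds:
            raise ValueError(
                f"need at least n_folds={self.n_folds} samples per class"
            )
        groups = self._groups(X, groups)
        if groups is not None:
            splitter = StratifiedGroupKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.random_state
            )
        else:
            splitter = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.random_state
            )
        splits = list(splitter.split(np.zeros(len(X)), y, groups))

        # grid search for (C, gamma) on CV accuracy; probability estimation is
        # deferred to the per-fold refits below to keep the grid affordable
        grid = GridSearchCV(
            self._pipeline(probability=False),
            {"svc__C": list(self.C_grid), "svc__gamma": list(self.gamma_grid)},
            scoring="accuracy",
            cv=splits,
            refit=False,
            n_jobs=None,
        )
        grid.fit(X, y)
        self.C_ = float(grid.best_params_["svc__C"])
        self.gamma_ = float(grid.best_params_["svc__gamma"])
        self.cv_results_ = pd.DataFrame(grid.cv_results_)

        # per-fold: fit with probabilities, pick the train-MCC-optimal
        # threshold, keep the fold model with the best test-fold MCC
        self.fold_results_ = []
        best = None
        for fold, (train_idx, test_idx) in enumerate(splits):
            pipe = self._pipeline(probability=True)
            pipe.set_params(svc__C=self.C_, svc__gamma=self.gamma_)
            X_train = [X[i] for i in train_idx]
            X_test = [X[i] for i in test_idx]
            with _svc_probability_warnings():
                pipe.fit(X_train, y[train_idx])
            train_scores = pipe.predict_proba(X_train)[:, 1]
            threshold, train_mcc = _best_threshold(
                train_scores, y[train_idx], self.threshold_grid
            )
            test_scores = pipe.predict_proba(X_test)[:, 1]
            test_mcc = metrics(confusion(test_scores > threshold, y[test_idx]))["mcc"]
            self.fold_results_.append(
                FoldResult(fold=fold, threshold=threshold,
                           train_mcc=train_mcc, test_mcc=test_mcc)
            )
            if best is None or test_mcc > best[0]:
                best = (test_mcc, pipe, threshold)
        assert best is not None
        _, self.model_, self.threshold_ = best
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: Sequence) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("SequonClassifier is not fitted")
        return self.model_.predict_proba(list(X))

    def predict_scores(self, X: Sequence) -> np.ndarray:
        """Glycosite probability score per sequon, in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X: Sequence) -> np.ndarray:
        return (self.predict_scores(X) > self.threshold_).astype(int)


def _best_threshold(
    scores: np.ndarray, y: np.ndarray, grid: Sequence[float]
) -> tuple[float, float]:
    """MCC-maximizing score threshold over a grid (ties -> smallest)."""
    best_t, best_mcc = None, -np.inf
    for t in grid:
        mcc = metrics(confusion(scores > t, y))["mcc"]
        if mcc > best_mcc:
            best_t, best_mcc = float(t), mcc
    assert best_t is not None
    return best_t, best_mcc


def grid_search_train(
    X: Sequence, y: Sequence[int], seed: int = 0, **params
) -> SequonClassifier:
    """Thin wrapper: train a SequonClassifier with the default protocol."""
    return SequonClassifier(random_state=seed, **params).fit(X, y)


def predict_scores(model: SequonClassifier, X: Sequence) -> np.ndarray:
    """Thin wrapper over :meth:`SequonClassifier.predict_scores`."""
    return model.predict_scores(X)
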