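"""Logistic-regression vetting of candidate breathing pauses.

Shallow breathing and movement artefact produce low-amplitude stretches that
the IBI detector flags as pauses. Six amplitude features of the thoracic
trace (mean absolute value and SD in windows before, inside, and after the
candidate, normalised to the full-recording SD) feed a plain logistic
regression; performance is reported as balanced accuracy under
leave-one-infant-out (LOIO) cross-validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import KFold, LeaveOneGroupOut

from .respiration import PauseEvent

log = logging.getLogger(__name__)

FEATURE_NAMES = [
    "pre_meanabs",
    "pre_sd",
    "in_meanabs",
    "in_sd",
    "post_meanabs",
    "post_sd",
]


@dataclass(frozen=True)
class PauseFeatures:
    pre_meanabs: float
    pre_sd: float
    in_meanabs: float
    in_sd: float
    post_meanabs: float
    post_sd: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES])


def extract_features(
    thorax: np.ndarray,
    fs: float,
    event: PauseEvent,
    recording_sd: Optional[float] = None,
) -> PauseFeatures:
    """Six amplitude features around one candidate pause.

    Windows (closed-open): [start-10, start-1), [start+1, end-1),
    [end+1, end+10) seconds; the trace is first divided by the SD of the
    full recording so that features are amplitude-scale invariant.
    """
    thorax = np.asarray(thorax, dtype=float)
    if event.duration_s <= 2.0:
        raise ValueError("in-pause window undefined for duration <= 2 s")
    if recording_sd is None:
        recording_sd = float(thorax.std())
    if recording_sd <= 0:
        raise ValueError("recording SD must be positive")
    x = thorax / recording_sd
    n = x.size

    def win(a_s: float, b_s: float) -> np.ndarray:
        i0, i1 = int(round(a_s * fs)), int(round(b_s * fs))
        if i0 < 0 or i1 > n or i1 <= i0:
            raise ValueError("feature window outside recording")
        return x[i0:i1]

    pre = win(event.start_s - 10.0, event.start_s - 1.0)
    inside = win(event.start_s + 1.0, event.end_s - 1.0)
    post = win(event.end_s + 1.0, event.end_s + 10.0)
    return PauseFeatures(
        pre_meanabs=float(np.mean(np.abs(pre))),
        pre_sd=float(np.std(pre)),
        in_meanabs=float(np.mean(np.abs(inside))),
        in_sd=float(np.std(inside)),
        post_meanabs=float(np.mean(np.abs(post))),
        post_sd=float(np.std(post)),
    )


def balanced_accuracy(pred, truth) -> float:
    """(sensitivity + specificity) / 2 for binary labels."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if truth.all() or not truth.any():
        raise ValueError("balanced accuracy undefined with one class in truth")
    return float(balanced_accuracy_score(truth, pred))


@dataclass
class PauseClassifier:
    """Fitted logistic regression over the six pause features."""

    coef: np.ndarray
    intercept: float
    threshold: float = 0.5

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": FEATURE_NAMES,
                "coef": self.coef.tolist(),
                "intercept": self.intercept,
                "threshold": self.threshold,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "PauseClassifier":
        d = json.loads(s)
        return cls(np.asarray(d["coef"]), float(d["intercept"]), float(d["threshold"]))


def _fit_logreg(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    # plain maximum-likelihood fit with intercept, no regularisation
    m = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    m.fit(X, y)
    return m


def train_classifier(df: pd.DataFrame) -> tuple[PauseClassifier, pd.DataFrame]:
    """Fit on all candidates and cross-validate leave-one-infant-out.

    ``df`` needs the six feature columns plus ``label`` (bool) and
    ``infant_id``. Returns the final model (fit on everything) and a CV
    report with per-fold and pooled balanced accuracy (fold id "pooled").
    With a single infant, falls back to 5-fold CV with a warning.
    """
    X = df[FEATURE_NAMES].to_numpy(dtype=float)
    y = df["label"].to_numpy(dtype=bool)
    groups = df["infant_id"].to_numpy()
    if y.all() or not y.any():
        raise ValueError("both classes required to train the classifier")

    if np.unique(groups).size < 2:
        log.warning("single infant: falling back to 5-fold cross-validation")
        splits = list(KFold(n_splits=5, shuffle=False).split(X))
        fold_ids = [f"fold{i}" for i in range(len(splits))]
    else:
        logo = LeaveOneGroupOut()
        splits = list(logo.split(X, y, groups))
        fold_ids = [str(groups[te][0]) for _, te in splits]

    rows = []
    pooled_pred = np.zeros_like(y)
    pooled_seen = np.zeros_like(y)
    for fid, (tr, te) in zip(fold_ids, splits):
        if y[tr].all() or not y[tr].any():
            log.warning("fold %s skipped: single class in training split", fid)
            continue
        m = _fit_logreg(X[tr], y[tr])
        p = m.predict_proba(X[te])[:, 1]
        pred = p > 0.5
        pooled_pred[te] = pred
        pooled_seen[te] = True
        ba = np.nan
        if y[te].any() and not y[te].all():
            ba = balanced_accuracy(pred, y[te])
        rows.append({"fold": fid, "n_test": len(te), "balanced_accuracy": ba})
    seen = pooled_seen.astype(bool)
    pooled_ba = balanced_accuracy(pooled_pred[seen], y[seen])
    rows.append({"fold": "pooled", "n_test": int(seen.sum()), "balanced_accuracy": pooled_ba})
    report = pd.DataFrame(rows)

    final = _fit_logreg(X, y)
    model = PauseClassifier(coef=final.coef_[0].copy(), intercept=float(final.intercept_[0]))
    return model, report


def classify(model: PauseClassifier, df: pd.DataFrame) -> pd.DataFrame:
    """Probability and verdict per candidate; P(true) == threshold counts as
    false (conservative tie-break). Non-finite feature rows are excluded."""
    X = df[FEATURE_NAMES].to_numpy(dtype=float)
    ok = np.isfinite(X).all(axis=1)
    if not ok.all():
        log.warning("excluding %d candidates with non-finite features", (~ok).sum())
    prob = np.full(len(df), np.nan)
    prob[ok] = model.predict_proba(X[ok])
    out = df.copy()
    out["prob_true"] = prob
    out["verdict"] = prob > model.threshold
    out["excluded"] = ~ok
    out.loc[~ok, "verdict"] = False
    return out
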