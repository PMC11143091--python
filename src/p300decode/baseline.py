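"""Logistic-regression benchmark on windowed ERP-mean features."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .epochs import EpochSet
from .nn.train import EvalMetrics, confusion_metrics

logger = logging.getLogger(__name__)

FEATURE_WINDOW_MS = (350.0, 400.0)


def extract_features(
    epochs: EpochSet, window_ms: tuple[float, float] = FEATURE_WINDOW_MS
) -> np.ndarray:
    """Per-trial, per-channel mean amplitude over the window (endpoints inclusive)."""
    lo, hi = window_ms
    times = epochs.times
    if lo < times[0] or hi > times[-1]:
        raise ValueError(f"feature window {window_ms} outside epoch range")
    mask = (times >= lo) & (times <= hi)
    return epochs.data[:, :, mask].mean(axis=2)


def session_overlay_average(epochs: EpochSet) -> EpochSet:
    """Average each trial slot across sessions (optional feature mode).

    Trials occupying the same (subject, scenario, block, run, position) slot in
    every session are averaged into one epoch; labels are identical across
    sessions by schedule reuse or the slot is dropped. Provided as the
    session-overlay reading of the feature-extraction protocol; per-trial
    features are the default.
    """
    meta = epochs.meta.copy()
    meta["label"] = epochs.labels
    keys = ["subject", "scenario", "block", "run", "trial_in_run"]
    data, labels, rows = [], [], []
    for key, grp in meta.groupby(keys):
        if grp["label"].nunique() != 1:
            continue  # target position differs across sessions for this slot
        data.append(epochs.data[grp.index.to_numpy()].mean(axis=0))
        labels.append(int(grp["label"].iloc[0]))
        row = dict(zip(keys, key))
        row["session"] = 0
        row["true_p300_latency"] = float(grp["true_p300_latency"].mean())
        rows.append(row)
    import pandas as pd

    from .epochs import META_COLUMNS

    meta_out = pd.DataFrame(rows)[list(META_COLUMNS)]
    return EpochSet(
        data=np.stack(data),
        labels=np.array(labels),
        meta=meta_out,
        layout=epochs.layout,
        sfreq=epochs.sfreq,
        tmin_ms=epochs.tmin_ms,
    )


def fit_logistic(features: np.ndarray, labels: np.ndarray) -> LogisticRegression:
    """Unpenalized ML logistic regression with intercept; ridge fallback on
    separation/non-convergence (logged)."""
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
        clf.fit(features, labels)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught) or not np.isfinite(
        clf.coef_
    ).all():
        logger.info("logistic fit unstable (likely separation); refitting with small L2")
        clf = LogisticRegression(penalty="l2", C=1e4, solver="lbfgs", max_iter=5000)
        clf.fit(features, labels)
    return clf


def fit_and_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Evaluate LR under the same leave-one-group-out protocol as the CNN.

    *groups* holds the per-trial subject id; each subject in turn is held out.
    With ``groups=None`` the model is fit and scored on the full set (used for
    oracle tests only).
    """
    if groups is None:
        clf = fit_logistic(features, labels)
        m = confusion_metrics(clf.predict(features), labels)
        return pd.DataFrame([{"subject": 0, **m.as_dict()}])
    rows = []
    for subj in np.unique(groups):
        test = groups == subj
        clf = fit_logistic(features[~test], labels[~test])
        m = confusion_metrics(clf.predict(features[test]), labels[test])
        rows.append({"subject": int(subj), **m.as_dict()})
    return pd.DataFrame(rows)


def evaluate_loso_lr(
    epochs: EpochSet, window_ms: tuple[float, float] = FEATURE_WINDOW_MS
) -> pd.DataFrame:
    """LOSO logistic-regression metrics per subject x session x scenario."""
    features = extract_features(epochs, window_ms)
    labels = epochs.labels
    meta = epochs.meta
    rows = []
    for subj in np.unique(meta["subject"]):
        test = (meta["subject"] == subj).to_numpy()
        clf = fit_logistic(features[~test], labels[~test])
        preds = clf.predict(features[test])
        test_meta = meta[test].reset_index(drop=True)
        test_labels = labels[test]
        for (session, scenario), idx in sorted(
            test_meta.groupby(["session", "scenario"]).indices.items()
        ):
            m = confusion_metrics(preds[idx], test_labels[idx])
            rows.append(
                {"subject": int(subj), "session": session, "scenario": scenario, **m.as_dict()}
            )
        pooled = confusion_metrics(preds, test_labels)
        rows.append({"subject": int(subj), "session": 0, "scenario": "all", **pooled.as_dict()})
    return pd.DataFrame(rows)


def compare_models(accuracies_a: np.ndarray, accuracies_b: np.ndarray) -> tuple[float, int, float]:
    """Independent two-sample t test with pooled variance, df = n1 + n2 - 2."""
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 values per model")
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, n1 + n2 - 2, 1.0
        raise ValueError("degenerate (zero) pooled variance with unequal means")
    t = float((a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    df = n1 + n2 - 2
    p = 2.0 * float(t_dist.sf(abs(t), df=df))
    return t, df, p
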