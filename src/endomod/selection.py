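"""Category-selective electrode identification.

A 6-way multinomial logistic classifier is fit to the post-stimulus features
of each electrode with stratified 5-fold cross-validation; pooled held-out
predictions give one-vs-rest true/false positive rates per category, and the
sensitivity index d' = Z(TPR) - Z(FPR).  An electrode is selected when its
maximum d' exceeds a threshold (default 0.5) and the winning category also
has the largest mean post-stimulus response (|stP| or stBHA), which guards
against electrodes that respond to everything except one category.

The multinomial fit uses a small fixed ridge penalty for stability: the
post-stimulus design has ~440 columns against ~384 training trials per fold,
so an unregularized fit is ill-posed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .features import FeatureSet

_RIDGE_C = 0.01   # modest, fixed L2 strength (sklearn C = 1/penalty)


@dataclass
class SelectionResult:
    electrode_id: str
    dprime_by_category: np.ndarray
    tpr_by_category: np.ndarray
    fpr_by_category: np.ndarray
    selected_category: int | None   # 1-based, None if unselected
    mean_stp_check: bool
    mean_stbha_check: bool


def dprime(tpr: float, fpr: float, n_pos: int, n_neg: int) -> float:
    """Sensitivity index Z(TPR) - Z(FPR), with rates clipped to
    [1/(2n), 1 - 1/(2n)] (each with its own n) before the probit transform."""
    if not (0 <= tpr <= 1 and 0 <= fpr <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("counts must be >= 1")
    tpr = np.clip(tpr, 1 / (2 * n_pos), 1 - 1 / (2 * n_pos))
    fpr = np.clip(fpr, 1 / (2 * n_neg), 1 - 1 / (2 * n_neg))
    return float(norm.ppf(tpr) - norm.ppf(fpr))


def fit_six_way(X_evk: np.ndarray, labels: np.ndarray, folds: int = 5,
                seed: int = 0, expected_categories: int | None = None
                ) -> pd.DataFrame:
    """Stratified k-fold CV multinomial classification; pooled held-out
    predictions yield per-category one-vs-rest TPR/FPR and d'.

    Returns a DataFrame indexed by category with columns tpr, fpr, n_pos,
    n_neg, dprime.
    """
    labels = np.asarray(labels)
    cats = np.unique(labels)
    if expected_categories is not None and cats.size != expected_categories:
        raise ValueError(
            f"expected {expected_categories} categories, found {cats.size}")
    counts = pd.Series(labels).value_counts()
    if counts.min() < folds + 1:
        raise ValueError("need more trials per category than CV folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(labels)
    for tr, te in skf.split(X_evk, labels):
        mu = X_evk[tr].mean(axis=0)
        sd = X_evk[tr].std(axis=0)
        sd[sd == 0] = 1.0
        clf = LogisticRegression(C=_RIDGE_C, solver="lbfgs", max_iter=2000)
        clf.fit((X_evk[tr] - mu) / sd, labels[tr])
        pred[te] = clf.predict((X_evk[te] - mu) / sd)

    rows = []
    for c in cats:
        pos = labels == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        tpr = float((pred[pos] == c).mean())
        fpr = float((pred[~pos] == c).mean())
        rows.append(
            {"category": int(c), "tpr": tpr, "fpr": fpr, "n_pos": n_pos,
             "n_neg": n_neg, "dprime": dprime(tpr, fpr, n_pos, n_neg)}
        )
    return pd.DataFrame(rows).set_index("category")


def _mean_response_winner(fs: FeatureSet, labels: np.ndarray, kind: str) -> int:
    """Category (1-based) with the largest mean post-stimulus response.

    stP is compared by the magnitude of the trial-averaged waveform (ERP
    polarity is reference-dependent), stBHA by its signed z-scored mean.
    """
    cols = np.asarray(fs.evk_labels["kind"]) == kind
    cats = np.unique(labels)
    score = np.empty(cats.size)
    for i, c in enumerate(cats):
        mean_wave = fs.X_evk[labels == c][:, cols].mean(axis=0)
        score[i] = np.abs(mean_wave).mean() if kind == "stP" else mean_wave.mean()
    return int(cats[np.argmax(score)])


def select_electrode(fs: FeatureSet, labels: np.ndarray, threshold: float = 0.5,
                     folds: int = 5, seed: int = 0,
                     require_both_checks: bool = False) -> SelectionResult:
    """Apply the d' threshold and mean-response constraint to one electrode.

    ``labels`` must align with ``fs.kept_trials``.  By default the
    mean-response constraint passes if *either* mean |stP| or mean stBHA picks
    the max-d' category; ``require_both_checks`` demands both.
    """
    rates = fit_six_way(fs.X_evk, labels, folds=folds, seed=seed)
    dps = rates["dprime"].to_numpy()
    best = int(rates.index[np.argmax(dps)])
    stp_winner = _mean_response_winner(fs, labels, "stP")
    stbha_winner = _mean_response_winner(fs, labels, "stBHA")
    stp_ok = stp_winner == best
    stbha_ok = stbha_winner == best
    check = (stp_ok and stbha_ok) if require_both_checks else (stp_ok or stbha_ok)
    selected = best if (dps.max() > threshold and check) else None
    return SelectionResult(
        electrode_id=fs.electrode_id,
        dprime_by_category=dps,
        tpr_by_category=rates["tpr"].to_numpy(),
        fpr_by_category=rates["fpr"].to_numpy(),
        selected_category=selected,
        mean_stp_check=stp_ok,
        mean_stbha_check=stbha_ok,
    )


def select_electrodes(feature_sets: list[FeatureSet], trial_table: pd.DataFrame,
                      threshold: float = 0.5, folds: int = 5, seed: int = 0,
                      require_both_checks: bool = False) -> list[SelectionResult]:
    """Run selection over all electrodes of a session."""
    cat_by_trial = trial_table.set_index("trial_index")["category"]
    out = []
    for fs in feature_sets:
        labels = cat_by_trial.loc[fs.kept_trials].to_numpy()
        out.append(
            select_electrode(fs, labels, threshold=threshold, folds=folds,
                             seed=seed, require_both_checks=require_both_checks)
        )
    return out


def permutation_threshold(X_evk: np.ndarray, labels: np.ndarray,
                          n_permutations: int = 100, quantile: float = 0.99,
                          folds: int = 5, seed: int = 0) -> float:
    """Label-permutation calibration of the d' cut: the ``quantile`` of the
    null distribution of the maximum per-category d' under shuffled labels."""
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(labels)
        null_max[i] = fit_six_way(X_evk, perm, folds=folds, seed=seed)["dprime"].max()
    return float(np.quantile(null_max, quantile))


def selection_table(results: list[SelectionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"electrode_id": r.electrode_id}
        for c, d in enumerate(r.dprime_by_category, start=1):
            row[f"dprime_cat{c}"] = d
        row["selected_category"] = (
            r.selected_category if r.selected_category is not None else ""
        )
        row["mean_stp_check"] = r.mean_stp_check
        row["mean_stbha_check"] = r.mean_stbha_check
        rows.append(row)
    return pd.DataFrame(rows)


def save_selection(results: list[SelectionResult], directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "selection.csv"
    selection_table(results).to_csv(path, index=False)
    return path
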