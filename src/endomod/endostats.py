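"""Downstream statistics on the per-trial modulation index (MI).

Covers the behavioural and spatial/temporal characterization of the
endogenous modulation: MI-reaction-time correlations split by preferred vs
non-preferred category, top-vs-bottom MI-quartile contrasts of RT and of
pre-stimulus activity with a random-projection permutation null,
cross-electrode MI correlations (same vs different selectivity, electrodes
more than 2 cm apart) with a trial-shuffle null, the MI autocorrelation with
its 2/sqrt(T) significance bound, and the control correlation between the
post-stimulus discriminant loadings and RT.

All permutation p-values use the add-one estimator
p = (1 + #{|null| >= |observed|}) / (1 + n_permutations) and are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr, ttest_rel


@dataclass
class PermutationSpec:
    n_permutations: int = 1000
    rng_seed: int = 0
    null_kind: str = "random_projection"   # or "label_shuffle"

    def validate(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


# --- MI vs behaviour --------------------------------------------------------

def mi_rt_correlation(mi: np.ndarray, rt: np.ndarray,
                      trial_mask: np.ndarray) -> float:
    """Spearman correlation between MI and RT over masked trials (the mask
    selects repeat trials with a recorded RT in the condition of interest)."""
    mi = np.asarray(mi, dtype=float)
    rt = np.asarray(rt, dtype=float)
    mask = np.asarray(trial_mask, dtype=bool)
    if mask.sum() < 5:
        raise ValueError("need at least 5 masked trials")
    rho, _ = spearmanr(mi[mask], rt[mask])
    return float(rho)


def quartile_contrast(mi: np.ndarray, values: np.ndarray) -> float:
    """mean(values | top ceil(N/4) trials by MI) - mean(values | bottom quarter).
    Ties in MI are broken by trial position (stable sort)."""
    mi = np.asarray(mi, dtype=float)
    values = np.asarray(values, dtype=float)
    if mi.size < 8:
        raise ValueError("need at least 8 trials")
    if np.ptp(mi) == 0:
        raise ValueError("constant MI: quartile ranking undefined")
    order = np.argsort(mi, kind="stable")
    q = int(np.ceil(mi.size / 4))
    return float(values[order[-q:]].mean() - values[order[:q]].mean())


def random_projection_null(X_pre: np.ndarray, beta_pre: np.ndarray,
                           statistic_fn: Callable[[np.ndarray], float],
                           spec: PermutationSpec,
                           observed_mi: np.ndarray | None = None,
                           ) -> tuple[float, np.ndarray, float]:
    """Permutation null for MI-ranking statistics via random projections.

    Each permutation draws a random support of the same size as the nonzero
    support of ``beta_pre`` over all pre-stimulus columns, fills it with
    N(0, 1) weights, computes the surrogate MI = X_pre beta, and re-evaluates
    ``statistic_fn(surrogate_mi)``.  Returns (observed, null_samples, p); the
    observed statistic uses ``observed_mi`` when given (e.g. the held-out MI
    from the nested CV), otherwise X_pre beta_pre.
    """
    spec.validate()
    X_pre = np.asarray(X_pre, dtype=float)
    beta_pre = np.asarray(beta_pre, dtype=float)
    support = int((beta_pre != 0).sum())
    if support == 0:
        raise ValueError("beta_pre has no nonzero entries")
    rng = np.random.default_rng(spec.rng_seed)
    if observed_mi is None:
        observed_mi = X_pre @ beta_pre
    observed = float(statistic_fn(np.asarray(observed_mi, dtype=float)))
    t1 = X_pre.shape[1]
    null = np.empty(spec.n_permutations)
    for i in range(spec.n_permutations):
        idx = rng.choice(t1, size=support, replace=False)
        b = np.zeros(t1)
        b[idx] = rng.standard_normal(support)
        null[i] = statistic_fn(X_pre @ b)
    p = (1 + np.count_nonzero(np.abs(null) >= abs(observed))) / (
        1 + spec.n_permutations)
    return observed, null, float(p)


# --- spatial structure ------------------------------------------------------

def cross_electrode_correlation(
    mi_by_electrode: np.ndarray,
    coordinates: np.ndarray,
    selectivity: np.ndarray,
    spec: PermutationSpec | None = None,
    min_distance_mm: float = 20.0,
) -> dict:
    """Pairwise Spearman correlation of MI across trials for electrode pairs
    more than ``min_distance_mm`` apart, averaged separately over pairs with
    the same vs different category selectivity.

    The null shuffles each electrode's MI series across trials independently
    (destroying the cross-electrode trial pairing) and recomputes both means;
    a full condition-label shuffle would rerun the entire model-fitting
    pipeline per permutation, which is approximated here without refits.  Returns a dict with keys
    same_mean, diff_mean, same_p, diff_p, n_same_pairs, n_diff_pairs.
    """
    mi = np.atleast_2d(np.asarray(mi_by_electrode, dtype=float))
    coords = np.asarray(coordinates, dtype=float)
    sel = np.asarray(selectivity)
    n_elec = mi.shape[0]
    if n_elec < 2:
        return {"same_mean": np.nan, "diff_mean": np.nan, "same_p": np.nan,
                "diff_p": np.nan, "n_same_pairs": 0, "n_diff_pairs": 0}
    dist = squareform(pdist(coords))
    pairs = [(i, j) for i in range(n_elec) for j in range(i + 1, n_elec)
             if dist[i, j] > min_distance_mm]
    same_pairs = [(i, j) for i, j in pairs if sel[i] == sel[j]]
    diff_pairs = [(i, j) for i, j in pairs if sel[i] != sel[j]]

    # Spearman = Pearson on ranks; rank once per electrode
    ranks = np.apply_along_axis(
        lambda v: pd.Series(v).rank().to_numpy(), 1, mi)

    def pair_means(rk: np.ndarray) -> tuple[float, float]:
        def corr(i, j):
            a, b = rk[i], rk[j]
            a = (a - a.mean()) / (a.std() + 1e-30)
            b = (b - b.mean()) / (b.std() + 1e-30)
            return float((a * b).mean())
        sm = np.mean([corr(i, j) for i, j in same_pairs]) if same_pairs else np.nan
        df = np.mean([corr(i, j) for i, j in diff_pairs]) if diff_pairs else np.nan
        return sm, df

    same_mean, diff_mean = pair_means(ranks)
    same_p = diff_p = np.nan
    if spec is not None and pairs:
        spec.validate()
        rng = np.random.default_rng(spec.rng_seed)
        null_same = np.empty(spec.n_permutations)
        null_diff = np.empty(spec.n_permutations)
        for k in range(spec.n_permutations):
            shuffled = np.stack([rng.permutation(ranks[e]) for e in range(n_elec)])
            null_same[k], null_diff[k] = pair_means(shuffled)
        if same_pairs:
            same_p = float((1 + np.count_nonzero(
                np.abs(null_same) >= abs(same_mean))) / (1 + spec.n_permutations))
        if diff_pairs:
            diff_p = float((1 + np.count_nonzero(
                np.abs(null_diff) >= abs(diff_mean))) / (1 + spec.n_permutations))
    return {
        "same_mean": same_mean, "diff_mean": diff_mean,
        "same_p": same_p, "diff_p": diff_p,
        "n_same_pairs": len(same_pairs), "n_diff_pairs": len(diff_pairs),
    }


# --- temporal structure -----------------------------------------------------

def mi_autocorrelation(mi: np.ndarray, max_lag: int = 20) -> dict:
    """Autocorrelation r_k = sum_{t<=T-k} (MI_t - m)(MI_{t+k} - m) /
    sum_{t<=T} (MI_t - m)^2 for k = 1..max_lag, with the approximate 95%
    bound 2/sqrt(T) and a lag-1 significance flag."""
    mi = np.asarray(mi, dtype=float)
    T = mi.size
    if T <= 40:
        raise ValueError("need more than 40 trials")
    if np.ptp(mi) == 0:
        raise ValueError("constant MI")
    m = mi.mean()
    d = mi - m
    denom = float(d @ d)
    r = np.array([float(d[: T - k] @ d[k:]) / denom for k in range(1, max_lag + 1)])
    bound = 2.0 / np.sqrt(T)
    return {"r": r, "bound": float(bound), "lag1_significant": bool(abs(r[0]) > bound)}


# --- post-stimulus control --------------------------------------------------

def loading_rt_correlation(loadings: np.ndarray, rt: np.ndarray,
                           preferred_mask: np.ndarray) -> float:
    """Spearman correlation between held-out stage-1 decision loadings
    (X_evk beta_evk, intercept excluded) and RT on preferred-condition
    repeat trials."""
    loadings = np.asarray(loadings, dtype=float)
    mask = np.asarray(preferred_mask, dtype=bool)
    if mask.sum() < 5:
        raise ValueError("need at least 5 masked trials")
    if np.ptp(loadings[mask]) == 0:
        raise ValueError("constant loadings: correlation undefined")
    rho, _ = spearmanr(loadings[mask], np.asarray(rt, dtype=float)[mask])
    return float(rho)


# --- per-electrode summary --------------------------------------------------

@dataclass
class EndoStats:
    electrode_id: str
    rho_preferred: float
    rho_nonpreferred: float
    delta_rt_quartile: float
    delta_rt_p: float
    prestim_quartile: dict        # mean/SD contrasts of stBHA and |stP| + p's
    autocorr: dict
    loading_rt_rho: float


def electrode_endostats(
    fit,
    X_pre: np.ndarray,
    pre_kinds: np.ndarray,
    trial_table: pd.DataFrame,
    kept_trials: np.ndarray,
    selected_category: int,
    spec: PermutationSpec | None = None,
) -> EndoStats:
    """Full downstream characterization of one electrode's fitted MI."""
    spec = spec or PermutationSpec()
    tt = trial_table.set_index("trial_index").loc[kept_trials]
    rt = tt["rt_ms"].to_numpy()
    cat = tt["category"].to_numpy()
    is_rep = tt["is_repeat"].to_numpy().astype(bool)
    has_rt = is_rep & np.isfinite(rt)
    pref = has_rt & (cat == selected_category)
    nonpref = has_rt & (cat != selected_category)

    mi = fit.mi
    if np.ptp(mi) == 0:
        # a fully null stage-2 fit (all coefficients zero in every fold)
        return EndoStats(
            electrode_id=fit.electrode_id,
            rho_preferred=np.nan, rho_nonpreferred=np.nan,
            delta_rt_quartile=np.nan, delta_rt_p=np.nan,
            prestim_quartile={}, autocorr={"r": np.full(20, np.nan),
                                           "bound": 2 / np.sqrt(mi.size),
                                           "lag1_significant": False},
            loading_rt_rho=loading_rt_correlation(fit.loadings_evk, rt, pref),
        )
    rho_pref = mi_rt_correlation(mi, rt, pref)
    rho_nonpref = mi_rt_correlation(mi, rt, nonpref)

    # quartile RT contrast restricted to preferred repeats, with the
    # random-projection null re-ranking the same trials
    pref_idx = np.flatnonzero(pref)
    beta_rep = fit.beta_pre
    if not np.any(beta_rep != 0):
        # a representative support for the null when the mean coefficient
        # vector is empty: fall back to a single random column
        beta_rep = np.zeros(X_pre.shape[1])
        beta_rep[0] = 1.0

    def rt_stat(mi_vec: np.ndarray) -> float:
        return quartile_contrast(mi_vec[pref_idx], rt[pref_idx])

    delta_rt, _, delta_rt_p = random_projection_null(
        X_pre, beta_rep, rt_stat, spec, observed_mi=mi)

    stbha_cols = pre_kinds == "stBHA"
    stp_cols = pre_kinds == "stP"
    pre_metrics = {
        "stbha_mean": X_pre[:, stbha_cols].mean(axis=1),
        "stbha_sd": X_pre[:, stbha_cols].std(axis=1),
        "abs_stp_mean": np.abs(X_pre[:, stp_cols]).mean(axis=1),
        "stp_sd": X_pre[:, stp_cols].std(axis=1),
    }
    prestim_quartile = {}
    for name, vals in pre_metrics.items():
        obs, _, p = random_projection_null(
            X_pre, beta_rep, lambda m, v=vals: quartile_contrast(m, v), spec,
            observed_mi=mi)
        prestim_quartile[name] = obs
        prestim_quartile[name + "_p"] = p

    return EndoStats(
        electrode_id=fit.electrode_id,
        rho_preferred=rho_pref,
        rho_nonpreferred=rho_nonpref,
        delta_rt_quartile=delta_rt,
        delta_rt_p=delta_rt_p,
        prestim_quartile=prestim_quartile,
        autocorr=mi_autocorrelation(mi),
        loading_rt_rho=loading_rt_correlation(fit.loadings_evk, rt, pref),
    )


def endostats_table(stats: list[EndoStats]) -> pd.DataFrame:
    rows = []
    for s in stats:
        row = {
            "electrode_id": s.electrode_id,
            "rho_preferred": s.rho_preferred,
            "rho_nonpreferred": s.rho_nonpreferred,
            "delta_rt_quartile_ms": s.delta_rt_quartile,
            "delta_rt_p": s.delta_rt_p,
            "r1": s.autocorr["r"][0],
            "autocorr_bound": s.autocorr["bound"],
            "lag1_significant": s.autocorr["lag1_significant"],
            "loading_rt_rho": s.loading_rt_rho,
        }
        row.update(s.prestim_quartile)
        rows.append(row)
    return pd.DataFrame(rows)


def group_paired_ttest(a: np.ndarray, b: np.ndarray) -> dict:
    """Group-level paired t-test across electrodes (report utility)."""
    res = ttest_rel(a, b)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "mean_diff": float(np.mean(np.asarray(a) - np.asarray(b)))}
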