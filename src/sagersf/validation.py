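"""Grouped k-fold validation of habitat surfaces.

Whole birds are withheld (a bird's locations never straddle the build/test
split), the model is refit on the remaining data, and the withheld used
locations are compared with the prediction by (1) area-adjusted bin
frequencies over 10 equal-width relative-probability bins - the withheld-use
share of a bin divided by the bin's share of the mapped area, near 1 under no
selection and increasing with bin rank for a good model, (2) the Spearman rank
correlation between bin rank and adjusted frequency, and (3) a rank-based AUC
(Mann-Whitney probability that a used row outranks an available row, ties
counted half).  Folds are independent ~20% draws of birds by default;
a strict k-way partition is also supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .layers import AVAILABLE_GROUP


def kfold_by_bird(table: pd.DataFrame, k: int = 5, holdout_fraction: float = 0.2,
                  seed: int = 0, group: str = "bird_id", response: str = "response",
                  mode: str = "repeated") -> list[np.ndarray]:
    """Assign whole birds to k withheld sets of ~20% of used rows each.

    Returns a list of k boolean masks over the table's rows (True = withheld).
    Available rows are never withheld - they stay in every building set.  In
    ``repeated`` mode each fold is an independent random draw of birds whose
    cumulative used-row share is closest to ``holdout_fraction`` (greedy over
    a shuffled bird order); ``partition`` mode deals birds into k disjoint
    folds balancing used-row counts.
    """
    used = table[table[response] == 1]
    birds = used[group].unique()
    if len(birds) < k:
        raise ValueError(f"need at least {k} birds, have {len(birds)}")
    counts = used.groupby(group).size()
    total = counts.sum()
    rng = np.random.default_rng(seed)
    masks = []
    if mode == "repeated":
        for _ in range(k):
            order = list(rng.permutation(birds))
            # greedy local search: add/remove whole birds while the withheld
            # share moves toward the target fraction
            withheld: set = set()
            share = 0.0
            improved = True
            while improved:
                improved = False
                for b in order:
                    s = counts[b] / total
                    if b not in withheld and abs(share + s - holdout_fraction) < abs(
                            share - holdout_fraction) - 1e-12:
                        withheld.add(b)
                        share += s
                        improved = True
                    elif b in withheld and len(withheld) > 1 and abs(
                            share - s - holdout_fraction) < abs(share - holdout_fraction) - 1e-12:
                        withheld.remove(b)
                        share -= s
                        improved = True
                if not improved:  # pairwise swaps escape add/remove optima
                    for b_in in list(withheld):
                        for b_out in order:
                            if b_out in withheld:
                                continue
                            delta = (counts[b_out] - counts[b_in]) / total
                            if abs(share + delta - holdout_fraction) < abs(
                                    share - holdout_fraction) - 1e-12:
                                withheld.remove(b_in)
                                withheld.add(b_out)
                                share += delta
                                improved = True
                                break
                        if improved:
                            break
            masks.append(table[group].isin(withheld).to_numpy()
                         & (table[response] == 1).to_numpy())
    elif mode == "partition":
        order = sorted(rng.permutation(birds), key=lambda b: -counts[b])
        fold_of: dict = {}
        load = np.zeros(k)
        for b in order:
            j = int(np.argmin(load))
            fold_of[b] = j
            load[j] += counts[b]
        for j in range(k):
            withheld = {b for b, f in fold_of.items() if f == j}
            masks.append(table[group].isin(withheld).to_numpy()
                         & (table[response] == 1).to_numpy())
    else:
        raise ValueError(f"unknown mode '{mode}'")
    return masks


def area_adjusted_frequencies(map_values, withheld_values, n_bins: int = 10,
                              binning: str = "width") -> pd.DataFrame:
    """Area-adjusted withheld-use frequency per prediction bin.

    ``map_values`` are the prediction values of every mapped cell (or of the
    availability sample standing in for the mapped area); ``withheld_values``
    the predictions at withheld used locations.  With ``binning='width'``
    (default) values are cut into ``n_bins`` equal-width intervals spanning
    [min, max] of the map; ``binning='area'`` uses map-value quantiles instead
    (equal-area bins).  For bin i the adjusted frequency is
    (n_i / N) / (a_i / A).  Bins with no area are reported with NaN frequency.
    """
    mv = np.asarray(map_values, dtype=float).ravel()
    wv = np.asarray(withheld_values, dtype=float).ravel()
    if wv.size == 0:
        raise ValueError("no withheld points on the surface")
    lo, hi = float(mv.min()), float(mv.max())
    if hi <= lo:
        edges = np.linspace(lo - 0.5, lo + 0.5, n_bins + 1)
    elif binning == "area":
        edges = np.unique(np.quantile(mv, np.linspace(0, 1, n_bins + 1)))
        if len(edges) < 4:
            edges = np.linspace(lo, hi, n_bins + 1)
    elif binning == "width":
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        raise ValueError(f"unknown binning '{binning}'")
    a_i = np.histogram(mv, bins=edges)[0].astype(float)
    n_i = np.histogram(np.clip(wv, edges[0], edges[-1]), bins=edges)[0].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = (n_i / n_i.sum()) / (a_i / a_i.sum())
    return pd.DataFrame({
        "bin": np.arange(1, len(edges)),
        "lower": edges[:-1], "upper": edges[1:],
        "withheld_count": n_i.astype(int),
        "area_fraction": a_i / a_i.sum(),
        "adjusted_frequency": u,
    })


def spearman_bins(bin_table: pd.DataFrame) -> float:
    """Spearman rank correlation between bin rank and adjusted frequency,
    over occupied bins (those with mapped area), ties mid-ranked."""
    occ = bin_table.dropna(subset=["adjusted_frequency"])
    occ = occ[occ["area_fraction"] > 0]
    if len(occ) < 3:
        raise ValueError("fewer than 3 occupied bins")
    r, _ = stats.spearmanr(occ["bin"], occ["adjusted_frequency"])
    return float(r)


def rank_auc(used_values, available_values) -> float:
    """Mann-Whitney AUC: P(used > available) with ties counted half."""
    u = np.asarray(used_values, dtype=float)
    a = np.asarray(available_values, dtype=float)
    if u.size == 0 or a.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(np.concatenate([u, a]))
    r_u = ranks[: u.size].sum()
    return float((r_u - u.size * (u.size + 1) / 2) / (u.size * a.size))


@dataclass
class ValidationResult:
    folds: pd.DataFrame              # per-fold r_s, auc, n_withheld
    bins: pd.DataFrame               # per-fold bin tables (stacked)
    average_rs: float
    average_auc: float
    full_auc: float                  # AUC of the model fit to all data
    r2: pd.Series = None             # auxiliary linear R^2 of u on bin rank


def _bin_r2(bin_table: pd.DataFrame) -> float:
    """Linear R^2 of adjusted frequency on bin rank (auxiliary statistic)."""
    occ = bin_table.dropna(subset=["adjusted_frequency"])
    if len(occ) < 3:
        return float("nan")
    r = np.corrcoef(occ["bin"], occ["adjusted_frequency"])[0, 1]
    return float(r ** 2)


def cross_validate(table: pd.DataFrame, covariates, k: int = 5,
                   holdout_fraction: float = 0.2, seed: int = 0,
                   n_bins: int = 10, mode: str = "repeated",
                   fit_fn=None, map_values_from: str = "available") -> ValidationResult:
    """k-fold by-bird cross-validation of one model specification.

    Each fold refits the model on the building rows, predicts the withheld
    used rows, and evaluates the area-adjusted frequency profile, its Spearman
    correlation with bin rank, and the AUC of withheld-used vs available rows.
    The mapped-area reference for binning is the availability sample (a
    uniform Monte Carlo sample of the study extent).
    """
    from .fitting import fit_mixed_logit

    if fit_fn is None:
        def fit_fn(tab):
            return fit_mixed_logit(tab, covariates)
    masks = kfold_by_bird(table, k=k, holdout_fraction=holdout_fraction, seed=seed)
    avail_mask = (table["response"] == 0).to_numpy()
    recs, bin_tabs = [], []
    for fold, withheld in enumerate(masks, start=1):
        build = table[~withheld]
        fit = fit_fn(build)
        pred_withheld = fit.predict(table[withheld])
        pred_avail = fit.predict(table[avail_mask])
        bt = area_adjusted_frequencies(pred_avail, pred_withheld, n_bins=n_bins)
        bt.insert(0, "fold", fold)
        bin_tabs.append(bt)
        try:
            rs = spearman_bins(bt)
        except ValueError:  # degenerate surface: too few occupied bins
            rs = float("nan")
        recs.append({
            "fold": fold,
            "n_withheld": int(withheld.sum()),
            "rs": rs,
            "auc": rank_auc(pred_withheld, pred_avail),
            "r2": _bin_r2(bt),
        })
    full_fit = fit_fn(table)
    full_auc = rank_auc(full_fit.predict(table[table["response"] == 1]),
                        full_fit.predict(table[avail_mask]))
    folds = pd.DataFrame(recs)
    return ValidationResult(
        folds=folds,
        bins=pd.concat(bin_tabs, ignore_index=True),
        average_rs=float(folds["rs"].mean(skipna=True)),
        average_auc=float(folds["auc"].mean()),
        full_auc=full_auc,
        r2=folds.set_index("fold")["r2"],
    )
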