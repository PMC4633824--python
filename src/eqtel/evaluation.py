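"""Causal-recovery and predictability metrics against simulation truth.

All metrics are pure functions of (predictions, truth): precision-recall of
the PIP ranking, cross-validated expression predictability, ordinary
explained variance for a selected SNP set, and detection power stratified by
minor-allele frequency and regulatory potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("eqtel")


@dataclass
class EvaluationReport:
    pr_curve: pd.DataFrame               # recall, precision per threshold step
    mean_prediction_r: float | None = None
    per_gene_r: dict | None = None
    per_gene_r2: dict | None = None
    power_by_maf: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out = {}
        if self.mean_prediction_r is not None:
            out["mean_prediction_r"] = self.mean_prediction_r
        if self.per_gene_r2:
            out["mean_r2"] = float(np.mean(list(self.per_gene_r2.values())))
        return out


def truth_pair_set(truth, snp_level: bool = False) -> set:
    """Truth expression-regulator pairs as (snp_id, gene_id) (or snp ids)."""
    pairs = set()
    for gid, lst in truth.expression_regulators.items():
        for snp, _eff in lst:
            pairs.add(snp if snp_level else (snp, gid))
    return pairs


def precision_recall(
    ranked: pd.DataFrame,
    truth,
    score_col: str = "pip",
    snp_level: bool = False,
) -> pd.DataFrame:
    """Precision-recall curve from a PIP ranking against simulation truth.

    ``ranked`` needs columns snp_id, gene_id and ``score_col``. Tied scores
    are expanded as a single threshold step, which reports the expected
    precision under random ordering of the ties. Returns a frame with
    non-decreasing recall and columns (recall, precision, threshold).
    """
    positives = truth_pair_set(truth, snp_level=snp_level)
    if not positives:
        raise ValueError("truth contains zero positive pairs")
    if snp_level:
        df = ranked.sort_values(score_col, ascending=False).drop_duplicates("snp_id")
        keys = df["snp_id"]
    else:
        df = ranked
        keys = list(zip(df["snp_id"], df["gene_id"]))
    is_pos = np.array([k in positives for k in keys], dtype=float)
    score = df[score_col].to_numpy(dtype=float)
    order = np.argsort(-score, kind="stable")
    score, is_pos = score[order], is_pos[order]
    # one step per distinct score value
    _, first_idx = np.unique(-score, return_index=True)
    boundaries = np.sort(first_idx)
    tp = np.cumsum(is_pos)
    n_called = np.arange(1, len(score) + 1)
    step_end = np.append(boundaries[1:] - 1, len(score) - 1)
    recall = tp[step_end] / len(positives)
    precision = tp[step_end] / n_called[step_end]
    return pd.DataFrame(
        {"recall": recall, "precision": precision, "threshold": score[step_end]}
    )


def precision_at(pr_curve: pd.DataFrame, recall: float) -> float:
    """Precision linearly interpolated at the first threshold reaching recall."""
    r = pr_curve["recall"].to_numpy()
    p = pr_curve["precision"].to_numpy()
    if recall <= r[0]:
        return float(p[0])
    i = int(np.searchsorted(r, recall, side="left"))
    if i >= len(r):
        return float(p[-1])
    if r[i] == recall and (i == 0 or r[i - 1] < recall):
        return float(p[i])
    frac = (recall - r[i - 1]) / (r[i] - r[i - 1])
    return float(p[i - 1] + frac * (p[i] - p[i - 1]))


def kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def cv_predictability(
    g,
    e,
    f,
    fit_fn,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[float, dict[str, float]]:
    """Cross-validated per-gene correlation of predicted vs actual expression.

    For each fold, ``fit_fn(g_train, e_train, f)`` refits the model on the
    training samples and must return a PosteriorSummary; held-out
    predictions are pooled per gene and correlated with the observed
    expression. Returns (mean over genes, per-gene dict).
    """
    from dataclasses import replace

    from eqtel.sampler import predict_expression

    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    n = g.n_samples
    rng = np.random.default_rng(seed)
    folds = kfold_indices(n, k_folds, rng)
    for fold in folds:
        if len(fold) < 3:
            raise ValueError("fold with < 3 samples")
    preds = {str(gid): np.full(n, np.nan) for gid in e.gene_ids}
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        g_tr = replace(g, dosages=g.dosages[train])
        g_te = replace(g, dosages=g.dosages[fold])
        e_tr = replace(e, values=e.values[:, train])
        summary = fit_fn(g_tr, e_tr, f)
        for gid in e.gene_ids:
            preds[str(gid)][fold] = predict_expression(summary, g_te, str(gid))
    per_gene = {}
    for j, gid in enumerate(e.gene_ids):
        pr = preds[str(gid)]
        y = e.values[j]
        if np.std(pr) == 0:
            per_gene[str(gid)] = 0.0
        else:
            per_gene[str(gid)] = float(np.corrcoef(pr, y)[0, 1])
    return float(np.mean(list(per_gene.values()))), per_gene


def explained_variance(y: np.ndarray, x_selected: np.ndarray) -> float:
    """OLS R^2 of expression on the selected SNP dosages."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(x_selected, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        return 0.0
    n = len(y)
    if X.shape[1] > n - 2:
        raise ValueError(f"{X.shape[1]} selected SNPs > n-2 = {n - 2}")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ coef
    tss = float(yc @ yc)
    return float(1.0 - resid @ resid / tss) if tss > 0 else 0.0


def cv_explained_variance(
    y: np.ndarray, x_selected: np.ndarray, k_folds: int = 5, seed: int = 0
) -> float:
    """Cross-validated R^2 variant (held-out residual sum of squares)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(x_selected, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    rng = np.random.default_rng(seed)
    pred = np.empty(n)
    for fold in kfold_indices(n, k_folds, rng):
        train = np.setdiff1d(np.arange(n), fold)
        ym = y[train].mean()
        Xm = X[train].mean(axis=0)
        coef, *_ = np.linalg.lstsq(X[train] - Xm, y[train] - ym, rcond=None)
        pred[fold] = (X[fold] - Xm) @ coef + ym
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def functional_explained_variance(
    y: np.ndarray,
    x_selected: np.ndarray,
    snp_pos: pd.DataFrame,
    intervals: pd.DataFrame,
    flank: int = 25,
) -> float:
    """Explained variance restricted to SNPs mapping to supplied intervals.

    ``snp_pos`` gives chrom/pos per column of ``x_selected`` (1-based);
    ``intervals`` is a 1-based inclusive interval frame (``read_bed``
    output), e.g. DNase footprints. SNPs whose +-flank window misses every
    interval are dropped before computing R^2.
    """
    from eqtel.functional_validation import footprint_fraction

    keep = []
    for i in range(len(snp_pos)):
        frac = footprint_fraction(snp_pos.iloc[[i]], intervals, flank=flank)
        keep.append(frac["pooled"] > 0)
    keep = np.asarray(keep, dtype=bool)
    return explained_variance(y, np.asarray(x_selected)[:, keep])


def power_by_maf(
    called: pd.DataFrame,
    truth,
    maf: dict[str, float],
    theta_hat: dict | None = None,
    n_bins: int = 10,
    potential_split: tuple[float, float] = (0.1, 1.0),
) -> pd.DataFrame:
    """Detection rate of truth regulators per MAF bin and potential stratum.

    ``called`` holds the reported pairs (snp_id, gene_id). Bins default to
    deciles of the truth regulators' MAF distribution. Strata: high
    potential (theta_hat >= potential_split[1]... i.e. == 1 numerically) vs
    low (theta_hat < potential_split[0]); pairs in between go to "mid".
    Empty bins are reported with count 0 and missing rate.
    """
    positives = sorted(truth_pair_set(truth))
    called_set = set(zip(called["snp_id"], called["gene_id"]))
    snps = [p[0] for p in positives]
    mafs = np.array([maf[s] for s in snps])
    edges = np.quantile(mafs, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    lo, hi = potential_split

    def stratum(pair):
        if theta_hat is None:
            return "all"
        th = theta_hat.get(pair, 0.0)
        if th >= hi:
            return "high"
        if th < lo:
            return "low"
        return "mid"

    rows = []
    strata = ["all"] if theta_hat is None else ["high", "mid", "low"]
    for b in range(n_bins):
        in_bin = [
            p for p, m in zip(positives, mafs)
            if edges[b] <= m < edges[b + 1] or (b == n_bins - 1 and m == edges[b + 1])
        ]
        for st in strata:
            members = [p for p in in_bin if stratum(p) == st]
            n_m = len(members)
            rate = (
                sum(p in called_set for p in members) / n_m if n_m else np.nan
            )
            rows.append((b, st, n_m, rate))
    return pd.DataFrame(rows, columns=["maf_bin", "stratum", "n", "rate"])


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(np.asarray(a, float), np.asarray(b, float))[0, 1])
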