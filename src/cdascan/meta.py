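"""Covariate-stratified meta-analysis of the discriminant model.

Covariates such as sex or population structure can inflate a pooled fit:
if both genotype frequencies and the trait mean differ between strata, a
single-cohort model picks up the between-stratum axis as spurious signal.
The meta-analysis scheme fits the model separately inside each stratum's
training portion of every cross-validation fold, averages the parameters
with sample-size weights, and predicts the pooled held-out samples of all
strata with the averaged model.  Within-stratum fits never see the
between-stratum axis, so the pooled prediction score stays calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cda import (CdaParameters, FitResult, Penalizers, _bayes_preds_free,
                  _fit_free, _Packing, _safe_corr, default_lambda_grid,
                  encode_onehot, kfold_indices, make_ygrid)
from .data_model import EncodingScheme, StratifiedCohort

__all__ = ["MetaFit", "meta_fit", "optimize_meta_penalizers", "meta_cv_score"]


@dataclass
class MetaFit:
    """Meta-analysis outcome: per-stratum fits, their weighted average, and
    the pooled cross-validated prediction score."""

    per_stratum_params: list[CdaParameters]
    weights: np.ndarray
    averaged_params: CdaParameters
    penalizers: Penalizers
    R: float
    fold_predictions: list[np.ndarray]
    converged: bool
    p: float | None = None


def _standardize_pooled(cohort: StratifiedCohort, y_override=None):
    ys_raw = ([np.asarray(v, float) for v in y_override] if y_override is not None
              else [p.y for _, p in cohort.strata])
    pooled = np.concatenate(ys_raw)
    mu, sd = float(np.mean(pooled)), float(np.std(pooled))
    sd = sd if sd > 0 else 1.0
    return [(v - mu) / sd for v in ys_raw], mu, sd


def _check(cohort: StratifiedCohort, folds: int):
    if len(cohort.strata) < 2:
        raise ValueError("meta-analysis needs at least two strata")
    m0 = cohort.strata[0][0].n_snps
    if any(g.n_snps != m0 for g, _ in cohort.strata):
        raise ValueError("all strata must share the same SNP set")
    if any(g.n_samples < folds for g, _ in cohort.strata):
        raise ValueError("every stratum needs at least one sample per fold")


def _meta_cv(strata_E, strata_ys, pk: _Packing, pen: Penalizers, fold_idx,
             tol, max_iter, warm=None, strata_G=None):
    """One grid point: within-fold per-stratum fits, weighted averaging,
    pooled held-out prediction.  Returns per-stratum standardized predictions."""
    lam2 = pen.lambda2 if pen.interactions else 0.0
    n_strata = len(strata_E)
    preds = [np.empty(len(y)) for y in strata_ys]
    converged = True
    folds = len(fold_idx[0])
    for f in range(folds):
        xs, wts, train_ys = [], [], []
        for s in range(n_strata):
            test = fold_idx[s][f]
            train = np.setdiff1d(np.arange(len(strata_ys[s])), test)
            key = (s, f)
            x0 = warm.get(key) if warm is not None else None
            Gs = strata_G[s][train] if strata_G is not None else None
            x, ok, _ = _fit_free(strata_E[s][train], strata_ys[s][train], pk,
                                 pen.lambda1, lam2, x0=x0, tol=tol,
                                 max_iter=max_iter, G=Gs)
            if warm is not None:
                warm[key] = x
            converged &= ok
            xs.append(x)
            wts.append(len(train))
            train_ys.append(strata_ys[s][train])
        wts = np.asarray(wts, float)
        x_avg = np.average(np.stack(xs), axis=0, weights=wts)
        pooled_train = np.concatenate(train_ys)
        mu, s2 = float(np.mean(pooled_train)), max(float(np.var(pooled_train)),
                                                   1e-12)
        grid = make_ygrid(mu, s2)
        for s in range(n_strata):
            test = fold_idx[s][f]
            Gs = strata_G[s][test] if strata_G is not None else None
            preds[s][test] = _bayes_preds_free(strata_E[s][test], Gs, x_avg,
                                               pk, mu, s2, grid)
    return preds, converged


def _setup(cohort, encoding, folds, seed, y_override=None):
    _check(cohort, folds)
    L = encoding.n_levels
    strata_E = [encode_onehot(g.values, L) for g, _ in cohort.strata]
    strata_G = [np.ascontiguousarray(g.values, dtype=np.int64)
                for g, _ in cohort.strata]
    strata_ys, mu0, sd0 = _standardize_pooled(cohort, y_override)
    fold_idx = [kfold_indices(len(y), folds, seed + s)
                for s, y in enumerate(strata_ys)]
    m = cohort.strata[0][0].n_snps
    return strata_E, strata_G, strata_ys, fold_idx, m, L, mu0, sd0


def meta_cv_score(cohort: StratifiedCohort, pen: Penalizers,
                  encoding: EncodingScheme, folds: int = 5, seed: int = 0,
                  tol: float = 1e-4, max_iter: int = 500,
                  y_override=None) -> float:
    """Pooled cross-validated R at fixed penalizers (no full-data refits).

    ``y_override`` substitutes per-stratum phenotype arrays, which is how the
    permutation null is generated without rebuilding the cohort.
    """
    strata_E, strata_G, strata_ys, fold_idx, m, L, _, _ = _setup(
        cohort, encoding, folds, seed, y_override)
    pk = _Packing(m, L, pen.interactions)
    preds, _ = _meta_cv(strata_E, strata_ys, pk, pen, fold_idx, tol, max_iter,
                        strata_G=strata_G)
    return _safe_corr(np.concatenate(strata_ys), np.concatenate(preds))


def meta_fit(cohort: StratifiedCohort, pen: Penalizers,
             encoding: EncodingScheme, folds: int = 5, seed: int = 0,
             tol: float = 1e-4, max_iter: int = 500) -> MetaFit:
    """Stratified meta-analysis at fixed penalizers.

    Fold boundaries are drawn independently per stratum but paired by fold
    number, so each fold's pooled test set is disjoint from every training
    portion that produced the averaged model.  The reported per-stratum and
    averaged parameters come from full-stratum refits at the same penalizers
    (weights n_s / sum n_s), on the internally standardized trait scale.
    """
    strata_E, strata_G, strata_ys, fold_idx, m, L, mu0, sd0 = _setup(
        cohort, encoding, folds, seed)
    pk = _Packing(m, L, pen.interactions)
    preds, ok = _meta_cv(strata_E, strata_ys, pk, pen, fold_idx, tol, max_iter,
                         strata_G=strata_G)
    R = _safe_corr(np.concatenate(strata_ys), np.concatenate(preds))
    lam2 = pen.lambda2 if pen.interactions else 0.0
    per_params, xs = [], []
    for s in range(len(strata_E)):
        x, okf, nit = _fit_free(strata_E[s], strata_ys[s], pk, pen.lambda1,
                                lam2, tol=tol, max_iter=max_iter,
                                G=strata_G[s])
        p = pk.to_params(x)
        p.converged, p.n_iter = okf, nit
        per_params.append(p)
        xs.append(x)
    sizes = np.asarray(cohort.sizes, float)
    weights = sizes / sizes.sum()
    avg = pk.to_params(np.average(np.stack(xs), axis=0, weights=weights))
    return MetaFit(per_stratum_params=per_params, weights=weights,
                   averaged_params=avg, penalizers=pen, R=R,
                   fold_predictions=[mu0 + sd0 * p for p in preds],
                   converged=ok)


def optimize_meta_penalizers(cohort: StratifiedCohort, grid1=None, grid2=None,
                             encoding: EncodingScheme = None, folds: int = 5,
                             seed: int = 0, tol: float = 1e-4,
                             max_iter: int = 500,
                             include_no_interaction: bool = True) -> MetaFit:
    """Grid search over shared (lambda1, lambda2 + inf) maximizing pooled R.

    Penalizers are shared across strata; ties go to larger penalizers.
    """
    if encoding is None:
        raise TypeError("encoding is required")
    grid1 = default_lambda_grid() if grid1 is None else np.asarray(grid1, float)
    grid2 = default_lambda_grid() if grid2 is None else np.asarray(grid2, float)
    g2f = np.sort(grid2[np.isfinite(grid2)])
    combos = [(l1, l2) for l2 in g2f for l1 in np.sort(grid1)]
    if include_no_interaction or np.any(np.isinf(grid2)):
        combos += [(l1, np.inf) for l1 in np.sort(grid1)]

    strata_E, strata_G, strata_ys, fold_idx, m, L, _, _ = _setup(
        cohort, encoding, folds, seed)
    warm = {True: {}, False: {}}
    pks = {True: _Packing(m, L, True), False: _Packing(m, L, False)}
    best = None
    for l1, l2 in combos:
        pen = Penalizers(l1, l2)
        pk = pks[pen.interactions]
        preds, _ = _meta_cv(strata_E, strata_ys, pk, pen, fold_idx, tol,
                            max_iter, warm=warm[pen.interactions],
                            strata_G=strata_G)
        R = _safe_corr(np.concatenate(strata_ys), np.concatenate(preds))
        if best is None or R >= best[1]:
            best = (pen, R)
    pen, _ = best
    return meta_fit(cohort, pen, encoding, folds=folds, seed=seed, tol=tol,
                    max_iter=max_iter)
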