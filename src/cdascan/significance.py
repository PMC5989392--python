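"""P-values for the cross-validated prediction score R.

The score is a correlation, so under the null its Fisher transform
``f = atanh(R)`` is approximately normal with standard error
``1 / sqrt(n - 3)``.  Selection of penalizers and cross-validation shift the
null center away from zero, so the null mean ``R0`` is estimated by refitting
under phenotype-label permutations (it is typically close to zero but may be
negative), and the one-sided p-value is ``P = 1 - Phi(z)`` with
``z = sqrt(n - 3) (atanh R - atanh R0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "SignificanceResult",
    "fisher_pvalue",
    "estimate_null_R0",
    "permutation_pvalue",
    "adjust_multiplicity",
]


@dataclass
class SignificanceResult:
    R: float
    R0: float
    n_eff: int
    z: float
    p: float
    method: str


def fisher_pvalue(R: float, R0: float, n: int) -> SignificanceResult:
    """One-sided upper-tail p-value for R against the permutation null mean R0."""
    if n <= 3:
        raise ValueError("Fisher transform needs n > 3")
    if not (abs(R) < 1 and abs(R0) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    z = float(np.sqrt(n - 3) * (np.arctanh(R) - np.arctanh(R0)))
    p = float(norm.sf(z))
    return SignificanceResult(R=float(R), R0=float(R0), n_eff=int(n),
                              z=z, p=p, method="fisher")


def _permuted_scores(score_fn, y, n_perm: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    out = np.empty(n_perm)
    for t in range(n_perm):
        out[t] = score_fn(y[rng.permutation(len(y))])
    return out


def estimate_null_R0(score_fn, y, n_perm: int = 10, seed: int = 0) -> float:
    """Mean prediction score over phenotype-permuted refits.

    ``score_fn(y_permuted) -> R`` must re-run the full inference (at the
    penalizers chosen for the observed data) on the permuted phenotypes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    return float(np.mean(_permuted_scores(score_fn, y, n_perm, seed)))


def permutation_pvalue(score_fn, y, R_obs: float, n_perm: int = 1000,
                       seed: int = 0) -> SignificanceResult:
    """Direct permutation p-value, add-one estimator.

    ``p = (1 + #{permuted R >= observed R}) / (1 + n_perm)``; the add-one
    keeps p strictly positive.
    """
    scores = _permuted_scores(score_fn, y, n_perm, seed)
    p = (1.0 + float(np.sum(scores >= R_obs))) / (1.0 + n_perm)
    return SignificanceResult(R=float(R_obs), R0=float(np.mean(scores)),
                              n_eff=len(np.asarray(y)), z=float("nan"),
                              p=p, method="permutation")


def adjust_multiplicity(pvals, method: str = "bh-fdr", alpha: float = 0.05):
    """Multiple-testing adjustment.

    ``bonferroni`` returns (adjusted p, reject flags at alpha);
    ``bh-fdr`` returns (Benjamini-Hochberg adjusted p, reject flags).
    """
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    K = len(p)
    if method == "bonferroni":
        adj = np.minimum(p * K, 1.0)
        return adj, p < alpha / K
    if method == "bh-fdr":
        from statsmodels.stats.multitest import multipletests
        reject, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        return adj, reject
    raise ValueError(f"unknown method: {method!r}")
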