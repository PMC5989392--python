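"""Model-based genotype-phenotype cohort simulator.

Cohorts are drawn exactly from the discriminant model: phenotypes come from
the standard normal, and for each individual the genotype vector is sampled
from the enumerated conditional distribution Pr(a | y) over all L^m genotype
states.  Enumeration bounds the SNP count (m <= 20 dominant, m <= 12
genotypic).  The ``strong``/``interaction``/``null`` presets reproduce the
simulation protocols: parameters drawn i.i.d. from per-block normal
distributions, with all phenotype-dependent blocks zero under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ridge as rr
from .cda import (CdaParameters, Penalizers, _GridSearcher, _penalizer_combos,
                  cross_validate, make_cv_scorer, optimize_penalizers)
from .data_model import DOMINANT, EncodingScheme, GenotypeMatrix, PhenotypeVector
from .significance import estimate_null_R0, fisher_pvalue

__all__ = [
    "SimSpec",
    "preset_spec",
    "draw_parameters",
    "enumerate_states",
    "state_energies",
    "enumerate_conditional",
    "sample_cohort",
    "power_experiment",
]

_ENUM_LIMIT = {2: 20, 3: 12}

#: Per-block (mean, sd) of the parameter priors for the published protocols.
#: strong: strong fields and interactions, recoverable at large n.
#: interaction: association carried almost entirely by the slope block J^(1).
#: null: phenotype-independent structure only (h^(1) = J^(1) = 0).
PRESETS = {
    "strong": {"h0": (-0.3, 0.1), "h1": (0.3, 0.1),
             "J0": (0.0, 0.05), "J1": (0.1, 0.05)},
    "interaction": {"h0": (0.0, 0.1), "h1": (0.0, 0.1),
             "J0": (0.0, 0.1), "J1": (0.1, 0.1)},
    "null": {"h0": (0.0, 0.1), "h1": (0.0, 0.0),
             "J0": (0.0, 0.1), "J1": (0.0, 0.0)},
}


@dataclass
class SimSpec:
    """Simulation protocol: cohort size, SNP count, encoding and parameter priors.

    ``parameter_dists`` maps block names (h0, h1, J0, J1) to (mean, sd).
    """

    m: int
    n: int
    encoding: EncodingScheme = field(default_factory=lambda: DOMINANT)
    parameter_dists: dict = field(default_factory=lambda: dict(PRESETS["null"]))
    seed: int = 0

    def __post_init__(self):
        limit = _ENUM_LIMIT[self.encoding.n_levels]
        if self.m > limit:
            raise ValueError(
                f"m = {self.m} exceeds the enumeration limit {limit} for the "
                f"{self.encoding.mode} encoding")
        for k in ("h0", "h1", "J0", "J1"):
            mean, sd = self.parameter_dists[k]
            if sd < 0:
                raise ValueError(f"negative sd for block {k}")


def preset_spec(name: str, m: int, n: int, seed: int = 0) -> SimSpec:
    """Build a SimSpec from one of the published protocols."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SimSpec(m=m, n=n, encoding=DOMINANT,
                   parameter_dists=dict(PRESETS[name]), seed=seed)


def draw_parameters(spec: SimSpec, rng: np.random.Generator | None = None
                    ) -> CdaParameters:
    """Draw i.i.d. model parameters from the per-block normal priors.

    Zero-reference entries (genotype level 0) stay exactly zero; couplings
    are drawn once per unordered pair and mirrored.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    m, L = spec.m, spec.encoding.n_levels
    params = CdaParameters.zeros(m, L)
    for l, key in ((0, "h0"), (1, "h1")):
        mean, sd = spec.parameter_dists[key]
        params.h[l, :, 1:] = rng.normal(mean, sd, size=(m, L - 1))
    for l, key in ((0, "J0"), (1, "J1")):
        mean, sd = spec.parameter_dists[key]
        for i in range(m):
            for j in range(i + 1, m):
                blk = rng.normal(mean, sd, size=(L - 1, L - 1))
                params.J[l, i, j, 1:, 1:] = blk
                params.J[l, j, i, 1:, 1:] = blk.T
    return params


def enumerate_states(m: int, n_levels: int) -> np.ndarray:
    """All L^m genotype states as an (S, m) integer array (last SNP fastest)."""
    S = n_levels ** m
    if m > _ENUM_LIMIT[n_levels]:
        raise ValueError("state space too large to enumerate")
    grids = np.indices((n_levels,) * m).reshape(m, S).T
    return grids.astype(np.int64)


def state_energies(params: CdaParameters, states: np.ndarray):
    """Phenotype-independent and -linear energies (e0, e1) for every state.

    ``H(a; y) = e0(a) + y * e1(a)``.
    """
    m = params.m
    e = np.zeros((2, len(states)))
    for l in (0, 1):
        e[l] += params.h[l, np.arange(m), states].sum(axis=1)
        for i in range(m):
            for j in range(i + 1, m):
                e[l] += params.J[l, i, j, states[:, i], states[:, j]]
    return e[0], e[1]


def enumerate_conditional(params: CdaParameters, y: float,
                          encoding: EncodingScheme):
    """Exact Pr(a | y) over all genotype states.

    Returns ``(states, probs, logZ)``; probabilities sum to one by
    construction.
    """
    states = enumerate_states(params.m, encoding.n_levels)
    e0, e1 = state_energies(params, states)
    logits = e0 + y * e1
    mx = logits.max()
    w = np.exp(logits - mx)
    Z = w.sum()
    return states, w / Z, float(np.log(Z) + mx)


def sample_cohort(spec: SimSpec, params: CdaParameters | None = None,
                  rng: np.random.Generator | None = None):
    """Draw a cohort: y_k ~ N(0, 1), then a^k ~ Pr(. | y_k) by enumeration.

    If ``params`` is omitted they are drawn first from the spec's priors
    (sharing the same seeded stream, so a spec fully determines the cohort).
    Returns ``(GenotypeMatrix, PhenotypeVector, CdaParameters)``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if params is None:
        params = draw_parameters(spec, rng)
    states = enumerate_states(spec.m, spec.encoding.n_levels)
    e0, e1 = state_energies(params, states)
    y = rng.normal(size=spec.n)
    u = rng.random(spec.n)
    geno = np.empty((spec.n, spec.m), dtype=np.int64)
    chunk = max(1, int(5e6) // len(states))
    for s in range(0, spec.n, chunk):
        sl = slice(s, min(s + chunk, spec.n))
        logits = e0[None, :] + y[sl, None] * e1[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        cdf = np.cumsum(w, axis=1)
        cdf /= cdf[:, -1:]
        pick = (cdf < u[sl, None]).sum(axis=1)
        geno[sl] = states[pick]
    g = GenotypeMatrix(geno.astype(float),
                       snp_ids=[f"snp{i + 1}" for i in range(spec.m)],
                       chrom=["1"] * spec.m,
                       pos=(np.arange(spec.m) + 1) * 1000,
                       sample_ids=[f"ind{k + 1}" for k in range(spec.n)])
    return g, PhenotypeVector(y), params


def _replicate_seeds(seed: int, replicates: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(replicates)]


def type1_error_experiment(replicates: int = 200, m: int = 10, n: int = 200,
                           alpha: float = 0.05, lambda_grid=None,
                           folds: int = 5, n_perm: int = 10, seed: int = 0):
    """Empirical type-I error of the full collective-association pipeline.

    Each replicate draws a null cohort (phenotype-independent fields and
    couplings only), optimizes the penalizer pair by cross-validated R,
    re-runs the identical optimizing inference on ``n_perm`` phenotype
    permutations to estimate the null mean R0, and records the
    Fisher-transform p-value.  Returns ``(p-value array, rejection rate at
    alpha)``.
    """
    if lambda_grid is None:
        lambda_grid = np.logspace(-2, 2, 3)
    combos = _penalizer_combos(lambda_grid, lambda_grid, tie_lambda=False,
                               include_no_interaction=True)
    pvals = np.empty(replicates)
    for r, rep_seed in enumerate(_replicate_seeds(seed, replicates)):
        spec = preset_spec("null", m=m, n=n, seed=rep_seed)
        g, pheno, _ = sample_cohort(spec)
        searcher = _GridSearcher(g, combos, spec.encoding, folds, rep_seed,
                                 tol=1e-4, max_iter=500)
        R = searcher.search(pheno.y)[0]
        R0 = estimate_null_R0(lambda yp: searcher.search(yp)[0], pheno.y,
                              n_perm=n_perm, seed=rep_seed + 1)
        pvals[r] = fisher_pvalue(R, R0, n).p
    return pvals, float(np.mean(pvals < alpha))


def power_experiment(spec: SimSpec, replicates: int, alpha: float = 0.05,
                     methods=("cda", "rr"), lambda_grid=None, folds: int = 5,
                     seed: int = 0, n_perm: int = 10):
    """Power comparison of CDA and ridge regression over replicate cohorts.

    Each replicate draws fresh parameters and a fresh cohort from the spec,
    optimizes a single shared penalizer per method by cross-validation on
    identical fold assignments, estimates the null mean R0 from ``n_perm``
    phenotype permutations, and records the Fisher-transform p-value.  Power
    is the fraction of replicates with p below ``alpha``.

    Returns ``(per-replicate DataFrame, summary dict)``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if lambda_grid is None:
        lambda_grid = np.logspace(-2, 2, 5)
    rows = []
    for r, rep_seed in enumerate(_replicate_seeds(seed, replicates)):
        rng = np.random.default_rng(rep_seed)
        g, pheno, _ = sample_cohort(
            SimSpec(spec.m, spec.n, spec.encoding, spec.parameter_dists,
                    seed=rep_seed), rng=rng)
        fold_seed = rep_seed
        row = {"replicate": r}
        if "cda" in methods:
            combos = _penalizer_combos(lambda_grid, None, tie_lambda=True,
                                       include_no_interaction=True)
            searcher = _GridSearcher(g, combos, spec.encoding, folds,
                                     fold_seed, tol=1e-4, max_iter=500)
            R, pen, _, _ = searcher.search(pheno.y)
            R0 = estimate_null_R0(lambda yp: searcher.search(yp)[0], pheno.y,
                                  n_perm=n_perm, seed=fold_seed + 1)
            sig = fisher_pvalue(R, R0, spec.n)
            row.update(R_cda=R, R0_cda=R0, p_cda=sig.p,
                       lambda_cda=pen.lambda1)
        if "rr" in methods:
            rfit = rr.rr_cross_validate(g, pheno, lambda_grid, folds=folds,
                                        seed=fold_seed)
            rr_score = rr.make_rr_scorer(g, lambda_grid, folds=folds,
                                         seed=fold_seed)
            R0r = estimate_null_R0(rr_score, pheno.y, n_perm=n_perm,
                                   seed=fold_seed + 2)
            sigr = fisher_pvalue(rfit.R, R0r, spec.n)
            row.update(R_rr=rfit.R, R0_rr=R0r, p_rr=sigr.p, lambda_rr=rfit.lam)
        rows.append(row)
    table = pd.DataFrame(rows)
    summary = {}
    if "cda" in methods:
        summary["mean_R_cda"] = float(table["R_cda"].mean())
        summary["power_cda"] = float((table["p_cda"] < alpha).mean())
    if "rr" in methods:
        summary["mean_R_rr"] = float(table["R_rr"].mean())
        summary["power_rr"] = float((table["p_rr"] < alpha).mean())
    return table, summary
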