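"""Pathway SNP-group construction, the association scan, and heritability.

A pathway's SNP set is the union of all SNPs within 50 kb of the coding
span of any member gene; pathways with fewer than 5 SNPs are dropped.  The
scan pipeline per pathway is: extract SNPs -> LD-prune -> covariate
stratification -> penalizer-optimized meta-analysis -> permutation-estimated
null mean R0 -> Fisher-transform p-value, with Bonferroni and
Benjamini-Hochberg flags over the whole scan.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cda import (Penalizers, cross_validate, default_lambda_grid,
                  optimize_penalizers)
from .data_model import (EncodingScheme, GENOTYPIC, GenotypeMatrix,
                         PhenotypeVector, ld_prune, stratify)
from .meta import meta_cv_score, optimize_meta_penalizers
from .significance import adjust_multiplicity, estimate_null_R0, fisher_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayDefinition",
    "GeneSpan",
    "HeritabilityEstimate",
    "ScanConfig",
    "read_gene_spans",
    "read_gmt",
    "map_snps_to_pathways",
    "pathway_scan",
    "heritability_split_half",
]


@dataclass
class GeneSpan:
    """Coding span of a gene, 1-based inclusive coordinates."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")


@dataclass
class PathwayDefinition:
    name: str
    genes: list[str]
    snp_indices: np.ndarray
    n_snps_pre_prune: int
    n_snps_post_prune: int | None = None


@dataclass
class HeritabilityEstimate:
    pathway: str
    r2: float
    ci95: tuple[float, float]
    tuned_penalizers: Penalizers


@dataclass
class ScanConfig:
    """Settings of the per-pathway association scan."""

    encoding: EncodingScheme = field(default_factory=lambda: GENOTYPIC)
    window_bp: int = 50_000
    min_snps: int = 5
    prune: bool = True
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.9
    stratify_rule: str = "binary-label"
    grid1: np.ndarray | None = None
    grid2: np.ndarray | None = None
    folds: int = 5
    n_perm_r0: int = 10
    seed: int = 0
    alpha: float = 0.05


def read_gene_spans(path) -> list[GeneSpan]:
    """Read gene spans from BED (0-based half-open; converted to 1-based
    inclusive internally).  Column 4 is the gene symbol."""
    spans = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line lacks a name column: {line!r}")
            chrom, start, end, gene = parts[:4]
            spans.append(GeneSpan(gene=gene, chrom=chrom,
                                  start=int(start) + 1, end=int(end)))
    return spans


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def map_snps_to_pathways(g: GenotypeMatrix, spans: list[GeneSpan],
                         sets: dict[str, list[str]],
                         window_bp: int = 50_000,
                         min_snps: int = 5) -> list[PathwayDefinition]:
    """Map each pathway to the union of SNPs within ``window_bp`` of any
    member gene's span (distance 0 inside the span, boundary inclusive).

    Genes missing from the span table are logged and skipped; pathways with
    fewer than ``min_snps`` mapped SNPs are dropped.
    """
    by_gene: dict[str, list[GeneSpan]] = {}
    for sp in spans:
        by_gene.setdefault(sp.gene, []).append(sp)
    pos = g.pos
    chrom = g.chrom
    out = []
    for name, genes in sets.items():
        mask = np.zeros(g.n_snps, dtype=bool)
        for gene in genes:
            if gene not in by_gene:
                logger.info("gene %s absent from span table; skipped", gene)
                continue
            for sp in by_gene[gene]:
                on_chrom = chrom == sp.chrom
                dist = np.maximum.reduce([sp.start - pos, pos - sp.end,
                                          np.zeros_like(pos)])
                mask |= on_chrom & (dist <= window_bp)
        idx = np.flatnonzero(mask)
        if len(idx) >= min_snps:
            out.append(PathwayDefinition(name=name, genes=list(genes),
                                         snp_indices=idx,
                                         n_snps_pre_prune=len(idx)))
    return out


def _pathway_seed(base: int, name: str) -> int:
    return (base * 1_000_003 + zlib.crc32(name.encode())) % (2 ** 31)


def pathway_scan(g: GenotypeMatrix, pheno: PhenotypeVector, covariate,
                 pathways: list[PathwayDefinition],
                 config: ScanConfig) -> pd.DataFrame:
    """Run the collective-association scan over pathways.

    Per-pathway seeds derive from the pathway name, so the result table is
    identical regardless of the order in which pathways are processed.
    """
    rows = []
    for pw in pathways:
        t0 = time.perf_counter()
        seed = _pathway_seed(config.seed, pw.name)
        sub = g.take_snps(pw.snp_indices)
        if config.prune:
            sub = ld_prune(sub, window=config.prune_window,
                           step=config.prune_step,
                           r2_threshold=config.prune_r2)
        pw.n_snps_post_prune = sub.n_snps
        row = {"pathway": pw.name, "n_snps_pre": pw.n_snps_pre_prune,
               "n_snps_post": sub.n_snps}
        if sub.n_snps == 0:
            row.update(status="skipped", R=np.nan, R0=np.nan, z=np.nan,
                       p=np.nan, lambda1=np.nan, lambda2=np.nan)
            rows.append(row)
            continue
        cohort = stratify(sub, pheno, covariate, rule=config.stratify_rule)
        fit = optimize_meta_penalizers(cohort, grid1=config.grid1,
                                       grid2=config.grid2,
                                       encoding=config.encoding,
                                       folds=config.folds, seed=seed)
        rng = np.random.default_rng(seed + 1)
        scores = []
        for _ in range(config.n_perm_r0):
            y_perm = [p.y[rng.permutation(p.n)] for _, p in cohort.strata]
            scores.append(meta_cv_score(cohort, fit.penalizers,
                                        config.encoding, folds=config.folds,
                                        seed=seed, y_override=y_perm))
        R0 = float(np.mean(scores))
        sig = fisher_pvalue(fit.R, R0, cohort.n_total)
        row.update(status="ok", R=fit.R, R0=R0, z=sig.z, p=sig.p,
                   lambda1=fit.penalizers.lambda1,
                   lambda2=fit.penalizers.lambda2)
        rows.append(row)
        logger.info("pathway %s: %d SNPs, R=%.3f, p=%.3g (%.1fs)", pw.name,
                    sub.n_snps, fit.R, sig.p, time.perf_counter() - t0)
    table = pd.DataFrame(rows)
    ok = table["status"] == "ok"
    table["p_bonferroni"] = np.nan
    table["fdr_flag"] = False
    if ok.any():
        p = table.loc[ok, "p"].to_numpy()
        adj_b, _ = adjust_multiplicity(p, "bonferroni", alpha=config.alpha)
        _, flags = adjust_multiplicity(p, "bh-fdr", alpha=config.alpha)
        table.loc[ok, "p_bonferroni"] = adj_b
        table.loc[ok, "fdr_flag"] = flags
    return table


def heritability_split_half(g: GenotypeMatrix, pheno: PhenotypeVector,
                            pathway: PathwayDefinition | None = None,
                            grid1=None, grid2=None,
                            encoding: EncodingScheme = GENOTYPIC,
                            folds: int = 5, seed: int = 0) -> HeritabilityEstimate:
    """Split-half broad-sense heritability of a SNP set.

    The cohort is split into random halves: the first half tunes the
    penalizers by cross-validated R; the inference is then repeated on the
    second half under those fixed penalizers, and r^2 is the squared
    correlation between the (held-out) predicted and actual trait values
    there.  The 95% CI comes from the Fisher transform of the correlation.
    """
    if g.n_samples < 40:
        raise ValueError("split-half heritability needs n >= 40")
    sub = g if pathway is None else g.take_snps(pathway.snp_indices)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(g.n_samples)
    half1, half2 = perm[: g.n_samples // 2], perm[g.n_samples // 2:]
    g1, y1 = sub.take_samples(half1), pheno.take(half1)
    g2, y2 = sub.take_samples(half2), pheno.take(half2)
    if grid1 is None:
        grid1 = default_lambda_grid(5)
    if grid2 is None:
        grid2 = default_lambda_grid(5)
    tuned = optimize_penalizers(g1, y1, grid1=grid1, grid2=grid2,
                                encoding=encoding, folds=folds,
                                seed=seed + 1).penalizers
    fit2 = cross_validate(g2, y2, tuned, encoding, folds=folds, seed=seed + 2,
                          fit_full=False)
    r = float(np.corrcoef(y2.y, fit2.fold_predictions)[0, 1]) \
        if np.std(fit2.fold_predictions) > 0 else 0.0
    n2 = len(half2)
    se = 1.0 / np.sqrt(n2 - 3)
    lo, hi = np.tanh(np.arctanh(r) - 1.96 * se), np.tanh(np.arctanh(r) + 1.96 * se)
    if lo <= 0 <= hi:
        ci = (0.0, float(max(lo * lo, hi * hi)))
    else:
        ci = (float(min(lo * lo, hi * hi)), float(max(lo * lo, hi * hi)))
    r2 = min(max(r * r, 0.0), 1.0)
    name = pathway.name if pathway is not None else "all-snps"
    return HeritabilityEstimate(pathway=name, r2=r2, ci95=ci,
                                tuned_penalizers=tuned)
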