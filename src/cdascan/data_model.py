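"""Genotype/phenotype containers, file readers, preprocessing and LD pruning.

The containers here are deliberately thin: a :class:`GenotypeMatrix` is an
``n x m`` allele-count matrix with per-SNP metadata, and a
:class:`PhenotypeVector` is a length-``n`` trait vector carrying the fitted
normal marginal (sample mean and variance) plus a record of any transform
applied.  Everything downstream (model fitting, simulation, pathway scans)
consumes these two types.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "EncodingScheme",
    "StratifiedCohort",
    "load_genotypes",
    "load_phenotypes",
    "round_dosages",
    "impute_missing",
    "transform_phenotype",
    "recode",
    "ld_prune",
    "stratify",
]


class EncodingScheme:
    """Genotype encoding: ``genotypic`` keeps levels {0,1,2}; ``dominant``
    collapses the homozygous-alternate count 2 onto 1 so levels are {0,1}.

    Level 0 is the zero-parameter reference in the discriminant model.
    """

    GENOTYPIC = "genotypic"
    DOMINANT = "dominant"

    def __init__(self, mode: str):
        if mode not in (self.GENOTYPIC, self.DOMINANT):
            raise ValueError(f"unknown encoding mode: {mode!r}")
        self.mode = mode

    @property
    def n_levels(self) -> int:
        """Number of genotype levels (3 genotypic, 2 dominant)."""
        return 3 if self.mode == self.GENOTYPIC else 2

    def __eq__(self, other) -> bool:
        return isinstance(other, EncodingScheme) and other.mode == self.mode

    def __repr__(self) -> str:
        return f"EncodingScheme({self.mode!r})"


GENOTYPIC = EncodingScheme(EncodingScheme.GENOTYPIC)
DOMINANT = EncodingScheme(EncodingScheme.DOMINANT)


@dataclass
class GenotypeMatrix:
    """``n`` samples x ``m`` SNPs allele-count matrix with SNP metadata.

    ``values`` may hold fractional imputed dosages straight after loading
    (``fractional`` is then True); all model code requires integer counts,
    obtained with :func:`round_dosages`.
    """

    values: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: np.ndarray
    fractional: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("genotype matrix must have n >= 1 samples and m >= 1 SNPs")
        for name, arr in (("snp_ids", self.snp_ids), ("chrom", self.chrom),
                          ("pos", self.pos)):
            if len(arr) != m:
                raise ValueError(f"{name} length {len(arr)} != m = {m}")
        if len(self.sample_ids) != n:
            raise ValueError(f"sample_ids length {len(self.sample_ids)} != n = {n}")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        if np.any(self.pos < 0):
            raise ValueError("positions must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def take_snps(self, idx) -> "GenotypeMatrix":
        """Subset to SNP indices ``idx`` (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(self.values[:, idx], self.snp_ids[idx],
                              self.chrom[idx], self.pos[idx], self.sample_ids,
                              fractional=self.fractional)

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(self.values[idx], self.snp_ids, self.chrom,
                              self.pos, self.sample_ids[idx],
                              fractional=self.fractional)


@dataclass
class PhenotypeVector:
    """Continuous trait values with their normal marginal model.

    ``mu_hat``/``sigma2_hat`` are the sample mean and (biased, 1/n) variance
    of ``y``; they parameterize the marginal Pr(y) = N(mu_hat, sigma2_hat)
    used by the Bayes phenotype predictor.
    """

    y: np.ndarray
    mu_hat: float = field(init=False)
    sigma2_hat: float = field(init=False)
    transform: str = "none"
    eps: float | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.y.size < 1:
            raise ValueError("empty phenotype vector")
        self.mu_hat = float(np.mean(self.y))
        self.sigma2_hat = float(np.var(self.y))
        if self.y.size > 1 and self.sigma2_hat <= 0:
            raise ValueError("phenotype variance must be positive")

    @property
    def n(self) -> int:
        return self.y.size

    def take(self, idx) -> "PhenotypeVector":
        idx = np.asarray(idx, dtype=int)
        return PhenotypeVector(self.y[idx], transform=self.transform, eps=self.eps)


@dataclass
class StratifiedCohort:
    """Disjoint covariate-defined sub-cohorts sharing one SNP set."""

    strata: list[tuple[GenotypeMatrix, PhenotypeVector]]
    labels: list[str]

    def __post_init__(self):
        if len(self.strata) < 1:
            raise ValueError("need at least one stratum")
        if any(g.n_samples == 0 for g, _ in self.strata):
            raise ValueError("empty stratum")
        for g, y in self.strata:
            if g.n_samples != y.n:
                raise ValueError("genotype/phenotype length mismatch in stratum")

    @property
    def sizes(self) -> list[int]:
        return [g.n_samples for g, _ in self.strata]

    @property
    def n_total(self) -> int:
        return sum(self.sizes)


# ---------------------------------------------------------------------------
# readers


def load_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT or DS) or a dosage TSV.

    The dosage TSV layout is samples x SNPs: a header row of SNP ids
    (first column name arbitrary), then one row per sample starting with
    the sample id.  Fractional dosages are stored as-is and flagged for
    rounding.  VCF reading uses cyvcf2 when available.
    """
    if format == "vcf":
        return _load_vcf(path)
    if format == "dosage-tsv":
        return _load_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _load_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from e
    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    cols, ids, chroms, poss = [], [], [], []
    fractional = False
    for var in vcf:
        fmt = var.FORMAT
        if "DS" in fmt:
            d = np.asarray(var.format("DS"), dtype=float).ravel()
            if not np.allclose(d, np.round(d)):
                fractional = True
        else:
            gts = np.asarray(var.genotypes, dtype=object)
            vals = []
            for gt in gts:
                alleles = gt[:-1]
                if any(al < 0 for al in alleles):
                    vals.append(np.nan)  # missing call
                else:
                    vals.append(float(sum(1 for al in alleles if al == 1)))
            d = np.array(vals, dtype=float)
        cols.append(d)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not cols:
        raise ValueError(f"no variant records in {path}")
    values = np.column_stack(cols)
    return GenotypeMatrix(values, ids, chroms, poss, samples, fractional=fractional)


def _load_dosage_tsv(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as e:
        raise ValueError(f"malformed dosage TSV {path}: {e}") from e
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"no variant records in {path}")
    values = df.to_numpy(dtype=float)
    fractional = not np.allclose(values, np.round(values))
    snp_ids = df.columns.to_numpy(dtype=object)
    # positional metadata is not carried by the TSV format
    return GenotypeMatrix(values, snp_ids,
                          np.array(["0"] * len(snp_ids), dtype=object),
                          np.zeros(len(snp_ids), dtype=np.int64),
                          df.index.to_numpy(dtype=object), fractional=fractional)


def load_phenotypes(path, trait: str | None = None) -> pd.DataFrame:
    """Read the phenotype TSV (sample_id, trait, covariates...)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("phenotype table needs at least sample id and trait columns")
    if trait is not None and trait not in df.columns:
        raise ValueError(f"trait column {trait!r} not in phenotype table")
    return df


# ---------------------------------------------------------------------------
# preprocessing


def impute_missing(g: GenotypeMatrix, strategy: str = "mode") -> GenotypeMatrix:
    """Handle missing genotype entries (NaN).

    ``mode`` fills each SNP's missing entries with its most frequent observed
    count (logging how many were filled); ``drop`` removes samples carrying
    any missing entry.
    """
    v = g.values
    miss = np.isnan(v)
    if not miss.any():
        return g
    if strategy == "mode":
        filled = v.copy()
        n_filled = 0
        for j in np.flatnonzero(miss.any(axis=0)):
            obs = v[~miss[:, j], j]
            if obs.size == 0:
                raise ValueError(f"SNP {g.snp_ids[j]} has no observed calls")
            counts, freqs = np.unique(obs, return_counts=True)
            mode = counts[np.argmax(freqs)]
            filled[miss[:, j], j] = mode
            n_filled += int(miss[:, j].sum())
        logger.info("imputed %d missing genotype calls to per-SNP modes",
                    n_filled)
        return replace(g, values=filled)
    if strategy == "drop":
        keep = np.flatnonzero(~miss.any(axis=1))
        if keep.size == 0:
            raise ValueError("every sample has a missing genotype")
        logger.info("dropped %d samples with missing genotypes",
                    g.n_samples - keep.size)
        return g.take_samples(keep)
    raise ValueError(f"unknown missing-data strategy: {strategy!r}")


def round_dosages(g: GenotypeMatrix) -> GenotypeMatrix:
    """Round fractional dosages to the nearest integer allele count.

    Uses round-half-away-from-zero, so 1.5 -> 2.  Entries must already lie
    in [0, 2].
    """
    v = g.values
    if np.isnan(v).any():
        raise ValueError("missing genotypes present; run impute_missing first")
    if np.any(v < 0) or np.any(v > 2):
        bad = np.argwhere((v < 0) | (v > 2))[0]
        raise ValueError(f"dosage outside [0, 2] at sample {bad[0]}, SNP {bad[1]}")
    rounded = np.floor(v + 0.5)  # half away from zero (entries are >= 0)
    out = replace(g, values=rounded, fractional=False)
    return out


def transform_phenotype(y, kind: str = "none", eps: float | None = None) -> PhenotypeVector:
    """Build a :class:`PhenotypeVector`, optionally log-transforming the trait.

    ``log_eps`` computes ln(y + eps); ``eps`` defaults to 1e-3 of the trait
    range (fractional traits near zero would otherwise hit the log
    singularity).
    """
    y = np.asarray(y, dtype=float).ravel()
    if kind == "none":
        return PhenotypeVector(y, transform="none")
    if kind == "log_eps":
        if eps is None:
            eps = 1e-3 * float(np.ptp(y))
        arg = y + eps
        if np.any(arg <= 0):
            raise ValueError("log transform argument non-positive; increase eps")
        return PhenotypeVector(np.log(arg), transform="log_eps", eps=float(eps))
    raise ValueError(f"unknown transform kind: {kind!r}")


def recode(g: GenotypeMatrix, scheme: EncodingScheme) -> GenotypeMatrix:
    """Apply the encoding scheme: dominant maps allele count 2 -> 1."""
    v = g.values
    if not np.all(np.isin(v, (0.0, 1.0, 2.0))):
        raise ValueError("recode requires integer allele counts in {0,1,2}; "
                         "round dosages first")
    if scheme.mode == EncodingScheme.DOMINANT:
        v = np.minimum(v, 1.0)
    return replace(g, values=v.copy())


# ---------------------------------------------------------------------------
# LD pruning


def ld_prune(g: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_threshold: float = 0.9, per_chromosome: bool = True) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on squared Pearson correlation.

    Mirrors PLINK ``--indep-pairwise window step threshold`` semantics: within
    each window of ``window`` SNPs (shifted by ``step``), every retained pair
    with r^2 above the threshold loses its later-index member.  Monomorphic
    SNPs are excluded from r^2 computation and retained with a warning.
    Deterministic; pruning runs per chromosome by default.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must be in (0, 1]")

    keep_mask = np.ones(g.n_snps, dtype=bool)
    if per_chromosome:
        groups = [np.flatnonzero(g.chrom == c) for c in pd.unique(g.chrom)]
    else:
        groups = [np.arange(g.n_snps)]
    v = g.values
    warned = False
    for idx in groups:
        mono = np.std(v[:, idx], axis=0) == 0
        if np.any(mono) and not warned:
            warnings.warn("monomorphic SNPs retained; excluded from r^2 pruning")
            warned = True
        removed = np.zeros(len(idx), dtype=bool)
        start = 0
        while True:
            win = np.arange(start, min(start + window, len(idx)))
            active = win[~removed[win] & ~mono[win]]
            if len(active) >= 2:
                sub = v[:, idx[active]]
                r = np.corrcoef(sub, rowvar=False)
                r2 = r * r
                for a in range(len(active)):
                    if removed[active[a]]:
                        continue
                    for b in range(a + 1, len(active)):
                        if removed[active[b]]:
                            continue
                        if r2[a, b] > r2_threshold:
                            removed[active[b]] = True
            if win[-1] >= len(idx) - 1:
                break
            start += step
        keep_mask[idx[removed]] = False
    return g.take_snps(np.flatnonzero(keep_mask))


# ---------------------------------------------------------------------------
# covariate stratification


def stratify(g: GenotypeMatrix, y: PhenotypeVector, covariate,
             rule: str = "binary-label") -> StratifiedCohort:
    """Split the cohort into two covariate-defined strata.

    ``binary-label`` requires exactly two distinct covariate values;
    ``median-split`` sends values <= median (ties included) to stratum 1.
    """
    cov = np.asarray(covariate)
    if cov.shape[0] != g.n_samples:
        raise ValueError("covariate length must equal sample count")
    if rule == "binary-label":
        levels = pd.unique(cov)
        if len(levels) != 2:
            raise ValueError(f"binary-label needs exactly 2 labels, got {len(levels)}")
        masks = [cov == levels[0], cov == levels[1]]
        labels = [str(levels[0]), str(levels[1])]
    elif rule == "median-split":
        med = float(np.median(cov.astype(float)))
        masks = [cov.astype(float) <= med, cov.astype(float) > med]
        labels = [f"<= {med:g}", f"> {med:g}"]
    else:
        raise ValueError(f"unknown stratification rule: {rule!r}")
    if any(not np.any(m) for m in masks):
        raise ValueError("stratification produced an empty stratum")
    strata = [(g.take_samples(np.flatnonzero(m)), y.take(np.flatnonzero(m)))
              for m in masks]
    return StratifiedCohort(strata, labels)
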