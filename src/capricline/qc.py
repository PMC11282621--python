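"""Genotype quality control: SNP/individual filters and subsampling.

The filter battery mirrors standard SNP-array QC for diversity studies:
individuals with high missing-call rates go first, then SNPs that are
unmapped, poorly called, rare (MAF), or out of Hardy-Weinberg proportions
under the conditional exact test.  Because survivor counts depend on the
order in which criteria are applied, the order is fixed and each
criterion's removals are reported separately.

``representative_subsample`` reduces an over-sampled breed to a target
size while preserving the breed's genotype covariance structure on its top
principal axes (a seeded greedy-swap search); breeds at or below the
target are returned whole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import yaml

from .io import MISSING, GenotypeMatrix

__all__ = [
    "QcConfig",
    "QcReport",
    "hwe_exact_test",
    "filter_variants",
    "representative_subsample",
]


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for the SNP/individual filter battery.

    ``maf_min``
        drop SNPs with minor allele frequency strictly below this (0.05).
    ``snp_missing_max``
        drop SNPs with missing call rate strictly above this (0.05).
    ``hwe_alpha``
        drop SNPs whose Hardy-Weinberg exact p-value is <= this (0.001);
        0 disables the test.
    ``ind_missing_max``
        drop individuals with missing call rate strictly above this (0.1).
    ``drop_unmapped``
        drop SNPs without a genomic position.
    ``subsample_min``/``subsample_max``
        target range of individuals kept per breed when subsampling.
    """

    maf_min: float = 0.05
    snp_missing_max: float = 0.05
    hwe_alpha: float = 0.001
    ind_missing_max: float = 0.1
    drop_unmapped: bool = True
    subsample_min: int = 15
    subsample_max: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_missing_max", "hwe_alpha", "ind_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.subsample_min > self.subsample_max:
            raise ValueError("subsample_min > subsample_max")

    @classmethod
    def from_yaml(cls, path) -> "QcConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc.get("qc", doc))


@dataclass
class QcReport:
    """Removal counts per criterion, in application order."""

    n_individuals_in: int = 0
    n_snps_in: int = 0
    n_ind_missing: int = 0
    n_unmapped: int = 0
    n_snp_missing: int = 0
    n_maf: int = 0
    n_hwe: int = 0
    n_individuals_out: int = 0
    n_snps_out: int = 0
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def as_text(self) -> str:
        lines = [
            f"individuals: {self.n_individuals_in} in, "
            f"{self.n_ind_missing} removed (missing rate), {self.n_individuals_out} out",
            f"SNPs: {self.n_snps_in} in; removed {self.n_unmapped} unmapped, "
            f"{self.n_snp_missing} missingness, {self.n_maf} MAF, {self.n_hwe} HWE; "
            f"{self.n_snps_out} out",
        ]
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity) whose conditional probability
    does not exceed that of the observed count — the probability-ordering
    ("exact") definition conventional in SNP QC, without mid-p correction.

    Returns a p-value in (0, 1].
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_ab  # copies of the rarer-or-not allele a
    n_b = 2 * n_bb + n_ab
    # heterozygote counts share the parity of min(n_a, n_b)
    n_minor = min(n_a, n_b)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = _log_het_prob(hets, n, n_a)
    obs = _log_het_prob(np.array([n_ab]), n, n_a)[0]
    # tolerate rounding when comparing equal log-probabilities
    keep = logp <= obs + 1e-10
    # normalize within the conditional distribution
    m = logp.max()
    probs = np.exp(logp - m)
    return float(min(1.0, probs[keep].sum() / probs.sum()))


def _log_het_prob(n_ab: np.ndarray, n: int, n_a: int) -> np.ndarray:
    """Log of the (unnormalized) conditional probability of n_ab heterozygotes."""
    n_b = 2 * n - n_a
    n_aa = (n_a - n_ab) // 2
    n_bb = (n_b - n_ab) // 2
    lf = math.lgamma
    num = lf(n + 1) + n_ab * math.log(2.0)
    den = np.array(
        [lf(a + 1) + lf(h + 1) + lf(b + 1) for a, h, b in zip(n_aa, n_ab, n_bb)]
    )
    return num - den


def _genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus counts of (0, 1, 2) codes, ignoring missing."""
    n0 = (calls == 0).sum(axis=0)
    n1 = (calls == 1).sum(axis=0)
    n2 = (calls == 2).sum(axis=0)
    return n0, n1, n2


def filter_variants(
    gm: GenotypeMatrix, config: QcConfig | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the individual and SNP filters; return survivors and a report.

    Individuals with missing rate above ``ind_missing_max`` are removed
    first; SNP criteria (unmapped, missingness, MAF, HWE) are then
    evaluated sequentially on the reduced matrix with all retained
    individuals pooled.  Removing every SNP yields an empty matrix with a
    warning, not an error.
    """
    config = config or QcConfig()
    if gm.n_individuals == 0 or gm.n_snps == 0:
        raise ValueError("empty genotype matrix")
    report = QcReport(n_individuals_in=gm.n_individuals, n_snps_in=gm.n_snps)

    miss_rate_ind = (gm.calls == MISSING).mean(axis=1)
    keep_ind = np.flatnonzero(miss_rate_ind <= config.ind_missing_max)
    report.n_ind_missing = gm.n_individuals - keep_ind.size
    gm = gm.take_individuals(keep_ind)
    report.n_individuals_out = gm.n_individuals
    if gm.n_individuals == 0:
        report.warnings.append("all individuals removed")
        report.n_snps_out = gm.n_snps
        return gm, report

    alive = np.ones(gm.n_snps, dtype=bool)

    if config.drop_unmapped:
        unmapped = np.array([not s.mapped for s in gm.snps])
        report.n_unmapped = int((alive & unmapped).sum())
        alive &= ~unmapped

    miss_rate_snp = (gm.calls == MISSING).mean(axis=0)
    fail = alive & (miss_rate_snp > config.snp_missing_max)
    report.n_snp_missing = int(fail.sum())
    alive &= ~fail

    n0, n1, n2 = _genotype_counts(gm.calls)
    n_called = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p_b = np.where(n_called > 0, (n1 + 2 * n2) / (2 * n_called), np.nan)
    maf = np.fmin(p_b, 1.0 - p_b)
    fail = alive & ((np.isnan(maf)) | (maf < config.maf_min))
    report.n_maf = int(fail.sum())
    alive &= ~fail

    if config.hwe_alpha > 0.0:
        fail = np.zeros(gm.n_snps, dtype=bool)
        for j in np.flatnonzero(alive):
            if n_called[j] == 0:
                fail[j] = True
                continue
            fail[j] = hwe_exact_test(int(n0[j]), int(n1[j]), int(n2[j])) <= config.hwe_alpha
        report.n_hwe = int(fail.sum())
        alive &= ~fail

    gm = gm.take_snps(np.flatnonzero(alive))
    report.n_snps_out = gm.n_snps
    if gm.n_snps == 0:
        report.warnings.append("all SNPs removed")
    return gm, report


def _prepare_projection(calls: np.ndarray, n_axes: int) -> np.ndarray:
    """Mean-impute, center and project a breed's calls onto its top axes."""
    x = calls.astype(float)
    x[calls == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    x = np.where(np.isnan(x), mu, x) - mu
    k = min(n_axes, min(x.shape) - 1) or 1
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    return x @ vt[:k].T


def _cov_objective(y: np.ndarray, subset: np.ndarray, full_cov: np.ndarray) -> float:
    sub_cov = np.cov(y[subset], rowvar=False, ddof=0)
    return float(np.linalg.norm(sub_cov - full_cov, ord="fro"))


def representative_subsample(
    gm: GenotypeMatrix,
    breed_id: str,
    target_n: int,
    seed: int,
    n_axes: int = 10,
    max_passes: int = 500,
) -> np.ndarray:
    """Pick ``target_n`` individuals of a breed preserving its covariance.

    The subsample minimizes the Frobenius distance between the subsample's
    and the full breed's genotype covariance on the breed's top ``n_axes``
    principal axes, via greedy swap refinement from a seeded random start.
    Deterministic for a fixed seed.  Returns indices into ``gm.individuals``.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    members = np.array(
        [i for i, (_, b) in enumerate(gm.individuals) if b == breed_id]
    )
    if members.size == 0:
        raise KeyError(f"unknown breed_id {breed_id!r}")
    if members.size <= target_n:
        return members

    y = _prepare_projection(gm.calls[members], n_axes)
    full_cov = np.cov(y, rowvar=False, ddof=0)
    rng = np.random.default_rng(seed)
    n = members.size
    selected = rng.choice(n, size=target_n, replace=False)
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    best = _cov_objective(y, np.flatnonzero(in_set), full_cov)

    for _ in range(max_passes):
        improved = False
        for i in np.flatnonzero(in_set):
            for j in np.flatnonzero(~in_set):
                in_set[i], in_set[j] = False, True
                obj = _cov_objective(y, np.flatnonzero(in_set), full_cov)
                if obj < best - 1e-12:
                    best = obj
                    improved = True
                    break
                in_set[i], in_set[j] = True, False
            else:
                continue
            break
        if not improved:
            break
    return members[np.flatnonzero(in_set)]
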