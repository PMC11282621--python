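"""Per-population diversity statistics and two-population Fst.

Observed heterozygosity (Ho) is the per-locus fraction of heterozygous
genotypes averaged over loci; expected heterozygosity (He) is Nei's
unbiased gene diversity, 2n/(2n-1) * 2p(1-p) per locus.  Their contrast
Fis = 1 - Ho/He is positive under an excess of homozygotes (inbreeding)
and negative under a deficit (e.g. recent admixture).  Differentiation
between two populations is Weir & Cockerham's (1984) theta, combined
across loci as the ratio of summed variance components.

All statistics use locus-wise non-missing counts; nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = [
    "PopStatResult",
    "FstResult",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "fis_from_het",
    "pairwise_fst",
    "population_stats",
    "diversity_from_genotypes",
    "summarize_diversity",
]


@dataclass(frozen=True)
class PopStatResult:
    """Ho, He and Fis for one population."""

    breed_id: str
    ho: float
    he: float
    fis: float
    n_loci_used: int
    n_individuals: int


@dataclass(frozen=True)
class FstResult:
    """Weir-Cockerham theta for one population against a reference."""

    breed_id: str
    reference_id: str
    theta: float
    n_loci_used: int


def _as_float_masked(calls: np.ndarray) -> np.ndarray:
    x = np.asarray(calls, dtype=float)
    x[np.asarray(calls) == MISSING] = np.nan
    return x


def observed_heterozygosity(calls: np.ndarray) -> float:
    """Mean over loci of the fraction of non-missing genotypes that are het.

    Loci with no non-missing call are skipped; if no locus is usable an
    error is raised.
    """
    calls = np.atleast_2d(np.asarray(calls))
    het = (calls == 1).sum(axis=0)
    n_called = (calls != MISSING).sum(axis=0)
    usable = n_called > 0
    if not usable.any():
        raise ValueError("no loci with a non-missing call")
    return float((het[usable] / n_called[usable]).mean())


def expected_heterozygosity(calls: np.ndarray) -> float:
    """Nei's unbiased gene diversity averaged over usable loci.

    Per locus with n genotyped individuals and counted-allele frequency p:
    he = 2n/(2n-1) * 2p(1-p).  Loci with fewer than one genotype (2n < 2)
    are skipped.
    """
    x = _as_float_masked(np.atleast_2d(np.asarray(calls)))
    n_called = np.sum(~np.isnan(x), axis=0)
    usable = n_called >= 1
    if not usable.any():
        raise ValueError("no loci with a non-missing call")
    with np.errstate(invalid="ignore"):
        p = np.nanmean(x, axis=0) / 2.0
    n = n_called[usable].astype(float)
    pq = 2.0 * p[usable] * (1.0 - p[usable])
    he = (2.0 * n / (2.0 * n - 1.0)) * pq
    return float(he.mean())


def fis_from_het(ho: float, he: float) -> float:
    """Inbreeding coefficient Fis = 1 - Ho/He (undefined at He = 0)."""
    if he <= 0.0:
        raise ValueError("undefined Fis: He = 0")
    return 1.0 - ho / he


def _locus_components(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham a, b, c variance components per locus (r = 2 pops).

    Follows the 1984 estimator with sample sizes n_i, allele frequencies
    p_i and observed het proportions h_i per population.  Loci where either
    population has no genotypes, or that are monomorphic across both
    populations, come back as NaN and are excluded by the caller.
    """
    xa, xb = _as_float_masked(calls_a), _as_float_masked(calls_b)
    n1 = np.sum(~np.isnan(xa), axis=0).astype(float)
    n2 = np.sum(~np.isnan(xb), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.nanmean(xa, axis=0) / 2.0
        p2 = np.nanmean(xb, axis=0) / 2.0
        h1 = np.sum(xa == 1.0, axis=0) / n1
        h2 = np.sum(xb == 1.0, axis=0) / n2

        r = 2.0
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    invalid = (n1 < 1) | (n2 < 1) | (n_bar <= 1.0)
    mono = (p_bar <= 0.0) | (p_bar >= 1.0)
    for arr in (a, b, c):
        arr[invalid | mono] = np.nan
    return a, b, c


def pairwise_fst(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    breed_id: str = "A",
    reference_id: str = "B",
) -> FstResult:
    """Weir-Cockerham theta between two populations, combined across loci.

    theta = sum(a) / sum(a + b + c) over loci polymorphic in the pooled
    pair; slightly negative values are possible by construction.  Both
    populations need at least two individuals and two usable loci.
    """
    calls_a = np.atleast_2d(np.asarray(calls_a))
    calls_b = np.atleast_2d(np.asarray(calls_b))
    if calls_a.shape[0] < 2 or calls_b.shape[0] < 2:
        raise ValueError("both populations need >= 2 individuals")
    a, b, c = _locus_components(calls_a, calls_b)
    usable = ~np.isnan(a)
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable (polymorphic) loci")
    denom = np.nansum(a[usable] + b[usable] + c[usable])
    theta = float(np.nansum(a[usable]) / denom)
    return FstResult(breed_id, reference_id, theta, int(usable.sum()))


def population_stats(
    gm: GenotypeMatrix, breed_id: str, locus_weighted_fis: bool = False
) -> PopStatResult:
    """Ho, He and Fis for one breed of a genotype matrix.

    By default Fis is the aggregate 1 - (mean Ho)/(mean He); with
    ``locus_weighted_fis`` it is instead 1 - sum(ho_l)/sum(he_l) over loci,
    which weights loci by their diversity.
    """
    calls = gm.breed_calls(breed_id)
    ho = observed_heterozygosity(calls)
    he = expected_heterozygosity(calls)
    if locus_weighted_fis:
        fis = _locus_weighted_fis(calls)
    else:
        fis = fis_from_het(ho, he)
    n_loci = int(((calls != MISSING).sum(axis=0) > 0).sum())
    return PopStatResult(breed_id, ho, he, fis, n_loci, calls.shape[0])


def _locus_weighted_fis(calls: np.ndarray) -> float:
    x = _as_float_masked(calls)
    n = np.sum(~np.isnan(x), axis=0).astype(float)
    usable = n >= 1
    with np.errstate(invalid="ignore"):
        p = np.nanmean(x, axis=0) / 2.0
    ho_l = np.sum(x == 1.0, axis=0)[usable] / n[usable]
    he_l = (2 * n[usable] / (2 * n[usable] - 1)) * 2 * p[usable] * (1 - p[usable])
    tot_he = he_l.sum()
    if tot_he <= 0:
        raise ValueError("undefined Fis: He = 0 at every locus")
    return float(1.0 - ho_l.sum() / tot_he)


def diversity_from_genotypes(
    gm: GenotypeMatrix,
    reference_id: str | None = "IRA_KUR",
    locus_weighted_fis: bool = False,
) -> pd.DataFrame:
    """Per-breed diversity table (ho, he, fis, fst_vs_ref) for a matrix.

    Fst is computed against ``reference_id`` when that breed is present
    (absent for the reference itself); pass ``None`` to skip Fst.
    """
    rows = []
    ref_calls = None
    if reference_id is not None and reference_id in gm.breed_ids:
        ref_calls = gm.breed_calls(reference_id)
    for bid in gm.breed_ids:
        s = population_stats(gm, bid, locus_weighted_fis=locus_weighted_fis)
        fst = np.nan
        if ref_calls is not None and bid != reference_id:
            fst = pairwise_fst(gm.breed_calls(bid), ref_calls, bid, reference_id).theta
        rows.append(
            {
                "breed_id": bid,
                "ho": s.ho,
                "he": s.he,
                "fis": s.fis,
                "fst_vs_ref": fst,
                "f_roh": np.nan,
                "distance_km": np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_diversity(
    table: pd.DataFrame, subset: list[str] | None = None
) -> dict[str, float]:
    """Unweighted means of ho, he and fis over a breed subset."""
    if subset is not None:
        if not subset:
            raise ValueError("empty subset")
        missing = set(subset) - set(table["breed_id"])
        if missing:
            raise KeyError(f"unknown breed ids {sorted(missing)}")
        table = table[table["breed_id"].isin(subset)]
    if table.empty:
        raise ValueError("empty subset")
    return {
        "ho": float(table["ho"].mean()),
        "he": float(table["he"].mean()),
        "fis": float(table["fis"].mean()),
    }
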