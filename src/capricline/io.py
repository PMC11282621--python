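"""Genotype and table input/output.

Genotypes travel as PLINK text PED/MAP pairs (whitespace-delimited, ``0`` =
missing allele).  In memory they become a :class:`GenotypeMatrix`: an
individuals x SNPs array of biallelic dosage codes counting copies of
``allele_b``, with ``MISSING`` (-1) for no-calls.  ``allele_b`` is always
the lexicographically later of the two observed alleles, so the coding is
deterministic and independent of file order; every downstream statistic
(Ho, He, Fis, Fst) is invariant to which allele is counted.

Breed metadata and per-breed diversity statistics are plain pandas
DataFrames serialized as CSV; absent values (printed "-" in the source
tables) are empty fields / NaN and round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeMatrix",
    "PedMapError",
    "read_ped_map",
    "write_ped_map",
    "read_diversity_table",
    "write_diversity_table",
    "DIVERSITY_COLUMNS",
    "BREED_COLUMNS",
]

#: Missing-genotype code in a calls matrix.
MISSING: int = -1

#: Column contract for diversity tables (per-breed statistics).
DIVERSITY_COLUMNS = ("breed_id", "ho", "he", "fis", "fst_vs_ref", "f_roh", "distance_km")

#: Column contract for breed metadata tables.
BREED_COLUMNS = ("breed_id", "breed_name", "country", "subregion", "lon", "lat", "n")


class PedMapError(ValueError):
    """Malformed PED/MAP input."""


@dataclass(frozen=True)
class SnpRecord:
    """One array SNP: identity, map position and the two alleles.

    ``allele_b`` is the counted allele (dosage 2 = homozygous allele_b);
    ``mapped`` is False for SNPs without a genomic position (chromosome
    ``0`` in the MAP file), which QC can drop.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    mapped: bool = True

    def __post_init__(self) -> None:
        if self.mapped and self.pos < 1:
            raise ValueError(f"{self.snp_id}: mapped SNP needs pos >= 1, got {self.pos}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs biallelic dosage matrix with breed labels.

    ``calls[i, j]`` counts copies of ``snps[j].allele_b`` carried by
    individual ``i`` (0, 1, 2) or :data:`MISSING`.
    """

    individuals: list[tuple[str, str]]  # (individual_id, breed_id)
    snps: list[SnpRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.individuals)}, {len(self.snps)})"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid call codes: {np.unique(self.calls[bad])}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def breed_ids(self) -> list[str]:
        """Unique breed ids in order of first appearance."""
        seen: dict[str, None] = {}
        for _, b in self.individuals:
            seen.setdefault(b)
        return list(seen)

    def breed_calls(self, breed_id: str) -> np.ndarray:
        """Calls submatrix for one breed (view)."""
        idx = [i for i, (_, b) in enumerate(self.individuals) if b == breed_id]
        if not idx:
            raise KeyError(f"unknown breed_id {breed_id!r}")
        return self.calls[idx]

    def take_individuals(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            [self.individuals[i] for i in idx], self.snps, self.calls[idx]
        )

    def take_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            self.individuals, [self.snps[j] for j in idx], self.calls[:, idx]
        )


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeMatrix`.

    The PED family-id column is taken as the breed id.  ``0`` alleles decode
    to :data:`MISSING`; the counted allele at each SNP is the
    lexicographically later of the two observed alleles.  A site with more
    than two observed alleles raises :class:`PedMapError` naming the SNP;
    a row of the wrong length raises naming the line.
    """
    map_path, ped_path = Path(map_path), Path(ped_path)

    snp_meta: list[tuple[str, str, int]] = []
    for ln, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise PedMapError(f"{map_path.name}:{ln}: expected 4 columns, got {len(parts)}")
        chrom, snp_id, _cm, pos = parts
        snp_meta.append((snp_id, chrom, int(pos)))
    if not snp_meta:
        raise PedMapError(f"{map_path.name}: no SNPs")
    n_snps = len(snp_meta)

    individuals: list[tuple[str, str]] = []
    allele_rows: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise PedMapError(
                f"{ped_path.name}:{ln}: expected {6 + 2 * n_snps} columns "
                f"for {n_snps} SNPs, got {len(parts)}"
            )
        fam, iid = parts[0], parts[1]
        individuals.append((iid, fam))
        alleles = parts[6:]
        allele_rows.append(
            [(alleles[2 * j], alleles[2 * j + 1]) for j in range(n_snps)]
        )

    snps: list[SnpRecord] = []
    calls = np.full((len(individuals), n_snps), MISSING, dtype=np.int8)
    for j, (snp_id, chrom, pos) in enumerate(snp_meta):
        observed = sorted(
            {a for row in allele_rows for a in row[j] if a != "0"}
        )
        if len(observed) > 2:
            raise PedMapError(f"SNP {snp_id}: more than two alleles {observed}")
        if len(observed) == 2:
            allele_a, allele_b = observed  # sorted: b is lexicographically later
        elif len(observed) == 1:
            allele_a, allele_b = "0", observed[0]  # monomorphic; count the sole allele
        else:
            allele_a, allele_b = "0", "N"  # fully missing site
        mapped = chrom != "0" and pos >= 1
        snps.append(SnpRecord(snp_id, chrom, pos if mapped else 0, allele_a, allele_b, mapped))
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue  # any missing allele -> missing genotype
            calls[i, j] = (a1 == allele_b) + (a2 == allele_b)
    return GenotypeMatrix(individuals, snps, calls)


def write_ped_map(
    gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a :class:`GenotypeMatrix` as a PLINK text PED/MAP pair."""
    with open(map_path, "w") as fh:
        for s in gm.snps:
            chrom = s.chrom if s.mapped else "0"
            pos = s.pos if s.mapped else 0
            fh.write(f"{chrom}\t{s.snp_id}\t0\t{pos}\n")
    with open(ped_path, "w") as fh:
        for i, (iid, fam) in enumerate(gm.individuals):
            fields = [fam, iid, "0", "0", "0", "-9"]
            for j, s in enumerate(gm.snps):
                c = gm.calls[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [s.allele_a, s.allele_a]
                elif c == 1:
                    fields += [s.allele_a, s.allele_b]
                else:
                    fields += [s.allele_b, s.allele_b]
            fh.write(" ".join(fields) + "\n")


def write_diversity_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a diversity table as CSV; absent values become empty fields."""
    missing = [c for c in ("breed_id",) if c not in table.columns]
    if missing:
        raise ValueError(f"diversity table lacks columns {missing}")
    table.to_csv(path, index=False, na_rep="")


def read_diversity_table(path: str | Path) -> pd.DataFrame:
    """Read a diversity table CSV; empty fields come back as NaN (absent)."""
    df = pd.read_csv(path)
    if "breed_id" not in df.columns:
        raise ValueError(f"{path}: not a diversity table (no breed_id column)")
    df["breed_id"] = df["breed_id"].astype(str)
    return df
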