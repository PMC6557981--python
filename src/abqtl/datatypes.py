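"""Core in-memory containers for advanced-backcross QTL analysis.

The whole package works in genetic (cM) coordinates on the 21 hexaploid
wheat chromosomes (1A..7A, 1B..7B, 1D..7D) and on a single genotype coding:

    0 = missing call
    1 = homozygous cultivated / recurrent-parent allele (CC)
    2 = heterozygous
    3 = homozygous exotic / donor allele (EE)

Every reader, simulator and statistic goes through these containers, so the
coding and coordinate conventions are defined exactly once, here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Genotype codes
MISSING = 0
CC = 1  # homozygous cultivated
HET = 2
EE = 3  # homozygous exotic
VALID_CODES = frozenset({MISSING, CC, HET, EE})

GENOMES = ("A", "B", "D")
#: Canonical chromosome order: genome-major (1A..7A, 1B..7B, 1D..7D).
CHROMOSOMES = tuple(f"{n}{g}" for g in GENOMES for n in range(1, 8))
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


def genome_of(chromosome: str) -> str:
    """Return the genome letter (A/B/D) of a chromosome label like '3D'."""
    if chromosome not in _CHROM_RANK:
        raise ValidationError(
            f"unknown chromosome {chromosome!r}; expected one of 1A..7D"
        )
    return chromosome[-1]


def chromosome_sort_key(chromosome: str) -> int:
    """Rank of a chromosome in the canonical 1A..7A,1B..7B,1D..7D order."""
    if chromosome not in _CHROM_RANK:
        raise ValidationError(f"unknown chromosome {chromosome!r}")
    return _CHROM_RANK[chromosome]


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: one row per marker with chromosome and cM position.

    ``frame`` has columns ``marker``, ``chrom``, ``pos_cM`` and is sorted by
    (chromosome in canonical order, position). Positions are genetic
    coordinates only; no physical (bp) coordinates exist in this package.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = ["marker", "chrom", "pos_cM"]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"map is missing columns {missing_cols}")
        if df["marker"].duplicated().any():
            dups = df["marker"][df["marker"].duplicated()].tolist()
            raise ValidationError(f"duplicate marker ids in map: {dups[:5]}")
        bad = sorted(set(df["chrom"]) - set(CHROMOSOMES))
        if bad:
            raise ValidationError(f"unknown chromosome labels in map: {bad}")
        if (df["pos_cM"] < 0).any() or not np.isfinite(df["pos_cM"]).all():
            raise ValidationError("map positions must be finite and >= 0 cM")
        for chrom, grp in df.groupby("chrom", sort=False):
            if not grp["pos_cM"].is_monotonic_increasing:
                raise ValidationError(
                    f"positions on chromosome {chrom} are not non-decreasing"
                )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneticMap":
        """Build a map from any (marker, chrom, pos_cM) frame, sorting it
        into canonical order first."""
        df = frame.loc[:, ["marker", "chrom", "pos_cM"]].copy()
        df["marker"] = df["marker"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos_cM"] = df["pos_cM"].astype(float)
        df["_rank"] = df["chrom"].map(_CHROM_RANK)
        if df["_rank"].isna().any():
            bad = sorted(set(df.loc[df["_rank"].isna(), "chrom"]))
            raise ValidationError(f"unknown chromosome labels in map: {bad}")
        df = (
            df.sort_values(["_rank", "pos_cM", "marker"], kind="mergesort")
            .drop(columns="_rank")
            .reset_index(drop=True)
        )
        return cls(df)

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.frame["marker"])

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosomes present, in canonical order."""
        present = set(self.frame["chrom"])
        return [c for c in CHROMOSOMES if c in present]

    def chromosome_table(self, chrom: str) -> pd.DataFrame:
        """Markers of one chromosome, ordered by position."""
        return self.frame[self.frame["chrom"] == chrom].reset_index(drop=True)

    def positions(self, chrom: str) -> np.ndarray:
        return self.chromosome_table(chrom)["pos_cM"].to_numpy()

    def position_of(self, marker: str) -> float:
        row = self.frame[self.frame["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not in map")
        return float(row["pos_cM"].iloc[0])

    def chromosome_of(self, marker: str) -> str:
        row = self.frame[self.frame["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not in map")
        return str(row["chrom"].iloc[0])


@dataclass
class GenotypeMatrix:
    """Line x marker genotype codes.

    ``codes`` is an integer DataFrame indexed by line id with one column per
    marker; entries are restricted to {0, 1, 2, 3}.
    """

    codes: pd.DataFrame

    def __post_init__(self) -> None:
        codes = self.codes
        if codes.index.duplicated().any():
            raise ValidationError("duplicate line ids in genotype matrix")
        if codes.columns.duplicated().any():
            raise ValidationError("duplicate marker ids in genotype matrix")
        values = codes.to_numpy()
        if values.size and not np.isin(values, list(VALID_CODES)).all():
            bad = np.argwhere(~np.isin(values, list(VALID_CODES)))
            i, j = bad[0]
            raise ValidationError(
                f"invalid genotype code {values[i, j]!r} for line "
                f"{codes.index[i]!r} at marker {codes.columns[j]!r}; "
                "allowed codes are 0 (missing), 1 (CC), 2 (het), 3 (EE)"
            )
        self.codes = codes.astype(np.int8)

    @property
    def lines(self) -> pd.Index:
        return self.codes.index

    @property
    def markers(self) -> pd.Index:
        return self.codes.columns

    @property
    def n_lines(self) -> int:
        return len(self.codes.index)

    def column(self, marker: str) -> pd.Series:
        """Per-line codes at one marker."""
        if marker not in self.codes.columns:
            raise KeyError(f"marker {marker!r} not genotyped")
        return self.codes[marker]


@dataclass
class PhenotypeTable:
    """Long-format multi-environment yield records.

    ``frame`` has columns ``line_id``, ``env_id``, ``yield_dt_ha`` (grain
    yield in decitons per hectare) and optionally ``rep`` for within-
    environment replicates.  (line, env[, rep]) keys are unique.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = ["line_id", "env_id", "yield_dt_ha"]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"phenotypes missing columns {missing_cols}")
        key = ["line_id", "env_id"] + (["rep"] if "rep" in df.columns else [])
        if df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key)].iloc[0]
            raise ValidationError(
                f"duplicate phenotype record for line {dup['line_id']!r} "
                f"in environment {dup['env_id']!r}"
            )
        if not np.isfinite(df["yield_dt_ha"].to_numpy(float)).all():
            raise ValidationError("yield values must be finite")

    @property
    def lines(self) -> pd.Index:
        return pd.Index(self.frame["line_id"].unique())

    @property
    def environments(self) -> pd.Index:
        return pd.Index(self.frame["env_id"].unique())

    @property
    def n_environments(self) -> int:
        return self.frame["env_id"].nunique()

    def line_means(self) -> pd.Series:
        """Per-line mean yield across environments (dt/ha)."""
        return self.frame.groupby("line_id")["yield_dt_ha"].mean()

    def to_matrix(self) -> pd.DataFrame:
        """Pivot to a line x environment matrix (NaN where unobserved).

        Requires at most one record per (line, environment); replicated
        designs must be averaged or analysed long-format.
        """
        if "rep" in self.frame.columns and self.frame["rep"].nunique() > 1:
            raise ValidationError(
                "replicated phenotypes cannot be pivoted to a line x "
                "environment matrix"
            )
        return self.frame.pivot(
            index="line_id", columns="env_id", values="yield_dt_ha"
        )


@dataclass
class Dataset:
    """A matched (map, genotypes, phenotypes) triple ready for scanning."""

    map: GeneticMap
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable

    def __post_init__(self) -> None:
        unknown = set(self.genotypes.markers) - set(self.map.markers)
        if unknown:
            name = sorted(unknown)[0]
            raise ValidationError(
                f"genotyped marker {name!r} is absent from the genetic map"
                + (f" (and {len(unknown) - 1} more)" if len(unknown) > 1 else "")
            )
        orphan = set(self.phenotypes.lines) - set(self.genotypes.lines)
        if orphan:
            name = sorted(orphan)[0]
            raise ValidationError(
                f"phenotyped line {name!r} is absent from the genotype matrix"
            )
        if self.phenotypes.n_environments < 1:
            raise ValidationError("phenotypes cover no environment")
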