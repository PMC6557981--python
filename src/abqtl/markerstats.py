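"""Per-genome marker summaries: counts, density per cM, recombination rate.

The recombination-rate estimator is deliberately transparent rather than
likelihood-based: for every adjacent marker pair on a chromosome and every
line where both calls are homozygous (codes 1 or 3), the pair is counted as
recombinant iff the two codes differ, and the genome rate is
100 * recombinant / informative pairs.  Heterozygous and missing calls are
phase-ambiguous at the pair level and are skipped.  This observed-fraction
proxy has an exact brute-force oracle under the simulator's pedigree; it is
not the multipoint estimator of mapping packages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    GENOMES,
    GeneticMap,
    GenotypeMatrix,
    ValidationError,
    genome_of,
)

__all__ = ["GenomeSummary", "genome_marker_stats", "recombination_rate"]


@dataclass(frozen=True)
class GenomeSummary:
    """Marker bookkeeping for one genome (A, B or D)."""

    genome: str
    n_markers: int
    map_length_cM: float
    density_per_cM: float  # NaN when undefined
    density_defined: bool


def genome_marker_stats(gmap: GeneticMap) -> list[GenomeSummary]:
    """Marker count, observed map length and density per genome.

    Map length is the sum over chromosomes of the observed marker span
    (max - min position); a genome whose chromosomes all carry a single
    marker has zero length and its density is flagged undefined rather
    than reported as infinity.
    """
    if gmap.n_markers == 0:
        raise ValidationError("empty map")
    df = gmap.frame.assign(genome=gmap.frame["chrom"].map(genome_of))
    out = []
    for genome in GENOMES:
        sub = df[df["genome"] == genome]
        if sub.empty:
            continue
        span = sub.groupby("chrom")["pos_cM"].agg(lambda s: s.max() - s.min())
        length = float(span.sum())
        n = int(len(sub))
        if length > 0:
            out.append(GenomeSummary(genome, n, length, n / length, True))
        else:
            out.append(GenomeSummary(genome, n, length, math.nan, False))
    return out


def recombination_rate(
    genotypes: GenotypeMatrix, gmap: GeneticMap
) -> pd.DataFrame:
    """Percent recombination per genome from adjacent homozygous pairs.

    Returns a frame indexed by genome with columns ``n_informative``,
    ``n_recombinant``, ``rate_percent`` and ``rate_defined``; a genome with
    no informative pair gets NaN and ``rate_defined=False``.
    """
    counts = {g: [0, 0] for g in GENOMES}  # genome -> [informative, recombinant]
    for chrom in gmap.chromosomes:
        markers = gmap.chromosome_table(chrom)["marker"]
        present = [m for m in markers if m in genotypes.markers]
        if len(present) < 2:
            continue
        codes = genotypes.codes[present].to_numpy()
        hom = (codes == 1) | (codes == 3)
        informative = hom[:, :-1] & hom[:, 1:]
        recombinant = informative & (codes[:, :-1] != codes[:, 1:])
        g = genome_of(chrom)
        counts[g][0] += int(informative.sum())
        counts[g][1] += int(recombinant.sum())
    rows = []
    for g in GENOMES:
        inf, rec = counts[g]
        rate = 100.0 * rec / inf if inf else math.nan
        rows.append((g, inf, rec, rate, inf > 0))
    return pd.DataFrame(
        rows,
        columns=["genome", "n_informative", "n_recombinant", "rate_percent",
                 "rate_defined"],
    ).set_index("genome")


def summary_table(gmap: GeneticMap, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Combined per-genome table of counts, density and recombination rate."""
    stats = {s.genome: s for s in genome_marker_stats(gmap)}
    rec = recombination_rate(genotypes, gmap)
    rows = []
    for g, s in stats.items():
        rate = rec.loc[g, "rate_percent"] if g in rec.index else math.nan
        rows.append(
            (g, s.n_markers, s.map_length_cM, s.density_per_cM, rate)
        )
    return pd.DataFrame(
        rows,
        columns=["genome", "n_markers", "map_length_cM", "density_per_cM",
                 "recomb_rate_percent"],
    )
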