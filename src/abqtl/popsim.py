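"""Synthetic advanced-backcross population and trial generator.

Simulates the data an AB-QTL grain-yield study produces but does not
deposit: BC2F3-style introgression lines obtained by explicit meiosis
(Haldane map function, no crossover interference) from a cross of a fully
homozygous elite recurrent parent with a fully homozygous exotic donor,
followed by repeated backcrossing to the elite parent and selfing; plus
multi-environment yield phenotypes with random environment, line-by-
environment and residual effects — the variance structure the marker-scan
model assumes, read forward.

Haplotypes are 0/1 arrays over the mapped markers of one chromosome
(0 = elite allele, 1 = exotic allele); genotype codes are 1 + the number of
exotic alleles (CC=1, het=2, EE=3).  With ``n_backcrosses = b`` and
``n_selfings = s`` the expected single-locus exotic allele frequency is
(1/2)^(b+1) and the expected residual heterozygosity is (1/2)^(b+s) — for
the BC2F3 design (b=2, s=2): 12.5% exotic alleles, 6.25% heterozygotes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CHROMOSOMES,
    GeneticMap,
    GenotypeMatrix,
    PhenotypeTable,
    ValidationError,
)

__all__ = [
    "CrossingScheme",
    "QTLEffect",
    "TrialDesign",
    "haldane_r",
    "simulate_gamete",
    "simulate_ab_population",
    "simulate_phenotypes",
    "mask_missing",
    "make_map",
]


@dataclass(frozen=True)
class CrossingScheme:
    """Population development plan: F1, then backcrosses, then selfings.

    The default (2 backcrosses, 2 selfings) derives one BC2F3 plant per
    line, the design of the advanced-backcross populations this package
    targets.
    """

    n_lines: int
    n_backcrosses: int = 2
    n_selfings: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValidationError("n_lines must be >= 1")
        if self.n_backcrosses < 0 or self.n_selfings < 0:
            raise ValidationError("generation counts must be >= 0")


@dataclass(frozen=True)
class QTLEffect:
    """An injected yield QTL at a mapped marker.

    ``additive_effect`` is the yield change (dt/ha) per exotic allele copy;
    ``dominance_effect`` is the extra deviation of heterozygotes.
    """

    marker_id: str
    additive_effect: float
    dominance_effect: float = 0.0


@dataclass(frozen=True)
class TrialDesign:
    """Multi-environment yield trial layout and variance components.

    Defaults describe a managed multi-site winter-wheat series: overall
    mean 74.5 dt/ha, environment SD 4 dt/ha, line-by-environment SD
    1.5 dt/ha, residual SD 3 dt/ha, five environments, one plot per line
    and environment.  ``n_reps`` > 1 adds within-environment replicate
    plots (for balanced-ANOVA cross-checks); field trials of this design
    have one plot per line per environment.
    """

    n_environments: int = 5
    mu: float = 74.5
    var_env: float = 16.0
    var_gxe: float = 2.25
    var_resid: float = 9.0
    seed: int = 0
    n_reps: int = 1

    def __post_init__(self) -> None:
        if self.n_environments < 2:
            raise ValidationError(
                "n_environments must be >= 2 (the scan model needs an "
                "environment stratum)"
            )
        if min(self.var_env, self.var_gxe, self.var_resid) < 0:
            raise ValidationError("variance components must be >= 0")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")


def haldane_r(d):
    """Haldane map function: cM distance -> recombination fraction.

    r = (1 - exp(-2 d / 100)) / 2, assuming no crossover interference.
    Accepts scalars or arrays; strictly increasing in d with asymptote 1/2.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("map distance must be >= 0 cM")
    r = 0.5 * (1.0 - np.exp(-2.0 * arr / 100.0))
    return float(r) if np.isscalar(d) or arr.ndim == 0 else r


def _meiosis(haps: np.ndarray, rec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual from an (n, 2, m) haplotype stack.

    ``rec`` holds the m-1 adjacent-interval recombination fractions.  Each
    gamete starts on a uniformly chosen parental haplotype and switches
    independently per interval with probability rec[i] (no interference).
    """
    n, _, m = haps.shape
    start = rng.integers(0, 2, size=(n, 1))
    if m == 1:
        chooser = start
    else:
        switches = rng.random((n, m - 1)) < rec
        chooser = (start + np.concatenate(
            [np.zeros((n, 1), dtype=np.int64), np.cumsum(switches, axis=1)],
            axis=1,
        )) % 2
    return haps[np.arange(n)[:, None], chooser, np.arange(m)[None, :]]


def simulate_gamete(
    haplotype_pair, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Draw one gamete from a plant's haplotype pair over one chromosome.

    ``haplotype_pair`` is a (2, m) array (or pair of length-m arrays) over
    the markers of the single chromosome in ``gmap``, in map order.
    """
    haps = np.asarray(haplotype_pair)
    if haps.shape[0] != 2 or haps.ndim != 2:
        raise ValidationError("haplotype_pair must be a (2, m) array")
    chroms = gmap.chromosomes
    if len(chroms) != 1:
        raise ValidationError("simulate_gamete expects a single-chromosome map")
    pos = gmap.positions(chroms[0])
    if haps.shape[1] != len(pos):
        raise ValidationError(
            f"haplotypes cover {haps.shape[1]} markers but the map has {len(pos)}"
        )
    rec = haldane_r(np.diff(pos)) if len(pos) > 1 else np.empty(0)
    return _meiosis(haps[None, :, :], rec, rng)[0]


def simulate_ab_population(
    gmap: GeneticMap, scheme: CrossingScheme, line_prefix: str = "L"
) -> GenotypeMatrix:
    """Simulate an advanced-backcross population over the whole map.

    Each line descends independently: F1 = elite x donor, then
    ``n_backcrosses`` rounds of crossing one gamete of the current plant to
    the (fully homozygous) elite parent, then ``n_selfings`` generations of
    selfing a single descendant.  Deterministic given ``scheme.seed``.
    """
    if gmap.n_markers == 0:
        raise ValidationError("cannot simulate from an empty map")
    rng = np.random.default_rng(scheme.seed)
    n = scheme.n_lines
    blocks = []
    marker_order = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        marker_order.extend(gmap.chromosome_table(chrom)["marker"].tolist())
        m = len(pos)
        rec = haldane_r(np.diff(pos)) if m > 1 else np.empty(0)
        # F1: one elite haplotype (0s), one donor haplotype (1s).
        haps = np.zeros((n, 2, m), dtype=np.int8)
        haps[:, 1, :] = 1
        for _ in range(scheme.n_backcrosses):
            gam = _meiosis(haps, rec, rng)
            haps = np.stack([gam, np.zeros_like(gam)], axis=1)
        for _ in range(scheme.n_selfings):
            gam1 = _meiosis(haps, rec, rng)
            gam2 = _meiosis(haps, rec, rng)
            haps = np.stack([gam1, gam2], axis=1)
        blocks.append(1 + haps.sum(axis=1, dtype=np.int8))
    codes = np.concatenate(blocks, axis=1)
    width = max(3, len(str(n)))
    lines = [f"{line_prefix}{i + 1:0{width}d}" for i in range(n)]
    return GenotypeMatrix(
        pd.DataFrame(codes, index=pd.Index(lines, name="line_id"),
                     columns=marker_order)
    )


def exotic_dose(codes) -> np.ndarray:
    """Exotic-allele count per genotype code: 1 -> 0, 2 -> 1, 3 -> 2.

    Missing calls (0) contribute no exotic dose.
    """
    arr = np.asarray(codes)
    return np.where(arr == 0, 0, arr - 1)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    effects: list[QTLEffect],
    design: TrialDesign,
) -> PhenotypeTable:
    """Generate multi-environment yield records for a simulated population.

    Y_ij = mu + sum_q (dose_iq * a_q + het_iq * d_q) + E_j + G_ij + eps,
    with E_j ~ N(0, var_env) per environment, G_ij ~ N(0, var_gxe) per
    (line, environment), eps ~ N(0, var_resid) per plot.  One record per
    (line, environment) unless ``design.n_reps`` > 1.
    """
    rng = np.random.default_rng(design.seed)
    codes = genotypes.codes
    genetic = np.full(genotypes.n_lines, design.mu, dtype=float)
    for eff in effects:
        if eff.marker_id not in codes.columns:
            raise KeyError(f"QTL effect marker {eff.marker_id!r} is not genotyped")
        col = codes[eff.marker_id].to_numpy()
        genetic = genetic + eff.additive_effect * exotic_dose(col)
        if eff.dominance_effect:
            genetic = genetic + eff.dominance_effect * (col == 2)
    n_lines, n_env, n_reps = genotypes.n_lines, design.n_environments, design.n_reps
    env_eff = rng.normal(0.0, np.sqrt(design.var_env), size=n_env)
    gxe = rng.normal(0.0, np.sqrt(design.var_gxe), size=(n_lines, n_env))
    resid = rng.normal(0.0, np.sqrt(design.var_resid), size=(n_lines, n_env, n_reps))
    y = genetic[:, None, None] + env_eff[None, :, None] + gxe[:, :, None] + resid
    env_ids = [f"E{j + 1:02d}" for j in range(n_env)]
    frame = pd.DataFrame(
        {
            "line_id": np.repeat(genotypes.lines.to_numpy(), n_env * n_reps),
            "env_id": np.tile(np.repeat(env_ids, n_reps), n_lines),
            "yield_dt_ha": y.reshape(-1),
        }
    )
    if n_reps > 1:
        frame["rep"] = np.tile(np.arange(1, n_reps + 1), n_lines * n_env)
    return PhenotypeTable(frame)


def mask_missing(
    genotypes: GenotypeMatrix, fraction: float, seed: int = 0
) -> GenotypeMatrix:
    """Set a random fraction of genotype calls to missing (code 0).

    Exercises missing-data handling downstream without touching phenotypes
    already simulated from the true codes.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("missing fraction must be in [0, 1]")
    if fraction == 0.0:
        return GenotypeMatrix(genotypes.codes.copy())
    rng = np.random.default_rng(seed)
    codes = genotypes.codes.to_numpy().copy()
    mask = rng.random(codes.shape) < fraction
    codes[mask] = 0
    return GenotypeMatrix(
        pd.DataFrame(codes, index=genotypes.lines, columns=genotypes.markers)
    )


def make_map(
    n_markers: int = 210,
    chrom_length_cM: float = 150.0,
    chromosomes: tuple[str, ...] = CHROMOSOMES,
) -> GeneticMap:
    """Evenly spaced synthetic marker map over the 21 wheat chromosomes.

    ``n_markers`` are distributed as evenly as possible across the listed
    chromosomes; each chromosome's markers run from 0 to ``chrom_length_cM``.
    """
    if n_markers < len(chromosomes):
        raise ValidationError("need at least one marker per chromosome")
    base, extra = divmod(n_markers, len(chromosomes))
    rows = []
    for k, chrom in enumerate(chromosomes):
        m = base + (1 if k < extra else 0)
        pos = np.linspace(0.0, chrom_length_cM, m) if m > 1 else np.array([0.0])
        for i, p in enumerate(pos):
            rows.append((f"{chrom}_m{i + 1:03d}", chrom, float(p)))
    return GeneticMap.from_frame(
        pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"])
    )
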