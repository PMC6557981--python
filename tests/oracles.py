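"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (enumeration,
raw sums of squares, hand-coded step-up) and never calls the package's own
computational paths.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps


def single_locus_frequencies(n_backcrosses: int, n_selfings: int):
    """Exact single-locus genotype distribution of an AB pedigree.

    Enumerates the Markov chain F1 -> BC_b -> F_(1+s) over genotype states
    (number of exotic alleles 0/1/2).  Returns
    (exotic allele frequency, het frequency, EE frequency).
    """
    # state probabilities for [0, 1, 2] exotic alleles; F1 is fully het
    dist = np.array([0.0, 1.0, 0.0])
    gamete_exotic = np.array([0.0, 0.5, 1.0])  # P(gamete carries exotic)
    for _ in range(n_backcrosses):
        # cross to the elite parent: offspring het iff gamete was exotic
        p_exotic_gamete = float(dist @ gamete_exotic)
        dist = np.array([1.0 - p_exotic_gamete, p_exotic_gamete, 0.0])
    for _ in range(n_selfings):
        new = np.zeros(3)
        new[0] += dist[0] + dist[1] * 0.25
        new[1] += dist[1] * 0.5
        new[2] += dist[2] + dist[1] * 0.25
        dist = new
    allele = float(dist @ np.array([0.0, 0.5, 1.0]))
    return allele, float(dist[1]), float(dist[2])


def _gamete_distribution(h1: int, h2: int, r: float):
    """Two-locus gamete probabilities from a diplotype.

    Haplotypes are 2-bit integers (bit 0 = locus 1 allele, bit 1 = locus 2
    allele).  Non-recombinant gametes keep a parental haplotype; a
    recombinant swaps the locus-2 bit.
    """
    rec1 = (h1 & 1) | (h2 & 2)
    rec2 = (h2 & 1) | (h1 & 2)
    out = {}
    for h, p in ((h1, (1 - r) / 2), (h2, (1 - r) / 2),
                 (rec1, r / 2), (rec2, r / 2)):
        out[h] = out.get(h, 0.0) + p
    return out


def two_locus_ab_distribution(r: float, n_backcrosses: int, n_selfings: int):
    """Exact diplotype distribution at two linked loci for an AB pedigree.

    Returns a dict mapping ordered diplotypes (h1, h2) to probability,
    starting from the F1 (11 / 00) and applying backcrosses to the fully
    elite parent (haplotype 0) then selfings, with recombination fraction
    ``r`` per meiosis.
    """
    dist = {(3, 0): 1.0}
    for _ in range(n_backcrosses):
        new = {}
        for (h1, h2), p in dist.items():
            for g, pg in _gamete_distribution(h1, h2, r).items():
                key = (g, 0)
                new[key] = new.get(key, 0.0) + p * pg
        dist = new
    for _ in range(n_selfings):
        new = {}
        for (h1, h2), p in dist.items():
            gam = _gamete_distribution(h1, h2, r)
            for (g1, p1), (g2, p2) in itertools.product(gam.items(), gam.items()):
                key = (g1, g2)
                new[key] = new.get(key, 0.0) + p * p1 * p2
        dist = new
    return dist


def expected_adjacent_recombinant_rate(r: float, n_backcrosses: int,
                                       n_selfings: int) -> float:
    """Expected % of recombinant homozygous adjacent pairs in AB lines.

    A line is informative iff both loci are homozygous; it counts as
    recombinant iff the two homozygous codes differ.
    """
    dist = two_locus_ab_distribution(r, n_backcrosses, n_selfings)
    p_inf = p_rec = 0.0
    for (h1, h2), p in dist.items():
        hom1 = (h1 & 1) == (h2 & 1)
        hom2 = (h1 & 2) == (h2 & 2)
        if hom1 and hom2:
            p_inf += p
            if ((h1 & 1) != 0) != ((h1 & 2) != 0):
                p_rec += p
    return 100.0 * p_rec / p_inf


def balanced_anova_p(y: np.ndarray) -> tuple[float, float]:
    """Classical two-way mixed ANOVA marker test from raw plot values.

    ``y`` has shape (a classes, b environments, n replicate lines).  Builds
    the full sums-of-squares decomposition and tests the class effect
    against the class-by-environment interaction:
    F = MS_class / MS_class_x_env with (a-1, (a-1)(b-1)) df.
    """
    a, b, n = y.shape
    grand = y.mean()
    class_means = y.mean(axis=(1, 2))
    env_means = y.mean(axis=(0, 2))
    cell_means = y.mean(axis=2)
    ss_class = n * b * ((class_means - grand) ** 2).sum()
    ss_int = n * ((cell_means - class_means[:, None] - env_means[None, :]
                   + grand) ** 2).sum()
    ms_class = ss_class / (a - 1)
    ms_int = ss_int / ((a - 1) * (b - 1))
    f = ms_class / ms_int
    return float(sps.f.sf(f, a - 1, (a - 1) * (b - 1))), float(f)


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, coded by hand."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
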