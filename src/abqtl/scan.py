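"""Genome-wide marker scan for exotic-allele yield effects.

Each marker is tested one at a time with the mixed hierarchical model

    Y_ijk = mu + M_i + E_j + M_i x E_j + eps_k(ij)

where the marker genotype M is fixed and environment E and the M x E
interaction are random.  Only the two homozygous classes enter the test:
lines heterozygous or missing at the marker are dropped for that marker,
because repeated selfing turns a plot sown from a heterozygous plant into
a mixture of both homozygotes, so its phenotype misrepresents true
heterozygotes.

The marker test is the balanced-anchored F-ratio: per-environment class
means (least-squares means per environment) are formed and the marker mean
square is tested against the marker-by-environment mean square,
F(1, n_env - 1).  With one plot per line and environment this is the exact
mixed-model test in the balanced case and a robust approximation under
moderate imbalance.

Downstream of the per-marker fits: Benjamini-Hochberg q-values with star
classes (*** for q < 0.001, ** for q < 0.01), the relative performance of
the homozygous exotic class RP(EE) = 100 * (LSM_EE - LSM_CC) / LSM_CC,
LOD = -log10(p), and merging of significant same-direction markers within
20 cM into QTL regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    Dataset,
    PhenotypeTable,
    ValidationError,
    chromosome_sort_key,
)

__all__ = [
    "MarkerScanResult",
    "QTLRegion",
    "GenomeScan",
    "fit_marker_model",
    "compute_rp",
    "fdr_classify",
    "merge_qtl",
    "scan_genome",
]

#: Smallest p-value reported; keeps p in (0, 1] and LOD finite even when
#: the interaction mean square vanishes (e.g. noise-free toys).
_P_FLOOR = float(np.finfo(np.float64).tiny)

#: q-value star classes, checked in order.
FDR_LEVELS = ((0.001, "***"), (0.01, "**"))


@dataclass(frozen=True)
class MarkerScanResult:
    """Per-marker model output in the published table's vocabulary."""

    marker_id: str
    chromosome: str
    position_cM: float
    p_value: float
    fdr_q: float
    fdr_class: str  # "***", "**" or "ns"
    lsm_cc: float
    lsm_ee: float
    rp_ee: float  # percent, unrounded
    lod: float
    n_cc: int
    n_ee: int

    @property
    def significant(self) -> bool:
        return self.fdr_class != "ns"


@dataclass(frozen=True)
class QTLRegion:
    """A run of same-direction significant markers merged within <=20 cM."""

    chromosome: str
    start_cM: float
    end_cM: float
    member_markers: tuple[str, ...]
    peak_marker: str
    peak_p_value: float
    peak_rp_ee: float
    direction: str  # "exotic_favorable" | "exotic_unfavorable"


@dataclass
class GenomeScan:
    """Scan output: ordered marker results plus skipped markers with reasons.

    Iterates and indexes as the list of :class:`MarkerScanResult`.
    """

    results: list[MarkerScanResult]
    skipped: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def __getitem__(self, i):
        return self.results[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])


class MarkerSkipped(ValueError):
    """The marker cannot be tested (class too small or degenerate fit)."""


def _anova_f_from_cells(cell_cc: np.ndarray, cell_ee: np.ndarray):
    """F-test of the marker effect from per-environment class means.

    ``cell_cc``/``cell_ee`` are the length-B vectors of CC and EE class
    means per environment.  Returns (p_value, F).  The two-way
    decomposition on the 2 x B cell-mean table gives
    F = MS_marker / MS_marker_x_env with (1, B-1) df; for balanced data
    this equals the same ratio computed from raw plot values, since the
    per-cell replicate count cancels.
    """
    cells = np.vstack([cell_cc, cell_ee])  # (2, B)
    b = cells.shape[1]
    if b < 2:
        raise MarkerSkipped("fewer than 2 environments with both classes")
    row_means = cells.mean(axis=1, keepdims=True)
    col_means = cells.mean(axis=0, keepdims=True)
    grand = cells.mean()
    ss_marker = b * float(((row_means - grand) ** 2).sum())
    resid = cells - row_means - col_means + grand
    ss_int = float((resid ** 2).sum())
    df_int = b - 1
    if ss_int <= 0.0:
        # Zero interaction mean square: either no signal at all (p = 1) or
        # a noise-free shift (p at the floating-point floor).
        return (1.0, 0.0) if ss_marker <= 0.0 else (_P_FLOOR, math.inf)
    f = ss_marker / (ss_int / df_int)
    p = float(sps.f.sf(f, 1, df_int))
    return max(p, _P_FLOOR), f


def _fit_from_matrix(y: np.ndarray, codes: np.ndarray, min_class_size: int = 2):
    """Core fit on a line x environment phenotype matrix (NaN = unobserved).

    Returns (p, lsm_cc, lsm_ee, lod, n_cc, n_ee); raises MarkerSkipped.
    """
    cc_mask = codes == 1
    ee_mask = codes == 3
    n_cc, n_ee = int(cc_mask.sum()), int(ee_mask.sum())
    if n_cc < min_class_size or n_ee < min_class_size:
        raise MarkerSkipped(
            f"homozygous class too small (CC={n_cc}, EE={n_ee}, "
            f"minimum {min_class_size})"
        )
    with np.errstate(invalid="ignore"):
        cell_cc = np.nanmean(y[cc_mask], axis=0)
        cell_ee = np.nanmean(y[ee_mask], axis=0)
    both = np.isfinite(cell_cc) & np.isfinite(cell_ee)
    if both.sum() < 2:
        raise MarkerSkipped("fewer than 2 environments observed in both classes")
    p, _ = _anova_f_from_cells(cell_cc[both], cell_ee[both])
    lsm_cc = float(cell_cc[both].mean())
    lsm_ee = float(cell_ee[both].mean())
    return p, lsm_cc, lsm_ee, -math.log10(p), n_cc, n_ee


def fit_marker_model(
    phenotypes: PhenotypeTable,
    genotype_at_marker: pd.Series,
    min_class_size: int = 2,
):
    """Fit the two-class mixed hierarchical model at one marker.

    ``genotype_at_marker`` maps line ids to codes {0,1,2,3}; lines coded
    heterozygous (2) or missing (0) are dropped.  Returns
    ``(p_value, lsm_cc, lsm_ee, lod, n_cc, n_ee)`` where the least-squares
    means average the per-environment class means.  Raises
    :class:`MarkerSkipped` when a homozygous class has fewer than
    ``min_class_size`` lines or the fit is degenerate.

    Handles replicated records (a ``rep`` column) by pooling plots within
    each class x environment cell, which leaves the balanced F-ratio equal
    to the raw-data MS_marker / MS_marker_x_env.
    """
    geno = pd.Series(genotype_at_marker)
    df = phenotypes.frame.merge(
        geno.rename("code"), left_on="line_id", right_index=True, how="inner"
    )
    hom = df[df["code"].isin([1, 3])]
    n_cc = hom.loc[hom["code"] == 1, "line_id"].nunique()
    n_ee = hom.loc[hom["code"] == 3, "line_id"].nunique()
    if n_cc < min_class_size or n_ee < min_class_size:
        raise MarkerSkipped(
            f"homozygous class too small (CC={n_cc}, EE={n_ee}, "
            f"minimum {min_class_size})"
        )
    cells = hom.groupby(["code", "env_id"])["yield_dt_ha"].mean().unstack("env_id")
    if 1 not in cells.index or 3 not in cells.index:
        raise MarkerSkipped("a homozygous class has no phenotype records")
    cell_cc = cells.loc[1].to_numpy()
    cell_ee = cells.loc[3].to_numpy()
    both = np.isfinite(cell_cc) & np.isfinite(cell_ee)
    if both.sum() < 2:
        raise MarkerSkipped("fewer than 2 environments observed in both classes")
    p, _ = _anova_f_from_cells(cell_cc[both], cell_ee[both])
    lsm_cc = float(cell_cc[both].mean())
    lsm_ee = float(cell_ee[both].mean())
    return p, lsm_cc, lsm_ee, -math.log10(p), n_cc, n_ee


def compute_rp(lsm_cc: float, lsm_ee: float) -> float:
    """Relative performance of the homozygous exotic class, in percent.

    RP(EE) = 100 * (LSM_EE - LSM_CC) / LSM_CC.  Positive values mean the
    exotic allele outyields the cultivated one.
    """
    if lsm_cc <= 0:
        raise ValueError("lsm_cc must be > 0 for a relative performance ratio")
    return 100.0 * (lsm_ee - lsm_cc) / lsm_cc


def fdr_classify(p_values) -> tuple[np.ndarray, list[str]]:
    """Benjamini-Hochberg q-values and star classes across one scan.

    Returns ``(q_values, classes)`` with class "***" for q < 0.001,
    "**" for q < 0.01 and "ns" otherwise.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values to classify")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    classes = []
    for qi in q:
        for level, stars in FDR_LEVELS:
            if qi < level:
                classes.append(stars)
                break
        else:
            classes.append("ns")
    return q, classes


def merge_qtl(results, max_gap_cM: float = 20.0) -> list[QTLRegion]:
    """Chain significant same-direction markers within ``max_gap_cM`` into QTL.

    Input must be sorted by (chromosome, position).  Significant markers
    sharing a chromosome and the sign of RP(EE) are merged while each
    consecutive gap is <= ``max_gap_cM``; a chain is broken by a change of
    chromosome, an intervening non-significant marker, an opposite-sign
    marker, or a gap beyond the rule.  The peak is the member with the
    smallest p-value (ties: larger \\|RP(EE)\\|, then lower cM).
    """
    results = list(results)
    order = [(chromosome_sort_key(r.chromosome), r.position_cM) for r in results]
    if order != sorted(order):
        raise ValidationError("scan results must be sorted by (chromosome, position)")
    regions: list[QTLRegion] = []
    chain: list[MarkerScanResult] = []

    def flush():
        if not chain:
            return
        peak = min(chain, key=lambda r: (r.p_value, -abs(r.rp_ee), r.position_cM))
        direction = "exotic_favorable" if peak.rp_ee > 0 else "exotic_unfavorable"
        regions.append(
            QTLRegion(
                chromosome=chain[0].chromosome,
                start_cM=chain[0].position_cM,
                end_cM=chain[-1].position_cM,
                member_markers=tuple(r.marker_id for r in chain),
                peak_marker=peak.marker_id,
                peak_p_value=peak.p_value,
                peak_rp_ee=peak.rp_ee,
                direction=direction,
            )
        )
        chain.clear()

    for r in results:
        if not r.significant:
            flush()
            continue
        sign = 1 if r.rp_ee > 0 else -1
        if chain:
            prev = chain[-1]
            prev_sign = 1 if prev.rp_ee > 0 else -1
            same = (
                r.chromosome == prev.chromosome
                and sign == prev_sign
                and (r.position_cM - prev.position_cM) <= max_gap_cM
            )
            if not same:
                flush()
        chain.append(r)
    flush()
    return regions


def scan_genome(
    dataset: Dataset,
    min_class_size: int = 2,
    merge_gap_cM: float = 20.0,
) -> GenomeScan:
    """Scan every mapped, genotyped marker of a dataset.

    Fits the per-marker model at each marker, applies Benjamini-Hochberg
    across all tested markers jointly, and computes RP(EE) and LOD.
    Markers that cannot be tested are recorded in ``GenomeScan.skipped``
    with the reason.  Deterministic for fixed input.
    """
    y = dataset.phenotypes.to_matrix()
    pheno_lines = y.index
    codes_df = dataset.genotypes.codes.reindex(pheno_lines)
    y_arr = y.to_numpy(dtype=float)

    fitted = []
    skipped: dict[str, str] = {}
    gmap = dataset.map.frame
    for marker, chrom, pos in gmap.itertuples(index=False):
        if marker not in codes_df.columns:
            skipped[marker] = "not genotyped"
            continue
        codes = codes_df[marker].to_numpy()
        try:
            p, lsm_cc, lsm_ee, lod, n_cc, n_ee = _fit_from_matrix(
                y_arr, codes, min_class_size
            )
        except MarkerSkipped as why:
            skipped[marker] = str(why)
            continue
        fitted.append((marker, chrom, float(pos), p, lsm_cc, lsm_ee, lod, n_cc, n_ee))

    if not fitted:
        raise ValidationError("no marker could be tested in this dataset")
    q, classes = fdr_classify([f[3] for f in fitted])
    results = [
        MarkerScanResult(
            marker_id=m, chromosome=c, position_cM=pos, p_value=p,
            fdr_q=float(qi), fdr_class=cls,
            lsm_cc=lcc, lsm_ee=lee, rp_ee=compute_rp(lcc, lee),
            lod=lod, n_cc=ncc, n_ee=nee,
        )
        for (m, c, pos, p, lcc, lee, lod, ncc, nee), qi, cls
        in zip(fitted, q, classes)
    ]
    return GenomeScan(results=results, skipped=skipped)
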