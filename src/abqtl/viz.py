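"""QTL-map figures: circular per-genome map and allele needle plots.

Both operations first assemble a plain plot-data table, write it as TSV,
and only then render it with matplotlib — so tests (and downstream users)
work with data, never pixels.

The circular map draws three concentric tracks per chromosome of the
selected genome (default D):

* outer: marker-density heat bins of fixed cM width (default 5 cM),
  coloured white (low) to red (high);
* middle: per-marker allele effects as percent deviation of the class
  least-squares mean from the population mean, the population mean being
  the 0% reference line, clipped at a symmetric axis limit (default 12%);
* inner: a Manhattan track of LOD = -log10(p), significant markers
  highlighted.

The needle plot shows one bar per homozygous line, sorted by descending
mean yield, coloured by carrier class (blue CC, red EE).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap, Normalize

from .datatypes import ValidationError, genome_of
from .scan import compute_rp

__all__ = ["CircosSpec", "circos_qtl_map", "needle_plot"]

_DENSITY_CMAP = LinearSegmentedColormap.from_list("density", ["white", "red"])
CC_COLOR = "#2166ac"  # blue: cultivated carriers
EE_COLOR = "#b2182b"  # red: exotic carriers


@dataclass(frozen=True)
class CircosSpec:
    """Layout parameters of the circular QTL map."""

    genome_filter: str = "D"
    density_bin_cM: float = 5.0
    effect_axis_limit: float = 12.0  # percent
    lod_axis_max: float = 30.0
    both_alleles: bool = False  # also draw the cultivated-class deviation

    def __post_init__(self) -> None:
        if self.density_bin_cM <= 0:
            raise ValidationError("density bin must be > 0 cM")
        if self.effect_axis_limit <= 0 or self.lod_axis_max <= 0:
            raise ValidationError("axis limits must be > 0")


def _circos_tables(gmap, results, population_mean, spec):
    """Build the density-bin and per-marker tables behind the circular map."""
    chroms = [c for c in gmap.chromosomes if genome_of(c) == spec.genome_filter]
    if not chroms:
        raise ValidationError(
            f"no markers on genome {spec.genome_filter} in this map"
        )
    by_marker = {r.marker_id: r for r in results}

    bin_rows = []
    marker_rows = []
    for chrom in chroms:
        table = gmap.chromosome_table(chrom)
        pos = table["pos_cM"].to_numpy()
        span = max(pos.max(), spec.density_bin_cM)
        edges = np.arange(0.0, span + spec.density_bin_cM, spec.density_bin_cM)
        counts, _ = np.histogram(pos, bins=edges)
        for lo, hi, n in zip(edges[:-1], edges[1:], counts):
            bin_rows.append((chrom, lo, hi, int(n)))
        for marker, _, p in table.itertuples(index=False):
            r = by_marker.get(marker)
            if r is None:
                continue
            eff_ee = compute_rp(population_mean, r.lsm_ee)
            eff_cc = compute_rp(population_mean, r.lsm_cc)
            lim = spec.effect_axis_limit
            marker_rows.append(
                (
                    chrom, marker, float(p),
                    eff_ee, float(np.clip(eff_ee, -lim, lim)),
                    eff_cc, float(np.clip(eff_cc, -lim, lim)),
                    min(r.lod, spec.lod_axis_max), r.significant,
                )
            )
    bins = pd.DataFrame(
        bin_rows, columns=["chrom", "bin_start_cM", "bin_end_cM", "n_markers"]
    )
    markers = pd.DataFrame(
        marker_rows,
        columns=[
            "chrom", "marker", "pos_cM",
            "effect_ee_pct", "effect_ee_drawn_pct",
            "effect_cc_pct", "effect_cc_drawn_pct",
            "lod_drawn", "significant",
        ],
    )
    if markers.empty:
        raise ValidationError(
            f"scan results cover no marker on genome {spec.genome_filter}"
        )
    return chroms, bins, markers


def circos_qtl_map(
    gmap,
    results,
    population_mean: float,
    out_path,
    spec: CircosSpec = CircosSpec(),
    data_prefix=None,
) -> dict[str, pd.DataFrame]:
    """Render the circular QTL map and emit its plot-data tables.

    Writes ``<prefix>.density.tsv`` and ``<prefix>.markers.tsv`` (prefix
    defaults to the figure path without extension), then the figure itself.
    Returns the two tables keyed ``"density"`` and ``"markers"``.
    """
    chroms, bins, markers = _circos_tables(gmap, results, population_mean, spec)
    prefix = Path(data_prefix) if data_prefix else Path(out_path).with_suffix("")
    bins.to_csv(f"{prefix}.density.tsv", sep="\t", index=False)
    markers.to_csv(f"{prefix}.markers.tsv", sep="\t", index=False)

    spans = {c: max(gmap.positions(c).max(), spec.density_bin_cM) for c in chroms}
    total = sum(spans.values())
    gap = 2 * np.pi * 0.01
    scale = (2 * np.pi - gap * len(chroms)) / total
    starts = {}
    theta = 0.0
    for c in chroms:
        starts[c] = theta
        theta += spans[c] * scale + gap

    def angle(chrom, pos):
        return starts[chrom] + pos * scale

    fig = plt.figure(figsize=(8, 8))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_ylim(0, 1.0)
    ax.axis("off")

    norm = Normalize(0, max(bins["n_markers"].max(), 1))
    for chrom, lo, hi, n in bins.itertuples(index=False):
        th = np.linspace(angle(chrom, lo), angle(chrom, hi), 8)
        ax.fill_between(th, 0.88, 0.98, color=_DENSITY_CMAP(norm(n)),
                        edgecolor="none")
    for c in chroms:
        th = np.linspace(angle(c, 0.0), angle(c, spans[c]), 32)
        ax.plot(th, np.full_like(th, 0.98), color="black", lw=0.8)
        ax.plot(th, np.full_like(th, 0.88), color="black", lw=0.8)
        ax.text(angle(c, spans[c] / 2), 1.04, c, ha="center", va="center")

    # effect ring: population mean = reference circle at mid-track
    lim = spec.effect_axis_limit
    e_lo, e_hi = 0.60, 0.84

    def effect_radius(pct):
        return e_lo + (pct + lim) / (2 * lim) * (e_hi - e_lo)

    for c in chroms:
        th = np.linspace(angle(c, 0.0), angle(c, spans[c]), 32)
        ax.plot(th, np.full_like(th, effect_radius(0.0)), color="grey",
                lw=0.6, ls="--")
    for row in markers.itertuples(index=False):
        th = angle(row.chrom, row.pos_cM)
        r0 = effect_radius(0.0)
        ax.plot([th, th], [r0, effect_radius(row.effect_ee_drawn_pct)],
                color=EE_COLOR, lw=0.9)
        if spec.both_alleles:
            ax.plot([th, th], [r0, effect_radius(row.effect_cc_drawn_pct)],
                    color=CC_COLOR, lw=0.9, alpha=0.6)

    # LOD Manhattan ring
    l_lo, l_hi = 0.30, 0.56
    for row in markers.itertuples(index=False):
        th = angle(row.chrom, row.pos_cM)
        r = l_lo + min(row.lod_drawn, spec.lod_axis_max) / spec.lod_axis_max \
            * (l_hi - l_lo)
        ax.plot(th, r, "o", ms=4 if row.significant else 2,
                color="red" if row.significant else "grey",
                mec="none", alpha=0.9)

    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return {"density": bins, "markers": markers}


def needle_plot(
    line_means: pd.Series,
    genotype_at_marker: pd.Series,
    out_path,
    data_path=None,
    title: str | None = None,
) -> pd.DataFrame:
    """Bar plot of per-line mean yield sorted high to low, coloured by allele.

    ``line_means`` maps line ids to mean yield (dt/ha); lines heterozygous
    or missing at the marker are excluded.  Writes the plot-data TSV
    (default ``<figure path>.tsv``) before rendering.  Returns the table
    with columns ``line_id``, ``mean_yield_dt_ha``, ``genotype_class``.
    """
    means = pd.Series(line_means, dtype=float)
    codes = pd.Series(genotype_at_marker).reindex(means.index)
    keep = codes.isin([1, 3])
    if not keep.any():
        raise ValidationError("no homozygous line to plot at this marker")
    table = pd.DataFrame(
        {
            "line_id": means.index[keep],
            "mean_yield_dt_ha": means[keep].to_numpy(),
            "genotype_class": np.where(codes[keep] == 1, "CC", "EE"),
        }
    ).sort_values(
        ["mean_yield_dt_ha", "line_id"], ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)

    data_path = data_path or f"{out_path}.tsv"
    table.to_csv(data_path, sep="\t", index=False)

    fig, ax = plt.subplots(figsize=(max(6, len(table) * 0.08), 4))
    colors = np.where(table["genotype_class"] == "CC", CC_COLOR, EE_COLOR)
    ax.bar(np.arange(len(table)), table["mean_yield_dt_ha"], color=colors,
           width=0.8)
    ax.set_ylabel("grain yield (dt/ha)")
    ax.set_xlabel("lines (sorted by mean yield)")
    ax.set_xticks([])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return table
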