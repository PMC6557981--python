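"""Readers/writers for the three TSV formats and the scan-result table.

All files are tab-separated UTF-8 with a header row; paths ending in
``.gz`` are transparently (de)compressed by pandas.

* map TSV: columns ``marker``, ``chrom``, ``pos_cM``
* genotype TSV: first column ``line_id``, remaining columns are marker ids,
  values in {0,1,2,3}
* phenotype TSV: columns ``line_id``, ``env_id``, ``yield_dt_ha``
  (optionally ``rep``)
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    Dataset,
    GeneticMap,
    GenotypeMatrix,
    PhenotypeTable,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Display columns of the published QTL-table layout.
SCAN_TABLE_COLUMNS = [
    "Marker", "Chr", "Pos", "P-value", "FDR", "(CC)", "(EE)", "% RP (EE)",
]


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    return GeneticMap.from_frame(df)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.frame.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    if "line_id" != df.columns[0]:
        raise ValidationError(
            f"genotype file must start with a line_id column, got {df.columns[0]!r}"
        )
    df = df.set_index("line_id")
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.integer):
        try:
            values = values.astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-integer genotype code: {exc}") from exc
    return GenotypeMatrix(pd.DataFrame(values, index=df.index, columns=df.columns))


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    genotypes.codes.to_csv(path, sep="\t", index_label="line_id")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "env_id": str})
    return PhenotypeTable(df)


def write_phenotypes(phenotypes: PhenotypeTable, path) -> None:
    phenotypes.frame.to_csv(path, sep="\t", index=False)


def read_dataset(map_path, geno_path, pheno_path) -> Dataset:
    """Read and cross-validate a (map, genotypes, phenotypes) triple.

    Raises :class:`ValidationError` naming the offending marker/line on any
    coding or consistency violation.
    """
    gmap = read_map(map_path)
    genotypes = read_genotypes(geno_path)
    phenotypes = read_phenotypes(pheno_path)
    ds = Dataset(gmap, genotypes, phenotypes)
    log.info(
        "read dataset: %d lines, %d markers, %d environments",
        genotypes.n_lines, gmap.n_markers, phenotypes.n_environments,
    )
    return ds


def write_dataset(ds: Dataset, map_path, geno_path, pheno_path) -> None:
    write_map(ds.map, map_path)
    write_genotypes(ds.genotypes, geno_path)
    write_phenotypes(ds.phenotypes, pheno_path)


def _format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def write_scan_table(results, path) -> None:
    """Write marker-scan results in the published eight-column layout.

    Class means and % RP (EE) are rounded to one decimal for display; the
    unrounded values (plus q-values, LOD and class sizes) go to a companion
    ``<path>.full.tsv`` machine-readable file.
    """
    results = list(results)
    if not results:
        raise ValidationError("no scan results to write")
    display = pd.DataFrame(
        {
            "Marker": [r.marker_id for r in results],
            "Chr": [r.chromosome for r in results],
            "Pos": [f"{r.position_cM:.1f}" for r in results],
            "P-value": [_format_p(r.p_value) for r in results],
            "FDR": [r.fdr_class for r in results],
            "(CC)": [f"{r.lsm_cc:.1f}" for r in results],
            "(EE)": [f"{r.lsm_ee:.1f}" for r in results],
            "% RP (EE)": [f"{r.rp_ee:.1f}" for r in results],
        },
        columns=SCAN_TABLE_COLUMNS,
    )
    display.to_csv(path, sep="\t", index=False)
    full = pd.DataFrame(
        {
            "marker": [r.marker_id for r in results],
            "chrom": [r.chromosome for r in results],
            "pos_cM": [r.position_cM for r in results],
            "p_value": [r.p_value for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "fdr_class": [r.fdr_class for r in results],
            "lsm_cc": [r.lsm_cc for r in results],
            "lsm_ee": [r.lsm_ee for r in results],
            "rp_ee": [r.rp_ee for r in results],
            "lod": [r.lod for r in results],
            "n_cc": [r.n_cc for r in results],
            "n_ee": [r.n_ee for r in results],
        }
    )
    full.to_csv(_companion_path(path), sep="\t", index=False)


def _companion_path(path) -> Path:
    p = Path(path)
    ext = p.suffix
    stem = p.name[: len(p.name) - len(ext)] if ext else p.name
    if ext == ".gz":
        inner = Path(stem).suffix
        stem = stem[: len(stem) - len(inner)]
        ext = inner + ext
    return p.with_name(f"{stem}.full{ext or '.tsv'}")
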