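import numpy as np
import pandas as pd
import pytest

from abqtl import (
    CrossingScheme,
    Dataset,
    GeneticMap,
    GenotypeMatrix,
    PhenotypeTable,
    QTLEffect,
    TrialDesign,
    make_map,
    simulate_ab_population,
    simulate_phenotypes,
)


@pytest.fixture
def tiny_map() -> GeneticMap:
    """Three markers on two chromosomes."""
    return GeneticMap.from_frame(
        pd.DataFrame(
            {
                "marker": ["m1", "m2", "m3"],
                "chrom": ["1D", "1D", "2D"],
                "pos_cM": [0.0, 12.5, 4.0],
            }
        )
    )


@pytest.fixture
def tiny_dataset(tiny_map) -> Dataset:
    genotypes = GenotypeMatrix(
        pd.DataFrame(
            [[1, 1, 3], [3, 3, 1]],
            index=pd.Index(["lineA", "lineB"], name="line_id"),
            columns=["m1", "m2", "m3"],
        )
    )
    phenotypes = PhenotypeTable(
        pd.DataFrame(
            {
                "line_id": ["lineA", "lineA", "lineB", "lineB"],
                "env_id": ["E01", "E02", "E01", "E02"],
                "yield_dt_ha": [70.0, 75.0, 72.0, 74.0],
            }
        )
    )
    return Dataset(tiny_map, genotypes, phenotypes)


def balanced_dataset(
    n_per_class: int = 4,
    n_env: int = 5,
    shift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    mu: float = 74.0,
):
    """Hand-built two-class dataset on a one-marker map.

    CC lines yield mu, EE lines mu + shift, plus iid N(0, noise_sd^2)
    plot noise; exactly one plot per line and environment.
    """
    rng = np.random.default_rng(seed)
    gmap = GeneticMap.from_frame(
        pd.DataFrame({"marker": ["mk"], "chrom": ["1D"], "pos_cM": [0.0]})
    )
    lines = [f"cc{i}" for i in range(n_per_class)] + [
        f"ee{i}" for i in range(n_per_class)
    ]
    codes = [1] * n_per_class + [3] * n_per_class
    genotypes = GenotypeMatrix(
        pd.DataFrame({"mk": codes}, index=pd.Index(lines, name="line_id"))
    )
    records = []
    for line, code in zip(lines, codes):
        for j in range(n_env):
            y = mu + (shift if code == 3 else 0.0)
            if noise_sd:
                y += rng.normal(0.0, noise_sd)
            records.append((line, f"E{j + 1:02d}", y))
    phenotypes = PhenotypeTable(
        pd.DataFrame(records, columns=["line_id", "env_id", "yield_dt_ha"])
    )
    return Dataset(gmap, genotypes, phenotypes)


def simulated_dataset(
    n_lines: int = 150,
    n_markers: int = 200,
    n_env: int = 5,
    effects: tuple = (),
    seed: int = 0,
):
    """Full simulator round: map -> AB population -> trial phenotypes."""
    gmap = make_map(n_markers=n_markers)
    genotypes = simulate_ab_population(
        gmap, CrossingScheme(n_lines=n_lines, seed=seed)
    )
    phenotypes = simulate_phenotypes(
        genotypes,
        [QTLEffect(m, a) for m, a in effects],
        TrialDesign(n_environments=n_env, seed=seed + 1),
    )
    return Dataset(gmap, genotypes, phenotypes)
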