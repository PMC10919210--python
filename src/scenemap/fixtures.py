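"""Synthetic fixture generators.

Every figure flavor in the package can be exercised without external data:
a group-shifted standard-normal matrix with a matching column annotation
table (the simulated clustered-heatmap input), a Bernoulli alteration
profile (a toy tumor variant table), and a dense long-form dot table
binding up to five variables.

All generators draw from one named, versioned RNG — NumPy's PCG64 via
``numpy.random.default_rng`` — seeded per call, so identical seeds give
bitwise-identical fixtures across sessions and platforms.
"""

from __future__ import annotations

import string
from typing import Sequence

import numpy as np

from .datamodel import (
    AlterationRecord,
    AlterationTable,
    AnnotationColumn,
    AnnotationTable,
    DotRecord,
    DotTable,
    LabeledMatrix,
    SceneMapError,
)

#: Fixed alteration vocabulary for the toy variant profile.
ALTERATION_CATEGORIES = ("SNV", "AMP", "DEL")


def _group_labels(k: int) -> list[str]:
    letters = string.ascii_uppercase
    return [letters[i] if i < 26 else f"G{i + 1}" for i in range(k)]


def make_fixture_matrix(
    n_rows: int = 30,
    n_cols: int = 10,
    n_col_groups: int = 2,
    group_shift: float = 1.0,
    seed: int = 0,
) -> tuple[LabeledMatrix, AnnotationTable]:
    """Random normal matrix with group-shifted columns plus its annotation.

    Entries are standard normal; columns belong to ``n_col_groups``
    contiguous, near-equal groups and every column in group ``g``
    (0-based) is shifted by ``g * group_shift``. The annotation table
    carries the categorical group label ("A", "B", ...) and one uniform
    numeric column ("score").
    """
    if n_rows <= 0 or n_cols <= 0:
        raise SceneMapError("fixture dimensions must be positive")
    if n_col_groups <= 0 or n_col_groups > n_cols:
        raise SceneMapError("need 1 <= n_col_groups <= n_cols")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_rows, n_cols))
    group_of_col = np.concatenate(
        [np.full(len(chunk), g) for g, chunk in enumerate(np.array_split(np.arange(n_cols), n_col_groups))]
    )
    values = values + group_of_col[None, :] * float(group_shift)
    labels = _group_labels(n_col_groups)
    col_ids = [f"s{j + 1}" for j in range(n_cols)]
    row_ids = [f"r{i + 1}" for i in range(n_rows)]
    annotation = AnnotationTable(
        index_ids=col_ids,
        columns={
            "group": AnnotationColumn(
                "group", "categorical", [labels[g] for g in group_of_col]
            ),
            "score": AnnotationColumn(
                "score", "numeric", list(rng.uniform(0.0, 1.0, size=n_cols))
            ),
        },
    )
    return LabeledMatrix(values, row_ids, col_ids), annotation


def make_fixture_alterations(
    n_samples: int = 20,
    n_genes: int = 5,
    per_gene_rates: Sequence[float] | None = None,
    seed: int = 0,
) -> AlterationTable:
    """Toy variant profile: each (sample, gene) pair altered independently.

    Gene ``g`` is altered in each sample with probability
    ``per_gene_rates[g]`` (default: evenly spaced rates from 0.6 down to
    0.1); the category of an altered pair is drawn uniformly from
    :data:`ALTERATION_CATEGORIES`.
    """
    if n_samples <= 0 or n_genes <= 0:
        raise SceneMapError("fixture dimensions must be positive")
    if per_gene_rates is None:
        per_gene_rates = list(np.linspace(0.6, 0.1, n_genes))
    if len(per_gene_rates) != n_genes:
        raise SceneMapError("per_gene_rates must have one rate per gene")
    for r in per_gene_rates:
        if not (0.0 <= r <= 1.0):
            raise SceneMapError(f"alteration rate outside [0, 1]: {r}")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    genes = [f"g{j + 1}" for j in range(n_genes)]
    records: list[AlterationRecord] = []
    for j, gene in enumerate(genes):
        hits = rng.random(n_samples) < per_gene_rates[j]
        cats = rng.integers(0, len(ALTERATION_CATEGORIES), size=n_samples)
        for i, sample in enumerate(samples):
            if hits[i]:
                records.append(
                    AlterationRecord(sample, gene, ALTERATION_CATEGORIES[cats[i]])
                )
    return AlterationTable(records=records)


def make_fixture_dots(
    n_rows: int = 6,
    n_cols: int = 6,
    n_hues: int = 2,
    seed: int = 0,
) -> DotTable:
    """Dense long-form dot table binding five distinct variables.

    Row and column keys are positional; ``value`` (dot size) is uniform on
    [0, 1], ``color_value`` is standard normal and independent of value,
    and ``hue`` cycles through ``n_hues`` levels by row block.
    """
    if n_rows <= 0 or n_cols <= 0 or n_hues <= 0:
        raise SceneMapError("fixture dimensions must be positive")
    rng = np.random.default_rng(seed)
    hues = [f"h{k + 1}" for k in range(n_hues)]
    records: list[DotRecord] = []
    for i in range(n_rows):
        for j in range(n_cols):
            records.append(
                DotRecord(
                    row_key=f"m{i + 1}",
                    col_key=f"c{j + 1}",
                    value=float(rng.uniform(0.0, 1.0)),
                    color_value=float(rng.standard_normal()),
                    hue=hues[i % n_hues],
                )
            )
    return DotTable(records=records)
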