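"""Seeded synthetic fixtures: labeled replicate compendia and tissue profiles.

The generator emulates the statistical structure of a pure-cell microarray
compendium on a log2-like expression scale: each gene has a baseline level
shared by all cell types, each cell type owns a disjoint block of marker
genes shifted up by ``marker_effect``, and each replicate adds independent
Gaussian noise.  Disjoint marker blocks give the resulting signature a
controllable, modest condition number, so deconvolution behavior can be
studied without confounding from collinearity.

All randomness derives from a single integer seed through
``numpy.random.SeedSequence`` spawning — one child stream per sample — so
outputs are bit-reproducible and individual samples are independent of
how many siblings were drawn.

Defaults mirror the desk-scale study conditions: 9 cell types x 10
replicates, 2,000 genes with 200 markers per type, a 4.0 log2-unit marker
shift (~16-fold) and replicate noise at a quarter of the marker effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Immune cell-type labels used by the default fixtures.
_IMMUNE_LABELS = (
    "DC",
    "CD4_T_naive",
    "CD8_T_naive",
    "CD8_T_memory",
    "M1",
    "M2",
    "NK",
    "T_helper",
    "Treg",
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic replicate compendium."""

    n_cell_types: int = 9
    n_replicates_per_type: int = 10
    n_genes: int = 2000
    n_markers_per_type: int = 200
    marker_effect: float = 4.0
    noise_sd: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.n_replicates_per_type < 2:
            raise ValueError("need at least 2 replicates per type")
        if self.n_markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError("marker blocks exceed the number of genes")
        if self.marker_effect <= 0:
            raise ValueError("marker_effect must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def cell_types(self) -> list[str]:
        if self.n_cell_types <= len(_IMMUNE_LABELS):
            return list(_IMMUNE_LABELS[: self.n_cell_types])
        return list(_IMMUNE_LABELS) + [
            f"type_{i:02d}" for i in range(len(_IMMUNE_LABELS), self.n_cell_types)
        ]


def generate_reference(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a labeled replicate expression matrix with marker structure.

    Returns
    -------
    expr:
        genes x samples matrix; sample IDs ``<type>_r<replicate>``.
    ann:
        sample annotation (index sample_id, column ``cell_type``).
    markers:
        marker ledger with columns ``gene_id`` and ``cell_type``.
    """
    types = spec.cell_types
    root = np.random.SeedSequence(spec.seed)
    n_samples = spec.n_cell_types * spec.n_replicates_per_type
    baseline_ss, *sample_ss = root.spawn(1 + n_samples)

    gene_ids = [f"gene_{i:05d}" for i in range(spec.n_genes)]
    baseline = np.random.default_rng(baseline_ss).normal(
        spec.baseline_mean, spec.baseline_sd, size=spec.n_genes
    )

    # type t owns the contiguous marker block [t*m, (t+1)*m)
    m = spec.n_markers_per_type
    type_means = np.tile(baseline[:, None], (1, spec.n_cell_types))
    marker_rows = []
    for t, ct in enumerate(types):
        block = slice(t * m, (t + 1) * m)
        type_means[block, t] += spec.marker_effect
        marker_rows.extend((gene_ids[g], ct) for g in range(t * m, (t + 1) * m))

    columns, data, ann_rows = [], [], []
    si = 0
    for t, ct in enumerate(types):
        for r in range(spec.n_replicates_per_type):
            rng = np.random.default_rng(sample_ss[si])
            si += 1
            profile = type_means[:, t] + rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
            sample_id = f"{ct}_r{r:02d}"
            columns.append(sample_id)
            data.append(profile)
            ann_rows.append((sample_id, ct))

    expr = pd.DataFrame(np.column_stack(data), index=pd.Index(gene_ids, name="feature_id"), columns=columns)
    ann = pd.DataFrame(ann_rows, columns=["sample_id", "cell_type"]).set_index("sample_id")
    markers = pd.DataFrame(marker_rows, columns=["gene_id", "cell_type"])
    return expr, ann, markers


def generate_tissue_profile(
    n_genes: int, seed: int, *, gene_ids: list[str] | None = None, scale: float = 6.0
) -> pd.DataFrame:
    """Generate a heavy-tailed positive single-sample tissue-like profile.

    A stand-in for a non-immune bulk tissue array: values are lognormal
    (median about ``scale``), strictly positive, and independent of any
    marker structure of :func:`generate_reference`.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = scale * rng.lognormal(mean=0.0, sigma=0.6, size=n_genes)
    if gene_ids is None:
        gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    return pd.DataFrame(
        {"tissue": values}, index=pd.Index(list(gene_ids), name="feature_id")
    )
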