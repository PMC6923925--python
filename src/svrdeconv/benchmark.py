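"""Benchmark drivers: pure-cell leave-one-out, in silico mixtures, spiked tissues.

Three designs, all working from a labeled pure-cell reference compendium:

* **pure-cell leave-one-out** — hold each replicate array out in turn,
  rebuild the signature from the rest, deconvolve the held-out profile;
  a pure sample's true composition is 1.0 for its own cell type, so the
  per-type mean of the dominant (own-type) fraction summarizes accuracy.
* **in silico mixtures** — per run, draw one replicate per cell type and
  Dirichlet(1,...,1) simplex weights (uniform on the simplex), synthesize
  the weighted-sum profile, rebuild the signature from the remaining
  arrays (the drawn components never leak into it), deconvolve, and
  record predicted vs true weights in a long-format ledger.
* **spiked tissues** — the same mixtures blended into a bulk tissue
  profile: value = tissue_fraction x tissue + (1 - tissue_fraction) x
  immune mixture, with tissue fractions such as 0.3/0.5/0.7.

Every run's randomness derives from the driver seed via SeedSequence
spawning, so ledgers are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconv import DeconvConfig, deconvolve
from .signature import build_signature

logger = logging.getLogger(__name__)


@dataclass
class MixtureDesign:
    """Ground truth of one synthetic mixture."""

    component_sample_ids: dict[str, str]  # cell_type -> sample_id
    weights: dict[str, float]  # cell_type -> simplex weight
    tissue_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.component_sample_ids) != set(self.weights):
            raise ValueError("component samples and weights must cover the same cell types")
        w = np.array(list(self.weights.values()), dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be a probability simplex vector")
        if not (0.0 <= self.tissue_fraction <= 1.0):
            raise ValueError("tissue_fraction must be in [0, 1]")


def make_insilico_mixture(
    reference: pd.DataFrame, ann: pd.DataFrame, design: MixtureDesign, name: str = "mixture"
) -> pd.DataFrame:
    """Weighted sum of one replicate profile per cell type."""
    missing = [s for s in design.component_sample_ids.values() if s not in reference.columns]
    if missing:
        raise ValueError(f"component sample(s) absent from reference: {missing}")
    for ct, sample in design.component_sample_ids.items():
        if ann.loc[sample, "cell_type"] != ct:
            raise ValueError(f"sample {sample!r} is not annotated as {ct!r}")
    values = np.zeros(reference.shape[0])
    for ct, sample in design.component_sample_ids.items():
        values += design.weights[ct] * reference[sample].to_numpy()
    return pd.DataFrame({name: values}, index=reference.index)


def spike_into_tissue(
    tissue_profile: pd.DataFrame, immune_mixture: pd.DataFrame, tissue_fraction: float
) -> pd.DataFrame:
    """Blend an immune mixture into a tissue profile at the given fraction."""
    if not (0.0 <= tissue_fraction <= 1.0):
        raise ValueError("tissue_fraction must be in [0, 1]")
    if not tissue_profile.index.equals(immune_mixture.index):
        raise ValueError("tissue and immune profiles must share identical gene order")
    blended = (
        tissue_fraction * tissue_profile.iloc[:, 0].to_numpy()
        + (1.0 - tissue_fraction) * immune_mixture.iloc[:, 0].to_numpy()
    )
    return pd.DataFrame({immune_mixture.columns[0]: blended}, index=immune_mixture.index)


@dataclass
class LooResult:
    """Per-sample fractions and the per-type summary of a leave-one-out run."""

    fractions: pd.DataFrame  # samples x cell types
    summary: pd.DataFrame  # per true type: n, mean/sd of own-type fraction


def run_pure_cell_loo(
    reference: pd.DataFrame,
    ann: pd.DataFrame,
    cfg: DeconvConfig | None = None,
    *,
    alpha: float = 0.05,
    step: int = 500,
    kappa_mode: str = "exact",
    probe_map: pd.Series | None = None,
) -> LooResult:
    """Pure-cell leave-one-out benchmark.

    For each sample: rebuild the signature without it, deconvolve it, and
    record the fractions.  The summary reports, per true cell type, the
    mean and SD of the fraction assigned to that type (the dominant
    fraction, since pure samples are 100% their own type).
    """
    cfg = cfg or DeconvConfig()
    counts = ann.loc[reference.columns, "cell_type"].value_counts()
    if (counts < 3).any():
        thin = counts[counts < 3]
        raise ValueError(
            f"leave-one-out needs >= 3 replicates per type (>= 2 remaining): {dict(thin)}"
        )
    rows = {}
    for sample in reference.columns:
        rest = reference.drop(columns=[sample])
        build = build_signature(
            rest, ann, probe_map, alpha=alpha, step=step, kappa_mode=kappa_mode
        )
        est = deconvolve(reference[[sample]], build.signature, cfg)
        rows[sample] = est.to_series()
    fractions = pd.DataFrame(rows).T
    fractions.index.name = "sample_id"

    truth = ann.loc[fractions.index, "cell_type"]
    own = pd.Series(
        [fractions.at[s, ct] for s, ct in truth.items()], index=fractions.index
    )
    summary = (
        pd.DataFrame({"cell_type": truth, "own_fraction": own})
        .groupby("cell_type")["own_fraction"]
        .agg(n="size", mean_dominant_fraction="mean", sd_dominant_fraction="std")
    )
    return LooResult(fractions=fractions, summary=summary)


def run_mixture_benchmark(
    reference: pd.DataFrame,
    ann: pd.DataFrame,
    n_mixtures: int = 100,
    seed: int = 0,
    cfg: DeconvConfig | None = None,
    *,
    alpha: float = 0.05,
    step: int = 500,
    kappa_mode: str = "exact",
    probe_map: pd.Series | None = None,
    tissue_profile: pd.DataFrame | None = None,
    tissue_fraction: float = 0.0,
) -> pd.DataFrame:
    """In silico mixture benchmark; optionally spiked into a tissue profile.

    Per run: one replicate per cell type is drawn uniformly, simplex
    weights come from Dirichlet(1,...,1), the signature is rebuilt from
    the non-component arrays, and the (optionally tissue-spiked) mixture
    is deconvolved.

    Returns a long-format ledger with one row per (mixture, cell type):
    columns ``mixture_id``, ``cell_type``, ``component_sample``,
    ``true_weight``, ``predicted_fraction``, ``tissue_fraction``,
    ``seed``.  Re-running with the same arguments reproduces the ledger
    bit-exactly, and re-synthesizing a mixture from its ledger rows
    reproduces the profile the deconvolution saw.
    """
    if n_mixtures < 1:
        raise ValueError("n_mixtures must be >= 1")
    cfg = cfg or DeconvConfig()
    if tissue_fraction > 0 and tissue_profile is None:
        raise ValueError("tissue_fraction > 0 requires a tissue profile")
    labels = ann.loc[reference.columns, "cell_type"]
    types = sorted(labels.unique())
    by_type = {ct: list(labels.index[labels == ct]) for ct in types}

    root = np.random.SeedSequence(seed)
    records = []
    for run, ss in enumerate(root.spawn(n_mixtures)):
        rng = np.random.default_rng(ss)
        components = {ct: by_type[ct][rng.integers(len(by_type[ct]))] for ct in types}
        weights = dict(zip(types, rng.dirichlet(np.ones(len(types)))))
        design = MixtureDesign(
            component_sample_ids=components,
            weights=weights,
            tissue_fraction=tissue_fraction,
            seed=seed,
        )
        mixture = make_insilico_mixture(reference, ann, design, name=f"mix_{run:03d}")
        if tissue_fraction > 0:
            mixture = spike_into_tissue(
                tissue_profile.loc[reference.index], mixture, tissue_fraction
            )
        rest = reference.drop(columns=list(components.values()))
        build = build_signature(
            rest, ann, probe_map, alpha=alpha, step=step, kappa_mode=kappa_mode
        )
        est = deconvolve(mixture, build.signature, cfg)
        predicted = est.to_series()
        for ct in types:
            records.append(
                {
                    "mixture_id": f"mix_{run:03d}",
                    "cell_type": ct,
                    "component_sample": components[ct],
                    "true_weight": weights[ct],
                    "predicted_fraction": predicted.get(ct, np.nan),
                    "tissue_fraction": tissue_fraction,
                    "seed": seed,
                }
            )
    return pd.DataFrame.from_records(records)


def resynthesize_from_ledger(
    ledger: pd.DataFrame,
    reference: pd.DataFrame,
    ann: pd.DataFrame,
    mixture_id: str,
    tissue_profile: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rebuild one mixture profile from its ledger rows (consistency check)."""
    rows = ledger[ledger["mixture_id"] == mixture_id]
    if rows.empty:
        raise ValueError(f"mixture {mixture_id!r} not in ledger")
    design = MixtureDesign(
        component_sample_ids=dict(zip(rows["cell_type"], rows["component_sample"])),
        weights=dict(zip(rows["cell_type"], rows["true_weight"])),
        tissue_fraction=float(rows["tissue_fraction"].iloc[0]),
        seed=int(rows["seed"].iloc[0]),
    )
    mixture = make_insilico_mixture(reference, ann, design, name=mixture_id)
    if design.tissue_fraction > 0:
        if tissue_profile is None:
            raise ValueError("ledger has tissue_fraction > 0; tissue profile required")
        mixture = spike_into_tissue(
            tissue_profile.loc[reference.index], mixture, design.tissue_fraction
        )
    return mixture
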