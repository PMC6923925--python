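"""Cell-composition deconvolution with epsilon-insensitive linear SVR.

A bulk expression profile is modeled as a convolution of cell-type
signatures:

    b_i = sum_j a_ij * x_j

where ``b_i`` is the mixture's expression of gene i, ``a_ij`` the
signature (median) expression of gene i in cell type j, and ``x_j`` the
unknown proportion of cell type j.  The coefficients are estimated by
linear epsilon-insensitive support vector regression under the L1
(epsilon-insensitive) loss — with the default epsilon = 0 this minimizes
the mean absolute error of the fit, which is robust to outlying genes.
Raw coefficients are then clipped at zero and renormalized onto the
probability simplex.

Expression values are used on the scale they arrive in (typically log2
RMA-style); no de-logging is performed.  Mixing is exactly linear only in
linear space, so signature and mixtures must share one scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVR

logger = logging.getLogger(__name__)


@dataclass
class DeconvConfig:
    """Solver settings for the epsilon-SVR deconvolution.

    epsilon:
        Width of the insensitivity tube; 0 gives pure L1 (MAE) regression.
    C:
        Loss/regularization trade-off of the SVR; larger C trusts the data
        more.
    fit_intercept:
        Fit a free intercept.  Off by default: the convolution model has no
        intercept, and a fitted one trades coefficient mass against the
        ridge penalty, biasing the recovered fractions even on noiseless
        mixtures.  Turn on only for cross-platform inputs with a known
        additive offset; the intercept is excluded from fraction
        normalization either way.
    standardize:
        Z-score the signature columns (and center the mixture) before
        fitting.  Off by default: signature and mixture share a normalized
        scale.
    min_overlap_error / min_overlap_warn:
        Gene-overlap fractions (relative to the signature) below which
        feature intersection errors out / warns.
    """

    epsilon: float = 0.0
    C: float = 1.0
    fit_intercept: bool = False
    standardize: bool = False
    min_overlap_error: float = 0.10
    min_overlap_warn: float = 0.50
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.C <= 0:
            raise ValueError("C must be > 0")


@dataclass
class FractionEstimate:
    """Estimated composition of one mixture sample."""

    cell_types: list[str]
    raw_coefficients: np.ndarray
    fractions: np.ndarray
    intercept: float = 0.0
    n_genes_used: int = 0

    def __post_init__(self) -> None:
        self.raw_coefficients = np.asarray(self.raw_coefficients, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.cell_types) != self.fractions.size:
            raise ValueError("cell_types and fractions length mismatch")
        if (self.fractions < 0).any() or abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be a probability simplex vector")

    def to_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=self.cell_types)


def intersect_features(
    mixture: pd.DataFrame, sig: pd.DataFrame, cfg: DeconvConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align mixture and signature on their shared genes, in signature order."""
    cfg = cfg or DeconvConfig()
    if mixture.shape[0] == 0 or sig.shape[0] == 0:
        raise ValueError("empty mixture or signature")
    shared = sig.index[sig.index.isin(mixture.index)]
    frac = len(shared) / sig.shape[0]
    if frac < cfg.min_overlap_error:
        raise ValueError(
            f"only {len(shared)}/{sig.shape[0]} signature genes found in the mixture "
            f"({frac:.1%}); check feature ID conventions"
        )
    if frac < cfg.min_overlap_warn:
        warnings.warn(
            f"low gene overlap: {len(shared)}/{sig.shape[0]} signature genes "
            f"({frac:.1%}) present in the mixture",
            stacklevel=2,
        )
    return mixture.loc[shared], sig.loc[shared]


def postprocess_fractions(raw_coefficients: np.ndarray) -> np.ndarray:
    """Clip negative coefficients to zero and renormalize to sum 1."""
    raw = np.asarray(raw_coefficients, dtype=float)
    if raw.size == 0:
        raise ValueError("empty coefficient vector")
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total <= 0.0:
        raise ValueError("all coefficients non-positive; cannot form fractions")
    return clipped / total


def deconvolve(
    mixture_profile: pd.DataFrame | pd.Series, sig: pd.DataFrame, cfg: DeconvConfig | None = None
) -> FractionEstimate:
    """Estimate cell-type fractions for a single mixture profile.

    The mixture may be a Series (gene-indexed) or a single-column
    DataFrame.  Features are intersected with the signature first; the SVR
    is solved deterministically (fixed tolerance, iteration cap and seed).
    """
    cfg = cfg or DeconvConfig()
    if isinstance(mixture_profile, pd.Series):
        mixture_profile = mixture_profile.to_frame()
    if mixture_profile.shape[1] != 1:
        raise ValueError(f"expected a single-sample profile, got {mixture_profile.shape[1]} columns")
    mix, sig_aligned = intersect_features(mixture_profile, sig, cfg)
    y = mix.iloc[:, 0].to_numpy(dtype=float)
    X = sig_aligned.to_numpy(dtype=float)
    if np.allclose(y, 0.0):
        raise ValueError("all-zero mixture profile")
    col_corr = np.corrcoef(X.T)
    if X.shape[1] > 1 and np.any(np.triu(col_corr, 1) > 1 - 1e-12):
        warnings.warn("signature has (near-)identical columns; fractions among them are arbitrary", stacklevel=2)

    if cfg.standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
        y = y - y.mean()

    model = LinearSVR(
        epsilon=cfg.epsilon,
        C=cfg.C,
        loss="epsilon_insensitive",
        fit_intercept=cfg.fit_intercept,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        dual=True,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Liblinear failed to converge.*")
        model.fit(X, y)
    raw = np.asarray(model.coef_, dtype=float).ravel()
    fractions = postprocess_fractions(raw)
    return FractionEstimate(
        cell_types=list(sig_aligned.columns),
        raw_coefficients=raw,
        fractions=fractions,
        intercept=float(np.atleast_1d(model.intercept_)[0]) if cfg.fit_intercept else 0.0,
        n_genes_used=len(mix),
    )


def aggregate_cell_types(est: FractionEstimate, ct_map: dict[str, list[str]]) -> FractionEstimate:
    """Sum predicted fractions into assay-level groups and renormalize.

    ``ct_map`` maps each assay cell type to the signature cell types whose
    fractions are summed (e.g. monocytes <- M1 + M2 + DC).  Signature types
    not covered by any group are dropped; the retained set is renormalized
    to sum to 1.
    """
    frac = est.to_series()
    unknown = [m for members in ct_map.values() for m in members if m not in frac.index]
    if unknown:
        raise ValueError(f"aggregation map references unknown cell type(s): {unknown[:5]}")
    grouped = pd.Series({assay: frac[members].sum() for assay, members in ct_map.items()})
    fractions = postprocess_fractions(grouped.to_numpy())
    return FractionEstimate(
        cell_types=list(grouped.index),
        raw_coefficients=grouped.to_numpy(),
        fractions=fractions,
        intercept=est.intercept,
        n_genes_used=est.n_genes_used,
    )


def deconvolve_batch(
    mixtures: pd.DataFrame,
    sig: pd.DataFrame,
    cfg: DeconvConfig | None = None,
    ct_map: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Deconvolve every column of ``mixtures``; returns samples x cell types.

    Per-sample failures are logged and reported as all-NaN rows; the run
    continues.  An empty mixture set yields an empty table with a warning.
    """
    cfg = cfg or DeconvConfig()
    columns = list(ct_map.keys()) if ct_map else list(sig.columns)
    if mixtures.shape[1] == 0:
        warnings.warn("deconvolve_batch: no mixture samples given", stacklevel=2)
        return pd.DataFrame(columns=columns)
    rows = {}
    for sample in mixtures.columns:
        try:
            est = deconvolve(mixtures[[sample]], sig, cfg)
            if ct_map:
                est = aggregate_cell_types(est, ct_map)
            rows[sample] = est.to_series()
        except ValueError as exc:
            logger.warning("deconvolution failed for sample %r: %s", sample, exc)
            rows[sample] = pd.Series(np.nan, index=columns)
    table = pd.DataFrame(rows).T
    table.index.name = "sample_id"
    return table[columns]
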