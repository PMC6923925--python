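"""Reference gene-expression signature matrix (RefGES) construction.

The signature matrix is built from a compendium of pure-cell replicate
profiles in four steps:

1.  one-way fixed-effects ANOVA per feature across cell types, features
    sorted by ascending p-value;
2.  a scan over the number of retained top-ranked features ``G`` (in
    multiples of ``step``, default 500), keeping the ``G`` whose
    feature x sample submatrix has the smallest condition number
    kappa = sigma_max / sigma_min;
3.  per-cell-type medians over replicate columns;
4.  optional collapsing of probes to genes, keeping for each gene the
    probe with the highest median over all source samples.

A low condition number makes the downstream regression robust to
perturbations of the mixture profile, which is the reason the scan --
rather than a fixed significance cutoff -- decides the signature size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ANOVA ranking
# ---------------------------------------------------------------------------

def anova_rank(expr: pd.DataFrame, ann: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rank features by one-way ANOVA across cell types.

    Parameters
    ----------
    expr:
        Features x samples expression matrix.
    ann:
        Sample annotation indexed by sample_id with a ``cell_type`` column;
        every column of ``expr`` must be annotated and every cell type must
        have at least two replicates (the within-group variance is
        undefined otherwise).
    alpha:
        Raw p-value cutoff for the ``significant`` flag (no multiple-testing
        correction is applied).

    Returns
    -------
    DataFrame with columns ``F_statistic``, ``p_value``, ``significant``,
    ``rank``, indexed by feature, sorted by ascending p-value.  Ties are
    broken by descending F then lexicographic feature ID, so the ordering
    is deterministic.  Zero-variance features get p = 1 (never selected).
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    missing = [s for s in expr.columns if s not in ann.index]
    if missing:
        raise ValueError(f"unannotated sample(s): {missing[:5]}")
    labels = ann.loc[expr.columns, "cell_type"]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("ANOVA needs at least 2 cell types")
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(f"cell type(s) with < 2 replicates: {dict(thin)}")

    X = expr.to_numpy(dtype=float)
    n = X.shape[1]
    k = len(counts)
    grand = X.mean(axis=1)

    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for ct, n_g in counts.items():
        cols = (labels == ct).to_numpy()
        gmean = X[:, cols].mean(axis=1)
        ssb += n_g * (gmean - grand) ** 2
        ssw += ((X[:, cols] - gmean[:, None]) ** 2).sum(axis=1)

    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    # Degenerate rows: no within-group variance.  If between-group variance
    # also vanishes the feature is constant -> p = 1, never selected; if the
    # groups differ exactly, separation is perfect -> p = 0.
    tol = np.maximum(1e-12, 1e-12 * np.abs(grand))
    const_rows = (ssw <= tol) & (ssb <= tol)
    perfect_rows = (ssw <= tol) & ~const_rows
    F = np.where(const_rows, 0.0, F)
    F = np.where(perfect_rows, np.inf, F)
    p = stats.f.sf(F, df_b, df_w)
    p = np.where(const_rows, 1.0, p)
    p = np.where(perfect_rows, 0.0, p)

    table = pd.DataFrame(
        {"F_statistic": F, "p_value": p, "significant": p < alpha},
        index=expr.index,
    )
    order = np.lexsort(
        (table.index.to_numpy(), -table["F_statistic"].to_numpy(), table["p_value"].to_numpy())
    )
    table = table.iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    return table


# ---------------------------------------------------------------------------
# Condition number and the G scan
# ---------------------------------------------------------------------------

def condition_number(matrix: np.ndarray | pd.DataFrame, mode: str = "exact") -> float:
    """2-norm condition number kappa = sigma_max / sigma_min.

    ``mode="exact"`` computes the full SVD.  ``mode="approx"`` computes the
    1-norm condition of the triangular factor of a QR decomposition — the
    classic fast estimate popularized by LINPACK-style ``kappa`` routines;
    it agrees with the exact value to within a modest factor and is cheaper
    for very tall matrices.  Returns ``inf`` when the matrix is singular.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError(f"condition_number needs a non-empty 2-D matrix, got shape {A.shape}")
    if not np.isfinite(A).all():
        raise ValueError("condition_number: matrix contains non-finite values")
    if mode == "exact":
        s = np.linalg.svd(A, compute_uv=False)
        # rank-deficient to working precision counts as singular
        tol = max(A.shape) * np.finfo(float).eps * s[0]
        if s[-1] <= tol:
            return np.inf
        return float(s[0] / s[-1])
    if mode == "approx":
        if A.shape[0] < A.shape[1]:
            A = A.T
        R = np.linalg.qr(A, mode="r")
        d = np.abs(np.diag(R))
        if d.min() == 0.0:
            return np.inf
        R_inv = linalg.solve_triangular(R, np.eye(R.shape[0]))
        return float(np.linalg.norm(R, 1) * np.linalg.norm(R_inv, 1))
    raise ValueError(f"unknown kappa mode {mode!r}; expected 'exact' or 'approx'")


@dataclass
class ConditionScan:
    """Result of the signature-size scan.

    ``grid`` holds one (G, kappa) row per evaluated candidate; ``G_star``
    is the G attaining the minimal kappa (the first one on exact ties).
    """

    grid: pd.DataFrame  # columns: G, kappa
    G_star: int

    def __post_init__(self) -> None:
        kappas = self.grid["kappa"].to_numpy()
        star = self.grid.loc[self.grid["G"] == self.G_star, "kappa"].to_numpy()
        if star.size != 1 or not (star[0] <= kappas).all():
            raise ValueError("G_star must attain the minimal kappa on the grid")

    @property
    def kappa_star(self) -> float:
        return float(self.grid.loc[self.grid["G"] == self.G_star, "kappa"].iloc[0])


def scan_optimal_G(
    ranked: pd.DataFrame,
    expr: pd.DataFrame,
    step: int = 500,
    *,
    kappa_mode: str = "exact",
    include_remainder: bool = False,
) -> ConditionScan:
    """Scan G = step, 2*step, ... over significant features, minimizing kappa.

    For each G the condition number of the top-G-feature x all-samples
    submatrix is evaluated; the grid stops at the number of significant
    features.  When fewer than ``step`` features are significant the grid
    is the single point at that count.  ``include_remainder`` appends the
    final partial bin (all significant features) when it is not a multiple
    of ``step``.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    missing = ranked.index.difference(expr.index)
    if len(missing):
        raise ValueError(f"ranked table contains features absent from expression matrix: {list(missing[:5])}")
    n_sig = int(ranked["significant"].sum())
    if n_sig == 0:
        raise ValueError("no significant features to scan")
    grid_Gs = list(range(step, n_sig + 1, step))
    if not grid_Gs:
        grid_Gs = [n_sig]
    elif include_remainder and grid_Gs[-1] != n_sig:
        grid_Gs.append(n_sig)
    top_features = ranked.index.to_numpy()
    rows = []
    for G in grid_Gs:
        sub = expr.loc[top_features[:G]]
        rows.append((G, condition_number(sub.to_numpy(), mode=kappa_mode)))
    grid = pd.DataFrame(rows, columns=["G", "kappa"])
    G_star = int(grid.loc[grid["kappa"].idxmin(), "G"])  # idxmin -> first minimum
    return ConditionScan(grid=grid, G_star=G_star)


# ---------------------------------------------------------------------------
# Medians and probe collapsing
# ---------------------------------------------------------------------------

def summarize_by_cell_type(
    expr: pd.DataFrame, ann: pd.DataFrame, cell_type_order: list[str] | None = None
) -> pd.DataFrame:
    """Median expression per feature within each cell type's replicates.

    Columns follow ``cell_type_order`` when given, else alphabetical order.
    """
    labels = ann.loc[expr.columns, "cell_type"]
    medians = expr.T.groupby(labels, observed=True).median().T
    order = cell_type_order or sorted(medians.columns)
    missing = set(order) - set(medians.columns)
    if missing:
        raise ValueError(f"cell type(s) in requested order not present: {sorted(missing)}")
    return medians[order]


def collapse_probes(
    sig: pd.DataFrame, source_expr: pd.DataFrame, probe_map: pd.Series
) -> pd.DataFrame:
    """Collapse a probe-level signature to gene level.

    For each gene with multiple probes, the retained probe is the one with
    the highest median over ALL source samples (ties broken by lexicographic
    probe ID).  Probes without a mapping are dropped (count logged).
    An empty map is the identity.
    """
    if len(probe_map) == 0:
        return sig
    mapped = sig.index.intersection(probe_map.index)
    n_dropped = len(sig.index) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropping %d unmapped probe(s)", n_dropped)
    if len(mapped) == 0:
        raise ValueError("no probe in the signature is covered by the probe map")
    overall_median = source_expr.loc[mapped].median(axis=1)
    choice = pd.DataFrame(
        {
            "gene": probe_map.loc[mapped].to_numpy(),
            "median": overall_median.to_numpy(),
            "probe": mapped.to_numpy(),
        }
    )
    # highest median wins; on ties the lexicographically first probe
    choice = choice.sort_values(["gene", "median", "probe"], ascending=[True, False, True])
    winners = choice.drop_duplicates("gene", keep="first")
    out = sig.loc[winners["probe"]]
    out.index = pd.Index(winners["gene"].to_numpy(), name="gene_symbol")
    return out.sort_index()


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class SignatureBuild:
    """Artifacts of a full signature build."""

    signature: pd.DataFrame  # genes x cell types (medians)
    scan: ConditionScan
    ranked: pd.DataFrame
    n_selected_probes: int = field(default=0)


def build_signature(
    expr: pd.DataFrame,
    ann: pd.DataFrame,
    probe_map: pd.Series | None = None,
    *,
    alpha: float = 0.05,
    step: int = 500,
    kappa_mode: str = "exact",
    cell_type_order: list[str] | None = None,
) -> SignatureBuild:
    """ANOVA-rank, scan for the optimal G, take per-type medians, collapse probes.

    When ``probe_map`` is ``None`` features are assumed to already be genes
    and no collapsing happens.
    """
    ranked = anova_rank(expr, ann, alpha=alpha)
    scan = scan_optimal_G(ranked, expr, step=step, kappa_mode=kappa_mode)
    selected = ranked.index[: scan.G_star]
    sig = summarize_by_cell_type(expr.loc[selected], ann, cell_type_order=cell_type_order)
    if probe_map is not None and len(probe_map):
        sig = collapse_probes(sig, expr, probe_map)
    return SignatureBuild(signature=sig, scan=scan, ranked=ranked, n_selected_probes=int(scan.G_star))


# ---------------------------------------------------------------------------
# LDA QA embedding
# ---------------------------------------------------------------------------

def lda_embed(expr: pd.DataFrame, ann: pd.DataFrame, n_axes: int = 3) -> pd.DataFrame:
    """Fisher linear-discriminant embedding of samples, for signature QA.

    Projects each sample (column of ``expr``) onto the leading discriminant
    axes — the directions maximizing between-class over within-class
    scatter.  With k classes at most k - 1 axes exist; fewer axes than
    requested are returned in that case.  A singular within-class scatter
    gets a scale-aware ridge (1e-6 * trace(S_W)/p on the diagonal) and a
    warning.

    Returns a samples x axes DataFrame (columns ``LD1``, ``LD2``, ...).
    """
    X = expr.to_numpy(dtype=float).T  # samples x features
    labels = ann.loc[expr.columns, "cell_type"].to_numpy()
    classes = np.unique(labels)
    k = len(classes)
    if k < 2:
        raise ValueError("LDA needs at least 2 classes")
    n_axes = min(n_axes, k - 1)
    p = X.shape[1]
    grand = X.mean(axis=0)
    S_w = np.zeros((p, p))
    S_b = np.zeros((p, p))
    for c in classes:
        Xc = X[labels == c]
        mu = Xc.mean(axis=0)
        d = Xc - mu
        S_w += d.T @ d
        m = (mu - grand)[:, None]
        S_b += len(Xc) * (m @ m.T)

    ridge = 1e-6 * np.trace(S_w) / p
    if ridge == 0.0:  # all classes are point masses; fall back to S_b scale
        ridge = max(1e-6 * np.trace(S_b) / p, 1e-12)
    try:
        evals, evecs = linalg.eigh(S_b, S_w)
    except linalg.LinAlgError:
        warnings.warn(
            "singular within-class scatter; applying ridge "
            f"{ridge:.3g} to its diagonal",
            stacklevel=2,
        )
        evals, evecs = linalg.eigh(S_b, S_w + ridge * np.eye(p))
    order = np.argsort(evals)[::-1][:n_axes]
    W = evecs[:, order]
    coords = (X - grand) @ W
    return pd.DataFrame(
        coords,
        index=expr.columns,
        columns=[f"LD{i + 1}" for i in range(coords.shape[1])],
    )
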