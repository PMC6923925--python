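"""Agreement statistics between predicted and true cell compositions.

Implements the agreement toolkit used to benchmark the deconvolution:

* MAPE — mean absolute percentage error, mean of |pred - truth|/truth x 100
  (zero-truth entries are excluded, with a logged count);
* Bland-Altman analysis — per-point (average, difference) pairs and the
  95% limits of agreement, LoA = mean difference +/- 1.96 x SD of the
  differences (sample SD, n-1 denominator);
* cumulative difference tables — the cumulative percentage of observations
  whose |difference| falls at or below each bin edge;
* grouped reports over a long-format prediction/truth ledger, emitting
  plot-ready tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: z-quantile defining the 95% limits of agreement.
LOA_Z = 1.96

#: default |difference| bin edges for cumulative tables (fraction units)
DEFAULT_BIN_EDGES = (0.01, 0.02, 0.05, 0.10, 0.20, 0.50)


@dataclass
class AgreementStats:
    """Summary agreement between predictions and truth for one group."""

    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    mape_percent: float
    n: int

    def __post_init__(self) -> None:
        if self.sd_difference < 0:
            raise ValueError("sd_difference must be >= 0")
        expected_lo = self.mean_difference - LOA_Z * self.sd_difference
        expected_hi = self.mean_difference + LOA_Z * self.sd_difference
        if not (
            np.isclose(self.loa_lower, expected_lo, rtol=0, atol=1e-9)
            and np.isclose(self.loa_upper, expected_hi, rtol=0, atol=1e-9)
        ):
            raise ValueError("LoA bounds must equal mean_difference +/- 1.96*SD")


def _as_arrays(predicted, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.size != t.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {t.size} truths")
    return p, t


def mape(predicted, truth) -> float:
    """Mean absolute percentage error, in percent.

    Entries with zero truth are excluded from the mean (count logged);
    an all-zero truth vector is an error.
    """
    p, t = _as_arrays(predicted, truth)
    nonzero = t != 0
    n_dropped = int((~nonzero).sum())
    if nonzero.sum() == 0:
        raise ValueError("all truth entries are zero; MAPE undefined")
    if n_dropped:
        logger.info("mape: excluded %d zero-truth entr%s", n_dropped, "y" if n_dropped == 1 else "ies")
    return float(np.mean(np.abs(p[nonzero] - t[nonzero]) / t[nonzero]) * 100.0)


def bland_altman(predicted, truth) -> tuple[AgreementStats, pd.DataFrame]:
    """Bland-Altman agreement analysis of predictions against truth.

    Returns the summary stats and a per-point table with columns
    ``average`` ((pred+truth)/2) and ``difference`` (pred - truth), the
    coordinates of a Bland-Altman scatter plot.
    """
    p, t = _as_arrays(predicted, truth)
    if p.size < 2:
        raise ValueError("Bland-Altman needs n >= 2 (SD undefined otherwise)")
    diff = p - t
    mean_d = float(diff.mean())
    sd_d = float(diff.std(ddof=1))
    stats = AgreementStats(
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_lower=mean_d - LOA_Z * sd_d,
        loa_upper=mean_d + LOA_Z * sd_d,
        mape_percent=mape(p, t) if (t != 0).any() else 0.0,
        n=int(p.size),
    )
    points = pd.DataFrame({"average": (p + t) / 2.0, "difference": diff})
    return stats, points


def cumulative_difference_table(predicted, truth, bin_edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Cumulative % of observations with |pred - truth| <= each edge.

    The table ends with an unbounded bin covering all observations (100%).
    Percentages are monotone non-decreasing; observation order is
    irrelevant.
    """
    p, t = _as_arrays(predicted, truth)
    if p.size == 0:
        raise ValueError("empty input")
    edges = list(bin_edges)
    if any(b >= a for b, a in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly ascending")
    absdiff = np.abs(p - t)
    rows = [(f"<= {edge:g}", float((absdiff <= edge).mean() * 100.0)) for edge in edges]
    rows.append(("all", 100.0))
    return pd.DataFrame(rows, columns=["bin", "cumulative_percent"])


def agreement_report(
    ledger: pd.DataFrame, group_by: str = "cell_type", bin_edges=DEFAULT_BIN_EDGES
) -> dict[str, pd.DataFrame]:
    """Grouped agreement statistics over a prediction/truth ledger.

    Parameters
    ----------
    ledger:
        Long-format table with columns ``sample`` (or ``mixture_id``),
        ``cell_type``, ``true_weight`` and ``predicted_fraction`` — the
        shape emitted by the benchmark drivers.
    group_by:
        ``"cell_type"`` (one group per signature cell type, the
        Bland-Altman view) or ``"sample"`` (one group per mixture, the
        MAPE box-plot view).

    Returns
    -------
    dict with keys ``stats`` (one AgreementStats row per group),
    ``ba_points`` (long-format Bland-Altman scatter coordinates) and
    ``cumulative`` (per-group cumulative difference tables).  Groups with
    fewer than 2 observations are skipped with a warning.
    """
    if ledger.empty:
        raise ValueError("empty ledger")
    key = {"cell_type": "cell_type", "sample": "sample"}.get(group_by)
    if key is None:
        raise ValueError(f"group_by must be 'cell_type' or 'sample', got {group_by!r}")
    frame = ledger.rename(columns={"mixture_id": "sample"}) if "sample" not in ledger.columns else ledger

    stat_rows, ba_frames, cum_frames = [], [], []
    for name, grp in frame.groupby(key, sort=True):
        if len(grp) < 2:
            logger.warning("agreement_report: group %r has n < 2, skipped", name)
            continue
        stats, points = bland_altman(grp["predicted_fraction"], grp["true_weight"])
        stat_rows.append(
            {
                key: name,
                "n": stats.n,
                "mean_difference": stats.mean_difference,
                "sd_difference": stats.sd_difference,
                "loa_lower": stats.loa_lower,
                "loa_upper": stats.loa_upper,
                "mape_percent": stats.mape_percent,
            }
        )
        points.insert(0, key, name)
        ba_frames.append(points)
        cum = cumulative_difference_table(grp["predicted_fraction"], grp["true_weight"], bin_edges)
        cum.insert(0, key, name)
        cum_frames.append(cum)
    if not stat_rows:
        raise ValueError("no group had enough observations for agreement statistics")
    return {
        "stats": pd.DataFrame(stat_rows).set_index(key),
        "ba_points": pd.concat(ba_frames, ignore_index=True),
        "cumulative": pd.concat(cum_frames, ignore_index=True),
    }


def plot_report(report: dict[str, pd.DataFrame], out_dir, group_key: str = "cell_type") -> list:
    """Optional figure rendering (Bland-Altman scatter + MAPE box plot).

    Requires matplotlib; the canonical outputs remain the TSV tables.
    Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    stats = report["stats"]
    points = report["ba_points"]
    groups = list(stats.index)
    ncols = min(3, len(groups))
    nrows = -(-len(groups) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for ax, g in zip(axes.ravel(), groups):
        sub = points[points[group_key] == g]
        ax.scatter(sub["average"], sub["difference"], s=8)
        for y in (stats.loc[g, "loa_lower"], stats.loc[g, "mean_difference"], stats.loc[g, "loa_upper"]):
            ax.axhline(y, ls="--", lw=0.8, color="grey")
        ax.set_title(str(g), fontsize=9)
    for ax in axes.ravel()[len(groups):]:
        ax.set_visible(False)
    fig.supxlabel("average of prediction and truth")
    fig.supylabel("prediction - truth")
    fig.tight_layout()
    ba_path = out_dir / "bland_altman.png"
    fig.savefig(ba_path, dpi=120)
    plt.close(fig)
    written.append(ba_path)

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(groups), 4))
    ax.bar(range(len(groups)), stats["mape_percent"])
    ax.set_xticks(range(len(groups)), [str(g) for g in groups], rotation=45, ha="right")
    ax.set_ylabel("MAPE (%)")
    fig.tight_layout()
    mape_path = out_dir / "mape.png"
    fig.savefig(mape_path, dpi=120)
    plt.close(fig)
    written.append(mape_path)
    return written
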