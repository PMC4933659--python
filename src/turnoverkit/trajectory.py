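"""Aging-trajectory index: proteome displacement as a percentage of WT aging.

The proteome-wide abundance changes of each group are condensed into a single
signed statistic.  Over the proteins that change significantly with wild-type
aging, let ``a_i = log2(OWT_i / YWT_i)`` be the aging effect and
``d_i = log2(G_i / YWT_i)`` a group's displacement from young wild-type.  Each
displacement is projected onto the direction of aging,

    s_i = sign(a_i) * d_i,

so changes in the same direction as aging are positive and opposite changes
negative, and the index is

    index(G) = 100 * mean(s_i) / mean(|a_i|).

By construction index(YWT) = 0 and index(OWT) = 100 on any protein set with a
non-degenerate aging effect.  The wild-type aging magnitude itself is also
reported on the linear scale, as the mean of max(r, 1/r) over the selected
proteins (so a halving and a doubling both count as a 2-fold change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryIndex",
    "select_aging_proteins",
    "wt_aging_magnitude",
    "trajectory_index",
    "trajectory_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrajectoryIndex:
    group: str
    index_percent: float
    n_proteins: int
    wt_aging_magnitude: float


def select_aging_proteins(
    stats: pd.DataFrame,
    threshold: float = 0.05,
    threshold_type: str = "p",
) -> pd.Index:
    """Proteins whose abundance changes significantly with wild-type aging.

    ``stats`` carries per-protein p_value (and q_value) for the OWT-vs-YWT
    comparison.  ``threshold_type`` selects raw p-values ("p", the default)
    or BH q-values ("q").  The threshold is strict (< threshold).
    """
    if threshold_type not in ("p", "q"):
        raise ValueError("threshold_type must be 'p' or 'q'")
    col = "p_value" if threshold_type == "p" else "q_value"
    if col not in stats.columns:
        raise ValueError(f"stats table lacks column {col!r}")
    sel = stats.loc[stats[col] < threshold, "protein"]
    if sel.empty:
        raise ValueError(
            f"no proteins pass {threshold_type} < {threshold}; relax the threshold"
        )
    return pd.Index(sel)


def wt_aging_magnitude(
    selected: pd.Index, owt_means: pd.Series, ywt_means: pd.Series
) -> float:
    """Mean absolute linear fold change from YWT to OWT over selected proteins.

    Per protein the magnitude is max(r, 1/r) with r = mean(OWT)/mean(YWT), so
    up- and down-regulation contribute symmetrically; proteins with a zero or
    missing denominator are dropped with a log entry.
    """
    o = owt_means.reindex(selected)
    y = ywt_means.reindex(selected)
    ok = (y > 0) & (o > 0) & y.notna() & o.notna()
    dropped = int((~ok).sum())
    if dropped:
        logger.info("wt_aging_magnitude: dropped %d proteins with zero means", dropped)
    r = (o[ok] / y[ok]).to_numpy()
    if r.size == 0:
        raise ValueError("no usable proteins for aging magnitude")
    return float(np.mean(np.maximum(r, 1.0 / r)))


def trajectory_index(
    group_means: pd.Series,
    ywt_means: pd.Series,
    owt_means: pd.Series,
    selected: pd.Index,
    group: str = "",
) -> TrajectoryIndex:
    """Signed percent-of-WT-aging displacement for one group."""
    g = group_means.reindex(selected)
    y = ywt_means.reindex(selected)
    o = owt_means.reindex(selected)
    ok = (g > 0) & (y > 0) & (o > 0)
    if not ok.all():
        logger.info("trajectory_index: dropped %d proteins", int((~ok).sum()))
    g, y, o = g[ok], y[ok], o[ok]
    if len(g) == 0:
        raise ValueError("no proteins with finite ratios for this group")
    a = np.log2(o.to_numpy() / y.to_numpy())
    d = np.log2(g.to_numpy() / y.to_numpy())
    denom = float(np.mean(np.abs(a)))
    if denom == 0:
        raise ValueError("degenerate aging effect: mean |log2(OWT/YWT)| is zero")
    index = 100.0 * float(np.mean(np.sign(a) * d)) / denom
    return TrajectoryIndex(
        group=group,
        index_percent=index,
        n_proteins=int(len(g)),
        wt_aging_magnitude=wt_aging_magnitude(pd.Index(g.index), o, y),
    )


def trajectory_table(
    group_means: pd.DataFrame,
    selected: pd.Index,
    young_wt: str = "YWT",
    old_wt: str = "OWT",
) -> pd.DataFrame:
    """Trajectory index for every group column of a group-means matrix."""
    rows = []
    for g in group_means.columns:
        ti = trajectory_index(
            group_means[g], group_means[young_wt], group_means[old_wt], selected, g
        )
        rows.append(
            {
                "group": g,
                "index_percent": ti.index_percent,
                "n_proteins": ti.n_proteins,
                "wt_aging_magnitude": ti.wt_aging_magnitude,
            }
        )
    return pd.DataFrame(rows)
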