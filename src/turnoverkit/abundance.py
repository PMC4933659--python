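"""Protein-level relative abundance, group contrasts and correlation analysis.

Relative abundance is the sum of a protein's unique-peptide MS1 peak areas per
sample.  Group contrasts are log2 ratios of group means.  Because contrasts
such as OWT/YWT and YmCAT/YWT share a denominator, their raw correlation is
inflated ("spurious correlation" of ratio variables); partial correlation
controlling the shared term removes that artifact and is the default
inferential tool here, rank-based to match Spearman-style reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .kinetics import adjust_fdr

__all__ = [
    "AbundanceMatrix",
    "ContrastRatios",
    "PartialCorrelationResult",
    "protein_abundance",
    "contrast_ratios",
    "partial_correlation",
    "pathway_correlations",
    "fisher_enrichment",
    "cluster_order",
    "group_difference_tests",
]

logger = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Proteins x samples matrix of non-negative MS1 peak areas."""

    values: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if (self.values.fillna(0) < 0).any().any():
            raise ValueError("abundance matrix must be non-negative")
        unmapped = set(self.values.columns) - set(self.sample_groups.index)
        if unmapped:
            raise ValueError(f"samples without a group: {sorted(unmapped)}")

    def group_means(self) -> pd.DataFrame:
        """Per-protein mean over each group's samples (NaN-aware)."""
        return self.values.T.groupby(self.sample_groups).mean().T


@dataclass
class ContrastRatios:
    """Per-protein log2 ratio of group means for one named contrast."""

    label: str
    numerator: str
    denominator: str
    log2_ratio: pd.Series
    n_dropped: int = 0


@dataclass(frozen=True)
class PartialCorrelationResult:
    r_partial: float
    p_value: float
    n: int
    controlled_variable: str
    method: str


def protein_abundance(
    peptide_areas: pd.DataFrame, area_column: str = "total_area"
) -> AbundanceMatrix:
    """Roll peptide areas up to protein level (sum of unique peptides).

    ``peptide_areas`` is tidy with columns protein, peptide, sample, group and
    an area column.  A peptide missing in a sample is absent from the sum,
    not imputed as zero; the resulting protein/sample cell is NaN only when
    no peptide of the protein was observed.
    """
    if (peptide_areas[area_column] < 0).any():
        raise ValueError("peptide areas must be non-negative")
    sums = (
        peptide_areas.groupby(["protein", "sample"], sort=True)[area_column]
        .sum()
        .unstack("sample")
    )
    groups = peptide_areas.drop_duplicates("sample").set_index("sample")["group"]
    return AbundanceMatrix(values=sums, sample_groups=groups.loc[sums.columns])


def contrast_ratios(
    matrix: AbundanceMatrix, contrasts: list[tuple[str, str]]
) -> list[ContrastRatios]:
    """log2(mean numerator group / mean denominator group) per protein.

    Proteins with a non-positive or missing group mean in either member are
    dropped from that contrast and counted.
    """
    means = matrix.group_means()
    out = []
    for num, den in contrasts:
        for g in (num, den):
            if g not in means.columns or matrix.sample_groups.eq(g).sum() == 0:
                raise ValueError(f"contrast group {g!r} has no samples")
        a, b = means[num], means[den]
        ok = (a > 0) & (b > 0)
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.info("%s/%s: dropped %d proteins with zero/missing mean", num, den, n_dropped)
        out.append(
            ContrastRatios(
                label=f"{num}/{den}",
                numerator=num,
                denominator=den,
                log2_ratio=np.log2(a[ok] / b[ok]),
                n_dropped=n_dropped,
            )
        )
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def partial_correlation(
    x, y, z, rank_based: bool = True, control_label: str = "z"
) -> PartialCorrelationResult:
    """First-order partial correlation of x and y controlling z.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); the
    p-value comes from t = r * sqrt((n - 3) / (1 - r^2)) on n - 3 degrees of
    freedom.  With ``rank_based`` (default) all three vectors are replaced by
    their ranks first, giving a Spearman-flavored partial correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if y.size != n or z.size != n:
        raise ValueError("x, y, z must have equal length")
    if n < 4:
        raise ValueError("need n >= 4 observations")
    if rank_based:
        x, y, z = (stats.rankdata(v) for v in (x, y, z))
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.std(v) == 0:
            raise ValueError(f"degenerate variance in {name}")
    r_xy, r_xz, r_yz = _pearson(x, y), _pearson(x, z), _pearson(y, z)
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError("control variable collinear with x or y")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 3) / (1 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 3))
    return PartialCorrelationResult(
        r_partial=r,
        p_value=p,
        n=n,
        controlled_variable=control_label,
        method="spearman-partial" if rank_based else "pearson-partial",
    )


def pathway_correlations(
    values_a: pd.Series,
    values_b: pd.Series,
    pathways: dict[str, set[str]],
    min_shared: int = 3,
    top_n: int = 10,
    dedupe_union: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-pathway Spearman correlation of two per-protein statistics.

    For each pathway, correlates the two series over the intersection of its
    members with both indices (skipped with a log entry below ``min_shared``
    shared proteins).  Also reports pooled statistics — Spearman r/p and OLS
    slope of b on a — over the union of the ``top_n`` most significant
    pathways' proteins (deduplicated by default; with ``dedupe_union=False``
    proteins enter once per pathway membership).
    """
    shared = values_a.index.intersection(values_b.index)
    rows = []
    members_by_pathway = {}
    for name, members in pathways.items():
        prots = shared.intersection(pd.Index(sorted(members)))
        if len(prots) < min_shared:
            logger.info("pathway %s skipped: %d shared proteins", name, len(prots))
            continue
        r, p = stats.spearmanr(values_a.loc[prots], values_b.loc[prots])
        rows.append((name, float(r), float(p), len(prots)))
        members_by_pathway[name] = prots
    table = pd.DataFrame(rows, columns=["pathway", "spearman_r", "p_value", "n_proteins"])
    pooled = {}
    if not table.empty:
        top = table.nsmallest(min(top_n, len(table)), "p_value")["pathway"]
        if dedupe_union:
            pool_idx = pd.Index([])
            for name in top:
                pool_idx = pool_idx.union(members_by_pathway[name])
            a, b = values_a.loc[pool_idx], values_b.loc[pool_idx]
        else:
            parts_a, parts_b = [], []
            for name in top:
                parts_a.append(values_a.loc[members_by_pathway[name]])
                parts_b.append(values_b.loc[members_by_pathway[name]])
            a, b = pd.concat(parts_a), pd.concat(parts_b)
        r, p = stats.spearmanr(a, b)
        fit = stats.linregress(a.to_numpy(), b.to_numpy())
        pooled = {
            "spearman_r": float(r),
            "p_value": float(p),
            "ols_slope": float(fit.slope),
            "ols_r": float(fit.rvalue),
            "n_proteins": int(len(a)),
        }
    return table, pooled


def fisher_enrichment(
    significant: set[str], pathways: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """One-sided (upper-tail) Fisher/hypergeometric pathway enrichment.

    For each pathway, tests over-representation of the significant set in the
    pathway within the universe; q-values are BH across pathways.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(significant) <= set(universe):
        raise ValueError("significant set must be a subset of the universe")
    M = len(universe)
    N = len(significant)
    rows = []
    for name, members in pathways.items():
        inset = set(members) & set(universe)
        k = len(inset & set(significant))
        n = len(inset)
        # P(X >= k) for X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append((name, k, n, p))
    table = pd.DataFrame(rows, columns=["pathway", "n_hits", "n_pathway", "p_value"])
    if not table.empty:
        table["q_value"] = adjust_fdr(table["p_value"].to_numpy())
    return table


def cluster_order(
    matrix: pd.DataFrame,
    axis: str = "rows",
    method: str = "complete",
    center_rows: bool = False,
) -> list:
    """Leaf order of agglomerative clustering with Euclidean distance.

    ``axis`` is "rows" or "columns"; ``method`` is any scipy linkage method
    (complete by default for protein heatmaps, "ward" for pathway heatmaps).
    Missing entries are imputed by the row mean for distance computation only.
    ``center_rows`` subtracts each row's mean first (difference-from-mean
    heatmaps).  Ties are resolved deterministically (lowest index first).
    """
    data = matrix if axis == "rows" else matrix.T
    if data.shape[0] == 0:
        raise ValueError("empty matrix")
    X = data.to_numpy(dtype=float)
    if np.isnan(X).any():
        all_missing = np.isnan(X).all(axis=1)
        if all_missing.any():
            raise ValueError("row with all entries missing")
        row_means = np.nanmean(X, axis=1)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = row_means[idx[0]]
    if center_rows:
        X = X - X.mean(axis=1, keepdims=True)
    if X.shape[0] == 1:
        return list(data.index)
    Z = linkage(pdist(X, metric="euclidean"), method=method)
    return [data.index[i] for i in leaves_list(Z)]


def group_difference_tests(
    matrix: AbundanceMatrix, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-protein Welch t-test on log2 abundances between two groups.

    Returns protein, log2 fold change (b over a), p_value and BH q_value;
    proteins observed in fewer than two samples per group are dropped.
    """
    cols_a = matrix.sample_groups[matrix.sample_groups == group_a].index
    cols_b = matrix.sample_groups[matrix.sample_groups == group_b].index
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError("both groups need samples")
    A = np.log2(matrix.values[cols_a].where(matrix.values[cols_a] > 0))
    B = np.log2(matrix.values[cols_b].where(matrix.values[cols_b] > 0))
    ok = (A.notna().sum(axis=1) >= 2) & (B.notna().sum(axis=1) >= 2)
    A, B = A[ok], B[ok]
    t, p = stats.ttest_ind(
        B.to_numpy(), A.to_numpy(), axis=1, equal_var=False, nan_policy="omit"
    )
    out = pd.DataFrame(
        {
            "protein": A.index,
            "log2_fc": B.mean(axis=1).to_numpy() - A.mean(axis=1).to_numpy(),
            "p_value": p,
        }
    )
    out["q_value"] = adjust_fdr(out["p_value"].to_numpy())
    return out
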