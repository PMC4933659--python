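"""First-order protein-turnover kinetics: half-life fits and group comparisons.

Percent newly synthesized protein rises toward 100 with labeling time t as

    y(t) = 100 + beta1 * exp(alpha * t),

with amplitude ``beta1 <= 0`` and rate ``alpha < 0`` (for complete labeling
``beta1 = -100`` and ``y = 100 * (1 - exp(alpha t))``).  The half-life is
``t_1/2 = ln(2) / |alpha|``.  Per protein and group the curve is fitted by
nonlinear least squares over all peptide observations; groups are compared by
ANCOVA on the log-linearized response ``z = ln(100 - y)``, which is linear in
t with slope alpha, using peptide identity as a blocking factor to absorb
peptide-to-peptide offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HalfLifeFit",
    "GroupComparison",
    "fit_half_life",
    "fit_all_half_lives",
    "compare_groups_ancova",
    "normalize_to_reference",
    "summarize_medians",
    "adjust_fdr",
]

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class HalfLifeFit:
    protein: str
    group: str
    alpha: float
    beta1: float
    half_life: float
    se_alpha: float
    n_obs: int
    n_peptides: int
    converged: bool


@dataclass(frozen=True)
class GroupComparison:
    protein: str
    group_a: str
    group_b: str
    delta_alpha: float
    p_value: float
    n_clipped: int = 0
    q_value: float = float("nan")


def _exp_model(t, beta1, alpha):
    return 100.0 + beta1 * np.exp(alpha * t)


def fit_half_life(observations: pd.DataFrame) -> HalfLifeFit:
    """Fit ``y = 100 + beta1 * exp(alpha t)`` for one protein in one group.

    ``observations`` must carry columns day, percent_new (and optionally
    peptide, protein, group).  Starting values are ``beta1 = -100`` (no
    pre-labeled protein at t = 0) and ``alpha = -ln(2) / median(day)``.
    Non-convergence is flagged on the result, not raised.
    """
    t = observations["day"].to_numpy(dtype=float)
    y = observations["percent_new"].to_numpy(dtype=float)
    protein = str(observations["protein"].iloc[0]) if "protein" in observations else ""
    group = str(observations["group"].iloc[0]) if "group" in observations else ""
    n_pep = observations["peptide"].nunique() if "peptide" in observations else 1
    if len(t) < 3 or np.unique(t).size < 2:
        raise ValueError(
            f"insufficient data for {protein}/{group}: need >= 3 observations "
            "spanning >= 2 distinct days"
        )
    p0 = (-100.0, -LN2 / float(np.median(t)))
    try:
        popt, pcov = curve_fit(
            _exp_model,
            t,
            y,
            p0=p0,
            maxfev=500 * (len(t) + 1),
            xtol=1e-12,
            ftol=1e-12,
        )
        beta1, alpha = float(popt[0]), float(popt[1])
        se_alpha = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
        converged = bool(np.isfinite(alpha) and alpha < 0 and beta1 <= 0)
    except RuntimeError:
        beta1, alpha, se_alpha, converged = np.nan, np.nan, np.nan, False
    half_life = LN2 / (-alpha) if converged else np.nan
    return HalfLifeFit(
        protein=protein,
        group=group,
        alpha=alpha,
        beta1=beta1,
        half_life=half_life,
        se_alpha=se_alpha,
        n_obs=len(t),
        n_peptides=int(n_pep),
        converged=converged,
    )


def fit_all_half_lives(observations: pd.DataFrame) -> pd.DataFrame:
    """Fit every (protein, group) cell of a percent-new table.

    Cells failing the data preconditions are skipped with a log entry.
    Returns a tidy frame of fit results.
    """
    rows = []
    for (protein, group), sub in observations.groupby(["protein", "group"], sort=True):
        try:
            fit = fit_half_life(sub)
        except ValueError:
            logger.info("skipping %s/%s: insufficient data", protein, group)
            continue
        rows.append(fit.__dict__)
    if not rows:
        raise ValueError("no (protein, group) cell had enough data to fit")
    return pd.DataFrame(rows)


def _ancova_design(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    """Design matrix for z ~ intercept + peptide blocks + day + group + day:group.

    Returns (X, z, interaction_column_index).
    """
    z = df["_z"].to_numpy()
    t = df["day"].to_numpy(dtype=float)
    # reference level = first-appearing group; indicator marks the other
    g = (df["group"] != df["group"].iloc[0]).to_numpy(dtype=float)
    peptides = pd.Categorical(df["peptide"])
    blocks = pd.get_dummies(peptides, drop_first=True).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), blocks, t, g, t * g])
    return X, z, X.shape[1] - 1


def compare_groups_ancova(
    obs_a: pd.DataFrame, obs_b: pd.DataFrame, clip_at: float = 99.9
) -> GroupComparison:
    """Test slope (turnover-rate) equality between two groups by ANCOVA.

    Both inputs carry day, percent_new, peptide (and protein/group labels).
    The response is linearized as ``z = ln(100 - y)`` so that the slope in t
    is the first-order rate alpha; the model is
    ``z ~ peptide_block + day + group + day:group`` and the reported p-value
    tests the day-by-group interaction (slope difference).  Observations with
    ``y >= 100`` are clipped to ``clip_at`` before the transform and counted.
    """
    frames = []
    for obs, tag in ((obs_a, "A"), (obs_b, "B")):
        df = obs.copy()
        if "group" not in df or df["group"].nunique() != 1:
            df["group"] = tag
        if "peptide" not in df:
            df["peptide"] = "pep0"
        frames.append(df)
    if frames[0]["group"].iloc[0] == frames[1]["group"].iloc[0]:
        frames[1] = frames[1].assign(group=frames[1]["group"].iloc[0] + "_b")
    df = pd.concat(frames, ignore_index=True)

    y = df["percent_new"].to_numpy(dtype=float)
    clipped = y >= 100.0
    n_clipped = int(clipped.sum())
    for tag, obs in (("A", frames[0]), ("B", frames[1])):
        grp_clip = (obs["percent_new"] >= 100.0).sum()
        if grp_clip == len(obs):
            raise ValueError(
                f"all observations in group {tag} required clipping; "
                "fit is unreliable"
            )
    if n_clipped:
        logger.info("clipped %d observations with percent_new >= 100", n_clipped)
        y = np.where(clipped, clip_at, y)
    df["_z"] = np.log(100.0 - y)

    X, z, j = _ancova_design(df)
    res = sm.OLS(z, X).fit()
    delta = float(res.params[j])
    p = float(res.pvalues[j])
    if not np.isfinite(p):  # identical data: zero residual variance
        p = 1.0
    protein = str(df["protein"].iloc[0]) if "protein" in df else ""
    return GroupComparison(
        protein=protein,
        group_a=str(frames[0]["group"].iloc[0]),
        group_b=str(frames[1]["group"].iloc[0]),
        delta_alpha=delta,
        p_value=p,
        n_clipped=n_clipped,
    )


def normalize_to_reference(
    fits: pd.DataFrame, reference_group: str
) -> tuple[pd.DataFrame, list[str]]:
    """Per-protein log2 half-life ratio of each group to the reference group.

    Proteins lacking a converged reference fit are dropped and returned in
    the log list.  Positive values mean a longer half-life than the reference.
    """
    if reference_group not in set(fits["group"]):
        raise ValueError(f"unknown reference group {reference_group!r}")
    conv = fits[fits["converged"]]
    ref = conv[conv["group"] == reference_group].set_index("protein")["half_life"]
    dropped = sorted(set(conv["protein"]) - set(ref.index))
    kept = conv[conv["protein"].isin(ref.index)].copy()
    kept["log2_hl_ratio"] = np.log2(
        kept["half_life"].to_numpy() / ref.loc[kept["protein"]].to_numpy()
    )
    out = kept[["protein", "group", "half_life", "log2_hl_ratio"]].reset_index(
        drop=True
    )
    for prot in dropped:
        logger.info("dropped %s: no converged reference fit", prot)
    return out, dropped


def summarize_medians(fits: pd.DataFrame) -> pd.Series:
    """Median half-life per group over converged fits only.

    Groups with zero converged fits are omitted with a warning.  Even counts
    use the midpoint of the central pair (numpy median convention).
    """
    out = {}
    for group, sub in fits.groupby("group", sort=True):
        ok = sub[sub["converged"]]
        if ok.empty:
            logger.warning("group %s has no converged fits; omitted", group)
            continue
        out[group] = float(np.median(ok["half_life"]))
    return pd.Series(out, name="median_half_life")


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
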