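"""Isotopologue-envelope deconvolution for heavy-leucine metabolic labeling.

A peptide with ``L`` leucine residues observed during a [5,5,5-2H3]-leucine
labeling experiment produces an envelope of ``L + 1`` isotopologue peaks,
indexed by the number of heavy leucines ``m = 0..L``.  Molecules synthesized
before the diet switch carry no label (``m = 0``); molecules synthesized
afterwards draw each leucine independently from a precursor pool in which a
fraction ``p`` of free leucine is heavy.  The expected envelope is therefore a
two-component mixture,

    P(m) = (1 - f) * [m == 0] + f * C(L, m) * p**m * (1 - p)**(L - m),

where ``f`` is the fraction of the peptide pool newly synthesized since the
diet switch.  This module fits ``(f, p)`` to observed peak areas by least
squares on the unit-normalized envelope, scores envelope quality by cosine
similarity to the best-fitting theoretical envelope (the "turnover score"),
estimates the precursor-pool enrichment per sample by profiling ``f`` out of
every peptide's fit, and derives/applies the turnover-score quality filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import comb

__all__ = [
    "LabeledPeptideSpectrum",
    "DeconvolutionResult",
    "theoretical_distribution",
    "turnover_score",
    "deconvolve_spectrum",
    "deconvolve_table",
    "estimate_pool_enrichment",
    "estimate_pool_per_sample",
    "derive_score_cutoff",
    "filter_by_score",
]

#: Mass increment (Da) of one [5,5,5-2H3]-leucine over light leucine.
HEAVY_LEUCINE_MASS_SHIFT = 3.0188325

#: Default turnover-score retention threshold.
DEFAULT_SCORE_CUTOFF = 0.98

_AREA_COL = re.compile(r"^area_m(\d+)$")


@dataclass(frozen=True)
class LabeledPeptideSpectrum:
    """One peptide's isotopologue peak-area envelope in one sample."""

    peptide: str
    protein: str
    sample: str
    group: str
    day: float
    leucine_count: int
    areas: np.ndarray

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "areas", areas)
        if self.leucine_count < 1:
            raise ValueError(f"leucine_count must be >= 1, got {self.leucine_count}")
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")
        if areas.ndim != 1 or areas.size != self.leucine_count + 1:
            raise ValueError(
                f"areas must have length L+1 = {self.leucine_count + 1}, "
                f"got shape {areas.shape}"
            )
        if np.any(areas < 0) or not np.all(np.isfinite(areas)):
            raise ValueError("areas must be finite and non-negative")

    @property
    def usable(self) -> bool:
        return bool(np.any(self.areas > 0))


@dataclass(frozen=True)
class DeconvolutionResult:
    """Fraction newly synthesized, pool enrichment and quality score."""

    fraction_new: float
    pool_enrichment: float
    turnover_score: float
    residual_ss: float
    pool_fixed: bool = False

    @property
    def percent_new(self) -> float:
        return 100.0 * self.fraction_new


def theoretical_distribution(L: int, f: float, p: float) -> np.ndarray:
    """Theoretical isotopologue distribution over m = 0..L heavy leucines.

    Mixture of a point mass at m = 0 (pre-existing protein, weight ``1 - f``)
    and a Binomial(L, p) envelope (newly synthesized protein, weight ``f``).

    Parameters
    ----------
    L : number of leucine residues in the peptide, >= 1.
    f : fraction of the peptide pool newly synthesized, in [0, 1].
    p : precursor-pool heavy-leucine enrichment, in [0, 1].
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must lie in [0, 1], got {f}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    dist = f * _binom_pmf(L, p)
    dist[0] += 1.0 - f
    return dist


def _binom_pmf(L: int, p) -> np.ndarray:
    """Binomial(L, p) pmf over m = 0..L, stable for any p in [0, 1].

    ``p`` may be a scalar (returns shape (L+1,)) or a vector of G candidate
    enrichments (returns shape (G, L+1)).  Direct evaluation — exact for the
    small L of tryptic peptides and free of the library edge cases at the
    extremes of p.
    """
    m = np.arange(L + 1)
    p = np.asarray(p, dtype=float)
    pm = p[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = comb(L, m) * pm**m * (1.0 - pm) ** (L - m)
    return out


def _normalize(areas: np.ndarray) -> np.ndarray:
    areas = np.asarray(areas, dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("envelope is all-zero; turnover score undefined")
    return areas / total


def turnover_score(
    observed: Sequence[float], L: int, f: float, p: float
) -> float:
    """Cosine similarity between an observed envelope and the model envelope.

    Scale-invariant; equals 1 exactly when the observed envelope is
    proportional to ``theoretical_distribution(L, f, p)``.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size != L + 1:
        raise ValueError(f"observed must have length L+1 = {L + 1}")
    if not np.any(obs > 0):
        raise ValueError("all-zero observed envelope: score undefined")
    theo = theoretical_distribution(L, f, p)
    denom = np.linalg.norm(obs) * np.linalg.norm(theo)
    return float(np.clip(obs @ theo / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Least-squares machinery.
#
# With a = normalized observed envelope, e0 = unit vector at m = 0 and
# b(p) = Binomial(L, p) pmf, the model is  T(f, p) = e0 + f * (b(p) - e0),
# linear in f.  The profiled optimum over f at fixed p is closed form:
#     f*(p) = clip( <a - e0, d> / <d, d> , 0, 1),  d = b(p) - e0.
# The remaining 1-D problem in p is solved on a grid plus Brent refinement.
# ---------------------------------------------------------------------------

_P_GRID = np.linspace(0.0, 1.0, 401)
_pmf_cache: dict[int, np.ndarray] = {}


def _grid_pmf(L: int) -> np.ndarray:
    """Binomial pmf matrix over the standard p grid, cached per L."""
    B = _pmf_cache.get(L)
    if B is None:
        B = _binom_pmf(L, _P_GRID)
        _pmf_cache[L] = B
    return B


def _profile_f(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Best f and its SSE for normalized envelope ``a`` against pmf ``b``."""
    d = b.copy()
    d[0] -= 1.0
    r = a.copy()
    r[0] -= 1.0
    dd = d @ d
    f = float(np.clip((r @ d) / dd, 0.0, 1.0)) if dd > 0 else 0.0
    resid = r - f * d
    return f, float(resid @ resid)


def _sse_at_p(a: np.ndarray, L: int, p: float) -> float:
    b = _binom_pmf(L, p)
    return _profile_f(a, b)[1]


def deconvolve_spectrum(
    spectrum: LabeledPeptideSpectrum, p_fixed: float | None = None
) -> DeconvolutionResult:
    """Fit the binomial-mixture model to one observed envelope.

    Minimizes the sum of squared differences between the unit-normalized
    observed envelope and :func:`theoretical_distribution` over ``f`` (and
    over ``p`` unless ``p_fixed`` is given).  With a single leucine the two
    parameters are not jointly identifiable, so ``p_fixed`` is required.
    """
    if not spectrum.usable:
        raise ValueError(f"all-zero envelope for peptide {spectrum.peptide}")
    L = spectrum.leucine_count
    a = _normalize(spectrum.areas)

    if p_fixed is not None:
        if not 0.0 < p_fixed <= 1.0:
            raise ValueError(f"p_fixed must lie in (0, 1], got {p_fixed}")
        b = _binom_pmf(L, p_fixed)
        f, sse = _profile_f(a, b)
        score = turnover_score(spectrum.areas, L, f, p_fixed)
        return DeconvolutionResult(f, p_fixed, score, sse, pool_fixed=True)

    if L < 2:
        raise ValueError(
            "f and p are not jointly identifiable with a single leucine; "
            "pass p_fixed (e.g. the per-sample pool-enrichment estimate)"
        )

    # Coarse grid then Brent refinement of the f-profiled objective in p.
    B = _grid_pmf(L)
    d = B.copy()
    d[:, 0] -= 1.0
    r = a.copy()
    r[0] -= 1.0
    dd = np.einsum("ij,ij->i", d, d)
    with np.errstate(invalid="ignore"):
        f_grid = np.where(dd > 0, np.clip((d @ r) / np.where(dd > 0, dd, 1.0), 0.0, 1.0), 0.0)
    sse_grid = (r @ r) - 2.0 * f_grid * (d @ r) + f_grid**2 * dd
    i = int(np.argmin(sse_grid))
    lo = _P_GRID[max(i - 1, 0)]
    hi = _P_GRID[min(i + 1, _P_GRID.size - 1)]
    res = minimize_scalar(
        lambda p: _sse_at_p(a, L, p),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    p_hat = float(res.x)
    if res.fun > sse_grid[i]:  # guard: keep the grid point on a bad bracket
        p_hat = float(_P_GRID[i])
    b = _binom_pmf(L, p_hat)
    f_hat, sse = _profile_f(a, b)
    score = turnover_score(spectrum.areas, L, f_hat, p_hat)
    return DeconvolutionResult(f_hat, p_hat, score, sse)


def estimate_pool_enrichment(
    spectra: Sequence[LabeledPeptideSpectrum],
) -> tuple[float, int]:
    """Estimate one sample's precursor-pool enrichment from its envelopes.

    Minimizes the total residual sum of squares over all qualifying spectra
    (usable, L >= 2) with each spectrum's fraction-new profiled out, i.e. the
    pool enrichment is treated as shared across every peptide of the sample.

    Returns ``(p_hat, n_spectra_used)``.
    """
    usable = [s for s in spectra if s.leucine_count >= 2 and s.usable]
    if not usable:
        raise ValueError(
            "no usable spectra with >= 2 leucines; supply p_fixed instead"
        )
    by_L: dict[int, np.ndarray] = {}
    for s in usable:
        by_L.setdefault(s.leucine_count, []).append(_normalize(s.areas))
    residuals = {}
    for L, rows in by_L.items():
        R = np.vstack(rows)
        R[:, 0] -= 1.0
        residuals[L] = (R, np.einsum("ij,ij->i", R, R))

    def total_sse_vector(p_values: np.ndarray) -> np.ndarray:
        """Total f-profiled SSE at each candidate enrichment."""
        total = np.zeros(p_values.size)
        for L, (R, rr) in residuals.items():
            d = _binom_pmf(L, p_values)  # (G, L+1)
            d[:, 0] -= 1.0
            dd = np.einsum("ij,ij->i", d, d)
            ud = R @ d.T  # (n, G)
            with np.errstate(invalid="ignore"):
                f = np.where(
                    dd > 0, np.clip(ud / np.where(dd > 0, dd, 1.0), 0.0, 1.0), 0.0
                )
            total += (rr[:, None] - 2.0 * f * ud + f**2 * dd).sum(axis=0)
        return total

    total = total_sse_vector(_P_GRID.copy())
    i = int(np.argmin(total))
    lo = float(_P_GRID[max(i - 1, 0)])
    hi = float(_P_GRID[min(i + 1, _P_GRID.size - 1)])

    def objective(p: float) -> float:
        return float(total_sse_vector(np.array([p]))[0])

    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    p_hat = float(res.x)
    if res.fun > total[i]:
        p_hat = float(_P_GRID[i])
    return max(p_hat, 1e-12), len(usable)


# ---------------------------------------------------------------------------
# Table-level interface (pipeline fast path).
# ---------------------------------------------------------------------------


def _area_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if _AREA_COL.match(c)]
    return sorted(cols, key=lambda c: int(_AREA_COL.match(c).group(1)))


def spectra_from_table(table: pd.DataFrame) -> list[LabeledPeptideSpectrum]:
    """Materialize :class:`LabeledPeptideSpectrum` objects from a peptide table."""
    cols = _area_columns(table)
    out = []
    for row in table.itertuples(index=False):
        L = int(row.leucine_count)
        areas = np.array(
            [getattr(row, c) for c in cols[: L + 1]], dtype=float
        )
        out.append(
            LabeledPeptideSpectrum(
                peptide=row.peptide,
                protein=row.protein,
                sample=row.sample,
                group=row.group,
                day=float(row.day),
                leucine_count=L,
                areas=areas,
            )
        )
    return out


def estimate_pool_per_sample(table: pd.DataFrame) -> pd.Series:
    """Per-sample pool-enrichment estimates from a peptide table."""
    estimates = {}
    for sample, sub in table.groupby("sample", sort=True):
        spectra = spectra_from_table(sub)
        p_hat, _ = estimate_pool_enrichment(spectra)
        estimates[sample] = p_hat
    return pd.Series(estimates, name="pool_enrichment")


def deconvolve_table(
    table: pd.DataFrame,
    pool: str | float = "per-sample",
) -> pd.DataFrame:
    """Deconvolve every envelope in a peptide table.

    ``pool`` is either ``"per-sample"`` (estimate the precursor enrichment
    from each sample's multi-leucine peptides, then fit f per envelope at that
    fixed enrichment — the recommended mode) or a numeric enrichment applied
    to all samples.

    Returns a tidy frame with columns peptide, protein, sample, group, day,
    leucine_count, fraction_new, percent_new, pool_enrichment, turnover_score,
    residual_ss.
    """
    if isinstance(pool, str):
        if pool != "per-sample":
            raise ValueError(f"unknown pool mode {pool!r}")
        pool_by_sample = estimate_pool_per_sample(table)
    else:
        if not 0.0 < float(pool) <= 1.0:
            raise ValueError(f"fixed pool enrichment must lie in (0, 1], got {pool}")
        pool_by_sample = None

    cols = _area_columns(table)
    records = []
    for (sample, L), sub in table.groupby(["sample", "leucine_count"], sort=True):
        L = int(L)
        p = float(pool_by_sample[sample]) if pool_by_sample is not None else float(pool)
        areas = sub[cols[: L + 1]].to_numpy(dtype=float)
        totals = areas.sum(axis=1)
        ok = totals > 0
        A = areas[ok] / totals[ok, None]
        b = _binom_pmf(L, p)
        d = b.copy()
        d[0] -= 1.0
        R = A.copy()
        R[:, 0] -= 1.0
        dd = d @ d
        f = np.clip((R @ d) / dd, 0.0, 1.0)
        resid = R - f[:, None] * d
        sse = np.einsum("ij,ij->i", resid, resid)
        theo = f[:, None] * b
        theo[:, 0] += 1.0 - f
        num = np.einsum("ij,ij->i", A, theo)
        den = np.linalg.norm(A, axis=1) * np.linalg.norm(theo, axis=1)
        score = np.clip(num / den, -1.0, 1.0)
        meta = sub.loc[ok, ["peptide", "protein", "sample", "group", "day"]]
        rec = meta.copy()
        rec["leucine_count"] = L
        rec["fraction_new"] = f
        rec["percent_new"] = 100.0 * f
        rec["pool_enrichment"] = p
        rec["turnover_score"] = score
        rec["residual_ss"] = sse
        records.append(rec)
    if not records:
        raise ValueError("no usable envelopes in table")
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# Turnover-score quality filter.
# ---------------------------------------------------------------------------


@dataclass
class RocCutoff:
    cutoff: float
    youden_j: float
    tpr_at_cutoff: float
    fpr_at_cutoff: float
    roc_points: pd.DataFrame = field(repr=False)
    labels: np.ndarray = field(repr=False)


def derive_score_cutoff(
    scores: Sequence[float], enrichments: Sequence[float]
) -> RocCutoff:
    """Derive a turnover-score cutoff from a receiver-operating curve.

    Each peptide is labeled a true positive when its own pool-enrichment
    estimate lies within two standard deviations of the mean enrichment over
    all peptides (a well-behaved envelope reports an enrichment consistent
    with the cohort), and a true negative otherwise.  Score thresholds are
    swept over the observed scores and the threshold maximizing Youden's
    J = TPR - FPR is returned (ties broken toward the more stringent cutoff).
    """
    scores = np.asarray(scores, dtype=float)
    enrich = np.asarray(enrichments, dtype=float)
    if scores.size != enrich.size:
        raise ValueError("scores and enrichments must align")
    if scores.size < 10:
        raise ValueError("need at least 10 results to derive a cutoff")
    mu, sd = enrich.mean(), enrich.std(ddof=1)
    labels = np.abs(enrich - mu) <= 2.0 * sd
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate ROC: all peptides carry the same label")

    thresholds = np.unique(scores)
    pred = scores[None, :] >= thresholds[:, None]
    tpr = (pred & labels).sum(axis=1) / n_pos
    fpr = (pred & ~labels).sum(axis=1) / n_neg
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())[-1]
    roc = pd.DataFrame({"threshold": thresholds, "tpr": tpr, "fpr": fpr, "youden_j": j})
    return RocCutoff(
        cutoff=float(thresholds[best]),
        youden_j=float(j[best]),
        tpr_at_cutoff=float(tpr[best]),
        fpr_at_cutoff=float(fpr[best]),
        roc_points=roc,
        labels=labels,
    )


def filter_by_score(
    results: pd.DataFrame, cutoff: float = DEFAULT_SCORE_CUTOFF
) -> tuple[pd.DataFrame, dict]:
    """Retain deconvolution results with turnover_score >= cutoff.

    Returns the retained frame and a rejection log with counts.
    """
    keep = results["turnover_score"] >= cutoff
    log = {
        "cutoff": cutoff,
        "n_in": int(len(results)),
        "n_retained": int(keep.sum()),
        "n_removed": int((~keep).sum()),
    }
    return results.loc[keep].reset_index(drop=True), log
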