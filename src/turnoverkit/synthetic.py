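"""Synthetic labeled-cohort generator with known ground truth.

Emulates the design of a heavy-leucine ([5,5,5-2H3]-Leu) metabolic-labeling
aging study in mice: four groups crossing age with mitochondrial-catalase
(mCAT) transgene status — YWT, OWT, YmCAT, OmCAT — sampled cross-sectionally
at labeling days 3, 7, 12 and 17 with three animals per group per day.  Every
downstream stage (deconvolution, kinetics, abundance contrasts, trajectory
index) can therefore be exercised against known truth without any external
download.

Two generators are provided:

* :func:`simulate_labeling_cohort` — peptide isotopologue envelopes under the
  binomial labeling model, with per-protein-per-group half-lives drawn
  log-normally around configured group medians, precursor-pool enrichment
  below one, peptide-specific ionization factors, multiplicative log-normal
  envelope noise and completely-at-random missingness.
* :func:`simulate_abundance_matrix` — an MS1 peak-area abundance matrix whose
  group structure mirrors the "reverse antagonistic pleiotropy" pattern: an
  aging subset of proteins shifts in OWT relative to YWT, the young transgenic
  group receives ``lambda_young`` times that shift and the old transgenic
  group ``lambda_old`` times it (defaults 1 and 0 — the heart pattern, where
  the young-mCAT proteome looks aged and the old-mCAT proteome looks young).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .deconvolution import theoretical_distribution

__all__ = [
    "AbundanceEffect",
    "SimulationConfig",
    "SyntheticCohort",
    "AbundanceData",
    "build_default_config",
    "simulate_labeling_cohort",
    "simulate_abundance_matrix",
    "simulate_percent_new",
]

_AMINO_ACIDS = np.array(list("ACDEFGHIKMNPQRSTVWY"))  # leucine placed explicitly

#: Group labels: Young/Old x wild-type/mCAT transgenic.
DEFAULT_GROUPS = ("YWT", "OWT", "YmCAT", "OmCAT")

#: Heart median half-lives (days) used as generator defaults.
DEFAULT_HEART_MEDIANS = {"YWT": 6.43, "OWT": 5.37, "YmCAT": 4.86, "OmCAT": 7.71}


@dataclass(frozen=True)
class AbundanceEffect:
    """Per-group log2-shift model for the abundance matrix.

    ``mean_abs_fc`` is the target mean absolute linear fold change of the
    aging subset between OWT and YWT (the wild-type aging magnitude).
    ``lambda_young``/``lambda_old`` scale that aging shift in the young and
    old transgenic groups.  ``sample_sd_log2`` is per-sample measurement
    noise on the log2 scale.
    """

    mean_abs_fc: float = 5.66
    lambda_young: float = 1.0
    lambda_old: float = 0.0
    affected_fraction: float = 0.3
    sample_sd_log2: float = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    groups: tuple[str, ...] = DEFAULT_GROUPS
    days: tuple[float, ...] = (3.0, 7.0, 12.0, 17.0)
    animals_per_day: int = 3
    n_proteins: int = 200
    peptides_per_protein: tuple[int, int] = (2, 4)
    leucines_per_peptide: tuple[int, int] = (1, 6)
    group_median_halflife: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEART_MEDIANS)
    )
    halflife_spread: float = 0.45
    pool_plateau: float = 0.5
    pool_rise_rate: float = 0.0
    envelope_cv: float = 0.05
    missing_rate: float = 0.05
    abundance_effect: AbundanceEffect = field(default_factory=AbundanceEffect)
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "halflife_spread",
            "pool_plateau",
            "pool_rise_rate",
            "envelope_cv",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"config field {name!r} must be finite, got {v}")
        if self.animals_per_day < 1:
            raise ValueError("animals_per_day must be >= 1")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.leucines_per_peptide[0] < 1:
            raise ValueError("leucines_per_peptide minimum must be >= 1")
        if self.peptides_per_protein[0] < 1:
            raise ValueError("peptides_per_protein minimum must be >= 1")
        if any(d < 0 for d in self.days) or not all(
            a < b for a, b in zip(self.days, self.days[1:])
        ):
            raise ValueError("days must be non-negative and strictly increasing")
        missing = set(self.group_median_halflife) - set(self.groups)
        if missing:
            raise ValueError(f"group_median_halflife has unknown groups: {missing}")
        if set(self.groups) - set(self.group_median_halflife):
            raise ValueError("every group needs a median half-life")
        if any(v <= 0 or not np.isfinite(v) for v in self.group_median_halflife.values()):
            raise ValueError("group median half-lives must be positive and finite")
        if not 0.0 < self.pool_plateau <= 1.0:
            raise ValueError("pool_plateau must lie in (0, 1]")
        if self.pool_rise_rate < 0:
            raise ValueError("pool_rise_rate must be >= 0")
        if self.envelope_cv < 0:
            raise ValueError("envelope_cv must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.halflife_spread < 0:
            raise ValueError("halflife_spread must be >= 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["abundance_effect"] = dataclasses.asdict(self.abundance_effect)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "abundance_effect" in d and isinstance(d["abundance_effect"], dict):
            d["abundance_effect"] = AbundanceEffect(**d["abundance_effect"])
        for key in ("groups", "days", "peptides_per_protein", "leucines_per_peptide"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Peptide table plus the ground truth that generated it."""

    table: pd.DataFrame
    truth_halflife: pd.DataFrame  # protein, group, half_life
    truth_pool: pd.Series  # sample -> enrichment
    config: SimulationConfig


@dataclass
class AbundanceData:
    """Protein x sample abundance matrix plus ground truth."""

    matrix: pd.DataFrame  # proteins x samples, linear peak areas
    sample_groups: pd.Series  # sample -> group
    group_means: pd.DataFrame  # proteins x groups, linear scale truth
    aging_subset: pd.Index  # proteins carrying the aging shift
    config: SimulationConfig


def build_default_config() -> SimulationConfig:
    """Default configuration reproducing the heart study design.

    Four groups x four labeling days x three animals = 48 samples; group
    median half-lives default to the heart values (OmCAT 7.71 d > YWT 6.43 d
    > OWT 5.37 d > YmCAT 4.86 d); precursor pool plateau 0.5.
    """
    cfg = SimulationConfig()
    cfg.validate()
    return cfg


def _pool_enrichment(config: SimulationConfig, day: float) -> float:
    if config.pool_rise_rate > 0:
        return config.pool_plateau * (1.0 - np.exp(-config.pool_rise_rate * day))
    return config.pool_plateau


def _sample_name(group: str, day: float, animal: int) -> str:
    d = int(day) if float(day).is_integer() else day
    return f"{group}_d{d}_a{animal}"


def _random_peptide(rng: np.random.Generator, n_leu: int, length: int = 12) -> str:
    """Random tryptic-looking sequence containing exactly ``n_leu`` leucines."""
    body = rng.choice(_AMINO_ACIDS, size=max(length - 1, n_leu))
    pos = rng.choice(len(body), size=n_leu, replace=False)
    body[pos] = "L"
    return "".join(body) + ("K" if rng.random() < 0.5 else "R")


def simulate_labeling_cohort(
    config: SimulationConfig, seed: int | None = None
) -> SyntheticCohort:
    """Generate a labeled cohort of peptide isotopologue envelopes.

    Per protein and group, a half-life is drawn log-normally around the
    group's configured median (log-scale SD ``halflife_spread``).  Per sample,
    the precursor-pool enrichment follows ``pool_plateau * (1 - exp(-r t))``
    (constant at the plateau when the rise rate is zero).  Each peptide's
    envelope is the binomial-mixture distribution at that protein's fraction
    new, scaled by a peptide-specific ionization factor, with multiplicative
    log-normal noise of the configured CV per channel; observations are then
    dropped completely at random at ``missing_rate``.

    Identical (config, seed) pairs produce identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    groups = list(config.groups)
    proteins = [f"P{i:05d}" for i in range(config.n_proteins)]

    # Per-protein per-group true half-lives, log-normal about the group median.
    z = rng.standard_normal((config.n_proteins, len(groups)))
    medians = np.array([config.group_median_halflife[g] for g in groups])
    hl = medians[None, :] * np.exp(config.halflife_spread * z)
    truth_halflife = pd.DataFrame(
        {
            "protein": np.repeat(proteins, len(groups)),
            "group": np.tile(groups, config.n_proteins),
            "half_life": hl.ravel(),
        }
    )

    # Peptides: leucine count, ionization factor, sequence.
    lo_n, hi_n = config.peptides_per_protein
    lo_L, hi_L = config.leucines_per_peptide
    pep_rows = []
    for prot in proteins:
        n_pep = int(rng.integers(lo_n, hi_n + 1))
        for _ in range(n_pep):
            L = int(rng.integers(lo_L, hi_L + 1))
            pep_rows.append(
                (
                    prot,
                    _random_peptide(rng, L),
                    L,
                    float(np.exp(rng.normal(0.0, 1.0))),  # ionization factor
                )
            )
    peptides = pd.DataFrame(
        pep_rows, columns=["protein", "peptide", "leucine_count", "ionization"]
    )

    samples = [
        (g, d, a)
        for g in groups
        for d in config.days
        for a in range(1, config.animals_per_day + 1)
    ]
    truth_pool = pd.Series(
        {
            _sample_name(g, d, a): _pool_enrichment(config, d)
            for g, d, a in samples
        },
        name="pool_enrichment",
    )

    max_L = int(peptides["leucine_count"].max())
    area_cols = [f"area_m{m}" for m in range(max_L + 1)]
    sigma = float(np.sqrt(np.log1p(config.envelope_cv**2)))
    hl_lookup = hl  # (n_proteins, n_groups)
    prot_index = {p: i for i, p in enumerate(proteins)}
    group_index = {g: j for j, g in enumerate(groups)}

    frames = []
    for g, d, a in samples:
        sample = _sample_name(g, d, a)
        p_t = truth_pool[sample]
        t_half = hl_lookup[
            peptides["protein"].map(prot_index).to_numpy(),
            group_index[g],
        ]
        f = 1.0 - np.exp(-d * np.log(2.0) / t_half)
        env = np.zeros((len(peptides), max_L + 1))
        for L in np.unique(peptides["leucine_count"]):
            mask = (peptides["leucine_count"] == L).to_numpy()
            dist = theoretical_distribution(int(L), 1.0, p_t)
            dist0 = np.zeros(int(L) + 1)
            dist0[0] = 1.0
            fm = f[mask][:, None]
            env[np.ix_(mask, np.arange(int(L) + 1))] = (1.0 - fm) * dist0 + fm * dist
        scale = peptides["ionization"].to_numpy()[:, None] * 1e6
        areas = env * scale
        if sigma > 0:
            noise = np.exp(rng.normal(0.0, sigma, size=areas.shape))
            areas = areas * noise
        # zero out channels beyond each peptide's L (noise must not fill them)
        m_grid = np.arange(max_L + 1)[None, :]
        areas[m_grid > peptides["leucine_count"].to_numpy()[:, None]] = np.nan

        frame = peptides[["peptide", "protein", "leucine_count"]].copy()
        frame["group"] = g
        frame["sample"] = sample
        frame["day"] = float(d)
        frame[area_cols] = areas
        if config.missing_rate > 0:
            keep = rng.random(len(frame)) >= config.missing_rate
            frame = frame.loc[keep]
        frames.append(frame)

    table = pd.concat(frames, ignore_index=True)
    table = table[
        ["peptide", "protein", "group", "sample", "day", "leucine_count"] + area_cols
    ]
    return SyntheticCohort(
        table=table,
        truth_halflife=truth_halflife,
        truth_pool=truth_pool,
        config=config,
    )


def _scaled_magnitudes(
    rng: np.random.Generator, n: int, mean_abs_fc: float
) -> np.ndarray:
    """Log2 effect magnitudes whose mean linear fold change hits the target.

    Shapes are 1 + |half-normal| (bounded away from zero so every affected
    protein is genuinely changed), scaled by a common factor solved so that
    mean(2**magnitude) equals ``mean_abs_fc``.
    """
    shape = 1.0 + np.abs(rng.standard_normal(n)) * 0.5
    if mean_abs_fc <= 1.0:
        return np.zeros(n)

    def gap(c: float) -> float:
        return np.mean(np.exp2(c * shape)) - mean_abs_fc

    c = brentq(gap, 1e-9, 20.0 / shape.max())
    return c * shape


def simulate_abundance_matrix(
    config: SimulationConfig, seed: int | None = None
) -> AbundanceData:
    """Generate an MS1 abundance matrix with a planted aging signature.

    Baseline protein intensities are log-normal.  A designated aging subset
    receives a signed log2 shift in OWT relative to YWT whose mean absolute
    linear fold change equals ``abundance_effect.mean_abs_fc``; the young and
    old transgenic groups receive ``lambda_young`` and ``lambda_old`` times
    the same shift.  Per-sample log2 noise is then added.
    """
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 7)
    eff = config.abundance_effect
    groups = list(config.groups)
    proteins = pd.Index([f"P{i:05d}" for i in range(config.n_proteins)], name="protein")

    base = rng.normal(20.0, 2.0, size=config.n_proteins)  # log2 baseline
    n_aging = int(round(eff.affected_fraction * config.n_proteins))
    aging_idx = np.sort(rng.choice(config.n_proteins, size=n_aging, replace=False))
    delta = np.zeros(config.n_proteins)
    signs = rng.choice([-1.0, 1.0], size=n_aging)
    delta[aging_idx] = signs * _scaled_magnitudes(rng, n_aging, eff.mean_abs_fc)

    lam = {"YWT": 0.0, "OWT": 1.0, "YmCAT": eff.lambda_young, "OmCAT": eff.lambda_old}
    group_log2 = {}
    for g in groups:
        group_log2[g] = base + lam.get(g, 0.0) * delta
    group_means = pd.DataFrame(
        {g: np.exp2(group_log2[g]) for g in groups}, index=proteins
    )

    sample_names, sample_group = [], []
    for g in groups:
        for d in config.days:
            for a in range(1, config.animals_per_day + 1):
                sample_names.append(_sample_name(g, d, a))
                sample_group.append(g)
    cols = {}
    for name, g in zip(sample_names, sample_group):
        noise = rng.normal(0.0, eff.sample_sd_log2, size=config.n_proteins)
        cols[name] = np.exp2(group_log2[g] + noise)
    matrix = pd.DataFrame(cols, index=proteins)
    return AbundanceData(
        matrix=matrix,
        sample_groups=pd.Series(sample_group, index=sample_names, name="group"),
        group_means=group_means,
        aging_subset=proteins[aging_idx],
        config=config,
    )


def simulate_percent_new(
    half_life_days: float,
    days: tuple[float, ...] = (3.0, 7.0, 12.0, 17.0),
    n_peptides: int = 3,
    replicates_per_day: int = 3,
    cv: float = 0.05,
    peptide_sd: float = 0.1,
    rng: np.random.Generator | None = None,
    group: str = "G",
    protein: str = "P00000",
    peptide_offsets: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate percent-new observations for one protein in one group.

    Noise enters multiplicatively (log-normal, coefficient of variation
    ``cv``) on the unlabeled fraction ``100 - y`` — the error structure under
    which the log-linearized kinetic regression is exact — plus a per-peptide
    multiplicative offset of log-scale SD ``peptide_sd`` (ionization and
    digestion efficiency differ between peptides, motivating the blocking
    factor in the group comparison).  When the same physical peptides are
    simulated in two groups, draw ``peptide_offsets`` once and pass them to
    both calls — the offsets belong to the peptide, not the group.
    """
    rng = np.random.default_rng() if rng is None else rng
    sigma = float(np.sqrt(np.log1p(cv**2)))
    k = np.log(2.0) / half_life_days
    rows = []
    if peptide_offsets is None:
        pep_offsets = rng.normal(0.0, peptide_sd, size=n_peptides)
    else:
        pep_offsets = np.asarray(peptide_offsets, dtype=float)
        if pep_offsets.size != n_peptides:
            raise ValueError("peptide_offsets must have length n_peptides")
    for j in range(n_peptides):
        for d in days:
            u_true = 100.0 * np.exp(-k * d)
            eps = rng.normal(0.0, sigma, size=replicates_per_day)
            u_obs = u_true * np.exp(pep_offsets[j] + eps)
            for u in u_obs:
                rows.append((protein, f"pep{j}", group, float(d), 100.0 - u))
    return pd.DataFrame(
        rows, columns=["protein", "peptide", "group", "day", "percent_new"]
    )
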