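"""End-to-end analysis pipeline chaining all stages with a run manifest.

Stage order: simulate (or load) -> deconvolve -> score filter -> kinetic fits
-> group comparisons (ANCOVA + BH) -> half-life normalization -> abundance
contrasts -> partial correlations -> pathway enrichment (optional) ->
trajectory index.  Any stage error aborts the run with the stage name; a
machine-readable manifest records the seed, thresholds and record counts in
and out of every stage.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import (
    AbundanceMatrix,
    contrast_ratios,
    fisher_enrichment,
    group_difference_tests,
    partial_correlation,
    protein_abundance,
)
from .deconvolution import DEFAULT_SCORE_CUTOFF, deconvolve_table, filter_by_score
from .io import read_gmt, read_peptide_table, write_manifest, write_peptide_table
from .kinetics import (
    adjust_fdr,
    compare_groups_ancova,
    fit_all_half_lives,
    normalize_to_reference,
    summarize_medians,
)
from .synthetic import (
    SimulationConfig,
    simulate_abundance_matrix,
    simulate_labeling_cohort,
)
from .trajectory import select_aging_proteins, trajectory_table

__all__ = ["PipelineError", "run_pipeline", "DEFAULT_CONTRASTS"]

logger = logging.getLogger(__name__)

#: Group contrasts of interest: WT aging, transgenic aging, transgene effect
#: in young and in old animals.
DEFAULT_CONTRASTS = [
    ("OWT", "YWT"),
    ("OmCAT", "YmCAT"),
    ("YmCAT", "YWT"),
    ("OmCAT", "OWT"),
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # propagate with stage context
        raise PipelineError(name, exc) from exc


def run_pipeline(
    config: SimulationConfig | None = None,
    out_dir: str | Path = "turnoverkit_run",
    seed: int | None = None,
    peptide_table: str | Path | None = None,
    abundance_table: str | Path | None = None,
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
    reference_group: str = "YWT",
    aging_old_group: str = "OWT",
    pool: str | float = "per-sample",
    selection_threshold: float = 0.05,
    selection_type: str = "p",
    gmt_path: str | Path | None = None,
    contrasts: list[tuple[str, str]] | None = None,
) -> dict:
    """Run the full analysis; returns the manifest dict.

    Either simulate inputs from ``config`` (the default) or supply a peptide
    table TSV (plus, optionally, a separate abundance table with the same
    dialect).  Artifacts are written as TSVs under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contrasts = contrasts or DEFAULT_CONTRASTS
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "score_cutoff": score_cutoff,
        "reference_group": reference_group,
        "selection_threshold": selection_threshold,
        "selection_type": selection_type,
        "stages": {},
    }

    # -- input ---------------------------------------------------------------
    if peptide_table is not None:
        table = _stage("read", read_peptide_table, peptide_table)
        abundance = None
        if abundance_table is not None:
            ab_tab = _stage("read", read_peptide_table, abundance_table)
            abundance = _make_abundance(ab_tab)
    else:
        config = config or SimulationConfig()
        if seed is None:
            seed = config.seed
        cohort = _stage("simulate", simulate_labeling_cohort, config, seed)
        table = cohort.table
        write_peptide_table(table, out / "peptide_table.tsv")
        cohort.truth_halflife.to_csv(out / "truth_halflife.tsv", sep="\t", index=False)
        ab = _stage("simulate", simulate_abundance_matrix, config, seed)
        abundance = AbundanceMatrix(values=ab.matrix, sample_groups=ab.sample_groups)
        abundance.values.to_csv(out / "abundance_matrix.tsv", sep="\t")
    manifest["stages"]["input"] = {
        "n_samples": int(table["sample"].nunique()),
        "n_spectra": int(len(table)),
    }

    # -- deconvolution + filter ----------------------------------------------
    deconv = _stage("deconvolve", deconvolve_table, table, pool)
    deconv.to_csv(out / "deconvolution.tsv", sep="\t", index=False)
    manifest["stages"]["deconvolve"] = {"n_in": int(len(table)), "n_out": int(len(deconv))}
    retained, flog = _stage("filter", filter_by_score, deconv, score_cutoff)
    retained.to_csv(out / "deconvolution_filtered.tsv", sep="\t", index=False)
    manifest["stages"]["filter"] = flog

    # -- kinetics ---------------------------------------------------------
    fits = _stage("fit", fit_all_half_lives, retained)
    fits.to_csv(out / "halflife_fits.tsv", sep="\t", index=False)
    medians = summarize_medians(fits)
    medians.to_csv(out / "median_halflife.tsv", sep="\t")
    manifest["stages"]["fit"] = {
        "n_fits": int(len(fits)),
        "n_converged": int(fits["converged"].sum()),
        "median_half_life": {k: float(v) for k, v in medians.items()},
    }

    comp_rows = []
    for ga, gb in contrasts:
        for protein, sub in retained.groupby("protein", sort=True):
            a = sub[sub["group"] == ga]
            b = sub[sub["group"] == gb]
            if (
                len(a) < 3
                or len(b) < 3
                or a["day"].nunique() < 2
                or b["day"].nunique() < 2
            ):
                continue
            try:
                c = compare_groups_ancova(a, b)
            except ValueError:
                continue
            comp_rows.append(
                {
                    "protein": protein,
                    "group_a": ga,
                    "group_b": gb,
                    "delta_alpha": c.delta_alpha,
                    "p_value": c.p_value,
                }
            )
    comparisons = pd.DataFrame(comp_rows)
    if not comparisons.empty:
        comparisons["q_value"] = np.nan
        for (_, _), idx in comparisons.groupby(["group_a", "group_b"]).groups.items():
            comparisons.loc[idx, "q_value"] = adjust_fdr(
                comparisons.loc[idx, "p_value"].to_numpy()
            )
    comparisons.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
    manifest["stages"]["compare"] = {"n_comparisons": int(len(comparisons))}

    normalized, dropped = _stage("normalize", normalize_to_reference, fits, reference_group)
    normalized.to_csv(out / "halflife_normalized.tsv", sep="\t", index=False)
    manifest["stages"]["normalize"] = {
        "n_rows": int(len(normalized)),
        "n_dropped_no_reference": len(dropped),
    }

    # -- abundance ---------------------------------------------------------
    if abundance is None:
        areas = retained.copy()
        totals = table.set_index(["peptide", "sample"]).filter(regex=r"^area_m\d+$").sum(
            axis=1
        )
        areas["total_area"] = totals.reindex(
            pd.MultiIndex.from_frame(areas[["peptide", "sample"]])
        ).to_numpy()
        abundance = _stage("contrast", protein_abundance, areas)
    ratios = _stage("contrast", contrast_ratios, abundance, contrasts)
    ratio_table = pd.concat(
        [r.log2_ratio.rename(r.label) for r in ratios], axis=1
    )
    ratio_table.to_csv(out / "contrast_ratios.tsv", sep="\t")
    manifest["stages"]["contrast"] = {r.label: int(r.log2_ratio.size) for r in ratios}

    # partial correlations between contrasts sharing a group, controlling the
    # shared group's (log) mean abundance
    means = abundance.group_means()
    pcor_rows = []
    by_label = {r.label: r for r in ratios}
    pairs = [
        ("OWT/YWT", "YmCAT/YWT", "YWT"),
        ("OWT/YWT", "OmCAT/YmCAT", None),
        ("OWT/YWT", "OmCAT/OWT", "OWT"),
    ]
    for la, lb, shared in pairs:
        if la not in by_label or lb not in by_label:
            continue
        a, b = by_label[la].log2_ratio, by_label[lb].log2_ratio
        idx = a.index.intersection(b.index)
        if len(idx) < 4:
            continue
        if shared is None:
            from scipy.stats import spearmanr

            r, p = spearmanr(a.loc[idx], b.loc[idx])
            pcor_rows.append(
                {"x": la, "y": lb, "control": "", "r": float(r), "p_value": float(p),
                 "n": len(idx), "method": "spearman"}
            )
        else:
            ctrl = np.log2(means.loc[idx, shared])
            res = partial_correlation(a.loc[idx], b.loc[idx], ctrl, control_label=shared)
            pcor_rows.append(
                {"x": la, "y": lb, "control": shared, "r": res.r_partial,
                 "p_value": res.p_value, "n": res.n, "method": res.method}
            )
    pcor_table = pd.DataFrame(pcor_rows)
    pcor_table.to_csv(out / "partial_correlations.tsv", sep="\t", index=False)
    manifest["stages"]["pcor"] = {"n_pairs": int(len(pcor_table))}

    # -- aging selection, enrichment, trajectory ----------------------------
    aging_stats = _stage(
        "aging_tests", group_difference_tests, abundance, reference_group, aging_old_group
    )
    aging_stats.to_csv(out / "aging_tests.tsv", sep="\t", index=False)
    try:
        selected = select_aging_proteins(aging_stats, selection_threshold, selection_type)
    except ValueError as exc:
        # no significant aging signal: the trajectory index is undefined, but
        # the kinetic results upstream remain valid — skip rather than abort
        logger.warning("trajectory skipped: %s", exc)
        manifest["stages"]["select"] = {"n_selected": 0}
        manifest["stages"]["trajectory"] = "skipped: no significant aging proteins"
        write_manifest(manifest, out / "manifest.json")
        return manifest
    manifest["stages"]["select"] = {"n_selected": int(len(selected))}

    if gmt_path is not None:
        pathways = read_gmt(gmt_path)
        universe = set(aging_stats["protein"])
        enrich = _stage(
            "enrich", fisher_enrichment, set(selected) & universe, pathways, universe
        )
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrich"] = {"n_pathways": int(len(enrich))}

    traj = _stage("trajectory", trajectory_table, means, selected, reference_group,
                  aging_old_group)
    traj.to_csv(out / "trajectory.tsv", sep="\t", index=False)
    manifest["stages"]["trajectory"] = {
        row["group"]: float(row["index_percent"]) for _, row in traj.iterrows()
    }
    # two-point young -> old line-plot data per genotype
    lines = []
    idx = traj.set_index("group")["index_percent"]
    for label, young, old in (("WT", "YWT", "OWT"), ("mCAT", "YmCAT", "OmCAT")):
        if young in idx and old in idx:
            lines.append({"line": label, "x": "young", "index_percent": float(idx[young])})
            lines.append({"line": label, "x": "old", "index_percent": float(idx[old])})
    pd.DataFrame(lines).to_csv(out / "trajectory_lines.tsv", sep="\t", index=False)

    write_manifest(manifest, out / "manifest.json")
    return manifest


def _make_abundance(table: pd.DataFrame) -> AbundanceMatrix:
    areas = table.copy()
    areas["total_area"] = table.filter(regex=r"^area_m\d+$").sum(axis=1)
    return protein_abundance(areas)
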