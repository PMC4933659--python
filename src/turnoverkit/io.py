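"""Table, gene-set and configuration I/O.

All tabular artifacts are TSV.  The peptide table dialect has columns
``peptide, protein, group, sample, day, leucine_count, area_m0..area_mK``
(K = the table-wide maximum leucine count; channels beyond a peptide's own
L are empty).  Pathway sets use GMT-style TSV: set name, description, then
member accessions.  Configuration round-trips through YAML or JSON.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import SimulationConfig

__all__ = [
    "read_peptide_table",
    "write_peptide_table",
    "read_gmt",
    "write_gmt",
    "load_config",
    "save_config",
    "write_manifest",
]

_AREA_RE = re.compile(r"^area_m(\d+)$")
_REQUIRED = ["peptide", "protein", "group", "sample", "day", "leucine_count"]


class PeptideTableError(ValueError):
    pass


def read_peptide_table(path: str | Path, psm_q_cutoff: float = 0.01) -> pd.DataFrame:
    """Read and validate a peptide isotopologue table.

    Validates the header, checks each row's ``leucine_count`` against the
    leucine tally of its sequence and rejects negative peak areas, naming the
    offending row (1-based, excluding the header).  When an optional
    ``psm_q`` column is present (spectrum-match FDR from the upstream search),
    rows with q >= ``psm_q_cutoff`` are removed.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise PeptideTableError(f"{path}: missing required columns {missing}")
    area_cols = sorted(
        (c for c in df.columns if _AREA_RE.match(c)),
        key=lambda c: int(_AREA_RE.match(c).group(1)),
    )
    if not area_cols:
        raise PeptideTableError(f"{path}: no area_m* columns")
    df["day"] = df["day"].astype(float)
    if df.empty:
        warnings.warn(f"{path}: empty peptide table", stacklevel=2)
        return df

    leu = df["peptide"].str.count("L")
    bad = df.index[leu != df["leucine_count"]]
    if len(bad):
        row = int(bad[0])
        raise PeptideTableError(
            f"{path}: row {row + 1}: leucine_count {df.loc[row, 'leucine_count']} "
            f"does not match {leu[row]} L residues in {df.loc[row, 'peptide']}"
        )
    areas = df[area_cols].to_numpy(dtype=float)
    neg = np.argwhere(areas < 0)
    if neg.size:
        row, col = int(neg[0, 0]), area_cols[int(neg[0, 1])]
        raise PeptideTableError(f"{path}: row {row + 1}: negative area in {col}")
    if "psm_q" in df.columns:
        df = df[df["psm_q"] < psm_q_cutoff].drop(columns=["psm_q"]).reset_index(drop=True)
    return df


def write_peptide_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> member..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT lines need name, description, members")
        sets[fields[0]] = set(filter(None, fields[2:]))
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "") -> None:
    lines = [
        "\t".join([name, description] + sorted(members))
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> SimulationConfig:
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    data = config.to_dict()
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(data, indent=2) + "\n")
    else:
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
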