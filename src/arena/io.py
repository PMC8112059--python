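"""Readers and writers for the pipeline's on-disk formats.

All genomic coordinates are 0-based half-open. Regions travel as 6-column
BED (name = region_id, score = 0, strand = "."), loops as 7-column BEDPE
(pair id in column 7), and everything tabular as TSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

BED_COLS = ["chrom", "start", "end", "region_id", "score", "strand"]
BEDPE_COLS = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "pair_id"]


def write_bed(regions: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({
        "chrom": regions["chrom"],
        "start": regions["start"],
        "end": regions["end"],
        "region_id": regions["region_id"],
        "score": 0,
        "strand": ".",
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLS)
    return df


def write_bedpe(interactions: pd.DataFrame, path: str | Path) -> None:
    interactions[BEDPE_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BEDPE_COLS)
    bad = df[df["start_a"].isna() | df["start_b"].isna()]
    if len(bad):
        raise ValueError(f"malformed BEDPE row at line {bad.index[0] + 1}")
    return df


def write_counts(counts: pd.DataFrame, roles: pd.DataFrame,
                 counts_path: str | Path, roles_path: str | Path) -> None:
    counts.to_csv(counts_path, sep="\t")
    roles.to_csv(roles_path, sep="\t", index=False)


def read_counts(counts_path: str | Path, roles_path: str | Path
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    roles = pd.read_csv(roles_path, sep="\t")
    missing = set(counts.columns) - set(roles["sample"])
    if missing:
        raise ValueError(f"samples without a role: {sorted(missing)}")
    return counts, roles


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
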