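"""File formats: cohort CSV, summary-statistic TSV, truth sidecars.

Summary statistics travel as tab-separated text with the columns
SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N.  Metadata rides in ``#``
comment lines (key=value) at the top of every file this package writes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

SUMSTAT_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
_VALID_ALLELES = {"A", "C", "G", "T"}


def _metadata_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in metadata.items())


def write_summary_stats(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistic frame missing columns: {missing}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_metadata_lines(metadata))
        df[SUMSTAT_COLUMNS].to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_summary_stats(path) -> pd.DataFrame:
    """Read and validate a summary-statistic TSV.

    Rows violating the per-field contracts (alleles in {A,C,G,T}, EAF in
    (0,1), SE > 0, P in (0,1]) are rejected individually with line-numbered
    log messages; a missing mandatory column is fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    df["EA"] = df["EA"].astype(str).str.upper()
    df["OA"] = df["OA"].astype(str).str.upper()
    bad = pd.Series(False, index=df.index)
    reasons = {}

    def flag(mask, reason):
        for i in df.index[mask & ~bad]:
            reasons[i] = reason
        return mask

    bad |= flag(~df["EA"].isin(_VALID_ALLELES) | ~df["OA"].isin(_VALID_ALLELES), "invalid allele")
    bad |= flag((df["EAF"] <= 0) | (df["EAF"] >= 1), "EAF outside (0,1)")
    bad |= flag(df["SE"] <= 0, "SE not > 0")
    bad |= flag((df["P"] <= 0) | (df["P"] > 1), "P outside (0,1]")
    for i, reason in reasons.items():
        log.warning("%s line %d: row rejected [%s]", path.name, i + 2, reason)
    kept = df[~bad].reset_index(drop=True)
    log.info("%s: read %d rows, rejected %d", path.name, len(df), int(bad.sum()))
    return kept


def write_cohort(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_lines(metadata))
        df.to_csv(fh, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_truth(truth: dict, path) -> None:
    """Structured sidecar recording the generator's planted parameters."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=str)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
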