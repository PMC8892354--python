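"""TSV/JSON readers and writers plus the run log.

TSV dialect: tab-separated, UTF-8, header row required, explicit ``NA``
token (a bare '.' is rejected as a missing-value marker), feature ids
matching ``^[A-Za-z0-9_.-]+$``. The counts table stores the effective
length (bp) as its second column.
"""

from __future__ import annotations

import hashlib
import json
import re
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .quantify import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_table",
    "write_table",
    "read_annotation",
    "RunLog",
]

FEATURE_ID_RE = re.compile(r"^[A-Za-z0-9_.-]+$")
NA_TOKEN = "NA"


def _read_tsv(path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=index_col, na_values=[NA_TOKEN], keep_default_na=False
        )
    except Exception as exc:  # surface the file in the message
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    if df.columns.str.contains("^Unnamed").any():
        raise ValueError(f"malformed TSV {path}: missing header fields")
    return df


def _check_feature_ids(ids, path) -> None:
    for i, fid in enumerate(ids):
        if fid == ".":
            raise ValueError(
                f"{path}, line {i + 2}: '.' is not a valid id or NA token (use {NA_TOKEN})"
            )
        if not FEATURE_ID_RE.match(str(fid)):
            raise ValueError(f"{path}, line {i + 2}: invalid feature id {fid!r}")


def read_counts(path) -> CountMatrix:
    """Counts TSV (feature_id, length, one column per sample) -> CountMatrix."""
    df = _read_tsv(path)
    if df.columns[0] != "feature_id" or df.columns[1] != "length":
        raise ValueError(f"{path}: first two columns must be feature_id, length")
    _check_feature_ids(df["feature_id"], path)
    df = df.set_index("feature_id")
    lengths = df.pop("length").astype(float)
    counts = df.astype("int64")
    return CountMatrix(counts, lengths)


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.lengths)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)


DESIGN_REQUIRED = ("sample_id", "block", "stage", "stage_class", "region",
                   "sex", "individual", "treatment")


def read_design(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = set(DESIGN_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design misses column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_table(path, index_col=0) -> pd.DataFrame:
    return _read_tsv(path, index_col=index_col)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=NA_TOKEN)


def read_annotation(path) -> pd.DataFrame:
    """Annotation TSV: feature_id, gene_id[, domain]."""
    df = _read_tsv(path)
    for col in ("feature_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: annotation misses column {col!r}")
    _check_feature_ids(df["feature_id"], path)
    return df.set_index("feature_id")


def check_design_matches(cm: CountMatrix, design: pd.DataFrame) -> None:
    """Every matrix sample must appear in the design (error names the sample)."""
    known = set(design["sample_id"])
    for sample in cm.samples:
        if sample not in known:
            raise ValueError(f"sample {sample!r} in count matrix absent from design")


class RunLog:
    """Append-only JSONL log: one record per pipeline stage.

    Records carry a timestamp, the config hash, the seed, thresholds in
    effect and input/output row counts — enough to audit which cut-offs
    (0.01, 2, 1.5, 2/3) produced a result file.
    """

    def __init__(self, path, config: dict | None = None, seed: int | None = None):
        self.path = Path(path)
        self.config_hash = hashlib.sha256(
            json.dumps(config or {}, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        self.seed = seed

    def record(self, stage: str, n_in: int, n_out: int, **extra) -> None:
        entry = {
            "stage": stage,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_in": int(n_in),
            "n_out": int(n_out),
            **extra,
        }
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")
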