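"""File formats and run configuration.

Canonical tabular dialect is TSV (UTF-8, header row); nested reports are
JSON; reads are FASTQ (Sanger Phred+33) via Biopython.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reads import SequencingRead

COUNT_COLUMNS = ["sequence", "time_day", "replicate", "count"]


class SchemaError(ValueError):
    """A tabular file does not match the expected schema."""


# ---------------------------------------------------------------------------
# FASTQ / FASTA


def read_fastq(path) -> list[SequencingRead]:
    """Lossless FASTQ (Phred+33) reader."""
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                SequencingRead(
                    rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"])
                )
            )
    except ValueError as exc:
        raise SchemaError(f"malformed FASTQ {path}: {exc}") from exc
    return reads


def write_fastq(path, reads) -> None:
    records = [
        SeqRecord(
            Seq(r.seq),
            id=r.id,
            description="",
            letter_annotations={"phred_quality": list(r.quals)},
        )
        for r in reads
    ]
    SeqIO.write(records, str(path), "fastq")


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path, extra_columns: tuple = ()) -> pd.DataFrame:
    """Typed TSV count table with schema validation.

    Duplicate (sequence, time, replicate) rows are aggregated with a
    warning; negative counts are schema errors.
    """
    df = pd.read_csv(path, sep="\t")
    required = list(extra_columns) + COUNT_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"count table {path} missing columns: {missing}")
    if (df["count"] < 0).any():
        raise SchemaError(f"count table {path} contains negative counts")
    key = [c for c in df.columns if c != "count"]
    if df.duplicated(key).any():
        warnings.warn("duplicate count rows aggregated", stacklevel=2)
        df = df.groupby(key, as_index=False)["count"].sum()
    df["count"] = df["count"].astype(int)
    return df[[*key, "count"]]


def write_count_table(path, df: pd.DataFrame) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"count table to write missing columns: {missing}")
    df.to_csv(path, sep="\t", index=False)


def write_ground_truth(path, members) -> None:
    """JSON sidecar with the simulator's hidden labels."""
    payload = [
        {
            "member_id": m.member_id,
            "true_class": m.true_class,
            "true_growth_rate": m.true_growth_rate,
        }
        for m in members
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    Defaults are the screen-analysis settings: clustering/mapping identity
    0.90 (random) / 0.80 (design), dereplication min count 2, expected-error
    cap 1.0, read-count prefilter 3, support filters (2 replicates, 10
    reads), 5x10 cross-validation, correlation threshold 0.75, near-zero
    variance ratio 95/5.
    """

    seed: int = 0
    n_members: int = 500
    insert_length: int = 60
    depth: int = 10_000
    n_replicates: int = 3
    time_points: tuple = (0, 2, 4, 6, 8)
    substitution_error_rate: float = 0.0
    g_functional: float = 0.05
    g_nonfunctional: float = -0.15
    min_acidic: int = 2
    min_aromatic: int = 1
    max_positive: int = 0
    cluster_identity: float = 0.90
    design_identity: float = 0.80
    min_derep_count: int = 2
    max_ee: float = 1.0
    min_total_reads: int = 3
    min_replicates: int = 2
    min_reads: int = 10
    threshold_mode: str = "target_fpr"
    target_fpr: float = 0.01
    fixed_threshold: float | None = None
    cv_k: int = 5
    cv_repeats: int = 10
    n_lambda: int = 50
    lambda_spacing: str = "linear"
    n_bootstrap: int = 50
    corr_threshold: float = 0.75
    train_frac: float = 0.75
    run_ml: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "time_points" in raw:
            raw = {**raw, "time_points": tuple(raw["time_points"])}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["time_points"] = list(d["time_points"])
        return d

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
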