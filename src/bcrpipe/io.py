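"""AIRR Rearrangement I/O and repertoire-level quality control.

Records live in a :class:`pandas.DataFrame` with one row per UMI-consensus
transcript, following the MiAIRR Rearrangement column vocabulary.  A
:class:`Repertoire` bundles one subject's records with its group label and
QC status.  The QC rules implemented here are the study-design ones:
non-productive transcripts are dropped, and subjects with fewer than 1,500
productive UMIs are excluded from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Columns every rearrangement table must carry.
REQUIRED_COLUMNS = (
    "sequence_id",
    "sequence",
    "productive",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "junction_aa",
    "germline_alignment",
    "duplicate_count",
    "subject_id",
)

#: Recognised cohort groups: healthy controls, mild/moderate and severe
#: ME/CFS, and multiple-sclerosis controls.
GROUPS = ("HC", "ME_mm", "ME_sa", "MS")

_TRUE_STRINGS = {"t", "true", "1", "yes", "y"}
_FALSE_STRINGS = {"f", "false", "0", "no", "n"}


class SchemaError(ValueError):
    """A rearrangement table is missing or mis-types a required column."""


@dataclass
class Repertoire:
    """One subject's rearrangement records plus cohort metadata.

    ``qc_status`` is ``"included"`` or ``"excluded:<reason>"``; it is set by
    :func:`apply_depth_threshold` and starts as ``"pending"``.
    """

    subject_id: str
    group: str
    records: pd.DataFrame
    qc_status: str = "pending"

    @property
    def total_umis(self) -> int:
        """Summed UMI weight (``duplicate_count``) over all records."""
        if len(self.records) == 0:
            return 0
        return int(self.records["duplicate_count"].sum())

    def __len__(self) -> int:  # records, not UMIs
        return len(self.records)


def _parse_productive(column: pd.Series, path: str | Path | None = None) -> pd.Series:
    out = []
    for row_number, value in enumerate(column, start=1):
        if isinstance(value, bool):
            out.append(value)
            continue
        text = str(value).strip().lower()
        if text in _TRUE_STRINGS:
            out.append(True)
        elif text in _FALSE_STRINGS:
            out.append(False)
        else:
            where = f" in {path}" if path else ""
            raise SchemaError(
                f"malformed boolean {value!r} in column 'productive' at data row "
                f"{row_number}{where}"
            )
    return pd.Series(out, index=column.index, dtype=bool)


def read_airr(path: str | Path) -> pd.DataFrame:
    """Read a MiAIRR Rearrangement TSV into a records DataFrame.

    Missing optional values are defaulted (``duplicate_count`` -> 1, string
    fields -> ``""``); row order is preserved.  Raises :class:`SchemaError`
    if a required column is absent or ``productive`` cannot be parsed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in REQUIRED_COLUMNS:
        if column not in df.columns:
            raise SchemaError(f"missing required column '{column}' in {path}")
    df["productive"] = _parse_productive(df["productive"], path)
    counts = df["duplicate_count"].replace("", "1")
    df["duplicate_count"] = pd.to_numeric(counts).astype(int)
    if len(df) and (df["duplicate_count"] < 1).any():
        raise SchemaError(f"non-positive duplicate_count in {path}")
    return df.reset_index(drop=True)


def write_airr(records: pd.DataFrame, path: str | Path) -> None:
    """Write records as a tab-separated Rearrangement table."""
    out = records.copy()
    out["productive"] = out["productive"].map({True: "T", False: "F"})
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the cohort metadata TSV (columns ``subject_id``, ``group``)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for column in ("subject_id", "group"):
        if column not in meta.columns:
            raise SchemaError(f"missing required column '{column}' in {path}")
    unknown = set(meta["group"]) - set(GROUPS)
    if unknown:
        raise SchemaError(f"unknown group labels {sorted(unknown)} in {path}")
    return meta


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def split_repertoires(records: pd.DataFrame, metadata: pd.DataFrame) -> list[Repertoire]:
    """Split a pooled records table into per-subject repertoires.

    Subjects follow the metadata row order; a subject with no records gets an
    empty repertoire so attrition is visible downstream.
    """
    by_subject = dict(tuple(records.groupby("subject_id", sort=False)))
    repertoires = []
    for row in metadata.itertuples(index=False):
        df = by_subject.get(row.subject_id)
        if df is None:
            df = records.iloc[0:0]
        repertoires.append(
            Repertoire(subject_id=row.subject_id, group=row.group, records=df.reset_index(drop=True))
        )
    return repertoires


def filter_productive(records: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the productive records, preserving row order."""
    return records[records["productive"]].reset_index(drop=True)


def apply_depth_threshold(
    repertoires: Iterable[Repertoire], min_umis: int = 1500
) -> tuple[list[Repertoire], list[Repertoire]]:
    """Split repertoires into (included, excluded) by productive UMI depth.

    A repertoire is excluded iff its summed ``duplicate_count`` over
    *productive* records is strictly below ``min_umis`` — a subject with
    exactly ``min_umis`` productive UMIs is kept.  Sets ``qc_status`` on
    every repertoire.
    """
    if min_umis < 1:
        raise ValueError(f"min_umis must be >= 1, got {min_umis}")
    included, excluded = [], []
    for rep in repertoires:
        depth = int(filter_productive(rep.records)["duplicate_count"].sum()) if len(rep) else 0
        if depth < min_umis:
            rep.qc_status = f"excluded:productive_umis={depth}<{min_umis}"
            excluded.append(rep)
        else:
            rep.qc_status = "included"
            included.append(rep)
    return included, excluded


def strip_allele(call: str) -> str:
    """Reduce a V/D/J call to its gene name.

    Takes the first call of a comma-separated multi-call, strips surrounding
    whitespace and drops the ``*NN`` allele suffix.  Duplicate-gene suffixes
    (``IGHV3-30-3``) are part of the gene name and retained.
    """
    if not call or not call.strip():
        raise ValueError("empty gene call")
    first = call.split(",")[0].strip()
    return first.split("*")[0].strip()


def strip_allele_series(calls: pd.Series) -> pd.Series:
    """Vectorized :func:`strip_allele`: unique calls are stripped once and
    broadcast back, which matters on pooled cohort-scale tables."""
    codes, uniques = pd.factorize(calls)
    stripped = np.array([strip_allele(u) for u in uniques], dtype=object)
    if (codes < 0).any():
        raise ValueError("missing gene call")
    return pd.Series(stripped[codes], index=calls.index)


def flag_aberrant_repertoires(
    repertoires: Iterable[Repertoire], max_gene_fraction: float = 0.9
) -> pd.DataFrame:
    """Diagnostic report of repertoires dominated by a single V gene.

    Mirrors the manual exclusion of a subject whose repertoire was 96%
    IGHV4-34: any subject whose top V gene exceeds ``max_gene_fraction`` of
    productive UMIs is flagged for review, never auto-excluded.
    """
    rows = []
    for rep in repertoires:
        records = filter_productive(rep.records)
        if len(records) == 0:
            continue
        genes = strip_allele_series(records["v_call"])
        usage = records.groupby(genes)["duplicate_count"].sum()
        usage = usage / usage.sum()
        top_gene = usage.idxmax()
        rows.append(
            {
                "subject_id": rep.subject_id,
                "group": rep.group,
                "top_v_gene": top_gene,
                "top_v_fraction": float(usage.loc[top_gene]),
                "flagged": bool(usage.loc[top_gene] > max_gene_fraction),
            }
        )
    return pd.DataFrame(rows)


def qc_report(repertoires: Sequence[Repertoire]) -> pd.DataFrame:
    """Tabulate per-subject QC status after depth thresholding."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in repertoires],
            "group": [r.group for r in repertoires],
            "n_records": [len(r) for r in repertoires],
            "productive_umis": [
                int(filter_productive(r.records)["duplicate_count"].sum()) if len(r) else 0
                for r in repertoires
            ],
            "qc_status": [r.qc_status for r in repertoires],
        }
    )
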