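"""Per-record and per-repertoire features.

Covers UMI-weighted germline gene usage, somatic hypermutation (mismatches
against the aligned germline), N-linked glycosylation sequons (N-X-S/T with
X != proline) in the translated variable region, and IgM/IgG isotype
composition.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import Repertoire, filter_productive, strip_allele

logger = logging.getLogger(__name__)

#: Alignment characters treated as uninformative when counting mismatches:
#: gap characters plus any nucleotide ambiguity code.
_UNAMBIGUOUS = frozenset("ACGTacgt")

SEGMENT_COLUMNS = {"v": "v_call", "d": "d_call", "j": "j_call"}


def gene_usage_matrix(repertoires: Iterable[Repertoire], segment: str = "v") -> pd.DataFrame:
    """Subjects x genes table of UMI-weighted usage proportions.

    Entry (s, g) is the fraction of subject s's productive UMIs whose
    allele-stripped call for the chosen segment is gene g.  Rows sum to 1;
    genes a subject never uses are 0.
    """
    column = SEGMENT_COLUMNS.get(segment.lower())
    if column is None:
        raise ValueError(f"segment must be one of {sorted(SEGMENT_COLUMNS)}, got {segment!r}")
    rows = {}
    for rep in repertoires:
        records = filter_productive(rep.records)
        if len(records) == 0:
            raise ValueError(f"empty repertoire for subject {rep.subject_id}")
        codes, uniques = pd.factorize(records[column])
        stripped = [strip_allele(u) for u in uniques]
        weights = records["duplicate_count"].to_numpy(dtype=float)
        sums = np.bincount(codes, weights=weights, minlength=len(uniques))
        usage = pd.Series(sums, index=stripped).groupby(level=0).sum()
        rows[rep.subject_id] = usage / usage.sum()
    matrix = pd.DataFrame(rows).T.fillna(0.0)
    matrix = matrix[sorted(matrix.columns)]
    matrix.index.name = "subject_id"
    return matrix


def combine_genes(usage: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """Per-subject summed usage of the listed genes (absent genes count 0)."""
    if len(genes) == 0:
        raise ValueError("empty gene list")
    present = [g for g in genes if g in usage.columns]
    combined = usage[present].sum(axis=1) if present else pd.Series(0.0, index=usage.index)
    combined.name = "+".join(genes)
    return combined


def _compared_mask(sequence: str, germline: str) -> np.ndarray:
    if len(sequence) != len(germline):
        raise ValueError(
            f"sequence length {len(sequence)} != germline alignment length {len(germline)}"
        )
    seq = np.frombuffer(sequence.encode(), dtype="S1")
    germ = np.frombuffer(germline.encode(), dtype="S1")
    ok = np.isin(seq, [c.encode() for c in _UNAMBIGUOUS]) & np.isin(
        germ, [c.encode() for c in _UNAMBIGUOUS]
    )
    return ok


def mutation_count(sequence: str, germline_alignment: str) -> int:
    """Number of aligned positions where read and germline differ.

    Positions holding a gap or ambiguity character in either string are
    skipped: the count covers substitutions only.
    """
    ok = _compared_mask(sequence, germline_alignment)
    seq = np.frombuffer(sequence.upper().encode(), dtype="S1")
    germ = np.frombuffer(germline_alignment.upper().encode(), dtype="S1")
    return int((ok & (seq != germ)).sum())


def mutation_frequency(sequence: str, germline_alignment: str) -> float:
    """Mutations per compared (non-gap, unambiguous) nucleotide position."""
    ok = _compared_mask(sequence, germline_alignment)
    compared = int(ok.sum())
    if compared == 0:
        raise ValueError("no comparable positions between sequence and germline")
    return mutation_count(sequence, germline_alignment) / compared


_X_ALLOWED = frozenset("ACDEFGHIKLMNQRSTVWY")  # standard amino acids minus proline


def count_nglyc_sites(aa_sequence: str) -> int:
    """Number of N-glycosylation sequons N-X-S/T (X != P), overlaps counted.

    Non-standard characters (``X``, stops) are tolerated but never take part
    in a motif.
    """
    aa = aa_sequence.upper()
    return sum(
        1
        for p in range(len(aa) - 2)
        if aa[p] == "N" and aa[p + 1] in _X_ALLOWED and aa[p + 2] in ("S", "T")
    )


def translate_in_frame(nt_sequence: str) -> str:
    """Standard-code translation from position 1 (frame 0).

    The simulator guarantees frame 0; a trailing incomplete codon is dropped.
    """
    usable = len(nt_sequence) - len(nt_sequence) % 3
    return str(Seq(nt_sequence[:usable]).translate())


def isotype_of(c_call: str) -> str:
    """Map a constant-region call to IgM / IgG / other by prefix."""
    call = (c_call or "").upper()
    if call.startswith("IGHM"):
        return "IgM"
    if call.startswith("IGHG"):
        return "IgG"
    return "other"


def isotype_proportions(rep: Repertoire | pd.DataFrame) -> dict[str, float]:
    """UMI-weighted fractions over {IgM, IgG, other}; fractions sum to 1."""
    records = rep.records if isinstance(rep, Repertoire) else rep
    records = filter_productive(records)
    calls = records["c_call"].fillna("")
    if len(records) == 0 or (calls.str.strip() == "").all():
        raise ValueError("no constant-region calls present")
    isotypes = calls.map(isotype_of)
    tally = records.groupby(isotypes)["duplicate_count"].sum()
    total = tally.sum()
    return {iso: float(tally.get(iso, 0)) / total for iso in ("IgM", "IgG", "other")}


def _batched_mismatches(sequences: pd.Series, germlines: pd.Series) -> np.ndarray:
    """Vectorized mutation counts for records grouped by alignment length."""
    counts = np.zeros(len(sequences), dtype=np.int64)
    lengths = sequences.str.len().to_numpy()
    germ_lengths = germlines.str.len().to_numpy()
    if (lengths != germ_lengths).any():
        bad = int(np.argmax(lengths != germ_lengths))
        raise ValueError(f"sequence/germline length mismatch at row {bad}")
    allowed = np.frombuffer(b"ACGT", dtype="S1")
    for length in np.unique(lengths):
        idx = np.nonzero(lengths == length)[0]
        if length == 0:
            continue
        seq = np.frombuffer(
            "".join(sequences.iloc[idx].str.upper()).encode(), dtype="S1"
        ).reshape(len(idx), length)
        germ = np.frombuffer(
            "".join(germlines.iloc[idx].str.upper()).encode(), dtype="S1"
        ).reshape(len(idx), length)
        ok = np.isin(seq, allowed) & np.isin(germ, allowed)
        counts[idx] = (ok & (seq != germ)).sum(axis=1)
    return counts


def record_features(records: pd.DataFrame, junction_only_nglyc: bool = False) -> pd.DataFrame:
    """Per-record feature table: mutation count/frequency, sequons, isotype.

    Sequons are counted over the full translated variable region by default;
    ``junction_only_nglyc=True`` restricts the scan to the CDR3 junction.
    Productive records whose translation contains an internal stop are
    flagged (``nglyc_sites`` set to NA) and logged, not dropped.
    """
    records = filter_productive(records)
    mutations = _batched_mismatches(records["sequence"], records["germline_alignment"])
    compared = np.array(
        [
            _compared_mask(s, g).sum()
            for s, g in zip(records["sequence"], records["germline_alignment"])
        ],
        dtype=np.int64,
    )
    nglyc = np.empty(len(records), dtype=object)
    n_stop = 0
    for i, row in enumerate(records.itertuples(index=False)):
        aa = row.junction_aa if junction_only_nglyc else translate_in_frame(row.sequence)
        if not junction_only_nglyc and "*" in aa[:-1]:
            nglyc[i] = pd.NA
            n_stop += 1
            continue
        nglyc[i] = count_nglyc_sites(aa)
    if n_stop:
        logger.warning(
            "%d productive records with internal stop codons excluded from sequon counting",
            n_stop,
        )
    return pd.DataFrame(
        {
            "sequence_id": records["sequence_id"].to_numpy(),
            "subject_id": records["subject_id"].to_numpy(),
            "mutation_count": mutations,
            "mutation_frequency": mutations / np.maximum(compared, 1),
            "nglyc_sites": nglyc,
            "isotype": records["c_call"].map(isotype_of).to_numpy(),
            "duplicate_count": records["duplicate_count"].to_numpy(),
        }
    )


def shm_summary(repertoires: Iterable[Repertoire]) -> pd.DataFrame:
    """Per subject x isotype SHM summary (UMI-weighted).

    Columns: mean mutation count, mean mutation frequency, mean sequons per
    sequence, UMI total.
    """
    rows = []
    for rep in repertoires:
        feats = record_features(rep.records)
        for isotype, sub in feats.groupby("isotype"):
            w = sub["duplicate_count"].to_numpy(dtype=float)
            glyc = sub["nglyc_sites"]
            glyc_ok = glyc.notna()
            rows.append(
                {
                    "subject_id": rep.subject_id,
                    "group": rep.group,
                    "isotype": isotype,
                    "mean_mutation_count": float(np.average(sub["mutation_count"], weights=w)),
                    "mean_mutation_frequency": float(
                        np.average(sub["mutation_frequency"], weights=w)
                    ),
                    "mean_nglyc_sites": float(
                        np.average(
                            glyc[glyc_ok].astype(float),
                            weights=sub.loc[glyc_ok, "duplicate_count"].astype(float),
                        )
                    )
                    if glyc_ok.any()
                    else float("nan"),
                    "umis": float(w.sum()),
                }
            )
    return pd.DataFrame(rows)
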