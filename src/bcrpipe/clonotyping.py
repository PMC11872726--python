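"""Cross-subject clonotype clustering and clonal network construction.

A clonotype is a set of BCRs sharing the same (allele-stripped) V gene,
J gene and CDR3 length whose CDR3 amino-acid sequences sit within a
normalized substitution distance of 0.15 of one another.  Records from all
subjects are pooled before clustering so shared/convergent clonotypes
between individuals are visible.

Clustering is single-linkage agglomeration cut at the distance threshold,
which for a fixed cut is exactly the connected components of the graph
joining pairs at distance <= threshold — the standard clonotype semantics
and the basis of the correctness tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io import filter_productive, strip_allele, strip_allele_series

__all__ = [
    "partition_candidates",
    "normalized_hamming",
    "cluster_clonotypes",
    "clonotype_table",
    "select_high_usage_subjects",
    "subsample_matched",
    "build_network",
]


def normalized_hamming(a: str, b: str) -> float:
    """Substitutions per amino acid between two equal-length CDR3s."""
    if len(a) != len(b) or len(a) == 0:
        raise ValueError(f"CDR3 lengths differ or are zero: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b)) / len(a)


def partition_candidates(records: pd.DataFrame) -> dict[tuple[str, str, int], pd.Index]:
    """Group record row indices by (V gene, J gene, CDR3 length).

    Gene names are allele-stripped, so ``IGHV3-30*01`` and ``IGHV3-30*04``
    fall in the same candidate group.  The partition is disjoint and
    exhaustive over the input rows.
    """
    if len(records) == 0:
        return {}
    keys = pd.DataFrame(
        {
            "v": strip_allele_series(records["v_call"]),
            "j": strip_allele_series(records["j_call"]),
            "length": records["junction_aa"].str.len(),
        },
        index=records.index,
    )
    return {
        (v, j, int(length)): idx.index
        for (v, j, length), idx in keys.groupby(["v", "j", "length"], sort=True)
    }


def _aa_matrix(cdr3s: list[str]) -> np.ndarray:
    length = len(cdr3s[0])
    return np.frombuffer("".join(cdr3s).encode(), dtype=np.uint8).reshape(len(cdr3s), length)


def cluster_clonotypes(records: pd.DataFrame, threshold: float = 0.15) -> pd.Series:
    """Assign every productive record a deterministic clonotype id.

    Within each (V, J, CDR3-length) candidate group, unique CDR3s are
    agglomerated by single linkage on normalized Hamming distance and the
    dendrogram is cut at ``threshold`` (pairs at distance <= threshold
    merge).  Ids are sequential, ordered by partition key then by the
    smallest member ``sequence_id``, so re-runs and record re-orderings give
    the same partition.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    assignment = pd.Series(index=records.index, dtype=object)
    clusters: list[tuple[str, tuple, pd.Index]] = []  # (min sequence_id, key, rows)
    for key, rows in partition_candidates(records).items():
        cdr3s = records.loc[rows, "junction_aa"]
        unique = sorted(set(cdr3s))
        if len(unique) == 1:
            labels = np.zeros(len(unique), dtype=int)
        else:
            matrix = _aa_matrix(unique)
            dist = pdist(matrix, metric="hamming")
            labels = fcluster(linkage(dist, method="single"), t=threshold, criterion="distance")
        label_of = dict(zip(unique, labels))
        member_rows: dict[int, list] = {}
        for row, cdr3 in cdr3s.items():
            member_rows.setdefault(label_of[cdr3], []).append(row)
        for label, row_list in sorted(member_rows.items()):
            idx = pd.Index(row_list)
            clusters.append((str(records.loc[idx, "sequence_id"].min()), key, idx))
    clusters.sort(key=lambda item: (item[1], item[0]))
    for number, (_, _, idx) in enumerate(clusters, start=1):
        assignment.loc[idx] = f"CT{number:06d}"
    return assignment.rename("clonotype_id")


def clonotype_table(records: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Summary table: id, V, J, CDR3 length, size, subjects, consensus CDR3.

    The consensus CDR3 is the member CDR3 with the highest UMI-weighted
    abundance (ties broken lexicographically).
    """
    df = records.assign(clonotype_id=assignment)
    rows = []
    for ct_id, sub in df.groupby("clonotype_id", sort=True):
        tally = sub.groupby("junction_aa")["duplicate_count"].sum()
        tally = tally.sort_index().sort_values(ascending=False, kind="stable")
        rows.append(
            {
                "clonotype_id": ct_id,
                "v_gene": strip_allele(sub["v_call"].iloc[0]),
                "j_gene": strip_allele(sub["j_call"].iloc[0]),
                "cdr3_length": len(sub["junction_aa"].iloc[0]),
                "size": int(sub["duplicate_count"].sum()),
                "n_subjects": sub["subject_id"].nunique(),
                "consensus_cdr3": tally.index[0],
            }
        )
    return pd.DataFrame(rows)


def select_high_usage_subjects(
    usage: pd.DataFrame,
    groups: pd.Series,
    gene: str,
    case_group: str,
    reference_group: str,
    k: float = 1.0,
) -> list[str]:
    """Case-group subjects whose usage of ``gene`` is elevated.

    A case subject is selected when its usage exceeds
    ``mean(reference) + k * sd(reference)`` (strict inequality; sd with
    n-1 denominator).  Mirrors the selection of patients with gene usage
    more than one reference standard deviation above the control mean.
    """
    if gene not in usage.columns:
        raise ValueError(f"gene {gene!r} not in usage matrix")
    reference = usage.loc[groups[groups == reference_group].index, gene]
    if len(reference) < 2:
        raise ValueError(f"reference group {reference_group!r} has fewer than 2 subjects")
    cutoff = reference.mean() + k * reference.std(ddof=1)
    cases = usage.loc[groups[groups == case_group].index, gene]
    return sorted(cases.index[cases > cutoff])


def subsample_matched(
    records: pd.DataFrame,
    groups: pd.Series,
    n_subjects: int = 10,
    total_umis: int = 5000,
    rng: np.random.Generator | None = None,
    subjects_by_group: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Depth-matched group subsets for network comparison.

    Per group: keep ``n_subjects`` subjects (the named ones, else drawn
    uniformly at random) and then draw exactly ``total_umis`` UMIs without
    replacement from their pooled productive records.  Returns the selected
    records with ``duplicate_count`` set to the number of drawn UMIs.
    """
    rng = np.random.default_rng() if rng is None else rng
    records = filter_productive(records)
    kept = []
    for group in sorted(groups.unique()):
        members = sorted(groups.index[groups == group])
        if subjects_by_group and group in subjects_by_group:
            chosen = list(subjects_by_group[group])
            missing = set(chosen) - set(members)
            if missing:
                raise ValueError(f"subjects {sorted(missing)} not in group {group!r}")
        else:
            if len(members) < n_subjects:
                raise ValueError(
                    f"group {group!r} has {len(members)} subjects < required {n_subjects}"
                )
            chosen = sorted(rng.choice(members, size=n_subjects, replace=False))
        sub = records[records["subject_id"].isin(chosen)].reset_index(drop=True)
        weights = sub["duplicate_count"].to_numpy(dtype=np.int64)
        total = int(weights.sum())
        if total < total_umis:
            raise ValueError(
                f"group {group!r} has {total} UMIs < required {total_umis} after subsetting"
            )
        if total == total_umis:
            kept.append(sub)
            continue
        umi_rows = np.repeat(np.arange(len(sub)), weights)
        draw = umi_rows[rng.permutation(total)[:total_umis]]
        counts = np.bincount(draw, minlength=len(sub))
        sub = sub.loc[counts > 0].assign(duplicate_count=counts[counts > 0])
        kept.append(sub.reset_index(drop=True))
    return pd.concat(kept, ignore_index=True)


@dataclass
class ClonotypeNetwork:
    """Graph of UMI-identified records joined within clonotypes."""

    graph: nx.Graph
    capped_clonotypes: list[str]

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_gexf(self, path) -> None:
        nx.write_gexf(self.graph, path)

    def write_edge_list(self, path) -> None:
        nx.write_edgelist(self.graph, path, delimiter="\t", data=False)


def build_network(
    records: pd.DataFrame,
    assignment: pd.Series,
    edge_cap: int = 50,
    mutation_frequency: pd.Series | None = None,
) -> ClonotypeNetwork:
    """One node per record; edges join members of the same clonotype.

    Clonotypes with at most ``edge_cap`` members are drawn as cliques; larger
    ones fall back to a star centred on the most abundant member (flagged in
    ``capped_clonotypes`` and as a node-free graph attribute) to avoid
    quadratic edge counts.  Node attributes carry subject, constant-region
    call and, when provided, mutation frequency.
    """
    graph = nx.Graph()
    df = records.assign(clonotype_id=assignment)
    for row in df.itertuples():
        attrs = {
            "subject_id": row.subject_id,
            "c_call": row.c_call,
            "clonotype_id": row.clonotype_id,
        }
        if mutation_frequency is not None:
            attrs["mutation_frequency"] = float(mutation_frequency.loc[row.Index])
        graph.add_node(row.sequence_id, **attrs)
    capped = []
    for ct_id, sub in df.groupby("clonotype_id", sort=True):
        ids = sub["sequence_id"].tolist()
        if len(ids) <= edge_cap:
            graph.add_edges_from(
                (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
            )
        else:
            hub_row = sub.sort_values(
                ["duplicate_count", "sequence_id"], ascending=[False, True], kind="stable"
            ).iloc[0]
            hub = hub_row["sequence_id"]
            graph.add_edges_from((hub, other) for other in ids if other != hub)
            capped.append(ct_id)
    graph.graph["capped_clonotypes"] = ",".join(capped)
    return ClonotypeNetwork(graph=graph, capped_clonotypes=capped)
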