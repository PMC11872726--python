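"""Clonality and diversity of a repertoire under fixed-depth resampling.

Two indices are computed on species-abundance vectors (species = unique CDR3
amino-acid sequence, or pre-clustered clonotype):

* Gini index of inequality ``G = sum_i (2i - S - 1) P_(i) / S`` with
  proportions sorted ascending — 0 for a perfectly even repertoire,
  approaching ``(S-1)/S`` when one clone dominates.
* Shannon entropy ``H = -sum_i P_i ln P_i`` in nats — maximal at ``ln S``
  for an even repertoire.

Because both indices depend on sequencing depth, repertoires are compared at
a common depth: each repertoire is rarefied (sampled without replacement at
the UMI level) to a fixed size, the indices are computed, and the procedure
is averaged over many iterations (defaults: 1,000 UMIs x 1,000 iterations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Repertoire, filter_productive

__all__ = [
    "AbundanceVector",
    "DiversityResult",
    "gini_index",
    "shannon_entropy",
    "abundance_vector",
    "resampled_diversity",
    "composition_bins",
]


@dataclass
class AbundanceVector:
    """Species labels with non-negative integer (or weighted) counts."""

    labels: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.labels) != len(self.counts):
            raise ValueError("labels and counts must have equal length")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def S(self) -> int:
        """Number of species with count > 0."""
        return int((self.counts > 0).sum())

    @property
    def proportions(self) -> np.ndarray:
        """Proportions of species with count > 0 (sum to 1)."""
        present = self.counts[self.counts > 0]
        return present / present.sum()


def _as_proportions(v: AbundanceVector | np.ndarray) -> np.ndarray:
    if isinstance(v, AbundanceVector):
        if v.total == 0:
            raise ValueError("abundance vector has zero total count")
        return v.proportions
    counts = np.asarray(v, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("abundance vector has zero total count")
    return counts / counts.sum()


def gini_index(v: AbundanceVector | np.ndarray) -> float:
    """Gini index of inequality of a species-abundance vector.

    With proportions ``P`` sorted ascending and ``i = 1..S``:
    ``G = sum_i (2i - S - 1) P_i / (S * sum_i P_i)``.  Returns 0 for uniform
    abundances and at most ``(S-1)/S``.
    """
    p = np.sort(_as_proportions(v))
    s = p.size
    i = np.arange(1, s + 1)
    return float(((2 * i - s - 1) * p).sum() / s)


def shannon_entropy(v: AbundanceVector | np.ndarray) -> float:
    """Shannon entropy ``H = -sum_i P_i ln P_i`` in nats (0 ln 0 := 0)."""
    p = _as_proportions(v)
    return float(-(p * np.log(p)).sum())


def abundance_vector(records: pd.DataFrame, unit: str = "cdr3") -> AbundanceVector:
    """UMI-weighted species abundances at the chosen clustering unit.

    ``unit="cdr3"`` tallies unique ``junction_aa`` strings; ``"clonotype"``
    requires a ``clonotype_id`` column (see :mod:`bcrpipe.clonotyping`).
    """
    column = _unit_column(records, unit)
    tally = records.groupby(records[column], sort=True)["duplicate_count"].sum()
    return AbundanceVector(tally.index.to_numpy(), tally.to_numpy())


def _unit_column(records: pd.DataFrame, unit: str) -> str:
    if unit == "cdr3":
        return "junction_aa"
    if unit == "clonotype":
        if "clonotype_id" not in records.columns:
            raise ValueError("unit='clonotype' requires a clonotype_id column")
        return "clonotype_id"
    raise ValueError(f"unknown diversity unit {unit!r}")


@dataclass
class DiversityResult:
    """Across-iteration mean Gini and Shannon at a fixed rarefaction depth."""

    gini: float
    shannon: float
    subsample_size: int
    iterations: int
    unit: str


def resampled_diversity(
    rep: Repertoire | pd.DataFrame,
    unit: str = "cdr3",
    subsample_size: int = 1000,
    iterations: int = 1000,
    rng: np.random.Generator | None = None,
) -> DiversityResult:
    """Mean Gini/Shannon over rarefaction draws at a fixed UMI depth.

    Each iteration draws ``subsample_size`` UMIs without replacement from the
    productive records (expanded by ``duplicate_count``), tallies species at
    the chosen unit and computes both indices; the across-iteration means are
    returned.  Raises if the repertoire is shallower than the subsample —
    such subjects should have been excluded by the depth threshold upstream.
    """
    records = rep.records if isinstance(rep, Repertoire) else rep
    records = filter_productive(records)
    column = _unit_column(records, unit)
    rng = np.random.default_rng() if rng is None else rng

    codes, _ = pd.factorize(records[column], sort=True)
    weights = records["duplicate_count"].to_numpy(dtype=np.int64)
    umi_species = np.repeat(codes, weights)
    total = umi_species.size
    if total < subsample_size:
        raise ValueError(
            f"insufficient depth: {total} productive UMIs < subsample of {subsample_size}"
        )
    n_species = codes.max() + 1 if total else 0

    if total == subsample_size:
        counts = np.bincount(umi_species, minlength=n_species)
        return DiversityResult(
            gini=gini_index(counts),
            shannon=shannon_entropy(counts),
            subsample_size=subsample_size,
            iterations=iterations,
            unit=unit,
        )

    ginis = np.empty(iterations)
    shannons = np.empty(iterations)
    for it in range(iterations):
        draw = umi_species[rng.permutation(total)[:subsample_size]]
        counts = np.bincount(draw, minlength=n_species)
        ginis[it] = gini_index(counts)
        shannons[it] = shannon_entropy(counts)
    return DiversityResult(
        gini=float(ginis.mean()),
        shannon=float(shannons.mean()),
        subsample_size=subsample_size,
        iterations=iterations,
        unit=unit,
    )


def composition_bins(rep: Repertoire | pd.DataFrame) -> dict[str, float]:
    """Repertoire fraction held by the top 1, 2-10, 11-100 and 101+ CDR3s.

    Unique CDR3s are ranked by UMI-weighted abundance (ties broken
    lexicographically by CDR3 string so the bins are deterministic); the four
    bin proportions sum to 1.
    """
    records = rep.records if isinstance(rep, Repertoire) else rep
    records = filter_productive(records)
    if len(records) == 0:
        raise ValueError("empty repertoire")
    tally = records.groupby("junction_aa")["duplicate_count"].sum()
    tally = tally.sort_index().sort_values(ascending=False, kind="stable")
    p = tally.to_numpy(dtype=float) / tally.sum()
    return {
        "top_1": float(p[:1].sum()),
        "top_2_10": float(p[1:10].sum()),
        "top_11_100": float(p[10:100].sum()),
        "top_101_plus": float(p[100:].sum()),
    }
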