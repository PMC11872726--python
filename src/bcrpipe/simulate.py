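"""Synthetic AIRR cohort generator with known ground truth.

Emits fully annotated heavy-chain rearrangement tables that reproduce the
statistical structure the analysis stack assumes — between-subject germline
gene-usage variation (Dirichlet perturbation of population frequencies),
heavy-tailed clonal expansion, isotype-conditional somatic hypermutation
(zero-inflated counts for IgM, overdispersed counts for IgG), sequon
creation by mutation, and configurable planted group effects — together
with a :class:`TruthLedger` that reconciles exactly with the emitted
records and enables parameter-recovery tests.

The planted case/control effect is a location shift on one gene's base
frequency applied before each case subject's Dirichlet draw.  The shift is
calibrated by fixed point so that the standardized difference (Cohen's d)
of the *measured*, UMI-weighted usage — whose between-subject variance has
a Dirichlet component and a clone-size weighting component — equals the
configured value.

The germline panel is a synthetic toy reference: valid unambiguous
nucleotide sequences under real gene names, frame 0 from position 1, no
internal stops and no germline sequons, so that sequons arise from
mutation as they largely do in vivo.  Every analysis downstream depends
only on gene names and mismatch counts, not on true IMGT sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GROUPS, Repertoire, write_airr, write_metadata

__all__ = [
    "SimulationConfig",
    "GermlineReference",
    "TruthLedger",
    "default_reference",
    "default_config",
    "null_config",
    "study_attrition_config",
    "sample_subject_usage",
    "sample_clone_sizes",
    "mutate_sequence",
    "simulate_cohort",
    "write_cohort",
]

# ---------------------------------------------------------------------------
# alphabets and codon machinery

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_BYTES = np.frombuffer(_AA.encode(), dtype=np.uint8)
_AA_INDEX = {aa: i for i, aa in enumerate(_AA)}

# one stop-free codon per amino acid, used for back-translation
_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "AGC", "T": "ACT", "V": "GTG", "W": "TGG", "Y": "TAT",
}
_BASE_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
# (20, 3) base codes for each amino acid's codon
_CODON_CODES = np.array(
    [[_BASE_CODE[b] for b in _CODON_OF[aa].encode()] for aa in _AA], dtype=np.uint8
)

def _build_translation_lut() -> np.ndarray:
    from Bio.Seq import Seq

    lut = np.zeros(64, dtype=np.uint8)
    letters = "ACGT"
    for i1, b1 in enumerate(letters):
        for i2, b2 in enumerate(letters):
            for i3, b3 in enumerate(letters):
                aa = str(Seq(b1 + b2 + b3).translate())
                lut[16 * i1 + 4 * i2 + i3] = ord(aa)
    return lut


_TRANS_LUT = _build_translation_lut()

_V_AA_LEN = 98   # 294 nt
_J_AA_LEN = 16   # 48 nt
_V_NT_LEN = 3 * _V_AA_LEN
_J_NT_LEN = 3 * _J_AA_LEN


def _translate_codes(codes: np.ndarray) -> np.ndarray:
    """Translate a (n, 3k) base-code matrix to a (n, k) amino-acid byte matrix."""
    # codon index 16 c1 + 4 c2 + c3 fits in uint8, so no widening is needed
    idx = (codes[:, 0::3] << 4) | (codes[:, 1::3] << 2) | codes[:, 2::3]
    return _TRANS_LUT[idx]


def _sample_mutation_cells(
    k_rec: np.ndarray, n_cols: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exactly ``k_rec[i]`` distinct column indices per row i.

    Samples with replacement and re-draws collisions; expected cost is
    O(total mutations), far below materialising a random matrix per row.
    Returns (row indices, column indices) of the mutated cells.
    """
    n_rows = len(k_rec)

    def dedupe(keys: np.ndarray) -> np.ndarray:
        keys.sort(kind="stable")
        if keys.size < 2:
            return keys
        return keys[np.concatenate([[True], keys[1:] != keys[:-1]])]

    rows = np.repeat(np.arange(n_rows, dtype=np.int64), k_rec)
    keys = dedupe(rows * n_cols + rng.integers(0, n_cols, size=rows.size))
    have = np.bincount(keys // n_cols, minlength=n_rows)
    deficit = k_rec - have
    while deficit.any():
        extra_rows = np.repeat(np.arange(n_rows, dtype=np.int64), deficit)
        new_keys = extra_rows * n_cols + rng.integers(0, n_cols, size=extra_rows.size)
        keys = dedupe(np.concatenate([keys, new_keys]))
        have = np.bincount(keys // n_cols, minlength=n_rows)
        deficit = k_rec - have
    return keys // n_cols, keys % n_cols


# ---------------------------------------------------------------------------
# germline reference

@dataclass
class GermlineReference:
    """Toy germline panel: gene name -> nucleotide sequence."""

    v: dict[str, str]
    d: dict[str, str]
    j: dict[str, str]

    def __post_init__(self) -> None:
        for panel in (self.v, self.d, self.j):
            for name, seq in panel.items():
                if not seq or set(seq) - set("ACGT"):
                    raise ValueError(f"sequence for {name} contains non-ACGT characters")
        names = list(self.v) + list(self.d) + list(self.j)
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene names in reference")


#: Population-level relative gene frequencies (normalized at use).  IGHV3-23
#: is the most used V gene, as in human repertoires; IGHJ4 dominates J usage.
DEFAULT_V_WEIGHTS = {
    "IGHV1-2": 0.050, "IGHV1-3": 0.020, "IGHV1-18": 0.045, "IGHV1-46": 0.045,
    "IGHV1-69": 0.045, "IGHV2-5": 0.030, "IGHV2-70": 0.030, "IGHV3-7": 0.050,
    "IGHV3-11": 0.040, "IGHV3-15": 0.040, "IGHV3-21": 0.050, "IGHV3-23": 0.125,
    "IGHV3-30": 0.050, "IGHV3-30-3": 0.020, "IGHV3-33": 0.045, "IGHV3-48": 0.045,
    "IGHV3-49": 0.020, "IGHV4-4": 0.030, "IGHV4-34": 0.050, "IGHV4-39": 0.050,
    "IGHV4-59": 0.055, "IGHV5-51": 0.045, "IGHV6-1": 0.030, "IGHV7-4-1": 0.020,
    # rare genes giving the panel a realistic dynamic range (matters for the
    # between-group median-usage correlation structure)
    "IGHV1-24": 0.008, "IGHV1-58": 0.004, "IGHV2-26": 0.006, "IGHV3-13": 0.008,
    "IGHV3-43": 0.004, "IGHV3-64": 0.003, "IGHV3-72": 0.005, "IGHV3-73": 0.003,
    "IGHV4-28": 0.006, "IGHV5-10-1": 0.006,
}
DEFAULT_D_WEIGHTS = {
    "IGHD1-26": 0.15, "IGHD2-2": 0.20, "IGHD3-10": 0.27,
    "IGHD3-22": 0.15, "IGHD4-17": 0.10, "IGHD6-19": 0.13,
}
DEFAULT_J_WEIGHTS = {
    "IGHJ1": 0.03, "IGHJ2": 0.07, "IGHJ3": 0.10,
    "IGHJ4": 0.45, "IGHJ5": 0.13, "IGHJ6": 0.22,
}

_REFERENCE_SEED = 894_211  # fixed: the panel is part of the package, not of a run


def _random_aa_no_sequon(rng: np.random.Generator, length: int) -> str:
    aa = list(_AA[i] for i in rng.integers(0, 20, size=length))
    for p in range(length - 2):  # scrub N-X-S/T so germline carries no sequons
        if aa[p] == "N" and aa[p + 1] != "P" and aa[p + 2] in "ST":
            aa[p] = "Q"
    return "".join(aa)


def _backtranslate(aa: str) -> str:
    return "".join(_CODON_OF[x] for x in aa)


def default_reference() -> GermlineReference:
    """Deterministic toy panel: 24 IGHV, 6 IGHD and 6 IGHJ genes."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    v = {name: _backtranslate(_random_aa_no_sequon(rng, _V_AA_LEN)) for name in DEFAULT_V_WEIGHTS}
    d = {
        name: "".join("ACGT"[i] for i in rng.integers(0, 4, size=15))
        for name in DEFAULT_D_WEIGHTS
    }
    j = {name: _backtranslate(_random_aa_no_sequon(rng, _J_AA_LEN)) for name in DEFAULT_J_WEIGHTS}
    return GermlineReference(v=v, d=d, j=j)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimulationConfig:
    """Cohort-level generator settings; defaults emulate the study cohort.

    Group sizes default to the post-QC cohort (HC=21, ME_mm=25, ME_sa=36,
    MS=28).  ``ighv3_30_effect`` is the planted standardized shift of the
    effect gene's usage in the effect group (default 0.70 on IGHV3-30 in
    ME_mm).  ``shallow_subjects`` adds extra subjects per group with fewer
    than 1,500 productive UMIs to exercise the depth filter.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 21, "ME_mm": 25, "ME_sa": 36, "MS": 28}
    )
    umis_per_subject: tuple[int, int] = (2000, 3200)
    shallow_subjects: dict[str, int] = field(default_factory=dict)
    shallow_depth_range: tuple[int, int] = (600, 1400)
    gene_base_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "v": dict(DEFAULT_V_WEIGHTS),
            "d": dict(DEFAULT_D_WEIGHTS),
            "j": dict(DEFAULT_J_WEIGHTS),
        }
    )
    dirichlet_concentration: float = 300.0
    clone_size_law: tuple[str, float] = ("zipf", 2.7)
    ighv3_30_effect: float = 0.70
    effect_gene: str = "IGHV3-30"
    effect_group: str = "ME_mm"
    igm_fraction_by_group: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.55, "ME_mm": 0.65, "ME_sa": 0.58, "MS": 0.50}
    )
    igm_concentration: float = 30.0  # Beta concentration of subject IgM fractions
    shm_model: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "IgM": {"kind": "zero_inflated_poisson", "zero_fraction": 0.75, "mean": 4.0},
            "IgG": {"kind": "negative_binomial", "mean": 15.0, "shape": 5.0},
        }
    )
    nglyc_rate: float = 0.01
    productive_rate: float = 0.98
    cdr3_length_range: tuple[int, int] = (8, 24)
    member_substitution_rate: float = 0.015
    seed: int = 0

    def validate(self) -> None:
        for group, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group_sizes[{group!r}] must be >= 2, got {n}")
        for segment, freqs in self.gene_base_freqs.items():
            values = np.array(list(freqs.values()), dtype=float)
            if (values < 0).any() or values.sum() <= 0:
                raise ValueError(f"gene_base_freqs[{segment!r}] must be non-negative weights")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if not np.isfinite(self.ighv3_30_effect):
            raise ValueError("ighv3_30_effect must be finite")
        for group, frac in self.igm_fraction_by_group.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"igm_fraction_by_group[{group!r}] must be in [0, 1]")
        if self.igm_concentration <= 0:
            raise ValueError("igm_concentration must be positive")
        if not 0 <= self.nglyc_rate <= 1:
            raise ValueError("nglyc_rate must be in [0, 1]")
        if not 0 < self.productive_rate <= 1:
            raise ValueError("productive_rate must be in (0, 1]")
        if not 0 <= self.member_substitution_rate < 1:
            raise ValueError("member_substitution_rate must be in [0, 1)")
        lo, hi = self.umis_per_subject
        if lo < 1 or hi < lo:
            raise ValueError("umis_per_subject must be a valid (low, high) range")
        lo, hi = self.cdr3_length_range
        if lo < 4 or hi < lo:
            raise ValueError("cdr3_length_range must be a valid range with low >= 4")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"group_sizes has unknown groups {sorted(unknown)}")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-like cohort: planted IGHV3-30 shift and IgM skew in ME_mm."""
    return SimulationConfig(seed=seed, **overrides)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Effect-free cohort: no usage shift, identical IgM fractions."""
    defaults = dict(
        ighv3_30_effect=0.0,
        igm_fraction_by_group={g: 0.55 for g in GROUPS},
    )
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)


def study_attrition_config(seed: int = 0, **overrides) -> SimulationConfig:
    """124-sample cohort with 14 planted shallow subjects (110 pass QC)."""
    defaults = dict(shallow_subjects={"HC": 2, "ME_mm": 3, "ME_sa": 4, "MS": 5})
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)


# ---------------------------------------------------------------------------
# sampling primitives

def sample_subject_usage(
    base_freqs: np.ndarray | Sequence[float],
    concentration: float,
    shift_spec: tuple[int, float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One subject's gene-usage probability vector.

    Draws from a Dirichlet centred on ``base_freqs`` with total
    ``concentration`` (larger -> less between-subject variability).
    ``shift_spec=(gene_index, delta)`` raises the target gene's expected
    usage by ``delta`` before the draw, renormalizing the other genes.
    """
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    rng = np.random.default_rng() if rng is None else rng
    p = np.asarray(base_freqs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("base_freqs must sum to 1")
    if shift_spec is not None:
        index, delta = shift_spec
        shifted = p.copy()
        new_target = np.clip(p[index] + delta, 1e-9, 1 - 1e-9)
        shifted *= (1.0 - new_target) / (1.0 - p[index])
        shifted[index] = new_target
        p = shifted / shifted.sum()
    return rng.dirichlet(concentration * p)


def sample_clone_sizes(
    n_clones: int | None = None,
    law: tuple[str, float] = ("zipf", 2.5),
    rng: np.random.Generator | None = None,
    total: int | None = None,
) -> np.ndarray:
    """Positive integer clone sizes under the configured size law.

    Either ``n_clones`` draws are returned, or clones are drawn until their
    sizes sum to ``total`` exactly (the final clone is truncated to fit).
    ``("zipf", a)`` is a discrete power law with tail exponent ``a``;
    ``("constant", c)`` gives every clone size ``c``.
    """
    if (n_clones is None) == (total is None):
        raise ValueError("specify exactly one of n_clones or total")
    if n_clones is not None and n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    name, param = law

    def draw(k: int) -> np.ndarray:
        if name == "zipf":
            sizes = rng.zipf(param, size=k)
            if total is not None:
                sizes = np.minimum(sizes, total)
            return sizes.astype(np.int64)
        if name == "constant":
            return np.full(k, int(param), dtype=np.int64)
        raise ValueError(f"unknown clone-size law {name!r}")

    if n_clones is not None:
        return draw(n_clones)
    sizes = []
    remaining = total
    while remaining > 0:
        batch = draw(max(16, remaining // 2))
        cut = np.searchsorted(batch.cumsum(), remaining)
        if cut < len(batch):
            batch = batch[: cut + 1]
            batch[-1] = remaining - batch[:-1].sum()
            sizes.append(batch)
            remaining = 0
        else:
            sizes.append(batch)
            remaining -= int(batch.sum())
    return np.concatenate(sizes)


def mutate_sequence(
    germline_nt: str, n_mutations: int, rng: np.random.Generator | None = None
) -> tuple[str, np.ndarray]:
    """Apply exactly ``n_mutations`` substitutions to a germline sequence.

    Positions are sampled without replacement; every substituted base
    differs from the original.  Returns the mutated sequence and the sorted
    mutated positions.
    """
    length = len(germline_nt)
    if not 0 <= n_mutations <= length:
        raise ValueError(f"n_mutations must be in [0, {length}], got {n_mutations}")
    if n_mutations == 0:
        return germline_nt, np.array([], dtype=np.int64)
    rng = np.random.default_rng() if rng is None else rng
    positions = np.sort(rng.choice(length, size=n_mutations, replace=False))
    codes = np.array([_BASE_CODE[b] for b in germline_nt.encode()], dtype=np.uint8)
    codes[positions] = (codes[positions] + rng.integers(1, 4, size=n_mutations)) % 4
    return _BASES[codes].tobytes().decode(), positions


# ---------------------------------------------------------------------------
# effect-size calibration

_CALIBRATION_CACHE: dict[tuple, float] = {}
_CALIBRATION_SEED = 52_387_911


def _measured_usage_draws(
    q: float,
    c: float,
    size_pool: list[np.ndarray],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample n subjects' measured (UMI-weighted) usage of one gene.

    Uses the Dirichlet aggregation property — the target gene's subject
    frequency is Beta(cq, c(1-q)) — and thins a pre-drawn clone-size vector
    by that frequency, which reproduces the exact distribution of
    UMI-weighted usage without emitting records.
    """
    q = min(max(q, 1e-9), 1 - 1e-9)
    p_subject = rng.beta(c * q, c * (1.0 - q), size=n)
    out = np.empty(n)
    pool_idx = rng.integers(0, len(size_pool), size=n)
    for i in range(n):
        sizes = size_pool[pool_idx[i]]
        mask = rng.random(len(sizes)) < p_subject[i]
        out[i] = sizes[mask].sum() / sizes.sum()
    return out


def calibrate_effect_shift(config: SimulationConfig) -> float:
    """Additive base-frequency shift realizing the configured Cohen's d.

    The shift is solved empirically: pseudo-cohorts of measured usage are
    drawn at the configured group sizes (effect group vs healthy controls),
    the sample Cohen's d is averaged, and the shift is rescaled until the
    mean realized d matches the configured value.  Calibrating on the
    *sample* statistic matters because heavy-tailed clone weighting biases
    small-sample standard deviations low, which an analytic population-sd
    calibration would not capture.  The result is cached per configuration;
    the calibration RNG is fixed, so cohorts remain reproducible.
    """
    d = config.ighv3_30_effect
    if d == 0:
        return 0.0
    weights = config.gene_base_freqs["v"]
    if config.effect_gene not in weights:
        raise ValueError(f"effect gene {config.effect_gene!r} not in V panel")
    values = np.array(list(weights.values()), dtype=float)
    q0 = weights[config.effect_gene] / values.sum()
    c = config.dirichlet_concentration
    n_case = config.group_sizes.get(config.effect_group, 25)
    control_candidates = [g for g in config.group_sizes if g != config.effect_group]
    n_control = config.group_sizes["HC"] if "HC" in config.group_sizes else (
        config.group_sizes[control_candidates[0]] if control_candidates else n_case
    )
    key = (
        round(q0, 12), c, d, config.umis_per_subject, config.clone_size_law,
        n_case, n_control,
    )
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    rng = np.random.default_rng(_CALIBRATION_SEED)
    lo, hi = config.umis_per_subject
    size_pool = [
        sample_clone_sizes(
            total=int(rng.integers(lo, hi + 1)), law=config.clone_size_law, rng=rng
        )
        for _ in range(2000)
    ]

    def mean_realized_d(delta: float, n_cohorts: int) -> float:
        total = 0.0
        for _ in range(n_cohorts):
            case = _measured_usage_draws(q0 + delta, c, size_pool, n_case, rng)
            control = _measured_usage_draws(q0, c, size_pool, n_control, rng)
            pooled = np.sqrt(
                ((n_case - 1) * case.var(ddof=1) + (n_control - 1) * control.var(ddof=1))
                / (n_case + n_control - 2)
            )
            total += (case.mean() - control.mean()) / pooled
        return total / n_cohorts

    # analytic start: population sd ignoring clone weighting
    delta = d * np.sqrt(q0 * (1 - q0) / (c + 1.0))
    for n_cohorts in (300, 600, 1200):
        realized = mean_realized_d(delta, n_cohorts)
        if realized > 0:
            delta *= d / realized
        delta = float(min(delta, 0.9 - q0))
    _CALIBRATION_CACHE[key] = float(delta)
    return float(delta)


# ---------------------------------------------------------------------------
# truth ledger

@dataclass
class TruthLedger:
    """Ground truth per subject and cohort, reconciling with emitted records.

    ``subjects`` is indexed by subject id with realized per-subject totals;
    ``usage`` maps segment -> subjects x genes table of the true sampled
    usage vectors; ``clone_sizes`` and ``mutation_counts`` hold per-subject
    arrays (productive clones / productive records in emission order).
    """

    subjects: pd.DataFrame
    usage: dict[str, pd.DataFrame]
    clone_sizes: dict[str, np.ndarray]
    mutation_counts: dict[str, np.ndarray]
    planted: dict[str, float | str]

    def reconcile(self, repertoires: Sequence[Repertoire]) -> None:
        """Raise AssertionError unless emitted records match the ledger."""
        from .io import filter_productive

        for rep in repertoires:
            row = self.subjects.loc[rep.subject_id]
            assert len(rep.records) == row["n_records"], rep.subject_id
            productive = filter_productive(rep.records)
            assert int(productive["duplicate_count"].sum()) == row["n_productive_umis"]
            igm = productive["c_call"].str.startswith("IGHM")
            assert int(productive.loc[igm, "duplicate_count"].sum()) == row["igm_umis"]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(outdir / "ledger_subjects.csv")
        for segment, table in self.usage.items():
            table.to_csv(outdir / f"ledger_usage_{segment}.csv")
        pd.DataFrame(
            [(s, i, int(v)) for s, arr in self.clone_sizes.items() for i, v in enumerate(arr)],
            columns=["subject_id", "clone_index", "size"],
        ).to_csv(outdir / "ledger_clone_sizes.csv", index=False)
        pd.DataFrame([self.planted]).to_csv(outdir / "ledger_planted.csv", index=False)


# ---------------------------------------------------------------------------
# cohort emission

class _EncodedReference:
    """Reference panels as aligned name lists and base-code matrices."""

    def __init__(self, reference: GermlineReference, config: SimulationConfig):
        self.v_names = list(config.gene_base_freqs["v"])
        self.d_names = list(config.gene_base_freqs["d"])
        self.j_names = list(config.gene_base_freqs["j"])
        for name in self.v_names:
            if name not in reference.v:
                raise ValueError(f"V gene {name!r} missing from reference")
        for name in self.d_names:
            if name not in reference.d:
                raise ValueError(f"D gene {name!r} missing from reference")
        for name in self.j_names:
            if name not in reference.j:
                raise ValueError(f"J gene {name!r} missing from reference")

        def encode(seq: str) -> np.ndarray:
            return np.array([_BASE_CODE[b] for b in seq.encode()], dtype=np.uint8)

        self.v_codes = np.stack([encode(reference.v[n]) for n in self.v_names])
        self.j_codes = np.stack([encode(reference.j[n]) for n in self.j_names])

        def freq_vector(weights: Mapping[str, float]) -> np.ndarray:
            values = np.array(list(weights.values()), dtype=float)
            return values / values.sum()

        self.v_freqs = freq_vector(config.gene_base_freqs["v"])
        self.d_freqs = freq_vector(config.gene_base_freqs["d"])
        self.j_freqs = freq_vector(config.gene_base_freqs["j"])


def _draw_mutation_counts(
    model: Mapping[str, float], size: int, rng: np.random.Generator
) -> np.ndarray:
    kind = model["kind"]
    if kind == "zero_inflated_poisson":
        counts = rng.poisson(model["mean"], size=size)
        counts[rng.random(size) < model["zero_fraction"]] = 0
    elif kind == "negative_binomial":
        shape = model["shape"]
        counts = rng.negative_binomial(shape, shape / (shape + model["mean"]), size=size)
    else:
        raise ValueError(f"unknown SHM model kind {kind!r}")
    return np.minimum(counts, _V_NT_LEN + _J_NT_LEN - 1).astype(np.int64)


def _emit_subject(
    subject_id: str,
    group: str,
    depth: int,
    config: SimulationConfig,
    enc: _EncodedReference,
    shift: tuple[int, float] | None,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict, np.ndarray, np.ndarray, np.ndarray]:
    """Generate one subject's records; returns (records, ledger row, true
    V/D/J usage vectors stacked, clone sizes, per-record mutation counts)."""
    c = config.dirichlet_concentration
    usage_v = sample_subject_usage(enc.v_freqs, c, shift, rng)
    usage_d = sample_subject_usage(enc.d_freqs, c, None, rng)
    usage_j = sample_subject_usage(enc.j_freqs, c, None, rng)

    sizes = sample_clone_sizes(total=depth, law=config.clone_size_law, rng=rng)
    n_productive_clones = len(sizes)
    n_extra = int(round(depth * (1.0 - config.productive_rate) / config.productive_rate))
    all_sizes = np.concatenate([sizes, np.ones(n_extra, dtype=np.int64)])
    n_clones = len(all_sizes)
    productive_clone = np.ones(n_clones, dtype=bool)
    productive_clone[n_productive_clones:] = False

    v_idx = rng.choice(len(enc.v_freqs), size=n_clones, p=usage_v)
    d_idx = rng.choice(len(enc.d_freqs), size=n_clones, p=usage_d)
    j_idx = rng.choice(len(enc.j_freqs), size=n_clones, p=usage_j)
    allele = np.where(rng.random(n_clones) < 0.8, "*01", "*02")
    igm_mean = config.igm_fraction_by_group.get(group, 0.55)
    igm_mean = min(max(igm_mean, 1e-6), 1 - 1e-6)
    # per-subject IgM fraction varies around the group mean
    igm_frac = rng.beta(
        igm_mean * config.igm_concentration, (1.0 - igm_mean) * config.igm_concentration
    )
    clone_is_igm = rng.random(n_clones) < igm_frac
    igg_subclass = rng.integers(1, 3, size=n_clones)  # IGHG1 / IGHG2

    lo_len, hi_len = config.cdr3_length_range
    span = hi_len - lo_len
    clone_len = lo_len + rng.binomial(span, 0.45, size=n_clones)
    # founder CDR3s: fixed C...W frame, random interior
    interior_total = int((clone_len - 2).sum())
    interior_flat = rng.integers(0, 20, size=interior_total).astype(np.uint8)

    n_records = int(all_sizes.sum())
    record_clone = np.repeat(np.arange(n_clones), all_sizes)
    shm = np.zeros(n_records, dtype=np.int64)
    rec_is_igm = clone_is_igm[record_clone]
    shm[rec_is_igm] = _draw_mutation_counts(config.shm_model["IgM"], int(rec_is_igm.sum()), rng)
    shm[~rec_is_igm] = _draw_mutation_counts(
        config.shm_model["IgG"], int((~rec_is_igm).sum()), rng
    )

    sequences = np.empty(n_records, dtype=object)
    germlines = np.empty(n_records, dtype=object)
    junctions = np.empty(n_records, dtype=object)

    code_w = _AA_INDEX["W"]
    code_c = _AA_INDEX["C"]
    code_n, code_p = _AA_INDEX["N"], _AA_INDEX["P"]
    code_s, code_t = _AA_INDEX["S"], _AA_INDEX["T"]
    aa_stop = ord("*")

    # founder CDR3s as a right-padded (n_clones, hi_len) amino-acid code
    # matrix; boolean-mask assignment fills the interiors in clone order
    col_grid = np.arange(hi_len)
    interior_mask_clone = (col_grid[None, :] >= 1) & (col_grid[None, :] < (clone_len - 1)[:, None])
    founder = np.zeros((n_clones, hi_len), dtype=np.uint8)
    founder[:, 0] = code_c
    founder[interior_mask_clone] = interior_flat
    founder[np.arange(n_clones), clone_len - 1] = code_w

    member_aa = founder[record_clone]
    interior_mask_rec = interior_mask_clone[record_clone]
    rec_len = clone_len[record_clone]
    if config.member_substitution_rate > 0:
        sub_mask = (rng.random((n_records, hi_len)) < config.member_substitution_rate)
        sub_mask &= interior_mask_rec
        n_subs = int(sub_mask.sum())
        if n_subs:
            member_aa[sub_mask] = (
                member_aa[sub_mask] + rng.integers(1, 20, size=n_subs).astype(np.uint8)
            ) % 20

    cdr3_nt = _CODON_CODES[member_aa].reshape(n_records, 3 * hi_len)
    v_germ = enc.v_codes[v_idx[record_clone]]
    j_germ = enc.j_codes[j_idx[record_clone]]
    v_mut = v_germ.copy()
    j_mut = j_germ.copy()

    # exactly k somatic mutations per record, restricted to the V and J
    # segments (CDR3 variation is modelled by the member-substitution step)
    if shm.max() > 0:
        mut_rows, mut_cols = _sample_mutation_cells(shm, _V_NT_LEN + _J_NT_LEN, rng)
        deltas = rng.integers(1, 4, size=mut_rows.size).astype(np.uint8)
        in_v = mut_cols < _V_NT_LEN
        v_mut[mut_rows[in_v], mut_cols[in_v]] = (
            v_germ[mut_rows[in_v], mut_cols[in_v]] + deltas[in_v]
        ) % 4
        j_cols = mut_cols[~in_v] - _V_NT_LEN
        j_mut[mut_rows[~in_v], j_cols] = (j_germ[mut_rows[~in_v], j_cols] + deltas[~in_v]) % 4

    # sequon planting: with per-mutation probability, a mutated record gains
    # an N-X-S/T motif (X != P) at a random in-frame position of the V region
    if config.nglyc_rate > 0:
        plant_p = 1.0 - (1.0 - config.nglyc_rate) ** np.minimum(shm, 60)
        planted = np.nonzero(rng.random(n_records) < plant_p)[0]
        if planted.size:
            non_p = np.array([i for i in range(20) if _AA[i] != "P"])
            aa_pos = rng.integers(2, _V_AA_LEN - 3, size=planted.size)
            x_aa = non_p[rng.integers(0, len(non_p), size=planted.size)]
            st_aa = np.where(rng.random(planted.size) < 0.5, code_s, code_t)
            triples = np.hstack(
                [
                    np.tile(_CODON_CODES[code_n], (planted.size, 1)),
                    _CODON_CODES[x_aa],
                    _CODON_CODES[st_aa],
                ]
            )
            v_mut[planted[:, None], (3 * aa_pos)[:, None] + np.arange(9)[None, :]] = triples

    realized_mutations = (v_mut != v_germ).sum(axis=1) + (j_mut != j_germ).sum(axis=1)

    # translation, internal-stop detection and sequon counting, done in
    # segment pieces plus the two windows that straddle segment boundaries
    v_aa = _translate_codes(v_mut)
    j_aa = _translate_codes(j_mut)
    has_stop = (v_aa == aa_stop).any(axis=1) | (j_aa[:, :-1] == aa_stop).any(axis=1)

    def _sequon_windows(aa_bytes: np.ndarray) -> np.ndarray:
        return (
            (aa_bytes[:, :-2] == ord("N"))
            & (aa_bytes[:, 1:-1] != ord("P"))
            & ((aa_bytes[:, 2:] == ord("S")) | (aa_bytes[:, 2:] == ord("T")))
        ).sum(axis=1)

    cdr3_windows = (
        (member_aa[:, :-2] == code_n)
        & (member_aa[:, 1:-1] != code_p)
        & ((member_aa[:, 2:] == code_s) | (member_aa[:, 2:] == code_t))
        & (col_grid[None, : hi_len - 2] < (rec_len - 2)[:, None])
    ).sum(axis=1)
    # V/CDR3 boundary: (V[-1], 'C', cdr3[1]); CDR3/J boundary: (cdr3[-2], 'W', J[0])
    rows = np.arange(n_records)
    boundary_v = (v_aa[:, -1] == ord("N")) & np.isin(member_aa[rows, 1], (code_s, code_t))
    boundary_j = (member_aa[rows, rec_len - 2] == code_n) & np.isin(
        j_aa[:, 0], (ord("S"), ord("T"))
    )
    sequon = _sequon_windows(v_aa) + _sequon_windows(j_aa) + cdr3_windows
    sequon += boundary_v.astype(np.int64) + boundary_j.astype(np.int64)
    nglyc_counts = np.where(has_stop, -1, sequon)

    # string assembly is the only per-CDR3-length work
    v_ascii, v_germ_ascii = _BASES[v_mut], _BASES[v_germ]
    j_ascii, j_germ_ascii = _BASES[j_mut], _BASES[j_germ]
    cdr3_ascii = _BASES[cdr3_nt]
    junction_ascii = _AA_BYTES[member_aa]
    for length in np.unique(rec_len):
        rows_l = rec_len == length
        total_len = _V_NT_LEN + 3 * int(length) + _J_NT_LEN
        seq_bytes = np.concatenate(
            [v_ascii[rows_l], cdr3_ascii[rows_l, : 3 * length], j_ascii[rows_l]], axis=1
        )
        germ_bytes = np.concatenate(
            [v_germ_ascii[rows_l], cdr3_ascii[rows_l, : 3 * length], j_germ_ascii[rows_l]],
            axis=1,
        )
        # decode via tolist: markedly faster than the S->U astype path
        sequences[rows_l] = [b.decode() for b in seq_bytes.view(f"S{total_len}").ravel()]
        germlines[rows_l] = [b.decode() for b in germ_bytes.view(f"S{total_len}").ravel()]
        junctions[rows_l] = [
            b.decode()
            for b in junction_ascii[rows_l, :length].copy().view(f"S{int(length)}").ravel()
        ]

    c_call = np.where(
        clone_is_igm[record_clone],
        "IGHM",
        np.char.add("IGHG", igg_subclass[record_clone].astype(str)),
    )
    records = pd.DataFrame(
        {
            "sequence_id": [f"{subject_id}-{i:06d}" for i in range(n_records)],
            "sequence": sequences,
            "productive": productive_clone[record_clone],
            "v_call": np.char.add(
                np.array(enc.v_names, dtype=object)[v_idx[record_clone]].astype(str),
                allele[record_clone],
            ),
            "d_call": np.char.add(
                np.array(enc.d_names, dtype=object)[d_idx[record_clone]].astype(str),
                allele[record_clone],
            ),
            "j_call": np.char.add(
                np.array(enc.j_names, dtype=object)[j_idx[record_clone]].astype(str),
                allele[record_clone],
            ),
            "c_call": c_call,
            "junction_aa": junctions,
            "germline_alignment": germlines,
            "duplicate_count": np.ones(n_records, dtype=np.int64),
            "subject_id": subject_id,
        }
    )

    productive_rec = productive_clone[record_clone]
    ledger_row = {
        "group": group,
        "depth_target": depth,
        "n_records": n_records,
        "n_productive_umis": int(productive_rec.sum()),
        "n_nonproductive": int(n_extra),
        "igm_umis": int((productive_rec & rec_is_igm).sum()),
        "true_igm_fraction": float(igm_frac),
        "igg_umis": int((productive_rec & ~rec_is_igm).sum()),
        "n_clones": int(n_productive_clones),
        "total_mutations": int(realized_mutations[productive_rec].sum()),
        "total_nglyc_sites": int(
            nglyc_counts[productive_rec & (nglyc_counts >= 0)].sum()
        ),
        "shallow": depth < 1500,
    }
    true_usage = np.concatenate([usage_v, usage_d, usage_j])
    return records, ledger_row, true_usage, sizes, realized_mutations[productive_rec]


def simulate_cohort(
    config: SimulationConfig, reference: GermlineReference | None = None
) -> tuple[list[Repertoire], TruthLedger]:
    """Simulate a full cohort; one repertoire per subject plus ground truth.

    Deterministic for a fixed config (byte-identical records across runs).
    Subjects of the effect group receive the calibrated usage shift of the
    effect gene; subjects listed in ``shallow_subjects`` are emitted below
    the 1,500-UMI depth threshold.
    """
    config.validate()
    reference = default_reference() if reference is None else reference
    enc = _EncodedReference(reference, config)
    rng = np.random.default_rng(config.seed)
    delta = calibrate_effect_shift(config)
    effect_index = (
        enc.v_names.index(config.effect_gene) if config.effect_gene in enc.v_names else None
    )

    repertoires: list[Repertoire] = []
    ledger_rows: dict[str, dict] = {}
    usage_rows: dict[str, np.ndarray] = {}
    clone_sizes: dict[str, np.ndarray] = {}
    mutation_counts: dict[str, np.ndarray] = {}
    lo, hi = config.umis_per_subject
    shallow_lo, shallow_hi = config.shallow_depth_range

    for group, n_subjects in config.group_sizes.items():
        n_shallow = config.shallow_subjects.get(group, 0)
        for i in range(n_subjects + n_shallow):
            subject_id = f"{group}_{i + 1:03d}"
            shallow = i >= n_subjects
            depth = int(
                rng.integers(shallow_lo, shallow_hi + 1)
                if shallow
                else rng.integers(lo, hi + 1)
            )
            shift = (
                (effect_index, delta)
                if (delta != 0 and group == config.effect_group and effect_index is not None)
                else None
            )
            records, row, true_usage, sizes, mutations = _emit_subject(
                subject_id, group, depth, config, enc, shift, rng
            )
            repertoires.append(Repertoire(subject_id=subject_id, group=group, records=records))
            ledger_rows[subject_id] = row
            usage_rows[subject_id] = true_usage
            clone_sizes[subject_id] = sizes
            mutation_counts[subject_id] = mutations

    subjects = pd.DataFrame(ledger_rows).T
    subjects.index.name = "subject_id"
    gene_names = enc.v_names + enc.d_names + enc.j_names
    usage_table = pd.DataFrame(usage_rows, index=gene_names).T
    usage_table.index.name = "subject_id"
    n_v, n_d = len(enc.v_names), len(enc.d_names)
    usage = {
        "v": usage_table.iloc[:, :n_v],
        "d": usage_table.iloc[:, n_v : n_v + n_d],
        "j": usage_table.iloc[:, n_v + n_d :],
    }
    ledger = TruthLedger(
        subjects=subjects,
        usage=usage,
        clone_sizes=clone_sizes,
        mutation_counts=mutation_counts,
        planted={
            "effect_gene": config.effect_gene,
            "effect_group": config.effect_group,
            "cohens_d": float(config.ighv3_30_effect),
            "base_shift": float(delta),
        },
    )
    return repertoires, ledger


def write_cohort(
    repertoires: Sequence[Repertoire],
    ledger: TruthLedger,
    outdir: str | Path,
) -> None:
    """Write the cohort as AIRR TSV + metadata TSV + ledger tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = pd.concat([rep.records for rep in repertoires], ignore_index=True)
    write_airr(records, outdir / "rearrangements.tsv")
    metadata = pd.DataFrame(
        {
            "subject_id": [rep.subject_id for rep in repertoires],
            "group": [rep.group for rep in repertoires],
        }
    )
    write_metadata(metadata, outdir / "metadata.tsv")
    ledger.write(outdir)
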