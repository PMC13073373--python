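"""Biophysical penalty terms and the scalar design fitness.

A candidate storage sequence is scored by six non-negative terms, combined
as a weighted sum to be *minimized*:

* objectives — GC composition (quadratic deviation from 50%), cumulative
  homopolymer penalty for runs longer than 3 nt, and deviation of the mean
  nearest-neighbor stacking free energy from a target of -1.45 kcal/mol;
* soft constraints — melting temperature outside [55, 65] degC (squared
  distance to the nearest bound), violation of a minimum Hamming distance to
  an archive of existing sequences, and reverse-complement self-similarity
  above 15%.

Tm uses the salt-corrected empirical model ``64.9 + 41 * (GC% - 16.4) / 100``
and therefore depends on base composition only.  The stacking-energy term
divides by the number of dinucleotide steps (L - 1), so a sequence whose
every step sits at the target scores exactly zero at any length, and takes
the absolute deviation (a signed value would reward overshooting in a
minimization).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .codec import DEFAULT_MAP, EncodingMap, NucleotideSequence, reverse_complement_digits

__all__ = [
    "FitnessWeights",
    "ThermoTable",
    "ConstraintConfig",
    "FitnessBreakdown",
    "FitnessEvaluator",
    "load_default_thermo",
    "gc_content",
    "gc_penalty",
    "homopolymer_blocks",
    "max_homopolymer",
    "hp_penalty",
    "dg_penalty",
    "melting_temperature",
    "melting_temperature_from_gc",
    "tm_penalty",
    "hamming_penalty",
    "rc_similarity",
    "rc_penalty",
    "total_fitness",
]

_DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


@dataclass(frozen=True)
class FitnessWeights:
    """Weights for (GC, HP, dG) objectives and (Tm, Hamming, RC) constraints.

    Homopolymer and melting-temperature terms carry the largest default
    weights because they dominate synthesizability.
    """

    w_obj: tuple[float, float, float] = (1.0, 10.0, 1.0)
    w_cons: tuple[float, float, float] = (5.0, 1.0, 5.0)

    def __post_init__(self) -> None:
        all_w = (*self.w_obj, *self.w_cons)
        if any(w < 0 for w in all_w):
            raise ValueError("weights must be non-negative")
        if not any(w > 0 for w in all_w):
            raise ValueError("at least one weight must be positive")


@dataclass(frozen=True)
class ThermoTable:
    """16-entry dinucleotide stacking table (kcal/mol) plus the target energy."""

    dg: dict[str, float]
    dg_target: float = -1.45

    def __post_init__(self) -> None:
        missing = set(_DINUCLEOTIDES) - set(self.dg)
        extra = set(self.dg) - set(_DINUCLEOTIDES)
        if missing or extra:
            raise ValueError(f"thermo table keys wrong: missing={sorted(missing)} extra={sorted(extra)}")
        if not all(np.isfinite(v) for v in self.dg.values()):
            raise ValueError("non-finite stacking energy")

    @classmethod
    def from_yaml(cls, path, dg_target: float = -1.45) -> "ThermoTable":
        with open(path) as fh:
            return cls(dg={k: float(v) for k, v in yaml.safe_load(fh).items()}, dg_target=dg_target)

    def as_array(self, mapping: EncodingMap = DEFAULT_MAP) -> np.ndarray:
        """Step energies indexed by ``4 * digit(first) + digit(second)``."""
        arr = np.empty(16)
        for step, v in self.dg.items():
            i = 4 * mapping.base_to_digit[step[0]] + mapping.base_to_digit[step[1]]
            arr[i] = v
        return arr


def load_default_thermo() -> ThermoTable:
    ref = resources.files("tchur") / "data" / "stacking_dg.yaml"
    with resources.as_file(ref) as path:
        return ThermoTable.from_yaml(path)


@dataclass(frozen=True)
class ConstraintConfig:
    tm_range: tuple[float, float] = (55.0, 65.0)
    rc_threshold: float = 0.15
    d_min: int = 0
    archive: tuple[NucleotideSequence, ...] = ()
    hp_limit: int = 3

    def __post_init__(self) -> None:
        if self.tm_range[0] >= self.tm_range[1]:
            raise ValueError("tm_range lower bound must be below upper bound")
        if not 0 < self.rc_threshold < 1:
            raise ValueError("rc_threshold must lie in (0, 1)")
        if self.d_min < 0:
            raise ValueError("d_min must be >= 0")


@dataclass(frozen=True)
class FitnessBreakdown:
    f_gc: float
    f_hp: float
    f_dg: float
    c_tm: float
    c_ham: float
    c_rc: float
    tm: float
    gc_percent: float
    rc_ratio: float
    min_hamming: int | None
    total: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------- term ops


def gc_content(seq: NucleotideSequence) -> float:
    """GC percentage in [0, 100]."""
    return _gc_from_digits(seq.digits, seq.mapping)


def _gc_digits(mapping: EncodingMap) -> tuple[int, int]:
    b2d = mapping.base_to_digit
    return b2d["G"], b2d["C"]


def _gc_from_digits(digits: np.ndarray, mapping: EncodingMap) -> float:
    g, c = _gc_digits(mapping)
    return float(np.count_nonzero((digits == g) | (digits == c))) / len(digits) * 100.0


def gc_penalty(seq: NucleotideSequence) -> float:
    """Quadratic deviation of GC% from the ideal 50%."""
    return (gc_content(seq) - 50.0) ** 2


def homopolymer_blocks(seq: NucleotideSequence) -> list[tuple[str, int]]:
    """Maximal runs in order; run lengths sum to L."""
    lengths = _run_lengths(seq.digits)
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    return [(seq.bases[s], int(h)) for s, h in zip(starts, lengths)]


def _run_lengths(digits: np.ndarray) -> np.ndarray:
    breaks = np.flatnonzero(np.diff(digits)) + 1
    edges = np.concatenate(([0], breaks, [len(digits)]))
    return np.diff(edges)


def max_homopolymer(seq: NucleotideSequence) -> int:
    return int(_run_lengths(seq.digits).max())


def hp_penalty(seq: NucleotideSequence, hp_limit: int = 3) -> float:
    """Cumulative squared excess over ``hp_limit`` for every long run."""
    return _hp_from_digits(seq.digits, hp_limit)


def _hp_from_digits(digits: np.ndarray, hp_limit: int) -> float:
    h = _run_lengths(digits)
    excess = h[h > hp_limit] - hp_limit
    return float(np.sum(excess.astype(np.float64) ** 2))


def dg_penalty(seq: NucleotideSequence, thermo: ThermoTable) -> float:
    """|mean per-step stacking energy - target| x 100 (length-normalized)."""
    if len(seq) < 2:
        warnings.warn("dg_penalty undefined for L < 2; returning 0", stacklevel=2)
        return 0.0
    table = thermo.as_array(seq.mapping)
    return _dg_from_digits(seq.digits, table, thermo.dg_target)


def _dg_from_digits(digits: np.ndarray, table: np.ndarray, dg_target: float) -> float:
    steps = 4 * digits[:-1].astype(np.int64) + digits[1:]
    return abs(float(table[steps].mean()) - dg_target) * 100.0


def dg_sum(seq: NucleotideSequence, thermo: ThermoTable) -> float:
    """Total stacking free energy of the sequence (kcal/mol), for reporting."""
    if len(seq) < 2:
        return 0.0
    table = thermo.as_array(seq.mapping)
    steps = 4 * seq.digits[:-1].astype(np.int64) + seq.digits[1:]
    return float(table[steps].sum())


def melting_temperature_from_gc(gc_percent: float) -> float:
    """Salt-corrected empirical Tm (degC) as a function of GC percentage."""
    return 64.9 + 41.0 * (gc_percent - 16.4) / 100.0


def melting_temperature(seq: NucleotideSequence) -> float:
    return melting_temperature_from_gc(gc_content(seq))


def tm_penalty(seq: NucleotideSequence, cfg: ConstraintConfig = ConstraintConfig()) -> float:
    """Squared distance of Tm to the nearest bound of the target interval."""
    return _tm_pen(melting_temperature(seq), cfg.tm_range)


def _tm_pen(tm: float, tm_range: tuple[float, float]) -> float:
    lo, hi = tm_range
    if tm < lo:
        return (lo - tm) ** 2
    if tm > hi:
        return (tm - hi) ** 2
    return 0.0


def hamming_penalty(
    seq: NucleotideSequence, cfg: ConstraintConfig
) -> tuple[int | None, float]:
    """(min distance to archive, squared violation of ``d_min``).

    An empty archive means single-sequence design mode: no distance is
    defined and the penalty is zero.
    """
    if not cfg.archive:
        return None, 0.0
    dmin_obs = min(_hamming(seq, a) for a in cfg.archive)
    if dmin_obs < cfg.d_min:
        return dmin_obs, float((cfg.d_min - dmin_obs) ** 2)
    return dmin_obs, 0.0


def _hamming(a: NucleotideSequence, b: NucleotideSequence) -> int:
    if len(a) != len(b):
        raise ValueError(f"archive length mismatch: {len(a)} vs {len(b)}")
    return int(np.count_nonzero(a.digits != b.digits))


def rc_similarity(seq: NucleotideSequence) -> float:
    """Fraction of positions matching the full-length reverse complement."""
    rc = reverse_complement_digits(seq.digits, seq.mapping)
    return float(np.count_nonzero(seq.digits == rc)) / len(seq)


def rc_penalty(seq: NucleotideSequence, cfg: ConstraintConfig = ConstraintConfig()) -> float:
    ratio = rc_similarity(seq)
    if ratio <= cfg.rc_threshold:
        return 0.0
    return (ratio - cfg.rc_threshold) * 100.0


def total_fitness(
    seq: NucleotideSequence,
    weights: FitnessWeights = FitnessWeights(),
    cfg: ConstraintConfig = ConstraintConfig(),
    thermo: ThermoTable | None = None,
) -> FitnessBreakdown:
    """Weighted scalar fitness (lower is better) with full term breakdown."""
    thermo = thermo or load_default_thermo()
    return FitnessEvaluator(len(seq), weights, cfg, thermo, seq.mapping).breakdown(seq.digits)


class FitnessEvaluator:
    """Pre-compiled evaluator for repeated scoring of digit vectors.

    Folds the thermo table, complement permutation and archive into arrays so
    optimizers can score thousands of candidates cheaply; semantics identical
    to the standalone term functions.
    """

    def __init__(
        self,
        length: int,
        weights: FitnessWeights = FitnessWeights(),
        constraints: ConstraintConfig = ConstraintConfig(),
        thermo: ThermoTable | None = None,
        mapping: EncodingMap = DEFAULT_MAP,
    ):
        if length < 1:
            raise ValueError("length must be >= 1")
        self.length = length
        self.weights = weights
        self.constraints = constraints
        self.thermo = thermo or load_default_thermo()
        self.mapping = mapping
        self._dg_table = self.thermo.as_array(mapping)
        b2d = mapping.base_to_digit
        self._comp = np.array(
            [b2d[{"A": "T", "T": "A", "C": "G", "G": "C"}[mapping.digit_to_base[d]]] for d in range(4)],
            dtype=np.int8,
        )
        self._gc_pair = _gc_digits(mapping)
        for a in constraints.archive:
            if len(a) != length:
                raise ValueError("archive sequence length differs from design length")
        self._archive = (
            np.stack([a.digits for a in constraints.archive]) if constraints.archive else None
        )

    def terms(self, digits: np.ndarray) -> FitnessBreakdown:
        d = np.asarray(digits, dtype=np.int8)
        g, c = self._gc_pair
        gc = float(np.count_nonzero((d == g) | (d == c))) / len(d) * 100.0
        f_gc = (gc - 50.0) ** 2
        f_hp = _hp_from_digits(d, self.constraints.hp_limit)
        f_dg = _dg_from_digits(d, self._dg_table, self.thermo.dg_target) if len(d) >= 2 else 0.0
        tm = melting_temperature_from_gc(gc)
        c_tm = _tm_pen(tm, self.constraints.tm_range)
        if self._archive is None:
            min_ham, c_ham = None, 0.0
        else:
            min_ham = int(np.count_nonzero(self._archive != d[None, :], axis=1).min())
            c_ham = float((self.constraints.d_min - min_ham) ** 2) if min_ham < self.constraints.d_min else 0.0
        rc = self._comp[d][::-1]
        ratio = float(np.count_nonzero(d == rc)) / len(d)
        c_rc = (ratio - self.constraints.rc_threshold) * 100.0 if ratio > self.constraints.rc_threshold else 0.0
        wo, wc = self.weights.w_obj, self.weights.w_cons
        total = (
            wo[0] * f_gc + wo[1] * f_hp + wo[2] * f_dg
            + wc[0] * c_tm + wc[1] * c_ham + wc[2] * c_rc
        )
        return FitnessBreakdown(
            f_gc=f_gc, f_hp=f_hp, f_dg=f_dg, c_tm=c_tm, c_ham=c_ham, c_rc=c_rc,
            tm=tm, gc_percent=gc, rc_ratio=ratio, min_hamming=min_ham, total=total,
        )

    breakdown = terms

    def evaluate(self, digits: np.ndarray) -> float:
        return self.terms(digits).total
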