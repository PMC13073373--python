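"""Substitution/insertion/deletion error channel and read-level scoring.

Designed sequences are stress-tested under three PCR-amplification noise
regimes (low / medium / high, centred at 50 / 200 / 500 cycles).  Per-cycle
base error rates scale linearly with the central cycle count to give
per-position probabilities, and indel probabilities are boosted inside
homopolymer runs (polymerase slippage).  Reads are scored by normalized
edit distance (NED = Levenshtein / max length, via edlib) and errors are
decomposed by type, homopolymer context and base-transition class
(GC->AT vs AT->GC).

The minimal-edit decomposition uses its own dynamic-programming backtrace
with the deterministic tie-break match > substitution > deletion >
insertion, so that counts always sum to the edit distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .codec import NucleotideSequence
from .fitness import _run_lengths

__all__ = [
    "ErrorRegime",
    "ChannelProfile",
    "ReadRecord",
    "ErrorSummary",
    "REGIMES",
    "regime_profile",
    "simulate_read",
    "replay_events",
    "normalized_edit_distance",
    "decompose_errors",
    "homopolymer_stats",
    "context_error_summary",
]


@dataclass(frozen=True)
class ErrorRegime:
    name: str
    cycle_range: tuple[int, int]
    central_cycles: int

    def __post_init__(self) -> None:
        lo, hi = self.cycle_range
        if not lo <= self.central_cycles <= hi:
            raise ValueError("central_cycles must lie inside cycle_range")


REGIMES: dict[str, ErrorRegime] = {
    "low": ErrorRegime("low", (10, 100), 50),
    "medium": ErrorRegime("medium", (50, 400), 200),
    "high": ErrorRegime("high", (100, 1000), 500),
}

# per-cycle base rates; at the high regime (500 cycles) these land at
# per-position probabilities of 0.03 / 0.08 / 0.02
DEFAULT_BASE_RATES = {"sub": 6e-5, "ins": 1.6e-4, "del": 4e-5}
_RATE_CAP = 0.30


@dataclass(frozen=True)
class ChannelProfile:
    p_sub: float
    p_ins: float
    p_del: float
    hp_threshold: int = 4
    hp_indel_multiplier: float = 3.0

    def __post_init__(self) -> None:
        for p in (self.p_sub, self.p_ins, self.p_del):
            if not 0.0 <= p < 1.0:
                raise ValueError("per-position probabilities must lie in [0, 1)")
        if self.p_sub + self.p_ins + self.p_del >= 1.0:
            raise ValueError("total error probability must stay below 1")
        if self.hp_indel_multiplier < 1.0:
            raise ValueError("hp_indel_multiplier must be >= 1")


def regime_profile(
    regime: str | ErrorRegime,
    base_rates: dict[str, float] | None = None,
    hp_threshold: int = 4,
    hp_indel_multiplier: float = 3.0,
) -> ChannelProfile:
    """Map a noise regime to per-position probabilities (linear in cycles)."""
    if isinstance(regime, str):
        try:
            regime = REGIMES[regime.lower()]
        except KeyError:
            raise ValueError(f"unknown error regime {regime!r}; choose from {sorted(REGIMES)}") from None
    rates = {**DEFAULT_BASE_RATES, **(base_rates or {})}
    c = regime.central_cycles
    return ChannelProfile(
        p_sub=min(rates["sub"] * c, _RATE_CAP),
        p_ins=min(rates["ins"] * c, _RATE_CAP),
        p_del=min(rates["del"] * c, _RATE_CAP),
        hp_threshold=hp_threshold,
        hp_indel_multiplier=hp_indel_multiplier,
    )


@dataclass
class ReadRecord:
    """A simulated read plus its replayable event log.

    Events are ``(ref_position, type, ref_base, alt_base)`` ordered by
    reference position; ``del`` drops the reference base, ``ins`` inserts
    ``alt_base`` *before* the reference base, ``sub`` replaces it.
    """

    read: str
    events: list[tuple[int, str, str, str]] = field(default_factory=list)


def _in_long_run(digits: np.ndarray, threshold: int) -> np.ndarray:
    lengths = _run_lengths(digits)
    return np.repeat(lengths >= threshold, lengths)


def simulate_read(ref: NucleotideSequence, profile: ChannelProfile, rng) -> ReadRecord:
    """One left-to-right pass drawing del / ins-before / sub / match per position."""
    d = ref.digits
    L = len(d)
    p_del = np.full(L, profile.p_del)
    p_ins = np.full(L, profile.p_ins)
    if profile.hp_indel_multiplier > 1.0:
        boost = _in_long_run(d, profile.hp_threshold)
        p_del[boost] *= profile.hp_indel_multiplier
        p_ins[boost] *= profile.hp_indel_multiplier
    total = p_del + p_ins + profile.p_sub
    if total.max() >= 1.0:  # keep the categorical draw valid under boosting
        scale = 0.999 / total.max()
        p_del *= scale
        p_ins *= scale
    u = rng.random(L)
    is_del = u < p_del
    is_ins = ~is_del & (u < p_del + p_ins)
    is_sub = ~is_del & ~is_ins & (u < p_del + p_ins + profile.p_sub)

    out = d.copy()
    sub_idx = np.flatnonzero(is_sub)
    if sub_idx.size:
        # alt drawn uniformly from the 3 non-reference bases
        off = rng.integers(0, 3, size=sub_idx.size).astype(np.int8)
        alt = off + (off >= d[sub_idx])
        out[sub_idx] = alt
    ins_bases = rng.integers(0, 4, size=L, dtype=np.int8)

    slots = np.empty(2 * L, dtype=np.int8)
    slots[0::2] = ins_bases
    slots[1::2] = out
    mask = np.zeros(2 * L, dtype=bool)
    mask[0::2] = is_ins
    mask[1::2] = ~is_del
    read_digits = slots[mask]

    lut = ref.mapping.digit_to_base
    events: list[tuple[int, str, str, str]] = []
    for i in np.flatnonzero(is_del | is_ins | is_sub):
        i = int(i)
        if is_del[i]:
            events.append((i, "del", lut[d[i]], ""))
        elif is_ins[i]:
            events.append((i, "ins", lut[d[i]], lut[ins_bases[i]]))
        else:
            events.append((i, "sub", lut[d[i]], lut[out[i]]))
    read = "".join(np.array(lut)[read_digits]) if read_digits.size else ""
    return ReadRecord(read=read, events=events)


def replay_events(ref: NucleotideSequence, events: list[tuple[int, str, str, str]]) -> str:
    """Reconstruct the read from the reference and an event log."""
    by_pos = {pos: (etype, alt) for pos, etype, _, alt in events}
    out: list[str] = []
    for i, base in enumerate(ref.bases):
        etype, alt = by_pos.get(i, ("match", ""))
        if etype == "ins":
            out.append(alt)
            out.append(base)
        elif etype == "del":
            pass
        elif etype == "sub":
            out.append(alt)
        else:
            out.append(base)
    return "".join(out)


def normalized_edit_distance(ref: str | NucleotideSequence, read: str | NucleotideSequence) -> float:
    """Levenshtein distance / max(len); 0 iff equal, bounded in [0, 1]."""
    a = ref.bases if isinstance(ref, NucleotideSequence) else ref
    b = read.bases if isinstance(read, NucleotideSequence) else read
    if not a and not b:
        return 0.0
    if not a or not b:
        return 1.0
    dist = edlib.align(b, a, task="distance")["editDistance"]
    return dist / max(len(a), len(b))


def decompose_errors(
    ref: str | NucleotideSequence, read: str | NucleotideSequence
) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Minimal-edit counts ``(n_sub, n_ins, n_del)`` and per-reference-nt rates.

    Backtrace tie-break: match > substitution > deletion > insertion.
    Counts always sum to the Levenshtein distance.
    """
    a = ref.bases if isinstance(ref, NucleotideSequence) else ref
    b = read.bases if isinstance(read, NucleotideSequence) else read
    n, m = len(a), len(b)
    D = np.empty((n + 1, m + 1), dtype=np.int32)
    D[0, :] = np.arange(m + 1)
    D[:, 0] = np.arange(n + 1)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        cost = (bb != ord(a[i - 1])).astype(np.int32)
        row_prev = D[i - 1]
        row = D[i]
        # the left-neighbor dependency forces a scalar scan within the row
        diag = row_prev[:-1] + cost
        up = row_prev[1:] + 1
        best = np.minimum(diag, up)
        acc = row[0]
        for j in range(1, m + 1):
            acc = min(best[j - 1], acc + 1)
            row[j] = acc
    n_sub = n_ins = n_del = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and a[i - 1] == b[j - 1] and D[i, j] == D[i - 1, j - 1]:
            i, j = i - 1, j - 1
        elif i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + 1:
            n_sub += 1
            i, j = i - 1, j - 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            n_del += 1
            i -= 1
        else:
            n_ins += 1
            j -= 1
    rates = tuple(c / n for c in (n_sub, n_ins, n_del)) if n else (0.0, 0.0, 0.0)
    return (n_sub, n_ins, n_del), rates


def _runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of every maximal run."""
    out = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            out.append((start, i - start))
            start = i
    return out


def _run_membership(seq: str, min_len: int, pad: int = 0) -> np.ndarray:
    """Boolean mask of positions in (or within ``pad`` nt of) runs >= min_len."""
    mask = np.zeros(len(seq), dtype=bool)
    for start, length in _runs(seq):
        if length >= min_len:
            lo = max(0, start - pad)
            hi = min(len(seq), start + length + pad)
            mask[lo:hi] = True
    return mask


def homopolymer_stats(
    reads: list[ReadRecord | str],
    ref: NucleotideSequence | None = None,
    hp_count_min: int = 3,
) -> tuple[float, float, float | None]:
    """(avg max run length, avg count of runs >= ``hp_count_min``, HP-indel %).

    The HP-indel share is the fraction of logged indel events whose reference
    position lies in or within 1 nt of a reference run >= 3; it needs event
    logs and a reference, otherwise ``None`` is returned for it.
    """
    if not reads:
        raise ValueError("need at least one read")
    seqs = [r.read if isinstance(r, ReadRecord) else r for r in reads]
    max_runs = []
    counts = []
    for s in seqs:
        runs = _runs(s) if s else []
        max_runs.append(max((h for _, h in runs), default=0))
        counts.append(sum(1 for _, h in runs if h >= hp_count_min))
    hp_indel_pct: float | None = None
    records = [r for r in reads if isinstance(r, ReadRecord)]
    if records and ref is not None:
        mask = _run_membership(ref.bases, 3, pad=1)
        n_indel = n_hp = 0
        for rec in records:
            for pos, etype, _, _ in rec.events:
                if etype in ("ins", "del"):
                    n_indel += 1
                    if mask[pos]:
                        n_hp += 1
        hp_indel_pct = 100.0 * n_hp / n_indel if n_indel else None
    return float(np.mean(max_runs)), float(np.mean(counts)), hp_indel_pct


@dataclass(frozen=True)
class ErrorSummary:
    ned: float
    sub_rate: float
    ins_rate: float
    del_rate: float
    hp_indel_pct: float | None
    hp_sub_pct: float | None
    gc_to_at_pct: float | None
    at_to_gc_pct: float | None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def context_error_summary(ref: NucleotideSequence, records: list[ReadRecord]) -> ErrorSummary:
    """Aggregate per-read event logs into the context-dependent error report.

    Percentages conditioned on substitutions (GC->AT, AT->GC, HP-Sub) are
    ``None`` when no substitution occurred, never 0.
    """
    if not records:
        raise ValueError("need at least one read record")
    L = len(ref)
    hp_mask = _run_membership(ref.bases, 3, pad=0)
    hp_adj_mask = _run_membership(ref.bases, 3, pad=1)
    n_sub = n_ins = n_del = 0
    gc_at = at_gc = hp_sub = hp_indel = 0
    neds = []
    for rec in records:
        neds.append(normalized_edit_distance(ref.bases, rec.read))
        for pos, etype, ref_base, alt in rec.events:
            if etype == "sub":
                n_sub += 1
                if ref_base in "GC" and alt in "AT":
                    gc_at += 1
                elif ref_base in "AT" and alt in "GC":
                    at_gc += 1
                if hp_mask[pos]:
                    hp_sub += 1
            elif etype == "ins":
                n_ins += 1
                hp_indel += hp_adj_mask[pos]
            else:
                n_del += 1
                hp_indel += hp_adj_mask[pos]
    n_reads = len(records)
    n_indel = n_ins + n_del
    return ErrorSummary(
        ned=float(np.mean(neds)),
        sub_rate=n_sub / (L * n_reads),
        ins_rate=n_ins / (L * n_reads),
        del_rate=n_del / (L * n_reads),
        hp_indel_pct=100.0 * hp_indel / n_indel if n_indel else None,
        hp_sub_pct=100.0 * hp_sub / n_sub if n_sub else None,
        gc_to_at_pct=100.0 * gc_at / n_sub if n_sub else None,
        at_to_gc_pct=100.0 * at_gc / n_sub if n_sub else None,
    )
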