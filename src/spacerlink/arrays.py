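"""CRT/MINCED-style detection of repeat-spacer CRISPR arrays.

Candidate arrays are seeded by exact k-mers (k = minimum repeat length)
that recur at spacings compatible with a repeat-spacer period, then the
shared seed is extended in both directions column-by-column while the
repeat copies stay within the configured mismatch tolerance against the
per-column majority consensus. An array whose spacers fall outside the
configured spacer length range is rejected wholesale, mirroring MINCED's
minimum-spacer-length (minSL) filter semantics.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .seqio import ScaffoldRecord


@dataclass(frozen=True)
class ArrayParams:
    """Detection parameters; defaults follow the CRT/MINCED conventions
    with the minimum spacer length raised to 25 bp."""

    min_repeat_len: int = 23
    max_repeat_len: int = 47
    min_spacer_len: int = 25
    max_spacer_len: int = 60
    min_repeats: int = 3
    max_repeat_mismatch_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.min_repeat_len > self.max_repeat_len:
            raise ValueError("min_repeat_len > max_repeat_len")
        if self.min_spacer_len > self.max_spacer_len:
            raise ValueError("min_spacer_len > max_spacer_len")
        if self.min_spacer_len < 1:
            raise ValueError("min_spacer_len must be >= 1")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")


@dataclass
class CrisprArray:
    """A detected repeat-spacer locus (0-based half-open coordinates)."""

    scaffold_id: str
    start: int
    end: int
    repeat_consensus: str
    repeats: list[tuple[int, str]] = field(default_factory=list)
    spacers: list[tuple[int, str]] = field(default_factory=list)

    @property
    def spacer_count(self) -> int:
        return len(self.spacers)

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


@dataclass
class SpacerSet:
    """A labelled collection of spacers extracted from one dataset."""

    label: str
    # (spacer_id, sequence, source_scaffold, array_index, ordinal)
    spacers: list[tuple[str, str, str, int, int]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.spacers)

    def sequences(self) -> list[str]:
        return [s[1] for s in self.spacers]


def _consensus(columns: list[str]) -> str:
    """Per-column majority; ties broken lexicographically (A<C<G<T)."""
    counts: dict[str, int] = {}
    for c in columns:
        counts[c] = counts.get(c, 0) + 1
    best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0][0]


def _within_budget(seq: str, chain: list[int], left: int, length: int,
                   max_frac: float) -> bool:
    """Whether repeat copies of ``length`` starting at seed−``left`` all stay
    within the per-repeat mismatch-fraction budget against the consensus."""
    starts = [p - left for p in chain]
    if any(s < 0 or s + length > len(seq) for s in starts):
        return False
    copies = [seq[s : s + length] for s in starts]
    cons = "".join(_consensus([c[i] for c in copies]) for i in range(length))
    budget = int(max_frac * length)
    return all(sum(a != b for a, b in zip(c, cons)) <= budget for c in copies)


def _column_unanimous(seq: str, chain: list[int], offset: int) -> bool:
    """Whether the column at seed+``offset`` is identical across all copies.

    Boundary extension is strict (unanimous columns only): the per-repeat
    mismatch budget would otherwise absorb random flanking columns and blur
    repeat boundaries; the budget is still enforced on the final repeats.
    """
    chars = set()
    for p in chain:
        pos = p + offset
        if pos < 0 or pos >= len(seq):
            return False
        chars.add(seq[pos])
    return len(chars) == 1 and "N" not in chars


def detect_arrays(record: ScaffoldRecord, params: ArrayParams | None = None) -> list[CrisprArray]:
    """Detect CRISPR arrays on one scaffold.

    Returns arrays sorted by start; a sequence too short to hold an array
    yields an empty list. Overlapping candidates are resolved greedily by
    (more repeats, longer span, smaller start).
    """
    params = params or ArrayParams()
    seq = record.sequence
    k = params.min_repeat_len
    min_period = params.min_repeat_len + params.min_spacer_len
    max_period = params.max_repeat_len + params.max_spacer_len
    if len(seq) < 2 * params.min_repeat_len + params.min_spacer_len:
        return []

    # exact k-mer index
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)

    candidates: list[CrisprArray] = []
    seen_spans: set[tuple[int, int]] = set()
    for kmer, positions in index.items():
        if len(positions) < params.min_repeats or "N" in kmer:
            continue
        # chain occurrences with period-compatible gaps
        chains: list[list[int]] = [[positions[0]]]
        for p in positions[1:]:
            gap = p - chains[-1][-1]
            if min_period <= gap <= max_period:
                chains[-1].append(p)
            else:
                chains.append([p])
        for chain in chains:
            if len(chain) < params.min_repeats:
                continue
            arr = _extend_candidate(seq, chain, k, params)
            if arr is None:
                continue
            span = (arr[0], arr[1])
            if span not in seen_spans:
                seen_spans.add(span)
                candidates.append(_build_array(record.id, seq, *arr))

    # greedy overlap resolution: more repeats, then longer span, then smaller start
    candidates.sort(key=lambda a: (-a.n_repeats, -(a.end - a.start), a.start))
    chosen: list[CrisprArray] = []
    for cand in candidates:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda a: a.start)
    return chosen


def _extend_candidate(seq: str, chain: list[int], k: int, params: ArrayParams):
    """Extend the shared seed k-mer to full repeat boundaries; validate spacers.

    Returns (start, end, repeat_starts, repeat_len) or None.
    """
    # extend to the full repeat first; spacer lengths are validated only
    # afterwards so an under-length spacer rejects the candidate instead of
    # silently truncating the repeat (MINCED minSL semantics)
    left = 0
    length = k
    while (
        length < params.max_repeat_len
        and _column_unanimous(seq, chain, -(left + 1))
    ):
        left += 1
        length += 1
    while (
        length < params.max_repeat_len
        and _column_unanimous(seq, chain, -left + length)
    ):
        length += 1

    if not _within_budget(seq, chain, left, length,
                          params.max_repeat_mismatch_fraction):
        return None

    repeat_starts = [p - left for p in chain]
    if repeat_starts[0] < 0 or repeat_starts[-1] + length > len(seq):
        return None
    # spacer validation: whole candidate rejected on violation (minSL semantics)
    for i in range(1, len(repeat_starts)):
        spacer_len = repeat_starts[i] - (repeat_starts[i - 1] + length)
        if not params.min_spacer_len <= spacer_len <= params.max_spacer_len:
            return None
    start = repeat_starts[0]
    end = repeat_starts[-1] + length
    return start, end, repeat_starts, length


def _build_array(scaffold_id: str, seq: str, start: int, end: int,
                 repeat_starts: list[int], repeat_len: int) -> CrisprArray:
    repeats = [(p, seq[p : p + repeat_len]) for p in repeat_starts]
    spacers = [
        (repeat_starts[i - 1] + repeat_len,
         seq[repeat_starts[i - 1] + repeat_len : repeat_starts[i]])
        for i in range(1, len(repeat_starts))
    ]
    cons = "".join(
        _consensus([r[1][i] for r in repeats]) for i in range(repeat_len)
    )
    return CrisprArray(
        scaffold_id=scaffold_id,
        start=start,
        end=end,
        repeat_consensus=cons,
        repeats=repeats,
        spacers=spacers,
    )


def extract_spacers(arrays: list[CrisprArray], label: str) -> SpacerSet:
    """Flatten arrays into a SpacerSet; ids encode scaffold|arrayN|spacerM."""
    spacers = []
    by_scaffold: dict[str, int] = defaultdict(int)
    for arr in arrays:
        by_scaffold[arr.scaffold_id] += 1
        array_index = by_scaffold[arr.scaffold_id]
        for ordinal, (_, seq) in enumerate(arr.spacers, start=1):
            spacer_id = f"{arr.scaffold_id}|array{array_index}|spacer{ordinal}"
            spacers.append((spacer_id, seq, arr.scaffold_id, array_index, ordinal))
    return SpacerSet(label=label, spacers=spacers)


def dereplicate_spacers(spacer_set: SpacerSet, rc_aware: bool = False) -> SpacerSet:
    """Collapse exact duplicate sequences (100% identity, equal length),
    keeping the first-seen id; optionally also collapse reverse complements."""
    from .seqio import reverse_complement

    kept: list[tuple[str, str, str, int, int]] = []
    seen: set[str] = set()
    for row in spacer_set.spacers:
        seq = row[1]
        if seq in seen:
            continue
        if rc_aware and reverse_complement(seq) in seen:
            continue
        seen.add(seq)
        kept.append(row)
    return SpacerSet(label=spacer_set.label, spacers=kept)
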