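"""Gapless spacer-to-protospacer matching with short-read BLASTn-like retention.

A spacer of length L may align to a target along any diagonal (gapless);
end-trimmed windows of the spacer down to ceil(min_query_coverage * L) are
allowed, internal gaps are not. Per (diagonal, strand) the longest window
with at most ``max_mismatches`` mismatches is reported (ties: fewer
mismatches, then leftmost). Significance uses Karlin-Altschul ungapped
statistics with blastn-short-like scoring (+1/-3) so the E-value criterion
is reproducible without an external aligner.

Retention defaults: <= 1 mismatch, no gaps, query coverage >= 0.90,
E-value <= 1e-4, both strands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arrays import SpacerSet
from .seqio import ScaffoldRecord, reverse_complement

#: minimum viral element size for host linking (bp)
VIRAL_ELEMENT_MIN_LEN = 10_000

_ENCODE = np.full(256, 250, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_ENCODE[ord("N")] = 255  # N never matches anything (not even N)


@dataclass(frozen=True)
class MatchParams:
    max_mismatches: int = 1
    min_query_coverage: float = 0.90
    max_evalue: float = 1e-4
    both_strands: bool = True
    reward: int = 1
    penalty: int = -3
    karlin_lambda: float = 1.374
    karlin_k: float = 0.711

    def __post_init__(self) -> None:
        if not 0 < self.min_query_coverage <= 1:
            raise ValueError("min_query_coverage must be in (0, 1]")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class ProtospacerMatch:
    """One retained gapless alignment (target coords 0-based half-open)."""

    spacer_id: str
    target_id: str
    target_start: int
    target_end: int
    strand: str
    aligned_length: int
    mismatches: int
    query_coverage: float
    evalue: float


@dataclass
class MatchTable:
    matches: list[ProtospacerMatch] = field(default_factory=list)

    def by_spacer(self) -> dict[str, list[ProtospacerMatch]]:
        out: dict[str, list[ProtospacerMatch]] = {}
        for m in self.matches:
            out.setdefault(m.spacer_id, []).append(m)
        return out

    def by_target(self) -> dict[str, list[ProtospacerMatch]]:
        out: dict[str, list[ProtospacerMatch]] = {}
        for m in self.matches:
            out.setdefault(m.target_id, []).append(m)
        return out

    def __len__(self) -> int:
        return len(self.matches)


def estimate_evalue(raw_score: int, query_length: int, database_length: int,
                    params: MatchParams | None = None) -> float:
    """Karlin-Altschul E-value for an ungapped nucleotide alignment.

    E = m * n * 2**(-S'), with bit score S' = (lambda*S - ln K) / ln 2.
    Non-positive raw scores return +inf so they can never pass the filter.
    """
    params = params or MatchParams()
    if raw_score <= 0:
        return math.inf
    bits = (params.karlin_lambda * raw_score - math.log(params.karlin_k)) / math.log(2)
    return query_length * database_length * 2.0 ** (-bits)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    enc = _ENCODE[arr]
    if np.any(enc == 250):
        bad = sorted({seq[i] for i in np.nonzero(enc == 250)[0]})
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    return enc


def _best_window(mm: list[bool], min_w: int, max_mm: int) -> tuple[int, int, int] | None:
    """Longest window (then fewest mismatches, then leftmost) with <= max_mm
    mismatches over a diagonal's per-column mismatch flags.

    Returns (offset, length, mismatches) or None.
    """
    n = len(mm)
    prefix = [0]
    for x in mm:
        prefix.append(prefix[-1] + int(x))
    for w in range(n, min_w - 1, -1):
        best = None
        for a in range(0, n - w + 1):
            k = prefix[a + w] - prefix[a]
            if k <= max_mm and (best is None or k < best[2]):
                best = (a, w, k)
        if best is not None:
            return best
    return None


def find_matches(spacer_id: str, spacer: str, target: ScaffoldRecord,
                 params: MatchParams | None = None,
                 database_length: int | None = None) -> list[ProtospacerMatch]:
    """All retained gapless alignments of ``spacer`` against one target.

    ``database_length`` is the n of the E-value formula; it defaults to the
    target length but callers searching many scaffolds pass the total.
    """
    params = params or MatchParams()
    spacer = spacer.upper()
    if len(spacer) < 10:
        raise ValueError(f"spacer {spacer_id!r} shorter than 10 nt")
    db_len = database_length if database_length is not None else target.length
    t_enc = _encode(target.sequence)
    out: list[ProtospacerMatch] = []
    strands = ["+", "-"] if params.both_strands else ["+"]
    for strand in strands:
        q = spacer if strand == "+" else reverse_complement(spacer)
        out.extend(
            _scan_strand(spacer_id, q, len(spacer), t_enc, target.id, strand,
                         params, db_len)
        )
    out.sort(key=lambda m: (m.target_start, m.strand, -m.aligned_length, m.mismatches))
    # one report per (spacer, target, start, strand)
    seen: set[tuple] = set()
    uniq = []
    for m in out:
        key = (m.spacer_id, m.target_id, m.target_start, m.strand)
        if key not in seen:
            seen.add(key)
            uniq.append(m)
    return uniq


def _scan_strand(spacer_id: str, query: str, spacer_len: int, t_enc: np.ndarray,
                 target_id: str, strand: str, params: MatchParams,
                 db_len: int) -> list[ProtospacerMatch]:
    L = len(query)
    n = len(t_enc)
    min_w = math.ceil(params.min_query_coverage * spacer_len)
    if n < min_w:
        return []
    q_enc = _encode(query)
    out: list[ProtospacerMatch] = []
    slack = L - min_w  # max total trimmed columns

    # full-length diagonals, vectorised mismatch totals with a cheap filter
    if n >= L:
        totals = np.zeros(n - L + 1, dtype=np.int32)
        for j in range(L):
            totals += t_enc[j : j + n - L + 1] != q_enc[j]
        candidates = np.nonzero(totals <= params.max_mismatches + slack)[0]
        for d in candidates:
            mm = (t_enc[d : d + L] != q_enc).tolist()
            hit = _pick(mm, d, 0, min_w, params, spacer_len, db_len)
            if hit is not None:
                out.append(_mk(spacer_id, target_id, strand, *hit))

    # overhanging diagonals at both target ends (few; pure python)
    for hang in range(1, slack + 1):
        # spacer hangs off target start: columns query[hang:] vs target[0:]
        if L - hang <= n:
            mm = (t_enc[: L - hang] != q_enc[hang:]).tolist()
            hit = _pick(mm, 0, hang, min_w, params, spacer_len, db_len)
            if hit is not None:
                out.append(_mk(spacer_id, target_id, strand, *hit))
        # spacer hangs off target end
        d = n - (L - hang)
        if 0 <= d and L - hang <= n:
            mm = (t_enc[d:] != q_enc[: L - hang]).tolist()
            hit = _pick(mm, d, 0, min_w, params, spacer_len, db_len)
            if hit is not None:
                out.append(_mk(spacer_id, target_id, strand, *hit))
    return out


def _pick(mm: list[bool], diag_start: int, _q_off: int, min_w: int,
          params: MatchParams, spacer_len: int, db_len: int):
    best = _best_window(mm, min_w, params.max_mismatches)
    if best is None:
        return None
    a, w, k = best
    score = params.reward * (w - k) + params.penalty * k
    ev = estimate_evalue(score, spacer_len, db_len, params)
    if ev > params.max_evalue:
        return None
    start = diag_start + a
    return start, start + w, w, k, w / spacer_len, ev


def _mk(spacer_id: str, target_id: str, strand: str, start: int, end: int,
        w: int, k: int, cov: float, ev: float) -> ProtospacerMatch:
    return ProtospacerMatch(
        spacer_id=spacer_id,
        target_id=target_id,
        target_start=start,
        target_end=end,
        strand=strand,
        aligned_length=w,
        mismatches=k,
        query_coverage=cov,
        evalue=ev,
    )


def match_all(spacers: SpacerSet, targets: list[ScaffoldRecord],
              params: MatchParams | None = None,
              viral_element_mode: bool = False) -> MatchTable:
    """Union of find_matches over all spacer/target pairs.

    With ``viral_element_mode`` targets shorter than 10 kbp are excluded
    from linking (viral elements must be at least 10 kbp to be linked).
    """
    params = params or MatchParams()
    ids = [t.id for t in targets]
    if len(set(ids)) != len(ids):
        raise ValueError("target ids are not unique")
    if viral_element_mode:
        targets = [t for t in targets if t.length >= VIRAL_ELEMENT_MIN_LEN]
    db_len = sum(t.length for t in targets)
    table = MatchTable()
    for spacer_id, seq, *_ in spacers.spacers:
        for target in targets:
            table.matches.extend(
                find_matches(spacer_id, seq, target, params, database_length=db_len)
            )
    return table
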