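"""Shared fixtures and the independent brute-force alignment oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from spacerlink import MatchParams, ScaffoldRecord
from spacerlink.seqio import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def brute_force_matches(spacer: str, target: str,
                        params: MatchParams) -> set[tuple[int, int, str, int]]:
    """Exhaustive enumeration over all (window, offset, strand) triples,
    reduced by the reporting convention: one alignment per (diagonal,
    strand) - longest window, then fewest mismatches, then leftmost - then
    one per (target start, strand) keeping the longest.

    Returns {(target_start, target_end, strand, mismatches)}. Written as a
    direct transcription of the retention rules, independent of the
    production search.
    """
    L = len(spacer)
    n = len(target)
    min_w = math.ceil(params.min_query_coverage * L)
    strands = [("+", spacer)]
    if params.both_strands:
        strands.append(("-", reverse_complement(spacer)))
    per_diag: dict[tuple[str, int], tuple] = {}
    for strand, q in strands:
        for w in range(min_w, L + 1):
            for a in range(0, L - w + 1):
                window = q[a : a + w]
                for o in range(0, n - w + 1):
                    mm = 0
                    ok = True
                    for x, y in zip(window, target[o : o + w]):
                        if x != y or x == "N" or y == "N":
                            mm += 1
                            if mm > params.max_mismatches:
                                ok = False
                                break
                    if not ok:
                        continue
                    score = params.reward * (w - mm) + params.penalty * mm
                    if score <= 0:
                        continue
                    bits = (params.karlin_lambda * score
                            - math.log(params.karlin_k)) / math.log(2)
                    evalue = L * n * 2.0 ** (-bits)
                    if evalue > params.max_evalue:
                        continue
                    key = (strand, o - a)
                    cand = (w, mm, a, o)
                    prev = per_diag.get(key)
                    if (prev is None
                            or (-cand[0], cand[1], cand[2])
                            < (-prev[0], prev[1], prev[2])):
                        per_diag[key] = cand
    # one report per (start, strand): keep longest, then fewest mismatches
    by_start: dict[tuple[int, str], tuple] = {}
    for (strand, _), (w, mm, _a, o) in per_diag.items():
        key = (o, strand)
        prev = by_start.get(key)
        if prev is None or (-w, mm) < (-prev[0], prev[1]):
            by_start[key] = (w, mm)
    return {(o, o + w, strand, mm) for (o, strand), (w, mm) in by_start.items()}


def as_tuples(matches) -> set[tuple[int, int, str, int]]:
    return {(m.target_start, m.target_end, m.strand, m.mismatches)
            for m in matches}


@pytest.fixture
def small_target(rng) -> ScaffoldRecord:
    return ScaffoldRecord("target", random_seq(rng, 5000))
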