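"""Cross-dataset CRISPR spacer conservation.

Sharing requires exact, equal-length sequence identity; a spacer matching
a proper substring of a longer spacer does not count. Reverse complements
are considered matches, and a spacer matching both directly and via its
reverse complement counts once. The reported percentage counts each shared
spacer once per dataset, i.e. 2*shared/(nA+nB); the literal single-count
reading shared/(nA+nB) is available via ``convention="single"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .arrays import SpacerSet
from .seqio import reverse_complement


@dataclass(frozen=True)
class SharedSpacerResult:
    dataset_a: str
    dataset_b: str
    n_a: int
    n_b: int
    shared: int
    percent_shared: float


def shared_percent(shared: int, n_a: int, n_b: int,
                   convention: str = "both") -> float:
    """Percent of spacers shared between two dereplicated complements.

    ``both`` (default): 2*shared/(nA+nB); ``single``: shared/(nA+nB).
    Rounded to 2 decimals.
    """
    if convention == "both":
        value = 100 * 2 * shared / (n_a + n_b)
    elif convention == "single":
        value = 100 * shared / (n_a + n_b)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return round(value, 2)


def _check_dereplicated(spacer_set: SpacerSet) -> None:
    seqs = spacer_set.sequences()
    if len(seqs) != len(set(seqs)):
        raise ValueError(
            f"spacer set {spacer_set.label!r} contains duplicate sequences; "
            "dereplicate at 100% identity first"
        )


def shared_spacers(set_a: SpacerSet, set_b: SpacerSet,
                   convention: str = "both") -> SharedSpacerResult:
    """Count spacers of A with an exact equal-length match (direct or
    reverse-complement) in B. Both inputs must be dereplicated."""
    _check_dereplicated(set_a)
    _check_dereplicated(set_b)
    b_seqs = set(set_b.sequences())
    shared = 0
    for seq in set_a.sequences():
        if seq in b_seqs or reverse_complement(seq) in b_seqs:
            shared += 1
    return SharedSpacerResult(
        dataset_a=set_a.label,
        dataset_b=set_b.label,
        n_a=set_a.size,
        n_b=set_b.size,
        shared=shared,
        percent_shared=shared_percent(shared, set_a.size, set_b.size, convention),
    )


def multi_copy_spacers(spacer_set: SpacerSet) -> list[tuple[str, int]]:
    """Spacer sequences encoded multiple times in one (undereplicated)
    dataset, reverse-complement collapsed, with occurrence counts >= 2,
    descending. The canonical representative is the first-seen orientation."""
    counts: Counter[str] = Counter()
    canonical: dict[str, str] = {}
    for seq in spacer_set.sequences():
        rc = reverse_complement(seq)
        key = canonical.get(seq) or canonical.get(rc)
        if key is None:
            key = seq
            canonical[seq] = key
            canonical[rc] = key
        counts[key] += 1
    out = [(seq, n) for seq, n in counts.items() if n >= 2]
    out.sort(key=lambda x: (-x[1], x[0]))
    return out
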