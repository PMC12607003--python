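"""Compact type V effector candidate mining and genome size/DTR screening.

The screen mirrors a manual hunt for streamlined class II nucleases next
to virally encoded CRISPR arrays: take the 10 kbp regions flanking each
array, call ORFs, keep those 300-800 aa (below the ~800 aa size of
Cas12j/CasPhi, the most streamlined experimentally validated virally
encoded class II effector), and scan the proteins for the three RuvC
catalytic motifs (RuvC-I/II/III contributing the catalytic D/E/D triad).
The default motif patterns are deliberately permissive regular
expressions; no formal community definition of these motifs exists, so
they are configuration, not doctrine.

Genome size classes follow the field's conventions: jumbo phage >= 200
kbp, megaphage >= 500 kbp. Direct terminal repeats (DTRs; identical
prefix and suffix, evidence of a complete circularizable genome) are
found exactly via the classic border (failure-function) computation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .arrays import CrisprArray
from .seqio import Interval, ScaffoldRecord, reverse_complement

JUMBO_THRESHOLD = 200_000
MEGAPHAGE_THRESHOLD = 500_000
FLANK_BP = 10_000
MIN_EFFECTOR_AA = 300
MAX_EFFECTOR_AA = 800

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class OrfRecord:
    """An ORF on the forward coordinate system; end includes the stop codon."""

    scaffold_id: str
    start: int
    end: int
    strand: str
    protein: str

    @property
    def length_aa(self) -> int:
        return (self.end - self.start) // 3 - 1


@dataclass(frozen=True)
class MotifProfile:
    """A RuvC motif: residue-class regex with one anchored catalytic
    residue (named group ``cat``) and the protein span it may occupy."""

    name: str
    pattern: str
    span: tuple[float, float]

    def __post_init__(self) -> None:
        if self.pattern.count("(?P<cat>") != 1:
            raise ValueError(f"profile {self.name} must anchor exactly one "
                             "catalytic residue via (?P<cat>...)")


DEFAULT_RUVC_PROFILES = (
    MotifProfile("RuvC-I", r"[ILMVF].{1,2}[TS].(?P<cat>D)", (0.0, 1 / 3)),
    MotifProfile("RuvC-II", r"(?P<cat>E).{2,3}[GA]", (1 / 3, 2 / 3)),
    MotifProfile("RuvC-III", r"[DN].(?P<cat>D)", (2 / 3, 1.0)),
)


@dataclass(frozen=True)
class EffectorCandidate:
    orf: OrfRecord
    source_scaffold: str
    array_start: int
    motifs_found: frozenset[str]
    complete_ruvc: bool


@dataclass(frozen=True)
class DtrResult:
    scaffold_id: str
    repeat_length: int
    min_len: int


def extract_flanking_windows(array: CrisprArray, scaffold: ScaffoldRecord,
                             flank: int = FLANK_BP) -> list[Interval]:
    """Up to two windows of ``flank`` bp directly upstream and downstream
    of an array, clipped at scaffold bounds; empty windows are omitted."""
    windows = []
    up_start = max(0, array.start - flank)
    if up_start < array.start:
        windows.append(Interval(scaffold.id, up_start, array.start))
    down_end = min(scaffold.length, array.end + flank)
    if array.end < down_end:
        windows.append(Interval(scaffold.id, array.end, down_end))
    return windows


def _orfs_one_strand(seq: str, scaffold_id: str, min_aa: int) -> list[tuple[int, int, str]]:
    """(start, end, protein) for forward-strand ORFs: per stop-delimited
    frame segment, the ORF from the first start codon to the stop codon."""
    n = len(seq)
    out = []
    for frame in range(3):
        seg_start = frame  # first codon position after the previous stop
        pending_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if pending_start is None and codon in START_CODONS:
                pending_start = pos
            if codon in STOP_CODONS:
                if pending_start is not None:
                    aa_len = (pos + 3 - pending_start) // 3 - 1
                    if aa_len >= min_aa:
                        cds = seq[pending_start : pos + 3]
                        # alternative starts translate as Met, prodigal-style
                        prot = "M" + str(Seq(cds[3:-3]).translate(table=11))
                        out.append((pending_start, pos + 3, prot))
                pending_start = None
                seg_start = pos + 3
        del seg_start
    return out


def call_orfs(record: ScaffoldRecord, min_aa: int = 1) -> list[OrfRecord]:
    """Minimal ORF caller: both strands, bacterial code (table 11), starts
    ATG/GTG/TTG, one (longest) ORF per stop-delimited frame segment, a stop
    codon required. Coordinates are forward-strand 0-based half-open and
    include the stop codon."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    orfs: list[OrfRecord] = []
    for s, e, prot in _orfs_one_strand(record.sequence, record.id, min_aa):
        orfs.append(OrfRecord(record.id, s, e, "+", prot))
    rc = reverse_complement(record.sequence)
    L = len(rc)
    for s, e, prot in _orfs_one_strand(rc, record.id, min_aa):
        orfs.append(OrfRecord(record.id, L - e, L - s, "-", prot))
    orfs.sort(key=lambda o: (o.start, o.strand))
    return orfs


def filter_candidate_orfs(orfs: list[OrfRecord],
                          min_aa: int = MIN_EFFECTOR_AA,
                          max_aa: int = MAX_EFFECTOR_AA) -> list[OrfRecord]:
    """Retain ORFs whose protein length is within [min_aa, max_aa], inclusive."""
    return [o for o in orfs if min_aa <= o.length_aa <= max_aa]


def scan_ruvc(protein: str,
              profiles: tuple[MotifProfile, ...] = DEFAULT_RUVC_PROFILES
              ) -> tuple[frozenset[str], bool, dict[str, int]]:
    """Scan a protein for RuvC motifs within each profile's allowed span.

    Returns (motifs_found, complete_ruvc, anchor position per motif).
    ``complete_ruvc`` requires all profiles found with strictly increasing
    catalytic anchor positions along the protein.
    """
    n = len(protein)
    anchors: dict[str, int] = {}
    for prof in profiles:
        lo = int(prof.span[0] * n)
        hi = n if prof.span[1] >= 1.0 else int(prof.span[1] * n)
        # overlapping search via lookahead so nearby motifs are not masked
        for m in re.finditer(f"(?=(?:{prof.pattern}))", protein):
            cat = m.start("cat")
            if lo <= cat < hi:
                anchors[prof.name] = cat
                break
    found = frozenset(anchors)
    ordered = [anchors[p.name] for p in profiles if p.name in anchors]
    complete = len(found) == len(profiles) and all(
        a < b for a, b in zip(ordered, ordered[1:])
    )
    return found, complete, anchors


def screen_effectors(scaffold: ScaffoldRecord, arrays: list[CrisprArray],
                     flank: int = FLANK_BP,
                     min_aa: int = MIN_EFFECTOR_AA,
                     max_aa: int = MAX_EFFECTOR_AA,
                     profiles: tuple[MotifProfile, ...] = DEFAULT_RUVC_PROFILES
                     ) -> list[EffectorCandidate]:
    """End-to-end per-scaffold screen: array flanks -> ORFs -> 300-800 aa
    filter -> RuvC scan. An ORF counts if it overlaps a flanking window."""
    candidates: list[EffectorCandidate] = []
    seen: set[tuple[int, int, str]] = set()
    orfs = call_orfs(scaffold, min_aa=min_aa) if arrays else []
    sized = filter_candidate_orfs(orfs, min_aa, max_aa)
    for array in arrays:
        windows = extract_flanking_windows(array, scaffold, flank)
        if not windows:
            continue
        for orf in sized:
            if not any(orf.start < w.end and orf.end > w.start for w in windows):
                continue
            key = (orf.start, orf.end, orf.strand)
            if key in seen:
                continue
            seen.add(key)
            motifs, complete, _ = scan_ruvc(orf.protein, profiles)
            candidates.append(EffectorCandidate(
                orf=orf,
                source_scaffold=scaffold.id,
                array_start=array.start,
                motifs_found=motifs,
                complete_ruvc=complete,
            ))
    return candidates


def summarize_effector_elements(candidates_by_element: dict[str, list[EffectorCandidate]]
                                ) -> dict[str, int]:
    """Per-element counts of unique candidate proteins (exact-sequence
    dereplication); elements without candidates are absent."""
    counts: dict[str, int] = {}
    for element, cands in candidates_by_element.items():
        unique = {c.orf.protein for c in cands}
        if unique:
            counts[element] = len(unique)
    return counts


def classify_genome_size(length_bp: int) -> str:
    """standard < 200 kbp <= jumbo < 500 kbp <= megaphage."""
    if length_bp <= 0:
        raise ValueError("genome length must be positive")
    if length_bp >= MEGAPHAGE_THRESHOLD:
        return "megaphage"
    if length_bp >= JUMBO_THRESHOLD:
        return "jumbo"
    return "standard"


def detect_dtr(record: ScaffoldRecord, min_len: int = 20) -> DtrResult:
    """Longest k >= min_len with sequence prefix(k) == suffix(k), else 0.

    Computed exactly via the KMP failure function (the longest border of
    the string), so runtime is linear in the sequence length.
    """
    seq = record.sequence
    n = len(seq)
    if n < 2 * min_len:
        return DtrResult(record.id, 0, min_len)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k > 0 and seq[i] != seq[k]:
            k = fail[k - 1]
        if seq[i] == seq[k]:
            k += 1
        fail[i] = k
    border = fail[n - 1]
    repeat = border if border >= min_len else 0
    return DtrResult(record.id, repeat, min_len)
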