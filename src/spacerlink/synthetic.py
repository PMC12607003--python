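"""Seeded synthetic host/viral communities with machine-readable ground truth.

The generator emits the inputs the downstream stages consume: host
scaffolds carrying repeat-spacer CRISPR arrays whose spacers are copied
(with controlled mismatch counts) from viral scaffolds, orphan spacers
with no target, viral scaffolds spanning standard to megaphage scales,
exact direct terminal repeats on selected viruses, viral CRISPR arrays
with nearby planted RuvC-motif ORFs, VIBRANT-style gene annotation tables
with configurable v-score neighborhoods, and CheckM-style MAG metadata.

Reproducibility contract: a fixed config and seed produce byte-identical
outputs. Every scaffold draws from its own RNG stream derived from the
root seed and a stable hash of the scaffold id, so adding scaffolds does
not perturb earlier ones.

Two consistency guarantees worth knowing about:

* Mismatches on planted spacers are placed inside the central window that
  every >= 90%-coverage end-trimmed alignment must contain, so the
  recorded mismatch count of a planted link equals the minimum mismatch
  count achievable by the matching engine - a 2-mismatch plant can never
  be rescued to a 1-mismatch alignment by end trimming.
* The single host base on each side of a planted array is set to differ
  from the corresponding spacer-adjacent base, so repeat boundary
  extension can never absorb a flanking column and planted boundaries are
  recovered exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arrays import ArrayParams
from .seqio import ScaffoldRecord, reverse_complement, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

AMG_CATEGORIES = (
    "Carbohydrate metabolism",
    "Methane metabolism",
    "Sulfur metabolism",
    "Amino acid metabolism",
    "Lipid metabolism",
    "Aromatic compound degradation",
)

#: one most-frequent codon per residue for reverse translation (standard code)
PREFERRED_CODON = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}

# protein template fragments carrying the three RuvC motif instances;
# filler residues are chosen so they cannot form any default motif
_MOTIF_I = "LATAD"   # [ILMVF] x{1,2} [TS] x D
_MOTIF_II = "EKKG"   # E x{2,3} [GA]
_MOTIF_III = "DKD"   # [DN] x D
_FILLER = "KRQHWY"


class SimulationError(ValueError):
    """Invalid configuration or infeasible feature placement."""


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_hosts: int = 12
    n_viruses: int = 20
    host_length: int = 60_000
    #: log-normal law for viral lengths: median (bp) and sigma of log-length
    viral_length_median: int = 30_000
    viral_length_sigma: float = 0.4
    #: explicit lengths for the first records (jumbo/megaphage plants)
    viral_extra_lengths: tuple[int, ...] = (250_000, 520_000)
    viral_min_length: int = 12_000
    arrays_per_host: tuple[int, int] = (1, 2)
    repeat_length: tuple[int, int] = (23, 40)
    spacer_length: tuple[int, int] = (25, 50)
    spacers_per_array: tuple[int, int] = (3, 8)
    planted_fraction: float = 0.7
    mismatch_law: tuple[tuple[int, float], ...] = ((0, 0.7), (1, 0.2), (2, 0.1))
    orphan_fraction: float = 0.3
    #: fraction of the spacer every retained trimmed alignment must cover
    protected_coverage: float = 0.90
    dtr_lengths: tuple[int, ...] = (100, 250)
    viral_array_fraction: float = 0.2
    effector_plant: float = 0.8
    effector_length_aa: int = 450
    amg_genes_per_scaffold: int = 12
    amg_viral_vscore: tuple[float, float] = (0.5, 1.0)
    # upper bound kept just under the 0.25 curation threshold so that
    # 3-decimal rounding cannot push a host-like score onto the boundary
    amg_host_vscore: tuple[float, float] = (0.0, 0.24)
    contamination_law: tuple[float, float] = (0.0, 8.0)
    completeness_law: tuple[float, float] = (70.0, 100.0)
    phylum_labels: tuple[str, ...] = (
        "Bacteroidota", "Cloacimonadota", "Firmicutes_B",
        "Proteobacteria", "Actinobacteriota",
    )

    def __post_init__(self) -> None:
        if isinstance(self.mismatch_law, dict):
            object.__setattr__(self, "mismatch_law",
                               tuple(sorted(self.mismatch_law.items())))
        for name in ("planted_fraction", "orphan_fraction", "viral_array_fraction",
                     "effector_plant"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.planted_fraction + self.orphan_fraction > 1 + 1e-12:
            raise SimulationError("planted_fraction + orphan_fraction must be <= 1")
        for name in ("arrays_per_host", "repeat_length", "spacer_length",
                     "spacers_per_array"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise SimulationError(f"{name} range ({lo}, {hi}) invalid")
        if self.spacer_length[0] < 1:
            raise SimulationError("spacer length minimum must be >= 1")
        probs = [p for _, p in self.mismatch_law]
        if abs(sum(probs) - 1) > 1e-9 or any(p < 0 for p in probs):
            raise SimulationError("mismatch_law probabilities must sum to 1")
        if any(k not in (0, 1, 2) for k, _ in self.mismatch_law):
            raise SimulationError("mismatch_law supports mismatch counts {0, 1, 2}")
        # planted arrays must be inside the default detector's parameter box,
        # otherwise the community is undetectable by construction
        d = ArrayParams()
        if not (d.min_repeat_len <= self.repeat_length[0]
                and self.repeat_length[1] <= d.max_repeat_len):
            raise SimulationError(
                f"repeat_length {self.repeat_length} outside the detectable "
                f"range [{d.min_repeat_len}, {d.max_repeat_len}]"
            )
        if not (d.min_spacer_len <= self.spacer_length[0]
                and self.spacer_length[1] <= d.max_spacer_len):
            raise SimulationError(
                f"spacer_length {self.spacer_length} outside the detectable "
                f"range [{d.min_spacer_len}, {d.max_spacer_len}]"
            )
        if self.spacers_per_array[0] < 1:
            raise SimulationError("arrays need at least one spacer")


@dataclass(frozen=True)
class PlantedArray:
    scaffold_id: str
    array_index: int
    start: int
    end: int
    repeat: str
    spacers: tuple[str, ...]
    spacer_ids: tuple[str, ...]


@dataclass(frozen=True)
class PlantedLink:
    spacer_id: str
    viral_scaffold: str
    position: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class PlantedMotifOrf:
    viral_scaffold: str
    start: int
    end: int
    strand: str
    length_aa: int


@dataclass
class GroundTruth:
    planted_arrays: list[PlantedArray] = field(default_factory=list)
    planted_links: list[PlantedLink] = field(default_factory=list)
    planted_dtrs: list[tuple[str, int]] = field(default_factory=list)
    planted_motif_orfs: list[PlantedMotifOrf] = field(default_factory=list)
    #: (scaffold, gene_index, kept, rule_id or "")
    amg_expected_verdicts: list[tuple[str, int, bool, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "planted_arrays": [dataclasses.asdict(a) for a in self.planted_arrays],
            "planted_links": [dataclasses.asdict(l) for l in self.planted_links],
            "planted_dtrs": list(self.planted_dtrs),
            "planted_motif_orfs": [dataclasses.asdict(o) for o in self.planted_motif_orfs],
            "amg_expected_verdicts": list(self.amg_expected_verdicts),
        }, indent=1, sort_keys=True)


@dataclass
class SyntheticCommunity:
    config: SimulationConfig
    hosts: list[ScaffoldRecord]
    viruses: list[ScaffoldRecord]
    mag_metadata: pd.DataFrame
    gene_table: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "hosts": outdir / "hosts.fasta",
            "viruses": outdir / "viruses.fasta",
            "mag_metadata": outdir / "mag_metadata.tsv",
            "gene_table": outdir / "gene_annotations.tsv",
            "truth": outdir / "ground_truth.json",
        }
        write_fasta(self.hosts, paths["hosts"])
        write_fasta(self.viruses, paths["viruses"])
        self.mag_metadata.to_csv(paths["mag_metadata"], sep="\t", index=False,
                                 lineterminator="\n")
        self.gene_table.to_csv(paths["gene_table"], sep="\t", index=False,
                               lineterminator="\n")
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def _stream(seed: int, scaffold_id: str) -> np.random.Generator:
    """Per-scaffold RNG stream: root seed + stable CRC32 of the id."""
    return np.random.default_rng([seed, zlib.crc32(scaffold_id.encode())])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


class _Registry:
    """Non-overlapping feature placement with rejection sampling."""

    def __init__(self, name: str) -> None:
        self.name = name
        self.intervals: list[tuple[int, int, str]] = []

    def blocked(self, start: int, end: int) -> str | None:
        for s, e, label in self.intervals:
            if start < e and end > s:
                return label
        return None

    def claim(self, start: int, end: int, label: str) -> None:
        other = self.blocked(start, end)
        if other is not None:
            raise SimulationError(
                f"feature {label!r} at [{start}, {end}) on {self.name} "
                f"overlaps previously planted feature {other!r}"
            )
        self.intervals.append((start, end, label))

    def place(self, rng: np.random.Generator, length: int, lo: int, hi: int,
              label: str, retries: int = 1000) -> int:
        """Uniformly choose a free start in [lo, hi - length]."""
        if hi - lo < length:
            raise SimulationError(
                f"no room for feature {label!r} ({length} bp) on {self.name}"
            )
        for _ in range(retries):
            start = int(rng.integers(lo, hi - length + 1))
            if self.blocked(start, start + length) is None:
                self.claim(start, start + length, label)
                return start
        raise SimulationError(
            f"could not place feature {label!r} on {self.name} after "
            f"{retries} attempts"
        )


def plant_array(sequence: str, repeat: str, spacers: list[str], position: int,
                registry: _Registry | None = None, label: str = "array") -> str:
    """Replace an interval of ``sequence`` with R(S_i R)^n starting at
    ``position``. The array needs >= 2 repeats flanking >= 1 spacer."""
    if not spacers:
        raise SimulationError("an array needs at least one spacer "
                              "(>= 2 repeats flanking >= 1 spacer)")
    if not repeat:
        raise SimulationError("repeat must be non-empty")
    array = repeat + "".join(s + repeat for s in spacers)
    if position < 0 or position + len(array) > len(sequence):
        raise SimulationError(
            f"array of {len(array)} bp at offset {position} does not fit in "
            f"sequence of {len(sequence)} bp"
        )
    if registry is not None:
        registry.claim(position, position + len(array), label)
    return sequence[:position] + array + sequence[position + len(array):]


def _effector_gene(rng: np.random.Generator, length_aa: int) -> str:
    """Nucleotide gene encoding a protein with the three RuvC motifs in
    their expected thirds, built by reverse translation with one preferred
    codon per residue; prefixed with a stop codon so the ORF caller starts
    exactly at the planted ATG."""
    third = length_aa // 3
    def filler(n: int) -> str:
        return "".join(_FILLER[i] for i in rng.integers(0, len(_FILLER), size=n))
    seg1 = "M" + filler(third // 2 - 1) + _MOTIF_I
    seg1 += filler(third - len(seg1))
    seg2 = filler(third // 2) + _MOTIF_II
    seg2 += filler(third - len(seg2))
    seg3 = filler(third // 2) + _MOTIF_III
    seg3 += filler(length_aa - len(seg1) - len(seg2) - len(seg3))
    protein = seg1 + seg2 + seg3
    assert len(protein) == length_aa
    dna = "".join(PREFERRED_CODON[aa] for aa in protein)
    return "TAA" + dna + "TAA"


def _draw_mismatch_count(rng: np.random.Generator,
                         law: tuple[tuple[int, float], ...]) -> int:
    ks = [k for k, _ in law]
    ps = np.array([p for _, p in law], dtype=float)
    return int(rng.choice(ks, p=ps / ps.sum()))


def _mutate_central(rng: np.random.Generator, spacer: str, k: int,
                    coverage: float) -> str:
    """Apply k substitutions inside the window every >= coverage end-trimmed
    alignment must contain, so trimming cannot reduce the mismatch count."""
    if k == 0:
        return spacer
    L = len(spacer)
    min_w = math.ceil(coverage * L)
    lo, hi = L - min_w, min_w  # positions contained in every valid window
    positions = rng.choice(np.arange(lo, hi), size=k, replace=False)
    chars = list(spacer)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def _guard_array_boundaries(seq: list[str], start: int, end: int,
                            spacers: list[str]) -> None:
    """Force the single base on each side of the array to differ from the
    corresponding spacer-adjacent base (see module docstring)."""
    order = "ACGT"
    if start > 0:
        avoid = spacers[0][-1]
        if seq[start - 1] == avoid:
            seq[start - 1] = order[(order.index(avoid) + 1) % 4]
    if end < len(seq):
        avoid = spacers[0][0]
        if seq[end] == avoid:
            seq[end] = order[(order.index(avoid) + 1) % 4]


def simulate_community(config: SimulationConfig) -> SyntheticCommunity:
    """Generate a complete synthetic community (see module docstring)."""
    truth = GroundTruth()

    viruses = _generate_viruses(config, truth)
    hosts = _generate_hosts(config, truth, viruses)
    mag_metadata = _generate_mag_metadata(config, hosts)
    gene_table = _generate_gene_table(config, truth, viruses)

    return SyntheticCommunity(
        config=config,
        hosts=hosts,
        viruses=viruses,
        mag_metadata=mag_metadata,
        gene_table=gene_table,
        truth=truth,
    )


def evaluate_link_recovery(truth: GroundTruth, table, max_mismatches: int = 1,
                           position_slack: int = 60) -> dict:
    """Score a match table against the planted links.

    A planted link counts as recovered when the table holds a match of the
    same spacer to the same viral scaffold overlapping the planted
    protospacer position. Links planted with more mismatches than
    ``max_mismatches`` are outside the retention criteria and excluded
    from the recall denominator (``recall_all`` keeps them). A match whose
    (spacer, virus) pair was never planted is a false link.
    """
    by: dict[tuple[str, str], list] = {}
    for m in table.matches:
        by.setdefault((m.spacer_id, m.target_id), []).append(m)
    expected = [l for l in truth.planted_links if l.mismatches <= max_mismatches]
    recovered = 0
    for link in expected:
        hits = by.get((link.spacer_id, link.viral_scaffold), [])
        if any(m.target_start < link.position + position_slack
               and m.target_end > link.position for m in hits):
            recovered += 1
    truth_pairs = {(l.spacer_id, l.viral_scaffold) for l in truth.planted_links}
    false_links = sorted({
        (m.spacer_id, m.target_id) for m in table.matches
        if (m.spacer_id, m.target_id) not in truth_pairs
    })
    return {
        "n_expected": len(expected),
        "n_recovered": recovered,
        "recall": recovered / len(expected) if expected else 1.0,
        "recall_all": (recovered / len(truth.planted_links)
                       if truth.planted_links else 1.0),
        "n_false_links": len(false_links),
        "false_links": false_links,
    }


def _generate_viruses(config: SimulationConfig, truth: GroundTruth
                      ) -> list[ScaffoldRecord]:
    records: list[ScaffoldRecord] = []
    for i in range(config.n_viruses):
        vid = f"virus_{i + 1:03d}"
        rng = _stream(config.seed, vid)
        if i < len(config.viral_extra_lengths):
            length = config.viral_extra_lengths[i]
        else:
            length = int(round(config.viral_length_median
                               * math.exp(config.viral_length_sigma * rng.standard_normal())))
            length = max(length, config.viral_min_length)
        seq = list(_random_seq(rng, length))
        registry = _Registry(vid)

        dtr_len = 0
        if i < len(config.dtr_lengths):
            dtr_len = config.dtr_lengths[i]
            seq[-dtr_len:] = seq[:dtr_len]
            registry.claim(0, dtr_len, "dtr_prefix")
            registry.claim(length - dtr_len, length, "dtr_suffix")
            truth.planted_dtrs.append((vid, dtr_len))

        if rng.random() < config.viral_array_fraction:
            repeat_len = int(rng.integers(config.repeat_length[0],
                                          config.repeat_length[1] + 1))
            repeat = _random_seq(rng, repeat_len)
            n_spacers = int(rng.integers(config.spacers_per_array[0],
                                         config.spacers_per_array[1] + 1))
            spacers = [
                _random_seq(rng, int(rng.integers(config.spacer_length[0],
                                                  config.spacer_length[1] + 1)))
                for _ in range(n_spacers)
            ]
            arr_len = repeat_len * (n_spacers + 1) + sum(len(s) for s in spacers)
            # margin of 1 on each side for the boundary guard
            start = registry.place(rng, arr_len + 2, dtr_len,
                                   length - dtr_len, "viral_array") + 1
            text = plant_array("".join(seq), repeat, spacers, start)
            seq = list(text)
            _guard_array_boundaries(seq, start, start + arr_len, spacers)
            truth.planted_arrays.append(PlantedArray(
                scaffold_id=vid, array_index=1, start=start,
                end=start + arr_len, repeat=repeat, spacers=tuple(spacers),
                spacer_ids=tuple(
                    f"{vid}|array1|spacer{j + 1}" for j in range(n_spacers)
                ),
            ))
            if rng.random() < config.effector_plant:
                gene = _effector_gene(rng, config.effector_length_aa)
                lo = max(dtr_len, start - 10_000)
                hi = min(length - dtr_len, start + arr_len + 10_000)
                gstart = registry.place(rng, len(gene), lo, hi, "effector_orf")
                seq[gstart : gstart + len(gene)] = gene
                truth.planted_motif_orfs.append(PlantedMotifOrf(
                    viral_scaffold=vid,
                    start=gstart + 3,       # past the guard stop codon
                    end=gstart + len(gene),
                    strand="+",
                    length_aa=config.effector_length_aa,
                ))
        records.append(ScaffoldRecord(id=vid, sequence="".join(seq)))
    return records


def _generate_hosts(config: SimulationConfig, truth: GroundTruth,
                    viruses: list[ScaffoldRecord]) -> list[ScaffoldRecord]:
    hosts: list[ScaffoldRecord] = []
    # viral intervals to avoid when sampling protospacers (planted features)
    viral_feature_spans: dict[str, list[tuple[int, int]]] = {v.id: [] for v in viruses}
    for arr in truth.planted_arrays:
        viral_feature_spans.setdefault(arr.scaffold_id, []).append((arr.start - 1, arr.end + 1))
    for orf in truth.planted_motif_orfs:
        viral_feature_spans.setdefault(orf.viral_scaffold, []).append((orf.start - 3, orf.end))
    for vid, dtr_len in truth.planted_dtrs:
        spans = viral_feature_spans.setdefault(vid, [])
        spans.append((0, dtr_len))

    dtr_by_virus = dict(truth.planted_dtrs)

    for i in range(config.n_hosts):
        hid = f"host_{i + 1:03d}"
        rng = _stream(config.seed, hid)
        seq = list(_random_seq(rng, config.host_length))
        registry = _Registry(hid)
        n_arrays = int(rng.integers(config.arrays_per_host[0],
                                    config.arrays_per_host[1] + 1))
        planted: list[dict] = []
        for a in range(n_arrays):
            repeat_len = int(rng.integers(config.repeat_length[0],
                                          config.repeat_length[1] + 1))
            repeat = _random_seq(rng, repeat_len)
            n_spacers = int(rng.integers(config.spacers_per_array[0],
                                         config.spacers_per_array[1] + 1))
            spacers: list[str] = []
            # per-spacer link target (viral scaffold, position, strand, k) or None
            link_specs: list[tuple[str, int, str, int] | None] = []
            for j in range(n_spacers):
                slen = int(rng.integers(config.spacer_length[0],
                                        config.spacer_length[1] + 1))
                u = rng.random()
                if u < config.planted_fraction and viruses:
                    virus = viruses[int(rng.integers(0, len(viruses)))]
                    dtr_len = dtr_by_virus.get(virus.id, 0)
                    pos = _sample_protospacer_position(
                        rng, virus, slen, viral_feature_spans[virus.id], dtr_len
                    )
                    viral_feature_spans[virus.id].append((pos, pos + slen))
                    protospacer = virus.sequence[pos : pos + slen]
                    strand = "+" if rng.random() < 0.5 else "-"
                    spacer = protospacer if strand == "+" else reverse_complement(protospacer)
                    k = _draw_mismatch_count(rng, config.mismatch_law)
                    spacer = _mutate_central(rng, spacer, k, config.protected_coverage)
                    link_specs.append((virus.id, pos, strand, k))
                else:
                    # orphan or background spacer: random sequence, no target
                    spacer = _random_seq(rng, slen)
                    link_specs.append(None)
                spacers.append(spacer)
            arr_len = repeat_len * (n_spacers + 1) + sum(len(s) for s in spacers)
            start = registry.place(rng, arr_len + 2, 0, config.host_length,
                                   f"array{a + 1}") + 1
            text = plant_array("".join(seq), repeat, spacers, start)
            seq = list(text)
            _guard_array_boundaries(seq, start, start + arr_len, spacers)
            planted.append({"start": start, "end": start + arr_len,
                            "repeat": repeat, "spacers": spacers,
                            "links": link_specs})
        # number arrays by position so truth ids match extraction order
        planted.sort(key=lambda p: p["start"])
        for idx, p in enumerate(planted, start=1):
            spacer_ids = tuple(
                f"{hid}|array{idx}|spacer{j + 1}" for j in range(len(p["spacers"]))
            )
            truth.planted_arrays.append(PlantedArray(
                scaffold_id=hid, array_index=idx, start=p["start"],
                end=p["end"], repeat=p["repeat"], spacers=tuple(p["spacers"]),
                spacer_ids=spacer_ids,
            ))
            for j, spec in enumerate(p["links"]):
                if spec is None:
                    continue
                virus_id, pos, strand, k = spec
                truth.planted_links.append(PlantedLink(
                    spacer_id=spacer_ids[j],
                    viral_scaffold=virus_id,
                    position=pos,
                    strand=strand,
                    mismatches=k,
                ))
        hosts.append(ScaffoldRecord(id=hid, sequence="".join(seq)))
    return hosts


def _sample_protospacer_position(rng: np.random.Generator, virus: ScaffoldRecord,
                                 slen: int, avoid: list[tuple[int, int]],
                                 dtr_len: int, retries: int = 1000) -> int:
    lo = dtr_len
    hi = virus.length - dtr_len - slen
    if hi <= lo:
        raise SimulationError(f"virus {virus.id} too short for a protospacer")
    for _ in range(retries):
        pos = int(rng.integers(lo, hi + 1))
        if all(pos >= e or pos + slen <= s for s, e in avoid):
            return pos
    raise SimulationError(
        f"could not place protospacer on {virus.id} after {retries} attempts"
    )


def _generate_mag_metadata(config: SimulationConfig,
                           hosts: list[ScaffoldRecord]) -> pd.DataFrame:
    rows = []
    for host in hosts:
        rng = _stream(config.seed, host.id + "|mag")
        phylum = config.phylum_labels[int(rng.integers(0, len(config.phylum_labels)))]
        completeness = round(float(rng.uniform(*config.completeness_law)), 2)
        contamination = round(float(rng.uniform(*config.contamination_law)), 2)
        rows.append({
            "mag_id": host.id,
            "phylum": phylum,
            "completeness": completeness,
            "contamination": contamination,
        })
    return pd.DataFrame(rows, columns=["mag_id", "phylum", "completeness",
                                       "contamination"])


# AMG curation scenarios cycled across viral scaffolds; each scaffold
# carries at most one planted AMG so scenarios cannot interact
_AMG_SCENARIOS = ("kept", "end_of_scaffold", "high_vscore", "hostlike_flanks")
_SCENARIO_RULE = {
    "kept": "",
    "end_of_scaffold": "END_OF_SCAFFOLD",
    "high_vscore": "HIGH_VSCORE",
    "hostlike_flanks": "HOSTLIKE_FLANKS",
}


def _generate_gene_table(config: SimulationConfig, truth: GroundTruth,
                         viruses: list[ScaffoldRecord]) -> pd.DataFrame:
    rows = []
    for i, virus in enumerate(viruses):
        rng = _stream(config.seed, virus.id + "|genes")
        n_genes = config.amg_genes_per_scaffold
        gene_span = max(300, (virus.length - 100) // max(n_genes, 1) - 50)
        scenario = _AMG_SCENARIOS[i % len(_AMG_SCENARIOS)]
        amg_index = 1 if scenario == "end_of_scaffold" else n_genes // 2
        hostlike = scenario == "hostlike_flanks"
        for g in range(1, n_genes + 1):
            start = (g - 1) * (gene_span + 50)
            end = start + gene_span
            strand = "+" if rng.random() < 0.5 else "-"
            is_amg = g == amg_index
            if is_amg:
                kegg_v = 1.0 if scenario == "high_vscore" else round(float(rng.uniform(0.0, 0.2)), 3)
                pfam_v = None
                category = AMG_CATEGORIES[i % len(AMG_CATEGORIES)]
                ko = f"K{10000 + i:05d}"
            else:
                law = config.amg_host_vscore if hostlike else config.amg_viral_vscore
                kegg_v = round(float(rng.uniform(*law)), 3)
                pfam_v = round(float(rng.uniform(*law)), 3)
                category = ""
                ko = f"K{20000 + g:05d}"
            rows.append({
                "scaffold": virus.id,
                "gene_index": g,
                "start": start + 1,
                "end": end,
                "strand": strand,
                "ko": ko,
                "kegg_vscore": kegg_v,
                "pfam_vscore": pfam_v,
                "is_amg": is_amg,
                "category": category,
            })
        kept = scenario == "kept"
        truth.amg_expected_verdicts.append(
            (virus.id, amg_index, kept, _SCENARIO_RULE[scenario])
        )
    return pd.DataFrame(rows, columns=["scaffold", "gene_index", "start", "end",
                                       "strand", "ko", "kegg_vscore",
                                       "pfam_vscore", "is_amg", "category"])
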