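"""Pipeline orchestration and report formatting.

``run_pipeline`` chains the stages end to end - simulate (optional),
detect arrays, match spacers to protospacers, build the virus-host
network, spacer conservation, AMG curation, effector mining, genome size
and DTR classification - writing each stage's TSV plus a JSON run
manifest. Re-running with the same inputs and seed produces identical
bytes.

Printed percentages use round-half-up, matching human reporting
convention, rather than banker's rounding.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__
from .amg import curate_amgs, rows_from_frame, summarize_categories
from .arrays import ArrayParams, detect_arrays, dereplicate_spacers, extract_spacers
from .conservation import multi_copy_spacers
from .effectors import classify_genome_size, detect_dtr, screen_effectors
from .matching import MatchParams, match_all
from .network import (MagMetadata, build_network, curate_cross_phylum,
                      flag_hyper_targeted)
from .seqio import read_fasta, to_one_based
from .synthetic import SimulationConfig, simulate_community

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def format_percent(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Human-convention percentage string: round-half-up, '%' suffix."""
    if denominator == 0:
        raise ValueError("denominator must be > 0")
    value = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return f"{value.quantize(quantum, rounding=ROUND_HALF_UP)}%"


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    #: when set, inputs are simulated instead of read from paths
    simulate: SimulationConfig | None = None
    host_fasta: str | None = None
    viral_fasta: str | None = None
    mag_metadata: str | None = None
    gene_table: str | None = None
    dataset_label: str = "community"
    array_params: ArrayParams = field(default_factory=ArrayParams)
    match_params: MatchParams = field(default_factory=MatchParams)
    hyper_threshold: int = 20


def _params_hash(config: RunConfig) -> str:
    blob = json.dumps({
        "seed": config.seed,
        "array_params": dataclasses.asdict(config.array_params),
        "match_params": dataclasses.asdict(config.match_params),
        "hyper_threshold": config.hyper_threshold,
        "simulate": dataclasses.asdict(config.simulate) if config.simulate else None,
    }, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary also written as JSON."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        if config.simulate is not None:
            community = simulate_community(config.simulate)
            community.write(out / "synthetic")
            hosts, viruses = community.hosts, community.viruses
            mag_frame = community.mag_metadata
            gene_frame = community.gene_table
        else:
            if not config.host_fasta or not config.viral_fasta:
                raise PipelineError(
                    "stage inputs: host_fasta and viral_fasta are required "
                    "when no simulation block is given"
                )
            hosts = read_fasta(config.host_fasta)
            viruses = read_fasta(config.viral_fasta)
            mag_frame = (pd.read_csv(config.mag_metadata, sep="\t")
                         if config.mag_metadata else pd.DataFrame())
            gene_frame = (pd.read_csv(config.gene_table, sep="\t")
                          if config.gene_table else pd.DataFrame())

        stage = "detect-arrays"
        host_arrays = [a for h in hosts for a in detect_arrays(h, config.array_params)]
        viral_arrays_by_scaffold = {
            v.id: detect_arrays(v, config.array_params) for v in viruses
        }
        viral_arrays = [a for arrs in viral_arrays_by_scaffold.values() for a in arrs]
        _write_tsv(_arrays_frame(host_arrays + viral_arrays), out / "arrays.tsv")

        stage = "match"
        spacers = extract_spacers(host_arrays, config.dataset_label)
        table = match_all(spacers, viruses, config.match_params,
                          viral_element_mode=True)
        _write_tsv(_matches_frame(table), out / "matches.tsv")

        stage = "network"
        # one MAG per host scaffold: the spacer's source scaffold is its MAG
        spacer_to_mag = {sid: scaffold for sid, _, scaffold, _, _ in spacers.spacers}
        net = build_network(table, spacer_to_mag)
        hyper = flag_hyper_targeted(net, config.hyper_threshold)
        metadata = _mag_metadata_map(mag_frame, host_arrays, hosts)
        cross = curate_cross_phylum(net, metadata)
        _write_tsv(pd.DataFrame(net.links(),
                                columns=["host", "virus", "n_spacer_matches"]),
                   out / "network_links.tsv")

        stage = "conserve"
        derep = dereplicate_spacers(spacers, rc_aware=True)
        multi = multi_copy_spacers(spacers)

        stage = "curate-amgs"
        if not gene_frame.empty:
            gene_rows = rows_from_frame(gene_frame)
            verdicts = curate_amgs(gene_rows)
            categories = summarize_categories(verdicts, gene_rows)
            _write_tsv(pd.DataFrame(
                [(v.scaffold, v.gene_index, v.kept,
                  ";".join(sorted(v.failed_rules))) for v in verdicts],
                columns=["scaffold", "gene_index", "kept", "failed_rules"]),
                out / "amg_verdicts.tsv")
            _write_tsv(categories, out / "amg_categories.tsv")
            amg_kept = sum(v.kept for v in verdicts)
            amg_total = len(verdicts)
        else:
            amg_kept = amg_total = 0

        stage = "mine-effectors"
        candidates_by_element = {}
        for v in viruses:
            cands = screen_effectors(v, viral_arrays_by_scaffold[v.id])
            if cands:
                candidates_by_element[v.id] = cands
        _write_tsv(_effector_frame(candidates_by_element), out / "effectors.tsv")

        stage = "classify-genomes"
        size_rows = []
        for v in viruses:
            dtr = detect_dtr(v)
            size_rows.append({
                "scaffold": v.id,
                "length_bp": v.length,
                "size_class": classify_genome_size(v.length),
                "dtr_length": dtr.repeat_length,
            })
        size_frame = pd.DataFrame(size_rows)
        _write_tsv(size_frame, out / "genome_sizes.tsv")

        stage = "report"
        n_hosts_net, n_virus_net, n_links = net.summary()
        summary = {
            "version": __version__,
            "seed": config.seed,
            "parameter_hash": _params_hash(config),
            "n_host_scaffolds": len(hosts),
            "n_viral_scaffolds": len(viruses),
            "n_host_arrays": len(host_arrays),
            "n_viral_arrays": len(viral_arrays),
            "n_spacers": spacers.size,
            "n_spacers_dereplicated": derep.size,
            "n_multi_copy_spacers": len(multi),
            "n_matches": len(table),
            "network_hosts": n_hosts_net,
            "network_viruses": n_virus_net,
            "network_unique_links": n_links,
            "n_hyper_targeted": len(hyper),
            "max_spacer_hits_per_link": max((n for _, _, n in net.links()),
                                            default=0),
            "n_cross_phylum_calls": len(cross),
            "amg_total": amg_total,
            "amg_kept": amg_kept,
            "n_effector_elements": len(candidates_by_element),
            "n_effector_candidates": sum(len(c) for c in
                                         candidates_by_element.values()),
            "size_classes": size_frame["size_class"].value_counts().to_dict(),
            "n_dtr_elements": int((size_frame["dtr_length"] > 0).sum()),
        }
        (out / "run_manifest.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n")
        return summary
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(f"stage {stage} failed: {exc}") from exc


def _arrays_frame(arrays) -> pd.DataFrame:
    rows = []
    for a in arrays:
        start1, end1 = to_one_based(a.start, a.end)
        rows.append({
            "scaffold": a.scaffold_id, "start1": start1, "end1": end1,
            "n_repeats": a.n_repeats, "repeat_consensus": a.repeat_consensus,
            "n_spacers": a.spacer_count,
        })
    return pd.DataFrame(rows, columns=["scaffold", "start1", "end1",
                                       "n_repeats", "repeat_consensus",
                                       "n_spacers"])


def _matches_frame(table) -> pd.DataFrame:
    rows = []
    for m in table.matches:
        start1, end1 = to_one_based(m.target_start, m.target_end)
        rows.append({
            "spacer_id": m.spacer_id, "target_id": m.target_id,
            "start1": start1, "end1": end1, "strand": m.strand,
            "aligned_len": m.aligned_length, "mismatches": m.mismatches,
            "coverage": round(m.query_coverage, 4),
            "evalue": f"{m.evalue:.3e}",
        })
    return pd.DataFrame(rows, columns=["spacer_id", "target_id", "start1",
                                       "end1", "strand", "aligned_len",
                                       "mismatches", "coverage", "evalue"])


def _effector_frame(candidates_by_element) -> pd.DataFrame:
    rows = []
    for element in sorted(candidates_by_element):
        for c in candidates_by_element[element]:
            start1, end1 = to_one_based(c.orf.start, c.orf.end)
            rows.append({
                "element": element, "orf_start1": start1, "orf_end1": end1,
                "strand": c.orf.strand, "length_aa": c.orf.length_aa,
                "motifs": ";".join(sorted(c.motifs_found)),
                "complete_ruvc": c.complete_ruvc,
            })
    return pd.DataFrame(rows, columns=["element", "orf_start1", "orf_end1",
                                       "strand", "length_aa", "motifs",
                                       "complete_ruvc"])


def _mag_metadata_map(mag_frame: pd.DataFrame, host_arrays, hosts
                      ) -> dict[str, MagMetadata]:
    if mag_frame.empty:
        return {}
    lengths_by_host: dict[str, list[int]] = {}
    host_len = {h.id: h.length for h in hosts}
    for a in host_arrays:
        lengths_by_host.setdefault(a.scaffold_id, []).append(host_len[a.scaffold_id])
    out = {}
    for rec in mag_frame.to_dict("records"):
        mag_id = str(rec["mag_id"])
        out[mag_id] = MagMetadata(
            mag_id=mag_id,
            phylum=str(rec.get("phylum", "") or ""),
            completeness=float(rec.get("completeness", 0.0)),
            contamination=float(rec.get("contamination", 0.0)),
            crispr_scaffold_lengths=tuple(lengths_by_host.get(mag_id, ())),
        )
    return out
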