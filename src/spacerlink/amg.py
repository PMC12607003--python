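"""Curation of VIBRANT-style auxiliary metabolic gene (AMG) tables.

Three filters mirror a manual curation of putative AMGs against
mis-binned host scaffolds and prophage margins:

1. ``END_OF_SCAFFOLD`` - the AMG is the first or last gene on its scaffold
   (gene ordinal, not bp distance).
2. ``HIGH_VSCORE`` - the AMG's own KEGG or Pfam v-score is >= 1 (a v-score
   of 1 marks an annotation as fully virus-like, i.e. likely a viral gene
   mislabelled as metabolic).
3. ``HOSTLIKE_FLANKS`` - every KEGG-v-scored gene among the up-to-four
   genes upstream and up-to-four downstream has a v-score below 0.25 (an
   entirely host-like neighborhood, suggesting a host genome fragment).
   Requires at least one scored flanking gene; the quantifier ("all") and
   threshold are exposed because the underlying rule is stated ambiguously
   in the field's practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

RULE_END = "END_OF_SCAFFOLD"
RULE_VSCORE = "HIGH_VSCORE"
RULE_FLANKS = "HOSTLIKE_FLANKS"

GENE_COLUMNS = ["scaffold", "gene_index", "start", "end", "strand",
                "ko", "kegg_vscore", "pfam_vscore", "is_amg", "category"]


@dataclass(frozen=True)
class GeneRow:
    scaffold: str
    gene_index: int  # 1-based ordinal along the scaffold
    start: int
    end: int
    strand: str
    ko: str = ""
    kegg_vscore: float | None = None
    pfam_vscore: float | None = None
    is_amg: bool = False
    category: str = ""


@dataclass(frozen=True)
class CurationVerdict:
    scaffold: str
    gene_index: int
    kept: bool
    failed_rules: frozenset[str]


def _isnan(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def rows_from_frame(frame: pd.DataFrame) -> list[GeneRow]:
    """Build GeneRows from a VIBRANT-style annotation table."""
    rows = []
    for rec in frame.to_dict("records"):
        rows.append(GeneRow(
            scaffold=str(rec["scaffold"]),
            gene_index=int(rec["gene_index"]),
            start=int(rec["start"]),
            end=int(rec["end"]),
            strand=str(rec["strand"]),
            ko="" if _isnan(rec.get("ko")) else str(rec.get("ko", "")),
            kegg_vscore=None if _isnan(rec.get("kegg_vscore")) else float(rec["kegg_vscore"]),
            pfam_vscore=None if _isnan(rec.get("pfam_vscore")) else float(rec["pfam_vscore"]),
            is_amg=bool(rec.get("is_amg", False)),
            category=str(rec.get("category", "") or ""),
        ))
    return rows


def curate_amgs(table: Iterable[GeneRow],
                flank_window: int = 4,
                flank_threshold: float = 0.25,
                flank_quantifier: str = "all") -> list[CurationVerdict]:
    """Apply the three curation rules to every AMG row.

    Verdicts are independent of row order; genes on a scaffold must have
    contiguous 1-based gene indices (a gap is an error because flanking
    context would be undefined).
    """
    if flank_quantifier not in ("all", "any"):
        raise ValueError("flank_quantifier must be 'all' or 'any'")
    by_scaffold: dict[str, list[GeneRow]] = {}
    for row in table:
        by_scaffold.setdefault(row.scaffold, []).append(row)

    verdicts: list[CurationVerdict] = []
    for scaffold in sorted(by_scaffold):
        genes = sorted(by_scaffold[scaffold], key=lambda g: g.gene_index)
        indices = [g.gene_index for g in genes]
        if indices != list(range(1, len(genes) + 1)):
            raise ValueError(
                f"scaffold {scaffold!r} has non-contiguous gene_index values: {indices}"
            )
        n = len(genes)
        for pos, gene in enumerate(genes):
            if not gene.is_amg:
                continue
            failed: set[str] = set()
            if pos == 0 or pos == n - 1:
                failed.add(RULE_END)
            if ((gene.kegg_vscore is not None and gene.kegg_vscore >= 1)
                    or (gene.pfam_vscore is not None and gene.pfam_vscore >= 1)):
                failed.add(RULE_VSCORE)
            flank_scores = [
                g.kegg_vscore
                for g in genes[max(0, pos - flank_window): pos]
                + genes[pos + 1: pos + 1 + flank_window]
                if g.kegg_vscore is not None
            ]
            if flank_scores:
                below = [s < flank_threshold for s in flank_scores]
                hit = all(below) if flank_quantifier == "all" else any(below)
                if hit:
                    failed.add(RULE_FLANKS)
            verdicts.append(CurationVerdict(
                scaffold=scaffold,
                gene_index=gene.gene_index,
                kept=not failed,
                failed_rules=frozenset(failed),
            ))
    return verdicts


def summarize_categories(verdicts: list[CurationVerdict],
                         table: Iterable[GeneRow]) -> pd.DataFrame:
    """Per-category counts and proportions over kept AMGs.

    Returns an empty frame when nothing is kept (no division by zero).
    """
    kept_keys = {(v.scaffold, v.gene_index) for v in verdicts if v.kept}
    categories = [
        row.category or "unassigned"
        for row in table
        if (row.scaffold, row.gene_index) in kept_keys and row.is_amg
    ]
    if not categories:
        return pd.DataFrame(columns=["category", "count", "proportion"])
    counts = pd.Series(categories).value_counts().sort_index()
    frame = counts.rename_axis("category").reset_index(name="count")
    frame["proportion"] = frame["count"] / frame["count"].sum()
    return frame
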