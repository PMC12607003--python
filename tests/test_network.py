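"""Virus-host network construction, hyper-targeting and cross-phylum curation."""

import pytest

from spacerlink import (MagMetadata, build_network, curate_cross_phylum,
                        flag_hyper_targeted)
from spacerlink.matching import MatchTable, ProtospacerMatch
from spacerlink.network import TargetingCell


def _match(spacer_id: str, target_id: str, start: int = 100) -> ProtospacerMatch:
    return ProtospacerMatch(
        spacer_id=spacer_id, target_id=target_id, target_start=start,
        target_end=start + 30, strand="+", aligned_length=30, mismatches=0,
        query_coverage=1.0, evalue=1e-10,
    )


def _table(rows) -> MatchTable:
    return MatchTable(matches=list(rows))


def test_single_mag_three_spacers_one_link():
    table = _table(_match(f"sp{i}", "V", start=100 * (i + 1)) for i in range(3))
    net = build_network(table, {f"sp{i}": "MAG1" for i in range(3)})
    assert net.summary() == (1, 1, 1)
    assert net.links() == [("MAG1", "V", 3)]


def test_vmag_aggregation_counts_spacer_once():
    # one spacer hitting two member scaffolds of one vMAG counts once
    table = _table([_match("sp1", "scafA"), _match("sp1", "scafB")])
    net = build_network(table, {"sp1": "MAG1"},
                        {"scafA": "vMAG_1", "scafB": "vMAG_1"})
    assert net.links() == [("MAG1", "vMAG_1", 1)]


def test_unassigned_spacer_is_error():
    with pytest.raises(ValueError, match="sp_lost"):
        build_network(_table([_match("sp_lost", "V")]), {})


def test_network_summary_shape():
    # 3 hosts x viruses with some sharing: summary counts distinct nodes/links
    rows, mags = [], {}
    links = [("MAG1", "V1", 2), ("MAG1", "V2", 1), ("MAG2", "V2", 1),
             ("MAG3", "V3", 4)]
    i = 0
    for host, virus, n in links:
        for _ in range(n):
            rows.append(_match(f"sp{i}", virus, start=50 * (i + 1)))
            mags[f"sp{i}"] = host
            i += 1
    net = build_network(_table(rows), mags)
    assert net.summary() == (3, 3, 4)
    assert net.unique_link_count <= sum(n for _, _, n in net.links())


def _engineered_network(counts):
    rows, mags = [], {}
    i = 0
    for virus, n in counts.items():
        for _ in range(n):
            rows.append(_match(f"sp{i}", virus, start=40 * (i + 1)))
            mags[f"sp{i}"] = "MAG1"
            i += 1
    return build_network(_table(rows), mags)


def test_hyper_targeting_boundary():
    net = _engineered_network({"V19": 19, "V20": 20, "V55": 55})
    flagged = flag_hyper_targeted(net, threshold=20)
    assert [(v, n) for _, v, n in flagged] == [("V55", 55), ("V20", 20)]


def test_hyper_targeting_monotone_in_threshold():
    net = _engineered_network({"V5": 5, "V20": 20, "V30": 30, "V55": 55})
    sizes = [len(flag_hyper_targeted(net, threshold=t)) for t in (5, 20, 30, 56)]
    assert sizes == sorted(sizes, reverse=True)


def _meta(mag, phylum, contamination=1.0, scaffold_len=50_000):
    return MagMetadata(mag_id=mag, phylum=phylum, completeness=90.0,
                       contamination=contamination,
                       crispr_scaffold_lengths=(scaffold_len,))


def _three_phylum_network():
    rows, mags = [], {}
    for i, host in enumerate(["MAG_bact", "MAG_cloa", "MAG_firm"]):
        rows.append(_match(f"sp{i}", "V", start=100 * (i + 1)))
        mags[f"sp{i}"] = host
    return build_network(_table(rows), mags)


def test_cross_phylum_three_phyla_call():
    net = _three_phylum_network()
    metadata = {
        "MAG_bact": _meta("MAG_bact", "Bacteroidota"),
        "MAG_cloa": _meta("MAG_cloa", "Cloacimonadota"),
        "MAG_firm": _meta("MAG_firm", "Firmicutes_B"),
    }
    [call] = curate_cross_phylum(net, metadata)
    assert call.phyla == ("Bacteroidota", "Cloacimonadota", "Firmicutes_B")


@pytest.mark.parametrize("kwargs", [
    {"contamination": 5.01},
    {"scaffold_len": 9_999},
])
def test_cross_phylum_support_removed_at_boundaries(kwargs):
    net = _three_phylum_network()
    metadata = {
        "MAG_bact": _meta("MAG_bact", "Bacteroidota", **kwargs),
        "MAG_cloa": _meta("MAG_cloa", "Cloacimonadota"),
        "MAG_firm": _meta("MAG_firm", "Firmicutes_B"),
    }
    [call] = curate_cross_phylum(net, metadata)
    assert "MAG_bact" not in call.supporting_hosts
    assert call.phyla == ("Cloacimonadota", "Firmicutes_B")


def test_cross_phylum_single_phylum_left_no_call():
    net = _three_phylum_network()
    metadata = {
        "MAG_bact": _meta("MAG_bact", "Bacteroidota", contamination=5.01),
        "MAG_cloa": _meta("MAG_cloa", "Cloacimonadota", scaffold_len=9_999),
        "MAG_firm": _meta("MAG_firm", "Firmicutes_B"),
    }
    assert curate_cross_phylum(net, metadata) == []


def test_cross_phylum_contamination_boundary_inclusive():
    # exactly 5.00% passes ("maximum contamination of 5.00%")
    net = _three_phylum_network()
    metadata = {
        "MAG_bact": _meta("MAG_bact", "Bacteroidota", contamination=5.00),
        "MAG_cloa": _meta("MAG_cloa", "Cloacimonadota"),
        "MAG_firm": _meta("MAG_firm", "Firmicutes_B"),
    }
    [call] = curate_cross_phylum(net, metadata)
    assert "MAG_bact" in call.supporting_hosts


def test_cross_phylum_same_phylum_no_call():
    net = _three_phylum_network()
    metadata = {m: _meta(m, "Bacteroidota")
                for m in ("MAG_bact", "MAG_cloa", "MAG_firm")}
    assert curate_cross_phylum(net, metadata) == []


def test_targeting_cell_percent_one_decimal():
    assert TargetingCell("a", "b", 138, 5446).percent == 2.5
    assert TargetingCell("a", "b", 516, 9299).percent == 5.5
    assert TargetingCell("a", "b", 0, 100).percent == 0.0


def test_cross_site_matrix_within_and_across(rng):
    """Spacers copied from a site's own viruses target within-site only;
    the across-site cell stays empty for unrelated viromes."""
    from conftest import random_seq
    from spacerlink.arrays import SpacerSet
    from spacerlink.network import cross_site_matrix
    from spacerlink.seqio import ScaffoldRecord

    virus_a = ScaffoldRecord("vA", random_seq(rng, 15_000))
    virus_b = ScaffoldRecord("vB", random_seq(rng, 15_000))
    spacers_a = SpacerSet(label="siteA", spacers=[
        (f"A|sp{i}", virus_a.sequence[1_000 * (i + 1): 1_000 * (i + 1) + 30],
         "hA", 1, i + 1)
        for i in range(4)
    ] + [("A|orphan", random_seq(rng, 30), "hA", 1, 5)])
    spacers_b = SpacerSet(label="siteB", spacers=[
        ("B|sp1", virus_b.sequence[2_000:2_030], "hB", 1, 1)])

    matrix = cross_site_matrix(
        {"siteA": spacers_a, "siteB": spacers_b},
        {"siteA": [virus_a], "siteB": [virus_b]})

    within_a = matrix.cell("siteA", "siteA")
    assert (within_a.matched_spacer_count, within_a.spacer_total) == (4, 5)
    assert within_a.percent == 80.0
    assert matrix.cell("siteA", "siteB").matched_spacer_count == 0
    assert matrix.cell("siteB", "siteB").matched_spacer_count == 1
    assert matrix.cell("siteB", "siteA").matched_spacer_count == 0
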