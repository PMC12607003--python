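"""The community generator: determinism, self-consistency, ground truth."""

import math

import pytest

from spacerlink.seqio import reverse_complement
from spacerlink.synthetic import (SimulationConfig, SimulationError,
                                  _Registry, plant_array, simulate_community)


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(seed=7, n_hosts=6, n_viruses=6, host_length=30_000,
                    viral_length_median=15_000, viral_length_sigma=0.3,
                    viral_extra_lengths=(), dtr_lengths=(80,),
                    arrays_per_host=(1, 1), spacers_per_array=(3, 5))
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def test_no_hosts_means_no_arrays_no_links():
    com = simulate_community(small_config(n_hosts=0, n_viruses=5,
                                          viral_array_fraction=0.0))
    assert com.hosts == []
    assert len(com.viruses) == 5
    assert com.truth.planted_links == []
    assert [a for a in com.truth.planted_arrays] == []


def test_all_planted_exact_spacers_occur_in_viral_fasta():
    com = simulate_community(small_config(
        planted_fraction=1.0, orphan_fraction=0.0, mismatch_law={0: 1.0}))
    viral_seqs = [v.sequence for v in com.viruses]
    spacers = [s for a in com.truth.planted_arrays
               if a.scaffold_id.startswith("host")
               for s in a.spacers]
    assert spacers
    for spacer in spacers:
        rc = reverse_complement(spacer)
        assert any(spacer in v or rc in v for v in viral_seqs)


def test_same_seed_byte_identical_outputs(tmp_path):
    config = small_config()
    paths1 = simulate_community(config).write(tmp_path / "a")
    paths2 = simulate_community(config).write(tmp_path / "b")
    for key in paths1:
        assert paths1[key].read_bytes() == paths2[key].read_bytes(), key


def test_different_seed_differs(tmp_path):
    c1 = simulate_community(small_config(seed=7))
    c2 = simulate_community(small_config(seed=8))
    assert c1.viruses[0].sequence != c2.viruses[0].sequence


def test_planted_links_refindable_with_recorded_mismatches():
    com = simulate_community(small_config())
    viruses = {v.id: v.sequence for v in com.viruses}
    spacer_by_id = {
        sid: seq
        for a in com.truth.planted_arrays
        for sid, seq in zip(a.spacer_ids, a.spacers)
    }
    assert com.truth.planted_links
    for link in com.truth.planted_links:
        spacer = spacer_by_id[link.spacer_id]
        target = viruses[link.viral_scaffold]
        window = target[link.position : link.position + len(spacer)]
        query = spacer if link.strand == "+" else reverse_complement(spacer)
        hamming = sum(a != b for a, b in zip(query, window))
        assert hamming == link.mismatches


def test_mismatches_confined_to_untrimmable_core():
    com = simulate_community(small_config(mismatch_law={2: 1.0}))
    viruses = {v.id: v.sequence for v in com.viruses}
    spacer_by_id = {
        sid: seq
        for a in com.truth.planted_arrays
        for sid, seq in zip(a.spacer_ids, a.spacers)
    }
    for link in com.truth.planted_links:
        spacer = spacer_by_id[link.spacer_id]
        L = len(spacer)
        min_w = math.ceil(0.9 * L)
        target = viruses[link.viral_scaffold]
        window = target[link.position : link.position + L]
        query = spacer if link.strand == "+" else reverse_complement(spacer)
        positions = [i for i, (a, b) in enumerate(zip(query, window)) if a != b]
        strand_positions = (positions if link.strand == "+"
                            else [L - 1 - p for p in positions])
        assert all(L - min_w <= p < min_w for p in strand_positions)


def test_zero_mismatch_fraction_converges_to_law():
    config = small_config(n_hosts=20, host_length=40_000,
                          arrays_per_host=(2, 2), spacers_per_array=(6, 8))
    com = simulate_community(config)
    total = sum(len(a.spacers) for a in com.truth.planted_arrays
                if a.scaffold_id.startswith("host"))
    zero_mm = sum(1 for l in com.truth.planted_links if l.mismatches == 0)
    p = config.planted_fraction * dict(config.mismatch_law)[0]
    sd = math.sqrt(total * p * (1 - p))
    assert abs(zero_mm - total * p) <= 3 * sd


def test_dtr_planted_on_selected_viruses():
    com = simulate_community(small_config())
    assert com.truth.planted_dtrs == [("virus_001", 80)]
    v = {v.id: v.sequence for v in com.viruses}["virus_001"]
    assert v[:80] == v[-80:]


def test_gene_table_verdict_ground_truth_is_self_consistent():
    from spacerlink.amg import curate_amgs, rows_from_frame
    com = simulate_community(small_config())
    verdicts = curate_amgs(rows_from_frame(com.gene_table))
    by_key = {(v.scaffold, v.gene_index): v for v in verdicts}
    assert com.truth.amg_expected_verdicts
    for scaffold, index, kept, rule in com.truth.amg_expected_verdicts:
        v = by_key[(scaffold, index)]
        assert v.kept is kept
        if rule:
            assert v.failed_rules == {rule}


@pytest.mark.parametrize("overrides, message", [
    (dict(spacer_length=(0, 50)), "minimum"),
    (dict(planted_fraction=0.8, orphan_fraction=0.5), "<= 1"),
    (dict(repeat_length=(10, 40)), "detectable"),
    (dict(spacer_length=(25, 90)), "detectable"),
    (dict(mismatch_law={0: 0.5, 3: 0.5}), "mismatch"),
])
def test_invalid_configs_rejected(overrides, message):
    with pytest.raises(SimulationError, match=message):
        small_config(**overrides)


def test_plant_array_interval_arithmetic():
    seq = "C" * 3_000
    repeat = "A" * 28
    spacers = ["G" * 30] * 3
    out = plant_array(seq, repeat, spacers, 1_000)
    span = 4 * 28 + 3 * 30
    assert len(out) == len(seq)
    assert out[:1_000] == seq[:1_000]
    assert out[1_000 + span:] == seq[1_000 + span:]
    assert out[1_000 : 1_000 + span] == repeat + "".join(s + repeat for s in spacers)


def test_plant_array_zero_spacers_rejected():
    with pytest.raises(SimulationError, match="at least one spacer"):
        plant_array("C" * 1_000, "A" * 28, [], 100)


def test_plant_array_overlap_error_names_both_features():
    registry = _Registry("scafX")
    seq = "C" * 2_000
    seq = plant_array(seq, "A" * 25, ["G" * 30], 500, registry, "first")
    with pytest.raises(SimulationError) as err:
        plant_array(seq, "T" * 25, ["G" * 30], 510, registry, "second")
    assert "first" in str(err.value) and "second" in str(err.value)


def test_plant_array_round_trip_with_detector(rng):
    from conftest import random_seq
    from spacerlink import detect_arrays, ScaffoldRecord
    seq = random_seq(rng, 9_000)
    repeat = random_seq(rng, 31)
    spacers = [random_seq(rng, 34) for _ in range(4)]
    planted = plant_array(seq, repeat, spacers, 4_000)
    span = 5 * 31 + 4 * 34
    # detectability guard applied by the generator: make flanks non-extendable
    chars = list(planted)
    if chars[3_999] == spacers[0][-1]:
        chars[3_999] = "ACGT"[("ACGT".index(spacers[0][-1]) + 1) % 4]
    if chars[4_000 + span] == spacers[0][0]:
        chars[4_000 + span] = "ACGT"[("ACGT".index(spacers[0][0]) + 1) % 4]
    [arr] = detect_arrays(ScaffoldRecord("s", "".join(chars)))
    assert (arr.start, arr.end) == (4_000, 4_000 + span)
    assert [s for _, s in arr.spacers] == spacers
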