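"""Flank windows, ORF calling, RuvC scanning, size classes and DTRs."""

import pytest

from conftest import random_seq
from spacerlink import (ScaffoldRecord, call_orfs, classify_genome_size,
                        detect_dtr, extract_flanking_windows,
                        filter_candidate_orfs, scan_ruvc, screen_effectors)
from spacerlink.arrays import CrisprArray
from spacerlink.effectors import summarize_effector_elements
from spacerlink.seqio import reverse_complement
from spacerlink.synthetic import _effector_gene


def _array(scaffold_id, start, end):
    return CrisprArray(scaffold_id=scaffold_id, start=start, end=end,
                       repeat_consensus="A" * 25)


def test_flanking_windows_both_sides():
    scaffold = ScaffoldRecord("s", "A" * 40_000)
    windows = extract_flanking_windows(_array("s", 15_000, 15_500), scaffold)
    assert [(w.start, w.end) for w in windows] == [(5_000, 15_000),
                                                  (15_500, 25_500)]
    assert sum(w.length for w in windows) <= 2 * 10_000


def test_flanking_windows_clipped():
    scaffold = ScaffoldRecord("s", "A" * 12_000)
    windows = extract_flanking_windows(_array("s", 0, 500), scaffold)
    assert [(w.start, w.end) for w in windows] == [(500, 10_500)]
    windows = extract_flanking_windows(_array("s", 11_000, 11_500), scaffold)
    assert [(w.start, w.end) for w in windows] == [(1_000, 11_000),
                                                   (11_500, 12_000)]


def test_call_orfs_planted_forward_and_reverse(rng):
    gene = _effector_gene(rng, 450)  # TAA + ATG...stop, 450 aa
    background = random_seq(rng, 8_000)
    seq = background[:3000] + gene + background[3000 + len(gene):]
    fwd = [o for o in call_orfs(ScaffoldRecord("s", seq), min_aa=300)
           if o.strand == "+"]
    assert any(o.start == 3003 and o.end == 3000 + len(gene)
               and o.length_aa == 450 for o in fwd)
    rc_seq = reverse_complement(seq)
    rev = [o for o in call_orfs(ScaffoldRecord("s", rc_seq), min_aa=300)
           if o.strand == "-"]
    L = len(rc_seq)
    assert any((L - o.end, L - o.start) == (3003, 3000 + len(gene))
               for o in rev)


def test_call_orfs_all_stops_empty():
    assert call_orfs(ScaffoldRecord("s", "TAA" * 200)) == []


def test_orf_protein_has_no_internal_stop(rng):
    seq = random_seq(rng, 20_000)
    for orf in call_orfs(ScaffoldRecord("s", seq), min_aa=50):
        assert "*" not in orf.protein
        assert orf.length_aa == (orf.end - orf.start) // 3 - 1
        assert orf.protein[0] == "M"


@pytest.mark.parametrize("aa, kept", [(299, False), (300, True),
                                      (800, True), (801, False)])
def test_candidate_length_bounds_inclusive(rng, aa, kept):
    gene = _effector_gene(rng, aa)
    seq = random_seq(rng, 1_000) + gene + random_seq(rng, 1_000)
    orfs = call_orfs(ScaffoldRecord("s", seq), min_aa=200)
    sized = filter_candidate_orfs(orfs)
    assert any(o.length_aa == aa for o in orfs)
    assert any(o.length_aa == aa for o in sized) is kept


def test_scan_ruvc_planted_motifs_complete(rng):
    protein = "M" + "K" * 100 + "LATAD" + "K" * 100 + "EKKG" + "K" * 100 + "DKD" + "K" * 50
    found, complete, anchors = scan_ruvc(protein)
    assert found == {"RuvC-I", "RuvC-II", "RuvC-III"}
    assert complete
    assert anchors["RuvC-I"] < anchors["RuvC-II"] < anchors["RuvC-III"]


def test_scan_ruvc_poly_a_empty():
    found, complete, _ = scan_ruvc("A" * 400)
    assert found == frozenset()
    assert not complete


def test_scan_ruvc_only_ruvc3():
    protein = "M" + "K" * 260 + "DKD" + "K" * 80
    found, complete, _ = scan_ruvc(protein)
    assert found == {"RuvC-III"}
    assert not complete


def test_scan_ruvc_motif_outside_span_ignored():
    # RuvC-I pattern sitting in the C-terminal third does not count
    protein = "M" + "K" * 300 + "LATAD" + "K" * 40
    found, _, _ = scan_ruvc(protein)
    assert "RuvC-I" not in found


def test_screen_effectors_end_to_end(rng):
    from spacerlink import detect_arrays
    from spacerlink.synthetic import plant_array

    seq = random_seq(rng, 40_000)
    repeat = random_seq(rng, 30)
    spacers = [random_seq(rng, 32) for _ in range(4)]
    seq = plant_array(seq, repeat, spacers, 20_000)
    arr_end = 20_000 + 5 * 30 + 4 * 32
    gene = _effector_gene(rng, 450)
    pos = arr_end + 2_000
    seq = seq[:pos] + gene + seq[pos + len(gene):]
    scaffold = ScaffoldRecord("v", seq)
    arrays = detect_arrays(scaffold)
    assert arrays, "planted array must be detectable"
    candidates = screen_effectors(scaffold, arrays)
    complete = [c for c in candidates if c.complete_ruvc]
    assert any(c.orf.start == pos + 3 and c.orf.length_aa == 450
               for c in complete)


def test_summarize_effector_elements_dedup():
    class FakeOrf:
        def __init__(self, protein):
            self.protein = protein

    class FakeCand:
        def __init__(self, protein):
            self.orf = FakeOrf(protein)

    grouped = {
        "e1": [FakeCand("MAAA"), FakeCand("MBBB"), FakeCand("MCCC")],
        "e2": [FakeCand("MAAA"), FakeCand("MAAA")],
        "e3": [],
    }
    assert summarize_effector_elements(grouped) == {"e1": 3, "e2": 1}


def test_classify_genome_size_thresholds():
    assert classify_genome_size(678_337) == "megaphage"
    assert classify_genome_size(500_000) == "megaphage"
    assert classify_genome_size(499_999) == "jumbo"
    assert classify_genome_size(364_000) == "jumbo"
    assert classify_genome_size(200_000) == "jumbo"
    assert classify_genome_size(199_999) == "standard"
    with pytest.raises(ValueError):
        classify_genome_size(0)


def test_classify_genome_size_monotone():
    order = {"standard": 0, "jumbo": 1, "megaphage": 2}
    lengths = [1, 10_000, 199_999, 200_000, 350_000, 499_999, 500_000, 700_000]
    ranks = [order[classify_genome_size(l)] for l in lengths]
    assert ranks == sorted(ranks)


def test_detect_dtr_planted_ends(rng):
    core = random_seq(rng, 5_000)
    dtr = random_seq(rng, 100)
    record = ScaffoldRecord("v", dtr + core + dtr)
    assert detect_dtr(record).repeat_length == 100


def test_detect_dtr_below_threshold(rng):
    core = random_seq(rng, 5_000)
    ends = random_seq(rng, 19)
    record = ScaffoldRecord("v", ends + core + ends)
    assert detect_dtr(record, min_len=20).repeat_length == 0
    assert detect_dtr(record, min_len=19).repeat_length == 19


def test_detect_dtr_random_sequence_zero_vs_brute_force(rng):
    seq = random_seq(rng, 50_000)
    record = ScaffoldRecord("v", seq)
    result = detect_dtr(record)
    # independent brute force over all prefix/suffix lengths
    brute = max((k for k in range(20, len(seq) // 2)
                 if seq[:k] == seq[-k:]), default=0)
    assert result.repeat_length == brute == 0


def test_detect_dtr_wrapping_extension_detected(rng):
    # wrapping the genome in one more identical terminal block keeps a DTR
    # detectable: the new terminal repeat is the added block itself
    core = random_seq(rng, 3_000)
    dtr = random_seq(rng, 60)
    ext = random_seq(rng, 25)
    base = detect_dtr(ScaffoldRecord("v", dtr + core + dtr)).repeat_length
    extended = detect_dtr(ScaffoldRecord("v", ext + dtr + core + dtr + ext))
    assert base == 60
    assert extended.repeat_length == 25
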