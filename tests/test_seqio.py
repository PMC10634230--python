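"""Sequence metrics: UU counting, windowed richness, motif search, FASTA I/O."""

import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlr7scan.seqio import (
    KNOWN_OLIGOS,
    TranscriptRecord,
    count_uu,
    extract_fragment,
    find_motif,
    interval_length,
    max_window_uu,
    normalize_sequence,
    read_transcriptome,
    select_longest_variant,
    uu_profile,
)

rna = st.text(alphabet="ACGU", min_size=0, max_size=300)


# --- independent oracles -------------------------------------------------

def bf_count_nonoverlapping(seq: str) -> int:
    """Greedy left-to-right disjoint UU matches, by explicit scan."""
    n = i = 0
    while i < len(seq) - 1:
        if seq[i] == "U" and seq[i + 1] == "U":
            n += 1
            i += 2
        else:
            i += 1
    return n


def bf_count_overlapping(seq: str) -> int:
    return sum(1 for i in range(len(seq) - 1) if seq[i] == seq[i + 1] == "U")


def bf_max_window(seq: str, window: int, mode: str) -> int:
    counter = bf_count_nonoverlapping if mode == "nonoverlapping" else bf_count_overlapping
    if len(seq) < window:
        return counter(seq)
    return max(counter(seq[i : i + window]) for i in range(len(seq) - window + 1))


# --- count_uu ------------------------------------------------------------

@pytest.mark.parametrize(
    "seq, nonov, ov",
    [
        (KNOWN_OLIGOS["polyA"], 0, 0),
        (KNOWN_OLIGOS["XIST1.1"], 2, 2),
        (KNOWN_OLIGOS["RNA9.2s"], 2, 2),
        ("UUU", 1, 2),
        ("UUUU", 2, 3),
        ("", 0, 0),
        ("NUUN", 1, 1),
    ],
)
def test_count_uu_examples(seq, nonov, ov):
    assert count_uu(seq, "nonoverlapping") == nonov
    assert count_uu(seq, "overlapping") == ov


def test_count_uu_rejects_unknown_mode():
    with pytest.raises(ValueError, match="mode"):
        count_uu("UU", "sideways")


@given(rna)
def test_count_uu_matches_oracles(seq):
    assert count_uu(seq, "nonoverlapping") == bf_count_nonoverlapping(seq)
    assert count_uu(seq, "overlapping") == bf_count_overlapping(seq)


@given(rna)
def test_mode_inequality_chain(seq):
    """overlapping >= nonoverlapping >= ceil(overlapping / 2)."""
    ov = count_uu(seq, "overlapping")
    nonov = count_uu(seq, "nonoverlapping")
    assert ov >= nonov >= math.ceil(ov / 2)


@given(rna, st.integers(min_value=0, max_value=5))
def test_a_padding_leaves_count_unchanged(seq, pad):
    """Non-U padding at either end never creates or destroys a UU."""
    padded = "A" * pad + seq + "A" * pad
    for mode in ("nonoverlapping", "overlapping"):
        assert count_uu(padded, mode) == count_uu(seq, mode)


# --- max_window_uu / uu_profile -----------------------------------------

def test_short_sequence_is_a_single_window():
    seq = "GU" * 20  # length 40 < default window
    assert max_window_uu(seq, 500) == (count_uu(seq), 1)


def test_window_inside_u_run():
    seq = "AA" + "UU" * 10 + "AA"
    count, start = max_window_uu(seq, 10, "nonoverlapping")
    assert count == 5
    assert 3 <= start <= 15  # the window lies fully inside the U-run


@given(st.text(alphabet="ACGUN", min_size=10, max_size=120), st.integers(2, 30))
def test_max_window_matches_bruteforce(seq, window):
    for mode in ("nonoverlapping", "overlapping"):
        count, start = max_window_uu(seq, window, mode)
        assert count == bf_max_window(seq, window, mode)
        assert start >= 1


def test_max_window_start_is_smallest_attaining():
    seq = "AUUA" + "G" * 20 + "AUUA"
    count, start = max_window_uu(seq, 4)
    assert (count, start) == (1, 1)


def test_window_below_two_rejected():
    with pytest.raises(ValueError):
        max_window_uu("ACGU", 1)


def test_profile_constant_on_homopolymer():
    prof = uu_profile("U" * 600, 500)
    assert len(prof) == 101
    assert len(set(prof.tolist())) == 1


def test_profile_consistency(rng):
    seq = "".join(rng.choice(list("ACGU"), size=800))
    for mode in ("nonoverlapping", "overlapping"):
        prof = uu_profile(seq, 500, mode)
        assert prof[0] == count_uu(seq[:500], mode)
        count, start = max_window_uu(seq, 500, mode)
        assert prof.max() == count
        assert prof[start - 1] == count


def test_profile_requires_window_length():
    with pytest.raises(ValueError, match="shorter"):
        uu_profile("ACGU", 500)


# --- find_motif ----------------------------------------------------------

@pytest.mark.parametrize(
    "oligo, hits",
    [("RNA9.2s", [11]), ("XIST1.1", [11]), ("polyA", []), ("RNA9.2a", [])],
)
def test_motif_in_benchmark_oligos(oligo, hits):
    assert find_motif(KNOWN_OLIGOS[oligo], "GUCCUUCAA") == hits


def test_motif_overlapping_hits():
    assert find_motif("UUUUU", "UU") == [1, 2, 3, 4]


@given(rna, st.text(alphabet="ACGU", min_size=1, max_size=4))
def test_reported_positions_really_match(seq, motif):
    for p in find_motif(seq, motif):
        assert seq[p - 1 : p - 1 + len(motif)] == motif
    # and no position is missed
    assert len(find_motif(seq, motif)) == len(
        [m.start() for m in re.finditer(f"(?={re.escape(motif)})", seq)]
    )


def test_bad_motif_rejected():
    with pytest.raises(ValueError):
        find_motif("ACGU", "GUX")
    with pytest.raises(ValueError):
        find_motif("ACGU", "")


# --- coordinates ---------------------------------------------------------

def test_interval_length_is_inclusive():
    assert interval_length(105, 851) == 747
    assert interval_length(1, 1) == 1
    with pytest.raises(ValueError):
        interval_length(5, 4)


def test_extract_fragment_roundtrip():
    seq = "ACGUACGUAC"
    assert extract_fragment(seq, 2, 5) == "CGUA"
    assert len(extract_fragment(seq, 2, 5)) == interval_length(2, 5)


# --- FASTA reading and variant selection ---------------------------------

def test_read_transcriptome_normalizes(tmp_path):
    fa = tmp_path / "t.fasta"
    fa.write_text(">G1|tx1\nacgt\n>G2|tx2\nGGNN\n")
    recs = read_transcriptome(fa)
    assert [r.gene_symbol for r in recs] == ["G1", "G2"]
    assert recs[0].sequence == "ACGU"
    assert recs[0].length == 4
    assert recs[1].sequence == "GGNN"  # N retained


def test_read_transcriptome_rejects_bad_alphabet(tmp_path):
    fa = tmp_path / "t.fasta"
    fa.write_text(">G1|tx1\nACXG\n")
    with pytest.raises(ValueError, match="tx1"):
        read_transcriptome(fa)


def test_read_transcriptome_rejects_empty_record(tmp_path):
    fa = tmp_path / "t.fasta"
    fa.write_text(">G1|tx1\n\n>G2|tx2\nACGU\n")
    with pytest.raises(ValueError, match="empty"):
        read_transcriptome(fa)


def test_header_rule_failure_names_header(tmp_path):
    fa = tmp_path / "t.fasta"
    fa.write_text(">onlyfield\nACGU\n")
    with pytest.raises(ValueError, match="onlyfield"):
        read_transcriptome(fa, delimiter="|", index=1)


def test_wrapped_fasta_lines(tmp_path):
    fa = tmp_path / "t.fasta"
    fa.write_text(">G1|tx1\nACGU\nACGU\n")
    assert read_transcriptome(fa)[0].sequence == "ACGUACGU"


def test_normalize_sequence_error_names_record():
    with pytest.raises(ValueError, match="myrec"):
        normalize_sequence("AB", "myrec")


def test_longest_variant_selection():
    recs = [
        TranscriptRecord("NR_10", "G1", "A" * 100),
        TranscriptRecord("NR_11", "G1", "A" * 250),
        TranscriptRecord("NR_20", "G2", "ACGU"),
    ]
    kept = select_longest_variant(recs)
    assert [r.transcript_id for r in kept] == ["NR_11", "NR_20"]


def test_longest_variant_tie_breaks_on_id():
    recs = [
        TranscriptRecord("NR_2", "G1", "ACGU"),
        TranscriptRecord("NR_1", "G1", "UGCA"),
    ]
    assert select_longest_variant(recs)[0].transcript_id == "NR_1"
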