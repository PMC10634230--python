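"""Transcript ingestion and UU / motif sequence metrics.

TLR7 is an endosomal single-stranded-RNA sensor whose minimal stimulatory
unit is a uridine pair (UU), with longer motifs such as 5'-GUCCUUCAA-3'
(the 3' core of the RNA9.2s ligand) binding with higher affinity.  This
module turns a transcriptome FASTA into per-gene ligand metrics:

* total UU dinucleotide count,
* "maximum UU richness" — the highest UU count in any fixed-length
  (default 500 nt) window of the transcript,
* exact-match positions of a query motif.

Coordinates are 1-based and inclusive at both ends throughout, the
convention used for transcript annotation in the field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Default TLR7-stimulatory motif (3' core of RNA9.2s).
TLR7_MOTIF = "GUCCUUCAA"

#: Published benchmark oligonucleotides from the TLR7 ligand-mapping
#: literature, useful as ground-truth fixtures: the XIST fragment carrying
#: the GUCCUUCAA motif ("XIST1.1"), the original stimulatory ligand
#: RNA9.2s, its non-stimulatory antisense RNA9.2a, and a poly(A) control.
KNOWN_OLIGOS = {
    "XIST1.1": "GUUGUCAAUGGUCCUUCAA",
    "RNA9.2s": "AGCUUAACCUGUCCUUCAA",
    "RNA9.2a": "UUGAAGGACAGGUUAAGCU",
    "polyA": "AAAAAAAAAAAAAAAAAAA",
}

_VALID_CHARS = frozenset("ACGUN")
_MOTIF_CHARS = frozenset("ACGU")
_U_RUN = re.compile("U+")


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript variant with a normalized RNA sequence."""

    transcript_id: str
    gene_symbol: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LigandProfile:
    """Per-gene sequence-level TLR7-ligand metrics."""

    gene_symbol: str
    transcript_id: str
    length: int
    uu_count: int
    max_window_uu: int
    max_window_start: int  # 1-based
    motif_hits: tuple[int, ...] = field(default_factory=tuple)  # 1-based

    @property
    def has_motif(self) -> bool:
        return len(self.motif_hits) > 0


def normalize_sequence(raw: str, record_id: str = "<sequence>") -> str:
    """Uppercase, map T to U, and validate the alphabet.

    Characters outside {A, C, G, U, T, N} (case-insensitive) are rejected;
    N is retained and treated downstream as a non-U, non-matching base.
    """
    seq = raw.upper().replace("T", "U")
    if not seq:
        raise ValueError(f"record {record_id!r}: empty sequence")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(
            f"record {record_id!r}: invalid characters {sorted(bad)!r} "
            "(allowed: A/C/G/U/T/N)"
        )
    return seq


def parse_gene_symbol(header: str, delimiter: str = "|", index: int = 0) -> str:
    """Extract the gene symbol from a FASTA header id.

    The default rule takes field ``index`` of the id split on ``delimiter``
    (e.g. ``>XIST|NR_001564`` -> ``XIST``).
    """
    parts = header.split(delimiter)
    if index >= len(parts) or not parts[index]:
        raise ValueError(
            f"header {header!r}: cannot extract gene symbol "
            f"(delimiter {delimiter!r}, field {index})"
        )
    return parts[index]


def read_transcriptome(
    fasta_path, delimiter: str = "|", index: int = 0
) -> list[TranscriptRecord]:
    """Read a transcriptome FASTA into normalized :class:`TranscriptRecord`s.

    Sequences are uppercased and DNA T is mapped to RNA U; records with
    characters outside the A/C/G/U/T/N alphabet raise an error naming the
    offending record.  File order is preserved.
    """
    records: list[TranscriptRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gene = parse_gene_symbol(rec.id, delimiter, index)
        parts = rec.id.split(delimiter)
        tid = delimiter.join(p for i, p in enumerate(parts) if i != index) or rec.id
        seq = normalize_sequence(str(rec.seq), rec.id)
        records.append(TranscriptRecord(tid, gene, seq))
    return records


def select_longest_variant(records: list[TranscriptRecord]) -> list[TranscriptRecord]:
    """Keep one variant per gene symbol: the longest, ties broken by the
    lexicographically smallest transcript id (deterministic)."""
    best: dict[str, TranscriptRecord] = {}
    order: list[str] = []
    for rec in records:
        cur = best.get(rec.gene_symbol)
        if cur is None:
            best[rec.gene_symbol] = rec
            order.append(rec.gene_symbol)
        elif rec.length > cur.length or (
            rec.length == cur.length and rec.transcript_id < cur.transcript_id
        ):
            best[rec.gene_symbol] = rec
    return [best[g] for g in order]


def count_uu(sequence: str, mode: str = "nonoverlapping") -> int:
    """Count UU dinucleotides in a normalized RNA sequence.

    ``nonoverlapping`` counts greedy left-to-right disjoint matches of
    "UU" (the semantics of common string-count functions, e.g. R's
    ``stringr::str_count`` used in the original screen); ``overlapping``
    counts every position i with s[i] == s[i+1] == 'U'.
    """
    if mode == "nonoverlapping":
        return sequence.count("UU")
    if mode == "overlapping":
        return sum(m.end() - m.start() - 1 for m in _U_RUN.finditer(sequence))
    raise ValueError(f"unknown counting mode {mode!r}")


def max_window_uu(
    sequence: str, window: int = 500, mode: str = "nonoverlapping"
) -> tuple[int, int]:
    """Maximum UU count over all length-``window`` segments of a transcript.

    A UU is attributed to a window only when both bases lie inside it.
    Returns ``(count, start)`` with ``start`` the smallest 1-based position
    achieving the maximum.  Sequences shorter than the window are treated
    as a single window starting at position 1.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    if len(sequence) < window:
        return count_uu(sequence, mode), 1
    counts = uu_profile(sequence, window, mode)
    best = int(np.argmax(counts))
    return int(counts[best]), best + 1


def uu_profile(
    sequence: str, window: int = 500, mode: str = "nonoverlapping"
) -> np.ndarray:
    """Windowed UU counts along a transcript, one per start position.

    Element i (0-based) is the UU count of the window starting at
    nucleotide i+1; the series has length ``len(sequence) - window + 1``.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    n = len(sequence)
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    if mode == "overlapping":
        # Indicator of a UU starting at each position; a window [i, i+w-1]
        # holds starts i..i+w-2, so windowed sums of width w-1 suffice.
        arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        is_u = arr == ord("U")
        starts = (is_u[:-1] & is_u[1:]).astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(starts)])
        return csum[window - 1 :] - csum[: n - window + 1]
    if mode == "nonoverlapping":
        return np.array(
            [sequence[i : i + window].count("UU") for i in range(n - window + 1)],
            dtype=np.int64,
        )
    raise ValueError(f"unknown counting mode {mode!r}")


def find_motif(sequence: str, motif: str = TLR7_MOTIF) -> list[int]:
    """All (overlapping) exact-match 1-based start positions of ``motif``."""
    if not motif:
        raise ValueError("motif must be non-empty")
    bad = set(motif.upper()) - _MOTIF_CHARS
    if bad:
        raise ValueError(f"motif contains invalid characters {sorted(bad)!r}")
    motif = motif.upper()
    hits: list[int] = []
    i = sequence.find(motif)
    while i != -1:
        hits.append(i + 1)
        i = sequence.find(motif, i + 1)
    return hits


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive interval (e.g. 105..851 -> 747 nt)."""
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based interval {start}..{end}")
    return end - start + 1


def extract_fragment(sequence: str, start: int, end: int) -> str:
    """Slice a transcript by 1-based inclusive coordinates."""
    if end > len(sequence):
        raise ValueError(f"interval end {end} beyond sequence length {len(sequence)}")
    interval_length(start, end)
    return sequence[start - 1 : end]


def profile_transcript(
    record: TranscriptRecord,
    motif: str = TLR7_MOTIF,
    window: int = 500,
    mode: str = "nonoverlapping",
) -> LigandProfile:
    count, start = max_window_uu(record.sequence, window, mode)
    return LigandProfile(
        gene_symbol=record.gene_symbol,
        transcript_id=record.transcript_id,
        length=record.length,
        uu_count=count_uu(record.sequence, mode),
        max_window_uu=count,
        max_window_start=start,
        motif_hits=tuple(find_motif(record.sequence, motif)),
    )


def profile_transcripts(
    records: list[TranscriptRecord],
    motif: str = TLR7_MOTIF,
    window: int = 500,
    mode: str = "nonoverlapping",
) -> pd.DataFrame:
    """Ligand profiles for a set of transcripts as a gene-indexed table."""
    rows = []
    for rec in records:
        p = profile_transcript(rec, motif, window, mode)
        rows.append(
            {
                "gene_symbol": p.gene_symbol,
                "transcript_id": p.transcript_id,
                "length": p.length,
                "uu_count": p.uu_count,
                "max_window_uu": p.max_window_uu,
                "max_window_start": p.max_window_start,
                "motif_hits": ",".join(map(str, p.motif_hits)),
                "has_motif": p.has_motif,
            }
        )
    return pd.DataFrame(rows).set_index("gene_symbol")
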