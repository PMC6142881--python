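"""Microsatellite (SSR) scanning and alignment mismatch counting.

Finds maximal tandem repeats of 1–6 nt motifs in nucleotide sequences —
the computational counterpart of sizing SSR amplicons and reading repeat
arrays off sequenced PCR products — and counts per-sequence mismatches
against a majority-rule consensus in an existing alignment. Alignment
itself is out of scope: sequences arrive aligned.

Coordinates are 1-based inclusive throughout, the convention of
molecular-biology reports and of GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "VALID_SYMBOLS",
    "DEFAULT_MIN_REPEATS",
    "SequenceAlphabetError",
    "Sequence",
    "SsrHit",
    "read_fasta",
    "scan_ssrs",
    "consensus_mismatches",
    "band_size_check",
    "hits_to_tsv",
    "hits_to_gff3",
]

VALID_SYMBOLS = frozenset("ACGTN-")

#: Minimum repeat count per motif length for a run to be reported.
#: 1-mers need 8 and 2-mers 5; longer motifs use common scanner practice.
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 8, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


class SequenceAlphabetError(ValueError):
    """Sequence contains symbols outside A, C, G, T, N, '-'."""


@dataclass(frozen=True)
class Sequence:
    """A (possibly gapped) nucleotide sequence in uppercase canonical form."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases) - VALID_SYMBOLS
        if bad:
            raise SequenceAlphabetError(
                f"sequence {self.id!r} contains invalid symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SsrHit:
    """One maximal tandem repeat: `motif` repeated `repeat_count` times.

    `start`/`end` are 1-based inclusive; the covered substring is an exact
    tandem repetition, so end − start + 1 = len(motif) × repeat_count.
    """

    motif: str
    repeat_count: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read plain or aligned (gapped) FASTA into :class:`Sequence` records."""
    return [Sequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _is_primitive(motif: str) -> bool:
    """True when the motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[: d] * (n // d):
            return False
    return True


def scan_ssrs(
    seq: Sequence,
    min_unit: int = 1,
    max_unit: int = 6,
    min_repeats: Mapping[int, int] | None = None,
) -> list[SsrHit]:
    """Find maximal tandem repeats of short motifs.

    A run is reported when (i) its motif is a primitive unit of length in
    [min_unit, max_unit] over {A, C, G, T} (gaps and N never enter a hit),
    (ii) it cannot be extended by a full unit on either side, and (iii) its
    repeat count reaches the per-unit-length threshold. When two reported
    runs would overlap, the longer one wins (ties: earlier start, then
    shorter unit). Motifs are reported as found on the given strand; no
    rotational canonicalization is applied.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    s = seq.bases
    n = len(s)
    candidates: list[SsrHit] = []
    for unit in range(min_unit, max_unit + 1):
        threshold = min_repeats.get(unit)
        if threshold is None:
            continue
        for start in range(n - unit + 1):
            motif = s[start : start + unit]
            if set(motif) - set("ACGT") or not _is_primitive(motif):
                continue
            # left-maximality: the same unit must not precede the run
            if start >= unit and s[start - unit : start] == motif:
                continue
            count = 1
            while s[start + count * unit : start + (count + 1) * unit] == motif:
                count += 1
            if count >= threshold:
                candidates.append(
                    SsrHit(
                        motif=motif,
                        repeat_count=count,
                        start=start + 1,
                        end=start + count * unit,
                    )
                )
    # longest-run-wins overlap suppression
    candidates.sort(key=lambda h: (-h.length, h.start, len(h.motif)))
    kept: list[SsrHit] = []
    for hit in candidates:
        if all(hit.end < k.start or hit.start > k.end for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: (h.start, h.end))
    return kept


def consensus_mismatches(aligned: list[Sequence]) -> dict[str, int]:
    """Per-sequence mismatch counts against the majority-rule consensus.

    For each alignment column the consensus is the strictly most frequent
    base among A, C, G, T (gaps and N never form consensus; ties leave the
    column without a consensus and it is excluded from counting). A
    sequence scores a mismatch at every consensus column where it carries a
    different symbol — a gap at such a column is a mismatch.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 aligned sequences")
    length = len(aligned[0])
    if any(len(s) != length for s in aligned):
        raise ValueError("ragged alignment: sequences differ in length")
    counts = {s.id: 0 for s in aligned}
    for col in range(length):
        column = [s.bases[col] for s in aligned]
        tally: dict[str, int] = {}
        for base in column:
            if base in "ACGT":
                tally[base] = tally.get(base, 0) + 1
        if not tally:
            continue
        top = max(tally.values())
        winners = [b for b, c in tally.items() if c == top]
        if len(winners) != 1:
            continue  # tied column: no consensus, excluded
        consensus = winners[0]
        for s, base in zip(aligned, column):
            if base != consensus:
                counts[s.id] += 1
    return counts


def band_size_check(product_length: int, expected_range: tuple[int, int]) -> bool:
    """Whether an amplicon length falls inside the expected size range (inclusive)."""
    lo, hi = expected_range
    if product_length <= 0 or lo <= 0 or hi <= 0:
        raise ValueError("lengths must be positive")
    if lo > hi:
        raise ValueError(f"inverted expected range ({lo}, {hi})")
    return lo <= product_length <= hi


def hits_to_tsv(hits_by_seq: Mapping[str, Iterable[SsrHit]]) -> str:
    """Render hits as a TSV table (1-based inclusive coordinates)."""
    lines = ["sequence_id\tmotif\trepeat_count\tstart\tend\tlength"]
    for seq_id, hits in hits_by_seq.items():
        for h in hits:
            lines.append(
                f"{seq_id}\t{h.motif}\t{h.repeat_count}\t{h.start}\t{h.end}\t{h.length}"
            )
    return "\n".join(lines) + "\n"


def hits_to_gff3(hits_by_seq: Mapping[str, Iterable[SsrHit]]) -> str:
    """Render hits as GFF3 microsatellite features."""
    lines = ["##gff-version 3"]
    for seq_id, hits in hits_by_seq.items():
        for i, h in enumerate(hits, 1):
            attrs = f"ID={seq_id}.ssr{i};motif={h.motif};repeats={h.repeat_count}"
            lines.append(
                f"{seq_id}\tndfa\tmicrosatellite\t{h.start}\t{h.end}\t.\t+\t.\t{attrs}"
            )
    return "\n".join(lines) + "\n"
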