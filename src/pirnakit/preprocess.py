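"""Raw FASTQ to clean, size-selected small-RNA inserts.

The read layout produced by the library protocol is::

    [4 nt UMI] [insert] [4 nt UMI] [3' adapter ...]        (one 75-cycle read)

Processing: (1) truncate at the 3' adapter (exact match; leftmost full
internal occurrence, or an adapter prefix of >= ``min_overlap`` nt anchored
at the read's 3' end); reads without adapter evidence are excluded,
(2) strip the 4 random nucleotides from either end, (3) keep inserts of
18-40 nt inclusive.  Counts are conserved:
``input == kept + untrimmed + short_after_umi + size_filtered``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "DEFAULT_ADAPTER3",
    "CleanRead",
    "PreprocessReport",
    "trim_adapter",
    "strip_umis",
    "size_select",
    "preprocess_reads",
    "preprocess_fastq",
    "write_clean_fasta",
]

DEFAULT_ADAPTER3 = "AGATCGGAAGAGCACACGTCT"
UMI_LEN = 4


@dataclass(frozen=True)
class CleanRead:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PreprocessReport:
    """Per-stage discard accounting."""

    input: int = 0
    kept: int = 0
    untrimmed: int = 0
    short_after_umi: int = 0
    size_filtered: int = 0
    below_min: int = 0
    above_max: int = 0

    def conserved(self) -> bool:
        return self.input == self.kept + self.untrimmed + self.short_after_umi + self.size_filtered

    def to_rows(self) -> list[tuple[str, int]]:
        return [
            ("input", self.input),
            ("kept", self.kept),
            ("untrimmed", self.untrimmed),
            ("short_after_umi", self.short_after_umi),
            ("size_filtered", self.size_filtered),
            ("size_below_min", self.below_min),
            ("size_above_max", self.above_max),
        ]


def trim_adapter(
    sequence: str, adapter3: str = DEFAULT_ADAPTER3, min_overlap: int = 6
) -> tuple[str, bool]:
    """Truncate at the leftmost adapter occurrence.

    Considers (a) the full adapter anywhere in the read and (b) adapter
    prefixes of length >= ``min_overlap`` anchored at the read's 3' end;
    the leftmost match of either kind wins.  Returns ``(sequence, trimmed)``;
    when no match exists the sequence is returned unchanged with
    ``trimmed=False`` (such reads are excluded downstream).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    cut = sequence.find(adapter3)
    # anchored adapter prefix at the 3' end: longest suffix of the read that
    # equals a proper adapter prefix gives the leftmost anchored cut
    max_suffix = min(len(sequence), len(adapter3) - 1)
    for slen in range(max_suffix, min_overlap - 1, -1):
        i = len(sequence) - slen
        if sequence[i:] == adapter3[:slen]:
            cut = i if cut == -1 else min(cut, i)
            break
    if cut == -1:
        return sequence, False
    return sequence[:cut], True


def strip_umis(sequence: str, umi_len: int = UMI_LEN) -> str | None:
    """Remove ``umi_len`` random nucleotides from both ends; ``None`` when the
    remaining insert would be empty (read too short, discarded)."""
    if len(sequence) < 2 * umi_len + 1:
        return None
    return sequence[umi_len:-umi_len]


def size_select(
    reads: Iterable[CleanRead], min_len: int = 18, max_len: int = 40
) -> tuple[list[CleanRead], int, int]:
    """Keep reads with ``min_len <= length <= max_len`` (inclusive); returns
    ``(kept, n_below, n_above)``."""
    kept: list[CleanRead] = []
    below = above = 0
    for read in reads:
        if read.length < min_len:
            below += 1
        elif read.length > max_len:
            above += 1
        else:
            kept.append(read)
    return kept, below, above


def preprocess_reads(
    raw: Iterable[tuple[str, str]],
    adapter3: str = DEFAULT_ADAPTER3,
    min_overlap: int = 6,
    min_len: int = 18,
    max_len: int = 40,
    umi_len: int = UMI_LEN,
) -> tuple[list[CleanRead], PreprocessReport]:
    """Full trim -> UMI strip -> size selection over ``(id, sequence)`` pairs."""
    report = PreprocessReport()
    sized: list[CleanRead] = []
    for read_id, seq in raw:
        report.input += 1
        trimmed, ok = trim_adapter(seq, adapter3, min_overlap)
        if not ok:
            report.untrimmed += 1
            continue
        insert = strip_umis(trimmed, umi_len)
        if insert is None:
            report.short_after_umi += 1
            continue
        sized.append(CleanRead(read_id, insert))
    kept, below, above = size_select(sized, min_len, max_len)
    report.below_min, report.above_max = below, above
    report.size_filtered = below + above
    report.kept = len(kept)
    return kept, report


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    for title, seq, _qual in SeqIO.QualityIO.FastqGeneralIterator(str(path)):
        yield title.split()[0], seq.upper()


def preprocess_fastq(
    path: str | Path,
    adapter3: str = DEFAULT_ADAPTER3,
    min_overlap: int = 6,
    min_len: int = 18,
    max_len: int = 40,
    umi_len: int = UMI_LEN,
) -> tuple[list[CleanRead], PreprocessReport]:
    return preprocess_reads(
        _iter_fastq(path), adapter3, min_overlap, min_len, max_len, umi_len
    )


def write_clean_fasta(reads: Iterable[CleanRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.id}\n{read.sequence}\n")
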