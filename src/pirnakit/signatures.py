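"""piRNA signature statistics.

Size distributions, positional nucleotide-frequency matrices around the
ping-pong anchors, z-scores for the 1U (antisense) and 10A (sense) biases,
the phased-biogenesis downstream-uridine frequency, and the TE-mapping
fraction — all weighted by alignment weight and normalized per million
hairpin-RNA (endo-siRNA) reads where applicable.

Conventions fixed here:

* "piRNA-sized" means read length > 22 nt (upper bound is the global 18-40
  size selection);
* frequency windows span 11 positions with the anchor at index 5; positions
  upstream of the read's 5' end are taken from the alignment target on the
  read strand;
* z = (f[anchor] - mean of the 11 per-position frequencies) / population SD
  of those 11 values; an all-equal window yields z = 0 with a degeneracy
  flag.  Reports print U for T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import Alignment, classify_te_orientation
from .refmodel import ReferenceBundle

__all__ = [
    "PIRNA_MIN_LEN",
    "WINDOW_LEN",
    "ANCHOR_INDEX",
    "SizeDistribution",
    "NucleotideFrequencyMatrix",
    "PingPongSignature",
    "PhasingSignature",
    "size_distribution",
    "positional_frequencies",
    "pingpong_zscore",
    "downstream_u_frequency",
    "te_mapping_fraction",
]

PIRNA_MIN_LEN = 23  # "longer than 22 nucleotides"
WINDOW_LEN = 11
ANCHOR_INDEX = 5
_DISPLAY = {"A": "A", "C": "C", "G": "G", "T": "U"}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class SizeDistribution:
    """Weighted read counts per (length 18..40, sense/antisense) with
    per-million-hpRNA normalization (NaN columns when the denominator is 0)."""

    table: pd.DataFrame
    hpRNA_total: float
    normalized_available: bool


def size_distribution(
    te_alignments: Sequence[Alignment],
    hpRNA_total: float,
    min_len: int = 18,
    max_len: int = 40,
) -> SizeDistribution:
    lengths = range(min_len, max_len + 1)
    counts = {o: {L: 0.0 for L in lengths} for o in ("sense", "antisense")}
    seen: dict[tuple[str, str], float] = {}
    for aln in te_alignments:
        orientation = classify_te_orientation(aln)
        key = (aln.read_id, orientation)
        seen[key] = seen.get(key, 0.0) + aln.weight
        if min_len <= aln.length <= max_len:
            counts[orientation][aln.length] += aln.weight
    rows = []
    available = hpRNA_total > 0
    for L in lengths:
        for orientation in ("sense", "antisense"):
            c = counts[orientation][L]
            rows.append(
                {
                    "length": L,
                    "orientation": orientation,
                    "count": c,
                    "per_million_hpRNA": (c * 1e6 / hpRNA_total) if available else float("nan"),
                }
            )
    return SizeDistribution(pd.DataFrame(rows), hpRNA_total, available)


@dataclass
class NucleotideFrequencyMatrix:
    """11 x {A,C,G,U} frequency matrix around a ping-pong anchor."""

    frequencies: pd.DataFrame  # index 0..10, columns A C G U
    anchor: str  # antisense_pos1 | sense_pos10
    n_reads: float  # total weight used
    n_dropped: int  # windows exceeding target bounds
    empty: bool = False


def _window_sequence(
    aln: Alignment,
    read_seq: str,
    target_seq: str,
    anchor_read_pos: int,
    up: int = ANCHOR_INDEX,
    down: int = WINDOW_LEN - ANCHOR_INDEX - 1,
) -> str | None:
    """Window of ``up + 1 + down`` bases centred on 1-based read position
    ``anchor_read_pos``; positions outside the read come from the target on
    the read strand.  ``None`` when the window exceeds the target."""
    out = []
    for offset in range(-up, down + 1):
        rp = anchor_read_pos + offset  # 1-based read coordinate
        if 1 <= rp <= len(read_seq):
            out.append(read_seq[rp - 1])
            continue
        if aln.strand == "+":
            tp = aln.start + rp - 1
            if not (0 <= tp < len(target_seq)):
                return None
            out.append(target_seq[tp])
        else:
            tp = aln.start + aln.length - rp
            if not (0 <= tp < len(target_seq)):
                return None
            out.append(_COMPLEMENT[target_seq[tp]])
    return "".join(out)


def positional_frequencies(
    alignments: Sequence[Alignment],
    reads: Mapping[str, str],
    targets: Mapping[str, str],
    anchor: str,
) -> NucleotideFrequencyMatrix:
    """Weighted per-position base frequencies in the 11-nt window around the
    anchor (antisense 1st base or sense 10th base) of piRNA-sized reads.

    Only alignments of reads > 22 nt in the matching orientation enter;
    windows that would run past the target are dropped and counted.
    """
    if anchor not in ("antisense_pos1", "sense_pos10"):
        raise ValueError(f"unknown anchor {anchor!r}")
    orientation = "antisense" if anchor == "antisense_pos1" else "sense"
    anchor_pos = 1 if anchor == "antisense_pos1" else 10
    weights = np.zeros((WINDOW_LEN, 4))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    dropped = 0
    for aln in alignments:
        if aln.length < PIRNA_MIN_LEN:
            continue
        if classify_te_orientation(aln) != orientation:
            continue
        window = _window_sequence(
            aln, reads[aln.read_id], targets[aln.target_id], anchor_pos
        )
        if window is None:
            dropped += 1
            continue
        usable = True
        for i, base in enumerate(window):
            if base not in base_idx:
                usable = False
                break
        if not usable:
            dropped += 1
            continue
        for i, base in enumerate(window):
            weights[i, base_idx[base]] += aln.weight
        total += aln.weight
    if total == 0:
        freq = pd.DataFrame(
            np.full((WINDOW_LEN, 4), np.nan), columns=["A", "C", "G", "U"]
        )
        return NucleotideFrequencyMatrix(freq, anchor, 0.0, dropped, empty=True)
    freq = pd.DataFrame(weights / total, columns=["A", "C", "G", "U"])
    return NucleotideFrequencyMatrix(freq, anchor, total, dropped)


@dataclass
class PingPongSignature:
    z_1U_antisense: float
    z_10A_sense: float
    degenerate_1U: bool = False
    degenerate_10A: bool = False


def pingpong_zscore(
    matrix: NucleotideFrequencyMatrix | pd.DataFrame,
    base: str,
    anchor_index: int = ANCHOR_INDEX,
) -> tuple[float, bool]:
    """z-score of the anchor-position frequency of ``base`` against the mean
    and population SD of that base's frequencies over the 11-position window.

    Returns ``(z, degenerate)``; a zero-SD window yields ``z = 0`` with the
    degeneracy flag set.
    """
    freq = matrix.frequencies if isinstance(matrix, NucleotideFrequencyMatrix) else matrix
    if base not in ("A", "C", "G", "U"):
        raise ValueError(f"base must be one of A/C/G/U, got {base!r}")
    values = freq[base].to_numpy(dtype=float)
    if len(values) != WINDOW_LEN:
        raise ValueError(f"expected an {WINDOW_LEN}-position window")
    if np.isnan(values).any():
        return 0.0, True
    sd = float(np.std(values))  # population SD (divisor n)
    if sd == 0.0:
        return 0.0, True
    return float((values[anchor_index] - values.mean()) / sd), False


def pingpong_signature(
    te_alignments: Sequence[Alignment],
    reads: Mapping[str, str],
    te_sequences: Mapping[str, str],
) -> tuple[PingPongSignature, NucleotideFrequencyMatrix, NucleotideFrequencyMatrix]:
    """Convenience wrapper: both anchor matrices and both z-scores."""
    m_as = positional_frequencies(te_alignments, reads, te_sequences, "antisense_pos1")
    m_s = positional_frequencies(te_alignments, reads, te_sequences, "sense_pos10")
    z1u, d1 = pingpong_zscore(m_as, "U")
    z10a, d2 = pingpong_zscore(m_s, "A")
    return PingPongSignature(z1u, z10a, d1, d2), m_as, m_s


@dataclass
class PhasingSignature:
    """Weighted frequency of uridine immediately 3' of aligned reads."""

    frequencies: dict[str, float]  # category -> frequency (NaN when n == 0)
    n_used: dict[str, float]
    n_dropped: int


def downstream_u_frequency(
    genome_alignments: Sequence[Alignment],
    bundle: ReferenceBundle,
    te_read_ids: set[str] | frozenset[str] = frozenset(),
) -> PhasingSignature:
    """Frequency of the genomic base just downstream of each alignment being
    uridine on the read strand, for piRNA-sized reads (> 22 nt).

    Categories: ``TE`` (reads that also map to a TE consensus), ``non_TE``
    and ``all``.  Alignments abutting a contig edge are dropped and counted.
    """
    totals = {"TE": 0.0, "non_TE": 0.0, "all": 0.0}
    hits = {"TE": 0.0, "non_TE": 0.0, "all": 0.0}
    dropped = 0
    for aln in genome_alignments:
        if aln.length < PIRNA_MIN_LEN:
            continue
        contig_seq = bundle.genome.contigs[aln.target_id]
        if aln.strand == "+":
            pos = aln.end
            if pos >= len(contig_seq):
                dropped += 1
                continue
            is_u = contig_seq[pos] == "T"
        else:
            pos = aln.start - 1
            if pos < 0:
                dropped += 1
                continue
            is_u = _COMPLEMENT[contig_seq[pos]] == "T"
        category = "TE" if aln.read_id in te_read_ids else "non_TE"
        for cat in (category, "all"):
            totals[cat] += aln.weight
            if is_u:
                hits[cat] += aln.weight
    freqs = {
        cat: (hits[cat] / totals[cat]) if totals[cat] > 0 else float("nan")
        for cat in totals
    }
    return PhasingSignature(freqs, totals, dropped)


def te_mapping_fraction(
    clean_reads: Mapping[str, str],
    te_alignments: Sequence[Alignment],
) -> tuple[float, bool]:
    """Fraction of piRNA-sized reads (> 22 nt) with at least one TE alignment.

    Returns ``(fraction, defined)``; ``defined`` is False (and the fraction 0)
    when there are no piRNA-sized reads.
    """
    sized = {rid for rid, seq in clean_reads.items() if len(seq) >= PIRNA_MIN_LEN}
    if not sized:
        return 0.0, False
    mapped = {a.read_id for a in te_alignments if a.read_id in sized}
    return len(mapped) / len(sized), True
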