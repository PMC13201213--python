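"""Exhaustive k-mismatch short-read placement with all-best-strata reporting.

Re-specifies the behaviour of a Bowtie1-style ``--all --best --strata`` run
as an internal operation at toy scale: for each read the mapper finds the
minimum achievable mismatch count m* over all offsets of both strands of all
targets (indels are not modelled) and reports exactly the placements tied at
m*.  Correctness is pinned by an independent brute-force scanner in the test
suite; the implementation below uses a pigeonhole seed index so that tens of
thousands of reads map in seconds.

``N`` never matches any base, including another ``N``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .refmodel import INFRASTRUCTURAL_CLASSES, ReferenceBundle, revcomp

__all__ = [
    "Alignment",
    "AlignmentPolicy",
    "TargetIndex",
    "map_reads",
    "annotate_infrastructural",
    "unique_genome_mappers",
    "classify_te_orientation",
    "alignments_to_frame",
]

# read bases 0..3; read N -> 4, target N -> 5, inter-target sentinel -> 6.
# 4 != 5 so N never matches, not even N vs N.
_READ_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_TARGET_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 5}


@dataclass(frozen=True)
class Alignment:
    """A placement of a read on a target.

    ``start`` is 0-based on the target's stored (plus) strand; the read
    occupies ``[start, start + length)``.  ``strand == '-'`` means the read
    sequence matches the reverse complement of that window.
    """

    read_id: str
    target_id: str
    target_class: str  # infrastructural | genome | TE
    start: int
    strand: str
    mismatches: int
    length: int
    weight: float = 1.0

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class AlignmentPolicy:
    max_mismatches: int = 1
    report: str = "all_best_strata"  # or "all"

    def __post_init__(self) -> None:
        if self.max_mismatches not in (0, 1, 2, 3):
            raise ValueError("max_mismatches must be in 0..3")
        if self.report not in ("all_best_strata", "all"):
            raise ValueError("report must be 'all_best_strata' or 'all'")


def _encode(seq: str, table: Mapping[str, int]) -> np.ndarray:
    return np.array([table[c] for c in seq], dtype=np.uint8)


class TargetIndex:
    """Concatenated, sentinel-separated target array plus a k-mer seed index.

    Built once per (target set, seed length); reused across reads.
    """

    def __init__(self, targets: Mapping[str, str], seed_len: int):
        if not targets:
            raise ValueError("targets must be nonempty")
        self.seed_len = seed_len
        self.names: list[str] = list(targets)
        gap = 48  # > max read length, so no window spans two targets silently
        parts: list[np.ndarray] = []
        starts: list[int] = []
        ends: list[int] = []
        offset = 0
        cat_parts: list[str] = []
        for name in self.names:
            seq = targets[name]
            starts.append(offset)
            ends.append(offset + len(seq))
            parts.append(_encode(seq, _TARGET_CODE))
            cat_parts.append(seq)
            offset += len(seq)
            parts.append(np.full(gap, 6, dtype=np.uint8))
            cat_parts.append("#" * gap)
            offset += gap
        self.array = np.concatenate(parts)
        self.starts = np.array(starts)
        self.ends = np.array(ends)
        self._cat = "".join(cat_parts)
        # seed index: k-mer string -> sorted positions in the concatenated array
        index: dict[str, list[int]] = defaultdict(list)
        k = seed_len
        for t_idx, name in enumerate(self.names):
            seq = targets[name]
            base = self.starts[t_idx]
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                index[kmer].append(base + i)
        self.index: dict[str, np.ndarray] = {
            kmer: np.array(pos, dtype=np.int64) for kmer, pos in index.items()
        }

    def locate(self, pos: int) -> tuple[str, int]:
        """Map a concatenated-array coordinate to (target name, local position)."""
        t_idx = int(np.searchsorted(self.ends, pos, side="right"))
        return self.names[t_idx], pos - int(self.starts[t_idx])

    def in_one_target(self, start: int, length: int) -> bool:
        t_idx = int(np.searchsorted(self.ends, start, side="right"))
        if t_idx >= len(self.names):
            return False
        return self.starts[t_idx] <= start and start + length <= self.ends[t_idx]

    def exact_occurrences(self, seq: str) -> list[int]:
        """All occurrences of ``seq`` (no N) in the concatenated targets."""
        if "N" in seq:
            return []
        out = []
        i = self._cat.find(seq)
        while i != -1:
            out.append(i)
            i = self._cat.find(seq, i + 1)
        return out


def _seed_len_for(max_mismatches: int) -> int:
    # pigeonhole: m+1 disjoint seeds must fit in the shortest read (18 nt)
    return {0: 12, 1: 9, 2: 6, 3: 4}[max_mismatches]


def _candidate_hits(
    index: TargetIndex, seq: str, max_mm: int
) -> tuple[np.ndarray, np.ndarray]:
    """Return (starts, mismatch counts) of all placements of ``seq`` on the
    forward concatenated array with mismatches <= max_mm."""
    L = len(seq)
    arr = index.array
    if L > len(arr):
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    candidates: set[int]
    if max_mm == 0:
        candidates = set(index.exact_occurrences(seq))
    else:
        k = index.seed_len
        n_seeds = max_mm + 1
        stride = L // n_seeds
        if stride < k:
            # read too short for disjoint pigeonhole seeds: exhaustive scan
            read_arr = _encode(seq, _READ_CODE)
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            mm_all = (windows != read_arr).sum(axis=1)
            cand = np.nonzero(mm_all <= max_mm)[0].astype(np.int64)
            mm = mm_all[cand]
            ok = np.array(
                [index.in_one_target(int(p), L) for p in cand], dtype=bool
            ) if cand.size else np.empty(0, dtype=bool)
            return cand[ok], mm[ok].astype(np.int64)
        candidates = set(index.exact_occurrences(seq))
        offsets = [i * stride for i in range(n_seeds)]
        for off in offsets:
            kmer = seq[off : off + k]
            hits = index.index.get(kmer)
            if hits is None:
                continue
            for p in hits:
                candidates.add(int(p) - off)
    if not candidates:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    cand = np.array(sorted(candidates), dtype=np.int64)
    cand = cand[(cand >= 0) & (cand + L <= len(arr))]
    if cand.size == 0:
        return cand, cand
    read_arr = _encode(seq, _READ_CODE)
    windows = arr[cand[:, None] + np.arange(L)]
    mm = (windows != read_arr).sum(axis=1)
    keep = mm <= max_mm
    cand, mm = cand[keep], mm[keep]
    # drop windows spanning a sentinel gap / target boundary
    if cand.size:
        ok = np.array([index.in_one_target(int(p), L) for p in cand])
        cand, mm = cand[ok], mm[ok]
    return cand, mm.astype(np.int64)


def map_reads(
    reads: Mapping[str, str] | Iterable[tuple[str, str]],
    targets: Mapping[str, str],
    policy: AlignmentPolicy,
    target_class: str = "genome",
    index: TargetIndex | None = None,
) -> list[Alignment]:
    """Map each read against both strands of every target.

    Under ``all_best_strata`` exactly the placements with the per-read minimal
    mismatch count are reported, each carrying weight ``1/n`` over the ``n``
    reported placements; under ``all`` every placement with mismatches <=
    ``policy.max_mismatches`` is reported with the same ``1/n`` weighting over
    the reported set.  Reads with no placement are simply absent from the
    output (unaligned is a status, not an error).
    """
    if not isinstance(reads, Mapping):
        reads = dict(reads)
    if index is None:
        index = TargetIndex(targets, _seed_len_for(policy.max_mismatches))
    out: list[Alignment] = []
    for read_id, seq in reads.items():
        L = len(seq)
        placements: list[tuple[int, str, int]] = []  # (cat start, strand, mm)
        fwd_pos, fwd_mm = _candidate_hits(index, seq, policy.max_mismatches)
        placements += [(int(p), "+", int(m)) for p, m in zip(fwd_pos, fwd_mm)]
        rc = revcomp(seq)
        rev_pos, rev_mm = _candidate_hits(index, rc, policy.max_mismatches)
        placements += [(int(p), "-", int(m)) for p, m in zip(rev_pos, rev_mm)]
        if not placements:
            continue
        if policy.report == "all_best_strata":
            best = min(m for _, _, m in placements)
            placements = [p for p in placements if p[2] == best]
        w = 1.0 / len(placements)
        for pos, strand, mm in placements:
            name, local = index.locate(pos)
            out.append(
                Alignment(read_id, name, target_class, local, strand, mm, L, w)
            )
    return out


def annotate_infrastructural(
    reads: Mapping[str, str],
    bundle: ReferenceBundle,
    max_mismatches: int = 1,
) -> tuple[dict[str, str], dict[str, float]]:
    """Flag reads matching infrastructural references (<= 1 mismatch).

    Returns ``(per-read class flag, per-class weighted totals)``.  A read
    hitting references of several classes is flagged with the class of its
    best-stratum hits; ties split the read's weight across classes.  The
    ``hpRNA`` total is the normalization denominator used downstream.
    Annotation does not remove reads from genome/TE mapping.
    """
    infra = bundle.infrastructural_sequences()
    totals: dict[str, float] = {cls: 0.0 for cls in INFRASTRUCTURAL_CLASSES}
    flags: dict[str, str] = {}
    if not infra:
        return flags, totals
    targets = {name: seq for name, (_cls, seq) in infra.items()}
    cls_of = {name: cls for name, (cls, _seq) in infra.items()}
    policy = AlignmentPolicy(max_mismatches=max_mismatches, report="all_best_strata")
    alignments = map_reads(reads, targets, policy, target_class="infrastructural")
    by_read: dict[str, list[Alignment]] = defaultdict(list)
    for aln in alignments:
        by_read[aln.read_id].append(aln)
    for read_id, alns in by_read.items():
        classes = sorted({cls_of[a.target_id] for a in alns})
        flags[read_id] = classes[0] if len(classes) == 1 else "+".join(classes)
        for cls in classes:
            totals[cls] += 1.0 / len(classes)
    return flags, totals


def unique_genome_mappers(alignments: Sequence[Alignment]) -> list[Alignment]:
    """Alignments of reads whose best-stratum genome placement set has size 1."""
    by_read: dict[str, list[Alignment]] = defaultdict(list)
    for aln in alignments:
        by_read[aln.read_id].append(aln)
    return [alns[0] for alns in by_read.values() if len(alns) == 1]


def classify_te_orientation(alignment: Alignment) -> str:
    """``sense`` when the read lies on the consensus (mRNA-like) strand."""
    return "sense" if alignment.strand == "+" else "antisense"


def alignments_to_frame(alignments: Sequence[Alignment]):
    """Alignment table as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "target": a.target_id,
                "class": a.target_class,
                "start": a.start,
                "strand": a.strand,
                "mismatches": a.mismatches,
                "length": a.length,
                "weight": a.weight,
            }
            for a in alignments
        ],
        columns=[
            "read_id",
            "target",
            "class",
            "start",
            "strand",
            "mismatches",
            "length",
            "weight",
        ],
    )
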