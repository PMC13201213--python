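"""Genome-tile quantification of uniquely mapping piRNA-sized reads.

Tiles partition each contig into fixed-width windows (default 1,000 nt).
Reads are excluded when their alignment overlaps the exclusion mask — the
100-nt-padded neighbourhoods of tRNA/snRNA/snoRNA features plus the
aubergine locus — and each surviving unique mapper is assigned to the tile
containing its 5' end.  Tile counts aggregate to piRNA-cluster abundances
(tiles whose midpoint lies inside the cluster) and can be expressed relative
to a reference library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .align import Alignment
from .refmodel import FeatureAnnotation, ReferenceGenome
from .signatures import PIRNA_MIN_LEN

__all__ = [
    "ExclusionMask",
    "TileTable",
    "build_mask",
    "tile_counts",
    "cluster_abundance",
    "relative_to_reference",
]

MASKED_CLASSES = ("tRNA", "snRNA", "snoRNA")


@dataclass
class ExclusionMask:
    """Merged, sorted intervals per contig (0-based half-open)."""

    intervals: dict[str, list[tuple[int, int]]]
    pad: int

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        for s, e in self.intervals.get(contig, ()):  # few intervals at toy scale
            if s < end and start < e:
                return True
        return False


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_mask(
    annotation: FeatureAnnotation,
    genome: ReferenceGenome,
    pad: int = 100,
) -> ExclusionMask:
    """tRNA/snRNA/snoRNA intervals padded ``pad`` nt both sides (clipped to
    contig bounds), plus the aubergine locus unpadded; merged and sorted."""
    raw: dict[str, list[tuple[int, int]]] = {}
    for rec in annotation.records:
        if rec.feature_class in MASKED_CLASSES:
            s = max(0, rec.start - pad)
            e = min(genome.length(rec.contig), rec.end + pad)
        elif rec.feature_class == "aub_locus":
            s, e = rec.start, rec.end
        else:
            continue
        raw.setdefault(rec.contig, []).append((s, e))
    return ExclusionMask({c: _merge(iv) for c, iv in raw.items()}, pad)


@dataclass
class TileTable:
    """Per-tile weighted unique-mapper counts with per-million-hpRNA values."""

    table: pd.DataFrame  # contig, start, end, count, per_million_hpRNA
    tile_width: int
    hpRNA_total: float
    n_masked: int  # alignments removed by the exclusion mask

    def value(self, contig: str, start: int) -> float:
        t = self.table
        row = t[(t["contig"] == contig) & (t["start"] == start)]
        return float(row["per_million_hpRNA"].iloc[0]) if len(row) else 0.0


def tile_counts(
    unique_alignments: Sequence[Alignment],
    mask: ExclusionMask,
    genome: ReferenceGenome,
    hpRNA_total: float,
    tile_width: int = 1_000,
    min_read_len: int = PIRNA_MIN_LEN,
) -> TileTable:
    """Count masked, genome-unique piRNA-sized reads per tile.

    Any overlap (>= 1 nt) with the mask removes a read; survivors are
    assigned to the tile containing their 5' end.
    """
    if tile_width <= 0:
        raise ValueError("tile_width must be positive")
    counts: dict[tuple[str, int], float] = {}
    n_masked = 0
    for aln in unique_alignments:
        if aln.length < min_read_len:
            continue
        if mask.overlaps(aln.target_id, aln.start, aln.end):
            n_masked += 1
            continue
        five_prime = aln.start if aln.strand == "+" else aln.end - 1
        tile_start = (five_prime // tile_width) * tile_width
        counts[(aln.target_id, tile_start)] = (
            counts.get((aln.target_id, tile_start), 0.0) + aln.weight
        )
    rows = []
    norm = hpRNA_total > 0
    for contig in genome.contigs:
        clen = genome.length(contig)
        for start in range(0, clen, tile_width):
            end = min(start + tile_width, clen)
            c = counts.get((contig, start), 0.0)
            rows.append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "count": c,
                    "per_million_hpRNA": (c * 1e6 / hpRNA_total) if norm else float("nan"),
                }
            )
    return TileTable(pd.DataFrame(rows), tile_width, hpRNA_total, n_masked)


def cluster_abundance(
    tile_table: TileTable, annotation: FeatureAnnotation
) -> pd.DataFrame:
    """Per-cluster sums of normalized tile values over tiles whose midpoint
    lies inside the cluster; clusters catching no tile get 0 and a flag."""
    t = tile_table.table
    mid = (t["start"] + t["end"]) / 2.0
    rows = []
    for rec in annotation.by_class("piRNA_cluster"):
        inside = (t["contig"] == rec.contig) & (mid >= rec.start) & (mid < rec.end)
        n_tiles = int(inside.sum())
        value = float(t.loc[inside, "per_million_hpRNA"].sum()) if n_tiles else 0.0
        rows.append(
            {
                "cluster": rec.name,
                "contig": rec.contig,
                "start": rec.start,
                "end": rec.end,
                "n_tiles": n_tiles,
                "abundance": value,
                "no_tiles": n_tiles == 0,
            }
        )
    return pd.DataFrame(rows)


def relative_to_reference(
    sample_abundances: pd.DataFrame, reference_abundances: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster sample/reference abundance ratios.

    Requires identical cluster sets; a zero reference abundance flags the
    ratio as undefined (NaN).
    """
    s = sample_abundances.set_index("cluster")["abundance"]
    r = reference_abundances.set_index("cluster")["abundance"]
    if set(s.index) != set(r.index):
        raise ValueError("sample and reference cluster sets differ")
    r = r.reindex(s.index)
    rows = []
    for cluster in s.index:
        ref = float(r[cluster])
        rows.append(
            {
                "cluster": cluster,
                "sample": float(s[cluster]),
                "reference": ref,
                "ratio": (float(s[cluster]) / ref) if ref > 0 else float("nan"),
                "undefined": ref <= 0,
            }
        )
    return pd.DataFrame(rows)
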