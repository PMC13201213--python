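"""Synthetic small-RNA library generator with ground truth.

Builds a toy reference (genome contigs, feature annotation, TE consensus
library) and emits raw FASTQ libraries carrying the statistical structure
piRNA analysis detects:

* piRNA-sized reads (23-32 nt) from TE fragments embedded in piRNA clusters,
  predominantly antisense to the TE consensus;
* a 1U bias: primary piRNA 5' ends fall on read-strand uridines with the
  configured probability;
* ping-pong pairs: with the configured probability an antisense piRNA gets a
  sense partner whose 5' end sits 10 nt into the antisense read, so the
  partner's 10th base is the complement of its mate's 1st (10A when the mate
  starts with U);
* phasing: the genomic base immediately 3' of a piRNA is uridine (on the
  read strand) with the configured probability, realized by joint rejection
  sampling of 5' position and length;
* 2'-O-methylated 3' ends on piRNAs/siRNAs, so that periodate oxidation
  retains them while depleting unmethylated miRNA/degradation background;
* hairpin-derived 21-nt siRNAs (the normalization denominator), 22-nt
  miRNAs, and 18-40-nt degradation fragments as background classes.

The genomic TE copies are carved from disjoint consensus segments so that
simulated piRNAs are genome-unique mappers, mirroring the uniqueness filter
the tile analysis applies to real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_ADAPTER3
from .refmodel import (
    FeatureAnnotation,
    FeatureRecord,
    ReferenceBundle,
    ReferenceGenome,
    TEConsensusLibrary,
    TEFragment,
    revcomp,
)

__all__ = [
    "SimConfig",
    "RefParams",
    "SimulatedRead",
    "SimulationError",
    "build_toy_reference",
    "simulate_small_rna_population",
    "apply_oxidation",
    "render_fastq",
    "write_truth",
    "read_truth",
    "simulate_te_counts",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one simulated small-RNA library."""

    seed: int
    n_reads: int = 10_000
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "piRNA": 0.55,
            "hpRNA_siRNA": 0.15,
            "miRNA": 0.20,
            "degradation": 0.10,
        }
    )
    piRNA_len_range: tuple[int, int] = (23, 32)
    piRNA_antisense_fraction: float = 0.8
    u1_bias: float = 0.9
    pingpong_fraction: float = 0.5
    phasing_downstream_u: float = 0.5
    methylation_prob: dict[str, float] = field(
        default_factory=lambda: {
            "piRNA": 1.0,
            "hpRNA_siRNA": 1.0,
            "miRNA": 0.0,
            "degradation": 0.0,
        }
    )
    oxidation_survival_unmethylated: float = 0.02
    adapter3: str = DEFAULT_ADAPTER3
    umi_len: int = 4
    read_length: int = 75

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise SimulationError("class_fractions must sum to 1")
        probs = [
            self.piRNA_antisense_fraction,
            self.u1_bias,
            self.pingpong_fraction,
            self.phasing_downstream_u,
            self.oxidation_survival_unmethylated,
            *self.class_fractions.values(),
            *self.methylation_prob.values(),
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise SimulationError("all probabilities must lie in [0, 1]")
        lo, hi = self.piRNA_len_range
        if not (0 < lo <= hi):
            raise SimulationError("bad piRNA_len_range")


@dataclass(frozen=True)
class RefParams:
    """Shape of the toy reference."""

    contig_lengths: tuple[int, ...] = (50_000, 50_000, 50_000)
    n_te: int = 4
    te_length: int = 2_000
    n_clusters: int = 2
    cluster_length: int = 8_000
    fragments_per_cluster: int = 3
    cluster_fragment_length: int = 600
    cluster_antisense_prob: float = 0.8
    n_dispersed_te: int = 4
    dispersed_te_length: int = 500
    n_rrna: int = 2
    rrna_length: int = 300
    n_snrna: int = 2
    snrna_length: int = 150
    n_snorna: int = 2
    snorna_length: int = 120
    n_mirna: int = 4
    mirna_length: int = 70
    n_trna: int = 4
    trna_length: int = 75
    hprna_length: int = 400
    aub_length: int = 2_000


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    true_class: str
    source: str
    contig: str
    start: int
    end: int
    strand: str
    methylated: bool
    partner_id: str | None = None
    te_name: str = ""
    orientation: str = ""  # sense/antisense relative to the TE consensus
    is_partner: bool = False  # emitted as the sense mate of a ping-pong pair


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _te_segment_allocator(te_library: dict[str, str]):
    """Yield disjoint (te_name, start, end) segments walking the library."""
    items = list(te_library.items())
    idx, offset = 0, 0

    def take(length: int) -> tuple[str, int, int]:
        nonlocal idx, offset
        while idx < len(items) and offset + length > len(items[idx][1]):
            idx += 1
            offset = 0
        if idx >= len(items):
            raise SimulationError(
                "TE consensus library too small for the requested genomic copies"
            )
        name = items[idx][0]
        seg = (name, offset, offset + length)
        offset += length
        return seg

    return take


def build_toy_reference(seed: int, params: RefParams | None = None) -> ReferenceBundle:
    """Deterministically build the toy genome, annotation and TE library.

    Every feature class appears at least once; piRNA clusters embed TE
    consensus fragments, predominantly antisense.  Byte-identical for a
    fixed seed.
    """
    params = params or RefParams()
    if params.n_clusters < 1:
        raise SimulationError("at least one piRNA cluster is required")
    rng = np.random.default_rng([seed, 0])

    te_library = {
        f"TE{i + 1}": _random_seq(rng, params.te_length) for i in range(params.n_te)
    }
    take_segment = _te_segment_allocator(te_library)

    contigs = {
        f"chr{i + 1}": list(_random_seq(rng, L))
        for i, L in enumerate(params.contig_lengths)
    }
    contig_names = list(contigs)
    cursors = {c: 500 for c in contig_names}
    records: list[FeatureRecord] = []
    fragments: list[TEFragment] = []

    def place(contig: str, length: int) -> int:
        gap = int(rng.integers(200, 800))
        start = cursors[contig] + gap
        end = start + length
        if end + 500 > len(contigs[contig]):
            raise SimulationError(
                f"features exceed contig {contig} length; enlarge contigs or "
                "reduce feature counts"
            )
        cursors[contig] = end
        return start

    def rand_strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    # piRNA clusters with embedded TE fragments
    for ci in range(params.n_clusters):
        contig = contig_names[ci % len(contig_names)]
        cstart = place(contig, params.cluster_length)
        cname = f"cluster{ci + 1}"
        records.append(
            FeatureRecord(contig, cstart, cstart + params.cluster_length, "+", "piRNA_cluster", cname)
        )
        inner = cstart + 100
        for _fi in range(params.fragments_per_cluster):
            inner += int(rng.integers(50, 300))
            fstart = inner
            fend = fstart + params.cluster_fragment_length
            if fend > cstart + params.cluster_length - 100:
                raise SimulationError("cluster too short for requested fragments")
            te_name, ts, te_end = take_segment(params.cluster_fragment_length)
            strand = "-" if rng.random() < params.cluster_antisense_prob else "+"
            seg = te_library[te_name][ts:te_end]
            embedded = seg if strand == "+" else revcomp(seg)
            contigs[contig][fstart:fend] = list(embedded)
            fragments.append(
                TEFragment(contig, fstart, fend, strand, te_name, ts, te_end, cname)
            )
            inner = fend

    # dispersed TE insertions (annotated as TE_insertion)
    for di in range(params.n_dispersed_te):
        contig = contig_names[di % len(contig_names)]
        start = place(contig, params.dispersed_te_length)
        te_name, ts, te_end = take_segment(params.dispersed_te_length)
        strand = rand_strand()
        seg = te_library[te_name][ts:te_end]
        embedded = seg if strand == "+" else revcomp(seg)
        contigs[contig][start : start + params.dispersed_te_length] = list(embedded)
        records.append(
            FeatureRecord(
                contig, start, start + params.dispersed_te_length, strand,
                "TE_insertion", f"{te_name}_ins{di + 1}",
            )
        )
        fragments.append(
            TEFragment(contig, start, start + params.dispersed_te_length, strand,
                       te_name, ts, te_end, "")
        )

    # infrastructural and other single-copy features over the random background
    simple = (
        [("rRNA", params.rrna_length)] * params.n_rrna
        + [("snRNA", params.snrna_length)] * params.n_snrna
        + [("snoRNA", params.snorna_length)] * params.n_snorna
        + [("miRNA", params.mirna_length)] * params.n_mirna
        + [("tRNA", params.trna_length)] * params.n_trna
        + [("hpRNA", params.hprna_length)]
        + [("aub_locus", params.aub_length)]
    )
    counters: dict[str, int] = {}
    for i, (cls, length) in enumerate(simple):
        contig = contig_names[i % len(contig_names)]
        start = place(contig, length)
        counters[cls] = counters.get(cls, 0) + 1
        records.append(
            FeatureRecord(contig, start, start + length, rand_strand(), cls,
                          f"{cls}{counters[cls]}")
        )

    genome = ReferenceGenome({c: "".join(seq) for c, seq in contigs.items()})
    annotation = FeatureAnnotation(records)
    annotation.validate_against(genome)
    return ReferenceBundle(genome, annotation, TEConsensusLibrary(te_library), fragments)


# ---------------------------------------------------------------------------
# read population


def _read_strand_base(genome_seq: str, g5: int, strand: str) -> str:
    return genome_seq[g5] if strand == "+" else _COMPLEMENT[genome_seq[g5]]


class _FragmentSampler:
    """Candidate 5'-end positions per (fragment, read strand), split by
    whether the read-strand base is T; margins guarantee that any piRNA
    length, its downstream base, and a full ping-pong partner fit inside
    the fragment."""

    def __init__(self, bundle: ReferenceBundle, len_range: tuple[int, int]):
        lo, hi = len_range
        self.lo, self.hi = lo, hi
        self.entries: list[dict] = []
        for frag in bundle.te_fragments:
            if not frag.in_cluster:
                continue  # dispersed copies are not piRNA sources
            seq = bundle.genome.contigs[frag.contig]
            for read_strand in ("+", "-"):
                if read_strand == "+":
                    g5_lo = frag.start + hi  # room for a '-'-strand partner
                    g5_hi = frag.end - hi - 1
                else:
                    g5_lo = frag.start + hi
                    g5_hi = frag.end - hi - 1
                if g5_hi <= g5_lo:
                    continue
                positions = np.arange(g5_lo, g5_hi)
                bases = np.array(
                    [_read_strand_base(seq, int(p), read_strand) for p in positions]
                )
                self.entries.append(
                    {
                        "fragment": frag,
                        "read_strand": read_strand,
                        "pos_t": positions[bases == "T"],
                        "pos_other": positions[bases != "T"],
                    }
                )
        if not self.entries:
            raise SimulationError(
                "reference has no usable cluster TE fragments; regenerate the "
                "reference with longer fragments or clusters"
            )

    def entry_for(self, rng: np.random.Generator, orientation: str) -> dict:
        # orientation is relative to the TE consensus: antisense reads run
        # opposite to the genome strand that carries the TE sense sequence
        matching = [
            e
            for e in self.entries
            if (e["read_strand"] != e["fragment"].strand)
            == (orientation == "antisense")
        ]
        if not matching:
            matching = self.entries
        return matching[int(rng.integers(0, len(matching)))]


def _phased_length(
    rng: np.random.Generator,
    genome_seq: str,
    g5: int,
    strand: str,
    len_range: tuple[int, int],
    want_downstream_t: bool,
) -> int | None:
    """A read length whose downstream genomic base (read strand) is/is not T."""
    lo, hi = len_range
    feasible = []
    for L in range(lo, hi + 1):
        down = g5 + L if strand == "+" else g5 - L
        base = _read_strand_base(genome_seq, down, strand)
        if (base == "T") == want_downstream_t:
            feasible.append(L)
    if not feasible:
        return None
    return int(feasible[int(rng.integers(0, len(feasible)))])


def _extract(genome_seq: str, g5: int, L: int, strand: str) -> tuple[str, int, int]:
    if strand == "+":
        start, end = g5, g5 + L
        return genome_seq[start:end], start, end
    start, end = g5 - L + 1, g5 + 1
    return revcomp(genome_seq[start:end]), start, end


def simulate_small_rna_population(
    bundle: ReferenceBundle, config: SimConfig
) -> list[SimulatedRead]:
    """Draw ``n_reads`` primary reads (plus ping-pong partners) with ground truth.

    Primary piRNAs get the 1U bias on their own 5' base and phased 3' ends;
    partners inherit exact 10-nt 5'-overlap geometry, with their own phased
    3' ends.  Background classes: 21-nt hairpin siRNAs, 22-nt miRNAs,
    18-40-nt degradation fragments.
    """
    rng = np.random.default_rng([config.seed, 1])
    sampler = _FragmentSampler(bundle, config.piRNA_len_range)
    classes = list(config.class_fractions)
    probs = np.array([config.class_fractions[c] for c in classes])
    mirnas = bundle.annotation.by_class("miRNA")
    hprnas = bundle.annotation.by_class("hpRNA")
    contig_names = list(bundle.genome.contigs)
    reads: list[SimulatedRead] = []
    counter = 0
    fallback_u1 = fallback_phase = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"sim{counter:07d}"

    def methylated(cls: str) -> bool:
        return bool(rng.random() < config.methylation_prob.get(cls, 0.0))

    draw = rng.choice(len(classes), size=config.n_reads, p=probs)
    for k in range(config.n_reads):
        cls = classes[int(draw[k])]
        if cls == "piRNA":
            orientation = (
                "antisense"
                if rng.random() < config.piRNA_antisense_fraction
                else "sense"
            )
            entry = sampler.entry_for(rng, orientation)
            frag: TEFragment = entry["fragment"]
            seq = bundle.genome.contigs[frag.contig]
            strand = entry["read_strand"]
            want_u1 = rng.random() < config.u1_bias
            pool = entry["pos_t"] if want_u1 else entry["pos_other"]
            if pool.size == 0:
                pool = entry["pos_other"] if want_u1 else entry["pos_t"]
                fallback_u1 += 1
            want_phase = rng.random() < config.phasing_downstream_u
            L = None
            g5 = int(pool[int(rng.integers(0, pool.size))])
            for _try in range(30):
                L = _phased_length(
                    rng, seq, g5, strand, config.piRNA_len_range, want_phase
                )
                if L is not None:
                    break
                g5 = int(pool[int(rng.integers(0, pool.size))])
            if L is None:
                fallback_phase += 1
                lo, hi = config.piRNA_len_range
                L = int(rng.integers(lo, hi + 1))
            insert, start, end = _extract(seq, g5, L, strand)
            rid = next_id()
            read = SimulatedRead(
                rid, insert, "piRNA", frag.in_cluster, frag.contig, start, end,
                strand, methylated("piRNA"), None, frag.te_name, orientation,
            )
            reads.append(read)
            if orientation == "antisense" and rng.random() < config.pingpong_fraction:
                p_strand = "-" if strand == "+" else "+"
                g5p = g5 + 9 if strand == "+" else g5 - 9
                want_phase_p = rng.random() < config.phasing_downstream_u
                Lp = _phased_length(
                    rng, seq, g5p, p_strand, config.piRNA_len_range, want_phase_p
                )
                if Lp is None:
                    # partner 5' end is fixed by ping-pong geometry, so no
                    # positional resampling is possible; fall back to a random
                    # length (slightly dilutes the phased signal, documented)
                    lo, hi = config.piRNA_len_range
                    Lp = int(rng.integers(lo, hi + 1))
                p_insert, p_start, p_end = _extract(seq, g5p, Lp, p_strand)
                pid = next_id()
                partner = SimulatedRead(
                    pid, p_insert, "piRNA", frag.in_cluster, frag.contig,
                    p_start, p_end, p_strand, methylated("piRNA"), rid,
                    frag.te_name, "sense", is_partner=True,
                )
                read.partner_id = pid
                reads.append(partner)
        elif cls == "hpRNA_siRNA":
            rec = hprnas[int(rng.integers(0, len(hprnas)))]
            L = 21
            pos = int(rng.integers(rec.start, rec.end - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = bundle.genome.fetch(rec.contig, pos, pos + L, strand)
            reads.append(
                SimulatedRead(next_id(), seq, cls, rec.name, rec.contig, pos,
                              pos + L, strand, methylated(cls))
            )
        elif cls == "miRNA":
            rec = mirnas[int(rng.integers(0, len(mirnas)))]
            L = 22
            pos = int(rng.integers(rec.start, rec.end - L + 1))
            seq = bundle.genome.fetch(rec.contig, pos, pos + L, rec.strand)
            reads.append(
                SimulatedRead(next_id(), seq, cls, rec.name, rec.contig, pos,
                              pos + L, rec.strand, methylated(cls))
            )
        else:  # degradation
            contig = contig_names[int(rng.integers(0, len(contig_names)))]
            clen = bundle.genome.length(contig)
            L = int(rng.integers(18, 41))
            pos = int(rng.integers(0, clen - L))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = bundle.genome.fetch(contig, pos, pos + L, strand)
            reads.append(
                SimulatedRead(next_id(), seq, cls, "genome", contig, pos,
                              pos + L, strand, methylated(cls))
            )
    if fallback_phase > 0.01 * max(1, len(reads)):
        raise SimulationError(
            "cluster sequence too T-poor to satisfy the requested biases; "
            "regenerate the reference"
        )
    return reads


def apply_oxidation(reads: Sequence[SimulatedRead], config: SimConfig) -> list[SimulatedRead]:
    """Periodate oxidation: methylated reads always survive; unmethylated ones
    survive with ``oxidation_survival_unmethylated``.  Output is a subset of
    the input, order preserved."""
    rng = np.random.default_rng([config.seed, 2])
    out = []
    for read in reads:
        if read.methylated or rng.random() < config.oxidation_survival_unmethylated:
            out.append(read)
    return out


# ---------------------------------------------------------------------------
# FASTQ + truth rendering


_TRUTH_COLUMNS = (
    "read_id",
    "class",
    "source",
    "contig",
    "start",
    "end",
    "strand",
    "te_name",
    "orientation",
    "methylated",
    "partner_id",
    "is_partner",
    "insert_len",
    "adapter_absent",
)


def render_fastq(
    reads: Sequence[SimulatedRead],
    config: SimConfig,
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write 4-line FASTQ records ``UMI4 + insert + UMI4 + adapter3`` truncated
    to ``read_length`` cycles (constant quality 'I'; 'G' fill past the
    adapter, as in dark-cycle sequencing) plus a sidecar truth table."""
    rng = np.random.default_rng([config.seed, 3])
    rows = []
    with open(fastq_path, "w") as fh:
        for read in reads:
            umi5 = _random_seq(rng, config.umi_len)
            umi3 = _random_seq(rng, config.umi_len)
            full = umi5 + read.sequence + umi3 + config.adapter3
            seq = full[: config.read_length]
            if len(seq) < config.read_length:
                seq = seq + "G" * (config.read_length - len(seq))
            adapter_absent = (
                2 * config.umi_len + len(read.sequence) >= config.read_length
            )
            fh.write(f"@{read.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            rows.append(
                (
                    read.read_id, read.true_class, read.source, read.contig,
                    read.start, read.end, read.strand, read.te_name,
                    read.orientation, read.methylated, read.partner_id or "",
                    read.is_partner, len(read.sequence), adapter_absent,
                )
            )
    truth = pd.DataFrame(rows, columns=list(_TRUTH_COLUMNS))
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def write_truth(reads: Sequence[SimulatedRead], path: str | Path) -> pd.DataFrame:
    rows = [
        (
            r.read_id, r.true_class, r.source, r.contig, r.start, r.end,
            r.strand, r.te_name, r.orientation, r.methylated,
            r.partner_id or "", r.is_partner, len(r.sequence), False,
        )
        for r in reads
    ]
    truth = pd.DataFrame(rows, columns=list(_TRUTH_COLUMNS))
    truth.to_csv(path, sep="\t", index=False)
    return truth


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


# ---------------------------------------------------------------------------
# TE mRNA count tables


def simulate_te_counts(
    seed: int,
    te_names: Sequence[str] = ("TE1", "TE2", "TE3", "TE4"),
    n_host: int = 200,
    fold_changes: dict[str, float] | None = None,
    mean_count: float = 500.0,
    dispersion: float = 20.0,
) -> pd.DataFrame:
    """Transcript-level count table for two conditions (a, b).

    Expected reads per transcript are proportional to expression rate x
    length (so the TPM arithmetic downstream undoes the length term); counts
    are negative-binomial with the given dispersion, and the per-TE fold
    change multiplies condition b's mean.  ``mean_count`` sets the average
    depth per transcript.  Columns: transcript_id, class (host|TE), length,
    count_a, count_b.
    """
    rng = np.random.default_rng([seed, 4])
    fold_changes = fold_changes or {}
    names = [f"host{i + 1}" for i in range(n_host)] + list(te_names)
    classes = ["host"] * n_host + ["TE"] * len(te_names)
    lengths = rng.integers(500, 8_000, size=len(names))
    rates = rng.lognormal(mean=0.0, sigma=1.0, size=len(names))
    weights = rates * lengths
    weights /= weights.sum()
    rows = []
    for name, cls, length, w in zip(names, classes, lengths, weights):
        mean_a = max(mean_count * len(names) * w, 1e-9)
        mean_b = mean_a * fold_changes.get(name, 1.0)
        p_a = dispersion / (dispersion + mean_a)
        p_b = dispersion / (dispersion + mean_b)
        count_a = int(rng.negative_binomial(dispersion, p_a))
        count_b = int(rng.negative_binomial(dispersion, p_b))
        rows.append((name, cls, int(length), count_a, count_b))
    return pd.DataFrame(
        rows, columns=["transcript_id", "class", "length", "count_a", "count_b"]
    )
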