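"""Reference sequences, annotations and coordinate conventions.

Every downstream module shares the conventions fixed here:

* coordinates are 0-based, half-open (BED-native) everywhere;
* sequences are stored as uppercase DNA over ``{A, C, G, T, N}`` — a ``U``
  in any report is a display alias for ``T``;
* the stored strand of a transposon consensus is its sense (mRNA-like)
  strand, so a read on the ``-`` strand of a consensus is TE-antisense;
* ``N`` never matches any base, including another ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FEATURE_CLASSES",
    "ReferenceGenome",
    "FeatureRecord",
    "FeatureAnnotation",
    "TEConsensusLibrary",
    "TEFragment",
    "ReferenceBundle",
    "revcomp",
    "load_reference",
    "write_reference",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_fragments",
    "write_fragments",
]

#: Feature classes used by the filtering and masking rules.
FEATURE_CLASSES = frozenset(
    {
        "rRNA",
        "snRNA",
        "snoRNA",
        "miRNA",
        "tRNA",
        "hpRNA",
        "piRNA_cluster",
        "TE_insertion",
        "aub_locus",
    }
)

#: Classes mapped against before the genome (ribosomal/structural small RNAs
#: plus the hairpin-RNA locus whose endo-siRNAs provide the normalization
#: denominator).
INFRASTRUCTURAL_CLASSES = ("rRNA", "snRNA", "snoRNA", "miRNA", "tRNA", "hpRNA")

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over ``{A,C,G,T,N}``."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceError(ValueError):
    """Malformed or inconsistent reference input."""


@dataclass
class ReferenceGenome:
    """Toy genome: mapping of contig id to nucleotide string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ReferenceError("genome has no contigs")
        for cid, seq in self.contigs.items():
            if not seq:
                raise ReferenceError(f"contig {cid!r} is empty")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ReferenceError(
                    f"contig {cid!r} contains characters outside A/C/G/T/N: {sorted(bad)}"
                )

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on *contig*; ``-`` returns the reverse
        complement.  An empty interval returns the empty string."""
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"interval [{start}, {end}) out of bounds for contig "
                f"{contig!r} of length {len(seq)}"
            )
        sub = seq[start:end]
        if strand == "+":
            return sub
        if strand == "-":
            return revcomp(sub)
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated interval (BED semantics, 0-based half-open)."""

    contig: str
    start: int
    end: int
    strand: str
    feature_class: str
    name: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ReferenceError(
                f"unknown feature class {self.feature_class!r} for {self.name!r}"
            )
        if self.strand not in ("+", "-"):
            raise ReferenceError(f"bad strand {self.strand!r} for {self.name!r}")
        if not (0 <= self.start < self.end):
            raise ReferenceError(
                f"bad interval [{self.start}, {self.end}) for {self.name!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FeatureAnnotation:
    records: list[FeatureRecord] = field(default_factory=list)

    def validate_against(self, genome: ReferenceGenome) -> None:
        for rec in self.records:
            if rec.contig not in genome.contigs:
                raise ReferenceError(
                    f"feature {rec.name!r} on unknown contig {rec.contig!r}"
                )
            if rec.end > genome.length(rec.contig):
                raise ReferenceError(
                    f"feature {rec.name!r} [{rec.start}, {rec.end}) exceeds contig "
                    f"{rec.contig!r} length {genome.length(rec.contig)}"
                )

    def by_class(self, feature_class: str) -> list[FeatureRecord]:
        return [r for r in self.records if r.feature_class == feature_class]


@dataclass
class TEConsensusLibrary:
    """Transposon consensus sequences keyed by element name (sense strand)."""

    elements: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.elements.items():
            if not seq:
                raise ReferenceError(f"TE consensus {name!r} is empty")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ReferenceError(
                    f"TE consensus {name!r} has characters outside A/C/G/T/N: {sorted(bad)}"
                )


@dataclass(frozen=True)
class TEFragment:
    """A segment of a TE consensus embedded in the toy genome.

    ``strand`` is the genome strand carrying the TE *sense* sequence:
    ``-`` means the plus strand of the genome holds the reverse complement
    of the consensus segment (an antisense insertion).
    """

    contig: str
    start: int
    end: int
    strand: str
    te_name: str
    te_start: int
    te_end: int
    in_cluster: str  # piRNA-cluster name, or "" for a dispersed insertion


@dataclass
class ReferenceBundle:
    genome: ReferenceGenome
    annotation: FeatureAnnotation
    te_library: TEConsensusLibrary
    te_fragments: list[TEFragment] = field(default_factory=list)

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        return self.genome.fetch(contig, start, end, strand)

    def infrastructural_sequences(self) -> dict[str, tuple[str, str]]:
        """Map of feature name -> (feature class, genomic sequence on the
        feature strand) for the infrastructural classes."""
        out: dict[str, tuple[str, str]] = {}
        for cls in INFRASTRUCTURAL_CLASSES:
            for rec in self.annotation.by_class(cls):
                out[rec.name] = (cls, self.genome.fetch(rec.contig, rec.start, rec.end, rec.strand))
        return out


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ReferenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ReferenceError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed(path: str | Path) -> FeatureAnnotation:
    """BED6 reader; the name column carries ``feature-class:name``."""
    records: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ReferenceError(
                    f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}"
                )
            contig, start, end, label, _score, strand = fields[:6]
            if ":" not in label:
                raise ReferenceError(
                    f"{path}:{lineno}: name column must be 'feature-class:name', got {label!r}"
                )
            feature_class, name = label.split(":", 1)
            try:
                records.append(
                    FeatureRecord(contig, int(start), int(end), strand, feature_class, name)
                )
            except (ValueError, ReferenceError) as exc:
                raise ReferenceError(f"{path}:{lineno}: {exc}") from exc
    return FeatureAnnotation(records)


def write_bed(annotation: FeatureAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in annotation.records:
            fh.write(
                f"{rec.contig}\t{rec.start}\t{rec.end}\t"
                f"{rec.feature_class}:{rec.name}\t0\t{rec.strand}\n"
            )


_FRAGMENT_COLUMNS = (
    "contig",
    "start",
    "end",
    "strand",
    "te_name",
    "te_start",
    "te_end",
    "in_cluster",
)


def write_fragments(fragments: Iterable[TEFragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_FRAGMENT_COLUMNS) + "\n")
        for fr in fragments:
            fh.write(
                f"{fr.contig}\t{fr.start}\t{fr.end}\t{fr.strand}\t"
                f"{fr.te_name}\t{fr.te_start}\t{fr.te_end}\t{fr.in_cluster}\n"
            )


def read_fragments(path: str | Path) -> list[TEFragment]:
    fragments: list[TEFragment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _FRAGMENT_COLUMNS:
            raise ReferenceError(f"{path}: unexpected fragment table header {header}")
        for line in fh:
            c, s, e, st, te, ts, te_e, clu = line.rstrip("\n").split("\t")
            fragments.append(TEFragment(c, int(s), int(e), st, te, int(ts), int(te_e), clu))
    return fragments


def load_reference(
    genome_path: str | Path,
    annotation_path: str | Path,
    te_path: str | Path,
    fragments_path: str | Path | None = None,
) -> ReferenceBundle:
    """Load and cross-validate genome FASTA, BED6 annotation and TE FASTA."""
    genome = ReferenceGenome(read_fasta(genome_path))
    annotation = read_bed(annotation_path) if annotation_path is not None else FeatureAnnotation()
    annotation.validate_against(genome)
    te_library = TEConsensusLibrary(read_fasta(te_path))
    fragments = read_fragments(fragments_path) if fragments_path else []
    return ReferenceBundle(genome, annotation, te_library, fragments)


def write_reference(bundle: ReferenceBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle to ``genome.fa``, ``features.bed``, ``te.fa`` (and
    ``te_fragments.tsv`` when present); returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": directory / "genome.fa",
        "annotation": directory / "features.bed",
        "te": directory / "te.fa",
    }
    write_fasta(bundle.genome.contigs, paths["genome"])
    write_bed(bundle.annotation, paths["annotation"])
    write_fasta(bundle.te_library.elements, paths["te"])
    if bundle.te_fragments:
        paths["fragments"] = directory / "te_fragments.tsv"
        write_fragments(bundle.te_fragments, paths["fragments"])
    return paths
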