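"""Pipeline driver: configuration, stage sequencing and report assembly.

Runs preprocess -> infrastructural annotation -> genome/TE mapping ->
signatures -> tiles (-> TE expression when a count table is given) and
writes one TSV per stage plus a headline summary.  Every output carries a
header comment with the config hash and seed; re-running with the same
config and inputs byte-reproduces all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import align, preprocess, signatures, te_expression, tiles
from .align import Alignment, AlignmentPolicy
from .refmodel import ReferenceBundle, load_reference

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "load_config",
    "save_config",
    "run_pipeline",
    "frame_to_alignments",
]

logger = logging.getLogger("pirnakit")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Every analysis tunable, with the package defaults."""

    seed: int = 0
    adapter3: str = preprocess.DEFAULT_ADAPTER3
    min_overlap: int = 6
    umi_len: int = 4
    min_len: int = 18
    max_len: int = 40
    size_select_all: bool = True  # size window applied to all downstream stages
    infra_max_mismatches: int = 1
    genome_max_mismatches: int = 1
    te_max_mismatches: int = 3
    window_len: int = 11
    anchor_offset: int = 5
    tile_width: int = 1000
    mask_pad: int = 100
    tpm_pseudo_abundance: float = 1.0

    def hash(self) -> str:
        payload = ";".join(
            f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


_BOOL = {"true": True, "false": False, "1": True, "0": False}


def load_config(path: str | Path) -> PipelineConfig:
    """Flat ``key = value`` config file; unknown keys are rejected."""
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    kwargs = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise PipelineError(f"{path}:{lineno}: unknown config key {key!r}")
            ftype = fields[key].type
            if ftype in ("int", int):
                kwargs[key] = int(value)
            elif ftype in ("float", float):
                kwargs[key] = float(value)
            elif ftype in ("bool", bool):
                kwargs[key] = _BOOL[value.lower()]
            else:
                kwargs[key] = value
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"{f.name} = {getattr(config, f.name)}\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pirnakit {stage} config={config.hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                       na_values=[""])


def frame_to_alignments(df: pd.DataFrame) -> list[Alignment]:
    return [
        Alignment(
            str(r.read_id), str(r.target), str(getattr(r, "class")), int(r.start),
            str(r.strand), int(r.mismatches), int(r.length), float(r.weight),
        )
        for r in df.itertuples(index=False)
    ]


def run_pipeline(
    config: PipelineConfig,
    fastq: str | Path,
    bundle: ReferenceBundle | None = None,
    reference_paths: dict[str, str | Path] | None = None,
    counts: pd.DataFrame | None = None,
    outdir: str | Path = "pirnakit_out",
    skip_tiles: bool = False,
) -> Path:
    """Execute all stages; returns the report directory.

    ``bundle`` or ``reference_paths`` (genome/annotation/te[/fragments]) must
    be given.  Stage failures raise :class:`PipelineError` naming the stage;
    outputs of completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    save_config(config, outdir / "config.txt")
    try:
        if bundle is None:
            if reference_paths is None:
                raise PipelineError("stage reference: no reference bundle or paths given")
            for key in ("genome", "annotation", "te"):
                if key not in reference_paths:
                    raise PipelineError(f"stage reference: missing input {key!r}")
                if not Path(reference_paths[key]).exists():
                    raise PipelineError(
                        f"stage reference: input {key!r} not found at "
                        f"{reference_paths[key]}"
                    )
            bundle = load_reference(
                reference_paths["genome"],
                reference_paths["annotation"],
                reference_paths["te"],
                reference_paths.get("fragments"),
            )

        stage = "preprocess"
        logger.info("stage %s", stage)
        clean, report = preprocess.preprocess_fastq(
            fastq, config.adapter3, config.min_overlap, config.min_len,
            config.max_len, config.umi_len,
        )
        reads = {r.id: r.sequence for r in clean}
        preprocess.write_clean_fasta(clean, outdir / "clean.fa")
        _write_tsv(
            pd.DataFrame(report.to_rows(), columns=["category", "count"]),
            outdir / "preprocess_report.tsv", config, stage,
        )
        logger.info("kept %d of %d reads", report.kept, report.input)

        stage = "infrastructural"
        logger.info("stage %s", stage)
        flags, infra_totals = align.annotate_infrastructural(
            reads, bundle, config.infra_max_mismatches
        )
        hp_total = infra_totals.get("hpRNA", 0.0)
        _write_tsv(
            pd.DataFrame(sorted(infra_totals.items()), columns=["class", "count"]),
            outdir / "infrastructural_counts.tsv", config, stage,
        )

        stage = "genome_mapping"
        logger.info("stage %s", stage)
        genome_alignments = align.map_reads(
            reads, bundle.genome.contigs,
            AlignmentPolicy(config.genome_max_mismatches), target_class="genome",
        )
        _write_tsv(
            align.alignments_to_frame(genome_alignments),
            outdir / "genome_alignments.tsv", config, stage,
        )

        stage = "te_mapping"
        logger.info("stage %s", stage)
        te_alignments = align.map_reads(
            reads, bundle.te_library.elements,
            AlignmentPolicy(config.te_max_mismatches), target_class="TE",
        )
        _write_tsv(
            align.alignments_to_frame(te_alignments),
            outdir / "te_alignments.tsv", config, stage,
        )

        stage = "signatures"
        logger.info("stage %s", stage)
        sizes = signatures.size_distribution(
            te_alignments, hp_total, config.min_len, config.max_len
        )
        _write_tsv(sizes.table, outdir / "size_distribution.tsv", config, stage)
        pp, m_as, m_s = signatures.pingpong_signature(
            te_alignments, reads, bundle.te_library.elements
        )
        for matrix, name in ((m_as, "freq_antisense_pos1"), (m_s, "freq_sense_pos10")):
            out = matrix.frequencies.copy()
            out.insert(0, "position", range(len(out)))
            _write_tsv(out, outdir / f"{name}.tsv", config, stage)
        te_read_ids = {a.read_id for a in te_alignments}
        phasing = signatures.downstream_u_frequency(
            genome_alignments, bundle, te_read_ids
        )
        te_fraction, te_fraction_defined = signatures.te_mapping_fraction(
            reads, te_alignments
        )

        cluster_table = None
        if not skip_tiles:
            stage = "tiles"
            logger.info("stage %s", stage)
            mask = tiles.build_mask(bundle.annotation, bundle.genome, config.mask_pad)
            unique = align.unique_genome_mappers(genome_alignments)
            tile_table = tiles.tile_counts(
                unique, mask, bundle.genome, hp_total, config.tile_width
            )
            _write_tsv(tile_table.table, outdir / "tiles.tsv", config, stage)
            cluster_table = tiles.cluster_abundance(tile_table, bundle.annotation)
            _write_tsv(cluster_table, outdir / "cluster_abundance.tsv", config, stage)

        if counts is not None:
            stage = "te_expression"
            logger.info("stage %s", stage)
            count_col = "count" if "count" in counts.columns else "count_a"
            _write_tsv(
                te_expression.te_summary(counts, count_col),
                outdir / "te_abundance.tsv", config, stage,
            )

        stage = "summary"
        rows = [
            ("n_input_reads", report.input),
            ("n_clean_reads", report.kept),
            ("hpRNA_total", hp_total),
            ("z_1U_antisense", pp.z_1U_antisense),
            ("z_10A_sense", pp.z_10A_sense),
            ("phasing_downstream_U_TE", phasing.frequencies["TE"]),
            ("phasing_downstream_U_non_TE", phasing.frequencies["non_TE"]),
            ("phasing_downstream_U_all", phasing.frequencies["all"]),
            ("te_mapping_fraction", te_fraction if te_fraction_defined else float("nan")),
        ]
        if cluster_table is not None:
            for row in cluster_table.itertuples(index=False):
                rows.append((f"cluster_abundance:{row.cluster}", row.abundance))
        _write_tsv(
            pd.DataFrame(rows, columns=["statistic", "value"]),
            outdir / "summary.tsv", config, stage,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
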