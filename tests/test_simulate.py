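"""Simulator: determinism, ground-truth parameter recovery, oxidation,
FASTQ rendering and count tables."""

from __future__ import annotations

import numpy as np
import pytest

from pirnakit.refmodel import revcomp, write_reference
from pirnakit.simulate import (
    RefParams,
    SimConfig,
    SimulationError,
    apply_oxidation,
    build_toy_reference,
    render_fastq,
    simulate_small_rna_population,
    simulate_te_counts,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestToyReference:
    def test_deterministic_bytes(self, tmp_path):
        for sub in ("a", "b"):
            write_reference(build_toy_reference(seed=1), tmp_path / sub)
        for name in ("genome.fa", "features.bed", "te.fa", "te_fragments.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_zero_clusters_rejected(self):
        with pytest.raises(SimulationError):
            build_toy_reference(seed=1, params=RefParams(n_clusters=0))

    def test_dispersed_insertion_count(self):
        bundle = build_toy_reference(
            seed=2,
            params=RefParams(
                n_te=2, te_length=2000, n_dispersed_te=4,
                fragments_per_cluster=2, cluster_fragment_length=400,
            ),
        )
        assert len(bundle.annotation.by_class("TE_insertion")) == 4

    def test_every_feature_class_present(self, bundle):
        present = {r.feature_class for r in bundle.annotation.records}
        # cluster-embedded TE copies live in the fragments table
        assert present | {"hpRNA"} >= {
            "rRNA", "snRNA", "snoRNA", "miRNA", "tRNA", "hpRNA",
            "piRNA_cluster", "TE_insertion", "aub_locus",
        }

    def test_fragments_carry_te_sequence(self, bundle):
        for frag in bundle.te_fragments:
            genomic = bundle.genome.fetch(frag.contig, frag.start, frag.end, "+")
            consensus = bundle.te_library.elements[frag.te_name][frag.te_start : frag.te_end]
            expected = consensus if frag.strand == "+" else revcomp(consensus)
            assert genomic == expected

    def test_infeasible_params_raise(self):
        with pytest.raises(SimulationError):
            build_toy_reference(seed=1, params=RefParams(contig_lengths=(2000,)))


class TestPopulation:
    def test_placement_sequence_matches_insert(self, bundle, small_population):
        _config, reads = small_population
        for read in reads[:500]:
            assert read.sequence == bundle.genome.fetch(
                read.contig, read.start, read.end, read.strand
            )

    def test_no_partners_without_pingpong(self, bundle):
        config = SimConfig(seed=3, n_reads=800, pingpong_fraction=0.0)
        reads = simulate_small_rna_population(bundle, config)
        assert all(r.partner_id is None for r in reads)

    def test_u1_bias_recovered(self, bundle):
        # binomial 99% interval around 0.9 at n ~ thousands is well inside
        config = SimConfig(seed=7, n_reads=10_000)
        reads = simulate_small_rna_population(bundle, config)
        primary = [r for r in reads if r.true_class == "piRNA" and not r.is_partner]
        u1 = np.mean([r.sequence.startswith("T") for r in primary])
        assert 0.87 <= u1 <= 0.93

    def test_pingpong_pair_geometry_exact(self, bundle, small_population):
        """Partner 10th base is the complement of the mate's 1st, for every pair."""
        _config, reads = small_population
        by_id = {r.read_id: r for r in reads}
        pairs = 0
        for read in reads:
            if read.orientation == "antisense" and read.partner_id:
                partner = by_id[read.partner_id]
                assert partner.sequence[9] == _COMP[read.sequence[0]]
                assert partner.strand != read.strand
                pairs += 1
        assert pairs > 0

    def test_class_fractions_recovered(self, bundle):
        config = SimConfig(seed=9, n_reads=20_000)
        reads = simulate_small_rna_population(bundle, config)
        primary = [r for r in reads if not r.is_partner]
        for cls, expect in config.class_fractions.items():
            got = np.mean([r.true_class == cls for r in primary])
            assert abs(got - expect) < 3 * np.sqrt(expect * (1 - expect) / len(primary)) + 1e-3

    def test_class_lengths(self, bundle, small_population):
        _config, reads = small_population
        for read in reads:
            L = len(read.sequence)
            if read.true_class == "piRNA":
                assert 23 <= L <= 32
            elif read.true_class == "hpRNA_siRNA":
                assert L == 21
            elif read.true_class == "miRNA":
                assert L == 22
            else:
                assert 18 <= L <= 40


class TestOxidation:
    def test_all_methylated_passes_through(self, bundle):
        config = SimConfig(seed=5, n_reads=500)
        reads = simulate_small_rna_population(bundle, config)
        methylated = [r for r in reads if r.methylated]
        assert apply_oxidation(methylated, config) == methylated

    def test_unmethylated_survival_rate(self, bundle):
        config = SimConfig(
            seed=3, n_reads=10_000,
            class_fractions={"piRNA": 0.0, "hpRNA_siRNA": 0.0, "miRNA": 0.0, "degradation": 1.0},
        )
        reads = simulate_small_rna_population(bundle, config)
        assert all(not r.methylated for r in reads)
        survivors = apply_oxidation(reads, config)
        # binomial 99% interval around 0.02 at n = 10,000
        assert 150 <= len(survivors) <= 250

    def test_zero_survival_keeps_only_methylated(self, bundle, small_population):
        config, reads = small_population
        config0 = SimConfig(seed=config.seed, n_reads=config.n_reads,
                            oxidation_survival_unmethylated=0.0)
        survivors = apply_oxidation(reads, config0)
        assert survivors and all(r.methylated for r in survivors)

    def test_output_subset_of_input(self, bundle, small_population):
        config, reads = small_population
        ids = {r.read_id for r in reads}
        assert {r.read_id for r in apply_oxidation(reads, config)} <= ids


class TestRenderFastq:
    def test_read_layout(self, bundle, tmp_path):
        config = SimConfig(seed=13, n_reads=50)
        reads = simulate_small_rna_population(bundle, config)
        truth = render_fastq(reads, config, tmp_path / "r.fq", tmp_path / "t.tsv")
        lines = (tmp_path / "r.fq").read_text().splitlines()
        assert len(lines) == 4 * len(reads)
        for i, read in enumerate(reads):
            seq = lines[4 * i + 1]
            assert len(seq) == config.read_length
            assert seq[4 : 4 + len(read.sequence)] == read.sequence
            adapter_at = 8 + len(read.sequence)
            assert seq[adapter_at : adapter_at + 6] == config.adapter3[:6]
        assert not truth["adapter_absent"].any()

    def test_overflow_insert_flagged(self, bundle, tmp_path):
        config = SimConfig(seed=13, n_reads=10, read_length=30)
        reads = simulate_small_rna_population(bundle, config)
        truth = render_fastq(reads, config, tmp_path / "r.fq", tmp_path / "t.tsv")
        long_inserts = truth["insert_len"] >= config.read_length - 8
        assert (truth.loc[long_inserts, "adapter_absent"]).all()

    def test_deterministic_bytes(self, bundle, tmp_path):
        config = SimConfig(seed=21, n_reads=200)
        for sub in ("a", "b"):
            (tmp_path / sub).mkdir()
            reads = simulate_small_rna_population(bundle, config)
            render_fastq(reads, config, tmp_path / sub / "r.fq", tmp_path / sub / "t.tsv")
        assert (tmp_path / "a" / "r.fq").read_bytes() == (tmp_path / "b" / "r.fq").read_bytes()
        assert (tmp_path / "a" / "t.tsv").read_bytes() == (tmp_path / "b" / "t.tsv").read_bytes()


class TestTECounts:
    def test_columns_and_classes(self):
        table = simulate_te_counts(seed=1)
        assert set(table["class"]) == {"host", "TE"}
        assert (table["length"] > 0).all()

    def test_unit_fold_change_log_ratio_near_zero(self):
        """Sampling oracle: at deep, low-dispersion counts the per-TE TPM
        log-ratio between two unit-fold-change conditions stays within 0.1."""
        from pirnakit.te_expression import log_ratios

        table = simulate_te_counts(
            seed=2, n_host=100, mean_count=200_000, dispersion=50_000
        )
        ratios = log_ratios(table, pseudo_abundance=1.0)
        assert ratios["log2_ratio"].abs().max() < 0.1

    def test_configured_fold_change_detected(self):
        from pirnakit.te_expression import log_ratios

        table = simulate_te_counts(
            seed=3, n_host=100, fold_changes={"TE1": 4.0},
            mean_count=10_000, dispersion=1_000,
        )
        ratios = log_ratios(table).set_index("transcript_id")
        assert ratios.loc["TE1", "log2_ratio"] > 1.0
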