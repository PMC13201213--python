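"""Signature statistics: size distribution arithmetic, frequency windows,
z-score conventions, phasing strand conventions, TE-mapping fraction."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from pirnakit.align import Alignment
from pirnakit.refmodel import ReferenceBundle, ReferenceGenome, FeatureAnnotation, TEConsensusLibrary, revcomp
from pirnakit.signatures import (
    downstream_u_frequency,
    pingpong_zscore,
    positional_frequencies,
    size_distribution,
    te_mapping_fraction,
)


def _aln(read_id, target, start, strand, length, weight=1.0, cls="TE"):
    return Alignment(read_id, target, cls, start, strand, 0, length, weight)


class TestSizeDistribution:
    def test_empty(self):
        dist = size_distribution([], hpRNA_total=1000)
        assert (dist.table["count"] == 0).all()

    def test_normalization_arithmetic(self):
        alns = [
            _aln("a", "TE1", 0, "-", 25),
            _aln("b", "TE1", 5, "-", 25),
            _aln("c", "TE1", 9, "-", 26),
        ]
        dist = size_distribution(alns, hpRNA_total=1000)
        t = dist.table.set_index(["length", "orientation"])
        assert t.loc[(25, "antisense"), "per_million_hpRNA"] == pytest.approx(2000)
        assert t.loc[(26, "antisense"), "per_million_hpRNA"] == pytest.approx(1000)

    def test_linearity_in_weights(self):
        alns = [_aln("a", "TE1", 0, "+", 30, weight=0.5)]
        single = size_distribution(alns, 100).table["per_million_hpRNA"]
        double = size_distribution(
            [_aln("a", "TE1", 0, "+", 30, weight=1.0)], 100
        ).table["per_million_hpRNA"]
        assert np.allclose(double, 2 * single)

    def test_zero_hprna_flagged(self):
        dist = size_distribution([_aln("a", "TE1", 0, "+", 30)], hpRNA_total=0)
        assert not dist.normalized_available
        assert dist.table["per_million_hpRNA"].isna().all()
        assert dist.table["count"].sum() == pytest.approx(1.0)


class TestPositionalFrequencies:
    def test_sense_anchor_point_mass(self):
        te = {"TE1": "ACGT" * 15}
        read = te["TE1"][10:35]  # 25 nt sense read
        m = positional_frequencies(
            [_aln("r", "TE1", 10, "+", 25)], {"r": read}, te, "sense_pos10"
        )
        anchor = m.frequencies.iloc[5]
        base = read[9].replace("T", "U")
        assert anchor[base] == pytest.approx(1.0)

    def test_all_anchor_u_gives_unit_frequency(self):
        te = {"TE1": "G" * 30 + "T" + "G" * 30}
        reads, alns = {}, []
        for i, start in enumerate((30, 30)):  # antisense reads starting on the T
            rid = f"r{i}"
            # antisense read whose 1st base is complement of plus-strand A... use '-' read over [start-24, start+1)
            reads[rid] = revcomp(te["TE1"][start - 24 : start + 1])
            alns.append(_aln(rid, "TE1", start - 24, "-", 25))
        m = positional_frequencies(alns, reads, te, "antisense_pos1")
        # plus-strand base at the anchor is T -> read-strand base is A, not U;
        # build the U case explicitly instead:
        te2 = {"TE1": "G" * 30 + "A" + "G" * 30}
        reads2 = {"r": revcomp(te2["TE1"][6:31])}
        m2 = positional_frequencies([_aln("r", "TE1", 6, "-", 25)], reads2, te2, "antisense_pos1")
        assert m2.frequencies.iloc[5]["U"] == pytest.approx(1.0)

    def test_manual_tally_oracle(self):
        rng = np.random.default_rng(5)
        te = {"TE1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])}
        alns, reads = [], {}
        for i, (start, strand) in enumerate([(10, "+"), (20, "+"), (15, "-"), (25, "-")]):
            rid = f"r{i}"
            L = 24
            seq = te["TE1"][start : start + L]
            reads[rid] = seq if strand == "+" else revcomp(seq)
            alns.append(_aln(rid, "TE1", start, strand, L))
        m = positional_frequencies(alns, reads, te, "sense_pos10")
        # direct per-position tally over the sense alignments only
        sense_reads = [reads["r0"], reads["r1"]]
        for offset in range(11):
            col = [r[10 - 1 - 5 + offset] for r in sense_reads]
            for base in "ACGT":
                expect = col.count(base) / len(col)
                got = m.frequencies.iloc[offset][base.replace("T", "U")]
                assert got == pytest.approx(expect)

    def test_window_out_of_bounds_dropped(self):
        te = {"TE1": "A" * 40}
        # antisense read at the very start: upstream context would run past the end
        reads = {"r": revcomp(te["TE1"][14:39])}
        m = positional_frequencies([_aln("r", "TE1", 14, "-", 25)], reads, te, "antisense_pos1")
        assert m.empty and m.n_dropped == 1

    def test_columns_sum_to_one(self, bundle, small_population):
        from pirnakit.align import AlignmentPolicy, map_reads

        _config, sim = small_population
        reads = {r.read_id: r.sequence for r in sim if r.true_class == "piRNA"}
        alns = map_reads(reads, bundle.te_library.elements, AlignmentPolicy(3), target_class="TE")
        for anchor in ("antisense_pos1", "sense_pos10"):
            m = positional_frequencies(alns, reads, bundle.te_library.elements, anchor)
            sums = m.frequencies.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-9)


class TestPingPongZscore:
    def test_anchor_equal_to_mean_gives_zero(self):
        values = [0.1, 0.5] + [0.3] * 9
        values[5], values[2] = 0.3, values[5]  # anchor at index 5 equals mean 0.3
        freq = pd.DataFrame({"A": 0.0, "C": 0.0, "G": 0.0, "U": values})
        freq["A"] = 1 - freq["U"]
        z, degenerate = pingpong_zscore(freq, "U")
        assert z == pytest.approx(0.0) and not degenerate

    @pytest.mark.parametrize("baseline,outlier", [(0.2, 0.9), (0.05, 0.1), (0.5, 0.0)])
    def test_single_outlier_closed_form(self, baseline, outlier):
        values = [baseline] * 11
        values[5] = outlier
        freq = pd.DataFrame({"A": 0.0, "C": 0.0, "G": 0.0, "U": values})
        z, degenerate = pingpong_zscore(freq, "U")
        assert abs(z) == pytest.approx(math.sqrt(10))
        assert not degenerate

    def test_degenerate_window(self):
        freq = pd.DataFrame({"A": [0.25] * 11, "C": [0.25] * 11,
                             "G": [0.25] * 11, "U": [0.25] * 11})
        z, degenerate = pingpong_zscore(freq, "U")
        assert z == 0.0 and degenerate


class TestDownstreamU:
    def _bundle(self, seq):
        genome = ReferenceGenome({"chr1": seq})
        return ReferenceBundle(genome, FeatureAnnotation([]), TEConsensusLibrary({"TE1": "ACGT" * 10}))

    def test_plus_strand_convention(self):
        seq = "G" * 25 + "T" + "G" * 10
        b = self._bundle(seq)
        sig = downstream_u_frequency(
            [_aln("r", "chr1", 0, "+", 25, cls="genome")], b
        )
        assert sig.frequencies["all"] == pytest.approx(1.0)

    def test_minus_strand_convention(self):
        seq = "G" * 9 + "A" + "G" * 30  # base 9 = A; complement T => downstream-U
        b = self._bundle(seq)
        sig = downstream_u_frequency(
            [_aln("r", "chr1", 10, "-", 25, cls="genome")], b
        )
        assert sig.frequencies["all"] == pytest.approx(1.0)

    def test_edge_alignment_dropped(self):
        seq = "G" * 25
        b = self._bundle(seq)
        sig = downstream_u_frequency([_aln("r", "chr1", 0, "+", 25, cls="genome")], b)
        assert sig.n_dropped == 1
        assert math.isnan(sig.frequencies["all"])

    def test_te_category_split(self):
        seq = "G" * 25 + "T" + "G" * 30
        b = self._bundle(seq)
        alns = [
            _aln("te_read", "chr1", 0, "+", 25, cls="genome"),
            _aln("other", "chr1", 5, "+", 25, cls="genome"),
        ]
        sig = downstream_u_frequency(alns, b, te_read_ids={"te_read"})
        assert sig.frequencies["TE"] == pytest.approx(1.0)
        assert sig.frequencies["non_TE"] == pytest.approx(0.0)


class TestTEMappingFraction:
    def test_arithmetic(self):
        reads = {f"r{i}": "A" * 25 for i in range(10)}
        alns = [_aln(f"r{i}", "TE1", 0, "+", 25) for i in range(9)]
        fraction, defined = te_mapping_fraction(reads, alns)
        assert defined and fraction == pytest.approx(0.9)

    def test_undefined_without_pirna_sized_reads(self):
        fraction, defined = te_mapping_fraction({"r": "A" * 20}, [])
        assert not defined and fraction == 0.0

    def test_short_reads_excluded(self):
        reads = {"long": "A" * 25, "short": "A" * 20}
        alns = [_aln("long", "TE1", 0, "+", 25), _aln("short", "TE1", 0, "+", 20)]
        fraction, defined = te_mapping_fraction(reads, alns)
        assert defined and fraction == pytest.approx(1.0)
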