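"""Alignment, SAM conversion, TTAA site calling and gene quantification."""

import numpy as np
import pandas as pd
import pytest

from pbscreen import sites, synthetic, trim
from pbscreen.errors import ParseError, ValidationError
from pbscreen.sites import GeneCountMatrix
from pbscreen.synthetic import GeneModel, SyntheticGenome
from tests.conftest import counts_from_clones


def frag(read_id, seq, side="PB5"):
    return trim.JunctionFragment(read_id, side, seq, 0)


class TestAlign:
    def test_forward_and_reverse_copies_located(self, small_genome):
        g = small_genome
        fwd = g.sequence[100:160]
        rev = synthetic.revcomp(g.sequence[200:260])
        alns, stats = sites.align_fragments(
            [frag("f", fwd), frag("r", rev)], g
        )
        assert stats.mapped == 2
        by_id = {a.read_id: a for a in alns}
        assert (by_id["f"].pos0, by_id["f"].strand) == (100, "+")
        assert (by_id["r"].pos0, by_id["r"].strand) == (200, "-")
        assert by_id["r"].matched_len == 60

    def test_absent_fragment_counted_unmapped(self, small_genome):
        alns, stats = sites.align_fragments(
            [frag("x", "TTAAGGCCTTAAGGCCTTAAGGCCTTAAGGCC")], small_genome
        )
        assert alns == [] and stats.unmapped == 1

    def test_repeated_fragment_counted_multimapped(self):
        seq = "ATCGGCTAAGCTCGCCAGTAGCTGTACGCTAGCTAGCTGGATCGGCTAAGCTCGCCAGTAGCTGTACG"
        g = SyntheticGenome("chrR", seq, [])
        alns, stats = sites.align_fragments([frag("m", seq[:25])], g)
        assert alns == [] and stats.multimapped == 1


class TestSamRoundTrip:
    def test_coordinate_conventions(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrT\tLN:1000\n"
            "readA\t0\tchrT\t101\t60\t50M\t*\t0\t0\t*\t*\n"
            "readB\t16\tchrT\t201\t60\t40M\t*\t0\t0\t*\t*\n"
            "readC\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
        )
        alns = sites.import_sam(sam)
        assert len(alns) == 2  # unmapped record skipped
        assert (alns[0].pos0, alns[0].strand, alns[0].matched_len) == (100, "+", 50)
        assert (alns[1].pos0, alns[1].strand) == (200, "-")
        assert alns[0].source == "SAM"

    def test_export_import_lossless(self, small_genome, tmp_path):
        g = small_genome
        frags = [
            frag("a", g.sequence[500:560]),
            frag("b", synthetic.revcomp(g.sequence[700:770])),
        ]
        alns, _ = sites.align_fragments(frags, g)
        sam = tmp_path / "out.sam"
        sites.export_sam(alns, g, sam)
        back = sites.import_sam(sam)
        assert [(a.read_id, a.chrom, a.pos0, a.strand, a.matched_len) for a in alns] == [
            (a.read_id, a.chrom, a.pos0, a.strand, a.matched_len) for a in back
        ]

    def test_headerless_sam_rejected(self, tmp_path):
        bad = tmp_path / "bad.sam"
        bad.write_text("readA\t0\tchrT\t101\t60\t50M\t*\t0\t0\t*\t*\n")
        with pytest.raises(ParseError):
            sites.import_sam(bad)


class TestCallSites:
    def test_reads_from_one_insertion_collapse_to_one_site(self, small_genome):
        g = small_genome
        t = g.ttaa_sites[5]
        frags = [frag(f"r{i}", g.sequence[t : t + 60], "PB5") for i in range(5)]
        alns, _ = sites.align_fragments(frags, g)
        called, dropped = sites.call_sites(alns, g, "PB5", "C0L")
        assert dropped == 0
        assert len(called) == 1
        s = called[0]
        assert (s.pos0, s.orientation, s.read_count["C0L"]) == (t, "+", 5)
        assert g.sequence[s.pos0 : s.pos0 + 4] == "TTAA"

    def test_alignment_far_from_ttaa_dropped(self, small_genome):
        g = small_genome
        # pick a start >= 10 bp from any TTAA
        start = next(
            p for p in range(1000, 2000)
            if all(abs(p - t) > 10 for t in g.ttaa_sites)
        )
        alns, _ = sites.align_fragments([frag("far", g.sequence[start : start + 60])], g)
        called, dropped = sites.call_sites(alns, g, "PB5", "L")
        assert called == [] and dropped == 1

    def test_both_sides_merge_into_one_site(self, small_genome):
        g = small_genome
        t = g.ttaa_sites[8]
        clone = synthetic.Clone("c", [(t, "+")], 10)
        r1, _ = synthetic.simulate_reads([clone], g, 3)
        frags = [
            trim.trim_junction_read(rid, seq, trim.TagLibraryConfig())
            for rid, seq in r1
        ]
        frags = [f for f in frags if isinstance(f, trim.JunctionFragment)]
        alns, _ = sites.align_fragments(frags, g)
        side_of = {f.read_id: f.side for f in frags}
        per = [
            sites.call_sites(
                [a for a in alns if side_of[a.read_id] == side], g, side, "L"
            )[0]
            for side in ("PB5", "PB3")
        ]
        merged = sites.merge_sites(*per)
        assert len(merged) == 1
        assert merged[0].side_support["PB5"] > 0
        assert merged[0].side_support["PB3"] > 0

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_end_to_end_recovers_exact_insertion_set(self, seed, tmp_path):
        """Error-free reads round-trip to exactly the simulated sites."""
        genome = synthetic.generate_genome(8, 25000, rng_seed=seed)
        library = synthetic.simulate_library(genome, 30, rng_seed=seed + 50)
        r1, r2 = synthetic.simulate_reads(library, genome, seed + 100)
        synthetic.write_fastq(r1, tmp_path / f"s{seed}.r1.fastq")
        frags, _ = trim.process_fastq_pair(tmp_path / f"s{seed}.r1.fastq")
        alns, _ = sites.align_fragments(frags, genome)
        side_of = {f.read_id: f.side for f in frags}
        per = []
        for side in ("PB5", "PB3"):
            called, dropped = sites.call_sites(
                [a for a in alns if side_of[a.read_id] == side], genome, side, "L"
            )
            assert dropped == 0
            per.append(called)
        merged = sites.merge_sites(*per)
        truth = {(genome.chrom, p, o) for c in library for p, o in c.insertions}
        called_set = {(s.chrom, s.pos0, s.orientation) for s in merged}
        assert called_set == truth
        # conservation: site reads cannot exceed aligned reads
        assert sum(s.total_reads for s in merged) <= len(alns)


class TestGeneCounts:
    def make_sites(self):
        return [
            sites.InsertionSite("chrT", 150, "+", read_count={"A": 3, "B": 1}),
            sites.InsertionSite("chrT", 500, "-", read_count={"A": 2}),
            sites.InsertionSite("chrT", 5000, "+", read_count={"B": 7}),
        ]

    def genes(self):
        return [
            GeneModel("g1", "chrT", 100, 600, "+", ((100, 600),)),
            GeneModel("g2", "chrT", 400, 900, "-", ((400, 900),)),
        ]

    def test_assignment_rules(self):
        m = sites.assign_to_genes(
            self.make_sites(), self.genes(), {"A": 100, "B": 100}
        )
        # site at 150 only in g1; site at 500 overlaps g1 and g2 (both count);
        # site at 5000 in no gene contributes nothing
        assert m.counts.loc["g1", "A"] == 5
        assert m.counts.loc["g2", "A"] == 2
        assert m.counts.loc["g1", "B"] == 1
        assert "g2" in m.gene_ids
        assert m.mutant_gene_counts()["A"] == 2

    def test_simulated_gene_coverage_matches_truth(self, screen_truth):
        genome, _, library, selected = screen_truth
        matrix = counts_from_clones(selected, genome)
        truth_genes = {
            g.gene_id
            for c in selected["C0L"]
            for p, _ in c.insertions
            for g in genome.genes
            if g.contains(p)
        }
        covered = set(matrix.counts.index[matrix.counts["C0L"] > 0])
        assert covered == truth_genes

    def test_cpm_arithmetic_and_scale_invariance(self):
        m = GeneCountMatrix(
            pd.DataFrame({"L": [10, 90]}, index=["g1", "g2"]),
            pd.Series({"L": 1_000_000}),
        )
        cpm = sites.normalize_cpm(m)
        assert cpm.loc["g1", "L"] == 10.0
        assert cpm["L"].sum() <= 1e6
        doubled = GeneCountMatrix(m.counts * 2, m.library_sizes * 2)
        assert np.allclose(sites.normalize_cpm(doubled), cpm)

    def test_cpm_zero_library_size_rejected(self):
        m = GeneCountMatrix(
            pd.DataFrame({"L": [1]}, index=["g"]), pd.Series({"L": 0})
        )
        with pytest.raises(ValidationError):
            sites.normalize_cpm(m)


class TestLibraryCorrelation:
    def test_identical_libraries_correlate_perfectly(self):
        counts = pd.DataFrame(
            {"A": [5, 10, 0, 3], "B": [5, 10, 0, 3], "C": [0, 1, 20, 2]},
            index=list("wxyz"),
        )
        m = GeneCountMatrix(counts, pd.Series({"A": 100, "B": 100, "C": 100}))
        corr, order = sites.library_correlation(m)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.loc["A", "B"] == pytest.approx(1.0)
        assert set(order) == {"A", "B", "C"}
        # A and B are identical so they must be adjacent leaves
        assert abs(order.index("A") - order.index("B")) == 1

    def test_matches_closed_form_pearson(self):
        counts = pd.DataFrame(
            {"A": [1, 5, 9], "B": [2, 4, 8], "C": [9, 1, 1]}, index=list("abc")
        )
        sizes = pd.Series({"A": 50, "B": 40, "C": 60})
        m = GeneCountMatrix(counts, sizes)
        corr, _ = sites.library_correlation(m)
        x = np.log2(counts / sizes * 1e6 + 0.5)
        for u in "ABC":
            for v in "ABC":
                xu, xv = x[u] - x[u].mean(), x[v] - x[v].mean()
                expected = (xu @ xv) / np.sqrt((xu @ xu) * (xv @ xv))
                assert corr.loc[u, v] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_library_warns_not_raises(self):
        counts = pd.DataFrame({"A": [1, 1], "B": [3, 9]}, index=["g1", "g2"])
        m = GeneCountMatrix(counts, pd.Series({"A": 2, "B": 12}))
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, _ = sites.library_correlation(m)
        assert corr.loc["A", "B"] == 0.0
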