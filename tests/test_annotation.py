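"""Gene-model construction, windows, mappability and consequence calls."""

import numpy as np
import pandas as pd
import pytest

import exindnm as ed
from exindnm.annotation import (CENTRAL_EXON, INTERGENIC, INTRON, OTHER_EXON,
                                exon_middle, merge_intervals, subtract_intervals)

from conftest import make_coding_gene


class TestBuildGeneModels:
    def test_transcript_union_gives_meta_exons(self, toy_annotation):
        """Two transcripts sharing exon 2: meta-exons are the interval union and
        the only internal exon is exon 2 (brute-force union oracle)."""
        genes, report = ed.build_gene_models(toy_annotation)
        (gene,) = [g for g in genes if g.gene_id == "geneA"]
        # oracle: per-base union of all exon intervals of geneA
        covered = np.zeros(1100, dtype=bool)
        for s, e in [(100, 200), (400, 500), (800, 1000), (150, 250), (400, 500)]:
            covered[s:e] = True
        runs = []
        in_run = False
        for i, c in enumerate(covered):
            if c and not in_run:
                runs.append([i, None]); in_run = True
            if not c and in_run:
                runs[-1][1] = i; in_run = False
        merged = [(s, e) for s, e in runs]
        assert merged == [(100, 250), (400, 500), (800, 1000)]
        assert gene.meta_exons == [(400, 500)]  # internal exon only
        assert gene.meta_introns == []

    def test_single_exon_gene_discarded(self, toy_annotation):
        genes, report = ed.build_gene_models(toy_annotation)
        assert "geneB" not in {g.gene_id for g in genes}
        assert report["removed_intronless"] == 1

    def test_overlapping_genes_both_discarded(self, toy_annotation):
        extra = toy_annotation.copy()
        clash = pd.DataFrame([
            ("chr1", "toy", "gene", 900, 2000, "+", ".", "geneC", ""),
            ("chr1", "toy", "exon", 900, 1100, "+", ".", "geneC", "t4"),
            ("chr1", "toy", "exon", 1400, 1500, "+", ".", "geneC", "t4"),
            ("chr1", "toy", "exon", 1900, 2000, "+", ".", "geneC", "t4"),
        ], columns=extra.columns)
        genes, report = ed.build_gene_models(pd.concat([extra, clash], ignore_index=True))
        ids = {g.gene_id for g in genes}
        assert "geneA" not in ids and "geneC" not in ids
        assert report["removed_overlapping"] == 2

    def test_malformed_interval_rejected_with_warning(self, toy_annotation):
        bad = toy_annotation.copy()
        bad.loc[len(bad)] = ("chr1", "toy", "exon", 450, 450, "+", ".", "geneA", "t1")
        with pytest.warns(UserWarning, match="malformed"):
            genes, _ = ed.build_gene_models(bad)
        (gene,) = [g for g in genes if g.gene_id == "geneA"]
        assert gene.meta_exons == [(400, 500)]

    def test_autosome_filter(self, toy_annotation):
        chrx = toy_annotation.copy()
        chrx["Chromosome"] = "chrX"
        genes, report = ed.build_gene_models(chrx, autosome_names=["chr1"])
        assert genes == [] and report["removed_non_autosomal"] == 2

    def test_utr_removed_from_meta_exons(self):
        rows = [
            ("chr1", "toy", "exon", 100, 200, "+", ".", "g", "t"),
            ("chr1", "toy", "exon", 300, 400, "+", ".", "g", "t"),
            ("chr1", "toy", "exon", 500, 600, "+", ".", "g", "t"),
            ("chr1", "toy", "exon", 700, 800, "+", ".", "g", "t"),
            ("chr1", "toy", "UTR", 100, 150, "+", ".", "g", "t"),
        ]
        ann = pd.DataFrame(rows, columns=["Chromosome", "Source", "Feature", "Start",
                                          "End", "Strand", "Frame", "gene_id",
                                          "transcript_id"])
        genes, _ = ed.build_gene_models(ann)
        assert genes[0].meta_exons == [(300, 400), (500, 600)]

    def test_exon_intron_lengths_tile_gene_span(self, small_world):
        for gene in small_world["genes"]:
            s, e = gene.span
            assert gene.exonic_length() + gene.intronic_length() == e - s


class TestWindows:
    def test_window_arithmetic(self):
        assert exon_middle(1000, 1101) == 1050
        assert exon_middle(1000, 1100) == 1049  # even length: floor

    def test_window_span_and_width(self, small_world):
        for w in small_world["windows"]:
            assert w.width == 2001
            assert w.end - w.start == 2001
            assert w.start == w.center - 1000

    def test_label_vector_matches_bruteforce_interval_scan(self, small_world):
        """Per-position labels equal an independent interval-membership lookup."""
        genes = small_world["genes"]
        windows = small_world["windows"]
        by_id = {g.gene_id: g for g in genes}
        for w in windows[:20]:
            anchor = by_id[w.source_gene_id]
            for off in range(0, w.width, 37):
                pos = w.start + off
                expect = INTERGENIC
                for g in genes:
                    if g.chrom != w.chrom:
                        continue
                    if any(s <= pos < e for s, e in g.meta_introns):
                        expect = INTRON
                    if any(s <= pos < e for s, e in g.meta_exons):
                        expect = OTHER_EXON
                anchor_exon = [iv for iv in anchor.meta_exons
                               if iv[0] <= w.center < iv[1]][0]
                if anchor_exon[0] <= pos < anchor_exon[1]:
                    expect = CENTRAL_EXON
                assert w.site_labels[off] == expect, (w.source_gene_id, pos)

    def test_labels_shift_invariant(self):
        """Shifting all coordinates by a constant leaves label vectors unchanged."""
        def build(shift):
            g = ed.GeneModel("g", "c", "+",
                             meta_exons=[(s + shift, e + shift)
                                         for s, e in [(2000, 2101), (3000, 3101)]],
                             meta_introns=[(2101 + shift, 3000 + shift)])
            return ed.extract_windows([g], {"c": 10000 + shift}, width=801)

        base = build(0)
        moved = build(500)
        assert len(base) == len(moved) == 2
        for a, b in zip(base, moved):
            assert np.array_equal(a.site_labels, b.site_labels)

    def test_offchromosome_window_dropped(self):
        g = ed.GeneModel("g", "c", "+", meta_exons=[(100, 201)], meta_introns=[])
        with pytest.warns(UserWarning, match="dropped"):
            assert ed.extract_windows([g], {"c": 5000}, width=2001) == []

    def test_saturated_central_exon(self):
        g = ed.GeneModel("g", "c", "+", meta_exons=[(1000, 3001)], meta_introns=[])
        (w,) = ed.extract_windows([g], {"c": 10000}, width=2001)
        assert (w.site_labels == CENTRAL_EXON).all()


class TestMappability:
    def test_empty_mask_is_identity(self, small_world):
        mask = ed.MappabilityMask({})
        windows = small_world["windows"]
        assert ed.filter_windows_by_mappability(windows, mask) == windows

    def test_single_base_overlap_removes_window(self, small_world):
        w = small_world["windows"][0]
        mask = ed.MappabilityMask({w.chrom: [(w.start, w.start + 1)]})
        assert w not in ed.filter_windows_by_mappability([w], mask)

    def test_random_mask_matches_pairwise_overlap_oracle(self, small_world, rng):
        windows = small_world["windows"]
        chroms = list(small_world["chrom_lengths"])
        regions = {c: [(int(s), int(s) + int(rng.integers(1, 400)))
                       for s in rng.integers(0, small_world["chrom_lengths"][c], size=15)]
                   for c in chroms}
        mask = ed.MappabilityMask(regions)
        kept = ed.filter_windows_by_mappability(windows, mask)
        for w in windows:
            hit = any(s < w.end and e > w.start
                      for s, e in regions.get(w.chrom, []))
            assert (w in kept) == (not hit)


class TestConsequence:
    def test_known_codon_changes(self):
        # CTG(Leu) -> CTA(Leu) at codon pos 3; ATG(Met) -> GTG(Val) at codon pos 1
        genome, gene = make_coding_gene(["ATGCTGAAA"], [], offset=10)
        assert ed.classify_consequence("chr1", 15, "G", "A", gene, genome) == "synonymous"
        assert ed.classify_consequence("chr1", 10, "A", "G", gene, genome) == "nonsynonymous"

    def test_intronic_is_noncoding(self):
        genome, gene = make_coding_gene(["ATGCTG", "AAATTT", "GGGCCC"],
                                        ["TTTTT", "AAAAA"], offset=10)
        intron_pos = gene.cds_intervals[0][1]  # first intron base
        ref = genome.fetch("chr1", intron_pos, intron_pos + 1)
        alt = "A" if ref != "A" else "C"
        assert ed.classify_consequence("chr1", intron_pos, ref, alt, gene, genome) == "noncoding"

    def test_ref_mismatch_raises(self):
        genome, gene = make_coding_gene(["ATGCTGAAA"], [], offset=10)
        with pytest.raises(ValueError, match="ref allele"):
            ed.classify_consequence("chr1", 10, "C", "G", gene, genome)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_snvs_match_whole_protein_oracle(self, strand, rng):
        """100 random coding SNVs labelled identically to a full-CDS
        translate-and-compare oracle, on both strands."""
        from Bio.Seq import Seq

        bases = "ACGT"
        exons = ["".join(rng.choice(list(bases), size=30)) for _ in range(3)]
        total = sum(len(e) for e in exons)
        exons[-1] += "A" * ((-total) % 3)
        introns = ["".join(rng.choice(list(bases), size=20)) for _ in range(2)]
        genome, gene = make_coding_gene(exons, introns, strand=strand, offset=20)

        ivs = sorted(gene.cds_intervals)
        cds_positions = [p for s, e in ivs for p in range(s, e)]

        def spliced_with(pos=None, alt=None):
            seq = ""
            for s, e in ivs:
                part = genome.fetch("chr1", s, e)
                if pos is not None and s <= pos < e:
                    part = part[:pos - s] + alt + part[pos - s + 1:]
                seq += part
            return str(Seq(seq).reverse_complement()) if strand == "-" else seq

        protein_ref = str(Seq(spliced_with()).translate())
        for _ in range(100):
            pos = int(rng.choice(cds_positions))
            ref = genome.fetch("chr1", pos, pos + 1)
            alt = str(rng.choice([b for b in bases if b != ref]))
            got = ed.classify_consequence("chr1", pos, ref, alt, gene, genome)
            protein_alt = str(Seq(spliced_with(pos, alt)).translate())
            expect = "synonymous" if protein_alt == protein_ref else "nonsynonymous"
            assert got == expect, (strand, pos, ref, alt)


class TestIntervalOps:
    def test_merge_and_subtract(self):
        assert merge_intervals([(5, 10), (1, 6), (20, 30)]) == [(1, 10), (20, 30)]
        assert subtract_intervals([(0, 100)], [(10, 20), (50, 60)]) == [
            (0, 10), (20, 50), (60, 100)]
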