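import numpy as np
import pytest

from ciliascreen.motif_scan import (
    BedFormatError,
    IUPACMotif,
    PromoterSet,
    extract_promoters,
    genes_with_motif,
    motif_enrichment,
    read_promoter_fasta,
    reverse_complement,
    scan_motif,
    write_promoter_fasta,
)

from oracles import sliding_window_motif_oracle


class TestIUPACMotif:
    def test_validates_alphabet(self):
        assert IUPACMotif("cannTG").pattern == "CANNTG"
        with pytest.raises(ValueError):
            IUPACMotif("CAXXTG")
        with pytest.raises(ValueError):
            IUPACMotif("")

    def test_reverse_complement_of_degenerate_codes(self):
        assert IUPACMotif("CANNTG").reverse_complement().pattern == "CANNTG"
        assert IUPACMotif("RYSWKM").reverse_complement().pattern == "KMWSRY"

    def test_expansions_enumerate_concrete_sequences(self):
        assert sorted(IUPACMotif("CR").expansions()) == ["CA", "CG"]
        assert len(IUPACMotif("CANNTG").expansions()) == 16


class TestScanMotif:
    def test_ebox_found_by_inspection(self):
        hits = scan_motif("TTCACGTGTT", IUPACMotif("CANNTG"))
        assert [(h.offset, h.strand, h.matched) for h in hits] == [
            (2, "+", "CACGTG")
        ]

    def test_empty_sequence_has_no_hits(self):
        assert scan_motif("", IUPACMotif("CANNTG")) == []

    def test_overlapping_hits_all_reported(self):
        # CACATG at 0 and CATGTG at 2 overlap
        hits = scan_motif("CACATGTG", IUPACMotif("CANNTG"))
        assert [h.offset for h in hits] == [0, 2]

    def test_sequence_n_matches_only_code_n(self):
        assert scan_motif("CANNTG", IUPACMotif("CANNTG"))
        assert not scan_motif("NACGTG", IUPACMotif("CANNTG"))
        assert scan_motif("ACGNT", IUPACMotif("ACGNT"))

    @pytest.mark.parametrize(
        "seq,motif",
        [
            ("TTCACGTGTT", "CANNTG"),
            ("CACATGTGCATGCANNTG".replace("N", "A"), "CANNTG"),
            ("ACGTACGTACGTACGT", "RYS"),
            ("GGGGGG", "CANNTG"),
        ],
    )
    def test_both_strands_matches_sliding_window_oracle(self, seq, motif):
        hits = scan_motif(seq, IUPACMotif(motif), both_strands=True)
        assert sorted((h.offset, h.strand) for h in hits) == (
            sliding_window_motif_oracle(seq, motif, True)
        )

    def test_hits_mirror_on_reverse_complement(self):
        seq = "TTCACGTGATCCATTGAC"
        motif = IUPACMotif("CANNTG")
        fwd = scan_motif(seq, motif, both_strands=True)
        rev = scan_motif(reverse_complement(seq), motif, both_strands=True)
        mirrored = sorted(
            (len(seq) - h.offset - len(motif), {"+": "-", "-": "+"}[h.strand])
            for h in rev
        )
        assert sorted((h.offset, h.strand) for h in fwd) == mirrored

    def test_palindromic_motif_double_reports_but_presence_dedupes(self):
        seq = "TTCACGTGTT"  # CACGTG is its own reverse complement
        hits = scan_motif(seq, IUPACMotif("CACGTG"), both_strands=True)
        assert len(hits) == 2
        assert {h.strand for h in hits} == {"+", "-"}
        present, counts = genes_with_motif(
            PromoterSet({"g": seq}, 10, {}), IUPACMotif("CACGTG")
        )
        assert present == {"g"} and counts["g"] == 2


class TestExtractPromoters:
    def write_genome(self, tmp_path, contigs):
        fa = tmp_path / "genome.fa"
        fa.write_text(
            "".join(f">{name}\n{seq}\n" for name, seq in contigs.items())
        )
        return fa

    def write_bed(self, tmp_path, lines):
        bed = tmp_path / "genes.bed"
        bed.write_text("".join(lines))
        return bed

    def test_plus_strand_window_by_inspection(self, tmp_path):
        fa = self.write_genome(tmp_path, {"chrI": "ACGTACGTACGT"})
        bed = self.write_bed(tmp_path, ["chrI\t8\t12\tgeneA\t0\t+\n"])
        prom = extract_promoters(fa, bed, upstream=4)
        assert prom["geneA"] == "ACGT"  # positions 4..7

    def test_minus_strand_is_reverse_complement(self, tmp_path):
        # non-palindromic control: upstream of a minus-strand gene ending at 4
        fa = self.write_genome(tmp_path, {"chrI": "ACGTTTGGACGT"})
        bed = self.write_bed(tmp_path, ["chrI\t0\t4\tgeneB\t0\t-\n"])
        prom = extract_promoters(fa, bed, upstream=4)
        # genome[4:8] = TTGG; reverse complement computed by hand = CCAA
        assert prom["geneB"] == "CCAA"

    def test_contig_start_clips_with_warning(self, tmp_path, caplog):
        fa = self.write_genome(tmp_path, {"chrI": "ACGTACGTACGT"})
        bed = self.write_bed(tmp_path, ["chrI\t2\t6\tgeneC\t0\t+\n"])
        with caplog.at_level("WARNING"):
            prom = extract_promoters(fa, bed, upstream=5)
        assert prom["geneC"] == "AC"
        assert prom.clipped["geneC"] == 3
        assert any("clipped" in r.message for r in caplog.records)

    def test_length_plus_clip_equals_upstream(self, tmp_path):
        fa = self.write_genome(tmp_path, {"chrI": "ACGT" * 10})
        bed = self.write_bed(
            tmp_path,
            ["chrI\t3\t9\tg1\t0\t+\n", "chrI\t30\t38\tg2\t0\t-\n"],
        )
        prom = extract_promoters(fa, bed, upstream=6)
        for g in ("g1", "g2"):
            assert len(prom[g]) + prom.clipped[g] == 6

    def test_soft_masked_bases_uppercased(self, tmp_path):
        fa = self.write_genome(tmp_path, {"chrI": "acgtACGTacgt"})
        bed = self.write_bed(tmp_path, ["chrI\t8\t12\tg\t0\t+\n"])
        assert extract_promoters(fa, bed, upstream=4)["g"] == "ACGT"

    def test_missing_contig_and_malformed_bed(self, tmp_path):
        fa = self.write_genome(tmp_path, {"chrI": "ACGT"})
        with pytest.raises(KeyError):
            extract_promoters(
                fa, self.write_bed(tmp_path, ["chrX\t0\t4\tg\t0\t+\n"]), 2
            )
        with pytest.raises(BedFormatError):
            extract_promoters(fa, self.write_bed(tmp_path, ["chrI\t0\t4\tg\n"]), 2)

    def test_fasta_round_trip(self, tmp_path):
        prom = PromoterSet({"a": "ACGTAC", "b": "GGTTAA"}, 6, {})
        path = tmp_path / "prom.fa"
        write_promoter_fasta(prom, path)
        again = read_promoter_fasta(path, nominal_length=6)
        assert again.sequences == prom.sequences


class TestGenesWithMotif:
    def test_monotone_under_code_widening(self):
        rng = np.random.default_rng(0)
        seqs = {
            f"g{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(40)
        }
        prom = PromoterSet(seqs, 60, {})
        narrow, _ = genes_with_motif(prom, IUPACMotif("CACGTG"))
        wide, _ = genes_with_motif(prom, IUPACMotif("CANNTG"))
        assert narrow <= wide

    def test_counts_agree_with_per_gene_scans(self):
        rng = np.random.default_rng(1)
        prom = PromoterSet(
            {f"g{i}": "".join(rng.choice(list("ACGT"), size=80)) for i in range(20)},
            80,
            {},
        )
        motif = IUPACMotif("CANNTG")
        present, counts = genes_with_motif(prom, motif)
        for g in prom.genes():
            assert counts[g] == len(scan_motif(prom[g], motif, both_strands=True))
        assert present == {g for g, c in counts.items() if c}


class TestMotifEnrichment:
    def build(self, fg_rate, bg_rate, n=60, seed=0):
        rng = np.random.default_rng(seed)
        seqs, fg = {}, set()
        for i in range(n):
            gene = f"g{i}"
            rate = fg_rate if i < n // 2 else bg_rate
            if i < n // 2:
                fg.add(gene)
            has = rng.random() < rate
            seqs[gene] = ("TT" * 10 + "CACGTG" + "TT" * 10) if has else "TT" * 23
        return fg, set(seqs), PromoterSet(seqs, 46, {})

    def test_fold_two_on_balanced_all_vs_half(self):
        fg, bg, prom = self.build(1.0, 0.0)
        result, table = motif_enrichment(fg, bg, prom, IUPACMotif("CANNTG"))
        assert result.fold == pytest.approx(2.0)

    def test_equal_rates_give_zero_chi2(self):
        # exactly half of each class carries the motif -> perfect independence
        with_motif = "TT" * 10 + "CACGTG" + "TT" * 10
        without = "TT" * 23
        seqs = {
            f"g{i}": (with_motif if i % 2 == 0 else without) for i in range(60)
        }
        fg = {f"g{i}" for i in range(30)}
        result, _ = motif_enrichment(
            fg, set(seqs), PromoterSet(seqs, 46, {}), IUPACMotif("CANNTG")
        )
        assert result.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_foreground_must_be_proper_subset(self):
        fg, bg, prom = self.build(1.0, 0.0)
        with pytest.raises(ValueError):
            motif_enrichment(bg, bg, prom, IUPACMotif("CANNTG"))
        with pytest.raises(ValueError):
            motif_enrichment({"ghost"}, bg, prom, IUPACMotif("CANNTG"))
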