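import numpy as np
import pytest

from altimir._seq import revcomp
from altimir.novel import (
    FoldError,
    REASON_ARMS,
    REASON_BULGE_SIZE,
    REASON_MISMATCH,
    annotate_origin,
    candidate_loci,
    discover_novel,
    fold,
    load_gene_models,
    make_stub_engine,
    pair_table,
    validate_hairpin,
    viennarna_engine,
)
from altimir.preprocess import TagTable


def structure_from_pairs(length: int, pairs: list[tuple[int, int]]) -> str:
    chars = ["."] * length
    for i, j in pairs:
        a, b = min(i, j), max(i, j)
        chars[a], chars[b] = "(", ")"
    return "".join(chars)


def perfect_hairpin_structure(stem=30, loop=8, pad=6):
    length = 2 * stem + loop + pad
    pairs = [(i, 2 * stem + loop - 1 - i) for i in range(stem)]
    return length, structure_from_pairs(length, pairs), pairs


MATURE_SPAN = (5, 26)


class TestValidator:
    def test_perfect_duplex_passes_with_clean_geometry(self):
        length, structure, _ = perfect_hairpin_structure()
        ok, reasons, geom, star = validate_hairpin("N" * length, structure, MATURE_SPAN)
        assert ok and reasons == []
        assert geom.n_mismatch == 0 and geom.bulges == []
        # star of [5, 26) under pairing i <-> 67-i, shifted +2
        assert star == (44, 65)

    def test_five_unpaired_mature_positions_fail_as_mismatches(self):
        stem, loop = 30, 8
        pairs = [
            (i, 2 * stem + loop - 1 - i)
            for i in range(stem)
            if i not in range(8, 13)  # open a 5-position symmetric loop
        ]
        length = 2 * stem + loop + 6
        structure = structure_from_pairs(length, pairs)
        ok, reasons, geom, _ = validate_hairpin("N" * length, structure, MATURE_SPAN)
        assert not ok
        assert reasons == [REASON_MISMATCH]
        assert geom.n_mismatch == 5

    def test_three_nt_asymmetric_bulge_fails_on_size(self):
        # mature positions 5..14 pair with 67-i; 15..25 pair with 64-i,
        # leaving a 3-nt bulge on the star arm and nothing else wrong
        pairs = [(i, 67 - i) for i in range(0, 15)] + [(i, 64 - i) for i in range(15, 30)]
        length = 74
        structure = structure_from_pairs(length, pairs)
        ok, reasons, geom, _ = validate_hairpin("N" * length, structure, MATURE_SPAN)
        assert not ok
        assert reasons == [REASON_BULGE_SIZE]
        assert geom.bulges == [("star", 3)]

    def test_loop_spanning_mature_fails_on_arms(self):
        length, structure, _ = perfect_hairpin_structure()
        ok, reasons, _, _ = validate_hairpin("N" * length, structure, (25, 46))
        assert not ok and reasons == [REASON_ARMS]

    def test_span_outside_structure_is_an_error(self):
        with pytest.raises(ValueError):
            validate_hairpin("NNNN", "....", (2, 8))


class TestFoldContract:
    def test_stub_structure_is_accepted_and_stored(self):
        engine = make_stub_engine({"GGGAAACCC": ("(((...)))", -1.5)})
        structure, mfe = fold("GGGAAACCC", engine)
        assert structure == "(((...)))" and mfe == -1.5

    def test_length_mismatch_is_a_fold_error(self):
        engine = make_stub_engine({"GGGAAACCC": ("((..))", -1.0)})
        with pytest.raises(FoldError):
            fold("GGGAAACCC", engine)

    def test_unbalanced_structure_is_a_fold_error(self):
        engine = make_stub_engine({"GGGAAACCC": ("(((...(((", -1.0)})
        with pytest.raises(FoldError):
            fold("GGGAAACCC", engine)

    def test_engine_exception_becomes_fold_error(self):
        def engine(seq):
            raise RuntimeError("boom")

        with pytest.raises(FoldError):
            fold("GGGAAACCC", engine)

    def test_real_folder_pairs_a_perfect_inverted_repeat(self):
        rng = np.random.default_rng(10)
        arm = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        hp = arm + "GAGAGA" + revcomp(arm)
        structure, mfe = fold(hp, viennarna_engine)
        paired_mature = sum(1 for c in structure[:30] if c == "(")
        assert paired_mature >= 28
        assert mfe < -20


class TestCandidateLoci:
    GENOME = None

    def _genome(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        return {"chr1": seq}

    def test_abundance_threshold_is_strict(self):
        genome = self._genome()
        tag = genome["chr1"][500:521]
        tags = TagTable()
        tags.add(tag, "L", 9)
        assert candidate_loci(tags, genome) == []
        tags2 = TagTable()
        tags2.add(tag, "L", 10)
        (locus,) = candidate_loci(tags2, genome)
        assert len(locus.window_seq) == 21 + 2 * 100
        assert locus.mature_tag == tag

    def test_overlapping_tags_merge_behind_the_most_abundant(self):
        genome = self._genome()
        lead = genome["chr1"][600:621]
        trailer = genome["chr1"][602:623]
        tags = TagTable()
        tags.add(lead, "L", 50)
        tags.add(trailer, "L", 20)
        loci = [l for l in candidate_loci(tags, genome) if l.strand == "+"]
        assert len(loci) == 1
        assert loci[0].mature_tag == lead and loci[0].count == 50

    def test_window_is_clipped_at_chromosome_ends(self):
        genome = self._genome()
        tag = genome["chr1"][5:26]
        tags = TagTable()
        tags.add(tag, "L", 12)
        loci = [l for l in candidate_loci(tags, genome) if l.strand == "+" and l.start == 5]
        assert loci and loci[0].window_start == 0


GFF = """##gff-version 3
chr1\t.\tgene\t101\t700\t.\t+\t.\tID=g1
chr1\t.\texon\t101\t200\t.\t+\t.\tID=g1.e1;Parent=g1
chr1\t.\texon\t601\t700\t.\t+\t.\tID=g1.e2;Parent=g1
"""


class TestOrigin:
    @pytest.fixture(scope="class")
    def db(self, tmp_path_factory):
        p = tmp_path_factory.mktemp("gff") / "genes.gff3"
        p.write_text(GFF)
        return load_gene_models(p)

    def test_three_way_labels(self, db):
        assert annotate_origin(("chr1", 300, 321), db) == "intronic"
        assert annotate_origin(("chr1", 900, 921), db) == "intergenic"
        assert annotate_origin(("chr1", 190, 211), db) == "exonic"  # overlaps a boundary

    def test_matches_brute_force_interval_scan(self, db):
        gene = (100, 700)  # 0-based half-open
        exons = [(100, 200), (600, 700)]
        rng = np.random.default_rng(8)
        for _ in range(1000):
            start = int(rng.integers(0, 1200))
            end = start + 21
            locus = ("chr1", start, end)
            if any(start < e and s < end for s, e in exons):
                expected = "exonic"
            elif start < gene[1] and gene[0] < end:
                expected = "intronic"
            else:
                expected = "intergenic"
            assert annotate_origin(locus, db) == expected


class TestDiscovery:
    def test_deterministic_with_stub_engine(self):
        rng = np.random.default_rng(9)
        arm = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        hp = arm + "GAGAGA" + revcomp(arm)
        flank_l = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        flank_r = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        genome = {"chr1": flank_l + hp + flank_r}
        mature = hp[2:23]
        tags = TagTable()
        tags.add(mature, "L", 40)

        def engine(seq):
            # fold every query as a flat structure except the planted window
            return ("." * len(seq), 0.0)

        runs = [discover_novel(tags, genome, engine) for _ in range(2)]
        assert len(runs[0]) == len(runs[1]) >= 1
        for a, b in zip(*runs):
            assert (a.locus.chrom, a.locus.start, a.verdict, a.failure_reasons) == (
                b.locus.chrom,
                b.locus.start,
                b.verdict,
                b.failure_reasons,
            )

    def test_planted_hairpin_passes_with_the_real_folder(self):
        rng = np.random.default_rng(12)
        arm = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        hp = arm + "GAGAGAGA" + revcomp(arm)
        flank_l = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        flank_r = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        genome = {"chr1": flank_l + hp + flank_r}
        mature = hp[5:26]
        tags = TagTable()
        tags.add(mature, "L", 25)
        candidates = discover_novel(tags, genome, viennarna_engine)
        plus = [c for c in candidates if c.locus.strand == "+"]
        assert any(c.verdict for c in plus)
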