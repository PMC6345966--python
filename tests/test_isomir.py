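import numpy as np
import pytest

from oracles import brute_force_isomir, enumerate_isomir_tags

from altimir._seq import revcomp
from altimir.annotation import AnnotationIndex, MatureAnnotation
from altimir.isomir import (
    BOTH_END,
    CANONICAL,
    NONTEMPLATE_3P,
    SHIFTED,
    START_SITE,
    SUBSTITUTION,
    TEMPLATE_3P,
    arm_usage,
    assign_isomirs,
    classify_isomir,
    isomir_summary,
    nta_base_composition,
)
from altimir.preprocess import TagTable
from altimir.quantify import ExpressionMatrix, normalize_rpm
import pandas as pd


def make_locus(seed=0, mat_len=21, stem=30, loop=8, pad=6):
    rng = np.random.default_rng(seed)
    arm = "".join("ACGT"[i] for i in rng.integers(0, 4, stem))
    loop_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, loop))
    pad_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, pad))
    hp = arm + loop_seq + revcomp(arm) + pad_seq
    s = 5
    mature = MatureAnnotation("mir-5p", "mir", "5p", "hp", s, s + mat_len, hp[s : s + mat_len])
    return mature, hp


class TestDecisionTree:
    def setup_method(self):
        self.mature, self.hp = make_locus()
        self.s, self.e = self.mature.start, self.mature.end

    def classify(self, tag):
        return classify_isomir(tag, self.mature, self.hp)

    def test_canonical(self):
        rec = self.classify(self.mature.sequence)
        assert rec.category == CANONICAL and (rec.offset5, rec.offset3) == (0, 0)

    def test_shifted_both_ends_plus_one(self):
        rec = self.classify(self.hp[self.s + 1 : self.e + 1])
        assert rec.category == SHIFTED and (rec.offset5, rec.offset3) == (1, 1)

    def test_template_addition(self):
        rec = self.classify(self.hp[self.s : self.e + 1])
        assert rec.category == TEMPLATE_3P and rec.offset3 == 1 and rec.tail == ""

    def test_template_deletion(self):
        rec = self.classify(self.hp[self.s : self.e - 2])
        assert rec.category == TEMPLATE_3P and rec.offset3 == -2

    def test_nontemplate_tail_disagreeing_with_template(self):
        template_next = self.hp[self.e]
        tail = "A" if template_next != "A" else "C"
        rec = self.classify(self.mature.sequence + tail)
        assert rec.category == NONTEMPLATE_3P and rec.tail == tail and rec.offset5 == 0

    def test_start_site_upstream_extension(self):
        rec = self.classify(self.hp[self.s - 1 : self.e])
        assert rec.category == START_SITE and rec.offset5 == -1

    def test_both_end_variation(self):
        rec = self.classify(self.hp[self.s - 1 : self.e + 1])
        assert rec.category == BOTH_END and (rec.offset5, rec.offset3) == (-1, 1)

    def test_internal_substitution(self):
        seq = self.mature.sequence
        new = "A" if seq[10] != "A" else "G"
        rec = self.classify(seq[:10] + new + seq[11:])
        assert rec.category == SUBSTITUTION and rec.mismatch_positions == (10,)

    def test_final_base_mismatch_is_a_tail_not_a_substitution(self):
        seq = self.mature.sequence
        new = "A" if seq[-1] != "A" else "G"
        rec = self.classify(seq[:-1] + new)
        assert rec.category == NONTEMPLATE_3P and rec.tail == new

    def test_first_base_mismatch_is_unassigned(self):
        seq = self.mature.sequence
        new = "A" if seq[0] != "A" else "G"
        assert self.classify(new + seq[1:]) is None

    def test_out_of_range_tag_length_rejected(self):
        with pytest.raises(ValueError):
            self.classify("ACGTACGTACGTACGTA")  # 17 nt


class TestOracleEquivalence:
    def test_agrees_with_brute_force_on_enumerated_tags(self):
        """Exhaustive windowed substrings, 3' extensions and substitution
        variants classify identically under the package implementation and
        the independent enumeration oracle."""
        disagreements = []
        for seed in range(6):
            mature, hp = make_locus(seed=seed, mat_len=20 + seed % 3)
            for tag in sorted(enumerate_isomir_tags(mature.start, mature.end, hp)):
                rec = classify_isomir(tag, mature, hp)
                expected = brute_force_isomir(tag, mature.start, mature.end, hp)
                got = None if rec is None else (rec.category, rec.offset5, rec.offset3, rec.tail)
                if got != expected:
                    disagreements.append((tag, got, expected))
        assert not disagreements, disagreements[:5]

    def test_window_growth_only_rescues_unassigned_tags(self):
        mature, hp = make_locus(seed=3)
        for tag in sorted(enumerate_isomir_tags(mature.start, mature.end, hp, window=5)):
            narrow = classify_isomir(tag, mature, hp, window=5)
            wide = classify_isomir(tag, mature, hp, window=8)
            if narrow is not None:
                assert wide is not None and wide.category == narrow.category


class TestSummaries:
    def _assigned(self, mature, hp, counts):
        tags = TagTable()
        template_next = hp[mature.end]
        tail = "A" if template_next != "A" else "C"
        tags.add(mature.sequence, "L", counts[0])
        tags.add(mature.sequence + tail, "L", counts[1])
        idx = AnnotationIndex(hairpins={"hp": hp}, matures=[mature])
        return assign_isomirs(tags, idx)

    def test_proportions_and_dominance(self):
        mature, hp = make_locus(1)
        assigned = self._assigned(mature, hp, (80, 20))
        (summary,) = isomir_summary(assigned, "L", library_total=1_000_000)
        total = summary.total_rpm
        assert summary.category_rpm[CANONICAL] / total == pytest.approx(0.8)
        assert summary.dominance == pytest.approx(0.8)
        assert summary.n_distinct_isomirs == 2

    def test_single_isomir_dominance_is_one(self):
        mature, hp = make_locus(2)
        assigned = self._assigned(mature, hp, (5, 0))
        assigned = [(r, c) for r, c in assigned if sum(c.values())]
        (summary,) = isomir_summary(assigned, "L", library_total=1000)
        assert summary.dominance == 1.0

    def test_dominance_is_scale_invariant(self):
        mature, hp = make_locus(4)
        s1 = isomir_summary(self._assigned(mature, hp, (60, 40)), "L", 10_000)[0]
        s2 = isomir_summary(self._assigned(mature, hp, (600, 400)), "L", 10_000)[0]
        assert s1.dominance == pytest.approx(s2.dominance)

    def test_category_proportions_sum_to_one(self):
        mature, hp = make_locus(5)
        assigned = self._assigned(mature, hp, (70, 30))
        (summary,) = isomir_summary(assigned, "L", 1_000_000)
        props = [v / summary.total_rpm for v in summary.category_rpm.values()]
        assert sum(props) == pytest.approx(1.0)


class TestNTAComposition:
    def _records(self, tail_counts):
        mature, hp = make_locus(6)
        template_next = hp[mature.end]
        tags = TagTable()
        bases = [b for b in "ACGT" if b != template_next]
        mapping = dict(zip("ACU", bases))  # place requested tails on safe bases
        for rna_base, n in tail_counts.items():
            if n:
                tags.add(mature.sequence + mapping[rna_base], "L", n)
        idx = AnnotationIndex(hairpins={"hp": hp}, matures=[mature])
        assigned = assign_isomirs(tags, idx)
        return assigned, mapping

    def test_weighted_proportions(self):
        assigned, mapping = self._records({"A": 32, "C": 30, "U": 38})
        comp = nta_base_composition(assigned, "L")
        by_dna = {mapping[k].replace("T", "U"): v for k, v in {"A": 0.32, "C": 0.30, "U": 0.38}.items()}
        for base, expected in by_dna.items():
            assert comp[base] == pytest.approx(expected)
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_single_tail(self):
        assigned, mapping = self._records({"A": 7})
        comp = nta_base_composition(assigned, "L")
        assert comp[mapping["A"].replace("T", "U")] == 1.0

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            assert nta_base_composition([], "L") == {}


class TestArmUsage:
    def _matrix(self, c5, c3):
        mature, hp = make_locus(7)
        star_seq = revcomp(mature.sequence)
        s3 = hp.find(star_seq)
        m3 = MatureAnnotation("mir-3p", "mir", "3p", "hp", s3, s3 + len(star_seq), star_seq)
        idx = AnnotationIndex(hairpins={"hp": hp}, matures=[mature, m3])
        raw = pd.DataFrame({"L": [c5, c3]}, index=["mir-5p", "mir-3p"])
        m = ExpressionMatrix(raw=raw)
        normalize_rpm(m, {"L": 1_000_000})
        return m, idx

    @pytest.mark.parametrize(
        "c5,c3,ratio", [(160, 10, 4.0), (50, 50, 0.0), (16384, 1, 14.0)]
    )
    def test_log2_ratios(self, c5, c3, ratio):
        m, idx = self._matrix(c5, c3)
        got5, got3, log2r, p = arm_usage(m, idx, "hp", "L")
        assert (got5, got3) == (c5, c3)
        assert log2r == pytest.approx(ratio)

    def test_balanced_arms_are_not_significant(self):
        m, idx = self._matrix(50, 50)
        *_, p = arm_usage(m, idx, "hp", "L")
        assert p == 1.0

    def test_missing_arm_is_an_error(self):
        mature, hp = make_locus(8)
        idx = AnnotationIndex(hairpins={"hp": hp}, matures=[mature])
        raw = pd.DataFrame({"L": [5]}, index=["mir-5p"])
        m = ExpressionMatrix(raw=raw)
        with pytest.raises(ValueError):
            arm_usage(m, idx, "hp", "L")
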