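import warnings

import numpy as np
import pytest

from hrscreen import errors
from hrscreen.variants import (
    FRAMESHIFT,
    MISSENSE,
    SYNONYMOUS,
    CodingSequence,
    CodingVariant,
    apply_indel,
    classify_indel,
    describe_frameshift,
    parse_coding_variant,
    stop_position_from_fs,
    translate_to_stop,
)

CDS = "ATGAAACTCTTAGGGTAA"  # MKLLG*


class TestCodingSequence:
    def test_valid_cds_accepted(self):
        assert len(CodingSequence("toy", CDS)) == 18

    @pytest.mark.parametrize(
        "seq", ["ATGAAACTC", "TTGAAACTCTAA", "ATGAAACT", "ATGNNNTAA"]
    )
    def test_invalid_cds_rejected(self, seq):
        with pytest.raises(errors.SequenceError):
            CodingSequence("bad", seq)


class TestParse:
    def test_deletion_span_and_length_check(self):
        v = parse_coding_variant("c.1413_1426del14")
        assert (v.del_start, v.del_end) == (1413, 1426)
        assert v.deletion_length == 14 and v.inserted == ""
        with pytest.raises(errors.NomenclatureError, match="length"):
            parse_coding_variant("c.1413_1426del13")

    def test_single_base_deletion(self):
        v = parse_coding_variant("c.7_7del")
        assert (v.del_start, v.del_end) == (7, 7)

    def test_insertion_with_bases(self):
        v = parse_coding_variant("c.6_7insACG")
        assert v.deletion_length == 0 and v.inserted == "ACG"

    def test_bracket_allele_normalised_to_single_replacement(self):
        v = parse_coding_variant("c.[80_83del4;79_84ins22]")
        assert (v.del_start, v.del_end) == (80, 83)
        assert v.inserted is None and v.ins_length == 22
        assert v.net_length_change == 18 and not v.shifts_frame
        assert "normalised" in v.note

    def test_empty_variant_rejected(self):
        with pytest.raises(errors.CoordinateError):
            CodingVariant(del_start=5, del_end=4, inserted="")

    @pytest.mark.parametrize("bad", ["c.del", "p.L3S", "c.5_3del", "c.1_2insXY"])
    def test_malformed_descriptors(self, bad):
        with pytest.raises((errors.NomenclatureError, errors.CoordinateError)):
            parse_coding_variant(bad)


class TestApplyIndel:
    def test_deletion_reduces_length_by_span(self):
        cds = CodingSequence("toy", CDS)
        out = apply_indel(cds, parse_coding_variant("c.7_7del"))
        assert out == "ATGAAATCTTAGGGTAA"
        assert len(out) == len(CDS) - 1

    def test_length_bookkeeping(self):
        cds = CodingSequence("toy", CDS)
        v = CodingVariant(4, 6, inserted="GGGGG")
        assert len(apply_indel(cds, v)) == len(CDS) - 3 + 5

    def test_out_of_range_rejected(self):
        cds = CodingSequence("toy", CDS)
        with pytest.raises(errors.CoordinateError):
            apply_indel(cds, CodingVariant(17, 30, inserted=""))

    def test_length_only_insertion_cannot_apply(self):
        cds = CodingSequence("toy", CDS)
        v = parse_coding_variant("c.[80_83del4;79_84ins22]")
        with pytest.raises(errors.SequenceError, match="length-only"):
            apply_indel(cds, v)


class TestTranslate:
    @pytest.mark.parametrize(
        "nt,protein,stop",
        [
            ("ATGTAA", "M", True),
            (CDS, "MKLLG", True),
            ("ATGAAATCTTAGGGTAA", "MKS", True),
            ("ATGAAA", "MK", False),
        ],
    )
    def test_codon_table_examples(self, nt, protein, stop):
        assert translate_to_stop(nt) == (protein, stop)

    def test_non_acgt_rejected(self):
        with pytest.raises(errors.SequenceError):
            translate_to_stop("ATGNNA")


class TestFrameshiftNomenclature:
    def test_constructed_example(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = describe_frameshift("MKLLG", "MKS")
        assert d.notation == "p.L3SfsX2"
        assert d.stop_position == 4 and d.kind == FRAMESHIFT

    def test_identical_proteins_rejected(self):
        with pytest.raises(errors.NotAFrameshiftError):
            describe_frameshift("MKLLG", "MKLLG")

    @pytest.mark.parametrize(
        "text,stop",
        [
            ("p.L471LfsX56", 527),  # retained anchor: pos + offset
            ("p.A10AfsX1", 11),
            ("p.L3SfsX2", 4),       # substituted anchor: pos + offset - 1
            ("p.R27LfsX3", 29),
        ],
    )
    def test_stop_position_conventions(self, text, stop):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert stop_position_from_fs(text) == stop

    def test_substituted_anchor_warns(self):
        with pytest.warns(UserWarning, match="convention"):
            stop_position_from_fs("p.R27LfsX3")

    def test_malformed_nomenclature(self):
        with pytest.raises(errors.NomenclatureError):
            stop_position_from_fs("p.L471Lfs")


def random_cds(rng, n_codons):
    codons = ["ATG"]
    stops = {"TAA", "TAG", "TGA"}
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in stops:
            codons.append(c)
    codons.append(rng.choice(["TAA", "TAG", "TGA"]))
    return CodingSequence("rand", "".join(codons))


class TestProperties:
    def test_roundtrip_on_random_cds_indel_pairs(self):
        """Frameshift notation and stop arithmetic agree over 1000 random pairs.

        Draws where the shifted frame reaches no stop before the sequence end
        (or coincidentally re-encodes the reference) are redrawn; the stop
        round trip is checked on 1000 genuine frameshift-to-stop pairs.
        """
        rng = np.random.default_rng(42)
        checked = attempts = 0
        while checked < 1000 and attempts < 5000:
            attempts += 1
            cds = random_cds(rng, int(rng.integers(10, 40)))
            n = len(cds)
            net = int(rng.choice([1, 2, -1, -2]))
            pos = int(rng.integers(4, n - 5))
            if net > 0:
                var = CodingVariant(pos + 1, pos, inserted="".join(rng.choice(list("ACGT"), net)))
            else:
                var = CodingVariant(pos, pos - net - 1, inserted="")
            mutant = apply_indel(cds, var)
            assert len(mutant) == n + net
            alt, has_stop = translate_to_stop(mutant)
            ref, _ = translate_to_stop(cds.sequence)
            if not has_stop or alt == ref:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = describe_frameshift(ref, alt)
                assert stop_position_from_fs(d.notation) == len(alt) + 1
            checked += 1
        assert checked == 1000

    def test_frame_arithmetic_determines_kind(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            cds = random_cds(rng, 20)
            pos = int(rng.integers(4, len(cds) - 8))
            span = int(rng.integers(1, 7))
            var = CodingVariant(pos, pos + span - 1, inserted="")
            kind = classify_indel(cds, var).kind
            if span % 3 == 0:
                assert kind in (SYNONYMOUS, MISSENSE)
            else:
                assert kind in (FRAMESHIFT, "stop-loss")
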