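"""Anchored extraction, barcode pairing, quality filtering, count tables."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from matescreen.read_extraction import (
    RegistryIndex,
    Status,
    assign_variant,
    build_count_table,
    extract_after_anchor,
    extract_barcode_pair,
    mean_quality,
    quality_filter,
    revcomp,
)
from matescreen.screen_model import (
    AmpliconScheme,
    BARCODE_FORWARD_ANCHOR,
    BARCODE_REVERSE_ANCHOR,
    PEPTIDE_ANCHOR,
    reverse_translate,
)

PEPTIDE = AmpliconScheme.peptide()
PAIRS = AmpliconScheme.barcode_pair()


def naive_extract(read, anchor, payload_len):
    """Sliding-window oracle: O(n*m) scan for the first exact anchor match."""
    for i in range(len(read) - len(anchor) + 1):
        if read[i : i + len(anchor)] == anchor:
            start = i + len(anchor)
            if start + payload_len <= len(read):
                return read[start : start + payload_len]
            return None
    return None


dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestAnchoredExtraction:
    def test_constructed_read(self):
        payload = "A" * 27
        res = extract_after_anchor("ACGT" + PEPTIDE_ANCHOR + payload + "TT", PEPTIDE)
        assert res.status is Status.ASSIGNED
        assert res.payload == payload

    def test_missing_anchor(self):
        res = extract_after_anchor("ACGT" * 30, PEPTIDE)
        assert res.status is Status.NO_ANCHOR
        assert res.payload is None

    def test_truncated_payload_is_no_anchor(self):
        res = extract_after_anchor(PEPTIDE_ANCHOR + "A" * 10, PEPTIDE)
        assert res.status is Status.NO_ANCHOR

    def test_reverse_complement_fallback(self):
        payload = "ACGTACGTACGTACGTACGTACGTACG"
        read = revcomp("CC" + PEPTIDE_ANCHOR + payload + "GG")
        assert extract_after_anchor(read, PEPTIDE).payload == payload
        strict = AmpliconScheme.peptide(orientation_policy="as_is")
        assert extract_after_anchor(read, strict).status is Status.NO_ANCHOR

    def test_first_occurrence_wins(self):
        p1, p2 = "A" * 27, "C" * 27
        read = PEPTIDE_ANCHOR + p1 + PEPTIDE_ANCHOR + p2
        assert extract_after_anchor(read, PEPTIDE).payload == p1

    def test_position_invariance(self, rng):
        payload = "".join(rng.choice(list("ACGT"), size=27))
        for pad in ("", "T", "GATTACA", "ACGT" * 10):
            read = pad + PEPTIDE_ANCHOR + payload
            assert extract_after_anchor(read, PEPTIDE).payload == payload

    @given(prefix=dna, payload_and_tail=dna)
    def test_matches_naive_oracle_on_planted_anchors(self, prefix, payload_and_tail):
        read = prefix + PEPTIDE_ANCHOR + payload_and_tail
        expected = naive_extract(read, PEPTIDE_ANCHOR, 27)
        got = extract_after_anchor(read, AmpliconScheme.peptide(orientation_policy="as_is"))
        assert got.payload == expected
        assert (got.status is Status.ASSIGNED) == (expected is not None)

    def test_matches_naive_oracle_on_random_reads(self, rng):
        # randomized equivalence at scale, forward-only policy
        scheme = AmpliconScheme.peptide(orientation_policy="as_is")
        bases = np.array(list("ACGT"))
        for _ in range(2000):
            read = "".join(rng.choice(bases, size=int(rng.integers(0, 90))))
            if rng.random() < 0.5:
                cut = int(rng.integers(0, len(read) + 1))
                read = read[:cut] + PEPTIDE_ANCHOR + read[cut:]
            assert (
                extract_after_anchor(read, scheme).payload
                == naive_extract(read, PEPTIDE_ANCHOR, 27)
            )


class TestBarcodePairs:
    def _amplicon(self, a_bc, alpha_bc, pad5="ACG", pad3="TT"):
        return (
            pad5
            + BARCODE_FORWARD_ANCHOR
            + a_bc
            + "ACCGGT"
            + revcomp(alpha_bc)
            + revcomp(BARCODE_REVERSE_ANCHOR)
            + pad3
        )

    def test_constructed_amplicon(self):
        a_bc, alpha_bc = "A" * 15, "C" * 15
        res = extract_barcode_pair(self._amplicon(a_bc, alpha_bc), PAIRS)
        assert res.status is Status.ASSIGNED
        assert res.pair == (a_bc, alpha_bc)

    def test_reverse_oriented_amplicon(self):
        a_bc, alpha_bc = "ACGTA" * 3, "TTGCA" * 3
        res = extract_barcode_pair(revcomp(self._amplicon(a_bc, alpha_bc)), PAIRS)
        assert res.pair == (a_bc, alpha_bc)

    def test_forward_anchor_only_is_no_anchor(self):
        read = "ACG" + BARCODE_FORWARD_ANCHOR + "A" * 20
        assert extract_barcode_pair(read, PAIRS).status is Status.NO_ANCHOR

    def test_wrong_scheme_mode_raises(self):
        with pytest.raises(ValueError):
            extract_barcode_pair("ACGT", PEPTIDE)
        with pytest.raises(ValueError):
            extract_after_anchor("ACGT", PAIRS)


class TestQualityFilter:
    def test_extremes(self):
        high = [("r1", "ACGT", "I" * 4)]  # Q40
        low = [("r2", "ACGT", "#" * 4)]  # Q2
        assert [ok for *_, ok in quality_filter(high, 20.0)] == [True]
        assert [ok for *_, ok in quality_filter(low, 20.0)] == [False]

    def test_matches_mean_then_compare_oracle(self, rng):
        records = []
        for i in range(1000):
            n = int(rng.integers(1, 80))
            qual = "".join(chr(33 + int(q)) for q in rng.integers(0, 42, size=n))
            records.append((f"r{i}", "A" * n, qual))
        got = [ok for *_, ok in quality_filter(records, 20.0)]
        expected = [
            sum(ord(c) - 33 for c in qual) / len(qual) >= 20.0 for *_, qual in records
        ]
        assert got == expected

    def test_mean_quality_arithmetic(self):
        assert mean_quality("II") == pytest.approx(40.0)
        assert mean_quality(chr(33) + chr(73)) == pytest.approx(20.0)


class TestAssignment:
    @pytest.fixture()
    def registry(self, make_record):
        return [
            make_record("SL9", "SLYNTVATL", barcodes=("A" * 15,)),
            make_record("3L", "SLLNTVATL", barcodes=("C" * 15,)),
            make_record("868-1", "GAHDYALN", kind="TCR", group_id="868",
                        barcodes=("G" * 15,)),
            make_record("868-2", "GAHDYALN", kind="TCR", group_id="868",
                        barcodes=("T" * 15,)),
        ]

    def test_exact_payload_match(self, registry):
        index = RegistryIndex(registry, PEPTIDE)
        from matescreen.read_extraction import ExtractionResult

        res = ExtractionResult("r", Status.ASSIGNED, payload=reverse_translate("SLYNTVATL"))
        assert assign_variant(res, index).variant == "SL9"

    def test_one_substitution_unassigned_by_default(self, registry):
        index = RegistryIndex(registry, PEPTIDE)
        from matescreen.read_extraction import ExtractionResult

        payload = reverse_translate("SLYNTVATL")
        mutated = "C" + payload[1:] if payload[0] != "C" else "G" + payload[1:]
        res = assign_variant(
            ExtractionResult("r", Status.ASSIGNED, payload=mutated), index
        )
        assert res.status is Status.UNASSIGNED_PAYLOAD

    def test_hamming1_flag_recovers_single_substitution(self, registry):
        index = RegistryIndex(registry, PEPTIDE, hamming1=True)
        from matescreen.read_extraction import ExtractionResult

        payload = reverse_translate("SLYNTVATL")
        mutated = ("C" if payload[0] != "C" else "G") + payload[1:]
        res = assign_variant(
            ExtractionResult("r", Status.ASSIGNED, payload=mutated), index
        )
        assert res.variant == "SL9"

    def test_barcode_clones_map_to_distinct_strains_same_group(self, registry):
        index = RegistryIndex(registry, PAIRS)
        from matescreen.read_extraction import ExtractionResult

        r1 = assign_variant(
            ExtractionResult("r", Status.ASSIGNED, pair=("G" * 15, "A" * 15)), index
        )
        r2 = assign_variant(
            ExtractionResult("r", Status.ASSIGNED, pair=("T" * 15, "A" * 15)), index
        )
        assert r1.variant == ("868-1", "SL9")
        assert r2.variant == ("868-2", "SL9")
        by_id = {rec.strain_id: rec for rec in registry}
        assert by_id["868-1"].group_id == by_id["868-2"].group_id == "868"


class TestCountTable:
    def _write_fastq(self, path, seqs):
        with open(path, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")

    def test_conservation_and_statuses(self, tmp_path, make_record):
        registry = [make_record("SL9", "SLYNTVATL", barcodes=("A" * 15,))]
        good = PEPTIDE_ANCHOR + reverse_translate("SLYNTVATL")
        bad_payload = PEPTIDE_ANCHOR + "T" * 27
        no_anchor = "ACGT" * 20
        path = tmp_path / "r1.fastq"
        self._write_fastq(path, [good, good, good, bad_payload, no_anchor])
        table = build_count_table({"rep1": path}, PEPTIDE, registry)
        assert table.counts.loc["SL9", "rep1"] == 3
        assert table.unassigned.loc["unassigned_payload", "rep1"] == 1
        assert table.unassigned.loc["no_anchor", "rep1"] == 1
        assert table.total_reads()["rep1"] == 5
        assert (
            table.counts["rep1"].sum() + table.unassigned["rep1"].sum()
            == table.total_reads()["rep1"]
        )

    def test_low_quality_reads_are_tallied_not_counted(self, tmp_path, make_record):
        registry = [make_record("SL9", "SLYNTVATL", barcodes=("A" * 15,))]
        good = PEPTIDE_ANCHOR + reverse_translate("SLYNTVATL")
        path = tmp_path / "r1.fastq"
        with open(path, "w") as fh:
            fh.write(f"@ok\n{good}\n+\n{'I' * len(good)}\n")
            fh.write(f"@low\n{good}\n+\n{'#' * len(good)}\n")
        table = build_count_table({"rep1": path}, PEPTIDE, registry)
        assert table.counts.loc["SL9", "rep1"] == 1
        assert table.unassigned.loc["low_quality", "rep1"] == 1

    def test_empty_fastq_gives_zero_table(self, tmp_path, make_record):
        registry = [make_record("SL9", "SLYNTVATL", barcodes=("A" * 15,))]
        path = tmp_path / "empty.fastq"
        path.write_text("")
        table = build_count_table({"rep1": path}, PEPTIDE, registry)
        assert int(table.counts.to_numpy().sum()) == 0
        assert int(table.unassigned.to_numpy().sum()) == 0
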