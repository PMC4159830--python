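"""Tag cleaning, virtual library construction, mapping and accounting."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgetag.simulate import DEFAULT_ADAPTOR, reverse_complement, simulate_library
from dgetag.tags import (
    CleanTagSet,
    ExpressionTable,
    build_virtual_library,
    extract_clean_tags,
    map_tags,
    saturation_curve,
    strand_report,
    tpm_normalize,
)

ADAPTOR = DEFAULT_ADAPTOR
TAG_A = "CATG" + "A" * 17
TAG_C = "CATG" + "C" * 17


def _lib(transcripts: dict[str, str]):
    gene_map = {t: t.rsplit("_", 1)[0] for t in transcripts}
    return build_virtual_library(transcripts, gene_map)


class TestExtractCleanTags:
    def test_tag_plus_adaptor_retained(self):
        tags = extract_clean_tags([TAG_A + ADAPTOR], ADAPTOR)
        assert tags.counts == Counter({TAG_A: 1})
        assert tags.clean_total == 1 and tags.distinct_count == 1

    def test_rejection_classes(self):
        reads = [
            ADAPTOR + "A" * 21,          # adaptor at position 0 -> empty tag
            TAG_A[:10] + "N" + TAG_A[11:] + ADAPTOR,  # N inside -> contains_n
            TAG_A + "AAAA" + ADAPTOR[:10],  # adaptor not fully present -> truncated, kept
            "CATGAA" + ADAPTOR,          # too short after trimming
            "TTTT" + "A" * 17 + ADAPTOR,  # no CATG prefix
        ]
        tags = extract_clean_tags(reads, ADAPTOR)
        assert tags.report["empty_tag"] == 1
        assert tags.report["contains_n"] == 1
        assert tags.report["bad_length"] == 1
        assert tags.report["no_catg_prefix"] == 1
        assert tags.counts == Counter({TAG_A: 1})

    def test_read_without_adaptor_truncated_to_tag(self):
        read = TAG_A + "GGGGGGGGGGGGGG"  # filler that is not the adaptor
        tags = extract_clean_tags([read], ADAPTOR)
        assert tags.counts == Counter({TAG_A: 1})

    def test_empty_stream_gives_zeroed_report(self):
        tags = extract_clean_tags([], ADAPTOR)
        assert tags.clean_total == 0
        assert tags.report["raw_total"] == 0

    def test_partition_of_raw_reads(self):
        reads = [TAG_A + ADAPTOR] * 5 + [ADAPTOR + "C" * 21] * 2 + ["CATGNN" + "A" * 15 + ADAPTOR]
        r = extract_clean_tags(reads, ADAPTOR).report
        rejected = r["empty_tag"] + r["bad_length"] + r["contains_n"] + r["no_catg_prefix"]
        assert r["clean_total"] + rejected == r["raw_total"] == 8


class TestVirtualLibrary:
    def test_single_catg_site_hand_example(self):
        seq = "AAACATGTTTTTTTTTTTTTTTTTAA"  # one CATG with a full 17-nt overhang
        lib = _lib({"G1_T01": seq})
        assert len(lib) == 1
        (key,) = lib.hits
        assert key == seq[3:24]
        assert lib.hits[key][0].strand == "sense"
        assert reverse_complement(seq).find("CATG") >= len(seq) - 20  # no antisense key fits

    def test_both_strands_indexed(self):
        tag_rc = reverse_complement(TAG_A)
        seq = TAG_A + "G" * 5 + tag_rc  # antisense strand contains CATG+17
        lib = _lib({"G1_T01": seq})
        strands = {h.strand for hits in lib.hits.values() for h in hits}
        assert strands == {"sense", "antisense"}

    def test_shared_tag_is_ambiguous(self):
        lib = _lib({"G1_T01": "AA" + TAG_A, "G2_T01": "CC" + TAG_A})
        assert lib.genes(TAG_A) == {"G1", "G2"}
        assert not lib.is_unambiguous(TAG_A)

    def test_short_overhang_skipped(self):
        lib = _lib({"G1_T01": "CATG" + "A" * 16})  # only 16 nt after CATG
        assert len(lib) == 0

    def test_positions_within_bounds(self, small_transcriptome):
        transcripts = {g.transcript_id: g.seq for g in small_transcriptome}
        lib = build_virtual_library(
            transcripts, {g.transcript_id: g.gene_id for g in small_transcriptome}
        )
        for tag, hits in lib.hits.items():
            assert tag.startswith("CATG") and len(tag) == 21
            for h in hits:
                assert 0 <= h.pos <= len(transcripts[h.transcript_id]) - 21

    def test_contains_every_canonical_tag(self, small_transcriptome):
        lib = build_virtual_library(
            {g.transcript_id: g.seq for g in small_transcriptome},
            {g.transcript_id: g.gene_id for g in small_transcriptome},
        )
        for g in small_transcriptome:
            if g.canonical_tag is not None:
                assert g.canonical_tag in lib

    def test_missing_gene_map_entry_is_error(self):
        with pytest.raises(KeyError, match="G1_T01"):
            build_virtual_library({"G1_T01": TAG_A}, {})


class TestMapTags:
    def test_exact_unique_hit_unambiguous(self):
        lib = _lib({"G1_T01": TAG_A, "G2_T01": TAG_C})
        result = map_tags(CleanTagSet(counts=Counter({TAG_A: 3})), lib)
        assert result.sense_counts.to_dict() == {"G1": 3}
        assert result.summary["unambiguous_total"] == 3

    def test_one_mismatch_to_two_genes_is_ambiguous(self):
        lib = _lib({"G1_T01": TAG_A, "G2_T01": TAG_A[:-1] + "G"})
        query = TAG_A[:-1] + "T"  # distance 1 from both keys, no exact hit
        result = map_tags(CleanTagSet(counts=Counter({query: 2})), lib)
        assert result.summary["ambiguous_total"] == 2
        assert result.sense_counts.empty

    def test_distance_two_is_unknown(self):
        lib = _lib({"G1_T01": TAG_A})
        query = TAG_A[:-2] + "GG"
        result = map_tags(CleanTagSet(counts=Counter({query: 1})), lib)
        assert result.summary["unknown_total"] == 1

    def test_exact_tier_beats_mismatch_tier(self):
        # query matches G1 exactly and G2 at distance 1 -> unambiguous for G1
        lib = _lib({"G1_T01": TAG_A, "G2_T01": TAG_A[:-1] + "G"})
        result = map_tags(CleanTagSet(counts=Counter({TAG_A: 5})), lib)
        assert result.sense_counts.to_dict() == {"G1": 5}

    def test_partition_identity(self):
        lib = _lib({"G1_T01": TAG_A, "G2_T01": TAG_C})
        tags = CleanTagSet(
            counts=Counter({TAG_A: 3, TAG_C[:-1] + "G": 2, "CATG" + "T" * 17: 4})
        )
        s = map_tags(tags, lib).summary
        assert (
            s["unambiguous_total"] + s["ambiguous_total"] + s["unknown_total"]
            == tags.clean_total
        )

    def test_agrees_with_bruteforce_hamming_oracle(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        keys = ["CATG" + "".join(rng.choice(bases, 17)) for _ in range(300)]
        transcripts = {f"G{i}_T01": key for i, key in enumerate(keys)}
        lib = _lib(transcripts)
        queries = []
        for _ in range(200):
            base = keys[rng.integers(len(keys))]
            n_mut = rng.integers(0, 3)
            tag = list(base)
            for pos in rng.choice(21, size=n_mut, replace=False):
                tag[pos] = rng.choice([b for b in "ACGT" if b != tag[pos]])
            queries.append("".join(tag))
        tags = CleanTagSet(counts=Counter(queries))
        result = map_tags(tags, lib).assignments.set_index("tag")

        key_mat = np.array([list(k) for k in lib.hits])
        key_list = list(lib.hits)
        for tag in tags.counts:
            dist = (np.array(list(tag)) != key_mat).sum(axis=1)
            for d in (0, 1):
                genes = {
                    g
                    for i in np.flatnonzero(dist == d)
                    for g in lib.genes(key_list[i])
                }
                if genes:
                    break
            expected = (
                "unknown" if not genes else "unambiguous" if len(genes) == 1 else "ambiguous"
            )
            assert result.loc[tag, "status"] == expected

    def test_error_free_counts_equal_sampled_truth(self, small_transcriptome, small_truth):
        canonical = [g.canonical_tag for g in small_transcriptome if g.detectable]
        assert len(canonical) == len(set(canonical))  # no tag collisions in fixture
        reads, sampled = simulate_library(
            small_truth, small_transcriptome, "P",
            depth=30_000, error_rate=0.0, antisense_fraction=0.0, seed=8,
        )
        lib = build_virtual_library(
            {g.transcript_id: g.seq for g in small_transcriptome},
            {g.transcript_id: g.gene_id for g in small_transcriptome},
        )
        result = map_tags(extract_clean_tags(reads, ADAPTOR), lib)
        observed = result.sense_counts
        for gid, true_count in sampled[sampled > 0].items():
            assert observed.get(gid, 0) == true_count


class TestTPM:
    def test_definition(self):
        assert tpm_normalize(np.array([5]), 1_000_000)[0] == 5.0
        assert tpm_normalize(np.array([0]), 123)[0] == 0.0

    def test_sum_identity(self):
        counts = pd.Series([10, 20, 30])
        tpm = tpm_normalize(counts, 1000)
        assert tpm.sum() == pytest.approx(counts.sum() / 1000 * 1e6)
        assert tpm.sum() <= 1e6

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tpm_normalize(np.array([1]), 0)

    def test_expression_table_tpm_identity(self):
        table = ExpressionTable(
            pd.DataFrame({"P": [2, 0], "M": [1, 1], "F1": [0, 4]},
                         index=pd.Index(["g1", "g2"], name="gene_id")),
            {"P": 100, "M": 200, "F1": 400},
        )
        assert table.tpm.loc["g1", "P"] == pytest.approx(2 / 100 * 1e6)
        assert table.tpm.loc["g2", "F1"] == pytest.approx(4 / 400 * 1e6)

    def test_tsv_round_trip(self, tmp_path):
        table = ExpressionTable(
            pd.DataFrame({"P": [2, 0], "M": [1, 1], "F1": [0, 4]},
                         index=pd.Index(["g1", "g2"], name="gene_id")),
            {"P": 100, "M": 200, "F1": 400},
        )
        path = tmp_path / "expr.tsv"
        table.to_tsv(path)
        back = ExpressionTable.from_tsv(path)
        pd.testing.assert_frame_equal(back.counts, table.counts)
        assert back.clean_totals == table.clean_totals


class TestSaturation:
    def test_single_repeated_tag_constant_distinct(self):
        lib = _lib({"G1_T01": TAG_A})
        curve = saturation_curve([TAG_A] * 50, lib, step=10)
        assert (curve["distinct_tags"] == 1).all()
        assert (curve["genes_detected"] == 1).all()

    def test_curves_monotone(self, small_transcriptome, small_truth):
        reads, _ = simulate_library(
            small_truth, small_transcriptome, "F1", depth=20_000, seed=12
        )
        lib = build_virtual_library(
            {g.transcript_id: g.seq for g in small_transcriptome},
            {g.transcript_id: g.gene_id for g in small_transcriptome},
        )
        curve = saturation_curve((r[:21] for r in reads), lib, step=1000)
        assert (curve["distinct_tags"].diff().dropna() >= 0).all()
        assert (curve["genes_detected"].diff().dropna() >= 0).all()
        # saturation: gene discovery flattens over the last 10% of the stream
        last = curve[curve["tags_processed"] >= 0.9 * len(reads)]
        n_detectable = sum(g.detectable for g in small_transcriptome)
        assert last["genes_detected"].iloc[-1] - last["genes_detected"].iloc[0] < 0.01 * n_detectable


class TestStrandReport:
    def test_hand_built_three_gene_fixture(self):
        sense_g3 = "CATG" + "G" * 17
        lib = _lib(
            {
                "G1_T01": TAG_A,
                "G2_T01": "AA" + reverse_complement(TAG_C),
                "G3_T01": sense_g3 + "TT" + reverse_complement(TAG_A[:4] + "T" * 17),
            }
        )
        tags = CleanTagSet(
            counts=Counter(
                {TAG_A: 2, TAG_C: 3, sense_g3: 1, "CATG" + "T" * 17: 4}
            )
        )
        result = map_tags(tags, lib)
        report = strand_report(result)
        assert report["sense_genes"] == 2  # G1, G3
        assert report["antisense_genes"] == 2  # G2, G3
        assert report["both_strands"] == 1  # G3
        assert report["sense_antisense_ratio"] == pytest.approx(1.0)

    def test_ratio_invariant_under_copy_scaling(self):
        lib = _lib({"G1_T01": TAG_A, "G2_T01": "AA" + reverse_complement(TAG_C)})
        for scale in (1, 7):
            tags = CleanTagSet(counts=Counter({TAG_A: 1 * scale, TAG_C: 5 * scale}))
            report = strand_report(map_tags(tags, lib))
            assert report["sense_antisense_ratio"] == pytest.approx(1.0)

    def test_no_antisense_reports_none(self):
        lib = _lib({"G1_T01": TAG_A})
        report = strand_report(map_tags(CleanTagSet(counts=Counter({TAG_A: 1})), lib))
        assert report["antisense_genes"] == 0
        assert report["sense_antisense_ratio"] is None


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    copies=st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=20),
    seed=st.integers(min_value=0, max_value=100),
)
def test_partition_identity_property(copies, seed):
    """unambiguous + ambiguous + unknown always equals the clean total."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    keys = ["CATG" + "".join(rng.choice(bases, 17)) for _ in range(10)]
    lib = _lib({f"G{i}_T01": k for i, k in enumerate(keys)})
    tags = Counter()
    for i, c in enumerate(copies):
        tag = "CATG" + "".join(rng.choice(bases, 17))
        tags[tag] += c
    s = map_tags(CleanTagSet(counts=tags), lib).summary
    assert s["unambiguous_total"] + s["ambiguous_total"] + s["unknown_total"] == sum(tags.values())
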