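"""Exact mapping, per-position profiles and strand accumulation."""

import math

import pytest

from artsrna import ReadSet, ReferenceSeq, build_profile, map_exact, strand_accumulation
from artsrna._seq import revcomp
from artsrna.mapping import mapped_total, sequence_rpm

from conftest import naive_map, random_library, random_seq


def test_forward_read_single_hit(rng):
    ref = ReferenceSeq("r", random_seq(rng, 200))
    read = ref.sequence[5:26]
    hits = map_exact(ReadSet(reads=((read, 1),)), [ref])
    assert [(h.strand, h.start, h.end, h.weight) for h in hits] == [("+", 5, 26, 1.0)]


def test_reverse_read_reported_in_forward_coordinates(rng):
    ref = ReferenceSeq("r", random_seq(rng, 200))
    read = revcomp(ref.sequence[5:26])
    hits = map_exact(ReadSet(reads=((read, 1),)), [ref])
    assert [(h.strand, h.start, h.end) for h in hits] == [("-", 5, 26)]
    assert ref.sequence[5:26] == revcomp(read)


def test_homopolymer_multi_hits_share_weight():
    ref = ReferenceSeq("r", "A" * 10)
    hits = map_exact(ReadSet(reads=(("AAAA", 1),)), [ref])
    assert len(hits) == 7
    assert [h.start for h in hits] == list(range(7))
    assert all(h.strand == "+" and h.weight == pytest.approx(1 / 7) for h in hits)
    assert sum(h.weight for h in hits) == pytest.approx(1.0)


def test_read_with_n_never_maps(rng):
    ref = ReferenceSeq("r", random_seq(rng, 100))
    read = ref.sequence[10:30][:-1] + "N"
    assert map_exact(ReadSet(reads=((read, 1),)), [ref]) == []


def test_mapping_strand_symmetric(rng):
    ref = ReferenceSeq("r", random_seq(rng, 300))
    for _ in range(20):
        seq = (
            ref.sequence[int(rng.integers(0, 280)) :][:21]
            if rng.random() < 0.7
            else random_seq(rng, 21)
        )
        fwd = map_exact(ReadSet(reads=((seq, 1),)), [ref])
        rev = map_exact(ReadSet(reads=((revcomp(seq), 1),)), [ref])
        flip = {"+": "-", "-": "+"}
        assert sorted((h.strand, h.start) for h in rev) == sorted(
            (flip[h.strand], h.start) for h in fwd
        )


@pytest.mark.parametrize("seed", range(5))
def test_map_exact_matches_naive_scan(seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    ref = ReferenceSeq("r", random_seq(rng, int(rng.integers(100, 2000))))
    library = random_library(rng, ref, n_reads=40)
    assert map_exact(library, [ref]) == naive_map(library, [ref])


def test_weighted_counts_conserve_mapped_reads(rng):
    ref = ReferenceSeq("r", random_seq(rng, 500))
    library = random_library(rng, ref, n_reads=60)
    hits = map_exact(library, [ref])
    total_weighted = sum(h.weighted_count for h in hits)
    assert total_weighted == pytest.approx(mapped_total(hits, library))


def test_rpm_definition(rng):
    ref = ReferenceSeq("r", random_seq(rng, 100))
    read = ref.sequence[10:31]
    filler = "N" * 21  # unmappable, pads the library total
    library = ReadSet(reads=((read, 70), (filler, 999_930)))
    hits = map_exact(library, [ref])
    profiles = build_profile(hits, library, denominator="library_total")
    table = profiles["r"].table
    assert table["count"].sum() == pytest.approx(70)
    assert table["rpm"].iloc[0] == pytest.approx(70.0)


def test_mapped_total_denominator(rng):
    ref = ReferenceSeq("r", random_seq(rng, 100))
    library = ReadSet(reads=((ref.sequence[0:21], 30), ("N" * 21, 70)))
    hits = map_exact(library, [ref])
    profiles = build_profile(hits, library, denominator="mapped_total")
    assert profiles["r"].denominator == 30
    assert profiles["r"].table["rpm"].sum() == pytest.approx(1e6)


def test_no_hits_empty_profile(rng):
    ref = ReferenceSeq("r", random_seq(rng, 100))
    library = ReadSet(reads=(("N" * 21, 5),))
    assert build_profile([], library) == {}


def test_empty_library_denominator_error():
    with pytest.raises(ValueError, match="empty library"):
        build_profile([], ReadSet(reads=()))


def test_profile_matches_brute_force_tally(rng):
    ref = ReferenceSeq("r", random_seq(rng, 400))
    library = random_library(rng, ref, n_reads=50)
    hits = map_exact(library, [ref])
    profiles = build_profile(hits, library)
    tally: dict[tuple, float] = {}
    for h in naive_map(library, [ref]):
        key = (h.strand, h.start, h.length)
        tally[key] = tally.get(key, 0.0) + h.count * h.weight
    table = profiles["r"].table
    got = {
        (row.strand, row.start0, row.length): row.count for row in table.itertuples()
    }
    assert got.keys() == tally.keys()
    assert all(math.isclose(got[k], tally[k]) for k in tally)


def test_strand_accumulation_guide_and_star(rng):
    ref = ReferenceSeq("r", random_seq(rng, 200))
    guide = ref.sequence[30:51]
    star = revcomp(ref.sequence[100:121])
    library = ReadSet(reads=((guide, 5338), (star, 500), ("N" * 21, 994_162)))
    hits = map_exact(library, [ref])
    profile = build_profile(hits, library)["r"]
    g_rpm, s_rpm = strand_accumulation(hits, guide, star, profile)
    assert g_rpm == pytest.approx(5338.0)
    assert s_rpm == pytest.approx(500.0)


def test_strand_accumulation_zero_star(rng):
    ref = ReferenceSeq("r", random_seq(rng, 200))
    guide = ref.sequence[30:51]
    library = ReadSet(reads=((guide, 10),))
    hits = map_exact(library, [ref])
    profile = build_profile(hits, library)["r"]
    _, s_rpm = strand_accumulation(hits, guide, "T" * 21, profile)
    assert s_rpm == 0.0
    with pytest.raises(ValueError):
        strand_accumulation(hits, guide, guide, profile)
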