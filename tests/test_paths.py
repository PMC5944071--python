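"""Parsimonious mutation-path inference, ambiguity grouping and naming."""

from __future__ import annotations

from collections import Counter
from itertools import product

import pytest

from macall.paths import (
    CONVERSION,
    GAIN,
    LOSS,
    MutationEvent,
    apply_path,
    enumerate_shortest_paths,
    extract_consensus_events,
    flag_pac,
    format_hgvs,
)


# --------------------------------------------------------- brute-force oracle


def oracle_event_space(observed):
    events = []
    for a in observed:
        for b in observed:
            if a != b:
                events.append(MutationEvent(CONVERSION, from_allele=a, to_allele=b))
    for b in observed:
        events.append(MutationEvent(GAIN, to_allele=b))
    for a in observed:
        events.append(MutationEvent(LOSS, from_allele=a))
    return events


def oracle_apply(genotype, event):
    alleles = list(genotype)
    if event.kind == CONVERSION:
        if event.from_allele not in alleles:
            return None
        alleles.remove(event.from_allele)
        alleles.append(event.to_allele)
    elif event.kind == GAIN:
        alleles.append(event.to_allele)
    else:
        if event.from_allele not in alleles or len(alleles) == 1:
            return None
        alleles.remove(event.from_allele)
    return tuple(sorted(alleles))


def oracle_shortest_paths(start, target, observed, max_len=4):
    """Exhaustive enumeration of all event sequences up to ``max_len``."""
    start = tuple(sorted(start))
    target = tuple(sorted(target))
    if start == target:
        return [()]
    space = oracle_event_space(observed)
    for length in range(1, max_len + 1):
        hits = []
        for seq in product(space, repeat=length):
            g = start
            for event in seq:
                g = oracle_apply(g, event)
                if g is None:
                    break
            if g == target:
                hits.append(tuple(seq))
        if hits:
            return sorted(hits)
    return []


# ------------------------------------------------------------------- examples


class TestEnumerateShortestPaths:
    def test_identity_genotypes_single_empty_path(self):
        assert enumerate_shortest_paths(("A", "A"), ("A", "A"), ["A"]) == [()]

    def test_single_conversion(self):
        paths = enumerate_shortest_paths(("A", "A"), ("A", "C"), ["A", "C"])
        assert paths == [
            (MutationEvent(CONVERSION, from_allele="A", to_allele="C"),)
        ]

    def test_conversion_plus_gain_ambiguity(self):
        paths = enumerate_shortest_paths(("A", "C"), ("C", "C", "G"), ["A", "C", "G"])
        assert all(len(p) == 2 for p in paths)
        multisets = {frozenset(Counter(p).items()) for p in paths}
        expected = {
            frozenset(
                Counter(
                    [
                        MutationEvent(CONVERSION, from_allele="A", to_allele="G"),
                        MutationEvent(GAIN, to_allele="C"),
                    ]
                ).items()
            ),
            frozenset(
                Counter(
                    [
                        MutationEvent(CONVERSION, from_allele="A", to_allele="C"),
                        MutationEvent(GAIN, to_allele="G"),
                    ]
                ).items()
            ),
        }
        assert multisets == expected

    def test_every_path_reaches_target(self):
        paths = enumerate_shortest_paths(("A", "C"), ("C", "C", "G"), ["A", "C", "G"])
        for p in paths:
            assert apply_path(("A", "C"), p) == ("C", "C", "G")

    @pytest.mark.parametrize(
        "start,target,observed",
        [
            (("A", "A"), ("C", "C"), ["A", "C"]),
            (("A",), ("A", "C", "C"), ["A", "C"]),
            (("A", "C", "G"), ("A",), ["A", "C", "G"]),
            (("A", "A", "C"), ("C", "G"), ["A", "C", "G"]),
            (("A", "C"), ("G", "T"), ["A", "C", "G", "T"]),
        ],
    )
    def test_matches_exhaustive_enumeration(self, start, target, observed):
        got = enumerate_shortest_paths(start, target, observed)
        expected = oracle_shortest_paths(start, target, observed)
        assert sorted(got) == sorted(expected)
        assert len({len(p) for p in got}) == 1  # all minimal length


class TestConsensus:
    def test_single_path_all_certain(self):
        (path,) = enumerate_shortest_paths(("A", "A"), ("A", "C"), ["A", "C"])
        certain, ambiguous = extract_consensus_events([path])
        assert certain == list(path) and ambiguous == []

    def test_order_differences_do_not_create_ambiguity(self):
        paths = enumerate_shortest_paths(("A", "A"), ("C", "G"), ["A", "C", "G"])
        certain, ambiguous = extract_consensus_events(paths)
        assert Counter(certain) == Counter(
            [
                MutationEvent(CONVERSION, from_allele="A", to_allele="C"),
                MutationEvent(CONVERSION, from_allele="A", to_allele="G"),
            ]
        )
        assert ambiguous == []

    def test_ambiguous_conversion_and_gain(self):
        paths = enumerate_shortest_paths(("A", "C"), ("C", "C", "G"), ["A", "C", "G"])
        certain, ambiguous = extract_consensus_events(paths)
        assert certain == []
        kinds = {(e.kind, e.from_allele): e for e in ambiguous}
        conv = kinds[(CONVERSION, "A")]
        assert conv.ambiguous_targets == frozenset({"C", "G"})
        gain = kinds[(GAIN, None)]
        assert gain.ambiguous_targets == frozenset({"C", "G"})

    def test_repeated_event_multiset_semantics(self):
        paths = enumerate_shortest_paths(("A", "A"), ("C", "C"), ["A", "C"])
        certain, ambiguous = extract_consensus_events(paths)
        # the same conversion is needed twice
        assert Counter(certain)[
            MutationEvent(CONVERSION, from_allele="A", to_allele="C")
        ] == 2
        assert ambiguous == []


class TestPacFlag:
    def test_conversion_to_existing_allele(self):
        events = [MutationEvent(CONVERSION, from_allele="A", to_allele="C")]
        assert flag_pac(events, ("A", "C"), ("C", "C")) == "yes"

    def test_conversion_to_novel_allele(self):
        events = [MutationEvent(CONVERSION, from_allele="A", to_allele="C")]
        assert flag_pac(events, ("A", "A"), ("A", "C")) == "no"

    def test_copy_number_change_is_not_pac(self):
        events = [MutationEvent(GAIN, to_allele="C")]
        assert flag_pac(events, ("A", "C"), ("A", "C", "C")) == "no"

    def test_ambiguous_when_some_targets_pre_exist(self):
        events = [
            MutationEvent(
                CONVERSION, from_allele="A", ambiguous_targets=frozenset({"C", "G"})
            )
        ]
        assert flag_pac(events, ("A", "C"), ("C", "C")) == "ambiguous"


class TestHgvs:
    def test_gain(self):
        event = MutationEvent(GAIN, to_allele="A")
        assert format_hgvs(event, "chr1", 1000, "A") == "g.1000gainA"

    def test_loss(self):
        event = MutationEvent(LOSS, from_allele="A")
        assert format_hgvs(event, "chr1", 1000, "A") == "g.1000lossA"

    def test_ambiguous_gain_star(self):
        event = MutationEvent(GAIN, ambiguous_targets=frozenset({"A", "C"}))
        assert format_hgvs(event, "chr1", 1000, "A") == "g.1000gain*"

    def test_reference_substitution(self):
        event = MutationEvent(CONVERSION, from_allele="A", to_allele="C")
        assert format_hgvs(event, "chr1", 1000, "A") == "g.1000A>C"

    def test_non_reference_allele_uses_flanks(self):
        event = MutationEvent(CONVERSION, from_allele="G", to_allele="C")
        assert format_hgvs(event, "chr1", 1000, "A") == "g.999_1001G>C"

    def test_ambiguous_conversion_pipes(self):
        event = MutationEvent(
            CONVERSION, from_allele="A", ambiguous_targets=frozenset({"C", "G"})
        )
        assert format_hgvs(event, "chr1", 1000, "A") == "g.1000A>C|g.1000A>G"

    def test_single_unit_deletion(self):
        event = MutationEvent(CONVERSION, from_allele="AAAA", to_allele="AAA")
        assert format_hgvs(event, "chr1", 1000, "AAAA") == "g.1003del"

    def test_single_unit_insertion(self):
        event = MutationEvent(CONVERSION, from_allele="AAAA", to_allele="AAAAA")
        assert format_hgvs(event, "chr1", 1000, "AAAA") == "g.1003_1004insA"
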