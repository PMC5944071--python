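"""Parsimonious inference of mutation events from genotype pairs.

A called mutation site provides a t0 genotype and an outgrowth genotype;
the reportable events are the most parsimonious sequences of

* conversion of one allele copy to another (substitution, insertion or
  deletion),
* gain of one allele copy (copy-number gain),
* loss of one allele copy (copy-number loss)

transforming the former into the latter.  When several shortest paths exist,
only events shared by all of them are reported as certain; remaining events
of the same kind and starting allele present in every path are grouped into
a single ambiguous event with the set of possible targets.  Conversions that
increase the count of a pre-existing allele without changing copy number are
flagged as potential allelic conversions (PACs).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "MutationEvent",
    "MutationPath",
    "enumerate_shortest_paths",
    "extract_consensus_events",
    "flag_pac",
    "format_hgvs",
    "apply_path",
]

Genotype = tuple[str, ...]

CONVERSION = "conversion"
GAIN = "gain"
LOSS = "loss"


@dataclass(frozen=True, order=True)
class MutationEvent:
    """A single mutation event, possibly with an ambiguous target set."""

    kind: str  # conversion | gain | loss
    from_allele: Optional[str] = None
    to_allele: Optional[str] = None
    ambiguous_targets: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.kind == CONVERSION:
            if self.from_allele is None or (
                self.to_allele is None and self.ambiguous_targets is None
            ):
                raise ValueError("conversion requires from and to (or target set)")
            if self.to_allele is not None and self.from_allele == self.to_allele:
                raise ValueError("conversion must change the allele")
        elif self.kind == GAIN:
            if self.to_allele is None and self.ambiguous_targets is None:
                raise ValueError("gain requires a target allele or set")
        elif self.kind == LOSS:
            if self.from_allele is None and self.ambiguous_targets is None:
                raise ValueError("loss requires a source allele or set")
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")

    @property
    def is_ambiguous(self) -> bool:
        return self.ambiguous_targets is not None


MutationPath = tuple[MutationEvent, ...]


def _apply_event(genotype: Genotype, event: MutationEvent) -> Genotype:
    alleles = list(genotype)
    if event.kind == CONVERSION:
        alleles.remove(event.from_allele)
        alleles.append(event.to_allele)
    elif event.kind == GAIN:
        alleles.append(event.to_allele)
    else:  # loss
        alleles.remove(event.from_allele)
    return tuple(sorted(alleles))


def apply_path(genotype: Genotype, path: Sequence[MutationEvent]) -> Genotype:
    """Apply events in order; used to verify enumerated paths."""
    g = tuple(sorted(genotype))
    for event in path:
        g = _apply_event(g, event)
    return g


def _successor_events(genotype: Genotype, observed: Sequence[str]) -> list[MutationEvent]:
    events: list[MutationEvent] = []
    present = sorted(set(genotype))
    for a in present:
        for b in observed:
            if b != a:
                events.append(MutationEvent(CONVERSION, from_allele=a, to_allele=b))
    for b in observed:
        events.append(MutationEvent(GAIN, to_allele=b))
    if len(genotype) > 1:
        for a in present:
            events.append(MutationEvent(LOSS, from_allele=a))
    events.sort()
    return events


def enumerate_shortest_paths(
    t0_genotype: Sequence[str],
    outgrowth_genotype: Sequence[str],
    observed_alleles: Sequence[str],
) -> list[MutationPath]:
    """All minimal-length event sequences from t0 to outgrowth genotype.

    Breadth-first over genotype multisets; raises ``ValueError`` when the
    depth cap (ploidy difference + differing alleles + 2) is exceeded, which
    indicates an unreachable target (e.g. an allele not in ``observed_alleles``).
    """
    start = tuple(sorted(t0_genotype))
    target = tuple(sorted(outgrowth_genotype))
    if not start or not target:
        raise ValueError("genotypes must be non-empty")
    observed = sorted(set(observed_alleles) | set(start))
    diff = sum((Counter(target) - Counter(start)).values()) + sum(
        (Counter(start) - Counter(target)).values()
    )
    cap = abs(len(target) - len(start)) + diff + 2
    if start == target:
        return [()]
    frontier: list[tuple[Genotype, MutationPath]] = [(start, ())]
    for depth in range(1, cap + 1):
        next_frontier: list[tuple[Genotype, MutationPath]] = []
        hits: list[MutationPath] = []
        for genotype, path in frontier:
            for event in _successor_events(genotype, observed):
                g2 = _apply_event(genotype, event)
                p2 = path + (event,)
                if g2 == target:
                    hits.append(p2)
                else:
                    next_frontier.append((g2, p2))
        if hits:
            return sorted(hits)
        frontier = next_frontier
    raise ValueError(
        f"no path from {start} to {target} within depth cap {cap}"
    )


def extract_consensus_events(
    paths: Sequence[MutationPath],
) -> tuple[list[MutationEvent], list[MutationEvent]]:
    """Split shortest-path events into certain and ambiguous groups.

    Certain events are the multiset intersection across all paths (order is
    ignored).  The remaining events are grouped by (kind, starting allele);
    a group present in every path becomes one ambiguous event whose target
    set is the union of the group's target alleles.
    """
    if not paths:
        raise ValueError("at least one path required")
    counters = [Counter(p) for p in paths]
    certain_counter = counters[0].copy()
    for c in counters[1:]:
        certain_counter &= c
    certain = sorted(certain_counter.elements())

    remainders = [c - certain_counter for c in counters]
    ambiguous: list[MutationEvent] = []
    # conversions share a starting allele; gains and losses group by kind
    # (their "starting allele" is the copy-number change itself)
    def group_key(e: MutationEvent) -> tuple[str, Optional[str]]:
        return (e.kind, e.from_allele if e.kind == CONVERSION else None)

    keys = {group_key(e) for c in remainders for e in c}
    for kind, from_allele in sorted(keys, key=lambda t: (t[0], t[1] or "")):
        group_counts = []
        targets: set[str] = set()
        for c in remainders:
            members = [
                e for e in c.elements() if group_key(e) == (kind, from_allele)
            ]
            group_counts.append(len(members))
            for e in members:
                if e.to_allele is not None:
                    targets.add(e.to_allele)
                elif e.kind == LOSS and e.from_allele is not None:
                    targets.add(e.from_allele)
        n = min(group_counts)
        if n == 0:
            continue
        for _ in range(n):
            ambiguous.append(
                MutationEvent(
                    kind,
                    from_allele=from_allele,
                    ambiguous_targets=frozenset(targets),
                )
            )
    return certain, ambiguous


def flag_pac(
    events: Sequence[MutationEvent],
    t0_genotype: Sequence[str],
    outgrowth_genotype: Sequence[str],
) -> str:
    """Potential-allelic-conversion flag: "no", "yes" or "ambiguous".

    A conversion whose target already exists in the t0 genotype, with equal
    genotype cardinalities, increases the count of an existing allele
    without a copy-number change — the signature of gene conversion or a
    larger rearrangement.  For ambiguous conversions the flag is ambiguous
    when only some possible targets pre-exist.
    """
    if len(t0_genotype) != len(outgrowth_genotype):
        return "no"
    t0_alleles = set(t0_genotype)
    saw_ambiguous = False
    for event in events:
        if event.kind != CONVERSION:
            continue
        if event.is_ambiguous:
            hits = {t for t in event.ambiguous_targets if t in t0_alleles}
            if hits and hits != set(event.ambiguous_targets):
                saw_ambiguous = True
            elif hits:
                return "yes"
        elif event.to_allele in t0_alleles:
            return "yes"
    return "ambiguous" if saw_ambiguous else "no"


def _conversion_string(pos: int, from_allele: str, to_allele: str, ref: str) -> str:
    if from_allele == ref:
        if len(from_allele) == len(to_allele) == 1:
            return f"g.{pos}{from_allele}>{to_allele}"
        if len(to_allele) < len(from_allele):
            # deletion of the trailing reference bases
            del_start = pos + len(to_allele)
            del_end = pos + len(from_allele) - 1
            if del_start == del_end:
                return f"g.{del_start}del"
            return f"g.{del_start}_{del_end}del"
        if len(to_allele) > len(from_allele):
            inserted = to_allele[len(from_allele) :]
            anchor = pos + len(from_allele) - 1
            return f"g.{anchor}_{anchor + 1}ins{inserted}"
        end = pos + len(from_allele) - 1
        return f"g.{pos}_{end}delins{to_allele}"
    # mutation within a non-reference allele: identify via flanking positions
    return f"g.{pos - 1}_{pos + len(from_allele)}{from_allele}>{to_allele}"


def format_hgvs(event: MutationEvent, chrom: str, pos: int, ref_allele: str) -> str:
    """HGVS-style name for an event anchored at a 1-based position.

    Copy-number events use the ``gain``/``loss`` keywords; an ambiguous
    copy-number allele is written ``*``; ambiguous conversions list each
    alternative joined by pipes.
    """
    if event.kind == GAIN:
        allele = "*" if event.is_ambiguous else event.to_allele
        return f"g.{pos}gain{allele}"
    if event.kind == LOSS:
        allele = "*" if event.is_ambiguous else event.from_allele
        return f"g.{pos}loss{allele}"
    if event.is_ambiguous:
        return "|".join(
            _conversion_string(pos, event.from_allele, t, ref_allele)
            for t in sorted(event.ambiguous_targets)
        )
    return _conversion_string(pos, event.from_allele, event.to_allele, ref_allele)
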