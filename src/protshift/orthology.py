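"""Conservative dual-reference orthology assignment and group consistency.

A query transcript is accepted only when its best hit in each of two
reference species exists, passes the e-value threshold, and the two hit
genes are themselves an annotated orthologous pair (dual-reference
anchoring). Transcripts sharing an anchor pair across query species form an
orthology group; groups can be compared against an independent clustering.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from .io_formats import HitRecord

log = logging.getLogger(__name__)

REJECTION_REASONS = ("missing_hit_a", "missing_hit_b", "evalue_fail", "pair_discrepancy")


class OrthologPair(NamedTuple):
    """An annotated orthologous gene pair between the two reference species."""

    ref_a_gene: str
    ref_b_gene: str


@dataclass(frozen=True)
class Assignment:
    """A transcript anchored to a reference ortholog pair."""

    transcript: str
    pair: OrthologPair
    evalue_a: float
    evalue_b: float
    bitscore_a: float
    bitscore_b: float


@dataclass(frozen=True)
class Rejection:
    transcript: str
    reason: str


@dataclass
class OrthologyGroup:
    """Transcripts from several query species sharing one anchor pair."""

    group_id: str
    anchor: OrthologPair
    members: dict[str, str]  # species -> transcript

    def transcript_set(self) -> set[str]:
        return set(self.members.values())


@dataclass
class ConsistencyReport:
    n_groups_a: int
    n_consistent: int
    fraction: float
    consistent_ids: list[str]


@dataclass
class GroupBuildResult:
    groups: list[OrthologyGroup]
    dropped_duplicates: list[tuple[str, str]]  # (species, transcript)
    n_discarded_small: int


def _hit_sort_key(r: HitRecord) -> tuple[float, float, str]:
    # lowest e-value wins; ties by highest bitscore, then lexicographic subject
    return (r.evalue, -r.bitscore, r.subject_id)


def best_hits(records: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Reduce a hit table to the single best hit per query."""
    best: dict[str, HitRecord] = {}
    for r in records:
        cur = best.get(r.query_id)
        if cur is None or _hit_sort_key(r) < _hit_sort_key(cur):
            best[r.query_id] = r
    return best


def assign_reference_orthologs(
    hits_a: Iterable[HitRecord],
    hits_b: Iterable[HitRecord],
    pairs: Sequence[OrthologPair | tuple[str, str]],
    evalue_max: float = 1e-40,
) -> tuple[dict[str, Assignment], list[Rejection]]:
    """Anchor each query transcript to an ortholog pair of the two references.

    A transcript is assigned iff it has a best hit in *both* reference
    species with e-value <= ``evalue_max`` and the (best_a, best_b) subject
    genes form a pair in the reference orthology table. Every unassigned
    transcript appears exactly once in the rejection list with the first
    applicable reason among missing_hit_a, missing_hit_b, evalue_fail,
    pair_discrepancy.
    """
    pair_list = [OrthologPair(*p) for p in pairs]
    if not pair_list:
        raise ValueError("empty ortholog pair table")
    pair_set = set(pair_list)
    if len(pair_set) < len(pair_list):
        log.warning("ortholog pair table contains %d duplicate pair(s)", len(pair_list) - len(pair_set))
    ba = best_hits(hits_a)
    bb = best_hits(hits_b)
    assignments: dict[str, Assignment] = {}
    rejections: list[Rejection] = []
    for q in sorted(set(ba) | set(bb)):
        a = ba.get(q)
        b = bb.get(q)
        if a is None:
            rejections.append(Rejection(q, "missing_hit_a"))
            continue
        if b is None:
            rejections.append(Rejection(q, "missing_hit_b"))
            continue
        if a.evalue > evalue_max or b.evalue > evalue_max:
            rejections.append(Rejection(q, "evalue_fail"))
            continue
        pair = OrthologPair(a.subject_id, b.subject_id)
        if pair not in pair_set:
            rejections.append(Rejection(q, "pair_discrepancy"))
            continue
        assignments[q] = Assignment(q, pair, a.evalue, b.evalue, a.bitscore, b.bitscore)
    return assignments, rejections


def _assignment_sort_key(a: Assignment) -> tuple[float, float, str]:
    return (a.evalue_a + a.evalue_b, -(a.bitscore_a + a.bitscore_b), a.transcript)


def build_orthology_groups(
    assignments_by_species: Mapping[str, Mapping[str, Assignment]],
    min_species: int = 2,
) -> GroupBuildResult:
    """Collect transcripts anchored to the same pair into orthology groups.

    Within a species, several transcripts (e.g. assembly isoforms) may map
    to one pair; the best one (lowest combined e-value, ties by combined
    bitscore then transcript id) is kept and the rest logged. Groups
    represented by fewer than ``min_species`` query species are discarded
    and counted.
    """
    by_pair: dict[OrthologPair, dict[str, Assignment]] = {}
    dropped: list[tuple[str, str]] = []
    for species in sorted(assignments_by_species):
        for transcript in sorted(assignments_by_species[species]):
            a = assignments_by_species[species][transcript]
            slot = by_pair.setdefault(a.pair, {})
            cur = slot.get(species)
            if cur is None:
                slot[species] = a
            elif _assignment_sort_key(a) < _assignment_sort_key(cur):
                dropped.append((species, cur.transcript))
                slot[species] = a
            else:
                dropped.append((species, a.transcript))
    groups: list[OrthologyGroup] = []
    n_discarded = 0
    for pair in sorted(by_pair):
        slot = by_pair[pair]
        if len(slot) < min_species:
            n_discarded += 1
            continue
        groups.append(
            OrthologyGroup(
                group_id=f"OG{len(groups) + 1:06d}",
                anchor=pair,
                members={sp: a.transcript for sp, a in sorted(slot.items())},
            )
        )
    if dropped:
        log.info("collapsed %d within-species duplicate assignment(s)", len(dropped))
    return GroupBuildResult(groups, dropped, n_discarded)


def check_group_consistency(
    groups_a: Sequence[OrthologyGroup | Iterable[str]],
    groups_b: Sequence[Iterable[str]],
    overlap_mode: str = "equality",
) -> ConsistencyReport:
    """Fraction of A-groups whose membership agrees with an independent clustering.

    An A-group is consistent when some B cluster, restricted to the
    transcript universe of A, equals the A-group restricted to the universe
    of B (``overlap_mode='equality'``), or contains it
    (``overlap_mode='subset'``). A-groups entirely outside the B universe
    are vacuously consistent.
    """
    if overlap_mode not in ("equality", "subset"):
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
    ids_a: list[str] = []
    sets_a: list[set[str]] = []
    for i, g in enumerate(groups_a):
        if isinstance(g, OrthologyGroup):
            ids_a.append(g.group_id)
            sets_a.append(g.transcript_set())
        else:
            ids_a.append(str(i))
            sets_a.append(set(g))
    sets_b = [set(s) for s in groups_b]
    owner: dict[str, int] = {}
    for idx, s in enumerate(sets_b):
        for t in s:
            if t in owner:
                raise ValueError(f"transcript {t!r} occurs in two independent groups")
            owner[t] = idx
    universe_a: set[str] = set().union(*sets_a) if sets_a else set()
    universe_b = set(owner)
    consistent_ids: list[str] = []
    for gid, sa in zip(ids_a, sets_a):
        target = sa & universe_b
        if not target:
            consistent_ids.append(gid)
            continue
        candidates = {owner[t] for t in target}
        for ci in candidates:
            if overlap_mode == "subset":
                if target <= sets_b[ci]:
                    consistent_ids.append(gid)
                    break
            else:
                if (sets_b[ci] & universe_a) == target:
                    consistent_ids.append(gid)
                    break
    n = len(sets_a)
    k = len(consistent_ids)
    return ConsistencyReport(n, k, k / n if n else 0.0, consistent_ids)


# ---------------------------------------------------------------------------
# tabular I/O

def read_pair_table(path: str | Path) -> list[OrthologPair]:
    """Read a 2-column TSV of reference-A gene / reference-B gene pairs."""
    pairs: list[OrthologPair] = []
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: row {lineno}: expected 2 columns")
            pairs.append(OrthologPair(row[0].strip(), row[1].strip()))
    return pairs


def write_pair_table(pairs: Iterable[OrthologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.ref_a_gene}\t{p.ref_b_gene}\n")


def read_group_table(path: str | Path) -> list[set[str]]:
    """Read an independent clustering as a (group_id, transcript) TSV."""
    by_id: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: row {lineno}: expected 2 columns")
            by_id.setdefault(row[0].strip(), set()).add(row[1].strip())
    return [by_id[k] for k in sorted(by_id)]


def write_assignments(
    assignments_by_species: Mapping[str, Mapping[str, Assignment]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tspecies\tref_a\tref_b\tevalue_a\tevalue_b\n")
        for species in sorted(assignments_by_species):
            for t in sorted(assignments_by_species[species]):
                a = assignments_by_species[species][t]
                fh.write(
                    f"{a.transcript}\t{species}\t{a.pair.ref_a_gene}\t{a.pair.ref_b_gene}\t"
                    f"{a.evalue_a:.6g}\t{a.evalue_b:.6g}\n"
                )


def write_rejections(
    rejections_by_species: Mapping[str, Sequence[Rejection]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tspecies\treason\n")
        for species in sorted(rejections_by_species):
            for r in rejections_by_species[species]:
                fh.write(f"{r.transcript}\t{species}\t{r.reason}\n")


def write_groups(groups: Iterable[OrthologyGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tref_a\tref_b\tspecies\ttranscript\n")
        for g in groups:
            for sp in sorted(g.members):
                fh.write(
                    f"{g.group_id}\t{g.anchor.ref_a_gene}\t{g.anchor.ref_b_gene}\t"
                    f"{sp}\t{g.members[sp]}\n"
                )
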