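"""File formats and core containers: aligned FASTA, BLAST tabular hits, CDS.

Alignments are one orthology group each, with species-tagged headers of the
form ``species|seq_id``. Reading normalises case and maps any character
outside the closed alphabet (20 residues, ``-``, ``X``) to ``X``; writing
produces 60-column wrapped FASTA, so a read/write round trip is the
identity on valid alignments.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import GAP, UNKNOWN, VALID_CHARS

log = logging.getLogger(__name__)


@dataclass
class AlignedSequence:
    """One row of a multiple alignment: a species-tagged residue string."""

    seq_id: str
    species: str
    residues: str


@dataclass
class Alignment:
    """A protein (or codon) multiple alignment for one orthology group."""

    group_id: str
    members: list[AlignedSequence]

    @property
    def n_columns(self) -> int:
        return len(self.members[0].residues) if self.members else 0

    @property
    def species(self) -> set[str]:
        return {m.species for m in self.members}

    def validate(self) -> None:
        """Check equal row lengths, unique (species, seq_id), closed alphabet."""
        if not self.members:
            raise ValueError(f"alignment {self.group_id!r} has no members")
        width = len(self.members[0].residues)
        seen: set[tuple[str, str]] = set()
        for m in self.members:
            if len(m.residues) != width:
                raise ValueError(
                    f"alignment {self.group_id!r}: record {m.species}|{m.seq_id} has "
                    f"length {len(m.residues)}, expected {width}"
                )
            key = (m.species, m.seq_id)
            if key in seen:
                raise ValueError(
                    f"alignment {self.group_id!r}: duplicate record {m.species}|{m.seq_id}"
                )
            seen.add(key)
            bad = set(m.residues) - VALID_CHARS
            if bad:
                raise ValueError(
                    f"alignment {self.group_id!r}: record {m.species}|{m.seq_id} "
                    f"contains invalid characters {sorted(bad)}"
                )


@dataclass(frozen=True)
class SpeciesPartition:
    """Foreground clade versus temperate reference species."""

    foreground: frozenset[str]
    references: frozenset[str]

    def __init__(self, foreground: Iterable[str], references: Iterable[str]):
        object.__setattr__(self, "foreground", frozenset(foreground))
        object.__setattr__(self, "references", frozenset(references))
        if self.foreground & self.references:
            raise ValueError(
                f"species in both roles: {sorted(self.foreground & self.references)}"
            )
        if len(self.references) < 1:
            raise ValueError("need at least one reference species")
        if len(self.foreground) < 2:
            raise ValueError("need at least two foreground species")

    def swapped(self) -> "SpeciesPartition":
        """Exchange foreground and reference roles (for antisymmetry checks)."""
        return SpeciesPartition(self.references, self.foreground)


class HitRecord(NamedTuple):
    """One best-hit row from a BLAST-style tabular search."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float


def default_species_rule(header: str) -> str:
    """Species label = token before the first ``|`` of the FASTA header."""
    return header.split("|", 1)[0]


def _seq_id_from_header(header: str) -> str:
    return header.split("|", 1)[1] if "|" in header else header


def _sanitize(seq: str, label: str) -> str:
    s = seq.upper()
    n_bad = sum(1 for c in s if c not in VALID_CHARS)
    if n_bad:
        log.warning("%d non-alphabet character(s) in %s mapped to %s", n_bad, label, UNKNOWN)
        s = "".join(c if c in VALID_CHARS else UNKNOWN for c in s)
    return s


def read_alignment_fasta(
    path: str | Path,
    species_rule: Callable[[str], str] | None = None,
    group_id: str | None = None,
) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Parameters
    ----------
    path
        Aligned FASTA file; all records must have equal length.
    species_rule
        Maps a FASTA header to a species label (default: token before the
        first ``|``). The remainder after the first ``|`` is the seq_id.
    group_id
        Orthology-group identifier; defaults to the file stem.
    """
    path = Path(path)
    rule = species_rule or default_species_rule
    members: list[AlignedSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        members.append(
            AlignedSequence(
                seq_id=_seq_id_from_header(header),
                species=rule(header),
                residues=_sanitize(str(rec.seq), header),
            )
        )
    if not members:
        raise ValueError(f"empty alignment file: {path}")
    aln = Alignment(group_id=group_id or path.stem, members=members)
    aln.validate()
    return aln


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as 60-column wrapped FASTA, headers ``species|seq_id``."""
    if not aln.members:
        raise ValueError(f"refusing to write empty alignment {aln.group_id!r}")
    records = [
        SeqRecord(Seq(m.residues), id=f"{m.species}|{m.seq_id}", description="")
        for m in aln.members
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column BLAST outfmt-6 table (columns 1, 2, 11, 12 consumed).

    Rows whose e-value or bitscore does not parse as a number are dropped
    with a logged count; a row with fewer than 12 columns is a hard error.
    """
    records: list[HitRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}: row {lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError:
                n_skipped += 1
                continue
            if evalue < 0:
                n_skipped += 1
                continue
            records.append(HitRecord(parts[0], parts[1], evalue, bitscore))
    if n_skipped:
        log.warning("%s: rejected %d row(s) with unparsable e-value/bitscore", path, n_skipped)
    return records


def write_hit_table(records: Iterable[HitRecord], path: str | Path) -> None:
    """Write hit records as a 12-column outfmt-6 table (filler mid columns)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t90.00\t100\t0\t0\t1\t100\t1\t100\t"
                f"{r.evalue:.3g}\t{r.bitscore:.1f}\n"
            )


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read a plain (unaligned) FASTA file into a seq_id -> sequence map."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"empty FASTA file: {path}")
    return seqs


def _translate_codon(codon: str, table: CodonTable.CodonTable, stops: set[str]) -> str:
    if codon in stops:
        return "*"
    return table.forward_table.get(codon, UNKNOWN)


def backtranslate_alignment(
    protein_aln: Alignment,
    cds: Mapping[str, str],
    genetic_code: int = 1,
) -> Alignment:
    """Thread coding sequences through a protein alignment (codon alignment).

    Each gap column becomes ``---`` and each residue is replaced by its
    source codon, so the output has 3x the protein column count. The CDS of
    each member (keyed by seq_id) must translate exactly to its ungapped
    protein under the requested genetic code; ``X`` matches any codon. A
    terminal stop codon is tolerated and dropped.
    """
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    stops = set(table.stop_codons)
    out_members: list[AlignedSequence] = []
    for m in protein_aln.members:
        if m.seq_id not in cds:
            raise ValueError(f"no CDS provided for {m.seq_id!r}")
        nt = cds[m.seq_id].upper().replace("U", "T")
        ungapped = m.residues.replace(GAP, "")
        if len(nt) == 3 * len(ungapped) + 3 and nt[-3:] in stops:
            nt = nt[:-3]
        if len(nt) != 3 * len(ungapped):
            raise ValueError(
                f"CDS length mismatch for {m.seq_id!r}: {len(nt)} nt vs "
                f"{len(ungapped)} residues (expected {3 * len(ungapped)} nt)"
            )
        for i, res in enumerate(ungapped):
            codon = nt[3 * i : 3 * i + 3]
            aa = _translate_codon(codon, table, stops)
            if res != UNKNOWN and aa != res:
                raise ValueError(
                    f"translation mismatch for {m.seq_id!r} at residue index {i}: "
                    f"codon {codon} translates to {aa}, alignment has {res}"
                )
        chunks: list[str] = []
        pos = 0
        for res in m.residues:
            if res == GAP:
                chunks.append("---")
            else:
                chunks.append(nt[3 * pos : 3 * pos + 3])
                pos += 1
        out_members.append(AlignedSequence(m.seq_id, m.species, "".join(chunks)))
    return Alignment(group_id=protein_aln.group_id, members=out_members)
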