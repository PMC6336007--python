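"""Per-column reliability scoring and high-quality column extraction.

Columns are scored on the 0-9 scale used by alignment reliability filters:
here the score is ``floor(9 * mean pairwise identity)`` over the non-gap,
non-``X`` residues of the column (integer arithmetic, so ties round down
exactly). Columns with fewer than two scorable residues score 0. An
externally computed score track (e.g. from an aligner's own consistency
index) can be substituted for the internal score.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AA_CODE_LOOKUP, GAP_BYTE, seq_to_bytes
from .io_formats import AlignedSequence, Alignment

log = logging.getLogger(__name__)


@dataclass
class ColumnScoreTrack:
    """Per-column integer scores (0-9) and gap fractions for one alignment."""

    scores: np.ndarray  # int, in [0, 9]
    gap_fraction: np.ndarray  # float, in [0, 1]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        self.gap_fraction = np.asarray(self.gap_fraction, dtype=float)
        if self.scores.shape != self.gap_fraction.shape:
            raise ValueError("scores and gap_fraction must have equal length")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 9):
            raise ValueError("column scores must lie in [0, 9]")


def alignment_to_matrix(aln: Alignment) -> np.ndarray:
    """Stack alignment rows into a (n_members, n_columns) uint8 byte matrix."""
    return np.vstack([seq_to_bytes(m.residues) for m in aln.members])


def score_columns(aln: Alignment) -> ColumnScoreTrack:
    """Score every column of an alignment (>= 2 members required)."""
    if len(aln.members) < 2:
        raise ValueError(f"alignment {aln.group_id!r}: need >= 2 members to score columns")
    mat = alignment_to_matrix(aln)
    codes = AA_CODE_LOOKUP[mat]  # -1 for gap/X
    n_cols = mat.shape[1]
    counts = np.zeros((20, n_cols), dtype=np.int64)
    for r in range(20):
        counts[r] = (codes == r).sum(axis=0)
    n_valid = counts.sum(axis=0)
    identical_pairs = (counts * (counts - 1) // 2).sum(axis=0)
    total_pairs = n_valid * (n_valid - 1) // 2
    scores = np.zeros(n_cols, dtype=int)
    nz = total_pairs > 0
    scores[nz] = 9 * identical_pairs[nz] // total_pairs[nz]
    gap_fraction = (mat == GAP_BYTE).mean(axis=0) if len(aln.members) else np.zeros(n_cols)
    return ColumnScoreTrack(scores=scores, gap_fraction=gap_fraction)


def filter_columns(
    aln: Alignment,
    track: ColumnScoreTrack | None = None,
    min_score: int = 8,
    max_gap_fraction: float = 0.0,
) -> tuple[Alignment, np.ndarray]:
    """Keep columns with score >= min_score and gap fraction <= max_gap_fraction.

    Returns the filtered alignment and the strictly increasing index map
    from filtered to original columns (0-based internally; reports use
    1-based positions). Removing every column yields an empty (zero-column)
    alignment with a logged warning, not an error.
    """
    if track is None:
        track = score_columns(aln)
    if len(track.scores) != aln.n_columns:
        raise ValueError(
            f"score track length {len(track.scores)} != alignment width {aln.n_columns}"
        )
    keep = (track.scores >= min_score) & (track.gap_fraction <= max_gap_fraction)
    index_map = np.nonzero(keep)[0]
    if index_map.size == 0:
        log.warning("alignment %r: all %d columns removed by filter", aln.group_id, aln.n_columns)
    mat = alignment_to_matrix(aln)[:, index_map]
    members = [
        AlignedSequence(m.seq_id, m.species, mat[i].tobytes().decode("ascii"))
        for i, m in enumerate(aln.members)
    ]
    return Alignment(group_id=aln.group_id, members=members), index_map


def read_score_track(path: str | Path, n_columns: int) -> np.ndarray:
    """Read an external per-column score TSV (1-based column_index, score).

    Columns absent from the file score 0.
    """
    scores = np.zeros(n_columns, dtype=int)
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or not "".join(row).strip() or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: row {lineno}: expected 2 columns")
            col = int(row[0])
            if not 1 <= col <= n_columns:
                raise ValueError(
                    f"{path}: row {lineno}: column index {col} outside 1..{n_columns}"
                )
            scores[col - 1] = int(row[1])
    return scores


def write_index_map(index_map: np.ndarray, path: str | Path) -> None:
    """Write the filtered -> original column map, both sides 1-based."""
    with open(path, "w") as fh:
        fh.write("filtered_column\toriginal_column\n")
        for filt, orig in enumerate(index_map, 1):
            fh.write(f"{filt}\t{int(orig) + 1}\n")
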