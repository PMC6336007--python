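"""Concordant substitution sites and the statistics built on them.

The core object is the concordant substitution site: an alignment column
where every reference species carries one residue and every foreground
species carries a different one, with no gaps or unknowns — the signature
of a substitution fixed on the shared ancestral branch of the foreground
clade. Sites pooled across orthology groups feed:

* a 20x20 directed count matrix (reference residue -> foreground residue);
* per-side residue composition profiles;
* per-residue 2x2 chi-square usage tests (Bonferroni over the 20 residues);
* per-residue-pair directional imbalance tests — an exact two-sided
  binomial test of a->b counts against the symmetry null p0 = 0.5, with
  Benjamini-Hochberg FDR adjustment over the tested pairs.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alphabet import AA_CODE_LOOKUP, AA_INDEX, AMINO_ACIDS
from .column_quality import alignment_to_matrix
from .io_formats import Alignment, SpeciesPartition

log = logging.getLogger(__name__)

AA_LIST = list(AMINO_ACIDS)


@dataclass(frozen=True)
class SubstitutionSite:
    """One concordant reference->foreground replacement at an alignment column.

    ``column`` is the original 1-based alignment column.
    """

    group_id: str
    column: int
    ref_residue: str
    fg_residue: str

    def __post_init__(self) -> None:
        if self.ref_residue not in AA_INDEX or self.fg_residue not in AA_INDEX:
            raise ValueError(
                f"site residues must be standard amino acids, got "
                f"{self.ref_residue!r} -> {self.fg_residue!r}"
            )
        if self.ref_residue == self.fg_residue:
            raise ValueError(f"site at {self.group_id}:{self.column} is not a substitution")


@dataclass
class SubstitutionCountMatrix:
    """20x20 directed substitution counts, rows = reference residue."""

    counts: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def percentages(self) -> pd.DataFrame:
        """Counts as percentages of all observed substitutions."""
        total = self.total
        if total == 0:
            return self.counts.astype(float)
        return 100.0 * self.counts / total

    def transposed(self) -> "SubstitutionCountMatrix":
        return SubstitutionCountMatrix(self.counts.T.copy())


@dataclass
class CompositionProfile:
    """Per-residue counts and frequencies over the 20 amino acids."""

    counts: pd.Series

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def freqs(self) -> pd.Series:
        """Counts normalised to frequencies; all-NaN (flagged) when empty."""
        total = self.total
        if total == 0:
            log.warning("composition profile has zero total; frequencies undefined")
            return pd.Series(np.nan, index=self.counts.index)
        return self.counts / total


@dataclass
class UsageBiasResult:
    residue: str
    count_ref: int
    count_fg: int
    chi2: float
    p_raw: float
    p_bonferroni: float
    significant: bool
    favored_in_foreground: bool | None  # None when counts are equal


@dataclass
class ImbalanceResult:
    residue_a: str
    residue_b: str
    n_ab: int  # reference a -> foreground b
    n_ba: int
    log2_ratio: float  # NaN when either direction is unobserved
    p_raw: float
    q_bh: float
    significant: bool


def detect_concordant_sites(
    aln: Alignment,
    partition: SpeciesPartition,
    require_all_foreground: bool = True,
    column_map: Sequence[int] | np.ndarray | None = None,
) -> list[SubstitutionSite]:
    """Find columns where the foreground clade shows one concordant substitution.

    A column yields a site iff every reference sequence carries the same
    residue Y, every foreground sequence carries the same residue X != Y,
    and no gap or ``X`` occurs in any of them. With
    ``require_all_foreground=False``, gaps/unknowns count as absence and
    concordance is scored over the species actually present (>= 2 distinct
    foreground species, >= 1 reference species).

    ``column_map`` maps local 0-based columns to original 1-based columns
    (as produced by column filtering); default is the identity.
    """
    rows_by_species: dict[str, list[int]] = {}
    for i, m in enumerate(aln.members):
        rows_by_species.setdefault(m.species, []).append(i)
    if require_all_foreground:
        missing = (partition.foreground | partition.references) - set(rows_by_species)
        if missing:
            raise ValueError(
                f"alignment {aln.group_id!r} is missing partition species: {sorted(missing)}"
            )
    fg_rows = [i for sp in sorted(partition.foreground) for i in rows_by_species.get(sp, [])]
    ref_rows = [i for sp in sorted(partition.references) for i in rows_by_species.get(sp, [])]
    if aln.n_columns == 0 or not fg_rows or not ref_rows:
        return []
    codes = AA_CODE_LOOKUP[alignment_to_matrix(aln)]
    # column_map entries (as produced by filter_columns) are 0-based originals
    if column_map is None:
        originals = np.arange(aln.n_columns) + 1
    else:
        originals = np.asarray(column_map, dtype=int) + 1
        if originals.size != aln.n_columns:
            raise ValueError("column_map length must equal the alignment width")
    sites: list[SubstitutionSite] = []
    fg = codes[fg_rows]
    ref = codes[ref_rows]
    if require_all_foreground:
        ok = (
            (fg >= 0).all(axis=0)
            & (ref >= 0).all(axis=0)
            & (fg == fg[0]).all(axis=0)
            & (ref == ref[0]).all(axis=0)
            & (fg[0] != ref[0])
        )
        for c in np.nonzero(ok)[0]:
            sites.append(
                SubstitutionSite(
                    group_id=aln.group_id,
                    column=int(originals[c]),
                    ref_residue=AMINO_ACIDS[ref[0, c]],
                    fg_residue=AMINO_ACIDS[fg[0, c]],
                )
            )
        return sites
    # permissive mode: species with gaps/X at the column are treated as absent
    fg_species_rows = {
        sp: rows_by_species[sp] for sp in sorted(partition.foreground) if sp in rows_by_species
    }
    ref_species_rows = {
        sp: rows_by_species[sp] for sp in sorted(partition.references) if sp in rows_by_species
    }
    for c in range(aln.n_columns):
        fg_res: set[int] = set()
        n_fg_species = 0
        for sp, rows in fg_species_rows.items():
            vals = {int(codes[r, c]) for r in rows}
            if -1 in vals:
                continue
            n_fg_species += 1
            fg_res |= vals
        if n_fg_species < 2 or len(fg_res) != 1:
            continue
        ref_res: set[int] = set()
        n_ref_species = 0
        for sp, rows in ref_species_rows.items():
            vals = {int(codes[r, c]) for r in rows}
            if -1 in vals:
                continue
            n_ref_species += 1
            ref_res |= vals
        if n_ref_species < 1 or len(ref_res) != 1:
            continue
        x = fg_res.pop()
        y = ref_res.pop()
        if x != y:
            sites.append(
                SubstitutionSite(
                    group_id=aln.group_id,
                    column=int(originals[c]),
                    ref_residue=AMINO_ACIDS[y],
                    fg_residue=AMINO_ACIDS[x],
                )
            )
    return sites


def pool_sites(per_group_sites: Iterable[Iterable[SubstitutionSite]]) -> list[SubstitutionSite]:
    """Concatenate per-group site lists, preserving provenance and order."""
    pooled: list[SubstitutionSite] = []
    seen: set[tuple[str, int]] = set()
    for sites in per_group_sites:
        for s in sites:
            key = (s.group_id, s.column)
            if key in seen:
                raise ValueError(f"duplicate site at {s.group_id}:{s.column} while pooling")
            seen.add(key)
            pooled.append(s)
    return pooled


def accumulate_matrix(sites: Iterable[SubstitutionSite]) -> SubstitutionCountMatrix:
    """Accumulate sites into the 20x20 directed count matrix."""
    counts = np.zeros((20, 20), dtype=int)
    for s in sites:
        counts[AA_INDEX[s.ref_residue], AA_INDEX[s.fg_residue]] += 1
    return SubstitutionCountMatrix(pd.DataFrame(counts, index=AA_LIST, columns=AA_LIST))


def global_composition(alns: Iterable[Alignment], species: str) -> CompositionProfile:
    """Residue composition of one species over all its aligned sequences.

    Counts every non-gap, non-``X`` residue of that species across the
    supplied alignments.
    """
    counts = np.zeros(20, dtype=np.int64)
    seen = False
    for aln in alns:
        for m in aln.members:
            if m.species != species:
                continue
            seen = True
            codes = AA_CODE_LOOKUP[np.frombuffer(m.residues.encode("ascii"), dtype=np.uint8)]
            counts += np.bincount(codes[codes >= 0], minlength=20)
    if not seen:
        raise ValueError(f"species {species!r} absent from every alignment")
    return CompositionProfile(pd.Series(counts, index=AA_LIST))


def site_composition(
    sites: Iterable[SubstitutionSite],
) -> tuple[CompositionProfile, CompositionProfile]:
    """Reference-side and foreground-side residue usage over substitution sites."""
    ref = np.zeros(20, dtype=np.int64)
    fg = np.zeros(20, dtype=np.int64)
    for s in sites:
        ref[AA_INDEX[s.ref_residue]] += 1
        fg[AA_INDEX[s.fg_residue]] += 1
    return (
        CompositionProfile(pd.Series(ref, index=AA_LIST)),
        CompositionProfile(pd.Series(fg, index=AA_LIST)),
    )


def test_usage_bias(
    ref_profile: CompositionProfile,
    fg_profile: CompositionProfile,
    alpha: float = 1e-15,
) -> list[UsageBiasResult]:
    """Per-residue 2x2 chi-square usage tests with Bonferroni factor 20.

    For each residue r the table is (r vs not-r) x (reference vs
    foreground), chi-square without continuity correction. The Bonferroni
    family size is fixed at 20 (one test per residue).
    """
    total_ref = ref_profile.total
    total_fg = fg_profile.total
    if total_ref == 0 or total_fg == 0:
        raise ValueError("usage-bias test requires non-empty profiles on both sides")
    results: list[UsageBiasResult] = []
    for aa in AA_LIST:
        c_ref = int(ref_profile.counts[aa])
        c_fg = int(fg_profile.counts[aa])
        both = c_ref + c_fg
        rest = (total_ref - c_ref) + (total_fg - c_fg)
        if both == 0 or rest == 0:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(
                [[c_ref, total_ref - c_ref], [c_fg, total_fg - c_fg]], correction=False
            )
        p_bonf = min(1.0, 20.0 * p)
        f_ref = c_ref / total_ref
        f_fg = c_fg / total_fg
        favored = None if f_fg == f_ref else (f_fg > f_ref)
        results.append(
            UsageBiasResult(aa, c_ref, c_fg, float(chi2), float(p), p_bonf, p_bonf < alpha, favored)
        )
    return results


def global_usage_chi2(
    ref_profile: CompositionProfile, fg_profile: CompositionProfile
) -> tuple[float, float, int]:
    """Secondary 20-category goodness-of-fit style test (2 x 20 contingency).

    Residues unobserved on both sides are dropped. Returns (chi2, p, dof).
    """
    ref = ref_profile.counts.to_numpy()
    fg = fg_profile.counts.to_numpy()
    keep = (ref + fg) > 0
    if keep.sum() < 2:
        return 0.0, 1.0, 0
    chi2, p, dof, _ = stats.chi2_contingency(np.vstack([ref[keep], fg[keep]]), correction=False)
    return float(chi2), float(p), int(dof)


def exact_binomial_pvalue(k: int, n: int) -> float:
    """Two-sided exact binomial p-value of ``k`` successes in ``n`` trials, p0=0.5.

    Two-sided by the minimum-likelihood rule: the sum of the probabilities
    of all outcomes whose point probability does not exceed the observed
    one (with the conventional 1 + 1e-7 relative slack for floating-point
    ties, as in the standard exact-test implementations).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        return 1.0
    pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
    threshold = pmf[k] * (1.0 + 1e-7)
    return float(min(1.0, pmf[pmf <= threshold].sum()))


def normal_proportion_pvalue(k: int, n: int) -> float:
    """Two-sided normal-approximation proportion test against p0 = 0.5."""
    if n == 0:
        return 1.0
    z = (k - 0.5 * n) / math.sqrt(0.25 * n)
    return float(2.0 * stats.norm.sf(abs(z)))


def test_directional_imbalance(
    matrix: SubstitutionCountMatrix,
    q_threshold: float = 0.05,
    method: str = "exact",
) -> list[ImbalanceResult]:
    """Test each unordered residue pair for directional substitution asymmetry.

    For every pair (a, b) with n_ab + n_ba > 0, the a->b count is tested
    against the symmetric null p0 = 0.5 (exact two-sided binomial by
    default, ``method='normal'`` for the normal-approximation proportion
    test). BH adjustment runs over the tested pairs only; pairs never
    observed in either direction are omitted. ``log2_ratio`` is NaN when a
    direction is unobserved; its p-value is still valid.
    """
    if method not in ("exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    pvalue = exact_binomial_pvalue if method == "exact" else normal_proportion_pvalue
    counts = matrix.counts
    rows: list[tuple[str, str, int, int, float, float]] = []
    for a, b in combinations(AA_LIST, 2):
        n_ab = int(counts.loc[a, b])
        n_ba = int(counts.loc[b, a])
        n = n_ab + n_ba
        if n == 0:
            continue
        p = pvalue(n_ab, n)
        l2 = math.log2(n_ab / n_ba) if n_ab > 0 and n_ba > 0 else math.nan
        rows.append((a, b, n_ab, n_ba, l2, p))
    if not rows:
        return []
    _, q_values, _, _ = multipletests([r[5] for r in rows], method="fdr_bh")
    return [
        ImbalanceResult(a, b, n_ab, n_ba, l2, p, float(q), float(q) < q_threshold)
        for (a, b, n_ab, n_ba, l2, p), q in zip(rows, q_values)
    ]
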