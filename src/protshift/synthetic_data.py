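"""Synthetic orthologue alignments, hit tables and ground truth.

The generator emulates the signal the analysis looks for with the minimal
process that produces it: a star-like two-level substitution model. Per
column, an ancestral residue is drawn from ``ancestral_freqs``; with
probability ``p_shared`` a single substitution happens on the shared
ancestral branch of the foreground clade (target drawn uniformly over the
19 alternatives, re-weighted by any matching ``bias_pairs`` multiplier and
renormalised); every tip sequence then accumulates independent private
substitutions (probability ``p_private`` per column, uniform over the 19
alternatives) and gaps (``p_gap``). Reference tips never receive the shared
event. Ground truth records each shared event whose concordance survives,
i.e. no private substitution or gap anywhere in that column.

All randomness flows from the single configured seed through one
``numpy.random.Generator`` (PCG64), so a fixed seed gives byte-identical
outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from .alphabet import AA_INDEX, AMINO_ACIDS, codes_to_seq
from .io_formats import (
    AlignedSequence,
    Alignment,
    HitRecord,
    SpeciesPartition,
    write_alignment_fasta,
    write_hit_table,
)
from .orthology import OrthologPair, write_pair_table

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic substitution process.

    Defaults describe the standard scenario used throughout the test
    battery: 50 orthology groups of 300 columns over 4 foreground and 2
    reference species, a 5% per-column chance of a shared ancestral-branch
    substitution, light private noise and gaps, uniform ancestral residue
    frequencies.
    """

    n_groups: int = 50
    seq_length: int = 300
    n_foreground: int = 4
    n_reference: int = 2
    ancestral_freqs: np.ndarray | None = None  # default: uniform over 20
    p_shared: float = 0.05
    bias_pairs: tuple[tuple[str, str, float], ...] = ()
    p_private: float = 0.005
    p_gap: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.seq_length < 1:
            raise ValueError("n_groups and seq_length must be >= 1")
        if self.n_foreground < 2:
            raise ValueError("need at least 2 foreground species")
        if self.n_reference < 1:
            raise ValueError("need at least 1 reference species")
        for name in ("p_shared", "p_private", "p_gap"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.ancestral_freqs is not None:
            f = np.asarray(self.ancestral_freqs, dtype=float)
            if f.shape != (20,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("ancestral_freqs must be a 20-vector summing to 1")
            self.ancestral_freqs = f
        norm_bias = []
        for s, t, w in self.bias_pairs:
            if s not in AA_INDEX or t not in AA_INDEX or s == t:
                raise ValueError(f"invalid bias pair ({s!r}, {t!r})")
            if not w > 0:
                raise ValueError(f"bias weight for ({s}, {t}) must be > 0, got {w}")
            norm_bias.append((s, t, float(w)))
        self.bias_pairs = tuple(norm_bias)

    @property
    def foreground_species(self) -> tuple[str, ...]:
        return tuple(f"fg{i + 1}" for i in range(self.n_foreground))

    @property
    def reference_species(self) -> tuple[str, ...]:
        return tuple(f"ref{i + 1}" for i in range(self.n_reference))

    def partition(self) -> SpeciesPartition:
        return SpeciesPartition(self.foreground_species, self.reference_species)

    def freqs(self) -> np.ndarray:
        if self.ancestral_freqs is None:
            return np.full(20, 1.0 / 20.0)
        return self.ancestral_freqs


@dataclass
class GroundTruth:
    """What the generator planted: concordant sites and/or orthology groups."""

    planted_sites: list[tuple[str, int, str, str]] = field(default_factory=list)
    # ortholog pair -> {query species -> transcript}
    planted_groups: dict[OrthologPair, dict[str, str]] = field(default_factory=dict)


@dataclass
class SimulatedHits:
    """Synthetic best-hit tables against two reference species."""

    hits_a: dict[str, list[HitRecord]]
    hits_b: dict[str, list[HitRecord]]
    pairs: list[OrthologPair]
    truth: GroundTruth


def target_weight_matrix(bias_pairs: Sequence[tuple[str, str, float]]) -> np.ndarray:
    """Row-normalised target-choice probabilities for shared substitutions.

    Row s: uniform weight 1 on the 19 alternatives, multiplied by any
    matching bias multiplier, then renormalised. Diagonal is zero.
    """
    w = np.ones((20, 20))
    np.fill_diagonal(w, 0.0)
    for s, t, mult in bias_pairs:
        w[AA_INDEX[s], AA_INDEX[t]] *= mult
    return w / w.sum(axis=1, keepdims=True)


def expected_log2_imbalance(
    bias_pairs: Sequence[tuple[str, str, float]],
    source: str,
    target: str,
    freqs: np.ndarray | None = None,
) -> float:
    """Closed-form expected log2(n_st / n_ts) under the target-reweighting rule.

    The rate of source->target truth sites is proportional to
    ``freq[source] * P(target | source)`` with P from
    :func:`target_weight_matrix`; the expectation is the log2 ratio of the
    two directed rates.
    """
    p = target_weight_matrix(bias_pairs)
    f = np.full(20, 1.0 / 20.0) if freqs is None else np.asarray(freqs, float)
    s, t = AA_INDEX[source], AA_INDEX[target]
    return float(np.log2((f[s] * p[s, t]) / (f[t] * p[t, s])))


def simulate_alignments(config: SimulationConfig) -> tuple[list[Alignment], GroundTruth]:
    """Generate one alignment per orthology group plus the planted-site truth."""
    rng = np.random.default_rng(config.seed)
    freqs = config.freqs()
    target_probs = target_weight_matrix(config.bias_pairs)
    species_order = config.reference_species + config.foreground_species
    n_ref = config.n_reference
    alignments: list[Alignment] = []
    truth = GroundTruth()
    for g in range(config.n_groups):
        gid = f"og{g:04d}"
        length = config.seq_length
        ancestral = rng.choice(20, size=length, p=freqs)
        shared_mask = rng.random(length) < config.p_shared
        fg_base = ancestral.copy()
        n_shared = int(shared_mask.sum())
        if n_shared:
            probs = target_probs[ancestral[shared_mask]]
            u = rng.random(n_shared)
            targets = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
            fg_base[shared_mask] = np.minimum(targets, 19)
        clean = np.ones(length, dtype=bool)
        members: list[AlignedSequence] = []
        for i, sp in enumerate(species_order):
            seq = (ancestral if i < n_ref else fg_base).copy()
            private = rng.random(length) < config.p_private
            if private.any():
                offset = rng.integers(0, 19, size=int(private.sum()))
                seq[private] = (seq[private] + 1 + offset) % 20
            gaps = rng.random(length) < config.p_gap
            clean &= ~private & ~gaps
            members.append(
                AlignedSequence(
                    seq_id=f"{sp}_{gid}", species=sp, residues=codes_to_seq(seq, gaps)
                )
            )
        alignments.append(Alignment(group_id=gid, members=members))
        for c in np.nonzero(shared_mask & clean)[0]:
            truth.planted_sites.append(
                (gid, int(c) + 1, AMINO_ACIDS[ancestral[c]], AMINO_ACIDS[fg_base[c]])
            )
    return alignments, truth


_CODONS_BY_AA: dict[str, list[str]] = {}


def _codons_for(aa: str, table_id: int = 1) -> list[str]:
    if not _CODONS_BY_AA:
        table = CodonTable.unambiguous_dna_by_id[table_id]
        for codon, res in sorted(table.forward_table.items()):
            _CODONS_BY_AA.setdefault(res, []).append(codon)
    return _CODONS_BY_AA[aa]


def simulate_cds(alignments: Iterable[Alignment], seed: int = 0) -> dict[str, dict[str, str]]:
    """Emit a consistent CDS per sequence (uniform synonymous codon choice).

    Returns group_id -> {seq_id -> CDS}; gap columns contribute nothing.
    """
    rng = np.random.default_rng([seed, 104729])
    out: dict[str, dict[str, str]] = {}
    for aln in alignments:
        per_seq: dict[str, str] = {}
        for m in aln.members:
            codons: list[str] = []
            for res in m.residues:
                if res == "-":
                    continue
                options = _codons_for(res)
                codons.append(options[int(rng.integers(0, len(options)))])
            per_seq[m.seq_id] = "".join(codons)
        out[aln.group_id] = per_seq
    return out


def simulate_hit_tables(
    config: SimulationConfig, n_discrepant: int = 0, n_weak: int = 0
) -> SimulatedHits:
    """Generate dual-reference best-hit tables with planted orthology truth.

    Every planted group yields, in each query (foreground) species, one
    transcript with consistent strong hits (e-value <= 1e-45) to a
    generated reference gene pair present in the pair table.
    ``n_discrepant`` extra transcripts hit a non-paired gene combination;
    ``n_weak`` extra transcripts carry an e-value above the 1e-40 cutoff.
    """
    if n_discrepant > 0 and config.n_groups < 2:
        raise ValueError("discrepant transcripts require at least 2 planted pairs")
    rng = np.random.default_rng([config.seed, 7919])
    species = config.foreground_species
    pairs = [OrthologPair(f"ga{i:05d}", f"zb{i:05d}") for i in range(config.n_groups)]
    hits_a: dict[str, list[HitRecord]] = {sp: [] for sp in species}
    hits_b: dict[str, list[HitRecord]] = {sp: [] for sp in species}
    truth = GroundTruth()

    def strong_evalue() -> float:
        return float(10.0 ** rng.uniform(-180.0, -45.0))

    def bitscore() -> float:
        return float(rng.uniform(200.0, 900.0))

    for i, pair in enumerate(pairs):
        truth.planted_groups[pair] = {}
        for sp in species:
            t = f"{sp}_t{i:05d}"
            hits_a[sp].append(HitRecord(t, pair.ref_a_gene, strong_evalue(), bitscore()))
            hits_b[sp].append(HitRecord(t, pair.ref_b_gene, strong_evalue(), bitscore()))
            truth.planted_groups[pair][sp] = t
    for k in range(n_discrepant):
        sp = species[k % len(species)]
        i = k % config.n_groups
        j = (i + 1) % config.n_groups
        t = f"{sp}_d{k:04d}"
        hits_a[sp].append(HitRecord(t, pairs[i].ref_a_gene, strong_evalue(), bitscore()))
        hits_b[sp].append(HitRecord(t, pairs[j].ref_b_gene, strong_evalue(), bitscore()))
    for k in range(n_weak):
        sp = species[k % len(species)]
        i = k % config.n_groups
        t = f"{sp}_w{k:04d}"
        weak = float(10.0 ** rng.uniform(-39.0, -15.0))
        hits_a[sp].append(HitRecord(t, pairs[i].ref_a_gene, weak, bitscore()))
        hits_b[sp].append(HitRecord(t, pairs[i].ref_b_gene, strong_evalue(), bitscore()))
    return SimulatedHits(hits_a=hits_a, hits_b=hits_b, pairs=pairs, truth=truth)


def perturb_groups(
    member_sets: Sequence[Iterable[str]], k: int, rng: np.random.Generator
) -> list[set[str]]:
    """Break exactly ``k`` groups of a clustering by exiling one member each.

    The exiled transcript becomes a singleton cluster, so the perturbed
    clustering stays a partition and exactly ``k`` of the original groups
    fail the full-overlap consistency check.
    """
    out = [set(s) for s in member_sets]
    if not 0 <= k <= len(out):
        raise ValueError(f"k={k} outside 0..{len(out)}")
    if any(len(s) < 2 for s in out):
        raise ValueError("all groups must have >= 2 members to be perturbable")
    chosen = rng.choice(len(out), size=k, replace=False)
    singletons: list[set[str]] = []
    for i in sorted(int(c) for c in chosen):
        exile = sorted(out[i])[0]
        out[i].discard(exile)
        singletons.append({exile})
    return out + singletons


# ---------------------------------------------------------------------------
# dataset writers / plain-text config

def write_dataset(
    outdir: str | Path,
    alignments: Sequence[Alignment],
    truth: GroundTruth,
    hits: SimulatedHits | None = None,
) -> None:
    """Write a full synthetic dataset: alignments/, truth TSVs, hit tables."""
    outdir = Path(outdir)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(parents=True, exist_ok=True)
    for aln in alignments:
        write_alignment_fasta(aln, aln_dir / f"{aln.group_id}.fasta")
    write_truth_sites(truth, outdir / "truth_sites.tsv")
    if hits is not None:
        hit_dir = outdir / "hits"
        hit_dir.mkdir(exist_ok=True)
        for sp in sorted(hits.hits_a):
            write_hit_table(hits.hits_a[sp], hit_dir / f"{sp}_refa.tsv")
            write_hit_table(hits.hits_b[sp], hit_dir / f"{sp}_refb.tsv")
        write_pair_table(hits.pairs, outdir / "pairs.tsv")
        with open(outdir / "truth_groups.tsv", "w") as fh:
            fh.write("ref_a\tref_b\tspecies\ttranscript\n")
            for pair in sorted(hits.truth.planted_groups):
                for sp, t in sorted(hits.truth.planted_groups[pair].items()):
                    fh.write(f"{pair.ref_a_gene}\t{pair.ref_b_gene}\t{sp}\t{t}\n")


def write_truth_sites(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tcolumn\tref_residue\tfg_residue\n")
        for gid, col, src, dst in truth.planted_sites:
            fh.write(f"{gid}\t{col}\t{src}\t{dst}\n")


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Echo a configuration as a plain-text key=value file."""
    with open(path, "w") as fh:
        fh.write(f"n_groups = {config.n_groups}\n")
        fh.write(f"seq_length = {config.seq_length}\n")
        fh.write(f"n_foreground = {config.n_foreground}\n")
        fh.write(f"n_reference = {config.n_reference}\n")
        if config.ancestral_freqs is not None:
            fh.write("ancestral_freqs = " + ",".join(f"{x:.10g}" for x in config.ancestral_freqs) + "\n")
        fh.write(f"p_shared = {config.p_shared}\n")
        if config.bias_pairs:
            fh.write(
                "bias_pairs = " + ";".join(f"{s}:{t}:{w:g}" for s, t, w in config.bias_pairs) + "\n"
            )
        fh.write(f"p_private = {config.p_private}\n")
        fh.write(f"p_gap = {config.p_gap}\n")
        fh.write(f"seed = {config.seed}\n")


def read_config(path: str | Path) -> SimulationConfig:
    """Parse a plain-text key=value configuration file."""
    kwargs: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key in ("n_groups", "seq_length", "n_foreground", "n_reference", "seed"):
                kwargs[key] = int(value)
            elif key in ("p_shared", "p_private", "p_gap"):
                kwargs[key] = float(value)
            elif key == "ancestral_freqs":
                kwargs[key] = np.array([float(x) for x in value.split(",")])
            elif key == "bias_pairs":
                triples = []
                for item in value.split(";"):
                    s, t, w = item.split(":")
                    triples.append((s.strip(), t.strip(), float(w)))
                kwargs[key] = tuple(triples)
            else:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
    return SimulationConfig(**kwargs)  # type: ignore[arg-type]
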