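"""Independent brute-force oracles, deliberately written without reusing
any vectorised code path from the package."""
import numpy as np
from scipy.stats import binom


def brute_force_sites(aln, partition):
    """Column-by-column concordant-site scan over raw residue strings."""
    found = []
    for c in range(aln.n_columns):
        fg = [m.residues[c] for m in aln.members if m.species in partition.foreground]
        ref = [m.residues[c] for m in aln.members if m.species in partition.references]
        chars = fg + ref
        if any(ch in "-X" for ch in chars):
            continue
        if len(set(fg)) != 1 or len(set(ref)) != 1:
            continue
        if fg[0] == ref[0]:
            continue
        found.append((aln.group_id, c + 1, ref[0], fg[0]))
    return found


def direct_binomial_two_sided(k, n):
    """Double-tail summation of the binomial(n, 1/2) pmf, sorted-order oracle."""
    pmf = binom.pmf(np.arange(n + 1), n, 0.5)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    cutoff = np.searchsorted(sorted_pmf, pmf[k] * (1 + 1e-7), side="right")
    return float(min(1.0, csum[cutoff - 1]))
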