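"""Independent brute-force reference implementations used to cross-check the
package's statistics. These deliberately use naive loops and first-principles
formulas, not the vectorised code paths under test."""

from __future__ import annotations

import itertools
import math

import numpy as np


def zscores_bruteforce(counts) -> list[float]:
    """Within-window z-scores by explicit mean/population-sd loops."""
    n = len(counts)
    mu = sum(counts) / n
    var = sum((c - mu) ** 2 for c in counts) / n
    sd = math.sqrt(var)
    return [(c - mu) / sd for c in counts]


def spearman_rho_bruteforce(x, y) -> float:
    """Rank (average ties) then Pearson, all by hand."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def spearman_exact_p_bruteforce(x, y) -> float:
    """Two-sided exact permutation p for the rank correlation (tiny n only)."""
    n = len(x)
    obs = abs(spearman_rho_bruteforce(x, y))
    hits = total = 0
    y = list(y)
    for perm in itertools.permutations(range(n)):
        r = spearman_rho_bruteforce(x, [y[i] for i in perm])
        if abs(r) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def bh_qvalues_bruteforce(pvals) -> list[float]:
    """Benjamini-Hochberg step-up by the textbook definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * m / rank_from_end)
        q[i] = val
        prev = val
    return q


def asite_codon_bruteforce(five_prime_pos, length, offset, cds_start, cds_end):
    """Walk the transcript nucleotide by nucleotide to locate the A-site codon."""
    asite = five_prime_pos + offset
    pos = cds_start
    codon_index = 0
    while pos + 3 <= cds_end:
        if pos <= asite < pos + 3:
            return codon_index
        pos += 3
        codon_index += 1
    return None  # outside the CDS


def codon_filter_removed_bruteforce(
    asite_codon, codons, target, window
):
    """Should this read be removed? Scan every codon in the +/-window."""
    if asite_codon is None:
        return False
    for j in range(asite_codon - window, asite_codon + window + 1):
        if 0 <= j < len(codons) and codons[j] == target:
            return True
    return False


def occupancy_bruteforce(matrices_counts, codons_per_tx, exclude_start, exclude_end):
    """O_c, E_c per codon string via explicit per-instance loops."""
    observed: dict[str, float] = {}
    expected: dict[str, float] = {}
    for tid, counts in matrices_counts.items():
        codons = codons_per_tx[tid]
        n = len(counts)
        window = list(range(exclude_start, n - exclude_end))
        total = sum(counts[i] for i in window)
        if total == 0 or not window:
            continue
        e = total / len(window)
        for i in window:
            c = codons[i]
            if c in ("TAA", "TAG", "TGA"):
                continue
            observed[c] = observed.get(c, 0.0) + counts[i]
            expected[c] = expected.get(c, 0.0) + e
    return observed, expected


def welch_t_bruteforce(a, b):
    """Welch's t statistic and Satterthwaite df from the defining formulas."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, df
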