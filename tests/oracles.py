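"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (explicit
loops, full distance matrices, grid search) and shares no code with the
package internals it checks.
"""

from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive-likelihood grid oracle for 2-site EM phasing

# haplotypes over two biallelic sites, order (00, 01, 10, 11)
TWO_SITE_HAPS = [(0, 0), (0, 1), (1, 0), (1, 1)]


def _pairs_for_genotype(g: Tuple[int, int]) -> List[Tuple[int, int, int]]:
    """Ordered-pair resolutions (i, j, multiplicity) of a 2-site genotype."""
    out: Dict[Tuple[int, int], int] = {}
    for i, h1 in enumerate(TWO_SITE_HAPS):
        for j, h2 in enumerate(TWO_SITE_HAPS):
            if (h1[0] + h2[0], h1[1] + h2[1]) == g:
                key = (min(i, j), max(i, j))
                out[key] = out.get(key, 0) + 1
    return [(i, j, m) for (i, j), m in out.items()]


def grid_phase_oracle(
    genotype_counts: Dict[Tuple[int, int], int],
) -> np.ndarray:
    """MLE haplotype frequencies by coarse-to-fine simplex grid search.

    ``genotype_counts`` maps 2-site genotypes (variant-allele dosages,
    each 0/1/2) to individual counts.  Returns frequencies for the four
    haplotypes 00, 01, 10, 11 at ~3e-5 grid resolution.
    """
    classes = [
        (_pairs_for_genotype(g), n) for g, n in genotype_counts.items() if n > 0
    ]

    def loglik(fgrid: np.ndarray) -> np.ndarray:
        ll = np.zeros(fgrid.shape[0])
        for pairs, n in classes:
            prob = np.zeros(fgrid.shape[0])
            for i, j, m in pairs:
                prob += m * fgrid[:, i] * fgrid[:, j]
            ll += n * np.log(np.maximum(prob, 1e-300))
        return ll

    center = np.array([0.25, 0.25, 0.25, 0.25])
    step = 0.02
    for step in (0.02, 0.004, 8e-4, 1.6e-4, 3.2e-5):
        offsets = np.arange(-10, 11) * step
        cands = []
        for d1 in offsets:
            for d2 in offsets:
                for d3 in offsets:
                    f1 = center[1] + d1
                    f2 = center[2] + d2
                    f3 = center[3] + d3
                    f0 = 1.0 - f1 - f2 - f3
                    if min(f0, f1, f2, f3) < -1e-12:
                        continue
                    cands.append((max(f0, 0.0), f1, f2, f3))
        fgrid = np.array(cands)
        center = fgrid[int(np.argmax(loglik(fgrid)))]
    return center


# ---------------------------------------------------------------------------
# AMOVA from the full pairwise distance matrix


def amova_oracle(
    pairs: Sequence[Tuple[str, str]], groups: Sequence[str]
) -> Tuple[float, float, float]:
    """(σ²_among, σ²_within, Φ_ST) from an explicit 0/1 distance matrix."""
    chroms: List[str] = []
    chrom_group: List[str] = []
    for (a, b), g in zip(pairs, groups):
        chroms += [a, b]
        chrom_group += [g, g]
    n = len(chroms)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = 0.0 if chroms[i] == chroms[j] else 1.0

    def ss(indices: List[int]) -> float:
        tot = 0.0
        for i, j in combinations(indices, 2):
            tot += d[i, j]
        return tot / len(indices)

    ss_total = ss(list(range(n)))
    labels = sorted(set(chrom_group))
    ss_within = 0.0
    sizes = []
    for g in labels:
        idx = [i for i, gg in enumerate(chrom_group) if gg == g]
        sizes.append(len(idx))
        ss_within += ss(idx)
    ss_among = ss_total - ss_within

    df_among = len(labels) - 1
    df_within = n - len(labels)
    sigma_w = ss_within / df_within
    n_prime = (n - sum(s * s for s in sizes) / n) / df_among
    sigma_a = (ss_among / df_among - sigma_w) / n_prime
    phi = sigma_a / (sigma_a + sigma_w)
    return sigma_a, sigma_w, phi


# ---------------------------------------------------------------------------
# Weir–Cockerham θ by scalar evaluation of the component formulas


def wc_theta_oracle(populations: Sequence[Sequence[Tuple[str, str]]]) -> float:
    """Multi-allelic θ: per-allele a, b, c components via plain loops."""
    r = len(populations)
    alleles = sorted({x for pop in populations for g in pop for x in g})
    n_i = [len(pop) for pop in populations]
    n_bar = sum(n_i) / r
    n_c = (r * n_bar - sum(n * n for n in n_i) / (r * n_bar)) / (r - 1)

    sum_a = sum_b = sum_c = 0.0
    for allele in alleles:
        p = []
        h = []
        for pop in populations:
            count = sum((g[0] == allele) + (g[1] == allele) for g in pop)
            het = sum(
                1 for g in pop if (g[0] == allele) != (g[1] == allele)
            )
            p.append(count / (2 * len(pop)))
            h.append(het / len(pop))
        p_bar = sum(n * pi for n, pi in zip(n_i, p)) / (r * n_bar)
        s2 = sum(n * (pi - p_bar) ** 2 for n, pi in zip(n_i, p)) / (
            (r - 1) * n_bar
        )
        h_bar = sum(n * hi for n, hi in zip(n_i, h)) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2
        sum_a += a
        sum_b += b
        sum_c += c
    return sum_a / (sum_a + sum_b + sum_c)
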