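"""Population statistics for star-allele cohorts.

Gene-counting frequency tables, activity-class aggregation over the
evaluable-chromosome denominator, contingency tests (Pearson χ² and the
likelihood-ratio G-test, the single-predictor reduction of a multinomial
log-linear model), two-level haplotypic AMOVA with label-identity
distance and an individual-level permutation test, multi-allelic
Weir–Cockerham θ with an individual-resampling bootstrap CI, and the
Kruskal–Wallis / Mann–Whitney / Benjamini–Hochberg battery used for
ancestry–phenotype association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .alleles import (
    ActivityClass,
    AlleleDefinitions,
    OTHERS,
    parse_star_label,
)
from .diplotyping import DiplotypeCall

__all__ = [
    "FrequencyTable",
    "AmovaResult",
    "FstEstimate",
    "TestResult",
    "allele_frequencies",
    "duplication_carrier_table",
    "activity_class_table",
    "chi2_independence",
    "g_test_independence",
    "amova",
    "pairwise_fst",
    "wc_theta",
    "kruskal_wallis",
    "mann_whitney",
    "bh_fdr",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class FrequencyTable:
    """Counts and percentage frequencies per stratum (plus a Total column)."""

    counts: pd.DataFrame
    pct: pd.DataFrame
    chromosomes: pd.Series


@dataclass
class AmovaResult:
    sigma_among: float
    sigma_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: Optional[float]
    n_permutations: int


@dataclass
class FstEstimate:
    theta: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_bootstrap: int


@dataclass
class TestResult:
    statistic: float
    df: Optional[float]
    p_value: float
    method: str


# ---------------------------------------------------------------------------
# frequency tables


def _star_sort_key(label: str) -> Tuple[int, int, int]:
    """Sort base alleles numerically, then duplications, Others last."""
    if label == OTHERS:
        return (2, 0, 0)
    try:
        base, mult = parse_star_label(label)
        return (0 if mult == 1 else 1, int(base.lstrip("*")), mult)
    except ValueError:
        return (2, 1, 0)


def _evaluable(calls: Sequence[DiplotypeCall]) -> List[DiplotypeCall]:
    good = [c for c in calls if not c.blocked]
    skipped = len(calls) - len(good)
    if skipped:
        warnings.warn(
            f"{skipped} blocked individual(s) excluded from frequency table",
            stacklevel=3,
        )
    if not good:
        raise ValueError("no evaluable individuals")
    return good


def allele_frequencies(
    calls: Sequence[DiplotypeCall],
    strata: Mapping[str, str] | None = None,
) -> FrequencyTable:
    """Gene-counting allele frequencies: two slots per individual.

    A ×N label occupies a single slot, so each stratum's counts sum to
    2 × (number of individuals) regardless of copy number.
    """
    good = _evaluable(calls)
    records = []
    for c in good:
        stratum = "Total" if strata is None else strata.get(c.individual_id)
        if stratum is None:
            continue
        for slot in c.slots:
            records.append((stratum, slot))
    df = pd.DataFrame(records, columns=["stratum", "allele"])
    counts = df.pivot_table(
        index="allele", columns="stratum", aggfunc="size", fill_value=0
    )
    if strata is not None:
        counts["Total"] = counts.sum(axis=1)
    counts = counts.loc[sorted(counts.index, key=_star_sort_key)]
    chromosomes = counts.sum(axis=0)
    pct = 100.0 * counts / chromosomes
    return FrequencyTable(counts=counts, pct=pct, chromosomes=chromosomes)


def duplication_carrier_table(
    calls: Sequence[DiplotypeCall],
    strata: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-stratum count and percentage of individuals with > 2 gene copies."""
    good = _evaluable(calls)
    rows = []
    for c in good:
        stratum = "Total" if strata is None else strata.get(c.individual_id)
        if stratum is None:
            continue
        rows.append((stratum, c.total_copy_number > 2))
    df = pd.DataFrame(rows, columns=["stratum", "carrier"])
    out = df.groupby("stratum")["carrier"].agg(carriers="sum", n="count")
    if strata is not None:
        out.loc["Total"] = out.sum()
    out["pct"] = 100.0 * out["carriers"] / out["n"]
    return out


def activity_class_table(
    calls: Sequence[DiplotypeCall],
    defs: AlleleDefinitions,
    strata: Mapping[str, str] | None = None,
) -> FrequencyTable:
    """Allele slots aggregated by predicted activity class.

    Slots whose activity is not determined (unassignable "Others"
    haplotypes and ND-activity alleles) are removed from both numerator
    and denominator, giving the evaluable-chromosome denominator.
    Surplus copies of ambiguous duplications never occupied a slot, so
    they are absent by construction.
    """
    good = _evaluable(calls)
    records = []
    for c in good:
        stratum = "Total" if strata is None else strata.get(c.individual_id)
        if stratum is None:
            continue
        for slot in c.slots:
            act = defs.classify_activity(slot)
            if act is ActivityClass.ND:
                continue
            records.append((stratum, act.value))
    df = pd.DataFrame(records, columns=["stratum", "activity"])
    counts = df.pivot_table(
        index="activity", columns="stratum", aggfunc="size", fill_value=0
    )
    if strata is not None:
        counts["Total"] = counts.sum(axis=1)
    order = [
        a.value
        for a in (ActivityClass.NONE, ActivityClass.REDUCED,
                  ActivityClass.NORMAL, ActivityClass.HIGH)
        if a.value in counts.index
    ]
    counts = counts.loc[order]
    chromosomes = counts.sum(axis=0)
    pct = 100.0 * counts / chromosomes
    return FrequencyTable(counts=counts, pct=pct, chromosomes=chromosomes)


# ---------------------------------------------------------------------------
# contingency tests


def _validate_table(table: np.ndarray) -> np.ndarray:
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2×2")
    if (obs < 0).any():
        raise ValueError("negative counts in contingency table")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"row {i} has zero marginal total")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise ValueError(f"column {j} has zero marginal total")
    return obs


def chi2_independence(table) -> TestResult:
    """Pearson χ² test of independence (no continuity correction)."""
    obs = _validate_table(table)
    res = sps.chi2_contingency(obs, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.dof),
        p_value=float(res.pvalue),
        method="pearson-chi2",
    )


def g_test_independence(table) -> TestResult:
    """Likelihood-ratio (G²) test of independence.

    ``G² = 2 Σ O ln(O/E)`` over cells with O > 0 — the LR test of the
    saturated against the independence log-linear model, i.e. what a
    multinomial log-linear model reduces to for a single categorical
    predictor.
    """
    obs = _validate_table(table)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    mask = obs > 0
    g2 = 2.0 * float((obs[mask] * np.log(obs[mask] / expected[mask])).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(
        statistic=g2,
        df=float(df),
        p_value=float(sps.chi2.sf(g2, df)),
        method="g-test",
    )


# ---------------------------------------------------------------------------
# AMOVA


def _encode_pairs(
    pairs: Sequence[Tuple[str, str]],
) -> Tuple[np.ndarray, List[str]]:
    labels = sorted({x for p in pairs for x in p})
    lut = {lab: k for k, lab in enumerate(labels)}
    arr = np.array([[lut[a], lut[b]] for a, b in pairs], dtype=np.intp)
    return arr, labels


def _amova_phi(
    arr: np.ndarray,
    group_indices: Sequence[np.ndarray],
    n_alleles: int,
) -> Tuple[float, float, float]:
    """(σ²_among, σ²_within, Φ_ST) for identity-distance haplotypic AMOVA.

    With δ(i,j) ∈ {0, 1} the sums of squared distances reduce to pair
    counts computable from allele counts, so no distance matrix is built.
    """
    total_counts = np.bincount(arr.ravel(), minlength=n_alleles)
    n_tot = int(total_counts.sum())
    n_groups = len(group_indices)

    def sum_d(counts: np.ndarray, n: int) -> float:
        # Σ_{i<j} δ = all pairs − same-label pairs
        return n * (n - 1) / 2.0 - float((counts * (counts - 1)).sum()) / 2.0

    ss_total = sum_d(total_counts, n_tot) / n_tot
    ss_within = 0.0
    group_sizes = []
    for idx in group_indices:
        counts = np.bincount(arr[idx].ravel(), minlength=n_alleles)
        n_g = int(counts.sum())
        group_sizes.append(n_g)
        ss_within += sum_d(counts, n_g) / n_g
    ss_among = ss_total - ss_within

    df_among = n_groups - 1
    df_within = n_tot - n_groups
    sigma_within = ss_within / df_within
    n_prime = (n_tot - sum(g * g for g in group_sizes) / n_tot) / df_among
    sigma_among = (ss_among / df_among - sigma_within) / n_prime
    denom = sigma_among + sigma_within
    phi = sigma_among / denom if denom != 0.0 else 0.0
    return sigma_among, sigma_within, phi


def amova(
    pairs: Sequence[Tuple[str, str]],
    groups: Sequence[str],
    *,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> AmovaResult:
    """Two-level AMOVA on per-individual allele-label pairs.

    Distance between chromosomes is label identity (0 same allele, 1
    different).  The permutation test reassigns *individuals* to groups
    (both chromosomes travelling together) and counts permutations with
    Φ_ST at least the observed value.
    """
    if len(pairs) != len(groups):
        raise ValueError("pairs and groups must align")
    group_labels = sorted(set(groups))
    if len(group_labels) < 2:
        raise ValueError("need at least 2 groups")
    arr, labels = _encode_pairs(pairs)
    groups_arr = np.asarray(groups)
    group_indices = [np.flatnonzero(groups_arr == g) for g in group_labels]
    for g, idx in zip(group_labels, group_indices):
        if len(idx) < 1:
            raise ValueError(f"group {g!r} has no individuals")

    sigma_a, sigma_w, phi = _amova_phi(arr, group_indices, len(labels))

    p_value: Optional[float] = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        sizes = [len(idx) for idx in group_indices]
        bounds = np.cumsum([0, *sizes])
        n = len(pairs)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            perm_indices = [
                perm[bounds[k]:bounds[k + 1]] for k in range(len(sizes))
            ]
            _, _, phi_p = _amova_phi(arr, perm_indices, len(labels))
            if phi_p >= phi:
                hits += 1
        p_value = hits / n_permutations

    denom = sigma_a + sigma_w
    pct_among = 100.0 * sigma_a / denom if denom != 0.0 else 0.0
    return AmovaResult(
        sigma_among=sigma_a,
        sigma_within=sigma_w,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        phi_st=phi,
        p_value=p_value,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST


def wc_theta(group_genotypes: Sequence[np.ndarray]) -> float:
    """Multi-allelic Weir–Cockerham θ over diploid genotype arrays.

    Each element of ``group_genotypes`` is an (n_i, 2) integer array of
    allele codes.  Per-allele variance components a, b, c are summed over
    alleles: θ = Σa / Σ(a+b+c).  Returns 0 (with a warning) for a
    monomorphic collection.
    """
    r = len(group_genotypes)
    if r < 2:
        raise ValueError("need at least two populations")
    n_i = np.array([g.shape[0] for g in group_genotypes], dtype=float)
    if (n_i < 2).any():
        raise ValueError("each population needs at least 2 individuals")
    n_alleles = int(max(int(g.max()) for g in group_genotypes)) + 1

    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)

    p = np.empty((r, n_alleles))
    h = np.empty((r, n_alleles))
    for k, g in enumerate(group_genotypes):
        counts = np.bincount(g.ravel(), minlength=n_alleles).astype(float)
        p[k] = counts / (2.0 * n_i[k])
        het_rows = g[:, 0] != g[:, 1]
        h[k] = (
            np.bincount(g[het_rows].ravel(), minlength=n_alleles).astype(float)
            / n_i[k]
        )

    w = n_i[:, None]
    p_bar = (w * p).sum(axis=0) / (r * n_bar)
    s2 = (w * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (w * h).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0

    denom = float((a + b + c).sum())
    if denom == 0.0:
        warnings.warn("monomorphic populations: θ defined as 0", stacklevel=2)
        return 0.0
    return float(a.sum() / denom)


def pairwise_fst(
    pairs_a: Sequence[Tuple[str, str]],
    pairs_b: Sequence[Tuple[str, str]],
    *,
    n_bootstrap: int = 3000,
    seed: int = 0,
) -> FstEstimate:
    """Weir–Cockerham θ between two groups with a bootstrap percentile CI.

    Bootstrap resamples *individuals* within each group; the CI lower
    bound is truncated at 0, while a negative point estimate is reported
    as computed.
    """
    arr, _labels = _encode_pairs(list(pairs_a) + list(pairs_b))
    ga = arr[: len(pairs_a)]
    gb = arr[len(pairs_a):]
    theta = wc_theta([ga, gb])

    ci_low = ci_high = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        na, nb = ga.shape[0], gb.shape[0]
        thetas = np.empty(n_bootstrap)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for bi in range(n_bootstrap):
                ia = rng.integers(0, na, na)
                ib = rng.integers(0, nb, nb)
                thetas[bi] = wc_theta([ga[ia], gb[ib]])
        ci_low = max(0.0, float(np.percentile(thetas, 2.5)))
        ci_high = float(np.percentile(thetas, 97.5))
    return FstEstimate(
        theta=theta, ci_low=ci_low, ci_high=ci_high, n_bootstrap=n_bootstrap
    )


# ---------------------------------------------------------------------------
# rank tests and FDR


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H with tie correction; χ² p-value on k−1 df."""
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0.0:
        return TestResult(0.0, float(len(samples) - 1), 1.0, "kruskal-wallis")
    stat, p = sps.kruskal(*samples)
    return TestResult(
        float(stat), float(len(samples) - 1), float(p), "kruskal-wallis"
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Mann–Whitney U (for the first sample), normal approximation with
    tie correction, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return TestResult(len(a) * len(b) / 2.0, None, 1.0, "mann-whitney")
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return TestResult(float(res.statistic), None, float(res.pvalue), "mann-whitney")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        return ps
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(ps, method="fdr_bh")[1]
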