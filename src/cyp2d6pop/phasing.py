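"""Haplotype-frequency estimation by expectation–maximization.

Unphased diploid genotypes over the 11-site panel are resolved into
haplotype pairs under Hardy–Weinberg random pairing: the classic
Excoffier–Slatkin gene-counting EM.  Each individual's genotype is
expanded into every compatible haplotype pair (missing sites are
marginalized, i.e. summed over both states), the E-step weighs each
resolution by ``2 f_i f_j`` (``f_i²`` when homozygous), and the M-step
re-estimates frequencies from expected haplotype counts.

Copy-number bookkeeping: individuals with one gene copy (CN = 1, i.e.
*5 heterozygotes) contribute a single chromosome whose haplotype is read
from their homozygous-appearing calls; CN = 0 individuals contribute
nothing.  Individuals with CN ≥ 3 are phased as ordinary diploids — the
extra copy shares a sequence with one of the two haplotypes and is
resolved downstream by the diplotyping step.

The likelihood is multimodal in principle, so ``em_phase`` runs several
restarts (random Dirichlet initializations plus one allele-frequency
product initialization) and keeps the best; with a fixed seed the result
is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .alleles import AlleleDefinitions, Haplotype, PANEL_SIZE

logger = logging.getLogger(__name__)

#: floor frequency used only while ranking resolutions of a record that is
#: incompatible with every positive-frequency haplotype
POSTERIOR_FLOOR = 1e-12

#: guard against combinatorial blow-up when expanding a single genotype
MAX_EXPANSIONS = 1 << 16

ANCESTRY_TOL = 1e-6


@dataclass
class GenotypeRecord:
    """One individual's unphased panel genotype plus cohort covariates.

    ``site_calls`` holds 11 unordered diploid state pairs; ``None`` inside
    a pair marks a missing call.  ``ancestry`` is the (Amerindian,
    African, European) genomic-ancestry triple.
    """

    individual_id: str
    site_calls: Tuple[Tuple[Optional[str], Optional[str]], ...]
    region: Optional[str] = None
    skin_color: Optional[str] = None
    ancestry: Optional[Tuple[float, float, float]] = None
    copy_number_raw: Optional[float] = None
    copy_number: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.site_calls) != PANEL_SIZE:
            raise ValueError(
                f"{self.individual_id}: expected {PANEL_SIZE} site calls, "
                f"got {len(self.site_calls)}"
            )
        if self.ancestry is not None:
            if len(self.ancestry) != 3:
                raise ValueError(f"{self.individual_id}: ancestry must have 3 parts")
            if any(not (0.0 <= a <= 1.0) for a in self.ancestry):
                raise ValueError(
                    f"{self.individual_id}: ancestry proportions outside [0, 1]"
                )
            if abs(sum(self.ancestry) - 1.0) > ANCESTRY_TOL:
                raise ValueError(
                    f"{self.individual_id}: ancestry proportions sum to "
                    f"{sum(self.ancestry):.8f}, not 1"
                )


@dataclass
class BestPair:
    """Most probable phase of one individual under the final frequencies."""

    haplotypes: Tuple[Haplotype, Optional[Haplotype]]
    posterior: float
    tied: bool = False


@dataclass
class PhasingResult:
    haplotype_frequencies: Dict[Haplotype, float]
    per_individual_best_pair: Dict[str, BestPair]
    log_likelihood_trace: List[float]
    n_iterations: int
    converged: bool
    excluded_ids: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genotype encoding and expansion


def _encode_genotype(record: GenotypeRecord, defs: AlleleDefinitions) -> List[int]:
    """Per-site genotype codes: 0 hom-ref, 1 het, 2 hom-var, -1 missing."""
    codes: List[int] = []
    for site, (a, b) in zip(defs.sites, record.site_calls):
        if a is None or b is None:
            codes.append(-1)
            continue
        total = 0
        for state in (a, b):
            if state == site.variant_state:
                total += 1
            elif state != site.reference_state:
                raise ValueError(
                    f"{record.individual_id}: state {state!r} not assayed at "
                    f"site {site.label}"
                )
        codes.append(total)
    return codes


def _expansion_size(codes: Sequence[int]) -> int:
    size = 1
    for c in codes:
        size *= 4 if c == -1 else (2 if c == 1 else 1)
    return size


def _expand_pairs(codes: Sequence[int]) -> Dict[Tuple[int, int], int]:
    """All ordered haplotype-pair resolutions of a diploid genotype.

    Haplotypes are bitmasks over the panel (bit set = variant state).
    Returns unordered pairs (i ≤ j) with their ordered multiplicity, so
    that the genotype likelihood is ``Σ mult · f_i · f_j``.
    """
    if _expansion_size(codes) > MAX_EXPANSIONS:
        raise ValueError("genotype has too many missing/het sites to expand")
    pairs: Dict[Tuple[int, int], int] = {(0, 0): 1}
    for s, c in enumerate(codes):
        bit = 1 << s
        if c == 0:
            options = [(0, 0)]
        elif c == 2:
            options = [(bit, bit)]
        elif c == 1:
            options = [(bit, 0), (0, bit)]
        else:  # missing: marginalize over all four ordered state pairs
            options = [(0, 0), (bit, 0), (0, bit), (bit, bit)]
        new: Dict[Tuple[int, int], int] = {}
        for (h1, h2), mult in pairs.items():
            for o1, o2 in options:
                key = (h1 | o1, h2 | o2)
                new[key] = new.get(key, 0) + mult
        pairs = new
    # canonicalize to unordered pairs
    out: Dict[Tuple[int, int], int] = {}
    for (h1, h2), mult in pairs.items():
        key = (h1, h2) if h1 <= h2 else (h2, h1)
        out[key] = out.get(key, 0) + mult
    return out


def _expand_haploid(codes: Sequence[int]) -> Dict[int, int]:
    """Compatible single haplotypes of a one-copy individual."""
    haps: Dict[int, int] = {0: 1}
    for s, c in enumerate(codes):
        bit = 1 << s
        if c == 1:
            raise ValueError(
                "heterozygous call in a single-copy individual is contradictory"
            )
        options = [0, bit] if c == -1 else ([bit] if c == 2 else [0])
        new: Dict[int, int] = {}
        for h, mult in haps.items():
            for o in options:
                new[h | o] = new.get(h | o, 0) + mult
        haps = new
    return haps


def _mask_to_haplotype(mask: int, defs: AlleleDefinitions) -> Haplotype:
    return tuple(
        site.variant_state if mask >> i & 1 else site.reference_state
        for i, site in enumerate(defs.sites)
    )


def _haplotype_to_mask(h: Haplotype, defs: AlleleDefinitions) -> int:
    mask = 0
    for i, (site, state) in enumerate(zip(defs.sites, h)):
        if state == site.variant_state:
            mask |= 1 << i
        elif state != site.reference_state:
            raise ValueError(f"state {state!r} not assayed at site {site.label}")
    return mask


# ---------------------------------------------------------------------------
# EM


@dataclass
class _FlatExpansions:
    """CSR-style flattening of all per-individual resolutions."""

    n_dip: int
    n_hap: int
    n_haps: int
    pair_i: np.ndarray  # haplotype index of slot 1, per pair row
    pair_j: np.ndarray
    pair_m: np.ndarray  # ordered multiplicity
    pair_ind: np.ndarray  # diploid-individual index per pair row
    hap_i: np.ndarray
    hap_m: np.ndarray
    hap_ind: np.ndarray  # haploid-individual index per row

    @property
    def total_chromosomes(self) -> int:
        return 2 * self.n_dip + self.n_hap


def _flatten(
    dip_pairs: List[List[Tuple[int, int, int]]],
    hap_singles: List[List[Tuple[int, int]]],
    n_haps: int,
) -> _FlatExpansions:
    pi, pj, pm, pind = [], [], [], []
    for ind, plist in enumerate(dip_pairs):
        for i, j, m in plist:
            pi.append(i)
            pj.append(j)
            pm.append(float(m))
            pind.append(ind)
    hi, hm, hind = [], [], []
    for ind, slist in enumerate(hap_singles):
        for i, m in slist:
            hi.append(i)
            hm.append(float(m))
            hind.append(ind)
    return _FlatExpansions(
        n_dip=len(dip_pairs),
        n_hap=len(hap_singles),
        n_haps=n_haps,
        pair_i=np.asarray(pi, dtype=np.intp),
        pair_j=np.asarray(pj, dtype=np.intp),
        pair_m=np.asarray(pm),
        pair_ind=np.asarray(pind, dtype=np.intp),
        hap_i=np.asarray(hi, dtype=np.intp),
        hap_m=np.asarray(hm),
        hap_ind=np.asarray(hind, dtype=np.intp),
    )


def _run_em(
    flat: _FlatExpansions,
    freqs0: np.ndarray,
    tol: float,
    max_iter: int,
) -> Tuple[np.ndarray, List[float], int, bool]:
    """Core EM loop; returns (freqs, log-likelihood trace, n_iter, converged)."""
    freqs = freqs0.copy()
    trace: List[float] = []
    converged = False
    it = 0
    tiny = np.finfo(float).tiny
    for it in range(1, max_iter + 1):
        counts = np.zeros(flat.n_haps)
        ll = 0.0
        if flat.n_dip:
            w = flat.pair_m * freqs[flat.pair_i] * freqs[flat.pair_j]
            tot = np.bincount(flat.pair_ind, weights=w, minlength=flat.n_dip)
            dead = tot <= 0.0
            if dead.any():
                # individual lost all mass numerically: uniform responsibility
                fix = dead[flat.pair_ind]
                w[fix] = flat.pair_m[fix]
                tot = np.bincount(flat.pair_ind, weights=w, minlength=flat.n_dip)
                ll = -np.inf
            ll += float(np.log(np.maximum(tot, tiny)).sum())
            resp = w / tot[flat.pair_ind]
            counts += np.bincount(flat.pair_i, weights=resp, minlength=flat.n_haps)
            counts += np.bincount(flat.pair_j, weights=resp, minlength=flat.n_haps)
        if flat.n_hap:
            w = flat.hap_m * freqs[flat.hap_i]
            tot = np.bincount(flat.hap_ind, weights=w, minlength=flat.n_hap)
            dead = tot <= 0.0
            if dead.any():
                fix = dead[flat.hap_ind]
                w[fix] = flat.hap_m[fix]
                tot = np.bincount(flat.hap_ind, weights=w, minlength=flat.n_hap)
                ll = -np.inf
            ll += float(np.log(np.maximum(tot, tiny)).sum())
            resp = w / tot[flat.hap_ind]
            counts += np.bincount(flat.hap_i, weights=resp, minlength=flat.n_haps)
        freqs = counts / flat.total_chromosomes
        trace.append(ll)
        if len(trace) >= 2 and np.isfinite(trace[-2]):
            if trace[-1] - trace[-2] < tol:
                converged = True
                break
    return freqs, trace, it, converged


def em_phase(
    cohort: Sequence[GenotypeRecord],
    defs: AlleleDefinitions,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 5,
    seed: int = 0,
) -> PhasingResult:
    """Maximum-likelihood haplotype frequencies and best per-individual phase.

    Runs ``n_restarts`` random initializations plus one allele-frequency
    product initialization and keeps the highest final log-likelihood.
    """
    if not cohort:
        raise ValueError("empty cohort")

    dip_expansions: List[Tuple[str, Dict[Tuple[int, int], int]]] = []
    hap_expansions: List[Tuple[str, Dict[int, int]]] = []
    excluded: List[str] = []
    for rec in cohort:
        codes = _encode_genotype(rec, defs)
        if rec.copy_number == 0:
            excluded.append(rec.individual_id)
            continue
        if all(c == -1 for c in codes):
            excluded.append(rec.individual_id)
            warnings.warn(
                f"{rec.individual_id}: all sites missing, excluded from phasing",
                stacklevel=2,
            )
            continue
        if rec.copy_number == 1:
            hap_expansions.append((rec.individual_id, _expand_haploid(codes)))
        else:
            dip_expansions.append((rec.individual_id, _expand_pairs(codes)))
    if not dip_expansions and not hap_expansions:
        raise ValueError("no phaseable individuals in cohort")

    # haplotype universe = union of all masks appearing in any expansion
    universe: Dict[int, int] = {}
    for _id, pairs in dip_expansions:
        for i, j in pairs:
            for m in (i, j):
                if m not in universe:
                    universe[m] = len(universe)
    for _id, haps in hap_expansions:
        for m in haps:
            if m not in universe:
                universe[m] = len(universe)
    masks_sorted = sorted(universe)
    index = {m: k for k, m in enumerate(masks_sorted)}
    n_haps = len(masks_sorted)

    dip_pairs = [
        [(index[i], index[j], mult) for (i, j), mult in pairs.items()]
        for _id, pairs in dip_expansions
    ]
    hap_singles = [
        [(index[m], mult) for m, mult in haps.items()]
        for _id, haps in hap_expansions
    ]

    # product initialization from per-site variant frequencies
    var_counts = np.zeros(PANEL_SIZE)
    chrom_counts = np.zeros(PANEL_SIZE)
    for rec in cohort:
        if rec.copy_number == 0:
            continue
        codes = _encode_genotype(rec, defs)
        ploidy = 1 if rec.copy_number == 1 else 2
        for s, c in enumerate(codes):
            if c == -1:
                continue
            var_counts[s] += c if ploidy == 2 else c / 2
            chrom_counts[s] += ploidy
    with np.errstate(invalid="ignore"):
        q = np.where(chrom_counts > 0, var_counts / np.maximum(chrom_counts, 1), 0.5)
    q = np.clip(q, 1e-6, 1 - 1e-6)
    product_init = np.empty(n_haps)
    for k, mask in enumerate(masks_sorted):
        p = 1.0
        for s in range(PANEL_SIZE):
            p *= q[s] if mask >> s & 1 else 1 - q[s]
        product_init[k] = p
    product_init /= product_init.sum()

    rng = np.random.default_rng(seed)
    inits = [product_init] + [
        rng.dirichlet(np.ones(n_haps)) for _ in range(n_restarts)
    ]

    flat = _flatten(dip_pairs, hap_singles, n_haps)
    best: Optional[Tuple[float, np.ndarray, List[float], int, bool]] = None
    for f0 in inits:
        freqs, trace, n_iter, conv = _run_em(flat, f0, tol, max_iter)
        final_ll = trace[-1]
        if best is None or final_ll > best[0]:
            best = (final_ll, freqs, trace, n_iter, conv)
    assert best is not None
    _ll, freqs, trace, n_iter, conv = best

    hap_freqs = {
        _mask_to_haplotype(m, defs): float(freqs[index[m]]) for m in masks_sorted
    }

    best_pairs: Dict[str, BestPair] = {}
    for (ind_id, pairs) in dip_expansions:
        ranked = _rank_pairs(pairs, index, freqs, defs)
        (pair, post, tied) = ranked
        best_pairs[ind_id] = BestPair(pair, post, tied)
    for (ind_id, haps) in hap_expansions:
        ws = {m: mult * max(freqs[index[m]], 0.0) for m, mult in haps.items()}
        tot = sum(ws.values())
        if tot <= 0.0:
            ws = {m: float(mult) for m, mult in haps.items()}
            tot = sum(ws.values())
        items = sorted(
            ws.items(), key=lambda kv: (-kv[1], _mask_to_haplotype(kv[0], defs))
        )
        top_m, top_w = items[0]
        tied = len(items) > 1 and abs(items[1][1] - top_w) <= 1e-12 * max(top_w, 1.0)
        best_pairs[ind_id] = BestPair(
            (_mask_to_haplotype(top_m, defs), None), top_w / tot, tied
        )

    return PhasingResult(
        haplotype_frequencies=hap_freqs,
        per_individual_best_pair=best_pairs,
        log_likelihood_trace=trace,
        n_iterations=n_iter,
        converged=conv,
        excluded_ids=excluded,
    )


def _rank_pairs(
    pairs: Mapping[Tuple[int, int], int],
    index: Mapping[int, int],
    freqs: np.ndarray,
    defs: AlleleDefinitions,
) -> Tuple[Tuple[Haplotype, Haplotype], float, bool]:
    """Best unordered resolution with Hardy–Weinberg weights, tie-flagged."""
    weights: Dict[Tuple[int, int], float] = {}
    for (i, j), mult in pairs.items():
        weights[(i, j)] = mult * freqs[index[i]] * freqs[index[j]]
    tot = sum(weights.values())
    if tot <= 0.0:
        weights = {
            (i, j): mult * max(freqs[index[i]], POSTERIOR_FLOOR)
            * max(freqs[index[j]], POSTERIOR_FLOOR)
            for (i, j), mult in pairs.items()
        }
        tot = sum(weights.values())
    decoded = {
        key: (_mask_to_haplotype(key[0], defs), _mask_to_haplotype(key[1], defs))
        for key in weights
    }
    items = sorted(weights.items(), key=lambda kv: (-kv[1], decoded[kv[0]]))
    top_key, top_w = items[0]
    tied = len(items) > 1 and abs(items[1][1] - top_w) <= 1e-12 * max(top_w, 1.0)
    return decoded[top_key], top_w / tot, tied


def phase_posterior(
    record: GenotypeRecord,
    freqs: Mapping[Haplotype, float],
    defs: AlleleDefinitions,
) -> List[Tuple[Tuple[Haplotype, Haplotype], float]]:
    """All compatible unordered resolutions of one record, ranked.

    Weights follow Hardy–Weinberg: ``2 f_i f_j`` for i ≠ j, ``f_i²``
    otherwise, normalized over the record's compatible pairs.  A record
    incompatible with every positive-frequency haplotype falls back to a
    floor frequency, i.e. effectively uniform weighting.
    """
    codes = _encode_genotype(record, defs)
    pairs = _expand_pairs(codes)
    mask_freq = {
        _haplotype_to_mask(h, defs): f for h, f in freqs.items()
    }
    weights: Dict[Tuple[int, int], float] = {}
    for (i, j), mult in pairs.items():
        weights[(i, j)] = mult * mask_freq.get(i, 0.0) * mask_freq.get(j, 0.0)
    tot = sum(weights.values())
    if tot <= 0.0:
        weights = {
            (i, j): mult
            * max(mask_freq.get(i, 0.0), POSTERIOR_FLOOR)
            * max(mask_freq.get(j, 0.0), POSTERIOR_FLOOR)
            for (i, j), mult in pairs.items()
        }
        tot = sum(weights.values())
    decoded = {
        key: (_mask_to_haplotype(key[0], defs), _mask_to_haplotype(key[1], defs))
        for key in weights
    }
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], decoded[kv[0]]))
    return [(decoded[key], w / tot) for key, w in ranked]
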