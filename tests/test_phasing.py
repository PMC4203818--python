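"""EM haplotype-frequency estimation and posterior phase ranking."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cyp2d6pop import em_phase, load_definition_table, phase_posterior
from cyp2d6pop.phasing import GenotypeRecord

from conftest import make_record
from oracles import grid_phase_oracle

# hypothesis @given cannot take pytest fixtures; use a module-level catalogue
_DEFS = load_definition_table()


def hap(defs, label):
    return defs.defs[label].defining_states


def test_all_homozygous_equals_gene_counting(defs):
    cohort = (
        [make_record(f"a{i}", "*1", "*1", defs) for i in range(6)]
        + [make_record(f"b{i}", "*2", "*2", defs) for i in range(3)]
        + [make_record(f"c{i}", "*4", "*4", defs) for i in range(1)]
    )
    res = em_phase(cohort, defs, seed=0)
    assert res.converged
    freqs = res.haplotype_frequencies
    assert freqs[hap(defs, "*1")] == pytest.approx(0.6, abs=1e-9)
    assert freqs[hap(defs, "*2")] == pytest.approx(0.3, abs=1e-9)
    assert freqs[hap(defs, "*4")] == pytest.approx(0.1, abs=1e-9)
    for best in res.per_individual_best_pair.values():
        assert best.posterior == pytest.approx(1.0, abs=1e-12)


def test_single_het_site_phases_uniquely(defs):
    # *1/*39 differ only at 4180: the single-het phase is unambiguous
    cohort = [make_record("x", "*1", "*39", defs)]
    res = em_phase(cohort, defs, seed=0)
    freqs = res.haplotype_frequencies
    assert freqs[hap(defs, "*1")] == pytest.approx(0.5, abs=1e-9)
    assert freqs[hap(defs, "*39")] == pytest.approx(0.5, abs=1e-9)
    best = res.per_individual_best_pair["x"]
    assert set(best.haplotypes) == {hap(defs, "*1"), hap(defs, "*39")}
    assert best.posterior == pytest.approx(1.0, abs=1e-12)


def _two_site_cohort(defs, genotype_counts):
    """Records varying only at panel sites 100 and 4180 (others hom-ref).

    ``genotype_counts``: {(dosage_100, dosage_4180): n individuals}.
    """
    cohort = []
    k = 0
    for (g1, g2), n in genotype_counts.items():
        for _ in range(n):
            calls = []
            for site in defs.sites:
                if site.label == "100":
                    dose = g1
                elif site.label == "4180":
                    dose = g2
                else:
                    dose = 0
                pair = {
                    0: (site.reference_state, site.reference_state),
                    1: (site.reference_state, site.variant_state),
                    2: (site.variant_state, site.variant_state),
                }[dose]
                calls.append(pair)
            cohort.append(
                GenotypeRecord(individual_id=f"i{k}", site_calls=tuple(calls))
            )
            k += 1
    return cohort


def test_em_matches_exhaustive_grid_oracle(defs):
    """Double-het resolution: EM equals the grid-searched MLE within 1e-4."""
    genotype_counts = {
        (1, 1): 7,  # double heterozygotes: ambiguous cis/trans
        (0, 0): 4,
        (0, 1): 4,
        (2, 1): 2,
        (1, 0): 2,
        (2, 2): 1,
    }
    cohort = _two_site_cohort(defs, genotype_counts)
    res = em_phase(cohort, defs, seed=0, n_restarts=5)
    oracle = grid_phase_oracle(genotype_counts)

    def freq_of(d1, d2):
        states = []
        for site in defs.sites:
            if site.label == "100":
                states.append(site.variant_state if d1 else site.reference_state)
            elif site.label == "4180":
                states.append(site.variant_state if d2 else site.reference_state)
            else:
                states.append(site.reference_state)
        return res.haplotype_frequencies.get(tuple(states), 0.0)

    em = np.array([freq_of(0, 0), freq_of(0, 1), freq_of(1, 0), freq_of(1, 1)])
    assert np.max(np.abs(em - oracle)) < 1e-4


def test_log_likelihood_never_decreases(defs):
    rng = np.random.default_rng(5)
    labels = ["*1", "*2", "*4", "*17", "*41"]
    cohort = [
        make_record(
            f"i{k}", labels[rng.integers(5)], labels[rng.integers(5)], defs
        )
        for k in range(40)
    ]
    res = em_phase(cohort, defs, seed=3)
    diffs = np.diff(res.log_likelihood_trace)
    assert (diffs >= -1e-9).all()


def test_frequency_recovery_on_synthetic_cohort(defs):
    """n=500 draws: estimates within 3 binomial SEs for common haplotypes."""
    rng = np.random.default_rng(11)
    labels = ["*1", "*2", "*4", "*17", "*41", "*10"]
    true = np.array([0.40, 0.25, 0.15, 0.10, 0.07, 0.03])
    n = 500
    cohort = [
        make_record(
            f"i{k}",
            labels[rng.choice(6, p=true)],
            labels[rng.choice(6, p=true)],
            defs,
        )
        for k in range(n)
    ]
    res = em_phase(cohort, defs, seed=0)
    for lab, p in zip(labels, true):
        if p < 0.02:
            continue
        est = res.haplotype_frequencies.get(hap(defs, lab), 0.0)
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(est - p) < 3 * se, (lab, est, p)


def test_restart_stability(defs):
    rng = np.random.default_rng(2)
    labels = ["*1", "*2", "*4", "*17", "*41", "*35"]
    cohort = [
        make_record(
            f"i{k}", labels[rng.integers(6)], labels[rng.integers(6)], defs
        )
        for k in range(60)
    ]
    lls = [
        em_phase(cohort, defs, seed=s, n_restarts=5).log_likelihood_trace[-1]
        for s in (0, 1)
    ]
    assert abs(lls[0] - lls[1]) < 1e-6


def test_haploid_and_deleted_individuals(defs):
    """CN=1 contributes one chromosome; CN=0 contributes none."""
    cohort = [
        make_record("d1", "*1", "*1", defs),
        make_record("d2", "*1", "*1", defs),
        make_record("h1", "*2", None, defs, copy_number=1),
        make_record("z1", None, None, defs, copy_number=0),
    ]
    res = em_phase(cohort, defs, seed=0)
    assert res.excluded_ids == ["z1"]
    # 5 chromosomes: 4 × *1, 1 × *2
    assert res.haplotype_frequencies[hap(defs, "*1")] == pytest.approx(0.8)
    assert res.haplotype_frequencies[hap(defs, "*2")] == pytest.approx(0.2)
    assert res.per_individual_best_pair["h1"].haplotypes[1] is None


def test_empty_cohort_rejected(defs):
    with pytest.raises(ValueError):
        em_phase([], defs)


# -- posterior ranking -------------------------------------------------------


def test_posterior_homozygote_is_certain(defs):
    rec = make_record("x", "*1", "*1", defs)
    ranked = phase_posterior(
        rec, {hap(defs, "*1"): 1.0}, defs
    )
    assert len(ranked) == 1
    assert ranked[0][1] == pytest.approx(1.0)


def test_posterior_follows_frequencies(defs):
    # *1/*2 genotype: het at -1584, 2850, 4180; the trans resolutions
    # involve haplotypes of frequency 0 and get probability 0
    rec = make_record("x", "*1", "*2", defs)
    freqs = {hap(defs, "*1"): 0.5, hap(defs, "*2"): 0.5}
    ranked = phase_posterior(rec, freqs, defs)
    assert ranked[0][0] == tuple(sorted([hap(defs, "*1"), hap(defs, "*2")]))
    assert ranked[0][1] == pytest.approx(1.0)


def test_posterior_symmetric_under_uniform_frequencies(defs):
    # double het at two sites -> both resolutions weigh 2 f_i f_j equally
    cohort = _two_site_cohort(defs, {(1, 1): 1})
    rec = cohort[0]
    # uniform over the 4 two-site haplotypes
    ranked_all = phase_posterior(
        rec,
        {h: 0.25 for h, _ in _uniform_two_site(defs)},
        defs,
    )
    assert len(ranked_all) == 2
    assert ranked_all[0][1] == pytest.approx(0.5)
    assert ranked_all[1][1] == pytest.approx(0.5)


def _uniform_two_site(defs):
    out = []
    for d1 in (0, 1):
        for d2 in (0, 1):
            states = []
            for site in defs.sites:
                if site.label == "100":
                    states.append(
                        site.variant_state if d1 else site.reference_state
                    )
                elif site.label == "4180":
                    states.append(
                        site.variant_state if d2 else site.reference_state
                    )
                else:
                    states.append(site.reference_state)
            out.append((tuple(states), 0.25))
    return out


def test_posterior_incompatible_falls_back_to_floor(defs):
    rec = make_record("x", "*4", "*17", defs)
    # frequencies assign no mass to anything compatible with this record
    ranked = phase_posterior(rec, {hap(defs, "*1"): 1.0}, defs)
    total = sum(p for _, p in ranked)
    assert total == pytest.approx(1.0)
    assert all(p > 0 for _, p in ranked)


@given(
    pair=st.tuples(
        st.sampled_from(["*1", "*2", "*4", "*17", "*41", "*10", "*35"]),
        st.sampled_from(["*1", "*2", "*4", "*17", "*41", "*10", "*35"]),
    ),
    weights=st.lists(
        st.floats(min_value=0.01, max_value=1.0), min_size=7, max_size=7
    ),
)
def test_posterior_is_a_distribution(pair, weights):
    """Ranked resolutions always form a normalized distribution."""
    defs = _DEFS
    labels = ["*1", "*2", "*4", "*17", "*41", "*10", "*35"]
    w = np.array(weights)
    freqs = {hap(defs, lab): float(x) for lab, x in zip(labels, w / w.sum())}
    rec = make_record("x", pair[0], pair[1], defs)
    ranked = phase_posterior(rec, freqs, defs)
    probs = np.array([p for _, p in ranked])
    assert probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert ((probs >= 0) & (probs <= 1 + 1e-12)).all()
    # sorted non-increasing
    assert (np.diff(probs) <= 1e-12).all()
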