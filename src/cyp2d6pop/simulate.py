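"""Synthetic admixed cohorts with known ground truth.

Each simulated individual belongs to a geographic region, draws a
(Amerindian, African, European) ancestry triple from the region's
Dirichlet, and fills two gene-copy slots: each slot picks an ancestral
origin from the ancestry triple and then a star allele from that
ancestry's haplotype-frequency profile.  Whole star alleles are drawn as
units, so linkage across the 11 panel sites is perfect — exactly the
star-allele model the analysis assumes.  Duplication events promote a
non-deleted slot to ×N with a configurable multiplier distribution; *5
draws reduce copy number.  The relative-quantification readout is
``true CN / 2`` plus normal noise, and genotype calls can be masked at a
configurable missingness rate.

The default profiles are invented numbers chosen only to reproduce the
qualitative continental contrasts (CYP2D6*4 enriched in Europeans,
*17/*29 in Africans, high *1/*2 in Amerindians) and an overall allele
mix, admixture gradient and ~8% duplication-carrier rate on the scale
reported for Brazil; they claim no literature accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .alleles import (
    AlleleDefinitions,
    DELETION_ALLELE,
    Haplotype,
    PANEL_SIZE,
    format_star_label,
    load_definition_table,
)
from .diplotyping import DiplotypeCall, MAX_COPY_NUMBER, assemble_diplotype
from .phenotyping import PhenotypeCall, predict_phenotype
from .phasing import GenotypeRecord

ANCESTRIES = ("Amerindian", "African", "European")
REGIONS = ("North", "Northeast", "Southeast", "South")


@dataclass
class AncestralProfile:
    """Star-allele haplotype frequencies of one ancestral population."""

    name: str
    haplotype_frequencies: Dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.haplotype_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"profile {self.name}: frequencies sum to {total}, not 1"
            )
        if any(f < 0 for f in self.haplotype_frequencies.values()):
            raise ValueError(f"profile {self.name}: negative frequency")


@dataclass
class SimConfig:
    """Study-design knobs of the generator."""

    region_sizes: Dict[str, int]
    region_dirichlet: Dict[str, Tuple[float, float, float]]
    duplication_prob: float = 0.042
    duplication_multipliers: Dict[int, float] = field(
        default_factory=lambda: {2: 0.80, 3: 0.15, 4: 0.04, 5: 0.01}
    )
    missing_rate: float = 0.0
    # RQ noise small relative to the 0.05 replicate SD assumed by the
    # caller, so that (as in a well-run assay) >99% of CN calls pass
    rq_sd: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.region_sizes.values()):
            raise ValueError("negative region size")
        if not 0.0 <= self.duplication_prob <= 1.0:
            raise ValueError("duplication_prob outside [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate outside [0, 1]")
        if abs(sum(self.duplication_multipliers.values()) - 1.0) > 1e-9:
            raise ValueError("duplication multiplier probabilities must sum to 1")


@dataclass
class TrueIndividual:
    """Hidden truth for one simulated individual."""

    individual_id: str
    region: str
    skin_color: str
    ancestry: Tuple[float, float, float]
    base_labels: Tuple[str, str]
    multipliers: Tuple[int, int]
    copy_number: int
    diplotype: DiplotypeCall
    phenotype: PhenotypeCall

    @property
    def slot_labels(self) -> Tuple[str, str]:
        return tuple(
            format_star_label(b, m) if b != DELETION_ALLELE else b
            for b, m in zip(self.base_labels, self.multipliers)
        )


def _allele_states(label: str, defs: AlleleDefinitions) -> Optional[Haplotype]:
    d = defs.defs.get(label)
    if d is None:
        raise ValueError(f"profile references unknown allele {label!r}")
    return d.defining_states


def _draw_color(
    ancestry: Tuple[float, float, float], rng: np.random.Generator
) -> str:
    """Self-reported color loosely correlated with genomic ancestry.

    Invented rule: category weights grow with the matching ancestry
    component, mimicking the loose ancestry–color association of census
    self-classification.
    """
    amer, afr, eur = ancestry
    w_white = max(eur - 0.40, 0.02)
    w_black = max(afr - 0.05, 0.02)
    w_brown = 0.18 + 0.5 * amer + 0.3 * min(afr, eur)
    weights = np.array([w_white, w_brown, w_black])
    weights /= weights.sum()
    return ["White", "Brown", "Black"][rng.choice(3, p=weights)]


def simulate_cohort(
    config: SimConfig,
    profiles: Mapping[str, AncestralProfile],
    defs: Optional[AlleleDefinitions] = None,
) -> Tuple[List[GenotypeRecord], List[TrueIndividual]]:
    """Generate genotype records plus the hidden truth behind them."""
    if defs is None:
        defs = load_definition_table()
    for name in ANCESTRIES:
        if name not in profiles:
            raise ValueError(f"missing ancestral profile {name!r}")
        for lab in profiles[name].haplotype_frequencies:
            _allele_states(lab, defs)  # raises on unknown labels

    rng = np.random.default_rng(config.seed)
    profile_labels = {
        name: list(profiles[name].haplotype_frequencies) for name in ANCESTRIES
    }
    profile_freqs = {
        name: np.array(list(profiles[name].haplotype_frequencies.values()))
        for name in ANCESTRIES
    }

    records: List[GenotypeRecord] = []
    truth: List[TrueIndividual] = []
    counter = 0
    for region in config.region_sizes:
        alpha = np.asarray(config.region_dirichlet[region], dtype=float)
        for _ in range(config.region_sizes[region]):
            counter += 1
            ind_id = f"{region[:2].upper()}{counter:05d}"
            ancestry = tuple(rng.dirichlet(alpha))

            bases: List[str] = []
            mults: List[int] = []
            while True:
                bases.clear()
                mults.clear()
                for _slot in range(2):
                    origin = ANCESTRIES[rng.choice(3, p=np.asarray(ancestry))]
                    lab = profile_labels[origin][
                        rng.choice(
                            len(profile_labels[origin]), p=profile_freqs[origin]
                        )
                    ]
                    mult = 1
                    if lab != DELETION_ALLELE and (
                        rng.random() < config.duplication_prob
                    ):
                        ks = list(config.duplication_multipliers)
                        mult = ks[
                            rng.choice(
                                len(ks),
                                p=np.array(
                                    list(config.duplication_multipliers.values())
                                ),
                            )
                        ]
                    bases.append(lab)
                    mults.append(mult)
                cn = sum(
                    0 if b == DELETION_ALLELE else m
                    for b, m in zip(bases, mults)
                )
                if cn <= MAX_COPY_NUMBER:
                    break  # redraw the (rare) >6-copy combinations

            # truth diplotype and phenotype (duplication assignment known)
            slot_labels = tuple(
                format_star_label(b, m) if b != DELETION_ALLELE else b
                for b, m in zip(bases, mults)
            )
            true_call = DiplotypeCall(
                individual_id=ind_id,
                allele_a=slot_labels[0],
                allele_b=slot_labels[1],
                total_copy_number=cn,
            )
            true_pheno = predict_phenotype(true_call, defs)

            # observable genotype: unordered diploid calls per site
            state_vectors = [
                _allele_states(b, defs)
                for b in bases
                if b != DELETION_ALLELE
            ]
            site_calls: List[Tuple[Optional[str], Optional[str]]] = []
            for s in range(PANEL_SIZE):
                if not state_vectors:
                    site_calls.append((None, None))
                elif len(state_vectors) == 1:
                    # hemizygous: assay reports a homozygous-appearing call
                    st = state_vectors[0][s]
                    site_calls.append((st, st))
                else:
                    site_calls.append(
                        (state_vectors[0][s], state_vectors[1][s])
                    )
            if config.missing_rate > 0 and state_vectors:
                for s in range(PANEL_SIZE):
                    if rng.random() < config.missing_rate:
                        site_calls[s] = (None, None)

            rq = cn / 2.0 + (
                rng.normal(0.0, config.rq_sd) if config.rq_sd > 0 else 0.0
            )
            rq = max(rq, 0.01)  # the assay never reports non-positive RQ

            color = _draw_color(ancestry, rng)
            records.append(
                GenotypeRecord(
                    individual_id=ind_id,
                    site_calls=tuple(site_calls),
                    region=region,
                    skin_color=color,
                    ancestry=ancestry,
                    copy_number_raw=rq,
                    copy_number=None,
                )
            )
            truth.append(
                TrueIndividual(
                    individual_id=ind_id,
                    region=region,
                    skin_color=color,
                    ancestry=ancestry,
                    base_labels=tuple(bases),
                    multipliers=tuple(mults),
                    copy_number=cn,
                    diplotype=true_call,
                    phenotype=true_pheno,
                )
            )
    return records, truth


# ---------------------------------------------------------------------------
# the default Brazilian-like scenario


def default_profiles() -> Dict[str, AncestralProfile]:
    """Invented ancestral haplotype-frequency profiles (see module docs)."""
    return {
        "European": AncestralProfile(
            "European",
            {
                "*1": 0.39, "*2": 0.26, "*3": 0.012, "*4": 0.15, "*5": 0.035,
                "*9": 0.013, "*10": 0.015, "*17": 0.002, "*29": 0.002,
                "*34": 0.001, "*35": 0.045, "*39": 0.005, "*41": 0.07,
            },
        ),
        "African": AncestralProfile(
            "African",
            {
                "*1": 0.31, "*2": 0.20, "*3": 0.002, "*4": 0.03, "*5": 0.065,
                "*9": 0.006, "*10": 0.035, "*17": 0.20, "*29": 0.09,
                "*34": 0.002, "*35": 0.01, "*39": 0.01, "*41": 0.04,
            },
        ),
        "Amerindian": AncestralProfile(
            "Amerindian",
            {
                "*1": 0.56, "*2": 0.28, "*4": 0.04, "*5": 0.02, "*10": 0.01,
                "*17": 0.01, "*29": 0.005, "*35": 0.02, "*39": 0.015,
                "*41": 0.04,
            },
        ),
    }


def brazil_like_preset(
    seed: int = 0,
) -> Tuple[SimConfig, Dict[str, AncestralProfile]]:
    """The documented default scenario: 4 regions × 255 individuals.

    Region Dirichlet concentrations follow the qualitative admixture
    gradient (Amerindian share highest in the North, African in the
    Northeast, European in the South); duplication and noise settings
    give ~8% duplication carriers and near-error-free copy-number calls.
    """
    config = SimConfig(
        region_sizes={r: 255 for r in REGIONS},
        region_dirichlet={
            # (Amerindian, African, European)
            "North": (1.8, 1.3, 2.9),
            "Northeast": (0.8, 2.2, 3.0),
            "Southeast": (0.7, 1.6, 3.7),
            "South": (0.5, 0.9, 4.6),
        },
        duplication_prob=0.042,
        missing_rate=0.0,
        # small relative to the 0.05 replicate SD assumed by the caller, so
        # that (as in a well-run assay) >99% of copy-number calls pass
        rq_sd=0.015,
        seed=seed,
    )
    return config, default_profiles()
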