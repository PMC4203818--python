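"""End-to-end cohort analysis: genotypes → diplotypes → statistics bundle.

``call_diplotypes`` runs copy-number calling, EM phasing and diplotype
assembly; ``run_pipeline`` adds phenotyping and the statistical battery
(frequency tables, activity classes, phenotype tables, contingency
tests, AMOVA, pairwise F_ST, ancestry–phenotype rank tests) and can
write everything as provenance-stamped TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .alleles import AlleleDefinitions, load_definition_table, parse_star_label
from .diplotyping import DiplotypeCall, assemble_diplotype, call_copy_number
from .phasing import GenotypeRecord, PhasingResult, em_phase
from .phenotyping import (
    Phenotype,
    PhenotypeCall,
    phenotype_table,
    predict_phenotype,
)
from .popstats import (
    AmovaResult,
    FstEstimate,
    TestResult,
    activity_class_table,
    allele_frequencies,
    amova,
    bh_fdr,
    chi2_independence,
    duplication_carrier_table,
    g_test_independence,
    kruskal_wallis,
    mann_whitney,
    pairwise_fst,
)

logger = logging.getLogger(__name__)

ANCESTRY_NAMES = ("Amerindian", "African", "European")


@dataclass
class PipelineConfig:
    seed: int = 0
    replicate_sd: float = 0.05
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    em_restarts: int = 5
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    pool_threshold: int = 5
    nd_dominant_partner: bool = False

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    allele_freq_by_region: pd.DataFrame
    allele_freq_by_color: pd.DataFrame
    carrier_by_region: pd.DataFrame
    activity_by_region: pd.DataFrame
    phenotype_by_region: pd.DataFrame
    phenotype_by_color: pd.DataFrame
    phenotype_by_region_color: pd.DataFrame
    amova_results: pd.DataFrame
    fst_pairwise: pd.DataFrame
    association_tests: pd.DataFrame
    ancestry_by_phenotype: pd.DataFrame
    diplotypes: pd.DataFrame
    provenance: Dict[str, str]
    allele_label_counts: Dict[str, int] = field(default_factory=dict)


def call_diplotypes(
    records: Sequence[GenotypeRecord],
    defs: Optional[AlleleDefinitions] = None,
    config: Optional[PipelineConfig] = None,
) -> Tuple[List[DiplotypeCall], PhasingResult]:
    """Copy-number calling + EM phasing + diplotype assembly."""
    defs = defs or load_definition_table()
    config = config or PipelineConfig()

    staged: List[GenotypeRecord] = []
    for rec in records:
        cn = rec.copy_number
        if cn is None and rec.copy_number_raw is not None:
            cnc = call_copy_number(rec.copy_number_raw, config.replicate_sd)
            cn = cnc.cn_integer if cnc.pass_flag else None
        staged.append(dataclasses.replace(rec, copy_number=cn))

    phasing = em_phase(
        staged,
        defs,
        tol=config.em_tol,
        max_iter=config.em_max_iter,
        n_restarts=config.em_restarts,
        seed=config.seed,
    )

    calls: List[DiplotypeCall] = []
    for rec in staged:
        if rec.copy_number is None:
            calls.append(
                DiplotypeCall.make_blocked(
                    rec.individual_id, "missing or failed copy-number call"
                )
            )
            continue
        if rec.copy_number == 0:
            calls.append(
                assemble_diplotype(
                    ("", None), 0, defs, individual_id=rec.individual_id
                )
            )
            continue
        best = phasing.per_individual_best_pair.get(rec.individual_id)
        if best is None:
            calls.append(
                DiplotypeCall.make_blocked(rec.individual_id, "unphaseable")
            )
            continue
        h1, h2 = best.haplotypes
        lab1 = defs.match_haplotype(h1)
        lab2 = defs.match_haplotype(h2) if h2 is not None else None
        calls.append(
            assemble_diplotype(
                (lab1, lab2), rec.copy_number, defs,
                individual_id=rec.individual_id,
            )
        )
    return calls, phasing


def _label_maps(
    records: Sequence[GenotypeRecord],
) -> Tuple[Dict[str, str], Dict[str, str], Dict[str, str]]:
    region = {r.individual_id: r.region for r in records if r.region}
    color = {r.individual_id: r.skin_color for r in records if r.skin_color}
    both = {
        r.individual_id: f"{r.region}/{r.skin_color}"
        for r in records
        if r.region and r.skin_color
    }
    return region, color, both


def _slot_pairs(
    calls: Sequence[DiplotypeCall], strata: Dict[str, str]
) -> Tuple[List[Tuple[str, str]], List[str]]:
    pairs, groups = [], []
    for c in calls:
        if c.blocked:
            continue
        g = strata.get(c.individual_id)
        if g is None:
            continue
        pairs.append(c.slots)
        groups.append(g)
    return pairs, groups


def _pool_rare(counts: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Pool alleles with total count below the threshold into 'rare'."""
    totals = counts.sum(axis=1)
    keep = counts.loc[totals >= threshold]
    rare = counts.loc[totals < threshold]
    if len(rare):
        keep = pd.concat([keep, rare.sum(axis=0).to_frame("rare").T])
    return keep


def run_pipeline(
    records: Sequence[GenotypeRecord],
    config: Optional[PipelineConfig] = None,
    defs: Optional[AlleleDefinitions] = None,
    out_dir: Union[str, Path, None] = None,
) -> ReportBundle:
    """Run every analysis stage and (optionally) write the report bundle."""
    config = config or PipelineConfig()
    defs = defs or load_definition_table()

    logger.info("pipeline start: %d individuals, seed=%d", len(records), config.seed)
    calls, _phasing = call_diplotypes(records, defs, config)
    phenos = [
        predict_phenotype(c, defs, nd_dominant_partner=config.nd_dominant_partner)
        for c in calls
    ]

    region, color, both = _label_maps(records)

    freq_region = allele_frequencies(calls, region)
    freq_color = allele_frequencies(calls, color)
    carriers = duplication_carrier_table(calls, region)
    activity = activity_class_table(calls, defs, region)

    pheno_region = phenotype_table(phenos, region)
    pheno_color = phenotype_table(phenos, color)
    pheno_rc = phenotype_table(phenos, both)

    # observed-label bookkeeping (both counting conventions)
    observed = sorted(freq_region.counts.index)
    n_dup = sum(1 for lab in observed if "x" in lab)
    label_counts = {
        "distinct_labels": len(observed),
        "base_labels": len(observed) - n_dup - ("Others" in observed),
        "duplication_labels": n_dup,
    }

    # contingency tests
    tests: List[Dict[str, object]] = []

    def add_test(name: str, res: TestResult) -> None:
        tests.append(
            {
                "test": name,
                "method": res.method,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
        )

    def pheno_counts(strata: Dict[str, str]) -> pd.DataFrame:
        rows = [
            (strata[p.individual_id], p.phenotype.value)
            for p in phenos
            if p.individual_id in strata
        ]
        df = pd.DataFrame(rows, columns=["stratum", "phenotype"])
        counts = df.pivot_table(
            index="phenotype", columns="stratum", aggfunc="size", fill_value=0
        )
        return counts.loc[counts.sum(axis=1) > 0]

    region_cols = [c for c in freq_region.counts.columns if c != "Total"]
    if len(region_cols) >= 2:
        pooled = _pool_rare(
            freq_region.counts[region_cols], config.pool_threshold
        )
        add_test("allele_by_region_chi2", chi2_independence(pooled.T.values))
        act_cols = [c for c in activity.counts.columns if c != "Total"]
        add_test(
            "activity_by_region_chi2",
            chi2_independence(activity.counts[act_cols].T.values),
        )
        add_test(
            "phenotype_by_region_gtest",
            g_test_independence(pheno_counts(region).T.values),
        )
    color_cols = [c for c in freq_color.counts.columns if c != "Total"]
    if len(color_cols) >= 2:
        add_test(
            "phenotype_by_color_gtest",
            g_test_independence(pheno_counts(color).T.values),
        )

    # AMOVA by region and by color
    amova_rows = []
    for name, strata in (("region", region), ("color", color)):
        pairs, groups = _slot_pairs(calls, strata)
        if len(set(groups)) < 2:
            continue
        res: AmovaResult = amova(
            pairs, groups, n_permutations=config.n_permutations, seed=config.seed
        )
        amova_rows.append(
            {
                "stratification": name,
                "pct_among": res.pct_among,
                "pct_within": res.pct_within,
                "phi_st": res.phi_st,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
        )
    amova_df = pd.DataFrame(amova_rows)

    # pairwise F_ST
    fst_rows = []
    for name, strata in (("region", region), ("color", color)):
        pairs, groups = _slot_pairs(calls, strata)
        garr = np.asarray(groups)
        for ga, gb in itertools.combinations(sorted(set(groups)), 2):
            pa = [p for p, g in zip(pairs, garr) if g == ga]
            pb = [p for p, g in zip(pairs, garr) if g == gb]
            est: FstEstimate = pairwise_fst(
                pa, pb, n_bootstrap=config.n_bootstrap, seed=config.seed
            )
            fst_rows.append(
                {
                    "stratification": name,
                    "group_a": ga,
                    "group_b": gb,
                    "theta": est.theta,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_bootstrap": est.n_bootstrap,
                }
            )
    fst_df = pd.DataFrame(fst_rows)

    # ancestry vs phenotype: Kruskal–Wallis + pairwise Mann–Whitney + BH
    anc_by_id = {
        r.individual_id: r.ancestry for r in records if r.ancestry is not None
    }
    pheno_by_id = {p.individual_id: p.phenotype for p in phenos}
    anc_rows = []
    for ai, aname in enumerate(ANCESTRY_NAMES):
        values: Dict[str, List[float]] = {}
        for ind, anc in anc_by_id.items():
            ph = pheno_by_id.get(ind)
            if ph is None or ph is Phenotype.ND:
                continue
            values.setdefault(ph.value, []).append(anc[ai])
        if len(values) < 2:
            continue
        kw = kruskal_wallis(values)
        add_test(f"{aname.lower()}_ancestry_by_phenotype_kw", kw)
        classes = sorted(values)
        mw_pairs = list(itertools.combinations(classes, 2))
        raw_ps = []
        for ca, cb in mw_pairs:
            mw = mann_whitney(values[ca], values[cb])
            raw_ps.append(mw.p_value)
        adj = bh_fdr(raw_ps) if raw_ps else []
        for (ca, cb), raw, a_p in zip(mw_pairs, raw_ps, adj):
            anc_rows.append(
                {
                    "ancestry": aname,
                    "comparison": f"{ca} vs {cb}",
                    "mean_a": float(np.mean(values[ca])),
                    "mean_b": float(np.mean(values[cb])),
                    "p_raw": raw,
                    "p_fdr": a_p,
                }
            )
    ancestry_df = pd.DataFrame(anc_rows)

    tests_df = pd.DataFrame(tests)
    diplo_df = pd.DataFrame(
        {
            "id": [c.individual_id for c in calls],
            "diplotype": [
                "blocked" if c.blocked else f"{c.allele_a}/{c.allele_b}"
                for c in calls
            ],
            "copy_number": [c.total_copy_number for c in calls],
            "ambiguous_duplication": [c.duplication_ambiguous for c in calls],
            "phenotype": [p.phenotype.value for p in phenos],
            "active_copies": [p.active_copies for p in phenos],
        }
    )

    provenance = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": str(config.seed),
        "n_individuals": str(len(records)),
    }

    bundle = ReportBundle(
        allele_freq_by_region=freq_region.pct.round(6),
        allele_freq_by_color=freq_color.pct.round(6),
        carrier_by_region=carriers,
        activity_by_region=activity.pct.round(6),
        phenotype_by_region=pheno_region.round(6),
        phenotype_by_color=pheno_color.round(6),
        phenotype_by_region_color=pheno_rc.round(6),
        amova_results=amova_df,
        fst_pairwise=fst_df,
        association_tests=tests_df,
        ancestry_by_phenotype=ancestry_df,
        diplotypes=diplo_df,
        provenance=provenance,
        allele_label_counts=label_counts,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


_BUNDLE_FILES = {
    "allele_freq_by_region": "allele_frequencies_by_region.tsv",
    "allele_freq_by_color": "allele_frequencies_by_color.tsv",
    "carrier_by_region": "duplication_carriers_by_region.tsv",
    "activity_by_region": "activity_classes_by_region.tsv",
    "phenotype_by_region": "phenotypes_by_region.tsv",
    "phenotype_by_color": "phenotypes_by_color.tsv",
    "phenotype_by_region_color": "phenotypes_by_region_color.tsv",
    "amova_results": "amova.tsv",
    "fst_pairwise": "fst_pairwise.tsv",
    "association_tests": "association_tests.tsv",
    "ancestry_by_phenotype": "ancestry_by_phenotype.tsv",
    "diplotypes": "diplotypes.tsv",
}


def write_bundle(bundle: ReportBundle, out_dir: Union[str, Path]) -> None:
    """Write every table as TSV with a provenance comment header."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = "".join(
        f"# {k}: {v}\n" for k, v in sorted(bundle.provenance.items())
    )
    for attr, fname in _BUNDLE_FILES.items():
        df: pd.DataFrame = getattr(bundle, attr)
        with (out / fname).open("w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=attr not in ("diplotypes",))
    log_lines = [f"{k}: {v}" for k, v in sorted(bundle.provenance.items())]
    log_lines += [
        f"allele labels observed ({k}): {v}"
        for k, v in bundle.allele_label_counts.items()
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
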