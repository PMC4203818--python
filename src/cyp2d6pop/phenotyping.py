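"""Predicted metabolizer phenotype from a star-allele diplotype.

Classification assumes dominance of the most efficient allele:

* UM (ultrarapid): at least three active gene copies;
* EM (extensive): one or two active alleles;
* IM (intermediate): two reduced-activity alleles, or one reduced and
  one inactive allele;
* PM (poor): two inactive alleles;
* ND (not determined): any slot is an unassignable "Others" haplotype or
  carries an allele of undetermined activity, or the individual's
  duplication could not be assigned to an allele, or the copy-number
  call failed.

Whether a single ND-activity allele should block classification when the
partner allele is normal is not settled; the default propagates ND, and
``nd_dominant_partner=True`` lets the normal partner dominate instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Mapping, Sequence

import pandas as pd

from .alleles import ActivityClass, AlleleDefinitions, parse_star_label
from .diplotyping import DiplotypeCall


class Phenotype(str, Enum):
    PM = "PM"
    IM = "IM"
    EM = "EM"
    UM = "UM"
    ND = "ND"


#: canonical row order for phenotype tables
PHENOTYPE_ORDER = (
    Phenotype.PM, Phenotype.IM, Phenotype.EM, Phenotype.UM, Phenotype.ND
)


@dataclass(frozen=True)
class PhenotypeCall:
    individual_id: str
    phenotype: Phenotype
    active_copies: int


def predict_phenotype(
    d: DiplotypeCall,
    defs: AlleleDefinitions,
    *,
    nd_dominant_partner: bool = False,
) -> PhenotypeCall:
    """Apply the dominance rules to one diplotype call."""
    if d.blocked:
        return PhenotypeCall(d.individual_id, Phenotype.ND, 0)
    if d.duplication_ambiguous:
        return PhenotypeCall(d.individual_id, Phenotype.ND, 0)

    activities = [defs.classify_activity(slot) for slot in d.slots]
    if ActivityClass.ND in activities:
        if not (
            nd_dominant_partner
            and any(a in (ActivityClass.NORMAL, ActivityClass.HIGH)
                    for a in activities)
        ):
            return PhenotypeCall(d.individual_id, Phenotype.ND, 0)

    active = 0
    for slot, act in zip(d.slots, activities):
        if act in (ActivityClass.NORMAL, ActivityClass.HIGH):
            base, mult = parse_star_label(slot)
            # a ×N slot of a normal-function base carries N active copies
            if defs.classify_activity(base) is ActivityClass.NORMAL:
                active += mult
    if active >= 3:
        return PhenotypeCall(d.individual_id, Phenotype.UM, active)
    if active >= 1:
        return PhenotypeCall(d.individual_id, Phenotype.EM, active)
    if all(a is ActivityClass.NONE for a in activities):
        return PhenotypeCall(d.individual_id, Phenotype.PM, 0)
    return PhenotypeCall(d.individual_id, Phenotype.IM, 0)


def phenotype_table(
    phenotypes: Sequence[PhenotypeCall],
    strata: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Percentage table of phenotype classes per stratum, with an N row.

    ``strata`` maps individual id → stratum label; with ``None`` a single
    "Total" column is produced.  Empty strata are dropped with a warning.
    """
    rows: Dict[str, Dict[str, int]] = {}
    for call in phenotypes:
        label = "Total" if strata is None else strata.get(call.individual_id)
        if label is None:
            warnings.warn(
                f"{call.individual_id}: no stratum label, omitted", stacklevel=2
            )
            continue
        rows.setdefault(label, {})
        rows[label][call.phenotype.value] = (
            rows[label].get(call.phenotype.value, 0) + 1
        )
    if not rows:
        raise ValueError("no individuals with stratum labels")

    columns = sorted(rows)
    data = {}
    for col in columns:
        n = sum(rows[col].values())
        if n == 0:
            warnings.warn(f"stratum {col!r} is empty, omitted", stacklevel=2)
            continue
        pct = [100.0 * rows[col].get(p.value, 0) / n for p in PHENOTYPE_ORDER]
        data[col] = pct + [float(n)]
    index = [p.value for p in PHENOTYPE_ORDER] + ["N"]
    return pd.DataFrame(data, index=index)
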