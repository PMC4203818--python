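import warnings
from types import SimpleNamespace
from typing import Optional, Tuple

import pytest
from hypothesis import HealthCheck, settings

from cyp2d6pop import (
    GenotypeRecord,
    brazil_like_preset,
    call_diplotypes,
    load_definition_table,
    predict_phenotype,
    simulate_cohort,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def defs():
    return load_definition_table()


def make_record(
    ind_id: str,
    allele_a: Optional[str],
    allele_b: Optional[str],
    defs,
    *,
    copy_number: Optional[int] = 2,
    region: Optional[str] = None,
    color: Optional[str] = None,
    ancestry: Optional[Tuple[float, float, float]] = None,
) -> GenotypeRecord:
    """Unphased genotype record of a known allele pair (or single copy)."""
    vecs = [
        defs.defs[a].defining_states
        for a in (allele_a, allele_b)
        if a is not None and a != "*5"
    ]
    calls = []
    for s in range(len(defs.sites)):
        if not vecs:
            calls.append((None, None))
        elif len(vecs) == 1:
            calls.append((vecs[0][s], vecs[0][s]))
        else:
            calls.append((vecs[0][s], vecs[1][s]))
    return GenotypeRecord(
        individual_id=ind_id,
        site_calls=tuple(calls),
        region=region,
        skin_color=color,
        ancestry=ancestry,
        copy_number=copy_number,
    )


@pytest.fixture(scope="session")
def preset_run(defs):
    """One full pipeline pass over the default Brazilian-like cohort."""
    config, profiles = brazil_like_preset(seed=1)
    records, truth = simulate_cohort(config, profiles, defs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        calls, phasing = call_diplotypes(records, defs)
    phenos = [predict_phenotype(c, defs) for c in calls]
    return SimpleNamespace(
        config=config,
        profiles=profiles,
        records=records,
        truth=truth,
        calls=calls,
        phasing=phasing,
        phenos=phenos,
    )
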