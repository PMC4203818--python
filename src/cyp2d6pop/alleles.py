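"""CYP2D6 variant panel and star-allele definitions.

The package works with an 11-site panel of CYP2D6 polymorphisms
(gene-relative positions −1584 … 4180).  A *star allele* is a named
haplotype over this panel; the catalogue shipped with the package covers
the alleles detectable by the panel: 13 base alleles (12 sequence-defined
plus the whole-gene deletion *5, which carries no sequence) and their
observed duplications (*1x2, *1x3, *2x2, *2x5, *4x2, *17x2, *35x2).

Haplotype→allele assignment is by *perfect match only*: a fully observed
haplotype either equals a base definition at all 11 sites or is pooled
into the ``"Others"`` bin.  *5 is never sequence-matched — it is derived
from the copy-number assay downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence, Tuple, Union

#: Gene-relative positions of the panel, in fixed order.
PANEL_LABELS: Tuple[str, ...] = (
    "-1584", "31", "100", "1023", "1846",
    "2549", "2615", "2850", "2988", "3183", "4180",
)
PANEL_SIZE = len(PANEL_LABELS)

VALID_STATES = frozenset({"A", "C", "G", "T", "del"})

#: Label for haplotypes that perfectly match no catalogued allele.
OTHERS = "Others"
#: The whole-gene deletion allele (copy-number derived, no sequence).
DELETION_ALLELE = "*5"
#: ASCII multiplication sign used in duplication labels, e.g. "*1x2".
MULT_SIGN = "x"

#: A haplotype is an 11-tuple of states; ``None`` marks a missing state.
Haplotype = Tuple[Optional[str], ...]


class ActivityClass(str, Enum):
    """Predicted enzyme activity of a star allele."""

    NONE = "none"
    REDUCED = "reduced"
    NORMAL = "normal"
    HIGH = "high"
    ND = "ND"


_ACTIVITY_WORDS = {
    "None": ActivityClass.NONE,
    "Decr": ActivityClass.REDUCED,
    "Normal": ActivityClass.NORMAL,
    "Incr": ActivityClass.HIGH,
    "ND": ActivityClass.ND,
}


class DefinitionTableError(ValueError):
    """Raised when an allele-definition table fails to parse or validate."""


@dataclass(frozen=True)
class VariantSite:
    """One panel position with its two assayed states."""

    label: str
    reference_state: str
    variant_state: str
    panel_index: int

    def __post_init__(self) -> None:
        if self.reference_state == self.variant_state:
            raise DefinitionTableError(
                f"site {self.label}: reference and variant states are identical"
            )


@dataclass(frozen=True)
class StarAlleleDef:
    """A named star allele: defining states, copy multiplier and activity.

    ``defining_states`` is ``None`` only for the whole-gene deletion *5.
    """

    name: str
    base_allele: str
    copy_multiplier: int
    defining_states: Optional[Haplotype]
    activity: ActivityClass
    whole_gene_deletion: bool = False


def parse_star_label(name: str) -> Tuple[str, int]:
    """Split a star label into (base allele, copy multiplier).

    "*1" -> ("*1", 1); "*1x2" -> ("*1", 2).
    """
    if MULT_SIGN in name:
        base, _, mult = name.rpartition(MULT_SIGN)
        try:
            k = int(mult)
        except ValueError as exc:
            raise ValueError(f"malformed star label {name!r}") from exc
        if not base.startswith("*") or k < 2:
            raise ValueError(f"malformed star label {name!r}")
        return base, k
    if not name.startswith("*"):
        raise ValueError(f"malformed star label {name!r}")
    return name, 1


def format_star_label(base: str, multiplier: int) -> str:
    return base if multiplier == 1 else f"{base}{MULT_SIGN}{multiplier}"


def duplication_activity(base_activity: ActivityClass) -> ActivityClass:
    """Activity of an ``×N`` (N ≥ 2) allele from its base allele's activity.

    Duplicating a normal-function allele increases activity; extra copies
    of a no-function allele remain inactive; duplications of reduced or
    undetermined alleles have undetermined activity.
    """
    if base_activity is ActivityClass.NORMAL:
        return ActivityClass.HIGH
    if base_activity is ActivityClass.NONE:
        return ActivityClass.NONE
    return ActivityClass.ND


class AlleleDefinitions:
    """The panel of variant sites plus the star-allele catalogue."""

    def __init__(self, sites: Sequence[VariantSite], defs: Sequence[StarAlleleDef]):
        if len(sites) != PANEL_SIZE:
            raise DefinitionTableError(
                f"expected {PANEL_SIZE} sites, got {len(sites)}"
            )
        if tuple(s.label for s in sites) != PANEL_LABELS:
            raise DefinitionTableError("site labels or order differ from the panel")
        self.sites: Tuple[VariantSite, ...] = tuple(sites)
        self.defs: dict[str, StarAlleleDef] = {}
        for d in defs:
            if d.name in self.defs:
                raise DefinitionTableError(f"duplicate allele name {d.name}")
            self.defs[d.name] = d
        self._validate()
        # fast lookup for perfect matching (base, sequence-defined alleles)
        self._by_states = {
            d.defining_states: d.name for d in self.base_definitions()
            if d.defining_states is not None
        }

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        seen_states: dict[Haplotype, str] = {}
        for d in self.defs.values():
            if d.defining_states is None:
                if not d.whole_gene_deletion:
                    raise DefinitionTableError(
                        f"{d.name}: only the whole-gene deletion may lack states"
                    )
                continue
            if len(d.defining_states) != PANEL_SIZE:
                raise DefinitionTableError(f"{d.name}: wrong state-vector length")
            for site, state in zip(self.sites, d.defining_states):
                if state not in (site.reference_state, site.variant_state):
                    raise DefinitionTableError(
                        f"{d.name}: state {state!r} not assayed at site {site.label}"
                    )
            if d.copy_multiplier == 1:
                prev = seen_states.get(d.defining_states)
                if prev is not None:
                    raise DefinitionTableError(
                        f"{d.name} and {prev} share identical defining states"
                    )
                seen_states[d.defining_states] = d.name
        for d in self.defs.values():
            if d.copy_multiplier > 1 and d.base_allele not in self.defs:
                raise DefinitionTableError(
                    f"{d.name}: base allele {d.base_allele} not defined"
                )

    # -- queries --------------------------------------------------------------

    def base_definitions(self) -> list[StarAlleleDef]:
        """The non-duplicated allele definitions (copy multiplier 1)."""
        return [d for d in self.defs.values() if d.copy_multiplier == 1]

    def sequence_defined_bases(self) -> list[StarAlleleDef]:
        """Base definitions that carry a state vector (excludes *5)."""
        return [d for d in self.base_definitions() if d.defining_states is not None]

    def match_haplotype(self, haplotype: Haplotype) -> str:
        """Assign a fully observed haplotype to a star allele.

        Only perfect matches at all 11 sites count; anything else is
        pooled as ``"Others"``.  The deletion allele *5 is never returned
        here (it has no sequence and is called from copy number).
        """
        h = tuple(haplotype)
        if len(h) != PANEL_SIZE:
            raise ValueError(f"haplotype has {len(h)} states, expected {PANEL_SIZE}")
        if any(s is None for s in h):
            raise ValueError(
                "haplotype contains missing states; phase or marginalize first"
            )
        return self._by_states.get(h, OTHERS)

    def classify_activity(self, star: str) -> ActivityClass:
        """Activity class of a star label, ``"Others"`` included (→ ND)."""
        if star == OTHERS:
            return ActivityClass.ND
        d = self.defs.get(star)
        if d is not None:
            return d.activity
        base, mult = parse_star_label(star)
        if mult > 1 and base in self.defs:
            return duplication_activity(self.defs[base].activity)
        raise KeyError(f"unknown star allele {star!r}")


def all_panel_haplotypes(
    sites: Sequence[VariantSite],
) -> Iterator[Haplotype]:
    """Enumerate all 2^11 fully observed haplotypes over the panel."""
    choices = [(s.reference_state, s.variant_state) for s in sites]
    for combo in itertools.product(*choices):
        yield combo


def load_definition_table(
    source: Union[str, Path, None] = None,
) -> AlleleDefinitions:
    """Load an allele-definition TSV; default is the packaged catalogue.

    Dialect: header ``allele<TAB>-1584<TAB>…<TAB>4180<TAB>multiplier<TAB>
    activity``; states are single bases or ``del``; a row of ``-`` states
    marks the whole-gene deletion.
    """
    if source is None:
        ref = resources.files("cyp2d6pop").joinpath("data/allele_definitions.tsv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(source).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise DefinitionTableError("empty definition table")

    header = lines[0].split("\t")
    expected = ["allele", *PANEL_LABELS, "multiplier", "activity"]
    if header != expected:
        raise DefinitionTableError(
            f"line 1: malformed header; expected {expected!r}"
        )

    raw_defs: list[StarAlleleDef] = []
    rows: list[Tuple[int, str, list[str], int, ActivityClass]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(expected):
            raise DefinitionTableError(
                f"line {lineno}: expected {len(expected)} columns, got {len(fields)}"
            )
        name = fields[0]
        states = fields[1 : 1 + PANEL_SIZE]
        try:
            multiplier = int(fields[1 + PANEL_SIZE])
        except ValueError:
            raise DefinitionTableError(
                f"line {lineno}: multiplier {fields[1 + PANEL_SIZE]!r} not an integer"
            ) from None
        activity_word = fields[2 + PANEL_SIZE]
        if activity_word not in _ACTIVITY_WORDS:
            raise DefinitionTableError(
                f"line {lineno}: unknown activity {activity_word!r}"
            )
        is_deletion = all(s == "-" for s in states)
        if not is_deletion:
            for s in states:
                if s not in VALID_STATES:
                    raise DefinitionTableError(
                        f"line {lineno}: invalid state {s!r}"
                    )
        rows.append((lineno, name, states, multiplier, _ACTIVITY_WORDS[activity_word]))

    # derive per-site reference/variant states: reference from the all-*1 row,
    # variant as the unique alternative observed across the table
    base_rows = [r for r in rows if r[3] == 1 and not all(s == "-" for s in r[2])]
    if not base_rows:
        raise DefinitionTableError("no sequence-defined base alleles in table")
    sites: list[VariantSite] = []
    for i, label in enumerate(PANEL_LABELS):
        observed = {r[2][i] for r in base_rows}
        if len(observed) != 2:
            raise DefinitionTableError(
                f"site {label}: expected exactly 2 states, saw {sorted(observed)}"
            )
        ref = base_rows[0][2][i]  # first row is the all-reference allele
        (var,) = observed - {ref}
        sites.append(VariantSite(label, ref, var, i))

    for lineno, name, states, multiplier, activity in rows:
        base, label_mult = parse_star_label(name)
        if label_mult != multiplier:
            raise DefinitionTableError(
                f"line {lineno}: label {name} disagrees with multiplier {multiplier}"
            )
        is_deletion = all(s == "-" for s in states)
        raw_defs.append(
            StarAlleleDef(
                name=name,
                base_allele=base,
                copy_multiplier=multiplier,
                defining_states=None if is_deletion else tuple(states),
                activity=activity,
                whole_gene_deletion=is_deletion,
            )
        )
    return AlleleDefinitions(sites, raw_defs)
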