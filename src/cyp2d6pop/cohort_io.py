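"""Reading and writing the cohort genotype table.

One row per individual, tab-separated, fixed versioned header::

    id  region  color  amerindian  african  european  -1584_1  -1584_2 ... 4180_1  4180_2  rq  cn

with two state columns per panel site (panel order) and ``.`` for
missing values.  Row-level problems are aggregated and reported together
with their line numbers.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

from .alleles import PANEL_LABELS, VALID_STATES
from .phasing import ANCESTRY_TOL, GenotypeRecord

MISSING = "."

COHORT_COLUMNS: Tuple[str, ...] = (
    "id",
    "region",
    "color",
    "amerindian",
    "african",
    "european",
    *(f"{label}_{k}" for label in PANEL_LABELS for k in (1, 2)),
    "rq",
    "cn",
)


class CohortParseError(ValueError):
    """Aggregated row-level validation failures of a cohort file."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "cohort file invalid:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


def _parse_row(fields: List[str], lineno: int) -> GenotypeRecord:
    vals = dict(zip(COHORT_COLUMNS, fields))
    ind_id = vals["id"]
    region = None if vals["region"] == MISSING else vals["region"]
    color = None if vals["color"] == MISSING else vals["color"]

    ancestry_raw = [vals["amerindian"], vals["african"], vals["european"]]
    ancestry: Optional[Tuple[float, float, float]]
    if all(a == MISSING for a in ancestry_raw):
        ancestry = None
    else:
        try:
            triple = tuple(float(a) for a in ancestry_raw)
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric ancestry") from None
        if any(not (0.0 <= a <= 1.0) for a in triple):
            raise ValueError(f"line {lineno}: ancestry proportion outside [0, 1]")
        if abs(sum(triple) - 1.0) > ANCESTRY_TOL:
            raise ValueError(
                f"line {lineno}: ancestry proportions sum to "
                f"{sum(triple):.8f}, not 1"
            )
        ancestry = triple

    site_calls = []
    for label in PANEL_LABELS:
        pair = []
        for k in (1, 2):
            s = vals[f"{label}_{k}"]
            if s == MISSING:
                pair.append(None)
            elif s in VALID_STATES:
                pair.append(s)
            else:
                raise ValueError(
                    f"line {lineno}: unknown state {s!r} at site {label}"
                )
        site_calls.append(tuple(pair))

    rq = None if vals["rq"] == MISSING else float(vals["rq"])
    cn = None if vals["cn"] == MISSING else int(vals["cn"])
    return GenotypeRecord(
        individual_id=ind_id,
        site_calls=tuple(site_calls),
        region=region,
        skin_color=color,
        ancestry=ancestry,
        copy_number_raw=rq,
        copy_number=cn,
    )


def read_cohort(path: Union[str, Path]) -> List[GenotypeRecord]:
    """Parse and validate a cohort file; all row errors reported at once."""
    path = Path(path)
    problems: List[str] = []
    records: List[GenotypeRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise CohortParseError(["file is empty"]) from None
        if tuple(header) != COHORT_COLUMNS:
            raise CohortParseError(
                [f"line 1: malformed header (expected {len(COHORT_COLUMNS)} "
                 f"fixed column names starting with 'id')"]
            )
        for lineno, fields in enumerate(reader, start=2):
            if not fields:
                continue
            if len(fields) != len(COHORT_COLUMNS):
                problems.append(
                    f"line {lineno}: expected {len(COHORT_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
                continue
            try:
                records.append(_parse_row(fields, lineno))
            except ValueError as exc:
                problems.append(str(exc))
    if problems:
        raise CohortParseError(problems)
    return records


def write_cohort(
    records: Sequence[GenotypeRecord], path: Union[str, Path]
) -> None:
    """Write records in the cohort dialect (floats at full precision)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COHORT_COLUMNS)
        for rec in records:
            row: List[str] = [
                rec.individual_id,
                rec.region if rec.region is not None else MISSING,
                rec.skin_color if rec.skin_color is not None else MISSING,
            ]
            if rec.ancestry is None:
                row += [MISSING] * 3
            else:
                row += [repr(float(a)) for a in rec.ancestry]
            for pair in rec.site_calls:
                for s in pair:
                    row.append(s if s is not None else MISSING)
            row.append(
                repr(float(rec.copy_number_raw))
                if rec.copy_number_raw is not None
                else MISSING
            )
            row.append(
                str(rec.copy_number) if rec.copy_number is not None else MISSING
            )
            writer.writerow(row)
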