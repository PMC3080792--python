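"""Quantitative membrane-enrichment (P/H ratio) classification.

P is the membrane fraction, H the total tissue homogenate; each protein
carries normalized spectral-index values sin_P and sin_H whose ratio P/H
measures membrane enrichment. Finite ratio > 1 is membrane-enriched,
finite < 1 depleted; sin_H = 0 with sin_P > 0 yields an INFINITE ratio
(detected in the membrane fraction only), and no evidence in either sample
leaves the ratio UNDEFINED.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal, Sequence

INFINITE = math.inf
UNDEFINED = None

RatioClass = Literal["PM_enriched", "depleted", "PM_only", "undetermined"]

_UNANNOTATED = {"undecided", "unknown", "na", "n/a", ""}
_INF_TOKENS = {"inf", "infinite", "infinity", "∞"}


@dataclass
class ProteinQuantRecord:
    """One quantified protein row."""

    protein_id: str
    accession: str = ""
    description: str = ""
    abundance_P: float = 0.0  # ng per mg membrane protein
    sin_P: float | None = None
    sin_H: float | None = None
    ratio_PH: float | None = None  # nonneg float, INFINITE, or UNDEFINED
    locations_raw: str = ""

    def __post_init__(self) -> None:
        if self.abundance_P < 0:
            raise ValueError(f"{self.protein_id}: abundance must be nonnegative")
        if self.ratio_PH is UNDEFINED and self.sin_P is not None and self.sin_H is not None:
            self.ratio_PH = compute_ratio(self.sin_P, self.sin_H)

    @property
    def locations(self) -> set[str]:
        """Compartment labels, split on ';' and ',', case-folded, trimmed.

        Placeholder tokens (undecided/unknown/NA) map to no annotation.
        """
        tokens = re.split(r"[;,]", self.locations_raw)
        return {
            tok for tok in (t.strip().casefold() for t in tokens)
            if tok not in _UNANNOTATED
        }

    @property
    def annotated(self) -> bool:
        return bool(self.locations)


@dataclass
class QuantSummary:
    n_records: int
    n_enriched: int
    n_depleted: int
    n_infinite: int
    n_ratio_undefined: int
    n_ratio_equal_one: int
    n_location_annotated: int
    per_compartment: dict[str, int] = field(default_factory=dict)
    abundance_min: float | None = None
    abundance_max: float | None = None

    def __post_init__(self) -> None:
        total = (
            self.n_enriched + self.n_depleted + self.n_infinite
            + self.n_ratio_undefined + self.n_ratio_equal_one
        )
        assert total == self.n_records, "ratio classes must partition the records"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"


def compute_ratio(sin_P: float | None, sin_H: float | None) -> float | None:
    """P/H ratio with the detected-in-P-only and no-evidence conventions."""
    if sin_P is not None and sin_P < 0 or sin_H is not None and sin_H < 0:
        raise ValueError("spectral index values must be nonnegative")
    if sin_P is None or sin_H is None or (sin_P == 0 and sin_H == 0):
        return UNDEFINED
    if sin_H == 0:
        return INFINITE
    return sin_P / sin_H


def classify_record(record: ProteinQuantRecord) -> RatioClass:
    """Map a record's ratio to its membrane-enrichment class."""
    r = record.ratio_PH
    if r is UNDEFINED or r == 1.0:
        return "undetermined"
    if r == INFINITE:
        return "PM_only"
    if r > 1.0:
        return "PM_enriched"
    return "depleted"


_PREDICATE_FIELDS = {
    "ratio_class", "ratio_finite", "ratio_gt", "ratio_lt",
    "abundance_min", "abundance_max", "annotated", "location_contains",
}


def filter_count(
    records: Sequence[ProteinQuantRecord], predicate: dict
) -> tuple[int, list[str]]:
    """Count records matching a declarative predicate; returns (count, ids).

    Predicate fields (all combined with AND):
      ratio_class: one of the RatioClass labels
      ratio_finite: bool — ratio defined and finite
      ratio_gt / ratio_lt: finite-ratio bounds (imply ratio_finite)
      abundance_min / abundance_max: inclusive abundance bounds
      annotated: bool — has at least one compartment label
      location_contains: compartment label that must be present
    """
    unknown = set(predicate) - _PREDICATE_FIELDS
    if unknown:
        raise ValueError(f"unknown predicate fields: {sorted(unknown)}")

    def matches(rec: ProteinQuantRecord) -> bool:
        r = rec.ratio_PH
        finite = r is not UNDEFINED and r != INFINITE
        if "ratio_class" in predicate and classify_record(rec) != predicate["ratio_class"]:
            return False
        if "ratio_finite" in predicate and finite != predicate["ratio_finite"]:
            return False
        if "ratio_gt" in predicate and not (finite and r > predicate["ratio_gt"]):
            return False
        if "ratio_lt" in predicate and not (finite and r < predicate["ratio_lt"]):
            return False
        if "abundance_min" in predicate and rec.abundance_P < predicate["abundance_min"]:
            return False
        if "abundance_max" in predicate and rec.abundance_P > predicate["abundance_max"]:
            return False
        if "annotated" in predicate and rec.annotated != predicate["annotated"]:
            return False
        if "location_contains" in predicate:
            if predicate["location_contains"].casefold() not in rec.locations:
                return False
        return True

    ids = sorted(rec.protein_id for rec in records if matches(rec))
    return len(ids), ids


def location_summary(
    records: Sequence[ProteinQuantRecord],
    abundance_subset: Iterable[str] | None = None,
) -> QuantSummary:
    """Summarize ratio classes and compartment membership.

    A record listing several compartments counts once toward each. The
    abundance range covers ``abundance_subset`` ids when given, else all
    records.
    """
    n_enriched = n_depleted = n_inf = n_undef = n_one = n_annot = 0
    per_compartment: dict[str, int] = {}
    for rec in records:
        cls = classify_record(rec)
        if cls == "PM_enriched":
            n_enriched += 1
        elif cls == "depleted":
            n_depleted += 1
        elif cls == "PM_only":
            n_inf += 1
        elif rec.ratio_PH == 1.0:
            n_one += 1
        else:
            n_undef += 1
        if rec.annotated:
            n_annot += 1
            for loc in rec.locations:
                per_compartment[loc] = per_compartment.get(loc, 0) + 1
    subset_ids = set(abundance_subset) if abundance_subset is not None else None
    abundances = [
        rec.abundance_P
        for rec in records
        if subset_ids is None or rec.protein_id in subset_ids
    ]
    return QuantSummary(
        n_records=len(records),
        n_enriched=n_enriched,
        n_depleted=n_depleted,
        n_infinite=n_inf,
        n_ratio_undefined=n_undef,
        n_ratio_equal_one=n_one,
        n_location_annotated=n_annot,
        per_compartment=dict(sorted(per_compartment.items())),
        abundance_min=min(abundances) if abundances else None,
        abundance_max=max(abundances) if abundances else None,
    )


# ---------------------------------------------------------------------------
# TSV I/O

_COLUMNS = [
    "protein_id", "accession", "description", "abundance_P_ng_per_mg",
    "sin_P", "sin_H", "ratio_PH", "locations",
]


def _parse_ratio(token: str) -> float | None:
    token = token.strip()
    if not token or token.casefold() in {"nan", "undefined", "none"}:
        return UNDEFINED
    if token.casefold() in _INF_TOKENS:
        return INFINITE
    value = float(token)
    if value < 0:
        raise ValueError(f"negative ratio {token!r}")
    return value


def read_quant_tsv(stream: IO[str] | str) -> list[ProteinQuantRecord]:
    """Read the quant TSV dialect (header row required, '#' comments allowed).

    The ratio column accepts literal "inf"/"∞"; an empty ratio with sin
    columns present is recomputed from them.
    """
    lines = stream.splitlines() if isinstance(stream, str) else stream.read().splitlines()
    header: list[str] | None = None
    records: list[ProteinQuantRecord] = []
    for raw in lines:
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            missing = {"protein_id"} - set(header)
            if missing:
                raise ValueError(f"quant table missing columns: {sorted(missing)}")
            continue
        row = dict(zip(header, (f.strip() for f in fields)))

        def num(key: str) -> float | None:
            val = row.get(key, "")
            return float(val) if val else None

        records.append(
            ProteinQuantRecord(
                protein_id=row["protein_id"],
                accession=row.get("accession", ""),
                description=row.get("description", ""),
                abundance_P=num("abundance_P_ng_per_mg") or 0.0,
                sin_P=num("sin_P"),
                sin_H=num("sin_H"),
                ratio_PH=_parse_ratio(row.get("ratio_PH", "")),
                locations_raw=row.get("locations", ""),
            )
        )
    if header is None:
        raise ValueError("empty quant table")
    return records


def write_quant_tsv(records: Sequence[ProteinQuantRecord], stream: IO[str]) -> None:
    stream.write("\t".join(_COLUMNS) + "\n")
    for rec in records:
        if rec.ratio_PH is UNDEFINED:
            ratio = ""
        elif rec.ratio_PH == INFINITE:
            ratio = "inf"
        else:
            ratio = repr(rec.ratio_PH)
        stream.write(
            "\t".join(
                [
                    rec.protein_id,
                    rec.accession,
                    rec.description,
                    repr(rec.abundance_P),
                    "" if rec.sin_P is None else repr(rec.sin_P),
                    "" if rec.sin_H is None else repr(rec.sin_H),
                    ratio,
                    rec.locations_raw,
                ]
            )
            + "\n"
        )
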