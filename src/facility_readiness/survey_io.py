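"""Facility survey reading/writing and response coding.

The interchange format is a UTF-8 CSV with a header row: six covariate
columns (``facility_id, tier, managing_authority, region, teaching,
monthly_delivery_volume``) followed by one column per survey item.
Response cells use a configurable vocabulary; the documented default is

====== ==================
token  meaning
====== ==================
``1``  yes
``0``  no
``dk`` don't know
``na`` not applicable
(blank) missing
====== ==================

Coding rules applied by :func:`code_responses` before aggregation:
yes -> 1; no, don't-know and missing -> 0. Not-applicable cells are
handled per purpose: for additive scoring they are excluded and the
denominator adjusted (mask ``applicable=False``); for PCA they are coded
0 so the matrix stays dense.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import ManagingAuthority, MatrixPurpose, Response, Tier
from .errors import (CoverageError, FormatError, ParseError, TierMismatchError)
from .registry import IndexSpec, ItemRegistry

COVARIATE_COLUMNS = ("facility_id", "tier", "managing_authority", "region",
                     "teaching", "monthly_delivery_volume")

#: Default response vocabulary (input token, lower-cased -> Response).
DEFAULT_VOCABULARY: dict[str, Response] = {
    "1": Response.YES, "yes": Response.YES,
    "0": Response.NO, "no": Response.NO,
    "dk": Response.DONT_KNOW, "dont_know": Response.DONT_KNOW,
    "na": Response.NOT_APPLICABLE, "not_applicable": Response.NOT_APPLICABLE,
    "": Response.MISSING, "missing": Response.MISSING,
}

#: Canonical token written per response.
_WRITE_TOKEN: dict[Response, str] = {
    Response.YES: "1", Response.NO: "0", Response.DONT_KNOW: "dk",
    Response.NOT_APPLICABLE: "na", Response.MISSING: "",
}


@dataclass
class FacilityRecord:
    """One facility's covariates plus raw item responses."""

    facility_id: str
    tier: Tier
    managing_authority: ManagingAuthority
    region: str
    responses: dict[str, Response] = field(default_factory=dict)
    teaching: Optional[bool] = None
    monthly_delivery_volume: Optional[int] = None

    def __post_init__(self) -> None:
        if self.monthly_delivery_volume is not None and self.monthly_delivery_volume < 0:
            raise ValueError(
                f"facility {self.facility_id!r}: negative delivery volume")


@dataclass
class ResponseMatrix:
    """Facilities x items binary matrix with applicability mask."""

    facility_ids: list[str]
    item_ids: list[str]
    values: np.ndarray      # (n_facilities, n_items) of 0/1
    applicable: np.ndarray  # boolean mask, same shape
    purpose: MatrixPurpose
    tier: Optional[Tier] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.applicable = np.asarray(self.applicable, dtype=bool)
        if self.values.shape != (len(self.facility_ids), len(self.item_ids)):
            raise ValueError("values shape does not match axis labels")
        if self.applicable.shape != self.values.shape:
            raise ValueError("applicable mask shape does not match values")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("values must be 0/1")
        if self.purpose is MatrixPurpose.PCA and not self.applicable.all():
            raise ValueError("pca-purpose matrix must be fully applicable")
        if self.purpose is MatrixPurpose.ADDITIVE and (self.values[~self.applicable] != 0).any():
            raise ValueError("additive-purpose matrix has nonzero masked cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _parse_response(token: str, vocabulary: Mapping[str, Response],
                    row: int, column: str) -> Response:
    key = token.strip().lower()
    try:
        return vocabulary[key]
    except KeyError:
        raise ParseError(
            f"row {row}, column {column!r}: unknown response token {token!r}") from None


def read_facility_survey(path: str | Path, registry: ItemRegistry,
                         vocabulary: Mapping[str, Response] | None = None,
                         ) -> list[FacilityRecord]:
    """Read a facility survey CSV into records, validating against the registry.

    Columns must be the six covariates plus item columns known to the
    registry; anything else is rejected so typos surface early.
    """
    vocabulary = dict(DEFAULT_VOCABULARY if vocabulary is None else vocabulary)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in COVARIATE_COLUMNS:
            if col not in header:
                raise FormatError(f"{path.name}: missing required column {col!r}")
        item_columns = [c for c in header if c not in COVARIATE_COLUMNS]
        unknown = [c for c in item_columns if c not in registry]
        if unknown:
            raise FormatError(f"{path.name}: unknown columns {unknown}")
        records: list[FacilityRecord] = []
        seen_ids: set[str] = set()
        for rownum, row in enumerate(reader, start=2):
            fid = (row["facility_id"] or "").strip()
            if not fid:
                raise ParseError(f"row {rownum}: empty facility_id")
            if fid in seen_ids:
                raise ParseError(f"row {rownum}: duplicate facility_id {fid!r}")
            seen_ids.add(fid)
            try:
                tier = Tier(row["tier"].strip())
            except ValueError:
                raise ParseError(
                    f"row {rownum}, column 'tier': unknown value {row['tier']!r}") from None
            try:
                authority = ManagingAuthority(row["managing_authority"].strip())
            except ValueError:
                raise ParseError(
                    f"row {rownum}, column 'managing_authority': "
                    f"unknown value {row['managing_authority']!r}") from None
            teaching_raw = (row["teaching"] or "").strip()
            teaching = None if teaching_raw == "" else teaching_raw == "1"
            vol_raw = (row["monthly_delivery_volume"] or "").strip()
            if vol_raw == "":
                volume = None
            else:
                try:
                    volume = int(vol_raw)
                except ValueError:
                    raise ParseError(
                        f"row {rownum}, column 'monthly_delivery_volume': "
                        f"not a count: {vol_raw!r}") from None
                if volume < 0:
                    raise ParseError(
                        f"row {rownum}: negative delivery volume {volume}")
            responses = {
                col: _parse_response(row[col] or "", vocabulary, rownum, col)
                for col in item_columns
            }
            records.append(FacilityRecord(
                facility_id=fid, tier=tier, managing_authority=authority,
                region=(row["region"] or "").strip(), teaching=teaching,
                monthly_delivery_volume=volume, responses=responses))
    return records


def write_facility_survey(records: Sequence[FacilityRecord], path: str | Path,
                          item_ids: Sequence[str] | None = None) -> None:
    """Write records as survey CSV (canonical response tokens)."""
    path = Path(path)
    if item_ids is None:
        item_ids = sorted({iid for rec in records for iid in rec.responses})
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(COVARIATE_COLUMNS) + list(item_ids))
        for rec in records:
            row = [
                rec.facility_id,
                rec.tier.value,
                rec.managing_authority.value,
                rec.region,
                "" if rec.teaching is None else ("1" if rec.teaching else "0"),
                "" if rec.monthly_delivery_volume is None else str(rec.monthly_delivery_volume),
            ]
            row.extend(_WRITE_TOKEN[rec.responses[iid]] if iid in rec.responses else ""
                       for iid in item_ids)
            writer.writerow(row)


def code_responses(records: Sequence[FacilityRecord], index: IndexSpec,
                   purpose: MatrixPurpose | str) -> ResponseMatrix:
    """Encode raw responses for one index into a 0/1 matrix.

    yes -> 1; no/don't-know/missing -> 0. A not-applicable response is
    masked (additive purpose) or coded 0 (pca purpose). All records must
    belong to the index's tier; each index item must appear in at least
    one record.
    """
    purpose = MatrixPurpose(purpose)
    wrong = [r.facility_id for r in records if r.tier is not index.tier]
    if wrong:
        raise TierMismatchError(
            f"records not of tier {index.tier.value}: {wrong[:5]}")
    if not records:
        raise ValueError("no records to code")
    n, p = len(records), len(index.items)
    values = np.zeros((n, p), dtype=np.int8)
    applicable = np.ones((n, p), dtype=bool)
    uncovered = [iid for iid in index.items
                 if not any(iid in r.responses for r in records)]
    if uncovered:
        raise CoverageError(
            f"{index.name.value}/{index.tier.value}: items with no responses "
            f"in any record: {uncovered}")
    for i, rec in enumerate(records):
        for j, iid in enumerate(index.items):
            resp = rec.responses.get(iid, Response.MISSING)
            if resp is Response.YES:
                values[i, j] = 1
            elif resp is Response.NOT_APPLICABLE:
                if purpose is MatrixPurpose.ADDITIVE:
                    applicable[i, j] = False
                # pca purpose: stays 0, applicable stays True
    return ResponseMatrix(
        facility_ids=[r.facility_id for r in records],
        item_ids=list(index.items),
        values=values, applicable=applicable, purpose=purpose,
        tier=index.tier)
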