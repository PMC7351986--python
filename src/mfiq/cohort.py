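"""Recovery-group classification and participant-flow accounting.

Groups are defined from the 12-month Neck Disability Index (NDI, a 0-100 %
self-report disability score): severe >= 30 %, mild 10-29 %, recovered < 10 %.
The mild band is read as the half-open interval [10, 30) so the three bands
tile [0, 100] with no gap at non-integer NDI values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

GROUPS = ("severe", "mild", "recovered")

#: NDI % at or above which a participant is classified severe.
SEVERE_THRESHOLD = 30.0
#: NDI % at or above which (and below SEVERE_THRESHOLD) a participant is mild.
MILD_THRESHOLD = 10.0

FLAG_COLUMNS = ("returned", "scan_quality_ok", "quartile_amenable")


class FlowValidationError(ValueError):
    """Participant flow flags are inconsistent (e.g. a quality flag on a non-returnee)."""


def assign_group(ndi_percent: float) -> str:
    """Classify a participant's recovery group from the 12-month NDI %.

    Parameters
    ----------
    ndi_percent : float
        Neck Disability Index on the 0-100 % scale.

    Returns
    -------
    str
        ``"severe"`` (>= 30), ``"mild"`` ([10, 30)) or ``"recovered"`` (< 10).
    """
    ndi = float(ndi_percent)
    if not 0.0 <= ndi <= 100.0:
        raise ValueError(f"NDI % must lie in [0, 100], got {ndi_percent!r}")
    if ndi >= SEVERE_THRESHOLD:
        return "severe"
    if ndi >= MILD_THRESHOLD:
        return "mild"
    return "recovered"


@dataclass(frozen=True)
class FlowCounts:
    """Participant-flow bookkeeping from enrolment to the analysed sub-study.

    The arithmetic identities ``returned_12mo = enrolled - lost_to_attrition``
    and ``included = returned_12mo - excluded_poor_quality -
    excluded_not_amenable`` are enforced at construction.
    """

    enrolled: int
    lost_to_attrition: int
    returned_12mo: int
    excluded_poor_quality: int
    excluded_not_amenable: int
    included: int

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise FlowValidationError(f"{name} must be >= 0, got {value}")
        if self.returned_12mo != self.enrolled - self.lost_to_attrition:
            raise FlowValidationError(
                "returned_12mo must equal enrolled - lost_to_attrition "
                f"({self.enrolled} - {self.lost_to_attrition} != {self.returned_12mo})"
            )
        expected_included = (
            self.returned_12mo - self.excluded_poor_quality - self.excluded_not_amenable
        )
        if self.included != expected_included:
            raise FlowValidationError(
                "included must equal returned_12mo - exclusions "
                f"(expected {expected_included}, got {self.included})"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def apply_flow(flags: pd.DataFrame) -> tuple[list, FlowCounts]:
    """Apply the study's inclusion flow to per-participant flags.

    Parameters
    ----------
    flags : pandas.DataFrame
        One row per enrolled participant with columns ``participant_id``,
        ``returned`` (bool), ``scan_quality_ok`` and ``quartile_amenable``
        (nullable bools). Quality/amenability flags must be present for every
        returnee and absent (NA) for non-returnees; amenability is only judged
        on scans of acceptable quality.

    Returns
    -------
    (included_ids, FlowCounts)
        Identifiers of included participants and the flow accounting.
    """
    missing = [c for c in ("participant_id",) + FLAG_COLUMNS if c not in flags.columns]
    if missing:
        raise FlowValidationError(f"flag table missing columns: {missing}")

    returned = flags["returned"]
    if returned.isna().any():
        raise FlowValidationError("'returned' flag must be set for every enrolled participant")
    returned = returned.astype(bool)

    quality = flags["scan_quality_ok"]
    amenable = flags["quartile_amenable"]

    if quality[~returned].notna().any():
        raise FlowValidationError("scan_quality_ok set for a participant who did not return")
    if amenable[~returned].notna().any():
        raise FlowValidationError("quartile_amenable set for a participant who did not return")
    if quality[returned].isna().any():
        raise FlowValidationError("scan_quality_ok missing for a returned participant")

    quality_ok = returned & quality.fillna(False).astype(bool)
    if amenable[quality_ok].isna().any():
        raise FlowValidationError("quartile_amenable missing for a quality-OK returnee")
    if amenable[returned & ~quality_ok].notna().any():
        raise FlowValidationError(
            "quartile_amenable set for a poor-quality scan (amenability is judged on usable scans)"
        )

    included_mask = quality_ok & amenable.fillna(False).astype(bool)
    counts = FlowCounts(
        enrolled=int(len(flags)),
        lost_to_attrition=int((~returned).sum()),
        returned_12mo=int(returned.sum()),
        excluded_poor_quality=int((returned & ~quality.fillna(False).astype(bool)).sum()),
        excluded_not_amenable=int((quality_ok & ~amenable.fillna(False).astype(bool)).sum()),
        included=int(included_mask.sum()),
    )
    included_ids = flags.loc[included_mask, "participant_id"].tolist()
    return included_ids, counts


def flow_from_counts(
    enrolled: int,
    lost_to_attrition: int,
    excluded_poor_quality: int,
    excluded_not_amenable: int,
) -> FlowCounts:
    """Build per-participant flags from aggregate counts and run :func:`apply_flow`.

    Convenience for reproducing published flow diagrams where only the
    aggregate counts are known.
    """
    returned = enrolled - lost_to_attrition
    if returned < 0:
        raise FlowValidationError("more attrition than enrolment")
    if excluded_poor_quality + excluded_not_amenable > returned:
        raise FlowValidationError("more exclusions than returnees")

    ids = [f"P{i:03d}" for i in range(enrolled)]
    returned_flags = [True] * returned + [False] * lost_to_attrition
    quality: list = [pd.NA] * enrolled
    amenable: list = [pd.NA] * enrolled
    for i in range(returned):
        if i < excluded_poor_quality:
            quality[i] = False
        else:
            quality[i] = True
            amenable[i] = i >= excluded_poor_quality + excluded_not_amenable
    flags = pd.DataFrame(
        {
            "participant_id": ids,
            "returned": returned_flags,
            "scan_quality_ok": pd.array(quality, dtype="boolean"),
            "quartile_amenable": pd.array(amenable, dtype="boolean"),
        }
    )
    _, counts = apply_flow(flags)
    return counts


def write_flow_report(counts: FlowCounts, path: str | Path) -> None:
    """Serialize a flow accounting to JSON (mirrors a participant flowchart)."""
    Path(path).write_text(json.dumps(counts.to_dict(), indent=2) + "\n")


def group_sizes(ndi_values: Iterable[float]) -> dict[str, int]:
    """Partition NDI scores into groups and count each group."""
    sizes = {g: 0 for g in GROUPS}
    for ndi in ndi_values:
        sizes[assign_group(ndi)] += 1
    return sizes
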