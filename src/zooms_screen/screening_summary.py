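"""Sample selection and zooarchaeological quantification (NISP / %NISP).

Covers the screening workflow around the mass spectrometry itself: the
five-criterion filter that picks unidentified bone fragments for collagen
fingerprinting, per-site NISP tallies with the group-wise percentage
conventions used in faunal tables (per-taxon percentages over the taxon's
order-group NISP, group percentages over total NISP), and integration of
molecular determinations into the morphological NISP without double
counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .identify import UNDETERMINED, TaxonAssignment

__all__ = [
    "SIZE_CLASSES",
    "ORDER_GROUPS",
    "TAPHONOMY_FLAGS",
    "BoneRecord",
    "SiteSummary",
    "round_half_up",
    "format_percent",
    "select_for_zooms",
    "tally_counts",
    "percent_within_group",
    "integrate_zooms_nisp",
    "load_bone_records",
    "bone_records_to_frame",
]

logger = logging.getLogger(__name__)

SIZE_CLASSES = ("0-1", "1-2", "2-3", "3-4", "4-5", ">5")
BODY_SIZE_CLASSES = ("large", "medium-large", "medium", "medium-small", "small", "indet")
ORDER_GROUPS = ("Lagomorpha", "Carnivora", "Ungulata", "indet")
TAPHONOMY_FLAGS = ("combustion", "manganese", "concretion")

#: Non-taxon determination statuses.
_NON_DETERMINATE = {"indeterminate", "unidentified", ""}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (faunal tables round 9.745 % to 9.7, 25.776 to 25.8)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(x: float, ndigits: int = 1) -> str:
    """Render a percentage, dropping the trailing '.0' of whole numbers."""
    r = round_half_up(x, ndigits)
    return str(int(r)) if r == int(r) else f"{r:.{ndigits}f}"


def _size_class_of(size_cm: float) -> str:
    bounds = (1, 2, 3, 4, 5)
    for hi, label in zip(bounds, SIZE_CLASSES):
        if size_cm <= hi:
            return label
    return ">5"


@dataclass
class BoneRecord:
    """One bone fragment with the metadata the screening filter needs."""

    specimen_id: str
    site: str
    stratigraphic_unit: str = ""
    size_cm: float | None = None
    size_class: str = ""
    body_size_class: str = "indet"
    taphonomy_flags: frozenset[str] = frozenset()
    trabeculae_visible: bool | None = None
    in_situ_position_known: bool | None = None
    cortical_quality_ok: bool | None = None
    morphological_taxon: str = "unidentified"
    order_group: str = "indet"

    def __post_init__(self) -> None:
        self.taphonomy_flags = frozenset(self.taphonomy_flags)
        if not self.size_class and self.size_cm is not None:
            self.size_class = _size_class_of(self.size_cm)
        if self.size_cm is not None and self.size_class:
            if _size_class_of(self.size_cm) != self.size_class:
                raise ValueError(
                    f"{self.specimen_id}: size_cm {self.size_cm} inconsistent "
                    f"with size_class {self.size_class!r}"
                )

    @property
    def is_determinate(self) -> bool:
        return self.morphological_taxon not in _NON_DETERMINATE


@dataclass
class SiteSummary:
    """Per-site faunal tallies with ZooMS screening outcome."""

    site: str
    total_nr: int = 0
    total_nisp: int = 0
    determinate_pct: float = 0.0
    group_nisp: dict[str, int] = field(default_factory=dict)
    group_pct: dict[str, float] = field(default_factory=dict)
    taxon_nisp: dict[str, dict[str, int]] = field(default_factory=dict)
    zooms_tested: int = 0
    zooms_determined: int = 0
    zooms_success_pct: int | None = None


_CRITERION_FIELDS = (
    "size_cm",
    "trabeculae_visible",
    "in_situ_position_known",
    "cortical_quality_ok",
)

#: Maximum number of taphonomic alteration flags tolerated per severity level.
_TAPHONOMY_ALLOWANCE = {"none": 0, "moderate": 1, "heavy": len(TAPHONOMY_FLAGS)}


def select_for_zooms(
    records: list[BoneRecord], taphonomy_severity: str = "moderate"
) -> list[str]:
    """Apply the five screening criteria; returns specimen ids in input order.

    A fragment is kept when it is morphologically unidentified, larger than
    2 cm, shows trabeculae, has a known in-situ position, acceptable cortical
    bone, and carries no more taphonomic alteration than the configured
    severity allows (none: no flags, moderate: at most one, heavy: any).
    Records missing a criterion field are excluded with a logged warning.
    """
    if taphonomy_severity not in _TAPHONOMY_ALLOWANCE:
        raise ValueError(f"unknown taphonomy severity {taphonomy_severity!r}")
    allowance = _TAPHONOMY_ALLOWANCE[taphonomy_severity]
    out: list[str] = []
    for rec in records:
        missing = [f for f in _CRITERION_FIELDS if getattr(rec, f) is None]
        if missing:
            logger.warning("%s: missing criterion field(s) %s, excluded",
                           rec.specimen_id, missing)
            continue
        if rec.morphological_taxon != "unidentified":
            continue
        if not (
            rec.size_cm > 2
            and rec.trabeculae_visible
            and rec.in_situ_position_known
            and rec.cortical_quality_ok
        ):
            continue
        if len(rec.taphonomy_flags & set(TAPHONOMY_FLAGS)) > allowance:
            continue
        out.append(rec.specimen_id)
    return out


def tally_counts(records: list[BoneRecord]) -> dict[str, SiteSummary]:
    """NISP tallies per site.

    ``determinate_pct`` is 100 x NISP / NR rounded half-up to one decimal
    (e.g. 612 of 6,280 -> 9.7).  Group percentages are over total NISP and
    per-taxon counts are nested under their order group so percentages
    within the group can be derived.
    """
    summaries: dict[str, SiteSummary] = {}
    for rec in sorted(records, key=lambda r: r.site):
        s = summaries.setdefault(rec.site, SiteSummary(site=rec.site))
        s.total_nr += 1
        if rec.is_determinate:
            s.total_nisp += 1
            grp = rec.order_group
            s.group_nisp[grp] = s.group_nisp.get(grp, 0) + 1
            bygrp = s.taxon_nisp.setdefault(grp, {})
            bygrp[rec.morphological_taxon] = bygrp.get(rec.morphological_taxon, 0) + 1
    for s in summaries.values():
        if s.total_nr:
            s.determinate_pct = round_half_up(100.0 * s.total_nisp / s.total_nr, 1)
        if s.total_nisp:
            s.group_pct = {
                g: round_half_up(100.0 * n / s.total_nisp, 1)
                for g, n in s.group_nisp.items()
            }
    return summaries


def percent_within_group(summary: SiteSummary, taxon: str) -> float | None:
    """%NISP of a taxon over its order-group NISP (one decimal, half-up).

    Follows the faunal-table convention where e.g. 112 red deer of 509
    ungulates prints as 22.  Returns None when the taxon's group has zero
    NISP (undefined), 0.0 when the taxon itself has zero.
    """
    for grp, taxa in summary.taxon_nisp.items():
        if taxon in taxa:
            denom = summary.group_nisp.get(grp, 0)
            if denom == 0:
                return None
            return round_half_up(100.0 * taxa[taxon] / denom, 1)
    return 0.0


def integrate_zooms_nisp(
    records: list[BoneRecord],
    assignments: list[TaxonAssignment],
) -> pd.DataFrame:
    """Combine morphological NISP with ZooMS determinations, per category.

    ZooMS categories (including group-level ones such as "Caprinae/Cervidae")
    add to the table only for specimens that are not already morphologically
    determined; a conflicting assignment for a determined specimen raises a
    logged warning and morphology wins.
    """
    by_id = {r.specimen_id: r for r in records}
    morph: dict[str, int] = {}
    for rec in records:
        if rec.is_determinate:
            morph[rec.morphological_taxon] = morph.get(rec.morphological_taxon, 0) + 1
    zooms: dict[str, int] = {}
    counted: set[str] = set()
    for a in assignments:
        if not a.determined or a.sample_id in counted:
            continue
        counted.add(a.sample_id)
        rec = by_id.get(a.sample_id)
        if rec is not None and rec.is_determinate:
            logger.warning(
                "%s: ZooMS assignment %r conflicts with morphological %r; morphology wins",
                a.sample_id, a.assignment, rec.morphological_taxon,
            )
            continue
        zooms[a.assignment] = zooms.get(a.assignment, 0) + 1
    categories = sorted(set(morph) | set(zooms))
    df = pd.DataFrame(
        {
            "category": categories,
            "morphological_nisp": [morph.get(c, 0) for c in categories],
            "zooms_nisp": [zooms.get(c, 0) for c in categories],
        }
    )
    df["combined_nisp"] = df["morphological_nisp"] + df["zooms_nisp"]
    return df


_LIST_SEP = "|"


def bone_records_to_frame(records: list[BoneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "site": [r.site for r in records],
            "stratigraphic_unit": [r.stratigraphic_unit for r in records],
            "size_cm": [r.size_cm for r in records],
            "size_class": [r.size_class for r in records],
            "body_size_class": [r.body_size_class for r in records],
            "taphonomy_flags": [
                _LIST_SEP.join(sorted(r.taphonomy_flags)) for r in records
            ],
            "trabeculae_visible": [r.trabeculae_visible for r in records],
            "in_situ_position_known": [r.in_situ_position_known for r in records],
            "cortical_quality_ok": [r.cortical_quality_ok for r in records],
            "morphological_taxon": [r.morphological_taxon for r in records],
            "order_group": [r.order_group for r in records],
        }
    )


def _opt_bool(v) -> bool | None:
    if pd.isna(v):
        return None
    if isinstance(v, str):
        return v.strip().lower() in {"true", "1", "yes"}
    return bool(v)


def load_bone_records(path) -> list[BoneRecord]:
    """Read a bones.csv written by :func:`bone_records_to_frame`."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        flags = row.taphonomy_flags
        flagset = frozenset(
            f for f in str(flags).split(_LIST_SEP) if f and not pd.isna(flags)
        ) if not pd.isna(flags) else frozenset()
        records.append(
            BoneRecord(
                specimen_id=str(row.specimen_id),
                site=str(row.site),
                stratigraphic_unit="" if pd.isna(row.stratigraphic_unit) else str(row.stratigraphic_unit),
                size_cm=None if pd.isna(row.size_cm) else float(row.size_cm),
                size_class="" if pd.isna(row.size_class) else str(row.size_class),
                body_size_class=str(row.body_size_class),
                taphonomy_flags=flagset,
                trabeculae_visible=_opt_bool(row.trabeculae_visible),
                in_situ_position_known=_opt_bool(row.in_situ_position_known),
                cortical_quality_ok=_opt_bool(row.cortical_quality_ok),
                morphological_taxon=str(row.morphological_taxon),
                order_group=str(row.order_group),
            )
        )
    return records
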