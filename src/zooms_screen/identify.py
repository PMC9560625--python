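"""Taxonomic assignment of monoisotopic peak lists against a marker database.

Assignment follows screening practice for fragmented Palaeolithic bone: a
species-level call needs at least two diagnostic markers and strict dominance
over every competing taxon; tied or inseparable taxa escalate to the smallest
registered ambiguity group covering them (e.g. "Bos/Bison",
"Ursus sp./Lynx lynx"); a determination resting on a single shared peptide
(the 1453.7-type case) is assigned its registered group and flagged for
morphological review; samples whose matches carry no diagnostic information
remain "undetermined".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .marker_db import DEFAULT_MATCH_TOL, MarkerDatabase, candidates_for_peak
from .preprocess import PeakList

__all__ = [
    "UNDETERMINED",
    "TaxonAssignment",
    "match_markers",
    "assign_taxon",
    "batch_identify",
    "assignments_to_frame",
]

UNDETERMINED = "undetermined"

#: Default number of diagnostic markers required for a dominant single-taxon call.
DEFAULT_MIN_DIAGNOSTIC = 2


class ConsistencyError(ValueError):
    """Raised when matches reference taxa unknown to the database."""


@dataclass
class TaxonAssignment:
    """Per-sample determination: a taxon, an ambiguity group, or undetermined."""

    sample_id: str
    matched_markers: list[tuple[float, str, str]] = field(default_factory=list)
    assignment: str = UNDETERMINED
    n_diagnostic: int = 0
    needs_morphological_review: bool = False

    @property
    def determined(self) -> bool:
        return self.assignment != UNDETERMINED


def match_markers(
    pl: PeakList, db: MarkerDatabase, tol: float = DEFAULT_MATCH_TOL
) -> list[tuple[float, str, str]]:
    """Query every monoisotopic peak against the database.

    Returns all hits as ``(observed_mz, taxon, series)`` tuples; a peak whose
    mass is shared by several taxa yields one tuple per taxon.
    """
    out: list[tuple[float, str, str]] = []
    for peak in pl.peaks:
        if not peak.is_monoisotopic:
            continue
        for taxon, series in sorted(candidates_for_peak(db, peak.mz, tol)):
            out.append((peak.mz, taxon, series))
    return out


def _single_peak_assignment(taxa: list[str], db: MarkerDatabase) -> str:
    """Category for a determination resting on one diagnostic peak."""
    if len(taxa) == 1:
        label = taxa[0]
        if label in db.ambiguity_groups:
            return label
        group = db.smallest_group_covering([label])
        return group if group is not None else label
    group = db.smallest_group_covering(taxa)
    return group if group is not None else UNDETERMINED


def assign_taxon(
    matches: list[tuple[float, str, str]],
    db: MarkerDatabase,
    min_diagnostic: int = DEFAULT_MIN_DIAGNOSTIC,
    sample_id: str = "",
) -> TaxonAssignment:
    """Resolve marker matches into a taxon, ambiguity group, or undetermined.

    Decision order:

    1. score each candidate label by its number of distinct matched
       diagnostic markers;
    2. a unique label reaching ``min_diagnostic`` and strictly dominating all
       others is assigned directly;
    3. tied leaders escalate to the smallest registered ambiguity group
       covering them all;
    4. a single matched diagnostic peak yields the group registered for that
       peptide and sets ``needs_morphological_review``;
    5. matches resolving only to an order-wide label (e.g. "Ungulata")
       yield that label;
    6. anything else is "undetermined".
    """
    known = db.known_labels()
    for _, taxon, _ in matches:
        if taxon not in known:
            raise ConsistencyError(f"matched taxon {taxon!r} not in database")

    diagnostic_mass = {
        (m.taxon, m.series): m.diagnostic for m in db.markers
    }
    # distinct diagnostic (peak, label) support
    peaks_by_label: dict[str, set[float]] = {}
    diagnostic_peaks: set[float] = set()
    for mz_obs, taxon, series in matches:
        if diagnostic_mass.get((taxon, series), False):
            peaks_by_label.setdefault(taxon, set()).add(mz_obs)
            diagnostic_peaks.add(mz_obs)

    result = TaxonAssignment(sample_id=sample_id, matched_markers=list(matches))
    if not peaks_by_label:
        return result
    result.n_diagnostic = len(diagnostic_peaks)

    scores = {label: len(p) for label, p in peaks_by_label.items()}
    best = max(scores.values())
    leaders = sorted(label for label, sc in scores.items() if sc == best)

    if len(diagnostic_peaks) == 1:
        result.assignment = _single_peak_assignment(leaders, db)
        result.needs_morphological_review = result.determined
        return result

    if best >= min_diagnostic and len(leaders) == 1:
        result.assignment = leaders[0]
        return result

    # ties, or no label with enough support: escalate to a covering group
    cands = leaders if best >= min_diagnostic else sorted(scores)
    group = db.smallest_group_covering(cands)
    if group is not None:
        result.assignment = group
    elif len(cands) == 1:
        result.assignment = cands[0]
    return result


def identify_peaklist(
    pl: PeakList,
    db: MarkerDatabase,
    tol: float = DEFAULT_MATCH_TOL,
    min_diagnostic: int = DEFAULT_MIN_DIAGNOSTIC,
) -> TaxonAssignment:
    """match_markers + assign_taxon for one sample."""
    matches = match_markers(pl, db, tol)
    return assign_taxon(matches, db, min_diagnostic, sample_id=pl.sample_id)


def batch_identify(
    peaklists: list[PeakList],
    db: MarkerDatabase,
    tol: float = DEFAULT_MATCH_TOL,
    min_diagnostic: int = DEFAULT_MIN_DIAGNOSTIC,
) -> tuple[list[TaxonAssignment], int]:
    """Identify a batch and report the screening success rate.

    The success rate is ``100 * determined / tested`` rounded to the nearest
    integer (half away from zero), the convention used when reporting e.g.
    84 of 94 as 89%.
    """
    if not peaklists:
        raise ValueError("batch_identify needs at least one peak list")
    assignments = [identify_peaklist(pl, db, tol, min_diagnostic) for pl in peaklists]
    n_det = sum(a.determined for a in assignments)
    rate = success_rate(n_det, len(assignments))
    return assignments, rate


def success_rate(n_determined: int, n_tested: int) -> int:
    """Integer percentage of determined samples (half-up rounding)."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    from .screening_summary import round_half_up

    return int(round_half_up(100.0 * n_determined / n_tested, 0))


def assignments_to_frame(assignments: list[TaxonAssignment]) -> pd.DataFrame:
    """Tabulate assignments for export (assignments.csv)."""
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in assignments],
            "assignment": [a.assignment for a in assignments],
            "n_diagnostic": [a.n_diagnostic for a in assignments],
            "matched_markers": [
                ";".join(f"{mz:.3f}:{taxon}:{series}" for mz, taxon, series in a.matched_markers)
                for a in assignments
            ],
            "needs_morphological_review": [
                a.needs_morphological_review for a in assignments
            ],
        }
    )
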