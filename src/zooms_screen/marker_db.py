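"""Collagen peptide-marker database for ZooMS taxonomic comparison.

A marker database maps taxa (species, genera, families or named multi-taxon
groups) to the monoisotopic masses of their diagnostic tryptic collagen
peptides.  Published working lists are assembled from several reference
compilations; this package ships a small *illustrative* example table
(``data/markers_example.tsv``) whose masses are plausible but synthetic,
intended for demonstration and testing — real screening should load the
user's own curated table.

Ambiguity groups ("Bos/Bison", "Caprinae/Cervidae", ...) are data, not code:
they live in a second TSV so users can mirror the determination categories of
their own study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .spectra_io import ParameterError

__all__ = [
    "MarkerPeptide",
    "MarkerDatabase",
    "MarkerFormatError",
    "load_markers",
    "candidates_for_peak",
    "example_database",
    "DEFAULT_MATCH_TOL",
]

#: Default marker-matching tolerance (Th).
DEFAULT_MATCH_TOL = 0.2

_MASS_LO, _MASS_HI = 700.0, 3500.0


class MarkerFormatError(ValueError):
    """Raised for malformed marker or group tables."""


@dataclass(frozen=True)
class MarkerPeptide:
    """One collagen peptide marker of one taxon.

    ``diagnostic`` flags markers that discriminate the taxon within its
    group; non-diagnostic markers (e.g. the mammal-wide deamidation target
    peptides) are matched and reported but never drive an assignment.
    """

    taxon: str
    series: str
    mono_mz: float
    diagnostic: bool = True

    def __post_init__(self) -> None:
        if not self.series:
            raise MarkerFormatError("marker series label must be non-empty")
        if not _MASS_LO <= self.mono_mz <= _MASS_HI:
            raise MarkerFormatError(
                f"marker mass {self.mono_mz} outside ({_MASS_LO}, {_MASS_HI})"
            )


@dataclass
class MarkerDatabase:
    """Marker peptides plus named ambiguity groups.

    ``ambiguity_groups`` maps a group label to its member labels; members may
    themselves be group labels and are expanded recursively.
    """

    markers: list[MarkerPeptide]
    ambiguity_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, float]] = set()
        for m in self.markers:
            key = (m.taxon, m.series, m.mono_mz)
            if key in seen:
                raise MarkerFormatError(f"duplicate marker {key}")
            seen.add(key)

    @property
    def taxa(self) -> set[str]:
        return {m.taxon for m in self.markers}

    def known_labels(self) -> set[str]:
        labels = set(self.taxa) | set(self.ambiguity_groups)
        for members in self.ambiguity_groups.values():
            labels.update(members)
        return labels

    def expand(self, label: str) -> frozenset[str]:
        """All leaf taxa reachable from a label (the label itself if a leaf)."""
        out: set[str] = set()
        stack, visited = [label], set()
        while stack:
            cur = stack.pop()
            if cur in visited:
                continue
            visited.add(cur)
            if cur in self.ambiguity_groups:
                stack.extend(self.ambiguity_groups[cur])
            else:
                out.add(cur)
        return frozenset(out)

    def covers(self, group: str, label: str) -> bool:
        """True if `label` (leaf or group) falls within ambiguity group `group`."""
        return self.expand(label) <= self.expand(group)

    def smallest_group_covering(self, labels) -> str | None:
        """The registered group with the fewest leaf taxa covering all labels."""
        best: tuple[int, str] | None = None
        for name in self.ambiguity_groups:
            if all(self.covers(name, lb) for lb in labels):
                size = len(self.expand(name))
                if best is None or (size, name) < best:
                    best = (size, name)
        return best[1] if best else None

    def groups_containing(self, label: str) -> list[str]:
        """Registered groups covering a label, smallest first."""
        hits = [g for g in self.ambiguity_groups if self.covers(g, label)]
        return sorted(hits, key=lambda g: (len(self.expand(g)), g))

    def markers_for(self, taxon: str, include_shared: bool = True) -> list[MarkerPeptide]:
        """All markers expected in a spectrum of `taxon`.

        Includes the taxon's own rows and, when ``include_shared`` is set,
        rows registered at any group level covering the taxon (family-wide,
        order-wide and mammal-wide peptides).
        """
        out = [m for m in self.markers if m.taxon == taxon]
        if include_shared:
            for m in self.markers:
                if m.taxon != taxon and m.taxon in self.ambiguity_groups and self.covers(
                    m.taxon, taxon
                ):
                    out.append(m)
        return sorted(out, key=lambda m: m.mono_mz)


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MarkerFormatError(f"{path}: missing column(s) {missing}")
    return df


def load_markers(markers_path, groups_path=None) -> MarkerDatabase:
    """Load a marker TSV (taxon, series, mono_mz, diagnostic) and optional
    groups TSV (group_name, member_taxon) into a validated MarkerDatabase.
    """
    df = _read_table(markers_path, ["taxon", "series", "mono_mz", "diagnostic"])
    markers = []
    for i, row in enumerate(df.itertuples(), start=2):  # 1-based incl. header
        try:
            markers.append(
                MarkerPeptide(
                    taxon=str(row.taxon),
                    series=str(row.series),
                    mono_mz=float(row.mono_mz),
                    diagnostic=bool(int(row.diagnostic)),
                )
            )
        except (MarkerFormatError, ValueError) as exc:
            raise MarkerFormatError(f"{markers_path} row {i}: {exc}") from exc
    groups: dict[str, tuple[str, ...]] = {}
    if groups_path is not None:
        gdf = _read_table(groups_path, ["group_name", "member_taxon"])
        for name, sub in gdf.groupby("group_name", sort=False):
            groups[str(name)] = tuple(str(t) for t in sub["member_taxon"])
    return MarkerDatabase(markers=markers, ambiguity_groups=groups)


def candidates_for_peak(
    db: MarkerDatabase, mz: float, tol: float = DEFAULT_MATCH_TOL
) -> set[tuple[str, str]]:
    """All ``(taxon, series)`` whose marker mass lies within ``tol`` of ``mz``."""
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    return {(m.taxon, m.series) for m in db.markers if abs(m.mono_mz - mz) <= tol}


def example_database() -> MarkerDatabase:
    """The illustrative marker/group tables shipped with the package."""
    data = resources.files("zooms_screen").joinpath("data")
    with resources.as_file(data.joinpath("markers_example.tsv")) as mp, resources.as_file(
        data.joinpath("groups_example.tsv")
    ) as gp:
        return load_markers(mp, gp)
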