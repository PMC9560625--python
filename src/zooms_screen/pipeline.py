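"""End-to-end screening orchestration: spectra → taxa → %Gln → site tables.

A single :class:`RunConfig` drives the full analysis: replicate spectra are
read and averaged, processed to monoisotopic peak lists, matched against the
marker database, %Gln is fitted for the target peptides, and per-site
summaries are written.  Individual failing samples are logged and skipped —
screening reports undetermined samples rather than aborting — and a run log
records every parameter actually used.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deamidation import (
    DEFAULT_TARGETS,
    TargetPeptide,
    aggregate_site_stats,
    fit_gln_fraction,
    results_to_frame,
)
from .identify import (
    DEFAULT_MIN_DIAGNOSTIC,
    assignments_to_frame,
    identify_peaklist,
    success_rate,
)
from .marker_db import DEFAULT_MATCH_TOL, MarkerDatabase, load_markers
from .preprocess import PreprocessConfig, estimate_noise, process_spectrum
from .screening_summary import (
    integrate_zooms_nisp,
    load_bone_records,
    tally_counts,
)
from .spectra_io import (
    DEFAULT_GRID_STEP,
    ReplicateSet,
    average_replicates,
    read_spectrum,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_REPLICATE_RE = re.compile(r"^(?P<sample>.+?)[_-]rep(?P<idx>\d+)$")
_SPECTRUM_SUFFIXES = {".txt", ".csv", ".xy", ".mzml"}


@dataclass
class RunConfig:
    """All paths and parameters of one pipeline run."""

    spectra_dir: str
    markers_tsv: str
    out_dir: str
    groups_tsv: str | None = None
    bones_csv: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    grid_step: float = DEFAULT_GRID_STEP
    match_tol: float = DEFAULT_MATCH_TOL
    min_diagnostic: int = DEFAULT_MIN_DIAGNOSTIC
    deamidation_tol: float = 0.2
    deamidation_min_sn: float = 3.5
    targets: tuple[TargetPeptide, ...] = DEFAULT_TARGETS
    extraction_protocol: str = "acid_demineralised"

    def __post_init__(self) -> None:
        for attr in ("spectra_dir", "markers_tsv"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        targets = tuple(
            TargetPeptide(**t) for t in raw.pop("targets", [])
        ) or DEFAULT_TARGETS
        return cls(preprocess=pre, targets=targets, **raw)


def _collect_replicates(spectra_dir: Path) -> dict[str, list[Path]]:
    groups: dict[str, list[Path]] = {}
    for path in sorted(spectra_dir.iterdir()):
        if path.suffix.lower() not in _SPECTRUM_SUFFIXES:
            continue
        m = _REPLICATE_RE.match(path.stem)
        sample = m.group("sample") if m else path.stem
        groups.setdefault(sample, []).append(path)
    return groups


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full screening analysis and write the output bundle.

    Writes assignments.csv, deamidation.csv, site_deamidation.csv,
    site_summary.csv, combined_nisp.csv (when bone records are supplied)
    and run_log.txt under ``cfg.out_dir``.  Returns the in-memory results.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = load_markers(cfg.markers_tsv, cfg.groups_tsv)
    records = load_bone_records(cfg.bones_csv) if cfg.bones_csv else []
    site_of = {r.specimen_id: r.site for r in records}

    groups = _collect_replicates(Path(cfg.spectra_dir))
    if not groups:
        logger.warning("no spectra found in %s", cfg.spectra_dir)

    assignments = []
    deam_results = []
    failed: list[str] = []
    for sample_id, paths in groups.items():
        try:
            spectra = [
                read_spectrum(p, sample_id=sample_id, replicate_index=i + 1)
                for i, p in enumerate(paths)
            ]
            rs = ReplicateSet(sample_id=sample_id, spectra=spectra)
            averaged = average_replicates(rs, cfg.grid_step)
            noise = estimate_noise(averaged, cfg.preprocess.noise_window)
            corrected, peaklist = process_spectrum(averaged, cfg.preprocess)
            assignments.append(
                identify_peaklist(peaklist, db, cfg.match_tol, cfg.min_diagnostic)
            )
            for target in cfg.targets:
                # S/N gating against the raw-profile noise level at the peptide
                noise_at = float(np.interp(target.mono_mz, averaged.mz, noise))
                deam_results.append(
                    fit_gln_fraction(
                        corrected,
                        target,
                        tol=cfg.deamidation_tol,
                        min_sn=cfg.deamidation_min_sn,
                        noise=noise_at,
                        sample_id=sample_id,
                    )
                )
        except Exception as exc:  # skip-and-log per sample
            logger.error("sample %s failed: %s", sample_id, exc)
            failed.append(sample_id)

    a_df = assignments_to_frame(assignments)
    a_df.to_csv(out / "assignments.csv", index=False)
    d_df = results_to_frame(deam_results)
    d_df.to_csv(out / "deamidation.csv", index=False)
    site_deam = aggregate_site_stats(deam_results, site_of) if deam_results else pd.DataFrame()
    site_deam.to_csv(out / "site_deamidation.csv", index=False)

    summaries = tally_counts(records) if records else {}
    tested_by_site: dict[str, int] = {}
    det_by_site: dict[str, int] = {}
    for a in assignments:
        site = site_of.get(a.sample_id, "")
        tested_by_site[site] = tested_by_site.get(site, 0) + 1
        if a.determined:
            det_by_site[site] = det_by_site.get(site, 0) + 1
    summary_rows = []
    for site, summary in sorted(summaries.items()):
        tested = tested_by_site.get(site, 0)
        det = det_by_site.get(site, 0)
        summary.zooms_tested = tested
        summary.zooms_determined = det
        summary.zooms_success_pct = success_rate(det, tested) if tested else None
        summary_rows.append(
            {
                "site": site,
                "total_nr": summary.total_nr,
                "total_nisp": summary.total_nisp,
                "determinate_pct": summary.determinate_pct,
                "zooms_tested": tested,
                "zooms_determined": det,
                "zooms_success_pct": summary.zooms_success_pct,
            }
        )
    pd.DataFrame(
        summary_rows,
        columns=[
            "site", "total_nr", "total_nisp", "determinate_pct",
            "zooms_tested", "zooms_determined", "zooms_success_pct",
        ],
    ).to_csv(out / "site_summary.csv", index=False)

    combined = None
    if records:
        combined = integrate_zooms_nisp(records, assignments)
        combined.to_csv(out / "combined_nisp.csv", index=False)

    n_tested = len(assignments)
    n_det = sum(a.determined for a in assignments)
    overall_rate = success_rate(n_det, n_tested) if n_tested else None

    with open(out / "run_log.txt", "w") as log:
        log.write("zooms-screen run log\n")
        for key, value in dataclasses.asdict(cfg).items():
            log.write(f"{key} = {value!r}\n")
        log.write(f"samples_tested = {n_tested}\n")
        log.write(f"samples_determined = {n_det}\n")
        log.write(f"success_rate_pct = {overall_rate}\n")
        log.write(f"samples_failed = {failed!r}\n")

    return {
        "assignments": assignments,
        "deamidation": deam_results,
        "site_deamidation": site_deam,
        "site_summaries": summaries,
        "combined_nisp": combined,
        "success_rate": overall_rate,
        "failed_samples": failed,
    }
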