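"""Glutamine deamidation (%Gln) by two-component isotope-envelope deconvolution.

Deamidation converts a glutamine side-chain amide to a carboxylate, adding
+0.98402 Da (O - N - H on monoisotopic masses).  In a MALDI spectrum the
native and deamidated forms of a target peptide therefore overlap: the
deamidated envelope sits ~0.016 Th below the native +1 isotope positions.
The observed envelope around a target peptide (defaults: the collagen
peptides at m/z 1105.6 and 1706.7) is modelled as

    observed = c * [alpha * E0 + (1 - alpha) * E1]

where E0 is the theoretical isotope envelope at the native positions, E1 the
same envelope displaced by +0.98402 Th, and alpha in [0, 1] is the fraction
of undeamidated glutamine (%Gln; 1 = intact, 0 = fully deamidated).  The two
non-negative amplitudes are estimated by NNLS, which makes alpha exactly
invariant to intensity scaling.

Theoretical envelopes come from an averagine-style elemental composition
scaled to the peptide mass (a stored composition can override it), expanded
by convolving the NIST isotopic-abundance vectors of each element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass
from scipy.optimize import nnls

from .preprocess import ISOTOPE_SPACING, PeakList
from .spectra_io import ParameterError, Spectrum

__all__ = [
    "DEAMIDATION_SHIFT",
    "deamidation_mass_shift",
    "averagine_composition",
    "isotope_envelope",
    "TargetPeptide",
    "DEFAULT_TARGETS",
    "DeamidationResult",
    "fit_gln_fraction",
    "aggregate_site_stats",
    "results_to_frame",
]


def deamidation_mass_shift() -> float:
    """Mass added by one deamidation event, from NIST monoisotopic masses.

    The side-chain amide (-NH2) becomes a carboxylate (-OH): the elemental
    change is +O -N -H, i.e. 15.99491 - 14.00307 - 1.00783 = +0.98402 Da.
    """
    nm = _pt_mass.nist_mass
    return nm["O"][16][0] - nm["N"][14][0] - nm["H"][1][0]


DEAMIDATION_SHIFT = deamidation_mass_shift()

#: Averagine model: average elemental composition per 111.1254 Da of peptide.
_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_MASS = 111.1254

_MASS_LO, _MASS_HI = 700.0, 3500.0


def averagine_composition(mass: float) -> dict[str, int]:
    """Integer elemental composition of an averagine peptide of given mass."""
    if not _MASS_LO < mass < _MASS_HI:
        raise ParameterError(f"peptide mass {mass} outside ({_MASS_LO}, {_MASS_HI})")
    scale = mass / _AVERAGINE_MASS
    comp = {el: max(0, int(round(n * scale))) for el, n in _AVERAGINE.items()}
    comp["C"] = max(1, comp["C"])
    comp["H"] = max(1, comp["H"])
    return comp


def _element_abundances(element: str) -> np.ndarray:
    """Isotopic abundance vector of an element, indexed by neutron offset."""
    data = _pt_mass.nist_mass[element]
    isotopes = sorted(k for k in data if k != 0 and data[k][1] > 0)
    lightest = isotopes[0]
    vec = np.zeros(isotopes[-1] - lightest + 1)
    for a in isotopes:
        vec[a - lightest] = data[a][1]
    return vec


def isotope_envelope(
    composition: dict[str, int] | None = None,
    mass: float | None = None,
    k: int = 5,
) -> np.ndarray:
    """First ``k`` aggregated isotope abundances of a peptide, summing to 1.

    The distribution is the convolution of each element's isotopic-abundance
    vector repeated per atom count (exponentiation by squaring, truncated to
    the first ``k`` nucleon offsets).  When only a mass is given, an
    averagine composition scaled to that mass is used.
    """
    if composition is None:
        if mass is None:
            raise ParameterError("provide a composition or a mass")
        composition = averagine_composition(mass)

    def conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.convolve(a, b)[:k]

    result = np.array([1.0])
    for element, count in composition.items():
        if count <= 0:
            continue
        base = _element_abundances(element)[:k]
        # exponentiation by squaring of the convolution power base**count
        power, n = base, count
        acc = None
        while n:
            if n & 1:
                acc = power if acc is None else conv(acc, power)
            n >>= 1
            if n:
                power = conv(power, power)
        result = conv(result, acc)
    if result.size < k:
        result = np.pad(result, (0, k - result.size))
    total = result.sum()
    if total <= 0:
        raise ParameterError("degenerate isotope envelope")
    return result / total


@dataclass(frozen=True)
class TargetPeptide:
    """A deamidation target peptide identified by its monoisotopic m/z.

    ``composition`` may store the true elemental formula; otherwise the
    envelope falls back to the averagine model at ``mono_mz``.
    """

    name: str
    mono_mz: float
    n_gln_sites: int = 1
    k: int = 5
    composition: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ParameterError("at least 4 isotope positions are required")
        if self.n_gln_sites < 1:
            raise ParameterError("n_gln_sites must be >= 1")

    def envelope(self) -> np.ndarray:
        comp = dict(self.composition) if self.composition else None
        return isotope_envelope(composition=comp, mass=self.mono_mz, k=self.k)


#: The two collagen peptides routinely used for %Gln screening.
DEFAULT_TARGETS = (
    TargetPeptide("P1105", 1105.6),
    TargetPeptide("P1706", 1706.7),
)


@dataclass
class DeamidationResult:
    """%Gln estimate for one sample and one target peptide.

    ``gln_fraction`` is NaN when the fit was not usable (monoisotopic signal
    below the S/N floor or no intensity at the required positions).
    """

    sample_id: str
    peptide: str
    gln_fraction: float
    fit_rss: float
    usable: bool

    def __post_init__(self) -> None:
        if self.usable and not 0.0 <= self.gln_fraction <= 1.0:
            raise ParameterError("gln_fraction must lie in [0, 1]")


def _observed_from_spectrum(
    s: Spectrum, positions: np.ndarray, tol: float
) -> np.ndarray:
    obs = np.zeros(positions.size)
    for j, pos in enumerate(positions):
        sel = (s.mz >= pos - tol) & (s.mz <= pos + tol)
        if np.any(sel):
            obs[j] = float(s.intensity[sel].max())
    return obs


def _observed_from_peaklist(
    pl: PeakList, positions: np.ndarray, tol: float
) -> tuple[np.ndarray, float]:
    """Envelope intensities from a deisotoped peak list, plus mono S/N."""
    obs = np.zeros(positions.size)
    mono_sn = 0.0
    points: list[tuple[float, float]] = []
    for p in pl.peaks:
        if abs(p.mz - positions[0]) <= tol and p.envelope:
            points = list(p.envelope)
            mono_sn = p.sn
            break
    else:  # fall back to all peaks, flattening isotope envelopes
        for p in pl.peaks:
            points.extend(p.envelope if p.envelope else [(p.mz, p.intensity)])
        for p in pl.peaks:
            # a fully deamidated cluster starts one position up
            if abs(p.mz - positions[0]) <= tol or abs(p.mz - positions[1]) <= tol:
                mono_sn = max(mono_sn, p.sn)
    for j, pos in enumerate(positions):
        vals = [i for mz, i in points if abs(mz - pos) <= tol]
        if vals:
            obs[j] = max(vals)
    return obs, mono_sn


def fit_gln_fraction(
    source: "Spectrum | PeakList | np.ndarray",
    peptide: TargetPeptide,
    tol: float = 0.2,
    min_sn: float = 3.5,
    noise: float | None = None,
    sample_id: str | None = None,
) -> DeamidationResult:
    """Estimate %Gln for one target peptide by NNLS envelope deconvolution.

    ``source`` may be a profile spectrum, a deisotoped peak list, or a raw
    vector of ``k + 1`` already-extracted envelope intensities.  From a
    spectrum or peak list, observed intensities are read at
    ``mono_mz + j * 1.00235`` for ``j = 0..k`` (one extra position captures
    the +0.98402-shifted component).  The native envelope E0 and its shifted copy E1 are fitted
    with non-negative amplitudes (a, b); ``gln_fraction = a / (a + b)``.

    The result is flagged unusable when the monoisotopic position has S/N
    below ``min_sn`` (peak-list S/N, or intensity over ``noise`` — a robust
    whole-spectrum noise scale estimated when not given) or when no signal is
    found at any required position.
    """
    k = peptide.k
    positions = peptide.mono_mz + ISOTOPE_SPACING * np.arange(k + 1)
    if sample_id is None:
        sample_id = getattr(source, "sample_id", "")

    if isinstance(source, np.ndarray):
        if source.size != k + 1:
            raise ParameterError(f"observed vector must have length {k + 1}")
        obs = np.clip(source.astype(float), 0.0, None)
        if not np.any(obs > 0):
            return DeamidationResult(sample_id, peptide.name, math.nan, math.nan, False)
        mono_sn = math.inf if noise is None else float(obs[np.argmax(obs > 0)]) / noise
    elif isinstance(source, Spectrum):
        obs = _observed_from_spectrum(source, positions, tol)
        if not np.any(obs > 0):
            return DeamidationResult(sample_id, peptide.name, math.nan, math.nan, False)
        if noise is None:
            med = np.median(source.intensity)
            noise = 1.4826 * float(np.median(np.abs(source.intensity - med)))
        # S/N of the cluster's monoisotopic peak: the first occupied position
        # (position 1 for a fully deamidated sample, whose native mono is absent)
        mono = float(obs[np.argmax(obs > 0)])
        mono_sn = mono / noise if noise > 0 else math.inf
    else:
        obs, mono_sn = _observed_from_peaklist(source, positions, tol)

    if not np.any(obs > 0) or mono_sn < min_sn:
        return DeamidationResult(sample_id, peptide.name, math.nan, math.nan, False)

    env = peptide.envelope()
    e0 = np.concatenate([env, [0.0]])
    e1 = np.concatenate([[0.0], env])
    design = np.column_stack([e0, e1])
    coef, _ = nnls(design, obs)
    a, b = float(coef[0]), float(coef[1])
    if a + b <= 0:
        return DeamidationResult(sample_id, peptide.name, math.nan, math.nan, False)
    alpha = min(1.0, max(0.0, a / (a + b)))
    rss = float(np.sum((obs - design @ coef) ** 2))
    return DeamidationResult(sample_id, peptide.name, alpha, rss, True)


def results_to_frame(results: list[DeamidationResult]) -> pd.DataFrame:
    """Tabulate per-sample results for export (deamidation.csv)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "peptide": [r.peptide for r in results],
            "gln_fraction": [r.gln_fraction for r in results],
            "fit_rss": [r.fit_rss for r in results],
            "usable": [r.usable for r in results],
        }
    )


def aggregate_site_stats(
    results: list[DeamidationResult],
    site_of: dict[str, str],
) -> pd.DataFrame:
    """Per-site, per-peptide n / mean / median / 2 SE of usable %Gln values.

    ``two_se`` is twice the standard error ``sd / sqrt(n)`` (sample sd,
    ddof=1; zero when n = 1).  Groups with no usable result are omitted with
    a warning.  Values are reported rounded to 2 decimals.
    """
    import warnings

    rows = []
    df = results_to_frame(results)
    df["site"] = [site_of.get(s, "") for s in df["sample_id"]]
    for (site, peptide), sub in df.groupby(["site", "peptide"], sort=True):
        vals = sub.loc[sub["usable"], "gln_fraction"].to_numpy()
        if vals.size == 0:
            warnings.warn(f"no usable deamidation results for {site}/{peptide}")
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {
                "site": site,
                "peptide": peptide,
                "n": int(vals.size),
                "mean": round(float(np.mean(vals)), 2),
                "median": round(float(np.median(vals)), 2),
                "two_se": round(2.0 * sd / math.sqrt(vals.size), 2),
            }
        )
    return pd.DataFrame(rows, columns=["site", "peptide", "n", "mean", "median", "two_se"])
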