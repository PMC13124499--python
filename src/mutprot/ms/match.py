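"""Fragment matching, PSM scoring and spectral similarity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masses import TheoreticalFragment, peptide_mass, precursor_mz, theoretical_fragments
from .spectra import Spectrum

FRAGMENT_TOL_DA = 0.6
PRECURSOR_TOL_PPM = 10.0

#: exponential-decay theoretical intensity ladder by fragment index
_LADDER_DECAY = 0.08


@dataclass(frozen=True)
class FragmentMatch:
    series: str
    index: int
    charge: int
    theoretical_mz: float
    observed_mz: float
    observed_intensity: float
    error_da: float


def ladder_intensity(index: int) -> float:
    """Theoretical relative intensity of the fragment at ladder ``index``."""
    return float(np.exp(-_LADDER_DECAY * index))


def match_fragments(
    theoretical: list[TheoreticalFragment],
    spectrum: Spectrum,
    fragment_tol: float = FRAGMENT_TOL_DA,
) -> list[FragmentMatch]:
    """Greedy nearest-peak matching within +/- fragment_tol.

    Each observed peak is used at most once; candidate pairs are taken in
    order of increasing |error|, ties broken toward the more intense peak.
    """
    if len(spectrum) == 0 or not theoretical:
        return []
    mz = spectrum.mz
    inten = spectrum.intensity
    candidates = []
    for t in theoretical:
        lo = np.searchsorted(mz, t.mz - fragment_tol, side="left")
        hi = np.searchsorted(mz, t.mz + fragment_tol, side="right")
        for j in range(lo, hi):
            candidates.append((abs(mz[j] - t.mz), -inten[j], j, t))
    candidates.sort(key=lambda c: (c[0], c[1]))
    used_peaks: set[int] = set()
    used_frags: set[int] = set()
    matches = []
    for err, _neg_int, j, t in candidates:
        if j in used_peaks or id(t) in used_frags:
            continue
        used_peaks.add(j)
        used_frags.add(id(t))
        matches.append(
            FragmentMatch(
                series=t.series,
                index=t.index,
                charge=t.charge,
                theoretical_mz=t.mz,
                observed_mz=float(mz[j]),
                observed_intensity=float(inten[j]),
                error_da=float(mz[j] - t.mz),
            )
        )
    matches.sort(key=lambda m: (m.series, m.index, m.charge))
    return matches


def precursor_within_tol(
    spectrum: Spectrum,
    neutral_mass: float,
    tol_ppm: float = PRECURSOR_TOL_PPM,
) -> bool:
    theo = precursor_mz(neutral_mass, spectrum.charge)
    return abs(spectrum.precursor_mz - theo) / theo * 1e6 <= tol_ppm


def score_psm(
    sequence: str,
    spectrum: Spectrum,
    variable_mods: tuple[tuple[int, float], ...] = (),
    fragment_charges: tuple[int, ...] = (1,),
    fragment_tol: float = FRAGMENT_TOL_DA,
) -> tuple[float, list[FragmentMatch]]:
    """Matched-ion count plus sqrt-intensity cosine against the ladder model.

    A perfect singly-charged self-spectrum of a length-n peptide scores
    2(n-1) + 1: all fragments matched, cosine exactly 1.
    """
    theo = theoretical_fragments(sequence, fragment_charges, variable_mods)
    matches = match_fragments(theo, spectrum, fragment_tol)
    if not matches:
        return 0.0, []
    pred = np.array([ladder_intensity(m.index) for m in matches])
    obs = np.sqrt(np.array([m.observed_intensity for m in matches]))
    denom = np.linalg.norm(pred) * np.linalg.norm(obs)
    cosine = float(pred @ obs / denom) if denom > 0 else 0.0
    return len(matches) + cosine, matches


def spectral_similarity(
    spec_a: Spectrum,
    spec_b: Spectrum,
    bin_width: float = FRAGMENT_TOL_DA,
) -> tuple[float, bool]:
    """Cosine of sqrt-transformed, binned intensity vectors; symmetric.

    Returns ``(similarity, ok)``; an empty spectrum yields (0.0, False).
    """
    if len(spec_a) == 0 or len(spec_b) == 0:
        return 0.0, False

    def binned(spec: Spectrum) -> dict[int, float]:
        out: dict[int, float] = {}
        for mz, inten in zip(spec.mz, spec.intensity):
            b = int(np.floor(mz / bin_width))
            out[b] = out.get(b, 0.0) + inten
        return out

    a, b = binned(spec_a), binned(spec_b)
    keys = sorted(set(a) | set(b))
    va = np.sqrt([a.get(k, 0.0) for k in keys])
    vb = np.sqrt([b.get(k, 0.0) for k in keys])
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    if denom == 0:
        return 0.0, False
    return float(np.clip(va @ vb / denom, 0.0, 1.0)), True


def shift_y_ions(spectrum: Spectrum, sequence: str, delta: float,
                 fragment_tol: float = FRAGMENT_TOL_DA,
                 current_shift: float = 0.0) -> Spectrum:
    """Shift peaks matching y-ions of ``sequence`` by ``delta``.

    ``current_shift`` is the C-terminal label shift already present in the
    spectrum (used to locate heavy y-ions before moving them)."""
    theo = [
        t for t in theoretical_fragments(sequence, cterm_shift=current_shift)
        if t.series == "y"
    ]
    matches = match_fragments(theo, spectrum, fragment_tol)
    shifted_idx = set()
    mz = spectrum.mz.copy()
    for m in matches:
        j = int(np.argmin(np.abs(spectrum.mz - m.observed_mz)))
        if j not in shifted_idx:
            mz[j] += delta / m.charge
            shifted_idx.add(j)
    return Spectrum(
        spectrum_id=spectrum.spectrum_id + "_yshift",
        precursor_mz=spectrum.precursor_mz,
        charge=spectrum.charge,
        mz=mz,
        intensity=spectrum.intensity.copy(),
    )
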