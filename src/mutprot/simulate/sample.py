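"""Compose a full synthetic MS sample: mutant-peptide spectra, reference
background spectra and unmatched noise spectra, with spectrum-level truth."""

from __future__ import annotations

import numpy as np

from ..ms.digest import digest
from ..ms.search import enumerate_mutant_peptides
from ..ms.spectra import Spectrum
from .spectra import simulate_spectrum


def simulate_sample_spectra(
    entries,
    reference: list[tuple[str, str]],
    config,
    rng: np.random.Generator | None = None,
) -> tuple[list[Spectrum], dict[str, str]]:
    """Returns (spectra, truth) with truth mapping spectrum id -> expected
    peptide sequence ("" for unmatched noise spectra)."""
    rng = rng if rng is not None else config.rng("spectra")
    z = config.spectrum_charge
    spectra: list[Spectrum] = []
    truth: dict[str, str] = {}

    for entry in entries:
        peptides = [
            p for p in enumerate_mutant_peptides(entry)
            if p.missed_cleavages == 0 and "C" not in p.sequence
        ] or enumerate_mutant_peptides(entry)
        if not peptides:
            continue
        pep = min(peptides, key=lambda p: (p.missed_cleavages, abs(len(p) - 14)))
        for rep in range(config.mutant_spectrum_replicates):
            sid = f"mut|{entry.entry_id}|{pep.sequence}|r{rep + 1}"
            spectra.append(simulate_spectrum(pep.sequence, z, config, rng, sid))
            truth[sid] = pep.sequence

    background: list[str] = []
    for acc, seq in reference:
        background.extend(
            p.sequence for p in digest(seq, max_missed=0)
            if "C" not in p.sequence and 8 <= len(p) <= 20
        )
    background = sorted(set(background))
    if background and config.n_background_spectra > 0:
        idx = rng.choice(len(background),
                         size=min(config.n_background_spectra, len(background)),
                         replace=False)
        for i in sorted(idx):
            pep = background[i]
            sid = f"bg|{pep}"
            spectra.append(simulate_spectrum(pep, z, config, rng, sid))
            truth[sid] = pep

    for k in range(config.n_unmatched_spectra):
        n_peaks = int(rng.integers(10, 30))
        sid = f"noise|{k + 1}"
        spectra.append(
            Spectrum(
                spectrum_id=sid,
                precursor_mz=float(rng.uniform(400, 1200)),
                charge=z,
                mz=np.sort(rng.uniform(150, 1500, size=n_peaks)),
                intensity=rng.uniform(0, 0.05 * config.intensity_scale**2,
                                      size=n_peaks),
            )
        )
        truth[sid] = ""
    return spectra, truth
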