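"""MS/MS spectrum simulation from theoretical b/y ladders.

Fragment peaks follow an exponential-decay intensity ladder with
multiplicative lognormal noise; per-fragment dropout, additive noise peaks
and bounded m/z jitter complete the noise model. In the noiseless limit the
peak m/z set equals the theoretical singly-charged b/y set exactly and the
scorer's intensity cosine is exactly 1.
"""

from __future__ import annotations

import numpy as np

from ..ms.masses import peptide_mass, precursor_mz, theoretical_fragments
from ..ms.match import ladder_intensity
from ..ms.spectra import Spectrum


def simulate_spectrum(
    sequence: str,
    charge: int,
    config,
    rng: np.random.Generator | None = None,
    spectrum_id: str | None = None,
    variable_mods: tuple[tuple[int, float], ...] = (),
) -> Spectrum:
    if not sequence:
        raise ValueError("empty peptide")
    if not 1 <= charge <= 5:
        raise ValueError(f"charge {charge} outside 1..5")
    rng = rng if rng is not None else config.rng("spectra")

    mzs: list[float] = []
    intensities: list[float] = []
    for frag in theoretical_fragments(sequence, (1,), variable_mods):
        if config.fragment_dropout > 0 and rng.random() < config.fragment_dropout:
            continue
        # squared ladder so the scorer's sqrt-intensity cosine is exact at 1
        inten = (config.intensity_scale * ladder_intensity(frag.index)) ** 2
        if config.intensity_cv > 0:
            sigma = float(np.sqrt(np.log(1 + config.intensity_cv**2)))
            inten *= float(rng.lognormal(-sigma**2 / 2, sigma))
        jitter = 0.0
        if config.mz_jitter_sd > 0:
            jitter = float(
                np.clip(
                    rng.normal(0.0, config.mz_jitter_sd),
                    -config.mz_jitter_bound,
                    config.mz_jitter_bound,
                )
            )
        mzs.append(frag.mz + jitter)
        intensities.append(inten)

    for _ in range(config.n_noise_peaks):
        mzs.append(float(rng.uniform(150.0, 1500.0)))
        intensities.append(float(rng.uniform(0.0, 0.05 * config.intensity_scale**2)))

    neutral = peptide_mass(sequence, variable_mods)
    return Spectrum(
        spectrum_id=spectrum_id or f"sim:{sequence}/{charge}",
        precursor_mz=precursor_mz(neutral, charge),
        charge=charge,
        mz=np.array(mzs, dtype=float),
        intensity=np.array(intensities, dtype=float),
    )
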