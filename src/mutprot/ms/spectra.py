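"""Centroided spectra and the MGF dialect used throughout.

TITLE is the spectrum id; PEPMASS and CHARGE are honored. Peaks are kept
sorted by m/z.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class Spectrum:
    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if mz.size and (np.any(mz <= 0) or np.any(inten < 0)):
            raise ValueError("m/z must be > 0 and intensities >= 0")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    def __len__(self) -> int:
        return int(self.mz.size)


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.6f} {inten:.4f}\n")
            fh.write("END IONS\n")


def read_mgf(path: str | Path) -> list[Spectrum]:
    spectra = []
    title = None
    pepmass = charge = None
    peaks: list[tuple[float, float]] = []
    in_block = False
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                in_block, title, pepmass, charge, peaks = True, None, None, None, []
            elif line == "END IONS":
                if pepmass is None or charge is None:
                    raise ValueError(f"line {line_no}: block lacks PEPMASS or CHARGE")
                arr = np.array(peaks, dtype=float).reshape(-1, 2)
                spectra.append(
                    Spectrum(
                        spectrum_id=title or f"scan_{len(spectra) + 1}",
                        precursor_mz=pepmass,
                        charge=charge,
                        mz=arr[:, 0],
                        intensity=arr[:, 1],
                    )
                )
                in_block = False
            elif in_block:
                if line.startswith("TITLE="):
                    title = line[6:]
                elif line.startswith("PEPMASS="):
                    pepmass = float(line[8:].split()[0])
                elif line.startswith("CHARGE="):
                    charge = int(line[7:].rstrip("+-"))
                elif "=" not in line:
                    cols = line.split()
                    peaks.append((float(cols[0]), float(cols[1])))
    return spectra
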