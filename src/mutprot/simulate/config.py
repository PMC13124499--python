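"""Simulation configuration with partitioned random streams."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    pass


#: fixed stream ids so adding a generator never perturbs another
_STREAMS = {"sequences": 11, "variants": 23, "spectra": 37, "chromatograms": 53}


@dataclass
class SimulationConfig:
    seed: int = 0

    # reference set
    n_proteins: int = 20
    min_protein_len: int = 60
    max_protein_len: int = 400

    # planted variants
    n_missense: int = 8
    n_frameshift: int = 2
    n_negatives_per_clause: int = 1
    vaf_min: float = 0.15
    vaf_max: float = 0.6
    depth_mean: float = 100.0
    normal_error_rate: float = 0.002

    # spectrum noise model
    fragment_dropout: float = 0.05
    n_noise_peaks: int = 10
    mz_jitter_sd: float = 0.05
    mz_jitter_bound: float = 0.3
    intensity_scale: float = 1000.0
    intensity_cv: float = 0.2

    # search-sample composition
    n_background_spectra: int = 100
    n_unmatched_spectra: int = 5
    mutant_spectrum_replicates: int = 2
    spectrum_charge: int = 2

    # chromatogram model
    peak_rt: float = 10.0
    peak_width: float = 0.1          # Gaussian sigma, minutes
    sampling_interval: float = 0.01  # minutes
    rt_span: float = 2.0             # half-width of the sampled window
    baseline_noise_sd: float = 0.0
    response_factor: float = 1e4     # area units per fmol

    # quant
    n_transitions: int = 3
    spike_amount: float = 10.0
    transition_cv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fragment_dropout",):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {p}")
        if self.min_protein_len < 60:
            raise ConfigError("min_protein_len must be >= 60")
        if self.min_protein_len > self.max_protein_len:
            raise ConfigError("min_protein_len > max_protein_len")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if self.sampling_interval <= 0:
            raise ConfigError("sampling_interval must be > 0")
        if self.peak_width <= 0:
            raise ConfigError("peak_width must be > 0")
        if not (0 <= self.vaf_min <= self.vaf_max <= 1):
            raise ConfigError("need 0 <= vaf_min <= vaf_max <= 1")
        if self.mz_jitter_bound >= 0.6:
            raise ConfigError("mz_jitter_bound must stay inside the 0.6 Da match tolerance")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one named stream of this config."""
        if stream not in _STREAMS:
            raise ConfigError(f"unknown stream {stream!r}")
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if seed is not None:
            data["seed"] = seed
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
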