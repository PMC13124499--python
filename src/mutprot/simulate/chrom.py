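"""PRM chromatogram simulation: co-eluting Gaussian light/heavy pairs.

The true area of each trace is amount * response_factor; amplitude is set
so the analytic Gaussian integral A*s*sqrt(2*pi) equals that area.
Baseline noise is additive Gaussian, clipped non-negative.
"""

from __future__ import annotations

import numpy as np

from ..prm import ChromTrace


def simulate_chromatogram(
    analyte_amount: float,
    spike_amount: float,
    config,
    rng: np.random.Generator | None = None,
    analyte_id: str = "analyte",
    transition_id: str = "y6",
) -> tuple[ChromTrace, ChromTrace]:
    if analyte_amount < 0 or spike_amount < 0:
        raise ValueError("amounts must be >= 0")
    rng = rng if rng is not None else config.rng("chromatograms")
    t = np.arange(
        config.peak_rt - config.rt_span,
        config.peak_rt + config.rt_span + config.sampling_interval / 2,
        config.sampling_interval,
    )

    def trace(amount: float, channel: str) -> ChromTrace:
        area = amount * config.response_factor
        amplitude = area / (config.peak_width * np.sqrt(2 * np.pi))
        y = amplitude * np.exp(-((t - config.peak_rt) ** 2) / (2 * config.peak_width**2))
        if config.baseline_noise_sd > 0:
            y = y + rng.normal(0.0, config.baseline_noise_sd, size=t.size)
        return ChromTrace(
            analyte_id=analyte_id,
            channel=channel,
            transition_id=transition_id,
            rt=t,
            intensity=np.clip(y, 0.0, None),
        )

    return trace(analyte_amount, "light"), trace(spike_amount, "heavy")


def simulate_longitudinal(
    pre_amount: float,
    post_fold_change: float,
    timepoints: list[str],
    config,
    rng: np.random.Generator | None = None,
    analyte_id: str = "analyte",
) -> tuple[dict[tuple[str, str], tuple[ChromTrace, ChromTrace]], dict[str, float]]:
    """Light/heavy pairs per (timepoint, transition) plus true amounts.

    The first timepoint is presurgical at ``pre_amount``; later points are
    ``pre_amount * post_fold_change``. Transition-level lognormal noise at
    ``config.transition_cv`` perturbs each transition's effective amount.
    """
    if not timepoints:
        raise ValueError("empty timepoint list")
    if config.n_transitions < 2:
        raise ValueError("need >= 2 transitions")
    rng = rng if rng is not None else config.rng("chromatograms")
    truth: dict[str, float] = {}
    traces: dict[tuple[str, str], tuple[ChromTrace, ChromTrace]] = {}
    sigma = (
        float(np.sqrt(np.log(1 + config.transition_cv**2)))
        if config.transition_cv > 0 else 0.0
    )
    for i, tp in enumerate(timepoints):
        true_amount = pre_amount if i == 0 else pre_amount * post_fold_change
        truth[tp] = true_amount
        for k in range(config.n_transitions):
            amount = true_amount
            if sigma > 0:
                amount *= float(rng.lognormal(-sigma**2 / 2, sigma))
            transition = f"t{k + 1}"
            traces[(tp, transition)] = simulate_chromatogram(
                amount, config.spike_amount, config, rng,
                analyte_id=analyte_id, transition_id=transition,
            )
    return traces, truth
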