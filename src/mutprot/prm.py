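"""PRM quantification: peak detection, AUC integration, absolute amounts,
longitudinal summaries and the paired pre/post test.

The heavy (spiked standard) channel anchors retention time; the amount is
spike_amount * AUC_light / AUC_heavy.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

RT_TOL_MIN = 0.2
SNR_THRESHOLD = 3.0
BOUNDARY_FRACTION = 0.05


class TraceError(ValueError):
    """Bad chromatogram trace or integration parameters."""


@dataclass(frozen=True)
class ChromTrace:
    analyte_id: str
    channel: str      # "light" | "heavy"
    transition_id: str
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if rt.shape != inten.shape:
            raise TraceError("rt and intensity arrays differ in length")
        if rt.size >= 2 and np.any(np.diff(rt) <= 0):
            raise TraceError("retention times must be strictly increasing")
        if np.any(inten < 0):
            raise TraceError("intensities must be >= 0")
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class PeakIntegration:
    apex_time: float
    left_time: float
    right_time: float
    area: float
    detected: bool
    apex_intensity: float = 0.0
    snr: float = 0.0


def _moving_median3(x: np.ndarray) -> np.ndarray:
    if x.size < 3:
        return x.copy()
    out = x.copy()
    stacked = np.stack([x[:-2], x[1:-1], x[2:]])
    out[1:-1] = np.median(stacked, axis=0)
    return out


def detect_peak(
    trace: ChromTrace,
    rt_window: tuple[float, float],
    snr_threshold: float = SNR_THRESHOLD,
    boundary_fraction: float = BOUNDARY_FRACTION,
    anchor_rt: float | None = None,
) -> PeakIntegration:
    """Locate and bound the chromatographic peak inside ``rt_window``.

    Apex is the maximum of the median-baseline-subtracted signal; with
    ``anchor_rt`` set (light channel anchored to the heavy apex), the local
    maximum nearest the anchor wins instead of the global one. Boundaries
    are where the 3-point-median-smoothed signal falls below
    ``boundary_fraction`` of the apex. Detection requires apex
    signal-to-baseline-noise >= ``snr_threshold``.
    """
    lo, hi = rt_window
    if lo >= hi:
        raise TraceError(f"inverted window {rt_window}")
    if lo > trace.rt[-1] or hi < trace.rt[0]:
        raise TraceError(f"window {rt_window} outside trace range "
                         f"({trace.rt[0]}, {trace.rt[-1]})")
    mask = (trace.rt >= lo) & (trace.rt <= hi)
    if mask.sum() < 5:
        raise TraceError("fewer than 5 samples in window")
    rt = trace.rt[mask]
    raw = trace.intensity[mask]
    baseline = float(np.median(raw))
    signal = raw - baseline
    smooth = _moving_median3(signal)

    if anchor_rt is None:
        apex_idx = int(np.argmax(signal))
    else:
        # local maxima of the smoothed signal; nearest to anchor wins
        candidates = [
            i for i in range(1, len(smooth) - 1)
            if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]
            and signal[i] > 0
        ]
        apex_idx = (
            min(candidates, key=lambda i: (abs(rt[i] - anchor_rt), -signal[i]))
            if candidates else int(np.argmax(signal))
        )
    apex_signal = float(signal[apex_idx])
    noise = float(np.median(np.abs(raw - baseline))) or 1e-12
    snr = apex_signal / noise
    detected = snr >= snr_threshold and apex_signal > 0
    if not detected:
        return PeakIntegration(
            apex_time=float(rt[apex_idx]), left_time=float(rt[apex_idx]),
            right_time=float(rt[apex_idx]), area=0.0, detected=False,
            apex_intensity=apex_signal, snr=snr,
        )
    cut = boundary_fraction * apex_signal
    left = apex_idx
    while left > 0 and smooth[left - 1] > cut:
        left -= 1
    right = apex_idx
    while right < len(smooth) - 1 and smooth[right + 1] > cut:
        right += 1
    integ = integrate(trace, (float(rt[left]), float(rt[right])))
    return PeakIntegration(
        apex_time=float(rt[apex_idx]),
        left_time=float(rt[left]),
        right_time=float(rt[right]),
        area=integ,
        detected=True,
        apex_intensity=apex_signal,
        snr=snr,
    )


def integrate(trace: ChromTrace, boundaries: tuple[float, float]) -> float:
    """Trapezoidal AUC over [left, right], linear baseline subtracted.

    The baseline runs between the boundary intensities; the net signal is
    floored at 0 before integration.
    """
    left, right = boundaries
    if left >= right:
        raise TraceError(f"inverted boundaries {boundaries}")
    if left < trace.rt[0] or right > trace.rt[-1]:
        raise TraceError(f"boundaries {boundaries} outside trace")
    mask = (trace.rt >= left) & (trace.rt <= right)
    rt = trace.rt[mask]
    y = trace.intensity[mask]
    if rt.size < 2:
        return 0.0
    baseline = y[0] + (y[-1] - y[0]) * (rt - rt[0]) / (rt[-1] - rt[0])
    net = np.maximum(y - baseline, 0.0)
    return float(np.trapezoid(net, rt))


def absolute_amount(auc_light: float, auc_heavy: float, spike_amount: float) -> float:
    if auc_heavy <= 0:
        raise TraceError("heavy standard not detected (AUC <= 0)")
    if auc_light < 0 or spike_amount < 0:
        raise TraceError("negative AUC or spike amount")
    return spike_amount * auc_light / auc_heavy


def co_elution_check(
    light: PeakIntegration, heavy: PeakIntegration, rt_tol: float = RT_TOL_MIN
) -> tuple[bool, str]:
    """Inclusive apex-agreement check; undetected peaks fail with a reason."""
    if not light.detected:
        return False, "light peak not detected"
    if not heavy.detected:
        return False, "heavy peak not detected"
    delta = abs(light.apex_time - heavy.apex_time)
    if delta <= rt_tol:
        return True, ""
    return False, f"apex offset {delta:.3f} min exceeds tolerance {rt_tol}"


@dataclass(frozen=True)
class QuantResult:
    analyte_id: str
    timepoint: str
    amounts: tuple[float, ...]        # per detected transition, fmol
    mean_amount: float | None
    se_amount: float | None
    spike_amount: float
    co_elution_ok: bool
    n_detected: int
    n_undetected: int


def quantify_pair(
    light: ChromTrace,
    heavy: ChromTrace,
    spike_amount: float,
    rt_window: tuple[float, float] | None = None,
    snr_threshold: float = SNR_THRESHOLD,
    rt_tol: float = RT_TOL_MIN,
) -> tuple[float | None, bool]:
    """Amount (fmol) for one light/heavy transition pair, or None if the
    heavy standard is undetected."""
    window = rt_window or (float(heavy.rt[0]), float(heavy.rt[-1]))
    heavy_peak = detect_peak(heavy, window, snr_threshold)
    if not heavy_peak.detected:
        return None, False
    light_peak = detect_peak(light, window, snr_threshold,
                             anchor_rt=heavy_peak.apex_time)
    if not light_peak.detected:
        # no endogenous signal: a valid zero measurement
        return 0.0, False
    ok, _ = co_elution_check(light_peak, heavy_peak, rt_tol)
    return absolute_amount(light_peak.area, heavy_peak.area, spike_amount), ok


def summarize_timepoints(
    per_transition: dict[tuple[str, str], list[float | None]],
    spike_amount: float,
    co_elution: dict[tuple[str, str], bool] | None = None,
) -> list[QuantResult]:
    """Mean +/- SE over detected transitions per (analyte, timepoint).

    ``per_transition`` maps (analyte, timepoint) -> per-transition amounts,
    None marking an undetected transition.
    """
    results = []
    for (analyte, timepoint), amounts in sorted(per_transition.items()):
        detected = [a for a in amounts if a is not None]
        n_undet = len(amounts) - len(detected)
        if not detected:
            results.append(QuantResult(analyte, timepoint, (), None, None,
                                       spike_amount, False, 0, n_undet))
            continue
        mean = float(np.mean(detected))
        se = (
            float(np.std(detected, ddof=1) / math.sqrt(len(detected)))
            if len(detected) >= 2 else None
        )
        results.append(
            QuantResult(
                analyte_id=analyte,
                timepoint=timepoint,
                amounts=tuple(detected),
                mean_amount=mean,
                se_amount=se,
                spike_amount=spike_amount,
                co_elution_ok=(co_elution or {}).get((analyte, timepoint), True),
                n_detected=len(detected),
                n_undetected=n_undet,
            )
        )
    return results


def paired_pre_post_test(
    pre: dict[str, float],
    post: dict[str, float],
    log_transform: bool = False,
) -> tuple[float | None, float | None, bool]:
    """Classical paired t-test on per-analyte (pre - post) differences.

    Returns ``(t, p, degenerate)``; all-zero-variance differences give
    ``(None, None, True)`` rather than a number.
    """
    if set(pre) != set(post):
        raise ValueError(f"unpaired analyte ids: {set(pre) ^ set(post)}")
    if len(pre) < 2:
        raise ValueError("need >= 2 paired analytes")
    keys = sorted(pre)
    a = np.array([pre[k] for k in keys], dtype=float)
    b = np.array([post[k] for k in keys], dtype=float)
    if log_transform:
        a, b = np.log(a), np.log(b)
    if np.allclose(a - b, (a - b)[0]) and np.std(a - b) == 0:
        return None, None, True
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), False


def write_quant_report(results: list[QuantResult], tsv_path: str | Path,
                       json_path: str | Path | None = None) -> None:
    lines = ["analyte\ttimepoint\tn_detected\tn_undetected\tmean_fmol\tse_fmol\t"
             "spike_fmol\tco_elution_ok"]
    for r in results:
        mean = "" if r.mean_amount is None else f"{r.mean_amount:.4f}"
        se = "" if r.se_amount is None else f"{r.se_amount:.4f}"
        lines.append(f"{r.analyte_id}\t{r.timepoint}\t{r.n_detected}\t"
                     f"{r.n_undetected}\t{mean}\t{se}\t{r.spike_amount}\t"
                     f"{int(r.co_elution_ok)}")
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    if json_path is not None:
        import json

        Path(json_path).write_text(json.dumps(
            [r.__dict__ for r in results], indent=2, default=list))


def plot_quant_series(results: list[QuantResult], image_path: str | Path) -> None:
    """Mean +/- SE vs timepoint per analyte (longitudinal summary figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    analytes = sorted({r.analyte_id for r in results})
    fig, ax = plt.subplots(figsize=(6, 4))
    for analyte in analytes:
        rs = [r for r in results if r.analyte_id == analyte and r.mean_amount is not None]
        x = range(len(rs))
        means = [r.mean_amount for r in rs]
        ses = [r.se_amount or 0.0 for r in rs]
        ax.errorbar(x, means, yerr=ses, marker="o", capsize=3, label=analyte)
        ax.set_xticks(list(x), [r.timepoint for r in rs], rotation=30)
    ax.set_ylabel("amount (fmol)")
    ax.set_xlabel("timepoint")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(image_path, dpi=120)
    plt.close(fig)


# --- chromatogram CSV dialect ---------------------------------------------

CSV_COLUMNS = ["analyte", "channel", "transition", "rt", "intensity"]


def write_chromatograms(traces: list[ChromTrace], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for t in traces:
            for rt, inten in zip(t.rt, t.intensity):
                writer.writerow([t.analyte_id, t.channel, t.transition_id,
                                 f"{rt:.6f}", f"{inten:.6f}"])


def read_chromatograms(path: str | Path) -> list[ChromTrace]:
    groups: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    order: list[tuple[str, str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise TraceError(f"missing column(s) {sorted(missing)}")
        for row in reader:
            key = (row["analyte"], row["channel"], row["transition"])
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append((float(row["rt"]), float(row["intensity"])))
    traces = []
    for key in order:
        pts = sorted(groups[key])
        traces.append(
            ChromTrace(
                analyte_id=key[0], channel=key[1], transition_id=key[2],
                rt=np.array([p[0] for p in pts]),
                intensity=np.array([p[1] for p in pts]),
            )
        )
    return traces
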