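"""pHluorin fusion-event detection.

An ROI trace transient counts as a DCV fusion event when it appears
suddenly (rise to peak within a couple of frames) and its peak rises at
least twice the noise SD above the local baseline.  Noise is estimated
robustly from the baseline epoch; events during the NH4+ dequench are
excluded; events before the first stimulation train are labeled
spontaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .io import EpochTimeline, MovieStack, RoiBox

__all__ = [
    "FluorescenceTrace",
    "FusionEvent",
    "DetectionParams",
    "extract_trace",
    "detect_events",
    "auto_candidate_rois",
    "cumulative_histogram",
    "events_to_table",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection thresholds.

    ``k_sd`` is the peak threshold in noise SDs (the 2xSD rule);
    ``rise_frames_max`` operationalizes "suddenly appeared";
    ``candidate_k_sd`` thresholds the smoothed temporal-difference stack
    used only for unattended ROI placement.
    """

    k_sd: float = 2.0
    rise_frames_max: int = 2
    refractory_s: float = 2.0
    baseline_window_frames: int = 20
    candidate_k_sd: float = 6.0
    candidate_smooth_sigma_px: float = 1.0
    candidate_dedup_px: float = 3.0

    def __post_init__(self) -> None:
        if self.k_sd <= 0 or self.rise_frames_max < 1:
            raise ValueError("k_sd must be > 0 and rise_frames_max >= 1")


@dataclass(frozen=True)
class FluorescenceTrace:
    roi: RoiBox
    values: np.ndarray
    frame_rate_hz: float
    baseline_mean: float
    noise_sd: float
    noise_floored: bool = False  # True when MAD was 0 and the unit floor applied


@dataclass(frozen=True)
class FusionEvent:
    roi_id: int
    t_onset_s: float
    t_peak_s: float
    peak_dF: float
    duration_s: float
    snr: float
    epoch_label: str = "stim"


def extract_trace(movie: MovieStack, roi: RoiBox,
                  timeline: EpochTimeline) -> FluorescenceTrace:
    """Mean-intensity trace of the ROI box, with robust baseline noise.

    ``noise_sd`` is 1.4826 x MAD of the baseline-epoch samples (robust to
    occasional spontaneous events); a floor of 1 camera unit is applied
    (and flagged) when the MAD is exactly zero, as on noiseless synthetic
    movies.
    """
    if not roi.inside(movie.shape_rc):
        raise ValueError(f"ROI {roi.roi_id} at {roi.center_rc} leaves image bounds")
    sr, sc = roi.slices()
    values = movie.data[:, sr, sc].mean(axis=(1, 2))
    base_mask = timeline.frame_mask("baseline", movie.n_frames, movie.frame_rate_hz)
    if base_mask.sum() < 10:
        raise ValueError("baseline epoch absent or shorter than 10 frames; "
                         "cannot estimate noise")
    base = values[base_mask]
    baseline_mean = float(np.median(base))
    mad = float(np.median(np.abs(base - baseline_mean)))
    noise_sd = 1.4826 * mad
    floored = noise_sd == 0.0
    if floored:
        noise_sd = 1.0
    return FluorescenceTrace(roi, values, movie.frame_rate_hz,
                             baseline_mean, noise_sd, floored)


def _local_baseline(values: np.ndarray, threshold: float, window: int) -> np.ndarray:
    """Trailing-median baseline, frozen while the trace sits above threshold.

    Handles slow drift without letting an ongoing event drag the baseline up.
    """
    n = len(values)
    base = np.empty(n)
    hist: list[float] = []
    current = float(values[0])
    for k in range(n):
        base[k] = current
        if values[k] - current <= threshold:  # sub-threshold: baseline may follow
            hist.append(float(values[k]))
            if len(hist) > window:
                hist.pop(0)
            current = float(np.median(hist))
    return base


def detect_events(trace: FluorescenceTrace, timeline: EpochTimeline,
                  params: DetectionParams = DetectionParams(),
                  trigger_frames: np.ndarray | None = None) -> list[FusionEvent]:
    """Apply the sudden-appearance / 2xSD rule to one ROI trace.

    An event is reported when dF = value - local baseline crosses
    ``k_sd x noise_sd``, the trace reaches its peak within
    ``rise_frames_max`` frames of the crossing, and no event was reported
    in this ROI within ``refractory_s``.  Duration is the contiguous
    supra-threshold dwell time.  Events with onset inside the NH4 epoch
    are discarded; onsets before the first stimulation train are labeled
    ``spontaneous``.

    ``trigger_frames`` restricts reported onsets to within two frames of a
    candidate trigger.  Automated ROI placement supplies its trigger times
    here, mirroring the manual workflow where an ROI is placed around a
    seen event: without that anchor, a whole-trace scan at 2xSD would
    accept baseline noise excursions anywhere in the recording.
    """
    values = np.asarray(trace.values, dtype=float)
    dt = 1.0 / trace.frame_rate_hz
    thr = params.k_sd * trace.noise_sd
    base = _local_baseline(values, thr, params.baseline_window_frames)
    dF = values - base
    above = dF > thr

    t_first_train = timeline.t_first_train_s
    events: list[FusionEvent] = []
    last_onset_s = -np.inf
    k = 0
    n = len(values)
    while k < n:
        if not above[k]:
            k += 1
            continue
        run_start = k
        while k < n and above[k]:
            k += 1
        run = slice(run_start, k)
        peak_idx = run_start + int(np.argmax(dF[run]))
        t_onset = run_start * dt
        # sudden appearance: peak reached within rise_frames_max of crossing
        if peak_idx - run_start + 1 > params.rise_frames_max:
            continue
        if timeline.in_kind(t_onset, "nh4"):
            continue
        if trigger_frames is not None and (
                len(trigger_frames) == 0
                or np.abs(np.asarray(trigger_frames) - run_start).min() > 2):
            continue
        if t_onset - last_onset_s < params.refractory_s:
            continue
        last_onset_s = t_onset
        label = "stim"
        if t_first_train is not None and t_onset < t_first_train:
            label = "spontaneous"
        events.append(FusionEvent(
            roi_id=trace.roi.roi_id,
            t_onset_s=t_onset,
            t_peak_s=peak_idx * dt,
            peak_dF=float(dF[peak_idx]),
            duration_s=(k - run_start) * dt,
            snr=float(dF[peak_idx] / trace.noise_sd),
            epoch_label=label,
        ))
    return events


def auto_candidate_rois(movie: MovieStack, timeline: EpochTimeline,
                        params: DetectionParams = DetectionParams(),
                        return_triggers: bool = False):
    """Place candidate 3x3 ROIs at sudden brightness increases.

    The statistic is the frame-to-frame difference of the spatially
    smoothed movie; frames inside (or entering) the NH4 epoch are excluded
    so the pool dequench does not flood the detector.  Manually supplied
    ROI tables always take precedence over this helper.

    With ``return_triggers=True`` each ROI comes with the frame indices at
    which it triggered, for use as the ``trigger_frames`` anchor of
    :func:`detect_events`.
    """
    sm = ndi.gaussian_filter(movie.data, sigma=(0, params.candidate_smooth_sigma_px,
                                                params.candidate_smooth_sigma_px))
    n = movie.n_frames
    if n < 5:
        return ([], []) if return_triggers else []
    # two-frame averages either side of the step: fusion transients persist
    # over the decay, so averaging nearly halves the noise of the statistic
    after = 0.5 * (sm[2:n - 1] + sm[3:n])
    before = 0.5 * (sm[1:n - 2] + sm[0:n - 3])
    diff = after - before
    frame_of = np.arange(2, n - 1)   # index of the first brightened frame
    dt = 1.0 / movie.frame_rate_hz
    # exclude windows touching the NH4 epoch (pool dequench is not fusion)
    ok = np.ones(len(frame_of), dtype=bool)
    for off in (-2, -1, 0, 1):
        ok &= ~np.asarray(timeline.in_kind((frame_of + off) * dt, "nh4"))
    if not ok.any():
        return ([], []) if return_triggers else []
    med = np.median(diff[ok])
    sd = 1.4826 * np.median(np.abs(diff[ok] - med))
    if sd == 0.0:
        sd = 1e-6
    thr = med + params.candidate_k_sd * sd

    # spatial local maxima per frame, above threshold, outside NH4;
    # a border margin is excluded because boundary reflection in the
    # smoothing kernel inflates the local noise variance there
    maxfilt = ndi.maximum_filter(diff, size=(1, 3, 3))
    hit = (diff >= maxfilt) & (diff > thr)
    hit[~ok] = False
    m = int(np.ceil(3 * params.candidate_smooth_sigma_px))
    hit[:, :m, :] = hit[:, -m:, :] = hit[:, :, :m] = hit[:, :, -m:] = False
    cand = np.argwhere(hit)
    if len(cand) == 0:
        return ([], []) if return_triggers else []
    # deduplicate in space, keeping the strongest response; every candidate
    # point contributes its trigger frame to the ROI it merges into
    order = np.argsort(diff[tuple(cand.T)])[::-1]
    kept: list[tuple[int, int]] = []
    triggers: list[set[int]] = []
    for idx in order:
        k, r, c = cand[idx]
        for j, (r2, c2) in enumerate(kept):
            if (r - r2) ** 2 + (c - c2) ** 2 < params.candidate_dedup_px ** 2:
                triggers[j].add(int(frame_of[k]))
                break
        else:
            kept.append((int(r), int(c)))
            triggers.append({int(frame_of[k])})
    rows, cols = movie.shape_rc
    rois, roi_triggers = [], []
    order2 = np.argsort([r * cols + c for r, c in kept])
    for i, j in enumerate(order2):
        r, c = kept[j]
        r = min(max(r, 1), rows - 2)
        c = min(max(c, 1), cols - 2)
        rois.append(RoiBox((r, c), 1, roi_id=i))
        roi_triggers.append(np.array(sorted(triggers[j])))
    return (rois, roi_triggers) if return_triggers else rois


def dedup_events(events: list[FusionEvent], rois: list[RoiBox],
                 radius_px: float = 4.0, dt_max_s: float = 1.0) -> list[FusionEvent]:
    """Merge events reported by neighboring ROIs for the same transient.

    Two events are duplicates when their ROI centers lie within
    ``radius_px`` and their onsets within ``dt_max_s``; the higher-SNR
    event is kept.  Needed when automated candidate placement yields more
    than one ROI on a bright fusion site.
    """
    centers = {r.roi_id: r.center_rc for r in rois}
    kept: list[FusionEvent] = []
    for e in sorted(events, key=lambda e: -e.snr):
        r, c = centers[e.roi_id]
        dup = any(
            abs(e.t_onset_s - k.t_onset_s) <= dt_max_s
            and (r - centers[k.roi_id][0]) ** 2 + (c - centers[k.roi_id][1]) ** 2
            <= radius_px ** 2
            for k in kept)
        if not dup:
            kept.append(e)
    return sorted(kept, key=lambda e: e.t_onset_s)


def cumulative_histogram(events_per_neuron: dict[str, list[FusionEvent]],
                         t_max_s: float, bin_s: float = 1.0) -> pd.DataFrame:
    """Per-neuron cumulative event counts over time plus the across-neuron median.

    Mirrors the cumulative median histogram used to summarize fusion-event
    timing per condition.  Returns a frame indexed by bin edge time with one
    column per neuron and a ``median`` column; every column is monotone
    nondecreasing.
    """
    edges = np.arange(0.0, t_max_s + bin_s, bin_s)
    out = {}
    for neuron, events in events_per_neuron.items():
        times = np.sort([e.t_onset_s for e in events])
        out[str(neuron)] = np.searchsorted(times, edges, side="right")
    df = pd.DataFrame(out, index=pd.Index(edges, name="time_s"))
    df["median"] = df.median(axis=1) if len(out) else 0.0
    return df


def events_to_table(events_by_neuron: dict[str, list[FusionEvent]],
                    condition: str = "", experiment_id: str = "") -> pd.DataFrame:
    """Flatten detected events into the result-table schema."""
    rows = []
    for neuron, events in events_by_neuron.items():
        for e in events:
            rows.append({
                "neuron_id": neuron, "condition": condition,
                "experiment_id": experiment_id, "roi_id": e.roi_id,
                "t_onset_s": e.t_onset_s, "t_peak_s": e.t_peak_s,
                "peak_dF": e.peak_dF, "snr": e.snr,
                "duration_s": e.duration_s, "epoch_label": e.epoch_label,
            })
    cols = ["neuron_id", "condition", "experiment_id", "roi_id", "t_onset_s",
            "t_peak_s", "peak_dF", "snr", "duration_s", "epoch_label"]
    return pd.DataFrame(rows, columns=cols)
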