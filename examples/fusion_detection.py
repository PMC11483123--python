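"""Detect DCV fusion events in a simulated pHluorin movie.

Simulates a KO-like neuron (stationary quenched vesicles, fusion during
the 2x8x50 AP stimulation, NH4+ dequench at the end), places candidate
ROIs automatically, and applies the 2xSD sudden-appearance rule.
"""

from vesiclefuse.fusion import auto_candidate_rois, detect_events, extract_trace
from vesiclefuse.simulate import condition_preset, default_timeline, make_scene, render_movie

cfg = condition_preset("KO-like", seed=42)
timeline = default_timeline(cfg)
truth = make_scene(cfg, timeline)
movie = render_movie(truth, cfg, timeline)

rois, triggers = auto_candidate_rois(movie, timeline, return_triggers=True)
events = []
for roi, trig in zip(rois, triggers):
    trace = extract_trace(movie, roi, timeline)
    events.extend(detect_events(trace, timeline, trigger_frames=trig))

print(f"scheduled fusion events: {len(truth.fusion_schedule)}")
print(f"detected events:         {len(events)}")
for ev in sorted(events, key=lambda e: e.t_onset_s)[:5]:
    print(f"  onset {ev.t_onset_s:6.1f} s  peak dF {ev.peak_dF:6.1f}  "
          f"snr {ev.snr:4.1f}  duration {ev.duration_s:.1f} s")
# Each line is one vesicle fusing: onset on the movie clock, peak
# brightness jump over the local baseline, its ratio to the baseline
# noise SD (>= 2 by the detection rule), and how long it stayed bright.
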