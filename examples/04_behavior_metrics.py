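"""Behavioral quantification of a synthetic recording.

From one seeded ground-truth trace: nose speed, sleep bouts (runs of no
detectable nose movement), the lethargus interval (longest non-pumping
run), the sleep summary over their intersection, the rank correlation
between frame-subtraction activity and nose speed, and an event-aligned
average of activity around lethargus onset across several worms.
"""

import numpy as np

from wormsleep import (
    event_aligned_mean,
    lethargus_interval,
    nose_speed,
    rank_correlation,
    sleep_bouts_from_speed,
    sleep_summary,
    standard_fixture,
)

behavior, trace = standard_fixture(seed=3)
dt = trace.frame_interval_s

speeds = nose_speed(behavior.nose_positions_um(), dt)
bouts = sleep_bouts_from_speed(speeds, epsilon_um_s=0.5, frame_interval_s=dt)
lethargus = lethargus_interval(behavior.pumping, dt)
summary = sleep_summary(bouts, lethargus)

print(f"mean nose speed:   {speeds.mean():.1f} um/s")
print(f"lethargus:         [{lethargus.start_s:.0f} s, {lethargus.end_s:.0f} s)")
print(f"sleep bouts:       {summary['bout_count']} inside lethargus")
print(f"total sleep:       {summary['total_sleep_s']:.0f} s "
      f"({100 * summary['sleep_fraction']:.0f}% of lethargus)")

n = min(len(speeds), len(trace.values))
rho = rank_correlation(trace.values[:n], speeds[:n])
print(f"Spearman rho (activity vs nose speed): {rho:.3f}")

traces, events = [], []
for seed in range(5):
    bt, tr = standard_fixture(seed=seed)
    traces.append(tr.values)
    onset = lethargus_interval(bt.pumping, dt).start_s
    events.append(int(onset / dt))
offsets, mean, sem = event_aligned_mean(traces, events, window_before=60,
                                        window_after=60)
at_onset = np.flatnonzero(offsets == 0)[0]
print(
    f"\nevent-aligned activity (5 worms, lethargus onset):\n"
    f"  60 s before onset: {mean[0]:.0f} +/- {sem[0]:.0f}\n"
    f"  at onset:          {mean[at_onset]:.0f} +/- {sem[at_onset]:.0f}\n"
    f"  60 s after onset:  {mean[-1]:.0f} +/- {sem[-1]:.0f}\n"
    "Activity collapses at the transition into quiescence-rich lethargus."
)
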