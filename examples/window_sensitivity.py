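"""How sensitive are pairing and abundance to the temporal matching window?

The 10-s window is a processing convention, not a measured quantity. This
example reconciles the same simulated survey (with realistic clumpy
exponential flock spacing and a 2-s rear recording lag) under windows from
2 to 20 s. A too-narrow window breaks true pairs apart (inflating NoMatch
and N_hat); widening it beyond the true lag spread mostly adds spurious
cross-flock pairs. Pair count is monotone non-decreasing in the window by
construction.
"""

import dataclasses

import pandas as pd

from doublecount import (
    SimConfig,
    capture_summary,
    chapman_estimate,
    reconcile_records,
    simulate_survey,
)

cfg = SimConfig.independent_detection(
    0.9, 0.7, n_flocks=3000, seed=5, spacing_dist="exponential"
)
cfg = dataclasses.replace(
    cfg, rear=dataclasses.replace(cfg.rear, time_lag_mean_s=2.0, time_lag_sd_s=1.0)
)
data = simulate_survey(cfg)

rows = []
for window in (2, 4, 6, 8, 10, 14, 20):
    events = reconcile_records(data.front + data.rear, data.taxonomy, window_s=window)
    paired = sum(ev.is_paired for ev in events)
    (cs,) = capture_summary(events, lambda ev: "all")
    rows.append({
        "window_s": window,
        "paired": paired,
        "nomatch_share": 1 - paired / len(events),
        "N_hat": chapman_estimate(cs).N_hat,
    })

table = pd.DataFrame(rows)
print(table.round(3).to_string(index=False))
print(f"\ntrue flock count: {cfg.n_flocks}; rear lag ~N(+2 s, 1 s). "
      "N_hat stabilizes once the window covers the lag distribution.")
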