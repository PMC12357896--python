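"""Obfuscate the wearable event stream directly (longitudinal sifting).

Whole days of events are exchanged between subjects with similar daily
energy profiles, start times are jittered within the day, and kcal values
receive multiplicative noise.  Event counts and durations are preserved;
the per-subject outcome decorrelates as the level grows.
"""

import pandas as pd
from scipy import stats

from twinsift import CohortSpec, generate_cohort, apply_exclusions, dslo

bundle = generate_cohort(CohortSpec(n_subjects=400, seed=5))
clean, _ = apply_exclusions(bundle)
events = clean.events
print(f"{len(events)} events from {events['subject_id'].nunique()} subjects")


def per_subject_outcome(ev):
    dur = (ev["end"] - ev["start"]).dt.total_seconds()
    agg = ev.assign(dur=dur).groupby("subject_id").agg(
        sum_aeb=("kcal", "sum"), sum_seconds=("dur", "sum"))
    return agg["sum_aeb"] / (agg["sum_seconds"] / 86400.0)


base = per_subject_outcome(events)
for level in ("small", "medium", "large"):
    twin_events = dslo(events, level, seed=1)
    twin = per_subject_outcome(twin_events)
    joined = pd.concat([base.rename("orig"), twin.rename("twin")], axis=1).dropna()
    rho = stats.spearmanr(joined["orig"], joined["twin"]).statistic
    print(f"{level:>8}: {len(twin_events)} events (count preserved), "
          f"per-subject outcome rank correlation vs original = {rho:.3f}")
# rank correlation near 1 means per-subject outcomes are barely perturbed;
# larger levels push it down, protecting activity patterns
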