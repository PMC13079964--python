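"""Generate one synthetic participant and score their week of sleep.

Builds a 7-day, 1-minute-epoch actigraphy record from a 'Good sleeper'
profile, runs epoch-level sleep/wake scoring and night summarization, and
prints the per-night parameters next to the generator's ground truth.
"""

import numpy as np

from actisleep import scoring, synth

rec, truth = synth.generate_participant(
    synth.DEFAULT_SQW_PROFILES[0], n_days=7, seed=1, participant_id="demo"
)
print(f"record: {len(rec)} one-minute epochs starting {rec.start_time}")

nights, day_types = scoring.summarize_record(rec)
gt = {n.night_index: n for n in truth.nights}
print(f"\n{'night':>5} {'scored dur':>10} {'true dur':>9} {'scored eff':>10} {'true eff':>9}")
for n in nights:
    g = gt[n.night_index]
    print(f"{n.night_index:>5} {n.duration:>10.0f} {g.duration:>9.0f} "
          f"{n.efficiency:>10.1f} {g.efficiency:>9.1f}")

sqw = scoring.sleep_qual_week(nights)
cons = scoring.sleep_cons(nights, day_types)
print(f"\nSleepQualWeek = {sqw.score:.0f}  ->  class {sqw.class_id} ({sqw.class_name})")
print(f"SleepCons     = {cons.score:.1f}  ->  class {cons.class_id} ({cons.class_name})")
print("\nDurations are minutes asleep per night; efficiency is the percentage")
print("of the rest interval spent asleep. The weekly score sums four 0-3")
print("subscores (lower = better); the consistency score weighs night-to-night")
print("variability in minutes (lower = more regular).")
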