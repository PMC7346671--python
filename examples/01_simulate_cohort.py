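"""Generate a small synthetic accelerometer cohort and inspect it.

The generator emulates a hip-worn accelerometer study of older women:
15-s vector-magnitude count streams over 7 calendar days, daily sleep logs
with missing entries, baseline covariates, and an annual physical-
functioning panel, all with known latent structure.
"""

from sbpatterns import default_config, generate_cohort

cfg = default_config(n_participants=25, seed=7)
series, sleep_logs, covariates, pf_panel, truth = generate_cohort(cfg)

print(f"participants: {len(series)}")
print(f"epochs per participant: {series[0].n_epochs} "
      f"({series[0].n_days} days x 5760 15-s epochs)")
blank = ((sleep_logs["in_bed"] == "") | (sleep_logs["out_of_bed"] == "")).mean()
print(f"sleep-log records: {len(sleep_logs)} ({blank:.0%} with a missing field)")
print(f"PF panel rows: {len(pf_panel)} over {cfg.pf_model.n_years} annual visits")
print("latent pattern counts:",
      truth.pattern_by_participant.value_counts().sort_index().to_dict())
print("day archetype counts:",
      truth.day_archetype["archetype"].value_counts().sort_index().to_dict())

# Each participant's days are drawn mostly from one archetype; the pattern
# label is the recovery target for the two-phase clustering pipeline.
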