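# Example configuration: a reduced 10-participant, 2-week deployment with
# a stricter score-only trigger.  Any omitted field keeps its default.
cohort:
  n_participants: 10
  work_start: "09:00"
  work_end: "17:00"
engine:
  trigger_mode: score
  daily_nudge_cap: 4
weeks: 2
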