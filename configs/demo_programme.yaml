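# Demonstration training programme: four preparations of rest, pre-training,
# progressive and race-fit training, run from an untrained 2-year-old state.
#
# SYNTHETIC RECONSTRUCTION: phase durations and workout volumes are a
# plausible Australian-style programme shape chosen for demonstration; they
# are not a surveyed programme.  Weekly fast workouts replace that day's
# routine canter (fast-work days are exclusive).
#
# Run with:
#   osteofatigue programme --config configs/demo_programme.yaml --out-dir results/programme

preset: fitted
initial: {fBM: 0.61, D: 0.0}
phases:
  - {kind: rest, duration: 49}
  - kind: pre-training
    duration: 28
    workouts:
      - {speed: 5.0, distance: 2000, per: day}
  - kind: progressive
    duration: 63
    workouts:
      - {speed: 7.5, distance: 2400, per: day}
      - {speed: 13.8, distance: 800, per: week, weekday: 1}
      - {speed: 16.0, distance: 400, per: week, weekday: 4}
  - kind: race-fit
    duration: 56
    workouts:
      - {speed: 7.5, distance: 2000, per: day}
      - {speed: 13.8, distance: 1000, per: week, weekday: 1}
      - {speed: 16.0, distance: 800, per: week, weekday: 4}
  - {kind: rest, duration: 49}
  - kind: pre-training
    duration: 28
    workouts:
      - {speed: 5.0, distance: 2000, per: day}
  - kind: progressive
    duration: 63
    workouts:
      - {speed: 7.5, distance: 2400, per: day}
      - {speed: 13.8, distance: 800, per: week, weekday: 1}
      - {speed: 16.0, distance: 400, per: week, weekday: 4}
  - kind: race-fit
    duration: 56
    workouts:
      - {speed: 7.5, distance: 2000, per: day}
      - {speed: 13.8, distance: 1000, per: week, weekday: 1}
      - {speed: 16.0, distance: 800, per: week, weekday: 4}
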