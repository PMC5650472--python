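# Session file schema (version 1)

A session is one JSON document.  All times are in ms relative to the
lead-limb flexor (Br) burst onset of the step over the obstacle
(negative = before); distances in cm; speeds in m/s.  Unknown extra
fields are preserved on read.

```jsonc
{
  "schema_version": 1,
  "seed": 42,                    // root seed of the generating run (null for real data)
  "meets_inclusion": true,       // >=5 unobstructed steps, >=3 per acceleration condition
  "design": {                    // trial-count plan
    "n_matched_per_lead": 10,
    "n_vd_per_lead": 5,
    "n_accel_per_condition": 3,
    "accel_conditions": ["1L", "2L", "1R", "2R"],
    "n_unobstructed": 20
  },
  "base_config": {               // task kinematics (TaskConfig fields)
    "treadmill_speed": 0.45,
    "obstacle_speed": 0.45,
    "obstacle_spacing": 3.0,
    "obstacle_diameter": 10.0,
    "visibility_distance": 2.0,
    "acceleration": null,        // or AccelerationProfile fields
    "step_period": 500.0,
    "drift": null                // or {"amplitude_cm": ..., "correlation_ms": ...}
  },
  "cells": [                     // CellSpec per cell; the ground-truth block
    {
      "cell_id": "dtc000",
      "category": "DTC",         // DTC | TTC | BOTH | NONE | STEP_RELATED
      "trigger_dtc_cm": 31.2,    // null unless the category uses it
      "trigger_ttc_ms": null,
      "onset_jitter_sd": 150.0,
      "baseline_rate": 10.0,
      "peak_rate": 60.0,
      "peak_time": 0.0,
      "decay_time": 300.0,
      "tonic_vd_gain": 1.0
    }
  ],
  "trials": {                    // cell_id -> list of trials
    "dtc000": [
      {
        "trial_id": "dtc000-000-matched-L",
        "cell_id": "dtc000",
        "task": "matched",       // matched | visual_dissociation | accel_1L..2R | unobstructed
        "lead_limb": "left",
        "trial_seed": 123456789, // child seed; regenerates gait/gap/envelope/spikes
        "initial_dtc": 200.0,    // gap-trace starting distance
        "gait_events": [[-5500.0, "right", "Br_onset"], ...],
        "lead_limb_gait": "left",
        "spike_times_ms": [-4382.11, ...],   // sorted, >= 1 ms apart
        "truth_onset_ms": -662.0  // injected envelope onset; null/absent for real data
      }
    ]
  }
}
```

Notes:

- Gap traces are **not** stored sample-by-sample.  For obstacle trials
  they are regenerated on read from `task`, `gait_events`, `initial_dtc`
  and the gap sub-stream of `trial_seed` (the second of four fixed
  `spawn` children), bit-identically.  A trial without `trial_seed`
  cannot be read unless it is an unobstructed step.
- Omitting every `truth_onset_ms` yields a valid session; recovery
  metrics are simply unavailable (this is how real recordings would be
  stored).
- A missing required field (`trial_id`, `cell_id`, `task`, `lead_limb`,
  `spike_times_ms`, `gait_events`) raises a schema error naming the
  trial.
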