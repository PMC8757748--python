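"""Extract the 320 wavelet-grid features plus the scalar candidates.

Each normalized beat is transformed with a complex Morlet CWT and pooled
into a 20 (time) x 8 (frequency) grid of mean |coefficient| cells; the
ECG and pulse grids concatenate to 320 features, followed by PTT, 1/PTT,
heart rate, demographic-derived scalars and the SDPPG a-e amplitudes.
"""

import numpy as np

from cufflessbp import (CohortConfig, assemble_features, cwt_grid,
                        generate_participant, synthesize_record)
from cufflessbp.prep import summarize_window

profile = generate_participant(CohortConfig(), rng_seed=7)
record = synthesize_record(profile, 135.0, 88.0, 72.0, 12.0, rng_seed=9)
summary, ecg_beat, pulse_beat = summarize_window(record)

grid = cwt_grid(pulse_beat)
print("pulse grid shape:", grid.cells.shape, "(20 time x 8 frequency bands)")
hot_t, hot_f = np.unravel_index(np.argmax(grid.cells), grid.cells.shape)
print(f"most energetic cell: time band {hot_t + 1}, frequency band {hot_f + 1}"
      " (1-indexed from the start of each normalized axis)")

fv = assemble_features(summary, ecg_beat, pulse_beat,
                       {"age": profile.age, "weight": profile.weight,
                        "height": profile.height})
print("feature vector length:", len(fv), "(320 wavelet + 14 scalars)")
print("ptt_ms %.1f  inv_ptt %.5f  sqrt_weight %.2f  bmi %.1f"
      % (fv["ptt_ms"], fv["inv_ptt"], fv["sqrt_weight"], fv["bmi"]))
print("SDPPG a=%.4f b=%.4f" % (fv["sdppg_a"], fv["sdppg_b"]))
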