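"""Prepare one raw record: fiducials, PTT, heart rate, averaged beats.

The 10-s window is reduced to one normalized beat per waveform (unit
duration, unit amplitude); PTT is the median R-peak-to-pulse-upstroke
delay over the window's beats.
"""

from cufflessbp import CohortConfig, generate_participant, synthesize_record
from cufflessbp.prep import summarize_window

profile = generate_participant(CohortConfig(), rng_seed=42)
record = synthesize_record(profile, sbp=120.0, dbp=80.0, hr=65.0,
                           duration=12.0, rng_seed=3)

summary, ecg_beat, pulse_beat = summarize_window(record)
print(f"R peaks detected : {len(summary.r_peak_indices)}")
print(f"T peaks detected : {len(summary.t_peak_indices)}")
print(f"pulse onsets     : {len(summary.pulse_onset_indices)}")
print(f"heart rate       : {summary.heart_rate:.1f} bpm")
print(f"PTT (estimated)  : {summary.ptt:.1f} ms")
print(f"PTT (embedded)   : {record.truth['ptt_ms']:.1f} ms")
print(f"quality flags    : {summary.quality_flags or 'none'}")
print(f"averaged ECG beat: {len(ecg_beat.samples)} samples on [0,1) s, "
      f"range [{ecg_beat.samples.min():.0f}, {ecg_beat.samples.max():.0f}], "
      f"{ecg_beat.n_beats_averaged} beats averaged")
# The estimated PTT should sit within ~2 ms of the embedded delay.
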