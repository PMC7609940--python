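#!/usr/bin/env python
"""Generate one subject's stimulation paradigm, EEG recording and
behavioral session; write them to results/sim/.

Finding to check here: the paradigm contains 360 + 360 subthreshold
trials in 12 blocks with 4 suprathreshold pulses per block, and the
behavioral blocks hold 5 x 32 target trials (16 paired) plus 16 catch
trials.
"""

from pathlib import Path

from mupulse.behavior_sim import simulate_behavior_session
from mupulse.events import make_event_sequence
from mupulse.io import write_recording
from mupulse.params import SubjectParams
from mupulse.simulate import simulate_eeg

OUT = Path("results/sim")
OUT.mkdir(parents=True, exist_ok=True)

events = make_event_sequence(360, 360, 4, 12, 2.0, 0.3, seed=1)
events.to_tsv(OUT / "paradigm.tsv")
counts = events.counts()
print(f"paradigm: {counts['sub_single']} singles, "
      f"{counts['sub_train']} trains, "
      f"{counts.get('supra_left', 0) + counts.get('supra_right', 0)} supra "
      f"pulses in {events.block.max() + 1} blocks "
      f"({events.end_time() / 60:.1f} min)")

# one full 32-channel subject (smaller trial counts keep this quick);
# the raw binary goes under scratch/, only text outputs under results/
RAW = Path("scratch/sim")
RAW.mkdir(parents=True, exist_ok=True)
demo = make_event_sequence(60, 60, 4, 2, 2.0, 0.3, seed=2)
rec = simulate_eeg(demo, SubjectParams(), seed=2)
write_recording(rec, RAW / "subject00")
print(f"recording: {rec.n_channels} channels x {rec.duration:.0f} s "
      f"at {rec.rate:.0f} Hz -> {RAW}/subject00.dat")

session = simulate_behavior_session("A2", SubjectParams(), n_blocks=3,
                                    seed=3)
session.to_tsv(OUT / "behavior_A2_subject00.tsv")
n_catch = int(session.is_catch.sum())
print(f"behavior session: {len(session)} trials, {n_catch} catch "
      f"({n_catch // 3} per block), "
      f"threshold {session.threshold_50:.2f} mA, "
      f"subthreshold {session.sub_intensity:.3f} mA")
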