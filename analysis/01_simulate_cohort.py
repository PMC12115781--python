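"""Simulate a synthetic cohort and write it as on-disk E4-style artifacts.

Emits, per subject, EDA.csv / HR.csv / TEMP.csv in the E4 export dialect,
the continuous stress annotation, and the generator's ground truth, under
results/cohort/.  The cohort is a scaled-down version of the study-scale
default (12 x 7200 s): 4 subjects x 300 s keeps the later model-selection
steps quick while preserving the six-segment structure.
"""

from pathlib import Path

import stresswear as sw
from stresswear import sensor_io

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 7

params = sw.GeneratorParams(n_subjects=4, session_duration=300.0, seed=SEED)
cohort = sw.generate_cohort(params)

for session, trace, truth in cohort:
    subject_dir = OUT / session.subject_id
    subject_dir.mkdir(parents=True, exist_ok=True)
    for name, rec in session.channels.items():
        sensor_io.write_channel_csv(rec, subject_dir / f"{name}.csv")
    sensor_io.write_stress_trace(trace, subject_dir / "stress.csv")
    rows = zip(truth.window_start, truth.true_class, truth.segment_id)
    (subject_dir / "ground_truth.csv").write_text(
        "window_start,true_class,segment_id\n"
        + "".join(f"{t:g},{c},{s}\n" for t, c, s in rows)
    )

total = sum(s.channels["HR"].duration for s, _, _ in cohort)
missing = {
    name: float(__import__("numpy").isnan(cohort[0][0].channels[name].samples).mean())
    for name in ("EDA", "HR", "TEMP")
}
print(f"wrote {params.n_subjects} subjects x {params.session_duration:g} s "
      f"({total:g} s total) to {OUT}")
print(f"subject 1 missing fractions (target {params.missing_rate}): "
      + ", ".join(f"{k}={v:.4f}" for k, v in missing.items()))
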