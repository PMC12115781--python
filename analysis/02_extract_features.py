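"""Read the simulated cohort back from disk, align channels and extract features.

Exercises the full ingestion path (E4 CSV readers -> 4 Hz alignment with
median imputation -> 19 window features + 30 lag features) and writes one
combined feature table to results/features.csv.
"""

from pathlib import Path

import pandas as pd

import stresswear as sw
from stresswear.features import FeatureTable
from stresswear.pipeline import sessions_to_features

ROOT = Path(__file__).resolve().parent.parent / "results"

sessions = []
for subject_dir in sorted((ROOT / "cohort").iterdir()):
    if not subject_dir.is_dir():
        continue
    channels = {
        name: sw.read_channel_csv(subject_dir / f"{name}.csv", name)
        for name in ("EDA", "HR", "TEMP")
    }
    duration = channels["HR"].duration
    boundaries = [duration * k / 6 for k in range(7)]
    sessions.append(
        sw.SessionRecording(subject_dir.name, channels, segment_boundaries=boundaries)
    )

table = sessions_to_features(sessions)
sw.write_feature_table(table, ROOT / "features.csv")

n_current = len([c for c in table.feature_columns if "_lag" not in c])
n_lag = len([c for c in table.feature_columns if "_lag" in c])
per_subject = table.frame.groupby("subject_id").size()
print(f"{len(sessions)} subjects -> {len(table)} feature rows "
      f"({n_current} current-window + {n_lag} lag columns)")
print("rows per subject:", dict(per_subject))
print(f"wrote {ROOT / 'features.csv'}")
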