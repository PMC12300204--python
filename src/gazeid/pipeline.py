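"""End-to-end assembly: recordings -> common positions -> segment samples.

This is the glue the CLI and the evaluation protocol share: it filters
NaN-contaminated stimulus positions per trial, enforces a common position
set across every (subject, session) trial, cuts the 303-sample windows and
stacks the unscaled per-segment channel matrices into a
:class:`~gazeid.evaluation.SampleSet`.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from . import segmentation as seg
from .errors import ValidationError
from .evaluation import SampleSet
from .features import raw_segment_channels
from .io import GazeRecording, StimulusSchedule


def build_sample_set(
    recordings: Mapping[tuple[str, str], GazeRecording],
    schedule: StimulusSchedule,
    x_positions: int,
) -> SampleSet:
    """Segment every trial over a common set of ``x_positions`` positions.

    ``recordings`` maps (subject_id, session_id) to one trial.  Every
    subject must appear in every session; positions contaminated by NaN in
    any trial are discarded before the first ``x_positions`` clean ones are
    kept for all trials alike.
    """
    subjects = sorted({k[0] for k in recordings})
    sessions = sorted({k[1] for k in recordings})
    missing = [(u, s) for u in subjects for s in sessions if (u, s) not in recordings]
    if missing:
        raise ValidationError(f"missing trials for {missing[:3]}...")

    per_trial_valid = {
        key: seg.filter_valid_positions(rec, schedule) for key, rec in recordings.items()
    }
    positions = seg.select_common_positions(per_trial_valid, x_positions)

    channels, labels, session_ids, pos_idx, seg_idx = [], [], [], [], []
    for label, subject in enumerate(subjects):
        for session in sessions:
            rec = recordings[(subject, session)]
            for p in positions:
                window = seg.extract_window(rec, p, schedule)
                bundle = seg.split_segments(window)
                raw = raw_segment_channels(window, bundle)
                for g in range(raw.shape[0]):
                    channels.append(raw[g])
                    labels.append(label)
                    session_ids.append(session)
                    pos_idx.append(p)
                    seg_idx.append(g)

    return SampleSet(
        channels=np.stack(channels),
        labels=np.asarray(labels, dtype=np.int64),
        session_ids=np.asarray(session_ids),
        position_index=np.asarray(pos_idx, dtype=np.int64),
        segment_index=np.asarray(seg_idx, dtype=np.int64),
        subjects=tuple(subjects),
    )
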