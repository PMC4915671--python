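"""End-to-end analysis: recordings -> cleaned harmonics -> subject components.

The cascade per trial: zero-phase 50 Hz low-pass, segmentation into
coherence cycles, per-channel amplitude artifact flagging, per-cycle joint
harmonic fits (phase-referenced to trial onset), coherent averaging of the
retained cycles into a trial-level component.  Trials and subjects are then
excluded by the 15%-of-cycles and fewer-than-three-trials rules, and the
retained trials are coherently averaged into subject-level components — the
input to the statistics layer (cycle -> trial -> subject hierarchy).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from . import preprocess as pp
from .spectral import cycle_components
from .stimulus import StimulusSpec
from .synth import HARMONICS, EEGRecording, harmonic_frequencies

__all__ = ["extract_study_components", "trial_component"]


def trial_component(
    recording: EEGRecording,
    spec: StimulusSpec,
    harmonics=HARMONICS,
    threshold: float = pp.DEFAULT_THRESHOLD_UV,
    cutoff: float = pp.DEFAULT_CUTOFF_HZ,
    artifact_rule: str = "peak_to_peak",
):
    """Process one trial; returns (re, im, n_cycles_used, n_flagged).

    ``re``/``im`` are (n_channels, n_harmonics) coherent means over the
    retained (unflagged) cycles, or NaN when every cycle is flagged.
    """
    freqs = harmonic_frequencies(spec)
    fvals = [freqs[h] for h in harmonics]
    filtered = pp.lowpass(recording, cutoff=cutoff)
    epoch = pp.segment_cycles(filtered, spec)
    flags = pp.flag_artifacts(epoch, threshold=threshold, rule=artifact_rule)
    keep = [s for s, f in zip(epoch.slices, flags) if not f]
    n_flagged = int(flags.sum())
    if not keep:
        shape = (recording.n_channels, len(harmonics))
        return np.full(shape, np.nan), np.full(shape, np.nan), 0, n_flagged
    re_c, im_c = cycle_components(
        filtered.samples, filtered.sampling_rate, keep, fvals
    )
    return re_c.mean(axis=0), im_c.mean(axis=0), len(keep), n_flagged


def extract_study_components(
    recordings: Iterable[EEGRecording | tuple],
    spec: StimulusSpec,
    harmonics=HARMONICS,
    threshold: float = pp.DEFAULT_THRESHOLD_UV,
    cycle_fraction: float = pp.DEFAULT_CYCLE_FRACTION,
    min_trials: int = pp.DEFAULT_MIN_TRIALS,
    cutoff: float = pp.DEFAULT_CUTOFF_HZ,
    artifact_rule: str = "peak_to_peak",
):
    """Run the full cascade over a stream of trial recordings.

    ``recordings`` yields EEGRecording objects (or (recording, ...) tuples,
    e.g. from :func:`flowssvep.synth.iter_study`; extra tuple entries are
    ignored).  Returns (subject_components, trial_components, report):

    - subject_components: tidy table (subject, pattern, speed, channel,
      harmonic, freq_hz, re, im, n_trials, n_cycles) over retained subjects
      and trials only;
    - trial_components: the same at trial level, for all trials, with
      n_cycles_used and n_flagged;
    - report: the :class:`~flowssvep.preprocess.ExclusionReport`.
    """
    freqs = harmonic_frequencies(spec)
    trial_rows = []
    arrays = {}
    for item in recordings:
        rec = item[0] if isinstance(item, tuple) else item
        re, im, n_used, n_flagged = trial_component(
            rec, spec, harmonics, threshold, cutoff, artifact_rule
        )
        key = (rec.subject, rec.pattern, rec.speed, rec.trial)
        arrays[key] = (re, im, n_used)
        trial_rows.append(
            dict(
                subject=rec.subject, pattern=rec.pattern, speed=rec.speed,
                trial=rec.trial, n_cycles=spec.cycles_per_trial,
                n_flagged=n_flagged, n_cycles_used=n_used,
            )
        )
    trial_table = pd.DataFrame(trial_rows)
    report = pp.apply_exclusions(
        trial_table, min_trials=min_trials, cycle_fraction=cycle_fraction
    )
    retained = report.retained_trials()

    # trial-level tidy table
    n_channels = next(iter(arrays.values()))[0].shape[0]
    channels = np.arange(1, n_channels + 1)
    tidy_trials = []
    for row in trial_table.itertuples():
        re, im, n_used = arrays[(row.subject, row.pattern, row.speed, row.trial)]
        for j, h in enumerate(harmonics):
            tidy_trials.append(
                pd.DataFrame(
                    {
                        "subject": row.subject, "pattern": row.pattern,
                        "speed": row.speed, "trial": row.trial,
                        "channel": channels, "harmonic": h,
                        "freq_hz": freqs[h], "re": re[:, j], "im": im[:, j],
                        "n_cycles_used": n_used, "n_flagged": row.n_flagged,
                    }
                )
            )
    trial_components = pd.concat(tidy_trials, ignore_index=True)

    # subject level: coherent mean over retained trials
    subj_rows = []
    for (subj, pattern, speed), g in retained.groupby(
        ["subject", "pattern", "speed"], sort=True
    ):
        stack_re, stack_im, cyc = [], [], 0
        for row in g.itertuples():
            re, im, n_used = arrays[(subj, pattern, speed, row.trial)]
            stack_re.append(re)
            stack_im.append(im)
            cyc += n_used
        re_m = np.mean(stack_re, axis=0)
        im_m = np.mean(stack_im, axis=0)
        for j, h in enumerate(harmonics):
            subj_rows.append(
                pd.DataFrame(
                    {
                        "subject": subj, "pattern": pattern, "speed": speed,
                        "channel": channels, "harmonic": h,
                        "freq_hz": freqs[h],
                        "re": re_m[:, j], "im": im_m[:, j],
                        "n_trials": len(g), "n_cycles": cyc,
                    }
                )
            )
    subject_components = (
        pd.concat(subj_rows, ignore_index=True)
        if subj_rows
        else pd.DataFrame(
            columns=["subject", "pattern", "speed", "channel", "harmonic",
                     "freq_hz", "re", "im", "n_trials", "n_cycles"]
        )
    )
    return subject_components, trial_components, report
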