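"""Condition-epoch extraction and standardization.

A full task run is sliced into per-condition series by taking each
block's stimulus-period volumes, shifted forward by a rigid hemodynamic
lag (default 2 volumes = 4 s at TR 2 s), and concatenating blocks of the
same condition in temporal order.  Epochs are then z-scored per column;
all scoring, orientation, and weight estimation downstream operate on
standardized data, so regressions carry no intercept.

Standardization uses the maximum-likelihood (ddof=0) variance so a
standardized column has residual variance exactly 1 in the BIC closed
form.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import TaskDesign
from .exceptions import DegenerateSignalError, EpochRangeError
from .simulate import RoiTimeSeries, TaskRun

DEFAULT_LAG_VOLUMES = 2


def extract_epochs(
    run: TaskRun,
    design: TaskDesign,
    lag_volumes: int = DEFAULT_LAG_VOLUMES,
    clip_final: bool = True,
) -> dict[str, RoiTimeSeries]:
    """Slice a run into per-condition stimulus epochs.

    For each block, rows ``[stim_start + lag, stop + lag)`` are taken and
    concatenated per condition, preserving temporal order.  With lag 0 the
    extracted rows over all conditions exactly partition the stimulus
    volumes of the run.

    A run that ends exactly at the last stimulus volume (the standard
    acquisition) leaves no room to shift the final block, so by default
    that one window is clipped at the end of the run and the final block
    contributes ``lag_volumes`` fewer rows.  Pass ``clip_final=False``
    to demand full windows everywhere.

    Raises
    ------
    EpochRangeError
        If a shifted window runs past the end of the run and cannot be
        clipped (any non-final block, ``clip_final=False``, or a lag so
        large the final window would be empty).
    """
    if lag_volumes < 0:
        raise ValueError("lag_volumes must be non-negative")
    n = run.series.n_timepoints
    parts: dict[str, list[pd.DataFrame]] = {}
    final = run.blocks[-1] if run.blocks else None
    for block in run.blocks:
        lo = block.stim_start + lag_volumes
        hi = block.stop + lag_volumes
        if hi > n:
            if clip_final and block is final and lo < n:
                hi = n
            else:
                raise EpochRangeError(
                    f"block window [{lo}, {hi}) exceeds run length {n} "
                    f"at lag {lag_volumes}"
                )
        parts.setdefault(block.condition, []).append(run.series.data.iloc[lo:hi])
    out = {}
    for cond in design.conditions:
        if cond not in parts:
            continue
        df = pd.concat(parts[cond], ignore_index=True)
        out[cond] = RoiTimeSeries(
            subject=run.subject, group=run.group, condition=cond, data=df
        )
    return out


def standardize(series: RoiTimeSeries) -> RoiTimeSeries:
    """Z-score every column to mean 0 and unit (ML) variance.

    Idempotent, and invariant to affine transforms of the input up to the
    sign of the scale factor.

    Raises
    ------
    DegenerateSignalError
        Naming the offending ROI if any column is constant.
    """
    x = series.values()
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # ddof=0
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        names = [series.rois[i] for i in bad]
        raise DegenerateSignalError(f"constant ROI column(s): {', '.join(names)}")
    z = (x - mu) / sd
    df = pd.DataFrame(z, columns=list(series.rois))
    return RoiTimeSeries(
        subject=series.subject,
        group=series.group,
        condition=series.condition,
        data=df,
    )
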