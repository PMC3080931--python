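"""Background filtering and probe→miRNA summarisation.

Microarrays carry many replicate probes per miRNA; a large fraction of probes
sit at or below the array's background signal and must be removed before any
group comparison.  Filtering operates at probe level — a probe is retained
when its mean intensity across all samples strictly exceeds the background
threshold — and retained probes are then collapsed to one row per miRNA by
taking, per sample, the median over that miRNA's retained probes.  The median
is robust to a single aberrant probe, which matters because probe effects are
shared across samples and would otherwise propagate into every group mean.

The default threshold mimics the common "background ≈ median signal per
array" convention: the median over arrays of each array's median intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, ProbeAnnotation


@dataclass(frozen=True)
class FilterReport:
    n_input_records: int
    n_retained_records: int
    background_threshold: float
    n_detectable_mirnas: int


def default_threshold(matrix: ExpressionMatrix) -> float:
    """Median over arrays of the per-array median signal."""
    if matrix.n_probes == 0:
        raise ValueError("empty expression matrix")
    per_array_median = matrix.values.median(axis=0)
    return float(per_array_median.median())


def filter_background(
    matrix: ExpressionMatrix,
    threshold: float,
    annotation: ProbeAnnotation | None = None,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Retain probes whose mean intensity across all samples exceeds ``threshold``.

    The inequality is strict, so a probe sitting exactly at background is
    dropped.  When ``annotation`` is given, the report also counts how many
    distinct miRNAs keep at least one probe (the "detectable" miRNAs).
    """
    if threshold <= 0:
        raise ValueError(f"background threshold must be > 0, got {threshold}")
    means = matrix.values.mean(axis=1)
    keep = means > threshold
    filtered = ExpressionMatrix(matrix.values.loc[keep], dict(matrix.groups))
    if annotation is not None:
        detectable = {annotation[p] for p in filtered.probe_ids if p in annotation}
        n_detectable = len(detectable)
    else:
        n_detectable = filtered.n_probes
    report = FilterReport(
        n_input_records=matrix.n_probes,
        n_retained_records=filtered.n_probes,
        background_threshold=float(threshold),
        n_detectable_mirnas=n_detectable,
    )
    return filtered, report


def collapse_to_mirna(matrix: ExpressionMatrix, annotation: ProbeAnnotation) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per miRNA (per-sample median).

    Every probe in ``matrix`` must be annotated; the output keeps the first-
    appearance order of miRNAs among the retained probes.
    """
    missing = [p for p in matrix.probe_ids if p not in annotation]
    if missing:
        raise KeyError(f"probe(s) without miRNA annotation: {missing[:5]}")
    mirna_index = pd.Index([annotation[p] for p in matrix.probe_ids], name="mirna_id")
    collapsed = matrix.values.groupby(mirna_index, sort=False).median()
    return ExpressionMatrix(collapsed, dict(matrix.groups))
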