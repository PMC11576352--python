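"""Per-variable box statistics and placement of individual samples.

For a chosen spectral variable the five-number summary (min, Q1, median,
Q3, max) is computed per class or over the whole cohort, and an individual
sample can be located within its group's distribution — its empirical
percentile and whether it sits inside the interquartile range.  This is the
descriptive bridge between a multivariate loading of interest and the
underlying per-sample intensities.

Quantiles use linear interpolation of order statistics (the "type 7"
convention, numpy's default) so results are reproducible across tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AnnotationTable, SpectraMatrix

__all__ = ["BoxStats", "box_stats", "locate_sample", "SamplePlacement"]

_STATS = ("min", "q1", "median", "q3", "max")


@dataclass
class BoxStats:
    """Five-number summaries per (group, variable).

    ``table`` has a (group, statistic) MultiIndex on rows and the ppm grid
    as columns; ``group_sizes`` maps group name to n.
    """

    table: pd.DataFrame
    group_sizes: dict[str, int]
    grouping: str

    def group(self, name: str) -> pd.DataFrame:
        """Statistics for one group: rows = min/q1/median/q3/max, cols = ppm."""
        return self.table.loc[name]

    def at(self, group: str, ppm: float) -> pd.Series:
        col = self.table.columns[np.argmin(np.abs(self.table.columns - ppm))]
        return self.table.loc[group][col]


def _five_numbers(values: np.ndarray) -> np.ndarray:
    qs = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0,
                     method="linear")
    return qs


def box_stats(matrix: SpectraMatrix, annotations: AnnotationTable | None = None,
              grouping: str = "whole") -> BoxStats:
    """Five-number summary of every variable, by class or whole cohort.

    ``grouping="by_class"`` requires every sample to be annotated; groups of
    one sample report all five numbers equal to that value.
    """
    if grouping not in ("whole", "by_class"):
        raise ValueError(f"unknown grouping {grouping!r}")
    groups: dict[str, list[int]] = {}
    if grouping == "whole":
        groups["all"] = list(range(matrix.n_samples))
    else:
        if annotations is None:
            raise ValueError("by_class grouping needs annotations")
        missing = [s for s in matrix.sample_ids
                   if s not in set(annotations.sample_ids)]
        if missing:
            raise ValueError(f"unannotated samples under by_class grouping: "
                             f"{missing}")
        for i, sid in enumerate(matrix.sample_ids):
            groups.setdefault(annotations.class_of(sid), []).append(i)
    frames = []
    sizes = {}
    for name in sorted(groups):
        idx = groups[name]
        sizes[name] = len(idx)
        qs = _five_numbers(matrix.X[idx])
        frames.append(pd.DataFrame(
            qs, index=pd.MultiIndex.from_product([[name], _STATS]),
            columns=matrix.ppm_grid))
    return BoxStats(table=pd.concat(frames), group_sizes=sizes,
                    grouping=grouping)


@dataclass
class SamplePlacement:
    sample_id: str
    group: str
    ppm: float                  # snapped grid position
    value: float
    percentile: float           # midrank / n, in (0, 1]
    inside_iqr: bool


def locate_sample(stats: BoxStats, matrix: SpectraMatrix,
                  annotations: AnnotationTable | None, sample_id: str,
                  ppm: float) -> SamplePlacement:
    """Place one sample's intensity at *ppm* within its group's distribution.

    The percentile is the sample's midrank (average rank among ties) divided
    by the group size, so the group maximum sits at 1.0 and the median of a
    large group near 0.5.
    """
    j = matrix.nearest_index(ppm)
    snapped = float(matrix.ppm_grid[j])
    value = float(matrix.X[matrix.index_of(sample_id), j])
    if stats.grouping == "whole":
        group = "all"
        members = list(range(matrix.n_samples))
    else:
        if annotations is None:
            raise ValueError("by_class placement needs annotations")
        group = annotations.class_of(sample_id)
        members = [i for i, s in enumerate(matrix.sample_ids)
                   if annotations.class_of(s) == group]
    if matrix.index_of(sample_id) not in members:
        raise KeyError(f"sample {sample_id!r} not in group {group!r}")
    values = matrix.X[members, j]
    n = len(values)
    less = int((values < value).sum())
    equal = int((values == value).sum())
    midrank = less + (equal + 1) / 2.0
    percentile = midrank / n
    g = stats.group(group)
    col = g.columns[np.argmin(np.abs(g.columns - snapped))]
    q1, q3 = float(g.loc["q1", col]), float(g.loc["q3", col])
    return SamplePlacement(sample_id=sample_id, group=group, ppm=snapped,
                           value=value, percentile=percentile,
                           inside_iqr=bool(q1 <= value <= q3))
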