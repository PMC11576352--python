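"""Core data containers shared by every stage of the workflow.

A single 1D spectrum is a ``Spectrum``; a cohort resampled onto one common
chemical-shift grid is a ``SpectraMatrix`` (n samples x p ppm variables);
sample class labels and clinical covariates live in an ``AnnotationTable``.
The canonical ppm orientation is descending, matching how NMR spectra are
displayed (high field to the right).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "SpectraMatrix", "AnnotationTable"]


@dataclass
class Spectrum:
    """One 1D spectrum: a ppm axis, matching intensities and free metadata."""

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D")
        if len(self.ppm) != len(self.intensity):
            raise ValueError(
                f"ppm ({len(self.ppm)}) and intensity ({len(self.intensity)}) "
                "lengths differ"
            )
        if len(self.ppm) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        d = np.diff(self.ppm)
        if np.all(d > 0):  # ascending input: store descending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d < 0):
            raise ValueError("ppm axis must be strictly monotone")

    def __len__(self) -> int:
        return len(self.ppm)


@dataclass
class SpectraMatrix:
    """n samples x p variables on a shared, strictly descending ppm grid."""

    sample_ids: list[str]
    ppm_grid: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.ppm_grid = np.asarray(self.ppm_grid, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.X.shape != (len(self.sample_ids), len(self.ppm_grid)):
            raise ValueError(
                f"X shape {self.X.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.ppm_grid)} ppm points"
            )
        if not np.all(np.diff(self.ppm_grid) < 0):
            raise ValueError("ppm_grid must be strictly descending")
        if not np.all(np.isfinite(self.X)):
            bad = [self.sample_ids[i] for i in
                   np.unique(np.nonzero(~np.isfinite(self.X))[0])]
            raise ValueError(f"non-finite intensities in samples: {bad}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def row(self, sample_id: str) -> np.ndarray:
        return self.X[self.index_of(sample_id)]

    def index_of(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def nearest_index(self, ppm: float) -> int:
        """Grid index closest to *ppm*."""
        return int(np.argmin(np.abs(self.ppm_grid - ppm)))

    def subset(self, sample_ids: list[str]) -> "SpectraMatrix":
        idx = [self.index_of(s) for s in sample_ids]
        return SpectraMatrix(list(sample_ids), self.ppm_grid.copy(),
                             self.X[idx].copy())

    def drop(self, sample_ids: list[str]) -> "SpectraMatrix":
        keep = [s for s in self.sample_ids if s not in set(sample_ids)]
        return self.subset(keep)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sample_ids,
                            columns=self.ppm_grid)


@dataclass
class AnnotationTable:
    """sample_id -> class label plus free-form string covariates."""

    table: pd.DataFrame  # index sample_id, column "class" + covariates

    def __post_init__(self) -> None:
        if "class" not in self.table.columns:
            raise ValueError("annotation table needs a 'class' column")
        if self.table.index.has_duplicates:
            dupes = sorted(self.table.index[self.table.index.duplicated()])
            raise ValueError(f"duplicate sample ids in annotations: {dupes}")
        cls = self.table["class"]
        empty = self.table.index[(cls.isna()) | (cls.astype(str) == "")]
        if len(empty):
            raise ValueError(f"empty class label for samples: {list(empty)}")
        self.table = self.table.astype(str)

    @classmethod
    def from_mapping(cls, classes: dict[str, str],
                     covariates: dict[str, dict] | None = None
                     ) -> "AnnotationTable":
        df = pd.DataFrame({"class": pd.Series(classes, dtype=str)})
        if covariates:
            df = df.join(pd.DataFrame.from_dict(covariates, orient="index"))
        df.index.name = "sample_id"
        return cls(df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def classes(self) -> pd.Series:
        return self.table["class"]

    def class_of(self, sample_id: str) -> str:
        try:
            return str(self.table.loc[sample_id, "class"])
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not annotated") from None

    def members(self, class_label: str) -> list[str]:
        return list(self.table.index[self.table["class"] == class_label])
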