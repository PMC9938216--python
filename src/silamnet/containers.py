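"""Shared lightweight data containers.

Tabular data (quantification tables, cohorts, spectral counts, results) are
plain :class:`pandas.DataFrame` objects with documented schemas; graphs are
:class:`networkx.Graph`.  The dataclasses here hold the few composite objects
that carry metadata a bare array/frame cannot (frame rates, background
universes, detection rasters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared background universe.

    Parameters
    ----------
    sets : dict of str -> set of str
        Mapping from set name to member gene identifiers.
    universe : set of str
        The background universe; after :func:`silamnet.enrich.restrict_to_background`
        every set is a subset of it.
    empty_after_restriction : set of str
        Names of sets that became empty when intersected with the universe.
    """

    sets: dict[str, set[str]]
    universe: set[str]
    empty_after_restriction: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):  # dict already unique; guard subclasses
            raise ValueError("set names must be unique")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class TraceMatrix:
    """Fluorescence traces, one row per ROI, at a fixed frame rate.

    ``units`` is ``"raw"`` for camera fluorescence and ``"dff"`` after
    baseline normalization (ΔF/F₀).  ``kind`` selects the default peak
    detection threshold: cultured-neuron Ca²⁺ (0.15), acute-slice Ca²⁺
    (0.20) or glutamate sensor (0.01).
    """

    traces: np.ndarray  # shape (n_rois, n_frames)
    fs: float  # frames / second
    kind: str = "calcium_culture"  # calcium_culture | calcium_slice | glutamate
    units: str = "raw"  # raw | dff

    KINDS = ("calcium_culture", "calcium_slice", "glutamate")

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D (n_rois, n_frames) array")
        if self.traces.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {self.KINDS}")

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs


@dataclass
class EventRaster:
    """Binarized peak raster plus per-event metadata.

    ``raster`` is boolean (n_rois, n_frames) with True at peak frames.
    ``events`` has columns ``roi``, ``peak_frame``, ``amplitude`` (ΔF/F₀)
    and ``halfwidth_s``.
    """

    raster: np.ndarray
    fs: float
    events: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.ndim != 2:
            raise ValueError("raster must be 2-D (n_rois, n_frames)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.events is None:
            rois, frames = np.nonzero(self.raster)
            self.events = pd.DataFrame(
                {
                    "roi": rois,
                    "peak_frame": frames,
                    "amplitude": np.nan,
                    "halfwidth_s": np.nan,
                }
            )

    @property
    def n_rois(self) -> int:
        return self.raster.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raster.shape[1]

    def coactive_counts(self) -> np.ndarray:
        """Frame-wise count of ROIs with a peak."""
        return self.raster.sum(axis=0).astype(int)
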