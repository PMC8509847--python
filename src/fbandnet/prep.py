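"""ROI time-series containers, motion scrubbing, and nuisance regression.

Scrubbing follows the framewise censoring rule used for resting-state
motion control: a volume is censored when its DVARS-like derivative RMS
exceeds 8 and/or its framewise displacement exceeds 0.5, together with the
volume immediately before and the two volumes after the offender.
Censored volumes are recorded in a mask and excluded downstream at the
correlation step; they are never deleted before wavelet filtering, which
requires a contiguous series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RoiTimeseries",
    "MotionTrace",
    "compute_scrub_mask",
    "apply_scrub",
    "regress_nuisance",
]

MIN_VOLUMES = 32


@dataclass
class RoiTimeseries:
    """Regions x volumes signal matrix for one subject/session."""

    data: np.ndarray
    region_labels: list[str]
    tr: float
    subject_id: str = ""
    session: str = ""
    scrub_mask: np.ndarray | None = None  # True = volume retained

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D regions x volumes matrix")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} labels for {self.data.shape[0]} regions"
            )
        if self.data.shape[1] < MIN_VOLUMES:
            raise ValueError(
                f"{self.data.shape[1]} volumes < minimum {MIN_VOLUMES} required "
                "for a stable 4-level undecimated transform"
            )
        if self.scrub_mask is not None:
            self.scrub_mask = np.asarray(self.scrub_mask, dtype=bool)
            if self.scrub_mask.shape != (self.data.shape[1],):
                raise ValueError("scrub_mask length must equal volume count")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """Per-volume framewise displacement and DVARS-like motion summaries."""

    fd: np.ndarray
    dvars: np.ndarray

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        if self.fd.shape != self.dvars.shape or self.fd.ndim != 1:
            raise ValueError("fd and dvars must be 1-D vectors of equal length")
        if (self.fd < 0).any() or (self.dvars < 0).any():
            raise ValueError("motion values must be non-negative")

    def __len__(self) -> int:
        return len(self.fd)


def compute_scrub_mask(
    trace: MotionTrace,
    fd_threshold: float = 0.5,
    dvars_threshold: float = 8.0,
) -> np.ndarray:
    """Boolean per-volume retention mask (True = keep) from motion traces.

    A volume is censored iff it is an offender (fd > fd_threshold OR
    dvars > dvars_threshold), the volume immediately preceding an offender,
    or one of the two volumes following one. Windows truncate at the series
    boundaries and overlapping windows are unioned.
    """
    if fd_threshold <= 0 or dvars_threshold <= 0:
        raise ValueError("thresholds must be positive")
    n = len(trace)
    if n == 0:
        raise ValueError("empty motion trace")
    offenders = (trace.fd > fd_threshold) | (trace.dvars > dvars_threshold)
    excluded = np.zeros(n, dtype=bool)
    for idx in np.flatnonzero(offenders):
        excluded[max(idx - 1, 0) : min(idx + 3, n)] = True
    return ~excluded


def apply_scrub(ts: RoiTimeseries, mask: np.ndarray) -> RoiTimeseries:
    """Attach a retention mask to a time series without deleting volumes.

    Deleting volumes before filtering would break the contiguity the
    undecimated wavelet transform needs; censored volumes are instead
    dropped when correlations are computed.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ts.n_volumes,):
        raise ValueError(
            f"mask length {mask.shape} does not match volume count {ts.n_volumes}"
        )
    return replace(ts, scrub_mask=mask)


def regress_nuisance(ts: RoiTimeseries, nuisance: np.ndarray) -> RoiTimeseries:
    """Residualize every region's series against [intercept | nuisance].

    Each region is replaced by its ordinary least-squares residual, which is
    orthogonal to the intercept and every nuisance column. Applying the
    operation twice is a no-op (projection).
    """
    nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuisance.shape[0] != ts.n_volumes:
        nuisance = nuisance.T
    if nuisance.shape[0] != ts.n_volumes:
        raise ValueError("nuisance rows must match the volume count")
    design = np.column_stack([np.ones(ts.n_volumes), nuisance])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify the first column that adds no rank
        for col in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : col + 1]) == np.linalg.matrix_rank(
                design[:, :col]
            ):
                raise ValueError(
                    f"nuisance design is rank deficient: column {col - 1} is "
                    "linearly dependent on the preceding columns"
                )
        raise ValueError("nuisance design is rank deficient")
    beta, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    residuals = ts.data.T - design @ beta
    return replace(ts, data=residuals.T)
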