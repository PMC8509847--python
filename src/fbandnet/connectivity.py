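"""Per-band, per-session region-by-region Pearson connectivity."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .wavelets import BandSet

log = logging.getLogger(__name__)

MIN_RETAINED_VOLUMES = 8

__all__ = ["ConnectivityMatrix", "band_connectivity", "n_unique_pairs"]


def n_unique_pairs(n_regions: int) -> int:
    """Unique off-diagonal pairs of an ``n_regions``-node undirected graph."""
    return n_regions * (n_regions - 1) // 2


@dataclass
class ConnectivityMatrix:
    """Symmetric unit-diagonal Pearson matrix for one band and session."""

    values: np.ndarray
    band_index: int
    subject_id: str = ""
    session: str = ""
    n_volumes_used: int = 0
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("connectivity diagonal must be exactly 1")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """The n(n-1)/2 unique off-diagonal correlations, row-major order."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


def band_connectivity(
    bands: BandSet,
    band_index: int,
    scrub_mask: np.ndarray | None = None,
) -> ConnectivityMatrix:
    """Pearson correlation of band-limited region series over retained volumes.

    ``scrub_mask`` (True = keep) removes censored volumes from the
    correlation; the band series themselves were computed on the full
    contiguous series. Regions with zero variance over the retained volumes
    get correlation 0 with every other region (logged); a zero weight never
    survives positive-weight density thresholding downstream.
    """
    series = bands.band(band_index)
    if scrub_mask is not None:
        scrub_mask = np.asarray(scrub_mask, dtype=bool)
        if scrub_mask.shape != (series.shape[1],):
            raise ValueError("scrub_mask length must equal the volume count")
        series = series[:, scrub_mask]
    n_used = series.shape[1]
    if n_used < MIN_RETAINED_VOLUMES:
        raise ValueError(
            f"only {n_used} retained volumes; at least {MIN_RETAINED_VOLUMES} "
            "are required to estimate correlations"
            if n_used > 0
            else "no retained volumes"
        )
    sd = series.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(series)
    if degenerate.any():
        log.warning(
            "zero-variance region(s) %s over retained volumes; correlations set to 0",
            list(np.flatnonzero(degenerate)),
        )
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(
        values=corr,
        band_index=band_index,
        subject_id=bands.subject_id or "",
        session=bands.session or "",
        n_volumes_used=n_used,
        region_labels=list(bands.region_labels) if bands.region_labels else None,
    )
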