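"""Synthetic paired pre/post ROI time-series cohorts with known band structure.

The generator emulates a paired resting-state design: each subject is
scanned at baseline and after treatment, and each session's region
signals are sums of band-limited Gaussian processes, one per wavelet
detail band plus a coarse approximation. Cross-regional structure is
imposed per band by a factor of a target correlation matrix, and the
band-limiting uses the same stationary-wavelet reconstruction filters as
the analysis, so the planted structure lives exactly in the analyzed
bands. Treatment effects are planted as connectivity changes (delta r) on
chosen edges in chosen bands of the post session.

Because adjacent wavelet bands overlap spectrally, a band-j correlation
measured after analysis filtering mixes the generating correlations of
neighboring bands. The generator pre-compensates for this by solving the
linear band-mixing system, so measured band correlations match the
requested ground truth in expectation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import default_region_labels
from .prep import MotionTrace, RoiTimeseries
from .topology import Graph
from .wavelets import band_transfer_functions

log = logging.getLogger(__name__)

__all__ = [
    "ModularTemplate",
    "EffectEdge",
    "CohortSpec",
    "PairedCohort",
    "modular_correlation_template",
    "generate_cohort",
    "generate_motion_trace",
    "generate_clinical_scores",
    "make_toy_graph",
    "write_cohort",
]


@dataclass(frozen=True)
class ModularTemplate:
    """Block-structured target correlations: communities of regions with a
    common within-module and a weaker between-module correlation."""

    n_modules: int = 6
    within_r: float = 0.5
    between_r: float = 0.1


@dataclass(frozen=True)
class EffectEdge:
    """A planted treatment effect: post-session band correlation of edge
    (i, j) changes by ``delta_r``."""

    i: int
    j: int
    band: int
    delta_r: float


@dataclass
class CohortSpec:
    n_subjects: int = 12
    n_regions: int = 76
    n_volumes: int = 180
    tr: float = 2.0
    base_connectivity: ModularTemplate | dict[int, np.ndarray] = field(
        default_factory=ModularTemplate
    )
    effect_edges: list[EffectEdge] = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0
    levels: int = 4
    wavelet: str = "db4"


@dataclass
class PairedCohort:
    pre: list[RoiTimeseries]
    post: list[RoiTimeseries]
    ground_truth: dict[str, list[np.ndarray]]  # session -> per-band matrices
    spec: CohortSpec
    clinical: pd.DataFrame | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.pre)


def modular_correlation_template(
    n_regions: int, n_modules: int = 6, within_r: float = 0.5, between_r: float = 0.1
) -> np.ndarray:
    """Unit-diagonal block correlation matrix with community structure."""
    labels = np.arange(n_regions) % n_modules
    same = labels[:, None] == labels[None, :]
    mat = np.where(same, within_r, between_r)
    np.fill_diagonal(mat, 1.0)
    return nearest_psd_correlation(mat)


def nearest_psd_correlation(mat: np.ndarray, warn: bool = False) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to a unit diagonal."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    if vals.min() >= -1e-12:
        return (mat + mat.T) / 2.0
    if warn:
        log.warning(
            "target matrix not positive semidefinite (min eigenvalue %.3g); "
            "projecting to the nearest valid correlation matrix",
            vals.min(),
        )
    clipped = vecs @ np.diag(np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(clipped), 1e-12, None))
    out = clipped / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _is_psd(mat: np.ndarray, tol: float = 1e-8) -> bool:
    return np.linalg.eigvalsh((mat + mat.T) / 2.0).min() >= -tol


def _band_targets(spec: CohortSpec) -> dict[str, list[np.ndarray]]:
    """Per-session per-band target correlation matrices (ground truth)."""
    if isinstance(spec.base_connectivity, ModularTemplate):
        t = spec.base_connectivity
        base = modular_correlation_template(
            spec.n_regions, t.n_modules, t.within_r, t.between_r
        )
        pre = [base.copy() for _ in range(spec.levels)]
    else:
        pre = []
        for band in range(1, spec.levels + 1):
            mat = np.asarray(spec.base_connectivity[band], dtype=float)
            if mat.shape != (spec.n_regions, spec.n_regions):
                raise ValueError(f"band {band} target has wrong shape {mat.shape}")
            if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 1.0):
                raise ValueError(f"band {band} target must be symmetric, unit diagonal")
            if not _is_psd(mat):
                mat = nearest_psd_correlation(mat, warn=True)
            pre.append(mat)
    post = [m.copy() for m in pre]
    for e in spec.effect_edges:
        if not 1 <= e.band <= spec.levels:
            raise ValueError(f"effect edge {e}: band out of range 1..{spec.levels}")
        if not (0 <= e.i < spec.n_regions and 0 <= e.j < spec.n_regions) or e.i == e.j:
            raise ValueError(f"effect edge {e}: invalid region pair")
        mat = post[e.band - 1]
        new_r = mat[e.i, e.j] + e.delta_r
        if abs(new_r) > 1:
            raise ValueError(
                f"effect edge ({e.i}, {e.j}) band {e.band}: resulting correlation "
                f"{new_r:.3f} outside [-1, 1]"
            )
        mat[e.i, e.j] = mat[e.j, e.i] = new_r
        if not _is_psd(mat):
            raise ValueError(
                f"effect edge ({e.i}, {e.j}) band {e.band} makes the post-session "
                "target matrix non positive semidefinite"
            )
    return {"pre": pre, "post": post}


def _band_mixing_matrix(n_volumes: int, levels: int, wavelet: str) -> np.ndarray:
    """Row-normalized (levels x levels) band-energy mixing matrix.

    Entry (j, k) is the share of analysis-band-j power contributed by the
    generating component of band k; the approximation component is folded
    into the coarsest band's column (it shares that band's correlations).
    """
    det, approx = band_transfer_functions(n_volumes, levels, wavelet)
    comps = list(det) + [approx]
    w = np.full(n_volumes // 2 + 1, 2.0)
    w[0] = 1.0
    if n_volumes % 2 == 0:
        w[-1] = 1.0
    g = np.array(
        [[np.sum(w * det[j] ** 2 * comps[k] ** 2) for k in range(levels + 1)]
         for j in range(levels)]
    )
    g[:, levels - 1] += g[:, levels]  # approximation uses the coarsest band's matrix
    g = g[:, :levels]
    return g / g.sum(axis=1, keepdims=True)


def _compensated_factors(
    targets: list[np.ndarray], mixing: np.ndarray
) -> list[np.ndarray]:
    """Factors L_j of leakage-compensated generating correlation matrices."""
    levels = len(targets)
    inv = np.linalg.inv(mixing)
    factors = []
    for j in range(levels):
        comp = sum(inv[j, k] * targets[k] for k in range(levels))
        comp = nearest_psd_correlation(comp)
        vals, vecs = np.linalg.eigh(comp)
        factors.append(vecs * np.sqrt(np.clip(vals, 0.0, None)))
    return factors


def _synthesize_session(
    factors: list[np.ndarray],
    n_volumes: int,
    noise_sd: float,
    levels: int,
    wavelet: str,
    rng: np.random.Generator,
) -> np.ndarray:
    det, approx = band_transfer_functions(n_volumes, levels, wavelet)
    n_regions = factors[0].shape[0]
    signal = np.zeros((n_regions, n_volumes))
    for j in range(levels):
        z = factors[j] @ rng.standard_normal((n_regions, n_volumes))
        signal += np.fft.irfft(np.fft.rfft(z, axis=1) * det[j], n_volumes, axis=1)
    # coarse approximation component, sharing the coarsest band's structure
    z = factors[levels - 1] @ rng.standard_normal((n_regions, n_volumes))
    signal += np.fft.irfft(np.fft.rfft(z, axis=1) * approx, n_volumes, axis=1)
    return noise_sd * signal


def generate_cohort(spec: CohortSpec) -> PairedCohort:
    """Generate a paired cohort; identical spec + seed is bit-reproducible."""
    targets = _band_targets(spec)
    mixing = _band_mixing_matrix(spec.n_volumes, spec.levels, spec.wavelet)
    factors = {s: _compensated_factors(targets[s], mixing) for s in ("pre", "post")}
    labels = default_region_labels(spec.n_regions)
    streams = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_subjects)
    pre, post = [], []
    for s in range(spec.n_subjects):
        sid = f"sub-{s + 1:02d}"
        for session, bucket, stream in (
            ("pre", pre, streams[2 * s]),
            ("post", post, streams[2 * s + 1]),
        ):
            rng = np.random.default_rng(stream)
            data = _synthesize_session(
                factors[session], spec.n_volumes, spec.noise_sd, spec.levels,
                spec.wavelet, rng,
            )
            bucket.append(
                RoiTimeseries(
                    data=data,
                    region_labels=labels,
                    tr=spec.tr,
                    subject_id=sid,
                    session=session,
                )
            )
    return PairedCohort(pre=pre, post=post, ground_truth=targets, spec=spec)


def generate_motion_trace(
    n_volumes: int, spike_indices: list[int], seed: int = 0
) -> MotionTrace:
    """Motion trace whose FD exceeds 0.5 and DVARS exceeds 8 exactly at
    ``spike_indices`` and is sub-threshold elsewhere."""
    spikes = np.asarray(spike_indices, dtype=int)
    if len(spikes) and (spikes.min() < 0 or spikes.max() >= n_volumes):
        raise ValueError("spike indices must lie in [0, n_volumes)")
    rng = np.random.default_rng(seed)
    fd = rng.uniform(0.05, 0.35, size=n_volumes)
    dvars = rng.uniform(2.0, 6.0, size=n_volumes)
    fd[spikes] = rng.uniform(0.7, 1.5, size=len(spikes))
    dvars[spikes] = rng.uniform(9.0, 15.0, size=len(spikes))
    return MotionTrace(fd=fd, dvars=dvars)


def generate_clinical_scores(
    feature: np.ndarray,
    slope: float,
    noise_sd: float = 3.0,
    intercept: float = -12.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical table whose score change is linear in a network feature.

    Pre scores emulate a moderate-to-severe baseline (mean 30, SD 9);
    change = intercept + slope * feature + Gaussian noise, and
    post = pre + change (negative change = improvement).
    """
    feature = np.asarray(feature, dtype=float)
    n = len(feature)
    rng = np.random.default_rng(seed)
    pre = rng.normal(30.0, 9.0, size=n).clip(10, 60)
    change = intercept + slope * feature + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame(
        {
            "subject": [f"sub-{i + 1:02d}" for i in range(n)],
            "pre": np.round(pre),
            "post": np.round(pre + change),
            "change": np.round(pre + change) - np.round(pre),
            "age": rng.integers(12, 20, size=n),
            "sex": rng.integers(0, 2, size=n),
            "iq": np.round(rng.normal(108.0, 10.0, size=n)),
        }
    )


def make_toy_graph(kind: str, n: int, seed: int | None = None, **params) -> Graph:
    """Small graphs with closed-form metric values for oracle testing."""
    if n < 1:
        raise ValueError("n must be positive")
    if kind == "ring_lattice":
        k = params.get("k", 4)
        if k % 2 or k < 2 or k >= n:
            raise ValueError("ring lattice needs an even neighbor count 2 <= k < n")
        g = nx.watts_strogatz_graph(n, k, 0.0)
    elif kind == "watts_strogatz":
        k = params.get("k", 4)
        p = params.get("p", 0.1)
        if k % 2 or k < 2 or k >= n:
            raise ValueError("Watts-Strogatz needs an even neighbor count 2 <= k < n")
        g = nx.watts_strogatz_graph(n, k, p, seed=seed)
    elif kind == "erdos_renyi":
        g = nx.gnp_random_graph(n, params.get("p", 0.2), seed=seed)
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "path":
        g = nx.path_graph(n)
    else:
        raise ValueError(f"unknown toy graph family {kind!r}")
    return Graph.from_networkx(g, n=n)


def write_cohort(cohort: PairedCohort, directory: str | Path) -> Path:
    """Write one TSV per subject/session plus a JSON manifest.

    TSV layout: rows = labeled regions, columns = volumes. The manifest
    records subjects, session files, TR, seed and the planted effects, and
    is the entry point for the analysis pipeline.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subjects = []
    for pre_ts, post_ts in zip(cohort.pre, cohort.post):
        entry = {"subject_id": pre_ts.subject_id}
        for ts in (pre_ts, post_ts):
            name = f"{ts.subject_id}_ses-{ts.session}.tsv"
            frame = pd.DataFrame(
                ts.data,
                index=ts.region_labels,
                columns=[f"vol_{v + 1:04d}" for v in range(ts.n_volumes)],
            )
            frame.to_csv(directory / name, sep="\t", index_label="region")
            entry[ts.session] = name
        subjects.append(entry)
    manifest = {
        "schema_version": 1,
        "tr": cohort.spec.tr,
        "n_volumes": cohort.spec.n_volumes,
        "n_regions": cohort.spec.n_regions,
        "seed": cohort.spec.seed,
        "levels": cohort.spec.levels,
        "wavelet": cohort.spec.wavelet,
        "planted_effects": [
            {"i": e.i, "j": e.j, "band": e.band, "delta_r": e.delta_r}
            for e in cohort.spec.effect_edges
        ],
        "subjects": subjects,
    }
    if cohort.clinical is not None:
        cohort.clinical.to_csv(directory / "clinical.tsv", sep="\t", index=False)
        manifest["clinical"] = "clinical.tsv"
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
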