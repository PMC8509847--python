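"""End-to-end orchestration: manifest in, report tables out.

The pipeline runs scrub -> nuisance -> stationary wavelet bands ->
per-band connectivity -> density-thresholded topology with AUC summaries
-> paired sign-permutation tests with Bonferroni and BH-FDR control ->
FDR subnetworks -> optional clinical regressions, fully reproducible from
a config and a seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import ConnectivityMatrix, band_connectivity, n_unique_pairs
from .inference import (
    bonferroni_threshold,
    build_fdr_subnetwork,
    paired_feature_table,
    Subnetwork,
)
from .clinical import regress_outcome
from .prep import MotionTrace, RoiTimeseries, apply_scrub, compute_scrub_mask
from .topology import (
    NODAL_METRICS,
    build_density_stack,
    density_grid,
    metric_curves,
)
from .wavelets import sdwt_decompose

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "read_manifest", "run_pipeline", "write_tables"]

GLOBAL_METRICS_BASE = ("c_net", "l_net", "efficiency")
GLOBAL_METRICS_NORM = ("c_norm", "l_norm", "sigma")


@dataclass
class RunConfig:
    manifest: str
    out_dir: str = "results/pipeline"
    seed: int = 0
    bands: tuple[int, ...] = (1, 2, 3, 4)
    density_low: float = 0.10
    density_high: float = 0.50
    density_step: float = 0.01
    n_rand: int = 100  # rewired references per graph; 0 disables normalization
    n_realizations: int = 1_000_000
    alpha: float = 0.05
    boundary_mode: str = "periodic"
    levels: int = 4
    wavelet: str = "db4"
    scrubbing: bool = True
    clinical: bool = True
    nodal_metrics: tuple[str, ...] = NODAL_METRICS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not Path(self.manifest).exists():
            raise FileNotFoundError(f"manifest not found: {self.manifest}")
        if not self.bands or any(not 1 <= b <= self.levels for b in self.bands):
            raise ValueError(f"bands must be within 1..{self.levels}")
        unknown = set(self.nodal_metrics) - set(NODAL_METRICS)
        if unknown:
            raise ValueError(f"unknown nodal metrics: {sorted(unknown)}")

    def densities(self) -> np.ndarray:
        return density_grid(self.density_low, self.density_high, self.density_step)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All pipeline outputs, band-keyed, plus a provenance summary."""

    connectivity: dict[int, dict[str, list[ConnectivityMatrix]]]
    edge_tests: dict[int, pd.DataFrame]
    nodal_tests: dict[int, pd.DataFrame]
    global_tests: dict[int, pd.DataFrame]
    subnetworks: dict[int, Subnetwork]
    metric_auc: pd.DataFrame  # tidy per subject/session/band/metric/node AUC
    clinical_tests: pd.DataFrame | None
    summary: dict


def read_manifest(path: str | Path) -> dict:
    """Read and structurally validate a cohort manifest."""
    path = Path(path)
    with open(path) as fh:
        manifest = json.load(fh)
    for key in ("tr", "subjects"):
        if key not in manifest:
            raise ValueError(f"manifest missing required key {key!r}")
    if not manifest["subjects"]:
        raise ValueError("manifest lists no subjects")
    manifest["_root"] = path.parent
    return manifest


def _read_session_tsv(path: Path, tr: float, subject_id: str, session: str) -> RoiTimeseries:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.isna().any().any():
        bad = int(np.argmax(frame.isna().any(axis=1).to_numpy())) + 2  # header line 1
        raise ValueError(f"{path}: malformed/missing values near line {bad}")
    return RoiTimeseries(
        data=frame.to_numpy(dtype=float),
        region_labels=[str(x) for x in frame.index],
        tr=tr,
        subject_id=subject_id,
        session=session,
    )


def _read_motion_tsv(path: Path) -> MotionTrace:
    frame = pd.read_csv(path, sep="\t")
    return MotionTrace(fd=frame["fd"].to_numpy(), dvars=frame["dvars"].to_numpy())


def _load_sessions(manifest: dict, config: RunConfig):
    root: Path = manifest["_root"]
    tr = float(manifest["tr"])
    paired, dropped = [], []
    for entry in manifest["subjects"]:
        sid = entry.get("subject_id", "?")
        if "pre" not in entry or "post" not in entry:
            log.warning("subject %s is unpaired; dropped", sid)
            dropped.append(sid)
            continue
        sessions = {}
        for ses in ("pre", "post"):
            ts = _read_session_tsv(root / entry[ses], tr, sid, ses)
            motion_key = f"motion_{ses}"
            if config.scrubbing and motion_key in entry:
                mask = compute_scrub_mask(_read_motion_tsv(root / entry[motion_key]))
                ts = apply_scrub(ts, mask)
                log.info(
                    "subject %s %s: %d of %d volumes retained after scrubbing",
                    sid, ses, int(mask.sum()), len(mask),
                )
            sessions[ses] = ts
        paired.append(sessions)
    if not paired:
        raise ValueError("no paired subjects in manifest")
    return paired, dropped, tr


def run_pipeline(config: RunConfig) -> ReportBundle:
    config.validate()
    manifest = read_manifest(config.manifest)
    paired, dropped, tr = _load_sessions(manifest, config)
    n_subj = len(paired)
    densities = config.densities()
    labels = paired[0]["pre"].region_labels
    n_regions = len(labels)
    iu = np.triu_indices(n_regions, k=1)

    # --- band decomposition and connectivity -----------------------------
    connectivity: dict[int, dict[str, list[ConnectivityMatrix]]] = {
        b: {"pre": [], "post": []} for b in config.bands
    }
    for sessions in paired:
        for ses in ("pre", "post"):
            ts = sessions[ses]
            bands = sdwt_decompose(
                ts, levels=config.levels, wavelet=config.wavelet, mode=config.boundary_mode
            )
            for b in config.bands:
                connectivity[b][ses].append(
                    band_connectivity(bands, b, scrub_mask=ts.scrub_mask)
                )

    edge_tests: dict[int, pd.DataFrame] = {}
    nodal_tests: dict[int, pd.DataFrame] = {}
    global_tests: dict[int, pd.DataFrame] = {}
    subnetworks: dict[int, Subnetwork] = {}
    auc_rows: list[pd.DataFrame] = []

    for band_no, b in enumerate(config.bands):
        # --- edgewise connectivity change tests --------------------------
        pre_r = np.stack([c.upper_triangle() for c in connectivity[b]["pre"]])
        post_r = np.stack([c.upper_triangle() for c in connectivity[b]["post"]])
        table = paired_feature_table(
            pre_r, post_r, n_realizations=config.n_realizations,
            seed=config.seed + 1000 * band_no, alpha=config.alpha,
        )
        table.insert(0, "j_label", [labels[j] for j in iu[1]])
        table.insert(0, "i_label", [labels[i] for i in iu[0]])
        table.insert(0, "j", iu[1])
        table.insert(0, "i", iu[0])
        table["band"] = b
        edge_tests[b] = table
        subnetworks[b] = build_fdr_subnetwork(
            table, n_nodes=n_regions, band=b, alpha=config.alpha
        )

        # --- topology curves and AUCs ------------------------------------
        nodal_auc = {ses: {m: [] for m in config.nodal_metrics} for ses in ("pre", "post")}
        global_auc = {ses: {} for ses in ("pre", "post")}
        for ses in ("pre", "post"):
            for s, conn in enumerate(connectivity[b][ses]):
                stack = build_density_stack(conn, densities)
                curves = metric_curves(
                    stack,
                    metrics=config.nodal_metrics,
                    global_metrics=True,
                    n_rand=config.n_rand,
                    seed=config.seed + 7919 * s + 104729 * band_no,
                )
                for m in config.nodal_metrics:
                    nodal_auc[ses][m].append(curves[m].auc)
                    auc_rows.append(
                        pd.DataFrame(
                            {
                                "subject": conn.subject_id,
                                "session": ses,
                                "band": b,
                                "metric": m,
                                "node": labels,
                                "auc": curves[m].auc,
                            }
                        )
                    )
                for m in GLOBAL_METRICS_BASE + (
                    GLOBAL_METRICS_NORM if config.n_rand > 0 else ()
                ):
                    global_auc[ses].setdefault(m, []).append(curves[m].auc)

        # --- nodal paired tests (family of n_regions per metric) ---------
        frames = []
        for m in config.nodal_metrics:
            t = paired_feature_table(
                np.stack(nodal_auc["pre"][m]),
                np.stack(nodal_auc["post"][m]),
                n_realizations=config.n_realizations,
                seed=config.seed + 1000 * band_no,
                alpha=config.alpha,
            )
            t.insert(0, "node", labels)
            t.insert(0, "metric", m)
            t["bonferroni_threshold"] = bonferroni_threshold(config.alpha, n_regions)
            frames.append(t)
        nodal = pd.concat(frames, ignore_index=True)
        nodal["band"] = b
        nodal_tests[b] = nodal

        # --- global paired tests ------------------------------------------
        gframes = []
        for m, values in global_auc["pre"].items():
            t = paired_feature_table(
                np.asarray(values)[:, None],
                np.asarray(global_auc["post"][m])[:, None],
                n_realizations=config.n_realizations,
                seed=config.seed + 1000 * band_no,
                alpha=config.alpha,
            )
            t.insert(0, "metric", m)
            gframes.append(t)
        gtable = pd.concat(gframes, ignore_index=True)
        gtable["band"] = b
        global_tests[b] = gtable

    metric_auc = (
        pd.concat(auc_rows, ignore_index=True) if auc_rows else pd.DataFrame()
    )

    # --- clinical regressions (exploratory, uncorrected) ------------------
    clinical_tests = None
    if config.clinical and "clinical" in manifest:
        clin = pd.read_csv(manifest["_root"] / manifest["clinical"], sep="\t")
        cov = (
            clin[["age", "sex", "iq"]].to_numpy(dtype=float)
            if {"age", "sex", "iq"}.issubset(clin.columns)
            else None
        )
        clinical_tests = _clinical_regressions(clin, cov, config, connectivity)

    summary = {
        "schema_version": 1,
        "software_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_subjects": n_subj,
        "dropped_subjects": dropped,
        "bands": list(config.bands),
        "n_regions": n_regions,
        "n_edges_tested": n_unique_pairs(n_regions),
        "densities": [float(d) for d in densities],
        "n_rand": config.n_rand,
        "bonferroni_nodal": bonferroni_threshold(config.alpha, n_regions),
        "bonferroni_edges": bonferroni_threshold(config.alpha, n_unique_pairs(n_regions)),
        "subnetwork_sizes": {str(b): subnetworks[b].n_edges for b in config.bands},
    }
    return ReportBundle(
        connectivity=connectivity,
        edge_tests=edge_tests,
        nodal_tests=nodal_tests,
        global_tests=global_tests,
        subnetworks=subnetworks,
        metric_auc=metric_auc,
        clinical_tests=clinical_tests,
        summary=summary,
    )


def _clinical_regressions(clin, cov, config, connectivity):
    """BDI change regressed on mean-connectivity change and baseline, per band."""
    rows = []
    outcome = clin["change"].to_numpy(dtype=float)
    if cov is not None and len(outcome) < cov.shape[1] + 3:
        log.warning(
            "too few subjects (%d) to partial out %d covariates; "
            "fitting without covariates", len(outcome), cov.shape[1],
        )
        cov = None
    for b in config.bands:
        pre_mean = np.array([c.upper_triangle().mean() for c in connectivity[b]["pre"]])
        post_mean = np.array([c.upper_triangle().mean() for c in connectivity[b]["post"]])
        for kind, feat in (
            ("connectivity_change", post_mean - pre_mean),
            ("connectivity_baseline", pre_mean),
        ):
            try:
                res = regress_outcome(feat, outcome, covariates=cov)
            except ValueError as err:
                log.warning("clinical regression band %d %s skipped: %s", b, kind, err)
                continue
            rows.append(
                {
                    "band": b,
                    "feature": kind,
                    "slope": res.slope,
                    "p": res.p_value,
                    "n": res.n_used,
                    "stderr": res.stderr,
                }
            )
    return pd.DataFrame(rows)


def write_tables(bundle: ReportBundle, out_dir: str | Path) -> Path:
    """Write the report bundle as TSV tables plus a JSON summary.

    TSV dialect: tab-separated, header row, UTF-8, '.' decimal. Re-running
    with the same config and seed produces byte-identical output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for b, table in bundle.edge_tests.items():
        table.to_csv(out / f"edge_tests_band{b}.tsv", sep="\t", index=False)
    for b, table in bundle.nodal_tests.items():
        table.to_csv(out / f"nodal_tests_band{b}.tsv", sep="\t", index=False)
    for b, table in bundle.global_tests.items():
        table.to_csv(out / f"global_tests_band{b}.tsv", sep="\t", index=False)
    for b, sub in bundle.subnetworks.items():
        sub.edges.to_csv(out / f"subnetwork_edges_band{b}.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"node": range(len(sub.within_subnetwork_degree)),
             "within_subnetwork_degree": sub.within_subnetwork_degree}
        ).to_csv(out / f"subnetwork_degree_band{b}.tsv", sep="\t", index=False)
    if len(bundle.metric_auc):
        bundle.metric_auc.to_csv(out / "metric_auc.tsv", sep="\t", index=False)
    if bundle.clinical_tests is not None and len(bundle.clinical_tests):
        bundle.clinical_tests.to_csv(out / "clinical_tests.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(
        json.dumps(bundle.summary, indent=2, sort_keys=True)
    )
    return out
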