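"""End-to-end pipeline: generate -> parameterize -> featurize -> compare.

One :class:`PipelineConfig` (JSON-serializable) drives all stages.  A
single global seed fans out to per-subject and per-stage seeds through a
hash-based splitting rule, so re-running with the same config reproduces
byte-identical outputs.  Every written artifact is recorded, with its
SHA-256 checksum, in a :class:`ResultsBundle` (bundle.json).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ccio
from .synthetic import CohortConfig, CohortManifest, generate_cohort, derive_seed
from .parameterize import parameterize_mesh, make_template, GridSurface
from .morphometry import feature_field, FeatureField, medial_axis
from .stats import permutation_analysis, ratio_map, group_sample_from_fields

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline"]

_FEATURES = ("madmtbm", "mtbm", "mad", "detj")


@dataclass
class PipelineConfig:
    """Resolved configuration of one full analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    features: tuple[str, ...] = ("madmtbm", "detj", "mad")
    n_perms: int = 1000
    alpha_vertex: float = 0.05
    correction: str = "count"
    log_mad: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        self.features = tuple(self.features)
        for f in self.features:
            if f not in _FEATURES:
                raise ValueError(f"unknown feature {f!r}; choose from {_FEATURES}")
        if not 0 < self.alpha_vertex < 1:
            raise ValueError("alpha_vertex must be in (0, 1)")
        # the global seed overrides the cohort's own seed so one number
        # controls the whole run
        self.cohort.seed = derive_seed(self.seed, "cohort")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        return cls(**data)


@dataclass
class ResultsBundle:
    """Manifest of all artifacts written by one pipeline run."""

    out_dir: Path
    config: PipelineConfig
    artifacts: dict[str, str] = field(default_factory=dict)  # rel path -> sha256

    def record(self, path: Path) -> None:
        rel = str(Path(path).relative_to(self.out_dir))
        self.artifacts[rel] = hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def save(self) -> Path:
        payload = {
            "config": asdict(self.config),
            "artifacts": self.artifacts,
        }
        path = self.out_dir / "bundle.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    def verify(self) -> None:
        """Re-hash every listed artifact; mismatch or absence is an error."""
        for rel, digest in self.artifacts.items():
            p = self.out_dir / rel
            if not p.exists():
                raise FileNotFoundError(f"bundle artifact missing: {p}")
            if hashlib.sha256(p.read_bytes()).hexdigest() != digest:
                raise ValueError(f"bundle artifact changed on disk: {p}")


def _stats_frame(maps, dims) -> pd.DataFrame:
    n_u, n_v = dims
    i, j = np.meshgrid(np.arange(n_u), np.arange(n_v), indexing="ij")
    return pd.DataFrame({
        "vertex": np.arange(n_u * n_v),
        "u_idx": i.ravel(),
        "v_idx": j.ravel(),
        "M": maps.m,
        "p": maps.p,
        "significant": maps.mask().astype(int),
    })


def run_pipeline(config: PipelineConfig, out_dir) -> ResultsBundle:
    """Execute all stages and return the artifact bundle.

    Stage order: synthetic cohort generation, per-subject conformal-grid
    parameterization, template construction (vertex-wise mean of the
    reference group A after rigid alignment), per-subject feature fields,
    then per-feature group statistics with ratio maps for the scalar
    features.  Any stage failure aborts with the offending subject named.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ResultsBundle(out_dir=out_dir, config=config)

    t0 = time.perf_counter()
    mesh_dir = out_dir / "meshes"
    manifest = generate_cohort(config.cohort, mesh_dir)
    for p in manifest.paths():
        bundle.record(p)
    bundle.record(mesh_dir / "manifest.csv")
    bundle.record(mesh_dir / "config.json")
    logger.info("generated %d subjects in %.1fs", len(manifest.table),
                time.perf_counter() - t0)

    t0 = time.perf_counter()
    grid_dir = out_dir / "grids"
    grid_dir.mkdir(exist_ok=True)
    grids: dict[str, GridSurface] = {}
    for row in manifest.table.itertuples():
        try:
            mesh = ccio.read_mesh(manifest.path_of(row.subject_id),
                                  subject_id=row.subject_id)
            grids[row.subject_id] = parameterize_mesh(mesh, config.cohort.grid_dims)
        except Exception as exc:
            raise RuntimeError(
                f"parameterization failed for subject {row.subject_id}: {exc}"
            ) from exc
        bundle.record(ccio.write_grid(grids[row.subject_id],
                                      grid_dir / f"{row.subject_id}.npz"))
    logger.info("parameterized %d subjects in %.1fs", len(grids),
                time.perf_counter() - t0)

    groups = manifest.groups()
    ref_group = groups[0]
    ref_ids = list(manifest.subjects(ref_group)["subject_id"])
    template = make_template([grids[s] for s in ref_ids])
    bundle.record(ccio.write_grid(template, grid_dir / "template.npz"))

    t0 = time.perf_counter()
    feat_dir = out_dir / "features"
    feat_dir.mkdir(exist_ok=True)
    fields: dict[str, FeatureField] = {}
    for row in manifest.table.itertuples():
        try:
            fields[row.subject_id] = feature_field(grids[row.subject_id], template,
                                                   log_mad=config.log_mad)
        except Exception as exc:
            raise RuntimeError(
                f"feature computation failed for subject {row.subject_id}: {exc}"
            ) from exc
        bundle.record(ccio.write_features(fields[row.subject_id],
                                          feat_dir / f"{row.subject_id}.csv"))
    logger.info("featurized %d subjects in %.1fs", len(fields),
                time.perf_counter() - t0)

    t0 = time.perf_counter()
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(exist_ok=True)
    if len(groups) != 2:
        raise RuntimeError(f"group comparison needs exactly 2 groups, got {groups}")
    ids_a = list(manifest.subjects(groups[0])["subject_id"])
    ids_b = list(manifest.subjects(groups[1])["subject_id"])
    fields_a = [fields[s] for s in ids_a]
    fields_b = [fields[s] for s in ids_b]

    stat_scalars: dict[str, np.ndarray] = {}
    for feat in config.features:
        sample = group_sample_from_fields(fields_a, fields_b, feat)
        maps = permutation_analysis(
            sample, n_perms=config.n_perms,
            seed=derive_seed(config.seed, "stats", feat),
            alpha_vertex=config.alpha_vertex, correction=config.correction,
        )
        frame = _stats_frame(maps, config.cohort.grid_dims)
        frame.to_csv(stats_dir / f"stats_{feat}.csv", index=False)
        bundle.record(stats_dir / f"stats_{feat}.csv")
        omnibus = {
            "feature": feat,
            "c_obs": maps.c_obs,
            "p_corrected": maps.p_corrected,
            "n_perms": maps.n_perms,
            "alpha_vertex": maps.alpha_vertex,
            "seed": maps.seed,
            "correction": maps.correction,
        }
        path = stats_dir / f"omnibus_{feat}.json"
        path.write_text(json.dumps(omnibus, indent=2))
        bundle.record(path)
        stat_scalars[f"M_{feat}"] = maps.m
        stat_scalars[f"p_{feat}"] = maps.p

    # direction-of-change ratio maps for the scalar features
    for name, extract in (("mad", lambda f: f.mad.ravel()),
                          ("detj", lambda f: f.detj.ravel())):
        younger = np.stack([extract(f) for f in fields_a])
        older = np.stack([extract(f) for f in fields_b])
        ratio = ratio_map(younger, older)
        n_u, n_v = config.cohort.grid_dims
        i, j = np.meshgrid(np.arange(n_u), np.arange(n_v), indexing="ij")
        pd.DataFrame({"u_idx": i.ravel(), "v_idx": j.ravel(), "ratio": ratio}
                     ).to_csv(stats_dir / f"ratio_{name}.csv", index=False)
        bundle.record(stats_dir / f"ratio_{name}.csv")
        stat_scalars[f"ratio_{name}"] = ratio

    bundle.record(ccio.write_grid_vtk(template, stats_dir / "maps.vtk",
                                      scalars=stat_scalars))
    logger.info("statistics written in %.1fs", time.perf_counter() - t0)

    cfg_path = out_dir / "pipeline_config.json"
    cfg_path.write_text(config.to_json())
    bundle.record(cfg_path)
    bundle.save()
    return bundle
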