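"""End-to-end orchestration: simulate -> prep -> connectome -> measures ->
stats -> predict, with fixed stage filenames and a reproducibility manifest.

Each stage reads only its predecessors' files and writes its own, so stages
are individually re-runnable; a rerun with the same config reproduces
identical outputs.  The master seed fans out to per-stage, per-item seeds
through ``numpy.random.SeedSequence`` with counter-style entropy, so item
seeds are stable regardless of execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import tdcsgraph
from tdcsgraph.connectome import (
    ConnectivityMatrix,
    correlation_to_z,
    density_grid,
    threshold_by_density,
)
from tdcsgraph.graph_measures import (
    default_site_map,
    load_site_map,
    measure_vector,
    synthetic_site_map,
)
from tdcsgraph.group_stats import results_to_frame, sweep_compare
from tdcsgraph.outcome_prediction import build_feature_matrix, nested_cv_svm
from tdcsgraph.sample_prep import assign_groups, make_samples
from tdcsgraph.synthetic_data import (
    CohortConfig,
    make_cohort,
    read_metadata,
    read_timeseries,
    write_cohort,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "validate_inputs",
    "compute_measure_table",
    "PipelineError",
]

# stage ids used in seed fan-out; stable across releases
_STAGE_MEASURES = 4
_STAGE_PREDICT = 6


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name and offending item."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: str = "run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    d_min: float = 0.17
    d_max: float = 0.46
    step: float = 0.01
    feature_density: float = 0.3
    n_nulls: int = 100
    compute_sigma: bool = True
    T: int = 90
    stride: int = 35
    seed: int = 0
    outer_k: int = 5
    inner_k: int = 5
    paper_mode: bool = False
    group_aware: bool = True
    subject_level_stats: bool = False
    site_map_path: str | None = None

    def __post_init__(self) -> None:
        grid = density_grid(self.d_min, self.d_max, self.step)
        if not all(0 < d <= 1 for d in grid):
            raise ValueError("density grid must lie in (0, 1]")
        if not any(np.isclose(self.feature_density, d) for d in grid):
            raise ValueError(
                f"feature density {self.feature_density} is not on the grid"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cohort = CohortConfig.from_dict(data.pop("cohort", {}))
        return cls(cohort=cohort, **data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d


def _item_seed(master: int, stage: int, item: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=(master, stage, item))


def _resolve_site_map(config: RunConfig, subjects) -> dict[str, list[int]]:
    if config.site_map_path:
        sites = load_site_map(config.site_map_path)
    elif config.cohort.n_regions == 90:
        sites = default_site_map()
    else:
        electrodes = sorted(
            {e for s in subjects for e in s.stimulation_sites}
        )
        sites = synthetic_site_map(electrodes, config.cohort.n_regions)
    return sites


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: RunConfig, run_dir: Path) -> Path:
    """Generate the synthetic cohort and write it under cohort/."""
    subjects, series = make_cohort(config.cohort)
    return write_cohort(run_dir / "cohort", subjects, series, config.cohort)


def stage_prep(config: RunConfig, run_dir: Path) -> None:
    """Window the series into samples; write samples.csv and groups.csv."""
    cohort_dir = run_dir / "cohort"
    subjects = read_metadata(cohort_dir / "metadata.csv")
    groups = assign_groups(subjects)
    pd.DataFrame(
        [{"subject_id": s, "group": g} for s, g in groups.items()]
    ).to_csv(run_dir / "groups.csv", index=False)
    rows = []
    for s in subjects:
        for condition in ("pre", "post"):
            ts, _ = read_timeseries(
                cohort_dir / "timeseries" / f"{s.subject_id}_{condition}.csv"
            )
            n = ts.shape[1]
            n_windows = (n - config.T) // config.stride + 1
            for w in range(n_windows):
                rows.append(
                    {
                        "sample_id": f"{s.subject_id}_{condition}_w{w}",
                        "subject_id": s.subject_id,
                        "condition": condition,
                        "window_index": w,
                        "start": w * config.stride,
                        "T": config.T,
                    }
                )
    pd.DataFrame(rows).to_csv(run_dir / "samples.csv", index=False)


def stage_connectome(config: RunConfig, run_dir: Path) -> None:
    """Fisher-z connectivity for every sample; writes connectivity.npz."""
    cohort_dir = run_dir / "cohort"
    subjects = read_metadata(cohort_dir / "metadata.csv")
    series = {
        s.subject_id: {
            cond: read_timeseries(
                cohort_dir / "timeseries" / f"{s.subject_id}_{cond}.csv"
            )[0]
            for cond in ("pre", "post")
        }
        for s in subjects
    }
    samples = make_samples(series, T=config.T, stride=config.stride)
    matrices = {s.sample_id: correlation_to_z(s).z for s in samples}
    np.savez_compressed(run_dir / "connectivity.npz", **matrices)


def compute_measure_table(
    matrices: dict[str, np.ndarray],
    electrodes: dict[str, list[str]],
    sites: dict[str, list[int]],
    densities: list[float],
    n_nulls: int = 100,
    seed: int = 0,
    compute_sigma: bool = True,
) -> pd.DataFrame:
    """Tidy measure table for per-sample Fisher-z matrices.

    ``matrices`` maps sample_id (subject_condition_wN) -> z matrix;
    ``electrodes`` maps subject_id -> stimulation electrode labels.  One row
    per (sample, density, measure, scope).
    """
    rows = []
    for item, (sample_id, z) in enumerate(sorted(matrices.items())):
        subject_id, condition, wtag = sample_id.rsplit("_", 2)
        window_index = int(wtag[1:])
        c = ConnectivityMatrix(z=z)
        for d_idx, d in enumerate(densities):
            g = threshold_by_density(c, d)
            mv = measure_vector(
                g,
                sites=sites,
                electrodes=electrodes[subject_id],
                n_nulls=n_nulls,
                seed=_item_seed(seed, _STAGE_MEASURES, item * 1000 + d_idx),
                compute_sigma=compute_sigma,
            )
            common = {
                "sample_id": sample_id,
                "subject_id": subject_id,
                "condition": condition,
                "window_index": window_index,
                "density": d,
                "connected": mv.connected,
            }
            for name, value in mv.globals_dict().items():
                if name == "sigma" and not compute_sigma:
                    continue
                rows.append(
                    {**common, "measure": name, "scope": "global", "value": value}
                )
            for name, value in mv.site.items():
                rows.append(
                    {**common, "measure": name, "scope": "site", "value": value}
                )
    return pd.DataFrame(rows)


def stage_measures(config: RunConfig, run_dir: Path) -> None:
    """Graph measures across the density sweep; writes measures.csv."""
    subjects = read_metadata(run_dir / "cohort" / "metadata.csv")
    sites = _resolve_site_map(config, subjects)
    electrodes = {s.subject_id: list(s.stimulation_sites) for s in subjects}
    with np.load(run_dir / "connectivity.npz") as archive:
        matrices = {k: archive[k] for k in archive.files}
    table = compute_measure_table(
        matrices,
        electrodes,
        sites,
        density_grid(config.d_min, config.d_max, config.step),
        n_nulls=config.n_nulls,
        seed=config.seed,
        compute_sigma=config.compute_sigma,
    )
    table.to_csv(run_dir / "measures.csv", index=False)


def stage_stats(config: RunConfig, run_dir: Path) -> None:
    """Paired pre/post sweep comparison; writes stats.csv."""
    measures = pd.read_csv(run_dir / "measures.csv")
    groups = dict(
        pd.read_csv(run_dir / "groups.csv").itertuples(index=False, name=None)
    )
    results = sweep_compare(
        measures, groups, subject_level=config.subject_level_stats
    )
    results_to_frame(results).to_csv(run_dir / "stats.csv", index=False)


def stage_predict(config: RunConfig, run_dir: Path) -> None:
    """Nested-CV SVM prediction; writes prediction.json and roc.csv."""
    measures = pd.read_csv(run_dir / "measures.csv")
    groups = dict(
        pd.read_csv(run_dir / "groups.csv").itertuples(index=False, name=None)
    )
    fm = build_feature_matrix(measures, groups, density=config.feature_density)
    seed = int(_item_seed(config.seed, _STAGE_PREDICT, 0).generate_state(1)[0] % (2**31))
    report = nested_cv_svm(
        fm,
        outer_k=config.outer_k,
        inner_k=config.inner_k,
        seed=seed,
        group_aware=config.group_aware,
        paper_mode=config.paper_mode,
    )
    (run_dir / "prediction.json").write_text(
        json.dumps(report.to_dict(), indent=2)
    )
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
        run_dir / "roc.csv", index=False
    )


_STAGES = [
    ("simulate", stage_simulate),
    ("prep", stage_prep),
    ("connectome", stage_connectome),
    ("measures", stage_measures),
    ("stats", stage_stats),
    ("predict", stage_predict),
]


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Run the pipeline end to end; returns the run directory.

    ``stages`` restricts execution to a subset (their inputs must already
    exist in the run directory).  Any stage error aborts with the stage name.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config_dict = config.to_dict()
    config_json = json.dumps(config_dict, sort_keys=True)
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "tdcsgraph": tdcsgraph.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": [],
    }
    for name, fn in _STAGES:
        if stages is not None and name not in stages:
            continue
        try:
            fn(config, run_dir)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir


def validate_inputs(
    cohort_dir: str | Path, site_map: dict[str, list[int]] | None = None
) -> list[str]:
    """Check a cohort directory for shape and labeling problems.

    Returns a list of human-readable failure strings (empty = valid):
    consistent region counts across matrices, required metadata columns,
    and stimulation electrodes resolvable in the site map.
    """
    cohort_dir = Path(cohort_dir)
    failures: list[str] = []
    meta_path = cohort_dir / "metadata.csv"
    if not meta_path.exists():
        return [f"missing metadata file: {meta_path}"]
    df = pd.read_csv(meta_path)
    required = {
        "subject_id", "arm", "baseline_seizures", "followup_seizures",
        "stimulation_sites",
    }
    missing = required - set(df.columns)
    if missing:
        failures.append(f"metadata missing columns: {sorted(missing)}")
        return failures
    n_regions = None
    for subject_id in df["subject_id"]:
        for cond in ("pre", "post"):
            path = cohort_dir / "timeseries" / f"{subject_id}_{cond}.csv"
            if not path.exists():
                failures.append(f"missing time series: {path}")
                continue
            ts, _ = read_timeseries(path)
            if n_regions is None:
                n_regions = ts.shape[0]
            elif ts.shape[0] != n_regions:
                failures.append(
                    f"{subject_id} {cond}: {ts.shape[0]} regions, "
                    f"expected {n_regions}"
                )
    if site_map is not None:
        for _, row in df.iterrows():
            for electrode in str(row["stimulation_sites"]).split(";"):
                if electrode not in site_map:
                    failures.append(
                        f"electrode {electrode!r} of {row['subject_id']} "
                        "not in site map"
                    )
                elif n_regions is not None and any(
                    i >= n_regions for i in site_map[electrode]
                ):
                    failures.append(
                        f"site map for {electrode!r} exceeds "
                        f"{n_regions} regions"
                    )
    return failures
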