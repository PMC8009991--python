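"""Synthetic cohort generator for pre/post stimulation resting-state studies.

Emulates the data the downstream analysis assumes: a 90-region parcellation,
230-timepoint region-averaged BOLD series (TR = 2 s) with modular
inter-regional covariance and AR(1) temporal smoothness, a pre-to-post
reduction of within-module coupling for treatment responders, and Poisson
seizure diaries around a 20% seizure-reduction response rule.

The generator is fully deterministic for a fixed :class:`CohortConfig`
(including its seed): identical configs reproduce byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "make_covariance",
    "simulate_bold",
    "apply_responder_effect",
    "simulate_seizure_diary",
    "make_cohort",
    "write_cohort",
    "read_timeseries",
    "read_metadata",
    "DEFAULT_ELECTRODE_POOL",
]

# Cathode placements drawn from the 10-10 system labels used clinically for
# focal epilepsy stimulation (single sites and two-focus pairs).
DEFAULT_ELECTRODE_POOL: tuple[tuple[str, ...], ...] = (
    ("F7",),
    ("F4",),
    ("F8",),
    ("CP6",),
    ("Between C3-FC1",),
    ("Between C3-F3",),
    ("Between F4-Fz",),
    ("Between C4-P4",),
    ("F7", "F8"),
)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated pre/post stimulation cohort.

    Defaults follow the acquisition and design the analysis expects:
    90 regions, 230 retained volumes at TR = 2 s, 12 active and 8 sham
    subjects with 4 responders in the active arm.
    """

    n_regions: int = 90
    n_timepoints: int = 230
    tr: float = 2.0
    n_active: int = 12
    n_sham: int = 8
    n_responders: int = 4
    block_sizes: tuple[int, ...] = (15, 15, 15, 15, 15, 15)
    rho_within: float = 0.6
    rho_between: float = 0.15
    responder_effect: float = 0.4
    ar_coef: float = 0.4
    baseline_rate: float = 30.0
    responder_rate_ratio: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_regions:
            raise ValueError(
                f"block_sizes sum to {sum(self.block_sizes)}, expected "
                f"n_regions={self.n_regions}"
            )
        if not 0 <= self.rho_between < self.rho_within < 1:
            raise ValueError("require 0 <= rho_between < rho_within < 1")
        if self.n_responders > self.n_active:
            raise ValueError("n_responders cannot exceed n_active")
        if not 0 <= self.responder_effect < 1:
            raise ValueError("responder_effect must be in [0, 1)")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must be in [0, 1)")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not 0 <= self.responder_rate_ratio < 1:
            raise ValueError("responder_rate_ratio must be in [0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "block_sizes" in d:
            d["block_sizes"] = tuple(d["block_sizes"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["block_sizes"] = list(d["block_sizes"])
        return d


@dataclass
class SubjectRecord:
    """One patient-session: arm, seizure counts and stimulation sites."""

    subject_id: str
    arm: str  # "active" | "sham"
    baseline_seizures: int
    followup_seizures: int
    stimulation_sites: tuple[str, ...]
    true_responder: bool | None = None

    def __post_init__(self) -> None:
        if self.arm not in ("active", "sham"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.baseline_seizures < 0 or self.followup_seizures < 0:
            raise ValueError("seizure counts must be non-negative")
        if not self.stimulation_sites:
            raise ValueError("stimulation_sites must be non-empty")


def make_covariance(
    block_sizes: Sequence[int], rho_within: float, rho_between: float
) -> np.ndarray:
    """Block-structured correlation matrix with unit diagonal.

    Entries are ``rho_within`` inside diagonal blocks and ``rho_between``
    across blocks.  With ``0 <= rho_between <= rho_within < 1`` the result
    is symmetric positive definite (a non-negative perturbation of compound
    symmetry); positive definiteness is asserted via Cholesky anyway.
    """
    if not 0 <= rho_between <= rho_within < 1:
        raise ValueError("require 0 <= rho_between <= rho_within < 1")
    n = int(sum(block_sizes))
    cov = np.full((n, n), float(rho_between))
    start = 0
    for size in block_sizes:
        cov[start : start + size, start : start + size] = rho_within
        start += size
    np.fill_diagonal(cov, 1.0)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by pre
        raise ValueError("constructed covariance is not positive definite") from exc
    return cov


def apply_responder_effect(
    cov: np.ndarray, effect: float, block_sizes: Sequence[int]
) -> np.ndarray:
    """Scale within-block off-diagonal correlations by ``1 - effect``.

    Models the post-stimulation reduction of within-module coupling seen in
    treatment responders; weakening the strongest (retained) edges lowers
    clustering and efficiency and lengthens shortest paths downstream.
    """
    if not 0 <= effect < 1:
        raise ValueError("effect must be in [0, 1)")
    if effect == 0:
        return cov.copy()
    out = cov.copy()
    start = 0
    for size in block_sizes:
        sl = slice(start, start + size)
        block = out[sl, sl] * (1.0 - effect)
        out[sl, sl] = block
        start += size
    np.fill_diagonal(out, np.diag(cov))
    try:
        np.linalg.cholesky(out)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "effect-modified covariance is not positive definite; "
            "use a smaller effect"
        ) from exc
    return out


def simulate_bold(
    cov: np.ndarray,
    n_timepoints: int,
    ar_coef: float = 0.4,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Draw an AR(1)-colored multivariate Gaussian series (regions x time).

    x_t = a * x_{t-1} + sqrt(1 - a^2) * L @ eps_t with L the Cholesky factor
    of ``cov``; the stationary cross-covariance then equals ``cov`` exactly,
    while ``a`` adds the temporal smoothness of band-limited BOLD.  The chain
    is initialised from its stationary distribution, so no burn-in is needed.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    if not 0 <= ar_coef < 1:
        raise ValueError("ar_coef must be in [0, 1)")
    try:
        chol = np.linalg.cholesky(np.asarray(cov, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    n = cov.shape[0]
    rng = np.random.default_rng(seed)
    innovations = chol @ rng.standard_normal((n, n_timepoints))
    out = np.empty((n, n_timepoints))
    out[:, 0] = innovations[:, 0]
    scale = np.sqrt(1.0 - ar_coef**2)
    for t in range(1, n_timepoints):
        out[:, t] = ar_coef * out[:, t - 1] + scale * innovations[:, t]
    return out


def simulate_seizure_diary(
    baseline_rate: float,
    rate_ratio: float,
    responder: bool,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[int, int]:
    """Poisson 4-week seizure counts (baseline, follow-up).

    Follow-up mean is ``baseline_rate * rate_ratio`` for responders and
    ``baseline_rate`` otherwise.  Baseline draws are conditioned on being
    at least 1, matching the inclusion criterion of at least one seizure
    during the 4-week baseline.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    rng = np.random.default_rng(seed)
    baseline = 0
    while baseline == 0:
        baseline = int(rng.poisson(baseline_rate))
    followup_mean = baseline_rate * rate_ratio if responder else baseline_rate
    followup = int(rng.poisson(followup_mean))
    return baseline, followup


def make_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectRecord], dict[str, dict[str, np.ndarray]]]:
    """Simulate subjects and their pre/post region-by-time series.

    Responders draw their post series from the effect-modified covariance;
    non-responders and sham subjects draw fresh noise from the unmodified
    covariance.  Response labels used downstream come from the simulated
    seizure counts (the operational definition), so ``true_responder`` and
    the count-derived label can disagree for individual subjects.
    """
    cov_pre = make_covariance(
        config.block_sizes, config.rho_within, config.rho_between
    )
    cov_post_responder = apply_responder_effect(
        cov_pre, config.responder_effect, config.block_sizes
    )
    master = np.random.SeedSequence(config.seed)
    n_total = config.n_active + config.n_sham
    # 3 independent streams per subject: pre series, post series, diary.
    streams = master.spawn(3 * n_total)

    subjects: list[SubjectRecord] = []
    series: dict[str, dict[str, np.ndarray]] = {}
    for idx in range(n_total):
        active = idx < config.n_active
        responder = active and idx < config.n_responders
        subject_id = f"sub-{idx + 1:02d}"
        sites = DEFAULT_ELECTRODE_POOL[idx % len(DEFAULT_ELECTRODE_POOL)]
        baseline, followup = simulate_seizure_diary(
            config.baseline_rate,
            config.responder_rate_ratio,
            responder,
            seed=streams[3 * idx + 2],
        )
        subjects.append(
            SubjectRecord(
                subject_id=subject_id,
                arm="active" if active else "sham",
                baseline_seizures=baseline,
                followup_seizures=followup,
                stimulation_sites=sites,
                true_responder=responder if active else None,
            )
        )
        cov_post = cov_post_responder if responder else cov_pre
        series[subject_id] = {
            "pre": simulate_bold(
                cov_pre, config.n_timepoints, config.ar_coef, streams[3 * idx]
            ),
            "post": simulate_bold(
                cov_post, config.n_timepoints, config.ar_coef, streams[3 * idx + 1]
            ),
        }
    return subjects, series


def region_labels(n_regions: int) -> list[str]:
    """Default region names ROI001..ROInnn."""
    return [f"ROI{i + 1:03d}" for i in range(n_regions)]


def write_cohort(
    out_dir: str | Path,
    subjects: Sequence[SubjectRecord],
    series: dict[str, dict[str, np.ndarray]],
    config: CohortConfig | None = None,
) -> Path:
    """Write metadata CSV and per-subject/-condition time-series CSVs.

    Each time-series file has one column per region (header row of region
    labels) and one row per timepoint; loaders transpose back to
    regions x time.
    """
    out_dir = Path(out_dir)
    ts_dir = out_dir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "arm": s.arm,
                "baseline_seizures": s.baseline_seizures,
                "followup_seizures": s.followup_seizures,
                "stimulation_sites": ";".join(s.stimulation_sites),
                "true_responder": "" if s.true_responder is None else s.true_responder,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "metadata.csv", index=False)
    labels = None
    for subject_id, conditions in series.items():
        for condition, mat in conditions.items():
            if labels is None:
                labels = region_labels(mat.shape[0])
            df = pd.DataFrame(mat.T, columns=labels)
            df.to_csv(ts_dir / f"{subject_id}_{condition}.csv", index=False)
    if config is not None:
        (out_dir / "cohort_config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=False)
        )
    return out_dir


def read_timeseries(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Load one time-series CSV -> (regions x time matrix, region labels)."""
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float).T, list(df.columns)


def read_metadata(path: str | Path) -> list[SubjectRecord]:
    """Load the cohort metadata CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    subjects = []
    for _, row in df.iterrows():
        tr = row.get("true_responder")
        if pd.isna(tr) or tr == "":
            true_responder = None
        else:
            true_responder = str(tr).strip().lower() in ("true", "1", "yes", "y")
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                arm=str(row["arm"]),
                baseline_seizures=int(row["baseline_seizures"]),
                followup_seizures=int(row["followup_seizures"]),
                stimulation_sites=tuple(
                    str(row["stimulation_sites"]).split(";")
                ),
                true_responder=true_responder,
            )
        )
    return subjects
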