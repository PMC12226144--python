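"""Fully synthetic subject cohorts with Ising-derived connectivity.

The generator emulates the downstream shape of a neurodevelopmental
resting-state study: each subject has an age drawn uniformly from the study
span (8-22 years by default), a group label (control / adhd), head-motion
summary covariates, and a "true" Ising temperature that declines linearly
with age plus Gaussian jitter,

    T_i = intercept + slope * (age_i - age_min) + N(0, noise_sd),

clipped to the regressor's training interval. Connectivity matrices are then
actual Ising simulations at T_i under the chosen preset, so the full
pipeline — estimation, age trends, group bootstrap, confound regression —
can be exercised end to end with a known ground truth. Motion covariates are
truncated normals within the usual retention range (< 1.5 mm / < 1.5 deg)
and independent of age unless a dependence is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .coarse_grain import PRESETS, SimPreset, ising_connectivity, save_matrix
from .errors import ConfigError

__all__ = ["CohortSpec", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs of the synthetic cohort."""

    n_subjects: int = 150
    age_range: tuple[float, float] = (8.0, 22.0)
    slope: float = -0.02       # temperature change per year
    intercept: float = 2.35    # temperature at the youngest age
    noise_sd: float = 0.03
    t_clip: tuple[float, float] = (1.8, 2.5)
    group_fractions: dict = field(default_factory=lambda: {"control": 0.69, "adhd": 0.31})
    motion_mean: float = 0.6   # mm / deg, truncated normal on [0, 1.5]
    motion_sd: float = 0.3
    motion_limit: float = 1.5
    motion_age_corr: float = 0.0  # optional linear age dependence of max_motion
    sim_preset: str = "small"
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if abs(sum(self.group_fractions.values()) - 1.0) > 1e-9:
            raise ConfigError("group fractions must sum to 1")


def _truncated_normal(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    spec: CohortSpec,
    make_matrices: bool = True,
    preset: SimPreset | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray] | None]:
    """Draw a cohort table (with ground-truth temperatures) and, optionally,
    one simulated connectivity matrix per subject.

    ``make_matrices=False`` returns only the phenotype table, which is enough
    for label-level checks and orders of magnitude faster.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, size=spec.n_subjects)
    t_raw = spec.intercept + spec.slope * (ages - lo) + rng.normal(0.0, spec.noise_sd, spec.n_subjects)
    c_lo, c_hi = spec.t_clip
    if (t_raw < c_lo).all() or (t_raw > c_hi).all():
        raise ConfigError(
            f"slope/intercept place every temperature outside the clip range {spec.t_clip}"
        )
    t_true = np.clip(t_raw, c_lo, c_hi)
    names, fracs = zip(*spec.group_fractions.items())
    groups = rng.choice(names, size=spec.n_subjects, p=fracs)
    motion = _truncated_normal(
        spec.motion_mean, spec.motion_sd, 0.0, spec.motion_limit, spec.n_subjects, rng
    )
    if spec.motion_age_corr:
        # mix in a scaled age signal, then re-clip to the retention range
        z_age = (ages - ages.mean()) / ages.std()
        motion = np.clip(
            motion + spec.motion_age_corr * spec.motion_sd * z_age, 0.0, spec.motion_limit
        )
    rotation = _truncated_normal(
        spec.motion_mean, spec.motion_sd, 0.0, spec.motion_limit, spec.n_subjects, rng
    )
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(spec.n_subjects)],
            "group": groups,
            "age": ages,
            "max_motion": motion,
            "max_rotation": rotation,
            "T_true": t_true,
        }
    )
    matrices = None
    if make_matrices:
        sim_preset = preset or PRESETS[spec.sim_preset]
        ss = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
        matrices = {}
        for i, row in table.iterrows():
            sim_seed = int(ss[i].generate_state(1)[0] % (2**31))
            cfg = sim_preset.config(float(row["T_true"]), sim_seed)
            matrices[row["subject_id"]] = ising_connectivity(
                cfg, sim_preset.block_size, sim_preset.target_n
            )
    return table, matrices


def write_cohort(table: pd.DataFrame, matrices: dict[str, np.ndarray] | None, outdir: str | Path) -> Path:
    """Emit the phenotype table and per-subject matrices in the formats the
    estimator and cohort statistics consume (ground truth kept alongside)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pheno = table.rename(
        columns={"max_motion": "max_motion_mm", "max_rotation": "max_rotation_deg"}
    )
    pheno.to_csv(outdir / "phenotype.csv", index=False)
    if matrices:
        mdir = outdir / "matrices"
        mdir.mkdir(exist_ok=True)
        for sid, conn in matrices.items():
            save_matrix(conn, mdir / f"{sid}.csv")
    return outdir
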