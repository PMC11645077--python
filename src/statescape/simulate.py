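"""Synthetic two-group cohorts with planted Ising-parameter differences.

The generator inverts the analysis chain: per-subject pairwise-MEM
parameters (group base values plus an optional patient-group delta plus
per-subject Gaussian jitter) are sampled into binarized state sequences, or
into continuous BOLD-like surrogates whose per-ROI mean-threshold
binarization recovers those sequences.  Ground-truth parameters are kept so
downstream stages can be validated by parameter and effect recovery.

Default cohort dimensions follow the study design this package targets:
two groups of 63 (controls) and 55 (patients) subjects, eight ROIs, 888
time points per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ising import MEMParameters, boltzmann_distribution, sample_ising
from .signals import StateSequence, empirical_distribution

__all__ = [
    "CohortConfig",
    "BehaviorLoading",
    "BehaviorSpec",
    "Subject",
    "Cohort",
    "default_cohort_config",
    "planted_cohort_config",
    "generate_cohort",
    "generate_behavior",
    "generate_toy_image",
    "write_cohort",
]


@dataclass
class CohortConfig:
    """Full description of a synthetic two-group cohort.

    ``base_h`` / ``base_J`` define the control-group model; the patient
    group adds ``patient_delta_h`` / ``patient_delta_J``.  Each subject's
    parameters are further perturbed by i.i.d. ``N(0, subject_jitter_sd^2)``
    noise (symmetrised for J) to emulate inter-individual variability.
    ``mode="continuous"`` emits spin amplitude ``+-amplitude`` plus Gaussian
    noise (optionally AR(1)-smoothed) instead of raw spins.
    """

    n_rois: int = 8
    n_controls: int = 63
    n_patients: int = 55
    n_timepoints: int = 888
    base_h: np.ndarray | None = None
    base_J: np.ndarray | None = None
    patient_delta_h: np.ndarray | None = None
    patient_delta_J: np.ndarray | None = None
    subject_jitter_sd: float = 0.05
    mode: str = "binary"
    amplitude: float = 1.0
    noise_sd: float = 0.5
    ar_coeff: float = 0.0
    seed: int = 0

    def __post_init__(self):
        n = self.n_rois
        if n < 2:
            raise ValueError("n_rois must be >= 2")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.subject_jitter_sd < 0:
            raise ValueError("subject_jitter_sd must be >= 0")
        if self.mode not in ("binary", "continuous"):
            raise ValueError("mode must be 'binary' or 'continuous'")
        self.base_h = np.zeros(n) if self.base_h is None else np.asarray(self.base_h, float)
        self.base_J = np.zeros((n, n)) if self.base_J is None else np.asarray(self.base_J, float)
        self.patient_delta_h = (
            np.zeros(n) if self.patient_delta_h is None else np.asarray(self.patient_delta_h, float)
        )
        self.patient_delta_J = (
            np.zeros((n, n)) if self.patient_delta_J is None else np.asarray(self.patient_delta_J, float)
        )
        for name, M in (("base_J", self.base_J), ("patient_delta_J", self.patient_delta_J)):
            if M.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if not np.allclose(M, M.T) or not np.allclose(np.diag(M), 0):
                raise ValueError(f"{name} must be symmetric with zero diagonal")
        if self.base_h.shape != (n,) or self.patient_delta_h.shape != (n,):
            raise ValueError("h vectors must have length n_rois")


def default_cohort_config(**overrides) -> CohortConfig:
    """Null cohort at study dimensions: identical groups, mild jitter.

    Base parameters: slightly negative fields (h = -0.2, regions inactive
    more often than active, as is typical of sparse binarized BOLD) and a
    nearest-neighbour coupling chain (J = 0.3) plus a stronger J12 = 0.6
    link, giving the landscape non-trivial structure.
    """
    cfg = dict(n_rois=8, n_controls=63, n_patients=55, n_timepoints=888)
    cfg.update(overrides)
    n = cfg["n_rois"]
    if "base_h" not in cfg:
        cfg["base_h"] = np.full(n, -0.2)
    if "base_J" not in cfg:
        J = np.zeros((n, n))
        for i in range(n - 1):
            J[i, i + 1] = J[i + 1, i] = 0.3
        J[0, 1] = J[1, 0] = 0.6
        cfg["base_J"] = J
    return CohortConfig(**cfg)


def planted_cohort_config(delta: float = 0.6, edge: tuple[int, int] = (0, 1), **overrides) -> CohortConfig:
    """Cohort whose patient group loses ``delta`` of coupling on one edge.

    With the default edge (0, 1) and delta 0.6 the patient group's J12 drops
    from 0.6 to 0.0: the control-analogue group keeps the deeper co-activation
    basin, mirroring the direction reported for patient cohorts (lower
    connectivity, shallower paired-state basins).
    """
    cfg = default_cohort_config(**overrides)
    dJ = np.array(cfg.patient_delta_J)
    i, j = edge
    dJ[i, j] -= delta
    dJ[j, i] -= delta
    cfg.patient_delta_J = dJ
    return cfg


@dataclass
class Subject:
    subject_id: str
    group: str  # "control" | "patient"
    params: MEMParameters  # ground truth
    states: StateSequence
    series: pd.DataFrame | None = None  # continuous surrogate (mode="continuous")


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[Subject] = field(default_factory=list)

    @property
    def groups(self) -> pd.Series:
        return pd.Series({s.subject_id: s.group for s in self.subjects}, name="group")

    def group_params(self) -> dict[str, MEMParameters]:
        """Noise-free ground-truth parameters of each group."""
        c = self.config
        return {
            "control": MEMParameters(c.base_h, c.base_J),
            "patient": MEMParameters(c.base_h + c.patient_delta_h, c.base_J + c.patient_delta_J),
        }


def _jitter_params(h, J, sd, rng) -> MEMParameters:
    n = h.size
    if sd > 0:
        h = h + rng.normal(0, sd, n)
        upper = rng.normal(0, sd, (n, n))
        pert = np.triu(upper, 1)
        J = J + pert + pert.T
    return MEMParameters(h=h, J=J)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> Cohort:
    """Sample a full two-group cohort; bit-reproducible given (config, seed)."""
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    cohort = Cohort(config=config)
    specs = [("control", config.n_controls, np.zeros_like(config.base_h), np.zeros_like(config.base_J)),
             ("patient", config.n_patients, config.patient_delta_h, config.patient_delta_J)]
    idx = 0
    for group, count, dh, dJ in specs:
        for g_i in range(count):
            idx += 1
            sub_seed = root.spawn(1)[0]
            rng = np.random.default_rng(sub_seed)
            params = _jitter_params(config.base_h + dh, config.base_J + dJ,
                                    config.subject_jitter_sd, rng)
            states = sample_ising(params, config.n_timepoints, seed=rng, method="exact")
            sid = f"{'C' if group == 'control' else 'P'}{g_i + 1:03d}"
            states.subject_id = sid
            series = None
            if config.mode == "continuous":
                noise = rng.normal(0, config.noise_sd, states.spins.shape)
                if config.ar_coeff:
                    a = config.ar_coeff
                    for t in range(1, noise.shape[0]):
                        noise[t] = a * noise[t - 1] + np.sqrt(1 - a * a) * noise[t]
                values = config.amplitude * states.spins + noise
                series = pd.DataFrame(values, columns=states.roi_names)
            cohort.subjects.append(Subject(sid, group, params, states, series))
    return cohort


# ---------------------------------------------------------------------------
# behavioural covariates


@dataclass
class BehaviorLoading:
    """Linear link between a score and the mean probability of target states."""

    target_states: tuple[int, ...]
    coefficient: float
    noise_sd: float
    group_shift: float = 0.0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be > 0")


@dataclass
class BehaviorSpec:
    loadings: dict[str, BehaviorLoading]
    intercept: float = 0.0


def generate_behavior(cohort: Cohort, spec: BehaviorSpec, seed: int | None = None) -> pd.DataFrame:
    """One behavioural score row per subject.

    score = intercept + coefficient * mean(empirical probability of the
    target states) + group_shift (patients only) + Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    probs = {s.subject_id: empirical_distribution(s.states).probs for s in cohort.subjects}
    for name, load in spec.loadings.items():
        col = {}
        for s in cohort.subjects:
            p = probs[s.subject_id][list(load.target_states)].mean()
            val = spec.intercept + load.coefficient * p
            if s.group == "patient":
                val += load.group_shift
            col[s.subject_id] = val + rng.normal(0, load.noise_sd)
        rows[name] = col
    df = pd.DataFrame(rows)
    df.index.name = "subject_id"
    df.insert(0, "group", cohort.groups.reindex(df.index))
    return df


# ---------------------------------------------------------------------------
# toy volumetric fixture


def generate_toy_image(n_rois: int, voxels_per_roi: int, series, seed: int | None = None,
                       noise_sd: float = 0.0):
    """A 4-D volume + label volume whose ROI means reproduce ``series``.

    Voxels of ROI ``r`` (label value ``r``) carry that ROI's time series
    plus i.i.d. Gaussian noise; label 0 is background.  Returned as nibabel
    images with identity affine (an in-memory fixture for the extraction
    stage, not an anatomically meaningful volume).
    """
    import nibabel as nib

    values = np.asarray(series, dtype=float)
    if values.ndim != 2 or values.shape[1] != n_rois:
        raise ValueError("series must be T x n_rois")
    if voxels_per_roi < 1:
        raise ValueError("voxels_per_roi must be >= 1")
    rng = np.random.default_rng(seed)
    T = values.shape[0]
    nvox = n_rois * voxels_per_roi + 1  # one background voxel
    data = np.zeros((nvox, 1, 1, T))
    labels = np.zeros((nvox, 1, 1), dtype=np.int16)
    for r in range(n_rois):
        sl = slice(r * voxels_per_roi, (r + 1) * voxels_per_roi)
        block = np.tile(values[:, r], (voxels_per_roi, 1))
        if noise_sd > 0:
            block = block + rng.normal(0, noise_sd, block.shape)
        data[sl, 0, 0, :] = block
        labels[sl, 0, 0] = r + 1
    affine = np.eye(4)
    return nib.Nifti1Image(data, affine), nib.Nifti1Image(labels, affine)


# ---------------------------------------------------------------------------
# on-disk layout (CLI)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Per-subject series CSVs, a subjects table and ground-truth parameters."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    rows = []
    for s in cohort.subjects:
        rows.append({"subject_id": s.subject_id, "group": s.group})
        df = s.series if s.series is not None else pd.DataFrame(
            s.states.spins, columns=s.states.roi_names)
        df.to_csv(out / "timeseries" / f"{s.subject_id}.csv", index=False)
        np.savetxt(out / "truth" / f"{s.subject_id}_h.csv", s.params.h, delimiter=",")
        np.savetxt(out / "truth" / f"{s.subject_id}_J.csv", s.params.J, delimiter=",")
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
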