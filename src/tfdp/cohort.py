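"""Phenomenological generator of patient-like two-peak profiles and cohorts.

The mechanistic mixture simulator places derivative peaks strictly inside the
span of its components' Tms, but measured tear profiles show emergent peak
positions (e.g. a second apex above every component Tm).  Cohort-level
work therefore uses a phenomenological model that controls the biomarker
directly: the fluorescence ratio is a baseline plus one logistic step per
transition, so the derivative apexes sit exactly at the chosen (t1m, t2m).

``generate_cohort`` draws per-subject (t1m, t2m) from class-conditional
Gaussians whose default means are the two cluster averages observed in
patients — (67.9, 77.7) degC for the control-like class and (64.6, 79.3) degC
for the glaucoma-like class — jitters the nuisance shape parameters, and
derives per-subject random streams deterministically from the cohort seed.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, DegenerateSpecWarning, InvalidInputError
from .io import DEFAULT_GRID, NanoDSFRun, TemperatureGrid, write_runs

__all__ = [
    "TwoPeakSpec",
    "ClassSpec",
    "ShapeJitter",
    "CohortConfig",
    "CohortDataset",
    "generate_profile",
    "generate_cohort",
    "CONTROL_LABEL",
    "POAG_LABEL",
]

CONTROL_LABEL = "CONTROL"  # encoded 0
POAG_LABEL = "POAG"  # encoded 1


@dataclass(frozen=True)
class TwoPeakSpec:
    """Shape of one two-transition ratio profile.

    The ratio curve is ``baseline + slope*(T-35) + amp1*L((T-t1m)/width1)
    + amp2*L((T-t2m)/width2)`` with L the logistic CDF; F330 decays linearly
    from ``f330_level`` and F350 = ratio * F330.  Widths are the logistic
    scale in degC (derivative FWHM ~ 3.5 x width); amplitudes are the ratio
    step heights.  Defaults mimic a healthy tear profile.
    """

    t1m: float = 67.9
    t2m: float = 77.7
    width1: float = 0.8
    width2: float = 0.8
    amp1: float = 0.25
    amp2: float = 0.25
    ratio_baseline: float = 0.85
    ratio_slope: float = 5e-4
    f330_level: float = 1000.0
    f330_decay: float = 0.002
    noise_sigma_rel: float = 0.002

    def __post_init__(self) -> None:
        if self.width1 <= 0 or self.width2 <= 0:
            raise InvalidInputError("transition widths must be > 0")
        if self.amp1 < 0 or self.amp2 < 0:
            raise InvalidInputError("amplitudes must be >= 0")
        if self.f330_level <= 0:
            raise InvalidInputError("f330_level must be > 0")
        if self.noise_sigma_rel < 0:
            raise InvalidInputError("noise_sigma_rel must be >= 0")
        if self.amp1 > 0 and self.amp2 > 0 and not self.t1m < self.t2m:
            raise InvalidInputError("t1m must be < t2m when both transitions are present")


def generate_profile(
    spec: TwoPeakSpec,
    grid: TemperatureGrid = DEFAULT_GRID,
    seed: int | np.random.Generator | None = None,
    sample_id: str = "synthetic",
    label: str | None = None,
) -> NanoDSFRun:
    """Generate one melting run from a two-peak spec.

    With zero noise the derivative of the ratio has local maxima at ``t1m``
    and ``t2m`` (exact when the transitions are well separated).  A spec with
    both amplitudes zero warns and returns a flat (featureless) profile.
    """
    t = grid.values
    if spec.amp1 == 0 and spec.amp2 == 0:
        warnings.warn("both amplitudes are zero: flat profile", DegenerateSpecWarning, stacklevel=2)
    ratio = (
        spec.ratio_baseline
        + spec.ratio_slope * (t - 35.0)
        + spec.amp1 * expit((t - spec.t1m) / spec.width1)
        + spec.amp2 * expit((t - spec.t2m) / spec.width2)
    )
    f330 = spec.f330_level * (1.0 - spec.f330_decay * (t - 35.0))
    f350 = ratio * f330
    if spec.noise_sigma_rel > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        f330 = f330 * (1.0 + spec.noise_sigma_rel * rng.standard_normal(t.shape))
        f350 = f350 * (1.0 + spec.noise_sigma_rel * rng.standard_normal(t.shape))
    return NanoDSFRun(sample_id=sample_id, temperatures=t.copy(), f330=f330, f350=f350, label=label)


@dataclass(frozen=True)
class ClassSpec:
    """Class-conditional distribution of the biomarker: Gaussian (t1m, t2m)
    means and SDs (degC) and the class size."""

    mean_t1m: float
    mean_t2m: float
    sd_t1m: float = 0.8
    sd_t2m: float = 0.8
    n: int = 100

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("need n >= 2 subjects per class")
        if self.sd_t1m < 0 or self.sd_t2m < 0:
            raise ConfigurationError("SDs must be >= 0")
        if not self.mean_t1m < self.mean_t2m:
            raise ConfigurationError("mean_t1m must be < mean_t2m")


@dataclass(frozen=True)
class ShapeJitter:
    """Between-subject SDs of the nuisance shape parameters."""

    width_sd: float = 0.10
    amp_sd: float = 0.010
    baseline_sd: float = 0.020
    slope_sd: float = 1e-4
    level_rel_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("width_sd", "amp_sd", "baseline_sd", "slope_sd", "level_rel_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """A two-class cohort: per-class biomarker distributions, shared shape
    jitter and noise, and the master seed.  Class means default to the
    cluster averages seen in patients."""

    control: ClassSpec = field(default_factory=lambda: ClassSpec(67.9, 77.7))
    poag: ClassSpec = field(default_factory=lambda: ClassSpec(64.6, 79.3))
    jitter: ShapeJitter = field(default_factory=ShapeJitter)
    base_shape: TwoPeakSpec = field(default_factory=TwoPeakSpec)
    noise_sigma_rel: float = 0.002
    seed: int = 0


@dataclass
class CohortDataset:
    """Generated runs, integer labels (CONTROL=0, POAG=1) and the generating
    truth table (sample_id, label, true_t1m, true_t2m)."""

    runs: list[NanoDSFRun]
    labels: np.ndarray
    truth: pd.DataFrame

    def __post_init__(self) -> None:
        if not (len(self.runs) == len(self.labels) == len(self.truth)):
            raise InvalidInputError("runs, labels and truth must have equal lengths")

    def checksum(self) -> str:
        """SHA-256 over all channel data and truth values (reproducibility probe)."""
        h = hashlib.sha256()
        for run in self.runs:
            h.update(run.sample_id.encode())
            h.update(run.temperatures.tobytes())
            h.update(run.f330.tobytes())
            h.update(run.f350.tobytes())
        h.update(self.labels.astype(np.int64).tobytes())
        h.update(self.truth.to_csv(index=False).encode())
        return h.hexdigest()

    def write(self, runs_path, truth_path) -> None:
        write_runs(self.runs, runs_path)
        self.truth.to_csv(truth_path, index=False, float_format="%.6g")


def _child_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    # stable integer mix: SeedSequence over (cohort seed, subject index)
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), int(subject_index))))


def _draw_subject(
    rng: np.random.Generator, cls: ClassSpec, cfg: CohortConfig
) -> TwoPeakSpec:
    for _ in range(1000):
        t1m = rng.normal(cls.mean_t1m, cls.sd_t1m)
        t2m = rng.normal(cls.mean_t2m, cls.sd_t2m)
        if t1m < t2m - 4.0:
            break
    else:
        raise ConfigurationError("could not draw t1m < t2m - 4 degC; check class means/SDs")
    j = cfg.jitter
    base = cfg.base_shape
    return replace(
        base,
        t1m=t1m,
        t2m=t2m,
        width1=max(0.3, base.width1 + rng.normal(0.0, j.width_sd)),
        width2=max(0.3, base.width2 + rng.normal(0.0, j.width_sd)),
        amp1=max(0.01, base.amp1 + rng.normal(0.0, j.amp_sd)),
        amp2=max(0.01, base.amp2 + rng.normal(0.0, j.amp_sd)),
        ratio_baseline=base.ratio_baseline + rng.normal(0.0, j.baseline_sd),
        ratio_slope=base.ratio_slope + rng.normal(0.0, j.slope_sd),
        f330_level=base.f330_level * max(0.2, 1.0 + rng.normal(0.0, j.level_rel_sd)),
        noise_sigma_rel=cfg.noise_sigma_rel,
    )


def generate_cohort(config: CohortConfig, grid: TemperatureGrid = DEFAULT_GRID) -> CohortDataset:
    """Generate a labelled two-class cohort of melting runs.

    Per subject, (t1m, t2m) are drawn from the class-conditional Gaussians
    (rejection-resampled so t1m < t2m - 4 degC), shape parameters are
    jittered, and the profile is generated with a child random stream derived
    deterministically from ``config.seed`` and the subject index — so the
    whole dataset is reproducible bit-for-bit.
    """
    runs: list[NanoDSFRun] = []
    labels: list[int] = []
    truth_rows = []
    subject = 0
    for label_name, label_int, cls in (
        (CONTROL_LABEL, 0, config.control),
        (POAG_LABEL, 1, config.poag),
    ):
        for _ in range(cls.n):
            rng = _child_rng(config.seed, subject)
            spec = _draw_subject(rng, cls, config)
            sid = f"{label_name}_{subject:04d}"
            runs.append(generate_profile(spec, grid, seed=rng, sample_id=sid, label=label_name))
            labels.append(label_int)
            truth_rows.append(
                {"sample_id": sid, "label": label_name, "true_t1m": spec.t1m, "true_t2m": spec.t2m}
            )
            subject += 1
    return CohortDataset(runs=runs, labels=np.asarray(labels), truth=pd.DataFrame(truth_rows))
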