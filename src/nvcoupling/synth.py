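"""Synthetic BOLD phantoms with known lag, connectivity, group-effect, and
brain-behavior ground truth.

The generative model: a latent low-frequency signal s(t) is sampled on a
grid extended by max_lag samples on both ends, so that integer TR shifts
are genuine translations (no wrap-around). Venous voxels carry s(t) plus
noise (true lag 0 by construction); each voxel of region r carries
s(t - d_r) + w_r * g_r(t) plus noise, where d_r is the region's integer lag,
g_r a region-shared signal controlling connectivity, and the noise is
independent per voxel. Patients receive additive per-region lag and
connectivity offsets; behavioral scores are linear mixtures of a subject's
true regional metric and independent noise tuned to a target correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .imaging import BinaryMask, BoldImage, LabelAtlas

__all__ = [
    "BehaviorSpec",
    "SimulationConfig",
    "GroundTruth",
    "Subject",
    "make_toy_atlas",
    "simulate_subject",
    "simulate_cohort",
]


class BehaviorSpec(NamedTuple):
    score: str
    region: int
    metric: str  # "lag" or "weight"
    target_correlation: float


@dataclass
class SimulationConfig:
    n_regions: int = 6
    voxels_per_region: int = 20
    n_venous_voxels: int = 12
    n_timepoints: int = 150
    tr_seconds: float = 2.32
    max_lag: int = 3
    region_lags: Sequence[int] | None = None
    shared_signal_weight: Sequence[float] | float = 0.5
    noise_sd: float = 0.5
    band: tuple[float, float] = (0.01, 0.08)
    group_lag_offset: Sequence[float] | float = 0.0
    group_connectivity_offset: Sequence[float] | float = 0.0
    lag_jitter_sd: float = 0.0
    weight_jitter_sd: float = 0.0
    behavior_spec: Sequence[BehaviorSpec] = ()
    n_per_group: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_regions", "voxels_per_region", "n_venous_voxels",
                     "n_timepoints", "n_per_group", "max_lag"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_timepoints <= 2 * self.max_lag + 2:
            raise ValueError("n_timepoints must exceed 2*max_lag + 2")
        if self.region_lags is None:
            # alternating small lags by default, all within the window
            base = [0, 1, -1, 2, -2, 3, -3]
            self.region_lags = tuple(base[i % len(base)] for i in range(self.n_regions))
        self.region_lags = tuple(int(d) for d in self.region_lags)
        if len(self.region_lags) != self.n_regions:
            raise ValueError("region_lags must have one entry per region")
        if any(abs(d) > self.max_lag for d in self.region_lags):
            raise ValueError(f"|region_lags| must be <= max_lag={self.max_lag}")
        self.shared_signal_weight = self._per_region(self.shared_signal_weight,
                                                     "shared_signal_weight")
        if any(w < 0 for w in self.shared_signal_weight):
            raise ValueError("shared_signal_weight must be >= 0")
        self.group_lag_offset = self._per_region(self.group_lag_offset,
                                                 "group_lag_offset")
        self.group_connectivity_offset = self._per_region(
            self.group_connectivity_offset, "group_connectivity_offset")
        low, high = self.band
        if not (0 <= low < high < 1.0 / (2 * self.tr_seconds)):
            raise ValueError("band must satisfy 0 <= low < high < Nyquist")
        self.behavior_spec = tuple(BehaviorSpec(*b) for b in self.behavior_spec)
        for b in self.behavior_spec:
            if abs(b.target_correlation) > 1:
                raise ValueError(f"|target_correlation| > 1 for score {b.score!r}")
            if not (1 <= b.region <= self.n_regions):
                raise ValueError(f"behavior_spec region {b.region} out of range")
            if b.metric not in ("lag", "weight"):
                raise ValueError(f"behavior_spec metric must be 'lag' or 'weight', "
                                 f"got {b.metric!r}")

    def _per_region(self, value, name) -> tuple[float, ...]:
        if np.isscalar(value):
            return tuple(float(value) for _ in range(self.n_regions))
        value = tuple(float(v) for v in value)
        if len(value) != self.n_regions:
            raise ValueError(f"{name} must be scalar or length n_regions")
        return value


@dataclass
class GroundTruth:
    """What was injected: per-voxel lag (NaN on background), realized
    per-region lags and shared-signal weights, group label, and seed."""

    true_lag: np.ndarray
    region_lags: dict[int, int]
    region_weights: dict[int, float]
    group: str
    seed: int


@dataclass
class Subject:
    subject_id: str
    group: str
    bold: BoldImage
    atlas: LabelAtlas
    venous_mask: BinaryMask
    ground_truth: GroundTruth


def make_toy_atlas(
    n_regions: int, voxels_per_region: int, n_venous_voxels: int
) -> tuple[LabelAtlas, BinaryMask]:
    """Flat phantom grid: region r occupies a contiguous block of
    voxels_per_region voxels (label r), the venous compartment sits after all
    regions (label 0 in the atlas). Regions and venous voxels are disjoint by
    construction."""
    if n_regions < 1 or voxels_per_region < 1 or n_venous_voxels < 1:
        raise ValueError("all make_toy_atlas arguments must be >= 1")
    total = n_regions * voxels_per_region + n_venous_voxels
    labels = np.zeros((total, 1, 1), dtype=np.int32)
    for r in range(n_regions):
        labels[r * voxels_per_region:(r + 1) * voxels_per_region] = r + 1
    venous = np.zeros((total, 1, 1), dtype=bool)
    venous[n_regions * voxels_per_region:] = True
    return LabelAtlas(labels), BinaryMask(venous)


def _bandlimited_noise(rng: np.random.Generator, n: int, tr: float,
                       band: tuple[float, float]) -> np.ndarray:
    """White Gaussian noise band-passed to `band`, unit-variance normalized."""
    x = rng.standard_normal(n)
    low, high = band
    if low > 0:
        sos = spsig.butter(2, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    else:
        sos = spsig.butter(2, high, btype="lowpass", fs=1.0 / tr, output="sos")
    y = spsig.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _realize_subject_params(config: SimulationConfig, rng: np.random.Generator,
                            group: str):
    """Per-subject realized region lags and weights (group offsets + jitter)."""
    lags, weights = [], []
    for r in range(config.n_regions):
        d = float(config.region_lags[r])
        w = config.shared_signal_weight[r]
        if group == "patient":
            d += config.group_lag_offset[r]
            w += config.group_connectivity_offset[r]
        if config.lag_jitter_sd > 0:
            d += rng.normal(0, config.lag_jitter_sd)
        if config.weight_jitter_sd > 0:
            w += rng.normal(0, config.weight_jitter_sd)
        lags.append(int(np.clip(round(d), -config.max_lag, config.max_lag)))
        weights.append(max(0.0, w))
    return lags, weights


def simulate_subject(
    config: SimulationConfig,
    subject_seed: int,
    group: str = "control",
) -> tuple[BoldImage, LabelAtlas, BinaryMask, GroundTruth]:
    """Generate one subject. Deterministic in (config, subject_seed, group)."""
    if group not in ("control", "patient"):
        raise ValueError(f"group must be 'control' or 'patient', got {group!r}")
    rng = np.random.default_rng([config.seed, int(subject_seed)])
    lags, weights = _realize_subject_params(config, rng, group)

    atlas, venous = make_toy_atlas(config.n_regions, config.voxels_per_region,
                                   config.n_venous_voxels)
    T, L = config.n_timepoints, config.max_lag
    latent = _bandlimited_noise(rng, T + 2 * L, config.tr_seconds, config.band)
    shared = [_bandlimited_noise(rng, T, config.tr_seconds, config.band)
              for _ in range(config.n_regions)]

    data = np.zeros((*atlas.data.shape, T))
    true_lag = np.full(atlas.data.shape, np.nan)
    ref = latent[L:L + T]
    for r in range(config.n_regions):
        vox = atlas.data == r + 1
        d = lags[r]
        base = latent[L - d:L - d + T]  # base(t) = ref(t - d): delayed copy
        data[vox] = base + weights[r] * shared[r]
        true_lag[vox] = d
    data[venous.data] = ref
    true_lag[venous.data] = 0.0
    if config.noise_sd > 0:
        data += config.noise_sd * rng.standard_normal(data.shape)

    bold = BoldImage(data, config.tr_seconds, np.eye(4))
    gt = GroundTruth(
        true_lag=true_lag,
        region_lags={r + 1: lags[r] for r in range(config.n_regions)},
        region_weights={r + 1: weights[r] for r in range(config.n_regions)},
        group=group,
        seed=int(subject_seed),
    )
    return bold, atlas, venous, gt


def simulate_cohort(config: SimulationConfig) -> tuple[list[Subject], pd.DataFrame]:
    """Generate a two-group cohort plus a subject records table.

    Controls use base parameters; patients add the group offsets. Behavioral
    scores are built as rho * z(metric_true) + sqrt(1 - rho^2) * eps so the
    expected score-metric correlation equals the target."""
    if config.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    subjects: list[Subject] = []
    idx = 0
    for group, prefix in (("control", "C"), ("patient", "P")):
        for k in range(config.n_per_group):
            bold, atlas, venous, gt = simulate_subject(config, idx, group)
            subjects.append(Subject(f"sub-{prefix}{k:03d}", group, bold, atlas,
                                    venous, gt))
            idx += 1

    rng = np.random.default_rng([config.seed, 982_451_653])  # cohort-level stream
    n = len(subjects)
    records = pd.DataFrame({
        "subject_id": [s.subject_id for s in subjects],
        "group": [s.group for s in subjects],
        "age": np.round(rng.uniform(19, 65, n), 1),
        "education": np.round(rng.uniform(6, 22, n), 1),
        "sex": rng.choice(["M", "F"], size=n, p=[0.7, 0.3]),
    })
    for spec in config.behavior_spec:
        if spec.metric == "lag":
            vals = np.array([s.ground_truth.region_lags[spec.region]
                             for s in subjects], dtype=float)
        else:
            vals = np.array([s.ground_truth.region_weights[spec.region]
                             for s in subjects], dtype=float)
        sd = vals.std()
        rho = spec.target_correlation
        if sd == 0:
            if rho != 0:
                raise ValueError(
                    f"metric {spec.metric!r} of region {spec.region} has zero "
                    f"variance across the cohort; cannot hit correlation {rho}")
            z = np.zeros(n)
        else:
            z = (vals - vals.mean()) / sd
        eps = rng.standard_normal(n)
        records[spec.score] = rho * z + np.sqrt(1.0 - rho * rho) * eps
    return subjects, records
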