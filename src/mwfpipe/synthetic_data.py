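"""Synthetic multi-echo phantoms and clinical cohorts with known ground truth.

Two generators live here:

* :func:`make_phantom` builds a 4D multi-echo magnitude volume from a
  multi-compartment exponential T2 decay model (myelin water, intra/
  extracellular water, free water), with spherical lesions embedded in a
  cuboid white-matter "brain" and a per-voxel ground-truth myelin water
  fraction (MWF) map.
* :func:`simulate_cohort` draws a cohort of subjects in which the
  lesion/NAWM MWF ratio linearly predicts the change in Timed Up and Go
  (TUG) time, with a tunable planted effect size.

Everything is deterministic for a fixed seed and never touches disk; the
writers live in :mod:`mwfpipe.io_cli`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionProtocol",
    "PoolSet",
    "PhantomSpec",
    "Phantom",
    "CohortParams",
    "pool_signal",
    "make_phantom",
    "simulate_cohort",
    "calibrate_noise_sd",
]

#: Short-T2 window attributed to myelin water, ms (half-open).
SHORT_WINDOW = (15.0, 40.0)
#: Total spectrum window used in the MWF denominator, ms (closed).
TOTAL_WINDOW = (15.0, 2000.0)


def default_echo_times() -> np.ndarray:
    """32 echoes at 10, 20, ..., 320 ms (a whole-cerebrum GRASE protocol)."""
    return np.arange(10.0, 321.0, 10.0)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Echo timing of a multi-echo T2 acquisition.

    Parameters
    ----------
    echo_times
        Echo times in ms, strictly increasing and positive.
    repetition_time
        TR in ms; metadata only, never enters the signal model.
    """

    echo_times: np.ndarray = field(default_factory=default_echo_times)
    repetition_time: float = 1000.0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.ndim != 1 or te.size == 0:
            raise ValueError("echo_times must be a non-empty 1D sequence")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        object.__setattr__(self, "echo_times", te)

    @property
    def n_echoes(self) -> int:
        return self.echo_times.size


@dataclass(frozen=True)
class PoolSet:
    """Discrete water pools of one tissue: (fraction, T2) pairs.

    Fractions must sum to 1 (within 1e-9); T2 values are in ms and must be
    positive.  ``total_signal`` scales the noise-free signal at TE=0.
    """

    fractions: np.ndarray
    t2s: np.ndarray
    total_signal: float = 1.0

    def __post_init__(self) -> None:
        f = np.atleast_1d(np.asarray(self.fractions, dtype=float))
        t2 = np.atleast_1d(np.asarray(self.t2s, dtype=float))
        if f.shape != t2.shape:
            raise ValueError("fractions and t2s must have the same length")
        if np.any(t2 <= 0):
            raise ValueError("all pool T2 values must be > 0")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("pool fractions must lie in [0, 1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"pool fractions must sum to 1, got {f.sum()!r}")
        if self.total_signal <= 0:
            raise ValueError("total_signal must be > 0")
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "t2s", t2)

    def mwf(
        self,
        short_window: tuple[float, float] = SHORT_WINDOW,
        total_window: tuple[float, float] = TOTAL_WINDOW,
    ) -> float:
        """Ground-truth myelin water fraction of this pool set.

        Sum of fractions with T2 in the half-open short window divided by the
        sum over the closed total window.
        """
        short = (self.t2s >= short_window[0]) & (self.t2s < short_window[1])
        total = (self.t2s >= total_window[0]) & (self.t2s <= total_window[1])
        denom = self.fractions[total].sum()
        if denom == 0:
            return float("nan")
        return float(self.fractions[short].sum() / denom)


def three_pool_nawm() -> PoolSet:
    """Default normal-appearing white matter: MWF 0.0999.

    Myelin water at T2 = 20 ms, intra/extracellular water at 80 ms, free
    water at 2000 ms — pool T2s placed centrally in the short/medium/long
    spectral windows.
    """
    return PoolSet(fractions=[0.0999, 0.8801, 0.02], t2s=[20.0, 80.0, 2000.0])


def three_pool_lesion() -> PoolSet:
    """Default demyelinated lesion tissue: MWF 0.080."""
    return PoolSet(fractions=[0.080, 0.900, 0.02], t2s=[20.0, 80.0, 2000.0])


def pool_signal(pools: PoolSet, protocol: AcquisitionProtocol) -> np.ndarray:
    """Noise-free multi-echo decay of a pool set.

    Value at echo i is ``total_signal * sum_j f_j * exp(-TE_i / T2_j)``:
    strictly positive and non-increasing in TE.
    """
    te = protocol.echo_times[:, None]
    decay = np.exp(-te / pools.t2s[None, :])
    return pools.total_signal * (decay * pools.fractions[None, :]).sum(axis=1)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of a synthetic brain phantom.

    The "brain" is the full cuboid grid, filled with NAWM; lesions are
    spheres carved out of it, each with its own pool set.  ``noise_sigma``
    is the per-channel noise standard deviation in the same arbitrary units
    as ``total_signal`` (so SNR at TE=0 is ``total_signal / noise_sigma``).
    """

    grid_shape: tuple[int, int, int] = (12, 12, 8)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 4.0)
    nawm_poolset: PoolSet = field(default_factory=three_pool_nawm)
    lesion_poolsets: tuple[PoolSet, ...] = field(
        default_factory=lambda: (three_pool_lesion(),)
    )
    lesion_geometry: tuple[tuple[tuple[int, int, int], float], ...] = field(
        default_factory=lambda: (((5, 5, 3), 3.0),)
    )
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if len(self.lesion_poolsets) != len(self.lesion_geometry):
            raise ValueError("one poolset is required per lesion blob")
        shape = np.asarray(self.grid_shape, dtype=float)
        for center, radius in self.lesion_geometry:
            c = np.asarray(center, dtype=float)
            if radius <= 0:
                raise ValueError("lesion radius must be > 0")
            if np.any(c - radius < -0.5) or np.any(c + radius > shape - 0.5):
                raise ValueError(
                    f"lesion blob at {center} with radius {radius} exceeds the grid"
                )


@dataclass(frozen=True)
class Phantom:
    """Output bundle of :func:`make_phantom`."""

    volume: np.ndarray  # 4D, echo along the last axis
    nawm_mask: np.ndarray  # binary 3D, lesions excluded
    lesion_mask: np.ndarray  # binary 3D
    truth_mwf: np.ndarray  # 3D ground-truth MWF map
    protocol: AcquisitionProtocol
    voxel_dims: tuple[float, float, float]


def _sphere_mask(shape: tuple[int, int, int], center, radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def make_phantom(
    spec: PhantomSpec,
    protocol: AcquisitionProtocol | None = None,
    seed: int = 0,
) -> Phantom:
    """Simulate a multi-echo phantom with ground truth.

    Every voxel's noise-free signal follows :func:`pool_signal` for its
    tissue; noise is then added per ``spec.noise_model``:

    * ``gaussian`` — additive zero-mean noise (the high-SNR limit);
    * ``rician`` — magnitude of the complex signal with independent
      Gaussian noise on both channels, the distribution of magnitude MRI.

    The NAWM mask excludes lesion voxels, so the two emitted masks are
    disjoint.  Reproducible for a fixed seed.
    """
    if protocol is None:
        protocol = AcquisitionProtocol()
    shape = tuple(spec.grid_shape)
    n_echo = protocol.n_echoes

    lesion_mask = np.zeros(shape, dtype=np.uint8)
    tissue = np.zeros(shape, dtype=np.int32)  # 0 = NAWM, k = lesion k
    for k, (center, radius) in enumerate(spec.lesion_geometry, start=1):
        blob = _sphere_mask(shape, center, radius)
        lesion_mask[blob] = 1
        tissue[blob] = k

    nawm_mask = np.asarray(1 - lesion_mask, dtype=np.uint8)

    poolsets = [spec.nawm_poolset, *spec.lesion_poolsets]
    curves = np.stack([pool_signal(p, protocol) for p in poolsets])
    truth = np.array([p.mwf() for p in poolsets])

    volume = curves[tissue]  # (x, y, z, echo)
    truth_mwf = truth[tissue]

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        if spec.noise_model == "gaussian":
            volume = volume + rng.normal(0.0, spec.noise_sigma, volume.shape)
        else:  # rician: magnitude of complex signal + 2-channel noise
            re = volume + rng.normal(0.0, spec.noise_sigma, volume.shape)
            im = rng.normal(0.0, spec.noise_sigma, volume.shape)
            volume = np.hypot(re, im)
    else:
        volume = volume.copy()

    assert volume.shape == shape + (n_echo,)
    return Phantom(
        volume=volume,
        nawm_mask=nawm_mask,
        lesion_mask=lesion_mask,
        truth_mwf=truth_mwf,
        protocol=protocol,
        voxel_dims=tuple(spec.voxel_dims),
    )


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic clinical cohort.

    The generative model per subject:

    * ``nawm_mwf ~ N(nawm_mwf_mean, nawm_mwf_sd)``,
    * ``mwf_ratio ~ N(mwf_ratio_mean, mwf_ratio_sd)`` clipped to (0, 1.5],
    * ``lesion_mwf = mwf_ratio * nawm_mwf``,
    * ``tug_day1 ~ N(tug_day1_mean, tug_day1_sd)`` (floored at 1 s),
    * ``delta_tug = intercept_beta0 + slope_beta1 * mwf_ratio + eps``,
      ``eps ~ N(0, noise_sd)``, and ``tug_day10 = tug_day1 + delta_tug``
      floored at 1 s.

    ``slope_beta1`` is negative by default: less myelin disruption (ratio
    closer to 1) gives a larger TUG reduction.  Defaults emulate the study
    cohort: 16 subjects, NAWM MWF 0.0999, mean ratio 0.80, day-1 TUG
    12.8 +/- 3.9 s, and an effect size giving population R^2 = 0.31 for the
    ratio -> delta-TUG regression (see :func:`calibrate_noise_sd`).
    """

    n_subjects: int = 16
    nawm_mwf_mean: float = 0.0999
    nawm_mwf_sd: float = 0.012
    mwf_ratio_mean: float = 0.80
    mwf_ratio_sd: float = 0.10
    slope_beta1: float = -17.0
    intercept_beta0: float = 12.5
    noise_sd: float = 2.5362
    tug_day1_mean: float = 12.8
    tug_day1_sd: float = 3.9

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        for name in ("nawm_mwf_sd", "mwf_ratio_sd", "noise_sd", "tug_day1_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def population_r_squared(self) -> float:
        """R^2 of the planted ratio -> delta-TUG association, before clipping."""
        signal = (self.slope_beta1 * self.mwf_ratio_sd) ** 2
        return signal / (signal + self.noise_sd**2)


def calibrate_noise_sd(slope_beta1: float, ratio_sd: float, r_squared: float) -> float:
    """Noise SD giving a target population R^2 for the planted association.

    Population R^2 = b1^2 s_x^2 / (b1^2 s_x^2 + s_e^2), solved for s_e.
    """
    if not 0 < r_squared < 1:
        raise ValueError("r_squared must be in (0, 1)")
    return abs(slope_beta1) * ratio_sd * np.sqrt(1.0 / r_squared - 1.0)


def simulate_cohort(params: CohortParams, seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic cohort table with a planted MWF-ratio -> TUG effect.

    Returns a DataFrame with columns ``subject_id, age, edss, tug_day1_s,
    tug_day10_s, lesion_volume_mm3, lesion_mwf, nawm_mwf, mwf_ratio``.
    Ages, EDSS scores and lesion volumes are nuisance covariates drawn to
    resemble an ambulatory relapsing-remitting MS cohort; none of them is
    linked to the outcome.
    """
    rng = np.random.default_rng(seed)
    n = params.n_subjects

    nawm = rng.normal(params.nawm_mwf_mean, params.nawm_mwf_sd, n)
    nawm = np.clip(nawm, 1e-4, None)
    ratio = rng.normal(params.mwf_ratio_mean, params.mwf_ratio_sd, n)
    ratio = np.clip(ratio, 1e-6, 1.5)
    lesion = ratio * nawm

    day1 = np.maximum(rng.normal(params.tug_day1_mean, params.tug_day1_sd, n), 1.0)
    eps = rng.normal(0.0, params.noise_sd, n)
    delta = params.intercept_beta0 + params.slope_beta1 * ratio + eps
    day10 = np.maximum(day1 + delta, 1.0)

    age = np.clip(rng.normal(47.0, 13.0, n), 18, 85).round(0)
    edss = np.clip(np.round(rng.normal(4.0, 1.8, n) * 2) / 2, 0.0, 8.0)
    lesion_volume = np.exp(rng.normal(np.log(7000.0), 0.6, n)).round(0)

    return pd.DataFrame(
        {
            "subject_id": [f"{i + 1:02d}" for i in range(n)],
            "age": age,
            "edss": edss,
            "tug_day1_s": day1,
            "tug_day10_s": day10,
            "lesion_volume_mm3": lesion_volume,
            "lesion_mwf": lesion,
            "nawm_mwf": nawm,
            "mwf_ratio": ratio,
        }
    )
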