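"""Synthetic cohort generator.

Emulates a rat xenograft study in which increasing numbers of activated,
CD25-expressing lymphocytes are implanted subcutaneously and imaged with a
CD25-targeted tracer over a 60-min dynamic scan:

* plasma clearance is biexponential, with 25% of the amplitude clearing
  with a 0.71-min half-time and 75% with an 8.4-min half-time, sampled at
  the 14 arterial blood-draw times (15 s ... 60 min);
* each lesion follows a reversible two-tissue compartment model whose true
  binding potential scales linearly with the implanted CD25+ cell count,
  BP = 4.06 * (cells / 10^6) + 0.17, via k3 = BP * k4;
* the default cohort has 11 animals spanning 0.17-1.9 x 10^6 cells, with
  injected doses drawn around 17.1 +/- 1.2 MBq.

Noise is multiplicative Gaussian; for framed tissue curves the coefficient
of variation is scaled by the inverse square root of the relative frame
duration, a standard surrogate for PET count statistics.  All generators
are bit-reproducible under a fixed seed, and every generated record carries
its ground-truth parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .compartment import KineticParams, simulate_2tc
from .input_function import BiexpParams
from .roi import DynamicVolume
from .tac import CohortRecord, TimeActivityCurve

__all__ = [
    "CohortSpec",
    "PLASMA_SAMPLE_TIMES_MIN",
    "default_frame_times",
    "make_plasma_tac",
    "make_lesion_tac",
    "make_cohort",
    "make_phantom",
]

#: arterial blood-draw times (min): 15, 30, 45, 60, 75, 90, 120, 180, 300,
#: 450, 600, 900, 1800 and 3600 s after injection
PLASMA_SAMPLE_TIMES_MIN = (
    np.array([15, 30, 45, 60, 75, 90, 120, 180, 300, 450, 600, 900, 1800, 3600])
    / 60.0
)
PLASMA_SAMPLE_TIMES_MIN.setflags(write=False)

#: default 60-min lesion frame schedule: 6x30 s, 6x1 min, 6x2.5 min, 6x6 min
DEFAULT_FRAME_DURATIONS_MIN = np.repeat([0.5, 1.0, 2.5, 6.0], 6)
DEFAULT_FRAME_DURATIONS_MIN.setflags(write=False)


def default_frame_times():
    """Frame midpoints and durations (min) of the default 24-frame schedule."""
    ends = np.cumsum(DEFAULT_FRAME_DURATIONS_MIN)
    mids = ends - DEFAULT_FRAME_DURATIONS_MIN / 2.0
    return mids, DEFAULT_FRAME_DURATIONS_MIN.copy()


@dataclass
class CohortSpec:
    """Generating conditions of the synthetic cohort.

    ``base_k1``/``base_k2`` set the nonspecific delivery and washout so that
    the nonspecific distribution volume K1/k2 = 0.5; ``base_k4`` sets the
    dissociation rate, and k3 follows from the target binding potential.
    ``plasma_amplitude`` is the t=0 plasma concentration for the reference
    17.1 MBq dose and is scaled per animal by the actual dose.
    """

    n_animals: int = 11
    cell_range: tuple = (0.17, 1.9)  # 10^6 CD25+ cells
    bp_slope: float = 4.06  # BP per 10^6 cells
    bp_intercept: float = 0.17  # nonspecific BP at 0 cells
    frac_fast: float = 0.25
    t_half_fast: float = 0.71  # min
    t_half_slow: float = 8.4  # min
    plasma_amplitude: float = 800.0  # kBq/ml at t=0 for the reference dose
    base_k1: float = 0.125  # ml cm^-3 min^-1
    base_k2: float = 0.25  # min^-1
    base_k4: float = 0.12  # min^-1
    dose_mean: float = 17.1  # MBq
    dose_sd: float = 1.2  # MBq
    weight_mean: float = 300.0  # g
    weight_sd: float = 25.0  # g
    control_bp_mean: float = 0.42  # background BP of uninflamed tissue
    control_bp_sd: float = 0.20  # inter-animal spread of the background BP
    noise_cv: float = 0.005  # tissue-curve coefficient of variation
    plasma_noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.cell_range
        if not (0 < lo < hi):
            raise ValueError("cell_range must be positive and ordered")
        if self.noise_cv < 0 or self.plasma_noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")

    def plasma_params(self, dose: float | None = None) -> BiexpParams:
        scale = 1.0 if dose is None else dose / self.dose_mean
        return BiexpParams(
            amplitude=self.plasma_amplitude * scale,
            frac_fast=self.frac_fast,
            t_half_fast=self.t_half_fast,
            t_half_slow=self.t_half_slow,
        )

    def true_bp(self, cd25_cells: float) -> float:
        return self.bp_slope * cd25_cells + self.bp_intercept

    def kinetic_params(self, cd25_cells: float) -> KineticParams:
        bp = self.true_bp(cd25_cells)
        return KineticParams(
            self.base_k1, self.base_k2, bp * self.base_k4, self.base_k4, "2TCMR"
        )


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _noisy(values, cv, rng, durations=None):
    """Multiplicative Gaussian noise; CV scaled by 1/sqrt(relative duration)."""
    if cv < 0:
        raise ValueError("negative noise CV")
    if cv == 0:
        return values.copy()
    cv_i = np.full_like(values, cv, dtype=float)
    if durations is not None:
        durations = np.asarray(durations, dtype=float)
        cv_i *= np.sqrt(durations.mean() / durations)
    noisy = values * (1.0 + cv_i * rng.standard_normal(values.shape))
    return np.maximum(noisy, 0.0)


def make_plasma_tac(
    params: BiexpParams,
    sample_times=None,
    noise_cv: float = 0.0,
    seed=0,
) -> TimeActivityCurve:
    """Sampled plasma curve at the blood-draw times, optionally noisy."""
    if sample_times is None:
        sample_times = PLASMA_SAMPLE_TIMES_MIN
    sample_times = np.asarray(sample_times, dtype=float)
    clean = np.zeros_like(sample_times)
    for amp, lam in params.exponential_terms():
        clean += amp * np.exp(-lam * sample_times)
    values = _noisy(clean, noise_cv, _rng(seed))
    return TimeActivityCurve(sample_times, values, label="plasma")


def make_lesion_tac(
    cd25_cells: float,
    input_function: BiexpParams,
    spec: CohortSpec | None = None,
    frame_times=None,
    frame_durations=None,
    noise_cv: float = 0.0,
    seed=0,
):
    """Lesion curve for a given CD25+ cell count, with its ground truth.

    Returns ``(TimeActivityCurve, KineticParams)``; the true binding
    potential is ``bp_slope * cells + bp_intercept`` and enters through
    k3 = BP * k4.
    """
    if cd25_cells < 0:
        raise ValueError("cd25_cells must be >= 0")
    spec = spec or CohortSpec()
    if frame_times is None:
        frame_times, frame_durations = default_frame_times()
    params = spec.kinetic_params(cd25_cells)
    clean = simulate_2tc(params, input_function, frame_times)
    values = _noisy(clean.values, noise_cv, _rng(seed), durations=frame_durations)
    tac = TimeActivityCurve(
        np.asarray(frame_times, dtype=float),
        values,
        frame_durations=frame_durations,
        label="lesion",
    )
    return tac, params


def make_cohort(spec: CohortSpec | None = None, include_control: bool = True):
    """Generate the full synthetic cohort as a list of records.

    Cell counts are log-uniformly spaced across ``cell_range`` (the two
    endpoints are always included); doses and weights are drawn from
    truncated normals.  Control curves are null lesions simulated at 0
    cells (binding potential equal to the nonspecific intercept).
    """
    spec = spec or CohortSpec()
    if spec.n_animals >= 2:
        cells = np.geomspace(spec.cell_range[0], spec.cell_range[1], spec.n_animals)
    else:
        cells = np.array([spec.cell_range[0]])
    rng = _rng(spec.seed)
    records = []
    for i, n_cells in enumerate(cells):
        dose = 0.0
        while dose <= 0:
            dose = spec.dose_mean + spec.dose_sd * rng.standard_normal()
        weight = 0.0
        while weight <= 0:
            weight = spec.weight_mean + spec.weight_sd * rng.standard_normal()
        plasma_params = spec.plasma_params(dose)
        plasma = make_plasma_tac(
            plasma_params, noise_cv=spec.plasma_noise_cv, seed=rng
        )
        lesion, truth = make_lesion_tac(
            n_cells, plasma_params, spec, noise_cv=spec.noise_cv, seed=rng
        )
        control = None
        control_bp = None
        if include_control:
            # contralateral uninflamed tissue: background binding varies
            # between animals around control_bp_mean, independently of the
            # implanted-cell regression line
            control_bp = max(
                spec.control_bp_mean + spec.control_bp_sd * rng.standard_normal(),
                0.01,
            )
            frame_times, frame_durations = default_frame_times()
            control_params = KineticParams(
                spec.base_k1, spec.base_k2, control_bp * spec.base_k4,
                spec.base_k4, "2TCMR",
            )
            clean = simulate_2tc(control_params, plasma_params, frame_times)
            control = TimeActivityCurve(
                frame_times,
                _noisy(clean.values, spec.noise_cv, rng, durations=frame_durations),
                frame_durations=frame_durations,
                label="control",
            )
        records.append(
            CohortRecord(
                animal_id=f"rat{i + 1:02d}",
                cd25_cells=float(n_cells),
                injected_dose=float(dose),
                body_weight=float(weight),
                plasma=plasma,
                lesion=lesion,
                control=control,
                truth={
                    "true_bp": truth.bp,
                    **({"control_bp": control_bp} if control_bp is not None else {}),
                    "true_vd": truth.vd,
                    "K1": truth.k1,
                    "k2": truth.k2,
                    "k3": truth.k3,
                    "k4": truth.k4,
                    "amplitude_kBq_ml": plasma_params.amplitude,
                },
            )
        )
    return records


def make_phantom(
    lesion_mask,
    lesion_tac: TimeActivityCurve,
    background_tac: TimeActivityCurve | None = None,
    dims=(16, 16, 16),
    blur_sigma: float | None = None,
    voxel_volume: float = 1.0,
) -> DynamicVolume:
    """Build a 4-D phantom: lesion voxels follow ``lesion_tac``, the rest
    ``background_tac`` (zero when omitted); optional Gaussian blur emulates
    scanner resolution (and produces the partial-volume underestimate).

    ``lesion_mask`` is a boolean 3-D array of shape ``dims``.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if lesion_mask.shape != tuple(dims):
        raise ValueError("lesion mask shape must equal dims")
    if not lesion_mask.any():
        raise ValueError("empty lesion geometry")
    n_frames = len(lesion_tac)
    if background_tac is not None and len(background_tac) != n_frames:
        raise ValueError("background and lesion curves must share the frame grid")
    vox = np.zeros((n_frames,) + tuple(dims))
    for f in range(n_frames):
        if background_tac is not None:
            vox[f].fill(background_tac.values[f])
        vox[f][lesion_mask] = lesion_tac.values[f]
        if blur_sigma:
            vox[f] = ndimage.gaussian_filter(vox[f], blur_sigma)
    return DynamicVolume(
        vox,
        lesion_tac.times,
        voxel_volume=voxel_volume,
        frame_durations=lesion_tac.frame_durations,
    )


def sphere_mask(dims=(16, 16, 16), center=None, radius=4.0) -> np.ndarray:
    """Boolean sphere geometry helper for phantoms."""
    dims = tuple(dims)
    if center is None:
        center = tuple(d / 2.0 - 0.5 for d in dims)
    grids = np.ogrid[tuple(slice(0, d) for d in dims)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius**2
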