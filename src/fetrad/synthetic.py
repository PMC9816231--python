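"""Synthetic dynamic-PET cohorts with known ground truth.

Every downstream stage (parametric imaging, radiomics, modelling,
evaluation) is exercised on phantoms generated here, since no patient data
ship with the package.

Voxel kinetics follow a normalized gamma-variate,

    c(t) = A * u**alpha * exp(alpha * (1 - u)),   u = (t - t0) / (tp - t0)

for t > t0 and 0 otherwise.  The curve attains its maximum A exactly at the
peak time ``tp``, which gives time-to-peak classification an analytic
oracle.  Frame values are the exact interval averages of c(t) (PET frames
integrate activity over their duration); the integral has a closed form in
the regularized lower incomplete gamma function.  Additive Gaussian noise
with standard deviation proportional to the amplitude models frame noise —
count statistics, attenuation and partial-volume effects are deliberately
out of scope.

A simulated patient couples the phantom with six clinical covariates (age,
gender, KPS, WHO grade, MGMT, TERTp).  The binary short-term-survival label
is drawn from a logistic model whose linear predictor combines covariate
effects with a kinetic-phenotype effect; the intercept is calibrated by
bisection so the cohort-mean event probability equals the requested
prevalence.  The kinetic phenotype (aggressive = early peak with washout,
indolent = late peak) influences the label, never the reverse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import special

from .parametric import DynamicImage, FrameSchedule, default_schedule

__all__ = [
    "KineticPhenotype",
    "TumorPhenotypeField",
    "PhantomSpec",
    "ClinicalCovariates",
    "SimulatedPatient",
    "PHENOTYPE_CLASSES",
    "DEFAULT_EFFECT_SIZES",
    "DEFAULT_KINETIC_EFFECT",
    "DEFAULT_STS_PREVALENCE",
    "gamma_variate",
    "frame_averages",
    "simulate_tac",
    "sphere_mask",
    "crescent_mask",
    "generate_phantom",
    "generate_cohort",
    "calibrate_intercept",
    "covariates_to_frame",
    "write_patient",
]


class InvalidPhenotypeError(ValueError):
    pass


class GeometryError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class KineticPhenotype:
    """Parameters of one gamma-variate time-activity curve.

    amplitude
        Peak activity concentration (arbitrary units, > 0).
    peak_time
        Minutes post-injection at which the noiseless curve peaks.
    onset_time
        Minutes before which activity is exactly zero (0 <= t0 < tp).
    shape
        Dimensionless sharpness alpha > 0; small alpha = broad plateau with
        slow washout, large alpha = narrow peak.
    """

    amplitude: float
    peak_time: float
    onset_time: float = 0.0
    shape: float = 1.0

    def __post_init__(self):
        if self.amplitude <= 0:
            raise InvalidPhenotypeError("amplitude must be positive")
        if self.peak_time - self.onset_time <= 0:
            raise InvalidPhenotypeError("peak_time must exceed onset_time")
        if self.onset_time < 0:
            raise InvalidPhenotypeError("onset_time must be nonnegative")
        if self.shape <= 0:
            raise InvalidPhenotypeError("shape must be positive")


def gamma_variate(t, phenotype: KineticPhenotype) -> np.ndarray:
    """Instantaneous gamma-variate activity at times ``t`` (minutes)."""
    t = np.asarray(t, dtype=float)
    tp, t0, a = phenotype.peak_time, phenotype.onset_time, phenotype.shape
    u = np.clip((t - t0) / (tp - t0), 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = phenotype.amplitude * np.where(u > 0, u ** a * np.exp(a * (1.0 - u)), 0.0)
    return val


def _frame_averages_vec(
    amplitude: np.ndarray,
    peak_time: np.ndarray,
    onset_time: np.ndarray,
    shape: float,
    schedule: FrameSchedule,
) -> np.ndarray:
    """Exact frame averages of gamma-variate curves, vectorized over voxels.

    The time integral of c(t) over [a, b] reduces to the regularized lower
    incomplete gamma function P:

        int c dt = A * exp(alpha) * (tp - t0) * alpha**-(alpha+1)
                   * Gamma(alpha+1) * [P(alpha+1, alpha*u_b) - P(alpha+1, alpha*u_a)]
    """
    amplitude = np.atleast_1d(np.asarray(amplitude, dtype=float))
    peak_time = np.atleast_1d(np.asarray(peak_time, dtype=float))
    onset_time = np.atleast_1d(np.asarray(onset_time, dtype=float))
    a = float(shape)
    edges = np.concatenate([schedule.starts, [schedule.ends[-1]]])
    span = (peak_time - onset_time)[:, None]
    u = np.clip((edges[None, :] - onset_time[:, None]) / span, 0.0, None)
    reg = special.gammainc(a + 1.0, a * u)
    # log-form of the prefactor for numerical safety at large alpha
    log_pref = a + special.gammaln(a + 1.0) - (a + 1.0) * np.log(a)
    integral = amplitude[:, None] * span * np.exp(log_pref) * np.diff(reg, axis=1)
    return integral / schedule.durations[None, :]


def frame_averages(phenotype: KineticPhenotype, schedule: FrameSchedule) -> np.ndarray:
    """Noiseless frame-interval averages of the phenotype's curve."""
    return _frame_averages_vec(
        np.array([phenotype.amplitude]),
        np.array([phenotype.peak_time]),
        np.array([phenotype.onset_time]),
        phenotype.shape,
        schedule,
    )[0]


def simulate_tac(
    phenotype: KineticPhenotype,
    schedule: FrameSchedule,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """One noisy TAC: exact frame averages plus i.i.d. Gaussian noise with
    standard deviation ``noise_sd * amplitude``."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    tac = frame_averages(phenotype, schedule)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tac = tac + rng.normal(0.0, noise_sd * phenotype.amplitude, size=tac.shape)
    return tac


# ---------------------------------------------------------------------------
# phantom geometry and generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TumorPhenotypeField:
    """Per-voxel phenotype assignment rule for the tumor sphere.

    Each tumor voxel draws its peak time uniformly from ``peak_time_range``
    (intratumoral kinetic heterogeneity) and its amplitude from a Gaussian
    with coefficient of variation ``amplitude_cv`` around ``amplitude``.
    """

    amplitude: float = 4.0
    amplitude_cv: float = 0.10
    peak_time_range: Tuple[float, float] = (6.5, 9.5)
    onset_time: float = 0.5
    shape: float = 0.25

    def draw(self, n: int, rng: np.random.Generator):
        amps = self.amplitude * np.clip(
            1.0 + self.amplitude_cv * rng.standard_normal(n), 0.2, None
        )
        tps = rng.uniform(*self.peak_time_range, size=n)
        return amps, tps


#: Tumor kinetic phenotype classes.  "aggressive" peaks early (TTP group 2)
#: with washout; "indolent" keeps accumulating tracer (late peak, group 5-6).
PHENOTYPE_CLASSES: Dict[str, TumorPhenotypeField] = {
    "aggressive": TumorPhenotypeField(peak_time_range=(6.5, 9.5), shape=0.25),
    "indolent": TumorPhenotypeField(peak_time_range=(26.0, 36.0), shape=2.0),
}

#: Healthy-brain background kinetics: moderate uptake, broad plateau.
DEFAULT_BACKGROUND = KineticPhenotype(amplitude=1.0, peak_time=20.0, onset_time=0.3, shape=0.25)


@dataclass
class PhantomSpec:
    """Everything needed to generate one dynamic brain-PET phantom."""

    grid_shape: Tuple[int, int, int] = (32, 32, 32)
    voxel_size: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_phenotype: KineticPhenotype = field(default_factory=lambda: DEFAULT_BACKGROUND)
    tumor_center: Tuple[float, float, float] = (21.5, 16.0, 16.0)
    tumor_radius: float = 5.0  # voxels
    tumor_phenotype_field: TumorPhenotypeField = field(
        default_factory=lambda: PHENOTYPE_CLASSES["aggressive"]
    )
    noise_sd: float = 0.05
    seed: int = 0
    schedule: FrameSchedule = field(default_factory=default_schedule)

    def __post_init__(self):
        c, r = np.asarray(self.tumor_center, float), float(self.tumor_radius)
        shape = np.asarray(self.grid_shape, float)
        if np.any(c - r < -0.5) or np.any(c + r > shape - 0.5):
            raise GeometryError("tumor sphere extends outside the voxel grid")


def sphere_mask(grid_shape, center, radius) -> np.ndarray:
    """Voxels whose centers lie within ``radius`` (voxel units) of ``center``."""
    idx = np.indices(grid_shape).astype(float)
    d2 = sum((idx[k] - center[k]) ** 2 for k in range(3))
    return d2 <= radius ** 2


def crescent_mask(grid_shape, tumor_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Analytic crescent-shaped background VOI in the contralateral (low-x)
    half of the grid: an in-plane annular band over a central z-slab.

    Stands in for the manually drawn healthy-hemisphere background VOI.
    """
    nx, ny, nz = grid_shape
    idx = np.indices(grid_shape).astype(float)
    cx, cy = nx * 0.45, ny * 0.5
    r = np.sqrt((idx[0] - cx) ** 2 + (idx[1] - cy) ** 2)
    band = (r >= ny * 0.28) & (r <= ny * 0.42)
    mask = band & (idx[0] < nx * 0.4) & (np.abs(idx[2] - nz * 0.5) <= nz * 0.2)
    if tumor_mask is not None:
        mask &= ~tumor_mask
    if not mask.any():
        raise GeometryError("crescent mask is empty for this grid")
    return mask


def generate_phantom(spec: PhantomSpec):
    """Generate one dynamic phantom.

    Returns ``(image, tumor_mask, background_mask)``.  All background voxels
    share the background phenotype; tumor voxels draw per-voxel amplitudes
    and peak times from the tumor phenotype field.  Bit-reproducible given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    schedule = spec.schedule
    nf = schedule.n_frames
    tumor = sphere_mask(spec.grid_shape, spec.tumor_center, spec.tumor_radius)
    bg_voi = crescent_mask(spec.grid_shape, tumor)

    bg = spec.background_phenotype
    bg_tac = frame_averages(bg, schedule)
    data = np.broadcast_to(bg_tac, spec.grid_shape + (nf,)).copy()

    n_t = int(tumor.sum())
    fld = spec.tumor_phenotype_field
    amps, tps = fld.draw(n_t, rng)
    data[tumor] = _frame_averages_vec(amps, tps, np.full(n_t, fld.onset_time), fld.shape, schedule)

    if spec.noise_sd > 0:
        sd = np.full(spec.grid_shape, spec.noise_sd * bg.amplitude)
        sd[tumor] = spec.noise_sd * amps
        data += sd[..., None] * rng.standard_normal(data.shape)
    data = np.clip(data, 0.0, None)

    image = DynamicImage(data=data, voxel_size=spec.voxel_size, schedule=schedule)
    return image, tumor, bg_voi


# ---------------------------------------------------------------------------
# clinical covariates and cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalCovariates:
    """Six clinical covariates; binary codes follow the 0/1 convention
    (0 = female / unmethylated / wildtype)."""

    age: float
    gender: int  # 1 = male
    kps: int  # Karnofsky 10-100, step 10
    who_grade: int  # 3 or 4
    mgmt: int  # 1 = methylated
    tertp: int  # 1 = mutated

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.gender not in (0, 1) or self.mgmt not in (0, 1) or self.tertp not in (0, 1):
            raise ValueError("binary covariates must be coded 0/1")
        if self.kps not in range(10, 101, 10):
            raise ValueError("KPS must be in 10..100 step 10")
        if self.who_grade not in (3, 4):
            raise ValueError("WHO grade must be 3 or 4")


@dataclass
class SimulatedPatient:
    """One simulated patient.

    ``image`` and the masks may be None when the cohort was generated
    lazily; :meth:`realize` synthesizes them on demand from
    ``phantom_spec`` (bit-identical to eager generation), which keeps the
    memory footprint of large cohorts flat.
    """

    image: Optional[DynamicImage]
    tumor_mask: Optional[np.ndarray]
    background_mask: Optional[np.ndarray]
    covariates: ClinicalCovariates
    sts_label: int
    latent_risk: float
    phenotype_class: str
    phantom_spec: Optional[PhantomSpec] = None
    ground_truth: dict = field(default_factory=dict)

    def realize(self) -> "SimulatedPatient":
        """Return a patient with image and masks materialized."""
        if self.image is not None or self.phantom_spec is None:
            return self
        image, tumor, bg = generate_phantom(self.phantom_spec)
        return SimulatedPatient(
            image=image, tumor_mask=tumor, background_mask=bg,
            covariates=self.covariates, sts_label=self.sts_label,
            latent_risk=self.latent_risk, phenotype_class=self.phenotype_class,
            phantom_spec=self.phantom_spec, ground_truth=self.ground_truth,
        )


#: Cohort-level default conditions: prevalence and covariate marginals track
#: the clinical characteristics of a 141-patient IDH-wildtype glioblastoma
#: cohort (about 60% male, ~78% TERTp-mutant, ~48% MGMT-methylated, ~67%
#: grade 4, median KPS 80, mean age ~58 y, 28.4% short-term survivors).
DEFAULT_STS_PREVALENCE = 0.284
COVARIATE_MARGINALS = {
    "p_male": 0.60,
    "p_tertp": 0.78,
    "p_mgmt": 0.48,
    "p_grade4": 0.67,
    "age_mean": 58.0,
    "age_sd": 13.0,
    "age_range": (19.0, 78.0),
    "kps_values": (40, 50, 60, 70, 80, 90, 100),
    "kps_probs": (0.03, 0.05, 0.10, 0.17, 0.35, 0.20, 0.10),
}

#: Log-odds of short-term survival per covariate.  Age and KPS enter the
#: linear predictor standardized ((age-58)/13, (kps-80)/20); binaries as 0/1.
#: Signs follow clinical direction: older age, male sex, grade 4 and TERTp
#: mutation raise risk; higher KPS and MGMT methylation lower it.
DEFAULT_EFFECT_SIZES: Dict[str, float] = {
    "age": 0.4,
    "gender": 0.2,
    "kps": -0.5,
    "who_grade": 0.3,
    "mgmt": -0.6,
    "tertp": 0.4,
}

#: Additional log-odds of short-term survival for an aggressive (early-peak)
#: tumor kinetic phenotype.
DEFAULT_KINETIC_EFFECT = 1.5

_AGE_SCALE = (58.0, 13.0)
_KPS_SCALE = (80.0, 20.0)


def _covariate_design(cov_frame) -> Dict[str, np.ndarray]:
    return {
        "age": (cov_frame["age"].to_numpy(float) - _AGE_SCALE[0]) / _AGE_SCALE[1],
        "gender": cov_frame["gender"].to_numpy(float),
        "kps": (cov_frame["kps"].to_numpy(float) - _KPS_SCALE[0]) / _KPS_SCALE[1],
        "who_grade": (cov_frame["who_grade"].to_numpy(float) == 4).astype(float),
        "mgmt": cov_frame["mgmt"].to_numpy(float),
        "tertp": cov_frame["tertp"].to_numpy(float),
    }


def calibrate_intercept(linear_terms: np.ndarray, prevalence: float,
                        tol: float = 1e-6) -> float:
    """Bisection for the intercept b such that mean(sigmoid(b + terms)) equals
    ``prevalence`` to within ``tol``."""
    lo, hi = -30.0, 30.0
    terms = np.asarray(linear_terms, dtype=float)

    def mean_p(b):
        return float(special.expit(b + terms).mean())

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * 0.1:
            break
    return 0.5 * (lo + hi)


def _draw_covariates(n: int, rng: np.random.Generator):
    import pandas as pd

    m = COVARIATE_MARGINALS
    age = np.clip(rng.normal(m["age_mean"], m["age_sd"], n), *m["age_range"])
    return pd.DataFrame(
        {
            "age": np.round(age, 1),
            "gender": rng.binomial(1, m["p_male"], n),
            "kps": rng.choice(m["kps_values"], size=n, p=m["kps_probs"]),
            "who_grade": np.where(rng.random(n) < m["p_grade4"], 4, 3),
            "mgmt": rng.binomial(1, m["p_mgmt"], n),
            "tertp": rng.binomial(1, m["p_tertp"], n),
        }
    )


def generate_cohort(
    n: int,
    sts_prevalence: float = DEFAULT_STS_PREVALENCE,
    effect_sizes: Optional[Dict[str, float]] = None,
    kinetic_effect: float = DEFAULT_KINETIC_EFFECT,
    seed: int = 0,
    p_aggressive: float = 0.5,
    grid_shape: Tuple[int, int, int] = (32, 32, 32),
    noise_sd: float = 0.05,
    generate_images: bool = True,
) -> List[SimulatedPatient]:
    """Simulate a cohort of patients with phantoms, covariates and labels.

    The label model is ``STS ~ Bernoulli(sigmoid(b0 + covariate effects +
    kinetic_effect * aggressive))`` with b0 calibrated so the cohort-mean
    event probability equals ``sts_prevalence``.  ``generate_images=False``
    skips phantom synthesis (covariates and labels only), useful for
    statistical checks of the label model.
    """
    if not 0 < sts_prevalence < 1:
        raise ConfigError("sts_prevalence must be in (0, 1)")
    if n < 10:
        raise ConfigError("cohort size must be at least 10")
    effects = dict(DEFAULT_EFFECT_SIZES if effect_sizes is None else effect_sizes)
    unknown = set(effects) - set(DEFAULT_EFFECT_SIZES)
    if unknown:
        raise ConfigError(f"unknown covariate(s) in effect_sizes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    cov = _draw_covariates(n, rng)
    design = _covariate_design(cov)
    terms = np.zeros(n)
    for name, beta in effects.items():
        terms += beta * design[name]

    aggressive = rng.random(n) < p_aggressive
    terms = terms + kinetic_effect * aggressive.astype(float)

    b0 = calibrate_intercept(terms, sts_prevalence)
    latent = b0 + terms
    labels = (rng.random(n) < special.expit(latent)).astype(int)

    patients: List[SimulatedPatient] = []
    for i in range(n):
        cls = "aggressive" if aggressive[i] else "indolent"
        covariates = ClinicalCovariates(
            age=float(cov.loc[i, "age"]),
            gender=int(cov.loc[i, "gender"]),
            kps=int(cov.loc[i, "kps"]),
            who_grade=int(cov.loc[i, "who_grade"]),
            mgmt=int(cov.loc[i, "mgmt"]),
            tertp=int(cov.loc[i, "tertp"]),
        )
        spec = PhantomSpec(
            grid_shape=grid_shape,
            tumor_phenotype_field=PHENOTYPE_CLASSES[cls],
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image = tumor = bg = None
        if generate_images:
            image, tumor, bg = generate_phantom(spec)
        patients.append(
            SimulatedPatient(
                image=image,
                tumor_mask=tumor,
                background_mask=bg,
                covariates=covariates,
                sts_label=int(labels[i]),
                latent_risk=float(latent[i]),
                phenotype_class=cls,
                phantom_spec=spec,
                ground_truth={"intercept": b0, "kinetic_effect": kinetic_effect,
                              "effect_sizes": effects},
            )
        )
    return patients


def covariates_to_frame(patients: List[SimulatedPatient]):
    """Cohort covariates + labels as a DataFrame (one row per patient)."""
    import pandas as pd

    rows = []
    for i, p in enumerate(patients):
        d = asdict(p.covariates)
        d["patient_id"] = i
        d["sts_label"] = p.sts_label
        d["phenotype_class"] = p.phenotype_class
        d["latent_risk"] = p.latent_risk
        d["phantom_seed"] = p.phantom_spec.seed if p.phantom_spec else -1
        rows.append(d)
    cols = ["patient_id", "age", "gender", "kps", "who_grade", "mgmt", "tertp",
            "phenotype_class", "latent_risk", "phantom_seed", "sts_label"]
    return pd.DataFrame(rows)[cols]


def write_patient(patient: SimulatedPatient, out_dir, patient_id: int) -> None:
    """Write one patient as 4D NIfTI + timing sidecar + mask NIfTIs."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = patient.image
    affine = np.diag(list(img.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(img.data.astype(np.float32), affine),
             out / f"patient{patient_id:04d}_dynamic.nii")
    nib.save(nib.Nifti1Image(patient.tumor_mask.astype(np.uint8), affine),
             out / f"patient{patient_id:04d}_tumor_mask.nii")
    nib.save(nib.Nifti1Image(patient.background_mask.astype(np.uint8), affine),
             out / f"patient{patient_id:04d}_background_mask.nii")
    with open(out / f"patient{patient_id:04d}_frames.json", "w") as fh:
        json.dump(img.schedule.to_dict(), fh, indent=1)
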