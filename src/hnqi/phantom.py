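"""Synthetic digital phantom and cohort simulator.

The phantom renders co-registered multi-modal head-and-neck volumes (DWI at
two b-values, a 60-frame DCE series, an FDG-PET SUV map and per-tumor GTV
masks) at two treatment timepoints (pre-RT and fraction 10) from known
ground-truth parameter maps, so that every downstream map computation,
subvolume segmentation and metric extraction can be checked against truth.
Tumors are spheres with optional necrotic cores (high ADC), low-blood-volume
blobs and low-ADC blobs — the subregions the adaptive-boost rule targets.

The cohort simulator draws per-tumor progression times from a proportional
hazards model with user-supplied log-hazard coefficients, plus patient-level
distant-failure/death/censoring times, giving survival tables with the same
clustering and censoring structure the per-tumor analysis assumes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import ParameterMaps, VolumeGrid

__all__ = [
    "AIFParams",
    "Blob",
    "TumorSpec",
    "PhantomSpec",
    "CohortSpec",
    "PhantomCase",
    "simulate_aif",
    "forward_tofts",
    "exp_conv",
    "render_phantom",
    "generate_covariates",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# Arterial input function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AIFParams:
    """Population arterial input function: linear bolus upslope followed by
    biexponential washout.

    Cp(t) = 0                                   for t <= t0
          = (A1 + A2) * (t - t0) / t_rise       for t0 < t <= t0 + t_rise
          = A1 exp(-m1 s) + A2 exp(-m2 s)       for s = t - t0 - t_rise > 0

    Amplitudes in mM, decay rates in 1/s, times in s. The curve is linear in
    (A1, A2) at fixed rates.
    """

    bolus_arrival_s: float = 10.0
    rise_s: float = 8.0
    amp1_mM: float = 4.0
    decay1_per_s: float = 0.01
    amp2_mM: float = 1.0
    decay2_per_s: float = 2.0e-4


def simulate_aif(params: AIFParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the population AIF on a time grid.

    Parameters
    ----------
    params : AIFParams
    times : array of float, s
        Strictly increasing acquisition times.

    Returns
    -------
    ndarray
        Plasma concentration (mM) per time point; zero before bolus arrival.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    t0, rise = params.bolus_arrival_s, params.rise_s
    peak = params.amp1_mM + params.amp2_mM
    cp = np.zeros_like(times)
    on_rise = (times > t0) & (times <= t0 + rise)
    cp[on_rise] = peak * (times[on_rise] - t0) / rise
    after = times > t0 + rise
    s = times[after] - t0 - rise
    cp[after] = params.amp1_mM * np.exp(-params.decay1_per_s * s) + params.amp2_mM * np.exp(
        -params.decay2_per_s * s
    )
    return cp


# ---------------------------------------------------------------------------
# Modified Tofts forward model
# ---------------------------------------------------------------------------

def exp_conv(cp: np.ndarray, times: np.ndarray, kep_per_s: np.ndarray | float) -> np.ndarray:
    """Trapezoidal convolution ``∫_0^t Cp(τ) exp(-kep (t-τ)) dτ``.

    Uses the exact recursion of the trapezoid rule with the exponential
    kernel, so the result equals brute-force trapezoidal quadrature of the
    integrand on the same grid to machine precision:

        I(t_{i+1}) = I(t_i) e^{-kΔ} + Δ/2 (Cp_i e^{-kΔ} + Cp_{i+1})

    ``kep_per_s`` may be a scalar or an array of shape (...,); the result has
    shape (..., n_times). Units: times s, kep 1/s.
    """
    cp = np.asarray(cp, dtype=float)
    times = np.asarray(times, dtype=float)
    kep = np.atleast_1d(np.asarray(kep_per_s, dtype=float))
    scalar = np.isscalar(kep_per_s) or np.ndim(kep_per_s) == 0
    out = np.zeros(kep.shape + times.shape, dtype=float)
    dt = np.diff(times)
    for i in range(times.size - 1):
        decay = np.exp(-kep * dt[i])
        out[..., i + 1] = out[..., i] * decay + 0.5 * dt[i] * (cp[i] * decay + cp[i + 1])
    return out[0] if scalar else out


def forward_tofts(
    ktrans: float,
    kep: float,
    vp: float,
    aif_curve: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Tissue concentration from the modified Tofts model.

    Ct(t) = vp Cp(t) + Ktrans ∫_0^t Cp(τ) exp(-kep (t-τ)) dτ

    ktrans and kep are in 1/min (the field's convention); times are in s —
    both rates are converted to 1/s internally so the quadrature is
    consistent. The convolution uses the trapezoid rule of :func:`exp_conv`.
    """
    if ktrans < 0 or kep < 0:
        raise ValueError("ktrans and kep must be >= 0")
    if not 0 <= vp < 1:
        raise ValueError("vp must be in [0, 1)")
    cp = np.asarray(aif_curve, dtype=float)
    times = np.asarray(times, dtype=float)
    conv = exp_conv(cp, times, kep / 60.0)
    return vp * cp + (ktrans / 60.0) * conv


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Blob:
    """A spherical subregion, in mm coordinates of the phantom frame."""

    center: tuple[float, float, float]
    radius_mm: float


@dataclass
class TumorSpec:
    """One spherical tumor with its ground-truth tissue parameters.

    Bulk tissue values fill the sphere; an optional necrotic core raises ADC
    above the necrosis-exclusion threshold, and optional blobs carve out
    subregions of low blood volume (via a reduced plasma fraction) and low
    ADC, the targets of the subvolume analysis. Mid-treatment the sphere
    shrinks to ``radius_mid`` and bulk ADC moves to ``adc_bulk_mid``; blobs
    persist at both timepoints.
    """

    kind: str  # "primary" | "nodal"
    center: tuple[float, float, float]  # mm
    radius_pre: float  # mm
    radius_mid: float  # mm
    adc_bulk_pre: float = 1.34e-3  # mm^2/s
    adc_bulk_mid: float = 1.62e-3  # mm^2/s
    ktrans: float = 0.25  # 1/min
    kep: float = 0.60  # 1/min
    vp: float = 0.06  # fraction; BV ~10.9 ml/100g at Hct 0.45
    suv_peak: float = 8.0
    necrotic_core_radius: float = 0.0  # mm; ADC set to necrosis_adc inside
    necrosis_adc: float = 3.0e-3  # mm^2/s, above the 2.7e-3 exclusion cut
    lowbv_blob: Blob | None = None
    lowbv_vp: float = 0.015  # BV ~2.7 ml/100g, below the 7.64 cut
    lowadc_blob: Blob | None = None
    lowadc_value: float = 0.9e-3  # mm^2/s, below the 1.2e-3 cut

    def __post_init__(self) -> None:
        if self.kind not in ("primary", "nodal"):
            raise ValueError(f"kind must be 'primary' or 'nodal', got {self.kind!r}")
        if self.radius_pre < 0 or self.radius_mid < 0:
            raise ValueError("radii must be >= 0")
        if not 0 <= self.vp < 1:
            raise ValueError("vp must be in [0, 1)")
        for blob in (self.lowbv_blob, self.lowadc_blob):
            if blob is not None:
                d = float(np.linalg.norm(np.subtract(blob.center, self.center)))
                if d + blob.radius_mm > self.radius_pre + 1e-9:
                    raise ValueError("blob must be contained in the pre-RT tumor sphere")


def _default_times() -> np.ndarray:
    # 60 DCE frames, uniform over 360 s
    return np.arange(60) * 6.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic case (both timepoints)."""

    grid_shape: tuple[int, int, int] = (48, 48, 32)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 3.0)  # mm
    tumors: list[TumorSpec] = field(default_factory=list)
    aif_params: AIFParams = field(default_factory=AIFParams)
    time_points_dce: np.ndarray = field(default_factory=_default_times)  # s
    b_values: tuple[float, float] = (50.0, 800.0)  # s/mm^2
    s0: float = 500.0  # baseline DWI signal
    noise_sd_dwi: float = 2.0
    noise_sd_dce: float = 0.01  # mM
    noise_sd_suv: float = 0.05
    # quiescent background tissue
    background_adc: float = 0.8e-3
    background_ktrans: float = 0.05
    background_kep: float = 0.30
    background_vp: float = 0.02
    background_suv: float = 1.0
    hematocrit: float = 0.45
    tissue_density: float = 1.0  # g/ml
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        b = tuple(self.b_values)
        if len(b) < 2 or not all(b2 > b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("b_values must be strictly increasing")
        t = np.asarray(self.time_points_dce, dtype=float)
        if t[0] != 0 or not np.all(np.diff(t) > 0):
            raise ValueError("time_points_dce must be strictly increasing starting at 0")
        self.time_points_dce = t


@dataclass
class TimepointData:
    """Rendered modalities and ground truth at one timepoint."""

    dwi: dict[float, VolumeGrid]  # keyed by b-value
    dce: np.ndarray  # (nx, ny, nz, n_frames), concentration units (mM)
    suv: VolumeGrid
    gtv_masks: list[VolumeGrid]  # one uint8 mask per tumor, spec order
    truth: ParameterMaps


@dataclass
class PhantomCase:
    """Output of :func:`render_phantom`: both timepoints plus the AIF."""

    spec: PhantomSpec
    pre: TimepointData
    mid: TimepointData
    aif_curve: np.ndarray

    def timepoint(self, name: str) -> TimepointData:
        if name not in ("pre", "mid"):
            raise KeyError(name)
        return self.pre if name == "pre" else self.mid


def _coordinate_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) + 0.5) * v
        for n, v in zip(spec.grid_shape, spec.voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _sphere_mask(coords, center, radius) -> np.ndarray:
    x, y, z = coords
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return d2 <= radius**2


def _truth_maps(spec: PhantomSpec, timepoint: str, coords) -> ParameterMaps:
    shape = spec.grid_shape
    adc = np.full(shape, spec.background_adc)
    ktrans = np.full(shape, spec.background_ktrans)
    kep = np.full(shape, spec.background_kep)
    vp = np.full(shape, spec.background_vp)
    suv = np.full(shape, spec.background_suv)

    x, y, z = coords
    for tm in spec.tumors:
        radius = tm.radius_pre if timepoint == "pre" else tm.radius_mid
        adc_bulk = tm.adc_bulk_pre if timepoint == "pre" else tm.adc_bulk_mid
        sphere = _sphere_mask(coords, tm.center, radius)
        adc[sphere] = adc_bulk
        ktrans[sphere] = tm.ktrans
        kep[sphere] = tm.kep
        vp[sphere] = tm.vp
        # smooth SUV falloff: Gaussian peak at the tumor center; sigma chosen
        # so the half-maximum surface sits well inside the sphere
        if radius > 0:
            sigma = radius / 1.5
            d2 = (x - tm.center[0]) ** 2 + (y - tm.center[1]) ** 2 + (z - tm.center[2]) ** 2
            bump = tm.suv_peak * np.exp(-d2 / (2 * sigma**2))
            suv[sphere] = np.maximum(suv[sphere], bump[sphere])
        if tm.lowbv_blob is not None:
            blob = _sphere_mask(coords, tm.lowbv_blob.center, tm.lowbv_blob.radius_mm)
            vp[blob & sphere] = tm.lowbv_vp
        if tm.lowadc_blob is not None:
            blob = _sphere_mask(coords, tm.lowadc_blob.center, tm.lowadc_blob.radius_mm)
            adc[blob & sphere] = tm.lowadc_value
        if tm.necrotic_core_radius > 0:
            core = _sphere_mask(coords, tm.center, tm.necrotic_core_radius)
            adc[core & sphere] = tm.necrosis_adc

    from .param_maps import bv_from_vp  # deferred: avoids import cycle at module load

    vs = spec.voxel_size
    vp_grid = VolumeGrid(vp, vs, "fraction")
    return ParameterMaps(
        adc=VolumeGrid(adc, vs, "mm^2/s"),
        ktrans=VolumeGrid(ktrans, vs, "1/min"),
        kep=VolumeGrid(kep, vs, "1/min"),
        vp=vp_grid,
        bv=bv_from_vp(vp_grid, spec.hematocrit, spec.tissue_density),
        suv=VolumeGrid(suv, vs, "SUV"),
    )


def _render_dce(truth: ParameterMaps, aif_curve, times) -> np.ndarray:
    """Noise-free DCE series from the voxelwise truth, grouping voxels that
    share a (ktrans, kep, vp) tuple so each unique curve is computed once."""
    kt = truth.ktrans.data.ravel()
    ke = truth.kep.data.ravel()
    vp = truth.vp.data.ravel()
    stacked = np.stack([kt, ke, vp], axis=1)
    uniq, inverse = np.unique(stacked, axis=0, return_inverse=True)
    curves = np.stack(
        [forward_tofts(k, e, v, aif_curve, times) for k, e, v in uniq]
    )
    dce = curves[inverse].reshape(truth.shape + (len(times),))
    return dce


def _render_timepoint(spec: PhantomSpec, timepoint: str, coords, aif_curve, rng_for) -> TimepointData:
    truth = _truth_maps(spec, timepoint, coords)
    vs = spec.voxel_size

    dwi = {}
    for i, b in enumerate(spec.b_values):
        signal = spec.s0 * np.exp(-b * truth.adc.data)
        noise = rng_for(f"dwi_{timepoint}_{i}").standard_normal(spec.grid_shape)
        dwi[float(b)] = VolumeGrid(signal + spec.noise_sd_dwi * noise, vs, "a.u.")

    dce = _render_dce(truth, aif_curve, spec.time_points_dce)
    dce = dce + spec.noise_sd_dce * rng_for(f"dce_{timepoint}").standard_normal(dce.shape)

    suv_noise = rng_for(f"suv_{timepoint}").standard_normal(spec.grid_shape)
    suv = VolumeGrid(truth.suv.data + spec.noise_sd_suv * suv_noise, vs, "SUV")

    masks = []
    for tm in spec.tumors:
        radius = tm.radius_pre if timepoint == "pre" else tm.radius_mid
        masks.append(
            VolumeGrid(_sphere_mask(coords, tm.center, radius).astype(np.uint8), vs, "mask")
        )
    return TimepointData(dwi=dwi, dce=dce, suv=suv, gtv_masks=masks, truth=truth)


def render_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render both timepoints of the phantom.

    Noise is additive Gaussian on each modality's signal; the underlying
    unit-variance noise field depends only on (seed, modality, timepoint),
    so rendering the same spec at a different noise SD scales the same
    realization — map-recovery error is then monotone in the SD by
    construction, and identical specs give bit-identical output.
    """
    extent = [n * v for n, v in zip(spec.grid_shape, spec.voxel_size)]
    for tm in spec.tumors:
        for c, r, e in zip(tm.center, [tm.radius_pre] * 3, extent):
            if c - tm.radius_pre < 0 or c + tm.radius_pre > e:
                raise ValueError(f"tumor at {tm.center} extends outside the grid")

    coords = _coordinate_grids(spec)
    aif_curve = simulate_aif(spec.aif_params, spec.time_points_dce)

    def rng_for(tag: str) -> np.random.Generator:
        # stable small-int stream id per modality/timepoint (process-independent)
        stream = zlib.crc32(tag.encode()) % (2**31)
        return np.random.default_rng([spec.seed, stream])

    pre = _render_timepoint(spec, "pre", coords, aif_curve, rng_for)
    mid = _render_timepoint(spec, "mid", coords, aif_curve, rng_for)
    return PhantomCase(spec=spec, pre=pre, mid=mid, aif_curve=aif_curve)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Generative model for a simulated trial cohort.

    Per-tumor locoregional progression times follow a proportional-hazards
    model ``h(t|x) = h0 exp(β'x)`` with exponential baseline; distant
    failure and death are patient-level exponential clocks independent of
    the covariates, and administrative censoring is uniform over
    ``censor_time_range`` (months). Defaults mirror a poor-prognosis
    chemoradiation cohort: 54 patients, 57% p16+, follow-up 10–58 months,
    roughly a quarter of patients failing distantly.
    """

    n_patients: int = 54
    p16_pos_frac: float = 0.57
    t4n3_frac: float = 0.85
    mean_nodal_tumors: float = 1.5  # Poisson mean; every patient has 1 primary
    betas: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.012  # locoregional events per month
    df_hazard: float = 0.008  # distant-failure events per month
    death_hazard: float = 0.003  # deaths per month
    censor_time_range: tuple[float, float] = (10.0, 58.0)  # months
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p16_pos_frac <= 1:
            raise ValueError("p16_pos_frac must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")


def generate_covariates(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-tumor covariates: patient-level p16 and T4/N3 indicators and
    a standardized per-tumor imaging metric (``adc_sd``, unit SD scale)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    rows = []
    for p in range(spec.n_patients):
        p16 = int(rng.random() < spec.p16_pos_frac)
        t4n3 = int(rng.random() < spec.t4n3_frac)
        n_nodal = rng.poisson(spec.mean_nodal_tumors)
        kinds = ["primary"] + ["nodal"] * n_nodal
        for j, kind in enumerate(kinds):
            rows.append(
                {
                    "patient_id": f"P{p:03d}",
                    "tumor_id": f"P{p:03d}_T{j}",
                    "kind": kind,
                    "p16": p16,
                    "t4n3": t4n3,
                    "adc_sd": rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec,
    per_tumor_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate per-tumor outcomes for a cohort.

    Returns one row per tumor with columns: patient_id, tumor_id, kind, the
    covariates, ``prog_time``/``df_time``/``death_time`` (months; NaN when
    the corresponding event never happens before censoring is irrelevant —
    latent times are reported uncensored), ``last_followup`` (administrative
    censoring time), and the observed ITFFR outcome ``time`` / ``event`` /
    ``event_type`` built by the per-tumor censoring rule: a tumor's clock is
    censored at the earliest of distant failure, death, or last follow-up.
    """
    rng = np.random.default_rng(spec.seed)
    if per_tumor_covariates is None:
        per_tumor_covariates = generate_covariates(spec, rng)
    df = per_tumor_covariates.copy()
    for name in spec.betas:
        if name not in df.columns:
            raise ValueError(f"unknown covariate in betas: {name!r}")

    lp = np.zeros(len(df))
    for name, beta in spec.betas.items():
        lp = lp + beta * df[name].to_numpy(dtype=float)
    hazard = spec.baseline_hazard * np.exp(lp)
    df["prog_time"] = rng.exponential(1.0 / hazard)

    lo, hi = spec.censor_time_range
    patients = df["patient_id"].unique()
    pat = pd.DataFrame(
        {
            "patient_id": patients,
            "df_time": rng.exponential(1.0 / spec.df_hazard, size=len(patients)),
            "death_time": rng.exponential(1.0 / spec.death_hazard, size=len(patients)),
            "last_followup": lo + (hi - lo) * rng.random(len(patients)),
        }
    )
    df = df.merge(pat, on="patient_id")

    censor = df[["df_time", "death_time", "last_followup"]].min(axis=1)
    event = df["prog_time"] <= censor
    df["event"] = event.astype(int)
    df["time"] = np.where(event, df["prog_time"], censor)
    first = np.argmin(df[["df_time", "death_time", "last_followup"]].to_numpy(), axis=1)
    censor_type = np.array(["DF", "death", "none"])[first]
    lr_type = np.where(df["kind"] == "primary", "LF", "RF")
    df["event_type"] = np.where(event, lr_type, censor_type)
    # latent clocks that fire after an earlier terminal event are unobserved
    df.loc[df["df_time"] > df[["death_time", "last_followup"]].min(axis=1), "df_time"] = np.nan
    df.loc[df["death_time"] > df["last_followup"], "death_time"] = np.nan
    df.loc[df["prog_time"] > censor, "prog_time"] = np.nan
    return df
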