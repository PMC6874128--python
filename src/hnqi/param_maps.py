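"""Voxelwise parametric maps: ADC, modified-Tofts (Ktrans, kep, vp), blood
volume and SUV.

ADC uses the two-point monoexponential inversion of the DWI signal; the
two b-values (50 and 800 s/mm^2 by default upstream) suppress the perfusion
contribution relative to a b=0 acquisition. The Tofts fit is a variable
projection: for each candidate efflux rate kep the two linear amplitudes
(Ktrans and vp) have a closed-form least-squares solution, so the fit is a
deterministic 1-D search over kep — no multistart heuristics — followed by
golden-section refinement of the kep bracket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid
from .phantom import exp_conv

__all__ = [
    "AdcResult",
    "ToftsFitResult",
    "compute_adc",
    "fit_modified_tofts",
    "bv_from_vp",
    "compute_suv",
]

KTRANS_MAX = 5.0  # 1/min
KEP_MAX = 10.0  # 1/min
VP_MAX = 1.0 - 1e-9


@dataclass
class AdcResult:
    """ADC map plus the QC counts the exclusion rules rely on."""

    adc: VolumeGrid
    n_invalid: int  # voxels with non-positive signal at either b (NaN in map)
    n_negative: int  # voxels where signal increased with b (ADC < 0)

    @property
    def invalid_fraction(self) -> float:
        return self.n_invalid / self.adc.data.size


def compute_adc(
    signal_b1: VolumeGrid,
    signal_b2: VolumeGrid,
    b1: float,
    b2: float,
) -> AdcResult:
    """Two-point ADC map: ``ADC = ln(S(b1)/S(b2)) / (b2 - b1)`` in mm^2/s.

    Voxels with non-positive signal at either b-value are flagged invalid and
    stored as NaN; voxels where the signal rises with b yield a negative ADC,
    which is kept (and counted) so downstream exclusion thresholds see it.
    """
    if b2 <= b1 or b1 < 0:
        raise ValueError(f"need b2 > b1 >= 0, got b1={b1}, b2={b2}")
    if not signal_b1.same_grid(signal_b2):
        raise ValueError("DWI volumes must share one grid")
    s1 = signal_b1.data.astype(float)
    s2 = signal_b2.data.astype(float)
    valid = (s1 > 0) & (s2 > 0)
    adc = np.full(s1.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = np.log(s1[valid] / s2[valid]) / (b2 - b1)
    n_invalid = int(np.count_nonzero(~valid))
    n_negative = int(np.count_nonzero(adc[valid] < 0))
    return AdcResult(signal_b1.like(adc, "mm^2/s"), n_invalid, n_negative)


@dataclass
class ToftsFitResult:
    ktrans: VolumeGrid  # 1/min
    kep: VolumeGrid  # 1/min
    vp: VolumeGrid  # fraction
    converged: VolumeGrid  # uint8; 0 where the fit hit the kep search bound
    sse: VolumeGrid  # residual sum of squares per voxel


def _solve_amplitudes(conv: np.ndarray, cp: np.ndarray, curves: np.ndarray):
    """Closed-form least squares for Ct ≈ a*conv + v*Cp per voxel, with the
    nonnegativity/bound constraints handled by candidate enumeration.

    conv: (N, T) convolution basis per voxel (kep-specific); cp: (T,);
    curves: (N, T). Returns (a, v, sse) arrays of shape (N,). ``a`` is
    Ktrans in 1/s units of the integration grid.
    """
    g11 = np.einsum("nt,nt->n", conv, conv)
    g12 = conv @ cp
    g22 = float(cp @ cp)
    b1 = np.einsum("nt,nt->n", conv, curves)
    b2 = curves @ cp
    yy = np.einsum("nt,nt->n", curves, curves)

    det = g11 * g22 - g12**2
    safe = det > 1e-300
    a_full = np.where(safe, (b1 * g22 - b2 * g12) / np.where(safe, det, 1.0), 0.0)
    v_full = np.where(safe, (b2 * g11 - b1 * g12) / np.where(safe, det, 1.0), 0.0)

    def sse_of(a, v):
        return yy - 2 * (a * b1 + v * b2) + a**2 * g11 + 2 * a * v * g12 + v**2 * g22

    # candidate constrained solutions: interior, each edge, origin
    a_only = np.where(g11 > 0, b1 / np.where(g11 > 0, g11, 1.0), 0.0)
    v_only = b2 / g22 if g22 > 0 else np.zeros_like(b2)

    cands = []
    for a, v in (
        (a_full, v_full),
        (np.maximum(a_only, 0.0), np.zeros_like(a_only)),
        (np.zeros_like(v_only), np.clip(v_only, 0.0, VP_MAX)),
        (np.zeros_like(a_full), np.zeros_like(v_full)),
    ):
        feasible = (a >= 0) & (v >= 0) & (v <= VP_MAX)
        s = np.where(feasible, sse_of(a, v), np.inf)
        cands.append((a, v, s))
    sses = np.stack([c[2] for c in cands])
    best = np.argmin(sses, axis=0)
    idx = np.arange(curves.shape[0])
    a = np.stack([c[0] for c in cands])[best, idx]
    v = np.stack([c[1] for c in cands])[best, idx]
    return a, v, sses[best, idx]


def fit_modified_tofts(
    dce: np.ndarray,
    aif_curve: np.ndarray,
    times: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask: np.ndarray | None = None,
    kep_grid: np.ndarray | None = None,
    refine: bool = True,
    n_refine: int = 20,
) -> ToftsFitResult:
    """Fit the modified Tofts model voxel by voxel.

    Parameters
    ----------
    dce : ndarray, (nx, ny, nz, n_frames)
        Tissue concentration series (already in concentration units).
    aif_curve, times : arrays of length n_frames
        Plasma input and acquisition times (s).
    mask : bool ndarray, optional
        Voxels to fit; others are NaN in the output maps.
    kep_grid : array, 1/min
        Candidate efflux rates for the coarse search (default 81 points on
        [0, 10]).
    refine : bool
        Golden-section refinement of kep within its grid bracket; with
        ``refine=False`` the fit is the pure grid argmin (the mode the
        exhaustive-search oracle checks).

    Returns fitted maps bounded to ktrans ∈ [0, 5] 1/min, kep ∈ [0, 10]
    1/min, vp ∈ [0, 1); ``converged`` is 0 where kep hit the upper search
    bound.
    """
    dce = np.asarray(dce, dtype=float)
    times = np.asarray(times, dtype=float)
    cp = np.asarray(aif_curve, dtype=float)
    if dce.ndim != 4:
        raise ValueError("dce must be 4D (x, y, z, t)")
    if dce.shape[-1] < 10:
        raise ValueError("need at least 10 DCE frames")
    if cp.shape != times.shape:
        raise ValueError("aif_curve and times must have equal length")
    if not np.any(cp > 0):
        raise ValueError("all-zero AIF: Tofts parameters are non-identifiable")

    shape = dce.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    curves = dce[mask]  # (N, T)
    n = curves.shape[0]

    if kep_grid is None:
        kep_grid = np.linspace(0.0, KEP_MAX, 81)
    kep_grid = np.asarray(kep_grid, dtype=float)

    # coarse search: shared convolution basis per grid point
    best_sse = np.full(n, np.inf)
    best_idx = np.zeros(n, dtype=int)
    best_a = np.zeros(n)
    best_v = np.zeros(n)
    bases = [exp_conv(cp, times, k / 60.0) for k in kep_grid]
    for i, conv in enumerate(bases):
        conv_n = np.broadcast_to(conv, curves.shape)
        a, v, sse = _solve_amplitudes(conv_n, cp, curves)
        better = sse < best_sse
        best_sse[better] = sse[better]
        best_idx[better] = i
        best_a[better] = a[better]
        best_v[better] = v[better]

    kep_best = kep_grid[best_idx]

    if refine and kep_grid.size > 2:
        lo = kep_grid[np.maximum(best_idx - 1, 0)]
        hi = kep_grid[np.minimum(best_idx + 1, kep_grid.size - 1)]

        def eval_sse(kep_vec):
            conv = exp_conv(cp, times, kep_vec / 60.0)
            return _solve_amplitudes(conv, cp, curves)

        gr = (np.sqrt(5.0) - 1.0) / 2.0
        x1 = hi - gr * (hi - lo)
        x2 = lo + gr * (hi - lo)
        _, _, f1 = eval_sse(x1)
        _, _, f2 = eval_sse(x2)
        for _ in range(n_refine):
            take1 = f1 < f2
            hi = np.where(take1, x2, hi)
            lo = np.where(take1, lo, x1)
            x1_new = hi - gr * (hi - lo)
            x2_new = lo + gr * (hi - lo)
            # re-evaluate both interior points (simple, fully vectorized)
            x1, x2 = x1_new, x2_new
            _, _, f1 = eval_sse(x1)
            _, _, f2 = eval_sse(x2)
        kep_ref = np.where(f1 < f2, x1, x2)
        a_ref, v_ref, sse_ref = _solve_amplitudes(
            exp_conv(cp, times, kep_ref / 60.0), cp, curves
        )
        better = sse_ref < best_sse
        kep_best = np.where(better, kep_ref, kep_best)
        best_a = np.where(better, a_ref, best_a)
        best_v = np.where(better, v_ref, best_v)
        best_sse = np.where(better, sse_ref, best_sse)

    ktrans = np.clip(best_a * 60.0, 0.0, KTRANS_MAX)  # 1/s grid units -> 1/min
    vp = np.clip(best_v, 0.0, VP_MAX)
    converged = kep_best < KEP_MAX - 1e-9

    def to_map(values, fill=np.nan, dtype=float, units=""):
        out = np.full(shape, fill, dtype=dtype)
        out[mask] = values
        return VolumeGrid(out, voxel_size, units)

    return ToftsFitResult(
        ktrans=to_map(ktrans, units="1/min"),
        kep=to_map(kep_best, units="1/min"),
        vp=to_map(vp, units="fraction"),
        converged=to_map(converged.astype(np.uint8), fill=0, dtype=np.uint8, units="flag"),
        sse=to_map(best_sse, units="sse"),
    )


def bv_from_vp(
    vp: VolumeGrid,
    hematocrit: float = 0.45,
    tissue_density: float = 1.0,
) -> VolumeGrid:
    """Blood volume in ml/100g from the plasma fraction.

    BV = 100 * vp / ((1 - Hct) * rho), clipped at 0. With the defaults
    (Hct 0.45, rho 1 g/ml) a plasma fraction of 0.042 maps to the
    7.64 ml/100g subvolume threshold.
    """
    if not 0 <= hematocrit < 1:
        raise ValueError("hematocrit must be in [0, 1)")
    if tissue_density <= 0:
        raise ValueError("tissue_density must be > 0")
    bv = 100.0 * vp.data / ((1.0 - hematocrit) * tissue_density)
    return vp.like(np.maximum(bv, 0.0), "ml/100g")


def compute_suv(
    activity_map: VolumeGrid,
    injected_dose: float,
    body_weight: float,
) -> VolumeGrid:
    """Standardized uptake value: activity (Bq/ml) normalized by injected
    dose (Bq) per body weight (g). Unitless under the 1 g/ml tissue
    convention."""
    if injected_dose <= 0 or body_weight <= 0:
        raise ValueError("injected_dose and body_weight must be > 0")
    return activity_map.like(activity_map.data * body_weight / injected_dose, "SUV")
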