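"""Cubic trajectory modelling and Frenet-Serret deformation parameters.

The implanted electrode is modelled as a third-order polynomial space curve
``r(t) = c0 + c1 t + c2 t^2 + c3 t^3`` (one cubic per axis, millimetres,
``t`` in [0, 1]) fitted by least squares to the extracted centerline, with
``t`` taken as the normalized cumulative chord-length of the centerline
points.  The fitted curve is resampled at 100 points uniform in arc length;
at each sample five deformation parameters are computed:

* the per-axis deviations from the straight chord joining the curve's
  endpoints (x: toward the midline, y: posterior, z: inferior, in mm), the
  chord point being taken at the same normalized arc fraction as the sample;
* curvature  kappa = |r' x r''| / |r'|^3          (mm^-1);
* torsion    tau   = (r' x r'') . r''' / |r' x r''|^2   (mm^-1),

both evaluated from the cubic's exact derivatives (r''' is constant).  Where
curvature falls below ``KAPPA_EPS`` the torsion is undefined (the binormal
direction is arbitrary); such samples are flagged and their torsion reported
as 0 so that downstream regional means can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import (
    DegenerateCurveError,
    FitFailureError,
    InvalidArgumentError,
    IrregularCurveError,
)

#: curvature (mm^-1) below which the torsion is treated as undefined
KAPPA_EPS = 1e-6

#: number of samples of the normalized profile
N_PROFILE_SAMPLES = 100


def poly_eval(coeffs: np.ndarray, t: np.ndarray, order: int = 0) -> np.ndarray:
    """Evaluate a (4, 3) per-axis cubic, or its ``order``-th derivative, at t.

    Returns an array of shape ``t.shape + (3,)``.
    """
    c = np.asarray(coeffs, dtype=float)
    t = np.asarray(t, dtype=float)
    for _ in range(order):
        # derivative of sum_k c_k t^k -> sum_k k c_k t^(k-1)
        c = c[1:] * np.arange(1, c.shape[0])[:, None]
    if c.shape[0] == 0:
        return np.zeros(t.shape + (3,))
    powers = t[..., None] ** np.arange(c.shape[0])
    return powers @ c


@dataclass(frozen=True)
class CubicCurveModel:
    """Per-axis cubic of a normalized parameter t in [0, 1].

    ``coeffs`` has shape (4, 3): rows are powers 0..3, columns x/y/z (mm).
    ``r_squared`` pools the residual and centered total sums of squares over
    the three axes; ``rms_residual`` is the pooled per-coordinate RMS,
    sqrt(SSR / (3 n)), in mm.
    """

    coeffs: np.ndarray
    r_squared: float
    rms_residual: float
    source_arc_length: float

    def __post_init__(self):
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (4, 3):
            raise InvalidArgumentError(f"coeffs must have shape (4, 3), got {c.shape}")
        object.__setattr__(self, "coeffs", c)

    def position(self, t):
        return poly_eval(self.coeffs, np.asarray(t, dtype=float))

    def deriv1(self, t):
        return poly_eval(self.coeffs, np.asarray(t, dtype=float), order=1)

    def deriv2(self, t):
        return poly_eval(self.coeffs, np.asarray(t, dtype=float), order=2)

    def deriv3(self, t):
        t = np.asarray(t, dtype=float)
        return np.broadcast_to(6.0 * self.coeffs[3], t.shape + (3,)).copy()

    def arc_length(self, n_quad: int = 2049) -> float:
        t = np.linspace(0.0, 1.0, n_quad)
        speed = np.linalg.norm(self.deriv1(t), axis=-1)
        return float(np.trapezoid(speed, t))


@dataclass
class DeformationProfile:
    """100-sample record of deviations, curvature and torsion along a lead.

    ``deviations`` has shape (n, 3) with columns x/y/z (mm, electrode-frame
    signs).  ``curvature``/``torsion`` are mm^-1 and are NaN until filled by
    :func:`frenet_profile`; ``torsion_defined`` marks samples where the
    curvature exceeds :data:`KAPPA_EPS`.  ``chord_start``/``chord_end`` are
    the curve endpoints the chord joins, kept so samples can be mapped back
    to electrode-frame positions.
    """

    t: np.ndarray
    arc_mm: np.ndarray
    deviations: np.ndarray
    curvature: np.ndarray
    torsion: np.ndarray
    torsion_defined: np.ndarray
    chord_start: np.ndarray
    chord_end: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    def positions(self) -> np.ndarray:
        """Electrode-frame sample positions: chord point + deviation."""
        frac = (self.arc_mm / self.arc_mm[-1])[:, None]
        chord = self.chord_start + frac * (self.chord_end - self.chord_start)
        return chord + self.deviations


def fit_cubic(skeleton) -> CubicCurveModel:
    """Least-squares third-order polynomial fit of an ordered centerline.

    ``skeleton`` must expose ``points`` (n, 3) in mm and ``cumulative_arc``
    (n,) strictly increasing; the regression parameter is the normalized
    cumulative chord-length t = arc / arc_total.
    """
    pts = np.asarray(skeleton.points, dtype=float)
    arc = np.asarray(skeleton.cumulative_arc, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] != arc.shape[0]:
        raise InvalidArgumentError("skeleton points/arc shapes inconsistent")
    n = pts.shape[0]
    if n < 8:
        raise InvalidArgumentError(f"need >= 8 skeleton points to fit a cubic, got {n}")
    if not np.all(np.diff(arc) > 0):
        raise InvalidArgumentError("cumulative_arc must be strictly increasing")

    t = (arc - arc[0]) / (arc[-1] - arc[0])
    design = np.vander(t, 4, increasing=True)
    if np.linalg.matrix_rank(design) < 4:
        raise FitFailureError("rank-deficient design: skeleton points do not span a cubic")
    coeffs, _, rank, _ = np.linalg.lstsq(design, pts, rcond=None)
    if rank < 4:
        raise FitFailureError("rank-deficient design: skeleton points do not span a cubic")

    resid = pts - design @ coeffs
    ssr = float(np.sum(resid**2))
    sst = float(np.sum((pts - pts.mean(axis=0)) ** 2))
    if sst <= 0:
        raise FitFailureError("all skeleton points identical; total variance is zero")
    r2 = 1.0 - ssr / sst
    rms = np.sqrt(ssr / (3.0 * n))
    return CubicCurveModel(
        coeffs=coeffs,
        r_squared=r2,
        rms_residual=float(rms),
        source_arc_length=float(arc[-1] - arc[0]),
    )


def _arc_sampler(model: CubicCurveModel, n_dense: int = 4001):
    """Dense arc-length table t -> s(t) for inverting to uniform arc samples."""
    t_dense = np.linspace(0.0, 1.0, n_dense)
    speed = np.linalg.norm(model.deriv1(t_dense), axis=-1)
    s = cumulative_trapezoid(speed, t_dense, initial=0.0)
    return t_dense, s


def deformation_profile(
    model: CubicCurveModel, n_samples: int = N_PROFILE_SAMPLES
) -> DeformationProfile:
    """Resample the fitted curve uniformly in arc length; compute deviations.

    The deviation at arc fraction f is curve(t(f)) minus the point at the
    same fraction f along the straight chord joining curve(0) and curve(1),
    reported per axis.  The first and last samples are exactly zero by
    construction.
    """
    p0 = model.position(0.0)
    p1 = model.position(1.0)
    chord = p1 - p0
    chord_len = float(np.linalg.norm(chord))
    if chord_len <= 1e-12:
        raise DegenerateCurveError("curve endpoints coincide; chord length is zero")

    t_dense, s_dense = _arc_sampler(model)
    total = s_dense[-1]
    s_targets = np.linspace(0.0, total, n_samples)
    t_samples = np.interp(s_targets, s_dense, t_dense)
    t_samples[0], t_samples[-1] = 0.0, 1.0

    pos = model.position(t_samples)
    frac = (s_targets / total)[:, None]
    dev = pos - (p0 + frac * chord)
    dev[0] = 0.0
    dev[-1] = 0.0

    nan = np.full(n_samples, np.nan)
    return DeformationProfile(
        t=t_samples,
        arc_mm=s_targets,
        deviations=dev,
        curvature=nan.copy(),
        torsion=nan.copy(),
        torsion_defined=np.zeros(n_samples, dtype=bool),
        chord_start=p0,
        chord_end=p1,
    )


def frenet_curvature_torsion(d1, d2, d3, kappa_eps: float = KAPPA_EPS):
    """Curvature and torsion from first/second/third derivative vectors.

    Accepts arrays of shape (..., 3); returns (kappa, tau, tau_defined).
    Where kappa < kappa_eps the torsion is reported as 0 with
    ``tau_defined`` False.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    d3 = np.asarray(d3, dtype=float)
    cross = np.cross(d1, d2)
    speed = np.linalg.norm(d1, axis=-1)
    cross_norm = np.linalg.norm(cross, axis=-1)
    kappa = cross_norm / speed**3
    defined = kappa >= kappa_eps
    denom = np.where(defined, cross_norm**2, 1.0)
    tau = np.where(defined, np.sum(cross * d3, axis=-1) / denom, 0.0)
    return kappa, tau, defined


def frenet_profile(model: CubicCurveModel, profile: DeformationProfile) -> DeformationProfile:
    """Fill curvature/torsion columns from the cubic's exact derivatives."""
    t = profile.t
    d1 = model.deriv1(t)
    speed = np.linalg.norm(d1, axis=-1)
    if np.any(speed <= 0):
        bad = float(t[int(np.argmin(speed))])
        raise IrregularCurveError(f"curve speed vanishes at t = {bad:.6f}")
    kappa, tau, defined = frenet_curvature_torsion(d1, model.deriv2(t), model.deriv3(t))
    return replace(
        profile,
        curvature=kappa,
        torsion=tau,
        torsion_defined=defined,
    )
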