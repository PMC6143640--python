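"""Fibre waviness: spatial period and amplitude in the orientation-tensor
eigenframe.

The main fibre direction ``e_u`` is the major eigenvector of the orientation
tensor; ``e_v`` and ``e_w`` follow in descending eigenvalue order. Fibre
trajectories are projected onto the (e_u, e_v) and (e_u, e_w) planes, the
transverse displacement is detrended, and the quasi-sinusoidal signal is
characterised either by its alternating extrema (period = twice the mean
extremum spacing, amplitude = mean absolute extremum displacement) or by a
least-squares sine fit seeded from the dominant spectral component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import least_squares

from .orientation import OrientationTensor

__all__ = [
    "EigenFrame",
    "WavinessEstimate",
    "eigenframe",
    "transverse_profile",
    "estimate_waviness",
    "waviness_report",
    "phi_amplitude_to_r0",
]


@dataclass
class EigenFrame:
    """Orthonormal right-handed triad of orientation-tensor eigenvectors."""

    e_u: np.ndarray
    e_v: np.ndarray
    e_w: np.ndarray
    eigenvalues: tuple[float, float, float]  # descending
    degenerate: bool = False

    def basis(self) -> np.ndarray:
        """Rows are (e_u, e_v, e_w)."""
        return np.stack([self.e_u, self.e_v, self.e_w])


@dataclass
class WavinessEstimate:
    plane: str            # "uv" or "uw"
    period: float         # lambda, µm
    period_sd: float
    amplitude: float      # R0, µm
    amplitude_sd: float
    n_measurements: int
    method: str

    def __post_init__(self) -> None:
        if not (self.period > 0):
            raise ValueError("waviness period must be > 0")
        if self.amplitude < 0:
            raise ValueError("waviness amplitude must be >= 0")


def eigenframe(a: OrientationTensor | np.ndarray) -> EigenFrame:
    """Eigenframe of a 3x3 orientation tensor, eigenvalues descending.

    Signs are fixed so that each of e_u, e_v has its largest-magnitude
    component positive; e_w completes a right-handed triad. A relative gap
    below 1e-6 between consecutive eigenvalues sets the degeneracy flag.
    """
    m = a.matrix if isinstance(a, OrientationTensor) else np.asarray(a, dtype=float)
    w, v = np.linalg.eigh(m)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]

    def fix(vec: np.ndarray) -> np.ndarray:
        k = int(np.argmax(np.abs(vec)))
        return vec if vec[k] >= 0 else -vec

    e_u = fix(v[:, 0])
    e_v = fix(v[:, 1])
    e_w = np.cross(e_u, e_v)
    scale = max(abs(w[0]), 1e-300)
    degenerate = (w[0] - w[1]) / scale < 1e-6 or (w[1] - w[2]) / scale < 1e-6
    return EigenFrame(e_u=e_u, e_v=e_v, e_w=e_w,
                      eigenvalues=tuple(float(x) for x in w),
                      degenerate=degenerate)


def transverse_profile(
    track: np.ndarray,
    frame: EigenFrame,
    plane: str = "uv",
    expected_period: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Detrended transverse displacement v(u) of a trajectory (µm vs µm).

    ``track`` is an (n, 3) array of physical points. Points are projected on
    ``e_u`` (abscissa) and ``e_v`` or ``e_w`` (ordinate), sorted by abscissa,
    and the best-fit straight line is removed. If ``expected_period`` is
    given, tracks spanning fewer than two periods are rejected.
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 3:
        raise ValueError("track must be an (n, 3) array of points")
    if len(track) < 5:
        raise ValueError("track too short: need at least 5 points")
    if plane == "uv":
        e_t = frame.e_v
    elif plane == "uw":
        e_t = frame.e_w
    else:
        raise ValueError("plane must be 'uv' or 'uw'")
    u = track @ frame.e_u
    v = track @ e_t
    order = np.argsort(u)
    u, v = u[order], v[order]
    span = u[-1] - u[0]
    if expected_period is not None and span < 2 * expected_period:
        raise ValueError(
            f"track too short: spans {span:.1f} µm, "
            f"need >= {2 * expected_period:.1f} µm (two periods)"
        )
    # remove best-fit straight line
    coeff = np.polyfit(u, v, 1)
    v = v - np.polyval(coeff, u)
    return u, v


def _dominant_period(u: np.ndarray, v: np.ndarray) -> float:
    """Period of the dominant spectral component (µm), via a uniform
    resampling and an rFFT periodogram."""
    n = max(len(u) * 4, 256)
    ug = np.linspace(u[0], u[-1], n)
    vg = np.interp(ug, u, v)
    vg = vg - vg.mean()
    spec = np.abs(np.fft.rfft(vg * np.hanning(n)))
    freqs = np.fft.rfftfreq(n, d=(ug[-1] - ug[0]) / (n - 1))
    k = int(np.argmax(spec[1:])) + 1  # skip DC
    if freqs[k] <= 0:
        raise ValueError("no oscillatory component found")
    return 1.0 / freqs[k]


def _alternating_extrema(
    u: np.ndarray, v_smooth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and signs (+1 max, -1 min) of alternating local extrema."""
    dv = np.diff(v_smooth)
    sign = np.sign(dv)
    sign[sign == 0] = 1
    turns = np.nonzero(np.diff(sign))[0] + 1
    if len(turns) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    # enforce alternation: keep the more extreme of consecutive same-kind turns
    keep: list[int] = []
    kinds_kept: list[int] = []
    for idx in turns:
        kind = 1 if sign[idx - 1] > 0 else -1
        if kinds_kept and kinds_kept[-1] == kind:
            # same kind twice: keep the more extreme one
            if abs(v_smooth[idx]) > abs(v_smooth[keep[-1]]):
                keep[-1] = idx
        else:
            keep.append(idx)
            kinds_kept.append(kind)
    return np.asarray(keep, dtype=int), np.asarray(kinds_kept, dtype=int)


def estimate_waviness(
    u: np.ndarray,
    v: np.ndarray,
    method: str = "extrema",
    plane: str = "uv",
) -> WavinessEstimate:
    """Estimate period lambda and amplitude R0 of a quasi-sinusoid v(u).

    ``extrema``: smooth v over a window of lambda_init/5 (lambda_init from
    the dominant spectral component), locate alternating maxima/minima;
    lambda = 2 x mean consecutive-extremum spacing (sd over spacings), R0 =
    mean absolute displacement at the extrema (sd over extrema), amplitudes
    read from the raw signal near each smoothed extremum.

    ``sinefit``: least-squares fit of R0*sin(2*pi*u/lambda + psi), period
    initialised from the spectral peak; the measurement count is the sample
    count.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be 1D arrays of equal length")
    lam_init = _dominant_period(u, v)

    if method == "sinefit":
        span = u[-1] - u[0]
        if span < 2 * lam_init:
            raise ValueError("sinefit needs at least two periods of samples")
        # linear solve for amplitude/phase at fixed lambda gives the start
        def model(params: np.ndarray) -> np.ndarray:
            r0, lam, psi = params
            return r0 * np.sin(2 * np.pi * u / lam + psi) - v

        s, c = np.sin(2 * np.pi * u / lam_init), np.cos(2 * np.pi * u / lam_init)
        a, b = np.linalg.lstsq(np.stack([s, c], axis=1), v, rcond=None)[0]
        r0_init = float(np.hypot(a, b))
        psi_init = float(np.arctan2(b, a))
        res = least_squares(
            model,
            x0=[max(r0_init, 1e-9), lam_init, psi_init],
            bounds=([0, 0.2 * lam_init, -2 * np.pi], [np.inf, 5 * lam_init, 2 * np.pi]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        r0, lam, _ = res.x
        return WavinessEstimate(
            plane=plane, period=float(lam), period_sd=0.0,
            amplitude=float(r0), amplitude_sd=0.0,
            n_measurements=len(u), method="sinefit",
        )

    if method != "extrema":
        raise ValueError("method must be 'extrema' or 'sinefit'")

    du = np.median(np.diff(u))
    sigma = max(lam_init / 5.0 / max(du, 1e-12) / 2.355, 0.0)  # FWHM = lam/5
    v_smooth = ndi.gaussian_filter1d(v, sigma, mode="nearest") if sigma > 0.3 else v
    idx, _kinds = _alternating_extrema(u, v_smooth)
    if len(idx) < 3:
        raise ValueError(
            f"extrema method needs >= 3 alternating extrema, found {len(idx)}"
        )
    u_ext = u[idx]
    # amplitude from the raw signal near each smoothed extremum
    halo = max(int(round(lam_init / 10.0 / max(du, 1e-12))), 0)
    amp = np.empty(len(idx))
    for k, i in enumerate(idx):
        lo, hi = max(i - halo, 0), min(i + halo + 1, len(v))
        window = v[lo:hi]
        amp[k] = np.abs(window).max()
    spacings = np.diff(u_ext)
    lam = 2.0 * float(spacings.mean())
    lam_sd = 2.0 * float(spacings.std(ddof=0))
    return WavinessEstimate(
        plane=plane, period=lam, period_sd=lam_sd,
        amplitude=float(amp.mean()), amplitude_sd=float(amp.std(ddof=0)),
        n_measurements=int(len(idx)), method="extrema",
    )


def waviness_report(
    tracks: list[np.ndarray],
    frame: EigenFrame,
    method: str = "extrema",
    min_measurements: int = 50,
) -> dict[str, WavinessEstimate]:
    """Per-plane waviness aggregated over all usable tracks.

    Per-track estimates are pooled weighting by their measurement counts.
    Emits a warning when the pooled count in a plane falls below
    ``min_measurements`` (default 50); unusable tracks (too few
    extrema) are skipped with a warning.
    """
    if not tracks:
        raise ValueError("waviness report needs at least one track")
    out: dict[str, WavinessEstimate] = {}
    for plane in ("uv", "uw"):
        estimates: list[WavinessEstimate] = []
        for ti, track in enumerate(tracks):
            try:
                u, v = transverse_profile(track, frame, plane=plane)
                estimates.append(estimate_waviness(u, v, method=method, plane=plane))
            except ValueError as exc:
                warnings.warn(f"track {ti} unusable in plane {plane}: {exc}",
                              stacklevel=2)
        if not estimates:
            raise ValueError(f"no usable track in plane {plane}")
        n_tot = sum(e.n_measurements for e in estimates)
        wts = np.array([e.n_measurements for e in estimates], dtype=float)
        wts /= wts.sum()
        lam = float(sum(w * e.period for w, e in zip(wts, estimates)))
        lam_sd = float(np.sqrt(sum(w * (e.period_sd**2 + (e.period - lam) ** 2)
                                   for w, e in zip(wts, estimates))))
        r0 = float(sum(w * e.amplitude for w, e in zip(wts, estimates)))
        r0_sd = float(np.sqrt(sum(w * (e.amplitude_sd**2 + (e.amplitude - r0) ** 2)
                                  for w, e in zip(wts, estimates))))
        if n_tot < min_measurements:
            warnings.warn(
                f"plane {plane}: only {n_tot} waviness measurements "
                f"(< {min_measurements})", stacklevel=2,
            )
        out[plane] = WavinessEstimate(
            plane=plane, period=lam, period_sd=lam_sd,
            amplitude=r0, amplitude_sd=r0_sd,
            n_measurements=n_tot, method=method,
        )
    return out


def phi_amplitude_to_r0(phi_amplitude_deg: float, period: float) -> float:
    """Approximate displacement amplitude from an orientation-angle amplitude.

    For x(u) = R0 sin(2 pi u / lambda), the slope amplitude is
    tan(Phi) = 2 pi R0 / lambda, hence R0 = lambda tan(Phi) / (2 pi). This
    converts the oscillation amplitude of the local in-plane angle phi_i
    along e_u into a displacement amplitude; approximate for large angles.
    """
    return period * np.tan(np.radians(phi_amplitude_deg)) / (2 * np.pi)
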