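"""Image reconstruction from radial k-space.

The pipeline is density-compensated Kaiser-Bessel gridding: ramp-weight the
radial samples, spread them onto a 1.5x oversampled Cartesian grid with a
width-4 Kaiser-Bessel kernel, inverse FFT, deapodize, and crop.  Dynamic
frames are assembled with a sliding window (default 90 profiles per frame,
step 60), so consecutive frames share k-space data.  An optional iterative
reconstruction solves the l1/l2-regularized least-squares problem

    argmin_x ||W^(1/2) (A x - y)||^2 + l1 ||Psi x||_1 + l2 ||x||^2

with FISTA, where A is the nonuniform sampling (NUFFT) operator, W the
density-compensation weights and Psi an orthogonal wavelet (or a
total-variation penalty).

Conventions: images are (row, col) arrays with the object center at pixel
(N//2, N//2); row maps to y, col to x.  Normalized k-space coordinates are
in cycles/pixel, components in [-0.5, 0.5].  The forward model of a sample
at k is sum_x I(x) exp(-2*pi*i k.x) over centered pixel coordinates x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt

from .trajectory import RadialTrajectory

__all__ = [
    "AcquisitionMeta",
    "KSpaceSeries",
    "FramePlan",
    "ImageSeries",
    "GriddingKernel",
    "NufftOperator2D",
    "plan_sliding_window",
    "grid_reconstruct",
    "regularized_reconstruct",
    "reconstruct_series",
    "baseline_high_quality",
    "apply_phase_correction",
    "fourier_zero_fill",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class AcquisitionMeta:
    """Sequence parameters of the multi-slice 2D UTE acquisition.

    The sequence loops over all slices at each spoke angle before advancing
    to the next angle, so the effective per-slice repetition time is
    ``n_slices * tr_profile_ms`` (114 ms for 38 slices at TR = 3 ms).
    """

    n_slices: int = 38
    tr_profile_ms: float = 3.0
    te_ms: float = 0.368
    flip_deg: float = 40.0
    fov_mm: float = 58.0
    slice_thickness_mm: float = 1.208
    injection_time_s: float | None = None

    @property
    def tr_eff_ms(self) -> float:
        return self.n_slices * self.tr_profile_ms

    @property
    def tr_eff_s(self) -> float:
        return self.tr_eff_ms / 1000.0


@dataclass
class KSpaceSeries:
    """Complex radial samples indexed (profile, sample, slice).

    ``profile_time`` holds seconds since acquisition start per profile
    (profile i at i * tr_eff); all slices of a profile share its angle and,
    to within the 3 ms intra-shot offsets, its time stamp.
    """

    data: np.ndarray
    traj: RadialTrajectory
    meta: AcquisitionMeta
    profile_time: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(
                f"k-space data must be (profile, sample, slice), got shape {self.data.shape}"
            )
        p, s, z = self.data.shape
        if (p, s) != (self.traj.n_profiles, self.traj.n_samples):
            raise ValueError(
                f"data shape {(p, s)} does not match trajectory "
                f"({self.traj.n_profiles}, {self.traj.n_samples})"
            )
        if z != self.meta.n_slices:
            raise ValueError(
                f"data has {z} slices but meta declares {self.meta.n_slices}"
            )
        if self.profile_time is None:
            self.profile_time = np.arange(p) * self.meta.tr_eff_s
        dt = np.diff(self.profile_time)
        if dt.size and not np.all(dt > 0):
            raise ValueError("profile_time must be strictly increasing")

    @property
    def n_profiles(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]


@dataclass
class FramePlan:
    """Sliding-window frame layout over the profile index axis.

    Frame k covers the 0-based half-open range [k*step, k*step + window);
    trailing profiles that cannot fill a window are dropped.  In the 1-based
    prose convention frame 1 covers profiles 1-90 and frame 2 profiles
    61-150 (i.e. 0-based 60..149).
    """

    window: int
    step: int
    frames: list[tuple[int, int]]
    frame_mid_time: np.ndarray
    tr_eff_s: float

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_duration_s(self) -> float:
        return self.window * self.tr_eff_s

    @property
    def frame_spacing_s(self) -> float:
        return self.step * self.tr_eff_s


@dataclass
class ImageSeries:
    """4D magnitude image series (frame, slice, row, col)."""

    frames: np.ndarray
    pixel_spacing_mm: float
    slice_thickness_mm: float
    frame_mid_time: np.ndarray
    recon_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.ndim != 4:
            raise ValueError(
                f"frames must be (frame, slice, row, col), got shape {self.frames.shape}"
            )
        if np.any(self.frames < 0):
            raise ValueError("magnitude frames must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def voxel_volume_ml(self) -> float:
        return self.pixel_spacing_mm**2 * self.slice_thickness_mm / 1000.0


def plan_sliding_window(
    n_profiles: int, window: int = 90, step: int = 60, tr_eff: float = 0.114
) -> FramePlan:
    """Plan overlapping frames of ``window`` profiles every ``step`` profiles.

    Number of frames = floor((n_profiles - window) / step) + 1.  Each frame
    lasts window * tr_eff seconds (10.26 s for the 90 x 114 ms default,
    reported as 10.2 s) and consecutive frames are step * tr_eff apart
    (6.84 s, reported as 6.8 s).  ``frame_mid_time`` is the midpoint of the
    profile-time range of the window.
    """
    if step < 1 or window < step:
        raise ValueError(f"need window >= step >= 1, got window={window}, step={step}")
    if n_profiles < window:
        raise ValueError(
            f"cannot plan any frame: {n_profiles} profiles < window {window}"
        )
    n_frames = (n_profiles - window) // step + 1
    frames = [(k * step, k * step + window) for k in range(n_frames)]
    mid = np.array([(start + (window - 1) / 2.0) * tr_eff for start, _ in frames])
    return FramePlan(
        window=window, step=step, frames=frames, frame_mid_time=mid, tr_eff_s=tr_eff
    )


# --------------------------------------------------------------------------
# gridding / NUFFT operator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GriddingKernel:
    """Kaiser-Bessel interpolation kernel specification.

    ``width`` is in oversampled-grid cells; ``beta`` defaults to the Beatty
    formula for the given width and oversampling, which minimizes the
    worst-case aliasing amplitude of the kernel/deapodization pair.
    """

    width: int = 4
    oversampling: float = 1.5
    beta: float | None = None

    def resolved_beta(self) -> float:
        if self.beta is not None:
            return self.beta
        w, os = self.width, self.oversampling
        return np.pi * np.sqrt((w / os) ** 2 * (os - 0.5) ** 2 - 0.8)

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError(f"kernel width must be >= 2, got {self.width}")
        if self.oversampling <= 1.0:
            raise ValueError(
                f"grid oversampling must exceed 1, got {self.oversampling}"
            )


def _kb_taps(u: np.ndarray, width: int, beta: float, grid_size: int):
    """Per-axis tap indices (mod grid) and kernel values for positions u."""
    half = width // 2
    base = np.floor(u).astype(np.int64)
    offsets = np.arange(-half + 1, half + 1)  # width taps
    idx = base[:, None] + offsets[None, :]
    d = idx - u[:, None]  # |d| <= width/2
    arg = 1.0 - (2.0 * d / width) ** 2
    arg = np.clip(arg, 0.0, None)
    vals = np.i0(beta * np.sqrt(arg)) / np.i0(beta)
    vals[(np.abs(d) > width / 2)] = 0.0
    return np.mod(idx, grid_size), vals


def _kb_deapodization(n_img: int, grid_size: int, width: int, beta: float) -> np.ndarray:
    """Image-domain apodization of the KB kernel at centered pixel offsets.

    Continuous Fourier transform of the width-W Kaiser-Bessel kernel,
    evaluated at spatial frequency x/G: W * sinh(sqrt(b^2-(pi W x/G)^2)) /
    (I0(b) * sqrt(...)), extended by sin/sqrt beyond the sinh branch.
    """
    x = (np.arange(n_img) - n_img // 2) / grid_size
    t = beta**2 - (np.pi * width * x) ** 2
    out = np.empty_like(t)
    pos = t > 0
    sq = np.sqrt(np.abs(t))
    out[pos] = np.sinh(sq[pos]) / sq[pos]
    out[~pos] = np.sinc(sq[~pos] / np.pi)  # sin(sq)/sq
    return width * out / np.i0(beta)


class NufftOperator2D:
    """Exact adjoint pair of gridding interpolation operators.

    ``forward`` maps an (N, N) complex image to complex samples at the given
    normalized k-space coordinates (type-2 NUFFT); ``adjoint`` is its exact
    conjugate transpose (gridding + inverse FFT + deapodization).  Both
    approximate the corresponding direct nonuniform DFT sums.
    """

    def __init__(
        self,
        coords: np.ndarray,
        n_img: int,
        kernel: GriddingKernel | None = None,
    ):
        kernel = kernel or GriddingKernel()
        self.n_img = int(n_img)
        self.kernel = kernel
        self.grid_size = int(round(kernel.oversampling * n_img))
        beta = kernel.resolved_beta()
        coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
        if np.any(np.abs(coords) > 0.5 + 1e-12):
            raise ValueError("normalized coordinates must lie in [-0.5, 0.5]")
        self.n_samples = coords.shape[0]
        g = self.grid_size
        # grid positions with DC at index g//2; component 0 = kx -> col axis
        u_col = coords[:, 0] * g + g // 2
        u_row = coords[:, 1] * g + g // 2
        self._ci, self._cv = _kb_taps(u_col, kernel.width, beta, g)
        self._ri, self._rv = _kb_taps(u_row, kernel.width, beta, g)
        a = _kb_deapodization(n_img, g, kernel.width, beta)
        self._deapod = np.outer(a, a)
        self._pad = (g - n_img) // 2

    def _embed(self, img: np.ndarray) -> np.ndarray:
        g, p, n = self.grid_size, self._pad, self.n_img
        out = np.zeros((g, g), dtype=np.complex128)
        out[p : p + n, p : p + n] = img
        return out

    def forward(self, img: np.ndarray) -> np.ndarray:
        """Image (N, N) -> complex samples (M,)."""
        if img.shape != (self.n_img, self.n_img):
            raise ValueError(f"expected image shape {(self.n_img,) * 2}, got {img.shape}")
        work = self._embed(np.asarray(img, dtype=np.complex128) / self._deapod)
        fk = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(work)))
        out = np.zeros(self.n_samples, dtype=np.complex128)
        w = self.kernel.width
        for a in range(w):
            for b in range(w):
                out += (
                    self._rv[:, a]
                    * self._cv[:, b]
                    * fk[self._ri[:, a], self._ci[:, b]]
                )
        return out

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Complex samples (M,) -> image (N, N); exact transpose of forward."""
        samples = np.asarray(samples, dtype=np.complex128).reshape(-1)
        if samples.size != self.n_samples:
            raise ValueError(
                f"expected {self.n_samples} samples, got {samples.size}"
            )
        g = self.grid_size
        grid = np.zeros((g, g), dtype=np.complex128)
        w = self.kernel.width
        for a in range(w):
            for b in range(w):
                np.add.at(
                    grid,
                    (self._ri[:, a], self._ci[:, b]),
                    samples * self._rv[:, a] * self._cv[:, b],
                )
        img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(grid))) * g * g
        p, n = self._pad, self.n_img
        return img[p : p + n, p : p + n] / self._deapod


def fourier_zero_fill(img: np.ndarray, factor: int) -> np.ndarray:
    """Zero-pad k-space by ``factor`` (sinc interpolation in image space)."""
    if factor == 1:
        return np.asarray(img, dtype=np.complex128)
    n = img.shape[-1]
    m = n * factor
    fk = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
    pad = (m - n) // 2
    big = np.zeros(img.shape[:-2] + (m, m), dtype=np.complex128)
    big[..., pad : pad + n, pad : pad + n] = fk
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(big))) * factor**2


def _check_range(k: KSpaceSeries, plan_range: tuple[int, int]) -> tuple[int, int]:
    p0, p1 = int(plan_range[0]), int(plan_range[1])
    if not (0 <= p0 < p1 <= k.n_profiles):
        raise ValueError(
            f"profile range [{p0}, {p1}) empty or outside 0..{k.n_profiles}"
        )
    block = k.data[p0:p1]
    if not np.all(np.isfinite(block)):
        bad = p0 + int(np.argwhere(~np.isfinite(block).all(axis=(1, 2)))[0, 0])
        raise ValueError(f"non-finite k-space sample in profile {bad}")
    return p0, p1


def _dcf_scale(n_profiles_in_range: int, n_samples: int) -> float:
    """Area element making the DCF-weighted adjoint quantitative.

    Each radial sample owns an annular sector of area |k| * dk_r * 2*pi/P
    with dk_r = 0.5/(S-1); the ramp weights already carry |k|/k_max, so the
    remaining scalar is k_max * dk_r * 2*pi / P.
    """
    return 0.5 * (0.5 / (n_samples - 1)) * 2.0 * np.pi / n_profiles_in_range


def grid_reconstruct(
    k: KSpaceSeries,
    plan_range: tuple[int, int],
    zero_fill: int = 1,
    kernel: GriddingKernel | None = None,
) -> np.ndarray:
    """Density-compensated gridding reconstruction of one profile range.

    Returns magnitude images (slice, row, col) of size matrix * zero_fill.
    """
    p0, p1 = _check_range(k, plan_range)
    n = k.traj.matrix_size
    coords = k.traj.coords[p0:p1].reshape(-1, 2)
    weights = k.traj.weights[p0:p1].reshape(-1)
    scale = _dcf_scale(p1 - p0, k.traj.n_samples)
    op = NufftOperator2D(coords, n, kernel)
    out = np.empty((k.n_slices, n * zero_fill, n * zero_fill))
    for z in range(k.n_slices):
        y = k.data[p0:p1, :, z].reshape(-1)
        img = op.adjoint(weights * y * scale)
        out[z] = np.abs(fourier_zero_fill(img, zero_fill))
    return out


# --------------------------------------------------------------------------
# regularized (FISTA) reconstruction
# --------------------------------------------------------------------------

def _wavelet_analysis(img, wavelet, level):
    coeffs = pywt.wavedec2(img, wavelet, level=level, mode="periodization")
    return pywt.coeffs_to_array(coeffs)


def _wavelet_synthesis(arr, slices, wavelet):
    coeffs = pywt.array_to_coeffs(arr, slices, output_format="wavedec2")
    return pywt.waverec2(coeffs, wavelet, mode="periodization")


def _soft_threshold(c: np.ndarray, thr: float) -> np.ndarray:
    mag = np.abs(c)
    return c * np.maximum(1.0 - thr / np.maximum(mag, 1e-30), 0.0)


def _tv_seminorm(img: np.ndarray) -> float:
    gx = np.diff(img, axis=-1)
    gy = np.diff(img, axis=-2)
    return float(np.sum(np.abs(gx)) + np.sum(np.abs(gy)))


def _power_iteration_lipschitz(op: NufftOperator2D, sw: np.ndarray, n: int, seed: int = 0,
                               n_iter: int = 20) -> float:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    x /= np.linalg.norm(x)
    lam = 1.0
    for _ in range(n_iter):
        y = op.adjoint(sw**2 * op.forward(x))
        lam = np.linalg.norm(y)
        x = y / max(lam, 1e-30)
    return lam


def regularized_reconstruct(
    k: KSpaceSeries,
    plan_range: tuple[int, int],
    l1_weight: float = 0.00536,
    l2_weight: float = 0.0016,
    transform: str = "db4",
    wavelet_levels: int = 3,
    n_iter: int = 50,
    zero_fill: int = 1,
    kernel: GriddingKernel | None = None,
    dcf_in_solve: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """l1/l2-regularized iterative reconstruction (monotone FISTA).

    Solves ``argmin_x ||W^(1/2)(A x - y)||^2 + l1 ||Psi x||_1 + l2 ||x||^2``
    per slice, with Psi an orthogonal wavelet (any pywt name, default
    Daubechies-4, 3 levels, periodized) or ``transform="tv"`` for an
    anisotropic total-variation penalty.  ``dcf_in_solve=False`` drops the
    density weights from the data term (plain least squares).  The default
    weights, l1 = 0.00536 and l2 = 0.0016 (ratio 3.35), are the empirically
    determined values of the study protocol; as in the toolbox they were
    tuned for, the data are normalized per slice so the solution has peak
    magnitude near one, making the weights scale-free (the output is scaled
    back).  Raises if the objective increases persistently (step-size
    failure).
    """
    if l1_weight < 0 or l2_weight < 0:
        raise ValueError("regularization weights must be nonnegative")
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    p0, p1 = _check_range(k, plan_range)
    n = k.traj.matrix_size
    coords = k.traj.coords[p0:p1].reshape(-1, 2)
    weights = k.traj.weights[p0:p1].reshape(-1)
    scale = _dcf_scale(p1 - p0, k.traj.n_samples)
    op = NufftOperator2D(coords, n, kernel)
    sw = np.sqrt(weights * scale) if dcf_in_solve else np.full_like(weights, np.sqrt(scale))

    lip = _power_iteration_lipschitz(op, sw, n, seed=seed)
    step = 1.0 / (2.0 * (1.05 * lip + l2_weight))
    use_tv = transform == "tv"
    if use_tv:
        from skimage.restoration import denoise_tv_chambolle

    out = np.empty((k.n_slices, n * zero_fill, n * zero_fill))
    for z in range(k.n_slices):
        y_raw = k.data[p0:p1, :, z].reshape(-1)
        x = op.adjoint(weights * scale * y_raw)  # density-compensated adjoint init
        ref = float(np.abs(x).max())
        if ref == 0.0:
            out[z] = 0.0
            continue
        x = x / ref
        y = sw * y_raw / ref

        def objective(img):
            resid = sw * op.forward(img) - y
            val = float(np.vdot(resid, resid).real + l2_weight * np.vdot(img, img).real)
            if l1_weight > 0:
                if use_tv:
                    val += l1_weight * (_tv_seminorm(img.real) + _tv_seminorm(img.imag))
                else:
                    arr, _sl = _wavelet_analysis(img, transform, wavelet_levels)
                    val += l1_weight * float(np.sum(np.abs(arr)))
            return val

        def prox(img, thr):
            if l1_weight == 0 or thr == 0:
                return img
            if use_tv:
                re = denoise_tv_chambolle(img.real, weight=thr)
                im = denoise_tv_chambolle(img.imag, weight=thr)
                return re + 1j * im
            arr, sl = _wavelet_analysis(img, transform, wavelet_levels)
            return _wavelet_synthesis(_soft_threshold(arr, thr), sl, transform)

        def grad(img):
            return 2.0 * op.adjoint(sw * (sw * op.forward(img) - y)) + 2.0 * l2_weight * img

        v = x.copy()
        t_k = 1.0
        f_prev = objective(x)
        n_bad = 0
        for _ in range(n_iter):
            x_new = prox(v - step * grad(v), step * l1_weight)
            f_new = objective(x_new)
            if f_new > f_prev * (1 + 1e-6):
                # momentum overshoot: restart from the last accepted iterate
                t_k = 1.0
                x_new = prox(x - step * grad(x), step * l1_weight)
                f_new = objective(x_new)
                if f_new > f_prev * (1 + 1e-6):
                    n_bad += 1
                    if n_bad >= 5:
                        raise RuntimeError(
                            "objective increased persistently; step size estimate failed"
                        )
                    x_new, f_new = x, f_prev
                else:
                    n_bad = 0
            else:
                n_bad = 0
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k**2))
            v = x_new + ((t_k - 1.0) / t_next) * (x_new - x)
            x, t_k, f_prev = x_new, t_next, f_new
        out[z] = np.abs(fourier_zero_fill(x, zero_fill)) * ref
    return out


# --------------------------------------------------------------------------
# series assembly
# --------------------------------------------------------------------------

def reconstruct_series(
    k: KSpaceSeries,
    plan: FramePlan,
    mode: str = "gridding",
    zero_fill: int = 2,
    kernel: GriddingKernel | None = None,
    **reg_kwargs,
) -> ImageSeries:
    """Reconstruct one image volume per sliding-window frame."""
    if mode not in ("gridding", "regularized"):
        raise ValueError(f"mode must be 'gridding' or 'regularized', got {mode!r}")
    if plan.frames and plan.frames[-1][1] > k.n_profiles:
        raise ValueError("frame plan extends beyond available profiles")
    n_out = k.traj.matrix_size * zero_fill
    frames = np.empty((plan.n_frames, k.n_slices, n_out, n_out))
    for f, rng in enumerate(plan.frames):
        if mode == "gridding":
            frames[f] = grid_reconstruct(k, rng, zero_fill=zero_fill, kernel=kernel)
        else:
            frames[f] = regularized_reconstruct(
                k, rng, zero_fill=zero_fill, kernel=kernel, **reg_kwargs
            )
    return ImageSeries(
        frames=frames,
        pixel_spacing_mm=k.meta.fov_mm / n_out,
        slice_thickness_mm=k.meta.slice_thickness_mm,
        frame_mid_time=plan.frame_mid_time.copy(),
        recon_meta={
            "window": plan.window,
            "step": plan.step,
            "mode": mode,
            "zero_fill": zero_fill,
        },
    )


def baseline_high_quality(
    k: KSpaceSeries,
    n_spokes: int = 3000,
    mode: str = "gridding",
    zero_fill: int = 2,
    kernel: GriddingKernel | None = None,
    **reg_kwargs,
) -> np.ndarray:
    """High-quality pre-contrast volume from the first ``n_spokes`` profiles.

    Used for histogram-based lesion quantification; requires that the
    baseline period actually contains that many profiles.
    """
    inj = k.meta.injection_time_s
    if inj is not None:
        n_baseline = int(np.searchsorted(k.profile_time, inj))
    else:
        n_baseline = k.n_profiles
    if n_baseline < n_spokes:
        raise ValueError(
            f"only {n_baseline} baseline profiles available, need {n_spokes}"
        )
    if mode == "gridding":
        return grid_reconstruct(k, (0, n_spokes), zero_fill=zero_fill, kernel=kernel)
    return regularized_reconstruct(
        k, (0, n_spokes), zero_fill=zero_fill, kernel=kernel, **reg_kwargs
    )


def apply_phase_correction(k: KSpaceSeries, phase_table: np.ndarray) -> KSpaceSeries:
    """Multiply each sample by exp(i * phase); magnitudes are unchanged.

    Hook for measured-trajectory / B0 phase-evolution corrections supplied
    per (profile, sample); the same table is applied to every slice.
    """
    phase_table = np.asarray(phase_table, dtype=np.float64)
    if phase_table.shape != k.data.shape[:2]:
        raise ValueError(
            f"phase table shape {phase_table.shape} does not match "
            f"data {k.data.shape[:2]}"
        )
    return replace(k, data=k.data * np.exp(1j * phase_table)[:, :, None])
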