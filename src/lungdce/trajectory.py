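"""Tiny-golden-angle radial k-space trajectories and density compensation.

Continuous center-out radial scanning samples each spoke from the k-space
center to the edge.  Successive spokes are rotated by a fixed increment; the
generalized (tiny) golden angles psi_N = 180 / (phi + N - 1) degrees, with
phi the golden ratio, give quasi-uniform angular coverage of any consecutive
subset of spokes while keeping per-step gradient jumps small.  Because the
center of k-space is heavily oversampled by radial readouts, samples are
weighted by their radial distance |k| (ramp / inverse-density weighting)
before gridding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0

__all__ = [
    "GOLDEN_RATIO",
    "RadialTrajectory",
    "tiny_golden_angle",
    "build_trajectory",
    "density_weights",
]


def tiny_golden_angle(order: int) -> float:
    """Angular increment (degrees) of the tiny-golden-angle sequence.

    psi_N = 180 / (phi + N - 1) with phi = (1 + sqrt(5)) / 2.  ``order=1``
    is the conventional golden angle (111.2461 deg); ``order=7`` gives the
    23.63 deg increment used for multi-slice UTE lung imaging, small enough
    to limit eddy-current/gradient jumps between shots.
    """
    if not isinstance(order, (int, np.integer)) or isinstance(order, bool):
        raise TypeError(f"order must be an integer, got {order!r}")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    return 180.0 / (GOLDEN_RATIO + order - 1)


@dataclass
class RadialTrajectory:
    """Center-out radial sampling pattern with density-compensation weights.

    Attributes
    ----------
    n_profiles, n_samples : int
        Number of spokes and of samples per spoke.
    matrix_size : int
        Acquisition matrix (e.g. 96); ``scaled_coords`` multiplies the
        normalized coordinates by this value.
    angles : (n_profiles,) float array
        Spoke angles in degrees, in [0, 360).
    coords : (n_profiles, n_samples, 2) float array
        Normalized k-space positions, each component in [-0.5, 0.5],
        in cycles per pixel; axis order (profile, sample, component),
        component 0 = kx, 1 = ky.
    weights : (n_profiles, n_samples) float array
        Ramp density-compensation factors, max 1 at the spoke tip.
    """

    n_profiles: int
    n_samples: int
    matrix_size: int
    angles: np.ndarray
    coords: np.ndarray
    weights: np.ndarray = field(repr=False)
    dc_floor: float = 0.01

    def scaled_coords(self) -> np.ndarray:
        """Coordinates scaled to the acquisition matrix (|k| up to matrix/2)."""
        return self.coords * self.matrix_size

    @property
    def radii(self) -> np.ndarray:
        """Normalized radial distance |k| per (profile, sample)."""
        return np.hypot(self.coords[..., 0], self.coords[..., 1])

    def flat_coords(self) -> np.ndarray:
        """(n_profiles * n_samples, 2) view of the normalized coordinates."""
        return self.coords.reshape(-1, 2)

    def save(self, path) -> None:
        np.savez(
            path,
            angles=self.angles,
            coords=self.coords,
            weights=self.weights,
            meta=np.array(
                [self.n_profiles, self.n_samples, self.matrix_size], dtype=np.int64
            ),
            dc_floor=np.array([self.dc_floor]),
        )

    @classmethod
    def load(cls, path) -> "RadialTrajectory":
        with np.load(path) as f:
            n_p, n_s, m = (int(v) for v in f["meta"])
            return cls(
                n_profiles=n_p,
                n_samples=n_s,
                matrix_size=m,
                angles=f["angles"],
                coords=f["coords"],
                weights=f["weights"],
                dc_floor=float(f["dc_floor"][0]),
            )


def build_trajectory(
    n_profiles: int,
    n_samples: int,
    matrix_size: int = 96,
    angle_increment: float | None = None,
    tiny_golden_order: int = 7,
    dc_floor: float | None = None,
) -> RadialTrajectory:
    """Build a center-out radial trajectory.

    Spoke ``i`` is at angle ``(i * angle_increment) mod 360`` (computed
    directly, not by cumulative addition, to avoid accumulating rounding
    error); its sample ``j`` sits at radius ``0.5 * j / (n_samples - 1)``
    along that direction, so the spoke runs from k = 0 to the edge of the
    normalized k-space square.  When ``angle_increment`` is None the
    tiny-golden-angle increment of ``tiny_golden_order`` is used.

    ``dc_floor`` defaults to ``1 / (8 (n_samples - 1))``, the value for
    which the floored ramp weight equals the area of the disk-shaped
    k-space cell the DC sample actually owns (radius half a radial step);
    a larger floor overweights the center and adds a uniform intensity
    offset to the images.
    """
    if n_profiles < 1:
        raise ValueError(f"n_profiles must be >= 1, got {n_profiles}")
    if n_samples < 2:
        raise ValueError(
            f"n_samples must be >= 2 (center-out radius undefined otherwise), got {n_samples}"
        )
    if matrix_size < 1:
        raise ValueError(f"matrix_size must be >= 1, got {matrix_size}")
    if angle_increment is None:
        angle_increment = tiny_golden_angle(tiny_golden_order)
    if dc_floor is None:
        dc_floor = min(0.1, 1.0 / (8.0 * (n_samples - 1)))

    i = np.arange(n_profiles, dtype=np.float64)
    angles = np.mod(i * float(angle_increment), 360.0)
    radii = 0.5 * np.arange(n_samples, dtype=np.float64) / (n_samples - 1)
    ang_rad = np.deg2rad(angles)
    direction = np.stack([np.cos(ang_rad), np.sin(ang_rad)], axis=-1)  # (P, 2)
    coords = radii[None, :, None] * direction[:, None, :]  # (P, S, 2)

    traj = RadialTrajectory(
        n_profiles=n_profiles,
        n_samples=n_samples,
        matrix_size=matrix_size,
        angles=angles,
        coords=coords,
        weights=np.empty((n_profiles, n_samples)),
        dc_floor=dc_floor,
    )
    traj.weights = density_weights(traj, dc_floor=dc_floor)
    return traj


def density_weights(traj: RadialTrajectory, dc_floor: float = 0.01) -> np.ndarray:
    """Ramp density-compensation weights, |k| / |k_max|, max 1 per spoke.

    The k = 0 sample would receive weight 0 under pure ramp weighting,
    discarding the DC information; it is assigned ``dc_floor`` instead.
    Weights are identical across profiles (radial symmetry).
    """
    if not 0.0 < dc_floor <= 0.1:
        raise ValueError(f"dc_floor must lie in (0, 0.1], got {dc_floor}")
    radii = traj.radii
    k_max = radii.max()
    if k_max <= 0:
        raise ValueError("trajectory has no nonzero samples")
    w = radii / k_max
    w[w == 0.0] = dc_floor
    return w
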