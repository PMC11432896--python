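"""Shared fixtures: tiny phantoms, trajectories and direct-DFT oracles.

The direct nonuniform-DFT oracles deliberately use naive summation (slow,
obviously correct) and share no code with the FFT-based gridding they
check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import lungdce as L

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from lungdce.synthetic import (
    Compartment,
    Ellipse,
    Enhancement,
    PhantomSpec,
    delta_r1_for_relative_enhancement,
    enhancement_peak_value,
)


def direct_nudft_forward(img: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Naive type-2 NUDFT: sum over centered pixels (oracle)."""
    n = img.shape[0]
    c = np.arange(n) - n // 2
    x, y = np.meshgrid(c, c, indexing="xy")
    out = np.empty(coords.shape[0], dtype=np.complex128)
    for j, (kx, ky) in enumerate(coords):
        out[j] = np.sum(img * np.exp(-2j * np.pi * (kx * x + ky * y)))
    return out


def direct_nudft_adjoint(values: np.ndarray, coords: np.ndarray, n: int) -> np.ndarray:
    """Naive type-1 NUDFT adjoint onto an n x n centered grid (oracle)."""
    c = np.arange(n) - n // 2
    x, y = np.meshgrid(c, c, indexing="xy")
    out = np.zeros((n, n), dtype=np.complex128)
    for (kx, ky), v in zip(coords, values):
        out += v * np.exp(2j * np.pi * (kx * x + ky * y))
    return out


def nrmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))


def scaled_enhancement(
    peak_re: float,
    t1_ms: float,
    tr_eff_ms: float,
    t_inj: float,
    arrival: float,
    tau_in: float,
    tau_out: float,
    time_scale: float = 1.0,
) -> Enhancement:
    """Enhancement course hitting a target peak RE (time constants scaled)."""
    dr1 = delta_r1_for_relative_enhancement(peak_re, t1_ms, 40.0, tr_eff_ms)
    t_in, t_out = tau_in * time_scale, tau_out * time_scale
    return Enhancement(
        dr1 / enhancement_peak_value(t_in, t_out),
        t_inj + arrival * time_scale,
        t_in,
        t_out,
    )


def tiny_phantom(
    noise_sd: float = 0.0,
    drift_amplitude: float = 0.0,
    n_slices: int = 2,
    seed: int = 7,
    duration_s: float = 16.0,
) -> PhantomSpec:
    """Small two-compartment dynamic phantom (matrix 32) for fast tests.

    Injection at 6 s, effective TR = n_slices * 3 ms; body shell plus a
    lung pair with one enhancing vessel blob.
    """
    tr_eff = n_slices * 3.0
    t_inj = 6.0
    z = n_slices
    comps = [
        Compartment("body", 1900, 0.5, Enhancement(), [[Ellipse(0, 0, 13, 11)]] * z),
        Compartment(
            "parenchyma",
            1800,
            0.25,
            scaled_enhancement(2.5, 1800, tr_eff, t_inj, 0.3, 2.0, 20.0),
            [[Ellipse(-5.5, 0, 4.5, 6.5), Ellipse(5.5, 0, 4.5, 6.5)]] * z,
        ),
        Compartment(
            "vessel",
            5000,
            0.8,
            scaled_enhancement(8.0, 5000, tr_eff, t_inj, 0.15, 0.6, 6.0),
            [[Ellipse(-5.5, -1, 2.0, 2.6), Ellipse(5.5, -1, 2.0, 2.6)]] * z,
        ),
    ]
    return PhantomSpec(
        matrix_size=32,
        fov_mm=29.0,
        n_slices=n_slices,
        slice_thickness_mm=2.0,
        compartments=comps,
        injection_time_s=t_inj,
        duration_s=duration_s,
        noise_sd=noise_sd,
        drift_amplitude=drift_amplitude,
        drift_period_s=10.0,
        seed=seed,
        name="tiny",
    )


@pytest.fixture(scope="session")
def tiny_sim():
    """Noise-free tiny-phantom simulation shared across tests."""
    spec = tiny_phantom()
    n_prof = int(spec.duration_s / (spec.tr_eff_ms / 1000.0))
    # 2x readout oversampling, as UTE acquisitions use
    traj = L.build_trajectory(n_prof, 64, matrix_size=32)
    k, gt = L.simulate_kspace(spec, traj)
    return spec, traj, k, gt


@pytest.fixture(scope="session")
def uniform_traj_32():
    """402 uniformly spaced spokes at matrix 32 (fully sampled)."""
    return L.build_trajectory(402, 32, matrix_size=32, angle_increment=360.0 / 402)
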