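"""Deterministic, seeded generators for every input class.

These emulate the inputs the analysis modules consume — toy reaction
networks with closed-form equilibria, PIV-like velocity-field sequences with
a prescribed lateral correlation length, advancing fluorescence-front mask
stacks, and noisy fold-change observations for calibration tests — so the
whole package is testable without any external data.  Identical
specification and seed give bit-identical output; generators never read
files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import Constraint, ConstraintSet
from .motility import VelocityField
from .parameters import ParameterSet, reference_parameters

__all__ = ["toy_binding_network", "synthetic_velocity_fields",
           "synthetic_front_masks", "FrontMaskStack",
           "noisy_foldchange_observations"]


def toy_binding_network(K: float = 1.0, total_a: float = 1.0,
                        total_b: float = 1.0):
    """Two-species reversible binding A + B <-> C with analytic equilibrium.

    Returns (scheme, params, equilibrium) where equilibrium maps species to
    their closed-form steady-state concentrations:
    C* = ((a0 + b0 + K) - sqrt((a0 + b0 + K)^2 - 4 a0 b0)) / 2.
    """
    if K <= 0 or total_a < 0 or total_b < 0:
        raise ValueError("K must be positive and totals nonnegative")
    s = total_a + total_b + K
    # numerically stable smaller root (avoids cancellation at large K)
    c = 2.0 * total_a * total_b / (s + np.sqrt(s * s - 4.0 * total_a * total_b))
    scheme = {"reactions": [{"id": 1, "type": "binding",
                             "reactants": ("A", "B"), "products": ("C",),
                             "parameters": ("K",)}],
              "species": ("A", "B", "C")}
    params = {"K": K, "A0": total_a, "B0": total_b}
    equilibrium = {"A": total_a - c, "B": total_b - c, "C": c}
    return scheme, params, equilibrium


def _exponential_correlated_field(shape: tuple[int, int], spacing: float,
                                  length: float, rng: np.random.Generator
                                  ) -> np.ndarray:
    """Zero-mean unit-variance Gaussian field with isotropic exponential
    spatial correlation exp(-r/length), by spectral filtering of white noise
    on a 2x zero-padded grid (reduces periodic wrap-around)."""
    ny, nx = shape
    py, px = 2 * ny, 2 * nx
    ky = np.fft.fftfreq(py, d=spacing) * 2.0 * np.pi
    kx = np.fft.fftfreq(px, d=spacing) * 2.0 * np.pi
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    # 2-D spectral density of the exponential covariance (Matern nu = 1/2):
    # S(k) prop. (1 + (k L)^2)^(-3/2)
    spec = (1.0 + k2 * length ** 2) ** (-1.5)
    noise = rng.standard_normal((py, px))
    f = np.fft.ifft2(np.fft.fft2(noise) * np.sqrt(spec)).real
    f = f[:ny, :nx]
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def synthetic_velocity_fields(length_um: float = 50.0,
                              v_mean_um_min: float = 0.3,
                              angle_sd_deg: float = 0.0,
                              fluct_sd_um_min: float = 0.15,
                              shape: tuple[int, int] = (48, 48),
                              spacing_um: float = 10.0,
                              n_frames: int = 28,
                              frame_interval_min: float = 30.0,
                              seed: int = 0) -> list[VelocityField]:
    """PIV-like velocity-field sequence with imposed lateral correlations.

    The lateral component is a Gaussian random field with exponential
    spatial covariance of correlation length ``length_um`` and standard
    deviation ``fluct_sd_um_min``, superposed on a mean flow of speed
    ``v_mean_um_min`` toward wound closure (+x); ``angle_sd_deg`` adds
    per-vector directional jitter to the mean flow.  Defaults mirror the
    imaging protocol: 30-min cadence over 15 h (28 frames) on a ~480-um
    field of view.
    """
    if length_um <= 0:
        raise ValueError("correlation length must be positive")
    if min(shape) < 8:
        raise ValueError("grid must be at least 8x8")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    x, y = np.meshgrid(np.arange(nx) * spacing_um, np.arange(ny) * spacing_um)
    fields = []
    for i in range(n_frames):
        theta = np.deg2rad(angle_sd_deg) * rng.standard_normal(shape) \
            if angle_sd_deg > 0 else np.zeros(shape)
        u = v_mean_um_min * np.cos(theta)
        v = v_mean_um_min * np.sin(theta)
        if fluct_sd_um_min > 0:
            v = v + fluct_sd_um_min * _exponential_correlated_field(
                shape, spacing_um, length_um, rng)
        fields.append(VelocityField(x, y, u, v,
                                    time_min=i * frame_interval_min))
    return fields


@dataclass
class FrontMaskStack:
    """Binary fluorescence-front masks with calibration metadata."""

    masks: np.ndarray  # (n_frames, ny, nx) bool
    frame_interval_min: float
    pixel_size_um: float
    true_speed_um_h: float


def synthetic_front_masks(speed_um_h: float = 20.0,
                          noise_px: float = 0.0,
                          n_frames: int = 28,
                          shape: tuple[int, int] = (64, 128),
                          frame_interval_min: float = 30.0,
                          pixel_size_um: float = 1.125,
                          start_col: int = 8,
                          seed: int = 0) -> FrontMaskStack:
    """Advancing binary front with optional per-row jitter of ``noise_px``."""
    if speed_um_h < 0:
        raise ValueError("speed must be nonnegative")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    masks = np.zeros((n_frames, ny, nx), dtype=bool)
    px_per_frame = speed_um_h / 60.0 * frame_interval_min / pixel_size_um
    cols = np.arange(nx)
    for i in range(n_frames):
        front = start_col + px_per_frame * i
        jitter = noise_px * rng.standard_normal(ny) if noise_px > 0 else \
            np.zeros(ny)
        per_row = np.clip(np.round(front + jitter), 0, nx - 1).astype(int)
        masks[i] = cols[None, :] <= per_row[:, None]
    return FrontMaskStack(masks, frame_interval_min, pixel_size_um, speed_um_h)


def noisy_foldchange_observations(params: ParameterSet | None = None,
                                  noise_sd_log: float = 0.0,
                                  seed: int = 0,
                                  variables: tuple[str, ...] = (
                                      "bcat", "dpagt1_mrna", "gpt", "ecad_aj"),
                                  tol: float = 0.1) -> ConstraintSet:
    """Simulated fold-change targets for calibration tests.

    Solves the Wnt OFF and ON steady states at ``params``, perturbs the
    fold changes with multiplicative lognormal noise of scale
    ``noise_sd_log`` (natural-log sd), and packages them as constraints.
    """
    from .simulate import WNT_OFF, WNT_ON, find_steady_state
    if params is None:
        params = reference_parameters()
    rng = np.random.default_rng(seed)
    off = find_steady_state(params, wnt0=WNT_OFF)
    from .model import pack_independent
    from .simulate import steady_state_newton
    from .model import full_state_from_independent
    p_on = params.with_overrides(WNT0=WNT_ON)
    x_on = steady_state_newton(p_on, pack_independent(off))
    on = (full_state_from_independent(x_on, p_on) if x_on is not None
          else find_steady_state(p_on))
    out = []
    for v in variables:
        fold = on[v] / off[v]
        noisy = fold * float(np.exp(noise_sd_log * rng.standard_normal())) \
            if noise_sd_log > 0 else fold
        out.append(Constraint(f"fold_{v}", "fold_change", v, target=noisy,
                              tol=tol))
    return tuple(out)
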