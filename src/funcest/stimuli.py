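"""Stimulus scatterplots and simulated hand-drawn responses.

The study design crosses generating function (linear / quadratic / cubic)
x number of points (6 / 24) x presentation scale (small / large) x 2
replicates = 24 scatterplot problems. Small-scale plots show the identical
point cloud shrunk about the origin so it fills 40% of the plotting area
(each axis extent multiplied by sqrt(0.4)).

Simulated drawers replace human participants: a drawer observes the
scatterplot and produces a dense trace sampled from the Gaussian-process
posterior under a latent hyperparameter profile (small length scale ->
data-tracking response, large length scale -> smooth global-trend
response), plus hand-motion jitter and, optionally, short x-backtracking
segments that exercise downstream trace repair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gp
from .exceptions import InvalidArgumentError
from .traces import DrawnTrace

__all__ = [
    "DesignCell",
    "Scatterplot",
    "DrawerProfile",
    "full_design",
    "make_stimulus",
    "simulate_drawer",
    "default_coefficients",
    "SMALL_SCALE_ZOOM",
]

GENERATOR_DEGREE = {"linear": 1, "quadratic": 2, "cubic": 3}

#: Per-axis shrink factor for small-scale plots: the point cloud fills 40%
#: of the plotting *area*, so each axis extent shrinks by sqrt(0.4).
SMALL_SCALE_ZOOM = float(np.sqrt(0.4))


@dataclass(frozen=True)
class DesignCell:
    """One cell of the factorial stimulus design."""

    generator: str
    n_points: int
    scale: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.generator not in GENERATOR_DEGREE:
            raise InvalidArgumentError(f"unknown generator {self.generator!r}")
        if self.n_points not in (6, 24):
            raise InvalidArgumentError("n_points must be 6 or 24")
        if self.scale not in ("small", "large"):
            raise InvalidArgumentError("scale must be 'small' or 'large'")
        if self.replicate < 1:
            raise InvalidArgumentError("replicate must be >= 1")

    @property
    def problem_id(self) -> str:
        """Short label, e.g. ``L6S-1`` for linear, 6 points, small, rep 1."""
        return (
            f"{self.generator[0].upper()}{self.n_points}"
            f"{self.scale[0].upper()}-{self.replicate}"
        )


def full_design(n_replicates: int = 2) -> list[DesignCell]:
    """Enumerate the full 3 x 2 x 2 x n_replicates design (24 cells)."""
    return [
        DesignCell(g, n, s, r)
        for g in ("linear", "quadratic", "cubic")
        for n in (6, 24)
        for s in ("small", "large")
        for r in range(1, n_replicates + 1)
    ]


@dataclass(frozen=True)
class Scatterplot:
    """One stimulus: normalized point coordinates plus its design cell."""

    x: np.ndarray
    y: np.ndarray
    cell: DesignCell
    true_coefficients: np.ndarray
    stimulus_noise_sd: float

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape or self.x.size != self.cell.n_points:
            raise InvalidArgumentError("x and y must both have cell.n_points entries")
        if np.abs(self.x).max() > 1 + 1e-12 or np.abs(self.y).max() > 1 + 1e-12:
            raise InvalidArgumentError("coordinates must lie within [-1, 1]")


@dataclass(frozen=True)
class DrawerProfile:
    """Latent style of a simulated drawer.

    ``theta_true`` sets the GP posterior the drawer samples from (its length
    scale is the local-vs-global dial), ``motor_sd`` the hand-jitter SD in
    axis units, and ``backtrack_prob`` the chance of injecting one short
    reversed-x segment into the trace.
    """

    theta_true: gp.GPHyperParams
    motor_sd: float = 0.01
    backtrack_prob: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.motor_sd) or self.motor_sd < 0:
            raise InvalidArgumentError("motor_sd must be finite and >= 0")
        if not 0.0 <= self.backtrack_prob <= 1.0:
            raise InvalidArgumentError("backtrack_prob must be in [0, 1]")


def default_coefficients(generator: str) -> np.ndarray:
    """Default polynomial coefficients (constant term first) per generator.

    Chosen so the zero-noise curve spans most of the [-1, 1] axis range.
    """
    return {
        "linear": np.array([0.0, 0.8]),
        "quadratic": np.array([-0.5, 0.0, 1.2]),
        "cubic": np.array([0.0, -0.6, 0.0, 1.4]),
    }[generator]


def make_stimulus(
    cell: DesignCell,
    coefficients,
    stimulus_noise_sd: float,
    seed: int,
) -> Scatterplot:
    """Generate one stimulus scatterplot.

    x-locations are uniform draws over the drawing range; y is the
    polynomial plus additive Gaussian stimulus noise, truncated to the
    plotting frame. The random stream depends only on the seed — not on the
    scale — so the small-scale member of a replicate pair is exactly the
    large-scale cloud multiplied by the zoom factor (identical relative
    positions).
    """
    coeffs = np.asarray(coefficients, dtype=float)
    if coeffs.size != GENERATOR_DEGREE[cell.generator] + 1:
        raise InvalidArgumentError(
            f"{cell.generator} generator needs "
            f"{GENERATOR_DEGREE[cell.generator] + 1} coefficients, got {coeffs.size}"
        )
    if stimulus_noise_sd < 0:
        raise InvalidArgumentError("stimulus_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(-1.0, 1.0, size=cell.n_points))
    y = np.polynomial.polynomial.polyval(x, coeffs)
    if stimulus_noise_sd > 0:
        y = y + rng.normal(0.0, stimulus_noise_sd, size=cell.n_points)
    # The physical plot has bounded axes; points cannot leave the frame.
    y = np.clip(y, -1.0, 1.0)
    if cell.scale == "small":
        x = x * SMALL_SCALE_ZOOM
        y = y * SMALL_SCALE_ZOOM
    return Scatterplot(
        x=x,
        y=y,
        cell=cell,
        true_coefficients=coeffs,
        stimulus_noise_sd=float(stimulus_noise_sd),
    )


def simulate_drawer(
    stimulus: Scatterplot,
    profile: DrawerProfile,
    n_raw_points: int = 200,
    seed: int = 0,
    participant_id: str = "",
) -> DrawnTrace:
    """Simulate one hand-drawn response to a stimulus.

    The drawer's latent function is a sample from the GP posterior
    conditioned on the stimulus points under ``profile.theta_true``,
    evaluated on a dense grid spanning the axis, with independent Gaussian
    motor jitter added. With probability ``backtrack_prob`` one short
    reversed-x segment is re-traced (as when a pen doubles back), which
    downstream trace repair must remove.
    """
    if n_raw_points < 2:
        raise InvalidArgumentError("n_raw_points must be >= 2")
    if stimulus.x.size == 0:
        raise InvalidArgumentError("stimulus has no points")
    rng = np.random.default_rng(seed)
    xs = np.linspace(-1.0, 1.0, n_raw_points)
    post = gp.posterior_predictive(stimulus.x, stimulus.y, profile.theta_true, xs)
    # Sample one path from the posterior (jittered Cholesky for stability).
    L, _ = gp._cholesky_with_jitter(
        post.cov + 1e-10 * np.eye(n_raw_points), profile.theta_true.signal_var
    )
    ys = post.mean + L @ rng.standard_normal(n_raw_points)
    if profile.motor_sd > 0:
        ys = ys + rng.normal(0.0, profile.motor_sd, size=n_raw_points)

    if rng.random() < profile.backtrack_prob and n_raw_points >= 10:
        # Re-trace a short segment in reverse drawing order.
        seg_len = int(rng.integers(3, 7))
        i = int(rng.integers(seg_len, n_raw_points - 1))
        xs = np.concatenate([xs[: i + 1], xs[i - seg_len : i][::-1], xs[i + 1 :]])
        ys = np.concatenate([ys[: i + 1], ys[i - seg_len : i][::-1], ys[i + 1 :]])

    return DrawnTrace(
        x=xs,
        y=ys,
        participant_id=participant_id,
        problem_id=stimulus.cell.problem_id,
    )
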