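"""Closed-form EZ-DDM moment equations and Wiener first-passage sampling.

The drift-diffusion model (DDM) describes two-choice decisions as a Wiener
process with drift ``nu`` and diffusion coefficient ``s`` accumulating between
absorbing boundaries at 0 and ``alpha``, starting unbiased at ``alpha/2``.
Observed response time is the first-passage (decision) time plus a
non-decision time ``tau``; a response is "correct" when the upper boundary is
hit.

The EZ method of moments maps this three-parameter process to three summary
statistics — accuracy rate, mean RT, RT variance — in closed form, and back.
:func:`forward_moments` and :func:`inverse_ez` implement that bijection;
:func:`sample_trials` draws exact trial-level data from the first-passage
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DDMParams",
    "MomentTriple",
    "TrialSet",
    "forward_moments",
    "inverse_ez",
    "sample_trials",
]

#: Model-wide diffusion coefficient (evidence units per sqrt(second)).
#: The whole parameterization (alpha ~ 2-4, |nu| <= 3, tau ~ 0.2-0.4 s)
#: produces second-scale RTs only under this scaling.
DEFAULT_S = 1.0

# Drift magnitudes below this (in units of k = alpha*nu/s^2) switch the
# moment equations to their series expansion around nu = 0, keeping them
# continuous and numerically stable through zero drift.
_K_SERIES_THRESHOLD = 1e-3


@dataclass(frozen=True)
class DDMParams:
    """One participant-condition diffusion parameterization.

    Attributes
    ----------
    nu : float
        Drift rate (evidence units per second, signed).
    alpha : float
        Boundary separation (evidence units), > 0.
    tau : float
        Non-decision time (seconds), >= 0.
    s : float
        Diffusion coefficient (evidence units per sqrt(second)), > 0.
    """

    nu: float
    alpha: float
    tau: float
    s: float = DEFAULT_S

    def __post_init__(self) -> None:
        vals = (self.nu, self.alpha, self.tau, self.s)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite DDM parameters: {vals}")
        if self.alpha <= 0:
            raise ValueError(f"boundary separation must be > 0, got {self.alpha}")
        if self.tau < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.tau}")
        if self.s <= 0:
            raise ValueError(f"diffusion coefficient must be > 0, got {self.s}")


@dataclass(frozen=True)
class MomentTriple:
    """EZ-predicted accuracy, mean RT and RT variance for one parameterization."""

    pc: float   # predicted accuracy rate, in (0, 1)
    mrt: float  # predicted mean RT, seconds
    vrt: float  # predicted RT variance, seconds^2


@dataclass
class TrialSet:
    """Trial-level response times (seconds, > 0) and 0/1 accuracies."""

    rt: np.ndarray
    accuracy: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=np.int64)
        if self.rt.shape != self.accuracy.shape or self.rt.ndim != 1:
            raise ValueError("rt and accuracy must be equal-length 1-D vectors")
        if not np.all(self.rt > 0):
            raise ValueError("all response times must be strictly positive")

    def __len__(self) -> int:
        return self.rt.size

    def to_csv(self, path_or_buf) -> None:
        """Write as delimited text with columns rt, accuracy."""
        import pandas as pd

        pd.DataFrame({"rt": self.rt, "accuracy": self.accuracy}).to_csv(
            path_or_buf, index=False
        )

    @classmethod
    def from_csv(cls, path_or_buf) -> "TrialSet":
        import pandas as pd

        df = pd.read_csv(path_or_buf)
        return cls(rt=df["rt"].to_numpy(), accuracy=df["accuracy"].to_numpy())


# ---------------------------------------------------------------------------
# Forward moment equations
# ---------------------------------------------------------------------------

def forward_moments(params: DDMParams) -> MomentTriple:
    """Exact decision-process moments of the unbiased Wiener process.

    With ``k = alpha * nu / s**2``:

    .. math::

        P_c = 1/(1+e^{-k}), \\quad
        MRT = \\tau + \\frac{\\alpha}{2\\nu}(2P_c-1), \\quad
        VRT = \\frac{\\alpha s^2}{\\nu^3}\\left(P_c - \\tfrac12
              - k P_c(1-P_c)\\right)

    continuous across ``nu = 0`` via the limits
    ``Pc=1/2, MRT=tau+alpha^2/(4 s^2), VRT=alpha^4/(24 s^4)``.

    Because the start point is unbiased, decision time is independent of the
    boundary hit, so these are also the marginal RT moments over both correct
    and error responses.
    """
    pc, mrt, vrt = _forward_moments_floats(
        params.nu, params.alpha, params.tau, params.s
    )
    return MomentTriple(pc=pc, mrt=mrt, vrt=vrt)


def _forward_moments_floats(nu, alpha, tau, s):
    k = alpha * nu / s**2
    if abs(k) < _K_SERIES_THRESHOLD:
        # Series around nu = 0 (relative truncation error O(k^4) < 1e-12).
        pc = 1.0 / (1.0 + np.exp(-k))
        mrt = tau + alpha**2 / (4 * s**2) - alpha**4 * nu**2 / (48 * s**6)
        vrt = alpha**4 / (24 * s**4) - alpha**6 * nu**2 / (160 * s**8)
        return pc, mrt, vrt
    pc = 1.0 / (1.0 + np.exp(-k))
    mrt = tau + (alpha / (2 * nu)) * (2 * pc - 1)
    vrt = (alpha * s**2 / nu**3) * (pc - 0.5 - k * pc * (1 - pc))
    return pc, float(mrt), float(vrt)


# ---------------------------------------------------------------------------
# Inverse (EZ) equations
# ---------------------------------------------------------------------------

def inverse_ez(
    pc: float,
    mrt: float,
    vrt: float,
    s: float = DEFAULT_S,
    n: int | None = None,
) -> DDMParams:
    """Closed-form EZ estimator mapping (Pc, MRT, VRT) back to DDM parameters.

    With ``L = logit(Pc)``:

    .. math::

        \\nu = \\mathrm{sign}(P_c - 1/2)\\, s
               \\left[\\frac{L (P_c^2 L - P_c L + P_c - 1/2)}{VRT}\\right]^{1/4},
        \\quad \\alpha = \\frac{s^2 L}{\\nu}, \\quad
        \\tau = MRT - \\frac{\\alpha}{2\\nu}(2 P_c - 1).

    Exact inverse of :func:`forward_moments` on its range.

    Parameters
    ----------
    n
        Optional trial count enabling the classical edge correction: an
        observed ``pc`` of 0, 1/2 or 1 is replaced by ``1/(2n)``,
        ``1/2 + 1/(4n)`` or ``1 - 1/(2n)``. Intended for starting values and
        diagnostics only; with ``n=None`` (default) these inputs raise.
    """
    if not (np.isfinite(pc) and np.isfinite(mrt) and np.isfinite(vrt)):
        raise ValueError("non-finite summary statistics")
    if n is not None:
        if pc <= 0.0:
            pc = 1.0 / (2 * n)
        elif pc >= 1.0:
            pc = 1.0 - 1.0 / (2 * n)
        elif pc == 0.5:
            pc = 0.5 + 1.0 / (4 * n)
    if not 0.0 < pc < 1.0:
        raise ValueError(f"accuracy rate must lie in (0,1), got {pc}")
    if pc == 0.5:
        raise ValueError(
            "pc = 1/2 makes drift undefined; pass a trial count n for the "
            "edge correction"
        )
    if vrt <= 0:
        raise ValueError(f"RT variance must be > 0, got {vrt}")

    L = np.log(pc / (1.0 - pc))
    x = L * (pc**2 * L - pc * L + pc - 0.5) / vrt
    nu = np.sign(pc - 0.5) * s * x**0.25
    alpha = s**2 * L / nu
    tau = mrt - (alpha / (2 * nu)) * (2 * pc - 1)
    return DDMParams(nu=float(nu), alpha=float(alpha), tau=float(tau), s=s)


# ---------------------------------------------------------------------------
# Wiener first-passage sampling
# ---------------------------------------------------------------------------
#
# Trials are drawn from the exact first-passage-time distribution via the
# classical small-time / large-time series for the density of an unbiased
# Wiener process between two absorbing boundaries, inverted numerically on a
# fine grid.  With the start point at alpha/2 the decision time is
# independent of which boundary is hit, so accuracy is a Bernoulli(Pc) draw
# and decision times come from the common marginal density
#
#   g(t) = (2 cosh(v a / 2) / a^2) * exp(-v^2 t / 2) * f1(t / a^2)
#
# (in s=1 units, v = nu/s, a = alpha/s), where f1 is the standard
# zero-drift density with relative start point w = 1/2.

_N_GRID = 8192          # inverse-CDF grid resolution
_U_SWITCH = 0.1         # small-time <-> large-time series switch (scaled time)
_TAIL_LOG_EPS = 26.0    # run the grid until survival mass < e^-26 ~ 5e-12


def _f1_half(u: np.ndarray) -> np.ndarray:
    """Zero-drift two-boundary FPT density at scaled time u, start w=1/2."""
    out = np.empty_like(u)
    small = u < _U_SWITCH
    us = u[small]
    if us.size:
        acc = np.zeros_like(us)
        for k in range(-5, 6):
            c = 0.5 + 2 * k
            acc += c * np.exp(-c * c / (2 * us))
        out[small] = acc / np.sqrt(2 * np.pi * us**3)
    ul = u[~small]
    if ul.size:
        acc = np.zeros_like(ul)
        for k in range(1, 13):
            acc += k * np.exp(-k * k * np.pi**2 * ul / 2) * np.sin(k * np.pi / 2)
        out[~small] = np.pi * acc
    return out


def _decision_time_grid(nu: float, alpha: float, s: float):
    """CDF grid (t, F(t)) of the marginal decision-time distribution."""
    v = nu / s
    a = alpha / s
    # slowest decay rate of the density tail
    lam = v**2 / 2 + np.pi**2 / (2 * a**2)
    t_max = _TAIL_LOG_EPS / lam
    t = np.linspace(0.0, t_max, _N_GRID)
    u = t[1:] / a**2
    dens = np.zeros_like(t)
    dens[1:] = (2 * np.cosh(v * a / 2) / a**2) * np.exp(-(v**2) * t[1:] / 2) * _f1_half(u)
    cdf = np.concatenate(([0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(t))))
    cdf /= cdf[-1]  # discard O(1e-11) truncated tail mass
    return t, cdf


def sample_trials(
    params: DDMParams, n: int, rng: np.random.Generator
) -> TrialSet:
    """Draw ``n`` i.i.d. trials from the Wiener first-passage distribution.

    Decision times are sampled by inverse-CDF lookup on the exact series
    density; accuracy is an independent Bernoulli(Pc) draw, valid because the
    unbiased start point makes decision time and boundary choice independent.
    ``rt = decision time + tau``.
    """
    if n < 1:
        raise ValueError("need at least one trial")
    t, cdf = _decision_time_grid(params.nu, params.alpha, params.s)
    dt = np.interp(rng.random(n), cdf, t)
    pc = _forward_moments_floats(params.nu, params.alpha, params.tau, params.s)[0]
    acc = (rng.random(n) < pc).astype(np.int64)
    return TrialSet(rt=params.tau + dt, accuracy=acc)
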