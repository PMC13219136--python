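"""Hierarchical two-condition Wiener datasets and the contamination procedure.

The generator implements a within-subject two-condition design on the drift
rate: participant ``p`` in condition ``k`` has predicted drift
``mu_nu + beta * X_k`` (``X_k`` the 0/1 condition indicator), with

    nu_{p,k} ~ N(mu_nu + beta * X_k, sigma2_nu)
    alpha_p  ~ N(mu_alpha, sigma2_alpha)
    tau_p    ~ N(mu_tau,   sigma2_tau)

Population-level locations are drawn uniformly per named preset; the
dispersion parameters are fixed study-wide at sigma2_nu = 0.75,
sigma2_alpha = 0.5, sigma2_tau = 0.1.

Contamination replaces a fixed fraction (default 5%) of each
participant-by-condition cell: half the contaminants are *delayed startups*
(the clean RT plus uniform 2-3 s noise, accuracy untouched) and half are
*guesses* (the trial redrawn with drift 0, giving chance accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm_core import DDMParams, sample_trials

__all__ = [
    "PopulationParams",
    "IndividualParams",
    "Dataset",
    "PRESETS",
    "SIGMA2_NU",
    "SIGMA2_ALPHA",
    "SIGMA2_TAU",
    "draw_population",
    "draw_individuals",
    "generate_dataset",
    "contaminate",
]

# Fixed population dispersions used across every study condition.
SIGMA2_NU = 0.75
SIGMA2_ALPHA = 0.5
SIGMA2_TAU = 0.1

# Uniform ranges for (mu_nu, mu_alpha) per preset; mu_tau ~ U(0.2, 0.4) in all.
PRESETS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "main": ((-3.0, 3.0), (2.0, 4.0)),
    "low-nu/low-alpha": ((0.0, 1.0), (2.0, 2.5)),
    "low-nu/high-alpha": ((0.0, 1.0), (3.5, 4.0)),
    "high-nu/low-alpha": ((2.0, 3.0), (2.0, 2.5)),
    "high-nu/high-alpha": ((2.0, 3.0), (3.5, 4.0)),
}

MU_TAU_RANGE = (0.2, 0.4)

#: Individual non-decision times are resampled until they clear this floor
#: (seconds); alpha_p is resampled until positive. The stated normals put
#: non-negligible mass below zero, which the diffusion process cannot use.
TAU_FLOOR = 0.05

CONTAMINANT_TYPES = ("none", "delayed", "guess")


@dataclass(frozen=True)
class PopulationParams:
    """Population-level (hyper)parameters of the drift meta-regression."""

    mu_nu: float
    beta: float
    sigma2_nu: float
    mu_alpha: float
    sigma2_alpha: float
    mu_tau: float
    sigma2_tau: float

    def __post_init__(self) -> None:
        if min(self.sigma2_nu, self.sigma2_alpha, self.sigma2_tau) <= 0:
            raise ValueError("population variances must be > 0")
        if self.mu_alpha <= 0 or self.mu_tau <= 0:
            raise ValueError("mu_alpha and mu_tau must be > 0")


@dataclass
class IndividualParams:
    """Person-level diffusion parameters: nu is P x 2, alpha and tau length P."""

    nu: np.ndarray
    alpha: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.nu = np.atleast_2d(np.asarray(self.nu, dtype=float))
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        P = self.alpha.size
        if self.nu.shape != (P, 2) or self.tau.size != P:
            raise ValueError("shape mismatch: nu must be P x 2, alpha/tau length P")
        if np.any(self.alpha <= 0):
            raise ValueError("all alpha_p must be > 0")
        if np.any(self.tau < TAU_FLOOR):
            raise ValueError(f"all tau_p must be >= {TAU_FLOOR}")

    @property
    def n_participants(self) -> int:
        return self.alpha.size


class Dataset:
    """Trial-level records: participant, condition, rt, accuracy, contaminant.

    Thin wrapper around a :class:`pandas.DataFrame` enforcing the record
    schema and the balanced per-cell trial count.
    """

    COLUMNS = ("participant", "condition", "rt", "accuracy", "contaminant")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing dataset columns: {sorted(missing)}")
        if not set(df["contaminant"].unique()) <= set(CONTAMINANT_TYPES):
            raise ValueError("unknown contaminant tag")
        counts = df.groupby(["participant", "condition"]).size()
        if counts.nunique() != 1:
            raise ValueError("all participant-condition cells must have equal size")
        self.df = df.reset_index(drop=True)

    @property
    def trials_per_cell(self) -> int:
        return int(self.df.groupby(["participant", "condition"]).size().iloc[0])

    @property
    def n_participants(self) -> int:
        return self.df["participant"].nunique()

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path_or_buf) -> None:
        self.df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "Dataset":
        return cls(pd.read_csv(path_or_buf))


def draw_population(
    preset: str, beta: float, rng: np.random.Generator
) -> PopulationParams:
    """Draw one set of population parameters from a named preset.

    ``main`` uses mu_nu ~ U(-3,3), mu_alpha ~ U(2,4); the four follow-up
    presets cross low/high drift intercept (U(0,1) vs U(2,3)) with low/high
    boundary (U(2,2.5) vs U(3.5,4)). mu_tau ~ U(0.2,0.4) throughout;
    variances are the fixed study values.
    """
    try:
        nu_range, alpha_range = PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}"
        ) from None
    return PopulationParams(
        mu_nu=rng.uniform(*nu_range),
        beta=float(beta),
        sigma2_nu=SIGMA2_NU,
        mu_alpha=rng.uniform(*alpha_range),
        sigma2_alpha=SIGMA2_ALPHA,
        mu_tau=rng.uniform(*MU_TAU_RANGE),
        sigma2_tau=SIGMA2_TAU,
    )


def _truncated_normal(
    mu: float, sd: float, low: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Resample normal draws until all exceed ``low`` (keeps the bulk intact)."""
    out = rng.normal(mu, sd, size)
    bad = out < low
    while np.any(bad):
        out[bad] = rng.normal(mu, sd, int(bad.sum()))
        bad = out < low
    return out


def draw_individuals(
    pop: PopulationParams, P: int, rng: np.random.Generator
) -> IndividualParams:
    """Sample P participants' diffusion parameters from the hierarchy.

    Drift rates follow the meta-regression exactly; alpha_p and tau_p are
    drawn from the stated normals but resampled until alpha_p > 0 and
    tau_p >= TAU_FLOOR, since the first-passage process is undefined
    otherwise.
    """
    if P < 1:
        raise ValueError("need at least one participant")
    pred = np.array([pop.mu_nu, pop.mu_nu + pop.beta])
    nu = rng.normal(pred, np.sqrt(pop.sigma2_nu), size=(P, 2))
    alpha = _truncated_normal(pop.mu_alpha, np.sqrt(pop.sigma2_alpha), 1e-6, P, rng)
    tau = _truncated_normal(pop.mu_tau, np.sqrt(pop.sigma2_tau), TAU_FLOOR, P, rng)
    return IndividualParams(nu=nu, alpha=alpha, tau=tau)


def generate_dataset(
    ind: IndividualParams, T: int, rng: np.random.Generator, s: float = 1.0
) -> Dataset:
    """Generate T clean Wiener trials per participant per condition."""
    if T < 1:
        raise ValueError("need at least one trial per condition")
    frames = []
    for p in range(ind.n_participants):
        for k in (0, 1):
            params = DDMParams(ind.nu[p, k], ind.alpha[p], ind.tau[p], s)
            trials = sample_trials(params, T, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "participant": p,
                        "condition": k,
                        "rt": trials.rt,
                        "accuracy": trials.accuracy,
                        "contaminant": "none",
                    }
                )
            )
    return Dataset(pd.concat(frames, ignore_index=True))


def contaminate(
    data: Dataset,
    ind: IndividualParams,
    rng: np.random.Generator,
    rate: float = 0.05,
    s: float = 1.0,
) -> Dataset:
    """Replace ``round(rate * T)`` trials per participant-condition cell.

    Each selected trial independently becomes, with probability 1/2, a
    *delayed startup* — its RT increased by U(2,3) seconds, accuracy kept —
    or else a *guess* — rt and accuracy redrawn from a zero-drift process
    with the participant's own alpha_p and tau_p. All unselected trials are
    returned bit-identical.
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError(f"contamination rate must be in [0, 0.5], got {rate}")
    if (data.df["contaminant"] != "none").any():
        raise ValueError("dataset already contaminated")
    df = data.df.copy()
    T = data.trials_per_cell
    n_contam = int(round(rate * T))
    if n_contam == 0:
        return Dataset(df)
    contaminant = df["contaminant"].to_numpy(dtype=object)
    rt = df["rt"].to_numpy().copy()
    acc = df["accuracy"].to_numpy().copy()
    for (p, k), idx in df.groupby(["participant", "condition"]).indices.items():
        chosen = rng.choice(idx, size=n_contam, replace=False)
        delayed = rng.random(n_contam) < 0.5
        d_idx, g_idx = chosen[delayed], chosen[~delayed]
        rt[d_idx] += rng.uniform(2.0, 3.0, d_idx.size)
        contaminant[d_idx] = "delayed"
        if g_idx.size:
            guess = sample_trials(
                DDMParams(0.0, ind.alpha[p], ind.tau[p], s), g_idx.size, rng
            )
            rt[g_idx] = guess.rt
            acc[g_idx] = guess.accuracy
            contaminant[g_idx] = "guess"
    df["rt"] = rt
    df["accuracy"] = acc
    df["contaminant"] = contaminant
    return Dataset(df)
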