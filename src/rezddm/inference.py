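"""Hierarchical Bayesian EZ-DDM: proxy likelihood and MCMC posterior sampling.

Instead of a trial-level Wiener likelihood, each participant-condition cell
enters through the approximate sampling distributions of its three summary
statistics. With predicted moments ``(Pc, MRT, VRT)`` from the cell's
diffusion parameters:

    n_correct ~ Binomial(n_total, Pc)
    loc       ~ Normal(MRT, VRT / n)
    scale     ~ Normal(VRT, 2 VRT^2 / (n - 1))

The robust variant plugs the median / IQR-variance summaries into the same
structure unchanged. Individual parameters follow the drift meta-regression
hierarchy (``nu_{p,k} ~ N(mu_nu + beta X_k, sigma_nu^2)``, normal
population distributions for ``alpha_p`` and ``tau_p``), with weakly
informative hyperpriors.

Sampling is by an adaptive Metropolis-within-Gibbs scheme: a conjugate joint
Gibbs update for ``(mu_nu, beta)``, conjugate (rejection-truncated) Gibbs
updates for ``mu_alpha`` and ``mu_tau``, and adaptive random-walk Metropolis
on the log population scales and every individual parameter. The whole chain
runs inside a numba-compiled kernel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .ddm_core import inverse_ez
from .summaries import SummaryCell

__all__ = [
    "ModelSpec",
    "Model",
    "PosteriorSamples",
    "FitResult",
    "HYPER_NAMES",
    "build_model",
    "fit",
    "decision_statistic",
]

HYPER_NAMES = ("mu_nu", "beta", "sigma_nu", "mu_alpha", "sigma_alpha", "mu_tau", "sigma_tau")

_RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class ModelSpec:
    """Priors and tags of one hierarchical EZ-DDM fit.

    Location-scale hyperpriors are normal (``mu_alpha`` and ``mu_tau``
    truncated to positive support); population scales get half-normal
    priors. Defaults are weakly informative over the plausible ranges of
    two-choice RT experiments (drift intercepts within a few units of zero,
    boundaries around 2-4, non-decision times a few hundred ms).
    """

    mu_nu_prior: tuple[float, float] = (0.0, 2.0)
    beta_prior: tuple[float, float] = (0.0, 1.0)
    mu_alpha_prior: tuple[float, float] = (3.0, 1.0)   # truncated > 0
    mu_tau_prior: tuple[float, float] = (0.3, 0.25)    # truncated > 0
    sigma_nu_scale: float = 1.0
    sigma_alpha_scale: float = 1.0
    sigma_tau_scale: float = 1.0
    s: float = 1.0
    rt_scope: str = "correct_only"
    method: str = "standard"

    def __post_init__(self) -> None:
        if self.beta_prior[1] <= 0:
            raise ValueError("beta prior scale must be > 0 (Savage-Dickey needs a proper prior)")

    def beta_prior_pdf_at(self, value: float) -> float:
        m, sd = self.beta_prior
        return math.exp(-0.5 * ((value - m) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _moments_nb(nu, alpha, tau, s):
    k = alpha * nu / s**2
    pc = 1.0 / (1.0 + math.exp(-k))
    if abs(k) < 1e-3:
        mrt = tau + alpha**2 / (4 * s**2) - alpha**4 * nu**2 / (48 * s**6)
        vrt = alpha**4 / (24 * s**4) - alpha**6 * nu**2 / (160 * s**8)
    else:
        mrt = tau + (alpha / (2 * nu)) * (2 * pc - 1)
        vrt = (alpha * s**2 / nu**3) * (pc - 0.5 - k * pc * (1 - pc))
    return pc, mrt, vrt


@njit(cache=True)
def _cell_ll(nu, alpha, tau, s, nc, ntot, nrt, loc, scale):
    """Proxy log-likelihood of one cell, dropping data-only constants."""
    if alpha <= 0.0 or tau < 0.0:
        return -np.inf
    pc, mrt, vrt = _moments_nb(nu, alpha, tau, s)
    if not (vrt > 0.0 and math.isfinite(vrt) and math.isfinite(mrt)):
        return -np.inf
    p = min(max(pc, 1e-15), 1.0 - 1e-15)
    ll = nc * math.log(p) + (ntot - nc) * math.log(1.0 - p)
    v = vrt / nrt
    ll += -0.5 * math.log(2 * math.pi * v) - 0.5 * (loc - mrt) ** 2 / v
    v = 2.0 * vrt * vrt / (nrt - 1.0)
    ll += -0.5 * math.log(2 * math.pi * v) - 0.5 * (scale - vrt) ** 2 / v
    return ll


@njit(cache=True)
def _run_chain(seed, n_warmup, n_draws, thin,
               nc, ntot, nrt, loc, scale, s,
               prior, init_hyp, init_nu, init_alpha, init_tau):
    """One MCMC chain. Returns (hyper draws, individual draws, accept rates).

    prior = [m_munu, s_munu, m_beta, s_beta, m_mualpha, s_mualpha,
             m_mutau, s_mutau, sc_signu, sc_sigalpha, sc_sigtau]
    """
    np.random.seed(seed)
    P = nc.shape[0]

    mu_nu, beta = init_hyp[0], init_hyp[1]
    sig_nu, mu_alpha = init_hyp[2], init_hyp[3]
    sig_alpha, mu_tau, sig_tau = init_hyp[4], init_hyp[5], init_hyp[6]
    nu = init_nu.copy()
    alpha = init_alpha.copy()
    tau = init_tau.copy()

    cll = np.empty((P, 2))
    for p in range(P):
        for k in range(2):
            cll[p, k] = _cell_ll(nu[p, k], alpha[p], tau[p], s,
                                 nc[p, k], ntot[p, k], nrt[p, k],
                                 loc[p, k], scale[p, k])

    # adaptive RW step sizes: [log sig_nu, log sig_alpha, log sig_tau,
    #                          nu_p0 x P, nu_p1 x P, alpha_p x P, tau_p x P]
    n_rw = 3 + 4 * P
    lstep = np.full(n_rw, math.log(0.2))
    lstep[3 + 3 * P:] = math.log(0.05)  # tau moves on a smaller scale
    n_prop = np.zeros(n_rw)
    n_acc = np.zeros(n_rw)

    # per-participant joint adaptive-Metropolis state: the posterior of
    # (nu_p0, nu_p1, alpha_p, tau_p) lies on a narrow ridge when accuracy is
    # near ceiling, which defeats component-wise moves; a full-covariance
    # proposal learned during warmup walks the ridge directly.
    am_start = max(n_warmup // 3, 100)
    am_mean = np.zeros((P, 4))
    am_cov = np.zeros((P, 4, 4))
    am_count = 0
    am_lscale = np.full(P, math.log(0.6))  # times chol(cov): ~2.38/sqrt(4)
    am_prop = np.zeros(P)
    am_acc = np.zeros(P)
    chol = np.zeros((4, 4))
    vec = np.zeros(4)
    prop_vec = np.zeros(4)

    # interweaved non-centered (mu, sigma) group moves for alpha and tau
    nc_lscale = np.full(2, math.log(0.05))
    nc_prop = np.zeros(2)
    nc_acc = np.zeros(2)
    nc_new_ll = np.zeros((P, 2))
    nc_new_x = np.zeros(P)

    # compensated spread-scaling move state (see below)
    cs_lscale = math.log(0.1)
    cs_prop = 0.0
    cs_acc = 0.0
    cs_nu = np.zeros((P, 2))
    cs_alpha = np.zeros(P)
    cs_tau = np.zeros(P)
    cs_ll = np.zeros((P, 2))

    # whole-hierarchy scaling move state (see below)
    ws_lscale = math.log(0.05)
    ws_prop = 0.0
    ws_acc = 0.0

    hyp_out = np.empty((n_draws, 7))
    ind_out = np.empty((n_draws, 4 * P))

    total_iter = n_warmup + n_draws * thin
    stored = 0
    for it in range(total_iter):
        adapting = it < n_warmup
        adapt_rate = min(0.25, 2.0 / math.sqrt(it + 10.0))

        # --- (mu_nu, beta): conjugate joint Gibbs -----------------------
        tv = 1.0 / (sig_nu * sig_nu)
        a11 = 2.0 * P * tv + 1.0 / prior[1] ** 2
        a12 = P * tv
        a22 = P * tv + 1.0 / prior[3] ** 2
        sum_all = 0.0
        sum_k1 = 0.0
        for p in range(P):
            sum_all += nu[p, 0] + nu[p, 1]
            sum_k1 += nu[p, 1]
        b1 = sum_all * tv + prior[0] / prior[1] ** 2
        b2 = sum_k1 * tv + prior[2] / prior[3] ** 2
        det = a11 * a22 - a12 * a12
        c11 = a22 / det
        c12 = -a12 / det
        c22 = a11 / det
        m1 = c11 * b1 + c12 * b2
        m2 = c12 * b1 + c22 * b2
        l11 = math.sqrt(c11)
        l21 = c12 / l11
        l22 = math.sqrt(max(c22 - l21 * l21, 1e-300))
        z1 = np.random.normal()
        z2 = np.random.normal()
        mu_nu = m1 + l11 * z1
        beta = m2 + l21 * z1 + l22 * z2

        # --- mu_alpha, mu_tau: conjugate Gibbs, rejection-truncated > 0 -
        for which in range(2):
            if which == 0:
                x, sg, pm, psd = alpha, sig_alpha, prior[4], prior[5]
            else:
                x, sg, pm, psd = tau, sig_tau, prior[6], prior[7]
            prec = P / sg**2 + 1.0 / psd**2
            mean = (x.sum() / sg**2 + pm / psd**2) / prec
            sd = 1.0 / math.sqrt(prec)
            val = mean + sd * np.random.normal()
            tries = 0
            while val <= 0.0 and tries < 100:
                val = mean + sd * np.random.normal()
                tries += 1
            if val > 0.0:
                if which == 0:
                    mu_alpha = val
                else:
                    mu_tau = val

        # --- population scales: RW-MH on log sigma ----------------------
        for j in range(3):
            if j == 0:
                sg, sc = sig_nu, prior[8]
                sse = 0.0
                for p in range(P):
                    d0 = nu[p, 0] - mu_nu
                    d1 = nu[p, 1] - mu_nu - beta
                    sse += d0 * d0 + d1 * d1
                nterms = 2.0 * P
            elif j == 1:
                sg, sc = sig_alpha, prior[9]
                sse = 0.0
                for p in range(P):
                    d = alpha[p] - mu_alpha
                    sse += d * d
                nterms = 1.0 * P
            else:
                sg, sc = sig_tau, prior[10]
                sse = 0.0
                for p in range(P):
                    d = tau[p] - mu_tau
                    sse += d * d
                nterms = 1.0 * P
            lo = math.log(sg)
            ln = lo + math.exp(lstep[j]) * np.random.normal()
            sn = math.exp(ln)
            # log target in log-sigma space (Jacobian +log sigma)
            cur = -nterms * lo - sse / (2 * sg * sg) - 0.5 * sg * sg / sc**2 + lo
            new = -nterms * ln - sse / (2 * sn * sn) - 0.5 * sn * sn / sc**2 + ln
            n_prop[j] += 1
            if math.log(np.random.random() + 1e-300) < new - cur:
                n_acc[j] += 1
                if j == 0:
                    sig_nu = sn
                elif j == 1:
                    sig_alpha = sn
                else:
                    sig_tau = sn
        # (step-size adaptation for these applied at the bottom of the loop)

        # --- individual parameters: component-wise RW-MH ----------------
        for p in range(P):
            for k in range(2):
                j = 3 + k * P + p
                prop = nu[p, k] + math.exp(lstep[j]) * np.random.normal()
                mean_k = mu_nu + beta * k
                cur = cll[p, k] - 0.5 * (nu[p, k] - mean_k) ** 2 / sig_nu**2
                ll_new = _cell_ll(prop, alpha[p], tau[p], s,
                                  nc[p, k], ntot[p, k], nrt[p, k],
                                  loc[p, k], scale[p, k])
                new = ll_new - 0.5 * (prop - mean_k) ** 2 / sig_nu**2
                n_prop[j] += 1
                if math.log(np.random.random() + 1e-300) < new - cur:
                    n_acc[j] += 1
                    nu[p, k] = prop
                    cll[p, k] = ll_new
                if adapting:
                    lstep[j] += adapt_rate * ((n_acc[j] / n_prop[j]) - 0.44) * 0.5
            # alpha_p
            j = 3 + 2 * P + p
            prop = alpha[p] + math.exp(lstep[j]) * np.random.normal()
            if prop > 0.0:
                cur = cll[p, 0] + cll[p, 1] - 0.5 * (alpha[p] - mu_alpha) ** 2 / sig_alpha**2
                ll0 = _cell_ll(nu[p, 0], prop, tau[p], s, nc[p, 0], ntot[p, 0],
                               nrt[p, 0], loc[p, 0], scale[p, 0])
                ll1 = _cell_ll(nu[p, 1], prop, tau[p], s, nc[p, 1], ntot[p, 1],
                               nrt[p, 1], loc[p, 1], scale[p, 1])
                new = ll0 + ll1 - 0.5 * (prop - mu_alpha) ** 2 / sig_alpha**2
                n_prop[j] += 1
                if math.log(np.random.random() + 1e-300) < new - cur:
                    n_acc[j] += 1
                    alpha[p] = prop
                    cll[p, 0] = ll0
                    cll[p, 1] = ll1
            else:
                n_prop[j] += 1
            if adapting and n_prop[j] > 0:
                lstep[j] += adapt_rate * ((n_acc[j] / n_prop[j]) - 0.44) * 0.5
            # tau_p
            j = 3 + 3 * P + p
            prop = tau[p] + math.exp(lstep[j]) * np.random.normal()
            if prop >= 0.0:
                cur = cll[p, 0] + cll[p, 1] - 0.5 * (tau[p] - mu_tau) ** 2 / sig_tau**2
                ll0 = _cell_ll(nu[p, 0], alpha[p], prop, s, nc[p, 0], ntot[p, 0],
                               nrt[p, 0], loc[p, 0], scale[p, 0])
                ll1 = _cell_ll(nu[p, 1], alpha[p], prop, s, nc[p, 1], ntot[p, 1],
                               nrt[p, 1], loc[p, 1], scale[p, 1])
                new = ll0 + ll1 - 0.5 * (prop - mu_tau) ** 2 / sig_tau**2
                n_prop[j] += 1
                if math.log(np.random.random() + 1e-300) < new - cur:
                    n_acc[j] += 1
                    tau[p] = prop
                    cll[p, 0] = ll0
                    cll[p, 1] = ll1
            else:
                n_prop[j] += 1
            if adapting and n_prop[j] > 0:
                lstep[j] += adapt_rate * ((n_acc[j] / n_prop[j]) - 0.44) * 0.5

            # joint full-covariance move along the (nu, alpha, tau) ridge
            if am_count > 100:
                sc = math.exp(am_lscale[p])
                ok = True
                for a_ in range(4):
                    for b_ in range(4):
                        chol[a_, b_] = am_cov[p, a_, b_] / (am_count - 1)
                    chol[a_, a_] += 1e-10 + 1e-6 * chol[a_, a_]
                # in-place Cholesky of the 4x4 proposal covariance
                for a_ in range(4):
                    for b_ in range(a_ + 1):
                        acc_ = chol[a_, b_]
                        for c_ in range(b_):
                            acc_ -= chol[a_, c_] * chol[b_, c_]
                        if a_ == b_:
                            if acc_ <= 0.0:
                                ok = False
                                break
                            chol[a_, a_] = math.sqrt(acc_)
                        else:
                            chol[a_, b_] = acc_ / chol[b_, b_]
                    if not ok:
                        break
                if ok:
                    for a_ in range(4):
                        vec[a_] = np.random.normal()
                    for a_ in range(4):
                        step_ = 0.0
                        for b_ in range(a_ + 1):
                            step_ += chol[a_, b_] * vec[b_]
                        prop_vec[a_] = step_ * sc
                    pn0 = nu[p, 0] + prop_vec[0]
                    pn1 = nu[p, 1] + prop_vec[1]
                    pa = alpha[p] + prop_vec[2]
                    pt = tau[p] + prop_vec[3]
                    am_prop[p] += 1
                    if pa > 0.0 and pt >= 0.0:
                        cur = (cll[p, 0] + cll[p, 1]
                               - 0.5 * (nu[p, 0] - mu_nu) ** 2 / sig_nu**2
                               - 0.5 * (nu[p, 1] - mu_nu - beta) ** 2 / sig_nu**2
                               - 0.5 * (alpha[p] - mu_alpha) ** 2 / sig_alpha**2
                               - 0.5 * (tau[p] - mu_tau) ** 2 / sig_tau**2)
                        ll0 = _cell_ll(pn0, pa, pt, s, nc[p, 0], ntot[p, 0],
                                       nrt[p, 0], loc[p, 0], scale[p, 0])
                        ll1 = _cell_ll(pn1, pa, pt, s, nc[p, 1], ntot[p, 1],
                                       nrt[p, 1], loc[p, 1], scale[p, 1])
                        new = (ll0 + ll1
                               - 0.5 * (pn0 - mu_nu) ** 2 / sig_nu**2
                               - 0.5 * (pn1 - mu_nu - beta) ** 2 / sig_nu**2
                               - 0.5 * (pa - mu_alpha) ** 2 / sig_alpha**2
                               - 0.5 * (pt - mu_tau) ** 2 / sig_tau**2)
                        if math.log(np.random.random() + 1e-300) < new - cur:
                            am_acc[p] += 1
                            nu[p, 0] = pn0
                            nu[p, 1] = pn1
                            alpha[p] = pa
                            tau[p] = pt
                            cll[p, 0] = ll0
                            cll[p, 1] = ll1
                    if adapting and am_prop[p] > 0:
                        am_lscale[p] += adapt_rate * ((am_acc[p] / am_prop[p]) - 0.23)

        # accumulate per-participant Welford mean/covariance for the joint
        # proposals (reset once past the initialization transient; frozen
        # after warmup so the post-warmup kernel is Markovian)
        if it == am_start:
            am_count = 1
            for p in range(P):
                am_mean[p, 0] = nu[p, 0]
                am_mean[p, 1] = nu[p, 1]
                am_mean[p, 2] = alpha[p]
                am_mean[p, 3] = tau[p]
                for a_ in range(4):
                    for b_ in range(4):
                        am_cov[p, a_, b_] = 0.0
        elif am_start < it < n_warmup:
            am_count += 1
            for p in range(P):
                vec[0] = nu[p, 0]
                vec[1] = nu[p, 1]
                vec[2] = alpha[p]
                vec[3] = tau[p]
                for a_ in range(4):
                    d_ = vec[a_] - am_mean[p, a_]
                    am_mean[p, a_] += d_ / am_count
                    for b_ in range(a_ + 1):
                        e_ = vec[b_] - am_mean[p, b_]
                        am_cov[p, a_, b_] += d_ * e_
                        if a_ != b_:
                            am_cov[p, b_, a_] = am_cov[p, a_, b_]

        # --- interweaved non-centered moves on (mu, sigma) of the alpha and
        # tau hierarchies: with z_p = (x_p - mu)/sigma held fixed, a joint
        # (mu, log sigma) proposal rescales every individual at once, which
        # breaks the funnel coupling between the population scale and weakly
        # identified individuals. The hierarchy term cancels exactly in this
        # parameterization; only cell likelihoods, hyperpriors and the log
        # Jacobian remain.
        for g in range(2):
            if g == 0:
                mu_g, sig_g, pm, psd, sc_g = mu_alpha, sig_alpha, prior[4], prior[5], prior[9]
            else:
                mu_g, sig_g, pm, psd, sc_g = mu_tau, sig_tau, prior[6], prior[7], prior[10]
            step_sc = math.exp(nc_lscale[g])
            mu_new = mu_g + step_sc * np.random.normal()
            lsig_new = math.log(sig_g) + step_sc * np.random.normal()
            sig_new = math.exp(lsig_new)
            nc_prop[g] += 1
            if mu_new > 0.0:
                ratio = (
                    -0.5 * ((mu_new - pm) ** 2 - (mu_g - pm) ** 2) / psd**2
                    - 0.5 * (sig_new**2 - sig_g**2) / sc_g**2
                    + (lsig_new - math.log(sig_g))  # Jacobian of log-sigma move
                )
                ok = True
                for p in range(P):
                    x_old = alpha[p] if g == 0 else tau[p]
                    x_new = mu_new + sig_new * (x_old - mu_g) / sig_g
                    if (g == 0 and x_new <= 0.0) or (g == 1 and x_new < 0.0):
                        ok = False
                        break
                    if g == 0:
                        ll0 = _cell_ll(nu[p, 0], x_new, tau[p], s, nc[p, 0], ntot[p, 0],
                                       nrt[p, 0], loc[p, 0], scale[p, 0])
                        ll1 = _cell_ll(nu[p, 1], x_new, tau[p], s, nc[p, 1], ntot[p, 1],
                                       nrt[p, 1], loc[p, 1], scale[p, 1])
                    else:
                        ll0 = _cell_ll(nu[p, 0], alpha[p], x_new, s, nc[p, 0], ntot[p, 0],
                                       nrt[p, 0], loc[p, 0], scale[p, 0])
                        ll1 = _cell_ll(nu[p, 1], alpha[p], x_new, s, nc[p, 1], ntot[p, 1],
                                       nrt[p, 1], loc[p, 1], scale[p, 1])
                    nc_new_ll[p, 0] = ll0
                    nc_new_ll[p, 1] = ll1
                    nc_new_x[p] = x_new
                    ratio += ll0 + ll1 - cll[p, 0] - cll[p, 1]
                if ok and math.log(np.random.random() + 1e-300) < ratio:
                    nc_acc[g] += 1
                    for p in range(P):
                        if g == 0:
                            alpha[p] = nc_new_x[p]
                        else:
                            tau[p] = nc_new_x[p]
                        cll[p, 0] = nc_new_ll[p, 0]
                        cll[p, 1] = nc_new_ll[p, 1]
                    if g == 0:
                        mu_alpha, sig_alpha = mu_new, sig_new
                    else:
                        mu_tau, sig_tau = mu_new, sig_new
            if adapting and nc_prop[g] > 0:
                nc_lscale[g] += adapt_rate * ((nc_acc[g] / nc_prop[g]) - 0.23)

        # --- compensated spread scaling of the boundary hierarchy --------
        # The slowest posterior direction is the collective spread of the
        # alpha_p around mu_alpha (it carries sigma_alpha with it). Propose
        # alpha_p' = mu_alpha + c (alpha_p - mu_alpha) and sigma_alpha' =
        # c sigma_alpha jointly, compensating each cell's drift to preserve
        # its predicted accuracy (nu' = nu alpha/alpha' keeps k = alpha nu)
        # and each tau_p to preserve the participant's mean predicted RT, so
        # the likelihood change stays small along the move. Deterministic
        # expansion with symmetric log-normal c; the Jacobian is
        # (P+1) log c + 2 sum_p log(alpha_p / alpha_p').
        dc = math.exp(cs_lscale) * np.random.normal()
        c = math.exp(dc)
        cs_prop += 1
        ok = True
        ratio = 0.0
        for p in range(P):
            a_old = alpha[p]
            a_new = mu_alpha + c * (a_old - mu_alpha)
            if a_new <= 0.0:
                ok = False
                break
            dtau = 0.0
            for k in range(2):
                kk = a_old * nu[p, k] / s**2
                pc_ = 1.0 / (1.0 + math.exp(-kk))
                # (2 pc - 1)/k -> 1/2 as k -> 0
                rt_ = (2 * pc_ - 1) / kk if abs(kk) > 1e-4 else 0.5
                cs_nu[p, k] = kk * s**2 / a_new
                dtau += 0.5 * rt_ * (a_new**2 - a_old**2) / (2 * s**2)
            t_new = tau[p] - dtau
            if t_new < 0.0:
                ok = False
                break
            cs_alpha[p] = a_new
            cs_tau[p] = t_new
            for k in range(2):
                ll = _cell_ll(cs_nu[p, k], a_new, t_new, s, nc[p, k], ntot[p, k],
                              nrt[p, k], loc[p, k], scale[p, k])
                mean_k = mu_nu + beta * k
                ratio += (ll - cll[p, k]
                          - 0.5 * ((cs_nu[p, k] - mean_k) ** 2
                                   - (nu[p, k] - mean_k) ** 2) / sig_nu**2)
                cs_ll[p, k] = ll
            ratio += -0.5 * ((t_new - mu_tau) ** 2 - (tau[p] - mu_tau) ** 2) / sig_tau**2
            ratio += 2.0 * math.log(a_old / a_new)  # Jacobian (per-participant part)
        if ok:
            sa_new = c * sig_alpha
            # alpha-hierarchy residuals are scale-invariant: only -P log c remains
            ratio += -P * math.log(c)
            # half-normal prior on sigma_alpha (kernel) and its log-move Jacobian
            ratio += -0.5 * (sa_new**2 - sig_alpha**2) / prior[9] ** 2
            ratio += (P + 1) * math.log(c)
            if math.log(np.random.random() + 1e-300) < ratio:
                cs_acc += 1
                sig_alpha = sa_new
                for p in range(P):
                    alpha[p] = cs_alpha[p]
                    tau[p] = cs_tau[p]
                    nu[p, 0] = cs_nu[p, 0]
                    nu[p, 1] = cs_nu[p, 1]
                    cll[p, 0] = cs_ll[p, 0]
                    cll[p, 1] = cs_ll[p, 1]
        if adapting and cs_prop > 0:
            cs_lscale += adapt_rate * ((cs_acc / cs_prop) - 0.23)

        # --- whole-hierarchy scaling of the boundary block ---------------
        # Complementary collective move: scale mu_alpha, sigma_alpha and
        # every alpha_p by a common factor c, with nu' = nu c^(1/3)
        # (preserving each cell's predicted RT variance in the
        # accuracy-saturated regime) and tau_p compensating the mean
        # predicted RT. Walks the soft direction that ceiling-accuracy
        # cells leave open. Jacobian: (P + 2 + 2P/3) log c.
        dc = math.exp(ws_lscale) * np.random.normal()
        c = math.exp(dc)
        ws_prop += 1
        ok = True
        ratio = 0.0
        c3 = c ** (1.0 / 3.0)
        for p in range(P):
            a_old = alpha[p]
            a_new = c * a_old
            dmrt = 0.0
            for k in range(2):
                nv = nu[p, k] * c3
                cs_nu[p, k] = nv
                kk_o = a_old * nu[p, k] / s**2
                kk_n = a_new * nv / s**2
                pco = 1.0 / (1.0 + math.exp(-kk_o))
                pcn = 1.0 / (1.0 + math.exp(-kk_n))
                mo_ = (2 * pco - 1) * a_old / (2 * nu[p, k]) if abs(kk_o) > 1e-4 else a_old**2 / (4 * s**2)
                mn_ = (2 * pcn - 1) * a_new / (2 * nv) if abs(kk_n) > 1e-4 else a_new**2 / (4 * s**2)
                dmrt += 0.5 * (mn_ - mo_)
            t_new = tau[p] - dmrt
            if t_new < 0.0:
                ok = False
                break
            cs_alpha[p] = a_new
            cs_tau[p] = t_new
            for k in range(2):
                ll = _cell_ll(cs_nu[p, k], a_new, t_new, s, nc[p, k], ntot[p, k],
                              nrt[p, k], loc[p, k], scale[p, k])
                mean_k = mu_nu + beta * k
                ratio += (ll - cll[p, k]
                          - 0.5 * ((cs_nu[p, k] - mean_k) ** 2
                                   - (nu[p, k] - mean_k) ** 2) / sig_nu**2)
                cs_ll[p, k] = ll
            ratio += -0.5 * ((t_new - mu_tau) ** 2 - (tau[p] - mu_tau) ** 2) / sig_tau**2
        if ok:
            ma_new = c * mu_alpha
            sa_new = c * sig_alpha
            # hierarchy z-scores preserved: -P log c; priors; Jacobian
            ratio += -P * math.log(c)
            ratio += -0.5 * ((ma_new - prior[4]) ** 2 - (mu_alpha - prior[4]) ** 2) / prior[5] ** 2
            ratio += -0.5 * (sa_new**2 - sig_alpha**2) / prior[9] ** 2
            ratio += (P + 2 + 2.0 * P / 3.0) * math.log(c)
            if math.log(np.random.random() + 1e-300) < ratio:
                ws_acc += 1
                mu_alpha, sig_alpha = ma_new, sa_new
                for p in range(P):
                    alpha[p] = cs_alpha[p]
                    tau[p] = cs_tau[p]
                    nu[p, 0] = cs_nu[p, 0]
                    nu[p, 1] = cs_nu[p, 1]
                    cll[p, 0] = cs_ll[p, 0]
                    cll[p, 1] = cs_ll[p, 1]
        if adapting and ws_prop > 0:
            ws_lscale += adapt_rate * ((ws_acc / ws_prop) - 0.23)

        # adapt the three log-sigma steps on running acceptance
        if adapting:
            for j in range(3):
                if n_prop[j] > 0:
                    lstep[j] += adapt_rate * ((n_acc[j] / n_prop[j]) - 0.44) * 0.5

        if not adapting and (it - n_warmup + 1) % thin == 0:
            hyp_out[stored, 0] = mu_nu
            hyp_out[stored, 1] = beta
            hyp_out[stored, 2] = sig_nu
            hyp_out[stored, 3] = mu_alpha
            hyp_out[stored, 4] = sig_alpha
            hyp_out[stored, 5] = mu_tau
            hyp_out[stored, 6] = sig_tau
            for p in range(P):
                ind_out[stored, p] = nu[p, 0]
                ind_out[stored, P + p] = nu[p, 1]
                ind_out[stored, 2 * P + p] = alpha[p]
                ind_out[stored, 3 * P + p] = tau[p]
            stored += 1

    acc_rate = np.where(n_prop > 0, n_acc / np.maximum(n_prop, 1), 0.0)
    return hyp_out, ind_out, acc_rate


# ---------------------------------------------------------------------------
# Model construction and log-density
# ---------------------------------------------------------------------------

class Model:
    """Joint density over hyperparameters and individual diffusion parameters.

    Holds the per-cell summary data in dense ``(P, 2)`` arrays and exposes
    :meth:`logpdf` — the exact joint log-density (including normalizing
    constants) evaluable at any interior point — plus the packed arrays the
    sampling kernel consumes.
    """

    def __init__(self, cells: list[SummaryCell], spec: ModelSpec):
        participants = sorted({c.participant for c in cells})
        self.participants = participants
        P = len(participants)
        index = {pid: i for i, pid in enumerate(participants)}
        shape = (P, 2)
        self.nc = np.full(shape, -1.0)
        self.ntot = np.full(shape, -1.0)
        self.nrt = np.full(shape, -1.0)
        self.loc = np.full(shape, np.nan)
        self.scale = np.full(shape, np.nan)
        for c in cells:
            if c.condition not in (0, 1):
                raise ValueError(f"condition must be 0/1, got {c.condition}")
            if c.n < 4:
                raise ValueError(
                    f"cell (participant={c.participant}, condition={c.condition}) "
                    f"has n={c.n} < 4"
                )
            i = index[c.participant]
            self.nc[i, c.condition] = c.n_correct
            self.ntot[i, c.condition] = c.n_total
            self.nrt[i, c.condition] = c.n
            self.loc[i, c.condition] = c.loc
            self.scale[i, c.condition] = c.scale
        if np.any(self.nc < 0):
            raise ValueError("every participant must contribute both conditions")
        self.spec = spec
        self.P = P

    # prior vector consumed by the kernel
    @property
    def _prior_vec(self) -> np.ndarray:
        sp = self.spec
        return np.array([
            sp.mu_nu_prior[0], sp.mu_nu_prior[1],
            sp.beta_prior[0], sp.beta_prior[1],
            sp.mu_alpha_prior[0], sp.mu_alpha_prior[1],
            sp.mu_tau_prior[0], sp.mu_tau_prior[1],
            sp.sigma_nu_scale, sp.sigma_alpha_scale, sp.sigma_tau_scale,
        ])

    def logpdf(self, point: dict) -> float:
        """Joint log-density at a point, with all normalizing constants.

        ``point`` keys: the seven hyperparameters by name plus ``nu``
        (``(P, 2)``), ``alpha`` and ``tau`` (length ``P``). Returns ``-inf``
        outside the support (non-positive scales, ``alpha_p <= 0``,
        ``tau_p < 0``, ``mu_alpha/mu_tau <= 0``).
        """
        sp = self.spec
        mu_nu, beta = point["mu_nu"], point["beta"]
        sig_nu, sig_alpha, sig_tau = point["sigma_nu"], point["sigma_alpha"], point["sigma_tau"]
        mu_alpha, mu_tau = point["mu_alpha"], point["mu_tau"]
        nu = np.asarray(point["nu"], dtype=float).reshape(self.P, 2)
        alpha = np.asarray(point["alpha"], dtype=float)
        tau = np.asarray(point["tau"], dtype=float)
        if min(sig_nu, sig_alpha, sig_tau) <= 0 or mu_alpha <= 0 or mu_tau <= 0:
            return -np.inf
        if np.any(alpha <= 0) or np.any(tau < 0):
            return -np.inf

        def _norm_logpdf(x, m, sd):
            return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - m) / sd) ** 2

        def _halfnorm_logpdf(x, sc):
            return 0.5 * np.log(2 / np.pi) - np.log(sc) - 0.5 * (x / sc) ** 2

        def _truncnorm_logpdf(x, m, sd):
            # normal truncated to (0, inf)
            z = 0.5 * math.erfc(-m / (sd * math.sqrt(2)))
            return _norm_logpdf(x, m, sd) - np.log(z)

        lp = 0.0
        lp += _norm_logpdf(mu_nu, *sp.mu_nu_prior)
        lp += _norm_logpdf(beta, *sp.beta_prior)
        lp += _truncnorm_logpdf(mu_alpha, *sp.mu_alpha_prior)
        lp += _truncnorm_logpdf(mu_tau, *sp.mu_tau_prior)
        lp += _halfnorm_logpdf(sig_nu, sp.sigma_nu_scale)
        lp += _halfnorm_logpdf(sig_alpha, sp.sigma_alpha_scale)
        lp += _halfnorm_logpdf(sig_tau, sp.sigma_tau_scale)

        pred = np.stack([np.full(self.P, mu_nu), np.full(self.P, mu_nu + beta)], axis=1)
        lp += _norm_logpdf(nu, pred, sig_nu).sum()
        lp += _norm_logpdf(alpha, mu_alpha, sig_alpha).sum()
        lp += _norm_logpdf(tau, mu_tau, sig_tau).sum()

        for p in range(self.P):
            for k in range(2):
                ll = _cell_ll(nu[p, k], alpha[p], tau[p], sp.s,
                              self.nc[p, k], self.ntot[p, k], self.nrt[p, k],
                              self.loc[p, k], self.scale[p, k])
                if not np.isfinite(ll):
                    return -np.inf
                # binomial coefficient, dropped inside the kernel
                ll += (math.lgamma(self.ntot[p, k] + 1)
                       - math.lgamma(self.nc[p, k] + 1)
                       - math.lgamma(self.ntot[p, k] - self.nc[p, k] + 1))
                lp += ll
        return float(lp)

    def initial_point(self, jitter: float = 0.0, rng: np.random.Generator | None = None):
        """Method-of-moments starting values via edge-corrected EZ inversion."""
        nu0 = np.empty((self.P, 2))
        alpha0 = np.empty((self.P, 2))
        tau0 = np.empty((self.P, 2))
        for p in range(self.P):
            for k in range(2):
                n_tot = int(self.ntot[p, k])
                pc_hat = self.nc[p, k] / n_tot
                vrt_hat = max(self.scale[p, k], 1e-4)
                try:
                    est = inverse_ez(pc_hat, self.loc[p, k], vrt_hat,
                                     s=self.spec.s, n=n_tot)
                    nu0[p, k] = np.clip(est.nu, -7.0, 7.0)
                    alpha0[p, k] = np.clip(est.alpha, 0.3, 10.0)
                    tau0[p, k] = np.clip(est.tau, 0.01, 5.0)
                except ValueError:
                    nu0[p, k] = 0.0
                    alpha0[p, k] = 2.0
                    tau0[p, k] = 0.2
        alpha_i = alpha0.mean(axis=1)
        tau_i = tau0.mean(axis=1)
        hyp = np.array([
            nu0[:, 0].mean(),
            nu0[:, 1].mean() - nu0[:, 0].mean(),
            max(nu0.std(), 0.2),
            alpha_i.mean(),
            max(alpha_i.std(), 0.2),
            tau_i.mean(),
            max(tau_i.std(), 0.05),
        ])
        if jitter > 0 and rng is not None:
            hyp = hyp + jitter * rng.normal(size=7) * np.abs(hyp).clip(0.1, None)
            hyp[2], hyp[4], hyp[6] = np.abs(hyp[[2, 4, 6]])
            hyp[3] = max(hyp[3], 0.5)
            hyp[5] = max(hyp[5], 0.05)
            nu0 = nu0 + jitter * rng.normal(size=nu0.shape)
            alpha_i = np.maximum(alpha_i + jitter * rng.normal(size=self.P), 0.3)
            tau_i = np.maximum(tau_i + 0.2 * jitter * rng.normal(size=self.P), 0.01)
        return hyp, nu0, alpha_i, tau_i


def build_model(cells: list[SummaryCell], spec: ModelSpec | None = None) -> Model:
    """Assemble the hierarchical proxy-likelihood model from summary cells."""
    return Model(cells, spec if spec is not None else ModelSpec())


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """MCMC draws: hyperparameters (chain, draw, 7) and individuals (chain, draw, 4P)."""

    hyper: np.ndarray
    individual: np.ndarray
    chains: int
    warmup: int
    draws: int
    seed: int

    def hyper_frame(self):
        import pandas as pd

        flat = self.hyper.reshape(-1, len(HYPER_NAMES))
        return pd.DataFrame(flat, columns=list(HYPER_NAMES))


@dataclass
class FitResult:
    """Posterior summaries, convergence diagnostics and decision-statistic inputs."""

    summary: dict            # name -> {mean, sd, q2.5, q50, q97.5}
    rhat: dict               # name -> split-Rhat
    ess: dict                # name -> bulk effective sample size
    beta_mean: float
    beta_sd: float
    beta_prior_pdf0: float   # prior density of beta at 0 (Savage-Dickey numerator)
    converged: bool
    seed: int
    model_tag: str
    posterior: PosteriorSamples | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "summary": self.summary,
            "rhat": self.rhat,
            "ess": self.ess,
            "beta_mean": self.beta_mean,
            "beta_sd": self.beta_sd,
            "beta_prior_pdf0": self.beta_prior_pdf0,
            "converged": self.converged,
            "seed": self.seed,
            "model_tag": self.model_tag,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit(
    model: Model,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
    thin: int = 1,
    keep_individuals: bool = True,
) -> FitResult:
    """Run MCMC on the model and summarize the posterior.

    Deterministic given ``seed``: per-chain kernel seeds derive from a
    :class:`numpy.random.SeedSequence`. Convergence is assessed with
    split-R-hat on every hyperparameter; a fit with any R-hat above 1.05 is
    returned flagged (``converged=False``), never silently.
    """
    import arviz as az

    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s) % (2**32 - 1) for s in ss.generate_state(chains)]
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])

    hyp_all = np.empty((chains, draws, 7))
    ind_all = np.empty((chains, draws, 4 * model.P))
    for c in range(chains):
        jit = 0.0 if c == 0 else 0.1
        hyp0, nu0, alpha0, tau0 = model.initial_point(jitter=jit, rng=jitter_rng)
        hyp_out, ind_out, _ = _run_chain(
            chain_seeds[c], warmup, draws, thin,
            model.nc, model.ntot, model.nrt, model.loc, model.scale,
            model.spec.s, model._prior_vec, hyp0, nu0, alpha0, tau0,
        )
        hyp_all[c] = hyp_out
        ind_all[c] = ind_out

    idata = az.from_dict({name: hyp_all[:, :, i] for i, name in enumerate(HYPER_NAMES)})
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {n: float(rhat_ds[n].values) for n in HYPER_NAMES}
    ess = {n: float(ess_ds[n].values) for n in HYPER_NAMES}

    summary = {}
    for i, name in enumerate(HYPER_NAMES):
        x = hyp_all[:, :, i].ravel()
        q = np.quantile(x, [0.025, 0.5, 0.975])
        summary[name] = {
            "mean": float(x.mean()), "sd": float(x.std(ddof=1)),
            "q2.5": float(q[0]), "q50": float(q[1]), "q97.5": float(q[2]),
        }

    beta = hyp_all[:, :, 1].ravel()
    post = PosteriorSamples(
        hyper=hyp_all,
        individual=ind_all if keep_individuals else np.empty((chains, 0, 0)),
        chains=chains, warmup=warmup, draws=draws, seed=seed,
    )
    return FitResult(
        summary=summary,
        rhat=rhat,
        ess=ess,
        beta_mean=float(beta.mean()),
        beta_sd=float(beta.std(ddof=1)),
        beta_prior_pdf0=model.spec.beta_prior_pdf_at(0.0),
        converged=bool(all(r <= _RHAT_THRESHOLD for r in rhat.values())),
        seed=seed,
        model_tag=f"{model.spec.method}/{model.spec.rt_scope}",
        posterior=post,
    )


# ---------------------------------------------------------------------------
# Decision statistics
# ---------------------------------------------------------------------------

def decision_statistic(fit_result: FitResult, kind: str = "z_abs") -> float:
    """Evidence for a nonzero condition effect on drift.

    ``z_abs``
        ``|posterior mean(beta)| / posterior sd(beta)`` — threshold-free
        ordering for ROC construction.
    ``savage_dickey_bf10``
        Prior density of beta at 0 over posterior density at 0 (posterior
        density via a normal approximation from the posterior mean and sd).

    Both are monotone in the evidence for an effect, so downstream ROC
    curves are unchanged by the choice.
    """
    sd = fit_result.beta_sd
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("posterior sd of beta must be positive and finite")
    if kind == "z_abs":
        return abs(fit_result.beta_mean) / sd
    if kind == "savage_dickey_bf10":
        post0 = math.exp(-0.5 * (fit_result.beta_mean / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
        return fit_result.beta_prior_pdf0 / post0
    raise ValueError(f"unknown decision statistic {kind!r}")
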