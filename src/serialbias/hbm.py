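"""Hierarchical Bayesian estimation of DoG serial-bias parameters.

The model is fit to condition-level mean values (circular mean errors, mean
AUCs, or mean horizontal deviations) on the ten relative-color bins. With
rows ``i`` (participants) and columns ``j`` (report types, or report type x
time point for the four-level variant):

    y_ijb ~ Normal( alpha_ij * k(x_b; w_ij) + beta_ij, sigma^2 )
    alpha_ij ~ Normal( alpha_i + alpha_j, delta^2 )
    log w_ij ~ Normal( log w_j, tau_w^2 ),   beta_ij ~ Normal( beta_j, tau_b^2 )

where ``k(x; w) = w x c exp(-(wx)^2)`` is the unit-amplitude DoG shape,
participants enter as random effects (``alpha_i``), report types as fixed
effects (``alpha_j``), and ``delta^2`` captures participant-by-condition
interaction variability. Priors are weakly informative on the printed effect
scale and fully exposed through :class:`Priors`.

Posterior sampling uses a blocked Gibbs scheme exploiting the model's
conditional linearity: ``(alpha_ij, beta_ij)`` and all hierarchical means
have conjugate Gaussian full conditionals, the log-widths are updated with
adaptive random-walk Metropolis steps, and the scale hyperparameters with
univariate slice sampling. Chains are independent and seeded; the retained
total (12,000 draws for the three-level model, 2,000 for the four-level
one) is split evenly across chains and pooled for summaries. Convergence is
monitored with split R-hat on all population-level parameters; the
headline per-report amplitude is the participant-marginalized mean of the
``alpha_ij`` draws, summarized by its posterior mean and 95% highest
density interval (HDI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .circular import DOG_NORM
from .simulate import REPORT_TYPES

__all__ = [
    "Priors",
    "HierarchicalSpec",
    "PosteriorMatrix",
    "FitDiagnostics",
    "HierarchicalDoGModel",
    "fit_hbm3",
    "fit_hbm4",
    "compute_rhat",
    "compute_hdi",
    "posterior_summary",
    "participant_alpha_means",
]


@dataclass(frozen=True)
class Priors:
    """Prior scales. Amplitude-like scales are in the data's units
    (degrees for report errors, px for trajectory statistics)."""

    alpha_sd: float = 10.0      # alpha_i, alpha_j ~ Normal(0, alpha_sd^2)
    beta_sd: float = 5.0        # beta_j ~ Normal(0, beta_sd^2)
    delta_sd: float = 5.0       # delta ~ HalfNormal(delta_sd)
    sigma_sd: float = 5.0       # sigma ~ HalfNormal(sigma_sd)
    log_w_loc: float = float(np.log(0.02))  # log w_j ~ Normal(log_w_loc, log_w_sd^2)
    log_w_sd: float = 0.3
    tau_w_sd: float = 0.2       # tau_w ~ HalfNormal(tau_w_sd)
    tau_beta_sd: float = 2.0    # tau_b ~ HalfNormal(tau_beta_sd)
    #: hard support of the width, 1/degrees. The upper bound keeps the curve's
    #: peak (at 1/(w*sqrt(2))) outside the innermost +/-36-degree bins, where a
    #: near-zero kernel with an unbounded amplitude could mimic any data
    #: ("narrow-spike" non-identifiability); the lower bound keeps the peak
    #: inside the sampled +/-180-degree range.
    w_bounds: tuple = (0.005, 0.04)

    def scaled(self, factor: float) -> "Priors":
        """Rescale all amplitude-like prior widths (for px-valued data)."""
        return replace(
            self,
            alpha_sd=self.alpha_sd * factor,
            beta_sd=self.beta_sd * factor,
            delta_sd=self.delta_sd * factor,
            sigma_sd=self.sigma_sd * factor,
            tau_beta_sd=self.tau_beta_sd * factor,
        )


@dataclass
class HierarchicalSpec:
    """Sampler sizes and priors for one hierarchical fit.

    ``n_samples`` is the retained total pooled over chains; ``n_warmup``
    is likewise split evenly across chains. Defaults reproduce the standard
    sampler sizes: 12,000 warm-up / 12,000 retained for the three-level
    model and 2,000 / 2,000 for the four-level one.
    """

    levels: int = 3
    n_chains: int = 4
    n_warmup: int | None = None
    n_samples: int | None = None
    priors: Priors = field(default_factory=Priors)
    share_w: str = "cell"  # "cell" (hierarchical per cell) or "column"
    seed: int = 0

    def __post_init__(self):
        if self.levels not in (3, 4):
            raise ValueError("levels must be 3 or 4")
        default = 12_000 if self.levels == 3 else 2_000
        if self.n_warmup is None:
            self.n_warmup = default
        if self.n_samples is None:
            self.n_samples = default
        if min(self.n_chains, self.n_warmup, self.n_samples) <= 0:
            raise ValueError("chain/warmup/sample counts must be positive")
        if self.share_w not in ("cell", "column"):
            raise ValueError("share_w must be 'cell' or 'column'")


@dataclass
class PosteriorMatrix:
    """Pooled posterior draws of the cell-level DoG parameters.

    ``draws[param]`` has shape (samples, participants, report_types) for the
    three-level model and (samples, participants, report_types, time_points)
    for the four-level one, for param in {"alpha", "w", "beta"}.
    ``chain_draws`` keeps the per-chain layout (chains, draws, ...) of the
    population-level parameters for convergence diagnostics.
    """

    draws: dict
    participants: list
    report_types: list
    time_points: list | None
    chain_draws: dict
    hyper_draws: dict

    @property
    def shape(self):
        return self.draws["alpha"].shape

    def marginal_alpha(self) -> np.ndarray:
        """Population-level amplitude draws per report type (x time point):
        the mean over participants of the cell-level alpha draws."""
        return self.draws["alpha"].mean(axis=1)

    def to_dataset(self):
        """Named-dimension container (xarray.Dataset) of the pooled draws."""
        import xarray as xr

        dims = ["sample", "participant", "report_type"]
        coords = {
            "sample": np.arange(self.shape[0]),
            "participant": self.participants,
            "report_type": self.report_types,
        }
        if self.time_points is not None:
            dims.append("time_point")
            coords["time_point"] = self.time_points
        return xr.Dataset(
            {k: (dims, v) for k, v in self.draws.items()}, coords=coords
        )


@dataclass
class FitDiagnostics:
    rhat: dict
    hdi95: dict
    posterior_mean: dict
    max_rhat: float
    converged: bool
    messages: list


def compute_rhat(chains) -> float:
    """Split potential-scale-reduction R-hat for one scalar parameter.

    ``chains`` is (n_chains, n_draws). Each chain is halved, then the
    classic between/within-variance formula is applied:
    R-hat = sqrt(((n-1)/n * W + B/n) / W). Chains with (numerically) zero
    total variance are degenerate: returns NaN with a warning.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    half = arr.shape[1] // 2
    split = np.concatenate([arr[:, :half], arr[:, half: 2 * half]], axis=0)
    m, n = split.shape
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * np.var(chain_means, ddof=1)
    if w <= 1e-300 or not np.isfinite(w):
        warnings.warn("R-hat undefined: zero within-chain variance")
        return float("nan")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def compute_hdi(draws, mass: float = 0.95):
    """Shortest contiguous interval containing ``mass`` of the draws.

    Sorted-window algorithm: sort the draws, slide a window of
    ceil(mass * n) draws, return the narrowest one.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    if x.size < 100:
        raise ValueError(f"need >= 100 draws for an HDI, got {x.size}")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * x.size))
    widths = x[m - 1:] - x[: x.size - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


# --------------------------------------------------------------------------
# sampler internals
# --------------------------------------------------------------------------

def _kern(x, w):
    wx = w * x
    return wx * DOG_NORM * np.exp(-(wx**2))


def _slice_sample(logpdf, x0, rng, width=0.8, max_steps=40):
    """Univariate slice sampling with stepping-out and shrinkage (Neal 2003)."""
    y = logpdf(x0) - rng.exponential()
    lo = x0 - width * rng.uniform()
    hi = lo + width
    for _ in range(max_steps):
        if logpdf(lo) < y:
            break
        lo -= width
    for _ in range(max_steps):
        if logpdf(hi) < y:
            break
        hi += width
    for _ in range(max_steps * 3):
        x1 = rng.uniform(lo, hi)
        if logpdf(x1) >= y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # pathological shrinkage; keep the current value


def _log_halfnormal_scale(ls, ss, n, prior_sd):
    """Log-density of a scale parameter on the log scale.

    ``ss`` is the residual sum of squares of the n values the scale governs;
    prior is HalfNormal(prior_sd) on the natural scale (plus the Jacobian of
    the log transform).
    """
    s2 = np.exp(2.0 * ls)
    return -n * ls - ss / (2.0 * s2) - s2 / (2.0 * prior_sd**2) + ls


def _run_chain(y, x, priors: Priors, share_w: str, n_warmup: int, n_draws: int, rng):
    R, C, B = y.shape
    p = priors

    # data-driven initialization with chain-specific jitter (overdispersion)
    w0 = float(np.exp(p.log_w_loc))
    k0 = _kern(x, w0)
    kk = float(k0 @ k0)
    ks = float(k0.sum())
    det0 = kk * B - ks**2
    sy = y.sum(axis=2)
    sky = y @ k0
    a = (B * sky - ks * sy) / det0
    bta = (kk * sy - ks * sky) / det0
    a = a + rng.normal(0, 0.1 * np.std(a) + 0.05, a.shape)
    bta = bta + rng.normal(0, 0.1 * np.std(bta) + 0.05, bta.shape)
    lwb = (np.log(p.w_bounds[0]), np.log(p.w_bounds[1]))
    lw_col = np.clip(np.full(C, p.log_w_loc) + rng.normal(0, 0.2, C), *lwb)
    lw = np.tile(lw_col, (R, 1)) if share_w == "column" else np.clip(
        np.tile(lw_col, (R, 1)) + rng.normal(0, 0.1, (R, C)), *lwb
    )
    a_col = a.mean(axis=0)
    a_row = (a - a_col).mean(axis=1)
    b_col = bta.mean(axis=0)
    resid0 = y - a[..., None] * _kern(x, np.exp(lw)[..., None]) - bta[..., None]
    sigma = np.maximum(resid0.std(axis=(0, 2)), 1e-3)  # residual scale per column
    delta = max(float(np.std(a - a_row[:, None] - a_col[None, :])), 1e-2)
    tau_w = 0.1
    tau_b = max(float(np.std(bta - b_col)), 1e-2)

    step = np.full((R, C) if share_w == "cell" else C, 0.15)
    step_col = np.full(C, 0.1)
    step_ac = np.full(C, 0.5)
    step_bc = np.full(C, 0.5)
    adapt_rate = 0.05

    keep = {
        "alpha": np.empty((n_draws, R, C)),
        "w": np.empty((n_draws, R, C)),
        "beta": np.empty((n_draws, R, C)),
        "alpha_col": np.empty((n_draws, C)),
        "beta_col": np.empty((n_draws, C)),
        "log_w_col": np.empty((n_draws, C)),
        "alpha_row": np.empty((n_draws, R)),
        "delta": np.empty(n_draws),
        "sigma": np.empty((n_draws, C)),
        "tau_w": np.empty(n_draws),
        "tau_b": np.empty(n_draws),
    }

    def _marginal_ll(k, m_a, m_b, d2, tb2, s2):
        """Per-cell log-likelihood with (alpha, beta) integrated out.

        y | w ~ Normal(m_a k + m_b, sigma^2 I + delta^2 k k' + tau_b^2 11');
        evaluated via the 2x2 Woodbury identity, constants dropped.
        Collapsing the conditionally Gaussian amplitude/intercept makes the
        width update immune to the funnel where k ~= 0 leaves alpha free.
        """
        r = y - m_a[..., None] * k - m_b[..., None]
        skk = np.einsum("rcb,rcb->rc", k, k)
        sk = k.sum(axis=2)
        skr = np.einsum("rcb,rcb->rc", k, r)
        sr = r.sum(axis=2)
        srr = np.einsum("rcb,rcb->rc", r, r)
        m11 = s2 / d2 + skk
        m22 = s2 / tb2 + B
        det = m11 * m22 - sk**2
        quad = (srr - (m22 * skr**2 - 2.0 * sk * skr * sr + m11 * sr**2) / det) / s2
        return -0.5 * (np.log(det) + quad)

    k = _kern(x, np.exp(lw)[..., None])
    for it in range(n_warmup + n_draws):
        s2 = (sigma**2)[None, :]  # broadcast per-column residual variance
        d2, tb2 = delta**2, tau_b**2
        m_a = a_row[:, None] + a_col[None, :]
        m_b = np.broadcast_to(b_col[None, :], (R, C))

        # --- width update: collapsed random-walk Metropolis on log w ---
        if share_w == "cell":
            tw2 = tau_w**2
            lw_prop = lw + step * rng.standard_normal((R, C))
            k_prop = _kern(x, np.exp(lw_prop)[..., None])
            logr = _marginal_ll(k_prop, m_a, m_b, d2, tb2, s2) - _marginal_ll(
                k, m_a, m_b, d2, tb2, s2
            )
            logr += (
                (lw - lw_col[None, :]) ** 2 - (lw_prop - lw_col[None, :]) ** 2
            ) / (2 * tw2)
            inside = (lw_prop >= lwb[0]) & (lw_prop <= lwb[1])
            accept = inside & (np.log(rng.uniform(size=(R, C))) < logr)
            lw = np.where(accept, lw_prop, lw)
            k = np.where(accept[..., None], k_prop, k)
            # group move: shift a whole column's widths (and its mean) jointly,
            # so the column level does not have to mix through the cells
            t = step_col * rng.standard_normal(C)
            lwc_prop = lw_col + t
            lw_prop = lw + t[None, :]
            k_prop = _kern(x, np.exp(lw_prop)[..., None])
            logr_col = (
                _marginal_ll(k_prop, m_a, m_b, d2, tb2, s2)
                - _marginal_ll(k, m_a, m_b, d2, tb2, s2)
            ).sum(axis=0)
            logr_col += (
                (lw_col - p.log_w_loc) ** 2 - (lwc_prop - p.log_w_loc) ** 2
            ) / (2 * p.log_w_sd**2)
            inside = (
                (lwc_prop >= lwb[0]) & (lwc_prop <= lwb[1])
                & (lw_prop >= lwb[0]).all(axis=0) & (lw_prop <= lwb[1]).all(axis=0)
            )
            acc_col = inside & (np.log(rng.uniform(size=C)) < logr_col)
            lw_col = np.where(acc_col, lwc_prop, lw_col)
            lw = np.where(acc_col[None, :], lw_prop, lw)
            k = np.where(acc_col[None, :, None], k_prop, k)
            if it < n_warmup:
                step_col *= np.exp(adapt_rate * (acc_col.astype(float) - 0.44))
                step_col = np.clip(step_col, 1e-3, 2.0)
        else:  # one width per column, shared across participants
            lwc_prop = lw_col + step * rng.standard_normal(C)
            k_prop = np.broadcast_to(
                _kern(x, np.exp(lwc_prop)[None, :, None]), (R, C, B)
            )
            logr = (
                _marginal_ll(k_prop, m_a, m_b, d2, tb2, s2)
                - _marginal_ll(k, m_a, m_b, d2, tb2, s2)
            ).sum(axis=0)
            logr += (
                (lw_col - p.log_w_loc) ** 2 - (lwc_prop - p.log_w_loc) ** 2
            ) / (2 * p.log_w_sd**2)
            inside = (lwc_prop >= lwb[0]) & (lwc_prop <= lwb[1])
            accept = inside & (np.log(rng.uniform(size=C)) < logr)
            lw_col = np.where(accept, lwc_prop, lw_col)
            k = np.where(accept[None, :, None], k_prop, k)
            lw = np.tile(lw_col, (R, 1))
        if it < n_warmup:
            step *= np.exp(adapt_rate * (accept.astype(float) - 0.44))
            step = np.clip(step, 1e-3, 2.0)

        # --- joint conjugate draw of (alpha_ij, beta_ij) given the width ---
        skk = np.einsum("rcb,rcb->rc", k, k)
        sk = k.sum(axis=2)
        sky = np.einsum("rcb,rcb->rc", k, y)
        sy = y.sum(axis=2)
        p11 = skk / s2 + 1.0 / d2
        p12 = sk / s2
        p22 = B / s2 + 1.0 / tb2
        r1 = sky / s2 + (a_row[:, None] + a_col[None, :]) / d2
        r2 = sy / s2 + b_col[None, :] / tb2
        det = p11 * p22 - p12**2
        c11, c12, c22 = p22 / det, -p12 / det, p11 / det
        m1 = c11 * r1 + c12 * r2
        m2 = c12 * r1 + c22 * r2
        l11 = np.sqrt(c11)
        l21 = c12 / l11
        l22 = np.sqrt(np.maximum(c22 - l21**2, 1e-300))
        z1 = rng.standard_normal((R, C))
        z2 = rng.standard_normal((R, C))
        a = m1 + l11 * z1
        bta = m2 + l21 * z1 + l22 * z2

        # --- hierarchical means (all conjugate) ---
        prec = C / d2 + 1.0 / p.alpha_sd**2
        mean = ((a - a_col[None, :]).sum(axis=1) / d2) / prec
        a_row = mean + rng.standard_normal(R) / np.sqrt(prec)
        prec = R / d2 + 1.0 / p.alpha_sd**2
        mean = ((a - a_row[:, None]).sum(axis=0) / d2) / prec
        a_col = mean + rng.standard_normal(C) / np.sqrt(prec)
        # recentering move: only the sum alpha_i + alpha_j enters the
        # likelihood, so the row/column split mixes slowly; resample the
        # shared shift along that flat direction from its exact Gaussian
        # conditional to decorrelate the blocks
        shift_mean = (a_row.sum() - a_col.sum()) / (R + C)
        shift = shift_mean + rng.standard_normal() * p.alpha_sd / np.sqrt(R + C)
        a_row -= shift
        a_col += shift
        prec = R / tb2 + 1.0 / p.beta_sd**2
        mean = (bta.sum(axis=0) / tb2) / prec
        b_col = mean + rng.standard_normal(C) / np.sqrt(prec)

        # --- column translation moves ---
        # When delta (or tau_b) is small the centered hierarchy mixes by
        # O(delta) increments; translating a column's cells together with its
        # fixed effect moves at the data's own precision instead.
        resid = y - a[..., None] * k - bta[..., None]
        t = step_ac * rng.standard_normal(C)
        tk = t[None, :, None] * k
        dll = ((2.0 * tk * resid - tk * tk).sum(axis=(0, 2))) / (2.0 * s2[0])
        dll += (a_col**2 - (a_col + t) ** 2) / (2.0 * p.alpha_sd**2)
        acc = np.log(rng.uniform(size=C)) < dll
        ta = np.where(acc, t, 0.0)
        a_col = a_col + ta
        a = a + ta[None, :]
        resid = resid - ta[None, :, None] * k
        t = step_bc * rng.standard_normal(C)
        dll = ((2.0 * t[None, :, None] * resid).sum(axis=(0, 2)) - R * B * t**2) / (
            2.0 * s2[0]
        )
        dll += (b_col**2 - (b_col + t) ** 2) / (2.0 * p.beta_sd**2)
        acc_b = np.log(rng.uniform(size=C)) < dll
        tb = np.where(acc_b, t, 0.0)
        b_col = b_col + tb
        bta = bta + tb[None, :]
        if it < n_warmup:
            step_ac *= np.exp(adapt_rate * (acc.astype(float) - 0.44))
            step_ac = np.clip(step_ac, 1e-4, 100.0)
            step_bc *= np.exp(adapt_rate * (acc_b.astype(float) - 0.44))
            step_bc = np.clip(step_bc, 1e-4, 100.0)

        # --- width hierarchy hyperparameters ---
        if share_w == "cell":
            tw2 = tau_w**2
            prec = R / tw2 + 1.0 / p.log_w_sd**2
            mean = (lw.sum(axis=0) / tw2 + p.log_w_loc / p.log_w_sd**2) / prec
            lw_col = mean + rng.standard_normal(C) / np.sqrt(prec)
            ss = float(((lw - lw_col[None, :]) ** 2).sum())
            ltw = _slice_sample(
                lambda t: _log_halfnormal_scale(t, ss, R * C, p.tau_w_sd),
                np.log(tau_w), rng,
            )
            tau_w = float(np.exp(ltw))

        # --- scale hyperparameters (slice sampling on the log scale) ---
        ssr_col = ((y - a[..., None] * k - bta[..., None]) ** 2).sum(axis=(0, 2))
        for c in range(C):
            lsig = _slice_sample(
                lambda t, sc=ssr_col[c]: _log_halfnormal_scale(t, sc, R * B, p.sigma_sd),
                np.log(sigma[c]), rng,
            )
            sigma[c] = np.exp(lsig)
        ssa = float(((a - a_row[:, None] - a_col[None, :]) ** 2).sum())
        ldel = _slice_sample(
            lambda t: _log_halfnormal_scale(t, ssa, R * C, p.delta_sd),
            np.log(delta), rng,
        )
        delta = float(np.exp(ldel))
        # interweaving move for delta: hold the standardized cell deviations
        # fixed and rescale them with a proposed delta, so the scale mixes at
        # the data's precision instead of through cell-by-cell drift (the
        # centered parameterization's funnel)
        eta = (a - a_row[:, None] - a_col[None, :]) / delta
        ld_prop = np.log(delta) + 0.3 * rng.standard_normal()
        a_prop = a_row[:, None] + a_col[None, :] + np.exp(ld_prop) * eta
        r_cur = y - a[..., None] * k - bta[..., None]
        r_prop = y - a_prop[..., None] * k - bta[..., None]
        dll = float(((r_cur**2 - r_prop**2) / (2.0 * s2[..., None])).sum())
        dll += _log_halfnormal_scale(ld_prop, 0.0, 0, p.delta_sd)
        dll -= _log_halfnormal_scale(np.log(delta), 0.0, 0, p.delta_sd)
        if np.log(rng.uniform()) < dll:
            a = a_prop
            delta = float(np.exp(ld_prop))
        ssb = float(((bta - b_col[None, :]) ** 2).sum())
        ltb = _slice_sample(
            lambda t: _log_halfnormal_scale(t, ssb, R * C, p.tau_beta_sd),
            np.log(tau_b), rng,
        )
        tau_b = float(np.exp(ltb))

        if it >= n_warmup:
            j = it - n_warmup
            keep["alpha"][j] = a
            keep["w"][j] = np.exp(lw)
            keep["beta"][j] = bta
            keep["alpha_col"][j] = a_col
            keep["beta_col"][j] = b_col
            keep["log_w_col"][j] = lw_col
            keep["alpha_row"][j] = a_row
            keep["delta"][j] = delta
            keep["sigma"][j] = sigma
            keep["tau_w"][j] = tau_w
            keep["tau_b"][j] = tau_b
    return keep


def _prepare_matrix(summaries: pd.DataFrame, value_col: str, levels: int):
    need = {"participant", "report_type", "bin_center", value_col}
    if levels == 4:
        need.add("time_point")
    missing = need - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    participants = sorted(summaries["participant"].unique().tolist())
    present = summaries["report_type"].unique().tolist()
    report_types = [r for r in REPORT_TYPES if r in present] + sorted(
        set(present) - set(REPORT_TYPES)
    )
    bins = np.sort(summaries["bin_center"].unique().astype(float))
    if bins.size < 4:
        raise ValueError("need at least 4 condition bins")
    cols = ["participant", "report_type"] + (["time_point"] if levels == 4 else [])
    wide = summaries.pivot_table(
        index=cols, columns="bin_center", values=value_col, sort=True
    )
    if wide.isna().any().any():
        raise ValueError("incomplete bin grid: every cell needs every bin")
    if levels == 3:
        time_points = None
        y = np.empty((len(participants), len(report_types), bins.size))
        for r, pp in enumerate(participants):
            for c, rt in enumerate(report_types):
                y[r, c] = wide.loc[(pp, rt)].to_numpy(float)
    else:
        time_points = sorted(summaries["time_point"].unique().tolist())
        y = np.empty((len(participants), len(report_types) * len(time_points), bins.size))
        for r, pp in enumerate(participants):
            for c, (rt, tp) in enumerate(
                (rt, tp) for rt in report_types for tp in time_points
            ):
                y[r, c] = wide.loc[(pp, rt, tp)].to_numpy(float)
    return y, bins, participants, report_types, time_points


def _diagnose(chain_keep: list, participants, report_types, time_points, mass=0.95):
    """Pool chains, compute split R-hat, HDIs, and headline summaries."""
    n_chains = len(chain_keep)
    pooled = {
        name: np.concatenate([ck[name] for ck in chain_keep], axis=0)
        for name in ("alpha", "w", "beta")
    }
    hyper = {
        name: np.concatenate([ck[name] for ck in chain_keep], axis=0)
        for name in ("alpha_col", "beta_col", "log_w_col", "alpha_row",
                     "delta", "sigma", "tau_w", "tau_b")
    }
    chain_pop = {}
    C = chain_keep[0]["alpha_col"].shape[1]

    def _col_label(c):
        if time_points is None:
            return report_types[c]
        rt = report_types[c // len(time_points)]
        tp = time_points[c % len(time_points)]
        return f"{rt}@t{tp:g}"

    for c in range(C):
        chain_pop[f"alpha_pop[{_col_label(c)}]"] = np.stack(
            [ck["alpha"][:, :, c].mean(axis=1) for ck in chain_keep]
        )
        chain_pop[f"alpha_col[{_col_label(c)}]"] = np.stack(
            [ck["alpha_col"][:, c] for ck in chain_keep]
        )
        chain_pop[f"beta_col[{_col_label(c)}]"] = np.stack(
            [ck["beta_col"][:, c] for ck in chain_keep]
        )
        chain_pop[f"log_w_col[{_col_label(c)}]"] = np.stack(
            [ck["log_w_col"][:, c] for ck in chain_keep]
        )
    chain_pop["delta"] = np.stack([ck["delta"] for ck in chain_keep])
    for c in range(C):
        chain_pop[f"sigma[{_col_label(c)}]"] = np.stack(
            [ck["sigma"][:, c] for ck in chain_keep]
        )

    rhat, hdi, pmean, messages = {}, {}, {}, []
    for name, arr in chain_pop.items():
        rhat[name] = compute_rhat(arr) if n_chains >= 2 else float("nan")
        flat = arr.reshape(-1)
        hdi[name] = compute_hdi(flat, mass)
        pmean[name] = float(flat.mean())
    finite = [v for v in rhat.values() if np.isfinite(v)]
    max_rhat = max(finite) if finite else float("nan")
    converged = bool(np.isfinite(max_rhat) and max_rhat <= 1.05)
    if not converged:
        messages.append(
            f"possible non-convergence: max population-level R-hat = {max_rhat:.3f}"
        )
        warnings.warn(messages[-1])

    # reshape 4-level draws to (samples, R, J, T)
    if time_points is not None:
        J, T = len(report_types), len(time_points)
        pooled = {k: v.reshape(v.shape[0], v.shape[1], J, T) for k, v in pooled.items()}
    matrix = PosteriorMatrix(
        draws=pooled,
        participants=participants,
        report_types=report_types,
        time_points=time_points,
        chain_draws=chain_pop,
        hyper_draws=hyper,
    )
    diagnostics = FitDiagnostics(
        rhat=rhat, hdi95=hdi, posterior_mean=pmean,
        max_rhat=max_rhat, converged=converged, messages=messages,
    )
    return matrix, diagnostics


class HierarchicalDoGModel(BaseEstimator):
    """Hierarchical Bayesian DoG fit as an sklearn-style estimator.

    Parameters mirror :class:`HierarchicalSpec`; ``fit`` takes a tidy
    condition-summary table (columns: participant, report_type,
    [time_point,] bin_center, and the value column).

    Attributes
    ----------
    posterior_ : PosteriorMatrix
    diagnostics_ : FitDiagnostics
    summary_ : pandas.DataFrame
        Per report type (and time point): posterior mean amplitude, HDI
        bounds, sign verdict, and R-hat.
    """

    def __init__(self, levels: int = 3, n_chains: int = 4,
                 n_warmup: int | None = None, n_samples: int | None = None,
                 priors: Priors | None = None, share_w: str = "cell",
                 value_col: str | None = None, random_state: int = 0):
        self.levels = levels
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_samples = n_samples
        self.priors = priors
        self.share_w = share_w
        self.value_col = value_col
        self.random_state = random_state

    def _spec(self) -> HierarchicalSpec:
        return HierarchicalSpec(
            levels=self.levels, n_chains=self.n_chains, n_warmup=self.n_warmup,
            n_samples=self.n_samples, priors=self.priors or Priors(),
            share_w=self.share_w, seed=self.random_state,
        )

    def fit(self, X: pd.DataFrame, y=None):
        spec = self._spec()
        value_col = self.value_col or ("error_deg" if spec.levels == 3 else "mean_dev")
        data, bins, participants, report_types, time_points = _prepare_matrix(
            X, value_col, spec.levels
        )
        per_chain = spec.n_samples // spec.n_chains
        warm_chain = max(spec.n_warmup // spec.n_chains, 1)
        if per_chain * spec.n_chains != spec.n_samples:
            raise ValueError("n_samples must be divisible by n_chains")
        root = np.random.default_rng(spec.seed)
        chain_keep = [
            _run_chain(data, bins, spec.priors, spec.share_w, warm_chain, per_chain, rng)
            for rng in root.spawn(spec.n_chains)
        ]
        self.posterior_, self.diagnostics_ = _diagnose(
            chain_keep, participants, report_types, time_points
        )
        self.summary_ = posterior_summary(self.posterior_, self.diagnostics_)
        self.n_features_in_ = data.shape[-1]
        return self

    def score(self, X=None, y=None):
        """Negative max population R-hat (higher is better-converged)."""
        return -self.diagnostics_.max_rhat


def posterior_summary(matrix: PosteriorMatrix, diagnostics: FitDiagnostics | None = None,
                      mass: float = 0.95) -> pd.DataFrame:
    """Headline amplitude summaries per report type (and time point).

    The population amplitude is the participant-marginalized mean of the
    cell-level draws; the verdict records whether its HDI excludes zero
    ({credibly negative, inconclusive, credibly positive}).
    """
    marg = matrix.marginal_alpha()
    rows = []

    def _verdict(lo, hi):
        if hi < 0:
            return "credibly negative"
        if lo > 0:
            return "credibly positive"
        return "inconclusive"

    if matrix.time_points is None:
        for c, rt in enumerate(matrix.report_types):
            lo, hi = compute_hdi(marg[:, c], mass)
            key = f"alpha_pop[{rt}]"
            rows.append({
                "report_type": rt, "mean": float(marg[:, c].mean()),
                "hdi_low": lo, "hdi_high": hi, "verdict": _verdict(lo, hi),
                "rhat": diagnostics.rhat.get(key, float("nan")) if diagnostics else float("nan"),
            })
    else:
        for j, rt in enumerate(matrix.report_types):
            for t, tp in enumerate(matrix.time_points):
                lo, hi = compute_hdi(marg[:, j, t], mass)
                key = f"alpha_pop[{rt}@t{tp:g}]"
                rows.append({
                    "report_type": rt, "time_point": tp,
                    "mean": float(marg[:, j, t].mean()),
                    "hdi_low": lo, "hdi_high": hi, "verdict": _verdict(lo, hi),
                    "rhat": diagnostics.rhat.get(key, float("nan")) if diagnostics else float("nan"),
                })
    return pd.DataFrame(rows)


def participant_alpha_means(matrix: PosteriorMatrix) -> pd.DataFrame:
    """Posterior-mean amplitude per participant x report type (three-level)."""
    if matrix.time_points is not None:
        raise ValueError("participant amplitudes are reported for three-level fits")
    means = matrix.draws["alpha"].mean(axis=0)
    return pd.DataFrame(means, index=pd.Index(matrix.participants, name="participant"),
                        columns=matrix.report_types)


def fit_hbm3(summaries: pd.DataFrame, spec: HierarchicalSpec | None = None,
             value_col: str = "error_deg"):
    """Three-level hierarchical DoG fit of condition summaries.

    Returns ``(PosteriorMatrix, FitDiagnostics)``.
    """
    spec = spec or HierarchicalSpec(levels=3)
    est = HierarchicalDoGModel(
        levels=3, n_chains=spec.n_chains, n_warmup=spec.n_warmup,
        n_samples=spec.n_samples, priors=spec.priors, share_w=spec.share_w,
        value_col=value_col, random_state=spec.seed,
    ).fit(summaries)
    return est.posterior_, est.diagnostics_


def fit_hbm4(profiles: pd.DataFrame, spec: HierarchicalSpec | None = None,
             value_col: str = "mean_dev"):
    """Four-level (x time point) hierarchical DoG fit of deviation profiles."""
    spec = spec or HierarchicalSpec(levels=4)
    est = HierarchicalDoGModel(
        levels=4, n_chains=spec.n_chains, n_warmup=spec.n_warmup,
        n_samples=spec.n_samples, priors=spec.priors, share_w=spec.share_w,
        value_col=value_col, random_state=spec.seed,
    ).fit(profiles)
    return est.posterior_, est.diagnostics_
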