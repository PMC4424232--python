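"""Maximum simulated likelihood estimation of logit-family choice models.

Families
--------
``mnl``
    Multinomial logit with fixed coefficients (closed-form probabilities).
``rpl``
    Random parameters (mixed) logit: beta_i = beta + delta z_i + Gamma v_i
    with normal mixing, panel likelihood over each respondent's tasks.
``gmxl``
    Generalized mixed logit adding a log-normal individual scale factor
    sigma_i = exp(sigma_bar + tau w_i) and the weighting parameter gamma:
    beta_i = sigma_i (beta + delta z_i) + (gamma + sigma_i (1 - gamma)) Gamma v_i.
    sigma_bar is normalized to -tau^2/2 so E[sigma_i] = 1.
``gmxl_wtp``
    The same process reparameterised in WTP-space: non-price coefficients
    are money-denominated willingness-to-pay values theta multiplied by a
    positive price/scale coefficient beta_c, and the price coefficient is
    -sigma_i beta_c.

The simulated likelihood uses Halton draws (consecutive blocks per
respondent, first 10 points discarded, normal quantile transform), a
numerically stable log-sum-exp evaluation with a 1e-300 probability
floor, and analytic gradients for all families.  Internal transforms keep
tau >= 0 (exp) and gamma in (0, 1) (logistic) during optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .choice_data import ChoiceDataset, DataValidationError, sdc_dummies

logger = logging.getLogger(__name__)

_PRIMES = (
    2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61, 67,
    71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113,
)
_BURN = 10  # leading Halton points discarded
_LOG_FLOOR = np.log(1e-300)

FAMILIES = ("mnl", "rpl", "gmxl", "gmxl_wtp")


# ---------------------------------------------------------------------------
# Halton draws


def _radical_inverse(indices: np.ndarray, base: int) -> np.ndarray:
    idx = np.asarray(indices, dtype=np.int64).copy()
    out = np.zeros(idx.shape)
    f = 1.0 / base
    while idx.any():
        out += f * (idx % base)
        idx //= base
        f /= base
    return out


def halton_sequence(n: int, base: int) -> np.ndarray:
    """First ``n`` Halton points in ``base`` after the burn-in discard."""
    return _radical_inverse(np.arange(1 + _BURN, n + 1 + _BURN), base)


@dataclass(frozen=True)
class DrawSet:
    """Standard-normal quasi-random draws for simulated likelihood.

    ``v`` has shape (n_resp, n_draws, n_dims) for the random coefficients;
    ``w`` has shape (n_resp, n_draws) and supplies the scale dimension for
    GMXL families.  Draws are generated once per fit and reused across all
    optimizer iterations (panel structure).
    """

    v: np.ndarray
    w: np.ndarray
    seed: int

    @property
    def n_resp(self) -> int:
        return self.v.shape[0]

    @property
    def n_draws(self) -> int:
        return self.v.shape[1]

    @property
    def n_dims(self) -> int:
        return self.v.shape[2]


def halton_draws(n_resp: int, n_draws: int, n_dims: int, seed: int = 0) -> DrawSet:
    """Halton-based standard normal draws in respondent blocks.

    One Halton dimension (prime base) per random coefficient plus one for
    the GMXL scale draw; consecutive blocks of ``n_draws`` points are
    assigned to respondents.  The sequence is deterministic; ``seed`` is
    recorded for provenance and downstream reuse.
    """
    if n_resp < 1 or n_draws < 1 or n_dims < 1:
        raise ValueError("all draw-set sizes must be >= 1")
    if n_dims + 1 > len(_PRIMES):
        raise ValueError(f"at most {len(_PRIMES) - 1} random dimensions supported")
    total = n_resp * n_draws
    cols = [halton_sequence(total, _PRIMES[d]) for d in range(n_dims + 1)]
    u = np.column_stack(cols)
    z = stats.norm.ppf(u)
    z = z.reshape(n_resp, n_draws, n_dims + 1)
    return DrawSet(v=np.ascontiguousarray(z[:, :, :n_dims]), w=np.ascontiguousarray(z[:, :, n_dims]), seed=seed)


# ---------------------------------------------------------------------------
# Model specification and panel arrays


@dataclass(frozen=True)
class ModelSpec:
    """Estimation configuration.

    ``sdc`` selects the respondent dummies whose interactions with the
    design columns enter the model (empty tuple for none).  ``random_set``
    selects the columns with random coefficients; ``None`` means all
    design columns (in WTP-space the price column is never random: its
    randomness comes from the scale factor alone).
    """

    family: str = "rpl"
    correlated: bool = False
    sdc: tuple = ()
    random_set: tuple | None = None
    n_draws: int = 500
    draw_type: str = "halton"
    seed: int = 0
    gamma_mode: str = "free"  # "free" | "fixed"
    gamma_fixed: float = 0.0
    price_column: str = "price"
    maxiter: int = 1000
    gtol: float = 1e-5

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.gamma_mode not in ("free", "fixed"):
            raise ValueError("gamma_mode must be 'free' or 'fixed'")
        if self.draw_type != "halton":
            raise ValueError("only Halton draws are supported")


@dataclass
class Panel:
    """Rectangular array view of a validated ChoiceDataset."""

    X: np.ndarray  # (I, T, J, K) coded design columns, zeros for the opt-out
    optout: np.ndarray  # (I, T, J) bool
    chosen: np.ndarray  # (I, T) alternative index
    Z: pd.DataFrame  # SDC dummies indexed by respondent order
    respondent_ids: list
    column_names: list

    @property
    def n_resp(self):
        return self.X.shape[0]

    @property
    def n_tasks(self):
        return self.X.shape[1]

    @property
    def n_alts(self):
        return self.X.shape[2]

    @property
    def n_cols(self):
        return self.X.shape[3]


def build_panel(dataset: ChoiceDataset) -> Panel:
    """Reshape a long-format dataset into rectangular panel arrays.

    Requires a complete panel (same task count per respondent, same
    alternative count per task) — guaranteed for generated data and
    verified here for file input.
    """
    obs = dataset.obs
    i_idx, resp_ids = pd.factorize(obs["respondent_id"])
    pair = pd.MultiIndex.from_arrays([obs["respondent_id"], obs["task_id"]])
    tc, _ = pair.factorize()
    first = pd.DataFrame({"tc": tc, "i": i_idx}).drop_duplicates("tc").set_index("tc")
    first["t"] = first.groupby("i").cumcount()
    t_of_tc = first["t"].to_numpy()
    t_idx = t_of_tc[tc]
    j_idx = pd.Series(range(len(obs))).groupby(tc, sort=False).cumcount().to_numpy()

    I = len(resp_ids)
    T = t_idx.max() + 1
    J = j_idx.max() + 1
    counts = np.bincount(i_idx, minlength=I)
    if not np.all(counts == T * J):
        short = [resp_ids[k] for k in np.flatnonzero(counts != T * J)[:5]]
        raise DataValidationError(f"incomplete panel for respondents {short}")

    K = dataset.schema.n_columns
    X = np.zeros((I, T, J, K))
    X[i_idx, t_idx, j_idx] = dataset.coded
    optout = np.zeros((I, T, J), dtype=bool)
    optout[i_idx, t_idx, j_idx] = obs["optout"].to_numpy(dtype=bool)
    chosen = np.zeros((I, T), dtype=int)
    ch = obs["chosen"].to_numpy(dtype=bool)
    chosen[i_idx[ch], t_idx[ch]] = j_idx[ch]
    Z = sdc_dummies(dataset.respondents).reindex(resp_ids)
    return Panel(
        X=X,
        optout=optout,
        chosen=chosen,
        Z=Z,
        respondent_ids=list(resp_ids),
        column_names=dataset.schema.column_names,
    )


# ---------------------------------------------------------------------------
# Parameter bundle and packing


@dataclass
class ParamBundle:
    """Structural parameters on the natural (reported) scale.

    For ``gmxl_wtp``, ``beta`` holds the MK-denominated WTP means theta
    for non-price columns (the price slot is unused) and ``bc`` the
    positive price/scale coefficient; the preference-space price
    coefficient is -bc.
    """

    beta: np.ndarray
    asc: float = 0.0
    delta: np.ndarray | None = None  # (K, M)
    chol: np.ndarray | None = None  # (K, K) lower triangular, embedded
    tau: float | None = None
    gamma: float | None = None
    bc: float | None = None

    def implied_sd(self) -> np.ndarray | None:
        """Per-coefficient standard deviation implied by the Cholesky factor
        (Euclidean norm of each row)."""
        if self.chol is None:
            return None
        return np.sqrt((self.chol**2).sum(axis=1))


class _Layout:
    """Maps the flat optimizer vector to a ParamBundle and back.

    Internal transforms: tau = exp(t), gamma = logistic(g), bc = exp(b).
    Linear parameters are internally rescaled by the magnitude of their
    design column (the raw-MK price column otherwise makes the problem
    badly conditioned); ``unpack`` always returns natural-scale values.
    """

    def __init__(self, spec: ModelSpec, panel: Panel):
        self.spec = spec
        self.K = panel.n_cols
        self.M = len(spec.sdc)
        names = panel.column_names
        if spec.family == "gmxl_wtp" and spec.price_column not in names:
            raise ValueError(f"WTP-space needs a {spec.price_column!r} design column")
        self.price_idx = names.index(spec.price_column) if spec.price_column in names else None
        if spec.random_set is None:
            rand = list(range(self.K))
        else:
            bad = [c for c in spec.random_set if c not in names]
            if bad:
                raise ValueError(f"random_set columns not in design: {bad}")
            rand = sorted(names.index(c) for c in spec.random_set)
        if spec.family == "gmxl_wtp" and self.price_idx in rand:
            rand = [k for k in rand if k != self.price_idx]
        self.rand_idx = np.array(rand, dtype=int)
        self.mean_idx = (
            np.array([k for k in range(self.K) if k != self.price_idx], dtype=int)
            if spec.family == "gmxl_wtp"
            else np.arange(self.K)
        )

        mixed = spec.family in ("rpl", "gmxl", "gmxl_wtp")
        nr = len(self.rand_idx)
        if mixed and spec.correlated and nr < 2:
            raise ValueError("correlated fits need at least two random coefficients")
        self.n_chol = 0
        if mixed:
            self.n_chol = nr * (nr + 1) // 2 if spec.correlated else nr
        self.tril = np.tril_indices(nr)

        sizes = {
            "beta": len(self.mean_idx),
            "asc": 1,
            "delta": len(self.mean_idx) * self.M,
            "chol": self.n_chol,
        }
        if spec.family in ("gmxl", "gmxl_wtp"):
            sizes["tau"] = 1
            if spec.gamma_mode == "free":
                sizes["gamma"] = 1
        if spec.family == "gmxl_wtp":
            sizes["bc"] = 1
        self.slices = {}
        off = 0
        for key, sz in sizes.items():
            if sz:
                self.slices[key] = slice(off, off + sz)
                off += sz
        self.n_params = off

        # internal conditioning: scale linear entries by their column magnitude
        col_scale = np.maximum(1.0, np.abs(panel.X).max(axis=(0, 1, 2)))
        self.theta_scale = np.ones(self.n_params)
        if spec.family == "gmxl_wtp":
            row_scale = np.full(self.K, col_scale[self.price_idx])
        else:
            row_scale = 1.0 / col_scale
        self.theta_scale[self.slices["beta"]] = row_scale[self.mean_idx]
        if self.M:
            self.theta_scale[self.slices["delta"]] = np.repeat(row_scale[self.mean_idx], self.M)
        if self.n_chol:
            if spec.correlated:
                self.theta_scale[self.slices["chol"]] = row_scale[self.rand_idx][self.tril[0]]
            else:
                self.theta_scale[self.slices["chol"]] = row_scale[self.rand_idx]

    def unpack(self, theta: np.ndarray) -> ParamBundle:
        spec, K = self.spec, self.K
        theta = theta * self.theta_scale
        beta = np.zeros(K)
        beta[self.mean_idx] = theta[self.slices["beta"]]
        asc = float(theta[self.slices["asc"]][0])
        delta = None
        if self.M:
            delta = np.zeros((K, self.M))
            delta[self.mean_idx] = theta[self.slices["delta"]].reshape(len(self.mean_idx), self.M)
        chol = None
        if self.n_chol:
            nr = len(self.rand_idx)
            small = np.zeros((nr, nr))
            if spec.correlated:
                small[self.tril] = theta[self.slices["chol"]]
            else:
                small[np.diag_indices(nr)] = theta[self.slices["chol"]]
            chol = np.zeros((K, K))
            chol[np.ix_(self.rand_idx, self.rand_idx)] = small
        tau = gamma = bc = None
        if spec.family in ("gmxl", "gmxl_wtp"):
            tau = float(np.exp(theta[self.slices["tau"]][0]))
            gamma = (
                float(special.expit(theta[self.slices["gamma"]][0]))
                if spec.gamma_mode == "free"
                else float(spec.gamma_fixed)
            )
        if spec.family == "gmxl_wtp":
            bc = float(np.exp(theta[self.slices["bc"]][0]))
        return ParamBundle(beta=beta, asc=asc, delta=delta, chol=chol, tau=tau, gamma=gamma, bc=bc)

    def pack(self, p: ParamBundle) -> np.ndarray:
        theta = np.zeros(self.n_params)
        theta[self.slices["beta"]] = p.beta[self.mean_idx]
        theta[self.slices["asc"]] = p.asc
        if self.M:
            d = p.delta if p.delta is not None else np.zeros((self.K, self.M))
            theta[self.slices["delta"]] = d[self.mean_idx].reshape(-1)
        if self.n_chol:
            small = (p.chol if p.chol is not None else np.zeros((self.K, self.K)))[
                np.ix_(self.rand_idx, self.rand_idx)
            ]
            if self.spec.correlated:
                theta[self.slices["chol"]] = small[self.tril]
            else:
                theta[self.slices["chol"]] = np.diag(small)
        if "tau" in self.slices:
            theta[self.slices["tau"]] = np.log(max(p.tau if p.tau is not None else 0.1, 1e-8))
        if "gamma" in self.slices:
            g = min(max(p.gamma if p.gamma is not None else 0.5, 1e-6), 1 - 1e-6)
            theta[self.slices["gamma"]] = special.logit(g)
        if "bc" in self.slices:
            theta[self.slices["bc"]] = np.log(max(p.bc if p.bc is not None else 1e-3, 1e-12))
        return theta / self.theta_scale


# ---------------------------------------------------------------------------
# Individual coefficient simulation


def simulate_beta_i(
    params: ParamBundle,
    draws: DrawSet | None,
    Z: np.ndarray,
    family: str,
    rand_idx: np.ndarray | None = None,
    price_idx: int | None = None,
):
    """Per-respondent, per-draw coefficient arrays for a parameter bundle.

    Returns ``(beta_i, sigma, mix, gv)`` where ``beta_i`` has shape
    (I, R, K); ``sigma`` and ``mix`` are (I, R) scale and mixing weights
    (ones for MNL/RPL); ``gv`` is the (scaled) Gamma v_i component.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if params.tau is not None and params.tau < 0:
        raise ValueError("tau must be >= 0")
    if params.gamma is not None and not 0 <= params.gamma <= 1:
        raise ValueError("gamma must lie in [0, 1]")
    K = len(params.beta)
    I = Z.shape[0] if Z is not None and Z.ndim == 2 else (draws.n_resp if draws else 1)
    R = draws.n_draws if draws is not None and family != "mnl" else 1
    if rand_idx is None:
        rand_idx = np.arange(K)

    mean = np.broadcast_to(params.beta, (I, K)).copy()
    if params.delta is not None and Z is not None and Z.size:
        mean = mean + Z @ params.delta.T
    ones = np.ones((I, R))

    gv = np.zeros((I, R, K))
    if params.chol is not None and family != "mnl":
        nr = len(rand_idx)
        if draws.n_dims < nr:
            raise ValueError(f"draw set has {draws.n_dims} dims, need {nr}")
        small = params.chol[np.ix_(rand_idx, rand_idx)]
        gv[:, :, rand_idx] = np.einsum("kl,irl->irk", small, draws.v[:, :R, :nr])

    if family == "mnl":
        return mean[:, None, :], ones, ones, gv
    if family == "rpl":
        return mean[:, None, :] + gv, ones, ones, gv
    # gmxl / gmxl_wtp
    tau, gamma = params.tau or 0.0, params.gamma or 0.0
    sigma = np.exp(-(tau**2) / 2 + tau * draws.w[:, :R])
    mix = gamma + sigma * (1 - gamma)
    if family == "gmxl":
        return sigma[:, :, None] * mean[:, None, :] + mix[:, :, None] * gv, sigma, mix, gv
    # WTP-space: beta slot for price unused; price coefficient is -sigma*bc
    bc = params.bc
    if bc is None or price_idx is None:
        raise ValueError("WTP-space needs bc and a price column")
    gv = bc * gv
    beta_i = bc * sigma[:, :, None] * mean[:, None, :] + mix[:, :, None] * gv
    beta_i[:, :, price_idx] = -sigma * bc
    return beta_i, sigma, mix, gv


# ---------------------------------------------------------------------------
# Likelihood core


def _loglik_core(p: ParamBundle, panel: Panel, spec: ModelSpec, draws: DrawSet | None, layout: _Layout, want_grad: bool):
    Z = panel.Z[list(spec.sdc)].to_numpy(dtype=float) if spec.sdc else np.zeros((panel.n_resp, 0))
    if spec.sdc and np.isnan(Z).any():
        bad = [panel.respondent_ids[i] for i in np.flatnonzero(np.isnan(Z).any(axis=1))[:5]]
        raise DataValidationError(f"missing SDC values for respondents {bad}")
    beta_i, sigma, mix, gv = simulate_beta_i(
        p, draws, Z, spec.family, rand_idx=layout.rand_idx, price_idx=layout.price_idx
    )
    I, R, K = beta_i.shape
    T, J = panel.n_tasks, panel.n_alts

    V = np.einsum("itjk,irk->irtj", panel.X, beta_i, optimize=True)
    V = V + p.asc * panel.optout[:, None, :, :]
    if not np.all(np.isfinite(V)):
        bad = np.argwhere(~np.isfinite(V))[0]
        raise FloatingPointError(f"non-finite utility at (resp, draw, task, alt)={tuple(bad)}")
    Vmax = V.max(axis=3, keepdims=True)
    eV = np.exp(V - Vmax)
    denom = eV.sum(axis=3)
    logP = (V - Vmax) - np.log(denom)[:, :, :, None]

    ch = panel.chosen  # (I, T)
    logPc = np.take_along_axis(logP, ch[:, None, :, None], axis=3)[:, :, :, 0]  # (I,R,T)
    n_floored = int((logPc < _LOG_FLOOR).sum())
    if n_floored:
        logger.warning("floored %d simulated log-probabilities at 1e-300", n_floored)
        logPc = np.maximum(logPc, _LOG_FLOOR)
    logProd = logPc.sum(axis=2)  # (I, R)
    m = logProd.max(axis=1, keepdims=True)
    li = m[:, 0] + np.log(np.mean(np.exp(logProd - m), axis=1))
    ll = float(li.sum())
    if not want_grad:
        return ll, None, n_floored

    # draw weights
    omega = np.exp(logProd - m)
    omega /= omega.sum(axis=1, keepdims=True)  # (I, R)

    P = eV / denom[:, :, :, None]  # (I,R,T,J)
    xbar = np.einsum("irtj,itjk->irtk", P, panel.X, optimize=True)
    xch = np.take_along_axis(
        panel.X, ch[:, :, None, None].repeat(K, axis=3), axis=2
    )[:, :, 0, :]  # (I,T,K)
    s = (xch[:, None, :, :] - xbar).sum(axis=2)  # (I,R,K)
    opt_ch = np.take_along_axis(panel.optout, ch[:, :, None], axis=2)[:, :, 0]  # (I,T) bool
    P_opt = (P * panel.optout[:, None, :, :]).sum(axis=3)  # (I,R,T)
    a = opt_ch.sum(axis=1)[:, None] - P_opt.sum(axis=2)  # (I,R)

    grad = np.zeros(layout.n_params)
    fam = spec.family
    ridx = layout.rand_idx
    # scale applied to the mean-coefficient block
    if fam in ("mnl", "rpl"):
        wmean = omega  # (I,R)
    elif fam == "gmxl":
        wmean = omega * sigma
    else:
        wmean = omega * sigma * p.bc
    s_mean = s[:, :, layout.mean_idx]
    grad[layout.slices["beta"]] = np.einsum("ir,irk->k", wmean, s_mean)
    grad[layout.slices["asc"]] = float((omega * a).sum())
    if layout.M:
        grad[layout.slices["delta"]] = np.einsum("ir,irk,im->km", wmean, s_mean, Z).reshape(-1)
    if layout.n_chol:
        nr = len(ridx)
        wchol = omega * mix if fam in ("gmxl",) else omega
        if fam == "gmxl_wtp":
            wchol = omega * mix * p.bc
        s_r = s[:, :, ridx]
        v = draws.v[:, :R, :nr]
        if spec.correlated:
            G = np.einsum("ir,irk,irl->kl", wchol, s_r, v, optimize=True)
            grad[layout.slices["chol"]] = G[layout.tril]
        else:
            grad[layout.slices["chol"]] = np.einsum("ir,irk,irk->k", wchol, s_r, v, optimize=True)
    if "tau" in layout.slices:
        tau = p.tau
        dsig = draws.w[:, :R] - tau  # d log sigma / d tau
        # d beta_i/d tau = (w - tau) * (beta_i - gamma * gv)  [gv already bc-scaled for WTP]
        u = beta_i - (p.gamma or 0.0) * gv
        g_tau = float(np.einsum("ir,ir,irk->", omega, dsig, s * u, optimize=True))
        grad[layout.slices["tau"]] = g_tau * tau  # chain rule through tau = exp(t)
    if "gamma" in layout.slices:
        gamma = p.gamma
        dmix = 1.0 - sigma  # d mix / d gamma
        g_gam = float(np.einsum("ir,ir,irk->", omega, dmix, s * gv, optimize=True))
        grad[layout.slices["gamma"]] = g_gam * gamma * (1 - gamma)
    if "bc" in layout.slices:
        # beta_i is proportional to bc, so d ll/d log bc = sum omega s . beta_i
        grad[layout.slices["bc"]] = float(np.einsum("ir,irk->", omega, s * beta_i, optimize=True))
    grad *= layout.theta_scale  # chain rule through the internal conditioning
    return ll, grad, n_floored


def loglik_sml(
    params: ParamBundle,
    dataset: ChoiceDataset | Panel,
    draws: DrawSet | None,
    family: str = "rpl",
    spec: ModelSpec | None = None,
) -> float:
    """Simulated panel log-likelihood at ``params``.

    The product of a respondent's task probabilities is taken inside the
    draw average: sum_i log( (1/R) sum_r prod_t P(chosen | beta_ir) ).
    """
    panel = dataset if isinstance(dataset, Panel) else build_panel(dataset)
    if spec is None:
        M = 0 if params.delta is None else params.delta.shape[1]
        spec = ModelSpec(family=family, sdc=tuple(f"z{m}" for m in range(M)), correlated=True)
        if M:
            zcols = panel.Z.columns[:M]
            spec = replace(spec, sdc=tuple(zcols))
    layout = _Layout(spec, panel)
    ll, _, _ = _loglik_core(params, panel, spec, draws, layout, want_grad=False)
    return ll


def loglik_mnl(beta, asc, dataset: ChoiceDataset | Panel, delta=None, sdc: tuple = ()) -> float:
    """Multinomial logit log-likelihood with opt-out ASC (closed form)."""
    panel = dataset if isinstance(dataset, Panel) else build_panel(dataset)
    p = ParamBundle(beta=np.asarray(beta, dtype=float), asc=float(asc), delta=delta)
    spec = ModelSpec(family="mnl", sdc=tuple(sdc))
    return loglik_sml(p, panel, None, family="mnl", spec=spec)


# ---------------------------------------------------------------------------
# Fit results


@dataclass
class FitResult:
    """Estimated parameter bundle with fit statistics.

    ``params.beta`` is in utility units for preference-space families and
    in MK (WTP) for the WTP-space family.  ``se``, ``pvalues`` and
    ``cov`` are populated by :func:`std_errors`.
    """

    spec: ModelSpec
    params: ParamBundle
    theta: np.ndarray
    loglik: float
    k_params: int
    n_obs: int
    n_respondents: int
    converged: bool
    n_iter: int
    message: str
    column_names: list
    n_floored: int = 0
    sample_mean_sigma: float | None = None
    se: dict | None = None
    pvalues: dict | None = None
    cov: np.ndarray | None = None
    notes: list = field(default_factory=list)
    start: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return 2 * self.k_params - 2 * self.loglik

    def implied_sd(self):
        return self.params.implied_sd()


def aic(fit: FitResult) -> float:
    """Akaike information criterion, 2K - 2LL."""
    return 2 * fit.k_params - 2 * fit.loglik


def significance_stars(p: float) -> str:
    """Table convention: *** p<0.01, ** p<0.05, * p<0.1."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Fitting


def _identify_columns(panel: Panel) -> None:
    # variation is judged among service alternatives; opt-out rows are
    # structural zeros and carry no attribute information
    X = np.where(panel.optout[:, :, :, None], np.nan, panel.X)
    varies = np.zeros(panel.n_cols, dtype=bool)
    with np.errstate(all="ignore"):
        for k in range(panel.n_cols):
            within = np.nanmax(X[:, :, :, k], axis=2) - np.nanmin(X[:, :, :, k], axis=2)
            varies[k] = bool(np.nansum(within > 0) > 0)
    if not varies.all():
        names = [panel.column_names[k] for k in np.flatnonzero(~varies)]
        raise DataValidationError(
            f"design columns never vary within a task (not identified): {names}"
        )


def _minimize(fun, theta0, spec):
    res = optimize.minimize(
        fun,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": spec.maxiter,
            "maxfun": 5 * spec.maxiter,
            "ftol": 1e-11,
            "gtol": spec.gtol,
        },
    )
    return res


def fit_mnl(dataset: ChoiceDataset | Panel, sdc: tuple = (), spec: ModelSpec | None = None) -> FitResult:
    """Fit the multinomial logit by maximum likelihood from a zero start."""
    panel = dataset if isinstance(dataset, Panel) else build_panel(dataset)
    _identify_columns(panel)
    spec = spec or ModelSpec(family="mnl", sdc=tuple(sdc))
    if spec.family != "mnl":
        spec = replace(spec, family="mnl")
    layout = _Layout(spec, panel)

    state = {"floored": 0}

    def fun(theta):
        ll, grad, nf = _loglik_core(layout.unpack(theta), panel, spec, None, layout, True)
        state["floored"] += nf
        return -ll, -grad

    theta0 = np.zeros(layout.n_params)
    res = _minimize(fun, theta0, spec)
    p = layout.unpack(res.x)
    return FitResult(
        spec=spec,
        params=p,
        theta=res.x,
        loglik=-float(res.fun),
        k_params=layout.n_params,
        n_obs=panel.n_resp * panel.n_tasks,
        n_respondents=panel.n_resp,
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
        column_names=list(panel.column_names),
        n_floored=state["floored"],
        start=theta0,
    )


def fit_mixed(dataset: ChoiceDataset | Panel, spec: ModelSpec) -> FitResult:
    """Fit RPL / GMXL / WTP-space GMXL by maximum simulated likelihood.

    Start values come from the corresponding MNL fit (WTP-space starts
    map the MNL coefficients through the ratio with the price
    coefficient), with small positive Cholesky diagonals.  A fit that
    exhausts the iteration cap is returned flagged ``converged=False``.
    """
    panel = dataset if isinstance(dataset, Panel) else build_panel(dataset)
    if spec.family == "mnl":
        return fit_mnl(panel, spec=spec)
    _identify_columns(panel)
    layout = _Layout(spec, panel)
    draws = halton_draws(panel.n_resp, spec.n_draws, len(layout.rand_idx), seed=spec.seed)

    mnl = fit_mnl(panel, sdc=spec.sdc)
    p0 = ParamBundle(
        beta=mnl.params.beta.copy(),
        asc=mnl.params.asc,
        delta=None if mnl.params.delta is None else mnl.params.delta.copy(),
        chol=np.eye(panel.n_cols) * 0.1,
        tau=0.2,
        gamma=spec.gamma_fixed if spec.gamma_mode == "fixed" else 0.5,
        bc=None,
    )
    if spec.family == "gmxl_wtp":
        bp = mnl.params.beta[layout.price_idx]
        bc0 = max(abs(bp), 1e-4)
        p0.bc = bc0
        p0.beta = mnl.params.beta / bc0
        p0.beta[layout.price_idx] = 0.0
        if p0.delta is not None:
            p0.delta = p0.delta / bc0
        p0.chol = np.eye(panel.n_cols) * (0.1 / bc0)
    theta0 = layout.pack(p0)

    state = {"floored": 0}

    def fun(theta):
        ll, grad, nf = _loglik_core(layout.unpack(theta), panel, spec, draws, layout, True)
        state["floored"] += nf
        return -ll, -grad

    res = _minimize(fun, theta0, spec)
    p = layout.unpack(res.x)
    sample_mean_sigma = None
    notes = []
    if spec.family in ("gmxl", "gmxl_wtp"):
        sigma = np.exp(-(p.tau**2) / 2 + p.tau * draws.w)
        sample_mean_sigma = float(sigma.mean())
        if spec.gamma_mode == "free" and (p.gamma < 0.01 or p.gamma > 0.99):
            notes.append(
                f"weighting parameter gamma pinned near the boundary ({p.gamma:.4f}); "
                "the fit is effectively the GMNL-II limit (gamma -> 0) or GMNL-I (gamma -> 1)"
            )
    if not res.success:
        logger.warning("fit did not converge: %s", res.message)
    return FitResult(
        spec=spec,
        params=p,
        theta=res.x,
        loglik=-float(res.fun),
        k_params=layout.n_params,
        n_obs=panel.n_resp * panel.n_tasks,
        n_respondents=panel.n_resp,
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
        column_names=list(panel.column_names),
        n_floored=state["floored"],
        sample_mean_sigma=sample_mean_sigma,
        notes=notes,
        start=theta0,
    )


# ---------------------------------------------------------------------------
# Inference and fit statistics


def _report_scale_jacobian(layout: _Layout, theta: np.ndarray) -> np.ndarray:
    """Diagonal Jacobian from the raw optimizer scale to the reported scale
    (linear entries carry the internal conditioning factor; tau, gamma and
    bc are estimated on transformed axes)."""
    d = layout.theta_scale.copy()
    if "tau" in layout.slices:
        d[layout.slices["tau"]] = np.exp(theta[layout.slices["tau"]])
    if "gamma" in layout.slices:
        g = special.expit(theta[layout.slices["gamma"]])
        d[layout.slices["gamma"]] = g * (1 - g)
    if "bc" in layout.slices:
        d[layout.slices["bc"]] = np.exp(theta[layout.slices["bc"]])
    return d


def std_errors(fit: FitResult, dataset: ChoiceDataset | Panel, draws: DrawSet | None = None) -> FitResult:
    """Standard errors from the numerically differentiated Hessian.

    The Hessian of the negative (simulated) log-likelihood is obtained by
    central differences of the analytic gradient; the covariance is its
    inverse, mapped to the reported parameter scale by the delta method.
    P-values use the normal approximation.
    """
    panel = dataset if isinstance(dataset, Panel) else build_panel(dataset)
    spec = fit.spec
    layout = _Layout(spec, panel)
    if draws is None and spec.family != "mnl":
        draws = halton_draws(panel.n_resp, spec.n_draws, len(layout.rand_idx), seed=spec.seed)

    def grad_at(theta):
        _, g, _ = _loglik_core(layout.unpack(theta), panel, spec, draws, layout, True)
        return -g

    n = layout.n_params
    H = np.zeros((n, n))
    h = 1e-4 * np.maximum(1.0, np.abs(fit.theta))
    for j in range(n):
        tp, tm = fit.theta.copy(), fit.theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        H[:, j] = (grad_at(tp) - grad_at(tm)) / (2 * h[j])
    H = (H + H.T) / 2
    try:
        cov_raw = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        fit.notes.append("Hessian not invertible; covariance omitted")
        return fit
    diag = np.diag(cov_raw)
    if np.any(diag <= 0):
        fit.notes.append("Hessian not positive definite; covariance omitted")
        return fit
    d = _report_scale_jacobian(layout, fit.theta)
    cov = cov_raw * np.outer(d, d)
    se_vec = np.sqrt(np.diag(cov))

    # values on the reported scale, aligned with the layout vector
    rep = fit.theta * layout.theta_scale
    for key in ("tau", "gamma", "bc"):
        if key in layout.slices:
            rep[layout.slices[key]] = getattr(fit.params, key)

    se, pv = {}, {}
    for key, sl in layout.slices.items():
        se[key] = se_vec[sl].copy()
        z = rep[sl] / se_vec[sl]
        pv[key] = 2 * stats.norm.sf(np.abs(z))
    # implied coefficient SDs and their delta-method SEs
    if layout.n_chol:
        nr = len(layout.rand_idx)
        sd_small = fit.params.implied_sd()[layout.rand_idx]
        Jsd = np.zeros((nr, layout.n_params))
        small = fit.params.chol[np.ix_(layout.rand_idx, layout.rand_idx)]
        if spec.correlated:
            rows, cols = layout.tril
            for e, (r, c) in enumerate(zip(rows, cols)):
                Jsd[r, layout.slices["chol"].start + e] = small[r, c] / max(sd_small[r], 1e-12)
        else:
            for r in range(nr):
                Jsd[r, layout.slices["chol"].start + r] = np.sign(small[r, r]) or 1.0
        cov_sd = Jsd @ cov @ Jsd.T
        se["sd"] = np.sqrt(np.maximum(np.diag(cov_sd), 0))
        pv["sd"] = 2 * stats.norm.sf(np.abs(sd_small / np.maximum(se["sd"], 1e-300)))
    fit.se, fit.pvalues, fit.cov = se, pv, cov
    return fit


def lr_test(fit_restricted, fit_general, df: int | None = None):
    """Likelihood-ratio test of nested fits: 2(LL_g - LL_r) ~ chi2(df)."""
    llr, llg = fit_restricted.loglik, fit_general.loglik
    kr, kg = fit_restricted.k_params, fit_general.k_params
    if df is None:
        df = kg - kr
    if df <= 0:
        raise ValueError(f"models not nested: K_general={kg} <= K_restricted={kr}")
    if llg < llr - 1e-6:
        raise ValueError(f"general model has lower log-likelihood ({llg:.4f} < {llr:.4f})")
    stat = 2 * (llg - llr)
    return stat, df, float(stats.chi2.sf(stat, df))


def predicted_probabilities(fit: FitResult, dataset: ChoiceDataset | Panel, draws: DrawSet | None = None) -> np.ndarray:
    """Draw-averaged choice probabilities, shape (I, T, J)."""
    panel = dataset if isinstance(dataset, Panel) else build_panel(dataset)
    spec = fit.spec
    layout = _Layout(spec, panel)
    if draws is None and spec.family != "mnl":
        draws = halton_draws(panel.n_resp, spec.n_draws, len(layout.rand_idx), seed=spec.seed)
    Z = panel.Z[list(spec.sdc)].to_numpy(dtype=float) if spec.sdc else np.zeros((panel.n_resp, 0))
    beta_i, *_ = simulate_beta_i(
        fit.params, draws, Z, spec.family, rand_idx=layout.rand_idx, price_idx=layout.price_idx
    )
    V = np.einsum("itjk,irk->irtj", panel.X, beta_i, optimize=True)
    V = V + fit.params.asc * panel.optout[:, None, :, :]
    V -= V.max(axis=3, keepdims=True)
    eV = np.exp(V)
    P = eV / eV.sum(axis=3, keepdims=True)
    return P.mean(axis=1)


def pct_correct(fit: FitResult, dataset: ChoiceDataset | Panel, draws: DrawSet | None = None) -> float:
    """Percent of tasks whose observed choice is the modal predicted
    alternative (ties broken to the lowest alternative index)."""
    panel = dataset if isinstance(dataset, Panel) else build_panel(dataset)
    P = predicted_probabilities(fit, panel, draws)
    pred = P.argmax(axis=2)  # argmax takes the first (lowest) index on ties
    return float(100.0 * (pred == panel.chosen).mean())
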