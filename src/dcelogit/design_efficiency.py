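"""D-efficiency evaluation of choice designs under the MNL model.

An efficient design minimises the determinant of the asymptotic
variance-covariance (AVC) matrix of the MNL estimator evaluated at prior
coefficient values.  The D-error is det(AVC)^(1/K) for K parameters;
Bayesian D-error averages the point D-error over draws from normal
priors.  Designs can be scored for the opt-out (ASC included) and
forced-choice variants and averaged across them, mirroring how designs
are optimised for several model specifications at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import halton_draws
from .synthetic_data import ChoiceDesign


@dataclass(frozen=True)
class PriorSpec:
    """Point or Bayesian (normal) priors for design evaluation.

    A zero / ``None`` standard deviation degenerates to the point prior.
    """

    mean: np.ndarray
    sd: np.ndarray | None = None
    n_draws: int = 100
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            if np.any(sd < 0):
                raise ValueError("prior standard deviations must be >= 0")
            object.__setattr__(self, "sd", sd)

    @property
    def is_bayesian(self) -> bool:
        return self.sd is not None and np.any(self.sd > 0)

    def draws(self) -> np.ndarray:
        """Prior draws (n_draws, K) via the same Halton machinery used in
        estimation, for reproducibility."""
        if not self.is_bayesian:
            return self.mean[None, :]
        ds = halton_draws(1, self.n_draws, len(self.mean), seed=self.seed)
        return self.mean + ds.v[0] * self.sd


def _task_matrices(design: ChoiceDesign, include_optout: bool) -> list[np.ndarray]:
    X = design.coded()  # (T, J, K)
    T, J, K = X.shape
    if not include_optout:
        return [X[t] for t in range(T)]
    out = []
    for t in range(T):
        rows = np.zeros((J + 1, K + 1))
        rows[:J, :K] = X[t]
        rows[J, K] = 1.0  # opt-out ASC column
        out.append(rows)
    return out


def mnl_information(
    design: ChoiceDesign, beta: np.ndarray, include_optout: bool = False
) -> np.ndarray:
    """MNL information matrix sum_t sum_j P_j (x_j - xbar)(x_j - xbar)^T.

    ``xbar`` is the probability-weighted mean profile within each task;
    the AVC matrix is the inverse of the returned matrix.  With
    ``include_optout`` an all-zero alternative with an ASC column is
    appended to every task (and ``beta`` must carry the ASC last).
    """
    beta = np.asarray(beta, dtype=float)
    mats = _task_matrices(design, include_optout)
    K = mats[0].shape[1]
    if beta.shape != (K,):
        raise ValueError(f"beta has length {len(beta)}, design has {K} parameter columns")
    info = np.zeros((K, K))
    for Xt in mats:
        v = Xt @ beta
        v -= v.max()
        p = np.exp(v)
        p /= p.sum()
        xbar = p @ Xt
        dev = Xt - xbar
        info += (dev * p[:, None]).T @ dev
    return info


def d_error(
    design: ChoiceDesign,
    priors: PriorSpec,
    include_optout: bool = False,
) -> float:
    """D-error det(AVC)^(1/K); lower is better.

    Bayesian priors return the average point D-error over seeded prior
    draws.  A singular information matrix (an attribute that never
    varies) yields the infinite-D-error sentinel rather than an exception.
    """
    total = 0.0
    draws = priors.draws()
    for beta in draws:
        info = mnl_information(design, beta, include_optout=include_optout)
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0 or not np.isfinite(logdet):
            return np.inf
        K = info.shape[0]
        total += np.exp(-logdet / K)
    return total / len(draws)


def select_efficient_design(
    schema,
    priors: PriorSpec,
    n_candidates: int = 50,
    n_tasks: int = 12,
    n_alts: int = 2,
    seed: int = 0,
    include_optout: bool = False,
):
    """Pick the lowest-D-error design among seeded balanced randomizations.

    A light-weight stand-in for a dedicated D-efficient design search:
    candidate designs come from :func:`~dcelogit.synthetic_data.generate_design`
    with consecutive sub-seeds and the one minimising :func:`d_error` under
    ``priors`` is returned together with its D-error.
    """
    from .synthetic_data import generate_design

    if n_candidates < 1:
        raise ValueError("need at least one candidate design")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(2**31, size=n_candidates)
    best, best_err = None, np.inf
    for s in sub_seeds:
        cand = generate_design(schema, n_tasks=n_tasks, n_alts=n_alts, seed=int(s))
        err = d_error(cand, priors, include_optout=include_optout)
        if err < best_err:
            best, best_err = cand, err
    return best, best_err


def average_efficiency(
    design: ChoiceDesign,
    variants: list[dict],
    priors: PriorSpec,
    weights: list[float] | None = None,
) -> float:
    """Weighted mean D-error across model variants.

    Each variant is a dict with keys ``include_optout`` (bool) and
    optionally ``priors`` (a PriorSpec overriding the default).  Weights
    default to equal.
    """
    if not variants:
        raise ValueError("need at least one model variant")
    if weights is None:
        weights = [1.0] * len(variants)
    if len(weights) != len(variants):
        raise ValueError("weights must match variants")
    wsum = float(sum(weights))
    if wsum <= 0:
        raise ValueError("weights must sum to a positive value")
    total = 0.0
    for w, var in zip(weights, variants):
        pr = var.get("priors", priors)
        total += w * d_error(design, pr, include_optout=var.get("include_optout", False))
    return total / wsum
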