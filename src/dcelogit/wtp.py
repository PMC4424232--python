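"""Willingness-to-pay estimation: preference-space ratios and WTP-space.

In preference space, mean WTP for an attribute is the ratio of its
marginal utility to the negative marginal disutility of price,
-beta_k / beta_price, in MK per coded unit.  Because both numerator and
denominator may be randomly distributed, the population distribution of
the ratio can be ill-behaved; population SDs are therefore obtained by
seeded simulation from the fitted mixing distribution rather than the
delta method.  WTP-space fits avoid the ratio entirely: their non-price
coefficients are read directly as MK-denominated WTP.

Note on coded units: categorical attributes are effects coded, so a move
from the base level (-1) to a non-base level (+1) is a two-unit change;
reported WTP follows the per-coded-unit convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .estimation import FitResult, significance_stars

#: Survey-period exchange rate: 1000 MK ~ USD 4.00 -> 0.004 USD per MK.
DEFAULT_RATE = 0.004


@dataclass(frozen=True)
class WTPEstimate:
    """Per-attribute willingness-to-pay in MK and converted currency."""

    column: str
    mean_mk: float
    sd_mk: float | None = None
    mean_usd: float | None = None
    sd_usd: float | None = None
    stars: str = ""


def convert_currency(amount_mk: float, rate: float = DEFAULT_RATE) -> float:
    """MK -> USD at ``rate`` USD per MK, rounded half-away-from-zero to 2 dp."""
    if rate <= 0:
        raise ValueError(f"exchange rate must be positive, got {rate}")
    raw = Decimal(repr(float(amount_mk) * rate))
    sign = -1 if raw < 0 else 1
    return float(sign * abs(raw).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def wtp_ratio(
    fit: FitResult,
    column: str,
    n_sim: int = 100_000,
    seed: int = 0,
    rate: float = DEFAULT_RATE,
) -> WTPEstimate:
    """Preference-space WTP for one design column, -beta_k / beta_price.

    The population SD is simulated: coefficient vectors are drawn from the
    fitted normal mixing distribution (correlation via the Cholesky factor
    when present) and the ratio computed per draw.  Ratio distributions
    with a random price coefficient may have no finite moments; the
    simulated SD is a descriptive summary and is reported with that caveat.
    """
    if fit.spec.family == "gmxl_wtp":
        raise ValueError("wtp_ratio applies to preference-space fits; use extract_wtp_space")
    names = fit.column_names
    if column not in names:
        raise KeyError(column)
    k = names.index(column)
    pidx = names.index(fit.spec.price_column)
    beta_k = fit.params.beta[k]
    beta_p = fit.params.beta[pidx]
    if abs(beta_p) < 1e-8:
        raise ZeroDivisionError("price coefficient is numerically zero; WTP undefined")
    mean = -beta_k / beta_p
    sd = None
    if fit.params.chol is not None:
        rng = np.random.default_rng(seed)
        v = rng.standard_normal((n_sim, len(names)))
        draws = fit.params.beta + v @ fit.params.chol.T
        denom = draws[:, pidx]
        ok = np.abs(denom) > 1e-12
        ratios = -draws[ok, k] / denom[ok]
        sd = float(ratios.std())
    p = None
    if fit.pvalues is not None:
        p = float(fit.pvalues["beta"][k])
    return WTPEstimate(
        column=column,
        mean_mk=float(mean),
        sd_mk=sd,
        mean_usd=convert_currency(mean, rate),
        sd_usd=None if sd is None else convert_currency(sd, rate),
        stars="" if p is None else significance_stars(p),
    )


def _mean_cols(fit: FitResult) -> list[int]:
    names = fit.column_names
    if fit.spec.family == "gmxl_wtp":
        pidx = names.index(fit.spec.price_column)
        return [k for k in range(len(names)) if k != pidx]
    return list(range(len(names)))


def extract_wtp_space(fit: FitResult, rate: float = DEFAULT_RATE) -> list[WTPEstimate]:
    """Read MK-denominated WTP directly from a WTP-space fit.

    The mean and implied SD of each non-price coefficient are the WTP
    distribution; price is normalised to 1 in WTP-space and the
    preference-space-form price coefficient -beta_c is reported through
    ``fit.params.bc``.
    """
    if fit.spec.family != "gmxl_wtp":
        raise ValueError("extract_wtp_space requires a WTP-space fit")
    names = fit.column_names
    sds = fit.params.implied_sd()
    out = []
    mean_cols = _mean_cols(fit)
    for pos, k in enumerate(mean_cols):
        p = None if fit.pvalues is None else float(fit.pvalues["beta"][pos])
        sd = None if sds is None else float(sds[k])
        out.append(
            WTPEstimate(
                column=names[k],
                mean_mk=float(fit.params.beta[k]),
                sd_mk=sd,
                mean_usd=convert_currency(fit.params.beta[k], rate),
                sd_usd=None if sd is None else convert_currency(sd, rate),
                stars="" if p is None else significance_stars(p),
            )
        )
    return out


def wtp_table(estimates: list[WTPEstimate], rate: float = DEFAULT_RATE) -> str:
    """Readable WTP table in MK and USD (rate shown in the caption)."""
    lines = [
        f"WTP per coded unit (MK and USD at {rate} USD/MK)",
        f"{'attribute':<28}{'mean MK':>12}{'SD MK':>12}{'mean USD':>10}{'SD USD':>10}  sig",
    ]
    for e in estimates:
        sd_mk = "" if e.sd_mk is None else f"{e.sd_mk:.2f}"
        sd_usd = "" if e.sd_usd is None else f"{e.sd_usd:.2f}"
        lines.append(
            f"{e.column:<28}{e.mean_mk:>12.2f}{sd_mk:>12}{e.mean_usd:>10.2f}{sd_usd:>10}  {e.stars}"
        )
    return "\n".join(lines)
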