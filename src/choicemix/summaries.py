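"""Posterior-derived preference economics.

All ratio statistics are summarized as posterior distributions of the
per-draw ratio (not ratios of posterior means), which is why plug-in
arithmetic on a table of posterior means differs slightly from the
interval-bearing summaries. Equal-tailed intervals are the default
"95% CI"; highest-posterior-density intervals are available for
interval plots. Quantiles interpolate linearly between order statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .model import PosteriorDraws

#: raw units per model unit for each coefficient (cattle modelled per
#: 100 head, small stock per 200, wage per 10,000 KSh)
COEFFICIENT_UNIT_SCALE = {"intercept": 1.0, "access": 1.0, "cattle": 100.0,
                          "cons150": 1.0, "cons75": 1.0, "cult": 1.0,
                          "smlstk": 200.0, "wage": 10000.0}


def interval(samples, kind: str = "equal-tailed", level: float = 0.95):
    """(lower, upper) posterior interval of ``samples``.

    ``equal-tailed``: the (alpha/2, 1-alpha/2) linear-interpolation
    quantiles. ``hpd``: the shortest contiguous window of the sorted
    sample containing ceil(level*n) points (ties: the lowest window).
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if kind in ("equal-tailed", "eti"):
        alpha = 1.0 - level
        lo, hi = np.quantile(x, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)
    if kind == "hpd":
        xs = np.sort(x)
        n = xs.size
        w = min(int(math.ceil(level * n)), n)
        widths = xs[w - 1:] - xs[:n - w + 1]
        i = int(np.argmin(widths))
        return float(xs[i]), float(xs[i + w - 1])
    raise ValueError(f"unknown interval kind {kind!r}")


def _group_z(draws: PosteriorDraws, group: dict | None) -> np.ndarray:
    """Map a raw covariate profile onto the model's covariate scale."""
    names = draws.covariate_names
    if group:
        unknown = set(group) - set(names)
        if unknown:
            raise KeyError(f"unknown covariate(s) {sorted(unknown)}; the fit "
                           f"used {list(names)}")
    z = np.zeros(len(names))
    for c, name in enumerate(names):
        center, scale = draws.covariate_transforms.get(name, (0.0, 1.0))
        raw = (group or {}).get(name, center)
        z[c] = (raw - center) / scale
    return z


def group_coefficient_draws(draws: PosteriorDraws, attribute: str,
                            group: dict | None = None) -> np.ndarray:
    """Per-draw group coefficient kappa = m_k + G_k . z at the profile."""
    k = draws.coef_index(attribute)
    kappa = draws.stacked("m")[:, k]
    if len(draws.covariate_names):
        kappa = kappa + draws.stacked("G")[:, k, :] @ _group_z(draws, group)
    return kappa


@dataclass
class SubstitutionSummary:
    """Cattle-head value of an attribute (or of one raw unit of it)."""
    attribute: str
    group: dict | None
    per_unit: bool
    mean: float
    interval: tuple
    level: float
    samples: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        lo, hi = self.interval
        if lo > hi:
            raise ValueError("interval endpoints out of order")


def substitution_in_cattle(draws: PosteriorDraws, attribute: str,
                           group: dict | None = None, per_unit: bool = False,
                           level: float = 0.95) -> SubstitutionSummary:
    """Rate of substitution between an attribute and cattle, per draw.

    The per-head value of cattle in a draw is kappa_cattle / 100 (the
    coefficient is per 100 head). ``per_unit`` divides the attribute's
    coefficient by its own unit scale first (e.g. small stock per head
    rather than per 200 head).
    """
    kappa = group_coefficient_draws(draws, attribute, group)
    cattle = group_coefficient_draws(draws, "cattle", group)
    per_head = cattle / COEFFICIENT_UNIT_SCALE["cattle"]
    if np.mean(np.abs(cattle) < 1e-6) > 0.01:
        warnings.warn("cattle coefficient has posterior mass near zero; "
                      "substitution ratio is unstable", stacklevel=2)
    value = kappa / COEFFICIENT_UNIT_SCALE[attribute] if per_unit else kappa
    ratio = value / per_head
    return SubstitutionSummary(attribute=attribute, group=group,
                               per_unit=per_unit, mean=float(ratio.mean()),
                               interval=interval(ratio, level=level),
                               level=level, samples=ratio)


@dataclass
class ShareSummary:
    """Posterior percentage of individuals with a negative coefficient."""
    attribute: str
    group: dict | None
    mean: float
    interval: tuple
    level: float
    excluded_draws: int
    samples: np.ndarray = field(repr=False, default=None)


def share_with_negative_value(draws: PosteriorDraws, attribute: str,
                              group: dict | None = None,
                              level: float = 0.95) -> ShareSummary:
    """Percentage of the population placing negative value on an attribute.

    Per draw the coefficient distribution across individuals is
    Normal(kappa, s_k^2), so the share is Phi(-kappa / s_k) * 100.
    Draws with s_k <= 0 are excluded and counted (cannot occur in fitted
    draws; guards hand-built ones).
    """
    k = draws.coef_index(attribute)
    kappa = group_coefficient_draws(draws, attribute, group)
    s = draws.stacked("s")[:, k]
    ok = s > 0
    share = ndtr(-kappa[ok] / s[ok]) * 100.0
    if share.size == 0:
        raise ValueError(f"no draws with positive sd for {attribute!r}")
    return ShareSummary(attribute=attribute, group=group,
                        mean=float(share.mean()),
                        interval=interval(share, level=level), level=level,
                        excluded_draws=int((~ok).sum()), samples=share)


@dataclass
class CorrelationSummary:
    pair: tuple
    mean: float
    interval: tuple
    level: float
    samples: np.ndarray = field(repr=False, default=None)


def random_coefficient_correlation(draws: PosteriorDraws, attr_a: str,
                                   attr_b: str,
                                   level: float = 0.95) -> CorrelationSummary:
    """Posterior of the correlation between two random coefficients."""
    if "R" not in draws.params:
        raise ValueError("draws carry no correlation matrix")
    a, b = draws.coef_index(attr_a), draws.coef_index(attr_b)
    rho = draws.stacked("R")[:, a, b]
    return CorrelationSummary(pair=(attr_a, attr_b), mean=float(rho.mean()),
                              interval=interval(rho, level=level), level=level,
                              samples=rho)


def combine_group_coefficients(draws: PosteriorDraws, group: dict | None = None,
                               level: float = 0.95) -> pd.DataFrame:
    """Per-attribute coefficient summaries at a covariate profile.

    The all-zero (baseline) profile reproduces the population-mean
    summaries; e.g. with sex and membership covariates the baseline is
    the male non-member column of a group table.
    """
    rows = []
    for name in draws.coefficient_names:
        kappa = group_coefficient_draws(draws, name, group)
        lo, hi = interval(kappa, level=level)
        rows.append({"parameter": name, "mean": float(kappa.mean()),
                     "lower": lo, "upper": hi})
    return pd.DataFrame(rows)


def coefficient_table(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Population-mean and random-sd summaries, one row per coefficient."""
    m = draws.stacked("m")
    s = draws.stacked("s")
    rows = []
    for k, name in enumerate(draws.coefficient_names):
        m_lo, m_hi = interval(m[:, k], level=level)
        s_lo, s_hi = interval(s[:, k], level=level)
        rows.append({"parameter": name,
                     "mean": float(m[:, k].mean()), "mean_lower": m_lo,
                     "mean_upper": m_hi,
                     "sd": float(s[:, k].mean()), "sd_lower": s_lo,
                     "sd_upper": s_hi})
    return pd.DataFrame(rows)


def write_summary_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Delimited-text summary table plus a full-precision JSON variant."""
    df.to_csv(path, index=False, float_format=float_format)
    json_path = str(path)
    json_path = json_path[:-4] + ".json" if json_path.endswith(".csv") else json_path + ".json"
    df.to_json(json_path, orient="records", indent=2)


def plot_intervals(df: pd.DataFrame, path, value: str = "mean",
                   lower: str = "lower", upper: str = "upper") -> None:
    """Simple point-and-interval display of a summary table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1))
    ypos = np.arange(len(df))[::-1]
    ax.hlines(ypos, df[lower], df[upper], color="0.4")
    ax.plot(df[value], ypos, "o", color="crimson")
    ax.axvline(0.0, color="0.8", lw=1, zorder=0)
    ax.set_yticks(ypos)
    ax.set_yticklabels(df["parameter"])
    ax.set_xlabel("posterior mean and interval")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
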