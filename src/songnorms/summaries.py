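"""Posterior summaries: credible intervals, probability of direction,
covariance-to-correlation transforms and posterior contrasts.

An estimate is flagged significant when its 95% equal-tailed credible
interval excludes zero. The probability of direction (pd) is the
proportion of posterior draws sharing the sign of the posterior median; it
maps to a two-sided frequentist p-value analog as ``2 * (1 - pd)``.
Variance components cannot cross zero, so their summaries additionally
report the posterior mass below a small negligible-variance threshold as a
reproducible stand-in for inspecting the whole posterior distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ContrastResult:
    """Posterior summary of a scalar quantity."""

    label: str
    mean: float
    ci_low: float
    ci_high: float
    pd: float
    p_two_sided_analog: float
    significant: bool
    n_dropped: int = 0

    def as_dict(self) -> dict:
        return {
            "label": self.label, "estimate": self.mean,
            "CI_low": self.ci_low, "CI_high": self.ci_high,
            "pd": self.pd, "p_two_sided": self.p_two_sided_analog,
            "significant": self.significant,
        }


def credible_interval(samples, level: float = 0.95,
                      min_samples: int = 100) -> tuple[float, float]:
    """Equal-tailed quantile interval (linear-interpolation quantiles)."""
    x = np.asarray(samples, dtype=float)
    if x.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {x.size}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [tail, 1.0 - tail])
    return float(lo), float(hi)


def probability_of_direction(samples) -> tuple[float, float]:
    """Proportion of draws with the median's sign; exact zeros split evenly.

    Returns ``(pd, p_two_sided_analog)`` with ``pd`` in [0.5, 1] and the
    two-sided analog ``2 * (1 - pd)``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("probability_of_direction needs a non-empty sample")
    frac_pos = float(np.mean(x > 0) + 0.5 * np.mean(x == 0))
    pd_val = max(frac_pos, 1.0 - frac_pos)
    return pd_val, 2.0 * (1.0 - pd_val)


def summarize(samples, label: str = "", level: float = 0.95,
              min_samples: int = 100, n_dropped: int = 0) -> ContrastResult:
    """Full :class:`ContrastResult` for one posterior sample vector."""
    x = np.asarray(samples, dtype=float)
    lo, hi = credible_interval(x, level=level, min_samples=min_samples)
    pd_val, p_analog = probability_of_direction(x)
    return ContrastResult(
        label=label, mean=float(x.mean()), ci_low=lo, ci_high=hi,
        pd=pd_val, p_two_sided_analog=p_analog,
        significant=bool(lo > 0 or hi < 0), n_dropped=n_dropped,
    )


def cov_to_correlation(cov_draws, varA_draws, varB_draws,
                       label: str = "", level: float = 0.95
                       ) -> tuple[np.ndarray, ContrastResult]:
    """Per-draw correlation ``cov / sqrt(varA * varB)`` plus its summary.

    Draws must be aligned by iteration. Draws with a non-positive variance
    are dropped and counted in ``ContrastResult.n_dropped``.
    """
    cov = np.asarray(cov_draws, dtype=float)
    va = np.asarray(varA_draws, dtype=float)
    vb = np.asarray(varB_draws, dtype=float)
    if not (cov.shape == va.shape == vb.shape):
        raise ValueError("draw vectors must be aligned (equal lengths)")
    ok = (va > 0) & (vb > 0)
    r = cov[ok] / np.sqrt(va[ok] * vb[ok])
    res = summarize(r, label=label, level=level, n_dropped=int((~ok).sum()))
    return r, res


def variance_contrast(samplesA, samplesB, label: str = "",
                      level: float = 0.95) -> ContrastResult:
    """Posterior of the difference A − B between two aligned draw vectors."""
    a = np.asarray(samplesA, dtype=float)
    b = np.asarray(samplesB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("draw vectors must be aligned (equal lengths)")
    return summarize(a - b, label=label, level=level, min_samples=1)


def negligible_variance_mass(var_draws, threshold: float = 0.01) -> float:
    """Posterior mass of a variance component below ``threshold`` (z-scale).

    A reproducible proxy for visual inspection of a variance posterior:
    values near 1 indicate the component is effectively zero.
    """
    x = np.asarray(var_draws, dtype=float)
    if x.size == 0:
        raise ValueError("empty draw vector")
    return float(np.mean(x < threshold))


def summarize_fixed_effects(draws, level: float = 0.95) -> pd.DataFrame:
    """One row per (trait, term): estimate, CI, pd and significance flag."""
    rows = []
    for trait in draws.traits:
        for term in draws.x_columns:
            res = summarize(draws.beta_draws(term, trait),
                            label=f"{trait}:{term}", level=level)
            rows.append({"trait": trait, "term": term, **res.as_dict()})
    return pd.DataFrame(rows).drop(columns="label")


def summarize_random_effects(draws, level: float = 0.95,
                             negligible_threshold: float = 0.01) -> pd.DataFrame:
    """Variances and covariances of every context block, year and residual.

    Variance rows carry the below-threshold posterior mass instead of a
    significance flag (variance CIs cannot cross zero); covariance rows are
    flagged like any other contrast.
    """
    rows = []
    t_labels = draws.traits
    e_labels = draws.random_effects
    k = len(e_labels) * len(t_labels)

    def block_label(i):
        return f"{e_labels[i // len(t_labels)]}({t_labels[i % len(t_labels)]})"

    for ctx, g in draws.G.items():
        flat = g.reshape(-1, k, k)
        for i in range(k):
            for j in range(i, k):
                x = flat[:, i, j]
                is_var = i == j
                res = summarize(x, level=level)
                rows.append({
                    "component": f"G[{ctx}]",
                    "element": (block_label(i) if is_var
                                else f"{block_label(i)} x {block_label(j)}"),
                    "kind": "variance" if is_var else "covariance",
                    "estimate": res.mean, "CI_low": res.ci_low,
                    "CI_high": res.ci_high, "pd": res.pd,
                    "p_two_sided": res.p_two_sided_analog,
                    "significant": None if is_var else res.significant,
                    "mass_below_threshold": (
                        negligible_variance_mass(x, negligible_threshold)
                        if is_var else None),
                })
    extras = {"R_resid": draws.R}
    if draws.V_year is not None:
        extras["V_year"] = draws.V_year
    for name, arr in extras.items():
        nt = arr.shape[-1]
        flat = arr.reshape(-1, nt, nt)
        for i in range(nt):
            for j in range(i, nt):
                x = flat[:, i, j]
                is_var = i == j
                res = summarize(x, level=level)
                rows.append({
                    "component": name,
                    "element": (t_labels[i] if is_var
                                else f"{t_labels[i]} x {t_labels[j]}"),
                    "kind": "variance" if is_var else "covariance",
                    "estimate": res.mean, "CI_low": res.ci_low,
                    "CI_high": res.ci_high, "pd": res.pd,
                    "p_two_sided": res.p_two_sided_analog,
                    "significant": None if is_var else res.significant,
                    "mass_below_threshold": (
                        negligible_variance_mass(x, negligible_threshold)
                        if is_var else None),
                })
    return pd.DataFrame(rows)
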