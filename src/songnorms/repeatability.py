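"""Repeatability of reaction-norm slopes across repeated recordings.

Two-step procedure for birds recorded twice in the same social context:

1. Fit the random-regression model separately to the first and to the
   second recordings of the repeated-measures cohort (restricted to the
   random terms found variable in the main analysis) and extract, per
   individual and recording, the full posterior sample vector of the
   individual slope for a chosen (trait, gradient, context) combination.
2. Using the slope draws as the response, fit a univariate random-intercept
   model with recording order as a fixed factor and individual identity as
   a random effect — by default one fit per posterior draw index, pooling
   the results (a single fit on the stacked draw-level dataset is available
   behind a flag). Repeatability is the posterior of
   ``R = V_individual / (V_individual + V_residual)``.

Because stage-2 response rows are posterior draws rather than independent
measurements, R is a pragmatic, procedure-defined estimator, not a
likelihood-exact one; see the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (ChainConfig, ModelSpec, PosteriorDraws, PriorConfig,
                    build_design, gibbs_sample)

logger = logging.getLogger("songnorms")


@dataclass
class SlopePosterior:
    """Per-individual slope draws for both recordings of one target.

    ``draws`` has shape (n_individuals, 2, n_draws); axis 1 indexes the
    recording order (first, second).
    """

    trait: str
    gradient: str
    context: str
    individual_ids: tuple[str, ...]
    draws: np.ndarray

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[1] != 2:
            raise ValueError("draws must have shape (n_individuals, 2, n_draws)")
        if self.draws.shape[0] != len(self.individual_ids):
            raise ValueError("draws and individual_ids disagree")


@dataclass
class RepeatabilityResult:
    """Posterior summary of the slope-repeatability ratio."""

    trait: str
    gradient: str
    context: str
    R_mean: float
    CI_low: float
    CI_high: float
    n_individuals: int
    n_songs: int
    R_draws: np.ndarray

    def as_dict(self) -> dict:
        return {
            "trait": self.trait, "gradient": self.gradient,
            "context": self.context, "R_mean": self.R_mean,
            "CI_low": self.CI_low, "CI_high": self.CI_high,
            "n_individuals": self.n_individuals, "n_songs": self.n_songs,
        }


def repeatability_from_draws(v_ind, v_res) -> np.ndarray:
    """Per-draw ratio of among-individual to total variance, in [0, 1]."""
    v_ind = np.asarray(v_ind, dtype=float)
    v_res = np.asarray(v_res, dtype=float)
    if v_ind.shape != v_res.shape:
        raise ValueError("aligned draw vectors required")
    total = v_ind + v_res
    out = np.zeros_like(v_ind)
    nz = total > 0
    out[nz] = v_ind[nz] / total[nz]
    return out


def filter_repeated_same_context(recordings: pd.DataFrame) -> pd.DataFrame:
    """Individuals whose first two recordings share a social context.

    ``recordings`` needs one row per recording with ``individual_id``,
    ``recording_id``, ``context`` and a date ordering (``year`` + ``date``
    if available, else ``date``). Returns the first two recordings of each
    retained individual with ``recording_order`` re-assigned 1/2 by date;
    recordings beyond the second are ignored. May be empty.
    """
    df = recordings.copy()
    sort_cols = [c for c in ("year", "date") if c in df.columns]
    if not sort_cols:
        raise ValueError("recordings need a 'date' (and optionally 'year') column")
    df = df.sort_values(["individual_id", *sort_cols], kind="mergesort")
    first_two = df.groupby("individual_id", sort=False).head(2).copy()
    counts = first_two.groupby("individual_id")["recording_id"].transform("count")
    first_two = first_two[counts == 2]
    same = first_two.groupby("individual_id")["context"].transform("nunique") == 1
    kept = first_two[same].copy()
    kept["recording_order"] = kept.groupby("individual_id").cumcount() + 1
    return kept.reset_index(drop=True)


def _stage1_spec(trait: str, random_slopes: tuple[str, ...],
                 prior: PriorConfig) -> ModelSpec:
    # single-context cohort: no context fixed terms; random intercept plus
    # the slopes found variable in the main analysis
    return ModelSpec(
        responses=(trait,),
        fixed_terms=("intercept", "date", "age", "order", "position"),
        random_effects=("intercept", *random_slopes),
        include_year=True,
        prior=prior,
    )


def stage1_extract_slopes(
    songs: pd.DataFrame,
    cohort: pd.DataFrame,
    trait: str,
    gradient: str,
    context: str,
    chains: ChainConfig,
    prior: PriorConfig | None = None,
    random_slopes: tuple[str, ...] = ("order", "position"),
) -> tuple[SlopePosterior, tuple[PosteriorDraws, PosteriorDraws]]:
    """Fit first- and second-recording models and extract slope draws.

    ``cohort`` is the output of :func:`filter_repeated_same_context`. Only
    individuals recorded twice in ``context`` enter; individuals missing
    from either fit are excluded with a warning. ``random_slopes`` lists the
    slopes found variable in the main analysis (both gradients by default);
    the target ``gradient`` must be among them. Returns the paired slope
    posterior and the two underlying fits.
    """
    if gradient not in ("order", "position"):
        raise ValueError("gradient must be 'order' or 'position'")
    if gradient not in random_slopes:
        raise ValueError("the target gradient must be one of random_slopes")
    prior = prior or PriorConfig()
    cohort_ctx = cohort[cohort["context"] == context]
    spec = _stage1_spec(trait, random_slopes, prior)

    fits: list[PosteriorDraws] = []
    for rec_order in (1, 2):
        recs = cohort_ctx[cohort_ctx["recording_order"] == rec_order]
        data = songs.merge(
            recs[["individual_id", "recording_id"]], on=["individual_id",
                                                         "recording_id"])
        if data.empty:
            raise ValueError(f"no songs for recording order {rec_order} "
                             f"in context {context!r}")
        design = build_design(data, spec, first_recording_only=False)
        fits.append(gibbs_sample(design, spec, chains))

    ids = sorted(set(fits[0].ind_ids) & set(fits[1].ind_ids))
    lost = set(fits[0].ind_ids) ^ set(fits[1].ind_ids)
    if lost:
        logger.warning("individuals missing from one stage-1 fit: %s",
                       sorted(lost))
    if not ids:
        raise ValueError("no individual present in both stage-1 fits")
    draws = np.stack([
        np.stack([fit.slope_draws(i, gradient, trait) for fit in fits], axis=0)
        for i in ids
    ])
    return SlopePosterior(trait=trait, gradient=gradient, context=context,
                          individual_ids=tuple(ids), draws=draws), tuple(fits)


def stage2_repeatability(
    slopes: SlopePosterior,
    chains: ChainConfig,
    prior: PriorConfig | None = None,
    method: str = "per_draw",
    n_songs: int = 0,
    per_draw_subsample: int = 100,
) -> RepeatabilityResult:
    """Stage-2 fit: slope draws as responses, recording order fixed,
    individual identity random; R = V_individual / (V_individual + V_resid).

    ``method='per_draw'`` (default) repeats the stage-2 model across
    posterior draw indices (an evenly spaced subsample of
    ``per_draw_subsample`` indices for tractability) and pools the R draws.
    ``method='stacked'`` instead fits once on the full stacked draw-level
    dataset; stacking is faster but pseudo-replicates the response rows,
    which deflates the residual variance and biases R upward — it is kept
    for comparison, not inference (see the methods note).
    """
    n_ind, _, n_draws = slopes.draws.shape
    if n_ind < 4:
        raise ValueError(f"need >= 4 individuals with both recordings, got {n_ind}")
    prior = prior or PriorConfig()
    spec = ModelSpec(
        responses=("slope",),
        fixed_terms=("intercept", "order"),
        random_effects=("intercept",),
        include_year=False,
        prior=prior,
    )

    def fit_stack(draw_idx: np.ndarray, fit_chains: ChainConfig) -> np.ndarray:
        sub = slopes.draws[:, :, draw_idx]           # (n_ind, 2, m)
        m = len(draw_idx)
        ind = np.repeat(slopes.individual_ids, 2 * m)
        rec = np.tile(np.repeat([1, 2], m), n_ind)
        data = pd.DataFrame({
            "individual_id": ind,
            "context": slopes.context,
            "song_order": rec,            # recording order as the fixed factor
            "slope": sub.reshape(-1),
            "age": 0, "date": 0, "year": 0, "position": 0.0,
        })
        design = build_design(data, spec, first_recording_only=False)
        fit = gibbs_sample(design, spec, fit_chains, compute_log_posterior=False)
        v_ind = fit.g_draws(slopes.context, "intercept", "slope")
        v_res = fit.residual_draws("slope")
        return repeatability_from_draws(v_ind, v_res)

    if method == "stacked":
        r_draws = fit_stack(np.arange(n_draws), chains)
    elif method == "per_draw":
        take = min(per_draw_subsample, n_draws)
        picks = np.linspace(0, n_draws - 1, take).astype(int)
        per_fit = ChainConfig(1_500, 500, 10, n_chains=1, seed=chains.seed)
        r_draws = np.concatenate([
            fit_stack(np.array([idx]),
                      ChainConfig(per_fit.n_iterations, per_fit.burn_in,
                                  per_fit.thin, 1,
                                  seed=(chains.seed + 7919 * j) % (2**31 - 1)))
            for j, idx in enumerate(picks)])
    else:
        raise ValueError("method must be 'stacked' or 'per_draw'")

    lo, hi = np.quantile(r_draws, [0.025, 0.975])
    return RepeatabilityResult(
        trait=slopes.trait, gradient=slopes.gradient, context=slopes.context,
        R_mean=float(r_draws.mean()), CI_low=float(lo), CI_high=float(hi),
        n_individuals=n_ind, n_songs=int(n_songs), R_draws=r_draws,
    )


def slope_repeatability(
    songs: pd.DataFrame,
    recordings: pd.DataFrame,
    trait: str,
    gradient: str,
    context: str,
    chains: ChainConfig,
    prior: PriorConfig | None = None,
    method: str = "stacked",
) -> RepeatabilityResult:
    """End-to-end two-step repeatability for one target combination."""
    cohort = filter_repeated_same_context(recordings)
    slopes, _ = stage1_extract_slopes(songs, cohort, trait, gradient, context,
                                      chains, prior=prior)
    cohort_ctx = cohort[cohort["context"] == context]
    n_songs = int(songs.merge(
        cohort_ctx[["individual_id", "recording_id"]],
        on=["individual_id", "recording_id"]).shape[0])
    return stage2_repeatability(slopes, chains, prior=prior, method=method,
                                n_songs=n_songs)
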