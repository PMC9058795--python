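"""Bayesian random-regression (reaction-norm) mixed models via blocked Gibbs.

Fits uni- or bivariate linear mixed models of z-scored song traits with

* fixed effects: intercept, date, age, song order, singing position,
  social-context contrasts against the male-stimulus reference, and
  order-by-context interactions (each response gets its own coefficients);
* random effects: per social context, an individual block containing a
  random intercept and random slopes over z(order) and z(position) with a
  full within-context covariance matrix (cross-trait covariances included
  in the bivariate case; cross-context covariances structurally zero),
  plus a year intercept block and a cross-trait residual covariance.

The sampler is a blocked Gibbs scheme: (i) one *joint* multivariate-normal
draw of all location effects (fixed + year + individual) given the
covariance components, computed exactly by Schur-complement elimination of
the individual blocks and a matched perturbation of the right-hand side;
(ii) conjugate inverse-Wishart draws of every covariance block; (iii) under
the parameter-expanded prior family, a working-parameter (redundant
multiplicative) update per random block that rescales the block and its
covariance, which greatly improves mixing when variance components are
near zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .synthetic import CONTEXTS
from .traits import z_transform

logger = logging.getLogger("songnorms")

DEFAULT_FIXED_TERMS = ("intercept", "date", "age", "order", "position",
                       "context", "order:context")
DEFAULT_RANDOM_EFFECTS = ("intercept", "order", "position")

#: the published chain settings: 510,000 iterations, 10,000 burn-in,
#: thinning 500 -> exactly 1000 retained draws from a single chain.
PAPER_CHAIN_SETTINGS = (510_000, 10_000, 500)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run lengths. ``retained = floor((n_iterations - burn_in)/thin)``."""

    n_iterations: int
    burn_in: int = 0
    thin: int = 1
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.burn_in >= self.n_iterations:
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    def require_inference(self, minimum: int = 100) -> "ChainConfig":
        if self.retained < minimum:
            raise ValueError(
                f"chain retains {self.retained} draws; need >= {minimum} for inference")
        return self

    @classmethod
    def paper_faithful(cls, seed: int = 0) -> "ChainConfig":
        n_it, burn, thin = PAPER_CHAIN_SETTINGS
        return cls(n_it, burn, thin, n_chains=1, seed=seed)

    @classmethod
    def fast(cls, seed: int = 0, n_chains: int = 4) -> "ChainConfig":
        return cls(6_000, 1_000, 5, n_chains=n_chains, seed=seed)


def retained_samples(chains: ChainConfig) -> int:
    """Number of posterior draws kept per chain."""
    return chains.retained


@dataclass(frozen=True)
class PriorConfig:
    """Priors for the variance components and fixed effects.

    ``family`` selects between the parameter-expanded prior (inverse-Wishart
    on the working covariance, scale ``g_scale * I``, df defaulting to the
    block dimension, with independent N(0, ``alpha_var``) working
    parameters) and a plain inverse-Wishart prior on each block (identity
    scale times ``g_scale``, df defaulting to the block dimension). Fixed
    effects are independent N(0, ``beta_prior_var``); ``None`` means an
    improper flat prior.
    """

    family: str = "parameter_expanded"
    g_scale: float = 1.0
    g_df: float | None = None
    alpha_var: float = 1000.0
    beta_prior_var: float | None = 1e8
    r_scale: float = 1.0
    r_df: float | None = None
    year_scale: float = 1.0
    year_df: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("parameter_expanded", "inverse_wishart"):
            raise ValueError(f"unknown prior family {self.family!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description compiled by :func:`build_design`."""

    responses: tuple[str, ...]
    fixed_terms: tuple[str, ...] = DEFAULT_FIXED_TERMS
    random_effects: tuple[str, ...] = DEFAULT_RANDOM_EFFECTS
    include_year: bool = True
    include_individual: bool = True
    prior: PriorConfig = field(default_factory=PriorConfig)
    fix_residual: tuple[tuple[float, ...], ...] | None = None
    reference_context: str = "male"

    def __post_init__(self) -> None:
        if not 1 <= len(self.responses) <= 2:
            raise ValueError("1 or 2 response traits supported")
        if self.reference_context != "male":
            raise ValueError("the reference context is 'male'")

    @property
    def n_traits(self) -> int:
        return len(self.responses)

    def fixed_residual_matrix(self) -> np.ndarray | None:
        if self.fix_residual is None:
            return None
        r = np.asarray(self.fix_residual, dtype=float)
        if r.shape != (self.n_traits, self.n_traits):
            raise ValueError("fix_residual must be n_traits x n_traits")
        return r


# ---------------------------------------------------------------------------
# design construction


@dataclass
class DesignMatrices:
    """Compiled response, fixed-effect and random-effect design structures.

    ``Y`` is the (n, T) z-scored response matrix; ``X`` the (n, p) fixed
    design shared across traits; ``U`` the (n, e) within-individual gradient
    design (columns ordered as ``random_effects``). ``ind_index`` maps each
    row to an individual (−1 when the individual's context block was
    dropped); ``ind_context`` gives each individual's context. Column order
    is deterministic and recorded in ``x_columns``.
    """

    Y: np.ndarray
    X: np.ndarray
    U: np.ndarray
    ind_index: np.ndarray
    ind_ids: tuple[str, ...]
    ind_context: np.ndarray
    contexts: tuple[str, ...]
    year_index: np.ndarray | None
    year_ids: tuple
    x_columns: tuple[str, ...]
    random_effects: tuple[str, ...]
    traits: tuple[str, ...]
    rows_dropped: dict

    @property
    def n_obs(self) -> int:
        return self.Y.shape[0]

    @property
    def n_traits(self) -> int:
        return self.Y.shape[1]

    @property
    def n_individuals(self) -> int:
        return len(self.ind_ids)

    @property
    def n_years(self) -> int:
        return len(self.year_ids)

    def individuals_in(self, context: str) -> np.ndarray:
        return np.flatnonzero(self.ind_context == context)

    def z_block(self, context: str, effect: str):
        """Sparse (n x n_individuals-in-context) random-effect design block."""
        from scipy import sparse

        e = self.random_effects.index(effect)
        members = self.individuals_in(context)
        col_of = {j: c for c, j in enumerate(members)}
        rows, cols, vals = [], [], []
        for i in range(self.n_obs):
            j = self.ind_index[i]
            if j in col_of:
                rows.append(i)
                cols.append(col_of[j])
                vals.append(self.U[i, e])
        return sparse.csr_matrix((vals, (rows, cols)),
                                 shape=(self.n_obs, len(members)))


def build_design(
    songs: pd.DataFrame,
    spec: ModelSpec,
    first_recording_only: bool = True,
) -> DesignMatrices:
    """Compile a song table into model design structures.

    Keeps each individual's first recording (unless ``first_recording_only``
    is False), drops rows with missing covariates or responses (listwise,
    counted in ``rows_dropped``), z-transforms every continuous variable
    over the retained rows, dummy-codes context against the male reference
    (columns for contexts absent from the data are omitted), and forms
    order-by-context interaction columns as elementwise products of
    z(order) and the context dummies. Context blocks observed for fewer
    than two individuals are dropped with a warning.
    """
    df = songs.copy()
    dropped: dict[str, int] = {}

    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        raise ValueError(
            f"unknown context labels: {sorted(df.loc[bad_ctx, 'context'].unique())}")

    if first_recording_only and "recording_order" in df.columns:
        n0 = len(df)
        first = df.groupby("individual_id")["recording_order"].transform("min")
        df = df[df["recording_order"] == first]
        dropped["later_recordings"] = n0 - len(df)

    uses_position = ("position" in spec.fixed_terms
                     or "position" in spec.random_effects)
    needed = [*spec.responses]
    if "date" in spec.fixed_terms:
        needed.append("date")
    if ("order" in spec.fixed_terms or "order:context" in spec.fixed_terms
            or "order" in spec.random_effects):
        needed.append("song_order")
    if "age" in spec.fixed_terms:
        needed.append("age")
    if uses_position:
        needed.append("position")
    n0 = len(df)
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    dropped["missing_values"] = n0 - len(df)
    if dropped["missing_values"]:
        logger.info("dropped %d rows with missing covariates/responses",
                    dropped["missing_values"])
    if len(df) == 0:
        raise ValueError("no rows left after listwise deletion")
    df = df.reset_index(drop=True)
    n = len(df)

    uses_order = ("order" in spec.fixed_terms or "order:context" in spec.fixed_terms
                  or "order" in spec.random_effects)
    z_date = (z_transform(df["date"]) if "date" in spec.fixed_terms
              else np.zeros(n))
    z_order = (z_transform(df["song_order"]) if uses_order else np.zeros(n))
    z_pos = (z_transform(df["position"]) if uses_position else np.zeros(n))

    ctx = df["context"].to_numpy()
    present = [c for c in CONTEXTS if (ctx == c).any()]
    extra = [c for c in present if c != spec.reference_context]

    cols: list[str] = []
    parts: list[np.ndarray] = []
    for term in spec.fixed_terms:
        if term == "intercept":
            cols.append("intercept"); parts.append(np.ones(n))
        elif term == "date":
            cols.append("date"); parts.append(z_date)
        elif term == "age":
            cols.append("age"); parts.append(df["age"].to_numpy(float))
        elif term == "order":
            cols.append("order"); parts.append(z_order)
        elif term == "position":
            cols.append("position"); parts.append(z_pos)
        elif term == "context":
            for c in extra:
                cols.append(f"context_{c}"); parts.append((ctx == c).astype(float))
        elif term == "order:context":
            for c in extra:
                cols.append(f"order:context_{c}")
                parts.append(z_order * (ctx == c).astype(float))
        else:
            raise ValueError(f"unknown fixed term {term!r}")
    X = np.column_stack(parts) if parts else np.zeros((n, 0))

    u_parts = []
    for eff in spec.random_effects:
        if eff == "intercept":
            u_parts.append(np.ones(n))
        elif eff == "order":
            u_parts.append(z_order)
        elif eff == "position":
            u_parts.append(z_pos)
        else:
            raise ValueError(f"unknown random effect {eff!r}")
    U = np.column_stack(u_parts) if u_parts else np.zeros((n, 0))

    ind_ids_all, ind_codes = np.unique(df["individual_id"], return_inverse=True)
    ind_ctx = np.empty(len(ind_ids_all), dtype=object)
    ind_ctx[ind_codes] = ctx  # one context per individual (single recording)

    kept_contexts = []
    if spec.include_individual:
        for c in present:
            n_in = int((ind_ctx == c).sum())
            if n_in >= 2:
                kept_contexts.append(c)
            elif n_in > 0:
                warnings.warn(
                    f"context {c!r} has {n_in} individual(s); random block dropped",
                    UserWarning, stacklevel=2)
    keep_ind = np.isin(ind_ctx, kept_contexts)
    old_to_new = np.full(len(ind_ids_all), -1)
    old_to_new[keep_ind] = np.arange(int(keep_ind.sum()))
    ind_index = old_to_new[ind_codes]
    ind_ids = tuple(ind_ids_all[keep_ind])
    ind_context = ind_ctx[keep_ind].astype(str) if keep_ind.any() else np.array([], dtype=str)

    if spec.include_year:
        year_ids_arr, year_index = np.unique(df["year"], return_inverse=True)
        year_ids = tuple(year_ids_arr.tolist())
    else:
        year_index, year_ids = None, ()

    Y = np.column_stack([z_transform(df[r]) for r in spec.responses])

    return DesignMatrices(
        Y=Y, X=X, U=U,
        ind_index=ind_index, ind_ids=ind_ids, ind_context=ind_context,
        contexts=tuple(kept_contexts),
        year_index=year_index, year_ids=year_ids,
        x_columns=tuple(cols), random_effects=spec.random_effects,
        traits=tuple(spec.responses), rows_dropped=dropped,
    )


def prior_only_design(
    spec: ModelSpec,
    individuals_per_context: dict[str, int],
    n_years: int = 0,
) -> DesignMatrices:
    """A design with declared group levels but zero data rows.

    With no observations every full conditional collapses to its prior, so
    running the sampler on this design draws from the joint prior — used to
    check that the machinery reproduces analytic prior moments.
    """
    t = spec.n_traits
    e = len(spec.random_effects)
    ind_ids, ind_context = [], []
    for c, m in individuals_per_context.items():
        for j in range(m):
            ind_ids.append(f"{c}{j}")
            ind_context.append(c)
    return DesignMatrices(
        Y=np.zeros((0, t)),
        X=np.zeros((0, 0)),
        U=np.zeros((0, e)),
        ind_index=np.zeros(0, dtype=int),
        ind_ids=tuple(ind_ids),
        ind_context=np.asarray(ind_context, dtype=str),
        contexts=tuple(individuals_per_context),
        year_index=(np.zeros(0, dtype=int) if n_years else None),
        year_ids=tuple(range(n_years)),
        x_columns=(),
        random_effects=spec.random_effects,
        traits=tuple(spec.responses),
        rows_dropped={},
    )


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shaped ``(n_chains, n_draws, ...)``."""

    traits: tuple[str, ...]
    x_columns: tuple[str, ...]
    contexts: tuple[str, ...]
    ind_ids: tuple[str, ...]
    random_effects: tuple[str, ...]
    beta: np.ndarray                      # (C, S, p, T)
    G: dict[str, np.ndarray]              # context -> (C, S, k, k)
    V_year: np.ndarray | None             # (C, S, T, T)
    R: np.ndarray                         # (C, S, T, T)
    individual_effects: np.ndarray        # (C, S, n_ind, e, T)
    log_posterior: np.ndarray             # (C, S)
    chain_config: ChainConfig

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def _block_index(self, effect: str, trait: str) -> int:
        return (self.random_effects.index(effect) * len(self.traits)
                + self.traits.index(trait))

    def beta_draws(self, term: str, trait: str) -> np.ndarray:
        """All chains pooled: draws of one fixed-effect coefficient."""
        return self.beta[:, :, self.x_columns.index(term),
                         self.traits.index(trait)].ravel()

    def g_draws(self, context: str, effect_a: str, trait_a: str,
                effect_b: str | None = None, trait_b: str | None = None) -> np.ndarray:
        """Pooled draws of one (co)variance element of ``G[context]``."""
        a = self._block_index(effect_a, trait_a)
        b = a if effect_b is None else self._block_index(effect_b, trait_b or trait_a)
        return self.G[context][:, :, a, b].ravel()

    def residual_draws(self, trait_a: str, trait_b: str | None = None) -> np.ndarray:
        a = self.traits.index(trait_a)
        b = a if trait_b is None else self.traits.index(trait_b)
        return self.R[:, :, a, b].ravel()

    def slope_draws(self, individual_id: str, effect: str, trait: str) -> np.ndarray:
        """Pooled draws of one individual's deviation for (effect, trait)."""
        j = self.ind_ids.index(individual_id)
        e = self.random_effects.index(effect)
        t = self.traits.index(trait)
        return self.individual_effects[:, :, j, e, t].ravel()

    def to_dict(self) -> dict[str, np.ndarray]:
        """(chain, draw, ...) arrays for convergence diagnostics."""
        out: dict[str, np.ndarray] = {"beta": self.beta}
        for c, g in self.G.items():
            out[f"G_{c}"] = g
        if self.V_year is not None:
            out["V_year"] = self.V_year
        out["R"] = self.R
        return out


# ---------------------------------------------------------------------------
# sampler internals


_TRIL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _sample_invwishart_batch(scales: np.ndarray, dfs: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """Draw from IW(scales[b], dfs[b]) for a stack of b blocks (Bartlett).

    Uses the equivariance W = F A A' F' ~ Wishart(df, F F') for any square
    root F of the Wishart scale; F is taken as the inverse-transposed
    Cholesky factor of each IW scale matrix.
    """
    m, k, _ = scales.shape
    if k == 1:
        return (scales[:, 0, 0] / rng.chisquare(dfs)).reshape(m, 1, 1)
    if k not in _TRIL_CACHE:
        _TRIL_CACHE[k] = np.tril_indices(k, -1)
    tril = _TRIL_CACHE[k]
    diag = np.arange(k)
    l_scale = np.linalg.cholesky(scales)
    # F = L^{-T}: F F' = inv(scale)
    f = np.linalg.solve(l_scale, np.broadcast_to(np.eye(k), (m, k, k)).copy())
    a = np.zeros((m, k, k))
    a[:, diag, diag] = np.sqrt(rng.chisquare(dfs[:, None] - diag[None, :]))
    a[:, tril[0], tril[1]] = rng.standard_normal((m, k * (k - 1) // 2))
    mat = np.swapaxes(f, 1, 2) @ a          # (m, k, k), W = mat @ mat.T
    minv = np.linalg.inv(mat)
    g = np.swapaxes(minv, 1, 2) @ minv      # inv(W)
    return 0.5 * (g + np.swapaxes(g, 1, 2))


def _sample_invwishart(scale: np.ndarray, df: float, rng: np.random.Generator
                       ) -> np.ndarray:
    """Draw from IW(scale, df) by Bartlett decomposition (df > k - 1)."""
    return _sample_invwishart_batch(scale[None], np.array([float(df)]), rng)[0]


def invwishart_mean(scale: np.ndarray, df: float) -> np.ndarray:
    """Analytic mean of IW(scale, df); requires df > k + 1."""
    k = scale.shape[0]
    if df <= k + 1:
        raise ValueError("inverse-Wishart mean requires df > dim + 1")
    return np.asarray(scale, dtype=float) / (df - k - 1)


def _logdet(mat: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(mat)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-PD matrix in log-determinant")
    return float(ld)


def _log_invwishart(g: np.ndarray, scale: np.ndarray, df: float) -> float:
    k = g.shape[0]
    return float(-0.5 * (df + k + 1) * _logdet(g)
                 - 0.5 * np.trace(np.linalg.solve(g, scale)))


class _GibbsState:
    """One chain's mutable state plus per-design precomputed cross-products."""

    def __init__(self, design: DesignMatrices, spec: ModelSpec,
                 rng: np.random.Generator):
        self.rng = rng
        self.design = design
        self.spec = spec
        d = design
        self.n, self.T = d.Y.shape
        self.p = d.X.shape[1]
        self.e = d.U.shape[1]
        self.k = self.e * self.T
        self.n_years = d.n_years if spec.include_year else 0
        self.d_e = self.p + self.n_years           # dense effect-level columns
        self.d = self.d_e * self.T

        # dense design: fixed columns then year indicator columns
        Wd = np.zeros((self.n, self.d_e))
        Wd[:, :self.p] = d.X
        if self.n_years and self.n:
            Wd[np.arange(self.n), self.p + d.year_index] = 1.0
        self.Wd = Wd
        self.Mff = Wd.T @ Wd
        self.WdtY = Wd.T @ d.Y

        n_ind = d.n_individuals
        self.n_ind = n_ind
        self.valid = d.ind_index >= 0
        idx = d.ind_index[self.valid]
        Uv = d.U[self.valid]
        Yv = d.Y[self.valid]
        Wv = Wd[self.valid]
        self.Mjj = np.zeros((n_ind, self.e, self.e))
        self.Mfj = np.zeros((n_ind, self.d_e, self.e))
        self.TUY = np.zeros((n_ind, self.e, self.T))
        if n_ind and idx.size:
            np.add.at(self.Mjj, idx, Uv[:, :, None] * Uv[:, None, :])
            np.add.at(self.Mfj, idx, Wv[:, :, None] * Uv[:, None, :])
            np.add.at(self.TUY, idx, Uv[:, :, None] * Yv[:, None, :])
        self.ctx_of_ind = d.ind_context
        self.ctx_codes = np.array([d.contexts.index(c) for c in d.ind_context],
                                  dtype=int) if n_ind else np.zeros(0, dtype=int)
        self.members = {c: np.flatnonzero(d.ind_context == c) for c in d.contexts}
        rows_ctx = {}
        for c in d.contexts:
            in_c = np.zeros(self.n, dtype=bool)
            sel = self.valid.copy()
            sel[self.valid] = np.isin(idx, self.members[c])
            rows_ctx[c] = np.flatnonzero(sel)
        self.rows_ctx = rows_ctx

        # priors
        pr = spec.prior
        self.px = pr.family == "parameter_expanded"
        self.S0 = pr.g_scale * np.eye(self.k)
        self.nu0 = pr.g_df if pr.g_df is not None else float(self.k)
        self.SR0 = pr.r_scale * np.eye(self.T)
        self.nuR0 = pr.r_df if pr.r_df is not None else float(self.T + 1)
        self.Sy0 = pr.year_scale * np.eye(self.T)
        self.nuy0 = pr.year_df if pr.year_df is not None else float(self.T)
        self.alpha_var = pr.alpha_var
        self.beta_prec = (0.0 if pr.beta_prior_var is None
                          else 1.0 / pr.beta_prior_var)
        self.R_fixed = spec.fixed_residual_matrix()

        # initial state: identity covariances, unit working parameters
        self.G_eta = {c: np.eye(self.k) for c in d.contexts}
        self.alpha = {c: np.ones(self.k) for c in d.contexts}
        self.G = {c: np.eye(self.k) for c in d.contexts}
        self.Vy_eta = np.eye(self.T)
        self.alpha_y = np.ones(self.T)
        self.V_year = np.eye(self.T)
        self.R = (self.R_fixed.copy() if self.R_fixed is not None
                  else np.eye(self.T))
        self.beta = np.zeros((self.p, self.T))
        self.year_eff = np.zeros((self.n_years, self.T))
        self.A_ind = np.zeros((n_ind, self.e, self.T))

    # -- helpers ----------------------------------------------------------

    def _kron_batch(self, mats: np.ndarray, rinv: np.ndarray) -> np.ndarray:
        """Batched kron(mats[j], rinv) with effect-major/trait-minor order."""
        if self.T == 1:
            return mats * rinv[0, 0]
        a, b = mats.shape[-2:]
        out = mats[..., :, None, :, None] * rinv[None, :, None, :]
        return out.reshape(*mats.shape[:-2], a * self.T, b * self.T)

    def predictor(self) -> np.ndarray:
        P = self.design.X @ self.beta
        if self.n_years and self.n:
            P = P + self.year_eff[self.design.year_index]
        if self.n_ind and self.valid.any():
            idx = self.design.ind_index[self.valid]
            P[self.valid] += np.einsum("ne,net->nt", self.design.U[self.valid],
                                       self.A_ind[idx])
        return P

    def dense_predictor(self) -> np.ndarray:
        """Fixed + year part only (individual contributions excluded)."""
        P = self.design.X @ self.beta
        if self.n_years and self.n:
            P = P + self.year_eff[self.design.year_index]
        return P

    # -- Gibbs updates ----------------------------------------------------

    def update_locations(self, rinv: np.ndarray) -> None:
        rng = self.rng
        T, d_e, d, k = self.T, self.d_e, self.d, self.k
        c_rinv = np.linalg.cholesky(rinv)

        # dense-part precision: data term + priors
        A = self._kron_batch(self.Mff, rinv)
        prior_sd_dense = np.zeros(d)
        if self.p:
            A[np.arange(self.p * T), np.arange(self.p * T)] += self.beta_prec
            prior_sd_dense[:self.p * T] = np.sqrt(self.beta_prec)
        u2_f = prior_sd_dense * rng.standard_normal(d)
        if self.n_years:
            vy_inv = np.linalg.inv(self.V_year)
            ly = np.linalg.cholesky(vy_inv)
            for yblk in range(self.n_years):
                s = self.p * T + yblk * T
                A[s:s + T, s:s + T] += vy_inv
                u2_f[s:s + T] = ly @ rng.standard_normal(T)

        # right-hand side with perturbation noise
        b_f = (self.WdtY @ rinv).reshape(d)
        if self.n:
            xi = rng.standard_normal((self.n, T))
            zt = xi @ c_rinv.T
            b_f = b_f + (self.Wd.T @ zt).reshape(d)
        b_f = b_f + u2_f

        if self.n_ind:
            ginv_arr = np.stack([np.linalg.inv(self.G[c])
                                 for c in self.design.contexts])
            lg_arr = np.linalg.cholesky(ginv_arr)
            D = self._kron_batch(self.Mjj, rinv) + ginv_arr[self.ctx_codes]
            B = self._kron_batch(self.Mfj, rinv)          # (J, d, k)
            b_a = (self.TUY @ rinv).reshape(self.n_ind, k)
            if self.n and self.valid.any():
                idx = self.design.ind_index[self.valid]
                u1 = np.empty((self.e, T, self.n_ind))
                uv = self.design.U[self.valid]
                ztv = zt[self.valid]
                for ei in range(self.e):
                    for ti in range(T):
                        u1[ei, ti] = np.bincount(idx, weights=uv[:, ei] * ztv[:, ti],
                                                 minlength=self.n_ind)
                b_a = b_a + u1.reshape(k, self.n_ind).T
            b_a = b_a + np.einsum("jkl,jl->jk", lg_arr[self.ctx_codes],
                                  rng.standard_normal((self.n_ind, k)))

            try:
                rhs = np.concatenate([np.swapaxes(B, 1, 2), b_a[:, :, None]],
                                     axis=2)
                sol = np.linalg.solve(D, rhs)
                Xs, w = sol[:, :, :-1], sol[:, :, -1]           # (J, k, d), (J, k)
                if d:
                    S = A - np.einsum("jdk,jke->de", B, Xs)
                    cf = cho_factor(S, lower=True, check_finite=False)
                    f = cho_solve(cf, b_f - np.einsum("jdk,jk->d", B, w),
                                  check_finite=False)
                    a = w - np.einsum("jkd,d->jk", Xs, f)
                else:
                    f = np.zeros(0)
                    a = w
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(
                    f"non-PD conditional covariance in location update: {exc}"
                ) from exc
            self.A_ind = a.reshape(self.n_ind, self.e, T)
        elif d:
            try:
                cf = cho_factor(A, lower=True, check_finite=False)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(
                    f"non-PD conditional covariance in location update: {exc}"
                ) from exc
            f = cho_solve(cf, b_f, check_finite=False)
        else:
            f = np.zeros(0)

        F = f.reshape(d_e, T)
        self.beta = F[:self.p]
        if self.n_years:
            self.year_eff = F[self.p:]

    def _alpha_update(self, H: np.ndarray, resid: np.ndarray,
                      rinv: np.ndarray) -> np.ndarray:
        """Draw working parameters from their normal full conditional.

        ``H[i, e, t]`` is the gradient-times-eta design; residuals ``resid``
        exclude this block's contribution. Returns alpha of length e*T.
        """
        T = self.T
        kk = H.shape[1] * T
        if kk == 1:
            h = H[:, 0, 0]
            prec = float(h @ h) * rinv[0, 0] + 1.0 / self.alpha_var
            b = float(h @ resid[:, 0]) * rinv[0, 0]
            sd = 1.0 / np.sqrt(prec)
            return np.array([b / prec + sd * self.rng.standard_normal()])
        hth = np.einsum("iet,ifs->etfs", H, H)
        prec = (hth * rinv[None, :, None, :]).reshape(kk, kk)
        prec = prec + np.eye(kk) / self.alpha_var
        b = np.einsum("iet,it->et", H, resid @ rinv).reshape(kk)
        try:
            cov = np.linalg.inv(prec)
            noise_chol = np.linalg.cholesky(0.5 * (cov + cov.T))
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"non-PD working-parameter precision: {exc}") from exc
        return cov @ b + noise_chol @ self.rng.standard_normal(kk)

    def update_individual_blocks(self, rinv: np.ndarray) -> None:
        d = self.design
        contexts = d.contexts
        if not contexts:
            return
        if not self.px:
            scales = np.stack([
                self.S0 + self.A_ind[self.members[c]].reshape(-1, self.k).T
                @ self.A_ind[self.members[c]].reshape(-1, self.k)
                for c in contexts])
            dfs = np.array([self.nu0 + len(self.members[c]) for c in contexts])
            g_new = _sample_invwishart_batch(scales, dfs, self.rng)
            for i, c in enumerate(contexts):
                self.G[c] = g_new[i]
            return

        etas = {}
        scales = np.empty((len(contexts), self.k, self.k))
        dfs = np.empty(len(contexts))
        for i, c in enumerate(contexts):
            eta = (self.A_ind[self.members[c]].reshape(-1, self.k)
                   / self.alpha[c][None, :])
            etas[c] = eta
            scales[i] = self.S0 + eta.T @ eta
            dfs[i] = self.nu0 + len(self.members[c])
        g_eta_new = _sample_invwishart_batch(scales, dfs, self.rng)

        base = self.dense_predictor() if self.n else None
        resid_all = (d.Y - base) if self.n else None
        for i, c in enumerate(contexts):
            self.G_eta[c] = g_eta_new[i]
            J = self.members[c]
            eta = etas[c]
            rows = self.rows_ctx[c]
            if rows.size:
                eta_ind = eta.reshape(len(J), self.e, self.T)
                pos = np.full(self.n_ind, -1)
                pos[J] = np.arange(len(J))
                owners = pos[d.ind_index[rows]]
                H = d.U[rows][:, :, None] * eta_ind[owners]
                self.alpha[c] = self._alpha_update(H, resid_all[rows], rinv)
            else:
                self.alpha[c] = (np.sqrt(self.alpha_var)
                                 * self.rng.standard_normal(self.k))
            self.A_ind[J] = (self.alpha[c][None, :] * eta).reshape(
                len(J), self.e, self.T)
            self.G[c] = np.outer(self.alpha[c], self.alpha[c]) * self.G_eta[c]

    def update_year_block(self, rinv: np.ndarray) -> None:
        if not self.n_years:
            return
        T = self.T
        if self.px:
            eta = self.year_eff / self.alpha_y[None, :]
            s = self.Sy0 + eta.T @ eta
            self.Vy_eta = _sample_invwishart(s, self.nuy0 + self.n_years, self.rng)
            if self.n:
                H = eta[self.design.year_index][:, None, :]    # (n, 1, T)
                P_no_year = self.design.X @ self.beta
                if self.n_ind and self.valid.any():
                    idx = self.design.ind_index[self.valid]
                    P_no_year[self.valid] += np.einsum(
                        "ne,net->nt", self.design.U[self.valid], self.A_ind[idx])
                resid = self.design.Y - P_no_year
                self.alpha_y = self._alpha_update(H, resid, rinv)
            else:
                self.alpha_y = (np.sqrt(self.alpha_var)
                                * self.rng.standard_normal(T))
            self.year_eff = self.alpha_y[None, :] * eta
            self.V_year = np.outer(self.alpha_y, self.alpha_y) * self.Vy_eta
        else:
            s = self.Sy0 + self.year_eff.T @ self.year_eff
            self.V_year = _sample_invwishart(s, self.nuy0 + self.n_years, self.rng)

    def update_residual(self) -> None:
        if self.R_fixed is not None:
            return
        E = self.design.Y - self.predictor()
        s = self.SR0 + E.T @ E
        self.R = _sample_invwishart(s, self.nuR0 + self.n, self.rng)

    def log_posterior(self) -> float:
        rinv = np.linalg.inv(self.R)
        lp = 0.0
        if self.n:
            E = self.design.Y - self.predictor()
            lp += -0.5 * float(np.einsum("nt,ts,ns->", E, rinv, E))
            lp += -0.5 * self.n * _logdet(self.R)
        if self.p and self.beta_prec > 0:
            lp += -0.5 * self.beta_prec * float((self.beta ** 2).sum())
        for c in self.design.contexts:
            J = self.members[c]
            a_c = self.A_ind[J].reshape(len(J), self.k)
            ginv = np.linalg.inv(self.G[c])
            lp += -0.5 * float(np.einsum("jk,kl,jl->", a_c, ginv, a_c))
            lp += -0.5 * len(J) * _logdet(self.G[c])
            if self.px:
                lp += _log_invwishart(self.G_eta[c], self.S0, self.nu0)
                lp += -0.5 * float(self.alpha[c] @ self.alpha[c]) / self.alpha_var
            else:
                lp += _log_invwishart(self.G[c], self.S0, self.nu0)
        if self.n_years:
            vinv = np.linalg.inv(self.V_year)
            lp += -0.5 * float(np.einsum("jk,kl,jl->", self.year_eff, vinv,
                                         self.year_eff))
            lp += -0.5 * self.n_years * _logdet(self.V_year)
            if self.px:
                lp += _log_invwishart(self.Vy_eta, self.Sy0, self.nuy0)
                lp += -0.5 * float(self.alpha_y @ self.alpha_y) / self.alpha_var
            else:
                lp += _log_invwishart(self.V_year, self.Sy0, self.nuy0)
        if self.R_fixed is None:
            lp += _log_invwishart(self.R, self.SR0, self.nuR0)
        return lp


def gibbs_sample(
    design: DesignMatrices,
    spec: ModelSpec,
    chains: ChainConfig,
    log_every: int = 0,
    compute_log_posterior: bool = True,
) -> PosteriorDraws:
    """Run the blocked Gibbs sampler; returns retained draws per chain.

    Chains are independent and differ only by the RNG streams spawned from
    ``chains.seed``. Each iteration performs the joint location draw, the
    per-context covariance-block updates (with working-parameter expansion
    under the parameter-expanded family), the year block and the residual
    covariance update.
    """
    if chains.retained < 1:
        raise ValueError("chain configuration retains no draws")
    if spec.n_traits != design.n_traits:
        raise ValueError("spec and design disagree on the number of traits")

    n_ret = chains.retained
    seeds = np.random.SeedSequence(chains.seed).spawn(chains.n_chains)
    first = _GibbsState(design, spec, np.random.default_rng(seeds[0]))
    p, T, k, e = first.p, first.T, first.k, first.e

    beta = np.empty((chains.n_chains, n_ret, p, T))
    g = {c: np.empty((chains.n_chains, n_ret, k, k)) for c in design.contexts}
    vy = (np.empty((chains.n_chains, n_ret, T, T))
          if (spec.include_year and design.n_years) else None)
    r = np.empty((chains.n_chains, n_ret, T, T))
    ind_eff = np.empty((chains.n_chains, n_ret, design.n_individuals, e, T))
    logp = np.full((chains.n_chains, n_ret), np.nan)

    for chain in range(chains.n_chains):
        state = (first if chain == 0
                 else _GibbsState(design, spec, np.random.default_rng(seeds[chain])))
        kept = 0
        for it in range(chains.n_iterations):
            try:
                rinv = np.linalg.inv(state.R)
                state.update_locations(rinv)
                state.update_individual_blocks(rinv)
                state.update_year_block(rinv)
                state.update_residual()
            except RuntimeError as exc:
                raise RuntimeError(f"sampler aborted at iteration {it}: {exc}") from exc
            if it >= chains.burn_in and (it - chains.burn_in) % chains.thin == 0:
                if kept < n_ret:
                    beta[chain, kept] = state.beta
                    for c in design.contexts:
                        g[c][chain, kept] = state.G[c]
                    if vy is not None:
                        vy[chain, kept] = state.V_year
                    r[chain, kept] = state.R
                    ind_eff[chain, kept] = state.A_ind
                    if compute_log_posterior:
                        logp[chain, kept] = state.log_posterior()
                    kept += 1
            if log_every and (it + 1) % log_every == 0:
                logger.info("chain %d iteration %d/%d", chain, it + 1,
                            chains.n_iterations)

    return PosteriorDraws(
        traits=design.traits, x_columns=design.x_columns,
        contexts=design.contexts, ind_ids=design.ind_ids,
        random_effects=design.random_effects,
        beta=beta, G=g, V_year=vy, R=r,
        individual_effects=ind_eff, log_posterior=logp,
        chain_config=chains,
    )


# ---------------------------------------------------------------------------
# convergence diagnostics


def gelman_rubin(draws) -> pd.Series:
    """Rank-normalized split potential-scale-reduction factor per parameter.

    Accepts a :class:`PosteriorDraws`, a mapping of name -> (chain, draw,
    ...) arrays, or a single (chain, draw) array. Requires at least two
    chains. The split, rank-normalized variant is strictly more
    conservative than the classic statistic.
    """
    import arviz as az

    if isinstance(draws, PosteriorDraws):
        arrays = draws.to_dict()
    elif isinstance(draws, np.ndarray):
        arrays = {"x": draws}
    elif isinstance(draws, dict):
        arrays = draws
    else:
        raise TypeError("expected PosteriorDraws, dict or ndarray")
    n_chains = {v.shape[0] for v in arrays.values()}
    if min(n_chains) < 2:
        raise ValueError("Gelman-Rubin requires n_chains >= 2")
    lengths = {v.shape[1] for v in arrays.values()}
    if len(lengths) != 1:
        raise ValueError("all parameters must have equal retained lengths")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.rhat(az.convert_to_dataset(arrays), method="rank")
    out: dict[str, float] = {}
    for name, da in ds.items():
        vals = np.atleast_1d(np.asarray(da))
        if vals.ndim == 0 or vals.size == 1:
            out[str(name)] = float(vals.ravel()[0])
        else:
            for idx in np.ndindex(*vals.shape):
                suffix = ",".join(str(i) for i in idx)
                out[f"{name}[{suffix}]"] = float(vals[idx])
    return pd.Series(out, name="rhat")
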