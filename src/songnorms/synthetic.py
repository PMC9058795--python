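"""Synthetic song datasets with a known reaction-norm structure.

Generates song-level (and optionally syllable-level) tables that mimic a
field study of male collared flycatcher song: each individual is recorded
once (a subset twice), every song in a recording has a within-recording
order, a singing-position height (percent of vegetation height, sometimes
unrecorded), and three z-scale traits — song length (SL), maximum frequency
(MF) and complexity. Individuals carry context-specific random intercepts
and random slopes over song order and singing position, drawn from
per-context covariance matrices; years contribute correlated random
intercepts and songs a cross-trait correlated residual.

Because the generator *inverts* the random-regression model fitted
downstream, every fitted quantity has a recorded ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("male", "female", "none")
#: fixed-effect design terms, z-scale
FIXED_TERMS = (
    "intercept",
    "date",
    "age",
    "order",
    "position",
    "context_female",
    "context_none",
    "order:context_female",
    "order:context_none",
)
#: individual random effects, per trait
RANDOM_EFFECTS = ("intercept", "order", "position")


def _as_psd(mat: np.ndarray, label: str, tol: float = 1e-10) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{label}: covariance matrix must be square, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError(f"{label}: covariance matrix is not symmetric")
    if np.linalg.eigvalsh(mat).min() < -tol:
        raise ValueError(f"{label}: covariance matrix is not positive semi-definite")
    return 0.5 * (mat + mat.T)


@dataclass
class TrueParameters:
    """Ground-truth generator parameters on the z-scale.

    ``beta`` is a (n_traits, n_terms) coefficient table over
    :data:`FIXED_TERMS`. ``G`` maps each social context to the covariance
    matrix of individual deviations, ordered effect-major / trait-minor:
    ``[(intercept, t1), (intercept, t2), (order, t1), ...]`` — 6x6 for a
    bivariate design, 3x3 univariate. ``V_year`` and ``R_resid`` are
    cross-trait year and residual covariances. ``repeat_noise_sd`` is the
    SD of the between-recording drift added to each slope for individuals
    with a second recording, giving a true slope repeatability of
    ``var_slope / (var_slope + repeat_noise_sd**2)``.
    """

    traits: tuple[str, ...]
    beta: np.ndarray
    G: dict[str, np.ndarray]
    V_year: np.ndarray
    R_resid: np.ndarray
    repeat_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        if len(set(self.traits)) != len(self.traits):
            raise ValueError("trait labels must be unique")
        t = len(self.traits)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (t, len(FIXED_TERMS)):
            raise ValueError(
                f"beta must have shape ({t}, {len(FIXED_TERMS)}), got {self.beta.shape}"
            )
        k = len(RANDOM_EFFECTS) * t
        for ctx, mat in self.G.items():
            if ctx not in CONTEXTS:
                raise ValueError(f"unknown context {ctx!r}")
            self.G[ctx] = _as_psd(mat, f"G[{ctx}]")
            if self.G[ctx].shape != (k, k):
                raise ValueError(f"G[{ctx}] must be {k}x{k} for {t} trait(s)")
        self.V_year = _as_psd(self.V_year, "V_year")
        self.R_resid = _as_psd(self.R_resid, "R_resid")
        if self.V_year.shape != (t, t) or self.R_resid.shape != (t, t):
            raise ValueError("V_year and R_resid must be n_traits x n_traits")
        if self.repeat_noise_sd < 0:
            raise ValueError("repeat_noise_sd must be >= 0")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def beta_of(self, trait: str, term: str) -> float:
        return float(self.beta[self.traits.index(trait), FIXED_TERMS.index(term)])


@dataclass
class SimulationConfig:
    """Shape of the simulated study (defaults mimic the field design)."""

    n_individuals: int = 185
    context_probs: tuple[float, float, float] = (0.45, 0.21, 0.34)
    songs_per_recording: tuple[int, int] = (9, 126)
    position_beta: tuple[float, float] = (2.0, 2.0)
    missing_position_prob: float = 0.15
    n_years: int = 12
    prop_repeated: float = 0.20
    repeat_same_context_prob: float = 0.65
    prop_yearlings: float = 0.4
    season_length_days: int = 27
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.context_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or (probs > 1).any():
            raise ValueError("context_probs must be three probabilities")
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("context_probs must sum to 1")
        lo, hi = self.songs_per_recording
        if lo < 1 or hi < lo:
            raise ValueError("songs_per_recording must satisfy 1 <= min <= max")
        for name in ("missing_position_prob", "prop_repeated",
                     "repeat_same_context_prob", "prop_yearlings"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_individuals < 1 or self.n_years < 1:
            raise ValueError("n_individuals and n_years must be >= 1")


def _correlation_to_cov(sd: np.ndarray, corr: np.ndarray) -> np.ndarray:
    return np.outer(sd, sd) * corr


def default_true_parameters(traits: tuple[str, ...] = ("SL", "MF")) -> TrueParameters:
    """Defaults for the bivariate SL+MF design (or the univariate complexity one).

    Fixed effects reproduce the published population-level point estimates
    for SL and MF (date, age, order, position, context contrasts against the
    male-stimulus reference and order-by-context interactions). The male
    context embeds the two published slope correlations (-0.69 between SL
    order- and position-slopes, -0.71 between SL position- and MF
    order-slopes); remaining covariance magnitudes are realistic choices on
    the z-scale totalling ~1 phenotypic variance per trait.
    """
    traits = tuple(traits)
    if traits == ("SL", "MF"):
        beta = np.array([
            # int   date   age    order  pos    ctxF   ctxN   ord:F  ord:N
            [0.0, 0.052, 0.034, 0.044, 0.047, 0.067, 0.066, 0.285, 0.273],  # SL
            [0.0, 0.008, 0.011, -0.028, -0.014, 0.070, 0.014, 0.379, 0.060],  # MF
        ])
        sd_male = np.sqrt([0.20, 0.20, 0.10, 0.10, 0.10, 0.05])
        corr_male = np.eye(6)

        def setc(c, i, j, v):
            c[i, j] = c[j, i] = v

        setc(corr_male, 0, 1, 0.30)
        setc(corr_male, 0, 2, -0.20)
        setc(corr_male, 1, 3, -0.20)
        setc(corr_male, 0, 4, -0.10)
        setc(corr_male, 1, 5, -0.10)
        setc(corr_male, 2, 4, -0.69)   # SL order-slope vs SL position-slope
        setc(corr_male, 3, 4, -0.71)   # MF order-slope vs SL position-slope
        setc(corr_male, 2, 3, 0.55)
        setc(corr_male, 4, 5, 0.10)
        setc(corr_male, 2, 5, 0.05)
        setc(corr_male, 3, 5, 0.05)
        g_male = _correlation_to_cov(sd_male, corr_male)

        sd_female = np.sqrt([0.20, 0.20, 0.03, 0.03, 0.03, 0.03])
        corr_female = np.eye(6)
        setc(corr_female, 0, 1, 0.30)
        g_female = _correlation_to_cov(sd_female, corr_female)

        sd_none = np.sqrt([0.20, 0.20, 0.08, 0.03, 0.03, 0.03])
        corr_none = np.eye(6)
        setc(corr_none, 0, 1, 0.30)
        setc(corr_none, 0, 2, -0.20)
        g_none = _correlation_to_cov(sd_none, corr_none)

        return TrueParameters(
            traits=traits,
            beta=beta,
            G={"male": g_male, "female": g_female, "none": g_none},
            V_year=np.array([[0.05, 0.015], [0.015, 0.05]]),
            R_resid=np.array([[0.60, 0.15], [0.15, 0.60]]),
            repeat_noise_sd=float(np.sqrt(0.10)),  # true slope repeatability 0.5
        )
    if traits == ("complexity",):
        beta = np.array([[0.0, 0.043, -0.068, 0.024, 0.062, 0.040, -0.055, 0.078, -0.040]])
        g = np.diag([0.15, 0.02, 0.02])
        return TrueParameters(
            traits=traits,
            beta=beta,
            G={"male": g.copy(), "female": g.copy(), "none": g.copy()},
            V_year=np.array([[0.05]]),
            R_resid=np.array([[0.70]]),
            repeat_noise_sd=float(np.sqrt(0.02)),
        )
    raise ValueError(f"no built-in defaults for traits {traits!r}")


def simulate_individuals(
    config: SimulationConfig, params: TrueParameters
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw individuals and their ground-truth reaction norms.

    Returns ``(individuals, truth)``. ``individuals`` has one row per
    recording (individual_id, recording_id, recording_order, context, age,
    year, date, n_songs); ``truth`` one row per recording x effect x trait
    with the realized individual deviation. Each recording's slopes are an
    independent draw around the individual's stable slope with SD
    ``repeat_noise_sd`` (intercepts carry over unchanged), so the true
    slope repeatability across recordings is
    ``var_slope / (var_slope + repeat_noise_sd**2)``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    t = params.n_traits
    n_eff = len(RANDOM_EFFECTS)
    k = n_eff * t

    contexts = rng.choice(CONTEXTS, size=n, p=np.asarray(config.context_probs, float))
    ages = (rng.random(n) >= config.prop_yearlings).astype(int)  # 1 = adult
    years = rng.integers(0, config.n_years, size=n)
    dates = rng.integers(0, config.season_length_days + 1, size=n)

    # per-individual deviation vectors, per context
    dev = np.zeros((n, k))
    for ctx in CONTEXTS:
        mask = contexts == ctx
        if mask.sum() == 0:
            continue
        g = params.G[ctx]
        if np.allclose(g, 0.0):
            continue
        dev[mask] = rng.multivariate_normal(np.zeros(k), g, size=int(mask.sum()),
                                            method="eigh")

    repeated = rng.random(n) < config.prop_repeated
    same_ctx = rng.random(n) < config.repeat_same_context_prob

    ind_rows: list[dict] = []
    truth_rows: list[dict] = []
    lo, hi = config.songs_per_recording

    def add_recording(i: int, order: int, ctx: str, year: int, date: int,
                      deviation: np.ndarray) -> None:
        rec_id = f"rec{i:04d}_{order}"
        ind_rows.append({
            "individual_id": f"bird{i:04d}",
            "recording_id": rec_id,
            "recording_order": order,
            "context": ctx,
            "age": int(ages[i]),
            "year": int(year),
            "date": int(date),
            "n_songs": int(rng.integers(lo, hi + 1)),
        })
        for e_idx, eff in enumerate(RANDOM_EFFECTS):
            for t_idx, trait in enumerate(params.traits):
                truth_rows.append({
                    "individual_id": f"bird{i:04d}",
                    "recording_id": rec_id,
                    "recording_order": order,
                    "context": ctx,
                    "effect": eff,
                    "trait": trait,
                    "deviation": float(deviation[e_idx * t + t_idx]),
                })

    def recording_dev(i: int) -> np.ndarray:
        out = dev[i].copy()
        if params.repeat_noise_sd > 0:
            out[t:] += rng.normal(0.0, params.repeat_noise_sd,
                                  size=(n_eff - 1) * t)
        return out

    for i in range(n):
        add_recording(i, 1, contexts[i], years[i], dates[i], recording_dev(i))
        if repeated[i]:
            ctx2 = contexts[i] if same_ctx[i] else rng.choice(
                [c for c in CONTEXTS if c != contexts[i]])
            year2 = min(int(years[i]) + int(rng.integers(0, 2)), config.n_years - 1)
            date2 = int(rng.integers(0, config.season_length_days + 1))
            add_recording(i, 2, ctx2, year2, date2, recording_dev(i))

    return pd.DataFrame(ind_rows), pd.DataFrame(truth_rows)


def simulate_songs(
    individuals: pd.DataFrame,
    truth: pd.DataFrame,
    params: TrueParameters,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Generate the song table from individuals and their true reaction norms.

    Each trait value is the fixed-effect linear predictor plus the year
    effect, the individual's intercept and slope deviations applied to
    z-scored song order and singing position, plus a residual drawn jointly
    across traits from ``R_resid``. The realized full linear predictor is
    recorded in a ``linpred_<trait>`` column; positions are masked missing
    with ``missing_position_prob`` after trait generation.
    """
    missing = truth["individual_id"].isin(individuals["individual_id"])
    if not missing.all() or not individuals["individual_id"].isin(
            truth["individual_id"]).all():
        raise ValueError("truth table must cover exactly the simulated individuals")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    t = params.n_traits

    rows = []
    for rec in individuals.itertuples(index=False):
        for order in range(1, rec.n_songs + 1):
            rows.append((rec.individual_id, rec.recording_id, rec.recording_order,
                         rec.context, rec.age, rec.year, rec.date, order))
    songs = pd.DataFrame(rows, columns=[
        "individual_id", "recording_id", "recording_order", "context", "age",
        "year", "date", "song_order"])
    n = len(songs)

    position = 100.0 * rng.beta(*config.position_beta, size=n)

    # z-scores over the full simulated dataset (the generator's own scale)
    def z(x):
        x = np.asarray(x, dtype=float)
        s = x.std(ddof=1)
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    z_order = z(songs["song_order"])
    z_pos = z(position)
    z_date = z(songs["date"])

    ctx_f = (songs["context"] == "female").to_numpy(float)
    ctx_n = (songs["context"] == "none").to_numpy(float)
    X = np.column_stack([
        np.ones(n), z_date, songs["age"].to_numpy(float), z_order, z_pos,
        ctx_f, ctx_n, z_order * ctx_f, z_order * ctx_n,
    ])
    mu = X @ params.beta.T  # (n, t)

    year_levels = np.sort(individuals["year"].unique())
    year_eff = rng.multivariate_normal(np.zeros(t), params.V_year,
                                       size=len(year_levels), method="eigh")
    year_of = {y: year_eff[i] for i, y in enumerate(year_levels)}
    mu += np.stack([year_of[y] for y in songs["year"]])

    # individual deviations keyed by recording
    dev_tbl = truth.pivot_table(index="recording_id", columns=["effect", "trait"],
                                values="deviation")
    rec_idx = dev_tbl.index.get_indexer(songs["recording_id"])
    gradients = {"intercept": np.ones(n), "order": z_order, "position": z_pos}
    for eff, grad in gradients.items():
        block = dev_tbl[eff][list(params.traits)].to_numpy()  # (n_rec, t)
        mu += block[rec_idx] * grad[:, None]

    if np.allclose(params.R_resid, 0.0):
        resid = np.zeros((n, t))
    else:
        resid = rng.multivariate_normal(np.zeros(t), params.R_resid, size=n,
                                        method="eigh")
    values = mu + resid

    mask = rng.random(n) < config.missing_position_prob
    songs["position"] = np.where(mask, np.nan, position)
    for i, trait in enumerate(params.traits):
        songs[trait] = values[:, i]
        songs[f"linpred_{trait}"] = mu[:, i]
    return songs


def simulate_syllables(
    songs: pd.DataFrame,
    K_true: int = 20,
    cluster_spread: float = 50.0,
    seed: int = 0,
    sl_mean_s: float = 4.0,
    sl_sd_s: float = 0.5,
    complexity_mean: float = 0.55,
    complexity_sd: float = 0.12,
    syllables_per_song: tuple[int, int] = (8, 16),
) -> pd.DataFrame:
    """Emit a syllable table whose per-song type diversity hits a target complexity.

    ``K_true`` well-separated Gaussian clusters are laid out in the
    5-feature space (duration s; min/max/bandwidth/mean frequency Hz);
    ``cluster_spread`` is the within-cluster feature SD in Hz (scaled down
    for duration). Raw song lengths are mapped from the z-scale ``SL``
    column (if present) around ``sl_mean_s`` so songs stay in the species'
    3-5 s range; syllables tile the song span exactly. Target complexity is
    mapped from the z-scale ``complexity`` column (if present) and realized
    as ``round(target * n_syllables)`` distinct true types.
    """
    if K_true < 1:
        raise ValueError("K_true must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    # well separated centroids: frequency grid + distinct durations
    base_freq = 2000.0 + 400.0 * np.arange(K_true)
    centroids = np.column_stack([
        0.05 + 0.015 * np.arange(K_true),        # duration s
        base_freq,                                # min freq
        base_freq + 1500.0,                       # max freq
        np.full(K_true, 1500.0),                  # bandwidth
        base_freq + 400.0 + 40.0 * np.arange(K_true),  # mean freq
    ])

    lo, hi = syllables_per_song
    n = len(songs)
    sl_z = songs["SL"].to_numpy(float) if "SL" in songs else np.zeros(n)
    c_z = songs["complexity"].to_numpy(float) if "complexity" in songs else np.zeros(n)
    sl_raw = np.clip(sl_mean_s + sl_sd_s * sl_z, 1.0, None)
    c_raw = np.clip(complexity_mean + complexity_sd * c_z, 0.05, None)

    song_ids = (songs["recording_id"].astype(str) + "_s"
                + songs["song_order"].astype(str)) if "recording_id" in songs else (
        pd.Series([f"song{i}" for i in range(n)]))

    recs = []
    n_syll = rng.integers(lo, hi + 1, size=n)
    for i in range(n):
        m = int(n_syll[i])
        n_types = max(1, int(round(c_raw[i] * m)))
        if c_raw[i] > 1.0 or n_types > m:
            raise ValueError(
                f"infeasible complexity target {c_raw[i]:.3f} for {m} syllables "
                f"in song {song_ids.iloc[i]} (needs more distinct types than "
                f"syllables)")
        if n_types > K_true:
            n_types = K_true
        types = rng.choice(K_true, size=n_types, replace=False)
        labels = np.concatenate([types, rng.choice(types, size=m - n_types)])
        rng.shuffle(labels)
        step = sl_raw[i] / m
        for j, lab in enumerate(labels):
            c = centroids[lab]
            dur = step
            minf = max(c[1] + rng.normal(0, cluster_spread), 100.0)
            bw = max(c[3] + rng.normal(0, cluster_spread), 10.0)
            maxf = minf + bw
            frac = float(np.clip((c[4] - c[1]) / c[3] + rng.normal(
                0, cluster_spread / max(bw, 1.0)), 0.0, 1.0))
            meanf = minf + frac * bw
            recs.append({
                "song_id": song_ids.iloc[i],
                "onset": j * step,
                "duration": dur,
                "min_freq": minf,
                "max_freq": maxf,
                "bandwidth": bw,
                "mean_freq": meanf,
                "true_type": int(lab),
            })
    return pd.DataFrame(recs)


def simulate_dataset(
    config: SimulationConfig | None = None,
    params: TrueParameters | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: returns ``(songs, individuals, truth)``."""
    config = config or SimulationConfig()
    params = params or default_true_parameters()
    individuals, truth = simulate_individuals(config, params)
    songs = simulate_songs(individuals, truth, params, config)
    return songs, individuals, truth


def parameters_to_dict(params: TrueParameters) -> dict:
    """JSON/YAML-serializable form of :class:`TrueParameters`."""
    return {
        "traits": list(params.traits),
        "fixed_terms": list(FIXED_TERMS),
        "beta": params.beta.tolist(),
        "G": {ctx: mat.tolist() for ctx, mat in params.G.items()},
        "V_year": params.V_year.tolist(),
        "R_resid": params.R_resid.tolist(),
        "repeat_noise_sd": params.repeat_noise_sd,
    }


def parameters_from_dict(d: dict) -> TrueParameters:
    return TrueParameters(
        traits=tuple(d["traits"]),
        beta=np.asarray(d["beta"], dtype=float),
        G={ctx: np.asarray(m, dtype=float) for ctx, m in d["G"].items()},
        V_year=np.asarray(d["V_year"], dtype=float),
        R_resid=np.asarray(d["R_resid"], dtype=float),
        repeat_noise_sd=float(d.get("repeat_noise_sd", 0.0)),
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("context_probs", "songs_per_recording", "position_beta"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
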