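"""Table formats, run manifests and pipeline orchestration.

All tables are RFC-4180 CSV. A run manifest (JSON) records the seed,
config hash, input checksums, dropped rows and chain settings so that a
run is fully reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import (ChainConfig, ModelSpec, PriorConfig, build_design,
                    gibbs_sample, PosteriorDraws)
from .repeatability import slope_repeatability
from .summaries import summarize_fixed_effects, summarize_random_effects
from .synthetic import (CONTEXTS, config_from_dict,
                        config_to_dict, default_true_parameters,
                        parameters_from_dict, parameters_to_dict,
                        simulate_individuals, simulate_songs,
                        simulate_syllables)
from .traits import derive_song_traits

logger = logging.getLogger("songnorms")

SONG_COLUMNS = {
    "individual_id": str, "recording_id": str, "year": int, "date": float,
    "age": int, "context": str, "song_order": int,
}


def read_song_table(path) -> pd.DataFrame:
    """Read and validate a song table.

    Requires the documented header (individual_id, recording_id, year,
    date, age, context, song_order, position plus trait columns); contexts
    must be male/female/none, positions in [0, 100] or missing, and song
    orders consecutive from 1 within each recording. Raises ``ValueError``
    listing offending rows.
    """
    df = pd.read_csv(path)
    missing = set(SONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"unknown/missing columns: song table lacks {sorted(missing)}")

    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ValueError(
            f"invalid context in rows {df.index[bad].tolist()[:20]}: "
            f"{sorted(df.loc[bad, 'context'].unique())}")
    if "position" in df.columns:
        pos = df["position"]
        bad = pos.notna() & ((pos < 0) | (pos > 100))
        if bad.any():
            raise ValueError(
                f"position outside [0, 100] in rows {df.index[bad].tolist()[:20]}")
    bad_recs = []
    for rec, grp in df.groupby("recording_id"):
        orders = np.sort(grp["song_order"].to_numpy())
        if not np.array_equal(orders, np.arange(1, len(orders) + 1)):
            bad_recs.append(rec)
    if bad_recs:
        raise ValueError(
            f"non-consecutive song orders in recordings {bad_recs[:20]}")
    return df


def write_song_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    seed: int
    config_hash: str
    software_version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    rows_dropped: dict = field(default_factory=dict)
    chain_settings: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)
    convergence: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))


def draws_to_frame(draws: PosteriorDraws, chain: int) -> pd.DataFrame:
    """Flatten one chain's retained draws to a columnar table."""
    cols: dict[str, np.ndarray] = {}
    for ti, trait in enumerate(draws.traits):
        for pi, term in enumerate(draws.x_columns):
            cols[f"beta[{trait}:{term}]"] = draws.beta[chain, :, pi, ti]
    labels = [f"{e}({t})" for e in draws.random_effects for t in draws.traits]
    for ctx, g in draws.G.items():
        k = g.shape[-1]
        for i in range(k):
            for j in range(i, k):
                cols[f"G[{ctx}][{labels[i]},{labels[j]}]"] = g[chain, :, i, j]
    for name, arr in (("V_year", draws.V_year), ("R", draws.R)):
        if arr is None:
            continue
        nt = arr.shape[-1]
        for i in range(nt):
            for j in range(i, nt):
                cols[f"{name}[{draws.traits[i]},{draws.traits[j]}]"] = arr[chain, :, i, j]
    cols["log_posterior"] = draws.log_posterior[chain]
    return pd.DataFrame(cols)


def _chains_from_config(cfg: dict, seed: int) -> ChainConfig:
    preset = cfg.get("preset")
    if preset == "paper" or preset == "paper-faithful":
        return ChainConfig.paper_faithful(seed=seed)
    if preset == "fast" or preset is None and "n_iterations" not in cfg:
        return ChainConfig.fast(seed=seed, n_chains=int(cfg.get("n_chains", 4)))
    return ChainConfig(
        n_iterations=int(cfg["n_iterations"]),
        burn_in=int(cfg.get("burn_in", 0)),
        thin=int(cfg.get("thin", 1)),
        n_chains=int(cfg.get("n_chains", 1)),
        seed=seed,
    )


def apply_max_songs(songs: pd.DataFrame, max_songs: int) -> pd.DataFrame:
    """Keep at most the first ``max_songs`` songs per individual (robustness
    re-analysis design)."""
    return songs[songs["song_order"] <= max_songs].reset_index(drop=True)


def run_pipeline(config: dict, outdir, seed: int = 0) -> RunManifest:
    """Simulate (optionally), derive traits (optionally), fit the bivariate
    SL+MF and univariate complexity models, summarize, and estimate slope
    repeatability; write all artifacts plus a manifest to ``outdir``.

    Any stage failure aborts with the stage name; the manifest written so
    far is preserved under ``manifest_partial.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(config, sort_keys=True)
    manifest = RunManifest(
        seed=seed, config_hash=hashlib.sha256(cfg_text.encode()).hexdigest())
    stage = "setup"
    try:
        # ---- simulate or load -------------------------------------------
        stage = "simulate"
        if "songs" in config:
            songs = read_song_table(config["songs"])
            manifest.input_checksums[str(config["songs"])] = sha256_of(config["songs"])
            recordings = songs.drop_duplicates("recording_id")[
                ["individual_id", "recording_id", "year", "date", "context"]
                + (["recording_order"] if "recording_order" in songs else [])]
        else:
            sim_cfg = config_from_dict({**config.get("simulate", {}), "seed": seed})
            params = (parameters_from_dict(config["parameters"])
                      if "parameters" in config else default_true_parameters())
            individuals, truth = simulate_individuals(sim_cfg, params)
            songs = simulate_songs(individuals, truth, params, sim_cfg)
            recordings = individuals
            write_song_table(songs, outdir / "songs.csv")
            truth.to_csv(outdir / "truth_reaction_norms.csv", index=False)
            (outdir / "truth_parameters.yaml").write_text(
                yaml.safe_dump(parameters_to_dict(params), sort_keys=False))
            (outdir / "simulation_config.yaml").write_text(
                yaml.safe_dump(config_to_dict(sim_cfg), sort_keys=False))
        manifest.stages_completed.append(stage)

        # ---- syllables and traits (optional) ----------------------------
        if config.get("traits", {}).get("enabled", False):
            stage = "traits"
            tr_cfg = config["traits"]
            syl = simulate_syllables(songs, K_true=int(tr_cfg.get("K_true", 20)),
                                     seed=seed)
            syl.to_csv(outdir / "syllables.csv", index=False)
            derived = derive_song_traits(syl, K=int(tr_cfg.get("K", 20)), seed=seed)
            derived.to_csv(outdir / "traits.csv", index=False)
            manifest.stages_completed.append(stage)

        fit_cfg = config.get("fit", {})
        if fit_cfg.get("max_songs"):
            songs = apply_max_songs(songs, int(fit_cfg["max_songs"]))
        chains = _chains_from_config(fit_cfg, seed)
        manifest.chain_settings = {
            "n_iterations": chains.n_iterations, "burn_in": chains.burn_in,
            "thin": chains.thin, "n_chains": chains.n_chains,
            "retained": chains.retained,
        }
        prior = PriorConfig(family=fit_cfg.get("prior_family",
                                               "parameter_expanded"))

        # the bivariate SL+MF table may lack complexity: simulate a parallel
        # univariate complexity study under the same design when possible
        complexity_songs = songs
        if "complexity" not in songs.columns and "songs" not in config:
            sim_cfg_c = config_from_dict({**config.get("simulate", {}),
                                          "seed": seed + 1000})
            params_c = default_true_parameters(("complexity",))
            ind_c, truth_c = simulate_individuals(sim_cfg_c, params_c)
            complexity_songs = simulate_songs(ind_c, truth_c, params_c, sim_cfg_c)
            write_song_table(complexity_songs, outdir / "songs_complexity.csv")

        # ---- model fits --------------------------------------------------
        fits: dict[str, PosteriorDraws] = {}
        for name, responses, data in (
                ("bivariate", ("SL", "MF"), songs),
                ("complexity", ("complexity",), complexity_songs)):
            if not all(r in data.columns for r in responses):
                continue
            stage = f"fit_{name}"
            spec = ModelSpec(responses=responses, prior=prior)
            design = build_design(data, spec)
            manifest.rows_dropped[name] = design.rows_dropped
            draws = gibbs_sample(design, spec, chains,
                                 log_every=max(chains.n_iterations // 10, 1))
            fits[name] = draws
            for c in range(draws.n_chains):
                draws_to_frame(draws, c).to_csv(
                    outdir / f"draws_{name}_chain{c}.csv", index=False)
            stage = f"summarize_{name}"
            summarize_fixed_effects(draws).to_csv(
                outdir / f"summary_fixed_{name}.csv", index=False)
            summarize_random_effects(draws).to_csv(
                outdir / f"summary_random_{name}.csv", index=False)
            if draws.n_chains >= 2:
                from .model import gelman_rubin
                rh = gelman_rubin(draws)
                manifest.convergence[name] = {
                    "max_rhat": float(rh.max()), "n_parameters": int(len(rh))}
            manifest.stages_completed.append(f"fit_{name}")

        # ---- repeatability ----------------------------------------------
        rep_cfg = config.get("repeatability", {})
        targets = rep_cfg.get("targets",
                              [{"trait": "SL", "gradient": "order",
                                "context": "male"}])
        if rep_cfg.get("enabled", True) and "recording_order" in songs.columns:
            stage = "repeatability"
            rep_chains = _chains_from_config(
                rep_cfg.get("chains", fit_cfg), seed + 1)
            rows = []
            for tgt in targets:
                try:
                    res = slope_repeatability(
                        songs, recordings, tgt["trait"], tgt["gradient"],
                        tgt["context"], rep_chains, prior=prior)
                    rows.append(res.as_dict())
                except ValueError as exc:
                    logger.warning("repeatability target %s skipped: %s", tgt, exc)
            if rows:
                pd.DataFrame(rows).to_csv(outdir / "repeatability.csv", index=False)
            manifest.stages_completed.append(stage)

        manifest.write(outdir / "manifest.json")
        return manifest
    except Exception as exc:
        manifest.write(outdir / "manifest_partial.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
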