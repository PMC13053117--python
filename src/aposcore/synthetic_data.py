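"""Synthetic detection-game and bioassay data with known ground truth.

Every downstream stage of the pipeline — ingest/QC, detectability
statistics, the phylogenetic binomial model and the variance
decomposition — can be exercised against data whose generative parameters
are known exactly, so correctness is checked by parameter recovery rather
than by eyeballing.

The generator emulates the study design: ~1700 players playing 30-round
games in which each of 30 backgrounds appears exactly once, 120 butterfly
images (59 dorsal + 61 ventral across 61 species, three of them with two
dorsal morphotypes and five lacking a dorsal image), right-censoring of
detection at 10 s, and binomial Daphnia assays of 10 animals with 3-13
assays per species.  Detection times are drawn log-normally around a
latent per-image x background mean — the standard right-skewed choice for
human reaction times; the study itself implies no particular family.  One
designated background per image has its latent mean inflated above all
others, so the true most-cryptic background is known for oracle tests.
Species toxicity follows the logistic model fitted downstream:
logit(p) = beta0 + beta . z(predictors) + u, with u drawn from
N(0, sigma_phylo^2 * C) for the Brownian-motion correlation C of a
simulated pure-birth tree.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import detectability, phylo_cov

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_tree",
    "draw_species_effects",
    "simulate_ground_truth",
    "simulate_game_log",
    "simulate_assays",
    "simulate_dataset",
    "simulate_model_dataset",
]

# near-zero per-Daphnia death probability for control assays; the order of
# magnitude of observed control mortality, not a fitted quantity
CONTROL_DEATH_PROB = 0.005
N_CONTROL_ASSAYS = {"water": 18, "methanol": 18, "cricket": 10, "cockroach": 10}


@dataclass(frozen=True)
class SimConfig:
    """Design constants of a simulated study.

    Defaults reproduce the real study's scale: 61 species, 30 backgrounds
    = 30 rounds per game, 10-s timeout, 10 Daphnia per assay and 3-13
    assays per species.  ``beta0``/``beta_dorsal``/``beta_ventral``/
    ``beta_diff`` (log-odds per SD of predictor) and ``sigma_phylo``
    default to values on the scale of the fitted model's posterior.
    ``detection_noise`` is the log-scale SD of the log-normal detection
    times.
    """

    n_species: int = 61
    n_backgrounds: int = 30
    n_players: int = 1716
    games_per_player: int = 2
    rounds_per_game: int = 30
    timeout_s: float = 10.0
    beta0: float = -1.18
    beta_dorsal: float = -0.21
    beta_ventral: float = -0.06
    beta_diff: float = -0.27
    sigma_phylo: float = 1.0
    assays_min: int = 3
    assays_max: int = 13
    daphnia_per_assay: int = 10
    detection_noise: float = 0.35
    frac_cryptic_backgrounds: float = 0.2
    frac_noncompliant_players: float = 0.03
    n_missing_dorsal: int = 5
    n_dimorphic: int = 3
    learning_slope: float = -0.006
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_species": self.n_species,
            "n_backgrounds": self.n_backgrounds,
            "n_players": self.n_players,
            "games_per_player": self.games_per_player,
            "rounds_per_game": self.rounds_per_game,
            "daphnia_per_assay": self.daphnia_per_assay,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.timeout_s <= 0:
            raise ValueError("timeout_s must be > 0")
        if self.sigma_phylo < 0:
            raise ValueError("sigma_phylo must be >= 0")
        if not 0.0 <= self.frac_cryptic_backgrounds <= 1.0:
            raise ValueError("frac_cryptic_backgrounds must lie in [0, 1]")
        if not 0.0 <= self.frac_noncompliant_players <= 1.0:
            raise ValueError("frac_noncompliant_players must lie in [0, 1]")
        if not 0 < self.assays_min <= self.assays_max:
            raise ValueError("need 0 < assays_min <= assays_max")
        if self.rounds_per_game != self.n_backgrounds:
            raise ValueError(
                "rounds_per_game must equal n_backgrounds: each game shows "
                "every background exactly once"
            )
        if self.n_missing_dorsal + self.n_dimorphic > self.n_species:
            raise ValueError("missing-dorsal plus dimorphic species exceed n_species")
        if self.detection_noise < 0:
            raise ValueError("detection_noise must be >= 0")


@dataclass
class GroundTruth:
    """Latent state of one simulated study."""

    newick: str
    species: list[str]
    genera: dict[str, str]
    u: np.ndarray  # species random effects, log-odds, ordered as `species`
    sigma_phylo: float
    betas: dict[str, float]
    backgrounds: list[str]
    images: pd.DataFrame  # image_id, species_id, morphotype_id, side
    latent_means: np.ndarray  # seconds, (n_images, n_backgrounds)
    cryptic_background: dict[str, str]  # image_id -> designated background
    predictors: pd.DataFrame  # per-species z_dorsal, z_ventral, z_diff

    @property
    def correlation(self) -> phylo_cov.PhyloCorrelation:
        return phylo_cov.correlation_matrix(phylo_cov.read_newick(self.newick))


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_tree(n_species: int, seed: int, birth_rate: float = 1.0) -> str:
    """Ultrametric pure-birth tree with tips ``sp_001``... as a Newick string.

    Lineages split at exponential waiting times with total rate
    ``birth_rate * k`` for ``k`` extant lineages; after the last split the
    tree grows for one more exponential waiting time so that no terminal
    branch has zero length.  All root-to-tip distances are equal by
    construction.
    """
    if n_species < 2:
        raise ValueError("a tree needs at least 2 species")
    rng = np.random.default_rng(seed)
    root = {"t": 0.0, "children": []}
    root["children"] = [{"t": 0.0, "children": []}, {"t": 0.0, "children": []}]
    active = list(root["children"])
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(int(rng.integers(k)))
        node["children"] = [{"t": t, "children": []}, {"t": t, "children": []}]
        active.extend(node["children"])
    t += rng.exponential(1.0 / (birth_rate * n_species))
    counter = iter(range(1, n_species + 1))

    def render(node: dict, parent_t: float) -> str:
        if node["children"]:
            inner = ",".join(render(c, node_time(node)) for c in node["children"])
            body = f"({inner})"
            length = node_time(node) - parent_t
        else:
            body = f"sp_{next(counter):03d}"
            length = t - node["t"]
            return f"{body}:{length:.12g}"
        return f"{body}:{length:.12g}"

    def node_time(node: dict) -> float:
        # time at which this lineage split (its children's birth time)
        return node["children"][0]["t"]

    inner = ",".join(render(c, 0.0) for c in root["children"])
    return f"({inner});"


def draw_species_effects(
    corr: phylo_cov.PhyloCorrelation, sigma_phylo: float, rng: np.random.Generator
) -> np.ndarray:
    """One draw of u ~ MVN(0, sigma_phylo^2 * C) via the Cholesky factor."""
    if sigma_phylo < 0:
        raise ValueError("sigma_phylo must be >= 0")
    return sigma_phylo * (corr.cholesky() @ rng.standard_normal(len(corr.species)))


def simulate_ground_truth(config: SimConfig) -> GroundTruth:
    """Draw the latent state implied by ``config``.

    Deterministic in ``config.seed``.  The per-species predictors are the
    detectability statistics computed from the *latent* detection means by
    the same imputation and z-scoring code the pipeline applies to
    observed data, so the toxicity model's generative coefficients live on
    exactly the scale the fitted coefficients are reported on.
    """
    config.validate()
    rng_tree, rng_species, rng_latent, _, _ = _rngs(config.seed, 5)

    newick = simulate_tree(config.n_species, int(rng_tree.integers(2**31)))
    corr = phylo_cov.correlation_matrix(phylo_cov.read_newick(newick))
    species = corr.species  # sorted == sp_001.. order

    # genera: consecutive blocks of 2-6 species in tip-label order
    genera: dict[str, str] = {}
    g = 0
    i = 0
    while i < len(species):
        size = int(rng_species.integers(2, 7))
        g += 1
        for sp in species[i:i + size]:
            genera[sp] = f"gen_{g:02d}"
        i += size

    special = rng_species.choice(
        config.n_species, size=config.n_missing_dorsal + config.n_dimorphic,
        replace=False,
    )
    missing_dorsal = {species[i] for i in special[:config.n_missing_dorsal]}
    dimorphic = {species[i] for i in special[config.n_missing_dorsal:]}

    rows = []
    for sp in species:
        rows.append((f"img_{sp}_v", sp, sp, "ventral"))
        if sp in missing_dorsal:
            continue
        if sp in dimorphic:
            rows.append((f"img_{sp}_dm", sp, f"{sp}_m", "dorsal"))
            rows.append((f"img_{sp}_df", sp, f"{sp}_f", "dorsal"))
        else:
            rows.append((f"img_{sp}_d", sp, sp, "dorsal"))
    images = pd.DataFrame(
        rows, columns=["image_id", "species_id", "morphotype_id", "side"]
    ).sort_values("image_id", ignore_index=True)

    backgrounds = [f"bg_{i:02d}" for i in range(1, config.n_backgrounds + 1)]
    n_img = len(images)
    # per-image conspicuousness level spans near-immediate detection to
    # close to the ceiling, as in the observed detection-time ranges;
    # backgrounds add moderate variation on top
    level = rng_latent.uniform(0.5, 6.0, size=n_img)
    latent = level[:, None] + rng_latent.uniform(
        0.0, 1.5, size=(n_img, config.n_backgrounds)
    )
    n_mild = int(round(config.frac_cryptic_backgrounds * config.n_backgrounds))
    cryptic_background: dict[str, str] = {}
    for i, img in enumerate(images["image_id"]):
        order = rng_latent.permutation(config.n_backgrounds)
        if n_mild > 1:
            latent[i, order[1:n_mild]] += 1.0
        designated = int(order[0])
        latent[i, designated] = latent[i].max() + 2.0
        cryptic_background[img] = backgrounds[designated]

    u_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(5)[3]
    )
    u = draw_species_effects(corr, config.sigma_phylo, u_rng)

    latent_table = pd.DataFrame(
        {
            "image_id": np.repeat(images["image_id"].to_numpy(), config.n_backgrounds),
            "background_id": np.tile(backgrounds, n_img),
            "mean_time": latent.ravel(),
            "n_rounds": 1,
        }
    )
    predictors = detectability.species_predictors(latent_table, images)

    return GroundTruth(
        newick=newick,
        species=list(species),
        genera=genera,
        u=u,
        sigma_phylo=config.sigma_phylo,
        betas={
            "beta0": config.beta0,
            "beta_dorsal": config.beta_dorsal,
            "beta_ventral": config.beta_ventral,
            "beta_diff": config.beta_diff,
        },
        backgrounds=backgrounds,
        images=images,
        latent_means=latent,
        cryptic_background=cryptic_background,
        predictors=predictors,
    )


def simulate_game_log(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """One round log: players x games x rounds, one background per round.

    Within a game every background appears exactly once, in random order,
    and each round shows an image drawn uniformly from all images.  Times
    are log-normal around the latent mean (exactly the mean when
    ``detection_noise`` is zero), right-censored at the timeout.  A
    configurable fraction of "non-compliant" players find fewer than three
    butterflies, to exercise the QC filter.
    """
    config.validate()
    if rng is None:
        rng = _rngs(config.seed, 7)[5]
    n_games = config.n_players * config.games_per_player
    nbg = config.n_backgrounds
    n_img = len(truth.images)

    bg_idx = rng.permuted(
        np.tile(np.arange(nbg), (n_games, 1)), axis=1
    )  # (games, rounds)
    img_idx = rng.integers(n_img, size=(n_games, nbg))

    game_number = np.repeat(
        np.tile(np.arange(1, config.games_per_player + 1), config.n_players), nbg
    ).reshape(n_games, nbg)
    m = truth.latent_means[img_idx, bg_idx]
    m = np.maximum(m + config.learning_slope * (game_number - 1), 0.3)
    s = config.detection_noise
    if s > 0:
        time = m * np.exp(s * rng.standard_normal(m.shape) - 0.5 * s * s)
    else:
        time = m.copy()
    timeout = time >= config.timeout_s
    time[timeout] = config.timeout_s

    # non-compliant players: almost never find anything
    n_nc = int(round(config.frac_noncompliant_players * config.n_players))
    if n_nc > 0:
        nc_players = rng.choice(config.n_players, size=n_nc, replace=False)
        for p in nc_players:
            g0 = p * config.games_per_player
            rows = slice(g0, g0 + config.games_per_player)
            timeout[rows, :] = True
            time[rows, :] = config.timeout_s
            k = int(rng.integers(0, 3))  # 0-2 finds: below the QC threshold
            if k:
                flat = rng.choice(config.games_per_player * nbg, size=k, replace=False)
                gi, ri = np.unravel_index(flat, (config.games_per_player, nbg))
                timeout[g0 + gi, ri] = False
                time[g0 + gi, ri] = rng.uniform(1.0, 5.0, size=k)

    players = np.repeat(
        [f"u{p:05d}" for p in range(1, config.n_players + 1)],
        config.games_per_player,
    )
    game_ids = np.array(
        [f"{u}_g{j:02d}" for u, j in zip(players, np.tile(
            np.arange(1, config.games_per_player + 1), config.n_players))]
    )
    img_ids = truth.images["image_id"].to_numpy()
    sp_ids = truth.images["species_id"].to_numpy()
    sides = truth.images["side"].to_numpy()
    flat_img = img_idx.ravel()
    df = pd.DataFrame(
        {
            "user_id": np.repeat(players, nbg),
            "game_id": np.repeat(game_ids, nbg),
            "round_index": np.tile(np.arange(1, nbg + 1), n_games),
            "image_id": img_ids[flat_img],
            "species_id": sp_ids[flat_img],
            "side": sides[flat_img],
            "background_id": np.asarray(truth.backgrounds)[bg_idx.ravel()],
            "outcome": np.where(timeout.ravel(), "timeout", "found"),
            "time_s": time.ravel(),
        }
    )
    return df


def _model_eta(
    config: SimConfig, truth: GroundTruth, scores: pd.DataFrame, model: int
) -> pd.Series:
    z = scores.loc[truth.species]
    if model == 1:
        eta = (
            config.beta0
            + config.beta_dorsal * z["z_dorsal"]
            + config.beta_ventral * z["z_ventral"]
        )
    elif model == 2:
        eta = config.beta0 + config.beta_diff * z["z_diff"]
    else:
        raise ValueError("model must be 1 or 2")
    return eta + pd.Series(truth.u, index=truth.species)


def simulate_assays(
    config: SimConfig,
    truth: GroundTruth,
    detectability_scores: pd.DataFrame | None = None,
    model: int = 1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Binomial Daphnia assays given the (z-scored) detectability scores.

    ``detectability_scores`` should be the per-species predictor table the
    pipeline will feed into the model (same imputation, same z-scoring);
    by default the truth's latent-mean-derived table is used.  ``model``
    selects the generative fixed-effect structure (1: dorsal + ventral
    cryptic times; 2: dorsal-ventral difference statistic).  Control
    assays (water, methanol, cricket, cockroach) are generated with a
    near-zero death probability.
    """
    config.validate()
    if rng is None:
        rng = _rngs(config.seed, 7)[6]
    scores = truth.predictors if detectability_scores is None else detectability_scores
    p = expit(_model_eta(config, truth, scores, model).to_numpy(float))

    rows = []
    for sp, p_i in zip(truth.species, p):
        n_assays = int(rng.integers(config.assays_min, config.assays_max + 1))
        deaths = rng.binomial(config.daphnia_per_assay, p_i, size=n_assays)
        for d in deaths:
            rows.append((sp, "butterfly", config.daphnia_per_assay, int(d)))
    for cat, n_assays in N_CONTROL_ASSAYS.items():
        deaths = rng.binomial(config.daphnia_per_assay, CONTROL_DEATH_PROB, size=n_assays)
        for d in deaths:
            rows.append((cat, cat, config.daphnia_per_assay, int(d)))
    return pd.DataFrame(rows, columns=["subject_id", "category", "n_daphnia", "deaths"])


@dataclass
class SimulatedDataset:
    """Everything one simulated study produces, plus its ground truth."""

    config: SimConfig
    truth: GroundTruth
    rounds: pd.DataFrame
    assays_model1: pd.DataFrame
    assays_model2: pd.DataFrame

    def write(self, outdir: str) -> None:
        """Write the dataset as delimited text, Newick and JSON files."""
        os.makedirs(outdir, exist_ok=True)
        self.rounds.to_csv(os.path.join(outdir, "rounds.tsv"), sep="\t", index=False)
        self.assays_model1.to_csv(
            os.path.join(outdir, "assays_model1.tsv"), sep="\t", index=False
        )
        self.assays_model2.to_csv(
            os.path.join(outdir, "assays_model2.tsv"), sep="\t", index=False
        )
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(self.truth.newick + "\n")
        self.truth.images.to_csv(
            os.path.join(outdir, "images.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            {"species_id": self.truth.species,
             "tip_label": self.truth.species}
        ).to_csv(os.path.join(outdir, "mapping.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(self.truth.genera.items()), columns=["species_id", "genus"]
        ).to_csv(os.path.join(outdir, "taxonomy.tsv"), sep="\t", index=False)
        truth_dict = {
            "config": dataclasses.asdict(self.config),
            "betas": self.truth.betas,
            "sigma_phylo": self.truth.sigma_phylo,
            "u": {sp: float(v) for sp, v in zip(self.truth.species, self.truth.u)},
            "cryptic_background": self.truth.cryptic_background,
        }
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(truth_dict, fh, indent=1, sort_keys=True)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Simulate a full study (game log plus assay sets for both models)."""
    truth = simulate_ground_truth(config)
    rng_log, rng_a = _rngs(config.seed, 7)[5:7]
    rounds = simulate_game_log(config, truth, rng_log)
    assays1 = simulate_assays(config, truth, model=1, rng=rng_a)
    assays2 = simulate_assays(config, truth, model=2, rng=rng_a)
    return SimulatedDataset(config, truth, rounds, assays1, assays2)


def simulate_model_dataset(
    n_species: int,
    assays_per_species: int,
    beta: np.ndarray,
    sigma_phylo: float,
    seed: int,
    daphnia_per_assay: int = 10,
    predictor_names: tuple[str, ...] = ("z_diff",),
):
    """Small model-only dataset for parameter-recovery experiments.

    Generates a pure-birth tree, z-scored standard-normal predictors, a
    phylogenetically correlated species effect and binomial assay counts,
    and returns ``(ModelData, truth)`` where ``truth`` holds the exact
    generative parameters (including the realised ``u``).
    """
    from .bayes_glmm import ModelData

    beta = np.asarray(beta, dtype=float)
    if beta.size != len(predictor_names) + 1:
        raise ValueError("beta must hold intercept plus one slope per predictor")
    rng = np.random.default_rng(seed)
    newick = simulate_tree(n_species, int(rng.integers(2**31)))
    corr = phylo_cov.correlation_matrix(phylo_cov.read_newick(newick))
    X_species = np.column_stack(
        [np.ones(n_species)]
        + [
            detectability.zscore(rng.standard_normal(n_species))
            for _ in predictor_names
        ]
    )
    u = draw_species_effects(corr, sigma_phylo, rng)
    p = expit(X_species @ beta + u)
    species_idx = np.repeat(np.arange(n_species), assays_per_species)
    y = rng.binomial(daphnia_per_assay, p[species_idx])
    data = ModelData(
        y=y,
        n=np.full(len(y), daphnia_per_assay),
        species_idx=species_idx,
        X=X_species[species_idx],
        predictor_names=["Intercept", *predictor_names],
        species=corr.species,
        C=corr,
    )
    truth = {"beta": beta, "sigma_phylo": sigma_phylo, "u": u, "newick": newick}
    return data, truth
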