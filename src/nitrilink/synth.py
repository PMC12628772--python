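"""Synthetic activated-sludge community generator with planted structure.

Produces the inputs the downstream analysis assumes: a two-period
environmental time series, a samples-by-taxa count table with a small
nitrifier guild, taxa correlated with the guild at controllable strengths,
independent noise taxa, and a nitrification-rate series driven by the
associated taxa.  Every output is deterministic given the configuration
(including its seed), so the whole analysis chain can be verified by
parameter recovery.

The latent-to-composition map is a softmax of Gaussian latents (log-normal
like composition) and counts are multinomial at a fixed depth, which keeps
planted correlations interpretable on the log-abundance scale.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio

log = logging.getLogger("nitrilink")

#: Pseudocount used for any diagnostic log transform of counts.
PSEUDOCOUNT = 0.5

_ENV_VARS = ("ic", "nh4", "temperature", "salinity")

_DEFAULT_ENV_MEANS = {
    # per-period means (period 1, period 2); magnitudes typical of an
    # industrial AO process treating high-nitrogen wastewater
    "ic": (92.5, 62.7),
    "nh4": (44.4, 70.7),
    "temperature": (34.4, 31.8),
    "salinity": (1.7, 1.7),
}

_DEFAULT_ENV_SDS = {"ic": 10.0, "nh4": 15.0, "temperature": 1.3, "salinity": 0.25}

_NOISE_GENERA = (
    "Flavobacterium", "Thauera", "Zoogloea", "Dechloromonas", "Haliangium",
    "Terrimonas", "Ferruginibacter", "Rhodobacter", "Dokdonella", "Acidovorax",
)


class SimConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    ``association_strengths`` gives the target latent correlation between
    each associate taxon and the shared nitrifier signal; ``rate_weights``
    gives each associate's contribution to the nitrification rate per unit
    relative abundance.  Both default to deterministic grids when ``None``.
    """

    n_days_period1: int = 44
    n_days_period2: int = 48
    n_nitrifiers: int = 3
    n_associates: int = 12
    n_noise: int = 45
    association_strengths: tuple | None = None
    depth: int = 20000
    env_means: dict = field(default_factory=lambda: dict(_DEFAULT_ENV_MEANS))
    env_sds: dict = field(default_factory=lambda: dict(_DEFAULT_ENV_SDS))
    env_ar1: float = 0.6
    rate_weights: tuple | None = None
    rate_intercept: float = 15.0
    rate_noise_sd: float = 1.0
    rate_lag_days: int = 0
    hrt_days: float = 5.0
    seed: int = 0

    # latent geometry knobs (fixed across the study's experiments)
    nitrifier_driver_loading: float = 0.95
    latent_scale_nitrifier: float = 0.6
    latent_scale_associate: float = 0.8
    latent_scale_noise: float = 1.0
    base_offset_nitrifier: float = -0.5
    base_offset_associate: float = 0.5

    def __post_init__(self):
        if min(self.n_days_period1, self.n_days_period2) < 0:
            raise SimConfigError("period lengths must be >= 0")
        if self.n_days_period1 + self.n_days_period2 < 1:
            raise SimConfigError("at least one day must be simulated")
        if min(self.n_nitrifiers, self.n_associates, self.n_noise) < 0:
            raise SimConfigError("taxon group sizes must be >= 0")
        if self.depth < 1:
            raise SimConfigError("sequencing depth must be >= 1")
        if not 0.0 <= self.env_ar1 < 1.0:
            raise SimConfigError("env_ar1 must lie in [0, 1)")
        strengths = self.strengths()
        if len(strengths) != self.n_associates:
            raise SimConfigError(
                "association_strengths length must equal n_associates"
            )
        if any(not 0.0 < s <= 1.0 for s in strengths):
            raise SimConfigError("association strengths must lie in (0, 1]")
        if len(self.weights()) != self.n_associates:
            raise SimConfigError("rate_weights length must equal n_associates")
        missing = [v for v in _ENV_VARS if v not in self.env_means]
        if missing:
            raise SimConfigError(f"env_means missing variables: {missing}")

    def strengths(self) -> tuple:
        if self.association_strengths is not None:
            return tuple(self.association_strengths)
        if self.n_associates == 0:
            return ()
        return tuple(
            np.round(np.linspace(0.35, 0.9, self.n_associates), 4)
        )

    def weights(self) -> tuple:
        if self.rate_weights is not None:
            return tuple(self.rate_weights)
        # alternate signs so the rate tracks composition, not total load
        return tuple(
            120.0 * (1 if j % 2 == 0 else -1) * (0.5 + s)
            for j, s in enumerate(self.strengths())
        )

    @property
    def n_days(self) -> int:
        return self.n_days_period1 + self.n_days_period2

    @property
    def n_taxa(self) -> int:
        return self.n_nitrifiers + self.n_associates + self.n_noise

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise SimConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("association_strengths", "rate_weights"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["association_strengths"] = (
            None if self.association_strengths is None
            else list(self.association_strengths)
        )
        out["rate_weights"] = (
            None if self.rate_weights is None else list(self.rate_weights)
        )
        return out


def _taxon_ids(config: SimConfig) -> tuple:
    nit = [f"KTU_N{i + 1:03d}" for i in range(config.n_nitrifiers)]
    assoc = [f"KTU_A{i + 1:03d}" for i in range(config.n_associates)]
    noise = [f"KTU_X{i + 1:03d}" for i in range(config.n_noise)]
    return nit, assoc, noise


def simulate_environment(config: SimConfig) -> pd.DataFrame:
    """Generate the per-day environment table.

    Each variable follows a stationary AR(1) process around its period mean:
    innovations are scaled by sqrt(1 - phi^2) so the marginal standard
    deviation equals the configured one, and the initial state is drawn from
    the stationary distribution.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_days
    periods = np.r_[
        np.ones(config.n_days_period1, dtype=int),
        np.full(config.n_days_period2, 2, dtype=int),
    ]
    dates = pd.date_range("2018-05-01", periods=n, freq="D")
    table = {}
    for var in _ENV_VARS:
        mu = np.where(
            periods == 1, config.env_means[var][0], config.env_means[var][1]
        ).astype(float)
        sd = float(config.env_sds.get(var, 0.0))
        phi = config.env_ar1
        x = np.empty(n)
        innov_sd = sd * np.sqrt(1.0 - phi**2)
        prev = rng.normal(0.0, sd) if sd > 0 else 0.0
        for t in range(n):
            dev = phi * prev + (rng.normal(0.0, innov_sd) if sd > 0 else 0.0)
            # rng is advanced even when sd == 0 to keep streams aligned
            x[t] = mu[t] + dev
            prev = dev
        table[var] = x
    env = pd.DataFrame(table)
    env.insert(0, "period", periods)
    env.insert(0, "date", dates)
    env.index = pd.Index(
        [f"S{t + 1:03d}" for t in range(n)], name="sample_id"
    )
    return env


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_counts(config: SimConfig, env: pd.DataFrame):
    """Generate counts, annotations, and ground truth from an environment.

    Returns
    -------
    counts : DataFrame
        Samples-by-taxa integer counts; every row sums to ``config.depth``.
    annotation : DataFrame
        Lineage, genus, and nitrification gene flags per taxon, emulating a
        gene-prediction output joined with taxonomy.
    truth : DataFrame
        Role (nitrifier/associate/noise), planted correlation, and rate
        weight per taxon.
    """
    if len(env) != config.n_days:
        raise SimConfigError("environment table does not cover all days")
    if config.depth < config.n_taxa:
        log.warning(
            "depth %d is below the number of taxa %d; many taxa will be "
            "unobserved in each sample", config.depth, config.n_taxa,
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_days
    nit_ids, assoc_ids, noise_ids = _taxon_ids(config)
    taxa = nit_ids + assoc_ids + noise_ids

    # shared nitrifier signal: linear response to standardized NH4 and IC
    driver = _standardize(
        0.7 * _standardize(env["nh4"].to_numpy())
        + 0.7 * _standardize(env["ic"].to_numpy())
    )

    load = config.nitrifier_driver_loading
    z = np.empty((n, config.n_taxa))
    col = 0
    for _ in range(config.n_nitrifiers):
        resid = rng.normal(size=n)
        z[:, col] = load * driver + np.sqrt(1 - load**2) * resid
        col += 1
    strengths = config.strengths()
    for rho in strengths:
        resid = rng.normal(size=n)
        z[:, col] = rho * driver + np.sqrt(1 - rho**2) * resid
        col += 1
    for _ in range(config.n_noise):
        z[:, col] = rng.normal(size=n)
        col += 1

    scales = np.r_[
        np.full(config.n_nitrifiers, config.latent_scale_nitrifier),
        np.full(config.n_associates, config.latent_scale_associate),
        np.full(config.n_noise, config.latent_scale_noise),
    ]
    base = np.r_[
        np.full(config.n_nitrifiers, config.base_offset_nitrifier),
        np.full(config.n_associates, config.base_offset_associate),
        rng.normal(0.0, 1.0, size=config.n_noise),
    ]
    logits = base[None, :] + scales[None, :] * z
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)

    counts = np.vstack(
        [rng.multinomial(config.depth, probs[t]) for t in range(n)]
    )
    counts = pd.DataFrame(counts, index=env.index, columns=taxa)

    annotation = _build_annotation(config, nit_ids, assoc_ids, noise_ids)
    truth = pd.DataFrame(
        {
            "role": (
                ["nitrifier"] * config.n_nitrifiers
                + ["associate"] * config.n_associates
                + ["noise"] * config.n_noise
            ),
            "planted_correlation": np.r_[
                np.full(config.n_nitrifiers, np.nan),
                np.asarray(strengths, dtype=float),
                np.full(config.n_noise, np.nan),
            ],
            "rate_weight": np.r_[
                np.zeros(config.n_nitrifiers),
                np.asarray(config.weights(), dtype=float),
                np.zeros(config.n_noise),
            ],
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    return counts, annotation, truth


def _build_annotation(config, nit_ids, assoc_ids, noise_ids) -> pd.DataFrame:
    rows = []
    for i, tid in enumerate(nit_ids):
        if i % 2 == 0:
            genus, amo, nxr = "Nitrosomonas", True, False
        else:
            genus, amo, nxr = "Nitrospira", False, True
        rows.append((tid, genus, amo, nxr))
    for i, tid in enumerate(assoc_ids):
        rows.append((tid, _NOISE_GENERA[i % len(_NOISE_GENERA)], False, False))
    for i, tid in enumerate(noise_ids):
        genus, amo, nxr = _NOISE_GENERA[i % len(_NOISE_GENERA)], False, False
        # decoys exercising the two-criterion nitrifier selection
        if i == 0 and config.n_noise >= 1:
            genus = "Nitrospira"          # lineage without the gene flags
        elif i == 1 and config.n_noise >= 2:
            genus, amo = "Escherichia", True  # gene flag without the lineage
        rows.append((tid, genus, amo, nxr))
    ann = pd.DataFrame(
        rows, columns=["taxon_id", "genus", "amo", "nxr"]
    ).set_index("taxon_id")
    ann.insert(
        0,
        "lineage",
        ["d__Bacteria;g__" + g for g in ann["genus"]],
    )
    return ann


def simulate_rate(
    config: SimConfig, counts: pd.DataFrame, truth: pd.DataFrame
) -> pd.Series:
    """Generate the nitrification-rate series (mg-N/L/day).

    rate(day) = intercept + sum_taxa rate_weight * relative abundance +
    Gaussian noise.  With ``config.rate_lag_days`` > 0 the composition term
    is taken from ``rate_lag_days`` earlier (edge days reuse the first day).
    """
    if not counts.columns.equals(truth.index):
        raise SimConfigError("counts and ground truth must share taxa")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    rel = counts.to_numpy(dtype=float)
    rel /= rel.sum(axis=1, keepdims=True)
    contrib = rel @ truth["rate_weight"].to_numpy()
    if config.rate_lag_days > 0:
        lag = config.rate_lag_days
        contrib = np.r_[np.full(lag, contrib[0]), contrib[:-lag]]
    noise = rng.normal(0.0, config.rate_noise_sd, size=len(counts))
    rate = config.rate_intercept + contrib + noise
    return pd.Series(rate, index=counts.index, name="rate")


def simulate_dataset(config: SimConfig):
    """Run the full generator chain; returns (env, counts, annotation, truth, rate)."""
    env = simulate_environment(config)
    counts, annotation, truth = simulate_counts(config, env)
    rate = simulate_rate(config, counts, truth)
    return env, counts, annotation, truth, rate


def write_dataset(config: SimConfig, outdir) -> None:
    """Generate a dataset and write it under ``outdir``.

    Files: counts.tsv, annotation.csv, metadata.csv, ground_truth.csv and
    config.json.  Metadata carries the environment, the rate, and an
    influent/effluent nitrogen balance consistent with the rate at the
    configured hydraulic retention time so the chemistry stage can be run
    end to end on synthetic data.
    """
    outdir = Path(outdir)
    env, counts, annotation, truth, rate = simulate_dataset(config)
    meta = env.copy()
    meta["rate"] = rate

    # back out a nitrogen balance: production = rate * HRT
    influent_orgn = np.full(len(meta), 65.0)
    influent_no2 = np.full(len(meta), 0.5)
    in_sum = influent_orgn + meta["nh4"].to_numpy() + influent_no2
    production = np.clip(rate.to_numpy() * config.hrt_days, 0.0, in_sum * 0.99)
    out_sum = in_sum - production
    meta["influent_organic_n"] = influent_orgn
    meta["influent_nh4_n"] = meta["nh4"]
    meta["influent_no2_n"] = influent_no2
    meta["effluent_organic_n"] = 0.60 * out_sum
    meta["effluent_nh4_n"] = 0.35 * out_sum
    meta["effluent_no2_n"] = 0.05 * out_sum
    meta["hrt_days"] = config.hrt_days

    nio.write_count_table(counts, outdir / "counts.tsv")
    nio.atomic_write_text(outdir / "annotation.csv", annotation.to_csv())
    nio.write_metadata(meta, outdir / "metadata.csv")
    nio.atomic_write_text(outdir / "ground_truth.csv", truth.to_csv())
    nio.atomic_write_text(
        outdir / "config.json", json.dumps(config.to_dict(), indent=2)
    )
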