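"""Synthetic field-trial data with the statistical structure the analyses assume.

The raw field data behind the trial are unpublished, so this module generates
record-level destructive-sampling data, per-stump emergence counts and
trap x taxon community matrices whose distributions match the published
summary tables:

* infection outcomes per treatment are multinomial with the printed
  within-treatment proportions;
* developmental stages follow the printed population structure;
* emergence counts are negative binomial (NB2, variance mu + mu^2/theta)
  around a log-linear mean with Gaussian block effects and the printed
  treatment rate ratios;
* community counts are independent Poisson draws per trap and taxon, with
  an optional per-treatment multiplier to create compositional effects
  (1 everywhere = the null the trial observed).

One root seed drives everything; each dataset uses its own fixed substream,
so generating one dataset never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .vocab import OUTCOMES, STAGES, TREATMENTS

_PROB_TOL = 1e-9

# Fixed substream index per dataset: adding a dataset appends a key and
# cannot shift existing streams.
_STREAMS = {"destructive": 0, "emergence": 1, "community": 2}


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


def _default_outcome_probs() -> dict[str, tuple[float, ...]]:
    # Within-treatment outcome proportions implied by the published counts.
    out = {}
    for t, counts in datasets.TREATMENT_OUTCOME_COUNTS.items():
        total = sum(counts)
        out[t] = tuple(c / total for c in counts)
    return out


def _default_stage_probs() -> tuple[float, ...]:
    # larva/pupa/adult = 244/123/32 of 399.
    margins = {s: sum(c) for s, c in datasets.STAGE_OUTCOME_COUNTS.items()}
    total = sum(margins.values())
    return tuple(margins[s] / total for s in STAGES)


def _default_rate_ratios() -> dict[str, float]:
    rr = {"control": 1.0}
    rr.update({t: v["ratio"] for t, v in datasets.EMERGENCE_RATIOS.items()})
    return rr


def _default_depth_model() -> dict[str, tuple[float, float]]:
    # Normal(location, scale) per outcome, cm; negative = below ground.
    # Locations follow the published per-outcome depth means; scales chosen
    # to span the published ranges.
    return {
        "alive": (-16.36, 8.0),
        "nematode_killed": (-15.68, 8.0),
        "fungus_killed": (-9.4, 6.0),
        "indeterminate": (-13.36, 6.0),
    }


def _default_distance_model() -> dict[str, tuple[float, float]]:
    # (probability of distance exactly 0, mean of the nonzero exponential
    # tail) per outcome; medians of 0 with positive means require a point
    # mass at the bole.
    return {
        "alive": (0.6, 14.7),
        "nematode_killed": (0.6, 12.6),
        "fungus_killed": (0.6, 5.4),
        "indeterminate": (0.6, 7.5),
    }


def _default_taxon_means() -> dict[str, float]:
    # Broad-taxon expected counts per trap over a season: a few dominant
    # groups and a long tail of scarcer ones.
    return {
        "Coleoptera": 12.0,
        "Diptera": 20.0,
        "Hymenoptera": 6.0,
        "Lepidoptera": 2.0,
        "Myriopoda": 1.5,
        "Arachnida": 4.0,
        "Opilionidae": 1.0,
        "Auchenorhyncha": 1.0,
        "Collembola": 8.0,
    }


@dataclass
class SimulationConfig:
    """All tunables of the synthetic trial, with published-table defaults.

    ``outcome_probs`` maps treatment -> probabilities over the four
    infection outcomes (vocabulary order); ``stage_probs`` is over
    larva/pupa/adult; ``rate_ratios`` are emergence multipliers vs control
    (control must be 1); ``nb_dispersion`` is the NB2 theta
    (variance = mu + mu^2/theta); ``block_sd`` the SD of log-scale block
    effects. ``depth_model``/``distance_model`` give per-outcome location
    parameters for where infected weevils sit in the stump.
    """

    seed: int = 0
    n_blocks: int = 10
    treatments: tuple[str, ...] = TREATMENTS
    outcome_probs: dict[str, tuple[float, ...]] = field(default_factory=_default_outcome_probs)
    stage_probs: tuple[float, ...] = field(default_factory=_default_stage_probs)
    weevils_per_stump: float = 10.0
    emergence_intercept: float = float(np.log(20.0))
    rate_ratios: dict[str, float] = field(default_factory=_default_rate_ratios)
    block_sd: float = 0.3
    nb_dispersion: float = 5.0
    depth_model: dict[str, tuple[float, float]] = field(default_factory=_default_depth_model)
    distance_model: dict[str, tuple[float, float]] = field(default_factory=_default_distance_model)
    community_taxon_means: dict[str, float] = field(default_factory=_default_taxon_means)
    community_effect: dict[str, float] = field(default_factory=lambda: {t: 1.0 for t in TREATMENTS})

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if self.treatments[0] != "control":
            raise ConfigError("treatments must list control first")
        for t in self.treatments:
            probs = np.asarray(self.outcome_probs.get(t, ()), dtype=float)
            if probs.shape != (len(OUTCOMES),):
                raise ConfigError(f"outcome_probs[{t!r}] must have {len(OUTCOMES)} entries")
            if (probs < 0).any() or abs(probs.sum() - 1.0) > _PROB_TOL:
                raise ConfigError(f"outcome_probs[{t!r}] is not a probability vector: {probs}")
        stage = np.asarray(self.stage_probs, dtype=float)
        if stage.shape != (len(STAGES),) or (stage < 0).any() or abs(stage.sum() - 1.0) > _PROB_TOL:
            raise ConfigError(f"stage_probs is not a probability vector: {stage}")
        if self.rate_ratios.get("control") != 1.0:
            raise ConfigError("rate_ratios['control'] must equal 1")
        if any(r <= 0 for r in self.rate_ratios.values()):
            raise ConfigError("rate_ratios must be positive")
        if not self.nb_dispersion > 0:
            raise ConfigError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        if self.block_sd < 0:
            raise ConfigError("block_sd must be >= 0")
        if self.weevils_per_stump < 0:
            raise ConfigError("weevils_per_stump must be >= 0")
        if any(m < 0 for m in self.community_taxon_means.values()):
            raise ConfigError("community_taxon_means must be non-negative")
        if any(e < 0 for e in self.community_effect.values()):
            raise ConfigError("community_effect must be non-negative")
        for t in self.treatments:
            if t not in self.rate_ratios:
                raise ConfigError(f"rate_ratios missing treatment {t!r}")
            if t not in self.community_effect:
                raise ConfigError(f"community_effect missing treatment {t!r}")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one dataset's substream."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["treatments"] = list(d["treatments"])
        d["stage_probs"] = list(d["stage_probs"])
        d["outcome_probs"] = {k: list(v) for k, v in d["outcome_probs"].items()}
        d["depth_model"] = {k: list(v) for k, v in d["depth_model"].items()}
        d["distance_model"] = {k: list(v) for k, v in d["distance_model"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("treatments", "stage_probs"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("outcome_probs", "depth_model", "distance_model"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from a YAML or JSON document."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)


def _blocks(n: int) -> list[str]:
    return [f"B{i + 1:02d}" for i in range(n)]


def simulate_destructive(config: SimulationConfig) -> pd.DataFrame:
    """Record-level destructive-sampling data: one row per weevil.

    Per stump (block x treatment) the number of weevils found is Poisson
    around ``weevils_per_stump``; each weevil gets a stage, a
    treatment-conditional infection outcome, a depth draw (negative below
    ground, with the location model's small positive tail above) and a
    zero-inflated distance to the bole.
    """
    config.validate()
    rng = config.rng("destructive")
    rows = []
    for block in _blocks(config.n_blocks):
        for treatment in config.treatments:
            n = rng.poisson(config.weevils_per_stump)
            if n == 0:
                continue
            stages = rng.choice(len(STAGES), size=n, p=np.asarray(config.stage_probs))
            outcomes = rng.choice(
                len(OUTCOMES), size=n, p=np.asarray(config.outcome_probs[treatment])
            )
            for s_i, o_i in zip(stages, outcomes):
                outcome = OUTCOMES[o_i]
                loc, scale = config.depth_model[outcome]
                depth = rng.normal(loc, scale)
                p_zero, mean_nz = config.distance_model[outcome]
                dist = 0.0 if rng.random() < p_zero else rng.exponential(mean_nz)
                rows.append(
                    {
                        "block": block,
                        "treatment": treatment,
                        "stage": STAGES[s_i],
                        "outcome": outcome,
                        "depth_cm": depth,
                        "dist_bole_cm": dist,
                    }
                )
    return pd.DataFrame(
        rows, columns=["block", "treatment", "stage", "outcome", "depth_cm", "dist_bole_cm"]
    )


def simulate_emergence(config: SimulationConfig) -> pd.DataFrame:
    """Per-stump emergence counts over a complete randomised-block layout.

    Counts are gamma-Poisson (NB2) with mean
    exp(intercept + block_effect + log rate_ratio) and dispersion theta;
    block effects are Normal(0, block_sd^2) on the log scale.
    """
    config.validate()
    rng = config.rng("emergence")
    theta = config.nb_dispersion
    rows = []
    for block in _blocks(config.n_blocks):
        b = rng.normal(0.0, config.block_sd) if config.block_sd > 0 else 0.0
        for treatment in config.treatments:
            mu = float(np.exp(config.emergence_intercept + b + np.log(config.rate_ratios[treatment])))
            lam = rng.gamma(theta, mu / theta)
            count = int(rng.poisson(lam))
            rows.append({"block": block, "treatment": treatment, "emerged": count})
    return pd.DataFrame(rows, columns=["block", "treatment", "emerged"])


def simulate_community(config: SimulationConfig):
    """Trap x taxon community counts, one trap per block x treatment.

    Counts are independent Poisson with mean
    taxon_mean x community_effect[treatment]; effects of 1 everywhere give
    the compositional null.
    """
    from .community import CommunityMatrix

    config.validate()
    rng = config.rng("community")
    taxa = list(config.community_taxon_means)
    means = np.array([config.community_taxon_means[t] for t in taxa], dtype=float)
    labels, meta_rows, count_rows = [], [], []
    for block in _blocks(config.n_blocks):
        for treatment in config.treatments:
            label = f"trap_{block}_{treatment}"
            labels.append(label)
            meta_rows.append({"block": block, "treatment": treatment})
            count_rows.append(rng.poisson(means * config.community_effect[treatment]))
    counts = pd.DataFrame(count_rows, index=labels, columns=taxa)
    meta = pd.DataFrame(meta_rows, index=labels)
    return CommunityMatrix(counts=counts, meta=meta, granularity="broad")


# -- delimited-text output -----------------------------------------------


def write_destructive_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def write_emergence_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def write_community_csv(cm, path: str | Path) -> None:
    out = pd.concat([cm.meta, cm.counts], axis=1)
    out.index.name = "trap"
    out.to_csv(path)


def read_community_csv(path: str | Path, granularity: str = "broad"):
    from .community import CommunityMatrix

    df = pd.read_csv(path, index_col="trap")
    df.index.name = None
    meta = df[["block", "treatment"]]
    counts = df.drop(columns=["block", "treatment"])
    return CommunityMatrix(counts=counts, meta=meta, granularity=granularity)
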