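"""Synthetic two-diet, two-timepoint study generator.

Emulates the statistical structure the pipeline assumes: a gene x
sample log2 expression matrix for HFD vs LFD mice profiled at an early
("5d", n = 10 per diet) and a late ("12w", n = 12 per diet) timepoint,
a biological-process gene-set collection, a TF -> target regulon
collection, and a per-animal physiology table.  Three kinds of signal
are planted and recorded in a truth manifest:

* *regulons* — each planted TF's target block is shifted by
  ``direction * effect_size`` log2 units in HFD samples only, making the
  targets differentially expressed with a known direction;
* *processes* — planted process sets draw half their members from the
  planted (DE) genes, so they are enriched at the extremes of the
  t-ranking;
* *physiology links* — a latent animal-level Gaussian factor drives both
  a parameter and a gene module, with the slope calibrated through the
  bivariate-normal relation rho_S = (6/pi)*asin(rho_P/2) so the
  population Spearman correlation magnitude is ``link_rho_target``.

Timepoints are generated as independent cohorts over a shared gene
universe (distinct animals per timepoint); gene noise is Gaussian on
the log2 scale with constant standard deviation.  Everything is a pure
function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio

__all__ = [
    "SynthConfig",
    "TruthManifest",
    "SyntheticStudy",
    "generate_study",
    "write_study",
    "read_study",
]

TIMEPOINTS = ("5d", "12w")
DIETS = ("HFD", "LFD")


class ConfigurationError(ValueError):
    """An infeasible synthetic-study configuration."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic study design.

    Defaults mirror the emulated design: 10 animals per diet at 5 days
    and 12 per diet at 12 weeks, gene sets restricted to 15-500
    members, a planted log2 effect of 1.5 against residual noise SD 0.5,
    and phenotype-module links targeting Spearman |rho| = 0.9.
    """

    n_genes: int = 2000
    n_per_group: dict = field(default_factory=lambda: {"5d": 10, "12w": 12})
    n_processes: int = 120
    process_size_range: tuple = (15, 500)
    n_planted_processes: int = 5
    n_regulons: int = 60
    regulon_size_range: tuple = (10, 100)
    n_planted_regulons: int = 5
    planted_directions: tuple | None = None  # default: alternate +1/-1
    effect_size: float = 1.5
    noise_sd: float = 0.5
    n_physio_params: int = 11
    n_linked_params: int = 3
    link_module_size: int = 50
    link_rho_target: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_processes < 0 or self.n_regulons < 0:
            raise ConfigurationError("counts must be positive")
        for tp in TIMEPOINTS:
            if self.n_per_group.get(tp, 0) < 2:
                raise ConfigurationError(f"need >=2 animals per diet at {tp}")
        for lo, hi in (self.process_size_range, self.regulon_size_range):
            if not (1 <= lo <= hi <= self.n_genes):
                raise ConfigurationError(
                    "size range must satisfy 1 <= lo <= hi <= n_genes"
                )
        if not (0.0 <= self.link_rho_target < 1.0):
            raise ConfigurationError("link_rho_target must lie in [0, 1)")
        if self.n_planted_regulons > self.n_regulons:
            raise ConfigurationError("more planted regulons than regulons")
        if self.n_planted_processes > self.n_processes:
            raise ConfigurationError("more planted processes than processes")
        if self.n_linked_params > self.n_physio_params:
            raise ConfigurationError("more linked parameters than parameters")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        worst_planted = self.n_planted_regulons * self.regulon_size_range[1]
        worst_modules = self.n_linked_params * self.link_module_size
        if worst_planted + worst_modules > self.n_genes:
            raise ConfigurationError(
                "planted regulon targets and linked modules cannot be "
                f"disjoint within {self.n_genes} genes"
            )
        if (
            self.planted_directions is not None
            and len(self.planted_directions) != self.n_planted_regulons
        ):
            raise ConfigurationError(
                "planted_directions must have one entry per planted regulon"
            )


@dataclass
class TruthManifest:
    """What was planted: ids, directions, modules, per-gene DE status."""

    planted_regulons: dict  # TF -> +1 / -1
    planted_processes: tuple
    linked_params: dict  # parameter -> tuple of module genes
    de_direction: dict  # gene -> +1 / -1 (genes absent are null)

    def to_dict(self) -> dict:
        return {
            "planted_regulons": dict(self.planted_regulons),
            "planted_processes": list(self.planted_processes),
            "linked_params": {k: list(v) for k, v in self.linked_params.items()},
            "de_direction": dict(self.de_direction),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthManifest":
        return cls(
            planted_regulons={k: int(v) for k, v in d["planted_regulons"].items()},
            planted_processes=tuple(d["planted_processes"]),
            linked_params={k: tuple(v) for k, v in d["linked_params"].items()},
            de_direction={k: int(v) for k, v in d["de_direction"].items()},
        )


@dataclass
class SyntheticStudy:
    expression: pd.DataFrame  # genes x samples (both timepoints)
    samples: pd.DataFrame  # index sample id; columns diet, timepoint
    processes: dict  # name -> tuple of genes
    regulons: dict  # TF -> tuple of genes
    physiology: pd.DataFrame  # index animal id; params + timepoint column
    truth: TruthManifest
    config: SynthConfig

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.samples.index):
            raise ValueError("sample table rows must match expression columns")
        if set(self.physiology.index) != set(self.samples.index):
            raise ValueError("physiology rows must match the animals")
        if self.expression.index.duplicated().any():
            raise ValueError("gene identifiers must be unique")


def _pearson_for_spearman(rho_s: float) -> float:
    """Invert rho_S = (6/pi) * asin(rho_P / 2) (bivariate normal)."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _draw_size(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Log-uniform set size: many small sets, few large ones."""
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi + 0.49)))))


def generate_study(config: SynthConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from a validated config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    mu = rng.uniform(6.0, 12.0, config.n_genes)

    # --- regulons; planted ones get disjoint target blocks -------------
    lo_r, hi_r = config.regulon_size_range
    plant_effects = config.effect_size != 0 and config.n_planted_regulons > 0
    if config.planted_directions is not None:
        directions = [int(np.sign(d)) or 1 for d in config.planted_directions]
    else:
        directions = [1 if i % 2 == 0 else -1 for i in range(config.n_planted_regulons)]

    pool = rng.permutation(config.n_genes)
    cursor = 0
    regulons: dict[str, tuple] = {}
    de_direction = np.zeros(config.n_genes, dtype=int)
    planted_regulons: dict[str, int] = {}
    for i in range(config.n_regulons):
        name = f"TF{i + 1:03d}"
        size = int(rng.integers(lo_r, hi_r + 1))
        if i < config.n_planted_regulons:
            block = pool[cursor : cursor + size]
            cursor += size
            regulons[name] = tuple(sorted(genes[block]))
            if plant_effects:
                de_direction[block] = directions[i]
                planted_regulons[name] = directions[i]
        else:
            members = rng.choice(config.n_genes, size, replace=False)
            regulons[name] = tuple(sorted(genes[members]))
    de_pool = np.flatnonzero(de_direction != 0)

    # --- linked physiology modules: disjoint, from null genes ----------
    null_pool = rng.permutation(np.flatnonzero(de_direction == 0))
    param_names = [f"param_{i + 1:02d}" for i in range(config.n_physio_params)]
    plant_links = config.link_rho_target > 0 and config.n_linked_params > 0
    linked_params: dict[str, tuple] = {}
    module_idx: dict[str, np.ndarray] = {}
    if plant_links:
        for i in range(config.n_linked_params):
            name = param_names[i]
            block = null_pool[
                i * config.link_module_size : (i + 1) * config.link_module_size
            ]
            module_idx[name] = block
            linked_params[name] = tuple(sorted(genes[block]))
    module_sign = {
        name: rng.choice([-1.0, 1.0], size=len(block))
        for name, block in module_idx.items()
    }

    # --- processes; planted ones sample half their members from DE -----
    lo_p, hi_p = config.process_size_range
    processes: dict[str, tuple] = {}
    planted_processes: list[str] = []
    unplanted_tfs = [
        f"TF{i + 1:03d}"
        for i in range(config.n_planted_regulons, config.n_regulons)
    ]
    gene_index = {g: i for i, g in enumerate(genes)}
    for i in range(config.n_processes):
        name = f"PROC{i + 1:04d}"
        size = min(_draw_size(rng, lo_p, hi_p), config.n_genes - 1)
        if i < config.n_planted_processes and plant_effects and de_pool.size:
            n_sig = min(size // 2, de_pool.size)
            sig = rng.choice(de_pool, n_sig, replace=False)
            rest_pool = np.setdiff1d(np.arange(config.n_genes), sig)
            rest = rng.choice(rest_pool, size - n_sig, replace=False)
            members = np.concatenate([sig, rest])
            planted_processes.append(name)
        elif unplanted_tfs:
            # seed part of the set from a regulon's targets so that
            # cross-layer overlap edges exist by construction
            tf = unplanted_tfs[int(rng.integers(len(unplanted_tfs)))]
            tf_idx = np.array([gene_index[g] for g in regulons[tf]])
            n_tf = min(size // 4, tf_idx.size)
            part = rng.choice(tf_idx, n_tf, replace=False)
            rest_pool = np.setdiff1d(np.arange(config.n_genes), part)
            rest = rng.choice(rest_pool, size - n_tf, replace=False)
            members = np.concatenate([part, rest])
        else:
            members = rng.choice(config.n_genes, size, replace=False)
        processes[name] = tuple(sorted(genes[members]))

    # --- expression + physiology per timepoint --------------------------
    rho_p = _pearson_for_spearman(config.link_rho_target)
    slope = (
        config.noise_sd * rho_p / np.sqrt(1.0 - rho_p**2) if plant_links else 0.0
    )
    expr_blocks = []
    sample_rows = []
    physio_rows = []
    for tp in TIMEPOINTS:
        n = config.n_per_group[tp]
        sample_ids = [
            f"{tp}_{diet}_{i + 1:02d}" for diet in DIETS for i in range(n)
        ]
        is_hfd = np.array([sid.split("_")[1] == "HFD" for sid in sample_ids])
        block = mu[:, None] + rng.normal(
            0.0, config.noise_sd, (config.n_genes, 2 * n)
        )
        if plant_effects:
            block[:, is_hfd] += (de_direction * config.effect_size)[:, None]
        physio = pd.DataFrame(
            index=pd.Index(sample_ids, name="animal"), columns=param_names,
            dtype=float,
        )
        for name in param_names:
            latent = rng.normal(0.0, 1.0, 2 * n)
            physio[name] = latent
            if name in module_idx:
                block[module_idx[name], :] += (
                    module_sign[name][:, None] * slope * latent[None, :]
                )
        physio["timepoint"] = tp
        expr_blocks.append(
            pd.DataFrame(block, index=pd.Index(genes, name="gene"), columns=sample_ids)
        )
        sample_rows += [
            (sid, sid.split("_")[1], tp) for sid in sample_ids
        ]
        physio_rows.append(physio)

    expression = pd.concat(expr_blocks, axis=1)
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "diet", "timepoint"]
    ).set_index("sample")
    physiology = pd.concat(physio_rows, axis=0)

    truth = TruthManifest(
        planted_regulons=planted_regulons,
        planted_processes=tuple(planted_processes),
        linked_params=linked_params,
        de_direction={
            genes[i]: int(de_direction[i])
            for i in np.flatnonzero(de_direction != 0)
        },
    )
    return SyntheticStudy(
        expression=expression,
        samples=samples,
        processes=processes,
        regulons=regulons,
        physiology=physiology,
        truth=truth,
        config=config,
    )


def _config_to_dict(config: SynthConfig) -> dict:
    d = dataclasses.asdict(config)
    d["process_size_range"] = list(d["process_size_range"])
    d["regulon_size_range"] = list(d["regulon_size_range"])
    if d["planted_directions"] is not None:
        d["planted_directions"] = list(d["planted_directions"])
    return d


def _config_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    d["process_size_range"] = tuple(d["process_size_range"])
    d["regulon_size_range"] = tuple(d["regulon_size_range"])
    if d.get("planted_directions") is not None:
        d["planted_directions"] = tuple(d["planted_directions"])
    return SynthConfig(**d)


def write_study(study: SyntheticStudy, directory) -> dict:
    """Write the study as TSV / GMT / JSON files; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "samples": directory / "samples.tsv",
        "physiology": directory / "physiology.tsv",
        "processes": directory / "processes.gmt",
        "regulons": directory / "regulons.gmt",
        "truth": directory / "truth.json",
    }
    tio.write_expression(study.expression, paths["expression"])
    study.samples.to_csv(paths["samples"], sep="\t")
    study.physiology.to_csv(paths["physiology"], sep="\t")
    tio.write_gmt(study.processes, paths["processes"])
    tio.write_gmt(study.regulons, paths["regulons"])
    payload = {
        "truth": study.truth.to_dict(),
        "config": _config_to_dict(study.config),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}


def read_study(directory) -> SyntheticStudy:
    """Re-read a written study; inverse of :func:`write_study`."""
    directory = Path(directory)
    expression = tio.read_expression(directory / "expression.tsv")
    samples = pd.read_csv(directory / "samples.tsv", sep="\t", index_col=0)
    physiology = pd.read_csv(directory / "physiology.tsv", sep="\t", index_col=0)
    processes = {k: tuple(v) for k, v in tio.read_gmt(directory / "processes.gmt").items()}
    regulons = {k: tuple(v) for k, v in tio.read_gmt(directory / "regulons.gmt").items()}
    payload = json.loads((directory / "truth.json").read_text())
    return SyntheticStudy(
        expression=expression,
        samples=samples,
        processes=processes,
        regulons=regulons,
        physiology=physiology,
        truth=TruthManifest.from_dict(payload["truth"]),
        config=_config_from_dict(payload["config"]),
    )
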