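"""Synthetic PSM generator for an iTRAQ four-plex two-experiment design.

The raw spectra behind the rat SAH cerebral-artery proteome were never
deposited, so every downstream stage is exercised against simulated
peptide-spectrum matches with known ground truth. The generator emulates the
study design: two labeling experiments, channels mapped U0126 -> 114,
vehicle -> 115, sham -> 116 (117 quantified but unassigned), pooled protein
abundances, multiplicative reporter noise, a stated fraction of truly
regulated proteins, and decoy PSMs drawn from a lower score distribution.

Reporter intensities are multiplicative on the log2 scale:

    intensity(channel) = base_abundance * 2 ** (true_log2(channel) + eps),
    eps ~ Normal(0, noise_sd), independent per PSM and per channel,

so the expected per-PSM log2(115/116) ratio of a protein equals its true
vehicle-vs-sham effect. Peptide sequences are unique to one protein (no
shared-peptide protein inference is simulated), and decoy PSMs carry no
ground-truth entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .psm_io import PSMRecord, write_psm_table

__all__ = [
    "GeneratorConfig", "generate_experiment",
    "write_psm_table", "write_truth_table", "read_truth_table",
]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

TRUTH_COLUMNS = ["accession", "true_log2_vehicle", "true_log2_u0126", "status_vehicle", "reversed"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic iTRAQ experiment.

    Defaults are the study conditions used throughout the test suite:
    2,000 proteins, 10% truly regulated (5% up, 5% down in vehicle vs sham)
    with |log2| effect 1.5, all regulation reversed by U0126 treatment,
    per-PSM log2 reporter noise 0.3, about four PSMs per protein, two
    labeling experiments, and well-separated target/decoy score
    distributions (mean 40 vs 10, sd 5) around the Mascot-like floor of 18.
    """

    n_proteins: int = 2000
    #: (mean, dispersion) of the per-protein PSM count; counts are
    #: 1 + NegativeBinomial(dispersion, mean - 1) per labeling experiment.
    peptides_per_protein: tuple[float, float] = (4.0, 2.0)
    #: (log-mean, log-sd) of the per-protein reference intensity (natural log).
    base_abundance: tuple[float, float] = (11.5, 1.0)
    noise_sd: float = 0.3
    frac_up_vehicle: float = 0.05
    frac_down_vehicle: float = 0.05
    frac_reversed: float = 1.0
    effect_size: float = 1.5
    decoy_fraction: float = 0.1
    #: (mean, sd) of target and decoy search scores.
    target_score: tuple[float, float] = (40.0, 5.0)
    decoy_score: tuple[float, float] = (10.0, 5.0)
    n_experiments: int = 2
    seed: int = 0
    #: Condition mapped to channel 117 (None leaves 117 empty, matching the
    #: three-of-four-channel study design). May name any of the three
    #: conditions to duplicate it into the spare channel.
    channel_117: str | None = None

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be a positive integer")
        mean, dispersion = self.peptides_per_protein
        if mean < 1:
            raise ConfigError("peptides_per_protein mean must be >= 1")
        if dispersion <= 0:
            raise ConfigError("peptides_per_protein dispersion must be > 0")
        if self.base_abundance[1] < 0:
            raise ConfigError("base_abundance log-sd must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for name in ("frac_up_vehicle", "frac_down_vehicle", "frac_reversed", "decoy_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.frac_up_vehicle + self.frac_down_vehicle > 1.0:
            raise ConfigError("frac_up_vehicle + frac_down_vehicle must be <= 1")
        if self.decoy_fraction >= 1.0:
            raise ConfigError("decoy_fraction must be < 1")
        if self.effect_size <= 0:
            raise ConfigError("effect_size must be > 0")
        if self.target_score[1] < 0 or self.decoy_score[1] < 0:
            raise ConfigError("target_score / decoy_score sd must be >= 0")
        if self.n_experiments < 1:
            raise ConfigError("n_experiments must be a positive integer")
        if self.channel_117 is not None and self.channel_117 not in {"u0126", "vehicle", "sham"}:
            raise ConfigError("channel_117 must be one of u0126/vehicle/sham or None")


def _peptide(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        length = int(rng.integers(8, 16))
        seq = "".join(rng.choice(_AMINO_ACIDS, size=length))
        if seq not in used:
            used.add(seq)
            return seq


def _truth(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_proteins
    n_up = int(round(config.frac_up_vehicle * n))
    n_down = int(round(config.frac_down_vehicle * n))
    status = np.array(["none"] * n, dtype=object)
    regulated = rng.permutation(n)[: n_up + n_down]
    status[regulated[:n_up]] = "up"
    status[regulated[n_up:]] = "down"
    true_vehicle = np.where(status == "up", config.effect_size,
                            np.where(status == "down", -config.effect_size, 0.0))
    reversed_flag = np.zeros(n, dtype=bool)
    is_reg = status != "none"
    reversed_flag[is_reg] = rng.random(is_reg.sum()) < config.frac_reversed
    true_u0126 = np.where(is_reg & ~reversed_flag, true_vehicle, 0.0)
    return pd.DataFrame({
        "accession": [f"SYN{i:05d}" for i in range(n)],
        "true_log2_vehicle": true_vehicle,
        "true_log2_u0126": true_u0126,
        "status_vehicle": status,
        "reversed": reversed_flag,
    })


def generate_experiment(config: GeneratorConfig) -> tuple[list[PSMRecord], pd.DataFrame]:
    """Simulate PSM tables for ``config.n_experiments`` labeling experiments.

    Returns the PSM records (targets and decoys, all experiments interleaved
    by experiment) and the ground-truth table, one row per target protein.
    Identical config (including seed) yields byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _truth(config, rng)

    mean, dispersion = config.peptides_per_protein
    log_mu, log_sd = config.base_abundance
    base = np.exp(rng.normal(log_mu, log_sd, size=config.n_proteins))

    channel_truth = {114: "true_log2_u0126", 115: "true_log2_vehicle", 116: None}
    used_peptides: set[str] = set()
    records: list[PSMRecord] = []
    for exp_index in range(config.n_experiments):
        experiment_id = f"exp{exp_index + 1}"
        if mean > 1:
            p = dispersion / (dispersion + mean - 1.0)
            n_psms = 1 + rng.negative_binomial(dispersion, p, size=config.n_proteins)
        else:
            n_psms = np.ones(config.n_proteins, dtype=int)
        counter = 0
        for prot in range(config.n_proteins):
            row = truth.iloc[prot]
            for _ in range(int(n_psms[prot])):
                intensities = {}
                for channel, column in channel_truth.items():
                    true_log2 = 0.0 if column is None else float(row[column])
                    eps = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                    intensities[channel] = float(base[prot] * 2.0 ** (true_log2 + eps))
                if config.channel_117 is not None:
                    column = {"u0126": "true_log2_u0126", "vehicle": "true_log2_vehicle",
                              "sham": None}[config.channel_117]
                    true_log2 = 0.0 if column is None else float(row[column])
                    eps = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                    intensities[117] = float(base[prot] * 2.0 ** (true_log2 + eps))
                records.append(PSMRecord(
                    psm_id=f"{experiment_id}:{counter:06d}",
                    experiment_id=experiment_id,
                    peptide=_peptide(rng, used_peptides),
                    accession=str(row["accession"]),
                    score=float(rng.normal(*config.target_score)),
                    is_decoy=False,
                    intensities=intensities,
                ))
                counter += 1
        # Decoys: expected fraction decoy_fraction of all rows in the experiment.
        n_targets = counter
        f = config.decoy_fraction
        n_decoys = rng.binomial(n_targets, f / (1.0 - f)) if f > 0 else 0
        decoy_base = np.exp(rng.normal(log_mu, log_sd, size=n_decoys))
        for d in range(n_decoys):
            intensities = {}
            for channel in (114, 115, 116):
                eps = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                intensities[channel] = float(decoy_base[d] * 2.0 ** eps)
            records.append(PSMRecord(
                psm_id=f"{experiment_id}:{counter:06d}",
                experiment_id=experiment_id,
                peptide=_peptide(rng, used_peptides),
                accession=f"DECOY{exp_index + 1}_{d:05d}",
                score=float(rng.normal(*config.decoy_score)),
                is_decoy=True,
                intensities=intensities,
            ))
            counter += 1
    return records, truth


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", dtype={"accession": str})
    missing = set(TRUTH_COLUMNS) - set(truth.columns)
    if missing:
        raise ConfigError(f"truth table missing columns {sorted(missing)}")
    return truth
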