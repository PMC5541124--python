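"""Protein-level log2 reporter ratios and median normalization.

Each PSM contributes one log2 ratio per assigned non-reference channel,
log2(intensity[channel] / intensity[reference]); a protein's ratio in a
channel is the median of its PSM ratios (robust to single aberrant spectra).
Ratios are then normalized per channel within each labeling experiment by
subtracting the channel's median across proteins, which removes loading and
labeling bias; duplicate experiments are merged afterwards by averaging each
protein's ratios across the experiments in which it was quantified.

Protein-ratio tables are plain :class:`pandas.DataFrame` objects with columns
``accession, experiment_id, channel, log2_ratio, n_psms`` (after merging,
``experiment_id`` is replaced by ``n_experiments``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, QuantificationError
from .psm_io import PSMRecord

__all__ = [
    "ExperimentDesign", "DEFAULT_DESIGN", "psm_log2_ratio",
    "aggregate_protein", "median_normalize", "merge_experiments",
]

RATIO_COLUMNS = ["accession", "experiment_id", "channel", "log2_ratio", "n_psms"]

CONDITIONS = ("u0126", "vehicle", "sham", "unused")


@dataclass(frozen=True)
class ExperimentDesign:
    """Channel-to-condition assignment for one labeling experiment.

    The default mirrors the study: 114 -> u0126, 115 -> vehicle, 116 -> sham
    (the reference), 117 unused. ``experiment_id="*"`` applies the design to
    every experiment in a table.
    """

    experiment_id: str = "*"
    channel_map: Mapping[int, str] = field(default_factory=lambda: {
        114: "u0126", 115: "vehicle", 116: "sham", 117: "unused"})
    reference_channel: int = 116

    def validate(self) -> None:
        for channel, condition in self.channel_map.items():
            if channel not in (114, 115, 116, 117):
                raise ConfigError(f"channel_map: unknown channel {channel}")
            if condition not in CONDITIONS:
                raise ConfigError(f"channel_map: unknown condition {condition!r}")
        assigned = [c for c in self.channel_map.values() if c != "unused"]
        if len(assigned) != len(set(assigned)):
            raise ConfigError("channel_map: each condition may be assigned to at most one channel")
        if self.channel_map.get(self.reference_channel) != "sham":
            raise ConfigError("reference_channel must be mapped to the sham condition")

    def quantified_channels(self) -> list[int]:
        """Channels carrying a condition, excluding the reference."""
        return [ch for ch, cond in sorted(self.channel_map.items())
                if cond != "unused" and ch != self.reference_channel]

    def condition_of(self, channel: int) -> str:
        return self.channel_map[channel]


DEFAULT_DESIGN = ExperimentDesign()


def psm_log2_ratio(psm: PSMRecord, channel: int, reference_channel: int = 116) -> float | None:
    """log2(intensity[channel] / intensity[reference]), or None when either
    intensity is missing or zero (missing is a value, not an error)."""
    num = psm.intensities.get(channel)
    den = psm.intensities.get(reference_channel)
    if num is None or den is None or num == 0 or den == 0:
        return None
    return math.log2(num / den)


def _design_for(designs, experiment_id: str) -> ExperimentDesign:
    if isinstance(designs, ExperimentDesign):
        if designs.experiment_id not in ("*", experiment_id):
            raise ConfigError(
                f"design is for experiment {designs.experiment_id!r}, table has {experiment_id!r}")
        return designs
    try:
        return designs[experiment_id]
    except KeyError:
        raise ConfigError(f"no design for experiment {experiment_id!r}") from None


def aggregate_protein(
    psms: Sequence[PSMRecord],
    design: ExperimentDesign | Mapping[str, ExperimentDesign] = DEFAULT_DESIGN,
) -> pd.DataFrame:
    """Aggregate filtered PSMs to protein-level log2 ratios.

    Per (accession, experiment, channel): median of the per-PSM log2 ratios
    vs the reference channel and the count of contributing PSMs. Proteins
    with no usable PSM for a channel are absent for that channel. Empty input
    yields an empty table.
    """
    if isinstance(design, ExperimentDesign):
        design.validate()
    else:
        for d in design.values():
            d.validate()
    rows = []
    for psm in psms:
        d = _design_for(design, psm.experiment_id)
        for channel in d.quantified_channels():
            ratio = psm_log2_ratio(psm, channel, d.reference_channel)
            if ratio is not None:
                rows.append((psm.accession, psm.experiment_id, channel, ratio))
    if not rows:
        return pd.DataFrame(columns=RATIO_COLUMNS)
    table = pd.DataFrame(rows, columns=["accession", "experiment_id", "channel", "ratio"])
    agg = (table.groupby(["accession", "experiment_id", "channel"], sort=True)["ratio"]
           .agg(log2_ratio="median", n_psms="count").reset_index())
    return agg[RATIO_COLUMNS]


def median_normalize(
    ratios: pd.DataFrame, experiment_id: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center each channel's protein log2 ratios at zero per experiment.

    Returns the normalized table and an offsets table
    ``(experiment_id, channel, offset)`` where ``offset`` is the subtracted
    channel median. A channel with fewer than two proteins raises
    :class:`QuantificationError` naming the channel. Idempotent.
    """
    if experiment_id is not None:
        ratios = ratios[ratios["experiment_id"] == experiment_id]
    if ratios.empty:
        raise QuantificationError("no ratios to normalize")
    normalized = ratios.copy()
    offsets = []
    for (exp, channel), group in ratios.groupby(["experiment_id", "channel"], sort=True):
        if len(group) < 2:
            raise QuantificationError(
                f"channel {channel} in experiment {exp!r} has {len(group)} protein(s); "
                "need at least 2 to estimate a median offset")
        offset = float(group["log2_ratio"].median())
        normalized.loc[group.index, "log2_ratio"] = group["log2_ratio"] - offset
        offsets.append((exp, channel, offset))
    return normalized.reset_index(drop=True), pd.DataFrame(
        offsets, columns=["experiment_id", "channel", "offset"])


def merge_experiments(ratios: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Combine duplicate labeling experiments into one ratio per protein.

    The merged ratio is the mean of a protein's (normalized) log2 ratios
    across the experiments where it was quantified. With ``strict=True``, a
    protein-channel whose per-experiment ratios disagree in sign is dropped
    (concordance requirement) whenever it was seen in more than one
    experiment.
    """
    if ratios.empty:
        return pd.DataFrame(columns=["accession", "channel", "log2_ratio", "n_experiments", "n_psms"])
    grouped = ratios.groupby(["accession", "channel"], sort=True)
    merged = grouped.agg(
        log2_ratio=("log2_ratio", "mean"),
        n_experiments=("experiment_id", "nunique"),
        n_psms=("n_psms", "sum"),
    ).reset_index()
    if strict:
        sign_ok = grouped["log2_ratio"].agg(
            lambda v: len(v) == 1 or np.all(np.sign(v) == np.sign(v.iloc[0]))).reset_index(drop=True)
        merged = merged[sign_ok.values].reset_index(drop=True)
    return merged
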