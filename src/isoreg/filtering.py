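"""Target-decoy FDR estimation and the two-stage PSM filter.

The study's identification filter is reproduced in effect: PSMs are kept at
1% peptide-level FDR (estimated with a decoy approach) and a Mascot score
floor of 18. The semi-supervised rescoring step of tools like percolator is
deliberately not re-implemented; plain target-decoy q-values give the same
operational filter on well-separated score distributions.

For a score threshold t,

    FDR(t) = #{decoys with score >= t} / max(1, #{targets with score >= t})

and the q-value of a PSM with score s is min over thresholds t <= s of
FDR(t), which makes q-values monotone non-increasing in score. By default
q-values are estimated separately per labeling experiment (``experiment_id``);
``pool=True`` estimates them over the pooled table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, FilterError
from .psm_io import PSMRecord

__all__ = ["FilterConfig", "estimate_qvalues", "apply_filter"]


@dataclass(frozen=True)
class FilterConfig:
    """Retention rule: q-value at most ``fdr_threshold`` and score at least
    ``score_floor``. The defaults (1% FDR, floor 18) are the study's filter."""

    fdr_threshold: float = 0.01
    score_floor: float = 18.0

    def validate(self) -> None:
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ConfigError("fdr_threshold must be in (0, 1]")
        if not np.isfinite(self.score_floor):
            raise ConfigError("score_floor must be finite")


def _qvalues_one_group(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """q-values for one group of PSMs; vectorized over distinct thresholds."""
    n_targets = int((~is_decoy).sum())
    if n_targets == 0:
        raise FilterError("cannot estimate q-values: no target PSMs in group")
    thresholds = np.unique(scores)  # ascending
    # counts with score >= t for each distinct threshold t
    order = np.argsort(scores, kind="stable")
    sorted_scores = scores[order]
    sorted_decoy = is_decoy[order].astype(np.int64)
    total = len(scores)
    # index of first element >= t
    first_ge = np.searchsorted(sorted_scores, thresholds, side="left")
    decoy_cum = np.concatenate([np.cumsum(sorted_decoy[::-1])[::-1], [0]])
    decoys_ge = decoy_cum[first_ge]
    targets_ge = (total - first_ge) - decoys_ge
    fdr = decoys_ge / np.maximum(1, targets_ge)
    # q at threshold t = min FDR over thresholds <= t  (ascending running min)
    q_at_threshold = np.minimum.accumulate(fdr)
    idx = np.searchsorted(thresholds, scores)
    return q_at_threshold[idx]


def estimate_qvalues(psms: Sequence[PSMRecord], pool: bool = False) -> list[PSMRecord]:
    """Annotate every PSM (targets and decoys) with its target-decoy q-value.

    Pure: returns new records, input untouched and order preserved. Raises
    :class:`FilterError` on empty input or a group without any target PSM.
    """
    if not psms:
        raise FilterError("cannot estimate q-values on an empty PSM collection")
    scores = np.array([p.score for p in psms], dtype=float)
    decoys = np.array([p.is_decoy for p in psms], dtype=bool)
    qs = np.empty(len(psms), dtype=float)
    if pool:
        qs[:] = _qvalues_one_group(scores, decoys)
    else:
        groups: dict[str, list[int]] = {}
        for i, p in enumerate(psms):
            groups.setdefault(p.experiment_id, []).append(i)
        for experiment_id, idx in groups.items():
            idx_arr = np.array(idx)
            try:
                qs[idx_arr] = _qvalues_one_group(scores[idx_arr], decoys[idx_arr])
            except FilterError as exc:
                raise FilterError(f"experiment {experiment_id!r}: {exc}") from None
    return [p.with_q(float(q)) for p, q in zip(psms, qs)]


def apply_filter(psms: Sequence[PSMRecord], config: FilterConfig = FilterConfig()) -> list[PSMRecord]:
    """Retain target PSMs with q <= fdr_threshold and score >= score_floor.

    Requires q-values (see :func:`estimate_qvalues`); order is preserved and
    decoys are always dropped.
    """
    config.validate()
    for p in psms:
        if p.q_value is None:
            raise FilterError(f"PSM {p.psm_id!r} has no q-value; run estimate_qvalues first")
    return [p for p in psms
            if not p.is_decoy
            and p.q_value <= config.fdr_threshold
            and p.score >= config.score_floor]
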