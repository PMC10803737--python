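"""End-to-end orchestration helpers shared by the CLI and scripts.

Thin glue over the library modules: load (or receive) a run, calibrate RT
on high-confidence anchors, gate and score every candidate, and hand the
weight-independent (A, M, R) components to evaluation or identification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from mars.errors import DataError
from mars.psm_io import FilterConfig, SampleTyping, SpectrumCandidateSet
from mars.scoring import (
    DEFAULT_WEIGHTS,
    ModelWeights,
    MProvider,
    RescoredSpectrum,
    Rescorer,
    RNormalization,
    RTCalibration,
    RTPredictor,
    calibrate_rt,
    select_rt_anchors,
)


@dataclass
class ScoredRun:
    rescored: list[RescoredSpectrum]
    normalization: RNormalization
    calibration: RTCalibration


def score_run(
    sets: Sequence[SpectrumCandidateSet],
    typings: Mapping[str, SampleTyping],
    m_provider: MProvider,
    rt_predictor: RTPredictor,
    weights: ModelWeights = DEFAULT_WEIGHTS,
    filters: FilterConfig = FilterConfig(),
    anchor_alc: float = 95.0,
    robust_calibration: bool = False,
) -> ScoredRun:
    """Calibrate RT on ALC >= ``anchor_alc`` anchors, then rescore the run."""
    if not sets:
        raise DataError("empty run: no candidate sets")
    anchors = select_rt_anchors(sets, alc_threshold=anchor_alc)
    calibration = calibrate_rt(anchors, rt_predictor, robust=robust_calibration)
    rescorer = Rescorer(
        m_provider=m_provider,
        rt_predictor=rt_predictor,
        calibration=calibration,
        weights=weights,
        filters=filters,
    )
    rescored, norm = rescorer.rescore_run(sets, typings)
    return ScoredRun(rescored=rescored, normalization=norm, calibration=calibration)
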