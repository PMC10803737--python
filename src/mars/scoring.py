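"""Score providers, RT calibration and the composite affine model.

The composite ("MARS") score of a candidate is the positive affine
combination::

    (1 - alpha - beta) * A + alpha * (100 - M) + beta * R

with ``A`` the de novo confidence (ALC), ``M`` the MHC eluted-ligand
percentile rank reduced to the best (minimum) rank over the sample's
alleles, and ``R`` the retention-time agreement: ``delta_t`` =
|t_predicted − t_observed| min-max normalised onto [0,100] over the run
being scored, 100 = perfect agreement. With ``beta = 0`` the model reduces
to the two-factor (M+A) alpha model; with ``alpha = beta = 0`` it is the
plain ALC baseline.

External predictors (MHC rank, raw RT) are pluggable providers: table-backed
implementations read the TSV interchange formats; a self-contained toy PSSM
provider exists so nothing external is ever required. Raw RT predictions are
mapped to observed minutes by an affine least-squares calibration fitted on
high-confidence anchors (ALC >= 95), standing in for per-chromatography
transfer learning of a deep RT model.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mars.errors import DataError, ProviderError
from mars.psm_io import (
    AMINO_ACIDS,
    CandidateRecord,
    FilterConfig,
    SpectrumCandidateSet,
)

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class ModelWeights:
    """Weights (alpha on the M term, beta on the R term) of the composite."""

    alpha: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise DataError("alpha and beta must be non-negative")
        if self.alpha + self.beta > 1.0 + 1e-12:
            raise DataError(
                f"alpha + beta = {self.alpha + self.beta} exceeds 1 "
                "(positive affine combination required)"
            )


#: Fixed production weights of the three-factor model.
DEFAULT_WEIGHTS = ModelWeights(alpha=0.71, beta=0.08)


@dataclass
class ScoreVector:
    """The (A, M, R) triple for one candidate, plus its composite score."""

    a: float
    m: float
    r: float
    composite: float | None = None


@dataclass(frozen=True)
class RTRecord:
    peptide: str
    t_observed: float
    t_predicted: float

    @property
    def delta_t(self) -> float:
        return abs(self.t_predicted - self.t_observed)


@dataclass(frozen=True)
class RNormalization:
    """Run-level min-max bounds of delta_t used to place R on [0,100]."""

    delta_min: float
    delta_max: float

    def __post_init__(self) -> None:
        if self.delta_min > self.delta_max:
            raise DataError("delta_min must be <= delta_max")
        if self.delta_min < 0:
            raise DataError("delta bounds must be non-negative")


@dataclass(frozen=True)
class RTCalibration:
    """Affine map raw predictor output -> observed minutes."""

    slope: float
    intercept: float
    anchor_count: int
    residual_sd: float

    def apply(self, raw: float) -> float:
        return self.slope * raw + self.intercept


class MProvider(Protocol):
    """Per-allele eluted-ligand percentile rank provider."""

    def rank(self, peptide: str, allele: str) -> float: ...


class RTPredictor(Protocol):
    """Raw (uncalibrated) retention-time predictor."""

    def predict(self, peptide: str) -> float: ...


class TableMProvider:
    """M-rank provider backed by a (peptide, allele) -> rank table."""

    def __init__(self, table: Mapping[tuple[str, str], float]):
        self._table = dict(table)

    @classmethod
    def from_tsv(cls, path) -> "TableMProvider":
        df = pd.read_csv(path, sep="\t")
        required = {"peptide", "allele", "m_rank"}
        if not required.issubset(df.columns):
            raise DataError(f"{path}: provider table needs columns {sorted(required)}")
        return cls(
            {
                (str(r.peptide), str(r.allele)): float(r.m_rank)
                for r in df.itertuples()
            }
        )

    def rank(self, peptide: str, allele: str) -> float:
        try:
            return self._table[(peptide, allele)]
        except KeyError:
            raise ProviderError(
                f"no M-rank for peptide {peptide!r} under allele {allele!r}"
            ) from None


class TableRTPredictor:
    """Raw-RT predictor backed by a peptide -> raw_rt table."""

    def __init__(self, table: Mapping[str, float]):
        self._table = dict(table)

    @classmethod
    def from_tsv(cls, path) -> "TableRTPredictor":
        df = pd.read_csv(path, sep="\t")
        if not {"peptide", "raw_rt"}.issubset(df.columns):
            raise DataError(f"{path}: RT table needs columns ['peptide', 'raw_rt']")
        df = df.drop_duplicates(subset="peptide")
        return cls({str(r.peptide): float(r.raw_rt) for r in df.itertuples()})

    def predict(self, peptide: str) -> float:
        try:
            return self._table[peptide]
        except KeyError:
            raise ProviderError(f"no RT prediction for peptide {peptide!r}") from None


def m_score(peptide: str, alleles: Sequence[str], provider: MProvider) -> float:
    """Best-binding-allele reduction: minimum rank over the sample's alleles."""
    if not alleles:
        raise DataError("allele list is empty")
    ranks = []
    for allele in alleles:
        try:
            ranks.append(float(provider.rank(peptide, allele)))
        except ProviderError:
            raise
        except Exception as exc:  # provider plugin failure
            raise ProviderError(f"provider failed for allele {allele!r}: {exc}") from exc
    return min(ranks)


def pssm_score(peptide: str, pssm: np.ndarray) -> float:
    """Sum of per-position log-odds of a length-matched PSSM."""
    pssm = np.asarray(pssm, dtype=float)
    if pssm.shape != (len(peptide), len(AMINO_ACIDS)):
        raise DataError(
            f"PSSM shape {pssm.shape} incompatible with {len(peptide)}-mer query"
        )
    idx = [_AA_INDEX[aa] for aa in peptide]
    return float(pssm[np.arange(len(peptide)), idx].sum())


def toy_pssm_rank(
    peptide: str,
    pssm: np.ndarray,
    background_sampler: Callable[[np.random.Generator, int, int], np.ndarray] | None = None,
    n_background: int = 10_000,
    seed: int | None = 0,
) -> float:
    """Percentile rank of a query against random same-length background.

    Returns ``100 * fraction of n_background random peptides scoring >= the
    query``, i.e. the same convention as eluted-ligand percentile ranks:
    smaller = stronger motif match. Deterministic given ``seed``.

    ``background_sampler(rng, length, n)`` must return an (n, length) integer
    array of residue indices; the default samples residues uniformly.
    """
    if n_background < 100:
        raise DataError("n_background must be >= 100")
    pssm = np.asarray(pssm, dtype=float)
    query = pssm_score(peptide, pssm)
    rng = np.random.default_rng(seed)
    length = len(peptide)
    if background_sampler is None:
        bg = rng.integers(0, len(AMINO_ACIDS), size=(n_background, length))
    else:
        bg = np.asarray(background_sampler(rng, length, n_background))
    scores = pssm[np.arange(length)[None, :], bg].sum(axis=1)
    return float(100.0 * np.mean(scores >= query - 1e-12))


class PssmMProvider:
    """Toy M provider: percentile rank against a per-length PSSM set.

    A stand-in with the same contract as an external MHC predictor table;
    background score distributions are pre-sampled once per length so
    candidate-list scoring stays fast and deterministic.
    """

    def __init__(
        self,
        pssms_by_allele: Mapping[str, Mapping[int, np.ndarray]],
        n_background: int = 10_000,
        seed: int = 0,
    ):
        self._pssms = {a: dict(p) for a, p in pssms_by_allele.items()}
        self._n_background = n_background
        self._seed = seed
        self._bg_scores: dict[tuple[str, int], np.ndarray] = {}

    def _background(self, allele: str, length: int) -> np.ndarray:
        key = (allele, length)
        if key not in self._bg_scores:
            pssm = self._pssms[allele][length]
            allele_key = zlib.crc32(allele.encode()) % (2**31)
            rng = np.random.default_rng((self._seed, allele_key, length))
            bg = rng.integers(0, len(AMINO_ACIDS), size=(self._n_background, length))
            self._bg_scores[key] = np.sort(
                pssm[np.arange(length)[None, :], bg].sum(axis=1)
            )
        return self._bg_scores[key]

    def rank(self, peptide: str, allele: str) -> float:
        if allele not in self._pssms:
            raise ProviderError(f"no motif model for allele {allele!r}")
        if len(peptide) not in self._pssms[allele]:
            raise ProviderError(
                f"peptide length {len(peptide)} outside provider support for {allele!r}"
            )
        query = pssm_score(peptide, self._pssms[allele][len(peptide)])
        bg = self._background(allele, len(peptide))
        n_ge = len(bg) - np.searchsorted(bg, query - 1e-12, side="left")
        return float(100.0 * n_ge / len(bg))


def select_rt_anchors(
    sets: Iterable[SpectrumCandidateSet], alc_threshold: float = 95.0
) -> list[tuple[str, float]]:
    """High-confidence (peptide, observed RT) anchor pairs for calibration.

    Takes the top-ALC candidate of each spectrum when its ALC meets the
    threshold — a small but reliable identification set.
    """
    anchors = []
    for cset in sets:
        if cset.candidates and cset.candidates[0].alc >= alc_threshold:
            anchors.append((cset.candidates[0].peptide, cset.observed_rt))
    return anchors


def calibrate_rt(
    anchors: Sequence[tuple[str, float]],
    predictor: RTPredictor,
    robust: bool = False,
) -> RTCalibration:
    """Fit the affine map raw prediction -> observed minutes on anchors.

    ``robust=True`` uses a Theil–Sen median-slope fit, which tolerates the
    occasional wrong anchor identification.
    """
    if len(anchors) < 2:
        raise DataError(
            f"need >= 2 RT anchors, got {len(anchors)}; lower the ALC threshold"
        )
    raw = np.array([predictor.predict(p) for p, _ in anchors], dtype=float)
    obs = np.array([t for _, t in anchors], dtype=float)
    if np.ptp(raw) < 1e-12:
        raise DataError("zero variance in raw RT predictions; cannot calibrate")
    if robust:
        slope, intercept, *_ = stats.theilslopes(obs, raw)
    else:
        slope, intercept = np.polyfit(raw, obs, 1)
    resid = obs - (slope * raw + intercept)
    return RTCalibration(
        slope=float(slope),
        intercept=float(intercept),
        anchor_count=len(anchors),
        residual_sd=float(np.std(resid)),
    )


def r_score(delta_t: float, norm: RNormalization) -> float:
    """Min-max normalised RT agreement: 100 at delta_min, 0 at delta_max.

    Values outside the normalisation bounds are clamped; a degenerate run
    (delta_max == delta_min) scores 100 everywhere.
    """
    if delta_t < 0:
        raise DataError("delta_t must be non-negative")
    span = norm.delta_max - norm.delta_min
    if span <= 0:
        return 100.0
    clamped = min(max(delta_t, norm.delta_min), norm.delta_max)
    # guard against FP overshoot at the endpoints (e.g. 100.0000000000001)
    return min(100.0, max(0.0, 100.0 * (norm.delta_max - clamped) / span))


def composite_score(sv: ScoreVector, w: ModelWeights) -> float:
    """(1−α−β)·A + α·(100−M) + β·R, the re-ranking score on [0,100]."""
    for name, val in (("a", sv.a), ("m", sv.m), ("r", sv.r)):
        if not 0.0 <= val <= 100.0:
            raise DataError(f"score component {name}={val} outside [0,100]")
    return (
        (1.0 - w.alpha - w.beta) * sv.a
        + w.alpha * (100.0 - sv.m)
        + w.beta * sv.r
    )


@dataclass
class RescoredCandidate:
    record: CandidateRecord
    scores: ScoreVector


@dataclass
class RescoredSpectrum:
    spectrum_id: str
    sample_id: str
    ranked: list[RescoredCandidate]
    #: why the spectrum is unassigned, when ranked is empty
    unassigned_reason: str | None = None

    @property
    def identification(self) -> RescoredCandidate | None:
        return self.ranked[0] if self.ranked else None


def rescore_spectrum(
    cset: SpectrumCandidateSet,
    abc: Sequence[tuple[CandidateRecord, ScoreVector]],
    w: ModelWeights,
) -> list[tuple[CandidateRecord, ScoreVector]]:
    """Rank pre-gated, pre-scored candidates by descending composite.

    Ties break deterministically by higher A-score, then lexicographically
    smaller peptide. (Run-level plumbing — gating and score computation —
    lives in :class:`Rescorer`.)
    """
    for _, sv in abc:
        sv.composite = composite_score(sv, w)
    return sorted(
        abc,
        key=lambda cs: (-cs[1].composite, -cs[1].a, cs[0].peptide),
    )


class Rescorer:
    """End-to-end composite re-scoring of a run of candidate sets.

    Two passes: first gate candidates (ALC and M-rank) and collect every
    surviving delta_t to fix the run-level R normalisation; then compute R,
    composite, and the per-spectrum ranking. Spectra whose candidates all
    fail a gate are reported unassigned with the failing gate as reason.
    """

    def __init__(
        self,
        m_provider: MProvider,
        rt_predictor: RTPredictor,
        calibration: RTCalibration,
        weights: ModelWeights = DEFAULT_WEIGHTS,
        filters: FilterConfig = FilterConfig(),
    ):
        self.m_provider = m_provider
        self.rt_predictor = rt_predictor
        self.calibration = calibration
        self.weights = weights
        self.filters = filters

    def _gate_and_score(
        self, cset: SpectrumCandidateSet, alleles: Sequence[str]
    ) -> tuple[list[tuple[CandidateRecord, float, float, float]], str | None]:
        f = self.filters
        survivors = []
        any_alc = False
        for cand in cset.candidates:
            if not f.alc_min <= cand.alc <= f.alc_max:
                continue
            any_alc = True
            m = m_score(cand.peptide, alleles, self.m_provider)
            if m > f.m_max:
                continue
            t_pred = self.calibration.apply(self.rt_predictor.predict(cand.peptide))
            delta = abs(t_pred - cset.observed_rt)
            survivors.append((cand, m, t_pred, delta))
        if survivors:
            return survivors, None
        return [], ("all candidates failed the M-rank gate" if any_alc else "all candidates failed the ALC gate")

    def rescore_run(
        self,
        sets: Sequence[SpectrumCandidateSet],
        typings: Mapping[str, Sequence[str]],
    ) -> tuple[list[RescoredSpectrum], RNormalization]:
        gated: list[tuple[SpectrumCandidateSet, list, str | None]] = []
        deltas: list[float] = []
        for cset in sets:
            alleles = _alleles_for(typings, cset.sample_id)
            survivors, reason = self._gate_and_score(cset, alleles)
            gated.append((cset, survivors, reason))
            deltas.extend(s[3] for s in survivors)
        if deltas:
            norm = RNormalization(float(min(deltas)), float(max(deltas)))
        else:
            norm = RNormalization(0.0, 0.0)

        results: list[RescoredSpectrum] = []
        n_unassigned = 0
        for cset, survivors, reason in gated:
            scored = [
                (cand, ScoreVector(a=cand.alc, m=m, r=r_score(delta, norm)))
                for cand, m, _t_pred, delta in survivors
            ]
            ranked = rescore_spectrum(cset, scored, self.weights)
            if not ranked:
                n_unassigned += 1
            results.append(
                RescoredSpectrum(
                    spectrum_id=cset.spectrum_id,
                    sample_id=cset.sample_id,
                    ranked=[RescoredCandidate(c, sv) for c, sv in ranked],
                    unassigned_reason=reason,
                )
            )
        if n_unassigned:
            logger.info("%d spectra unassigned after gating", n_unassigned)
        return results, norm


def _alleles_for(typings: Mapping[str, Sequence[str]], sample_id: str) -> Sequence[str]:
    try:
        typing = typings[sample_id]
    except KeyError:
        raise DataError(f"no HLA typing for sample {sample_id!r}") from None
    return typing.alleles if hasattr(typing, "alleles") else typing
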