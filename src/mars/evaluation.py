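"""Evaluation statistics and model selection.

* F-rank: fractional rank of the true peptide among a spectrum's scored
  candidates (average competition rank inside tie groups, divided by the
  candidate count); lower is better, 1/n means unique top.
* FSR (full-sequence recall): fraction of spectra whose top candidate equals
  the true peptide up to I/L indistinguishability.
* FDP: 1 − TP/(TP+FP) over a score-sorted validated/failed series.
* Cross-validation folds are 8-mer disjoint: peptides sharing any 8-mer
  substring land in the same fold, so no sequence information leaks between
  training and test partitions.
* Weight selection is an exhaustive grid search of (alpha, beta) over the
  simplex alpha, beta >= 0, alpha + beta <= 1, minimising mean F-rank.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mars.errors import DataError
from mars.scoring import ModelWeights

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectrumEvaluation:
    spectrum_id: str
    f_rank: float
    correct_top: bool


@dataclass(frozen=True)
class FoldEvaluation:
    fold_id: int
    mean_f_rank: float
    fsr: float
    n_spectra: int


@dataclass
class FoldAssignment:
    """8-mer-disjoint fold partition of a peptide set."""

    fold_of: dict[str, int]
    component_of: dict[str, int]
    k: int


# ---------------------------------------------------------------------------
# Per-spectrum statistics


def f_rank(
    true_peptide: str, scored_candidates: Sequence[tuple[str, float]]
) -> float:
    """Fractional rank of the true peptide in a descending-score list.

    Ties use the average competition rank of the tie group; the result is
    divided by the total candidate count, so it lies in (0, 1].
    """
    if not scored_candidates:
        raise DataError("empty candidate list")
    scores = {p: s for p, s in scored_candidates}
    if true_peptide not in scores:
        raise DataError(
            f"true peptide {true_peptide!r} not among candidates "
            "(filter to recoverable spectra first)"
        )
    s_true = scores[true_peptide]
    all_scores = np.array([s for _, s in scored_candidates], dtype=float)
    n_greater = int(np.sum(all_scores > s_true + 1e-9))
    n_ties = int(np.sum(np.abs(all_scores - s_true) <= 1e-9))
    avg_rank = n_greater + (n_ties + 1) / 2.0
    return avg_rank / len(scored_candidates)


def fsr(evaluations: Sequence[SpectrumEvaluation]) -> float:
    """Full-sequence recall: fraction of spectra with correct top candidate."""
    if not evaluations:
        raise DataError("cannot compute FSR of an empty evaluation list")
    return sum(e.correct_top for e in evaluations) / len(evaluations)


# ---------------------------------------------------------------------------
# FDP curves


@dataclass
class ValidationSeries:
    """Score-sorted (peptide, score, validated) records for FDP estimation."""

    records: list[tuple[str, float, bool]]

    def __post_init__(self) -> None:
        scores = [s for _, s, _ in self.records]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise DataError("validation series must be sorted by descending score")

    @classmethod
    def from_unsorted(
        cls, records: Iterable[tuple[str, float, bool]]
    ) -> "ValidationSeries":
        return cls(sorted(records, key=lambda r: -r[1]))


def fdp_curve(series: ValidationSeries) -> pd.DataFrame:
    """Cumulative FDP = 1 − TP/(TP+FP) at every prefix of the series.

    The final row equals the overall failed fraction of the series.
    """
    if not series.records:
        raise DataError("empty validation series")
    rows = []
    tp = fp = 0
    for k, (peptide, score, validated) in enumerate(series.records, start=1):
        if validated:
            tp += 1
        else:
            fp += 1
        rows.append(
            {
                "prefix_k": k,
                "peptide": peptide,
                "score": score,
                "validated": validated,
                "tp": tp,
                "fp": fp,
                "fdp": 1.0 - tp / (tp + fp),
            }
        )
    return pd.DataFrame(rows)


def fdp_at_score(series: ValidationSeries, min_score: float) -> float:
    """FDP of the prefix with score >= ``min_score``."""
    prefix = [r for r in series.records if r[1] >= min_score]
    if not prefix:
        raise DataError(f"no records with score >= {min_score}")
    fp = sum(1 for r in prefix if not r[2])
    return fp / len(prefix)


# ---------------------------------------------------------------------------
# Confidence regions

#: (label, lower bound inclusive, upper bound exclusive) on the composite score
REGION_BOUNDS = (
    ("region1", 95.0, 100.0 + 1e-9),
    ("region2", 90.0, 95.0),
    ("region3", 80.0, 90.0),
    ("below", 0.0, 80.0),
)


def assign_region(score: float) -> str:
    """Confidence region of a composite score: >=95 / [90,95) / [80,90) / below."""
    if not 0.0 <= score <= 100.0:
        raise DataError(f"score {score} outside [0,100]")
    for label, lo, hi in REGION_BOUNDS:
        if lo <= score < hi:
            return label
    return "region1"  # score == 100 exactly


# ---------------------------------------------------------------------------
# 8-mer-disjoint folds


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        root = x
        while self.parent.setdefault(root, root) != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def kmer_set(peptide: str, k: int = 8) -> frozenset[str]:
    return frozenset(peptide[i : i + k] for i in range(len(peptide) - k + 1))


def partition_8mer_folds(
    peptides: Iterable[str],
    k: int = 5,
    seed: int = 0,
    weights: Mapping[str, int] | None = None,
) -> FoldAssignment:
    """Split peptides into k folds with no cross-fold shared 8-mer.

    Peptides sharing any 8-mer substring are joined into connected
    components; components are assigned whole to folds greedily, heaviest
    component first into the currently lightest fold (weight = spectrum
    count per peptide when given, else 1). The seed shuffles the order of
    equal-weight components before the stable sort.
    """
    peptides = sorted(set(peptides))
    if not peptides:
        raise DataError("no peptides to partition")
    short = [p for p in peptides if len(p) < 8]
    if short:
        raise DataError(f"peptides shorter than 8 aa cannot be partitioned: {short[:3]}")

    uf = _UnionFind()
    owner: dict[str, str] = {}
    for pep in peptides:
        uf.find(pep)
        for kmer in kmer_set(pep):
            if kmer in owner:
                uf.union(owner[kmer], pep)
            else:
                owner[kmer] = pep

    members: dict[str, list[str]] = {}
    for pep in peptides:
        members.setdefault(uf.find(pep), []).append(pep)
    components = sorted(members.values(), key=lambda ms: min(ms))
    if k > len(components):
        raise DataError(
            f"cannot build {k} folds from {len(components)} 8-mer-connected "
            "component(s)"
        )
    if k < 1:
        raise DataError("k must be >= 1")

    w = weights or {}
    comp_weight = [sum(w.get(p, 1) for p in ms) for ms in components]
    order = list(range(len(components)))
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    order.sort(key=lambda i: -comp_weight[i])  # stable: ties keep shuffled order

    fold_load = [0] * k
    fold_of: dict[str, int] = {}
    component_of: dict[str, int] = {}
    for comp_id, i in enumerate(order):
        target = min(range(k), key=lambda f: (fold_load[f], f))
        fold_load[target] += comp_weight[i]
        for pep in components[i]:
            fold_of[pep] = target
            component_of[pep] = comp_id
    return FoldAssignment(fold_of=fold_of, component_of=component_of, k=k)


# ---------------------------------------------------------------------------
# Grid search and cross-validation


@dataclass
class ScoredSpectrum:
    """One recoverable training spectrum with gated, pre-scored candidates.

    ``a``, ``m``, ``r`` are parallel arrays over the surviving candidates;
    ``true_index`` points at the true peptide's row.
    """

    spectrum_id: str
    peptides: list[str]
    a: np.ndarray
    m: np.ndarray
    r: np.ndarray
    true_index: int

    def __post_init__(self) -> None:
        n = len(self.peptides)
        if not (len(self.a) == len(self.m) == len(self.r) == n):
            raise DataError("score arrays must match candidate count")
        if not 0 <= self.true_index < n:
            raise DataError("true_index out of range")


class _FlatSpectra:
    """Flattened spectrum arrays for vectorised grid evaluation."""

    def __init__(self, spectra: Sequence[ScoredSpectrum]):
        if not spectra:
            raise DataError("empty spectrum list")
        self.spectra = list(spectra)
        self.a = np.concatenate([s.a for s in spectra]).astype(float)
        self.m = np.concatenate([s.m for s in spectra]).astype(float)
        self.r = np.concatenate([s.r for s in spectra]).astype(float)
        sizes = np.array([len(s.peptides) for s in spectra])
        self.sizes = sizes
        self.seg = np.repeat(np.arange(len(spectra)), sizes)
        offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        self.true_flat = offsets + np.array([s.true_index for s in spectra])

    def mean_f_rank(self, alpha: float, beta: float) -> float:
        s = (1.0 - alpha - beta) * self.a + alpha * (100.0 - self.m) + beta * self.r
        s_true = s[self.true_flat][self.seg]
        greater = np.bincount(
            self.seg, weights=(s > s_true + 1e-9), minlength=len(self.sizes)
        )
        ties = np.bincount(
            self.seg, weights=(np.abs(s - s_true) <= 1e-9), minlength=len(self.sizes)
        )
        franks = (greater + (ties + 1) / 2.0) / self.sizes
        return float(franks.mean())

    def evaluate(self, w: ModelWeights) -> list[SpectrumEvaluation]:
        out = []
        for spec in self.spectra:
            s = (
                (1.0 - w.alpha - w.beta) * spec.a
                + w.alpha * (100.0 - spec.m)
                + w.beta * spec.r
            )
            s_true = s[spec.true_index]
            greater = int(np.sum(s > s_true + 1e-9))
            ties = int(np.sum(np.abs(s - s_true) <= 1e-9))
            fr = (greater + (ties + 1) / 2.0) / len(spec.peptides)
            # correct_top mirrors identification: the deterministic tie-break
            # (composite, then A, then lexicographic peptide) selects one.
            order = sorted(
                range(len(spec.peptides)),
                key=lambda i: (-s[i], -spec.a[i], spec.peptides[i]),
            )
            out.append(
                SpectrumEvaluation(
                    spectrum_id=spec.spectrum_id,
                    f_rank=fr,
                    correct_top=(order[0] == spec.true_index),
                )
            )
        return out


def simplex_grid(grid_step: float, two_factor: bool = False) -> list[tuple[float, float]]:
    """Grid over {alpha, beta >= 0, alpha+beta <= 1} (beta fixed 0 in 1-D mode)."""
    if not 0 < grid_step <= 1:
        raise DataError("grid_step must be in (0, 1]")
    n = int(round(1.0 / grid_step))
    alphas = [i * grid_step for i in range(n + 1)]
    if two_factor:
        return [(a, 0.0) for a in alphas]
    return [
        (i * grid_step, j * grid_step)
        for i, j in itertools.product(range(n + 1), repeat=2)
        if i + j <= n
    ]


def grid_search_weights(
    training_spectra: Sequence[ScoredSpectrum],
    grid_step: float = 0.01,
    two_factor: bool = False,
) -> tuple[ModelWeights, float]:
    """Exhaustive simplex grid search minimising mean F-rank.

    Ties break toward smaller alpha, then smaller beta, so the simplest model
    wins; the grid contains the baseline (0,0), hence the optimum is never
    worse than the plain ALC model on the training data.
    """
    flat = _FlatSpectra(training_spectra)
    best: tuple[float, float] | None = None
    best_val = np.inf
    for alpha, beta in sorted(simplex_grid(grid_step, two_factor)):
        val = flat.mean_f_rank(alpha, beta)
        if val < best_val - 1e-12:
            best_val = val
            best = (alpha, beta)
    assert best is not None
    return ModelWeights(alpha=best[0], beta=best[1]), best_val


@dataclass
class CrossValidationResult:
    fold_evaluations: list[FoldEvaluation]
    fold_weights: list[ModelWeights]
    #: concatenated held-out per-spectrum evaluations (each spectrum once)
    test_evaluations: list[SpectrumEvaluation]

    @property
    def overall_fsr(self) -> float:
        return fsr(self.test_evaluations)

    @property
    def overall_mean_f_rank(self) -> float:
        return float(np.mean([e.f_rank for e in self.test_evaluations]))


def cross_validate(
    spectra: Sequence[ScoredSpectrum],
    k: int = 5,
    grid_step: float = 0.01,
    seed: int = 0,
    mode: str = "three_factor",
) -> CrossValidationResult:
    """k-fold CV with 8-mer-disjoint folds over the true peptides.

    ``mode``: ``"three_factor"`` (2-D grid), ``"two_factor"`` (beta = 0) or
    ``"baseline"`` (fixed alpha = beta = 0, no training). Per fold, weights
    are fitted on the other k−1 folds and applied to the held-out fold only;
    held-out predictions are concatenated for the overall statistics.
    """
    if k < 2:
        raise DataError("cross-validation needs k >= 2 (no held-out set otherwise)")
    if mode not in ("baseline", "two_factor", "three_factor"):
        raise DataError(f"unknown mode {mode!r}")
    true_peptides = {s.peptides[s.true_index] for s in spectra}
    counts: dict[str, int] = {}
    for s in spectra:
        pep = s.peptides[s.true_index]
        counts[pep] = counts.get(pep, 0) + 1
    assignment = partition_8mer_folds(true_peptides, k=k, seed=seed, weights=counts)

    fold_evals: list[FoldEvaluation] = []
    fold_weights: list[ModelWeights] = []
    all_tests: list[SpectrumEvaluation] = []
    for fold in range(k):
        train = [
            s for s in spectra if assignment.fold_of[s.peptides[s.true_index]] != fold
        ]
        test = [
            s for s in spectra if assignment.fold_of[s.peptides[s.true_index]] == fold
        ]
        if not test:
            logger.warning("fold %d is empty; skipped", fold)
            continue
        if mode == "baseline":
            w = ModelWeights(0.0, 0.0)
        else:
            w, _ = grid_search_weights(
                train, grid_step=grid_step, two_factor=(mode == "two_factor")
            )
        evals = _FlatSpectra(test).evaluate(w)
        fold_evals.append(
            FoldEvaluation(
                fold_id=fold,
                mean_f_rank=float(np.mean([e.f_rank for e in evals])),
                fsr=fsr(evals),
                n_spectra=len(evals),
            )
        )
        fold_weights.append(w)
        all_tests.extend(evals)
    return CrossValidationResult(fold_evals, fold_weights, all_tests)


def collect_scored_spectra(
    rescored: Sequence,  # list[mars.scoring.RescoredSpectrum]
    truth: Mapping[str, str],
) -> list[ScoredSpectrum]:
    """Build training/evaluation containers from a rescored run.

    Keeps only spectra whose true peptide survived gating into the candidate
    list (the recoverable denominator); the (a, m, r) components are
    weight-independent, so the same containers serve every model variant.
    """
    out: list[ScoredSpectrum] = []
    for rs in rescored:
        true_pep = truth.get(rs.spectrum_id)
        if true_pep is None or not rs.ranked:
            continue
        peptides = [rc.record.peptide for rc in rs.ranked]
        if true_pep not in peptides:
            continue
        out.append(
            ScoredSpectrum(
                spectrum_id=rs.spectrum_id,
                peptides=peptides,
                a=np.array([rc.scores.a for rc in rs.ranked]),
                m=np.array([rc.scores.m for rc in rs.ranked]),
                r=np.array([rc.scores.r for rc in rs.ranked]),
                true_index=peptides.index(true_pep),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reporting statistics (plumbing around standard implementations)


def wilcoxon_f_ranks(f_ranks_a: Sequence[float], f_ranks_b: Sequence[float]):
    """One-sided paired Wilcoxon signed-rank test that model B beats model A."""
    return stats.wilcoxon(f_ranks_a, f_ranks_b, alternative="greater")


def paired_t_fsr(fsr_a: Sequence[float], fsr_b: Sequence[float]):
    """Paired t-test on per-fold FSR values."""
    return stats.ttest_rel(fsr_b, fsr_a)
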