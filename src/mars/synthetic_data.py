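"""Self-contained immunopeptidomics fixture generator with known truth.

Emulates the candidate-list level at which the composite re-scorer
operates — no fragment spectra are simulated. Each synthetic spectrum
carries a "true" 8–13-mer drawn from an allele anchor motif plus decoys
built the way real de novo ambiguity arises (N-terminal transposition,
internal permutation, compensated isobaric substitution, point errors).
ALC scores are drawn so the true peptide tops the list in a configurable
fraction of spectra; M-ranks come from the toy PSSM provider (or controlled
rank ranges for regime fixtures); observed retention time follows an affine
map of the Kyte–Doolittle hydrophobicity sum plus Gaussian noise.

Everything is deterministic under a fixed seed, and all outputs use the
interchange dialects of :mod:`mars.psm_io` and :mod:`mars.scoring`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mars.errors import ConfigError
from mars.psm_io import (
    AMINO_ACIDS,
    CandidateRecord,
    DbSearchHit,
    GroundTruthEntry,
    SampleTyping,
    SpectrumCandidateSet,
    write_candidates,
    write_db_hits,
    write_ground_truth,
    write_typings,
)

logger = logging.getLogger(__name__)

#: Kyte–Doolittle hydropathy values (per residue).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_AA = np.array(list(AMINO_ACIDS))
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DECOY_SCHEMES = ("swap_first_two", "internal_shuffle", "isobaric_sub", "single_point")

#: mass-compensated digram<->single residue pairs (GG = N, GA = Q by mass)
_ISOBARIC = (("GG", "N"), ("GA", "Q"))


def hydrophobicity_sum(peptide: str) -> float:
    return float(sum(KYTE_DOOLITTLE[aa] for aa in peptide))


@dataclass
class MotifModel:
    """Per-length anchor-position PSSMs for one MHC-I allele.

    Anchors sit at position 2 and the C-terminus (the classical class I
    anchor positions); the modal anchor residue carries probability
    ``anchor_prob`` with the remainder spread uniformly, so anchor columns
    have strictly lower entropy than non-anchor columns. Stored matrices are
    log-odds against the uniform background.
    """

    allele: str
    pssms: dict[int, np.ndarray]

    @classmethod
    def default(
        cls,
        allele: str = "HLA-A*02:01",
        anchor_prob: float = 0.9,
        anchor_residues: tuple[str, str] = ("L", "V"),
        lengths: Sequence[int] = range(8, 14),
    ) -> "MotifModel":
        if not 0.05 < anchor_prob < 1.0:
            raise ConfigError("anchor_prob must be in (0.05, 1)")
        p2, pc = anchor_residues
        pssms = {}
        for length in lengths:
            probs = np.full((length, 20), 1.0 / 20)
            for pos, residue in ((1, p2), (length - 1, pc)):
                probs[pos] = (1.0 - anchor_prob) / 19.0
                probs[pos, _AA_INDEX[residue]] = anchor_prob
            pssms[length] = np.log(probs * 20.0)
        return cls(allele=allele, pssms=pssms)

    def position_probs(self, length: int) -> np.ndarray:
        return np.exp(self.pssms[length]) / 20.0


def sample_true_peptides(
    motif: MotifModel,
    n: int,
    length_probs: Mapping[int, float],
    rng: np.random.Generator,
) -> list[str]:
    """i.i.d. draws from the motif's per-position residue distribution."""
    if n == 0:
        return []
    lengths = np.array(sorted(length_probs))
    pvals = np.array([length_probs[l] for l in lengths], dtype=float)
    pvals = pvals / pvals.sum()
    drawn = rng.choice(lengths, size=n, p=pvals)
    out = []
    for length in drawn:
        probs = motif.position_probs(int(length))
        idx = [rng.choice(20, p=probs[pos]) for pos in range(int(length))]
        # candidate space is I->L collapsed everywhere downstream
        out.append("".join(_AA[idx]).replace("I", "L"))
    return out


def _isobaric_decoy(peptide: str, rng: np.random.Generator) -> str | None:
    """Swap a mass-compensated digram/single pair; None when impossible.

    Length is preserved by construction: a 2->1 replacement is applied only
    together with a compensating 1->2 replacement elsewhere.
    """
    options = []
    for digram, single in _ISOBARIC:
        d_positions = [
            i for i in range(len(peptide) - 1) if peptide[i : i + 2] == digram
        ]
        s_positions = [i for i, ch in enumerate(peptide) if ch == single]
        for di in d_positions:
            for si in s_positions:
                if si < di - 1 or si > di + 1:  # non-overlapping
                    options.append((di, digram, si, single))
    if not options:
        return None
    di, digram, si, single = options[rng.integers(len(options))]
    chars = list(peptide)
    if di < si:
        new = peptide[:di] + single + peptide[di + 2 : si] + digram + peptide[si + 1 :]
    else:
        new = peptide[:si] + digram + peptide[si + 1 : di] + single + peptide[di + 2 :]
    assert len(new) == len(peptide)
    return new


def _single_point(peptide: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(peptide)))
    # 'I' excluded: decoys live in the same collapsed space as the truth
    alternatives = [aa for aa in AMINO_ACIDS if aa != peptide[pos] and aa != "I"]
    return peptide[:pos] + alternatives[rng.integers(len(alternatives))] + peptide[pos + 1 :]


def make_decoys(
    true_peptide: str,
    n_decoys: int,
    schemes: Sequence[str] = DECOY_SCHEMES,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, str]]:
    """Generate distinct decoy candidates, each tagged with its scheme.

    ``swap_first_two`` is always included when the first two residues
    differ; schemes that cannot apply to the peptide are skipped (logged).
    ``single_point`` enumeration guarantees the requested count for any
    8-mer or longer.
    """
    unknown = set(schemes) - set(DECOY_SCHEMES)
    if unknown:
        raise ConfigError(f"unknown decoy scheme(s) {sorted(unknown)}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    decoys: dict[str, str] = {}

    if "swap_first_two" in schemes and true_peptide[0] != true_peptide[1]:
        swapped = true_peptide[1] + true_peptide[0] + true_peptide[2:]
        decoys[swapped] = "swap_first_two"

    attempts = 0
    max_attempts = 60 * n_decoys
    cycle = [s for s in schemes if s != "swap_first_two"]
    while len(decoys) < n_decoys and cycle and attempts < max_attempts:
        scheme = cycle[attempts % len(cycle)]
        attempts += 1
        if scheme == "internal_shuffle":
            if len(true_peptide) < 4:
                continue
            inner = list(true_peptide[1:-1])
            rng.shuffle(inner)
            cand = true_peptide[0] + "".join(inner) + true_peptide[-1]
        elif scheme == "isobaric_sub":
            maybe = _isobaric_decoy(true_peptide, rng)
            if maybe is None:
                continue
            cand = maybe
        else:
            cand = _single_point(true_peptide, rng)
        if cand != true_peptide and cand not in decoys:
            decoys[cand] = scheme

    if len(decoys) < n_decoys:
        # deterministic exhaustive point-mutation sweep tops up the list
        for pos in range(len(true_peptide)):
            for aa in AMINO_ACIDS:
                if len(decoys) >= n_decoys:
                    break
                if aa == true_peptide[pos] or aa == "I":
                    continue
                cand = true_peptide[:pos] + aa + true_peptide[pos + 1 :]
                if cand != true_peptide and cand not in decoys:
                    decoys[cand] = "single_point"
    if len(decoys) < n_decoys:
        logger.warning(
            "only %d/%d distinct decoys possible for %s",
            len(decoys),
            n_decoys,
            true_peptide,
        )
    return list(decoys.items())[:n_decoys]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.

    ``p_top`` is the probability (per recoverable spectrum) that the true
    peptide carries the highest ALC, i.e. the target of the ALC-only
    baseline full-sequence recall. ``m_mode`` selects how M-ranks arise:
    ``"pssm"`` scores every candidate against the toy motif PSSM (the
    default, realistic mode), ``"ranges"`` draws true/decoy ranks from the
    configured uniform ranges (controlled-regime fixtures), ``"noise"``
    draws every rank uniformly within the M gate (M carries no signal).
    """

    n_spectra: int = 2000
    sample_id: str = "S1"
    alleles: tuple[str, ...] = ("HLA-A*02:01",)
    n_candidates: int = 20
    seed: int = 0
    # truth / candidate structure
    recoverable_fraction: float = 0.923
    p_top: float = 0.70
    length_probs: Mapping[int, float] = field(
        default_factory=lambda: {8: 0.12, 9: 0.45, 10: 0.20, 11: 0.10, 12: 0.07, 13: 0.06}
    )
    anchor_prob: float = 0.9
    decoy_schemes: tuple[str, ...] = DECOY_SCHEMES
    # A-score model. In "signal" mode the true peptide beats the best decoy
    # by |N(0, a_margin_sd)| with probability p_top, and otherwise trails it
    # by a small exponential gap (mean a_gap_mean) — mirroring how ambiguous
    # permutations score close to the truth. In "noise" mode the true
    # peptide's ALC is drawn i.i.d. from the decoy distribution.
    a_mode: str = "signal"
    a_mean: float = 78.0
    a_sd: float = 7.0
    a_margin_sd: float = 1.5
    a_gap_mean: float = 2.5
    # M model
    m_mode: str = "pssm"
    m_true_range: tuple[float, float] = (0.01, 2.0)
    m_decoy_range: tuple[float, float] = (1.5, 10.0)
    pssm_background: int = 4000
    # RT model: observed = intercept + slope * KD-sum(true) + N(0, noise)
    rt_intercept: float = 30.0
    rt_slope: float = 0.8
    rt_noise_sd: float = 0.5
    rt_pred_err_sd: float = 0.3
    # DB search score of the true assignment
    neg10lgp_mean: float = 35.0
    neg10lgp_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory for reproducibility")
        for name in ("recoverable_fraction", "p_top"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        if self.n_candidates < 2:
            raise ConfigError("need at least 2 candidates per spectrum")
        if self.m_mode not in ("pssm", "ranges", "noise"):
            raise ConfigError(f"unknown m_mode {self.m_mode!r}")
        if self.a_mode not in ("signal", "noise"):
            raise ConfigError(f"unknown a_mode {self.a_mode!r}")

    # -- regime presets -----------------------------------------------------

    @classmethod
    def m_dominant(cls, seed: int = 0, **kw) -> "SimulationConfig":
        """M alone ranks the true peptide first; A is pure noise."""
        return cls(
            seed=seed,
            a_mode="noise",
            m_mode="ranges",
            m_true_range=(0.01, 1.0),
            m_decoy_range=(1.5, 10.0),
            rt_noise_sd=5.0,  # RT carries no usable signal at this noise
            rt_pred_err_sd=5.0,
            **kw,
        )

    @classmethod
    def a_dominant(cls, seed: int = 0, **kw) -> "SimulationConfig":
        """A alone is perfect; M and RT carry no signal."""
        return cls(
            seed=seed,
            p_top=1.0,
            m_mode="noise",
            rt_noise_sd=5.0,
            rt_pred_err_sd=5.0,
            **kw,
        )

    @classmethod
    def mixed(cls, seed: int = 0, **kw) -> "SimulationConfig":
        """All three factors informative but individually imperfect."""
        kw.setdefault("decoy_schemes", ("swap_first_two", "single_point"))
        return cls(
            seed=seed,
            p_top=0.70,
            m_mode="ranges",
            m_true_range=(0.01, 2.0),
            m_decoy_range=(0.5, 10.0),
            rt_noise_sd=0.8,
            rt_pred_err_sd=0.4,
            **kw,
        )


@dataclass
class SimulatedDataset:
    """In-memory result of one simulation plus optional written paths."""

    sets: list[SpectrumCandidateSet]
    db_hits: list[DbSearchHit]
    typing: SampleTyping
    m_table: dict[tuple[str, str], float]
    rt_table: dict[str, float]
    ground_truth: list[GroundTruthEntry]
    config: SimulationConfig
    paths: dict[str, Path] = field(default_factory=dict)


def _pssm_ranks(
    peptides: Sequence[str], motif: MotifModel, n_background: int, seed: int
) -> np.ndarray:
    """Percentile ranks of peptides vs a uniform background, per length."""
    ranks = np.empty(len(peptides))
    by_len: dict[int, list[int]] = {}
    for i, p in enumerate(peptides):
        by_len.setdefault(len(p), []).append(i)
    for length, idxs in by_len.items():
        pssm = motif.pssms[length]
        rng = np.random.default_rng((seed, length))
        bg = rng.integers(0, 20, size=(n_background, length))
        bg_scores = np.sort(pssm[np.arange(length)[None, :], bg].sum(axis=1))
        for i in idxs:
            q = pssm[np.arange(length), [_AA_INDEX[aa] for aa in peptides[i]]].sum()
            n_ge = n_background - np.searchsorted(bg_scores, q - 1e-12, side="left")
            ranks[i] = 100.0 * n_ge / n_background
    return ranks


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulatedDataset:
    """Generate one synthetic run; optionally write the five fixture files.

    Files written to ``outdir``: ``candidates.tsv``, ``db_hits.tsv``,
    ``typings.tsv``, ``providers.tsv`` (peptide, allele, m_rank, raw_rt),
    ``ground_truth.tsv``.
    """
    rng = np.random.default_rng(config.seed)
    motif = MotifModel.default(
        allele=config.alleles[0], anchor_prob=config.anchor_prob
    )
    trues = sample_true_peptides(motif, config.n_spectra, config.length_probs, rng)

    sets: list[SpectrumCandidateSet] = []
    db_hits: list[DbSearchHit] = []
    truth: list[GroundTruthEntry] = []
    m_table: dict[tuple[str, str], float] = {}
    rt_table: dict[str, float] = {}
    all_peptides_per_set: list[list[str]] = []

    for i, true_pep in enumerate(trues):
        sid = f"spec{i:05d}"
        recoverable = bool(rng.random() < config.recoverable_fraction)
        n_decoys = config.n_candidates - (1 if recoverable else 0)
        decoys = [
            d for d, _scheme in make_decoys(true_pep, n_decoys, config.decoy_schemes, rng)
        ]
        # decoys capped just under 100 so a winning truth is never tied
        decoy_alcs = np.clip(
            rng.normal(config.a_mean, config.a_sd, size=len(decoys)), 50.0, 99.9
        )
        scored = list(zip(decoys, decoy_alcs))
        if recoverable:
            best_decoy = float(decoy_alcs.max())
            if config.a_mode == "noise":
                true_alc = float(
                    np.clip(rng.normal(config.a_mean, config.a_sd), 50.0, 99.9)
                )
            elif rng.random() < config.p_top:
                true_alc = min(
                    100.0, best_decoy + abs(rng.normal(0.0, config.a_margin_sd)) + 0.05
                )
            else:
                gap = 0.2 + rng.exponential(config.a_gap_mean)
                true_alc = max(50.0, best_decoy - gap)
            scored.append((true_pep, true_alc))
        scored.sort(key=lambda pa: -pa[1])
        candidates = [
            CandidateRecord(sid, pep, float(alc), rank + 1)
            for rank, (pep, alc) in enumerate(scored)
        ]
        peptides = [pep for pep, _ in scored]
        kd_true = hydrophobicity_sum(true_pep)
        observed_rt = max(
            1.0,
            config.rt_intercept
            + config.rt_slope * kd_true
            + rng.normal(0.0, config.rt_noise_sd),
        )
        sets.append(SpectrumCandidateSet(sid, config.sample_id, observed_rt, candidates))
        all_peptides_per_set.append(peptides)

        # M-ranks
        if config.m_mode == "ranges":
            lo, hi = config.m_true_range
            m_true = float(rng.uniform(lo, hi))
            lo, hi = config.m_decoy_range
            m_decoys = rng.uniform(lo, hi, size=len(decoys))
            m_vals = {true_pep: m_true} if recoverable else {}
            m_vals.update(dict(zip(decoys, m_decoys)))
            if not recoverable:
                m_vals[true_pep] = m_true  # truth still needs a rank for filters
        elif config.m_mode == "noise":
            uniq = list(dict.fromkeys(peptides + [true_pep]))
            m_vals = dict(zip(uniq, rng.uniform(0.0, 10.0, size=len(uniq))))
        else:  # deferred: PSSM ranks computed in batch below
            m_vals = {}
        for allele in config.alleles:
            for pep, m in m_vals.items():
                m_table.setdefault((pep, allele), float(m))

        # raw RT predictions (consistent per peptide across spectra)
        for pep in set(peptides) | {true_pep}:
            if pep not in rt_table:
                rt_table[pep] = hydrophobicity_sum(pep) + float(
                    rng.normal(0.0, config.rt_pred_err_sd)
                )

        db_hits.append(
            DbSearchHit(
                sid,
                true_pep,
                float(
                    np.clip(
                        rng.normal(config.neg10lgp_mean, config.neg10lgp_sd), 0.0, 200.0
                    )
                ),
            )
        )
        truth.append(GroundTruthEntry(sid, true_pep, recoverable))

    if config.m_mode == "pssm":
        uniq = sorted({p for peps in all_peptides_per_set for p in peps} | set(trues))
        ranks = _pssm_ranks(uniq, motif, config.pssm_background, config.seed)
        for allele in config.alleles:
            for pep, m in zip(uniq, ranks):
                m_table[(pep, allele)] = float(m)

    typing = SampleTyping(config.sample_id, config.alleles)
    ds = SimulatedDataset(
        sets=sets,
        db_hits=db_hits,
        typing=typing,
        m_table=m_table,
        rt_table=rt_table,
        ground_truth=truth,
        config=config,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ds.paths = {
            "candidates": outdir / "candidates.tsv",
            "db_hits": outdir / "db_hits.tsv",
            "typings": outdir / "typings.tsv",
            "providers": outdir / "providers.tsv",
            "ground_truth": outdir / "ground_truth.tsv",
        }
        write_candidates(sets, ds.paths["candidates"])
        write_db_hits(db_hits, ds.paths["db_hits"])
        write_typings([typing], ds.paths["typings"])
        rows = [
            {
                "peptide": pep,
                "allele": allele,
                "m_rank": m,
                "raw_rt": rt_table[pep],
            }
            for (pep, allele), m in sorted(m_table.items())
        ]
        pd.DataFrame(rows).to_csv(ds.paths["providers"], sep="\t", index=False)
        write_ground_truth(truth, ds.paths["ground_truth"])
    return ds
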