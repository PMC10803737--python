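"""Domain types and tabular I/O for candidate lists, DB hits and typings.

All peptide text is held I->L collapsed: isoleucine and leucine are isobaric
and indistinguishable by standard MS2 fragmentation, so every sequence
comparison in the package happens in the collapsed 19-letter space.

The candidate reader speaks one neutral tab-separated dialect; engine-specific
exports are adapted by remapping column names through a ``dialect`` dict, so
no vendor format is hard-coded anywhere.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from mars.errors import DataError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Default column names of the neutral candidate-export dialect.
DEFAULT_DIALECT: dict[str, str] = {
    "spectrum_id": "spectrum_id",
    "sample_id": "sample_id",
    "peptide": "peptide",
    "alc": "alc",
    "rt_min": "rt_min",
    "export_rank": "export_rank",
}

_MOD_TOKEN = re.compile(r"\(([^)]*)\)|\[([^\]]*)\]")


def normalize_il(peptide: str) -> str:
    """Collapse isoleucine to leucine.

    Raises :class:`DataError` naming the first offending position if the
    string contains a character outside the 20-letter amino-acid alphabet.
    """
    if not peptide:
        raise DataError("empty peptide sequence")
    for pos, ch in enumerate(peptide):
        if ch not in _AA_SET:
            raise DataError(
                f"non-amino-acid character {ch!r} at position {pos} in {peptide!r}"
            )
    return peptide.replace("I", "L")


def strip_modifications(sequence: str) -> str:
    """Remove parenthesised / bracketed engine modification tags.

    ``"M(+15.99)TMSK"`` -> ``"MTMSK"``. The plain residue letters are kept;
    composite scoring operates on unmodified sequence text.
    """
    return _MOD_TOKEN.sub("", sequence)


@dataclass(frozen=True)
class CandidateRecord:
    """One de novo candidate for one spectrum (I->L collapsed)."""

    spectrum_id: str
    peptide: str
    alc: float
    export_rank: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.alc <= 100.0:
            raise DataError(
                f"ALC {self.alc} outside [0,100] for spectrum {self.spectrum_id!r}"
            )
        if "I" in self.peptide:
            raise DataError(f"peptide {self.peptide!r} not I->L collapsed")
        if self.export_rank < 1:
            raise DataError("export_rank must be >= 1")


@dataclass
class SpectrumCandidateSet:
    """One MS2 spectrum with its ordered candidate list and observed RT."""

    spectrum_id: str
    sample_id: str
    observed_rt: float
    candidates: list[CandidateRecord]

    def __post_init__(self) -> None:
        if self.observed_rt <= 0:
            raise DataError(
                f"observed RT must be positive (spectrum {self.spectrum_id!r})"
            )
        peptides = [c.peptide for c in self.candidates]
        if len(set(peptides)) != len(peptides):
            raise DataError(
                f"duplicate candidate peptides in spectrum {self.spectrum_id!r}"
            )

    @property
    def peptides(self) -> list[str]:
        return [c.peptide for c in self.candidates]


@dataclass(frozen=True)
class DbSearchHit:
    """A database-search assignment (−10·lgP score) for one spectrum."""

    spectrum_id: str
    peptide: str
    neg10lgp: float

    def __post_init__(self) -> None:
        if not pd.notna(self.neg10lgp) or self.neg10lgp in (float("inf"), float("-inf")):
            raise DataError(f"non-finite -10lgP for spectrum {self.spectrum_id!r}")


@dataclass(frozen=True)
class SampleTyping:
    """MHC-I typing of one sample: up to six classical class I alleles."""

    sample_id: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise DataError(f"sample {self.sample_id!r} has no alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise DataError(f"duplicate alleles for sample {self.sample_id!r}")


@dataclass(frozen=True)
class GroundTruthEntry:
    spectrum_id: str
    true_peptide: str
    recoverable: bool


@dataclass(frozen=True)
class FilterConfig:
    """Gates used for training-set selection and candidate gating.

    Defaults: ALC in [50, 100], M-rank <= 10, length 8-13 aa, −10lgP >= 20
    (the database-search confidence giving < 1% PSM-level FDR).
    """

    alc_min: float = 50.0
    alc_max: float = 100.0
    m_max: float = 10.0
    len_min: int = 8
    len_max: int = 13
    neg10lgp_min: float = 20.0


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing mandatory column(s) {missing}")


def read_candidates(
    path,
    dialect: Mapping[str, str] | None = None,
    max_candidates: int = 100,
    strip_mods: bool = True,
) -> list[SpectrumCandidateSet]:
    """Read a candidate export into grouped, collapsed, truncated sets.

    Parameters
    ----------
    path
        Tab-separated file with at least spectrum id, peptide, ALC and RT
        columns (names per ``dialect``; defaults to :data:`DEFAULT_DIALECT`).
    max_candidates
        Candidates retained per spectrum, highest ALC first (100 for HLA
        sample data, 20 for synthetic-library data).
    strip_mods
        Strip parenthesised modification tags from sequences; if False, any
        tag raises :class:`DataError`.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype={names["spectrum_id"]: str})
    _require_columns(
        df, [names[k] for k in ("spectrum_id", "peptide", "alc", "rt_min")], path
    )
    has_rank = names["export_rank"] in df.columns
    has_sample = names["sample_id"] in df.columns

    sets: list[SpectrumCandidateSet] = []
    for spectrum_id, grp in df.groupby(names["spectrum_id"], sort=False):
        seen: dict[str, CandidateRecord] = {}
        rts = grp[names["rt_min"]].astype(float)
        samples = (
            grp[names["sample_id"]].astype(str) if has_sample else pd.Series(["sample"] * len(grp))
        )
        for i, (_, row) in enumerate(grp.iterrows()):
            raw_seq = str(row[names["peptide"]])
            if strip_mods:
                raw_seq = strip_modifications(raw_seq)
            elif _MOD_TOKEN.search(raw_seq):
                raise DataError(
                    f"{path}: modification tag in {raw_seq!r} (strip_mods=False)"
                )
            alc = float(row[names["alc"]])
            if not 0.0 <= alc <= 100.0:
                raise DataError(
                    f"{path}: ALC {alc} outside [0,100] in row with spectrum "
                    f"{spectrum_id!r}, peptide {raw_seq!r}"
                )
            peptide = normalize_il(raw_seq)
            rank = int(row[names["export_rank"]]) if has_rank else i + 1
            rec = CandidateRecord(str(spectrum_id), peptide, alc, rank)
            prev = seen.get(peptide)
            if prev is not None:
                # I/L isomers listed separately by the engine merge after
                # collapse; keep the higher-ALC copy.
                logger.warning(
                    "spectrum %s: duplicate candidate %s after I->L collapse; "
                    "keeping higher ALC",
                    spectrum_id,
                    peptide,
                )
                if alc <= prev.alc:
                    continue
            seen[peptide] = rec
        ordered = sorted(seen.values(), key=lambda c: (-c.alc, c.export_rank))
        ordered = ordered[:max_candidates]
        sets.append(
            SpectrumCandidateSet(
                spectrum_id=str(spectrum_id),
                sample_id=str(samples.iloc[0]),
                observed_rt=float(rts.iloc[0]),
                candidates=ordered,
            )
        )
    return sets


def write_candidates(sets: Sequence[SpectrumCandidateSet], path) -> None:
    """Write sets back to the neutral dialect (lossless round trip)."""
    rows = [
        {
            "spectrum_id": s.spectrum_id,
            "sample_id": s.sample_id,
            "peptide": c.peptide,
            "alc": c.alc,
            "rt_min": s.observed_rt,
            "export_rank": c.export_rank,
        }
        for s in sets
        for c in s.candidates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_db_hits(path) -> list[DbSearchHit]:
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str})
    _require_columns(df, ["spectrum_id", "peptide", "neg10lgp"], path)
    return [
        DbSearchHit(str(r.spectrum_id), str(r.peptide), float(r.neg10lgp))
        for r in df.itertuples()
    ]


def write_db_hits(hits: Sequence[DbSearchHit], path) -> None:
    pd.DataFrame(
        [{"spectrum_id": h.spectrum_id, "peptide": h.peptide, "neg10lgp": h.neg10lgp} for h in hits]
    ).to_csv(path, sep="\t", index=False)


def read_typings(path) -> dict[str, SampleTyping]:
    """Read one-row-per-allele typing table into per-sample typings."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample_id", "allele"], path)
    out: dict[str, SampleTyping] = {}
    for sample_id, grp in df.groupby("sample_id", sort=False):
        out[str(sample_id)] = SampleTyping(str(sample_id), tuple(grp["allele"]))
    return out


def write_typings(typings: Iterable[SampleTyping], path) -> None:
    rows = [
        {"sample_id": t.sample_id, "allele": a} for t in typings for a in t.alleles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> list[GroundTruthEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str})
    _require_columns(df, ["spectrum_id", "true_peptide", "recoverable"], path)
    return [
        GroundTruthEntry(
            str(r.spectrum_id), str(r.true_peptide), bool(r.recoverable)
        )
        for r in df.itertuples()
    ]


def write_ground_truth(entries: Sequence[GroundTruthEntry], path) -> None:
    pd.DataFrame(
        [
            {
                "spectrum_id": e.spectrum_id,
                "true_peptide": e.true_peptide,
                "recoverable": e.recoverable,
            }
            for e in entries
        ]
    ).to_csv(path, sep="\t", index=False)


def build_ground_truth(
    db_hits: Sequence[DbSearchHit],
    sets: Sequence[SpectrumCandidateSet],
    filters: FilterConfig,
    m_of: Callable[[str, str], float],
) -> list[GroundTruthEntry]:
    """Select confidently DB-assigned spectra as training ground truth.

    A hit survives when −10lgP >= ``filters.neg10lgp_min``, the peptide
    length is within [len_min, len_max], and its allele-reduced M-rank (via
    ``m_of(peptide, sample_id)``) is <= ``filters.m_max`` — removing likely
    co-purification contaminants. ``recoverable`` flags whether the collapsed
    true peptide appears among the spectrum's candidates.

    Hits referencing spectra absent from ``sets`` are dropped (count logged).
    Output order follows ``sets`` order, so it is invariant to the order of
    the hit rows.
    """
    by_spectrum = {s.spectrum_id: s for s in sets}
    best_hit: dict[str, DbSearchHit] = {}
    dropped = 0
    for hit in db_hits:
        if hit.spectrum_id not in by_spectrum:
            dropped += 1
            continue
        prev = best_hit.get(hit.spectrum_id)
        if prev is None or hit.neg10lgp > prev.neg10lgp:
            best_hit[hit.spectrum_id] = hit
    if dropped:
        logger.warning("%d DB hits referenced unknown spectra and were dropped", dropped)

    entries: list[GroundTruthEntry] = []
    for cset in sets:
        hit = best_hit.get(cset.spectrum_id)
        if hit is None or hit.neg10lgp < filters.neg10lgp_min:
            continue
        true_peptide = normalize_il(strip_modifications(hit.peptide))
        if not filters.len_min <= len(true_peptide) <= filters.len_max:
            continue
        if m_of(true_peptide, cset.sample_id) > filters.m_max:
            continue
        recoverable = true_peptide in set(cset.peptides)
        entries.append(GroundTruthEntry(cset.spectrum_id, true_peptide, recoverable))
    if not entries:
        raise DataError(
            "no training spectra: no DB hit passed the -10lgP/length/M-rank filters"
        )
    return entries


def exclude_db_assigned(
    sets: Sequence[SpectrumCandidateSet],
    db_hits: Sequence[DbSearchHit],
    threshold: float = 20.0,
) -> list[SpectrumCandidateSet]:
    """Drop spectra confidently explained by the database search.

    Discovery mode operates on the remainder: spectra with no DB hit above
    ``threshold`` (−10lgP). An empty remainder is legitimate.
    """
    if threshold < 0:
        raise DataError("threshold must be >= 0")
    assigned = {h.spectrum_id for h in db_hits if h.neg10lgp > threshold}
    return [s for s in sets if s.spectrum_id not in assigned]
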