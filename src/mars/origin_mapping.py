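"""Stepwise mapping of identified peptides to their sequence origin.

Precedence is strict: an exact hit in canonical protein space wins
("HumanProtein"); otherwise a protein window at Hamming distance exactly 1
("OneAASubstitution", substitutions only — no indels); otherwise an exact
hit in six-/three-frame translated non-canonical space ("NonCanonical",
carrying the multi-label biotype set of *all* such hits — no hierarchy is
imposed among biotypes, because a peptide with several possible origins
cannot be faithfully assigned to one); otherwise "Unmatched".

All protein-space text is compared I->L collapsed on both sides, matching
how identifications are reported. Offsets are 0-based internally; report
writers convert to 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from mars.errors import DataError, ReferenceError
from mars.psm_io import normalize_il

logger = logging.getLogger(__name__)

CATEGORIES = ("HumanProtein", "OneAASubstitution", "NonCanonical", "Unmatched")

_DNA = frozenset("ACGTN")


@dataclass(frozen=True)
class Hit:
    """One matching locus for a peptide."""

    entry_id: str
    offset: int  # 0-based within the (translated) entry's protein text
    frame: int | None = None
    strand: str | None = None
    biotype: str | None = None
    sub_position: int | None = None  # 0-based within the peptide
    ref_residue: str | None = None
    query_residue: str | None = None


@dataclass(frozen=True)
class OriginAssignment:
    peptide: str
    category: str
    hits: tuple[Hit, ...]

    @property
    def biotypes(self) -> frozenset[str]:
        return frozenset(h.biotype for h in self.hits if h.biotype is not None)


@dataclass(frozen=True)
class TranslatedFragment:
    """A stop-free translated stretch (>= min length) of one reading frame."""

    frame: int  # 0..2 within the strand
    strand: str  # '+' or '-'
    peptide: str  # raw translation (not collapsed)
    aa_offset: int  # 0-based aa position within the frame's translation
    nt_start: int  # 0-based forward-strand coordinate of the fragment span
    nt_end: int  # exclusive


def translate_frames(
    nucleotide_seq: str,
    mode: str = "six_frame",
    min_fragment: int = 8,
) -> list[TranslatedFragment]:
    """Conceptual translation in three (sense) or six (both-strand) frames.

    Translation is split into fragments at stop codons and at 'X' (codons
    containing N); fragments shorter than ``min_fragment`` aa are discarded
    (below the 8-mer peptide length floor nothing can match).
    """
    if mode not in ("six_frame", "three_frame"):
        raise DataError(f"unknown translation mode {mode!r}")
    seq = nucleotide_seq.upper()
    bad = set(seq) - _DNA
    if bad:
        raise DataError(f"non-DNA character(s) {sorted(bad)} in nucleotide sequence")

    strands = [("+", seq)]
    if mode == "six_frame":
        strands.append(("-", str(Seq(seq).reverse_complement())))

    length = len(seq)
    fragments: list[TranslatedFragment] = []
    for strand, text in strands:
        for frame in range(3):
            n_codons = (len(text) - frame) // 3
            if n_codons <= 0:
                continue
            aa = str(Seq(text[frame : frame + 3 * n_codons]).translate())
            # break at stops and at ambiguous codons
            start = 0
            for i, ch in enumerate(aa + "*"):
                if ch in "*X":
                    if i - start >= min_fragment:
                        frag = aa[start:i]
                        if strand == "+":
                            nt_start = frame + 3 * start
                            nt_end = frame + 3 * i
                        else:
                            nt_end = length - (frame + 3 * start)
                            nt_start = length - (frame + 3 * i)
                        fragments.append(
                            TranslatedFragment(
                                frame=frame,
                                strand=strand,
                                peptide=frag,
                                aa_offset=start,
                                nt_start=nt_start,
                                nt_end=nt_end,
                            )
                        )
                    start = i + 1
    return fragments


@dataclass
class _Entry:
    entry_id: str
    collapsed: str
    biotype: str | None
    frame: int | None = None
    strand: str | None = None


class ReferenceCollection:
    """Substring-searchable protein space built from FASTA references.

    Protein FASTA entries enter directly; nucleotide entries are translated
    (``six_frame`` for genomic, ``three_frame`` for transcript sequences)
    and each stop-free fragment becomes a searchable entry. Biotype labels
    come from a ``biotype=<tag>`` key in the FASTA header description; an
    entry without one is labelled ``unannotated`` in non-canonical space.
    """

    def __init__(self, entries: Iterable[_Entry] = ()):  # internal ctor
        self.entries: list[_Entry] = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def _header_tags(description: str) -> dict[str, str]:
        return dict(
            tok.split("=", 1) for tok in description.split() if "=" in tok
        )

    @classmethod
    def from_protein_fasta(cls, *paths) -> "ReferenceCollection":
        coll = cls()
        for path in paths:
            for rec in SeqIO.parse(str(path), "fasta"):
                tags = cls._header_tags(rec.description)
                coll.entries.append(
                    _Entry(
                        entry_id=rec.id,
                        collapsed=str(rec.seq).upper().replace("I", "L"),
                        biotype=tags.get("biotype"),
                    )
                )
        if not coll.entries:
            raise ReferenceError(f"no protein entries read from {list(paths)}")
        return coll

    @classmethod
    def from_nucleotide_fasta(
        cls, *paths, mode: str = "six_frame", min_fragment: int = 8
    ) -> "ReferenceCollection":
        coll = cls()
        for path in paths:
            for rec in SeqIO.parse(str(path), "fasta"):
                tags = cls._header_tags(rec.description)
                src_mode = mode
                if tags.get("src") == "transcriptome":
                    src_mode = "three_frame"
                elif tags.get("src") == "genome":
                    src_mode = "six_frame"
                for frag in translate_frames(
                    str(rec.seq), mode=src_mode, min_fragment=min_fragment
                ):
                    coll.entries.append(
                        _Entry(
                            entry_id=(
                                f"{rec.id}|{frag.strand}{frag.frame}"
                                f":{frag.nt_start}-{frag.nt_end}"
                            ),
                            collapsed=frag.peptide.replace("I", "L"),
                            biotype=tags.get("biotype", "unannotated"),
                            frame=frag.frame,
                            strand=frag.strand,
                        )
                    )
        if not coll.entries:
            raise ReferenceError(f"no translatable entries read from {list(paths)}")
        return coll

    def merged_with(self, other: "ReferenceCollection") -> "ReferenceCollection":
        return ReferenceCollection(self.entries + other.entries)


def match_exact(peptide: str, collection: ReferenceCollection) -> list[Hit]:
    """All exact substring occurrences, ordered by (entry id, offset)."""
    hits: list[Hit] = []
    for entry in collection.entries:
        start = entry.collapsed.find(peptide)
        while start != -1:
            hits.append(
                Hit(
                    entry_id=entry.entry_id,
                    offset=start,
                    frame=entry.frame,
                    strand=entry.strand,
                    biotype=entry.biotype,
                )
            )
            start = entry.collapsed.find(peptide, start + 1)
    hits.sort(key=lambda h: (h.entry_id, h.offset))
    return hits


def _verify_window(peptide: str, window: str) -> tuple[int, int] | None:
    """Return (mismatch count capped at 2, position of first mismatch)."""
    mismatches = 0
    pos = -1
    for i, (p, w) in enumerate(zip(peptide, window)):
        if p != w:
            mismatches += 1
            if mismatches == 1:
                pos = i
            elif mismatches > 1:
                return (2, pos)
    return (mismatches, pos)


def match_hamming1(peptide: str, collection: ReferenceCollection) -> list[Hit]:
    """All equal-length windows at Hamming distance exactly 1 (substitution).

    Pigeonhole seed-and-verify: a window within distance 1 must match one of
    the two halves of the peptide exactly, so each half is located by exact
    substring search and the full window verified — equivalent to (and
    property-tested against) a brute-force scan of every window.
    """
    n = len(peptide)
    half = n // 2
    seeds = ((peptide[:half], 0), (peptide[half:], half))
    hits: dict[tuple[str, int], Hit] = {}
    for entry in collection.entries:
        text = entry.collapsed
        for seed, seed_off in seeds:
            start = text.find(seed)
            while start != -1:
                w_start = start - seed_off
                if 0 <= w_start <= len(text) - n:
                    window = text[w_start : w_start + n]
                    mism, pos = _verify_window(peptide, window)
                    if mism == 1:
                        hits[(entry.entry_id, w_start)] = Hit(
                            entry_id=entry.entry_id,
                            offset=w_start,
                            frame=entry.frame,
                            strand=entry.strand,
                            biotype=entry.biotype,
                            sub_position=pos,
                            ref_residue=window[pos],
                            query_residue=peptide[pos],
                        )
                start = text.find(seed, start + 1)
    return sorted(hits.values(), key=lambda h: (h.entry_id, h.offset))


def match_hamming1_brute(peptide: str, collection: ReferenceCollection) -> list[Hit]:
    """Position-by-position scan of every window; the independent oracle."""
    n = len(peptide)
    hits = []
    for entry in collection.entries:
        text = entry.collapsed
        for w_start in range(len(text) - n + 1):
            window = text[w_start : w_start + n]
            mism, pos = _verify_window(peptide, window)
            if mism == 1:
                hits.append(
                    Hit(
                        entry_id=entry.entry_id,
                        offset=w_start,
                        frame=entry.frame,
                        strand=entry.strand,
                        biotype=entry.biotype,
                        sub_position=pos,
                        ref_residue=window[pos],
                        query_residue=peptide[pos],
                    )
                )
    hits.sort(key=lambda h: (h.entry_id, h.offset))
    return hits


def categorize(
    peptide: str,
    protein_collection: ReferenceCollection | None,
    noncanonical_collection: ReferenceCollection | None,
) -> OriginAssignment:
    """Stepwise origin assignment with strict canonical-first precedence."""
    peptide = normalize_il(peptide)
    if protein_collection is not None:
        exact = match_exact(peptide, protein_collection)
        if exact:
            return OriginAssignment(peptide, "HumanProtein", tuple(exact))
        sub = match_hamming1(peptide, protein_collection)
        if sub:
            return OriginAssignment(peptide, "OneAASubstitution", tuple(sub))
    if noncanonical_collection is not None:
        nc = match_exact(peptide, noncanonical_collection)
        if nc:
            return OriginAssignment(peptide, "NonCanonical", tuple(nc))
    return OriginAssignment(peptide, "Unmatched", ())


def biotype_summary(
    assignments: Sequence[OriginAssignment],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category counts and upset-style biotype-combination counts.

    The combination table counts non-canonical peptides per *set* of
    biotype labels (multi-label, no hierarchy), descending.
    """
    cat_counts = Counter(a.category for a in assignments)
    cat_df = pd.DataFrame(
        [
            {"category": c, "count": cat_counts[c]}
            for c in CATEGORIES
            if cat_counts[c] > 0
        ]
    )
    combos = Counter(
        tuple(sorted(a.biotypes))
        for a in assignments
        if a.category == "NonCanonical"
    )
    combo_df = pd.DataFrame(
        [
            {"biotypes": "+".join(labels) if labels else "unannotated", "count": n}
            for labels, n in sorted(combos.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
    )
    return cat_df, combo_df


def write_assignments(assignments: Sequence[OriginAssignment], path) -> None:
    """Per-peptide TSV report (1-based inclusive coordinates)."""
    rows = []
    for a in assignments:
        if not a.hits:
            rows.append({"peptide": a.peptide, "category": a.category})
            continue
        for h in a.hits:
            rows.append(
                {
                    "peptide": a.peptide,
                    "category": a.category,
                    "entry_id": h.entry_id,
                    "start_1based": h.offset + 1,
                    "end_1based": h.offset + len(a.peptide),
                    "frame": h.frame,
                    "strand": h.strand,
                    "biotype": h.biotype,
                    "sub_position_1based": (
                        None if h.sub_position is None else h.sub_position + 1
                    ),
                    "ref_residue": h.ref_residue,
                    "query_residue": h.query_residue,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
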