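"""Peptide-to-proteome mapping and tryptic/semi-tryptic classification.

In a trypsin-digested lysate exposed to a dipeptidyl peptidase, intact
tryptic peptides are the substrate pool and semi-tryptic peptides (peptides
violating one tryptic boundary) are candidate exopeptidase products. This
module anchors peptides to a protein database, applies the three tryptic
classification rules, matches products back to their parent substrates by
coordinate arithmetic, and reconstructs N-terminal sequence context for
product-based modeling.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .constants import TRYPTIC_RESIDUES

#: Sentinel used as ``preceding_residue`` when a peptide starts at a
#: protein's first residue.
PROTEIN_N_TERMINUS = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """One entry of the protein database."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class PeptideLocation:
    """A peptide anchored to a protein position (1-based start).

    ``preceding_residue`` is the protein residue immediately before the
    peptide, or ``"-"`` at the protein N-terminus. ``ambiguous_flank`` is
    set when the peptide maps to several proteome positions whose preceding
    residues differ.
    """

    peptide: str
    protein_id: str
    start: int
    preceding_residue: str
    at_c_terminus: bool
    ambiguous_flank: bool = False

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start must be >= 1 (1-based coordinates)")


@dataclass(frozen=True)
class ClassifiedPeptide:
    """A located peptide with its tryptic/semi-tryptic call.

    ``criterion`` names which tryptic rule fired ("i", "ii" or "iii"),
    and is set exactly when ``cls == "tryptic"``.
    """

    location: PeptideLocation
    cls: str
    criterion: str | None = None

    def __post_init__(self) -> None:
        if self.cls not in ("tryptic", "semi_tryptic"):
            raise ValueError(f"unknown class {self.cls!r}")
        if (self.criterion is not None) != (self.cls == "tryptic"):
            raise ValueError("criterion must be set iff class is tryptic")


def load_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    The header token before the first whitespace is the accession;
    sequences are uppercased. Duplicate accessions raise.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate protein id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq).upper()))
    return records


class ProteomeIndex:
    """Substring index over a protein database.

    Proteins are concatenated (with a separator that cannot occur in a
    peptide) so each lookup is a single C-level scan; concatenated offsets
    are mapped back to (protein, position) by bisection. Hits come back in
    database order, then position order, matching the first-mapping-
    position convention.
    """

    SEP = "|"

    def __init__(self, proteins: Sequence[ProteinRecord]):
        self.proteins = list(proteins)
        self._by_id = {p.id: p for p in self.proteins}
        if len(self._by_id) != len(self.proteins):
            raise ValueError("duplicate protein ids in database")
        self._offsets = []
        pieces = []
        pos = 0
        for p in self.proteins:
            self._offsets.append(pos)
            pieces.append(p.sequence)
            pos += len(p.sequence) + 1
        self._text = self.SEP.join(pieces)

    def __len__(self) -> int:
        return len(self.proteins)

    def protein(self, protein_id: str) -> ProteinRecord:
        return self._by_id[protein_id]

    def find_all(self, peptide: str) -> list[tuple[str, int]]:
        """All (protein_id, 1-based start) occurrences, in database order."""
        if not peptide:
            raise ValueError("peptide must be non-empty")
        hits: list[tuple[str, int]] = []
        i = self._text.find(peptide)
        while i != -1:
            k = bisect.bisect_right(self._offsets, i) - 1
            prot = self.proteins[k]
            local = i - self._offsets[k]
            # separator-straddling match is impossible (SEP not a residue)
            hits.append((prot.id, local + 1))
            i = self._text.find(peptide, i + 1)
        return hits


def _location_at(index: ProteomeIndex, peptide: str, protein_id: str,
                 start: int, ambiguous: bool) -> PeptideLocation:
    prot = index.protein(protein_id)
    preceding = PROTEIN_N_TERMINUS if start == 1 else prot.sequence[start - 2]
    at_c = start - 1 + len(peptide) == len(prot.sequence)
    return PeptideLocation(peptide=peptide, protein_id=protein_id, start=start,
                           preceding_residue=preceding, at_c_terminus=at_c,
                           ambiguous_flank=ambiguous)


def locate_peptide(peptide: str, index: ProteomeIndex) -> PeptideLocation | None:
    """Locate a peptide in the proteome; ``None`` when unmapped.

    On multi-mapping, the first hit (database order, then position) is
    used and ``ambiguous_flank`` records whether the preceding residues
    disagree across hits.
    """
    hits = index.find_all(peptide)
    if not hits:
        return None
    flanks = set()
    for pid, start in hits:
        prot = index.protein(pid)
        flanks.add(PROTEIN_N_TERMINUS if start == 1 else prot.sequence[start - 2])
    pid, start = hits[0]
    return _location_at(index, peptide, pid, start, ambiguous=len(flanks) > 1)


def classify_peptide(loc: PeptideLocation, *,
                     allow_initiator_met: bool = True) -> ClassifiedPeptide:
    """Apply the three tryptic rules to a mapped peptide.

    (i) starts downstream of K/R and ends with K/R; (ii) starts downstream
    of K/R and ends at the protein C-terminus; (iii) ends with K/R and
    starts at the protein N-terminus. With ``allow_initiator_met`` (default
    on), start position 2 behind an initiator Met also counts as the
    protein N-terminus. Anything mapped that fails all three rules is
    semi-tryptic.
    """
    after_kr = loc.preceding_residue in TRYPTIC_RESIDUES
    ends_kr = loc.peptide[-1] in TRYPTIC_RESIDUES
    at_n = loc.preceding_residue == PROTEIN_N_TERMINUS or (
        allow_initiator_met and loc.start == 2 and loc.preceding_residue == "M"
    )
    if after_kr and ends_kr:
        return ClassifiedPeptide(loc, "tryptic", "i")
    if after_kr and loc.at_c_terminus:
        return ClassifiedPeptide(loc, "tryptic", "ii")
    if ends_kr and at_n:
        return ClassifiedPeptide(loc, "tryptic", "iii")
    return ClassifiedPeptide(loc, "semi_tryptic")


def classify_peptides(peptides: Iterable[str], index: ProteomeIndex, *,
                      allow_initiator_met: bool = True) -> pd.DataFrame:
    """Locate and classify many peptides into a tidy table.

    Returns one row per input peptide with columns peptide, protein_id,
    start, preceding_residue, class, criterion, ambiguous_flank; unmapped
    peptides get class ``"unmapped"``.
    """
    rows = []
    for pep in peptides:
        loc = locate_peptide(pep, index)
        if loc is None:
            rows.append((pep, None, None, None, "unmapped", None, False))
            continue
        cp = classify_peptide(loc, allow_initiator_met=allow_initiator_met)
        rows.append((pep, loc.protein_id, loc.start, loc.preceding_residue,
                     cp.cls, cp.criterion, loc.ambiguous_flank))
    return pd.DataFrame(rows, columns=["peptide", "protein_id", "start",
                                       "preceding_residue", "class",
                                       "criterion", "ambiguous_flank"])


@dataclass
class MatchSummary:
    """Product→substrate matching result."""

    pairs: list[tuple[PeptideLocation, PeptideLocation]] = field(default_factory=list)
    n_products: int = 0

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def match_rate(self) -> float:
        return self.n_matched / self.n_products if self.n_products else float("nan")


def match_products_to_substrates(products: Sequence[PeptideLocation],
                                 substrates: Sequence[PeptideLocation],
                                 offset: int) -> MatchSummary:
    """Match each product to the substrate it was cleaved from.

    A product matches a substrate when both map to the same protein, the
    product starts exactly ``offset`` residues downstream (the number of
    N-terminal residues the exopeptidase removes; 2 for dipeptidyl
    peptidases) and both end at the same protein position.
    """
    if offset < 1:
        raise ValueError("offset must be a positive integer")
    sub_by_key = {}
    for s in substrates:
        sub_by_key.setdefault(
            (s.protein_id, s.start, s.start + len(s.peptide)), s)
    out = MatchSummary(n_products=len(products))
    for p in products:
        key = (p.protein_id, p.start - offset, p.start + len(p.peptide))
        s = sub_by_key.get(key)
        if s is not None:
            out.pairs.append((p, s))
    return out


def extend_n_terminus(loc: PeptideLocation, index: ProteomeIndex,
                      n: int) -> str:
    """Prepend the ``n`` protein residues preceding the peptide.

    Used to turn a product back into the substrate sequence whose cleavage
    generated it. Raises when the peptide sits closer than ``n`` residues
    to the protein N-terminus.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return loc.peptide
    if loc.start - n < 1:
        raise ValueError(
            f"peptide at position {loc.start} cannot be extended by {n}")
    prot = index.protein(loc.protein_id)
    return prot.sequence[loc.start - 1 - n: loc.start - 1] + loc.peptide
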