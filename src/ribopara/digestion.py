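"""In silico tryptic digestion and peptide-uniqueness classification.

Trypsin cleaves C-terminal to lysine (K) and arginine (R) except when the
next residue is proline. Search engines run in "full tryptic" mode enumerate
all peptides with up to a configured number of missed cleavage sites; the
analyses here allow two, matching common database-search settings.

Peptide uniqueness decides which spectra can be attributed to a single
protein. A peptide is *unique* if exactly one registry protein contains it,
*pair_shared* if it occurs in precisely the two members of one paralog
group, and *multi_shared* otherwise. Only unique peptides can discriminate
paralogs; uniqueness is evaluated against the supplied registry (users who
need proteome-wide uniqueness should supply a proteome-scale registry).

Modifications (oxidation, TMT tags, ...) change peptide mass but not its
residue string; uniqueness is decided on the bare sequence, and modified
spectrum matches are expected to be keyed by their stripped sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from .registry import AMINO_ACIDS, Registry

UNIQUE = "unique"
PAIR_SHARED = "pair_shared"
MULTI_SHARED = "multi_shared"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings: missed-cleavage cap, length window, proline rule."""

    max_missed: int = 2
    min_len: int = 6
    max_len: int = 50
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with its 1-based position in the parent protein."""

    sequence: str
    parent: str
    start: int
    missed_cleavages: int


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based indices i such that trypsin cuts between residue i and i+1."""
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i)
    return sites


def tryptic_digest(
    sequence: str,
    *,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
    proline_rule: bool = True,
    parent: str = "",
) -> list[Peptide]:
    """Enumerate tryptic peptides of ``sequence``.

    Returns every peptide with 0..``max_missed`` internal retained cleavage
    sites and length within [``min_len``, ``max_len``], sorted by
    (start, length). Raises ``ValueError`` on non-amino-acid characters.
    """
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residues in sequence: {sorted(bad)}")
    sites = cleavage_sites(sequence, proline_rule)
    # segment boundaries: fragment k spans [bounds[k], bounds[k+1])
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    peptides = []
    n_seg = len(bounds) - 1
    for i in range(n_seg):
        for j in range(i, min(i + max_missed + 1, n_seg)):
            pep = sequence[bounds[i] : bounds[j + 1]]
            if min_len <= len(pep) <= max_len:
                peptides.append(
                    Peptide(
                        sequence=pep,
                        parent=parent,
                        start=bounds[i] + 1,
                        missed_cleavages=j - i,
                    )
                )
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def digest_protein(registry: Registry, accession: str, params: DigestParams) -> list[Peptide]:
    return tryptic_digest(
        registry.protein(accession).sequence,
        max_missed=params.max_missed,
        min_len=params.min_len,
        max_len=params.max_len,
        proline_rule=params.proline_rule,
        parent=accession,
    )


class PeptideIndex:
    """Map peptide sequence -> parent accessions, with uniqueness classes."""

    def __init__(self, registry: Registry, params: DigestParams) -> None:
        self.params = params
        self._pair_sets = {g.members for g in registry.groups.values()}
        parents: dict[str, set[str]] = {}
        by_parent: dict[str, set[str]] = {}
        for acc in sorted(registry.proteins):
            seqs = {p.sequence for p in digest_protein(registry, acc, params)}
            by_parent[acc] = seqs
            for s in seqs:
                parents.setdefault(s, set()).add(acc)
        self.parents: dict[str, frozenset[str]] = {
            s: frozenset(a) for s, a in parents.items()
        }
        self._by_parent = by_parent

    def classify(self, peptide_sequence: str) -> str:
        """Uniqueness class of a peptide, or ``"unknown"`` if never digested."""
        par = self.parents.get(peptide_sequence)
        if par is None:
            return UNKNOWN
        if len(par) == 1:
            return UNIQUE
        if par in self._pair_sets:
            return PAIR_SHARED
        return MULTI_SHARED

    def parents_of(self, peptide_sequence: str) -> frozenset[str]:
        return self.parents.get(peptide_sequence, frozenset())

    def unique_peptides(self, accession: str) -> set[str]:
        """Peptide sequences occurring in ``accession`` and nowhere else."""
        return {
            s for s in self._by_parent.get(accession, ())
            if len(self.parents[s]) == 1
        }

    def is_unique(self, peptide_sequence: str) -> bool:
        return self.classify(peptide_sequence) == UNIQUE

    def to_table(self) -> "list[tuple[str, str, str]]":
        """(peptide, semicolon-joined parents, class) rows, sorted by peptide."""
        return [
            (s, ";".join(sorted(self.parents[s])), self.classify(s))
            for s in sorted(self.parents)
        ]

    def write_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("peptide\tparents\tclass\n")
            for row in self.to_table():
                fh.write("\t".join(row) + "\n")


def build_peptide_index(
    registry: Registry, digest_params: DigestParams | None = None
) -> PeptideIndex:
    """Digest every registry protein and index peptide parenthood."""
    return PeptideIndex(registry, digest_params or DigestParams())


def classify_peptide(peptide_sequence: str, index: PeptideIndex) -> str:
    """Uniqueness class of ``peptide_sequence`` under ``index``.

    Sequences absent from the index yield the distinct value ``"unknown"``;
    they are never conflated with ``multi_shared``.
    """
    return index.classify(peptide_sequence)
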