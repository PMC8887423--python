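"""Protein and paralog registry.

The registry is the single source of truth for which proteins exist, which
pairs of them are paralogs (two genes arisen by duplication that occupy the
same position in the ribosome), and which member of each pair is the
*canonical* one. Drosophila melanogaster annotates 93 cytoplasmic ribosomal
protein (RP) genes -- 39 small-subunit and 54 large-subunit proteins --
including 13 paralog pairs, so each assembled ribosome carries 80 distinct
protein positions. One pair (RpS14a/RpS14b) encodes identical amino-acid
sequences and is therefore invisible to peptide-level mass spectrometry;
the remaining 12 pairs are sequence-distinguishable.

A bundled fixture with this exact bookkeeping ships with the package; its
sequences are synthetic (see :func:`load_bundled_registry`).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
SUBUNITS = ("SSU", "LSU", "other")
ROLES = ("canonical", "alternative", "none")


class RegistryError(ValueError):
    """Raised when a registry or its inputs violate an invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, gene symbol, sequence and paralog membership.

    ``role`` is ``"none"`` exactly when the protein belongs to no paralog
    group (``group_id is None``).
    """

    accession: str
    gene_symbol: str
    sequence: str
    subunit: str = "other"
    group_id: str | None = None
    role: str = "none"

    def __post_init__(self) -> None:
        if not self.accession:
            raise RegistryError("empty accession")
        if not self.sequence:
            raise RegistryError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise RegistryError(
                f"{self.accession}: invalid residues {sorted(bad)}"
            )
        if self.subunit not in SUBUNITS:
            raise RegistryError(f"{self.accession}: bad subunit {self.subunit!r}")
        if self.role not in ROLES:
            raise RegistryError(f"{self.accession}: bad role {self.role!r}")
        if (self.role != "none") != (self.group_id is not None):
            raise RegistryError(
                f"{self.accession}: role {self.role!r} inconsistent with "
                f"group_id {self.group_id!r}"
            )


@dataclass(frozen=True)
class ParalogGroup:
    """A canonical/alternative paralog pair.

    ``sequence_identical`` is always computed from the member sequences,
    never trusted from input annotation.
    """

    group_id: str
    canonical: str
    alternative: str
    sequence_identical: bool

    def __post_init__(self) -> None:
        if self.canonical == self.alternative:
            raise RegistryError(
                f"group {self.group_id}: canonical == alternative"
            )

    @property
    def members(self) -> frozenset[str]:
        return frozenset((self.canonical, self.alternative))


class Registry:
    """Validated collection of :class:`ProteinRecord` and :class:`ParalogGroup`."""

    def __init__(
        self,
        proteins: Iterable[ProteinRecord],
        groups: Iterable[ParalogGroup] = (),
    ) -> None:
        self.proteins: dict[str, ProteinRecord] = {}
        for rec in proteins:
            if rec.accession in self.proteins:
                raise RegistryError(f"duplicate accession {rec.accession}")
            self.proteins[rec.accession] = rec
        self.groups: dict[str, ParalogGroup] = {}
        seen_members: dict[str, str] = {}
        for grp in groups:
            if grp.group_id in self.groups:
                raise RegistryError(f"duplicate group {grp.group_id}")
            for acc in (grp.canonical, grp.alternative):
                if acc not in self.proteins:
                    raise RegistryError(
                        f"group {grp.group_id}: member {acc} not in registry"
                    )
                if acc in seen_members:
                    raise RegistryError(
                        f"protein {acc} in two groups "
                        f"({seen_members[acc]}, {grp.group_id})"
                    )
                seen_members[acc] = grp.group_id
            identical = (
                self.proteins[grp.canonical].sequence
                == self.proteins[grp.alternative].sequence
            )
            if grp.sequence_identical != identical:
                raise RegistryError(
                    f"group {grp.group_id}: sequence_identical flag "
                    f"disagrees with the sequences"
                )
            self.groups[grp.group_id] = grp

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, accession: str) -> bool:
        return accession in self.proteins

    def protein(self, accession: str) -> ProteinRecord:
        try:
            return self.proteins[accession]
        except KeyError:
            raise RegistryError(f"unknown accession {accession}") from None

    def group(self, group_id: str) -> ParalogGroup:
        try:
            return self.groups[group_id]
        except KeyError:
            raise RegistryError(f"unknown group {group_id}") from None

    def group_of(self, accession: str) -> ParalogGroup | None:
        gid = self.protein(accession).group_id
        return self.groups[gid] if gid is not None else None

    def gene_symbol(self, accession: str) -> str:
        return self.protein(accession).gene_symbol


def load_registry(fasta_source, annotation_table) -> Registry:
    """Build a :class:`Registry` from FASTA sequences plus an annotation table.

    Parameters
    ----------
    fasta_source
        Path or text handle to a FASTA file. The accession is the first
        whitespace-delimited token of the header.
    annotation_table
        Path or text handle to a UTF-8 tab-separated table with a header row
        and columns ``accession``, ``gene_symbol``, ``subunit``, ``group_id``
        (empty allowed) and ``role``.

    Every annotated accession must have a FASTA record; groups must have
    exactly one canonical and one alternative member.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(_as_handle(fasta_source), "fasta"):
        if rec.id in sequences:
            raise RegistryError(f"duplicate accession {rec.id} in FASTA")
        sequences[rec.id] = str(rec.seq).upper()

    proteins: list[ProteinRecord] = []
    by_group: dict[str, dict[str, str]] = {}
    handle = _as_handle(annotation_table)
    reader = csv.DictReader(handle, delimiter="\t")
    required = {"accession", "gene_symbol", "subunit", "group_id", "role"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise RegistryError(
            f"annotation table must have columns {sorted(required)}"
        )
    for row in reader:
        acc = row["accession"].strip()
        if acc not in sequences:
            raise RegistryError(f"annotated accession {acc} has no FASTA record")
        gid = row["group_id"].strip() or None
        role = row["role"].strip() or "none"
        proteins.append(
            ProteinRecord(
                accession=acc,
                gene_symbol=row["gene_symbol"].strip(),
                sequence=sequences[acc],
                subunit=row["subunit"].strip(),
                group_id=gid,
                role=role,
            )
        )
        if gid is not None:
            by_group.setdefault(gid, {})
            if role in by_group[gid]:
                raise RegistryError(f"group {gid}: two {role} members")
            by_group[gid][role] = acc

    groups = []
    for gid in sorted(by_group):
        members = by_group[gid]
        if set(members) != {"canonical", "alternative"}:
            raise RegistryError(
                f"group {gid} needs exactly one canonical and one "
                f"alternative member, got roles {sorted(members)}"
            )
        groups.append(
            ParalogGroup(
                group_id=gid,
                canonical=members["canonical"],
                alternative=members["alternative"],
                sequence_identical=(
                    sequences[members["canonical"]]
                    == sequences[members["alternative"]]
                ),
            )
        )
    return Registry(proteins, groups)


def count_positions(registry: Registry) -> int:
    """Number of distinct ribosomal positions: proteins minus paralog pairs.

    Each paralog pair occupies a single position, so 93 proteins with 13
    pairs give 80 positions.
    """
    return len(registry.proteins) - len(registry.groups)


def distinguishable_pairs(registry: Registry) -> list[ParalogGroup]:
    """Paralog pairs whose members differ in sequence, ordered by group_id.

    Sequence-identical pairs (RpS14a/RpS14b in the fly) cannot be told apart
    by any peptide and are excluded from all peptide-level analyses.
    """
    return [
        registry.groups[gid]
        for gid in sorted(registry.groups)
        if not registry.groups[gid].sequence_identical
    ]


def load_bundled_registry() -> Registry:
    """Load the bundled Drosophila ribosomal-protein fixture.

    The fixture reproduces the fly RP bookkeeping -- 93 proteins (39 SSU,
    54 LSU), 13 paralog pairs, RpS14a/b identical -- under the real gene
    symbols, but its amino-acid sequences are synthetic: deterministically
    generated tryptic-block sequences (see ``scripts/make_registry_fixture.py``)
    in which each distinguishable pair carries several equal-length peptides
    differing at 1-2 residues, mirroring how real paralog pairs present to
    the mass spectrometer.
    """
    data = resources.files("ribopara.data")
    fasta = (data / "dm_rp_synthetic.fasta").read_text()
    annot = (data / "dm_rp_synthetic.tsv").read_text()
    return load_registry(io.StringIO(fasta), io.StringIO(annot))


def _as_handle(source):
    if hasattr(source, "read"):
        return source
    return open(Path(source), "rt", encoding="utf-8")
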