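"""In-silico tryptic digestion and peptide→protein mapping.

Only peptides unique to one protein quantify that protein; peptides shared
between isoforms of a family (e.g. the 13-member PIP aquaporin subfamily,
with up to 96% within-subgroup identity) carry mixture information instead.
Uniqueness here is exact-substring based: exhaustive digestion of the whole
collection subsumes manual sequence alignment.  Because mass-only matching
cannot distinguish leucine from isoleucine, classification can optionally
treat I and L as equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .chem import validate_sequence

__all__ = [
    "ProteinRecord",
    "TrypticPeptide",
    "PeptideAssignment",
    "read_fasta",
    "write_fasta",
    "tryptic_digest",
    "build_peptide_map",
    "classify_uniqueness",
    "write_peptide_map",
]


class DigestError(ValueError):
    """Raised for invalid digestion inputs."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its accession (e.g. AGI code AT3G53420)."""

    accession: str
    sequence: str
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise DigestError("empty accession")
        validate_sequence(self.sequence)


@dataclass(frozen=True)
class TrypticPeptide:
    """A tryptic product with its position (0-based, end-exclusive)."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


@dataclass(frozen=True)
class PeptideAssignment:
    """A peptide with its parent proteins and uniqueness verdict."""

    sequence: str
    parents: tuple[str, ...]
    unique: bool
    missed_cleavages: int
    il_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.unique == (len(self.parents) == 1)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Load proteins from FASTA; the accession is the first header token."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        annotation = desc.split(None, 1)[1] if len(desc.split(None, 1)) > 1 else ""
        records.append(
            ProteinRecord(
                accession=rec.id, sequence=str(rec.seq).upper(), annotation=annotation
            )
        )
    if not records:
        raise DigestError(f"no FASTA records in {path}")
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            header = f">{p.accession}" + (f" {p.annotation}" if p.annotation else "")
            fh.write(header + "\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def cleavage_sites(sequence: str, suppress_before_proline: bool = True) -> list[int]:
    """Positions after which trypsin cuts: after K or R, not before P."""
    sites = []
    for i, ch in enumerate(sequence[:-1]):
        if ch in "KR":
            if suppress_before_proline and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def tryptic_digest(
    sequence: str,
    max_missed: int = 1,
    suppress_before_proline: bool = True,
) -> list[TrypticPeptide]:
    """All tryptic peptides with 0..max_missed internal missed cleavages.

    Peptides are returned in positional order (then by missed-cleavage
    count).  Concatenating the 0-missed products in order reproduces the
    protein sequence.
    """
    if not sequence:
        raise DigestError("empty sequence")
    seq = validate_sequence(sequence)
    if max_missed < 0:
        raise DigestError("max_missed must be >= 0")
    bounds = [0] + cleavage_sites(seq, suppress_before_proline) + [len(seq)]
    peptides = []
    for i in range(len(bounds) - 1):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j >= len(bounds):
                break
            peptides.append(
                TrypticPeptide(
                    sequence=seq[bounds[i] : bounds[j]],
                    start=bounds[i],
                    end=bounds[j],
                    missed_cleavages=m,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def build_peptide_map(
    proteins: Sequence[ProteinRecord],
    max_missed: int = 1,
    min_length: int = 5,
    max_length: int = 35,
    suppress_before_proline: bool = True,
) -> dict[str, tuple[str, ...]]:
    """Map every in-bounds tryptic peptide to the sorted tuple of parent
    accessions that produce it.

    Length bounds default to the MALDI-observable 5–35 residue range.
    Duplicate accessions are rejected; the map is deterministic for a given
    input, so rebuilding from the same collection is idempotent.
    """
    if not proteins:
        raise DigestError("no proteins supplied")
    seen = set()
    for p in proteins:
        if p.accession in seen:
            raise DigestError(f"duplicate accession {p.accession!r}")
        seen.add(p.accession)
    mapping: dict[str, set[str]] = {}
    for prot in proteins:
        for pep in tryptic_digest(prot.sequence, max_missed, suppress_before_proline):
            if min_length <= len(pep.sequence) <= max_length:
                mapping.setdefault(pep.sequence, set()).add(prot.accession)
    return {pep: tuple(sorted(accs)) for pep, accs in sorted(mapping.items())}


def _missed_count(sequence: str, suppress_before_proline: bool = True) -> int:
    return len(cleavage_sites(sequence, suppress_before_proline))


def classify_uniqueness(
    peptide_map: Mapping[str, tuple[str, ...]],
    family_subset: Iterable[str] | None = None,
    il_equivalent: bool = False,
) -> list[PeptideAssignment]:
    """Partition peptides into unique (one parent) and shared (≥2 parents),
    optionally restricted to a subset of accessions.

    With ``il_equivalent`` peptides differing only at I/L positions are
    collapsed into one entry (parents unioned), since isobaric residues are
    indistinguishable by mass; the member sequences are reported as
    ``il_variants``.
    """
    all_accessions = {a for accs in peptide_map.values() for a in accs}
    if family_subset is not None:
        subset = set(family_subset)
        unknown = subset - all_accessions
        if unknown:
            raise DigestError(f"unknown accessions in subset: {sorted(unknown)}")
    else:
        subset = all_accessions

    groups: dict[str, tuple[set[str], set[str]]] = {}
    for pep, accs in peptide_map.items():
        parents = set(accs) & subset
        if not parents:
            continue
        key = pep.replace("I", "L") if il_equivalent else pep
        seqs, parent_set = groups.setdefault(key, (set(), set()))
        seqs.add(pep)
        parent_set.update(parents)

    assignments = []
    for key in sorted(groups):
        seqs, parents = groups[key]
        canonical = min(seqs)
        assignments.append(
            PeptideAssignment(
                sequence=canonical,
                parents=tuple(sorted(parents)),
                unique=len(parents) == 1,
                missed_cleavages=_missed_count(canonical),
                il_variants=tuple(sorted(seqs)) if len(seqs) > 1 else (),
            )
        )
    return assignments


def write_peptide_map(
    assignments: Sequence[PeptideAssignment], path: str | Path
) -> None:
    """Tab-separated library table: peptide, accessions, missed, uniqueness."""
    with open(path, "w") as fh:
        fh.write("peptide\taccessions\tmissed_cleavages\tunique\n")
        for a in assignments:
            fh.write(
                f"{a.sequence}\t{';'.join(a.parents)}\t"
                f"{a.missed_cleavages}\t{'yes' if a.unique else 'no'}\n"
            )
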