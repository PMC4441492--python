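"""Germline switch-region reference handling.

Switch (S) regions are the long, pentamer-repeat-rich stretches upstream of
each immunoglobulin heavy-chain constant gene.  Class switch recombination
joins the donor region (Smu) to a downstream acceptor (Sgamma1, Sgamma3, ...),
and every junction read produced by the assay is a chimera of fragments of
these germline references.  This module owns the reference container and all
coordinate conventions.

Coordinates
-----------
Internally every interval is 0-based, half-open on a region's forward strand.
Reported/rendered coordinates are 1-based, inclusive, in the accession frame:
a region carries ``genomic_offset``, the 1-based genomic position of
``sequence[0]``, so local position ``i`` maps to genomic ``genomic_offset + i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")


class ValidationError(ValueError):
    """Input data violates a structural invariant (bad alphabet, bad interval)."""


class ConfigurationError(ValueError):
    """User-supplied configuration is inconsistent (missing names, bad params)."""


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    for i, base in enumerate(seq):
        if base not in DNA_ALPHABET:
            raise ValidationError(
                f"non-DNA character {base!r} at position {i + 1} (alphabet is A/C/G/T/N)"
            )
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` over A/C/G/T/N.

    Raises :class:`ValidationError` on any other character.
    """
    seq = _check_dna(seq)
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class SwitchRegion:
    """One germline switch-region segment junction fragments map to.

    ``genomic_offset`` is the 1-based genomic position (in ``accession``'s
    frame) of the first base of ``sequence``.
    """

    name: str
    sequence: str
    accession: str = ""
    genomic_offset: int = 1
    role: str | None = None  # "donor" | "acceptor" | None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_dna(self.sequence))
        if not self.sequence:
            raise ValidationError(f"region {self.name!r}: empty sequence")
        if self.genomic_offset < 1:
            raise ValidationError(
                f"region {self.name!r}: genomic_offset must be >= 1, got {self.genomic_offset}"
            )
        if self.role not in (None, "donor", "acceptor"):
            raise ValidationError(f"region {self.name!r}: bad role {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    # -- coordinate conversions ------------------------------------------------

    def local_to_genomic(self, interval: tuple[int, int]) -> tuple[int, int]:
        """0-based half-open local interval -> 1-based inclusive genomic interval."""
        start, end = interval
        if not (0 <= start < end <= len(self.sequence)):
            raise ValidationError(
                f"region {self.name!r}: interval {interval} out of bounds (len {len(self)})"
            )
        return (self.genomic_offset + start, self.genomic_offset + end - 1)

    def genomic_to_local(self, interval: tuple[int, int]) -> tuple[int, int]:
        """1-based inclusive genomic interval -> 0-based half-open local interval."""
        gstart, gend = interval
        start = gstart - self.genomic_offset
        end = gend - self.genomic_offset + 1
        if not (0 <= start < end <= len(self.sequence)):
            raise ValidationError(
                f"region {self.name!r}: genomic interval {interval} outside region"
            )
        return (start, end)

    def genomic_position(self, local: int) -> int:
        """0-based local position -> 1-based genomic coordinate of that base."""
        if not (0 <= local < len(self.sequence)):
            raise ValidationError(
                f"region {self.name!r}: position {local} out of bounds (len {len(self)})"
            )
        return self.genomic_offset + local

    def oriented(self, strand: str) -> str:
        """Region sequence as read along the given strand ("+" or "-")."""
        if strand == "+":
            return self.sequence
        if strand == "-":
            return revcomp(self.sequence)
        raise ValidationError(f"bad strand {strand!r}")


@dataclass
class ReferenceSet:
    """A validated collection of switch regions with designated donor/acceptor."""

    regions: dict[str, SwitchRegion]
    donor_name: str
    acceptor_name: str

    def __post_init__(self) -> None:
        for want in (self.donor_name, self.acceptor_name):
            if want not in self.regions:
                raise ConfigurationError(
                    f"region {want!r} not found; available: {sorted(self.regions)}"
                )
        if self.donor_name == self.acceptor_name:
            raise ConfigurationError("donor and acceptor must be distinct regions")

    @property
    def donor(self) -> SwitchRegion:
        return self.regions[self.donor_name]

    @property
    def acceptor(self) -> SwitchRegion:
        return self.regions[self.acceptor_name]

    def __getitem__(self, name: str) -> SwitchRegion:
        return self.regions[name]

    def __iter__(self):
        return iter(self.regions.values())


def _parse_description_kv(description: str) -> dict[str, str]:
    # FASTA description tokens of the form key=value, space separated.
    out: dict[str, str] = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            out[key] = value
    return out


def build_reference_set(
    regions: Iterable[SwitchRegion], donor_name: str, acceptor_name: str
) -> ReferenceSet:
    mapping: dict[str, SwitchRegion] = {}
    for region in regions:
        if region.name in mapping:
            raise ValidationError(f"duplicate region name {region.name!r}")
        role = (
            "donor"
            if region.name == donor_name
            else "acceptor"
            if region.name == acceptor_name
            else region.role
        )
        mapping[region.name] = SwitchRegion(
            name=region.name,
            sequence=region.sequence,
            accession=region.accession,
            genomic_offset=region.genomic_offset,
            role=role,
        )
    return ReferenceSet(mapping, donor_name, acceptor_name)


def load_references(path: str | Path, donor_name: str, acceptor_name: str) -> ReferenceSet:
    """Load switch-region references from a (multi-record) FASTA file.

    The description line may carry space-separated ``key=value`` pairs; the
    keys ``offset`` (1-based genomic position of the first base, default 1)
    and ``accession`` are recognised.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"reference FASTA not found: {path}")
    regions: list[SwitchRegion] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = _parse_description_kv(rec.description)
        try:
            offset = int(kv.get("offset", "1"))
        except ValueError as exc:
            raise ConfigurationError(f"record {rec.id!r}: bad offset {kv['offset']!r}") from exc
        regions.append(
            SwitchRegion(
                name=rec.id,
                sequence=str(rec.seq),
                accession=kv.get("accession", ""),
                genomic_offset=offset,
            )
        )
    if not regions:
        raise ConfigurationError(f"no FASTA records in {path}")
    return build_reference_set(regions, donor_name, acceptor_name)


def write_references(refs: ReferenceSet, path: str | Path) -> None:
    """Write a reference set back to FASTA, preserving offset/accession metadata."""
    records = []
    for region in refs:
        desc = f"offset={region.genomic_offset}"
        if region.accession:
            desc += f" accession={region.accession}"
        records.append(SeqRecord(Seq(region.sequence), id=region.name, description=desc))
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
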