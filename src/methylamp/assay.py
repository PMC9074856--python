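"""Assay definition for a targeted bisulfite PCR amplicon.

The assay is the fixed coordinate frame for the whole pipeline: a short
amplicon insert on the bisulfite top strand, the ordered CpG positions whose
joint methylation state constitutes the tissue marker, and the
methylation-independent primers flanking them. The default packaged assay
models the six-CpG island in the FAM101A locus that is unmethylated
specifically in cardiomyocytes (the insert sequence itself is a synthetic
stand-in; see ``data/default_assay.yaml``).

Conventions
-----------
* Coordinates are 0-based half-open internally. The 1-based inclusive
  ``locus_label`` string is a display label only.
* Only the bisulfite top strand is modelled (C->T conversion). Amplicon PCR
  with a fixed primer pair fixes read orientation, so the bottom (G->A)
  strand is never aligned; this is a deliberate limitation.
* In the converted reference, CpG cytosines are bivalent: both C (methylated,
  protected) and T (unmethylated, converted) match with zero penalty, so
  alignment is methylation-unbiased.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

_DNA_ALPHABET = frozenset("ACGT")

#: IUPAC ambiguity code used at CpG cytosines of the converted reference:
#: Y = pyrimidine = C or T.
CPG_AMBIGUITY = "Y"


def _check_dna(seq: str, fieldname: str) -> str:
    if not isinstance(seq, str):
        raise ValidationError(f"{fieldname}: expected a DNA string, got {type(seq).__name__}")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValidationError(
            f"{fieldname}: invalid DNA characters {sorted(bad)} (only A/C/G/T allowed)"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T/N string."""
    return str(Seq(seq).reverse_complement())


def _bisulfite_degenerate_match(primer: str, ref_window: str) -> bool:
    """True if ``primer`` matches ``ref_window`` allowing the bisulfite
    degeneracy C(ref) -> C or T (primer) at every position."""
    if len(primer) != len(ref_window):
        return False
    for p, r in zip(primer, ref_window):
        if p == r:
            continue
        if r == "C" and p == "T":
            continue
        return False
    return True


@dataclass(frozen=True)
class AssayDefinition:
    """A targeted bisulfite amplicon assay.

    Parameters
    ----------
    name
        Identifier used in FASTA headers and reports.
    reference_seq
        Unconverted top-strand amplicon insert, uppercase A/C/G/T, spanning
        primer footprint to primer footprint.
    locus_label
        Human-readable 1-based inclusive genomic interval, display only.
    cpg_offsets
        Ordered 0-based offsets into ``reference_seq``, each pointing at the
        C of a CpG dinucleotide. The default assay has exactly six.
    primer_fwd, primer_rev
        Locus-specific primer portions (as synthesised, i.e. matching the
        bisulfite-converted template); ``primer_fwd`` matches the insert
        prefix, the reverse complement of ``primer_rev`` the insert suffix,
        both under bisulfite degeneracy.
    adapter_fwd, adapter_rev
        Sequencing-adapter overhangs, stored verbatim for provenance.
    """

    name: str
    reference_seq: str
    locus_label: str
    cpg_offsets: tuple[int, ...]
    primer_fwd: str
    primer_rev: str
    adapter_fwd: str = ""
    adapter_rev: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.reference_seq, "reference_seq")
        _check_dna(self.primer_fwd, "primer_fwd")
        _check_dna(self.primer_rev, "primer_rev")
        if self.adapter_fwd:
            _check_dna(self.adapter_fwd, "adapter_fwd")
        if self.adapter_rev:
            _check_dna(self.adapter_rev, "adapter_rev")
        offsets = tuple(int(i) for i in self.cpg_offsets)
        object.__setattr__(self, "cpg_offsets", offsets)
        for prev, cur in zip(offsets, offsets[1:]):
            if cur <= prev:
                raise ValidationError(
                    f"cpg_offsets must be strictly increasing, got {prev} then {cur}"
                )
        n = len(self.reference_seq)
        for off in offsets:
            if not (0 <= off < n - 1):
                raise ValidationError(f"cpg_offset {off} out of range for a {n} bp reference")
            if self.reference_seq[off] != "C" or self.reference_seq[off + 1] != "G":
                raise ValidationError(
                    f"cpg_offset {off} does not point at a CpG: found "
                    f"'{self.reference_seq[off:off + 2]}'"
                )
        if len(self.primer_fwd) > n or len(self.primer_rev) > n:
            raise ValidationError("primer longer than reference_seq")
        if self.primer_fwd and not _bisulfite_degenerate_match(
            self.primer_fwd, self.reference_seq[: len(self.primer_fwd)]
        ):
            raise ValidationError(
                "primer_fwd does not match the reference prefix under bisulfite degeneracy"
            )
        rev_rc = reverse_complement(self.primer_rev)
        if rev_rc and not _bisulfite_degenerate_match(
            rev_rc, self.reference_seq[-len(rev_rc):]
        ):
            raise ValidationError(
                "reverse complement of primer_rev does not match the reference "
                "suffix under bisulfite degeneracy"
            )

    @property
    def insert_length(self) -> int:
        """Length of the amplicon insert (primer footprint to primer footprint)."""
        return len(self.reference_seq)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)

    @property
    def primer_fwd_footprint(self) -> tuple[int, int]:
        """0-based half-open interval of the forward primer on the insert."""
        return (0, len(self.primer_fwd))

    @property
    def primer_rev_footprint(self) -> tuple[int, int]:
        """0-based half-open interval of the reverse primer on the insert."""
        return (self.insert_length - len(self.primer_rev), self.insert_length)


@dataclass(frozen=True)
class ConvertedReference:
    """In-silico bisulfite-converted top-strand reference used for alignment.

    ``top_seq`` has every non-CpG cytosine replaced by T (full conversion of
    always-unmethylated positions) and the IUPAC code ``Y`` (C or T) at each
    CpG cytosine, so that alignment treats both methylation states as exact
    matches.
    """

    top_seq: str
    cpg_offsets: tuple[int, ...]
    non_cpg_c_offsets: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.top_seq)


def build_converted_reference(assay: AssayDefinition) -> ConvertedReference:
    """Convert the assay reference for bisulfite-aware alignment.

    Every C not in ``cpg_offsets`` becomes T; CpG cytosines become the
    bivalent code ``Y``. Positions of the non-CpG cytosines are enumerated —
    these are the conversion-rate reporters used downstream.
    """
    cpg = set(assay.cpg_offsets)
    chars = []
    non_cpg_c = []
    for i, base in enumerate(assay.reference_seq):
        if base == "C" and i in cpg:
            chars.append(CPG_AMBIGUITY)
        elif base == "C":
            non_cpg_c.append(i)
            chars.append("T")
        else:
            chars.append(base)
    return ConvertedReference(
        top_seq="".join(chars),
        cpg_offsets=assay.cpg_offsets,
        non_cpg_c_offsets=tuple(non_cpg_c),
    )


_REQUIRED_FIELDS = ("name", "reference_seq", "locus_label", "cpg_offsets", "primer_fwd", "primer_rev")


def load_assay(config_path: str | Path) -> AssayDefinition:
    """Load and validate an assay from a flat YAML key/value file.

    Raises
    ------
    ValidationError
        If a required field is missing, a sequence contains non-ACGT
        characters, or a CpG offset does not point at a CpG.
    """
    path = Path(config_path)
    if not path.exists():
        raise ValidationError(f"assay config not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"assay config {path} is not a key/value mapping")
    missing = [f for f in _REQUIRED_FIELDS if f not in raw]
    if missing:
        raise ValidationError(f"assay config {path} missing fields: {missing}")
    return AssayDefinition(
        name=str(raw["name"]),
        reference_seq=str(raw["reference_seq"]),
        locus_label=str(raw["locus_label"]),
        cpg_offsets=tuple(raw["cpg_offsets"] or ()),
        primer_fwd=str(raw["primer_fwd"]),
        primer_rev=str(raw["primer_rev"]),
        adapter_fwd=str(raw.get("adapter_fwd", "")),
        adapter_rev=str(raw.get("adapter_rev", "")),
    )


def default_assay() -> AssayDefinition:
    """The packaged default assay (synthetic FAM101A six-CpG island stand-in)."""
    ref = resources.files("methylamp.data") / "default_assay.yaml"
    with resources.as_file(ref) as path:
        return load_assay(path)


def export_reference_fasta(assay: AssayDefinition, path: str | Path) -> None:
    """Write the unconverted insert as a single-record FASTA file."""
    record = SeqRecord(
        Seq(assay.reference_seq), id=assay.name, description=assay.locus_label
    )
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "fasta")
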