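"""Amplicon-scale bisulfite-aware alignment and quality filtering.

At amplicon scale (reference < 200 bp) alignment can be exact: mates are
merged into one molecule sequence, then scored ungapped at every possible
offset on the converted reference. Bisulfite chemistry is encoded in the
match rules rather than in a mapping heuristic:

* a read T over a non-CpG reference C is the expected conversion product —
  never a mismatch (a read C there, i.e. incomplete conversion, matches too);
* CpG cytosines are bivalent (``Y``): read C and read T both match freely,
  so alignment is blind to methylation state;
* read ``N`` (an irreconcilable mate disagreement) is neither match nor
  mismatch.

The filters mirror standard amplicon QC: a successfully merged pair
("proper pair"), a unique best ("primary") placement, an insert size inside
the expected window, and a bounded mismatch rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .assay import ConvertedReference
from .errors import ConfigError, DataError

_N = ord("N")

# 4-bit base encoding for match-set arithmetic: A=1, C=2, G=4, T=8
_BASE_BITS = np.zeros(256, dtype=np.uint8)
_BASE_BITS[ord("A")] = 1
_BASE_BITS[ord("C")] = 2
_BASE_BITS[ord("G")] = 4
_BASE_BITS[ord("T")] = 8

_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_x] = _y


@dataclass
class AlignedMolecule:
    """One merged read pair placed on the converted amplicon reference.

    ``n_mismatches`` excludes bisulfite-expected conversions, CpG-bivalent
    positions and ``N`` bases. ``flags['primary']`` is False when no
    placement exists (merged sequence longer than the reference).
    """

    molecule_id: str
    offset: int
    matched_seq: str
    insert_size: int
    n_mismatches: int
    flags: dict

    @property
    def mismatch_rate(self) -> float:
        return self.n_mismatches / len(self.matched_seq) if self.matched_seq else 0.0


@dataclass
class MergedPair:
    seq: str
    merged_ok: bool
    shift: int | None = None  # offset of (revcomp R2) start relative to R1 start


def merge_pair(
    r1: str,
    r2: str,
    min_overlap: int = 20,
    min_identity: float = 0.75,
) -> MergedPair:
    """Merge a read pair into one molecule sequence in template orientation.

    R2 is reverse-complemented, then every relative placement with at least
    ``min_overlap`` overlapping bases is considered, largest overlap first
    (ties: smallest absolute shift, then leftmost). A placement whose
    overlap identity reaches 0.95 is accepted immediately; otherwise the
    best-scoring placement (matches minus disagreements) wins, provided its
    identity is at least ``min_identity`` — else ``merged_ok`` is False.
    Overlap disagreements become ``N``; where one mate reads ``N`` the other
    mate's base is kept.
    """
    if not r1 or not r2:
        raise DataError("merge_pair: empty read")
    a = np.frombuffer(r1.encode(), dtype=np.uint8)
    b = _COMPLEMENT[np.frombuffer(r2.encode(), dtype=np.uint8)[::-1]]
    la, lb = a.size, b.size
    shifts = _candidate_shifts(la, lb, min_overlap)

    def overlap(d: int) -> int:
        return min(la, d + lb) - max(0, d)
    best_d, best_score, best_ident = None, -(10**9), 0.0
    for d in shifts:
        a0, a1 = max(0, d), min(la, d + lb)
        sa = a[a0:a1]
        sb = b[a0 - d : a1 - d]
        informative = (sa != _N) & (sb != _N)
        agree = int(((sa == sb) & informative).sum())
        disagree = int(informative.sum()) - agree
        ident = agree / max(1, agree + disagree)
        score = agree - disagree
        if ident >= 0.95:
            best_d, best_score, best_ident = d, score, ident
            break
        if score > best_score:
            best_d, best_score, best_ident = d, score, ident
    if best_d is None or best_ident < min_identity:
        return MergedPair(seq="", merged_ok=False, shift=best_d)

    d = best_d
    start, end = min(0, d), max(la, d + lb)
    merged = np.full(end - start, _N, dtype=np.uint8)
    merged[-start : -start + la] = a
    bw = merged[d - start : d - start + lb]
    conflict = (bw != _N) & (b != _N) & (bw != b)
    fill = bw == _N
    bw[fill] = b[fill]
    bw[conflict] = _N
    return MergedPair(seq=merged.tobytes().decode(), merged_ok=True, shift=d)


@lru_cache(maxsize=1024)
def _candidate_shifts(la: int, lb: int, min_overlap: int) -> tuple[int, ...]:
    """Relative placements of (revcomp R2) on R1, largest overlap first
    (ties: smallest absolute shift, then leftmost)."""

    def overlap(d: int) -> int:
        return min(la, d + lb) - max(0, d)

    shifts = [d for d in range(-(lb - 1), la) if overlap(d) >= min(min_overlap, la, lb)]
    shifts.sort(key=lambda d: (-overlap(d), abs(d), d))
    return tuple(shifts)


@lru_cache(maxsize=64)
def _allowed_bits(conv_ref: ConvertedReference) -> np.ndarray:
    """Per-reference-position acceptable-base bitmask under bisulfite rules."""
    bits = np.empty(len(conv_ref), dtype=np.uint8)
    for i, ch in enumerate(conv_ref.top_seq):
        if ch == "Y":  # CpG cytosine: methylation-unbiased C/T
            bits[i] = _BASE_BITS[ord("C")] | _BASE_BITS[ord("T")]
        else:
            bits[i] = _BASE_BITS[ord(ch)]
    # non-CpG C positions are already T in top_seq; an unconverted read C is
    # not a mismatch either
    for i in conv_ref.non_cpg_c_offsets:
        bits[i] |= _BASE_BITS[ord("C")]
    return bits


def align_molecule(
    merged: str,
    conv_ref: ConvertedReference,
    molecule_id: str = "",
    merged_ok: bool = True,
) -> AlignedMolecule:
    """Place a merged molecule on the converted reference by exhaustive
    ungapped scan over all offsets, minimising bisulfite-aware mismatches
    (ties broken by the smallest offset)."""
    if not merged:
        return AlignedMolecule(
            molecule_id, 0, "", 0, 0,
            {"proper_pair": False, "primary": False, "merged_ok": merged_ok},
        )
    read = np.frombuffer(merged.encode(), dtype=np.uint8)
    ref_len = len(conv_ref)
    if read.size > ref_len:
        return AlignedMolecule(
            molecule_id, 0, merged, len(merged), 0,
            {"proper_pair": merged_ok, "primary": False, "merged_ok": merged_ok},
        )
    allowed = _allowed_bits(conv_ref)
    read_bits = _BASE_BITS[read]
    not_n = read != _N
    best_off, best_mm = 0, read.size + 1
    for off in range(ref_len - read.size + 1):
        window = allowed[off : off + read.size]
        mm = int((((read_bits & window) == 0) & not_n).sum())
        if mm < best_mm:
            best_off, best_mm = off, mm
            if mm == 0:
                break
    return AlignedMolecule(
        molecule_id=molecule_id,
        offset=best_off,
        matched_seq=merged,
        insert_size=len(merged),
        n_mismatches=best_mm,
        flags={"proper_pair": merged_ok, "primary": True, "merged_ok": merged_ok},
    )


def align_pair(
    r1: str,
    r2: str,
    conv_ref: ConvertedReference,
    molecule_id: str = "",
    min_overlap: int = 20,
    min_identity: float = 0.75,
) -> AlignedMolecule:
    """Convenience: merge a pair then align the merged molecule."""
    merged = merge_pair(r1, r2, min_overlap=min_overlap, min_identity=min_identity)
    if not merged.merged_ok:
        return AlignedMolecule(
            molecule_id, 0, "", 0, 0,
            {"proper_pair": False, "primary": False, "merged_ok": False},
        )
    return align_molecule(merged.seq, conv_ref, molecule_id=molecule_id, merged_ok=True)


FILTER_REASONS = ("merge_failed", "unaligned", "insert_size", "mismatch_rate")


def filter_alignments(
    mols: list[AlignedMolecule],
    insert_window: tuple[int, int],
    max_mismatch_rate: float = 0.1,
) -> tuple[list[AlignedMolecule], dict[str, int]]:
    """Apply the amplicon QC filters: merged proper pair, primary placement,
    insert size within ``insert_window`` (inclusive), mismatch rate at most
    ``max_mismatch_rate`` of the aligned length.

    Returns the passing molecules and a tally that partitions the input:
    each molecule is counted once, under its first failing reason or under
    ``kept``.
    """
    lo, hi = insert_window
    if lo > hi:
        raise ConfigError(f"insert_window min {lo} > max {hi}")
    tally = {reason: 0 for reason in FILTER_REASONS}
    tally["kept"] = 0
    kept = []
    for mol in mols:
        if not mol.flags.get("merged_ok", False):
            tally["merge_failed"] += 1
            continue
        if not mol.flags.get("primary", False):
            tally["unaligned"] += 1
            continue
        if not (lo <= mol.insert_size <= hi):
            tally["insert_size"] += 1
            continue
        if mol.mismatch_rate > max_mismatch_rate:
            tally["mismatch_rate"] += 1
            continue
        mol.flags["insert_ok"] = True
        tally["kept"] += 1
        kept.append(mol)
    tally["total"] = len(mols)
    return kept, tally


def default_insert_window(insert_length: int, slack: int = 5) -> tuple[int, int]:
    """Expected amplicon insert length plus/minus ``slack`` bp."""
    return (insert_length - slack, insert_length + slack)
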