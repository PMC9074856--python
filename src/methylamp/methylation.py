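"""Per-molecule CpG methylation-haplotype calling.

Each filtered molecule yields one haplotype call: the ordered state of the
marker CpGs (C on the converted strand = methylated, T = unmethylated,
anything else or uncovered = ambiguous), a tally of converted vs
unconverted non-CpG cytosines (the built-in bisulfite conversion-rate
reporters), and the all-or-nothing label the assay counts: a molecule is a
tissue-specific signal only if every CpG is unmethylated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignedMolecule
from .assay import ConvertedReference
from .errors import DataError

METH = "M"
UNMETH = "U"
AMBIG = "A"

FULLY_UNMETHYLATED = "FULLY_UNMETHYLATED"
OTHER = "OTHER"
UNEVALUABLE = "UNEVALUABLE"


@dataclass(frozen=True)
class HaplotypeCall:
    """One molecule's marker-CpG methylation states and QC tallies."""

    molecule_id: str
    cpg_states: tuple[str, ...]
    n_noncpg_c_total: int
    n_noncpg_c_converted: int
    label: str


def classify_states(cpg_states: Sequence[str]) -> str:
    """All-or-nothing labelling rule.

    FULLY_UNMETHYLATED iff every CpG reads unmethylated; UNEVALUABLE iff any
    CpG is ambiguous; OTHER otherwise.
    """
    if any(s == AMBIG for s in cpg_states):
        return UNEVALUABLE
    if all(s == UNMETH for s in cpg_states):
        return FULLY_UNMETHYLATED
    return OTHER


def call_haplotype(mol: AlignedMolecule, conv_ref: ConvertedReference) -> HaplotypeCall:
    """Extract the CpG haplotype and conversion tallies from one aligned
    molecule. Uncovered positions and non-C/T bases give AMBIG states."""
    seq = mol.matched_seq
    start, end = mol.offset, mol.offset + len(seq)
    states = []
    for off in conv_ref.cpg_offsets:
        if not (start <= off < end):
            states.append(AMBIG)
            continue
        base = seq[off - start]
        if base == "C":
            states.append(METH)
        elif base == "T":
            states.append(UNMETH)
        else:
            states.append(AMBIG)
    total = converted = 0
    for off in conv_ref.non_cpg_c_offsets:
        if not (start <= off < end):
            continue
        base = seq[off - start]
        if base == "T":
            total += 1
            converted += 1
        elif base == "C":
            total += 1
    return HaplotypeCall(
        molecule_id=mol.molecule_id,
        cpg_states=tuple(states),
        n_noncpg_c_total=total,
        n_noncpg_c_converted=converted,
        label=classify_states(states),
    )


@dataclass(frozen=True)
class ConversionEstimate:
    """Pooled bisulfite conversion rate with an exact binomial CI."""

    rate: float
    ci_low: float
    ci_high: float
    n_converted: int
    n_total: int


def _clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval."""
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def estimate_conversion_rate(
    calls: Iterable[HaplotypeCall], conf: float = 0.95
) -> ConversionEstimate:
    """Pool non-CpG cytosines over all calls: rate = converted / total.

    Raises ``DataError`` when no informative non-CpG cytosine was observed.
    """
    total = converted = 0
    for call in calls:
        total += call.n_noncpg_c_total
        converted += call.n_noncpg_c_converted
    if total == 0:
        raise DataError("no informative non-CpG cytosines: cannot estimate conversion rate")
    lo, hi = _clopper_pearson(converted, total, conf)
    return ConversionEstimate(
        rate=converted / total, ci_low=lo, ci_high=hi, n_converted=converted, n_total=total
    )


def tabulate_per_cpg(calls: Sequence[HaplotypeCall]) -> pd.DataFrame:
    """Per-CpG methylation frequency table: METH / (METH + UNMETH) at each
    site, ambiguous states excluded, counts reported alongside."""
    if not calls:
        raise DataError("no calls to tabulate")
    k = len(calls[0].cpg_states)
    rows = []
    for i in range(k):
        n_meth = sum(1 for c in calls if c.cpg_states[i] == METH)
        n_unmeth = sum(1 for c in calls if c.cpg_states[i] == UNMETH)
        n_ambig = len(calls) - n_meth - n_unmeth
        denom = n_meth + n_unmeth
        rows.append(
            {
                "cpg_index": i,
                "n_meth": n_meth,
                "n_unmeth": n_unmeth,
                "n_ambig": n_ambig,
                "meth_frequency": n_meth / denom if denom else np.nan,
            }
        )
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[HaplotypeCall]) -> pd.DataFrame:
    """Flatten calls for TSV export (one state character per CpG)."""
    return pd.DataFrame(
        {
            "molecule_id": [c.molecule_id for c in calls],
            "cpg_states": ["".join(c.cpg_states) for c in calls],
            "label": [c.label for c in calls],
            "n_noncpg_c_converted": [c.n_noncpg_c_converted for c in calls],
            "n_noncpg_c_total": [c.n_noncpg_c_total for c in calls],
        }
    )
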