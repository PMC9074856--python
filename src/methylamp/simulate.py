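"""Synthetic read generator for targeted bisulfite amplicon sequencing.

Emulates the data-generating process of a serum cfDNA methylation assay:
tissue-specific methylation haplotypes at the marker CpGs, cfDNA
fragmentation, bisulfite chemistry (incomplete and inappropriate
conversion), amplicon PCR (only fragments spanning both primer footprints
amplify), paired-end sequencing with substitution errors, spike-in
mixtures, and a longitudinal patient cohort. Every generator takes an
explicit seed and is byte-deterministic; each simulated sample is
accompanied by a truth table.

Default study conditions
------------------------
* fragment size: mode 150 bp, hard maximum 200 bp (serum cfDNA);
* sequencing: paired-end 2x150 bp, depth 35,000-74,000 pairs per cohort
  sample;
* chemistry: bisulfite conversion efficiency 0.99 per unmethylated C,
  inappropriate conversion 0.005 per methylated C, substitution error
  0.001 per sequenced base;
* packaged tissue profiles (fraction of molecules carrying the fully
  unmethylated marker haplotype): cardiomyocyte 0.78, heart ventricle 0.20,
  non-cardiac tissues and buffy coat 0.001, universally methylated control 0.

Each emitted read pair corresponds to one distinct simulated molecule, so
read-pair counts carry exact binomial statistics; PCR duplicate variance is
not modelled (the assay has no UMIs, and the analysis counts read pairs).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import AssayDefinition, build_converted_reference, default_assay
from .errors import DataError, ValidationError

UNMETH = "U"
METH = "M"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_x] = _y

_T = ord("T")


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueProfile:
    """Per-tissue distribution over marker methylation haplotypes.

    ``haplotype_freqs`` maps haplotype strings (one character per CpG,
    ``U`` = unmethylated / ``M`` = methylated) to their frequency in the
    tissue's genomic DNA.
    """

    tissue_name: str
    haplotype_freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        freqs = dict(self.haplotype_freqs)
        if not freqs:
            raise ValidationError(f"{self.tissue_name}: empty haplotype_freqs")
        lengths = {len(h) for h in freqs}
        if len(lengths) != 1:
            raise ValidationError(f"{self.tissue_name}: haplotypes of unequal length")
        for hap, f in freqs.items():
            if set(hap) - {UNMETH, METH}:
                raise ValidationError(f"{self.tissue_name}: bad haplotype string {hap!r}")
            if f < 0:
                raise ValidationError(f"{self.tissue_name}: negative frequency for {hap!r}")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.tissue_name}: haplotype frequencies sum to {total}, not 1"
            )
        object.__setattr__(self, "haplotype_freqs", freqs)

    @classmethod
    def from_u(cls, tissue_name: str, u: float, n_cpgs: int = 6) -> "TissueProfile":
        """Two-haplotype shorthand: fraction ``u`` fully unmethylated, the
        remainder fully methylated."""
        if not 0.0 <= u <= 1.0:
            raise ValidationError(f"{tissue_name}: u={u} outside [0, 1]")
        freqs: dict[str, float] = {}
        if u > 0:
            freqs[UNMETH * n_cpgs] = u
        if u < 1:
            freqs[METH * n_cpgs] = 1.0 - u
        return cls(tissue_name, freqs)

    @property
    def n_cpgs(self) -> int:
        return len(next(iter(self.haplotype_freqs)))

    @property
    def fully_unmethylated_fraction(self) -> float:
        return self.haplotype_freqs.get(UNMETH * self.n_cpgs, 0.0)


#: Packaged tissue profiles (fully-unmethylated marker haplotype fractions).
TISSUE_PROFILES: dict[str, TissueProfile] = {
    "cardiomyocyte": TissueProfile.from_u("cardiomyocyte", 0.78),
    "ventricle": TissueProfile.from_u("ventricle", 0.20),
    "skeletal_muscle": TissueProfile.from_u("skeletal_muscle", 0.001),
    "lung": TissueProfile.from_u("lung", 0.001),
    "spleen": TissueProfile.from_u("spleen", 0.001),
    "buffy_coat": TissueProfile.from_u("buffy_coat", 0.001),
    "methylated_control": TissueProfile.from_u("methylated_control", 0.0),
}


@dataclass(frozen=True)
class ChemistryModel:
    """Bisulfite chemistry and sequencing noise.

    ``conversion_efficiency``: probability an unmethylated C reads as T.
    ``inappropriate_conversion``: probability a methylated (protected) C
    nevertheless reads as T. ``seq_error_rate``: per-base substitution
    probability applied independently to each sequenced base.
    """

    conversion_efficiency: float = 0.99
    inappropriate_conversion: float = 0.005
    seq_error_rate: float = 0.001

    def __post_init__(self) -> None:
        for name in ("conversion_efficiency", "inappropriate_conversion", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class FragmentModel:
    """cfDNA fragment-length model: discretised log-normal with its mode at
    ``mode_length``, truncated at ``max_length``; ``dispersion`` is the
    log-scale sigma."""

    mode_length: int = 150
    max_length: int = 200
    dispersion: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.mode_length <= self.max_length:
            raise ValidationError(
                f"need 0 < mode_length <= max_length, got {self.mode_length}/{self.max_length}"
            )
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")

    @property
    def log_mu(self) -> float:
        # log-normal mode = exp(mu - sigma^2)
        return math.log(self.mode_length) + self.dispersion**2


@dataclass(frozen=True)
class MixtureSpec:
    """A sequencing sample as a weighted mixture of tissue profiles."""

    components: tuple[tuple[TissueProfile, float], ...]
    n_read_pairs: int
    seed: int

    def __post_init__(self) -> None:
        comps = tuple((p, float(w)) for p, w in self.components)
        object.__setattr__(self, "components", comps)
        if self.n_read_pairs <= 0:
            raise ValidationError("n_read_pairs must be positive")
        if any(w < 0 for _, w in comps):
            raise ValidationError("mixture weights must be non-negative")
        total = sum(w for _, w in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"mixture weights sum to {total}, not 1")


#: Per-patient true cardiomyocyte shedding fractions (pre, post, recovery)
#: for the default longitudinal cohort. Chosen to emulate the study cohort:
#: per-timepoint medians 0.018-0.020, three patients starting below the
#: detection limit, and two high outliers (one pre-existing cardiac damage,
#: one late rise).
DEFAULT_COHORT_FRACTIONS: dict[str, tuple[float, float, float]] = {
    "P01": (0.020, 0.024, 0.018),
    "P02": (0.035, 0.030, 0.028),
    "P03": (0.0005, 0.008, 0.004),
    "P04": (0.015, 0.018, 0.012),
    "P05": (0.028, 0.022, 0.025),
    "P06": (0.090, 0.040, 0.030),
    "P07": (0.0008, 0.012, 0.006),
    "P08": (0.0010, 0.009, 0.007),
    "P09": (0.025, 0.030, 0.085),
    "P10": (0.018, 0.016, 0.020),
}

DEFAULT_TIMEPOINTS = ("pre", "post", "recovery")


@dataclass(frozen=True)
class CohortSpec:
    """A longitudinal patient cohort: one sample per patient x timepoint."""

    n_patients: int = 10
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    fractions: Mapping[str, tuple[float, ...]] | None = None
    depth_range: tuple[int, int] = (35_000, 74_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValidationError(f"invalid depth_range {self.depth_range}")
        if self.fractions is None:
            if self.n_patients > len(DEFAULT_COHORT_FRACTIONS):
                raise ValidationError(
                    "no default shedding fractions beyond "
                    f"{len(DEFAULT_COHORT_FRACTIONS)} patients; supply `fractions`"
                )
            patients = sorted(DEFAULT_COHORT_FRACTIONS)[: self.n_patients]
            fr = {p: DEFAULT_COHORT_FRACTIONS[p][: len(self.timepoints)] for p in patients}
            object.__setattr__(self, "fractions", fr)
        fr = dict(self.fractions)
        if len(fr) != self.n_patients:
            raise ValidationError(
                f"fractions given for {len(fr)} patients, expected {self.n_patients}"
            )
        for pid, vals in fr.items():
            if len(vals) != len(self.timepoints):
                raise ValidationError(f"{pid}: expected {len(self.timepoints)} fractions")
            for v in vals:
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"{pid}: shedding fraction {v} outside [0, 1]")
        object.__setattr__(self, "fractions", fr)


# ---------------------------------------------------------------------------
# elementary draws
# ---------------------------------------------------------------------------

def draw_haplotype(profile: TissueProfile, rng: np.random.Generator) -> str:
    """Draw one molecule's methylation haplotype from a tissue profile."""
    haps = list(profile.haplotype_freqs)
    probs = np.array([profile.haplotype_freqs[h] for h in haps])
    idx = rng.choice(len(haps), p=probs / probs.sum())
    return haps[int(idx)]


@dataclass(frozen=True)
class Fragment:
    """One cfDNA fragment on the extended template around the amplicon.

    Coordinates are 0-based half-open on a template of length
    ``insert + 2 * max_length``, with the amplicon insert occupying
    ``[max_length, max_length + insert)``. ``amplifiable`` is true iff the
    fragment spans both primer footprints, i.e. covers the whole insert.
    """

    start: int
    end: int
    amplifiable: bool


def _draw_fragment_lengths(frag: FragmentModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample ``n`` discretised log-normal lengths in [1, max_length]."""
    out = np.empty(n, dtype=np.int64)
    got = 0
    while got < n:
        m = max(256, 2 * (n - got))
        x = np.rint(rng.lognormal(frag.log_mu, frag.dispersion, size=m)).astype(np.int64)
        x = x[(x >= 1) & (x <= frag.max_length)]
        take = min(x.size, n - got)
        out[got : got + take] = x[:take]
        got += take
    return out


def simulate_fragment(
    assay: AssayDefinition, frag: FragmentModel, rng: np.random.Generator
) -> Fragment:
    """Draw one cfDNA fragment and record whether it can amplify."""
    length = int(_draw_fragment_lengths(frag, 1, rng)[0])
    ext = assay.insert_length + 2 * frag.max_length
    start = int(rng.integers(0, ext - length + 1))
    s0 = frag.max_length
    e0 = s0 + assay.insert_length
    return Fragment(start, start + length, start <= s0 and start + length >= e0)


def bisulfite_convert_molecule(
    seq: str,
    methyl_states: Mapping[int, bool],
    chem: ChemistryModel,
    rng: np.random.Generator,
) -> str:
    """Apply bisulfite chemistry to one molecule.

    ``methyl_states`` maps every C position of ``seq`` to True (methylated,
    protected) or False (unmethylated). Unmethylated Cs convert to T with
    probability ``conversion_efficiency``; methylated Cs with probability
    ``inappropriate_conversion``. Non-C bases are untouched.
    """
    out = list(seq)
    for i, base in enumerate(seq):
        if base != "C":
            continue
        if i not in methyl_states:
            raise DataError(f"methyl_states missing C position {i}")
        p = chem.inappropriate_conversion if methyl_states[i] else chem.conversion_efficiency
        if rng.random() < p:
            out[i] = "T"
    return "".join(out)


# ---------------------------------------------------------------------------
# sample-level simulation
# ---------------------------------------------------------------------------

def _apply_seq_errors(reads: np.ndarray, eps: float, rng: np.random.Generator) -> None:
    """Substitute each base independently with probability ``eps`` (in place)."""
    if eps <= 0:
        return
    mask = rng.random(reads.shape) < eps
    n_err = int(mask.sum())
    if n_err == 0:
        return
    idx = _BASE_INDEX[reads[mask]]
    shift = rng.integers(1, 4, size=n_err)
    reads[mask] = _BASES[(idx + shift) % 4]


@dataclass
class SimulatedSample:
    """In-memory result of ``simulate_reads``: paired reads plus truth."""

    ids: list[str]
    r1: list[str]
    r2: list[str]
    truth: pd.DataFrame

    def pairs(self) -> Iterator[tuple[str, str, str]]:
        """Yield (molecule_id, r1_seq, r2_seq) triples."""
        return zip(self.ids, self.r1, self.r2)

    def write_fastq(self, out_r1: str | Path, out_r2: str | Path) -> None:
        _write_fastq(self.ids, self.r1, out_r1, mate=1)
        _write_fastq(self.ids, self.r2, out_r2, mate=2)


def _write_fastq(ids: Sequence[str], seqs: Sequence[str], path: str | Path, mate: int) -> None:
    # constant Q37 qualities; the downstream filters do not use them
    buf = "".join(
        f"@{mol_id}/{mate}\n{seq}\n+\n{'F' * len(seq)}\n"
        for mol_id, seq in zip(ids, seqs)
    ).encode()
    path = Path(path)
    try:
        if path.suffix == ".gz":
            # mtime pinned and FNAME suppressed so identical seeds give
            # byte-identical files regardless of file name or clock
            with open(path, "wb") as raw, gzip.GzipFile(
                filename="", fileobj=raw, mode="wb", compresslevel=1, mtime=0
            ) as gz:
                gz.write(buf)
        else:
            path.write_bytes(buf)
    except OSError as exc:
        raise DataError(f"cannot write FASTQ to {path}: {exc}") from exc


def simulate_reads(
    mix: MixtureSpec,
    assay: AssayDefinition | None = None,
    chem: ChemistryModel | None = None,
    frag: FragmentModel | None = None,
    read_length: int = 150,
    out_r1: str | Path | None = None,
    out_r2: str | Path | None = None,
) -> SimulatedSample:
    """Simulate one amplicon sequencing sample from a tissue mixture.

    Each read pair is a distinct molecule: a tissue component is drawn with
    the mixture weights, a methylation haplotype from that tissue's profile,
    a cfDNA fragment conditioned on spanning both primer footprints (PCR
    selects these), the insert is bisulfite-converted, and R1/R2 are read
    off the converted top strand (R1 5'->3', R2 the reverse complement from
    the other end) with independent substitution errors. Identical seeds
    give byte-identical FASTQ output.
    """
    assay = assay or default_assay()
    chem = chem or ChemistryModel()
    frag = frag or FragmentModel()
    if frag.max_length < assay.insert_length:
        raise DataError(
            f"max fragment length {frag.max_length} < amplicon insert "
            f"{assay.insert_length}: nothing can amplify"
        )
    conv_ref = build_converted_reference(assay)
    n = mix.n_read_pairs
    k = assay.n_cpgs
    for profile, _ in mix.components:
        if profile.n_cpgs != k:
            raise ValidationError(
                f"profile {profile.tissue_name} has {profile.n_cpgs} CpGs, assay has {k}"
            )
    rng = np.random.default_rng(mix.seed)

    # 1) tissue component per molecule
    weights = np.array([w for _, w in mix.components])
    comp_idx = rng.choice(len(mix.components), size=n, p=weights / weights.sum())

    # 2) haplotype per molecule (drawn per component, scattered back)
    hap_meth = np.zeros((n, k), dtype=bool)
    hap_strings = np.empty(n, dtype=object)
    for ci, (profile, _) in enumerate(mix.components):
        rows = np.flatnonzero(comp_idx == ci)
        if rows.size == 0:
            continue
        haps = list(profile.haplotype_freqs)
        probs = np.array([profile.haplotype_freqs[h] for h in haps])
        choice = rng.choice(len(haps), size=rows.size, p=probs / probs.sum())
        hap_arr = np.array([[c == METH for c in h] for h in haps], dtype=bool).reshape(
            len(haps), k
        )
        hap_meth[rows] = hap_arr[choice]
        hap_strings[rows] = np.array(haps, dtype=object)[choice]

    # 3) bisulfite conversion of the insert
    ref_arr = np.frombuffer(assay.reference_seq.encode(), dtype=np.uint8)
    mol = np.tile(ref_arr, (n, 1))
    if k > 0:
        cols = np.array(assay.cpg_offsets)
        thresh = np.where(hap_meth, chem.inappropriate_conversion, chem.conversion_efficiency)
        conv = rng.random((n, k)) < thresh
        sub = mol[:, cols]
        sub[conv] = _T
        mol[:, cols] = sub
    nc = np.array(conv_ref.non_cpg_c_offsets, dtype=int)
    if nc.size:
        conv = rng.random((n, nc.size)) < chem.conversion_efficiency
        sub = mol[:, nc]
        sub[conv] = _T
        mol[:, nc] = sub

    # 4) fragments, conditioned on amplifiability (rejection sampling)
    s0 = frag.max_length
    e0 = s0 + assay.insert_length
    ext = assay.insert_length + 2 * frag.max_length
    frag_start = np.empty(n, dtype=np.int64)
    frag_len = np.empty(n, dtype=np.int64)
    got = 0
    while got < n:
        m = max(1024, 2 * (n - got))
        lengths = _draw_fragment_lengths(frag, m, rng)
        starts = rng.integers(0, ext - lengths + 1)
        ok = (starts <= s0) & (starts + lengths >= e0)
        take = min(int(ok.sum()), n - got)
        frag_start[got : got + take] = starts[ok][:take]
        frag_len[got : got + take] = lengths[ok][:take]
        got += take

    # 5) paired reads off the converted template, with sequencing errors
    read_len = min(read_length, assay.insert_length)
    r1 = mol[:, :read_len].copy()
    _apply_seq_errors(r1, chem.seq_error_rate, rng)
    rc = _COMPLEMENT[mol[:, ::-1]]
    r2 = rc[:, :read_len].copy()
    _apply_seq_errors(r2, chem.seq_error_rate, rng)

    ids = [f"mol{i:07d}" for i in range(n)]
    r1_list = [row.tobytes().decode() for row in r1]
    r2_list = [row.tobytes().decode() for row in r2]
    tissues = np.array([p.tissue_name for p, _ in mix.components], dtype=object)[comp_idx]
    full_u = UNMETH * k
    truth = pd.DataFrame(
        {
            "molecule_id": ids,
            "tissue": tissues,
            "haplotype": hap_strings,
            "fully_unmethylated": [h == full_u for h in hap_strings],
            "frag_start": frag_start,
            "frag_end": frag_start + frag_len,
            # one read pair per molecule, so molecule- and read-level counts
            # coincide; kept explicit so either counting convention is testable
            "read_pairs": np.ones(n, dtype=int),
        }
    )
    sample = SimulatedSample(ids=ids, r1=r1_list, r2=r2_list, truth=truth)
    if out_r1 is not None or out_r2 is not None:
        if out_r1 is None or out_r2 is None:
            raise ValidationError("out_r1 and out_r2 must be given together")
        sample.write_fastq(out_r1, out_r2)
    return sample


def generate_cohort(
    spec: CohortSpec,
    assay: AssayDefinition | None = None,
    chem: ChemistryModel | None = None,
    frag: FragmentModel | None = None,
    out_dir: str | Path | None = None,
    read_length: int = 150,
    signal_profile: TissueProfile | None = None,
    background_profile: TissueProfile | None = None,
) -> pd.DataFrame:
    """Generate the longitudinal cohort: one sample per patient x timepoint.

    Each sample is a two-component mixture of the signal tissue (default:
    packaged cardiomyocyte profile) at the patient/timepoint's true shedding
    fraction into background (default: buffy coat), at a depth drawn
    uniformly from ``depth_range``. Returns the truth manifest; when
    ``out_dir`` is given, writes gzip FASTQ pairs and ``manifest.tsv``.
    """
    assay = assay or default_assay()
    chem = chem or ChemistryModel()
    frag = frag or FragmentModel()
    signal = signal_profile or TISSUE_PROFILES["cardiomyocyte"]
    background = background_profile or TISSUE_PROFILES["buffy_coat"]
    ss = np.random.SeedSequence(spec.seed)
    depth_rng = np.random.default_rng(ss.spawn(1)[0])
    patients = sorted(spec.fractions)
    children = ss.spawn(len(patients) * len(spec.timepoints))
    rows = []
    child_iter = iter(children)
    for pid in patients:
        for ti, tp in enumerate(spec.timepoints):
            c = float(spec.fractions[pid][ti])
            depth = int(depth_rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
            child_seed = int(next(child_iter).generate_state(1)[0] % (2**31))
            components = []
            if c > 0:
                components.append((signal, c))
            if c < 1:
                components.append((background, 1.0 - c))
            mix = MixtureSpec(tuple(components), n_read_pairs=depth, seed=child_seed)
            sample_id = f"{pid}-{tp}"
            out_r1 = out_r2 = None
            if out_dir is not None:
                out_dir_p = Path(out_dir)
                out_dir_p.mkdir(parents=True, exist_ok=True)
                out_r1 = out_dir_p / f"{sample_id}_R1.fastq.gz"
                out_r2 = out_dir_p / f"{sample_id}_R2.fastq.gz"
            simulate_reads(
                mix, assay, chem, frag, read_length=read_length, out_r1=out_r1, out_r2=out_r2
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "patient": pid,
                    "timepoint": tp,
                    "true_fraction": c,
                    "n_read_pairs": depth,
                    "seed": child_seed,
                    "r1": str(out_r1) if out_r1 else "",
                    "r2": str(out_r2) if out_r2 else "",
                }
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.tsv", sep="\t", index=False)
    return manifest
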