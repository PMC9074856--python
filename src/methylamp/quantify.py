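"""Sample- and cohort-level quantification of the marker signal.

The assay readout is the fully-unmethylated fraction f = k/N: the number of
molecules whose marker CpGs are all unmethylated over the evaluable
molecules (unevaluable calls are excluded from both numerator and
denominator; the molecule-count ratio k/(N-k) is reported as a secondary
column because both conventions appear in practice). Confidence bounds are
exact (Clopper-Pearson) binomial intervals. The limit of detection is the
one-sided exact binomial upper bound of the pooled negative controls, so a
sample is "detected" only when its fraction strictly exceeds what pure
background could plausibly produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .methylation import FULLY_UNMETHYLATED, OTHER, UNEVALUABLE, HaplotypeCall, _clopper_pearson

#: Mass of one haploid human genome in picograms.
HAPLOID_GENOME_PG = 3.3


@dataclass
class SampleQuant:
    """Per-sample marker quantification."""

    sample_id: str
    n_evaluable: int
    k_fully_unmeth: int
    n_unevaluable: int = 0
    genome_equivalents: float | None = None
    above_lod: bool | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k_fully_unmeth <= self.n_evaluable:
            raise DataError(
                f"{self.sample_id}: k={self.k_fully_unmeth} outside [0, {self.n_evaluable}]"
            )

    @property
    def fraction(self) -> float:
        """f = k / N over evaluable molecules."""
        return self.k_fully_unmeth / self.n_evaluable

    @property
    def ratio(self) -> float:
        """Secondary convention: unmethylated / methylated molecules, k/(N-k)."""
        rest = self.n_evaluable - self.k_fully_unmeth
        return self.k_fully_unmeth / rest if rest else np.inf

    @property
    def ci95(self) -> tuple[float, float]:
        """Exact binomial 95% interval on f."""
        return _clopper_pearson(self.k_fully_unmeth, self.n_evaluable, 0.95)


def quantify_sample(
    calls: Iterable[HaplotypeCall],
    sample_id: str = "sample",
    cfdna_mass_pg: float | None = None,
    genome_mass_pg: float = HAPLOID_GENOME_PG,
) -> SampleQuant:
    """Count evaluable and fully-unmethylated molecules into a SampleQuant.

    When the total cfDNA mass is supplied, the marker signal is also
    expressed in genome equivalents: f x cfdna_mass_pg / genome_mass_pg.

    Raises ``DataError`` when no molecule is evaluable.
    """
    k = n = n_unev = 0
    for call in calls:
        if call.label == FULLY_UNMETHYLATED:
            k += 1
            n += 1
        elif call.label == OTHER:
            n += 1
        else:
            n_unev += 1
    if n == 0:
        raise DataError(f"{sample_id}: no evaluable molecules — sample is unquantifiable")
    quant = SampleQuant(sample_id=sample_id, n_evaluable=n, k_fully_unmeth=k, n_unevaluable=n_unev)
    if cfdna_mass_pg is not None:
        quant.genome_equivalents = quant.fraction * cfdna_mass_pg / genome_mass_pg
    return quant


@dataclass(frozen=True)
class DetectionModel:
    """Negative-control-derived limit of detection on the fraction scale."""

    lod_fraction: float
    method_label: str
    negative_control_ids: tuple[str, ...]

    def is_above_lod(self, quant: SampleQuant) -> bool:
        """Strict exceedance: f == LoD is NOT detected."""
        return quant.fraction > self.lod_fraction


def estimate_lod(neg_quants: Sequence[SampleQuant], alpha: float = 0.05) -> DetectionModel:
    """Pool the negative controls and take the one-sided exact binomial
    upper (1 - alpha) bound on their fraction.

    With zero background counts this is the closed form 1 - alpha**(1/N).
    """
    if not neg_quants:
        raise DataError("estimate_lod: no negative control samples")
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha={alpha} outside (0, 1)")
    k = sum(q.k_fully_unmeth for q in neg_quants)
    n = sum(q.n_evaluable for q in neg_quants)
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha, k + 1, n - k))
    return DetectionModel(
        lod_fraction=upper,
        method_label=f"pooled exact binomial upper {1 - alpha:.0%} bound",
        negative_control_ids=tuple(q.sample_id for q in neg_quants),
    )


def spike_in_curve(
    series: Sequence[tuple[float, SampleQuant]],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float | None, DetectionModel]:
    """Calibration over a dilution series of (spike fraction pi, quant).

    The pi = 0 replicates define the LoD; the lowest detectable level is
    the smallest nonzero pi at which *every* replicate lies above it (None
    when no level qualifies). Returns (table, lowest detectable pi, LoD).
    """
    zero = [q for pi, q in series if pi == 0]
    if not zero:
        raise ConfigError("spike_in_curve: the series must contain a pi=0 negative level")
    lod = estimate_lod(zero, alpha=alpha)
    rows = []
    lowest: float | None = None
    for pi in sorted({pi for pi, _ in series}):
        reps = [q for p, q in series if p == pi]
        fs = np.array([q.fraction for q in reps], dtype=float)
        all_above = bool(all(lod.is_above_lod(q) for q in reps))
        if len(reps) == 1:
            warnings.warn(f"spike level {pi}: single replicate, SD undefined", stacklevel=2)
        rows.append(
            {
                "spike_fraction": pi,
                "n_replicates": len(reps),
                "mean_fraction": float(fs.mean()),
                "sd_fraction": float(fs.std(ddof=1)) if len(reps) > 1 else np.nan,
                "all_above_lod": all_above,
            }
        )
        if pi > 0 and all_above and (lowest is None or pi < lowest):
            lowest = pi
    return pd.DataFrame(rows), lowest, lod


@dataclass
class CohortSummary:
    """Longitudinal cohort summary."""

    samples: pd.DataFrame
    timepoint_medians: dict[str, float]
    pre_post_wilcoxon_p: float | None


def summarize_cohort(
    quants: Mapping[tuple[str, str], SampleQuant],
    timepoints: Sequence[str] = ("pre", "post", "recovery"),
    detection: DetectionModel | None = None,
) -> CohortSummary:
    """Per-timepoint medians and per-patient trajectories.

    ``quants`` is keyed by (patient, timepoint). Patients missing a
    timepoint are kept with a gap (NaN) and a warning. The pre-vs-post
    comparison is a paired two-sided Wilcoxon signed-rank test, reported
    descriptively only.
    """
    patients = sorted({p for p, _ in quants})
    rows = []
    for patient in patients:
        for tp in timepoints:
            q = quants.get((patient, tp))
            if q is None:
                warnings.warn(f"patient {patient} missing timepoint {tp}", stacklevel=2)
                rows.append(
                    {"patient": patient, "timepoint": tp, "fraction": np.nan,
                     "ratio": np.nan, "n_evaluable": 0, "k_fully_unmeth": 0,
                     "ci_low": np.nan, "ci_high": np.nan, "above_lod": None}
                )
                continue
            lo, hi = q.ci95
            rows.append(
                {
                    "patient": patient,
                    "timepoint": tp,
                    "fraction": q.fraction,
                    "ratio": q.ratio,
                    "n_evaluable": q.n_evaluable,
                    "k_fully_unmeth": q.k_fully_unmeth,
                    "ci_low": lo,
                    "ci_high": hi,
                    "above_lod": detection.is_above_lod(q) if detection else q.above_lod,
                }
            )
    df = pd.DataFrame(rows)
    medians = {
        tp: float(np.nanmedian(df.loc[df.timepoint == tp, "fraction"]))
        if (df.timepoint == tp).any() else np.nan
        for tp in timepoints
    }
    p_value: float | None = None
    if len(timepoints) >= 2:
        pre, post = timepoints[0], timepoints[1]
        wide = df.pivot(index="patient", columns="timepoint", values="fraction")
        if pre in wide and post in wide:
            paired = wide[[pre, post]].dropna()
            diffs = paired[pre] - paired[post]
            if len(paired) >= 2 and not np.allclose(diffs, 0):
                p_value = float(stats.wilcoxon(paired[pre], paired[post]).pvalue)
            elif len(paired) >= 2:
                p_value = 1.0
    return CohortSummary(samples=df, timepoint_medians=medians, pre_post_wilcoxon_p=p_value)


def reproducibility(q1: SampleQuant, q2: SampleQuant) -> dict:
    """Concordance of two independent preparations of the same specimen."""
    lo1, hi1 = q1.ci95
    lo2, hi2 = q2.ci95
    ci_overlap = max(lo1, lo2) <= min(hi1, hi2)
    f1, f2 = q1.fraction, q2.fraction
    return {
        "sample_ids": (q1.sample_id, q2.sample_id),
        "abs_difference": abs(f1 - f2),
        "ratio": f1 / f2 if f2 else np.inf,
        "ci_overlap": ci_overlap,
        "concordant": ci_overlap,
    }


def plot_cohort(summary: CohortSummary, path: str, lod: DetectionModel | None = None) -> None:
    """Per-patient trajectory panel (one subplot per patient; the shaded
    band marks the limit of detection)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summary.samples
    patients = sorted(df.patient.unique())
    ncol = min(5, len(patients))
    nrow = (len(patients) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow),
                             sharey=True, squeeze=False)
    order = list(df.timepoint.unique())
    for ax, patient in zip(axes.flat, patients):
        sub = df[df.patient == patient].set_index("timepoint").reindex(order)
        ax.plot(range(len(order)), sub.fraction, marker="o")
        if lod is not None:
            ax.axhspan(0, lod.lod_fraction, color="grey", alpha=0.4)
        ax.set_xticks(range(len(order)), order, rotation=45)
        ax.set_title(patient, fontsize=9)
    for ax in axes.flat[len(patients):]:
        ax.set_visible(False)
    axes[0][0].set_ylabel("fully-unmethylated fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
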