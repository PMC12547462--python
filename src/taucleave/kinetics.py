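"""Per-site cleavage kinetics: the relative frequency of cuts.

The central statistic of the pipeline is computed in two steps for each
accepted peptide (score above the minimum, located uniquely on the
substrate):

1. Per time point, the peptide's replicate intensities are averaged after a
   significance gate against the substrate-alone control samples; a time
   point where the peptide is undetected, or not significantly above the
   controls, contributes an average of zero.
2. Average-intensity ratios are formed, taking as reference the first
   average > 0 along the ordered time points.  The relative frequency of
   cuts for a P1 site at a time point is then the sum of these ratios over
   all peptides whose termini evidence that site.

The significance gate is a one-sided Welch t-test on log2(intensity + 1)
of the experiment replicates at that time point against the pooled control
intensities, at the configured alpha.  Peptides absent from every control
sample are digestion products by construction and are called significant
whenever they are seen in at least ``min_detect_replicates`` replicates,
avoiding degenerate zero-variance tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import PeptideMatch, PeptideObservation, derive_sites, map_peptide
from .substrate import SubstrateSequence


@dataclass(frozen=True)
class SampleInfo:
    condition: Literal["experiment", "control"]
    time_point: float | None  # seconds; None for time-independent controls
    replicate: int


@dataclass(frozen=True)
class TimeSeriesDesign:
    """Sample manifest for a digestion time course.

    ``samples`` maps sample id to its condition, time point (seconds) and
    replicate.  Time points must be strictly increasing and at least one
    control (substrate alone, no protease) sample must be declared.
    """

    time_points: tuple[float, ...]
    samples: Mapping[str, SampleInfo]

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError(f"time points must be strictly increasing: {tp}")
        object.__setattr__(self, "time_points", tp)
        if not self.control_samples():
            raise ValueError("design declares no control (substrate-alone) samples")
        for sid, info in self.samples.items():
            if info.condition == "experiment" and info.time_point not in tp:
                raise ValueError(
                    f"sample {sid!r} has time point {info.time_point} outside "
                    f"the declared grid {tp}"
                )

    def control_samples(self) -> list[str]:
        return [s for s, i in self.samples.items() if i.condition == "control"]

    def experiment_samples(self, time_point: float) -> list[str]:
        return [
            s
            for s, i in self.samples.items()
            if i.condition == "experiment" and i.time_point == time_point
        ]

    @classmethod
    def create(
        cls,
        time_points: Sequence[float],
        n_replicates: int,
        n_controls: int,
    ) -> "TimeSeriesDesign":
        """A regular design: ``exp_t{seconds}_r{rep}`` plus ``ctrl_r{rep}``."""
        samples: dict[str, SampleInfo] = {}
        for t in time_points:
            for r in range(1, n_replicates + 1):
                samples[f"exp_t{int(t)}_r{r}"] = SampleInfo("experiment", float(t), r)
        for r in range(1, n_controls + 1):
            samples[f"ctrl_r{r}"] = SampleInfo("control", None, r)
        return cls(time_points=tuple(float(t) for t in time_points), samples=samples)

    def to_manifest(self, path) -> None:
        rows = [
            {
                "sample_id": sid,
                "condition": info.condition,
                "time_s": "" if info.time_point is None else int(info.time_point),
                "replicate": info.replicate,
            }
            for sid, info in self.samples.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_manifest(cls, path) -> "TimeSeriesDesign":
        frame = pd.read_csv(path, sep="\t")
        samples: dict[str, SampleInfo] = {}
        time_points: list[float] = []
        for _, row in frame.iterrows():
            t = None if pd.isna(row["time_s"]) or row["time_s"] == "" else float(row["time_s"])
            samples[str(row["sample_id"])] = SampleInfo(
                condition=str(row["condition"]), time_point=t, replicate=int(row["replicate"])
            )
            if t is not None and t not in time_points:
                time_points.append(t)
        return cls(time_points=tuple(sorted(time_points)), samples=samples)


@dataclass(frozen=True)
class KineticsConfig:
    """Tunable parameters of the frequency computation.

    alpha:
        Significance level of the per-peptide, per-time-point gate (0.05).
    min_score:
        Minimum search-engine score for a peptide to enter the analysis
        (50; inclusive).
    log2_transform:
        Apply log2(x + 1) before the significance test (the +1 offset makes
        zero intensities finite; ratios always use raw averages).
    ambiguity:
        "unique-only" drops multi-locus peptides from the statistic (they
        are still counted in the QC report); "fractional" lets each locus
        contribute with weight 1 / n_matches.
    termini:
        "both" derives a site from each peptide terminus; "c-only" uses only
        the C-terminal P1 (sensitivity-analysis mode).
    min_detect_replicates:
        Detection shortcut for peptides absent from all controls: present in
        at least this many replicates at a time point => significant there.
    bh_correction:
        Optional Benjamini-Hochberg correction of the gate p-values across
        peptides within each time point (off by default: a single
        per-comparison alpha is the standard setting for this analysis).
    """

    alpha: float = 0.05
    min_score: float = 50.0
    log2_transform: bool = True
    ambiguity: Literal["unique-only", "fractional"] = "unique-only"
    termini: Literal["both", "c-only"] = "both"
    min_detect_replicates: int = 2
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")


def filter_by_score(
    peptides: Iterable[PeptideObservation], min_score: float
) -> list[PeptideObservation]:
    """Retain peptides with score >= min_score (boundary inclusive)."""
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    return [p for p in peptides if p.score >= min_score]


def welch_p_greater(experiment: np.ndarray, control: np.ndarray) -> float:
    """One-sided Welch t-test p-value for experiment mean > control mean.

    Degenerate inputs (either group of size < 2, or both groups with zero
    variance) fall back to a strict mean comparison: p = 0 when the
    experiment mean exceeds the control mean, else 1.
    """
    experiment = np.asarray(experiment, dtype=float)
    control = np.asarray(control, dtype=float)
    degenerate = (
        len(experiment) < 2
        or len(control) < 2
        or (np.var(experiment) == 0.0 and np.var(control) == 0.0)
    )
    if degenerate:
        return 0.0 if experiment.mean() > control.mean() else 1.0
    result = stats.ttest_ind(experiment, control, equal_var=False, alternative="greater")
    p = float(result.pvalue)
    if np.isnan(p):
        return 0.0 if experiment.mean() > control.mean() else 1.0
    return p


def significance_gate(
    experiment_intensities: Sequence[float],
    control_intensities: Sequence[float],
    alpha: float = 0.05,
    log2_transform: bool = True,
    min_detect_replicates: int = 2,
) -> bool:
    """Is a peptide's signal at one time point above the substrate-alone controls?

    Implements the gate described in the module docstring.  Raw intensities
    go in; the log2(x + 1) transform is applied here when enabled.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    experiment = np.asarray(experiment_intensities, dtype=float)
    control = np.asarray(control_intensities, dtype=float)
    if experiment.size < 1:
        raise ValueError("need at least one experiment replicate")
    if control.size < 1:
        raise ValueError("need at least one control intensity")
    if not np.any(experiment > 0):
        return False  # undetected at this time point
    if not np.any(control > 0):
        # Absent from every control: a digestion product by construction.
        return int(np.sum(experiment > 0)) >= min_detect_replicates
    if log2_transform:
        experiment = np.log2(experiment + 1.0)
        control = np.log2(control + 1.0)
    return welch_p_greater(experiment, control) < alpha


def average_intensities(
    peptide: PeptideObservation,
    design: TimeSeriesDesign,
    config: KineticsConfig = KineticsConfig(),
) -> np.ndarray:
    """Gated average intensity of one peptide per time point.

    The average is over the replicates available at that time point; time
    points where the peptide is undetected, fails the significance gate, or
    has no replicate samples are set to zero.
    """
    controls = np.asarray(
        [peptide.intensities.get(s, 0.0) for s in design.control_samples()], dtype=float
    )
    row = np.zeros(len(design.time_points))
    for k, t in enumerate(design.time_points):
        sample_ids = design.experiment_samples(t)
        if not sample_ids:
            continue
        values = np.asarray(
            [peptide.intensities.get(s, 0.0) for s in sample_ids], dtype=float
        )
        if significance_gate(
            values,
            controls,
            alpha=config.alpha,
            log2_transform=config.log2_transform,
            min_detect_replicates=config.min_detect_replicates,
        ):
            row[k] = values.mean()
    return row


def _gate_components(
    peptide: PeptideObservation,
    design: TimeSeriesDesign,
    config: KineticsConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-time raw means, pass/fail of the detection shortcut, and Welch
    p-values (NaN where the shortcut applied or the peptide is undetected).

    Separated out so the pipeline can apply Benjamini-Hochberg across
    peptides within each time point before thresholding the p-values.
    """
    controls = np.asarray(
        [peptide.intensities.get(s, 0.0) for s in design.control_samples()], dtype=float
    )
    n_t = len(design.time_points)
    means = np.zeros(n_t)
    detected = np.zeros(n_t, dtype=bool)
    pvalues = np.full(n_t, np.nan)
    for k, t in enumerate(design.time_points):
        sample_ids = design.experiment_samples(t)
        if not sample_ids:
            continue
        values = np.asarray(
            [peptide.intensities.get(s, 0.0) for s in sample_ids], dtype=float
        )
        if not np.any(values > 0):
            continue
        means[k] = values.mean()
        if not np.any(controls > 0):
            detected[k] = int(np.sum(values > 0)) >= config.min_detect_replicates
            continue
        if config.log2_transform:
            pvalues[k] = welch_p_greater(np.log2(values + 1.0), np.log2(controls + 1.0))
        else:
            pvalues[k] = welch_p_greater(values, controls)
    return means, detected, pvalues


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up); NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    adjusted = np.full_like(p, np.nan)
    finite = np.flatnonzero(~np.isnan(p))
    m = finite.size
    if m == 0:
        return adjusted
    order = finite[np.argsort(p[finite])]
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted


def intensity_ratios(averages: Sequence[float]) -> np.ndarray:
    """Average-intensity ratios relative to the first positive average.

    The reference time point gets ratio 1; earlier (zero) time points stay
    0; later zeros stay 0.  An all-zero row has no reference and raises.
    """
    averages = np.asarray(averages, dtype=float)
    positive = np.flatnonzero(averages > 0)
    if positive.size == 0:
        raise ValueError(
            "all-zero intensity row: no reference time point (peptide "
            "contributes nothing; skip it)"
        )
    return averages / averages[positive[0]]


@dataclass
class CutFrequencyMatrix:
    """P1 site x time point matrix of relative cut frequencies.

    ``frequencies`` is indexed by P1 position (ascending) with one column
    per time point (seconds).  ``provenance`` maps each P1 position to the
    indices of the contributing peptides.  Sites never evidenced by an
    accepted, significant peptide have no row.
    """

    frequencies: pd.DataFrame
    provenance: dict[int, list[int]]
    substrate_id: str = ""

    @property
    def sites(self) -> list[int]:
        return [int(i) for i in self.frequencies.index]

    @property
    def time_points(self) -> list[float]:
        return [float(c) for c in self.frequencies.columns]

    def max_over_time(self) -> pd.Series:
        """Per-site maximum relative frequency across the time course."""
        return self.frequencies.max(axis=1)

    def to_tsv(self, path, substrate: SubstrateSequence | None = None) -> None:
        out = self.frequencies.copy()
        out.insert(0, "p1", out.index)
        if substrate is not None:
            out.insert(1, "residue", [substrate.residue_at(i) for i in out["p1"]])
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def cut_frequency(
    site_evidence: Mapping[int, Sequence[tuple[int, float]]],
    ratios: Mapping[int, np.ndarray],
    time_points: Sequence[float],
    substrate_id: str = "",
) -> CutFrequencyMatrix:
    """Assemble the frequency matrix from site evidence and per-peptide ratios.

    ``site_evidence`` maps a P1 position to ``(peptide_id, weight)`` pairs
    (weight 1 for unique matches, 1/n for fractional multi-locus policy);
    ``ratios`` maps peptide id to its ratio row.  Each cell is the weighted
    sum of contributing ratios at that time point.
    """
    sites = sorted(site_evidence)
    matrix = np.zeros((len(sites), len(time_points)))
    provenance: dict[int, list[int]] = {}
    for i, p1 in enumerate(sites):
        contributors = []
        for peptide_id, weight in site_evidence[p1]:
            if peptide_id not in ratios:
                continue
            matrix[i] += weight * ratios[peptide_id]
            contributors.append(peptide_id)
        provenance[p1] = contributors
    frame = pd.DataFrame(matrix, index=sites, columns=list(time_points))
    return CutFrequencyMatrix(frequencies=frame, provenance=provenance, substrate_id=substrate_id)


def site_counts(matrix: CutFrequencyMatrix, cumulative: bool = False) -> pd.Series:
    """Number of cleavage sites with evidence at each time point.

    Per-time-point mode counts sites whose frequency is positive at that
    time point; cumulative mode counts sites positive at that or any earlier
    time point.
    """
    positive = matrix.frequencies > 0
    if cumulative:
        positive = positive.cummax(axis=1)
    return positive.sum(axis=0)


@dataclass
class QCReport:
    """Bookkeeping for a pipeline run (what was filtered and why)."""

    n_input: int = 0
    n_below_score: int = 0
    n_unmapped: int = 0
    n_ambiguous: int = 0
    n_all_zero: int = 0
    n_contributing: int = 0
    ambiguous_sequences: list[str] = field(default_factory=list)
    unmapped_sequences: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


@dataclass
class PipelineResult:
    matrix: CutFrequencyMatrix
    matches: list[PeptideMatch]
    qc: QCReport


def compute_cut_frequency(
    peptides: Iterable[PeptideObservation],
    substrate: SubstrateSequence,
    design: TimeSeriesDesign,
    config: KineticsConfig = KineticsConfig(),
) -> PipelineResult:
    """Full statistic: score filter, mapping, gating, ratios, per-site sums."""
    peptides = list(peptides)
    qc = QCReport(n_input=len(peptides))
    scored = filter_by_score(peptides, config.min_score)
    qc.n_below_score = len(peptides) - len(scored)

    # First pass: map and gather gate components per candidate peptide.
    candidates: list[tuple[int, PeptideObservation, list[PeptideMatch]]] = []
    for peptide_id, peptide in enumerate(scored):
        matches = map_peptide(peptide, substrate)
        if not matches:
            qc.n_unmapped += 1
            qc.unmapped_sequences.append(peptide.sequence)
            continue
        if matches[0].ambiguous:
            qc.n_ambiguous += 1
            qc.ambiguous_sequences.append(peptide.sequence)
            if config.ambiguity == "unique-only":
                continue
        candidates.append((peptide_id, peptide, matches))

    components = [
        _gate_components(peptide, design, config) for _, peptide, _ in candidates
    ]
    if config.bh_correction and components:
        pmatrix = np.vstack([p for _, _, p in components])
        for k in range(pmatrix.shape[1]):
            pmatrix[:, k] = benjamini_hochberg(pmatrix[:, k])
        components = [
            (means, detected, pmatrix[i]) for i, (means, detected, _) in enumerate(components)
        ]

    ratios: dict[int, np.ndarray] = {}
    site_evidence: dict[int, list[tuple[int, float]]] = {}
    accepted_matches: list[PeptideMatch] = []
    for (peptide_id, peptide, matches), (means, detected, pvalues) in zip(
        candidates, components
    ):
        significant = detected | (np.nan_to_num(pvalues, nan=1.0) < config.alpha)
        averages = np.where(significant, means, 0.0)
        if not np.any(averages > 0):
            qc.n_all_zero += 1
            continue
        ratios[peptide_id] = intensity_ratios(averages)
        qc.n_contributing += 1
        for match in matches:
            weight = 1.0 / match.n_matches if match.ambiguous else 1.0
            accepted_matches.append(match)
            for ev in derive_sites(
                match,
                substrate,
                peptide_id=peptide_id,
                termini=config.termini,
                allow_ambiguous=True,
            ):
                site_evidence.setdefault(ev.site.p1, []).append((peptide_id, weight))

    matrix = cut_frequency(site_evidence, ratios, design.time_points, substrate.id)
    return PipelineResult(matrix=matrix, matches=accepted_matches, qc=qc)
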