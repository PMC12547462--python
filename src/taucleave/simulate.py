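"""Ground-truthed synthetic digestion time courses.

The generator emulates a limited-proteolysis MS experiment: a substrate is
incubated with a protease, samples are drawn at fixed time points in
replicate, and the detectable proteolytic products are reported as a
peptide intensity table alongside substrate-alone control samples.

Simulation law
--------------
Each peptide bond ``i`` (P1 position ``i``, 1..L-1) of each substrate
molecule is cut at an exponentially distributed time with hazard rate
``lambda_i`` (per second), independently across bonds and molecules.  At
sampling time ``t`` a bond is therefore cut with probability
``1 - exp(-lambda_i * t)``, and because cut times are drawn once per
molecule, the cut pattern is nested across time points, as in a sampled
reaction.  The products of a molecule at time ``t`` are the maximal uncut
runs between cuts; defining cutting on the intact coordinate system is
equivalent to products being re-cut with the same hazards (implicit
secondary digestion).  Fibril protection is modelled statically: hazards of
bonds inside a designated core interval are multiplied by a protection
factor in (0, 1].

Products inside the detectable length window are tallied per replicate,
thresholded at a detection limit (minimum molecule count), scaled and
multiplied by lognormal noise to give intensities.  Control samples
(substrate alone) contain no products; an optional low-score spike-in
exercises the downstream score filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import all_site_classes
from .kinetics import CutFrequencyMatrix, SampleInfo, TimeSeriesDesign
from .substrate import SubstrateSequence

#: Default sampling grid: 15 s to 120 min, seven points.
DEFAULT_TIME_POINTS = (15.0, 60.0, 180.0, 600.0, 1800.0, 3600.0, 7200.0)

#: Default per-second hazard tiers for the four site classes (class 4 = 0);
#: one decade per class, mirroring the decade-wide frequency histogram bins
#: that define the classes downstream.
CLASS_RATES = {1: 2.0e-3, 2: 2.0e-4, 3: 2.0e-5, 4: 0.0}

#: Planted class-1 and class-2 P1 positions of the default tau-like truth:
#: the most efficiently cleaved sites of 2N4R tau, all in the C-terminal
#: half (the N-terminal half is protease resistant).
TAU_CLASS1_SITES = (256, 291, 308, 322, 376, 392, 408)
TAU_CLASS2_SITES = (266, 277, 278, 287, 289, 328, 344, 411, 428, 432)


@dataclass(frozen=True)
class DigestTruth:
    """Ground truth of a simulated digest.

    ``rates[i]`` is the hazard (per second) of the bond after residue
    ``i + 1``; ``site_classes`` records the planted class of each nonzero
    site; ``protection`` < 1 with a ``core`` interval suppresses hazards of
    bonds inside the core (both residues within the interval).
    """

    rates: np.ndarray
    site_classes: dict[int, int] = field(default_factory=dict)
    protection: float = 1.0
    core: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if np.any(rates < 0):
            raise ValueError("hazard rates must be nonnegative")
        if not (0.0 < self.protection <= 1.0):
            raise ValueError("protection factor must be in (0, 1]")
        object.__setattr__(self, "rates", rates)

    def effective_rates(self) -> np.ndarray:
        """Hazards after applying core protection."""
        rates = self.rates.copy()
        if self.core is not None and self.protection < 1.0:
            start, end = self.core
            # bonds with both residues inside the core: p1 in [start, end-1]
            rates[start - 1 : end - 1] *= self.protection
        return rates

    def sites(self) -> list[int]:
        """Planted P1 positions (nonzero hazard), ascending."""
        return [int(i) + 1 for i in np.flatnonzero(self.rates > 0)]

    def core_sites(self) -> list[int]:
        if self.core is None:
            return []
        start, end = self.core
        return [p1 for p1 in self.sites() if start <= p1 <= end - 1]

    def protected(self, protection: float) -> "DigestTruth":
        return replace(self, protection=protection)

    def to_json(self, path) -> None:
        payload = {
            "rates": {str(p1): self.rates[p1 - 1] for p1 in self.sites()},
            "site_classes": {str(k): v for k, v in self.site_classes.items()},
            "protection": self.protection,
            "core": list(self.core) if self.core else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def make_tau_like_truth(
    substrate: SubstrateSequence,
    class1_sites: Sequence[int] = TAU_CLASS1_SITES,
    class2_sites: Sequence[int] = TAU_CLASS2_SITES,
    class_rates: dict[int, float] | None = None,
    n_class3: int = 24,
    class3_start: int = 230,
    protection: float = 1.0,
) -> DigestTruth:
    """The default study truth: a tau-like hazard landscape.

    Class-1 and class-2 hazards are planted at the sites cleaved most
    efficiently in 2N4R tau; class-3 (poor) sites are scattered
    deterministically over small-hydrophobic residues of the C-terminal
    half; every bond in the protease-resistant N-terminal half keeps hazard
    zero (class 4).  The core region annotation of the substrate (when
    present) becomes the protection interval.
    """
    rates_by_class = dict(CLASS_RATES)
    if class_rates:
        rates_by_class.update(class_rates)
    L = len(substrate)
    rates = np.zeros(L - 1)
    site_classes: dict[int, int] = {}
    for p1 in class1_sites:
        rates[p1 - 1] = rates_by_class[1]
        site_classes[p1] = 1
    for p1 in class2_sites:
        rates[p1 - 1] = rates_by_class[2]
        site_classes[p1] = 2
    # Deterministic class-3 scatter: small hydrophobic P1 residues in the
    # C-terminal half not already planted, evenly thinned to n_class3.
    candidates = [
        p1
        for p1 in range(class3_start, L)
        if substrate.residue_at(p1) in "AVLIMT" and p1 not in site_classes
    ]
    if n_class3 > 0 and candidates:
        stride = max(1, len(candidates) // n_class3)
        for p1 in candidates[::stride][:n_class3]:
            rates[p1 - 1] = rates_by_class[3]
            site_classes[p1] = 3
    core = None
    try:
        region = substrate.region("core")
        core = (region.start, region.end)
    except KeyError:
        pass
    return DigestTruth(
        rates=rates, site_classes=site_classes, protection=protection, core=core
    )


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    n_molecules:
        Substrate molecules per replicate reaction (10^4).
    time_points:
        Sampling times in seconds (15 s .. 120 min, seven points).
    replicates / n_controls:
        Experiment replicates per time point and substrate-alone controls.
    min_len / max_len:
        Detectable product length window in residues (7, matching the usual
        minimum identifiable peptide length, up to 100: limited-proteolysis
        runs routinely identify very long products).
    min_count:
        Detection limit: products seen in fewer molecules than this in a
        replicate are not observed there.  The default (200, i.e. 2% of the
        default molecule count) gives a ~50-fold dynamic range between the
        faintest detectable product and a fully converted one, typical of
        label-free quantification of low-abundance digestion products.
    intensity_scale:
        Intensity units per molecule.
    lognormal_sigma:
        Sigma of the multiplicative lognormal intensity noise (0.3, i.e. a
        ~30% coefficient of variation, typical of label-free MS).
    score_range:
        Identification scores are drawn uniformly here, above the default
        score filter so simulated truth is never filtered away.
    n_low_score:
        Optional spike-in of low-score decoy rows (score below 50) to
        exercise the score filter.
    seed:
        Seed for the generator; fixed seed gives byte-identical outputs.
    """

    n_molecules: int = 10_000
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    replicates: int = 3
    n_controls: int = 3
    min_len: int = 7
    max_len: int = 100
    min_count: int = 200
    intensity_scale: float = 1.0e5
    lognormal_sigma: float = 0.3
    score_range: tuple[float, float] = (60.0, 300.0)
    n_low_score: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise ValueError("need at least one molecule")
        if len(self.time_points) == 0:
            raise ValueError("empty time grid")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid detectable length window")

    def design(self) -> TimeSeriesDesign:
        return TimeSeriesDesign.create(
            self.time_points, self.replicates, self.n_controls
        )


def molecule_fragments(cut_p1s: Sequence[int], L: int) -> list[tuple[int, int]]:
    """Products of one molecule given its cut P1 positions (1-based)."""
    bounds = [0] + sorted(cut_p1s) + [L]
    return [(a + 1, b) for a, b in zip(bounds, bounds[1:])]


def _tally_products(
    cut_times: np.ndarray, t: float, L: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised fragment census of one replicate at one time point.

    ``cut_times`` is (n_molecules, L-1); column ``i`` holds the cut time of
    the bond with P1 = i + 1 (inf where the hazard is zero).  Returns
    (starts, ends, counts) over distinct products, including undetectably
    long ones (filtering is the caller's job).
    """
    cut = cut_times <= t
    rows, cols = np.nonzero(cut)
    p1 = cols + 1
    n = cut_times.shape[0]
    if rows.size == 0:
        starts = np.array([1])
        ends = np.array([L])
        return starts, ends, np.array([n])
    first_of_row = np.empty(rows.size, dtype=bool)
    first_of_row[0] = True
    first_of_row[1:] = rows[1:] != rows[:-1]
    prev_p1 = np.empty_like(p1)
    prev_p1[0] = 0
    prev_p1[1:] = p1[:-1]
    prev_p1[first_of_row] = 0
    starts = prev_p1 + 1
    ends = p1
    # terminal fragment of each molecule that has >= 1 cut
    last_of_row = np.empty(rows.size, dtype=bool)
    last_of_row[-1] = True
    last_of_row[:-1] = rows[1:] != rows[:-1]
    tail_starts = p1[last_of_row] + 1
    tail_ends = np.full(tail_starts.size, L)
    n_uncut = n - np.unique(rows).size
    starts = np.concatenate([starts, tail_starts])
    ends = np.concatenate([ends, tail_ends])
    if n_uncut > 0:
        starts = np.concatenate([starts, [1]])
        ends = np.concatenate([ends, [L]])
    keys = starts.astype(np.int64) * (L + 1) + ends
    uniq, counts = np.unique(keys, return_counts=True)
    u_starts = (uniq // (L + 1)).astype(int)
    u_ends = (uniq % (L + 1)).astype(int)
    if n_uncut > 0:
        full = (u_starts == 1) & (u_ends == L)
        counts = counts.copy()
        counts[full] += n_uncut - 1  # the appended singleton already counted once
    return u_starts, u_ends, counts


@dataclass
class SimResult:
    """A simulated experiment: peptide table, design, and provenance."""

    table: pd.DataFrame
    design: TimeSeriesDesign
    truth: DigestTruth
    config: SimConfig
    substrate: SubstrateSequence
    species: pd.DataFrame  # per emitted peptide: sequence, loci, total count

    def peptide_table_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False, float_format="%.4f")

    def observations(self):
        """The emitted table as :class:`~taucleave.mapping.PeptideObservation`s."""
        from .mapping import observations_from_frame

        return observations_from_frame(self.table)

    def analyze(self, config=None):
        """Run the frequency pipeline on this simulated experiment."""
        from .kinetics import KineticsConfig, compute_cut_frequency

        return compute_cut_frequency(
            self.observations(), self.substrate, self.design, config or KineticsConfig()
        )

    def write(self, table_path, manifest_path=None, truth_path=None) -> None:
        with open(table_path, "w") as fh:
            fh.write(self.peptide_table_tsv())
        if manifest_path is not None:
            self.design.to_manifest(manifest_path)
        if truth_path is not None:
            self.truth.to_json(truth_path)


def simulate_digest(
    substrate: SubstrateSequence,
    truth: DigestTruth,
    config: SimConfig = SimConfig(),
    seed: int | None = None,
) -> SimResult:
    """Simulate a digestion time course and emit the peptide-table dialect.

    See the module docstring for the law.  ``seed`` overrides
    ``config.seed``.  All randomness flows from one generator, so a fixed
    seed reproduces the table byte for byte.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = len(substrate)
    rates = truth.effective_rates()
    if rates.shape != (L - 1,):
        raise ValueError(
            f"truth has {rates.shape[0]} bonds but substrate {substrate.id!r} "
            f"has {L - 1}"
        )
    design = config.design()
    exp_samples = [
        s for t in config.time_points for s in design.experiment_samples(t)
    ]
    sample_time = {
        s: design.samples[s].time_point for s in exp_samples
    }

    # Per-replicate reactions: draw bond cut times once, sample over time.
    with np.errstate(divide="ignore"):
        scale = np.where(rates > 0, 1.0 / np.where(rates > 0, rates, 1.0), np.inf)
    counts_by_interval: dict[tuple[int, int], np.ndarray] = {}
    n_samples = len(exp_samples)
    for r in range(config.replicates):
        cut_times = np.where(
            rates > 0,
            rng.exponential(scale=scale, size=(config.n_molecules, L - 1)),
            np.inf,
        )
        for t in config.time_points:
            sample_id = f"exp_t{int(t)}_r{r + 1}"
            column = exp_samples.index(sample_id)
            starts, ends, counts = _tally_products(cut_times, t, L)
            lengths = ends - starts + 1
            keep = (lengths >= config.min_len) & (lengths <= config.max_len)
            for s, e, c in zip(starts[keep], ends[keep], counts[keep]):
                row = counts_by_interval.setdefault(
                    (int(s), int(e)), np.zeros(n_samples)
                )
                row[column] += c

    # Merge loci that share an amino-acid sequence (MS sees sequences).
    counts_by_sequence: dict[str, np.ndarray] = {}
    loci_by_sequence: dict[str, list[tuple[int, int]]] = {}
    for (s, e) in sorted(counts_by_interval):
        sequence = substrate.subsequence(s, e)
        if sequence in counts_by_sequence:
            counts_by_sequence[sequence] += counts_by_interval[(s, e)]
        else:
            counts_by_sequence[sequence] = counts_by_interval[(s, e)].copy()
        loci_by_sequence.setdefault(sequence, []).append((s, e))

    sequences = sorted(counts_by_sequence, key=lambda q: (loci_by_sequence[q][0], q))
    counts = np.array([counts_by_sequence[q] for q in sequences]) if sequences else np.zeros((0, n_samples))
    counts[counts < config.min_count] = 0
    noise = rng.lognormal(
        mean=0.0, sigma=config.lognormal_sigma, size=counts.shape
    ) if counts.size else counts
    intensities = counts * config.intensity_scale * noise
    scores = rng.uniform(*config.score_range, size=len(sequences))

    detected = intensities.sum(axis=1) > 0 if len(sequences) else np.array([], bool)
    rows = []
    for i, sequence in enumerate(sequences):
        if not detected[i]:
            continue
        row = {"Sequence": sequence, "Score": round(float(scores[i]), 2)}
        for j, sample in enumerate(exp_samples):
            row[f"Intensity {sample}"] = intensities[i, j]
        for ctrl in design.control_samples():
            row[f"Intensity {ctrl}"] = 0.0
        rows.append(row)

    # Optional low-score decoys: shuffled substrate windows, score < 50.
    for k in range(config.n_low_score):
        start = int(rng.integers(1, L - config.min_len))
        letters = list(substrate.subsequence(start, start + config.min_len - 1))
        rng.shuffle(letters)
        row = {"Sequence": "".join(letters), "Score": round(float(rng.uniform(5, 49)), 2)}
        for sample in exp_samples:
            row[f"Intensity {sample}"] = float(rng.uniform(0.5, 2.0) * config.intensity_scale)
        for ctrl in design.control_samples():
            row[f"Intensity {ctrl}"] = 0.0
        rows.append(row)

    columns = ["Sequence", "Score"] + [
        f"Intensity {s}" for s in exp_samples
    ] + [f"Intensity {c}" for c in design.control_samples()]
    table = pd.DataFrame(rows, columns=columns)

    species = pd.DataFrame(
        {
            "sequence": sequences,
            "loci": [";".join(f"{s}-{e}" for s, e in loci_by_sequence[q]) for q in sequences],
            "total_count": counts.sum(axis=1) if len(sequences) else [],
        }
    )
    return SimResult(
        table=table,
        design=design,
        truth=truth,
        config=config,
        substrate=substrate,
        species=species,
    )


def truth_recovery_report(
    truth: DigestTruth,
    matrix: CutFrequencyMatrix,
    substrate: SubstrateSequence,
) -> dict:
    """How well the pipeline recovered the simulator's ground truth.

    Reports site detection sensitivity and precision, the Spearman rank
    correlation between planted hazard and recovered max frequency (over
    all planted sites; undetected ones count as frequency 0), and the
    truth-class vs recovered-class confusion matrix.
    """
    if matrix.substrate_id and matrix.substrate_id != substrate.id:
        raise ValueError(
            f"matrix computed on {matrix.substrate_id!r}, not {substrate.id!r}"
        )
    true_sites = set(truth.sites())
    max_freq = matrix.max_over_time()
    found_sites = {int(p1) for p1, v in max_freq.items() if v > 0}
    tp = len(true_sites & found_sites)
    sensitivity = tp / len(true_sites) if true_sites else float("nan")
    precision = tp / len(found_sites) if found_sites else float("nan")

    planted = sorted(true_sites)
    lam = np.array([truth.rates[p1 - 1] for p1 in planted])
    freq = np.array([float(max_freq.get(p1, 0.0)) for p1 in planted])
    # rank correlation is undefined for constant inputs (e.g. one hazard tier)
    if len(planted) >= 2 and np.unique(lam).size > 1 and np.unique(freq).size > 1:
        rho = float(stats.spearmanr(lam, freq).statistic)
    else:
        rho = float("nan")

    recovered = all_site_classes(matrix, substrate)
    confusion = np.zeros((4, 4), dtype=int)
    for p1, true_class in truth.site_classes.items():
        confusion[true_class - 1, recovered.loc[p1] - 1] += 1

    return {
        "n_true_sites": len(true_sites),
        "n_found_sites": len(found_sites),
        "sensitivity": sensitivity,
        "precision": precision,
        "spearman_rho": rho,
        "confusion": confusion,
        "recovered_classes": {p1: int(recovered.loc[p1]) for p1 in planted},
    }
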