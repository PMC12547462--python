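"""Fragment maps, P1-site classes, specificity profiles and comparisons.

A *fragment* at a given time point is a maximal run of substrate residues
covered without gaps by accepted proteolytic products: peptide intervals
that overlap or directly abut (no uncovered residue between them) are
merged.  Site classes summarise each P1 position by its maximum relative
cut frequency over the time course:

====== =============================
class  max relative frequency f
====== =============================
1      f >= 20
2      10 <= f < 20
3      0 < f < 10
4      f = 0 (no product detected)
====== =============================

The boundaries are half-open so that non-integer frequencies (sums of
intensity ratios) classify unambiguously.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import CutFrequencyMatrix
from .mapping import PeptideMatch, derive_sites
from .substrate import SubstrateSequence

SPECIFICITY_POSITIONS = [
    "P5", "P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'", "P5'",
]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals that overlap or directly abut.

    Adjacency counts as gapless: [10, 20] and [21, 30] merge because no
    uncovered residue separates them.  The result is sorted, pairwise
    non-overlapping and non-adjacent; the output is independent of input
    order and idempotent.
    """
    intervals = sorted(intervals)
    merged: list[list[int]] = []
    for start, end in intervals:
        if start > end:
            raise ValueError(f"invalid interval [{start}, {end}]")
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


@dataclass(frozen=True)
class Fragment:
    """One gapless covered run with its peptide and cleavage-site counts."""

    start: int
    end: int
    n_peptides: int
    n_sites: int


@dataclass
class FragmentMap:
    """Per-time-point fragment lists with global peptide/site totals."""

    entries: dict[float, list[Fragment]] = field(default_factory=dict)
    substrate_id: str = ""

    def totals(self, time_point: float) -> tuple[int, int]:
        """(Peps, Cls) at one time point: total peptides and distinct sites."""
        frags = self.entries[time_point]
        return sum(f.n_peptides for f in frags), sum(f.n_sites for f in frags)

    def to_bed(self, path) -> None:
        """BED-like TSV export; coordinates half-open 0-based in this export
        only (flagged in the header comment)."""
        with open(path, "w") as fh:
            fh.write("# coordinates: 0-based half-open (BED convention)\n")
            fh.write("substrate\tstart\tend\tname\tpeps\tcls\n")
            for t in sorted(self.entries):
                for k, f in enumerate(self.entries[t], start=1):
                    fh.write(
                        f"{self.substrate_id}\t{f.start - 1}\t{f.end}\t"
                        f"t{int(t)}_frag{k}\t{f.n_peptides}\t{f.n_sites}\n"
                    )

    def to_json(self, path) -> None:
        payload = {
            str(t): [
                {"start": f.start, "end": f.end, "peps": f.n_peptides, "cls": f.n_sites}
                for f in frags
            ]
            for t, frags in self.entries.items()
        }
        with open(path, "w") as fh:
            json.dump({"substrate": self.substrate_id, "fragments": payload}, fh, indent=2)


def group_fragments(
    matches: Sequence[PeptideMatch],
    substrate: SubstrateSequence,
) -> list[Fragment]:
    """Group accepted peptides at one time point into gapless fragments.

    Each fragment carries the number of peptides lying wholly inside it and
    the number of distinct cleavage sites evidenced by those peptides'
    termini (substrate termini never count as sites).
    """
    if not matches:
        return []
    intervals = merge_intervals((m.start, m.end) for m in matches)
    fragments = []
    for start, end in intervals:
        inside = [m for m in matches if start <= m.start and m.end <= end]
        sites: set[int] = set()
        for m in inside:
            for ev in derive_sites(m, substrate, allow_ambiguous=True):
                sites.add(ev.site.p1)
        fragments.append(
            Fragment(start=start, end=end, n_peptides=len(inside), n_sites=len(sites))
        )
    return fragments


def build_fragment_map(
    matches_per_time: Mapping[float, Sequence[PeptideMatch]],
    substrate: SubstrateSequence,
) -> FragmentMap:
    fmap = FragmentMap(substrate_id=substrate.id)
    for t, matches in matches_per_time.items():
        fmap.entries[float(t)] = group_fragments(list(matches), substrate)
    return fmap


def digest_interval(
    start: int, end: int, p1_sites: Sequence[int]
) -> list[tuple[int, int]]:
    """Products of cutting the fragment [start, end] after each P1 in
    ``p1_sites`` (sites outside the open interval are ignored)."""
    cuts = sorted(p for p in p1_sites if start <= p < end)
    bounds = [start - 1] + cuts + [end]
    return [(a + 1, b) for a, b in zip(bounds, bounds[1:])]


def classify_site(max_frequency: float) -> int:
    """Class label from the maximum relative cut frequency (see module docs)."""
    if max_frequency < 0:
        raise ValueError("frequencies are nonnegative")
    if max_frequency >= 20:
        return 1
    if max_frequency >= 10:
        return 2
    if max_frequency > 0:
        return 3
    return 4


def classify_sites(
    matrix: CutFrequencyMatrix, substrate: SubstrateSequence | None = None
) -> pd.DataFrame:
    """Per-site class table: p1, (residue,) max frequency over time, class.

    Sites absent from the matrix belong to class 4 by definition; this table
    lists only sites with a row (call :func:`all_site_classes` for the full
    per-bond labelling of a substrate).
    """
    max_freq = matrix.max_over_time()
    table = pd.DataFrame(
        {
            "p1": [int(i) for i in max_freq.index],
            "max_frequency": max_freq.to_numpy(),
            "site_class": [classify_site(v) for v in max_freq.to_numpy()],
        }
    )
    if substrate is not None:
        table.insert(1, "residue", [substrate.residue_at(i) for i in table["p1"]])
    return table


def all_site_classes(
    matrix: CutFrequencyMatrix, substrate: SubstrateSequence
) -> pd.Series:
    """Class label for every bond 1..L-1 (class 4 where no row exists)."""
    classes = pd.Series(4, index=range(1, len(substrate)), dtype=int)
    table = classify_sites(matrix)
    classes.loc[table["p1"].to_numpy()] = table["site_class"].to_numpy()
    return classes


def aa_distribution(
    p1_sites: Sequence[int],
    substrate: SubstrateSequence,
    window: int = 5,
) -> pd.DataFrame:
    """Amino-acid counts around cleavage sites, ``window`` residues each way.

    Rows are the 20 amino acids; columns run P<window>..P1 then
    P1'..P<window>'.  Positions falling outside the substrate are skipped,
    so a boundary-adjacent site contributes to fewer columns.
    """
    from .substrate import AMINO_ACIDS

    positions = [f"P{k}" for k in range(window, 0, -1)] + [
        f"P{k}'" for k in range(1, window + 1)
    ]
    counts = pd.DataFrame(0, index=list(AMINO_ACIDS), columns=positions)
    L = len(substrate)
    for p1 in p1_sites:
        if not (1 <= p1 <= L - 1):
            raise ValueError(f"invalid P1 site {p1} on substrate of length {L}")
        for k in range(1, window + 1):
            i = p1 - k + 1  # P1 is at p1 itself; Pk is k-1 residues upstream
            if 1 <= i <= L:
                counts.loc[substrate.residue_at(i), f"P{k}"] += 1
            j = p1 + k  # Pk' is k residues downstream of P1
            if 1 <= j <= L:
                counts.loc[substrate.residue_at(j), f"P{k}'"] += 1
    return counts


def compare_substrates(
    matrix_a: CutFrequencyMatrix,
    matrix_b: CutFrequencyMatrix,
    position_map: pd.DataFrame | None = None,
    restrict_common_times: bool = False,
) -> pd.DataFrame:
    """Per-site comparison of two frequency matrices.

    ``position_map`` (columns ``new_index``, ``wt_index``) translates matrix
    B's sites into matrix A's coordinate system first — use it to compare a
    segment-swapped construct against its parent on the parent's axis.
    Returns one row per site seen in either matrix with the per-substrate
    max frequencies, ``delta_max`` (A - B), per-time differences for shared
    time points and a status flag (``shared`` / ``A-only`` / ``B-only``).
    """
    freq_a = matrix_a.frequencies
    freq_b = matrix_b.frequencies
    if position_map is not None:
        translation = dict(
            zip(position_map["new_index"].astype(int), position_map["wt_index"].astype(int))
        )
        freq_b = freq_b.copy()
        freq_b.index = [translation[int(i)] for i in freq_b.index]
        freq_b = freq_b.sort_index()
    times_a = list(freq_a.columns)
    times_b = list(freq_b.columns)
    if times_a != times_b:
        if not restrict_common_times:
            raise ValueError(
                f"incompatible time grids {times_a} vs {times_b}; pass "
                "restrict_common_times=True to compare the overlap"
            )
        common = [t for t in times_a if t in times_b]
        freq_a = freq_a[common]
        freq_b = freq_b[common]
    rows = []
    for p1 in sorted(set(freq_a.index) | set(freq_b.index)):
        in_a = p1 in freq_a.index
        in_b = p1 in freq_b.index
        max_a = float(freq_a.loc[p1].max()) if in_a else 0.0
        max_b = float(freq_b.loc[p1].max()) if in_b else 0.0
        row = {
            "p1": int(p1),
            "max_a": max_a,
            "max_b": max_b,
            "delta_max": max_a - max_b,
            "status": "shared" if (in_a and in_b) else ("A-only" if in_a else "B-only"),
        }
        for t in freq_a.columns:
            va = float(freq_a.loc[p1, t]) if in_a else 0.0
            vb = float(freq_b.loc[p1, t]) if in_b else 0.0
            row[f"delta_t{int(t)}"] = va - vb
        rows.append(row)
    return pd.DataFrame(rows)
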