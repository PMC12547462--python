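"""Independent straight-line reference implementations used as test oracles.

Deliberately naive: plain loops and dicts, no code shared with the package,
so they check the pipeline rather than mirror it.
"""

import numpy as np
from scipy import stats


def brute_force_occurrences(peptide: str, substrate: str):
    """All 1-based (start, end) occurrences by scanning every position."""
    hits = []
    n, m = len(substrate), len(peptide)
    for start in range(n - m + 1):
        if substrate[start : start + m] == peptide:
            hits.append((start + 1, start + m))
    return hits


def coverage_components(intervals, length):
    """Connected components of the boolean coverage mask of 1-based
    inclusive intervals on positions 1..length."""
    covered = [False] * (length + 2)
    for s, e in intervals:
        for i in range(s, e + 1):
            covered[i] = True
    components = []
    i = 1
    while i <= length:
        if covered[i]:
            j = i
            while j + 1 <= length and covered[j + 1]:
                j += 1
            components.append((i, j))
            i = j + 1
        else:
            i += 1
    return components


def straight_line_frequencies(
    peptides, substrate, design, alpha=0.05, min_score=50.0, min_detect=2
):
    """Literal rendering of the two-step relative-frequency-of-cuts procedure.

    ``peptides`` are PeptideObservation-like objects (sequence, score,
    intensities).  Returns {p1: [frequency per time point]} using unique
    matches only and both peptide termini, the pipeline defaults.
    """
    time_points = list(design.time_points)
    controls = design.control_samples()
    L = len(substrate.residues)

    frequencies = {}
    for p in peptides:
        if p.score < min_score:
            continue
        hits = brute_force_occurrences(p.sequence, substrate.residues)
        if len(hits) != 1:
            continue
        start, end = hits[0]

        ctrl_values = [p.intensities.get(s, 0.0) for s in controls]
        averages = []
        for t in time_points:
            values = [p.intensities.get(s, 0.0) for s in design.experiment_samples(t)]
            if not any(v > 0 for v in values):
                averages.append(0.0)
                continue
            if not any(c > 0 for c in ctrl_values):
                significant = sum(v > 0 for v in values) >= min_detect
            else:
                a = np.log2(np.array(values) + 1.0)
                b = np.log2(np.array(ctrl_values) + 1.0)
                if len(a) < 2 or len(b) < 2 or (a.var() == 0 and b.var() == 0):
                    significant = a.mean() > b.mean()
                else:
                    pval = stats.ttest_ind(
                        a, b, equal_var=False, alternative="greater"
                    ).pvalue
                    significant = (a.mean() > b.mean()) if np.isnan(pval) else pval < alpha
            averages.append(float(np.mean(values)) if significant else 0.0)

        if not any(a > 0 for a in averages):
            continue
        reference = next(a for a in averages if a > 0)
        ratios = [a / reference for a in averages]

        sites = []
        if end < L:
            sites.append(end)
        if start > 1:
            sites.append(start - 1)
        for p1 in sites:
            row = frequencies.setdefault(p1, [0.0] * len(time_points))
            for k in range(len(time_points)):
                row[k] += ratios[k]
    return frequencies
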