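"""Peptide tables and peptide-to-substrate mapping.

Identified proteolytic products are located on the substrate by exact,
gapless substring matching (the searches behind such tables are sequence-
database searches, so the reported letters are taken at face value and
isoleucine/leucine are kept distinct).  Each located peptide evidences up to
two cleavage sites: the bond before its first residue (its N-terminal cut,
P1 = start - 1) and the bond after its last residue (its C-terminal cut,
P1 = end), except where a terminus coincides with a substrate terminus,
which is not a cut.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

from .substrate import CleavageSite, SubstrateSequence

logger = logging.getLogger(__name__)

#: Default rule for reducing a search-engine "modified sequence" string to a
#: bare amino-acid sequence: strip underscores and (possibly nested)
#: parenthesised/bracketed modification tags, e.g.
#: ``_VQIM(Oxidation (M))INK_``.  Applied innermost-first until stable.
DEFAULT_MOD_PATTERN = r"_|\([^()]*\)|\[[^\[\]]*\]"


@dataclass(frozen=True)
class PeptideObservation:
    """One identified peptide with its per-sample intensities.

    ``intensities`` maps sample id to a nonnegative intensity; which sample
    belongs to which condition / time point / replicate is resolved by the
    run's :class:`~taucleave.kinetics.TimeSeriesDesign`.
    """

    sequence: str
    score: float
    intensities: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("peptide sequence must be non-empty")
        for sample, value in self.intensities.items():
            if value < 0:
                raise ValueError(
                    f"negative intensity {value} in sample {sample!r} for "
                    f"peptide {self.sequence}"
                )


@dataclass(frozen=True)
class PeptideMatch:
    """An exact occurrence of a peptide on the substrate (1-based, inclusive)."""

    peptide: PeptideObservation
    start: int
    end: int
    n_matches: int
    ambiguous: bool


@dataclass(frozen=True)
class SiteEvidence:
    """One peptide terminus supporting one cleavage site."""

    site: CleavageSite
    peptide_id: int | str
    terminus: Literal["N", "C"]


def strip_modifications(sequence: str, pattern: str = DEFAULT_MOD_PATTERN) -> str:
    """Reduce a modified-peptide string to its bare sequence."""
    previous = None
    while previous != sequence:
        previous = sequence
        sequence = re.sub(pattern, "", sequence)
    return sequence


def read_peptide_table(
    source,
    design=None,
    sequence_column: str = "Sequence",
    score_column: str = "Score",
    intensity_prefix: str = "Intensity ",
    strip_mods: bool = True,
    mod_pattern: str = DEFAULT_MOD_PATTERN,
) -> list[PeptideObservation]:
    """Read a tab-delimited peptide table (MaxQuant peptides.txt dialect).

    One row per peptide; intensity columns are ``<intensity_prefix><sample>``.
    Missing or empty intensity cells are read as 0.  Rows whose sequence does
    not reduce to canonical amino-acid letters are rejected (skipped) and
    reported with their 1-based data row number.  When a ``design`` is given,
    every intensity column must correspond to a sample declared in it.
    """
    table = pd.read_csv(source, sep="\t", dtype={sequence_column: str})
    return observations_from_frame(
        table,
        design=design,
        sequence_column=sequence_column,
        score_column=score_column,
        intensity_prefix=intensity_prefix,
        strip_mods=strip_mods,
        mod_pattern=mod_pattern,
    )


def observations_from_frame(
    table: pd.DataFrame,
    design=None,
    sequence_column: str = "Sequence",
    score_column: str = "Score",
    intensity_prefix: str = "Intensity ",
    strip_mods: bool = True,
    mod_pattern: str = DEFAULT_MOD_PATTERN,
) -> list[PeptideObservation]:
    """In-memory counterpart of :func:`read_peptide_table`."""
    for column in (sequence_column, score_column):
        if column not in table.columns:
            raise ValueError(f"peptide table lacks mandatory column {column!r}")
    intensity_columns = [
        c for c in table.columns if c.startswith(intensity_prefix)
    ]
    if not intensity_columns:
        raise ValueError(
            f"peptide table has no intensity columns (prefix {intensity_prefix!r})"
        )
    samples = [c[len(intensity_prefix):] for c in intensity_columns]
    if design is not None:
        unknown = [s for s in samples if s not in design.samples]
        if unknown:
            raise ValueError(
                f"intensity columns reference samples not in the design: {unknown}"
            )
    observations: list[PeptideObservation] = []
    # Row-wise access via .iloc keeps column names with spaces intact.
    for idx in range(len(table)):
        row = table.iloc[idx]
        raw_sequence = row[sequence_column]
        if not isinstance(raw_sequence, str):
            logger.warning("row %d rejected: unparsable sequence %r", idx + 1, raw_sequence)
            continue
        sequence = strip_modifications(raw_sequence, mod_pattern) if strip_mods else raw_sequence
        if not sequence or not re.fullmatch(r"[ACDEFGHIKLMNPQRSTVWY]+", sequence):
            logger.warning("row %d rejected: unparsable sequence %r", idx + 1, raw_sequence)
            continue
        intensities = {}
        for sample, column in zip(samples, intensity_columns):
            value = row[column]
            intensities[sample] = 0.0 if pd.isna(value) else float(value)
        observations.append(
            PeptideObservation(
                sequence=sequence,
                score=float(row[score_column]),
                intensities=intensities,
            )
        )
    return observations


def write_peptide_table(
    peptides: Iterable[PeptideObservation],
    path,
    sequence_column: str = "Sequence",
    score_column: str = "Score",
    intensity_prefix: str = "Intensity ",
    float_format: str = "%.4f",
) -> None:
    """Write observations in the dialect read by :func:`read_peptide_table`."""
    peptides = list(peptides)
    samples: list[str] = []
    for p in peptides:
        for s in p.intensities:
            if s not in samples:
                samples.append(s)
    rows = []
    for p in peptides:
        row = {sequence_column: p.sequence, score_column: p.score}
        for s in samples:
            row[intensity_prefix + s] = p.intensities.get(s, 0.0)
        rows.append(row)
    columns = [sequence_column, score_column] + [intensity_prefix + s for s in samples]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def map_peptide(
    peptide: PeptideObservation, substrate: SubstrateSequence
) -> list[PeptideMatch]:
    """All exact, gapless occurrences of a peptide on the substrate.

    Overlapping occurrences count.  No occurrence returns an empty list
    (not an error); more than one occurrence marks every match ambiguous.
    """
    positions = []
    start = substrate.residues.find(peptide.sequence)
    while start != -1:
        positions.append(start)
        start = substrate.residues.find(peptide.sequence, start + 1)
    n = len(positions)
    return [
        PeptideMatch(
            peptide=peptide,
            start=pos + 1,
            end=pos + len(peptide.sequence),
            n_matches=n,
            ambiguous=n > 1,
        )
        for pos in positions
    ]


def derive_sites(
    match: PeptideMatch,
    substrate: SubstrateSequence,
    peptide_id: int | str = 0,
    termini: Literal["both", "c-only"] = "both",
    allow_ambiguous: bool = False,
) -> list[SiteEvidence]:
    """Cleavage sites evidenced by a located peptide's termini.

    A product is bounded by two cuts, so its C-terminal residue is the P1 of
    one site (unless it is the substrate C-terminus) and the residue before
    its N-terminal residue is the P1 of the other (unless the product starts
    at residue 1).  ``termini="c-only"`` restricts to the C-terminal cut for
    sensitivity analyses.
    """
    if match.ambiguous and not allow_ambiguous:
        raise ValueError(
            f"peptide {match.peptide.sequence!r} matches the substrate at "
            f"{match.n_matches} positions; resolve ambiguity (unique-only or "
            "fractional policy) before deriving sites"
        )
    L = len(substrate)
    evidence: list[SiteEvidence] = []
    if match.end < L:
        evidence.append(
            SiteEvidence(site=substrate.site(match.end), peptide_id=peptide_id, terminus="C")
        )
    if termini == "both" and match.start > 1:
        evidence.append(
            SiteEvidence(
                site=substrate.site(match.start - 1), peptide_id=peptide_id, terminus="N"
            )
        )
    return evidence


def match_table(matches: Iterable[PeptideMatch]) -> pd.DataFrame:
    """Per-peptide match table (sequence, start, end, n_matches, ambiguous)."""
    return pd.DataFrame(
        [
            {
                "sequence": m.peptide.sequence,
                "start": m.start,
                "end": m.end,
                "n_matches": m.n_matches,
                "ambiguous": m.ambiguous,
            }
            for m in matches
        ],
        columns=["sequence", "start", "end", "n_matches", "ambiguous"],
    )
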