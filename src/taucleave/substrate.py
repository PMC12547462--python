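"""Substrate sequences, region annotations and cleavage-site coordinates.

All residue coordinates in this package are 1-based and inclusive at both
ends, matching the residue numbering used in the degradomics literature
(e.g. "V256" means the valine at position 256 is the P1 residue of the
scissile bond between residues 256 and 257).  A cleavage site is identified
by its P1 position ``p1``; valid sites satisfy ``1 <= p1 <= L - 1`` because
the bond after the C-terminal residue does not exist.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Human tau, 2N4R isoform (441 residues; UniProt P10636-8).  Bundled as the
#: canonical test substrate: two N-terminal inserts (N1, N2), a proline-rich
#: middle, four microtubule-binding repeats (R1-R4), and the amyloid fibril
#: core spanning R3/R4 plus a short stretch after R4.
TAU_2N4R = (
    "MAEPRQEFEVMEDHAGTYGLGDRKDQGGYTMHQDQEGDTDAGLKESPLQTPTEDGSEEPG"
    "SETSDAKSTPTAEDVTAPLVDEGAPGKQAAAQPHTEIPEGTTAEEAGIGDTPSLEDEAAG"
    "HVTQARMVSKSKDGTGSDDKKAKGADGKTKIATPRGAAPPGQKGQANATRIPAKTPPAPK"
    "TPPSSGEPPKSGDRSGYSSPGSPGTPGSRSRTPSLPTPPTREPKKVAVVRTPPKSPSSAK"
    "SRLQTAPVPMPDLKNVKSKIGSTENLKHQPGGGKVQIINKKLDLSNVQSKCGSKDNIKHV"
    "PGGGSVQIVYKPVDLSKVTSKCGSLGNIHHKPGGGQVEVKSEKLDFKDRVQSKIGSLDNI"
    "THVPGGGNKKIETHKLTFRENAKAKTDHGAEIVYKSPVVSGDTSPRHLSNVSSTGSIDMV"
    "DSPQLATLADEVSASLAKQGL"
)

#: Default annotation of the fibril core: residues 306-378, i.e. repeats
#: R3 and R4 plus a few residues after R4.  Configurable because structural
#: studies delineate the beta-sheet region slightly differently.
DEFAULT_CORE = (306, 378)


@dataclass(frozen=True)
class RegionAnnotation:
    """A named contiguous region of the substrate, 1-based inclusive."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"region {self.name!r}: need 1 <= start <= end, got "
                f"[{self.start}, {self.end}]"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, i: int) -> bool:
        return self.start <= i <= self.end


@dataclass(frozen=True)
class CleavageSite:
    """A scissile bond, named by its P1 residue (N-terminal to the bond)."""

    p1: int
    p1_residue: str

    def label(self) -> str:
        return f"{self.p1_residue}{self.p1}"


@dataclass(frozen=True)
class SubstrateSequence:
    """A validated substrate with optional named region annotations."""

    id: str
    residues: str
    regions: tuple[RegionAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError(f"substrate {self.id!r} is empty")
        for pos, letter in enumerate(self.residues, start=1):
            if letter not in AMINO_ACIDS:
                raise ValueError(
                    f"substrate {self.id!r}: illegal residue {letter!r} at "
                    f"position {pos} (only the 20 canonical one-letter codes "
                    "are accepted)"
                )
        L = len(self.residues)
        for region in self.regions:
            if region.end > L:
                raise ValueError(
                    f"region {region.name!r} [{region.start}, {region.end}] "
                    f"extends past substrate length {L}"
                )
        object.__setattr__(self, "regions", tuple(self.regions))

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, i: int) -> str:
        """Residue letter at 1-based position ``i``."""
        if not (1 <= i <= len(self)):
            raise IndexError(
                f"position {i} outside substrate {self.id!r} of length {len(self)}"
            )
        return self.residues[i - 1]

    def subsequence(self, start: int, end: int) -> str:
        """Residues ``start..end``, 1-based inclusive."""
        if not (1 <= start <= end <= len(self)):
            raise IndexError(f"interval [{start}, {end}] outside [1, {len(self)}]")
        return self.residues[start - 1 : end]

    def region(self, name: str) -> RegionAnnotation:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"substrate {self.id!r} has no region named {name!r}")

    def site(self, p1: int) -> CleavageSite:
        """The cleavage site after residue ``p1``."""
        if not (1 <= p1 <= len(self) - 1):
            raise ValueError(
                f"p1={p1} is not a valid site on a substrate of length "
                f"{len(self)} (need 1 <= p1 <= L-1)"
            )
        return CleavageSite(p1=p1, p1_residue=self.residue_at(p1))


def tau_2n4r(core: tuple[int, int] = DEFAULT_CORE) -> SubstrateSequence:
    """The bundled 2N4R tau substrate with standard region annotations.

    Parameters
    ----------
    core:
        The fibril-core interval used for protection modelling; defaults to
        residues 306-378 (repeats R3/R4 and the stretch just after R4).
    """
    regions = (
        RegionAnnotation("N1", 45, 73),
        RegionAnnotation("N2", 74, 102),
        RegionAnnotation("R1", 244, 274),
        RegionAnnotation("R2", 275, 305),
        RegionAnnotation("R3", 306, 336),
        RegionAnnotation("R4", 337, 368),
        RegionAnnotation("core", core[0], core[1]),
    )
    return SubstrateSequence(id="TAU_2N4R", residues=TAU_2N4R, regions=regions)


def load_substrate(fasta_source, record_id: str | None = None) -> SubstrateSequence:
    """Load one substrate record from a FASTA file, path or handle.

    With more than one record in the source, ``record_id`` must name the one
    to load.  Sequences are validated against the canonical 20-letter
    alphabet; the error message names the first offending position.
    """
    if isinstance(fasta_source, (str, Path)):
        records = list(SeqIO.parse(str(fasta_source), "fasta"))
    else:
        records = list(SeqIO.parse(fasta_source, "fasta"))
    if not records:
        raise ValueError("FASTA source contains no records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"FASTA source contains duplicate ids: {sorted(ids)}")
    if record_id is None:
        if len(records) > 1:
            raise ValueError(
                f"FASTA source contains {len(records)} records ({ids}); "
                "pass record_id to select one"
            )
        record = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"no record with id {record_id!r} (found {ids})")
        record = matches[0]
    return SubstrateSequence(id=record.id, residues=str(record.seq).upper())


def write_substrate(seq: SubstrateSequence, fasta_path, width: int = 60) -> None:
    """Write a substrate as single-record FASTA."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{seq.id}\n")
        for i in range(0, len(seq), width):
            fh.write(seq.residues[i : i + width] + "\n")


@dataclass(frozen=True)
class SwappedConstruct:
    """A segment-swapped substrate plus its coordinate map back to wild type.

    ``position_map`` has one row per residue of the construct with columns
    ``new_index`` (position in the construct) and ``wt_index`` (position of
    the same residue in the parent sequence); both 1-based.  Cleavage sites
    on the construct can be reported in wild-type coordinates through
    :meth:`to_wildtype`.
    """

    sequence: SubstrateSequence
    position_map: pd.DataFrame

    def to_wildtype(self, new_index: int) -> int:
        row = self.position_map.loc[self.position_map["new_index"] == new_index]
        if row.empty:
            raise KeyError(f"no construct position {new_index}")
        return int(row["wt_index"].iloc[0])

    def to_construct(self, wt_index: int) -> int:
        row = self.position_map.loc[self.position_map["wt_index"] == wt_index]
        if row.empty:
            raise KeyError(f"no wild-type position {wt_index}")
        return int(row["new_index"].iloc[0])

    def write(self, fasta_path, map_path) -> None:
        write_substrate(self.sequence, fasta_path)
        self.position_map.to_csv(map_path, sep="\t", index=False)


def build_swapped_construct(
    seq: SubstrateSequence,
    seg_a: tuple[int, int],
    seg_b: tuple[int, int],
    construct_id: str | None = None,
) -> SwappedConstruct:
    """Exchange two disjoint segments of a substrate.

    ``seg_a`` must lie before ``seg_b``.  The result is
    ``prefix + segB + middle + segA + suffix`` (a direct splice), with the
    residue multiset conserved.  The accompanying position map records where
    every construct residue sat in the parent so that cleavage sites on the
    two sequences can be compared on a common axis.
    """
    a1, a2 = seg_a
    b1, b2 = seg_b
    L = len(seq)
    for name, (s, e) in (("seg_a", seg_a), ("seg_b", seg_b)):
        if not (1 <= s <= e <= L):
            raise ValueError(f"{name} [{s}, {e}] outside [1, {L}]")
    if a2 >= b1:
        raise ValueError(
            f"segments must be disjoint with seg_a before seg_b; got "
            f"[{a1}, {a2}] and [{b1}, {b2}]"
        )
    wt_order = (
        list(range(1, a1))
        + list(range(b1, b2 + 1))
        + list(range(a2 + 1, b1))
        + list(range(a1, a2 + 1))
        + list(range(b2 + 1, L + 1))
    )
    residues = "".join(seq.residues[i - 1] for i in wt_order)
    new_id = construct_id or f"{seq.id}_swap{a1}-{a2}x{b1}-{b2}"
    position_map = pd.DataFrame(
        {"new_index": range(1, L + 1), "wt_index": wt_order}
    )
    return SwappedConstruct(
        sequence=SubstrateSequence(id=new_id, residues=residues),
        position_map=position_map,
    )


def tau_cn(core: tuple[int, int] = DEFAULT_CORE) -> SwappedConstruct:
    """The tau CN construct: C-terminal residues 391-441 exchanged with
    N-terminal residues 42-98, used to probe whether the protease resistance
    of the N-terminal half follows the sequence or its position."""
    return build_swapped_construct(tau_2n4r(core), (42, 98), (391, 441), "TAU_CN")
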