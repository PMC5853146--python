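"""IgG-Fc N-glycan structures, trait classes, and the CE-LIF peak assignment table.

Structures are written in modified Oxford nomenclature: ``F`` core fucose,
``Ax`` number of antennary GlcNAc, ``B`` bisecting GlcNAc, ``[3]G1``/``[6]G1``
a single galactose on the alpha-1,3 or alpha-1,6 mannose arm, ``G2`` full
digalactosylation, ``Sx`` number of sialic acids.  The galactosylation trait of
a biantennary structure is G0 (agalactosylated), G1 (monogalactosylated,
including sialylated monogalactosylated forms) or G2 (digalactosylated);
monoantennary structures fall outside the G0/G1/G2 scheme and are classed
``other``.

The reference table maps the 22 peaks resolved in an IgG-Fc electropherogram
to 29 glycan structures.  Where structures comigrate in one peak, the
dominant (first-listed) structure defines the peak's galactosylation type.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "GlycanStructure",
    "ReferencePeak",
    "ReferenceTable",
    "ReferenceTableError",
    "OxfordNameError",
    "parse_oxford_name",
    "classify_trait",
    "build_reference_table",
    "G0_STRUCTURES",
    "G1_STRUCTURES",
]


class OxfordNameError(ValueError):
    """Raised when a glycan name does not follow the modified Oxford grammar."""


class ReferenceTableError(ValueError):
    """Raised when a reference table violates its structural invariants."""


_OXFORD_RE = re.compile(
    r"^(?P<fuc>F)?"
    r"A(?P<ant>[0-9])"
    r"(?P<bis>B)?"
    r"(?:\[(?P<arm>[0-9])\]G(?P<gal1>[0-9])|G(?P<gal>[0-9]))?"
    r"(?:S(?P<sia>[0-9]))?$"
)


@dataclass(frozen=True, order=True)
class GlycanStructure:
    """One Fc N-glycan in modified Oxford nomenclature.

    Invariants: ``galactoses <= antennae``; ``sialic_acids <= galactoses``;
    the arm annotation is present exactly when ``galactoses == 1``.
    """

    core_fucose: bool
    antennae: int
    bisecting: bool
    galactoses: int
    gal_arm: Optional[int]  # 3 or 6 when exactly one galactose, else None
    sialic_acids: int

    def __post_init__(self) -> None:
        if self.antennae not in (1, 2):
            raise OxfordNameError(f"antennae must be 1 or 2, got A{self.antennae}")
        if not 0 <= self.galactoses <= 2:
            raise OxfordNameError(f"galactoses must be 0-2, got G{self.galactoses}")
        if self.galactoses > self.antennae:
            raise OxfordNameError(
                f"more galactoses (G{self.galactoses}) than antennae (A{self.antennae})"
            )
        if self.sialic_acids > self.galactoses:
            raise OxfordNameError(
                f"more sialic acids (S{self.sialic_acids}) than galactoses "
                f"(G{self.galactoses})"
            )
        if (self.galactoses == 1) != (self.gal_arm is not None):
            raise OxfordNameError("arm annotation [3]/[6] required iff exactly one galactose")
        if self.gal_arm is not None and self.gal_arm not in (3, 6):
            raise OxfordNameError(f"galactose arm must be [3] or [6], got [{self.gal_arm}]")

    @property
    def name(self) -> str:
        parts = []
        if self.core_fucose:
            parts.append("F")
        parts.append(f"A{self.antennae}")
        if self.bisecting:
            parts.append("B")
        if self.galactoses == 1:
            parts.append(f"[{self.gal_arm}]G1")
        elif self.galactoses == 2:
            parts.append("G2")
        if self.sialic_acids:
            parts.append(f"S{self.sialic_acids}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.name


def parse_oxford_name(name: str) -> GlycanStructure:
    """Parse a modified Oxford glycan name, e.g. ``FA2B[6]G1S1``.

    The accepted grammar is ``F? A{1,2} B? ([3|6]G1 | G2)? S{1,2}?``.
    Formatting the result reproduces the input exactly.
    """
    if not isinstance(name, str) or not name:
        raise OxfordNameError("empty glycan name")
    m = _OXFORD_RE.match(name.strip())
    if m is None:
        # locate the first offending token for a useful message
        tail = re.sub(r"^F?A[12]B?", "", name.strip())
        raise OxfordNameError(f"malformed Oxford name {name!r}: unparsable token {tail or name!r}")
    gal = 0
    arm: Optional[int] = None
    if m.group("gal1") is not None:
        gal = int(m.group("gal1"))
        if gal != 1:
            raise OxfordNameError(
                f"malformed Oxford name {name!r}: arm annotation requires G1, got G{gal}"
            )
        arm = int(m.group("arm"))
    elif m.group("gal") is not None:
        gal = int(m.group("gal"))
        if gal == 1:
            raise OxfordNameError(
                f"malformed Oxford name {name!r}: G1 requires an arm annotation [3] or [6]"
            )
    sia = int(m.group("sia")) if m.group("sia") else 0
    return GlycanStructure(
        core_fucose=m.group("fuc") is not None,
        antennae=int(m.group("ant")),
        bisecting=m.group("bis") is not None,
        galactoses=gal,
        gal_arm=arm,
        sialic_acids=sia,
    )


def classify_trait(structure: GlycanStructure) -> str:
    """Galactosylation class of a structure: ``G0``, ``G1``, ``G2`` or ``other``.

    Biantennary structures are classed by galactose count; sialylation does not
    change the class (monogalactosylated S1 forms are G1).  Monoantennary
    structures are ``other``.
    """
    if structure.antennae != 2:
        return "other"
    return {0: "G0", 1: "G1", 2: "G2"}[structure.galactoses]


# Trait membership as quantified from the electropherogram:
#   G0 = A2 + A2B + FA2 + FA2B
#   G1 = A2[3]G1 + A2B[3]G1 + FA2[6]G1 + FA2[3]G1 + FA2B[6]G1 + FA2B[3]G1
#      + A2[3]G1S1 + FA2[6]G1S1 + A2B[3]G1S1 + FA2[3]G1S1
G0_STRUCTURES = frozenset({"A2", "A2B", "FA2", "FA2B"})
G1_STRUCTURES = frozenset(
    {
        "A2[3]G1",
        "A2B[3]G1",
        "FA2[6]G1",
        "FA2[3]G1",
        "FA2B[6]G1",
        "FA2B[3]G1",
        "A2[3]G1S1",
        "FA2[6]G1S1",
        "A2B[3]G1S1",
        "FA2[3]G1S1",
    }
)


@dataclass(frozen=True)
class ReferencePeak:
    """One annotated electropherogram peak: position in glucose units plus the
    comigrating structures, dominant first."""

    peak_id: int
    gu_position: float
    structures: tuple[GlycanStructure, ...]

    @property
    def dominant(self) -> GlycanStructure:
        return self.structures[0]

    @property
    def trait_class(self) -> str:
        return classify_trait(self.dominant)


# Default peak layout: 22 peaks, 29 structures (7 comigration pairs).  GU
# positions are package defaults chosen in the 4-12 range typical for APTS
# biantennary IgG glycans; sialylated species migrate earliest under reversed
# polarity, followed by neutral structures in order of size.
_DEFAULT_PEAKS: tuple[tuple[float, tuple[str, ...]], ...] = (
    (4.30, ("A2G2S2", "A2BG2S2")),
    (4.70, ("FA2G2S2", "FA2BG2S2")),
    (5.10, ("A2G2S1", "A2BG2S1")),
    (5.50, ("FA2G2S1", "FA2BG2S1")),
    (5.90, ("A2[3]G1S1",)),
    (6.20, ("FA2[6]G1S1",)),
    (6.50, ("A2B[3]G1S1",)),
    (6.80, ("FA2[3]G1S1",)),
    (7.10, ("A1",)),
    (7.40, ("FA1", "A1B")),
    (7.70, ("A2",)),
    (8.00, ("FA2",)),
    (8.30, ("A2B",)),
    (8.60, ("FA2B",)),
    (8.95, ("A2[3]G1",)),
    (9.30, ("A2B[3]G1",)),
    (9.65, ("FA2[6]G1",)),
    (10.00, ("FA2[3]G1",)),
    (10.35, ("FA2B[6]G1",)),
    (10.70, ("FA2B[3]G1",)),
    (11.05, ("A2G2", "A2BG2")),
    (11.40, ("FA2G2", "FA2BG2")),
)

DEFAULT_GU_TOLERANCE = 0.1
_EXPECTED_N_PEAKS = 22
_EXPECTED_N_STRUCTURES = 29


@dataclass(frozen=True)
class ReferenceTable:
    """The peak <-> structure assignment used for annotation and traits."""

    peaks: tuple[ReferencePeak, ...]
    gu_tolerance: float = DEFAULT_GU_TOLERANCE

    def __post_init__(self) -> None:
        problems = self.validate()
        if problems:
            raise ReferenceTableError(
                "invalid reference table:\n  - " + "\n  - ".join(problems)
            )

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.gu_tolerance <= 0:
            problems.append(f"gu_tolerance must be positive, got {self.gu_tolerance}")
        ids = [p.peak_id for p in self.peaks]
        if ids != list(range(1, len(self.peaks) + 1)):
            problems.append("peak_ids must be 1..n in elution order")
        gus = [p.gu_position for p in self.peaks]
        for a, b in zip(self.peaks, self.peaks[1:]):
            if not b.gu_position > a.gu_position:
                problems.append(
                    f"gu_positions not strictly increasing at peaks "
                    f"{a.peak_id}/{b.peak_id} ({a.gu_position} vs {b.gu_position})"
                )
        if gus and self.gu_tolerance > 0:
            for a, b in zip(self.peaks, self.peaks[1:]):
                if b.gu_position - a.gu_position <= 2 * self.gu_tolerance:
                    problems.append(
                        f"peaks {a.peak_id} and {b.peak_id} closer than 2x gu_tolerance"
                    )
        names = [s.name for p in self.peaks for s in p.structures]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            problems.append(f"duplicate structures across peaks: {', '.join(dupes)}")
        for p in self.peaks:
            if not p.structures:
                problems.append(f"peak {p.peak_id} lists no structures")
        return problems

    @property
    def n_structures(self) -> int:
        return len({s.name for p in self.peaks for s in p.structures})

    def structures(self) -> list[GlycanStructure]:
        return [s for p in self.peaks for s in p.structures]

    def peak(self, peak_id: int) -> ReferencePeak:
        return self.peaks[peak_id - 1]

    def trait_class_of(self, peak_id: int) -> str:
        return self.peak(peak_id).trait_class

    def peak_ids_by_class(self, trait_class: str) -> list[int]:
        return [p.peak_id for p in self.peaks if p.trait_class == trait_class]

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path_or_buf) -> None:
        """Serialize as CSV: peak_id, gu_position, structures (semicolon
        separated, dominant first), trait_class."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "peak_id": [p.peak_id for p in self.peaks],
                "gu_position": [p.gu_position for p in self.peaks],
                "structures": [";".join(s.name for s in p.structures) for p in self.peaks],
                "trait_class": [p.trait_class for p in self.peaks],
            }
        )
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, gu_tolerance: float = DEFAULT_GU_TOLERANCE) -> "ReferenceTable":
        import pandas as pd

        df = pd.read_csv(path_or_buf)
        peaks = tuple(
            ReferencePeak(
                peak_id=int(row.peak_id),
                gu_position=float(row.gu_position),
                structures=tuple(parse_oxford_name(n) for n in str(row.structures).split(";")),
            )
            for row in df.itertuples()
        )
        return cls(peaks=peaks, gu_tolerance=gu_tolerance)


def build_reference_table(
    override: Optional[Sequence[tuple[float, Sequence[str]]]] = None,
    gu_tolerance: float = DEFAULT_GU_TOLERANCE,
) -> ReferenceTable:
    """Build the default 22-peak / 29-structure reference table.

    ``override``, when given, is a sequence of ``(gu_position, structure
    names)`` pairs in elution order and replaces the default layout; it must
    satisfy all :class:`ReferenceTable` invariants.  The default table's G0 and
    G1 member sets are exactly the four agalactosylated and ten
    monogalactosylated structures that define the G0/G1 ratio.
    """
    layout = tuple(override) if override is not None else _DEFAULT_PEAKS
    peaks = tuple(
        ReferencePeak(
            peak_id=i + 1,
            gu_position=float(gu),
            structures=tuple(parse_oxford_name(n) for n in names),
        )
        for i, (gu, names) in enumerate(layout)
    )
    table = ReferenceTable(peaks=peaks, gu_tolerance=gu_tolerance)
    if override is None:
        # the shipped default must describe the published assignment exactly
        assert len(table.peaks) == _EXPECTED_N_PEAKS
        assert table.n_structures == _EXPECTED_N_STRUCTURES
    return table
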