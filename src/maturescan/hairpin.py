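"""Pre-miRNA hairpin representation and two-arm alignment.

A pre-miRNA is a single-stem-loop RNA: two arms that base-pair into a stem,
closed by an unpaired terminal loop.  Downstream feature extraction needs the
two arms laid out column-by-column — paired bases opposite each other,
bulged/unpaired bases opposite an explicit gap — so this module parses a
dot-bracket string into that gapped two-row alignment.

Coordinates are 0-based half-open internally; user-facing I/O converts to
1-based inclusive (miRBase convention) in :mod:`maturescan.io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple

import RNA

GAP = "-"
_VALID_BASES = frozenset("ACGU")

#: Folding engine identifier recorded in model metadata: MFE dot-brackets
#: (and hence every structural feature) can differ across engine versions.
ENGINE_VERSION = f"ViennaRNA-{RNA.__version__}"


class HairpinError(ValueError):
    """Invalid sequence, structure, or hairpin topology."""


def normalize_sequence(sequence: str) -> str:
    """Uppercase, map T->U, and validate the alphabet.

    IUPAC ambiguity codes are rejected rather than guessed at: a scanner fed
    an ``N`` would silently produce meaningless structure features.
    """
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise HairpinError(
            f"invalid characters after T->U normalization: {sorted(bad)}"
        )
    return seq


@dataclass
class PreMiRNA:
    """A precursor miRNA record: sequence plus optional secondary structure."""

    id: str
    sequence: str
    structure: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise HairpinError(f"{self.id}: empty sequence")
        self.sequence = normalize_sequence(self.sequence)
        if self.structure is not None:
            if len(self.structure) != len(self.sequence):
                raise HairpinError(
                    f"{self.id}: structure length {len(self.structure)} != "
                    f"sequence length {len(self.sequence)}"
                )
            pair_table(self.structure)  # raises on unbalanced brackets


def fold(premirna: PreMiRNA, temperature: float = 37.0) -> tuple[PreMiRNA, float]:
    """Predict the MFE secondary structure and fill it into the record.

    Returns a new :class:`PreMiRNA` with ``structure`` set, plus the minimum
    free energy in kcal/mol.  Uses the thermodynamic nearest-neighbour model
    at the given temperature (default 37 degC, the engine default).
    """
    md = RNA.md()
    md.temperature = temperature
    fc = RNA.fold_compound(premirna.sequence, md)
    structure, mfe = fc.mfe()
    return PreMiRNA(premirna.id, premirna.sequence, structure), float(mfe)


def pair_table(structure: str) -> list[int | None]:
    """Map each position to its pairing partner (``None`` if unpaired)."""
    pairs: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise HairpinError("unbalanced dot-bracket: unmatched ')'")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif ch != ".":
            raise HairpinError(f"unsupported dot-bracket character {ch!r}")
    if stack:
        raise HairpinError("unbalanced dot-bracket: unmatched '('")
    return pairs


def validate_single_stem(premirna: PreMiRNA) -> bool:
    """True iff the structure folds into exactly one hairpin loop.

    A hairpin loop shows up in dot-bracket as a ``(`` followed — across
    unpaired positions only — by a ``)``.  Exactly one such innermost loop
    means a single stem; zero means no stem at all; more means a
    multi-branched structure this method does not handle.
    """
    if premirna.structure is None:
        raise HairpinError(f"{premirna.id}: structure absent")
    return len(re.findall(r"\(\.*\)", premirna.structure)) == 1


class AlignmentColumn(NamedTuple):
    """One column of the two-arm alignment.

    ``five``/``three`` hold a base or :data:`GAP`; the indices point back
    into the precursor sequence (``None`` on the gap side).
    """

    five: str
    three: str
    five_index: int | None
    three_index: int | None
    paired: bool


@dataclass
class HairpinAlignment:
    """Gapped two-row alignment of the hairpin arms, basal end -> loop.

    ``loop_span`` is the half-open interval of terminal-loop nucleotides;
    ``arm5_span``/``arm3_span`` cover everything 5' respectively 3' of it
    (including unpaired basal segments and overhangs).
    """

    columns: list[AlignmentColumn]
    loop_span: tuple[int, int]
    arm5_span: tuple[int, int]
    arm3_span: tuple[int, int]
    sequence: str
    structure: str
    _col_of_five: dict[int, int] = field(default_factory=dict, repr=False)
    _col_of_three: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._col_of_five:
            for c, col in enumerate(self.columns):
                if col.five_index is not None:
                    self._col_of_five[col.five_index] = c
                if col.three_index is not None:
                    self._col_of_three[col.three_index] = c

    def column_of(self, seq_index: int, arm: str) -> int:
        """Column index holding the given sequence position on ``arm``."""
        table = self._col_of_five if arm == "5p" else self._col_of_three
        try:
            return table[seq_index]
        except KeyError:
            raise HairpinError(
                f"position {seq_index} is not on the {arm} arm"
            ) from None

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def align_arms(premirna: PreMiRNA) -> HairpinAlignment:
    """Build the gapped two-arm alignment by a two-pointer walk.

    Walks inward from both sequence ends: mutually paired positions become a
    paired column; an unpaired position becomes a one-sided column with a gap
    opposite.  When both sides are unpaired (internal loop), all 5'-side
    columns are emitted before the 3'-side ones — the choice is arbitrary but
    must be fixed for features to be deterministic.
    """
    if premirna.structure is None:
        raise HairpinError(f"{premirna.id}: structure absent, fold first")
    if not validate_single_stem(premirna):
        raise HairpinError(
            f"{premirna.id}: not a single-stem hairpin (rejected, not handled)"
        )
    seq, struct = premirna.sequence, premirna.structure
    pairs = pair_table(struct)

    innermost_open = max(i for i, ch in enumerate(struct) if ch == "(")
    loop_start = innermost_open + 1
    loop_end = pairs[innermost_open]
    assert loop_end is not None

    columns: list[AlignmentColumn] = []
    i, j = 0, len(seq) - 1
    while i < loop_start or j >= loop_end:
        i_live = i < loop_start
        j_live = j >= loop_end
        if i_live and j_live and pairs[i] == j:
            columns.append(AlignmentColumn(seq[i], seq[j], i, j, True))
            i += 1
            j -= 1
        elif i_live and pairs[i] is None:
            columns.append(AlignmentColumn(seq[i], GAP, i, None, False))
            i += 1
        elif j_live and pairs[j] is None:
            columns.append(AlignmentColumn(GAP, seq[j], None, j, False))
            j -= 1
        else:  # crossing pairs cannot occur in a nested single stem
            raise HairpinError(f"{premirna.id}: non-nested pairing at {i},{j}")

    return HairpinAlignment(
        columns=columns,
        loop_span=(loop_start, loop_end),
        arm5_span=(0, loop_start),
        arm3_span=(loop_end, len(seq)),
        sequence=seq,
        structure=struct,
    )
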