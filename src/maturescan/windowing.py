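"""Duplex-window construction and candidate enumeration.

The candidate unit of this method is the *duplex window*: the region of the
two-arm alignment holding a putative mature miRNA together with its star
strand.  For a putative mature start on the 5' arm, the window begins two
alignment columns basal of the start column (mimicking the 2-nt offset the
Drosha cut leaves between the lower stem and the duplex) and spans
``mature_len`` columns of the mature itself.

Boundary effects give four scenarios:

S1
    The window would begin before the precursor does; the absent upstream
    positions become virtual "missing" slots.
S2
    The window's last column carries a gap on the 5' side (a 3'-arm bulge);
    the end slides loop-ward to the next 5'-side nucleotide.
S3
    The window's first column carries a 5'-side gap; the start slides
    loop-ward to the next 5'-side nucleotide and the end is re-anchored so
    the window holds ``mature_len`` 5'-arm nucleotides counted from the
    pre-shift column.
S4
    Standard case: both boundary columns carry 5'-side nucleotides.

Window boundaries therefore never sit on a 5'-side gap.  When several
conditions co-occur the precedence is S3 > S2 > S1 (a window may still
receive virtual padding while tagged S2).
"""

from __future__ import annotations

from dataclasses import dataclass

from .hairpin import GAP, AlignmentColumn, HairpinAlignment

DEFAULT_MATURE_LEN = 22

SCENARIO_TRUNCATED = "S1"
SCENARIO_END_GAP = "S2"
SCENARIO_START_GAP = "S3"
SCENARIO_STANDARD = "S4"


class WindowError(ValueError):
    """Requested window does not fit on the hairpin."""


@dataclass(frozen=True)
class DuplexWindow:
    """A candidate duplex region on the arm alignment.

    ``mature_start`` is the 0-based sequence index of the putative mature
    start on ``arm``.  ``col_span`` is the half-open column interval of the
    real (non-virtual) window columns; ``n_virtual`` counts leading missing
    slots prepended when the window underflows the precursor start.
    """

    arm: str
    mature_start: int
    mature_len: int
    scenario: str
    col_span: tuple[int, int]
    n_virtual: int = 0

    def columns(self, alignment: HairpinAlignment) -> list[AlignmentColumn]:
        return alignment.columns[self.col_span[0] : self.col_span[1]]

    def first_five_index(self, alignment: HairpinAlignment) -> int | None:
        """Sequence index of the window's first 5'-arm nucleotide."""
        for col in self.columns(alignment):
            if col.five_index is not None:
                return col.five_index
        return None

    def nucleotide_count(self, alignment: HairpinAlignment) -> int:
        """Total bases (both rows, gaps excluded) inside the window."""
        return sum(
            (col.five != GAP) + (col.three != GAP)
            for col in self.columns(alignment)
        )


def _next_five_nucleotide(alignment: HairpinAlignment, col: int) -> int:
    """First column index >= ``col`` whose 5' side is a nucleotide."""
    for c in range(col, alignment.n_columns):
        if alignment.columns[c].five != GAP:
            return c
    raise WindowError("no 5'-arm nucleotide before the terminal loop")


def _anchor_column(
    alignment: HairpinAlignment, mature_start: int, arm: str, mature_len: int
) -> int:
    """Column anchoring the window: the mature-start column on the 5' arm.

    A 3'-arm mature written 5'->3' runs loop->basal, so its basal-most
    nucleotide (``start + mature_len - 1``) sits opposite the position that
    plays the role of the mature start in 5'-arm geometry; the same column
    rules then apply unchanged.
    """
    if arm == "5p":
        lo, hi = alignment.arm5_span
        if not lo <= mature_start < hi:
            raise WindowError(f"start {mature_start} not on the 5' arm")
        return alignment.column_of(mature_start, "5p")
    if arm == "3p":
        lo, hi = alignment.arm3_span
        basal_end = mature_start + mature_len - 1
        if not (lo <= mature_start and basal_end < hi):
            raise WindowError(
                f"mature [{mature_start}, {basal_end}] not on the 3' arm"
            )
        return alignment.column_of(basal_end, "3p")
    raise ValueError(f"arm must be '5p' or '3p', got {arm!r}")


def build_window(
    alignment: HairpinAlignment,
    mature_start: int,
    arm: str = "5p",
    mature_len: int = DEFAULT_MATURE_LEN,
) -> DuplexWindow:
    """Construct the duplex window for one putative mature start.

    Raises :class:`WindowError` when the mature would overrun the terminal
    loop or fall off the arm.
    """
    anchor = _anchor_column(alignment, mature_start, arm, mature_len)
    end_col = anchor + mature_len - 1
    if end_col >= alignment.n_columns:
        raise WindowError(
            f"mature at {mature_start} ({arm}) overlaps the terminal loop"
        )
    start_col = anchor - 2
    n_virtual = 0

    if start_col >= 0 and alignment.columns[start_col].five == GAP:
        scenario = SCENARIO_START_GAP
        pre_shift = start_col
        start_col = _next_five_nucleotide(alignment, pre_shift + 1)
        # re-anchor the end: mature_len 5'-arm nucleotides counted from the
        # pre-shift column (the gap column itself contributes none)
        seen = 0
        end_col = -1
        for c in range(pre_shift, alignment.n_columns):
            if alignment.columns[c].five != GAP:
                seen += 1
                if seen == mature_len:
                    end_col = c
                    break
        if end_col < 0:
            raise WindowError(
                f"mature at {mature_start} ({arm}) overlaps the terminal loop"
            )
    elif alignment.columns[end_col].five == GAP:
        scenario = SCENARIO_END_GAP
        end_col = _next_five_nucleotide(alignment, end_col + 1)
        if start_col < 0:
            n_virtual, start_col = -start_col, 0
    elif start_col < 0:
        scenario = SCENARIO_TRUNCATED
        n_virtual, start_col = -start_col, 0
    else:
        scenario = SCENARIO_STANDARD

    return DuplexWindow(
        arm=arm,
        mature_start=mature_start,
        mature_len=mature_len,
        scenario=scenario,
        col_span=(start_col, end_col + 1),
        n_virtual=n_virtual,
    )


@dataclass
class CandidateSet:
    """All duplex windows enumerable on one precursor.

    ``positive_index`` (training only) points at the window built from the
    annotated mature start.
    """

    premirna_id: str
    candidates: list[DuplexWindow]
    positive_index: int | None = None

    def index_of(self, arm: str, mature_start: int) -> int | None:
        for k, w in enumerate(self.candidates):
            if w.arm == arm and w.mature_start == mature_start:
                return k
        return None


def enumerate_candidates(
    alignment: HairpinAlignment,
    premirna_id: str = "",
    mature_len: int = DEFAULT_MATURE_LEN,
) -> CandidateSet:
    """Every arm position at which a duplex window can be built.

    Order is deterministic: 5' arm basal->loop, then 3' arm 5'->3'.  Every
    other putative position besides an annotated mature start serves as a
    negative example during training.
    """
    candidates: list[DuplexWindow] = []
    for arm, (lo, hi) in (("5p", alignment.arm5_span), ("3p", alignment.arm3_span)):
        for start in range(lo, hi):
            try:
                candidates.append(
                    build_window(alignment, start, arm=arm, mature_len=mature_len)
                )
            except WindowError:
                continue
    return CandidateSet(premirna_id=premirna_id, candidates=candidates)
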