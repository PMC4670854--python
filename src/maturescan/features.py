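"""The 94-dimensional feature vector describing one duplex window.

Layout (fixed; recorded in model metadata as :data:`FEATURE_LAYOUT_VERSION`):

==========  ====================================================================
slots       content
==========  ====================================================================
1-60        duplex-window nucleotide states, interleaved (5', 3') per
            alignment column, basal -> loop, up to 30 columns; unused
            slots 0
61-78       lower-stem states: the 9 columns immediately basal of the
            window, nearest-first
79-84       downstream states: the 3 columns immediately loop-ward of the
            window end
85-93       MFE1..MFE9 (kcal/mol)
94          distance (nt) from the window's first 5'-arm nucleotide to the
            terminal loop
==========  ====================================================================

Each nucleotide state is a single integer: 1-4 = A/C/G/U paired ("Ap"..),
5-8 = A/C/G/U unpaired ("A-" ..), 9 = alignment gap, 0 = slot beyond the
available data (virtual S1 slots, padding, or off-precursor flanks).

MFE1-5 are duplex cofolding energies of the window's two arm segments with
basal extensions of 0/3/5/9 columns (MFE2-4 probe the lower stem above the
Drosha site, whose stability profile positions the cut) and a 3-column
loop-ward extension (MFE5).  MFE6-9 are the differences
MFE2-MFE1, MFE3-MFE2, MFE4-MFE3, MFE5-MFE1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import RNA

from .hairpin import GAP, AlignmentColumn, HairpinAlignment
from .windowing import DuplexWindow

logger = logging.getLogger(__name__)

N_FEATURES = 94
N_WINDOW_SLOTS = 60
N_LOWER_STEM_SLOTS = 18
N_DOWNSTREAM_SLOTS = 6
N_MFE_FEATURES = 9
N_DISTANCE_FEATURES = 1

MAX_WINDOW_COLUMNS = N_WINDOW_SLOTS // 2
LOWER_STEM_COLUMNS = N_LOWER_STEM_SLOTS // 2
DOWNSTREAM_COLUMNS = N_DOWNSTREAM_SLOTS // 2

FEATURE_LAYOUT_VERSION = "maturescan-94-v1"

STATE_MISSING = 0
STATE_GAP = 9
_PAIRED_CODE = {"A": 1, "C": 2, "G": 3, "U": 4}
_UNPAIRED_CODE = {"A": 5, "C": 6, "G": 7, "U": 8}


def column_states(col: AlignmentColumn) -> tuple[int, int]:
    """State codes (5' side, 3' side) for one alignment column."""

    def side(base: str) -> int:
        if base == GAP:
            return STATE_GAP
        return _PAIRED_CODE[base] if col.paired else _UNPAIRED_CODE[base]

    return side(col.five), side(col.three)


def encode_window_states(
    window: DuplexWindow, alignment: HairpinAlignment
) -> np.ndarray:
    """Slots 1-60: interleaved per-column states of the duplex window.

    Virtual (S1) slots encode as 0.  Windows longer than 30 columns are
    truncated loop-ward so the Drosha-side geometry stays intact.
    """
    codes: list[int] = [STATE_MISSING, STATE_MISSING] * window.n_virtual
    for col in window.columns(alignment):
        codes.extend(column_states(col))
    codes = codes[:N_WINDOW_SLOTS]
    codes += [STATE_MISSING] * (N_WINDOW_SLOTS - len(codes))
    return np.asarray(codes, dtype=float)


def encode_flanks(
    window: DuplexWindow, alignment: HairpinAlignment
) -> tuple[np.ndarray, np.ndarray]:
    """Lower-stem (18) and downstream (6) flank state codes.

    Lower stem: the 9 columns immediately basal of the window start,
    nearest-first; downstream: the 3 columns past the window end toward the
    loop.  Columns falling off the precursor (or into the loop) pad as 0.
    """
    start_col, end_stop = window.col_span

    def states_at(c: int) -> tuple[int, int]:
        if 0 <= c < alignment.n_columns:
            return column_states(alignment.columns[c])
        return STATE_MISSING, STATE_MISSING

    lower: list[int] = []
    for k in range(1, LOWER_STEM_COLUMNS + 1):
        lower.extend(states_at(start_col - k))
    down: list[int] = []
    for k in range(DOWNSTREAM_COLUMNS):
        down.extend(states_at(end_stop + k))
    return np.asarray(lower, dtype=float), np.asarray(down, dtype=float)


def duplex_energy(segment5: str, segment3: str) -> float:
    """Cofolding MFE (kcal/mol) of two strand segments, 0 if either is empty.

    Segments are given 5'->3'; a fully unpairable pair of strands has
    energy 0 (no duplex forms).
    """
    if not segment5 or not segment3:
        return 0.0
    _, energy = RNA.cofold(f"{segment5}&{segment3}")
    return float(energy)


@dataclass(frozen=True)
class MfeProfile:
    """MFE1..MFE9 for one duplex window (kcal/mol)."""

    mfe1: float
    mfe2: float
    mfe3: float
    mfe4: float
    mfe5: float

    @property
    def mfe6(self) -> float:
        return self.mfe2 - self.mfe1

    @property
    def mfe7(self) -> float:
        return self.mfe3 - self.mfe2

    @property
    def mfe8(self) -> float:
        return self.mfe4 - self.mfe3

    @property
    def mfe9(self) -> float:
        return self.mfe5 - self.mfe1

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.mfe1, self.mfe2, self.mfe3, self.mfe4, self.mfe5,
                self.mfe6, self.mfe7, self.mfe8, self.mfe9,
            ]
        )


def _region_energy(alignment: HairpinAlignment, c0: int, c1: int) -> float:
    """Cofold the 5'- and 3'-arm segments spanned by columns [c0, c1]."""
    c0 = max(c0, 0)
    c1 = min(c1, alignment.n_columns - 1)
    if c0 > c1:
        logger.warning("empty MFE region after clipping; energy set to 0")
        return 0.0
    cols = alignment.columns[c0 : c1 + 1]
    seg5 = "".join(c.five for c in cols if c.five != GAP)
    # the 3' strand read 5'->3' runs loop -> basal end
    seg3 = "".join(c.three for c in reversed(cols) if c.three != GAP)
    if not seg5 or not seg3:
        logger.warning("one-sided MFE region (all gaps); energy set to 0")
    return duplex_energy(seg5, seg3)


def mfe_profile(window: DuplexWindow, alignment: HairpinAlignment) -> MfeProfile:
    """Free-energy profile of the window and its basal/loop-ward extensions."""
    start_col, end_stop = window.col_span
    end_col = end_stop - 1
    return MfeProfile(
        mfe1=_region_energy(alignment, start_col, end_col),
        mfe2=_region_energy(alignment, start_col - 3, end_col),
        mfe3=_region_energy(alignment, start_col - 5, end_col),
        mfe4=_region_energy(alignment, start_col - 9, end_col),
        mfe5=_region_energy(alignment, start_col, end_col + 3),
    )


def loop_distance(window: DuplexWindow, alignment: HairpinAlignment) -> int:
    """5'-arm nucleotides from the window start to the terminal loop.

    Half-open count over sequence positions ``[first window 5' nt,
    loop start)``; invariant to basal-segment length.
    """
    first = window.first_five_index(alignment)
    if first is None:
        return 0
    return alignment.loop_span[0] - first


def extract(window: DuplexWindow, alignment: HairpinAlignment) -> np.ndarray:
    """The full 94-feature vector for one candidate window."""
    lower, down = encode_flanks(window, alignment)
    vec = np.concatenate(
        [
            encode_window_states(window, alignment),
            lower,
            down,
            mfe_profile(window, alignment).as_array(),
            [float(loop_distance(window, alignment))],
        ]
    )
    assert vec.shape == (N_FEATURES,)
    return vec
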