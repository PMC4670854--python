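"""Synthetic single-stem-loop precursors with planted mature positions.

Emulates the geometry of animal pre-miRNAs — a mostly paired stem with
occasional mismatches and one-sided bulges, an unpaired terminal loop, a
basal segment, and a 2-nt 3' overhang — with a known, planted mature miRNA
so the whole scanning pipeline can be exercised against ground truth.

The planted rule places the mature start a fixed number of nucleotides
upstream of the terminal loop (default 24, putting the mature 3' end 2 nt
short of the loop — the canonical geometry of a Dicer cut) with small,
mostly-zero positional noise.  Because processing enzymes recognize local
sequence/structure, the planted site also carries determinants of the kind
real biogenesis leaves behind: a 5'-U at the mature start (the base AGO
loading favours), a well-paired duplex with a single central mismatch, and
a paired 2-nt shift region basal of the start.  Position alone is
deliberately insufficient to recover the site exactly — like the real task,
the benchmark requires the position-specific state features.

Structures are emitted as-built (the known pairing) rather than refolded,
so structural features are fully controlled; ``refold=True`` stress-tests
the folding path instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hairpin import PreMiRNA, align_arms, fold
from .windowing import DEFAULT_MATURE_LEN

_BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True)
class AnnotationRecord:
    """An annotated mature miRNA on a precursor (0-based half-open span)."""

    premirna_id: str
    mature_id: str
    start: int
    end: int
    arm: str


@dataclass
class SynthSpec:
    """Parameters of the synthetic precursor population.

    ``arm_len`` is the 5'-arm stem length in nucleotides (excluding the
    basal segment); ``bulge_rate``/``mismatch_rate`` are per-column
    probabilities; ``basal_overhang`` bounds the unpaired basal segment,
    with a 2-nt 3' overhang always added on top.  ``loop_distance_target``
    and ``start_noise`` define the planted rule: mature start =
    (loop start - target) + noise, noise drawn from ``start_noise`` (offset
    -> probability).
    """

    n_precursors: int = 200
    arm_len: tuple[int, int] = (30, 50)
    loop_len: tuple[int, int] = (4, 12)
    bulge_rate: float = 0.05
    mismatch_rate: float = 0.08
    basal_overhang: tuple[int, int] = (0, 8)
    loop_distance_target: int = 24
    start_noise: dict[int, float] = field(
        default_factory=lambda: {-1: 0.15, 0: 0.70, 1: 0.15}
    )
    mature_len: int = DEFAULT_MATURE_LEN
    plant_arms: tuple[str, ...] = ("5p", "3p")
    plant_site_determinants: bool = True
    refold: bool = False
    seed: int = 0

    def validate(self) -> None:
        lo = min(self.arm_len)
        if self.mature_len > lo:
            raise ValueError("mature_len exceeds the minimum arm length")
        if self.loop_distance_target < self.mature_len:
            raise ValueError(
                "loop_distance_target < mature_len: the mature would overlap "
                "the terminal loop"
            )
        if self.loop_distance_target + 1 > lo:
            raise ValueError("arms too short for the planted loop distance")
        for r in (self.bulge_rate, self.mismatch_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if abs(sum(self.start_noise.values()) - 1.0) > 1e-9:
            raise ValueError("start_noise probabilities must sum to 1")


@dataclass(frozen=True)
class StemColumnCounts:
    """Per-record tally of background stem columns (outside the planted
    duplex) by kind, for checking corruption-rate convergence."""

    background: int
    bulge: int
    mismatch: int


@dataclass
class SyntheticDataset:
    records: list[PreMiRNA]
    annotations: list[AnnotationRecord]
    column_counts: list[StemColumnCounts] = None


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n else ""


def _mismatch_base(rng: np.random.Generator, base: str) -> str:
    """A 3'-side base that neither Watson-Crick- nor wobble-pairs ``base``."""
    wobble = {"G": "U", "U": "G"}
    banned = {_COMPLEMENT[base], wobble.get(base, "")}
    choices = [b for b in "ACGU" if b not in banned]
    return choices[rng.integers(len(choices))]


def _build_one(
    spec: SynthSpec, rng: np.random.Generator, name: str
) -> tuple[PreMiRNA, AnnotationRecord, StemColumnCounts]:
    stem5_target = int(rng.integers(spec.arm_len[0], spec.arm_len[1] + 1))
    loop_len = int(rng.integers(spec.loop_len[0], spec.loop_len[1] + 1))
    u5 = int(rng.integers(spec.basal_overhang[0], spec.basal_overhang[1] + 1))
    u3 = u5 + 2  # 2-nt 3' overhang, as in Drosha products

    # planted position: mature start on the 5' arm, a fixed distance
    # upstream of the loop plus small noise
    loop_start = u5 + stem5_target
    offsets = sorted(spec.start_noise)
    probs = [spec.start_noise[o] for o in offsets]
    noise = int(rng.choice(offsets, p=probs))
    start5 = loop_start - spec.loop_distance_target + noise

    # site determinants (see module docstring): the duplex spanning the
    # planted mature is well-paired, starts with a U, and carries one
    # mismatch mid-duplex; the shift region just basal of it is paired
    duplex_lo, duplex_hi = start5 - 2, start5 + spec.mature_len
    mismatch_at = start5 + (10 if spec.mature_len > 12 else spec.mature_len // 2)

    # stem columns, basal -> loop; each holds (5' char, 3' char, paired)
    cols: list[tuple[str, str, bool]] = []
    in_duplex: list[bool] = []
    n5 = 0
    while n5 < stem5_target:
        idx = u5 + n5  # 5'-arm sequence index about to be placed
        in_site = spec.plant_site_determinants and duplex_lo <= idx < duplex_hi
        in_duplex.append(in_site)
        if in_site:
            if idx == mismatch_at:
                base = str(rng.choice(_BASES))
                cols.append((base, _mismatch_base(rng, base), False))
            else:
                base = "U" if idx == start5 else str(rng.choice(_BASES))
                cols.append((base, _COMPLEMENT[base], True))
            n5 += 1
            continue
        r = rng.random()
        if r < spec.bulge_rate:
            base = str(rng.choice(_BASES))
            if rng.random() < 0.5:
                cols.append((base, "-", False))
                n5 += 1
            else:
                cols.append(("-", base, False))
        elif r < spec.bulge_rate + spec.mismatch_rate:
            base = str(rng.choice(_BASES))
            cols.append((base, _mismatch_base(rng, base), False))
            n5 += 1
        else:
            base = str(rng.choice(_BASES))
            cols.append((base, _COMPLEMENT[base], True))
            n5 += 1

    prefix5 = _random_seq(rng, u5)
    loop_seq = _random_seq(rng, loop_len)
    suffix3 = _random_seq(rng, u3)

    arm5 = "".join(c[0] for c in cols if c[0] != "-")
    arm3 = "".join(c[1] for c in reversed(cols) if c[1] != "-")

    sequence = prefix5 + arm5 + loop_seq + arm3 + suffix3
    structure = (
        "." * u5
        + "".join("(" if c[2] else "." for c in cols if c[0] != "-")
        + "." * loop_len
        + "".join(")" if c[2] else "." for c in reversed(cols) if c[1] != "-")
        + "." * u3
    )

    counts = StemColumnCounts(
        background=sum(not d for d in in_duplex),
        bulge=sum(
            ("-" in (c[0], c[1])) and not d for c, d in zip(cols, in_duplex)
        ),
        mismatch=sum(
            "-" not in (c[0], c[1]) and not c[2] and not d
            for c, d in zip(cols, in_duplex)
        ),
    )

    record = PreMiRNA(name, sequence, structure)
    if spec.refold:
        record, _ = fold(record)

    arm = str(rng.choice(spec.plant_arms))
    if arm == "3p":
        # a 3'-arm mature written 5'->3' runs loop->basal; its basal-most
        # nucleotide sits opposite the position the planted rule selects as
        # the 5'-arm mature start, so both arms share one window geometry
        alignment = align_arms(record)
        col5 = alignment.column_of(start5, "5p")
        basal3 = None
        for c in list(range(col5, alignment.n_columns)) + list(
            range(col5 - 1, -1, -1)
        ):
            idx = alignment.columns[c].three_index
            if idx is not None:
                basal3 = idx
                break
        lo3, hi3 = alignment.arm3_span
        start3 = None if basal3 is None else basal3 - (spec.mature_len - 1)
        if start3 is not None and lo3 <= start3 and start3 + spec.mature_len <= hi3:
            start = start3
        else:  # partner region truncated by bulges; fall back to the 5' arm
            arm, start = "5p", start5
    else:
        start = start5

    ann = AnnotationRecord(
        premirna_id=name,
        mature_id=f"{name}-{arm}",
        start=start,
        end=start + spec.mature_len,
        arm=arm,
    )
    return record, ann, counts


def generate(spec: SynthSpec) -> SyntheticDataset:
    """Draw ``spec.n_precursors`` precursors; reproducible under ``seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records, annotations, counts = [], [], []
    for k in range(spec.n_precursors):
        rec, ann, cc = _build_one(spec, rng, f"synth-{k:04d}")
        records.append(rec)
        annotations.append(ann)
        counts.append(cc)
    return SyntheticDataset(records, annotations, counts)
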