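"""Scan precursors, rank candidate starts, and score position deviation.

Prediction quality is reported the way the field reports it: the signed
position deviation D(x) = predicted start - true start (in nucleotides along
the arm hosting the true mature), the cumulative fraction DS(+-k) of matures
predicted within k nt for k = 0..10, and the mean absolute deviation AD.
D(x) = 0 is an exact hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import extract
from .hairpin import HairpinError, PreMiRNA, align_arms, fold
from .model import TrainedModel
from .synthetic import AnnotationRecord
from .windowing import DEFAULT_MATURE_LEN, DuplexWindow, enumerate_candidates

DS_MAX_K = 10


@dataclass(frozen=True)
class RankedCandidate:
    arm: str
    mature_start: int  # 0-based sequence index
    scenario: str
    p_positive: float


@dataclass
class PredictionResult:
    """Ranked candidates per arm for one precursor.

    Ranking is by p_positive descending; ties break toward the basal-most
    (smaller) start so results are stable.
    """

    premirna_id: str
    ranked: dict[str, list[RankedCandidate]] = field(
        default_factory=lambda: {"5p": [], "3p": []}
    )

    def best(self, arm: str) -> RankedCandidate | None:
        lst = self.ranked.get(arm, [])
        return lst[0] if lst else None

    @property
    def best_overall(self) -> RankedCandidate | None:
        bests = [b for b in (self.best("5p"), self.best("3p")) if b is not None]
        if not bests:
            return None
        return max(bests, key=lambda r: (r.p_positive, -r.mature_start))


def scan(
    model: TrainedModel,
    premirna: PreMiRNA,
    mature_len: int = DEFAULT_MATURE_LEN,
) -> PredictionResult:
    """Fold (if needed), enumerate duplex windows, and rank them.

    Raises :class:`HairpinError` for multi-stem precursors.  A precursor
    whose arms cannot host any window yields an empty result, not an error.
    """
    if premirna.structure is None:
        premirna, _ = fold(premirna)
    alignment = align_arms(premirna)  # rejects multi-stem
    cset = enumerate_candidates(alignment, premirna.id, mature_len)
    result = PredictionResult(premirna_id=premirna.id)
    if not cset.candidates:
        return result
    X = np.vstack([extract(w, alignment) for w in cset.candidates])
    p_pos = model.predict_proba(X)[:, 0]
    for arm in ("5p", "3p"):
        rows = [
            RankedCandidate(w.arm, w.mature_start, w.scenario, float(p))
            for w, p in zip(cset.candidates, p_pos)
            if w.arm == arm
        ]
        rows.sort(key=lambda r: (-r.p_positive, r.mature_start))
        result.ranked[arm] = rows
    return result


def deviation_summary(deviations: list[int]) -> tuple[list[float], float]:
    """DS row (cumulative fraction within +-k, k=0..10) and AD."""
    if not deviations:
        return [float("nan")] * (DS_MAX_K + 1), float("nan")
    absdev = np.abs(np.asarray(deviations, dtype=float))
    ds = [float(np.mean(absdev <= k)) for k in range(DS_MAX_K + 1)]
    return ds, float(absdev.mean())


@dataclass
class DeviationReport:
    """Per-mature deviations plus the DS/AD summary."""

    table: pd.DataFrame  # premirna_id, mature_id, arm, true/pred start, D, wrong_arm
    ds: list[float]
    ad: float

    @property
    def n_scored(self) -> int:
        return int(self.table["deviation"].notna().sum())

    @property
    def exact_hit_rate(self) -> float:
        d = self.table["deviation"].dropna()
        return float((d == 0).mean()) if len(d) else float("nan")

    @property
    def wrong_arm_count(self) -> int:
        return int(self.table["wrong_arm"].sum())


def evaluate(
    results: dict[str, PredictionResult],
    annotations: list[AnnotationRecord],
) -> DeviationReport:
    """Score predictions against annotated matures.

    The deviation for each mature is computed against the best candidate on
    the *annotated* arm; when the model's overall best candidate sits on the
    other arm this is flagged (``wrong_arm``) but does not change D(x).
    Matures whose arm produced no candidate get a missing deviation and are
    excluded from DS/AD denominators.
    """
    rows = []
    for ann in annotations:
        if ann.premirna_id not in results:
            raise KeyError(f"no prediction for annotated id {ann.premirna_id!r}")
        res = results[ann.premirna_id]
        best = res.best(ann.arm)
        overall = res.best_overall
        rows.append(
            {
                "premirna_id": ann.premirna_id,
                "mature_id": ann.mature_id,
                "arm": ann.arm,
                "true_start": ann.start,
                "predicted_start": None if best is None else best.mature_start,
                "deviation": None if best is None else best.mature_start - ann.start,
                "wrong_arm": overall is not None and overall.arm != ann.arm,
            }
        )
    table = pd.DataFrame(rows)
    devs = [int(d) for d in table["deviation"].dropna()]
    ds, ad = deviation_summary(devs)
    return DeviationReport(table=table, ds=ds, ad=ad)
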