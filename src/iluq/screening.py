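"""Sequential RU-gated screening of candidate ion pairs.

Each stage predicts one property for the surviving candidates, drops those
whose representation uncertainty exceeds the stage's reliability threshold
(extrapolation-zone predictions), then keeps the candidates passing the
stage's cutoff in the stated direction (keep-low for viscosity and toxicity
proxies, keep-high for uptake).  Stages run in order, each consuming the
previous stage's survivors, so later — more expensive or more selective —
properties are only predicted for candidates that already meet the earlier
prerequisites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd

from .chem import Conditions, IonPair, STANDARD_CONDITIONS
from .uncertainty import ThresholdSpec


class StagePredictor(Protocol):
    """Anything that yields (ensemble prediction, RU) per candidate.

    :class:`iluq.models.ModelSuite` satisfies this via
    :func:`predictor_from_suite`; tests may use preset tables.
    """

    def __call__(self, pairs: list[IonPair], conditions: list[Conditions]
                 ) -> tuple[np.ndarray, np.ndarray]: ...


def predictor_from_suite(suite) -> StagePredictor:
    from .uncertainty import representation_uncertainty

    def predict(pairs, conditions):
        profiles = representation_uncertainty(suite, pairs, conditions)
        return (np.asarray([p.mean for p in profiles]),
                np.asarray([p.sd for p in profiles]))

    return predict


@dataclass
class ScreeningStage:
    """One property gate in the sequential screen.

    ``cutoff_rule`` is ``("absolute", x)`` — keep candidates with prediction
    <= x (keep_low) or >= x (keep_high) — or ``("percentile", q)`` with
    q in (0, 100): keep the best q percent of the *reliable* candidates at
    this stage.  Ties at an absolute cutoff are kept.
    """

    property_name: str
    predictor: StagePredictor
    threshold: ThresholdSpec
    direction: str = "keep_low"             # or "keep_high"
    cutoff_rule: tuple[str, float] = ("percentile", 50.0)
    conditions: Conditions = STANDARD_CONDITIONS

    def __post_init__(self) -> None:
        if self.direction not in ("keep_low", "keep_high"):
            raise ValueError(f"direction must be keep_low/keep_high, got {self.direction!r}")
        rule, x = self.cutoff_rule
        if rule not in ("absolute", "percentile"):
            raise ValueError(f"unknown cutoff rule {rule!r}")
        if rule == "percentile" and not 0 < x < 100 and x != 100:
            raise ValueError(f"cutoff percentile must lie in (0, 100], got {x}")
        if self.threshold.uncertainty_kind != "RU":
            raise ValueError("screening gates on RU; threshold must be RU-calibrated")


@dataclass
class StageRecord:
    """Audit record of one stage: conservation holds exactly —
    n_in = n_unreliable + n_failed_cutoff + n_survivors."""

    property_name: str
    n_in: int
    n_unreliable: int
    n_failed_cutoff: int
    n_survivors: int
    table: pd.DataFrame   # per candidate: prediction, ru, status


@dataclass
class ScreeningReport:
    """Stage-by-stage audit of a sequential screen."""

    stages: list[StageRecord] = field(default_factory=list)
    survivors: list[IonPair] = field(default_factory=list)

    def funnel(self) -> list[int]:
        """Candidate counts entering each stage plus the final survivor count."""
        if not self.stages:
            return [len(self.survivors)]
        return [s.n_in for s in self.stages] + [self.stages[-1].n_survivors]


def run_stage(candidates: list[IonPair], stage: ScreeningStage
              ) -> tuple[list[IonPair], StageRecord]:
    """Apply one screening stage; survivors are ordered by predicted merit
    (ascending for keep_low, descending for keep_high)."""
    n = len(candidates)
    if n == 0:
        empty = pd.DataFrame(columns=["pair_id", "prediction", "ru", "status"])
        return [], StageRecord(stage.property_name, 0, 0, 0, 0, empty)
    conds = [stage.conditions] * n
    pred, ru = stage.predictor(candidates, conds)
    pred = np.asarray(pred, dtype=float)
    ru = np.asarray(ru, dtype=float)
    unreliable = ru > stage.threshold.value
    reliable_idx = np.nonzero(~unreliable)[0]

    rule, x = stage.cutoff_rule
    keep = np.zeros(n, dtype=bool)
    if reliable_idx.size:
        rp = pred[reliable_idx]
        if rule == "absolute":
            ok = rp <= x if stage.direction == "keep_low" else rp >= x
        else:
            if stage.direction == "keep_low":
                cut = np.percentile(rp, x)
                ok = rp <= cut
            else:
                cut = np.percentile(rp, 100.0 - x)
                ok = rp >= cut
        keep[reliable_idx[ok]] = True

    status = np.where(unreliable, "unreliable", np.where(keep, "survivor", "failed_cutoff"))
    table = pd.DataFrame(
        {
            "pair_id": [c.pair_id for c in candidates],
            "prediction": pred,
            "ru": ru,
            "status": status,
        }
    )
    surv_idx = np.nonzero(keep)[0]
    order = np.argsort(pred[surv_idx], kind="stable")
    if stage.direction == "keep_high":
        order = order[::-1]
    survivors = [candidates[i] for i in surv_idx[order]]
    record = StageRecord(
        property_name=stage.property_name,
        n_in=n,
        n_unreliable=int(unreliable.sum()),
        n_failed_cutoff=int((status == "failed_cutoff").sum()),
        n_survivors=len(survivors),
        table=table,
    )
    assert record.n_in == record.n_unreliable + record.n_failed_cutoff + record.n_survivors
    return survivors, record


def run_sequential_screen(candidates: list[IonPair],
                          stages: list[ScreeningStage]) -> ScreeningReport:
    """Run the stages in order, each on the previous stage's survivors."""
    if not stages:
        raise ValueError("need at least one stage")
    names = [s.property_name for s in stages]
    if len(set(names)) != len(names):
        raise ValueError(f"stage properties must be distinct, got {names}")
    report = ScreeningReport()
    current = list(candidates)
    for k, stage in enumerate(stages):
        try:
            current, record = run_stage(current, stage)
        except Exception as exc:
            raise RuntimeError(f"stage {k} ({stage.property_name}) failed") from exc
        report.stages.append(record)
    report.survivors = current
    return report
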