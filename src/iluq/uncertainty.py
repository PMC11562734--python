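"""Model uncertainty (MU), representation uncertainty (RU) and reliability thresholds.

Both uncertainty kinds are the standard deviation of four predictions for a
queried pair:

- **MU** — four models sharing one representation but differing in
  hyperparameters; quantifies sensitivity to the model, not the featurization.
- **RU** — the four best models built on the four different representations
  (C-MF, MD, MI, MG); representations diverge outside the training domain,
  so RU grows where predictions extrapolate.

Reliability thresholds are calibrated on training-set uncertainties:
threshold I is the training maximum (every training prediction reliable);
threshold II is the Tukey upper fence Q3 + 1.5·IQR (training outliers deemed
unreliable).  A prediction is flagged unreliable iff its uncertainty strictly
exceeds the threshold, so ties stay reliable and threshold I never flags a
calibration point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import Conditions, IonPair
from .models import ModelSuite, TrainedModel, RU_REPRESENTATIONS

#: Standard-deviation convention: sample sd, divisor n-1.  Population mode
#: ("population") rescales every uncertainty by the same constant and is
#: threshold-neutral (flags are scale-equivariant).
DEFAULT_SD_MODE = "sample"


def member_spread(members: np.ndarray, sd_mode: str = DEFAULT_SD_MODE) -> np.ndarray:
    """Per-row spread of an (n, 4) member-prediction array under the
    documented sd convention (sample sd by default, population optional)."""
    ddof = 1 if sd_mode == "sample" else 0
    return np.asarray(members, dtype=float).std(axis=1, ddof=ddof)


_spread = member_spread


@dataclass(frozen=True)
class UncertaintyProfile:
    """Per-sample record of the four member predictions and their spread."""

    member_predictions: tuple[float, float, float, float]
    mean: float
    sd: float
    kind: str                 # "MU" or "RU"
    source: str               # representation name, or "cross-representation"
    sd_mode: str = DEFAULT_SD_MODE

    def __post_init__(self) -> None:
        if self.kind not in ("MU", "RU"):
            raise ValueError(f"kind must be MU or RU, got {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _profiles(members: np.ndarray, kind: str, source: str, sd_mode: str
              ) -> list[UncertaintyProfile]:
    means = members.mean(axis=1)
    sds = _spread(members, sd_mode)
    return [
        UncertaintyProfile(tuple(row), float(mu), float(sd), kind, source, sd_mode)
        for row, mu, sd in zip(members, means, sds)
    ]


def model_uncertainty(
    variant_models: list[TrainedModel],
    pairs: list[IonPair],
    conditions: list[Conditions] | None = None,
    sd_mode: str = DEFAULT_SD_MODE,
) -> list[UncertaintyProfile]:
    """MU profiles from the 4 hyperparameter variants of one representation."""
    if len(variant_models) != 4:
        raise ValueError(f"MU needs exactly 4 variant models, got {len(variant_models)}")
    kinds = {m.representation_kind for m in variant_models}
    tags = {m.scheme_tag for m in variant_models}
    if len(kinds) != 1 or len(tags) != 1:
        raise ValueError(
            f"variant models must share one representation and scheme, got {kinds}"
        )
    members = np.column_stack([m.predict(pairs, conditions) for m in variant_models])
    return _profiles(members, "MU", kinds.pop(), sd_mode)


def representation_uncertainty(
    suite: ModelSuite,
    pairs: list[IonPair],
    conditions: list[Conditions] | None = None,
    sd_mode: str = DEFAULT_SD_MODE,
) -> list[UncertaintyProfile]:
    """RU profiles across the suite's four best per-representation models.

    The stored ``mean`` is the equal-weight ensemble prediction, reused by
    :func:`iluq.ensemble.ensemble_predict`.
    """
    best = getattr(suite, "best_models", None)
    if best is not None:
        missing = [r for r in RU_REPRESENTATIONS if r not in best]
        if missing:
            raise ValueError(f"suite is missing representations {missing}")
    members = suite.member_predictions(pairs, conditions)
    return _profiles(members, "RU", "cross-representation", sd_mode)


@dataclass(frozen=True)
class ThresholdSpec:
    """A calibrated reliability cutoff with its calibration statistics."""

    kind: str                 # "I" (training max) or "II" (Tukey fence)
    value: float
    calibration_stats: dict
    uncertainty_kind: str = "RU"   # which uncertainty it was calibrated on
    source: str = "cross-representation"


def calibrate_threshold(
    training_uncertainties,
    kind: str = "II",
    uncertainty_kind: str = "RU",
    source: str = "cross-representation",
) -> ThresholdSpec:
    """Calibrate threshold I (max) or II (Q3 + 1.5·IQR) on training uncertainties.

    Quartiles use linear interpolation between order statistics.
    """
    u = np.asarray(list(training_uncertainties), dtype=float)
    if u.size < 4:
        raise ValueError(f"need at least 4 calibration values, got {u.size}")
    if not np.all(np.isfinite(u)) or np.any(u < 0):
        raise ValueError("calibration uncertainties must be finite and >= 0")
    q1, q3 = np.quantile(u, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    stats = {
        "Q1": float(q1),
        "Q3": float(q3),
        "IQR": float(iqr),
        "max": float(u.max()),
        "n": int(u.size),
    }
    if kind == "I":
        value = stats["max"]
    elif kind == "II":
        value = float(q3 + 1.5 * iqr)
    else:
        raise ValueError(f"threshold kind must be 'I' or 'II', got {kind!r}")
    return ThresholdSpec(kind=kind, value=value, calibration_stats=stats,
                         uncertainty_kind=uncertainty_kind, source=source)


def threshold_to_dict(spec: ThresholdSpec) -> dict:
    return {
        "kind": spec.kind,
        "value": spec.value,
        "calibration_stats": spec.calibration_stats,
        "uncertainty_kind": spec.uncertainty_kind,
        "source": spec.source,
    }


def threshold_from_dict(d: dict) -> ThresholdSpec:
    return ThresholdSpec(
        kind=d["kind"],
        value=float(d["value"]),
        calibration_stats=dict(d.get("calibration_stats", {})),
        uncertainty_kind=d.get("uncertainty_kind", "RU"),
        source=d.get("source", "cross-representation"),
    )


def flag_unreliable(
    profiles: list[UncertaintyProfile],
    threshold: ThresholdSpec,
    override_kind_check: bool = False,
) -> np.ndarray:
    """True where a profile's sd strictly exceeds the threshold (ties reliable)."""
    flags = np.empty(len(profiles), dtype=bool)
    for i, p in enumerate(profiles):
        if p.kind != threshold.uncertainty_kind and not override_kind_check:
            raise ValueError(
                f"threshold calibrated on {threshold.uncertainty_kind}, "
                f"profile {i} is {p.kind}"
            )
        flags[i] = p.sd > threshold.value
    return flags
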