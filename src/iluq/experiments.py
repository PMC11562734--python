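"""End-to-end synthetic study: train a suite, calibrate thresholds, probe OOD.

This is the workhorse behind the package's self-validation: on synthetic
in-domain data with known ground truth it trains the four-representation
suite, measures individual and ensemble test performance, calibrates
reliability thresholds on training uncertainties, and compares RU against
per-representation MU at flagging a structurally disjoint OOD family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import Conditions, PropertyDataset
from .ensemble import EvaluationReport, ensemble_predict, evaluate
from .models import ModelSuite, RU_REPRESENTATIONS, train_suite
from .synthetic import GeneratorSpec, generate_ion_library, generate_property_dataset
from .uncertainty import (
    ThresholdSpec,
    flag_unreliable,
    model_uncertainty,
    representation_uncertainty,
)
from .benchmark import calibrate_suite_thresholds

DEFAULT_MU_REPS = ("C-MF", "MD", "MG")


@dataclass
class RuExperimentResult:
    """Everything one seeded run of the synthetic RU study produces."""

    seed: int
    suite: ModelSuite
    train: PropertyDataset
    test: PropertyDataset
    ood: PropertyDataset
    member_test_reports: dict[str, EvaluationReport]
    ensemble_test_report: EvaluationReport
    member_test_predictions: np.ndarray        # (n_test, 4)
    ensemble_test_predictions: np.ndarray
    thresholds: dict[str, ThresholdSpec]
    ru_flag_rate_test: float
    ru_flag_rate_ood: float
    ood_flagged: dict[str, int] = field(default_factory=dict)  # method -> count


def run_ru_experiment(
    seed: int,
    property_name: str = "viscosity",
    n_train: int = 400,
    n_test: int = 100,
    n_ood: int = 200,
    threshold_kind: str = "II",
    mu_representations: tuple[str, ...] = DEFAULT_MU_REPS,
) -> RuExperimentResult:
    """One seeded run of the synthetic representation-uncertainty study.

    Generates disjoint in-domain train/test sets and an OOD probe set, trains
    the suite, calibrates RU and MU thresholds on training uncertainties, and
    counts flagged predictions on the test and OOD sets.
    """
    spec = GeneratorSpec(
        family="in_domain",
        property_name=property_name,
        seed=seed,
        n_records=n_train + n_test,
    )
    library = generate_ion_library(spec)
    full, _ = generate_property_dataset(library, spec)
    train = full.subset(range(n_train), split_label="train")
    test = full.subset(range(n_train, n_train + n_test), split_label="test")

    ood_spec = GeneratorSpec(
        family="ood",
        property_name=property_name,
        n_cations=60,
        n_anions=60,
        seed=seed,
        n_records=n_ood,
    )
    ood_library = generate_ion_library(ood_spec)
    ood, _ = generate_property_dataset(ood_library, ood_spec)

    suite = train_suite(train, seed=seed)

    member_reports: dict[str, EvaluationReport] = {}
    members = suite.member_predictions(test.pairs, test.conditions)
    for k, rep in enumerate(RU_REPRESENTATIONS):
        member_reports[rep] = evaluate(test.values, members[:, k])
    ens_pred = ensemble_predict(suite, test.pairs, test.conditions)
    ens_report = evaluate(test.values, ens_pred)

    thresholds = calibrate_suite_thresholds(
        suite, train.pairs, train.conditions,
        kind=threshold_kind, mu_representations=mu_representations,
    )

    ru_test = representation_uncertainty(suite, test.pairs, test.conditions)
    ru_ood = representation_uncertainty(suite, ood.pairs, ood.conditions)
    rate_test = float(flag_unreliable(ru_test, thresholds["RU"]).mean())
    rate_ood = float(flag_unreliable(ru_ood, thresholds["RU"]).mean())

    ood_flagged = {"RU": int(flag_unreliable(ru_ood, thresholds["RU"]).sum())}
    for rep in mu_representations:
        mu_ood = model_uncertainty(suite.variant_sets[rep], ood.pairs, ood.conditions)
        ood_flagged[f"MU:{rep}"] = int(
            flag_unreliable(mu_ood, thresholds[f"MU:{rep}"]).sum()
        )

    return RuExperimentResult(
        seed=seed,
        suite=suite,
        train=train,
        test=test,
        ood=ood,
        member_test_reports=member_reports,
        ensemble_test_report=ens_report,
        member_test_predictions=members,
        ensemble_test_predictions=ens_pred,
        thresholds=thresholds,
        ru_flag_rate_test=rate_test,
        ru_flag_rate_ood=rate_ood,
        ood_flagged=ood_flagged,
    )
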