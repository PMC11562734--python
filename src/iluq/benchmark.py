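"""Cross-product "non-IL" benchmarks for out-of-distribution evaluation.

Candidate sets are assembled the way deliberately out-of-domain probes are
built: sample 100 "non-cations" and 100 "non-anions" from a general pool and
take the full 100 × 100 = 10 000 cross product; repeat for several groups to
guard against a lucky draw.  Charge validation is relaxed — the probes are
arbitrary molecules, which is the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import Conditions, IonPair, STANDARD_CONDITIONS, parse_ion_pair
from .models import ModelSuite, RU_REPRESENTATIONS
from .uncertainty import (
    ThresholdSpec,
    calibrate_threshold,
    flag_unreliable,
    model_uncertainty,
    representation_uncertainty,
)


@dataclass
class BenchmarkGroup:
    """One full cross product of a sampled cation-side × anion-side pool."""

    group_id: str
    pairs: list[IonPair]
    conditions: Conditions = STANDARD_CONDITIONS
    provenance: dict = field(default_factory=dict)


def generate_cross_pairs(
    cations: list[str], anions: list[str], id_prefix: str = "x"
) -> list[IonPair]:
    """Exhaustive cross product of two SMILES pools, |cations|·|anions| pairs.

    Order is lexicographic in (cation index, anion index).  Duplicate entries
    in either pool are an error — deduplication is the caller's explicit
    choice, since silently collapsing the pool would change the group size.
    """
    if not cations or not anions:
        raise ValueError("both pools must be non-empty")
    if len(set(cations)) != len(cations):
        raise ValueError("duplicate entries in the cation pool")
    if len(set(anions)) != len(anions):
        raise ValueError("duplicate entries in the anion pool")
    # canonicalize each pool entry once; the cross product then assembles
    # validated components directly
    can_c = [parse_ion_pair(f"{c}.[Cl-]", "tmp", "relaxed").cation_smiles
             for c in cations]
    can_a = [parse_ion_pair(f"[Na+].{a}", "tmp", "relaxed").anion_smiles
             for a in anions]
    pairs: list[IonPair] = []
    for i, c in enumerate(can_c):
        for j, a in enumerate(can_a):
            pairs.append(
                IonPair(f"{id_prefix}-c{i:03d}a{j:03d}", c, a, "relaxed")
            )
    return pairs


def assemble_benchmark(
    cation_pool: list[str],
    anion_pool: list[str],
    n_groups: int = 5,
    cations_per_group: int = 100,
    anions_per_group: int = 100,
    seed: int = 0,
    conditions: Conditions = STANDARD_CONDITIONS,
) -> list[BenchmarkGroup]:
    """Assemble ``n_groups`` cross-product groups from seeded sub-samples.

    Within a group the sub-sample is drawn without replacement; across groups
    the draws are independent (groups may overlap).  Defaults give 5 groups
    of 10 000 candidates evaluated at standard ambient conditions.
    """
    if len(cation_pool) < cations_per_group or len(anion_pool) < anions_per_group:
        raise ValueError(
            f"pools of {len(cation_pool)}/{len(anion_pool)} too small for "
            f"{cations_per_group}x{anions_per_group} groups"
        )
    rng = np.random.default_rng(seed)
    groups: list[BenchmarkGroup] = []
    for g in range(n_groups):
        ci = rng.choice(len(cation_pool), size=cations_per_group, replace=False)
        ai = rng.choice(len(anion_pool), size=anions_per_group, replace=False)
        cats = [cation_pool[i] for i in ci]
        anis = [anion_pool[i] for i in ai]
        groups.append(
            BenchmarkGroup(
                group_id=f"group{g}",
                pairs=generate_cross_pairs(cats, anis, id_prefix=f"g{g}"),
                conditions=conditions,
                provenance={
                    "cation_indices": [int(i) for i in ci],
                    "anion_indices": [int(i) for i in ai],
                    "seed": seed,
                },
            )
        )
    return groups


#: Default MU methods reported alongside RU (fingerprint, descriptor, graph).
DEFAULT_MU_METHODS = ("MU:C-MF", "MU:MD", "MU:MG")


def evaluate_discrimination(
    suite: ModelSuite,
    thresholds: dict[str, ThresholdSpec],
    groups: list[BenchmarkGroup],
) -> pd.DataFrame:
    """Count unreliable-flagged candidates per method and group.

    ``thresholds`` maps method names — ``"RU"`` or ``"MU:<representation>"``
    — to threshold specs calibrated on the suite's training uncertainties of
    that same method.  Returns a tidy frame (method, group, n_flagged) plus a
    per-method mean row (group = "mean").
    """
    rows = []
    for method, thr in thresholds.items():
        counts = []
        for grp in groups:
            conds = [grp.conditions] * len(grp.pairs)
            if method == "RU":
                profiles = representation_uncertainty(suite, grp.pairs, conds)
            elif method.startswith("MU:"):
                rep = method[3:]
                if rep not in suite.variant_sets:
                    raise ValueError(f"suite has no variant set for {rep!r}")
                profiles = model_uncertainty(suite.variant_sets[rep], grp.pairs, conds)
            else:
                raise ValueError(f"unknown method {method!r}")
            n_flagged = int(flag_unreliable(profiles, thr).sum())
            counts.append(n_flagged)
            rows.append(
                {"method": method, "group": grp.group_id,
                 "n": len(grp.pairs), "n_flagged": n_flagged}
            )
        rows.append(
            {"method": method, "group": "mean",
             "n": int(np.mean([len(g.pairs) for g in groups])),
             "n_flagged": float(np.mean(counts))}
        )
    return pd.DataFrame(rows)


def calibrate_suite_thresholds(
    suite: ModelSuite,
    train_pairs: list[IonPair],
    train_conditions: list[Conditions],
    kind: str = "II",
    mu_representations: tuple[str, ...] = ("C-MF", "MD", "MG"),
) -> dict[str, ThresholdSpec]:
    """Calibrate RU and per-representation MU thresholds on the training set."""
    out: dict[str, ThresholdSpec] = {}
    ru = representation_uncertainty(suite, train_pairs, train_conditions)
    out["RU"] = calibrate_threshold([p.sd for p in ru], kind=kind,
                                    uncertainty_kind="RU")
    for rep in mu_representations:
        mu = model_uncertainty(suite.variant_sets[rep], train_pairs, train_conditions)
        out[f"MU:{rep}"] = calibrate_threshold(
            [p.sd for p in mu], kind=kind, uncertainty_kind="MU", source=rep
        )
    return out
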