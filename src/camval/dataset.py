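"""Dataset assembly: phantom cases, stratified split, montages, annotations.

:func:`generate_dataset` produces the full study-shaped bundle — training
and test case volumes, montage inputs, montage-aligned truth masks, and one
simulated annotator mask per profile for every positive test montage (only
positive cases are annotated, matching a study design in which annotators
mark drowning-associated findings on the drowning test cases).

The split is stratified by class.  ``split_ratio`` gives the training
fraction (rounded per class); explicit per-class test counts can be passed
instead to reproduce a fixed layout such as 25 + 25 test cases.  Everything
is a pure function of (config, counts, profiles, montage settings, seed);
the manifest records every derived seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .montage import Montage, build_montage, project_mask, select_slices
from .phantom import (AnnotatorProfile, CaseVolume, PhantomConfig,
                      generate_case, simulate_annotator)


@dataclass(frozen=True)
class MontageSettings:
    count: int = 6
    interval: int = 5
    layout: tuple[int, int] = (3, 2)
    orientation: str = "vertical"
    train_montages_per_case: int = 1
    test_montages_per_case: int = 5  # consecutive offsets 0..m-1

    def __post_init__(self) -> None:
        if self.layout[0] * self.layout[1] != self.count:
            raise ConfigurationError("layout must tile exactly `count` slices")
        m = max(self.train_montages_per_case, self.test_montages_per_case)
        if m < 1 or m > self.interval:
            raise ConfigurationError(
                "montages per case must be in [1, interval] (distinct offsets)"
            )


@dataclass
class DatasetBundle:
    train_cases: list[CaseVolume]
    test_cases: list[CaseVolume]
    train_montages: list[Montage]
    test_montages: list[Montage]
    truth_by_montage: dict[str, np.ndarray]  # montage_id -> bool mask
    annotator_masks: dict[tuple[str, str], np.ndarray]  # (montage_id, annotator)
    profiles: list[AnnotatorProfile]
    manifest: dict = field(default_factory=dict)


def _montages_for(case: CaseVolume, ms: MontageSettings,
                  n_offsets: int) -> list[tuple[Montage, np.ndarray]]:
    out = []
    for off in range(n_offsets):
        idx = select_slices(case, ms.count, ms.interval, off)
        m = build_montage(case, idx, ms.layout, ms.orientation)
        truth = project_mask(case.truth_masks, idx, ms.layout, ms.orientation)
        out.append((m, truth))
    return out


def generate_dataset(config: PhantomConfig, n_pos: int, n_neg: int,
                     profiles: list[AnnotatorProfile],
                     split_ratio: float = 0.85, seed: int = 0,
                     montage_settings: MontageSettings | None = None,
                     n_test: tuple[int, int] | None = None) -> DatasetBundle:
    """Generate the full two-class phantom dataset bundle.

    ``n_test = (n_test_pos, n_test_neg)`` overrides the rounded
    ``split_ratio`` when an exact test layout is required.
    """
    if n_pos < 2 or n_neg < 2:
        raise ConfigurationError("need at least 2 cases per class")
    if not 0 < split_ratio < 1:
        raise ConfigurationError("split_ratio must be in (0, 1)")
    ms = montage_settings or MontageSettings()
    needed = (max(ms.train_montages_per_case, ms.test_montages_per_case) - 1
              + (ms.count - 1) * ms.interval + 1)
    if needed > config.slices_per_case:
        raise ConfigurationError(
            f"montage settings need {needed} slices per case, "
            f"config provides {config.slices_per_case}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 41]))
    case_seed_base = int(rng.integers(0, 2 ** 31))

    cases_by_class: dict[int, list[CaseVolume]] = {1: [], 0: []}
    k = 0
    for label, n in ((1, n_pos), (0, n_neg)):
        for _ in range(n):
            cases_by_class[label].append(generate_case(config, label, case_seed_base + k))
            k += 1

    train_cases: list[CaseVolume] = []
    test_cases: list[CaseVolume] = []
    for label, n in ((1, n_pos), (0, n_neg)):
        if n_test is not None:
            nt = n_test[0] if label == 1 else n_test[1]
        else:
            nt = n - int(round(split_ratio * n))
        if nt < 1 or n - nt < 1:
            raise ConfigurationError(
                f"split leaves an empty partition for class {label}"
            )
        order = rng.permutation(n)
        cls = cases_by_class[label]
        test_cases += [cls[i] for i in order[:nt]]
        train_cases += [cls[i] for i in order[nt:]]

    train_montages, test_montages = [], []
    truth_by_montage: dict[str, np.ndarray] = {}
    for case in train_cases:
        for m, truth in _montages_for(case, ms, ms.train_montages_per_case):
            train_montages.append(m)
            truth_by_montage[m.montage_id] = truth
    for case in test_cases:
        for m, truth in _montages_for(case, ms, ms.test_montages_per_case):
            test_montages.append(m)
            truth_by_montage[m.montage_id] = truth

    annotator_masks: dict[tuple[str, str], np.ndarray] = {}
    pos_test = [m for m in test_montages if m.label == 1]
    for i, m in enumerate(pos_test):
        truth = truth_by_montage[m.montage_id]
        for prof in profiles:
            annotator_masks[(m.montage_id, prof.annotator_id)] = simulate_annotator(
                truth, prof, image_key=i
            )

    manifest = {
        "seed": seed,
        "case_seed_base": case_seed_base,
        "phantom_seed": config.seed,
        "n_pos": n_pos, "n_neg": n_neg,
        "split_ratio": split_ratio,
        "n_test": None if n_test is None else list(n_test),
        "montage": {
            "count": ms.count, "interval": ms.interval,
            "layout": list(ms.layout), "orientation": ms.orientation,
            "train_montages_per_case": ms.train_montages_per_case,
            "test_montages_per_case": ms.test_montages_per_case,
        },
        "profiles": [
            {"annotator_id": p.annotator_id, "area_scale": p.area_scale,
             "boundary_jitter_sd": p.boundary_jitter_sd,
             "omission_prob": p.omission_prob, "empty_prob": p.empty_prob,
             "seed": p.seed}
            for p in profiles
        ],
        "train_cases": [c.case_id for c in train_cases],
        "test_cases": [c.case_id for c in test_cases],
        "n_annotated_montages": len(pos_test),
        "n_annotator_masks": len(annotator_masks),
    }
    return DatasetBundle(
        train_cases=train_cases, test_cases=test_cases,
        train_montages=train_montages, test_montages=test_montages,
        truth_by_montage=truth_by_montage, annotator_masks=annotator_masks,
        profiles=profiles, manifest=manifest,
    )
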