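"""Synthetic admission-record generator with planted progression signals.

No public admission dataset accompanies this framework (insurer data are
private), so every stage is exercised on generated records that mimic the
structure the method assumes:

* a **dual-regime** ("T2DM-then-CVD") subpopulation: a T2DM code in the
  first episode, a CVD code in the last, and per-episode Bernoulli draws
  of comorbidity categories in between, with optional transition boosts
  that make a target category more likely in the episode after its source
  category appeared;
* a **single-regime** ("T2DM-only") subpopulation: comorbidity episodes
  followed by a terminal first-T2DM episode, and never a CVD code.

Category draw rates are configured per regime, so "exclusive" categories
(high rate in the dual regime, low or zero in the single regime) are
planted ground truth that the attribution stage should recover.  Each
category emits one representative ICD code per occurrence, cycling between
ICD-9 and ICD-10 forms to exercise both coding paths.  Generation is fully
reproducible per seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .attribution import FinalDiseaseNetwork
from .icd import IcdVersion, load_mapping

logger = logging.getLogger(__name__)

# Per-category per-episode occurrence probabilities (dual regime, single
# regime).  The asymmetry mirrors the qualitative prevalence contrast the
# framework targets: renal failure, fluid/electrolyte disorders, chronic
# pulmonary disease and hypertension elevated in the dual regime;
# depression, metastatic cancer and obesity elevated in the single regime.
DEFAULT_RATES: dict[str, tuple[float, float]] = {
    "Renal failure": (0.30, 0.04),
    "Solid tumor without metastasis": (0.20, 0.14),
    "Hypertension, uncomplicated": (0.10, 0.02),
    "Peptic ulcer disease excluding bleeding": (0.07, 0.04),
    "Fluid and electrolyte disorders": (0.08, 0.02),
    "Other neurological disorders": (0.06, 0.015),
    "Chronic pulmonary disease": (0.05, 0.01),
    "Liver disease": (0.03, 0.01),
    "Weight loss": (0.02, 0.01),
    "Hypertension, complicated": (0.02, 0.01),
    "Depression": (0.05, 0.25),
    "Metastatic cancer": (0.03, 0.20),
    "Obesity": (0.025, 0.09),
    "Drug abuse": (0.01, 0.025),
    "Paralysis": (0.008, 0.018),
    "Psychoses": (0.008, 0.014),
    "Hypothyroidism": (0.02, 0.02),
    "Rheumatoid arthritis/collagen vascular diseases": (0.02, 0.02),
    "Coagulopathy": (0.015, 0.015),
    "Deficiency anemia": (0.015, 0.015),
    "Blood loss anemia": (0.01, 0.01),
    "Alcohol abuse": (0.01, 0.01),
    "Lymphoma": (0.008, 0.008),
    "AIDS/HIV": (0.004, 0.004),
}

# Transition boosts applied in the dual regime: when the source category
# occurred in episode i, the target's draw probability in episode i+1 is
# multiplied (capped at 1).
DEFAULT_TRANSITION_BOOST: dict[tuple[str, str], float] = {
    ("Fluid and electrolyte disorders", "Renal failure"): 5.0,
    ("Weight loss", "Fluid and electrolyte disorders"): 4.0,
    ("Renal failure", "Chronic pulmonary disease"): 3.0,
}

_NOISE_CODES = [("ICD10", "Z00.0"), ("ICD9", "V70.0")]       # unmapped, valid
_EXCLUDED_CODES = [("ICD10", "S42.0"), ("ICD9", "780.60")]   # injury / fever


def _representative_codes() -> tuple[dict[str, list[tuple[str, str]]],
                                     list[tuple[str, str]],
                                     list[tuple[str, str]]]:
    """Representative (version, code) pairs from the bundled mapping."""
    tables = load_mapping()
    per_category: dict[str, list[tuple[str, str]]] = {}
    for category in tables.comorbidities.categories:
        reps = []
        seen_versions = set()
        for pattern in tables.comorbidities.patterns[category]:
            if pattern.version not in seen_versions:
                reps.append((pattern.version.value, pattern.representative()))
                seen_versions.add(pattern.version)
        per_category[category] = reps
    t2dm = [
        (p.version.value, p.representative())
        for p in tables.index_diseases["T2DM"].patterns
    ]
    cvd = []
    for subcat in sorted(tables.index_diseases["CVD"].subcategories):
        seen_versions = set()
        for p in tables.index_diseases["CVD"].subcategories[subcat]:
            # one code per (subcategory, version); later patterns can touch
            # chapters the default exclusion list strips (e.g. T82.1)
            if p.version not in seen_versions:
                cvd.append((p.version.value, p.representative()))
                seen_versions.add(p.version)
    return per_category, t2dm, cvd


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the study scale of 172 patients
    per cohort with roughly 1,150–1,240 admissions per cohort."""

    n_patients_ab: int = 172
    n_patients_a: int = 172
    n_episodes_range: tuple[int, int] = (3, 11)
    rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATES)
    )
    transition_boost: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRANSITION_BOOST)
    )
    codes_per_category: Optional[dict[str, list[tuple[str, str]]]] = None
    date_range: tuple[date, date] = (date(2000, 1, 1), date(2017, 12, 31))
    noise_rate: float = 0.3
    exclusion_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.n_episodes_range
        if lo > hi or lo < 2:
            raise ValueError("n_episodes_range must satisfy 2 <= min <= max")
        if hi < 3:
            raise ValueError(
                "dual-regime patients need >= 3 episodes (index, interim, outcome)"
            )
        for cat, (p_ab, p_a) in self.rates.items():
            if not (0 <= p_ab <= 1 and 0 <= p_a <= 1):
                raise ValueError(f"rates for {cat!r} must lie in [0, 1]")
        if any(m < 0 for m in self.transition_boost.values()):
            raise ValueError("transition multipliers must be >= 0")
        span = (self.date_range[1] - self.date_range[0]).days
        if span < hi:
            raise ValueError("date_range too narrow for the episode counts")


@dataclass
class PlantedTruth:
    """Ground truth the attribution stage is expected to recover."""

    exclusive_categories: set[str] = field(default_factory=set)
    boosted_transitions: set[tuple[str, str]] = field(default_factory=set)


def generate(config: SyntheticConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Emit a long-format episode table plus the planted truth.

    Every generated dual-regime patient satisfies the dual-cohort criteria
    and every single-regime patient the single-cohort criteria by
    construction (a comorbidity occurrence is injected into the window on
    the rare draw where none appeared).  Byte-identical output per seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    per_category = config.codes_per_category
    if per_category is None:
        per_category, t2dm_codes, cvd_codes = _representative_codes()
    else:
        _, t2dm_codes, cvd_codes = _representative_codes()
    categories = sorted(config.rates)
    missing = [c for c in categories if c not in per_category]
    if missing:
        raise ValueError(f"no representative codes for categories: {missing}")

    lo, hi = config.n_episodes_range
    span = (config.date_range[1] - config.date_range[0]).days
    version_cycle: dict[str, int] = {c: 0 for c in categories}
    rows: list[dict] = []

    def emit_category(cat: str) -> tuple[str, str]:
        reps = per_category[cat]
        version, code = reps[version_cycle[cat] % len(reps)]
        version_cycle[cat] += 1
        return version, code

    def draw_episodes(
        n_ep: int, regime: int, window: range
    ) -> list[list[tuple[str, str, Optional[str]]]]:
        """Per-episode code lists; items are (version, code, category)."""
        rate_vec = np.array([config.rates[c][regime] for c in categories])
        episode_cats: list[list[str]] = []
        prev: set[str] = set()
        for j in range(n_ep):
            probs = rate_vec.copy()
            if regime == 0 and j > 0:  # boosts act in the dual regime only
                for (src, tgt), mult in sorted(config.transition_boost.items()):
                    if src in prev and tgt in config.rates:
                        k = categories.index(tgt)
                        probs[k] = min(1.0, probs[k] * mult)
            hits = rng.random(len(categories)) < probs
            cats = [c for c, h in zip(categories, hits) if h]
            episode_cats.append(cats)
            prev = set(cats)
        # guarantee >=1 comorbidity occurrence inside the observation window
        if not any(episode_cats[j] for j in window):
            j = int(rng.integers(window.start, window.stop))
            weights = rate_vec / rate_vec.sum() if rate_vec.sum() else None
            forced = str(rng.choice(categories, p=weights))
            episode_cats[j] = [forced]
        out = []
        for cats in episode_cats:
            codes = [(*emit_category(c), c) for c in cats]
            if rng.random() < config.noise_rate:
                v, code = _NOISE_CODES[int(rng.integers(len(_NOISE_CODES)))]
                codes.append((v, code, None))
            if rng.random() < config.exclusion_rate:
                v, code = _EXCLUDED_CODES[int(rng.integers(len(_EXCLUDED_CODES)))]
                codes.append((v, code, None))
            if not codes:
                # every real admission carries at least one diagnosis code
                codes.append((*_NOISE_CODES[0], None))
            out.append(codes)
        return out

    def emit_patient(pid: str, episodes: list[list[tuple[str, str, str]]],
                     days: np.ndarray) -> None:
        for j, codes in enumerate(episodes):
            admit = config.date_range[0] + timedelta(days=int(days[j]))
            discharge = admit + timedelta(days=int(rng.integers(0, 14)))
            for version, code, _ in sorted(codes, key=lambda t: (t[0], t[1])):
                rows.append(
                    {
                        "patient_id": pid,
                        "episode_id": f"{pid}-E{j:03d}",
                        "admit_date": admit.isoformat(),
                        "discharge_date": discharge.isoformat(),
                        "icd_version": version,
                        "icd_code": code,
                    }
                )

    for i in range(config.n_patients_ab):
        n_ep = int(rng.integers(max(lo, 3), hi + 1))
        days = np.sort(rng.choice(span, size=n_ep, replace=False))
        episodes = draw_episodes(n_ep, regime=0, window=range(1, n_ep - 1))
        v, code = t2dm_codes[i % len(t2dm_codes)]
        episodes[0].append((v, code, "T2DM"))
        v, code = cvd_codes[i % len(cvd_codes)]
        episodes[-1].append((v, code, "CVD"))
        emit_patient(f"AB{i:04d}", episodes, days)

    for i in range(config.n_patients_a):
        n_ep = int(rng.integers(lo, hi + 1))
        days = np.sort(rng.choice(span, size=n_ep, replace=False))
        episodes = draw_episodes(n_ep, regime=1, window=range(0, n_ep - 1))
        v, code = t2dm_codes[i % len(t2dm_codes)]
        episodes[-1].append((v, code, "T2DM"))
        emit_patient(f"SG{i:04d}", episodes, days)

    truth = PlantedTruth(
        exclusive_categories={
            c for c, (p_ab, p_a) in config.rates.items() if p_ab > p_a
        },
        boosted_transitions={
            pair for pair, mult in config.transition_boost.items() if mult > 1
        },
    )
    table = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "episode_id", "admit_date", "discharge_date",
            "icd_version", "icd_code",
        ],
    )
    return table, truth


def truth_recovery_report(
    final: FinalDiseaseNetwork, truth: PlantedTruth, k: int
) -> dict:
    """Fraction of planted categories/transitions found in the top-k."""
    if not truth.exclusive_categories and not truth.boosted_transitions:
        return {"applicable": False}
    report: dict = {"applicable": True, "k": k}
    if truth.exclusive_categories:
        n = len(final.node_scores)
        kk = min(k, n)
        if kk < k:
            logger.warning("k=%d clamped to node count %d", k, n)
        top = [
            d
            for d, _ in sorted(
                final.node_scores.items(), key=lambda it: (-it[1], it[0])
            )[:kk]
        ]
        hits = truth.exclusive_categories & set(top)
        report["node_recovery"] = len(hits) / len(truth.exclusive_categories)
        report["top_nodes"] = top
    if truth.boosted_transitions:
        n = len(final.edge_scores)
        kk = min(k, n)
        top = [
            e
            for e, _ in sorted(
                final.edge_scores.items(), key=lambda it: (-it[1], it[0])
            )[:kk]
        ]
        hits = truth.boosted_transitions & set(top)
        report["edge_recovery"] = len(hits) / len(truth.boosted_transitions)
    return report


def write_truth(truth: PlantedTruth, path: Union[str, Path]) -> None:
    payload = {
        "exclusive_categories": sorted(truth.exclusive_categories),
        "boosted_transitions": [list(p) for p in sorted(truth.boosted_transitions)],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
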