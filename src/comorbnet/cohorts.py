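"""Record cleaning and dual-cohort selection from admission episodes.

Two cohorts anchor the analysis of how cardiovascular disease (CVD)
progresses in people with type 2 diabetes (T2DM):

* the **dual cohort** ("T2DM&CVD"): patients first diagnosed with T2DM and
  later with CVD, observed over the episodes between the two diagnoses;
* the **single cohort** ("T2DM only"): patients ever diagnosed with T2DM
  and never with CVD, observed over the episodes before the first T2DM
  diagnosis.

Both cohorts additionally require at least one code mapping to an
Elixhauser comorbidity category inside the observation window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .icd import (
    CodePattern,
    ComorbidityMap,
    IcdCode,
    IcdError,
    IcdVersion,
    IndexDiseaseDef,
    canonicalize,
    infer_version,
    matches,
)

logger = logging.getLogger(__name__)

COHORT_AB = "T2DM&CVD"
COHORT_A_ONLY = "T2DM only"


@dataclass(frozen=True)
class AdmissionEpisode:
    """One hospital admission: a dated episode carrying a set of ICD codes."""

    patient_id: str
    episode_id: str
    admit_date: date
    discharge_date: Optional[date]
    codes: frozenset[IcdCode]

    def __post_init__(self):
        if self.discharge_date is not None and self.discharge_date < self.admit_date:
            raise ValueError(
                f"episode {self.episode_id}: discharge before admission"
            )

    @property
    def sort_key(self) -> tuple:
        # admit date first; episode id breaks same-day ties deterministically
        return (self.admit_date, self.episode_id)


@dataclass
class PatientHistory:
    """A patient's episodes in chronological order (date, then episode id)."""

    patient_id: str
    episodes: list[AdmissionEpisode]

    def __post_init__(self):
        self.episodes = sorted(self.episodes, key=lambda e: e.sort_key)
        ids = [e.episode_id for e in self.episodes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"patient {self.patient_id}: duplicate episode ids")


@dataclass
class ObservationWindow:
    """The ordered sublist of a patient's episodes eligible for networks."""

    patient_id: str
    qualifying_episodes: list[AdmissionEpisode]
    first_A_date: Optional[date] = None
    first_B_date: Optional[date] = None


@dataclass
class CohortSelection:
    label: str
    members: dict[str, ObservationWindow] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Reading episode tables
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("patient_id", "episode_id", "admit_date", "icd_code")


def read_episode_table(
    source: Union[str, Path, pd.DataFrame],
) -> tuple[list[AdmissionEpisode], dict[str, int]]:
    """Parse a delimited episode table into episodes.

    Accepts long format (one code per row) or list format (semicolon-
    separated codes in ``icd_code``).  ``icd_version`` and
    ``discharge_date`` columns are optional; without a version column the
    version is inferred from the code shape and the inference is logged.
    Unparseable codes/rows are skipped and counted, never fatal.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"episode table missing required columns: {missing}")
    has_version = "icd_version" in df.columns
    if not has_version:
        logger.info("no icd_version column; inferring version from code shape")
    has_discharge = "discharge_date" in df.columns

    stats = {"rows": len(df), "rows_skipped": 0, "codes_skipped": 0}
    grouped: dict[tuple[str, str], dict] = {}
    for row in df.itertuples(index=False):
        try:
            pid = str(getattr(row, "patient_id"))
            eid = str(getattr(row, "episode_id"))
            admit = pd.Timestamp(getattr(row, "admit_date")).date()
        except (ValueError, TypeError):
            stats["rows_skipped"] += 1
            continue
        discharge = None
        if has_discharge:
            raw_discharge = getattr(row, "discharge_date")
            if isinstance(raw_discharge, str) and raw_discharge.strip():
                try:
                    discharge = pd.Timestamp(raw_discharge).date()
                except (ValueError, TypeError):
                    discharge = None
        entry = grouped.setdefault(
            (pid, eid), {"admit": admit, "discharge": discharge, "codes": set()}
        )
        raw_codes = str(getattr(row, "icd_code"))
        for raw in raw_codes.split(";"):
            raw = raw.strip()
            if not raw:
                continue
            try:
                if has_version and isinstance(getattr(row, "icd_version"), str):
                    version = IcdVersion.parse(getattr(row, "icd_version"))
                else:
                    version = infer_version(raw)
                entry["codes"].add(canonicalize(raw, version))
            except IcdError as exc:
                stats["codes_skipped"] += 1
                logger.debug("skipping code %r: %s", raw, exc)

    episodes = [
        AdmissionEpisode(
            patient_id=pid,
            episode_id=eid,
            admit_date=entry["admit"],
            discharge_date=entry["discharge"],
            codes=frozenset(entry["codes"]),
        )
        for (pid, eid), entry in grouped.items()
    ]
    episodes.sort(key=lambda e: (e.patient_id, e.sort_key))
    return episodes, stats


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def clean_records(
    episodes: Iterable[AdmissionEpisode],
    exclusions: Iterable[CodePattern],
) -> tuple[list[AdmissionEpisode], dict[str, int]]:
    """Apply the data filtering rules.

    (a) duplicate (patient, episode) records are collapsed (code sets
    unioned), (b) codes matching the exclusion patterns — physical
    injuries, fever, vomiting by default — are removed, and (c) episodes
    left without any valid code are dropped.  Total and idempotent; a
    count per removal reason is returned and logged.
    """
    exclusions = list(exclusions)
    stats = {"duplicates_collapsed": 0, "codes_excluded": 0, "episodes_dropped": 0}

    merged: dict[tuple[str, str], AdmissionEpisode] = {}
    for ep in episodes:
        key = (ep.patient_id, ep.episode_id)
        if key in merged:
            prev = merged[key]
            stats["duplicates_collapsed"] += 1
            merged[key] = AdmissionEpisode(
                patient_id=prev.patient_id,
                episode_id=prev.episode_id,
                admit_date=min(prev.admit_date, ep.admit_date),
                discharge_date=prev.discharge_date or ep.discharge_date,
                codes=prev.codes | ep.codes,
            )
        else:
            merged[key] = ep

    cleaned: list[AdmissionEpisode] = []
    for ep in sorted(merged.values(), key=lambda e: (e.patient_id, e.sort_key)):
        kept = []
        for code in sorted(ep.codes, key=lambda c: (c.version.value, c.canonical)):
            excluded = any(
                p.version is code.version and matches(code, p) for p in exclusions
            )
            if excluded:
                stats["codes_excluded"] += 1
            else:
                kept.append(code)
        if kept:
            cleaned.append(
                AdmissionEpisode(
                    patient_id=ep.patient_id,
                    episode_id=ep.episode_id,
                    admit_date=ep.admit_date,
                    discharge_date=ep.discharge_date,
                    codes=frozenset(kept),
                )
            )
        else:
            stats["episodes_dropped"] += 1
    logger.info("cleaning: %s", stats)
    return cleaned, stats


def build_histories(episodes: Iterable[AdmissionEpisode]) -> dict[str, PatientHistory]:
    by_patient: dict[str, list[AdmissionEpisode]] = {}
    for ep in episodes:
        by_patient.setdefault(ep.patient_id, []).append(ep)
    return {
        pid: PatientHistory(patient_id=pid, episodes=eps)
        for pid, eps in sorted(by_patient.items())
    }


# ---------------------------------------------------------------------------
# Cohort selection
# ---------------------------------------------------------------------------


def first_diagnosis(
    history: PatientHistory, disease: IndexDiseaseDef
) -> Optional[tuple[int, date]]:
    """Earliest episode (index, date) containing any code of the disease."""
    for idx, ep in enumerate(history.episodes):
        if any(disease.matches_code(code) for code in ep.codes):
            return idx, ep.admit_date
    return None


def _has_mapped_code(
    episodes: Iterable[AdmissionEpisode], cmap: ComorbidityMap
) -> bool:
    return any(
        cmap.map_code(code) is not None for ep in episodes for code in ep.codes
    )


def select_cohorts(
    histories: dict[str, PatientHistory],
    disease_A: IndexDiseaseDef,
    disease_B: IndexDiseaseDef,
    cmap: ComorbidityMap,
) -> tuple[CohortSelection, CohortSelection, dict[str, int]]:
    """Select the dual (A-then-B) and single (A-only) cohorts.

    Dual cohort: first-A strictly before first-B (by episode order and by
    date), at least one admission strictly between the two index episodes,
    and at least one mapped comorbidity code in the window.  The attached
    window spans from the first-A episode (inclusive — codes co-recorded
    with the index diagnosis count) up to, but excluding, the first-B
    episode.

    Single cohort: at least one A code, no B code anywhere, at least one
    admission strictly before the first-A date, and at least one mapped
    comorbidity code among those earlier episodes (the window).

    Returns both selections plus the patient-count funnel for the run
    manifest.
    """
    ab = CohortSelection(label=COHORT_AB)
    a_only = CohortSelection(label=COHORT_A_ONLY)
    funnel = {
        "patients": len(histories),
        "patients_with_A": 0,
        "patients_with_B": 0,
        "A_then_B": 0,
        "A_then_B_with_comorbidity": 0,
        "A_without_B": 0,
        "A_without_B_with_comorbidity": 0,
    }

    for pid in sorted(histories):
        history = histories[pid]
        first_a = first_diagnosis(history, disease_A)
        first_b = first_diagnosis(history, disease_B)
        if first_a is not None:
            funnel["patients_with_A"] += 1
        if first_b is not None:
            funnel["patients_with_B"] += 1
        if first_a is None:
            continue
        idx_a, date_a = first_a

        if first_b is not None:
            idx_b, date_b = first_b
            if idx_a >= idx_b or date_a >= date_b:
                # includes same-episode A and B: "first A then B" read strictly
                logger.debug("patient %s: A not strictly before B; excluded", pid)
                continue
            window = [
                ep
                for ep in history.episodes[idx_a:idx_b]
                if ep.admit_date < date_b
            ]
            has_between = any(
                ep.admit_date > date_a for ep in history.episodes[idx_a + 1 : idx_b]
            )
            if not has_between:
                continue
            funnel["A_then_B"] += 1
            if not _has_mapped_code(window, cmap):
                continue
            funnel["A_then_B_with_comorbidity"] += 1
            ab.members[pid] = ObservationWindow(
                patient_id=pid,
                qualifying_episodes=window,
                first_A_date=date_a,
                first_B_date=date_b,
            )
        else:
            window = [ep for ep in history.episodes if ep.admit_date < date_a]
            if not window:
                continue
            funnel["A_without_B"] += 1
            if not _has_mapped_code(window, cmap):
                continue
            funnel["A_without_B_with_comorbidity"] += 1
            a_only.members[pid] = ObservationWindow(
                patient_id=pid,
                qualifying_episodes=window,
                first_A_date=date_a,
            )

    if not ab.members or not a_only.members:
        logger.warning(
            "empty cohort(s): |%s|=%d, |%s|=%d",
            ab.label, len(ab), a_only.label, len(a_only),
        )
    return ab, a_only, funnel


def sample_equal(cohort: CohortSelection, n: int, seed: int) -> CohortSelection:
    """Uniform subsample without replacement; reproducible per seed."""
    if n > len(cohort):
        raise ValueError(f"cannot sample {n} from cohort of size {len(cohort)}")
    pids = sorted(cohort.members)
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(pids), size=n, replace=False).tolist())
    return CohortSelection(
        label=cohort.label,
        members={pids[i]: cohort.members[pids[i]] for i in chosen},
    )


def membership_table(*cohorts: CohortSelection) -> pd.DataFrame:
    """Flat cohort-membership table for export."""
    rows = []
    for cohort in cohorts:
        for pid in sorted(cohort.members):
            window = cohort.members[pid]
            rows.append(
                {
                    "patient_id": pid,
                    "cohort": cohort.label,
                    "first_A_date": window.first_A_date,
                    "first_B_date": window.first_B_date,
                    "n_qualifying_episodes": len(window.qualifying_episodes),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "cohort", "first_A_date", "first_B_date",
            "n_qualifying_episodes",
        ],
    )
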