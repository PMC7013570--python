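import pandas as pd
import pytest

from comorbnet import (
    SyntheticConfig,
    aggregate,
    attribution_adjust,
    build_histories,
    build_individual,
    clean_records,
    generate,
    load_mapping,
    read_episode_table,
    sample_equal,
    select_cohorts,
)


@pytest.fixture(scope="session")
def tables():
    return load_mapping()


@pytest.fixture(scope="session")
def t2dm(tables):
    return tables.index_diseases["T2DM"]


@pytest.fixture(scope="session")
def cvd(tables):
    return tables.index_diseases["CVD"]


def run_to_final(table: pd.DataFrame, tables, equalize_seed=None):
    """Generated episode table → (final network, baselines, cohorts)."""
    episodes, _ = read_episode_table(table)
    cleaned, _ = clean_records(episodes, tables.exclusions)
    histories = build_histories(cleaned)
    ab, a_only, _ = select_cohorts(
        histories,
        tables.index_diseases["T2DM"],
        tables.index_diseases["CVD"],
        tables.comorbidities,
    )
    if equalize_seed is not None:
        n = min(len(ab), len(a_only))
        ab = sample_equal(ab, n, equalize_seed)
        a_only = sample_equal(a_only, n, equalize_seed + 1)
    baseline_ab = aggregate(
        [build_individual(ab.members[p], tables.comorbidities) for p in sorted(ab.members)],
        label="N_dual",
    )
    baseline_a = aggregate(
        [build_individual(a_only.members[p], tables.comorbidities) for p in sorted(a_only.members)],
        label="N_single",
    )
    final = attribution_adjust(baseline_ab, baseline_a)
    return final, (baseline_ab, baseline_a), (ab, a_only)


@pytest.fixture(scope="session")
def pipeline_to_final():
    return run_to_final


@pytest.fixture(scope="session")
def small_run(tables):
    """A modest synthetic cohort pushed through the whole method once."""
    table, truth = generate(
        SyntheticConfig(n_patients_ab=60, n_patients_a=60, seed=42)
    )
    final, baselines, cohorts = run_to_final(table, tables)
    return {
        "table": table,
        "truth": truth,
        "final": final,
        "baselines": baselines,
        "cohorts": cohorts,
    }
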