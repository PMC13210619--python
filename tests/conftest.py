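"""Session fixtures: synthetic cohorts generated once and shared.

Cohort variants and their roles:

* ``default_run`` — the full 31/25 cohort with all planted class effects;
  the effect-recovery benchmark.
* ``null_run`` — class effects off (shorter recordings); chance-level
  control.
* ``fingerprint_run`` — class effects off but strong stable per-subject
  spectral fingerprints; the segment-wise leakage demonstration.
* ``beta_only_run`` — small cohort with only the fronto-central beta
  effect; importance-recovery and spectral-effect isolation.
* ``coupling_only_run`` — small cohort with only the fronto-parietal alpha
  coupling contrast; connectivity-effect isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from eegscreen.cohort import Roster, build_roster
from eegscreen.evaluation import (
    MetricsReport, ProtocolConfig, SegmentDataset,
    run_repeated_holdout, segmentwise_split_comparison,
)
from eegscreen.experiments import ExperimentConfig, prepare_dataset
from eegscreen.features import connectivity_feature_names, spectral_feature_names
from eegscreen.models import ModelConfig
from eegscreen.synthgen import (
    CohortSpec, fingerprint_only_spec, null_spec, write_cohort,
)


@dataclass
class CohortRun:
    spec: CohortSpec
    root: object
    roster: Roster
    dataset: SegmentDataset


def _prepare(spec: CohortSpec, root) -> CohortRun:
    write_cohort(spec, root)
    roster, dataset = prepare_dataset(ExperimentConfig(dataset_root=root))
    return CohortRun(spec=spec, root=root, roster=roster, dataset=dataset)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> CohortRun:
    return _prepare(CohortSpec(seed=11),
                    tmp_path_factory.mktemp("cohort_default"))


@pytest.fixture(scope="session")
def et_default_report(default_run) -> MetricsReport:
    """Spectral Extra Trees under the full ten-repeat protocol."""
    ds = default_run.dataset.select_features(spectral_feature_names())
    return run_repeated_holdout(
        default_run.roster, ds, ModelConfig(model_id="et"),
        ProtocolConfig(), keep_fitted=True,
    )


@pytest.fixture(scope="session")
def null_run(tmp_path_factory) -> CohortRun:
    return _prepare(null_spec(duration_range=(40.0, 60.0), seed=5),
                    tmp_path_factory.mktemp("cohort_null"))


@pytest.fixture(scope="session")
def et_null_report(null_run) -> MetricsReport:
    ds = null_run.dataset.select_features(spectral_feature_names())
    return run_repeated_holdout(null_run.roster, ds,
                                ModelConfig(model_id="et"), ProtocolConfig())


@pytest.fixture(scope="session")
def fingerprint_run(tmp_path_factory) -> CohortRun:
    return _prepare(fingerprint_only_spec(duration_range=(40.0, 60.0), seed=9),
                    tmp_path_factory.mktemp("cohort_fingerprint"))


@pytest.fixture(scope="session")
def leakage_comparison(fingerprint_run):
    ds = fingerprint_run.dataset.select_features(spectral_feature_names())
    return segmentwise_split_comparison(
        fingerprint_run.roster, ds, ModelConfig(model_id="et"),
        ProtocolConfig(),
    )


@pytest.fixture(scope="session")
def beta_only_run(tmp_path_factory) -> CohortRun:
    spec = CohortSpec(
        n_patients=12, n_controls=12, duration_range=(40.0, 60.0),
        effect_alpha_asym_shift=0.0, coupling_mdd=0.6, coupling_control=0.6,
        seed=3,
    )
    return _prepare(spec, tmp_path_factory.mktemp("cohort_beta"))


@pytest.fixture(scope="session")
def et_beta_report(beta_only_run) -> MetricsReport:
    ds = beta_only_run.dataset.select_features(spectral_feature_names())
    return run_repeated_holdout(beta_only_run.roster, ds,
                                ModelConfig(model_id="et"), ProtocolConfig(),
                                keep_fitted=True)


@pytest.fixture(scope="session")
def coupling_only_run(tmp_path_factory) -> CohortRun:
    spec = CohortSpec(
        n_patients=12, n_controls=12, duration_range=(40.0, 60.0),
        effect_beta_gain=1.0, effect_alpha_asym_shift=0.0,
        coupling_control=0.8, coupling_mdd=0.2, seed=13,
    )
    return _prepare(spec, tmp_path_factory.mktemp("cohort_coupling"))


@pytest.fixture(scope="session")
def coupling_family_reports(coupling_only_run) -> dict[str, MetricsReport]:
    """ET on each feature family for the coupling-only cohort."""
    protocol = ProtocolConfig(n_repeats=5)
    out = {}
    for name, cols in (("spectral", spectral_feature_names()),
                       ("connectivity", connectivity_feature_names())):
        ds = coupling_only_run.dataset.select_features(cols)
        out[name] = run_repeated_holdout(
            coupling_only_run.roster, ds, ModelConfig(model_id="et"),
            protocol, keep_fitted=(name == "connectivity"),
        )
    return out
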