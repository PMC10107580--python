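"""Shared fixtures: synthetic landscapes at two scales, curated and labelled.

All fixtures are generated programmatically at test time; the session-scoped
``default_run`` is the full-size study landscape reused by the acceptance
checks, the function-light ``small_run`` is a noise-free miniature."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from acqsar.curation import CompoundSet, CurationLog, RawEntry, curate
from acqsar.mmp import MMPSet, MMPSummary, detect_mmps, finalise_mmp_set, label_mmps
from acqsar.synth import GroundTruth, LandscapeSpec, default_landscape, generate


@dataclass
class PipelineRun:
    spec: LandscapeSpec
    truth: GroundTruth
    compounds: CompoundSet
    curation_log: CurationLog
    mmps_labelled: MMPSet     # including half-ACs
    mmps: MMPSet              # half-ACs removed
    summary: MMPSummary


def _run_pipeline(spec: LandscapeSpec) -> PipelineRun:
    table, truth = generate(spec)
    entries = [RawEntry(r.smiles, r.activity, r.unit) for r in table.itertuples()]
    compounds, log = curate(entries)
    labelled = label_mmps(detect_mmps(compounds), compounds)
    final, summary = finalise_mmp_set(labelled)
    return PipelineRun(
        spec=spec,
        truth=truth,
        compounds=compounds,
        curation_log=log,
        mmps_labelled=labelled,
        mmps=final,
        summary=summary,
    )


@pytest.fixture(scope="session")
def default_run() -> PipelineRun:
    """The full default landscape (~1000 compounds, noise sd 0.3, seed 0)."""
    return _run_pipeline(default_landscape(seed=0))


@pytest.fixture()
def toy_split():
    """A hand-built tie-free split whose inter, test and cores pair sets all
    contain both an AC and a non-AC: labels chosen so every delta is either
    >= 2.5 (AC) or <= 0.5 (non-AC)."""
    from acqsar.mmp import MMPRecord, MMPSet, assign_ac_class
    from acqsar.splitting import SplitInstance, derive_mmp_sets

    labels = {"a": 0.0, "b": 3.0, "c": 10.0, "d": 10.5, "e": 2.5, "f": 2.8, "g": 5.3, "h": 7.8}
    d_train = frozenset({"a", "b", "c", "d"})
    d_test = frozenset({"e", "f", "g", "h"})

    def rec(i, j, core):
        a1, a2 = labels[i], labels[j]
        return MMPRecord(
            i, j, core, "*X", "*Y", n_core=10, n_var_1=1, n_var_2=2,
            delta_label=abs(a1 - a2), ac_class=assign_ac_class(a1, a2),
            pd_label=i if a1 > a2 else j,
        )

    mmps = MMPSet(records=[
        rec("a", "b", "K1"), rec("c", "d", "K2"),          # train: AC + non-AC
        rec("a", "e", "K1"), rec("b", "f", "K3"),          # inter: AC + non-AC
        rec("g", "h", "K4"), rec("e", "f", "K5"),          # test, novel cores
        rec("f", "g", "K1"),                               # test, core seen in training
    ])
    m_train, m_inter, m_test, m_cores = derive_mmp_sets(d_train, d_test, mmps)
    split = SplitInstance(
        seed_index=0, fold_index=0, seed=0,
        d_train=d_train, d_test=d_test,
        m_train=m_train, m_inter=m_inter, m_test=m_test, m_cores=m_cores,
        c_train=frozenset(m_train.cores() | m_inter.cores()),
    )
    assert {r.ac_class for r in split.m_inter} == {"AC", "non-AC"}
    assert {r.ac_class for r in split.m_test} == {"AC", "non-AC"}
    assert {r.ac_class for r in split.m_cores} == {"AC", "non-AC"}
    return labels, split


@pytest.fixture(scope="session")
def small_noise_free_run() -> PipelineRun:
    """A noise-free miniature (6 scaffolds x 10 substituents, exact labels)."""
    spec = default_landscape(
        seed=3, n_scaffolds=6, n_substituents=10, noise_sd=0.0, duplicate_jitter=0.0
    )
    return _run_pipeline(spec)
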