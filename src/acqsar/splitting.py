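"""Compound-level random splits and the derived pair-level MMP sets.

The data set D is split at the level of individual molecules into k
near-equal random folds, repeated with m seeds. For each (seed, fold)
instance, every MMP falls into exactly one of three pair sets:

* ``M_train``: both compounds in the training set,
* ``M_inter``: exactly one compound in the training set (the setting where
  one activity is known a priori),
* ``M_test``: both compounds in the test set.

``M_cores`` is the subset of ``M_test`` whose canonical core SMILES does not
occur among the cores of ``M_train`` u ``M_inter`` — pairs with no near
analog reachable from training. Under k=2 the expected relative sizes are
|M_train| : |M_inter| : |M_test| = 1 : 2 : 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import CompoundSet
from .mmp import MMPSet


@dataclass(frozen=True)
class CrossValidationPlan:
    """k-fold cross-validation repeated with m random seeds."""

    m: int = 3
    k: int = 2
    seeds: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.m < 1 or self.k < 2:
            raise ValueError("need m >= 1 and k >= 2")
        if len(self.seeds) != self.m:
            raise ValueError("need exactly one seed per repetition")


@dataclass
class SplitInstance:
    """One (seed n, fold l) realisation of the compound- and pair-level split."""

    seed_index: int
    fold_index: int
    seed: int
    d_train: frozenset[str]
    d_test: frozenset[str]
    m_train: MMPSet
    m_inter: MMPSet
    m_test: MMPSet
    m_cores: MMPSet
    c_train: frozenset[str]

    def counts(self) -> dict[str, int]:
        return {
            "d_train": len(self.d_train),
            "d_test": len(self.d_test),
            "m_train": len(self.m_train),
            "m_inter": len(self.m_inter),
            "m_test": len(self.m_test),
            "m_cores": len(self.m_cores),
        }


def split_folds(ids: list[str], k: int, seed: int) -> list[list[str]]:
    """Uniform random partition into k near-equal folds: random permutation,
    then contiguous chunks, remainder going to the earliest folds."""
    if len(ids) < k:
        raise ValueError(f"cannot split {len(ids)} compounds into {k} folds")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    base, rem = divmod(len(ids), k)
    folds, start = [], 0
    for l in range(k):
        size = base + (1 if l < rem else 0)
        folds.append(perm[start : start + size])
        start += size
    return folds


def split_compounds(
    compounds: CompoundSet, plan: CrossValidationPlan
) -> list[tuple[int, int, frozenset[str], frozenset[str]]]:
    """Yield (seed_index, fold_index, d_train, d_test) for every (n, l)."""
    ids = sorted(r.compound_id for r in compounds)
    out = []
    for n, seed in enumerate(plan.seeds):
        folds = split_folds(ids, plan.k, seed)
        for l in range(plan.k):
            d_test = frozenset(folds[l])
            d_train = frozenset(ids) - d_test
            out.append((n, l, d_train, d_test))
    return out


def derive_mmp_sets(
    d_train: frozenset[str], d_test: frozenset[str], mmps: MMPSet
) -> tuple[MMPSet, MMPSet, MMPSet, MMPSet]:
    """Partition the MMPs into (m_train, m_inter, m_test) and extract m_cores."""
    train_recs, inter_recs, test_recs = [], [], []
    universe = d_train | d_test
    for r in mmps:
        missing = {r.id_1, r.id_2} - universe
        if missing:
            raise KeyError(f"MMP references compounds outside the split: {sorted(missing)}")
        n_in_train = (r.id_1 in d_train) + (r.id_2 in d_train)
        (test_recs, inter_recs, train_recs)[n_in_train].append(r)
    c_train = {r.core_smiles for r in train_recs} | {r.core_smiles for r in inter_recs}
    cores_recs = [r for r in test_recs if r.core_smiles not in c_train]
    return (
        MMPSet(records=train_recs),
        MMPSet(records=inter_recs),
        MMPSet(records=test_recs),
        MMPSet(records=cores_recs),
    )


def make_split_instances(
    compounds: CompoundSet, mmps: MMPSet, plan: CrossValidationPlan
) -> list[SplitInstance]:
    """All m*k SplitInstances of the repeated cross-validation plan."""
    instances = []
    for n, l, d_train, d_test in split_compounds(compounds, plan):
        m_train, m_inter, m_test, m_cores = derive_mmp_sets(d_train, d_test, mmps)
        c_train = frozenset(m_train.cores() | m_inter.cores())
        instances.append(
            SplitInstance(
                seed_index=n,
                fold_index=l,
                seed=plan.seeds[n],
                d_train=d_train,
                d_test=d_test,
                m_train=m_train,
                m_inter=m_inter,
                m_test=m_test,
                m_cores=m_cores,
                c_train=c_train,
            )
        )
    return instances


def write_split_instance(split: SplitInstance, compound_path, pair_path, manifest_path) -> None:
    """Persist one SplitInstance as compound/pair assignment CSVs + JSON manifest."""
    rows = [(cid, "train") for cid in sorted(split.d_train)] + [
        (cid, "test") for cid in sorted(split.d_test)
    ]
    pd.DataFrame(rows, columns=["compound_id", "role"]).to_csv(compound_path, index=False)

    core_pairs = split.m_cores.pairs()
    pair_rows = []
    for tag, mset in (("train", split.m_train), ("inter", split.m_inter), ("test", split.m_test)):
        for r in mset:
            pair_rows.append((r.id_1, r.id_2, tag, r.pair in core_pairs))
    pd.DataFrame(
        pair_rows, columns=["compound_id_1", "compound_id_2", "set", "in_cores"]
    ).to_csv(pair_path, index=False)

    manifest = {"seed_index": split.seed_index, "fold_index": split.fold_index, "seed": split.seed}
    manifest.update(split.counts())
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
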