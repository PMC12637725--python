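"""Shared fixtures: cached default-cohort pipeline runs and truth maps."""

from __future__ import annotations

import collections
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nephroniche import catalogs
from nephroniche.cell_typing import apply_typing, normalize_expression
from nephroniche.cohort import Cohort
from nephroniche.niche_typing import type_niches
from nephroniche.synthetic import default_config, generate_cohort
from nephroniche.tiling import NicheSet, tile_cohort


@dataclass
class PipelineRun:
    """One fully processed default cohort plus ground-truth lookups."""

    seed: int
    cohort: Cohort
    niches: NicheSet
    norm_niche: sp.csr_matrix
    true_type: pd.Series          # cell key -> true cell type
    niche_major: pd.Series        # niche_id -> majority true domain
    niche_subtype: pd.Series      # niche_id -> majority immune archetype ('')

    @property
    def condition_of(self) -> pd.Series:
        return self.cohort.samples.set_index("sample_id")["condition"]


def _build_run(seed: int) -> PipelineRun:
    cohort = generate_cohort(default_config(seed=seed))
    apply_typing(cohort, catalogs.CELL_TYPE_MARKERS)
    niches = tile_cohort(cohort, seed=seed)
    type_niches(niches, catalogs.NICHE_TYPE_MARKERS,
                catalogs.IMMUNE_SUBTYPE_MARKERS, seed=seed)
    truth = cohort.ground_truth.cells
    key = truth["sample_id"] + ":" + truth["cell_id"]
    true_type = pd.Series(truth["true_type"].to_numpy(), index=key)
    dom = dict(zip(key, truth["domain"]))
    subd = dict(zip(key, truth["subdomain"]))
    per_niche: dict[str, list] = {}
    per_niche_sub: dict[str, list] = {}
    for cell_key, nid in niches.assignment.items():
        per_niche.setdefault(nid, []).append(dom[cell_key])
        per_niche_sub.setdefault(nid, []).append(subd[cell_key])
    major = {}
    sub = {}
    for nid in niches.table["niche_id"]:
        major[nid] = collections.Counter(per_niche[nid]).most_common(1)[0][0]
        c = collections.Counter(x for x in per_niche_sub[nid] if x)
        sub[nid] = c.most_common(1)[0][0] if c else ""
    return PipelineRun(
        seed=seed,
        cohort=cohort,
        niches=niches,
        norm_niche=normalize_expression(niches.counts),
        true_type=true_type,
        niche_major=pd.Series(major),
        niche_subtype=pd.Series(sub),
    )


_RUN_CACHE: dict[int, PipelineRun] = {}


@pytest.fixture(scope="session")
def pipeline_run():
    """Factory: fully processed default cohort for a seed (cached)."""

    def get(seed: int = 1) -> PipelineRun:
        if seed not in _RUN_CACHE:
            _RUN_CACHE[seed] = _build_run(seed)
        return _RUN_CACHE[seed]

    return get


@pytest.fixture(scope="session")
def run1(pipeline_run) -> PipelineRun:
    """The seed-1 default cohort used throughout the suite."""
    return pipeline_run(1)
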