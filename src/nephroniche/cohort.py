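"""In-memory cohort container shared by the generator, readers and pipeline.

A cohort bundles the four on-disk artifacts of a segmented spatial
transcriptomics experiment (cells, transcripts, sparse counts, sample
metadata) plus, for synthetic cohorts, the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: sentinel cell_id for transcript spots not assigned to any cell
UNASSIGNED = ""

CELLS_COLUMNS = ["cell_id", "sample_id", "x_um", "y_um", "n_transcripts",
                 "type_label", "qc_pass"]
TRANSCRIPTS_COLUMNS = ["sample_id", "gene", "x_um", "y_um", "cell_id"]
SAMPLES_COLUMNS = ["sample_id", "condition", "biopsy_area_mm2"]

CONDITIONS = ("AIN", "ATN")


@dataclass
class GroundTruth:
    """Per-cell truth of a synthetic cohort plus the planted effect values.

    ``cells`` has one row per cell with columns ``sample_id, cell_id,
    true_type, domain, subdomain`` (``domain`` is the anatomical/niche
    archetype; ``subdomain`` the immune archetype or empty).
    """

    cells: pd.DataFrame
    planted: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "cells": {c: self.cells[c].tolist() for c in self.cells.columns},
            "planted": self.planted,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GroundTruth":
        return cls(cells=pd.DataFrame(d["cells"]), planted=d["planted"])


@dataclass
class Cohort:
    """Cells + transcripts + counts + sample metadata (+ optional truth).

    ``counts`` is a CSR matrix of shape (n_cells, n_genes) aligned with
    ``cells`` rows and ``genes``; rows hold the transcript spots assigned to
    each cell.
    """

    cells: pd.DataFrame
    transcripts: pd.DataFrame
    counts: sp.csr_matrix
    genes: list[str]
    samples: pd.DataFrame
    ground_truth: GroundTruth | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def cell_keys(self) -> pd.Index:
        """Globally unique cell keys '<sample_id>:<cell_id>'."""
        return pd.Index(self.cells["sample_id"] + ":" + self.cells["cell_id"])

    def validate(self) -> None:
        """Cross-table consistency checks (raise on violation)."""
        from .errors import ReferentialIntegrityError, SchemaError

        for col in CELLS_COLUMNS:
            if col not in self.cells.columns:
                raise SchemaError(f"cells table missing column {col!r}")
        for col in TRANSCRIPTS_COLUMNS:
            if col not in self.transcripts.columns:
                raise SchemaError(f"transcripts table missing column {col!r}")
        for col in SAMPLES_COLUMNS:
            if col not in self.samples.columns:
                raise SchemaError(f"samples table missing column {col!r}")
        if self.cells.duplicated(["sample_id", "cell_id"]).any():
            raise ReferentialIntegrityError("duplicate (sample_id, cell_id)")
        bad_cond = set(self.samples["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise SchemaError(f"unknown condition labels: {sorted(bad_cond)}")
        if (self.samples["biopsy_area_mm2"] <= 0).any():
            raise SchemaError("biopsy_area_mm2 must be positive")
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise SchemaError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        xy = self.cells[["x_um", "y_um"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise SchemaError("non-finite cell coordinates")
        # every assigned transcript must reference an existing cell
        assigned = self.transcripts[self.transcripts["cell_id"] != UNASSIGNED]
        keys = set(self.cells["sample_id"] + ":" + self.cells["cell_id"])
        t_keys = assigned["sample_id"] + ":" + assigned["cell_id"]
        dangling = sorted(set(t_keys) - keys)
        if dangling:
            raise ReferentialIntegrityError(
                "transcripts reference unknown cells: "
                + ", ".join(dangling[:10])
            )
        # row sums of counts agree with per-cell transcript totals
        row_sums = np.asarray(self.counts.sum(axis=1)).ravel()
        if not np.array_equal(row_sums, self.cells["n_transcripts"].to_numpy()):
            raise ReferentialIntegrityError(
                "counts row sums disagree with cells.n_transcripts"
            )
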