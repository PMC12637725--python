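"""Synthetic multi-sample spatial transcriptomics cohorts with planted effects.

Each sample is a rectangular tissue with nephron-like anatomy: horizontal
tubule bands (proximal tubule, thick ascending limb, distal convoluted
tubule, collecting duct), disjoint glomerular disks, vertical vascular
strips, fibrosis patches, injured-proximal-tubule patches and immune
aggregates carrying one of seven immune archetypes. Cells are typed first
(per-condition composition with planted AIN/ATN fold enrichments), placed
into their home domains, and expressed with a gamma-Poisson (negative
binomial) model. Condition effects are planted on the expression rates:

* an IFN-gamma response shift in immune domains of AIN samples,
* oxidative-phosphorylation suppression in tubular cells proportional to
  ``exp(-c * activity * I(x))`` where ``I`` is a smooth intensity field
  radiating from immune aggregates,
* IFNG transcript emission split across immune types at configured
  attribution fractions,
* archetype-specific chemokine programs (CXCL9/10/11 in myeloid
  inflammation, CXCL13/CCL19 in TLS-like aggregates, CXCL12 around plasma
  cells, ...), with myeloid-inflammation aggregates placed tangent to
  CD8-infiltrated aggregates in AIN and M2-like aggregates tangent to
  fibrosis patches.

Every immune aggregate carries a shared pan-immune infiltrate (an
``ANY_AGGREGATE`` placement pool plus a shared ambient T-cell program), so
immune niches form one major expression family whose subtypes differ by
archetype flavour — mirroring tissue where T cells pervade all immune
niches.

Transcript spots are scattered isotropically around their cell centroid
(sigma = cell_radius / 2); spots farther than one cell radius from the
centroid lose their cell assignment, emulating segmentation leakage. The
counts matrix holds assigned spots only, so its total equals the number of
cell-assigned transcript rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import catalogs
from .cohort import Cohort, GroundTruth, UNASSIGNED
from .errors import ConfigurationError

# ---------------------------------------------------------------------------
# configuration

TUBULE_DOMAINS = (
    "proximal tubule", "thick ascending limb", "distal convoluted tubule",
    "collecting duct", "injured proximal tubule",
)

AIN_ARCHETYPE_CYCLE = (
    "CD8 infiltrated kidney", "myeloid inflammation", "TLS-like",
    "plasma cell", "pDC", "M2-like", "inflammation with fibrosis",
    "CD8 infiltrated kidney", "myeloid inflammation", "TLS-like",
)
ATN_ARCHETYPE_CYCLE = (
    "CD8 infiltrated kidney", "M2-like", "myeloid inflammation", "pDC",
)

#: extra expression (counts/cell) added to every cell inside an aggregate
AMBIENT_PROGRAMS: dict[str, dict[str, float]] = {
    "myeloid inflammation": {
        "CXCL9": 4.0, "CXCL10": 4.0, "CXCL11": 3.0, "MMP9": 2.0,
        "IDO1": 2.0, "CSF2RB": 2.0,
    },
    "TLS-like": {
        "CXCL13": 2.5, "CCL19": 2.0, "CCL21": 1.0, "CXCR5": 1.5,
        "CCR7": 1.5, "CD28": 1.0, "ICOS": 1.0,
    },
    "CD8 infiltrated kidney": {"CXCR3": 5.0, "CXCR6": 3.0, "GZMK": 2.0,
                               "CD8A": 2.5, "GZMA": 1.5},
    # niche-level flavours use second-tier genes absent from the cell-typing
    # catalog, so per-cell identities are unaffected by the ambient signal
    "plasma cell": {"CXCL12": 5.0, "CCR4": 2.0, "JCHAIN": 2.5, "PRDM1": 3.0,
                    "DERL3": 3.0},
    "pDC": {"TCF4": 3.0, "GZMB": 3.0},
    # tissue-resident macrophage niches sit against fibrosis patches and
    # carry a matrix-remodelling program of their own
    "M2-like": {"CD163": 3.0, "MRC1": 3.0, "F13A1": 2.0, "STAB1": 2.0,
                "COL1A1": 3.5, "COL3A1": 3.5, "FN1": 2.5, "LUM": 2.5},
    "inflammation with fibrosis": {
        "COL5A1": 2.0, "PDGFRA": 2.0, "POSTN": 1.5, "CXCL9": 1.5,
    },
}

#: pan-immune ambient expression shared by every aggregate
SHARED_IMMUNE_AMBIENT: dict[str, float] = {
    "PTPRC": 4.0, "CD3E": 3.0, "CD3D": 2.0, "B2M": 2.0, "SLAMF7": 1.5,
    "CD38": 1.5, "GZMA": 1.0, "FASLG": 0.8,
}

#: extra per-domain ambient programs (stressed-tubule injury markers inside
#: injured patches; matrix program inside fibrosis patches)
DOMAIN_AMBIENT: dict[str, dict[str, float]] = {
    "fibrotic": {g: 1.2 for g in catalogs.FIBROSIS_PROGRAM},
    # half of the injury typing markers, scaled up: niches read as injured
    # while cells of other types passing through keep their own identity
    "injured proximal tubule": {"HAVCR1": 7.0, "SOX9": 6.0},
}

#: immune type -> archetype affinity. The ``ANY_AGGREGATE`` share places the
#: cell uniformly across all aggregates of its sample (the shared infiltrate
#: every immune niche carries); the remaining mass scatters uniformly.
ANY_AGGREGATE = "__any__"
IMMUNE_AFFINITY: dict[str, dict[str, float]] = {
    "CD4 T": {"TLS-like": 0.20, ANY_AGGREGATE: 0.60},
    "CD8 T": {"CD8 infiltrated kidney": 0.35, "myeloid inflammation": 0.10,
              ANY_AGGREGATE: 0.40},
    "Treg": {"TLS-like": 0.15, "CD8 infiltrated kidney": 0.10,
             "myeloid inflammation": 0.10, ANY_AGGREGATE: 0.50},
    "Proliferating T": {"CD8 infiltrated kidney": 0.20, "TLS-like": 0.15,
                        ANY_AGGREGATE: 0.50},
    "NK": {"CD8 infiltrated kidney": 0.15, "myeloid inflammation": 0.10,
           ANY_AGGREGATE: 0.50},
    "B": {"TLS-like": 0.35, ANY_AGGREGATE: 0.45},
    "Plasma": {"plasma cell": 0.20, "TLS-like": 0.05, ANY_AGGREGATE: 0.45},
    # pDC niches are defined purely by their cellular composition
    "pDC": {"pDC": 0.50, "TLS-like": 0.05, ANY_AGGREGATE: 0.20},
    "cDC1": {"TLS-like": 0.15, "myeloid inflammation": 0.15,
             ANY_AGGREGATE: 0.50},
    "Monocyte": {"myeloid inflammation": 0.35,
                 "inflammation with fibrosis": 0.10, ANY_AGGREGATE: 0.40},
    "Inflammatory myeloid": {"myeloid inflammation": 0.55,
                             "inflammation with fibrosis": 0.10,
                             ANY_AGGREGATE: 0.25},
    "Tissue-resident macrophage": {"M2-like": 0.55,
                                   "inflammation with fibrosis": 0.10,
                                   ANY_AGGREGATE: 0.25},
    "Mast": {ANY_AGGREGATE: 0.40},
}


@dataclass
class AnatomySpec:
    """Geometry of one simulated biopsy (all lengths in micrometres)."""

    band_cycle: tuple[str, ...] = (
        "proximal tubule", "thick ascending limb", "proximal tubule",
        "distal convoluted tubule", "proximal tubule", "collecting duct",
    )
    #: per-band widths (um), cycled with ``band_cycle``; narrow distal
    #: segments keep their cell density comparable to the bulk segments
    band_widths_um: tuple[float, ...] = (90.0, 100.0, 90.0, 70.0, 90.0, 70.0)
    glomerulus_count: int = 6
    glomerulus_radius_um: float = 45.0
    vascular_band_um: float = 40.0
    vascular_positions: tuple[float, ...] = (0.25, 0.72)
    fibrosis_count_ain: int = 5
    fibrosis_count_atn: int = 2
    fibrosis_radius_um: float = 55.0
    aggregate_count_ain: int = 10
    aggregate_count_atn: int = 4
    aggregate_radius_ain: float = 60.0
    aggregate_radius_atn: float = 50.0
    injured_count_ain: int = 1
    injured_count_atn: int = 6
    injured_radius_um: float = 50.0

    def validate(self) -> None:
        if len(self.band_widths_um) != len(self.band_cycle):
            raise ConfigurationError(
                "band_widths_um must match band_cycle length")
        if any(w <= 0 for w in self.band_widths_um):
            raise ConfigurationError("band widths must be positive")
        for name in ("glomerulus_radius_um",
                     "vascular_band_um", "fibrosis_radius_um",
                     "aggregate_radius_ain", "aggregate_radius_atn",
                     "injured_radius_um"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("glomerulus_count", "fibrosis_count_ain",
                     "fibrosis_count_atn", "aggregate_count_ain",
                     "aggregate_count_atn", "injured_count_ain",
                     "injured_count_atn"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def band_edges(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.band_widths_um)])

    def band_at(self, y: np.ndarray) -> np.ndarray:
        edges = self.band_edges()
        ym = np.mod(np.asarray(y, float), edges[-1])
        idx = np.clip(np.searchsorted(edges, ym, side="right") - 1,
                      0, len(self.band_cycle) - 1)
        return np.asarray(self.band_cycle, object)[idx]

    def band_intervals(self, name: str,
                       height_um: float) -> list[tuple[float, float]]:
        """(y0, y1) strips of a named band type within [0, height_um)."""
        edges = self.band_edges()
        total = edges[-1]
        out: list[tuple[float, float]] = []
        base = 0.0
        while base < height_um:
            for i, b in enumerate(self.band_cycle):
                y0, y1 = base + edges[i], base + edges[i + 1]
                if y0 >= height_um:
                    break
                if b == name:
                    out.append((y0, min(y1, height_um)))
            base += total
        return out


@dataclass
class EffectSpec:
    """Planted AIN-vs-ATN condition effects."""

    folds: dict[str, float | None] = field(
        default_factory=lambda: dict(catalogs.AIN_FOLDS))
    ifng_log_fold: float = math.log(3.0)
    ifng_tubule_gain: float = 5.0
    oxphos_suppression: float = 1.8
    atn_ifng_activity: float = 0.1
    ifng_attribution: dict[str, float] = field(
        default_factory=lambda: dict(catalogs.IFNG_ATTRIBUTION))
    ifng_budget: float = 3200.0
    ambient_programs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in AMBIENT_PROGRAMS.items()})
    #: pan-immune program added to every cell of every aggregate
    shared_immune_ambient: dict[str, float] = field(
        default_factory=lambda: dict(SHARED_IMMUNE_AMBIENT))
    domain_ambient: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DOMAIN_AMBIENT.items()})

    @classmethod
    def neutral(cls) -> "EffectSpec":
        """All folds 1, no expression shifts, no attribution planting."""
        return cls(folds={}, ifng_log_fold=0.0, ifng_tubule_gain=0.0,
                   oxphos_suppression=0.0, atn_ifng_activity=0.0,
                   ifng_attribution={}, ifng_budget=0.0,
                   ambient_programs={}, shared_immune_ambient={},
                   domain_ambient={})


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort."""

    panel: list[str]
    type_programs: dict[str, dict[str, float]]
    base_proportions: dict[str, float]
    anatomy: AnatomySpec = field(default_factory=AnatomySpec)
    effects: EffectSpec = field(default_factory=EffectSpec)
    n_samples_per_condition: int = 4
    cells_per_sample: int = 5000
    biopsy_area_mm2: float = 1.0
    seed: int = 0
    dispersion: float = 0.25
    cell_radius_um: float = 5.0
    dirichlet_concentration: float = 50000.0

    def validate(self) -> None:
        if not self.panel:
            raise ConfigurationError("gene panel is empty")
        if len(set(self.panel)) != len(self.panel):
            raise ConfigurationError("panel contains duplicate genes")
        if self.cells_per_sample < 0:
            raise ConfigurationError("cells_per_sample must be >= 0")
        if self.n_samples_per_condition < 1:
            raise ConfigurationError("need at least one sample per condition")
        if self.biopsy_area_mm2 <= 0:
            raise ConfigurationError("biopsy_area_mm2 must be positive")
        self.anatomy.validate()
        panel = set(self.panel)
        for t, prog in self.type_programs.items():
            missing = set(prog) - panel
            if missing:
                raise ConfigurationError(
                    f"type program {t!r} references genes absent from the "
                    f"panel: {sorted(missing)[:5]}")
            if any(r < 0 for r in prog.values()):
                raise ConfigurationError(f"negative rate in program {t!r}")
        for t in self.base_proportions:
            if t not in self.type_programs:
                raise ConfigurationError(f"no expression program for {t!r}")
        unknown = set(self.effects.folds) - set(self.base_proportions)
        if unknown:
            raise ConfigurationError(
                f"fold enrichment for unknown cell types: {sorted(unknown)}")
        for t, f in self.effects.folds.items():
            if f is not None and f <= 0:
                raise ConfigurationError(f"fold for {t!r} must be > 0")
        fr = self.effects.ifng_attribution
        if any(not (0.0 <= v <= 1.0) for v in fr.values()):
            raise ConfigurationError("attribution fractions must be in [0,1]")
        if sum(fr.values()) > 1.0 + 1e-9:
            raise ConfigurationError("attribution fractions sum above 1")
        if fr and "IFNG" not in panel:
            raise ConfigurationError(
                "IFNG attribution planted but IFNG not in panel")
        unknown = set(fr) - set(self.base_proportions)
        if unknown:
            raise ConfigurationError(
                f"attribution for unknown cell types: {sorted(unknown)}")
        for arch, prog in self.effects.ambient_programs.items():
            missing = set(prog) - panel
            if missing:
                raise ConfigurationError(
                    f"ambient program {arch!r} references genes absent from "
                    f"the panel: {sorted(missing)[:5]}")
        missing = set(self.effects.shared_immune_ambient) - panel
        if missing:
            raise ConfigurationError(
                f"shared immune ambient references genes absent from the "
                f"panel: {sorted(missing)[:5]}")

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.base_proportions)

    def condition_proportions(self, condition: str) -> dict[str, float]:
        """Expected cell-type proportions under a condition.

        AIN proportions are base * fold; one type may carry ``fold=None`` and
        absorbs the balancing mass so both conditions sum to 1.
        """
        types = self.cell_types
        p = np.array([self.base_proportions[t] for t in types], float)
        p = p / p.sum()
        if condition == "ATN":
            return dict(zip(types, p))
        folds = np.array(
            [1.0 if self.effects.folds.get(t) is None
             else self.effects.folds[t] for t in types])
        balance = [t for t in types if self.effects.folds.get(t, 1.0) is None]
        if len(balance) > 1:
            raise ConfigurationError("at most one balancing fold allowed")
        q = folds * p
        if balance:
            i = types.index(balance[0])
            rest = q.sum() - q[i]
            if rest >= 1.0:
                raise ConfigurationError(
                    "planted folds exceed unit mass; no room for the "
                    f"balancing type {balance[0]!r}")
            q[i] = 1.0 - rest
        q = q / q.sum()
        return dict(zip(types, q))


def default_type_programs(panel: list[str]) -> dict[str, dict[str, float]]:
    """Per-type mean expression rates (counts/cell) for the default taxonomy."""
    marker_rate = 8.0
    panel_set = set(panel)
    programs: dict[str, dict[str, float]] = {}
    for t, markers in catalogs.CELL_TYPE_MARKERS.items():
        rate = marker_rate
        if t == "Plasma":
            # plasma cells are numerous in inflamed tissue; a quieter program
            # keeps them from dominating every aggregate's niche profile
            rate = marker_rate * 2.0 / 3.0
        prog = {g: rate for g in markers}
        for g, rel in catalogs.SHARED_PROGRAMS.get(t, {}).items():
            prog[g] = prog.get(g, 0.0) + marker_rate * rel
        for g in catalogs.HOUSEKEEPING:
            prog[g] = prog.get(g, 0.0) + 1.0
        ox = 1.5 if t in catalogs.TUBULE_CELL_TYPES else 0.08
        if t == "Injured proximal tubule":
            ox = 0.5  # injured tubule runs a damped metabolic program
        for g in catalogs.GENE_SETS["Oxidative Phosphorylation"]:
            prog[g] = prog.get(g, 0.0) + ox
        base_ifng = 0.15 if t in catalogs.IMMUNE_CELL_TYPES else 0.05
        for g in catalogs.GENE_SETS["IFNg Response"]:
            prog[g] = prog.get(g, 0.0) + base_ifng
        for g in catalogs.GENE_SETS["JAK-STAT Signaling"]:
            prog[g] = prog.get(g, 0.0) + 0.1
        if t == "Fibroblast":
            for g in catalogs.FIBROSIS_PROGRAM:
                prog[g] = max(prog.get(g, 0.0), 2.0)
        programs[t] = {g: r for g, r in prog.items() if g in panel_set}
    return programs


def default_config(seed: int = 0, **overrides: Any) -> CohortConfig:
    """The default 4+4 AIN/ATN cohort (~5,000 cells/sample, ~300-gene panel)."""
    panel = catalogs.build_default_panel()
    cfg = CohortConfig(
        panel=panel,
        type_programs=default_type_programs(panel),
        base_proportions=dict(catalogs.BASE_PROPORTIONS),
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


# ---------------------------------------------------------------------------
# anatomy

@dataclass
class Anatomy:
    """Realised domain geometry of one sample; maps points to domain labels."""

    width_um: float
    height_um: float
    spec: AnatomySpec
    glomeruli: np.ndarray          # (n, 3) cx, cy, r
    vascular: np.ndarray           # (n, 2) x0, x1
    fibrosis: np.ndarray           # (n, 3)
    injured: np.ndarray            # (n, 3)
    aggregates: np.ndarray         # (n, 3)
    aggregate_archetypes: list[str]

    def band_label(self, y: np.ndarray) -> np.ndarray:
        return self.spec.band_at(y)

    @staticmethod
    def _in_disks(points: np.ndarray, disks: np.ndarray) -> np.ndarray:
        """Index of containing disk per point (-1 if none)."""
        hit = np.full(len(points), -1)
        for i, (cx, cy, r) in enumerate(disks):
            d2 = (points[:, 0] - cx) ** 2 + (points[:, 1] - cy) ** 2
            hit = np.where((hit < 0) & (d2 <= r * r), i, hit)
        return hit

    def label(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(domain, subdomain) per point; every point has exactly one domain."""
        points = np.asarray(points, float).reshape(-1, 2)
        domain = self.band_label(points[:, 1]).astype(object)
        subdomain = np.full(len(points), "", object)
        for x0, x1 in self.vascular:
            m = (points[:, 0] >= x0) & (points[:, 0] < x1)
            domain[m] = "vascular"
        hit = self._in_disks(points, self.glomeruli)
        domain[hit >= 0] = "glomerular"
        hit = self._in_disks(points, self.injured)
        domain[hit >= 0] = "injured proximal tubule"
        hit = self._in_disks(points, self.fibrosis)
        domain[hit >= 0] = "fibrotic"
        hit = self._in_disks(points, self.aggregates)
        m = hit >= 0
        domain[m] = "immune"
        subdomain[m] = [self.aggregate_archetypes[i] for i in hit[m]]
        return domain.astype(str), subdomain.astype(str)

    def ifng_intensity(self, points: np.ndarray) -> np.ndarray:
        """Smooth [0,1] field radiating from immune aggregates."""
        points = np.asarray(points, float).reshape(-1, 2)
        out = np.zeros(len(points))
        for cx, cy, r in self.aggregates:
            d2 = (points[:, 0] - cx) ** 2 + (points[:, 1] - cy) ** 2
            out += np.exp(-d2 / (2.0 * (1.6 * r) ** 2))
        return np.minimum(out, 1.0)


def layout_anatomy(spec: AnatomySpec, rng: np.random.Generator,
                   condition: str = "AIN",
                   width_um: float = 1000.0,
                   height_um: float = 1000.0) -> Anatomy:
    """Realise the domain geometry of one sample.

    Glomeruli are laid out on a jittered grid (guaranteeing disjoint disks);
    fibrosis patches at random; injured patches and CD8-infiltrated
    aggregates centred on proximal-tubule bands; in AIN each
    myeloid-inflammation aggregate is tangent to the previous CD8 aggregate
    and each M2-like aggregate tangent to a fibrosis patch.
    """
    spec.validate()
    ain = condition == "AIN"
    gr = spec.glomerulus_radius_um
    needed = spec.glomerulus_count * math.pi * gr ** 2
    if needed > width_um * height_um:
        raise ConfigurationError(
            "requested glomerular area exceeds tissue area")

    # glomeruli on a jittered grid
    ncol = max(1, int(math.ceil(math.sqrt(spec.glomerulus_count))))
    nrow = max(1, int(math.ceil(spec.glomerulus_count / ncol)))
    gx = (np.arange(ncol) + 0.5) / ncol * width_um
    gy = (np.arange(nrow) + 0.5) / nrow * height_um
    cells = [(x, y) for y in gy for x in gx][: spec.glomerulus_count]
    jitter = min(width_um / ncol, height_um / nrow) / 2 - gr
    jitter = max(jitter, 0.0)
    glomeruli = np.array(
        [[x + rng.uniform(-jitter, jitter),
          y + rng.uniform(-jitter, jitter), gr]
         for x, y in cells]).reshape(-1, 3)

    vw = spec.vascular_band_um
    vascular = np.array(
        [[p * width_um + rng.uniform(-0.03, 0.03) * width_um, 0.0]
         for p in spec.vascular_positions]).reshape(-1, 2)
    if len(vascular):
        vascular[:, 1] = vascular[:, 0] + vw

    def random_disks(n: int, r: float) -> np.ndarray:
        return np.array(
            [[rng.uniform(r, width_um - r), rng.uniform(r, height_um - r), r]
             for _ in range(n)]).reshape(-1, 3)

    n_fib = spec.fibrosis_count_ain if ain else spec.fibrosis_count_atn
    # fibrosis patches avoid vessels and glomeruli so fibrotic niches stay
    # a distinct transcriptional family
    fibrosis_list: list[list[float]] = []
    rf = spec.fibrosis_radius_um
    for _ in range(n_fib):
        for _attempt in range(60):
            cx = rng.uniform(rf, width_um - rf)
            cy = rng.uniform(rf, height_um - rf)
            clear_v = all(cx + rf + 15.0 < x0 or cx - rf - 15.0 > x1
                          for x0, x1 in vascular)
            clear_g = all((cx - gx_) ** 2 + (cy - gy_) ** 2
                          > (rf + gr_) ** 2
                          for gx_, gy_, gr_ in glomeruli)
            if clear_v and clear_g:
                break
        fibrosis_list.append([cx, cy, rf])
    fibrosis = np.array(fibrosis_list).reshape(-1, 3)

    pt_intervals = spec.band_intervals("proximal tubule", height_um)

    def pt_band_y() -> float:
        """Random y centred on a proximal-tubule band."""
        if not pt_intervals:
            return rng.uniform(0, height_um)
        widths = np.array([y1 - y0 for y0, y1 in pt_intervals])
        i = rng.choice(len(pt_intervals), p=widths / widths.sum())
        y0, y1 = pt_intervals[i]
        return (y0 + y1) / 2.0

    n_inj = spec.injured_count_ain if ain else spec.injured_count_atn
    # injured patches centred on proximal-tubule bands
    injured = []
    for _ in range(n_inj):
        cy = pt_band_y()
        cy = min(max(cy, spec.injured_radius_um),
                 height_um - spec.injured_radius_um)
        cx = rng.uniform(spec.injured_radius_um,
                         width_um - spec.injured_radius_um)
        injured.append([cx, cy, spec.injured_radius_um])
    injured_arr = np.array(injured).reshape(-1, 3)

    cycle = AIN_ARCHETYPE_CYCLE if ain else ATN_ARCHETYPE_CYCLE
    n_agg = spec.aggregate_count_ain if ain else spec.aggregate_count_atn
    ra = spec.aggregate_radius_ain if ain else spec.aggregate_radius_atn
    archetypes = [cycle[i % len(cycle)] for i in range(n_agg)]
    aggregates: list[list[float]] = []
    last_cd8: tuple[float, float] | None = None
    fib_cycle = 0

    def clear_of_existing(cx: float, cy: float) -> bool:
        return all((cx - ax) ** 2 + (cy - ay) ** 2 >= (0.98 * 2 * ra) ** 2
                   for ax, ay, _ in aggregates)

    def clear_of_fibrosis(cx: float, cy: float) -> bool:
        # only tissue-resident macrophage (M2-like) aggregates sit against
        # fibrosis; every other archetype keeps a clear margin
        return all((cx - fx) ** 2 + (cy - fy) ** 2
                   >= (fr + ra + 80.0) ** 2
                   for fx, fy, fr in fibrosis)

    # aggregates must not overlap each other (overlap would blend archetype
    # programs); tangent placements (paired archetypes) are allowed
    for arch in archetypes:
        cx = cy = 0.0
        # ATN biopsies show only small pockets of tubule-infiltrating
        # CD8 cells; their aggregate is reduced accordingly
        r_arch = ra if (ain or arch != "CD8 infiltrated kidney") else 0.6 * ra
        for _attempt in range(80):
            if arch == "CD8 infiltrated kidney":
                cx = rng.uniform(ra, width_um - ra)
                cy = min(max(pt_band_y(), ra), height_um - ra)
            elif ain and arch == "myeloid inflammation" and last_cd8:
                ang = rng.uniform(0, 2 * math.pi)
                cx = min(max(last_cd8[0] + 2 * ra * math.cos(ang), ra),
                         width_um - ra)
                cy = min(max(last_cd8[1] + 2 * ra * math.sin(ang), ra),
                         height_um - ra)
            elif ain and arch == "M2-like" and len(fibrosis):
                fx, fy, fr = fibrosis[fib_cycle % len(fibrosis)]
                ang = rng.uniform(0, 2 * math.pi)
                cx = min(max(fx + (fr + ra) * math.cos(ang), ra),
                         width_um - ra)
                cy = min(max(fy + (fr + ra) * math.sin(ang), ra),
                         height_um - ra)
            else:
                cx = rng.uniform(ra, width_um - ra)
                cy = rng.uniform(ra, height_um - ra)
            if clear_of_existing(cx, cy) and (
                    arch == "M2-like" or clear_of_fibrosis(cx, cy)):
                break
        if arch == "CD8 infiltrated kidney":
            last_cd8 = (cx, cy)
        elif ain and arch == "myeloid inflammation" and last_cd8:
            last_cd8 = None
        elif ain and arch == "M2-like" and len(fibrosis):
            fib_cycle += 1
        aggregates.append([cx, cy, r_arch])
    aggregates_arr = np.array(aggregates).reshape(-1, 3)

    return Anatomy(width_um, height_um, spec, glomeruli, vascular, fibrosis,
                   injured_arr, aggregates_arr, archetypes)


# ---------------------------------------------------------------------------
# cell placement

def _sample_in_disks(disks: np.ndarray, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(len(disks), size=n)
    r = disks[idx, 2] * np.sqrt(rng.uniform(size=n))
    a = rng.uniform(0, 2 * math.pi, size=n)
    return np.column_stack([disks[idx, 0] + r * np.cos(a),
                            disks[idx, 1] + r * np.sin(a)])


def _place_cells(types: np.ndarray, anatomy: Anatomy,
                 rng: np.random.Generator) -> np.ndarray:
    """Place each cell in its home domain (see module docstring)."""
    n = len(types)
    xy = np.empty((n, 2))
    W, H = anatomy.width_um, anatomy.height_um

    def uniform(n_pts: int) -> np.ndarray:
        return np.column_stack([rng.uniform(0, W, n_pts),
                                rng.uniform(0, H, n_pts)])

    def scatter_points(n_pts: int) -> np.ndarray:
        """Diffuse interstitial placement, keeping clear of fibrosis."""
        pts = uniform(n_pts)
        if len(anatomy.fibrosis) == 0:
            return pts
        for _ in range(40):
            bad = Anatomy._in_disks(pts, anatomy.fibrosis) >= 0
            if not bad.any():
                break
            pts[bad] = uniform(int(bad.sum()))
        return pts

    def in_band(band: str, n_pts: int) -> np.ndarray:
        """Rejection-sample within a band type, avoiding carve-outs."""
        if n_pts == 0:
            return np.empty((0, 2))
        pts = uniform(n_pts)
        for _ in range(60):
            # immune aggregates do not repel parenchyma: keep points whose
            # underlying band is right even if an aggregate covers them
            under = anatomy.band_label(pts[:, 1])
            hit_par = (
                (Anatomy._in_disks(pts, anatomy.glomeruli) >= 0)
                | (Anatomy._in_disks(pts, anatomy.fibrosis) >= 0)
                | (Anatomy._in_disks(pts, anatomy.injured) >= 0)
            )
            for x0, x1 in anatomy.vascular:
                hit_par |= (pts[:, 0] >= x0) & (pts[:, 0] < x1)
            bad = (under != band) | hit_par
            if not bad.any():
                break
            pts[bad] = uniform(int(bad.sum()))
        return pts

    def in_archetype(arch: str, n_pts: int) -> np.ndarray:
        disks = anatomy.aggregates[
            [i for i, a in enumerate(anatomy.aggregate_archetypes)
             if a == arch]]
        if len(disks) == 0 or n_pts == 0:
            return uniform(n_pts)
        return _sample_in_disks(disks, n_pts, rng)

    present = set(anatomy.aggregate_archetypes)
    for t in sorted(set(types.tolist())):
        idx = np.flatnonzero(types == t)
        m = len(idx)
        if m == 0:
            continue
        if t in ("Podocyte", "Parietal epithelial"):
            pts = (_sample_in_disks(anatomy.glomeruli, m, rng)
                   if len(anatomy.glomeruli) else uniform(m))
        elif t == "Endothelial":
            u = rng.uniform(size=m)
            pts = uniform(m)
            mv = u < 0.70
            if len(anatomy.vascular):
                k = int(mv.sum())
                xs = anatomy.vascular[
                    rng.integers(len(anatomy.vascular), size=k)]
                pts[mv] = np.column_stack(
                    [rng.uniform(xs[:, 0], xs[:, 1]), rng.uniform(0, H, k)])
            mg = (u >= 0.70) & (u < 0.78)
            if len(anatomy.glomeruli):
                pts[mg] = _sample_in_disks(anatomy.glomeruli,
                                           int(mg.sum()), rng)
        elif t == "Vascular smooth muscle":
            u = rng.uniform(size=m)
            pts = uniform(m)
            mv = u < 0.85
            if len(anatomy.vascular):
                k = int(mv.sum())
                xs = anatomy.vascular[
                    rng.integers(len(anatomy.vascular), size=k)]
                pts[mv] = np.column_stack(
                    [rng.uniform(xs[:, 0], xs[:, 1]), rng.uniform(0, H, k)])
        elif t == "Fibroblast":
            u = rng.uniform(size=m)
            pts = uniform(m)
            mf = u < 0.75
            if len(anatomy.fibrosis):
                pts[mf] = _sample_in_disks(anatomy.fibrosis,
                                           int(mf.sum()), rng)
            ma = (u >= 0.75) & (u < 0.85)
            if "inflammation with fibrosis" in present:
                pts[ma] = in_archetype("inflammation with fibrosis",
                                       int(ma.sum()))
        elif t == "Injured proximal tubule":
            u = rng.uniform(size=m)
            mi = (u < 0.85) & (len(anatomy.injured) > 0)
            pts = np.empty((m, 2))
            if len(anatomy.injured):
                pts[mi] = _sample_in_disks(anatomy.injured, int(mi.sum()), rng)
            pts[~mi] = in_band("proximal tubule", int((~mi).sum()))
        elif t in ("Proximal tubule", "Thick ascending limb",
                   "Distal convoluted tubule"):
            pts = in_band(t.lower(), m)
        elif t in ("Collecting duct principal",
                   "Collecting duct intercalated"):
            pts = in_band("collecting duct", m)
        elif t in IMMUNE_AFFINITY:
            aff = {a: w for a, w in IMMUNE_AFFINITY[t].items()
                   if a in present
                   or (a == ANY_AGGREGATE and len(anatomy.aggregates))}
            archs = sorted(aff)
            w = np.array([aff[a] for a in archs])
            scatter = max(0.0, 1.0 - float(w.sum()))
            probs = np.append(w, scatter)
            probs = probs / probs.sum()
            choice = rng.choice(len(probs), size=m, p=probs)
            pts = scatter_points(m)
            for j, a in enumerate(archs):
                mj = choice == j
                if a == ANY_AGGREGATE:
                    pts[mj] = _sample_in_disks(anatomy.aggregates,
                                               int(mj.sum()), rng)
                else:
                    pts[mj] = in_archetype(a, int(mj.sum()))
        else:
            pts = uniform(m)
        xy[idx] = pts
    return np.clip(xy, [0.0, 0.0],
                   [anatomy.width_um - 1e-9, anatomy.height_um - 1e-9])


# ---------------------------------------------------------------------------
# expression

def base_rates(types: np.ndarray, panel: list[str],
               programs: dict[str, dict[str, float]],
               baseline: float = 0.02) -> np.ndarray:
    """Per-cell per-gene mean emission rates before condition effects."""
    gene_idx = {g: i for i, g in enumerate(panel)}
    rates = np.full((len(types), len(panel)), baseline)
    for t in sorted(set(types.tolist())):
        rows = np.flatnonzero(types == t)
        for g, r in programs.get(t, {}).items():
            rates[rows, gene_idx[g]] += r
    return rates


def plant_condition_effects(rates: np.ndarray, panel: list[str],
                            condition: str, effects: EffectSpec,
                            domain: np.ndarray, subdomain: np.ndarray,
                            intensity: np.ndarray) -> np.ndarray:
    """Apply condition-dependent expression effects to a rate matrix.

    Composition folds are planted earlier, when per-condition proportions
    are drawn (see :meth:`CohortConfig.condition_proportions`); this
    function handles the expression-level effects: ambient programs, the
    immune-domain IFN-gamma response shift, tubular IFN-gamma coupling, and
    oxidative-phosphorylation suppression ``exp(-c * activity * I(x))``.
    """
    rates = rates.copy()
    gene_idx = {g: i for i, g in enumerate(panel)}
    activity = 1.0 if condition == "AIN" else effects.atn_ifng_activity

    for arch, prog in effects.ambient_programs.items():
        rows = np.flatnonzero(subdomain == arch)
        if len(rows) == 0:
            continue
        for g, r in prog.items():
            rates[rows, gene_idx[g]] += r
    if effects.shared_immune_ambient:
        rows = np.flatnonzero(domain == "immune")
        for g, r in effects.shared_immune_ambient.items():
            if g in gene_idx:
                rates[rows, gene_idx[g]] += r
    for dom_name, prog in effects.domain_ambient.items():
        rows = np.flatnonzero(domain == dom_name)
        if len(rows) == 0:
            continue
        for g, r in prog.items():
            if g in gene_idx:
                rates[rows, gene_idx[g]] += r

    ifng_cols = [gene_idx[g] for g in catalogs.GENE_SETS["IFNg Response"]
                 if g in gene_idx]
    ox_cols = [gene_idx[g]
               for g in catalogs.GENE_SETS["Oxidative Phosphorylation"]
               if g in gene_idx]
    immune_rows = np.flatnonzero(domain == "immune")
    if ifng_cols and len(immune_rows):
        rates[np.ix_(immune_rows, ifng_cols)] *= math.exp(
            effects.ifng_log_fold * activity)
    tub_rows = np.flatnonzero(np.isin(domain, TUBULE_DOMAINS))
    if len(tub_rows):
        local = (activity * intensity[tub_rows])[:, None]
        if ifng_cols:
            rates[np.ix_(tub_rows, ifng_cols)] *= (
                1.0 + effects.ifng_tubule_gain * local)
        if ox_cols:
            rates[np.ix_(tub_rows, ox_cols)] *= np.exp(
                -effects.oxphos_suppression * local)
    return rates


# ---------------------------------------------------------------------------
# cohort generation

def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` proportional to ``weights``."""
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), int)
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort (deterministic given config.seed).

    The first ``n_samples_per_condition`` samples are AIN, the rest ATN;
    per-sample RNGs are seeded ``seed + sample_index``.
    """
    config.validate()
    n_per = config.n_samples_per_condition
    sample_ids = [f"S{i + 1:02d}" for i in range(2 * n_per)]
    conditions = ["AIN"] * n_per + ["ATN"] * n_per
    types_list = config.cell_types
    side_um = math.sqrt(config.biopsy_area_mm2) * 1000.0

    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "condition": conditions,
        "biopsy_area_mm2": [config.biopsy_area_mm2] * len(sample_ids),
    })

    # pass 1: composition, placement, domains (cohort-wide totals are
    # needed before expression to plant IFNG attribution rates)
    per_sample: list[dict[str, Any]] = []
    for s_idx, (sid, cond) in enumerate(zip(sample_ids, conditions)):
        rng = np.random.default_rng(config.seed + s_idx)
        props = config.condition_proportions(cond)
        p = np.array([props[t] for t in types_list])
        if config.dirichlet_concentration and math.isfinite(
                config.dirichlet_concentration):
            alpha = np.maximum(config.dirichlet_concentration * p, 1e-9)
            p = rng.dirichlet(alpha)
        counts_per_type = _largest_remainder(p, config.cells_per_sample)
        types = np.repeat(np.asarray(types_list, object), counts_per_type)
        rng.shuffle(types)
        anatomy = layout_anatomy(config.anatomy, rng, cond, side_um, side_um)
        xy = _place_cells(types, anatomy, rng)
        domain, subdomain = anatomy.label(xy)
        per_sample.append(dict(sid=sid, cond=cond, rng=rng, types=types,
                               anatomy=anatomy, xy=xy, domain=domain,
                               subdomain=subdomain))

    attribution = config.effects.ifng_attribution
    type_totals: dict[str, int] = {t: 0 for t in attribution}
    for s in per_sample:
        for t in attribution:
            type_totals[t] += int((s["types"] == t).sum())

    gene_idx = {g: i for i, g in enumerate(config.panel)}
    cells_frames, truth_frames, spot_frames = [], [], []
    count_blocks = []
    for s in per_sample:
        rng, types, xy = s["rng"], s["types"], s["xy"]
        n = len(types)
        cell_ids = np.array([f"c{i + 1:05d}" for i in range(n)], object)
        rates = base_rates(types, config.panel, config.type_programs)
        intensity = s["anatomy"].ifng_intensity(xy)
        rates = plant_condition_effects(
            rates, config.panel, s["cond"], config.effects,
            s["domain"], s["subdomain"], intensity)
        if attribution and config.effects.ifng_budget > 0:
            col = gene_idx["IFNG"]
            # attribution owns IFNG entirely: zero the baseline everywhere
            # so realised fractions match the configured ones
            rates[:, col] = 0.0
            for t, frac in attribution.items():
                if type_totals[t] == 0:
                    continue
                rows = np.flatnonzero(types == t)
                rates[rows, col] = (frac * config.effects.ifng_budget
                                    / type_totals[t])

        if config.dispersion > 0 and n > 0:
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, config.dispersion,
                            size=rates.shape) * rates
        else:
            lam = rates
        raw = rng.poisson(lam) if n > 0 else np.zeros_like(rates, int)

        rows, cols = np.nonzero(raw)
        reps = raw[rows, cols]
        cell_of_spot = np.repeat(rows, reps)
        gene_of_spot = np.repeat(cols, reps)
        n_spots = len(cell_of_spot)
        off = rng.normal(0.0, config.cell_radius_um / 2.0, size=(n_spots, 2))
        keep = (off ** 2).sum(axis=1) <= config.cell_radius_um ** 2
        sx = xy[cell_of_spot, 0] + off[:, 0]
        sy = xy[cell_of_spot, 1] + off[:, 1]
        spot_cell = np.where(keep, cell_ids[cell_of_spot], UNASSIGNED)

        counts = sp.coo_matrix(
            (np.ones(int(keep.sum()), int),
             (cell_of_spot[keep], gene_of_spot[keep])),
            shape=(n, len(config.panel))).tocsr()
        counts.sum_duplicates()
        n_transcripts = np.asarray(counts.sum(axis=1)).ravel().astype(int)

        genes_arr = np.asarray(config.panel, object)
        spot_frames.append(pd.DataFrame({
            "sample_id": s["sid"],
            "gene": genes_arr[gene_of_spot],
            "x_um": sx, "y_um": sy,
            "cell_id": spot_cell,
        }))
        cells_frames.append(pd.DataFrame({
            "cell_id": cell_ids, "sample_id": s["sid"],
            "x_um": xy[:, 0] if n else np.empty(0),
            "y_um": xy[:, 1] if n else np.empty(0),
            "n_transcripts": n_transcripts,
            "type_label": "", "qc_pass": True,
        }))
        truth_frames.append(pd.DataFrame({
            "sample_id": s["sid"], "cell_id": cell_ids,
            "true_type": types.astype(str),
            "domain": s["domain"], "subdomain": s["subdomain"],
        }))
        count_blocks.append(counts)

    empty_cells = pd.DataFrame({c: pd.Series(dtype=d) for c, d in zip(
        ["cell_id", "sample_id", "x_um", "y_um", "n_transcripts",
         "type_label", "qc_pass"],
        [object, object, float, float, int, object, bool])})
    empty_spots = pd.DataFrame({c: pd.Series(dtype=d) for c, d in zip(
        ["sample_id", "gene", "x_um", "y_um", "cell_id"],
        [object, object, float, float, object])})
    cells = (pd.concat(cells_frames, ignore_index=True)
             if cells_frames else empty_cells)
    if cells.empty:
        cells = empty_cells
    spots = (pd.concat(spot_frames, ignore_index=True)
             if spot_frames else empty_spots)
    if spots.empty:
        spots = empty_spots
    counts_all = (sp.vstack(count_blocks).tocsr() if count_blocks
                  else sp.csr_matrix((0, len(config.panel)), dtype=int))
    truth_cells = (pd.concat(truth_frames, ignore_index=True)
                   if truth_frames else
                   pd.DataFrame(columns=["sample_id", "cell_id", "true_type",
                                         "domain", "subdomain"]))

    planted = {
        "folds": {t: config.condition_proportions("AIN")[t]
                  / config.condition_proportions("ATN")[t]
                  for t in types_list},
        "ifng_attribution": dict(attribution),
        "ifng_log_fold": config.effects.ifng_log_fold,
        "oxphos_suppression": config.effects.oxphos_suppression,
        "seed": config.seed,
    }
    truth = GroundTruth(cells=truth_cells, planted=planted)
    return Cohort(cells=cells, transcripts=spots, counts=counts_all,
                  genes=list(config.panel), samples=samples,
                  ground_truth=truth)
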