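"""Multiplex-panel phenotype assignment and PD-1 co-expression summaries.

A phenotype rule names a lineage and the marker flags it requires positive
and negative; rules are ranked by priority and the highest-priority match
wins.  PD-1 status is kept orthogonal to the lineage so any lineage —
including tumor cells, which occasionally express PD-1 constitutively —
can be PD-1 positive.

The default hierarchy puts tumor (NSE+) first so immune markers bleeding
onto tumor-adjacent segments cannot misclassify tumor cells, then CD8 T
cells, Tregs (CD4+FoxP3+), CD4 effectors, B cells (CD20+) and macrophages
(CD68+); everything else is "other".  The hierarchy is fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from tmeprox.core_io import CellTable


@dataclass(frozen=True)
class PhenotypeRule:
    lineage: str
    require_pos: tuple = ()
    require_neg: tuple = ()
    priority: int = 0  # lower rank = matched first


DEFAULT_RULES = (
    PhenotypeRule("tumor", ("NSE",), (), 0),
    PhenotypeRule("CD8 T cell", ("CD8",), (), 1),
    PhenotypeRule("Treg", ("CD4", "FOXP3"), (), 2),
    PhenotypeRule("CD4 Teff", ("CD4",), ("FOXP3",), 3),
    PhenotypeRule("B cell", ("CD20",), (), 4),
    PhenotypeRule("macrophage", ("CD68",), (), 5),
)

IMMUNE_LINEAGES = ("CD8 T cell", "Treg", "CD4 Teff", "B cell", "macrophage")


def load_rules(path) -> tuple:
    """Load phenotype rules from YAML: a list of mappings with keys
    ``lineage``, ``require_pos``, ``require_neg``, ``priority``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return tuple(
        PhenotypeRule(
            r["lineage"],
            tuple(r.get("require_pos", ())),
            tuple(r.get("require_neg", ())),
            int(r.get("priority", i)),
        )
        for i, r in enumerate(raw)
    )


def classify_phenotypes(
    cells: CellTable, rules: Sequence[PhenotypeRule] = DEFAULT_RULES
) -> CellTable:
    """Assign each cell the highest-priority matching lineage, or "other".

    Cells matching more than one rule are resolved by priority and flagged
    in a boolean ``ambiguous`` column (tallied in
    ``table.attrs['n_ambiguous']``).  Marker flags, including PD-1, are
    left untouched.
    """
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("rule priorities must be unique")
    for rule in rules:
        for m in rule.require_pos + rule.require_neg:
            if m not in cells.markers:
                raise KeyError(
                    f"rule {rule.lineage!r} references unknown marker {m!r}"
                )
    out = cells.copy()
    out.data = out.data.copy()
    n = len(out)
    lineage = np.full(n, "other", dtype=object)
    n_matches = np.zeros(n, int)
    assigned = np.zeros(n, bool)
    for rule in sorted(rules, key=lambda r: r.priority):
        match = np.ones(n, bool)
        for m in rule.require_pos:
            match &= out.data[m].to_numpy() == 1
        for m in rule.require_neg:
            match &= out.data[m].to_numpy() == 0
        n_matches += match
        take = match & ~assigned
        lineage[take] = rule.lineage
        assigned |= match
    out.data["lineage"] = lineage
    out.data["ambiguous"] = n_matches > 1
    out.attrs["n_ambiguous"] = int((n_matches > 1).sum())
    return out


@dataclass
class FieldSummary:
    """Counts for one high-power field (HPF), with per-lineage fractions
    normalized by the field's tumor-cell count."""

    field_id: str
    lineage_counts: dict
    area_mm2: float

    @property
    def tumor_cell_count(self) -> int:
        return int(self.lineage_counts.get("tumor", 0))

    @property
    def immune_cell_count(self) -> int:
        return int(sum(v for k, v in self.lineage_counts.items() if k != "tumor"))

    @property
    def tumor_normalized_fractions(self) -> dict:
        tc = self.tumor_cell_count
        if tc == 0:
            raise ValueError(f"field {self.field_id}: no tumor cells to normalize by")
        return {k: v / tc for k, v in self.lineage_counts.items() if k != "tumor"}


#: default HPF area, mm^2 (a 0.65 x 0.52 mm 20x field); configurable
DEFAULT_HPF_AREA_MM2 = 0.335


def summarize_field(
    cells: CellTable, field_id: str, area_mm2: float = DEFAULT_HPF_AREA_MM2
) -> FieldSummary:
    """Tally lineage counts for one field's classified cells."""
    if "lineage" not in cells.data.columns:
        raise ValueError("cells carry no lineage labels; run classify_phenotypes")
    counts = cells.data["lineage"].value_counts().to_dict()
    return FieldSummary(field_id, {k: int(v) for k, v in counts.items()}, area_mm2)


def select_hotspot_fields(fields: Sequence[FieldSummary], k: int = 10) -> list:
    """Pick the ``k`` fields richest in immune cells ("hot-spots" along the
    tumor-stroma interface); ties broken by field_id for determinism."""
    if k > len(fields):
        raise ValueError(f"requested {k} hot-spots from {len(fields)} fields")
    ranked = sorted(fields, key=lambda f: (-f.immune_cell_count, str(f.field_id)))
    return ranked[:k]


def pd1_coexpression_summary(
    cells: CellTable, area_mm2: float, pd1_marker: str = "PD1"
) -> pd.DataFrame:
    """Which cell types carry PD-1: per-lineage PD-1+ densities and the
    composition of the PD-1+ population.

    Returns one row per lineage with the PD-1+ count, density (cells/mm^2
    over ``area_mm2``) and the lineage's share of all PD-1+ cells
    (shares sum to 1 when any PD-1+ cell exists).
    """
    if area_mm2 <= 0:
        raise ValueError("field area must be positive")
    if "lineage" not in cells.data.columns:
        raise ValueError("cells carry no lineage labels; run classify_phenotypes")
    pd1 = cells.positive(pd1_marker)
    total_pd1 = int(pd1.sum())
    rows = []
    for lin in sorted(cells.data["lineage"].unique()):
        in_lin = cells.data["lineage"].to_numpy() == lin
        cnt = int((pd1 & in_lin).sum())
        rows.append(
            {
                "lineage": lin,
                "pd1_pos_count": cnt,
                "pd1_pos_density_per_mm2": cnt / area_mm2,
                "share_of_pd1_pos": cnt / total_pd1 if total_pd1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
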