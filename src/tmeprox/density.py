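"""Per-region marker densities, PD-L1 area fraction and pathologist-style
PD-L1 scoring.

Densities are cells/mm^2 of marker-positive cells within a region (IT, PT,
or TOTAL = pooled IT+PT counts over pooled area).  The area fraction is
positive pixels / tissue pixels with excluded pixels removed from both
numerator and denominator.  The pathologist score bins the percent of
PD-L1+ cells in a compartment (tumor cells TC, immune cells IC, or both)
into the conventional intervals <1%, 1%, 2-4%, 5-9%, 10-19% and 10-point
intervals thereafter, with the binomial positive/negative call at the 1%
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tmeprox.core_io import CellTable
from tmeprox.regions import RegionPartition

REGIONS = ("IT", "PT", "TOTAL")

#: (lower, upper, label) percent bins; upper bound exclusive except the last
PDL1_BINS = (
    (0.0, 1.0, "<1%"),
    (1.0, 2.0, "1%"),
    (2.0, 5.0, "2–4%"),
    (5.0, 10.0, "5–9%"),
    (10.0, 20.0, "10–19%"),
    (20.0, 30.0, "20–29%"),
    (30.0, 40.0, "30–39%"),
    (40.0, 50.0, "40–49%"),
    (50.0, 60.0, "50–59%"),
    (60.0, 70.0, "60–69%"),
    (70.0, 80.0, "70–79%"),
    (80.0, 90.0, "80–89%"),
    (90.0, 100.0, "90–100%"),
)

#: lineages treated as the immune-cell (IC) compartment for PD-L1 scoring
IMMUNE_LINEAGES = ("CD8 T cell", "CD4 Teff", "Treg", "B cell", "macrophage", "other")


@dataclass(frozen=True)
class DensityResult:
    specimen_id: str
    marker: str
    region: str
    count: int
    area_mm2: float

    @property
    def density(self) -> float:
        """Marker-positive cells per mm^2 of region area."""
        return self.count / self.area_mm2


@dataclass(frozen=True)
class AreaFractionResult:
    specimen_id: str
    positive_pixels: int
    total_pixels: int

    @property
    def fraction(self) -> float:
        return self.positive_pixels / self.total_pixels


@dataclass(frozen=True)
class PDL1Score:
    compartment: str  # TC | IC | TC+IC
    percent_positive: float
    n_cells: int

    @property
    def bin(self) -> str:
        p = self.percent_positive
        for lo, hi, label in PDL1_BINS:
            if lo <= p < hi or (label == PDL1_BINS[-1][2] and p >= lo):
                return label
        raise ValueError(f"percent {p} outside [0, 100]")

    @property
    def binomial_call(self) -> str:
        """Positive iff >= 1% of compartment cells are PD-L1+."""
        return "positive" if self.percent_positive >= 1.0 else "negative"


def compute_density(
    cells: CellTable,
    partition: RegionPartition,
    marker: str,
    region: str = "TOTAL",
) -> DensityResult:
    """Density of ``marker``-positive cells in a region.

    ``TOTAL`` pools IT and PT counts over the pooled IT+PT area (the "total
    TME"); EXCLUDED and OUTSIDE cells are never counted.  Cells must have
    been labeled by :func:`tmeprox.regions.assign_regions` first.
    """
    if region not in REGIONS:
        raise KeyError(f"region must be one of {REGIONS}")
    area = partition.area_mm2(region)
    if area <= 0:
        raise ValueError(f"{region} area is zero; density undefined")
    labels = cells.data["region"].to_numpy()
    if region == "TOTAL":
        in_region = (labels == "IT") | (labels == "PT")
    else:
        in_region = labels == region
    count = int((cells.positive(marker) & in_region).sum())
    return DensityResult(cells.specimen_id, marker, region, count, area)


def area_fraction(
    mask: np.ndarray,
    tissue_mask: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
    specimen_id: str = "",
) -> AreaFractionResult:
    """Fraction of tissue pixels that are stain-positive.

    ``mask`` is any array whose nonzero pixels are positive.  When given,
    ``tissue_mask`` restricts the denominator to tissue and
    ``exclusion_mask`` removes acellular/necrotic pixels from both numerator
    and denominator.
    """
    pos = np.asarray(mask) != 0
    valid = np.ones_like(pos, bool)
    if tissue_mask is not None:
        tissue = np.asarray(tissue_mask) != 0
        if tissue.shape != pos.shape:
            raise ValueError("tissue mask shape differs from stain mask")
        valid &= tissue
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask) != 0
        if excl.shape != pos.shape:
            raise ValueError("exclusion mask shape differs from stain mask")
        valid &= ~excl
    total = int(valid.sum())
    if total == 0:
        raise ValueError("no tissue pixels after exclusions; fraction undefined")
    return AreaFractionResult(specimen_id, int((pos & valid).sum()), total)


def score_pdl1(
    cells: CellTable,
    compartment: str = "TC+IC",
    marker: str = "PDL1",
    tumor_lineages: tuple = ("tumor",),
) -> PDL1Score:
    """Pathologist-style PD-L1 score for a compartment.

    The compartment is resolved from the ``lineage`` column: ``TC`` = tumor
    lineages, ``IC`` = all non-tumor lineages, ``TC+IC`` = every cell.
    Percent positive is 100 x PD-L1+ cells / compartment cells.
    """
    if "lineage" not in cells.data.columns:
        raise ValueError("cells carry no lineage labels; run phenotyping first")
    lineage = cells.data["lineage"].to_numpy()
    if compartment == "TC":
        in_comp = np.isin(lineage, tumor_lineages)
    elif compartment == "IC":
        in_comp = ~np.isin(lineage, tumor_lineages)
    elif compartment == "TC+IC":
        in_comp = np.ones(len(cells), bool)
    else:
        raise KeyError("compartment must be TC, IC or TC+IC")
    n = int(in_comp.sum())
    if n == 0:
        raise ValueError(f"compartment {compartment} is empty")
    pos = int((cells.positive(marker) & in_comp).sum())
    return PDL1Score(compartment, 100.0 * pos / n, n)
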