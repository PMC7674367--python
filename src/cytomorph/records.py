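"""Shared column conventions for cell-record tables.

Every statistical stage consumes a flat table with one row per cell, the
ten morphometric descriptors, and the grouping factors (population, animal,
layer, cell type).  The descriptors fall into three domains: *size*
(absolute geometry in physical units), *regularity* (dimensionless shape
ratios bounded in [0, 1]) and *density* (neighbour counts in a disc of
fixed radius around the cell).
"""

from __future__ import annotations

SIZE_DESCRIPTORS = ["area_um2", "perimeter_um", "major_um", "minor_um"]
REGULARITY_DESCRIPTORS = ["solidity", "extent", "inv_ar", "convex_circ"]
DENSITY_DESCRIPTORS = ["ngb50", "ngb100"]

DESCRIPTORS = SIZE_DESCRIPTORS + REGULARITY_DESCRIPTORS + DENSITY_DESCRIPTORS

DOMAINS = {
    "size": SIZE_DESCRIPTORS,
    "regularity": REGULARITY_DESCRIPTORS,
    "density": DENSITY_DESCRIPTORS,
}

#: Study populations: male, female and freemartin (intersex) individuals.
POPULATIONS = ["M", "F", "FM"]

LAYERS = ["molecular", "purkinje", "granular"]

CELL_TYPES = ["stellate", "basket", "purkinje", "granule", "golgi"]

#: Grouping columns expected alongside the descriptors.
GROUPING_COLUMNS = ["cell_id", "animal_id", "population", "layer", "cell_type"]

RECORD_COLUMNS = GROUPING_COLUMNS + DESCRIPTORS


def validate_records(df, require_descriptors: bool = True) -> None:
    """Raise ``ValueError`` if a cell-record table is malformed."""
    missing = [c for c in GROUPING_COLUMNS if c not in df.columns]
    if require_descriptors:
        missing += [c for c in DESCRIPTORS if c not in df.columns]
    if missing:
        raise ValueError(f"cell-record table is missing columns: {missing}")
    if df[DESCRIPTORS if require_descriptors else []].isna().any().any():
        raise ValueError("cell-record table contains missing descriptor values")
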