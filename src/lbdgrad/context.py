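"""Neural contextualisation of group difference maps.

A group t-map of gradient change is correlated against regional annotation
maps — pooled cell-type marker expression, cytoarchitectural axes, laminar
thickness, disease gene-set expression, a unimodal-to-transmodal network
ranking — with spin-permutation nulls, and the p_spin values are FDR-
adjusted across the full declared family of comparisons (one family per
t-map) to q_spin.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ParcelSphere, RegionalMap
from .nulls import SpinEnsemble, fdr, spin_test

logger = logging.getLogger("lbdgrad")

#: cortical cell-type marker genes (normative transcriptomic markers)
CELL_MARKERS: dict[str, list[str]] = {
    "excitatory_neurons": ["CUX2", "THEMIS", "RORB", "FEZF2"],
    "inhibitory_neurons": ["PAX6", "RELN", "VIP", "SV2C", "TLE4", "PVALB", "SST"],
    "astrocytes": ["AQP4", "GFAP"],
    "endothelial_cells": [
        "CLDN5", "SEMA3G", "EFNB2", "MFSD2A", "SLC16A1",
        "C1QA", "HBB", "ACTA2", "CNN1", "VWF", "TSHZ2",
    ],
    "microglia": ["CD74", "PTPRC"],
    "oligodendrocytes": ["PDGFRA", "BCAS1", "PLP1", "MBP", "RASGRF1", "ANKRD18A"],
}


def pooled_marker_map(expression: pd.DataFrame, markers: list[str], name: str = "markers") -> RegionalMap:
    """Per-region sum of the listed genes' normalised expression.

    Markers absent from the expression table are logged and skipped; at
    least one must be present.
    """
    if not markers:
        raise ValueError("empty marker set")
    if len(set(markers)) != len(markers):
        raise ValueError("duplicate marker symbols")
    present = [g for g in markers if g in expression.columns]
    absent = sorted(set(markers) - set(present))
    if not present:
        raise ValueError(f"none of the marker genes {markers} are in the expression table")
    if absent:
        logger.warning("marker set %s: %d gene(s) absent, skipped: %s", name, len(absent), absent)
    values = expression[present].sum(axis=1).to_numpy(dtype=float)
    return RegionalMap(region_ids=[str(r) for r in expression.index], values=values, name=name)


def cell_marker_maps(expression: pd.DataFrame) -> dict[str, RegionalMap]:
    """Pooled expression maps for every cell-type marker set."""
    return {
        name: pooled_marker_map(expression, genes, name=name)
        for name, genes in CELL_MARKERS.items()
    }


def contextualise(
    t_map: RegionalMap,
    annotations: list[RegionalMap],
    spins: SpinEnsemble,
) -> pd.DataFrame:
    """Spin-test the t-map against every annotation; one FDR family.

    Returns a frame with one row per annotation: name, rho, p_spin and
    q_spin (Benjamini-Hochberg across all annotations in this call — the
    family must therefore be declared in full up front).
    """
    if not annotations:
        raise ValueError("empty annotation family")
    rows = []
    for annot in annotations:
        res = spin_test(t_map, annot, spins)
        rows.append({"annotation": annot.name, "rho": res.rho_observed, "p_spin": res.p_spin})
    table = pd.DataFrame(rows)
    table["q_spin"] = fdr(table["p_spin"].to_numpy())
    return table


def axis_rank_map(
    network_labels: dict[str, str],
    ordering: list[str],
    region_ids: list[str],
    name: str = "unimodal_transmodal",
) -> RegionalMap:
    """Unimodal-to-transmodal ranking from a functional network allocation.

    Each region receives the rank of its network in ``ordering`` (1-based;
    regions of the same network are tied).
    """
    untagged = [r for r in region_ids if r not in network_labels]
    if untagged:
        raise ValueError(f"untagged region(s): {untagged[:5]}")
    rank_of = {net: k + 1 for k, net in enumerate(ordering)}
    unknown = sorted({network_labels[r] for r in region_ids} - set(rank_of))
    if unknown:
        raise ValueError(f"network(s) missing from the ordering: {unknown}")
    values = np.array([rank_of[network_labels[r]] for r in region_ids], dtype=float)
    return RegionalMap(region_ids=list(region_ids), values=values, name=name)


def synthetic_annotation_suite(
    sphere: ParcelSphere,
    expression: pd.DataFrame,
    seed: int = 0,
    n_axes: int = 8,
    smoothness: float = 0.75,
) -> list[RegionalMap]:
    """A 24-map annotation family: pooled cell-category maps, individual
    excitatory/inhibitory marker maps, and synthetic smooth stand-ins for
    the cytoarchitectural / laminar axes.

    The canonical family has 24 comparisons per t-map: 5 pooled cell
    categories, 4 excitatory and 7 inhibitory individual markers, and 8
    microarchitectural axes. The axes are histology-derived atlases in real
    analyses; here smooth synthetic maps stand in.
    """
    from .synthetic import make_smooth_map

    categories = [
        "excitatory_neurons", "inhibitory_neurons", "astrocytes",
        "endothelial_cells", "oligodendrocytes",
    ]
    maps = [pooled_marker_map(expression, CELL_MARKERS[c], name=c) for c in categories]
    singles = CELL_MARKERS["excitatory_neurons"] + CELL_MARKERS["inhibitory_neurons"]
    for gene in singles:
        if gene in expression.columns:
            maps.append(
                RegionalMap(
                    region_ids=[str(r) for r in expression.index],
                    values=expression[gene].to_numpy(dtype=float),
                    name=gene,
                )
            )
    for k in range(n_axes):
        maps.append(
            make_smooth_map(sphere, smoothness, seed=seed + 1000 + k, name=f"axis_{k + 1}")
        )
    return maps
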