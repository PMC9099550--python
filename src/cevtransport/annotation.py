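"""Protein origin/category classification and detection accounting.

Proteins quantified in circulating-EV isolates are classified by a cascade
over their curated annotation: membrane annotations with a subcellular
location decide first, then decisive GO cellular-component terms, then
GO biological-process terms, and finally tissue specificity / keywords /
description. The outcome is an origin (``cellular``, ``serum/plasma`` or
``unknown``) and a category (cell membrane, cell part, cell surface for
cellular proteins; apolipoprotein, coagulation factor, complement factor,
immunoglobulin or other for serum/plasma proteins).

Detection accounting applies the study's rule that a protein group counts
as detected in a plasma-type/transport slice when it was seen in at least
two of the three technical replicates of at least one donor; proteins
detected in one plasma type and never in the other form the "unique-to"
sets used to assess platelet contamination.

The decisive-term tables are configuration (the original adjudication was
manual); the defaults below cover the vocabulary the synthetic annotation
generator emits plus common UniProt terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationRecord",
    "ClassificationConfig",
    "DEFAULT_CONFIG",
    "DEFAULT_MARKER_MAP",
    "ClassTally",
    "classify_protein",
    "detection_filter",
    "tally",
    "count_markers",
    "platelet_ratio",
    "read_annotation_table",
]

ORIGINS = ("cellular", "serum/plasma", "unknown")
CELLULAR_CATEGORIES = ("cell membrane", "cell part", "cell surface")
SERUM_CATEGORIES = (
    "apolipoprotein",
    "coagulation factor",
    "complement factor",
    "immunoglobulin",
    "other",
)


@dataclass(frozen=True)
class AnnotationRecord:
    """Curated annotation of one protein group (UniProt-derived fields)."""

    protein_id: str
    gene_name: str = ""
    has_transmembrane: bool = False
    subcellular_locations: FrozenSet[str] = frozenset()
    go_cc: FrozenSet[str] = frozenset()
    go_bp: FrozenSet[str] = frozenset()
    keywords: FrozenSet[str] = frozenset()
    tissue_specificity: str = ""
    cd_marker: Optional[str] = None
    platelet_set: bool = False  # membership in the reference platelet proteome
    exosome_go: bool = False
    blood_microparticle_go: bool = False
    keratin: bool = False

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be nonempty")
        for name in ("subcellular_locations", "go_cc", "go_bp", "keywords"):
            object.__setattr__(
                self, name, frozenset(t.lower() for t in getattr(self, name))
            )


@dataclass(frozen=True)
class ClassificationConfig:
    """Decisive-term tables driving the classification cascade.

    All matching is lowercase substring-free (exact term membership).
    """

    membrane_locations: FrozenSet[str] = frozenset(
        {"cell membrane", "plasma membrane", "membrane"}
    )
    secreted_locations: FrozenSet[str] = frozenset({"secreted", "blood plasma", "serum"})
    surface_locations: FrozenSet[str] = frozenset(
        {"cell surface", "extracellular matrix", "basement membrane"}
    )
    part_locations: FrozenSet[str] = frozenset(
        {
            "cytoplasm",
            "cytosol",
            "nucleus",
            "mitochondrion",
            "endoplasmic reticulum",
            "golgi apparatus",
            "lysosome",
            "endosome",
            "cytoskeleton",
        }
    )
    cc_membrane: FrozenSet[str] = frozenset({"plasma membrane", "integral component of membrane"})
    cc_surface: FrozenSet[str] = frozenset({"cell surface", "extracellular matrix"})
    cc_part: FrozenSet[str] = frozenset(
        {
            "cytoplasm",
            "cytosol",
            "nucleus",
            "mitochondrion",
            "organelle",
            "endoplasmic reticulum",
            "golgi apparatus",
            "cytoskeleton",
            "ribosome",
            "proteasome",
        }
    )
    cc_serum: FrozenSet[str] = frozenset({"extracellular space", "extracellular region", "blood microparticle"})
    bp_part: FrozenSet[str] = frozenset(
        {"translation", "glycolysis", "cell cycle", "cytoskeleton organization"}
    )
    bp_serum: FrozenSet[str] = frozenset(
        {"complement activation", "blood coagulation", "lipid transport", "immune response"}
    )
    keyword_serum: FrozenSet[str] = frozenset({"secreted"})
    # serum/plasma subcategory decision, in priority order
    apolipoprotein_keywords: FrozenSet[str] = frozenset({"apolipoprotein", "lipid transport"})
    coagulation_keywords: FrozenSet[str] = frozenset(
        {"coagulation", "blood coagulation", "hemostasis", "fibrinolysis"}
    )
    complement_keywords: FrozenSet[str] = frozenset(
        {"complement", "complement activation", "complement pathway"}
    )
    immunoglobulin_keywords: FrozenSet[str] = frozenset(
        {"immunoglobulin", "immunoglobulin domain", "antibody"}
    )


DEFAULT_CONFIG = ClassificationConfig()

# Marker label -> cell types it indicates; multi-specific markers count once
# per cell type, so cell-type columns do not sum to the distinct-marker total.
DEFAULT_MARKER_MAP: Mapping[str, FrozenSet[str]] = {
    "CD14": frozenset({"Monoc./Macroph."}),
    "CD40": frozenset({"Monoc./Macroph.", "B Cell", "Endothelial cell"}),
    "CD41": frozenset({"Platelet"}),
    "CD62P": frozenset({"Platelet", "Endothelial cell"}),
    "CD81": frozenset(
        {"Endothelial cell", "Monoc./Macroph.", "Dendritic cell", "T Cell", "B Cell", "Granulocyte"}
    ),
    "CD102": frozenset({"NK cell", "Endothelial cell", "T Cell", "Monoc./Macroph.", "B Cell"}),
    "CD233": frozenset({"Erythrocyte"}),
    "HSPG2": frozenset({"Endothelial cell"}),
}


def _serum_category(rec: AnnotationRecord, cfg: ClassificationConfig) -> str:
    terms = rec.keywords | rec.go_bp
    gene = rec.gene_name.upper()
    if terms & cfg.apolipoprotein_keywords or gene.startswith("APO"):
        return "apolipoprotein"
    if terms & cfg.coagulation_keywords:
        return "coagulation factor"
    if terms & cfg.complement_keywords:
        return "complement factor"
    if terms & cfg.immunoglobulin_keywords or gene.startswith(("IGH", "IGK", "IGL")):
        return "immunoglobulin"
    return "other"


def classify_protein(
    rec: AnnotationRecord, config: ClassificationConfig = DEFAULT_CONFIG
) -> Tuple[str, str]:
    """Origin and category of one protein by the annotation cascade.

    Returns ``(origin, category)``; ``("unknown", "unknown")`` when no rule
    fires. Pure function of the record and configuration.
    """
    cfg = config
    locs = rec.subcellular_locations
    # 1. membrane annotations in conjunction with subcellular location
    if rec.has_transmembrane and locs & cfg.membrane_locations:
        return ("cellular", "cell membrane")
    # 2. subcellular location alone when decisive
    if locs & cfg.secreted_locations:
        return ("serum/plasma", _serum_category(rec, cfg))
    if locs & cfg.surface_locations:
        return ("cellular", "cell surface")
    if locs & cfg.part_locations:
        return ("cellular", "cell part")
    # 3. decisive GO cellular-component terms
    if rec.go_cc & cfg.cc_membrane and rec.has_transmembrane:
        return ("cellular", "cell membrane")
    if rec.go_cc & cfg.cc_serum:
        return ("serum/plasma", _serum_category(rec, cfg))
    if rec.go_cc & cfg.cc_surface:
        return ("cellular", "cell surface")
    if rec.go_cc & cfg.cc_part:
        return ("cellular", "cell part")
    if rec.go_cc & cfg.cc_membrane:
        return ("cellular", "cell membrane")
    # 4. GO biological-process terms
    if rec.go_bp & cfg.bp_serum:
        return ("serum/plasma", _serum_category(rec, cfg))
    if rec.go_bp & cfg.bp_part:
        return ("cellular", "cell part")
    # 5. tissue specificity / keywords / description
    if rec.keywords & cfg.keyword_serum or "plasma" in rec.tissue_specificity.lower():
        return ("serum/plasma", _serum_category(rec, cfg))
    return ("unknown", "unknown")


def detection_filter(
    detection: pd.DataFrame,
    min_replicates: int = 2,
    replicates_per_group: int = 3,
    strict: bool = True,
) -> Dict[str, Set[str]]:
    """Detected protein sets per plasma-type/transport slice.

    ``detection`` is a boolean protein-by-sample table whose columns carry a
    MultiIndex with levels ``plasma``, ``transport``, ``donor``,
    ``replicate``. A protein is detected in a slice when some donor shows it
    in at least ``min_replicates`` of that donor's technical replicates.

    Returns a dict with one key per ``(plasma, transport)`` slice (e.g.
    ``"PFP_C"``), plus ``"combined"``, per-plasma unions (``"PFP"``,
    ``"PPP"``), and the disjoint ``"unique_to_PFP"`` / ``"unique_to_PPP"``
    sets.
    """
    req = {"plasma", "transport", "donor", "replicate"}
    if not req.issubset(set(detection.columns.names)):
        raise ValueError(f"detection columns need MultiIndex levels {sorted(req)}")
    counts = detection.T.groupby(level=["plasma", "transport", "donor"]).sum().T
    group_sizes = detection.T.groupby(level=["plasma", "transport", "donor"]).size()
    if strict and not (group_sizes == replicates_per_group).all():
        bad = group_sizes[group_sizes != replicates_per_group]
        raise ValueError(
            f"replicate groups must have exactly {replicates_per_group} columns; "
            f"offending groups: {list(bad.index)} (pass strict=False to override)"
        )
    passed = counts >= min_replicates
    slices: Dict[str, Set[str]] = {}
    plasmas = sorted({p for p, _, _ in passed.columns})
    for plasma in plasmas:
        for transport in sorted({t for p, t, _ in passed.columns if p == plasma}):
            sub = passed.loc[:, (plasma, transport)]
            detected = set(sub.index[sub.any(axis=1)])
            slices[f"{plasma}_{transport}"] = detected
    for plasma in plasmas:
        slices[plasma] = set().union(
            *(v for k, v in slices.items() if k.startswith(plasma + "_"))
        )
    slices["combined"] = set().union(*(slices[p] for p in plasmas))
    if len(plasmas) == 2:
        a, b = plasmas
        slices[f"unique_to_{a}"] = slices[a] - slices[b]
        slices[f"unique_to_{b}"] = slices[b] - slices[a]
    return slices


@dataclass
class ClassTally:
    """Cross-tabulated protein counts per (origin, category) and data slice.

    ``counts`` is indexed by (origin, category) rows in the fixed scheme
    order with one column per slice. Totals are always computed from the
    category rows, never stored.
    """

    counts: pd.DataFrame

    def total(self, origin: str, slice_name: str) -> int:
        return int(self.counts.loc[origin].loc[:, slice_name].sum())

    def grand_total(self, slice_name: str) -> int:
        return int(self.counts.loc[:, slice_name].sum())

    def with_totals(self) -> pd.DataFrame:
        """Table-style layout with computed total rows appended."""
        rows = [self.counts]
        for origin in ("cellular", "serum/plasma"):
            total = self.counts.loc[origin].sum()
            total.name = (origin, f"total {origin}")
            rows.append(total.to_frame().T)
        grand = self.counts.sum()
        grand.name = ("", "total")
        rows.append(grand.to_frame().T)
        return pd.concat(rows)


def tally(
    records: Mapping[str, AnnotationRecord],
    detected_sets: Mapping[str, Set[str]],
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> ClassTally:
    """Cross-tabulate classified proteins over the detection slices.

    Every detected protein must have an annotation record; missing records
    raise with the offending ids listed.
    """
    all_detected = set().union(*detected_sets.values()) if detected_sets else set()
    missing = sorted(all_detected - set(records))
    if missing:
        raise KeyError(f"detected proteins without annotation records: {missing}")
    index = pd.MultiIndex.from_tuples(
        [("cellular", c) for c in CELLULAR_CATEGORIES]
        + [("serum/plasma", c) for c in SERUM_CATEGORIES]
        + [("unknown", "unknown")],
        names=["origin", "category"],
    )
    assigned = {pid: classify_protein(records[pid], config) for pid in all_detected}
    data = {}
    for slice_name, detected in detected_sets.items():
        col = pd.Series(0, index=index, dtype=int)
        for pid in detected:
            col.loc[assigned[pid]] += 1
        data[slice_name] = col
    return ClassTally(counts=pd.DataFrame(data, index=index))


def count_markers(
    records: Mapping[str, AnnotationRecord],
    detected_sets: Mapping[str, Set[str]],
    marker_map: Mapping[str, FrozenSet[str]] = DEFAULT_MARKER_MAP,
) -> pd.DataFrame:
    """Cell-type marker counts per slice, plus the distinct-marker total.

    A marker with several cell-type specificities is counted once in each
    cell type, so cell-type rows exceed the ``Total markers`` row's sum.
    """
    cell_types = sorted(set().union(*marker_map.values()))
    rows = cell_types + ["Total markers"]
    data = {}
    for slice_name, detected in detected_sets.items():
        markers = {
            records[pid].cd_marker
            for pid in detected
            if pid in records and records[pid].cd_marker in marker_map
        }
        col = pd.Series(0, index=rows, dtype=int)
        for m in markers:
            for ct in marker_map[m]:
                col[ct] += 1
        col["Total markers"] = len(markers)
        data[slice_name] = col
    return pd.DataFrame(data, index=rows)


def platelet_ratio(platelet_count: int, set_size: int) -> float:
    """Percentage of platelet-annotated proteins in a set, one decimal.

    E.g. 393 platelet proteins among 456 unique-to-PPP groups -> 86.2.
    """
    if set_size <= 0:
        raise ValueError("set size must be positive")
    return round(100.0 * platelet_count / set_size, 1)


def read_annotation_table(path) -> Dict[str, AnnotationRecord]:
    """Read an annotation TSV (set-valued fields ``;``-delimited)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")

    def split(s: str) -> FrozenSet[str]:
        return frozenset(t.strip() for t in s.split(";") if t.strip())

    def flag(s: str) -> bool:
        return s.strip().lower() in {"1", "true", "yes"}

    records = {}
    for _, row in df.iterrows():
        rec = AnnotationRecord(
            protein_id=row["protein_id"],
            gene_name=row.get("gene_name", ""),
            has_transmembrane=flag(row.get("has_transmembrane", "")),
            subcellular_locations=split(row.get("subcellular_locations", "")),
            go_cc=split(row.get("go_cc", "")),
            go_bp=split(row.get("go_bp", "")),
            keywords=split(row.get("keywords", "")),
            tissue_specificity=row.get("tissue_specificity", ""),
            cd_marker=row.get("cd_marker", "") or None,
            platelet_set=flag(row.get("platelet_set", "")),
            exosome_go=flag(row.get("exosome_go", "")),
            blood_microparticle_go=flag(row.get("blood_microparticle_go", "")),
            keratin=flag(row.get("keratin", "")),
        )
        records[rec.protein_id] = rec
    return records
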