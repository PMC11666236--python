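"""Guide detection, library-specific cell filtering, and guide-target maps.

A guide-capture experiment yields a cells x guides UMI count matrix alongside
the transcriptome. A guide is called *detected* in a cell when its capture
count reaches ``min_umi`` (default 1: any evidence counts, since guide capture
is the limiting step of the assay). Cells are then kept or dropped by the
library rule of the study design: control (NT) cells must carry exactly the
one non-targeting guide; pool (AGM) cells, infected at high multiplicity,
must carry more than one guide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NT_GUIDE = "NT_gRNA"

#: keep/drop reasons
KEPT = "kept"
ZERO_GUIDES = "zero_guides"
TOO_FEW = "too_few"
WRONG_MULTIPLICITY = "wrong_multiplicity"


@dataclass
class GuideLibrary:
    """Guide -> target map. ``table`` is indexed by guide_id with columns
    ``target`` (empty string for non-targeting) and ``guide_class``
    (``targeting`` | ``non_targeting``)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("guide_ids must be unique")
        targeting = self.table[self.table["guide_class"] == "targeting"]
        if (targeting["target"] == "").any():
            bad = targeting.index[targeting["target"] == ""].tolist()
            raise ValueError(f"targeting guides without a target gene: {bad}")

    @property
    def guide_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def targets(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.table.loc[self.table["guide_class"] == "targeting", "target"]:
            seen.setdefault(t)
        return list(seen)

    @property
    def target_of(self) -> dict[str, str]:
        return dict(zip(self.table.index, self.table["target"]))

    def guides_for(self, target: str) -> list[str]:
        return list(self.table.index[self.table["target"] == target])

    def n_guides_per_target(self) -> pd.Series:
        targeting = self.table[self.table["guide_class"] == "targeting"]
        return targeting.groupby("target").size()

    def to_tsv(self, path) -> None:
        out = self.table.reset_index().rename(columns={"index": "guide_id"})
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GuideLibrary":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        df = df.set_index("guide_id")
        return cls(df[["target", "guide_class"]])


def build_default_library(targets, guides_per_target) -> GuideLibrary:
    """49 targeting guides (5-7 per target over nine targets) plus one NT guide."""
    rows = []
    for target, n in zip(targets, guides_per_target):
        for i in range(1, n + 1):
            rows.append((f"{target}_g{i}", target, "targeting"))
    rows.append((NT_GUIDE, "", "non_targeting"))
    table = pd.DataFrame(rows, columns=["guide_id", "target", "guide_class"])
    return GuideLibrary(table.set_index("guide_id"))


def detect_guides(capture: pd.DataFrame, library: GuideLibrary, min_umi: int = 1,
                  barcodes=None) -> pd.DataFrame:
    """Call per-cell detected guide sets from capture counts.

    Parameters
    ----------
    capture
        cells x guides non-negative integer counts (index: cell barcodes).
    library
        The guide library; every capture column must be a known guide.
    min_umi
        Detection threshold (count >= min_umi), at least 1.
    barcodes
        Optional barcode universe from the expression matrix. Cells present
        there but absent from the capture matrix are reported as zero-guide
        cells rather than silently dropped.

    Returns
    -------
    pandas.DataFrame
        Indexed by barcode with columns ``detected_guides`` (tuple),
        ``detected_targets`` (tuple, sorted), ``n_guides``. Keep/drop status
        is decided separately by :func:`filter_cells_by_guides`.
    """
    if min_umi < 1:
        raise ValueError("min_umi must be >= 1")
    unknown = [g for g in capture.columns if g not in library.target_of]
    if unknown:
        raise ValueError(f"capture matrix contains unknown guide_ids: {unknown}")
    if (np.asarray(capture) < 0).any():
        raise ValueError("capture counts must be non-negative")
    if barcodes is not None:
        capture = capture.reindex(list(barcodes), fill_value=0)

    target_of = library.target_of
    hit = np.asarray(capture) >= min_umi
    cols = np.asarray(capture.columns)
    det_guides, det_targets = [], []
    for row in hit:
        gs = tuple(cols[row])
        det_guides.append(gs)
        det_targets.append(tuple(sorted({target_of[g] for g in gs} - {""})))
    return pd.DataFrame(
        {
            "detected_guides": det_guides,
            "detected_targets": det_targets,
            "n_guides": [len(g) for g in det_guides],
        },
        index=capture.index,
    )


def filter_cells_by_guides(assignment: pd.DataFrame,
                           library_type: pd.Series) -> pd.DataFrame:
    """Decide keep/drop per cell by the library-specific multiplicity rule.

    NT libraries keep cells with exactly one detected guide; AGM libraries
    keep cells with more than one. ``library_type`` maps each barcode to
    ``"NT"`` or ``"AGM"``.
    """
    missing = assignment.index.difference(library_type.index)
    if len(missing):
        raise ValueError(f"library_type missing for {len(missing)} cells")
    bad = set(library_type.unique()) - {"NT", "AGM"}
    if bad:
        raise ValueError(f"unknown library_type values: {sorted(bad)}")

    out = assignment.copy()
    ltype = library_type.reindex(assignment.index)
    n = out["n_guides"].to_numpy()
    reason = np.full(len(out), KEPT, dtype=object)
    reason[n == 0] = ZERO_GUIDES
    is_nt = (ltype == "NT").to_numpy()
    reason[is_nt & (n > 1)] = WRONG_MULTIPLICITY
    reason[~is_nt & (n == 1)] = TOO_FEW
    out["library_type"] = ltype.to_numpy()
    out["reason"] = reason
    out["keep"] = reason == KEPT
    return out


def guides_per_target_summary(assignment: pd.DataFrame,
                              library: GuideLibrary) -> pd.DataFrame:
    """Per-target cell tallies over kept cells.

    A cell counts once per target no matter how many of that target's guides
    it carries; per-guide cell counts are returned alongside.
    """
    if "keep" not in assignment.columns:
        raise ValueError("assignment must have keep decided (run filter_cells_by_guides)")
    kept = assignment[assignment["keep"]]
    target_cells = {t: 0 for t in library.targets}
    guide_cells = {g: 0 for g in library.guide_ids if library.target_of[g] != ""}
    for targets, gs in zip(kept["detected_targets"], kept["detected_guides"]):
        for t in targets:
            target_cells[t] += 1
        for g in gs:
            if g in guide_cells:
                guide_cells[g] += 1
    rows = []
    for t in library.targets:
        per_guide = {g: guide_cells[g] for g in library.guides_for(t)}
        rows.append({"target": t, "n_cells": target_cells[t],
                     "per_guide_cells": per_guide})
    return pd.DataFrame(rows).set_index("target")
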