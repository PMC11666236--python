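"""Seahorse XF real-time ATP-rate partitioning.

The assay measures oxygen consumption rate (OCR, pmol O2/min) and
extracellular acidification rate (ECAR, mpH/min) across three phases: basal,
after ATP-synthase inhibition (oligomycin), and after complex I/III
inhibition (rotenone + antimycin A). The arithmetic implemented here is the
instrument vendor's published calculation:

    OCR_ATP   = OCR_basal - OCR_oligo
    MitoATP   = OCR_ATP * 2 * P/O            (P/O = 2.75, 2 O atoms per O2)
    MitoPER   = (OCR_basal - OCR_rot) * CCF  (CO2 contribution factor 0.5)
    PER       = ECAR_basal * BF * Vol * Kvol (2.6 mpH^-1, 2.28 ul, 1.1)
    GlycoATP  = PER - MitoPER
    TotalATP  = MitoATP + GlycoATP
    Mito/Glyco ratio = MitoATP / GlycoATP

Note the MitoPER term uses total mitochondrial OCR (basal - rot), not the
ATP-linked portion; the calculation is implemented exactly as published and
the convention difference from some other formulations is documented rather
than resolved. ATP rates are in pmol ATP/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PHASES = ("basal", "oligo", "rot")


@dataclass(frozen=True)
class ATPConstants:
    """Printed constants of the ATP-rate calculation (all strictly positive)."""

    o2_per_atp_factor: float = 2.0   # molecular oxygen consumption rate
    p_o_ratio: float = 2.75          # ATP per O atom reduced
    co2_contribution: float = 0.5    # CCF
    buffer_factor: float = 2.6       # mpH^-1
    reaction_volume: float = 2.28    # ul
    kvol: float = 1.1

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


def read_trace_csv(path) -> pd.DataFrame:
    """Read a trace CSV (well, condition, phase, read_index, OCR, ECAR)."""
    df = pd.read_csv(path)
    required = {"well", "phase", "read_index", "OCR", "ECAR"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return df


def phase_means(trace: pd.DataFrame, strict: bool = True,
                reads_per_phase: int = 3) -> pd.DataFrame:
    """Per-well arithmetic phase means of OCR plus the basal ECAR mean.

    With ``strict`` (the default) every well must carry exactly
    ``reads_per_phase`` reads in each of the three phases; otherwise any
    positive number of reads per phase is accepted. A missing phase is
    always an error naming the well and phase.
    """
    if (trace[["OCR", "ECAR"]].to_numpy() < 0).any():
        raise ValueError("OCR/ECAR must be non-negative")
    bad_phase = set(trace["phase"]) - set(PHASES)
    if bad_phase:
        raise ValueError(f"unknown phases: {sorted(bad_phase)}")
    rows = []
    for well, grp in trace.groupby("well", sort=True):
        rec: dict = {"well": well}
        if "condition" in grp.columns:
            rec["condition"] = grp["condition"].iloc[0]
        for phase in PHASES:
            reads = grp[grp["phase"] == phase]
            if len(reads) == 0:
                raise ValueError(f"well {well}: missing phase {phase!r}")
            if strict and len(reads) != reads_per_phase:
                raise ValueError(
                    f"well {well}: phase {phase!r} has {len(reads)} reads, "
                    f"expected {reads_per_phase}")
            rec[f"ocr_{phase}"] = float(reads["OCR"].mean())
            if phase == "basal":
                rec["ecar_basal"] = float(reads["ECAR"].mean())
        rows.append(rec)
    return pd.DataFrame(rows).set_index("well")


def compute_atp_rates(means: pd.DataFrame,
                      constants: ATPConstants | None = None) -> pd.DataFrame:
    """ATP partitioning per well from phase means.

    Wells whose phase means violate basal >= oligo >= rot are flagged
    invalid with a reason and their rates set to NaN (never silently
    clamped); the Mito/Glyco ratio is additionally undefined when
    GlycoATP <= 0. Output columns carry units of pmol ATP/min.
    """
    c = constants or ATPConstants()
    out = means.copy()
    basal = out["ocr_basal"].to_numpy(float)
    oligo = out["ocr_oligo"].to_numpy(float)
    rot = out["ocr_rot"].to_numpy(float)
    ecar = out["ecar_basal"].to_numpy(float)

    valid = (basal >= oligo) & (oligo >= rot)
    reason = np.where(valid, "", "phase_order_violation")

    ocr_atp = basal - oligo
    mito_atp = ocr_atp * c.o2_per_atp_factor * c.p_o_ratio
    mito_per = (basal - rot) * c.co2_contribution
    per = ecar * c.buffer_factor * c.reaction_volume * c.kvol
    glyco_atp = per - mito_per
    total_atp = mito_atp + glyco_atp
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(glyco_atp > 0, mito_atp / glyco_atp, np.nan)
    reason = np.where(valid & (glyco_atp <= 0), "nonpositive_glyco_atp", reason)

    for name, vals in (("ocr_atp", ocr_atp), ("mito_atp", mito_atp),
                       ("mito_per", mito_per), ("per", per),
                       ("glyco_atp", glyco_atp), ("total_atp", total_atp)):
        out[name] = np.where(valid, vals, np.nan)
    out["mito_glyco_ratio"] = np.where(valid, ratio, np.nan)
    out["valid"] = valid
    out["invalid_reason"] = reason
    out.attrs["units"] = "pmol ATP/min"
    return out


def condition_summary(rates: pd.DataFrame,
                      condition_col: str = "condition") -> pd.DataFrame:
    """Per-condition mean and SD of the ATP rates over valid wells.

    Invalid wells are excluded (and counted); a condition with zero valid
    wells is an error. SD is reported as NaN for single-well conditions.
    """
    if condition_col not in rates.columns:
        raise ValueError(f"missing condition column {condition_col!r}")
    metrics = ["glyco_atp", "mito_atp", "total_atp", "mito_glyco_ratio"]
    rows = []
    for cond, grp in rates.groupby(condition_col, sort=True):
        ok = grp[grp["valid"]]
        if len(ok) == 0:
            raise ValueError(f"condition {cond!r} has zero valid wells")
        rec = {"condition": cond, "n_wells": len(ok),
               "n_excluded": int(len(grp) - len(ok))}
        for m in metrics:
            rec[f"{m}_mean"] = float(ok[m].mean())
            rec[f"{m}_sd"] = float(ok[m].std(ddof=1)) if len(ok) > 1 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("condition")
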