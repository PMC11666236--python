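"""Configuration objects for the synthetic-data generator and the pipeline.

The defaults encode the study design this package models: four perturbation
libraries (an iSAM line carrying a non-targeting guide or a 49-guide CRISPRa
pool against nine transcription factors, each with and without doxycycline
induction), endothelial subpopulations with canonical marker programs, and a
Seahorse real-time ATP-rate assay with three phases of three reads each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

#: The four perturbation libraries, in fixed order.
LIBRARIES = ("iSAM_NT", "iSAM_NT_DOX", "iSAM_AGM", "iSAM_AGM_DOX")

#: Nine target transcription factors of the activation pool. ZNF124 is the
#: planted null: its guides are present but activation has no effect on it.
DEFAULT_TARGETS = (
    "RUNX1T1", "NR4A1", "GATA2", "SMAD7", "ZNF124",
    "SOX6", "ZNF33A", "NFAT5", "TFDP2",
)
NULL_TARGET = "ZNF124"

#: Marker panels used for cluster annotation (panel order is the tie-break
#: priority). EHT cells additionally downregulate pan-endothelial genes.
DEFAULT_MARKER_PANELS = {
    "arterial": ["GJA4", "DLL4"],
    "venous": ["NRP2", "APLNR"],
    "EHT": ["RUNX1", "CD44"],
}
PAN_ENDOTHELIAL = ("PECAM1", "CDH5")
MITO_GENES = ("MT-CO1", "MT-CO2", "MT-ND1", "MT-ND2", "MT-CYB")

EFFECTOR_GENE = "IGFBP2"
DRIVER_TARGET = "RUNX1T1"


@dataclass
class PopulationSpec:
    """One endothelial subpopulation with an additive marker program.

    ``marker_shifts`` maps gene symbol -> additive shift applied to the
    shared baseline mean expression of that gene in cells of this population.
    Negative shifts model downregulation (e.g. pan-endothelial genes during
    the endothelial-to-haematopoietic transition); means are clipped at zero.
    """

    name: str
    base_fraction: float
    marker_shifts: dict[str, float] = field(default_factory=dict)


def default_populations() -> list[PopulationSpec]:
    return [
        PopulationSpec("arterial", 0.15, {"GJA4": 3.0, "DLL4": 3.0}),
        PopulationSpec("venous", 0.55, {"NRP2": 3.0, "APLNR": 3.0}),
        PopulationSpec(
            "EHT", 0.30,
            {"RUNX1": 3.0, "CD44": 3.0, "PECAM1": -2.0, "CDH5": -2.0},
        ),
    ]


@dataclass
class PerturbationConfig:
    """Design of the four-library CRISPRa perturbation experiment."""

    n_cells_per_library: int = 2000
    n_genes: int = 300
    populations: list[PopulationSpec] = field(default_factory=default_populations)
    targets: Sequence[str] = DEFAULT_TARGETS
    #: Per-target mean multiplier applied in guide-carrying cells of the
    #: DOX-induced AGM library. The null target stays at 1.0.
    activation_fold: dict[str, float] = field(default_factory=lambda: {
        t: (1.0 if t == NULL_TARGET else 2.0) for t in DEFAULT_TARGETS
    })
    #: Fold-expansion of the arterial base fraction upon DOX induction.
    #: DOX alone (NT line) expands the arterial compartment 1.63-fold; the
    #: activation pool expands it 3.33-fold.
    arterial_expansion_fold_NT: float = 1.63
    arterial_expansion_fold_AGM: float = 3.33
    effector_gene: str = EFFECTOR_GENE
    effector_induction_fold: float = 3.0
    driver_target: str = DRIVER_TARGET
    #: P(arterial | driver-guide carrier) / P(arterial | non-carrier) in the
    #: DOX-induced AGM library; plants the driver-guide enrichment signal.
    driver_arterial_ratio: float = 2.0
    #: Guides per target drawn to total 49 across nine targets (5-7 each).
    guides_per_target: tuple[int, ...] = (6, 5, 5, 6, 5, 6, 5, 6, 5)
    #: pmf of the number of distinct pool guides detected per AGM cell.
    moi_pmf: dict[int, float] = field(default_factory=lambda: {
        1: 0.10, 2: 0.25, 3: 0.30, 4: 0.20, 5: 0.10, 6: 0.05,
    })
    #: Expected number of ambient (spurious) guide molecules per cell.
    ambient_rate: float = 0.01
    #: Mean UMI count of a truly present guide (sampled as 1 + NB(mean-1)).
    guide_capture_mean: float = 20.0
    #: Negative-binomial dispersion (gamma shape) shared by all genes/guides.
    dispersion: float = 10.0
    #: Fraction of cells perturbed into QC-failing states (half low-coverage,
    #: half high-mitochondrial), emulating damaged/dying cells.
    qc_outlier_fraction: float = 0.04
    baseline_log_mean: float = -1.6
    baseline_log_sd: float = 1.0

    def validate(self) -> None:
        total = sum(p.base_fraction for p in self.populations)
        if not self.populations or abs(total - 1.0) > 1e-9:
            raise ValueError(f"population base_fractions must sum to 1, got {total}")
        if self.n_cells_per_library <= 0:
            raise ValueError("n_cells_per_library must be positive")
        for t, f in self.activation_fold.items():
            if f < 1.0:
                raise ValueError(f"activation_fold must be >= 1 (target {t}: {f})")
        if set(self.activation_fold) != set(self.targets):
            raise ValueError("activation_fold keys must match targets")
        if len(self.guides_per_target) != len(self.targets):
            raise ValueError("guides_per_target length must match targets")
        if any(not (5 <= g <= 7) for g in self.guides_per_target):
            raise ValueError("guides per target must be in 5-7")
        if abs(sum(self.moi_pmf.values()) - 1.0) > 1e-9:
            raise ValueError("moi_pmf must sum to 1")
        if min(self.moi_pmf) < 1:
            raise ValueError("moi_pmf support must be >= 1 guide per cell")


#: In vivo (embryonic aorta-gonad-mesonephros region) and in vitro
#: (iPSC-derived) reference populations.
IN_VIVO_POPULATIONS = ("aEC", "vEC", "aHEC")
IN_VITRO_POPULATIONS = ("IVD_Endo", "IVD_HPC")


@dataclass
class ReferencePanelConfig:
    """Cross-dataset reference panel for candidate-TF discovery.

    ``planted_tf_detection`` gives, per planted transcription factor, the
    detection probability (fraction of cells with count > 0) in each
    population. Defaults plant nine TFs detected in 70% of in vivo haemogenic
    endothelium but only 10% of in vitro-derived endothelium.
    """

    n_cells_in_vivo: int = 2000
    n_cells_in_vitro: int = 2000
    in_vivo_fractions: dict[str, float] = field(default_factory=lambda: {
        "aEC": 0.35, "vEC": 0.40, "aHEC": 0.25,
    })
    in_vitro_fractions: dict[str, float] = field(default_factory=lambda: {
        "IVD_Endo": 0.70, "IVD_HPC": 0.30,
    })
    planted_tfs: Sequence[str] = DEFAULT_TARGETS
    planted_detection: dict[str, float] = field(default_factory=lambda: {
        "aHEC": 0.70, "aEC": 0.15, "vEC": 0.15,
        "IVD_Endo": 0.10, "IVD_HPC": 0.10,
    })
    #: TFs detected everywhere (fail the in vitro gate) and TFs detected
    #: almost nowhere (fail the in vivo gate); both are decoys for selection.
    ubiquitous_tfs: Sequence[str] = ("FLI1", "ERG", "SOX7", "LMO2", "TAL1", "ETV2")
    silent_tfs: Sequence[str] = ("HOXA9", "MEIS1", "HLF")
    n_background_genes: int = 260
    dispersion: float = 10.0

    def validate(self) -> None:
        for name, fr in (("in_vivo", self.in_vivo_fractions),
                         ("in_vitro", self.in_vitro_fractions)):
            if not fr:
                raise ValueError(f"{name} populations must be non-empty")
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} fractions must sum to 1")
        for pop, p in self.planted_detection.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"detection probability out of [0,1] for {pop}: {p}")

    def tf_list(self) -> list[str]:
        return list(self.planted_tfs) + list(self.ubiquitous_tfs) + list(self.silent_tfs)


def null_reference_config(**kwargs) -> ReferencePanelConfig:
    """Reference panel with no planted differential detection (null model)."""
    cfg = ReferencePanelConfig(**kwargs)
    cfg.planted_detection = {p: 0.30 for p in
                             list(IN_VIVO_POPULATIONS) + list(IN_VITRO_POPULATIONS)}
    return cfg


@dataclass
class SeahorseConfig:
    """Phase-mean design of a Seahorse real-time ATP-rate assay.

    OCR means must be weakly decreasing across basal -> oligomycin ->
    rotenone/antimycin-A, matching the inhibitor cascade of the assay.
    The treated condition models the effector's glycolysis reduction.
    """

    conditions: dict[str, dict] = field(default_factory=lambda: {
        "CTR": {"ocr": (100.0, 40.0, 20.0), "ecar": 30.0},
        "IGFBP2": {"ocr": (100.0, 42.0, 20.0), "ecar": 18.0},
    })
    wells_per_condition: int = 3
    reads_per_phase: int = 3
    ocr_noise_sd: float = 2.0
    ecar_noise_sd: float = 1.0

    def validate(self) -> None:
        for cond, spec in self.conditions.items():
            basal, oligo, rot = spec["ocr"]
            if not basal >= oligo >= rot:
                raise ValueError(
                    f"phase means must satisfy basal >= oligo >= rot ({cond}: {spec['ocr']})"
                )
            if spec["ecar"] < 0:
                raise ValueError(f"ECAR mean must be non-negative ({cond})")


@dataclass
class TimecourseConfig:
    """Two-timepoint effector-treatment design (day 10 / day 13, +/- effector).

    At day 13 the effector induces an oxidative-phosphorylation gene program
    and the haemogenic marker RUNX1 while downregulating glycolytic enzymes
    and the arterial marker DLL4; day 10 shows no effect.
    """

    n_cells_per_condition: int = 800
    n_genes: int = 220
    oxphos_fold: float = 2.5
    glyco_fold: float = 0.5
    runx1_fold: float = 2.0
    dll4_fold: float = 0.6
    dispersion: float = 10.0

    oxphos_genes: Sequence[str] = (
        "NDUFA1", "NDUFB2", "NDUFS2", "SDHA", "UQCRC1",
        "CYC1", "COX5A", "COX7B", "ATP5F1A", "ATP5MC1",
    )
    glyco_genes: Sequence[str] = (
        "HK1", "HK2", "PFKL", "PFKP", "ENO1", "PKM", "LDHA", "SLC16A3",
    )


@dataclass
class SimulationConfig:
    """Top-level bundle: one seed, one design for every simulated input."""

    seed: int = 0
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    reference: ReferencePanelConfig = field(default_factory=ReferencePanelConfig)
    seahorse: SeahorseConfig = field(default_factory=SeahorseConfig)
    timecourse: TimecourseConfig = field(default_factory=TimecourseConfig)

    def validate(self) -> None:
        self.perturbation.validate()
        self.reference.validate()
        self.seahorse.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
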