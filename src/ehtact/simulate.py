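"""Ground-truthed synthetic inputs for every stage of the pipeline.

Three generators, all driven by one :class:`~ehtact.config.SimulationConfig`
and a single seeded random stream (identical config + seed gives bit-identical
output):

``simulate_reference_panel``
    An in vivo embryonic endothelium panel (arterial, venous, arterial
    haemogenic cells) and an in vitro iPSC-derived panel (endothelial and
    haematopoietic cells), with nine transcription factors planted at high
    detection in the in vivo haemogenic cells and low detection in vitro.

``simulate_perturbation_experiment``
    Four CRISPRa perturbation libraries (NT and 49-guide pool, each with and
    without doxycycline), with guide-capture counts, DOX-dependent activation
    of eight of nine targets, arterial-fraction expansion, driver-guide
    enrichment among arterial cells, and an induced downstream effector.

``simulate_seahorse``
    Phase-labelled OCR/ECAR well traces for the ATP-partitioning arithmetic.

Counts are negative-binomial (gamma-Poisson) with a shared dispersion; marker
programs are additive mean shifts on a common baseline, which keeps
clustering and annotation well-posed without modelling batch structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import (
    LIBRARIES,
    MITO_GENES,
    PAN_ENDOTHELIAL,
    PerturbationConfig,
    ReferencePanelConfig,
    SeahorseConfig,
    SimulationConfig,
    TimecourseConfig,
)
from .guides import NT_GUIDE, GuideLibrary, build_default_library

MARKER_GENES = ("GJA4", "DLL4", "NRP2", "APLNR", "RUNX1", "CD44")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts with the given mean matrix."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(dispersion, mean / dispersion)
    return rng.poisson(lam)


def _nb_mean_for_detection(p: float, dispersion: float) -> float:
    """Mean m with P(NB(m, r) > 0) = p, from P(0) = (r/(r+m))^r."""
    if not 0.0 <= p < 1.0:
        if p == 1.0:
            raise ValueError("detection probability 1.0 is not representable")
        raise ValueError(f"detection probability out of [0,1): {p}")
    if p == 0.0:
        return 0.0
    r = dispersion
    return r * ((1.0 - p) ** (-1.0 / r) - 1.0)


# ---------------------------------------------------------------------------
# reference panel


@dataclass
class ReferencePanelData:
    in_vivo: ad.AnnData
    in_vitro: ad.AnnData
    planted_tfs: list[str]
    #: planted detection probability per (gene, population)
    detection_truth: pd.DataFrame


def simulate_reference_panel(config: SimulationConfig) -> ReferencePanelData:
    """Simulate the in vivo / in vitro reference dataset pair.

    Raises ``ValueError`` on empty populations or detection probabilities
    outside [0, 1). Deterministic given ``config.seed``.
    """
    rc: ReferencePanelConfig = config.reference
    rc.validate()
    rng = np.random.default_rng(config.seed)
    r = rc.dispersion

    pops_vivo = list(rc.in_vivo_fractions)
    pops_vitro = list(rc.in_vitro_fractions)
    all_pops = pops_vivo + pops_vitro

    background = [f"BG{i:04d}" for i in range(rc.n_background_genes)]
    structural = ["PECAM1", "CDH5", "CD44", "GJA4", "DLL4"]
    genes = (background + structural + list(rc.planted_tfs)
             + list(rc.ubiquitous_tfs) + list(rc.silent_tfs))
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene symbols in reference panel design")

    # detection probability per gene x population
    det = pd.DataFrame(index=genes, columns=all_pops, dtype=float)
    bg_p = rng.beta(1.2, 4.0, size=rc.n_background_genes).clip(0.005, 0.95)
    for pop in all_pops:
        det.loc[background, pop] = bg_p
    det.loc["PECAM1"] = 0.90
    det.loc["CDH5"] = 0.90
    # a strong non-TF haemogenic marker: passes the fraction gates but must
    # be excluded by the TF gate downstream
    det.loc["CD44"] = {"aHEC": 0.80, "aEC": 0.20, "vEC": 0.20,
                       "IVD_Endo": 0.15, "IVD_HPC": 0.50}
    for g in ("GJA4", "DLL4"):  # arterial genes, high in vivo arterial lineages
        det.loc[g] = {"aHEC": 0.65, "aEC": 0.70, "vEC": 0.10,
                      "IVD_Endo": 0.40, "IVD_HPC": 0.10}
    for g in rc.planted_tfs:
        det.loc[g] = [rc.planted_detection.get(p, 0.1) for p in all_pops]
    for g in rc.ubiquitous_tfs:
        det.loc[g] = 0.80
    for g in rc.silent_tfs:
        det.loc[g] = 0.05
    det = det.reindex(columns=all_pops).fillna(0.1)

    means = det.map(lambda p: _nb_mean_for_detection(float(p), r))

    def _panel(n_cells: int, fractions: dict[str, float], prefix: str) -> ad.AnnData:
        pops = list(fractions)
        labels = rng.choice(pops, size=n_cells, p=[fractions[p] for p in pops])
        M = means[labels].to_numpy().T  # cells x genes
        counts = _nb_counts(rng, M, r)
        adata = ad.AnnData(
            X=sp.csr_matrix(counts),
            obs=pd.DataFrame(
                {"population": pd.Categorical(labels)},
                index=[f"{prefix}_{i:05d}" for i in range(n_cells)],
            ),
            var=pd.DataFrame(index=genes),
        )
        return adata

    in_vivo = _panel(rc.n_cells_in_vivo, rc.in_vivo_fractions, "VIVO")
    in_vitro = _panel(rc.n_cells_in_vitro, rc.in_vitro_fractions, "VITRO")
    return ReferencePanelData(in_vivo, in_vitro, list(rc.planted_tfs), det)


# ---------------------------------------------------------------------------
# perturbation experiment


@dataclass
class GroundTruth:
    """Per-cell and per-target planted truth of a perturbation simulation."""

    cells: pd.DataFrame
    targets: pd.DataFrame
    arterial_fraction: dict[str, float] = field(default_factory=dict)


@dataclass
class PerturbationData:
    adata: ad.AnnData
    guide_capture: pd.DataFrame
    metadata: pd.DataFrame
    truth: GroundTruth
    guide_library: GuideLibrary


def perturbation_gene_panel(p: PerturbationConfig, rng: np.random.Generator):
    """Gene symbols and shared baseline means for the perturbation design."""
    named = (list(MARKER_GENES) + list(PAN_ENDOTHELIAL) + list(p.targets)
             + [p.effector_gene] + list(MITO_GENES))
    n_bg = p.n_genes - len(named)
    if n_bg < 10:
        raise ValueError(f"n_genes too small for the named gene panel (need >= {len(named) + 10})")
    background = [f"BG{i:04d}" for i in range(n_bg)]
    genes = named + background
    baseline = np.empty(len(genes))
    idx = {g: i for i, g in enumerate(genes)}
    for g in MARKER_GENES:
        baseline[idx[g]] = 0.2
    for g in PAN_ENDOTHELIAL:
        baseline[idx[g]] = 3.0
    for g in p.targets:
        baseline[idx[g]] = 1.0
    baseline[idx[p.effector_gene]] = 4.0
    for g in MITO_GENES:
        baseline[idx[g]] = 1.1
    bg = np.exp(rng.normal(p.baseline_log_mean, p.baseline_log_sd, size=n_bg))
    baseline[len(named):] = bg.clip(0.02, 5.0)
    return genes, baseline


def library_population_fractions(p: PerturbationConfig) -> dict[str, dict[str, float]]:
    """Expected population fractions per library after arterial expansion.

    The expansion fold multiplies the arterial base fraction in the
    DOX-induced library of each line; the remaining populations are
    renormalised proportionally so fractions still sum to one.
    """
    base = {pop.name: pop.base_fraction for pop in p.populations}
    folds = {
        "iSAM_NT": 1.0,
        "iSAM_NT_DOX": p.arterial_expansion_fold_NT,
        "iSAM_AGM": 1.0,
        "iSAM_AGM_DOX": p.arterial_expansion_fold_AGM,
    }
    out = {}
    for lib, fold in folds.items():
        fr = dict(base)
        if "arterial" in fr and fold != 1.0:
            a = min(fr["arterial"] * fold, 0.95)
            scale = (1.0 - a) / (1.0 - fr["arterial"])
            fr = {k: (a if k == "arterial" else v * scale) for k, v in fr.items()}
        out[lib] = fr
    return out


def _draw_guide_sets(rng, n_cells: int, pool: list[str], moi_pmf: dict[int, float]):
    ks = sorted(moi_pmf)
    n_per_cell = rng.choice(ks, size=n_cells, p=[moi_pmf[k] for k in ks])
    pool_arr = np.asarray(pool)
    return [tuple(sorted(rng.choice(pool_arr, size=k, replace=False)))
            for k in n_per_cell]


def simulate_perturbation_experiment(config: SimulationConfig) -> PerturbationData:
    """Simulate the four-library CRISPRa experiment with full ground truth.

    Planted structure (all configurable):

    * DOX-induced AGM cells carrying a guide for target *g* express *g* with
      its mean multiplied by ``activation_fold[g]`` (the null target's fold
      is 1.0, so its guides are inert).
    * The arterial fraction of each library equals the base fraction times
      the library's expansion fold, renormalised.
    * In the DOX-induced AGM library, driver-guide (RUNX1T1-class) carriers
      are ``driver_arterial_ratio`` times as likely to be arterial, with the
      non-carrier rate renormalised against the realised carrier fraction so
      the library-level arterial fraction is preserved in expectation.
    * The effector gene is induced ``effector_induction_fold``-fold in
      arterial cells of that library whose guide set hits the driver target.
    """
    p: PerturbationConfig = config.perturbation
    p.validate()
    rng = np.random.default_rng(config.seed)

    library = build_default_library(p.targets, p.guides_per_target)
    if set(library.targets) != set(p.targets):
        raise ValueError("guide library and target list disagree")
    pool = [g for g in library.guide_ids if g != NT_GUIDE]
    driver_guides = set(library.guides_for(p.driver_target))

    genes, baseline = perturbation_gene_panel(p, rng)
    gidx = {g: i for i, g in enumerate(genes)}
    pop_shift = {}
    for pop in p.populations:
        shift = np.zeros(len(genes))
        for g, s in pop.marker_shifts.items():
            if g not in gidx:
                raise ValueError(f"marker gene {g} not in gene panel")
            shift[gidx[g]] = s
        pop_shift[pop.name] = shift

    lib_fracs = library_population_fractions(p)
    pop_names = [pop.name for pop in p.populations]
    n = p.n_cells_per_library

    obs_rows, count_blocks, capture_rows = [], [], []
    mito_idx = [gidx[g] for g in MITO_GENES]
    target_idx = {t: gidx[t] for t in p.targets}
    eff_idx = gidx[p.effector_gene]

    for lib in LIBRARIES:
        is_agm = lib.startswith("iSAM_AGM")
        is_dox = lib.endswith("_DOX")
        barcodes = [f"{lib}_{i:05d}" for i in range(n)]

        if is_agm:
            guide_sets = _draw_guide_sets(rng, n, pool, p.moi_pmf)
        else:
            guide_sets = [(NT_GUIDE,)] * n
        carrier = np.array(
            [any(g in driver_guides for g in gs) for gs in guide_sets]
        )

        fr = lib_fracs[lib]
        probs = np.array([fr[name] for name in pop_names])
        if is_agm and is_dox and p.driver_arterial_ratio != 1.0 and "arterial" in fr:
            w = carrier.mean()
            a = fr["arterial"]
            a_nc = a / (1.0 + w * (p.driver_arterial_ratio - 1.0))
            a_c = min(p.driver_arterial_ratio * a_nc, 0.99)
            pops_rest = np.array([fr[name] if name != "arterial" else 0.0
                                  for name in pop_names])
            pops_rest = pops_rest / pops_rest.sum()
            art_pos = pop_names.index("arterial")

            def _probs(a_x: float) -> np.ndarray:
                pr = pops_rest * (1.0 - a_x)
                pr[art_pos] = a_x
                return pr

            labels = np.empty(n, dtype=object)
            u = rng.random(n)  # one uniform per cell, fixed stream order
            for flag, a_x in ((True, a_c), (False, a_nc)):
                mask = carrier == flag
                cum = np.cumsum(_probs(a_x))
                labels[mask] = np.asarray(pop_names, dtype=object)[
                    np.searchsorted(cum, u[mask], side="right").clip(0, len(pop_names) - 1)
                ]
        else:
            labels = rng.choice(pop_names, size=n, p=probs / probs.sum())

        M = baseline[None, :] + np.stack([pop_shift[l] for l in labels])
        np.clip(M, 0.0, None, out=M)

        if is_agm and is_dox:
            for t, ti in target_idx.items():
                fold = p.activation_fold[t]
                if fold != 1.0:
                    t_guides = set(library.guides_for(t))
                    hit = np.array([any(g in t_guides for g in gs) for gs in guide_sets])
                    M[hit, ti] *= fold
            eff_mask = carrier & (labels == "arterial")
            M[eff_mask, eff_idx] *= p.effector_induction_fold

        # damaged-cell QC outliers: low coverage or high mitochondrial load
        n_out = int(round(p.qc_outlier_fraction * n))
        outlier = np.zeros(n, dtype=bool)
        if n_out:
            out_idx = rng.choice(n, size=n_out, replace=False)
            outlier[out_idx] = True
            half = n_out // 2
            M[out_idx[:half]] *= 0.12
            M[np.ix_(out_idx[half:], mito_idx)] *= 8.0

        count_blocks.append(sp.csr_matrix(_nb_counts(rng, M, p.dispersion)))

        cap = np.zeros((n, len(library.guide_ids)), dtype=np.int64)
        col = {g: j for j, g in enumerate(library.guide_ids)}
        for i, gs in enumerate(guide_sets):
            for g in gs:
                cap[i, col[g]] = 1 + _nb_counts(
                    rng, np.array([p.guide_capture_mean - 1.0]), p.dispersion
                )[0]
        if is_agm and p.ambient_rate > 0:
            n_amb = rng.poisson(p.ambient_rate, size=n)
            for i in np.nonzero(n_amb)[0]:
                for g in rng.choice(pool, size=n_amb[i]):
                    cap[i, col[g]] += 1
        capture_rows.append(pd.DataFrame(cap, index=barcodes,
                                         columns=library.guide_ids))

        obs_rows.append(pd.DataFrame({
            "library": lib,
            "library_type": "AGM" if is_agm else "NT",
            "dox": is_dox,
            "population": labels,
            "guides": [";".join(gs) for gs in guide_sets],
            "n_true_guides": [len(gs) for gs in guide_sets],
            "driver_carrier": carrier,
            "qc_outlier": outlier,
        }, index=barcodes))

    obs = pd.concat(obs_rows)
    adata = ad.AnnData(
        X=sp.vstack(count_blocks).tocsr(),
        obs=obs[["library", "library_type", "dox"]].copy(),
        var=pd.DataFrame(index=genes),
    )
    capture = pd.concat(capture_rows)
    truth_targets = pd.DataFrame({
        "target": list(p.targets),
        "activation_fold": [p.activation_fold[t] for t in p.targets],
        "is_null": [p.activation_fold[t] == 1.0 for t in p.targets],
    }).set_index("target")
    truth = GroundTruth(
        cells=obs,
        targets=truth_targets,
        arterial_fraction={lib: fr.get("arterial", 0.0)
                           for lib, fr in lib_fracs.items()},
    )
    return PerturbationData(adata, capture, adata.obs.copy(), truth, library)


# ---------------------------------------------------------------------------
# Seahorse traces


def simulate_seahorse(config: SimulationConfig) -> pd.DataFrame:
    """Simulate phase-labelled OCR/ECAR well traces.

    Returns a tidy frame (well, condition, phase, read_index, OCR, ECAR)
    with ``reads_per_phase`` reads per phase per well and additive Gaussian
    noise, truncated at zero. Phase means must satisfy basal >= oligo >= rot.
    """
    sc: SeahorseConfig = config.seahorse
    sc.validate()
    rng = np.random.default_rng(config.seed)
    phases = ("basal", "oligo", "rot")
    rows = []
    widx = 0
    for cond, spec in sc.conditions.items():
        ocr_means = dict(zip(phases, spec["ocr"]))
        for _ in range(sc.wells_per_condition):
            widx += 1
            well = f"W{widx:02d}"
            for phase in phases:
                for read in range(1, sc.reads_per_phase + 1):
                    ocr = max(0.0, ocr_means[phase]
                              + rng.normal(0.0, sc.ocr_noise_sd))
                    ecar = max(0.0, spec["ecar"]
                               + rng.normal(0.0, sc.ecar_noise_sd))
                    rows.append((well, cond, phase, read, ocr, ecar))
    return pd.DataFrame(rows, columns=["well", "condition", "phase",
                                       "read_index", "OCR", "ECAR"])


# ---------------------------------------------------------------------------
# two-timepoint effector treatment (day 10 / day 13)


def simulate_timecourse(config: SimulationConfig) -> ad.AnnData:
    """Two-timepoint, +/- effector design reusing the count machinery.

    At day 13 the effector induces the oxidative-phosphorylation program and
    RUNX1 while reducing glycolytic genes and DLL4; day 10 is unaffected.
    Condition labels: ``day10_CTR``, ``day10_IGFBP2``, ``day13_CTR``,
    ``day13_IGFBP2``.
    """
    tc: TimecourseConfig = config.timecourse
    rng = np.random.default_rng(config.seed)
    named = (list(tc.oxphos_genes) + list(tc.glyco_genes)
             + ["RUNX1", "DLL4", "GJA4"])
    n_bg = tc.n_genes - len(named)
    if n_bg < 10:
        raise ValueError("n_genes too small for the timecourse panel")
    genes = named + [f"BG{i:04d}" for i in range(n_bg)]
    base = np.empty(len(genes))
    base[:len(tc.oxphos_genes)] = 2.0
    base[len(tc.oxphos_genes):len(tc.oxphos_genes) + len(tc.glyco_genes)] = 2.0
    base[len(named) - 3:len(named)] = (1.0, 2.0, 2.0)  # RUNX1, DLL4, GJA4
    base[len(named):] = np.exp(rng.normal(-1.0, 1.0, n_bg)).clip(0.02, 5.0)

    gidx = {g: i for i, g in enumerate(genes)}
    blocks, obs_rows = [], []
    for cond in ("day10_CTR", "day10_IGFBP2", "day13_CTR", "day13_IGFBP2"):
        mean = base.copy()
        if cond == "day13_IGFBP2":
            for g in tc.oxphos_genes:
                mean[gidx[g]] *= tc.oxphos_fold
            for g in tc.glyco_genes:
                mean[gidx[g]] *= tc.glyco_fold
            mean[gidx["RUNX1"]] *= tc.runx1_fold
            mean[gidx["DLL4"]] *= tc.dll4_fold
        M = np.tile(mean, (tc.n_cells_per_condition, 1))
        blocks.append(sp.csr_matrix(_nb_counts(rng, M, tc.dispersion)))
        day, treatment = cond.split("_")
        obs_rows.append(pd.DataFrame({
            "condition": cond, "day": day, "treatment": treatment,
        }, index=[f"{cond}_{i:04d}" for i in range(tc.n_cells_per_condition)]))
    return ad.AnnData(X=sp.vstack(blocks).tocsr(), obs=pd.concat(obs_rows),
                      var=pd.DataFrame(index=genes))
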