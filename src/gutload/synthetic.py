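"""Seeded synthetic cohort generator.

Produces feature tables, dPCR/qPCR records, culture counts, and clinical
metadata with the statistical structure the analysis pipeline assumes, so
every stage runs end-to-end without external data:

* duodenal total loads log-normal with marginal mean 6.13 / SD 1.12 log10
  copies/mL, truncated to [log10(5e3), 9];
* saliva loads ~2.5 orders of magnitude higher with a narrower spread;
* oral-to-duodenal taxon transmission yielding ~85-89% paired overlap and
  ~64-66% non-paired overlap;
* mutually exclusive "disruptor" blooms that suppress strict anaerobes,
  raise total load, and drive symptom/cytokine responses;
* culture CFU with heavier plating noise on the anaerobic side;
* water blanks, volume bookkeeping with missing values, and qPCR records
  for Enterobacteriaceae-rich samples.

Every latent variable (true loads, bloom membership, true severe-symptom
states) is recorded in a ground-truth ledger for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .annotations import (
    BLOOD_AGAR_SUBSET,
    DISRUPTOR_SIGNATURE,
    MACCONKEY_SUBSET,
    builtin_annotations,
    gut_pool,
    oral_pool,
)
from .datamodel import (
    CYTOKINE_NAMES,
    SYMPTOM_NAMES,
    DPCRRecord,
    FeatureTable,
    QPCRRecord,
    SampleRecord,
    TaxonAnnotation,
    ValidationError,
)

# Per-genus baseline intensity hierarchy (log10 relative intensity, SD).
# The eight core oral genera carry most of the community mass (steep
# rank-abundance curve); the long tail sits 1.5-3 orders below them.
_CORE_ORAL = {
    "Streptococcus": (2.20, 0.55),
    "Prevotella": (2.00, 0.32),
    "Veillonella": (1.95, 0.32),
    "Prevotella 7": (1.90, 0.32),
    "Haemophilus": (1.80, 0.35),
    "Fusobacterium": (1.75, 0.32),
    "Neisseria": (1.70, 0.32),
    "Porphyromonas": (1.60, 0.55),
    "Rothia": (0.90, 0.35),
}
_TAIL_ORAL_TOP = 0.20  # intensity of the 9th-ranked oral genus
_TAIL_ORAL_STEP = 0.027  # linear taper of the oral tail
_GUT_COMMON_INTENSITY = (0.00, 0.35)
_DISRUPTOR_BASELINE_INTENSITY = (-0.10, 0.60)

#: Primary-bloom propensity per disruptor (Lactobacillus and the
#: Enterobacteriaceae variants bloom most often).
_BLOOM_WEIGHTS = {
    "Enterobacteriaceae": 28,
    "Escherichia-Shigella": 22,
    "Lactobacillus": 30,
    "Enterococcus": 18,
    "Aeromonas": 16,
    "Clostridium sensu stricto 1": 12,
    "Romboutsia": 11,
    "Bacteroides": 11,
}


class CohortConfig(BaseModel):
    """All generative parameters of the synthetic cohort."""

    n_subjects: int = Field(default=250, ge=0)
    n_paired_saliva: int = Field(default=21, ge=0)

    # duodenal total-load model (marginal, blooms included)
    load_mean_log10: float = 6.13
    load_sd_log10: float = 1.12
    load_min_log10: float = math.log10(5e3)
    load_max_log10: float = 9.0
    # baseline (bloom-free) component, calibrated so the marginal of
    # log10(baseline + bloom mass) matches the stated mean/SD above
    baseline_mean_log10: float = 5.80
    baseline_sd_log10: float = 1.15

    # saliva model: per-subject offset above the duodenal load
    saliva_offset_log10: float = 2.5
    saliva_offset_sd_log10: float = 0.35

    # oral-to-duodenal transmission
    saliva_inclusion: float = Field(default=0.75, ge=0, le=1)
    transmission: float = Field(default=0.88, ge=0, le=1)
    duodenum_unique_rate: float = Field(default=2.8, ge=0)
    disruptor_baseline_presence: float = Field(default=0.04, ge=0, le=1)
    # low-rate salivary carriage of gut-resident (facultative) genera; these
    # do not seed the duodenal community but count as oral presence
    gut_saliva_inclusion: float = Field(default=0.26, ge=0, le=1)
    # the 8 core oral genera are near-universally carried; the oral tail rate
    # is solved so the pool-wide mean inclusion equals saliva_inclusion
    core_saliva_inclusion: float = Field(default=0.80, ge=0, le=1)

    # disruptor blooms
    bloom_probability: float = Field(default=0.2, ge=0, le=1)
    bloom_mean_log10: float = 6.5
    bloom_sd_log10: float = 1.0
    co_bloom_probability: float = Field(default=0.45, ge=0, le=1)
    co_bloom_attenuation_log10: tuple[float, float] = (0.1, 0.5)
    anaerobe_suppression_k: float = 8.0

    # sequencing
    depth_mean: float = 50000.0
    depth_sd: float = 1500.0
    depth_min: int = 46000

    # dPCR / volumes / blanks
    extract_volume_ul: float = 100.0
    dilution_duodenum: float = 10.0
    dilution_saliva: float = 1000.0
    dpcr_noise_sd_log10: float = 0.05
    duo_volume_mean_log10: float = -0.2296  # 95% CI 0.18-1.93 mL
    duo_volume_sd_log10: float = 0.2629
    sal_volume_mean_log10: float = -0.1683  # 95% CI 0.36-1.28 mL
    sal_volume_sd_log10: float = 0.1405
    missing_volume_fraction_duodenum: float = 11 / 250
    missing_volume_fraction_saliva: float = 10 / 21
    blank_mean_log10: float = 3.5
    blank_sd_log10: float = 0.15
    n_blanks: int = Field(default=10, ge=0)

    # culture
    aerobic_plating_noise_sd_log10: float = 0.5
    anaerobic_plating_noise_sd_log10: float = 1.2
    copies_per_genome_aerobic: int = 8
    copies_per_genome_anaerobic: int = 4
    missing_culture_fraction: float = 6 / 250

    # symptoms / cytokines
    symptom_intercept: float = -1.0
    symptom_slope: float = 0.5  # per log10 copies/mL of disruptor load
    symptom_subject_sd: float = 2.5
    il8_effect_log10: float = 0.08
    cytokine_mean_log10: float = 1.3
    cytokine_sd_log10: float = 0.25
    missing_cytokine_fraction: float = 18 / 250

    # Klebsiella qPCR
    klebsiella_fraction_of_entero: float = 0.5
    klebsiella_detect_probability: float = 16 / 22
    klebsiella_noise_sd_log10: float = 0.3
    qpcr_trigger_copies_per_ml: float = 1e5

    # metadata flags
    p_probiotics: float = 49 / 250
    p_smoker: float = 16 / 250
    p_antibiotics_6mo: float = 100 / 250
    p_ppi: float = 106 / 250
    p_antibiotics_current: float = 0.06

    @model_validator(mode="after")
    def _check(self):
        if self.load_min_log10 >= self.load_max_log10:
            raise ValueError("load truncation bounds out of order")
        if self.n_paired_saliva > self.n_subjects:
            raise ValueError("more paired saliva samples than subjects")
        lo, hi = self.co_bloom_attenuation_log10
        if lo > hi:
            raise ValueError("co-bloom attenuation range out of order")
        return self


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, plus the ground-truth ledger."""

    config: CohortConfig
    seed: int
    duodenum_counts: FeatureTable
    saliva_counts: Optional[FeatureTable]
    dpcr_records: list[DPCRRecord]
    qpcr_records: list[QPCRRecord]
    sample_records: list[SampleRecord]
    annotations: dict[str, TaxonAnnotation]
    subject_map: dict[str, tuple[str, str]]  # subject -> (duodenum id, saliva id)
    truth: dict = field(default_factory=dict)


def taxon_intensity_params() -> dict[str, tuple[float, float]]:
    """Baseline (mean log10 intensity, SD) for every genus in the pool."""
    params: dict[str, tuple[float, float]] = {}
    tail_rank = 0
    for genus in oral_pool():
        if genus in _CORE_ORAL:
            params[genus] = _CORE_ORAL[genus]
        else:
            params[genus] = (_TAIL_ORAL_TOP - _TAIL_ORAL_STEP * tail_rank, 0.35)
            tail_rank += 1
    for genus in gut_pool():
        if genus in DISRUPTOR_SIGNATURE:
            params[genus] = _DISRUPTOR_BASELINE_INTENSITY
        else:
            params[genus] = _GUT_COMMON_INTENSITY
    return params


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def plant_disruptor_bloom(
    community: pd.Series,
    bloom_loads: Mapping[str, float],
    suppression_k: float,
    annotations: Optional[dict[str, TaxonAnnotation]] = None,
) -> pd.Series:
    """Add disruptor bloom mass to a community (copies/mL) and suppress
    strict anaerobes.

    The bloom fraction f = bloom mass / (original + bloom mass) scales the
    suppression: every strict anaerobe not itself blooming is multiplied by
    exp(-k * f).  The total load increases by at least the bloom mass net of
    suppression; with k = 0 only the bloom taxa change.
    """
    annotations = annotations if annotations is not None else builtin_annotations()
    out = community.astype(float).copy()
    bloom_total = float(sum(bloom_loads.values()))
    if bloom_total <= 0:
        return out
    f = bloom_total / (out.sum() + bloom_total)
    factor = math.exp(-suppression_k * f)
    for taxon in out.index:
        ann = annotations.get(taxon)
        if (
            ann is not None
            and ann.oxygen_class == "strict_anaerobe"
            and taxon not in bloom_loads
        ):
            out[taxon] *= factor
    for taxon, load in bloom_loads.items():
        out[taxon] = out.get(taxon, 0.0) + load
    return out


def emit_culture_counts(
    community: pd.Series,
    rng: np.random.Generator,
    config: CohortConfig,
) -> tuple[float, float]:
    """CFU/mL for aerobic (MacConkey) and anaerobic (blood agar) plating.

    CFU = genome load of the plate-appropriate subset x log-normal plating
    noise; the anaerobic side is noisier (oxygen exposure during handling).
    """
    aero_16s = float(sum(community.get(t, 0.0) for t in MACCONKEY_SUBSET))
    anaero_16s = float(sum(community.get(t, 0.0) for t in BLOOD_AGAR_SUBSET))
    aero = (
        (aero_16s / config.copies_per_genome_aerobic)
        * 10 ** rng.normal(0.0, config.aerobic_plating_noise_sd_log10)
        if aero_16s > 0
        else 0.0
    )
    anaero = (
        (anaero_16s / config.copies_per_genome_anaerobic)
        * 10 ** rng.normal(0.0, config.anaerobic_plating_noise_sd_log10)
        if anaero_16s > 0
        else 0.0
    )
    return aero, anaero


def _community_from_membership(
    rng: np.random.Generator,
    members: list[str],
    params: dict[str, tuple[float, float]],
    taxa: list[str],
) -> pd.Series:
    """Draw log-normal intensities for the member taxa and normalize to
    proportions over the full taxon pool."""
    intensities = pd.Series(0.0, index=taxa)
    for t in members:
        mean, sd = params[t]
        intensities[t] = 10 ** rng.normal(mean, sd)
    total = intensities.sum()
    if total <= 0:
        return intensities
    return intensities / total


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_cohort(config: CohortConfig, seed: int) -> CohortBundle:
    """Generate a full input bundle, deterministic under (config, seed)."""
    rng = np.random.default_rng(seed)
    annotations = builtin_annotations()
    taxa = [g for g in annotations]
    oral = oral_pool()
    gut = gut_pool()
    gut_commons = [t for t in gut if t not in set(DISRUPTOR_SIGNATURE)]
    params = taxon_intensity_params()
    disruptors = list(DISRUPTOR_SIGNATURE)
    bloom_weights = np.array([_BLOOM_WEIGHTS[d] for d in disruptors], dtype=float)
    bloom_weights /= bloom_weights.sum()
    att_lo, att_hi = config.co_bloom_attenuation_log10

    n_core = sum(1 for t in oral if t in _CORE_ORAL)
    tail_incl = (config.saliva_inclusion * len(oral) - config.core_saliva_inclusion * n_core) / max(
        len(oral) - n_core, 1
    )
    tail_incl = float(np.clip(tail_incl, 0.0, 1.0))
    incl = {t: (config.core_saliva_inclusion if t in _CORE_ORAL else tail_incl) for t in oral}

    n = config.n_subjects
    duo_ids = [f"D{i + 1:03d}" for i in range(n)]
    sal_ids = [f"S{i + 1:03d}" for i in range(config.n_paired_saliva)]
    subject_ids = [f"P{i + 1:03d}" for i in range(n)]

    duo_counts = np.zeros((n, len(taxa)), dtype=np.int64)
    sal_counts = np.zeros((config.n_paired_saliva, len(taxa)), dtype=np.int64)
    true_duo_loads = np.zeros((n, len(taxa)))
    true_sal_loads = np.zeros((config.n_paired_saliva, len(taxa)))
    true_totals = np.zeros(n)
    sal_totals = np.zeros(config.n_paired_saliva)
    bloom_primary: dict[str, Optional[str]] = {}
    bloom_members: dict[str, list[str]] = {}
    dpcr_records: list[DPCRRecord] = []
    qpcr_records: list[QPCRRecord] = []
    sample_records: list[SampleRecord] = []
    true_volumes: dict[str, float] = {}
    true_severe = np.zeros((n, len(SYMPTOM_NAMES)), dtype=bool)
    saliva_membership: dict[str, list[str]] = {}
    duodenal_membership: dict[str, list[str]] = {}

    for i in range(n):
        sid, did = subject_ids[i], duo_ids[i]
        # --- community membership -------------------------------------
        sal_members = [t for t in oral if rng.random() < incl[t]]
        transmitted = [t for t in sal_members if rng.random() < config.transmission]
        sal_members += [t for t in gut if rng.random() < config.gut_saliva_inclusion]
        # gut-resident taxa absent from saliva: non-disruptor commensals plus
        # an occasional low-level disruptor carrier
        k_unique = min(int(rng.poisson(config.duodenum_unique_rate)), len(gut_commons))
        unique = list(rng.choice(gut_commons, size=k_unique, replace=False)) if k_unique else []
        carriers = [t for t in disruptors if rng.random() < config.disruptor_baseline_presence]
        members = sorted(set(transmitted) | set(unique) | set(carriers))
        saliva_membership[sid] = sal_members
        duodenal_membership[sid] = members

        # --- baseline absolute community ------------------------------
        props = _community_from_membership(rng, members, params, taxa)
        baseline_log10 = _truncated_normal(
            rng,
            config.baseline_mean_log10,
            config.baseline_sd_log10,
            config.load_min_log10,
            config.load_max_log10,
        )
        community = props * 10**baseline_log10

        # --- disruptor bloom -------------------------------------------
        primary = None
        blooming: dict[str, float] = {}
        if rng.random() < config.bloom_probability:
            primary = str(rng.choice(disruptors, p=bloom_weights))
            b = 10 ** rng.normal(config.bloom_mean_log10, config.bloom_sd_log10)
            blooming[primary] = b
            for other in disruptors:
                if other != primary and rng.random() < config.co_bloom_probability:
                    blooming[other] = b * 10 ** -rng.uniform(att_lo, att_hi)
            community = plant_disruptor_bloom(
                community, blooming, config.anaerobe_suppression_k, annotations
            )
        total = community.sum()
        cap = 10**config.load_max_log10
        if total > cap:
            community *= cap / total
            total = community.sum()
        bloom_primary[did] = primary
        bloom_members[did] = sorted(blooming)
        true_duo_loads[i] = community.to_numpy()
        true_totals[i] = total

        # --- sequencing reads ------------------------------------------
        depth = max(int(round(rng.normal(config.depth_mean, config.depth_sd))), config.depth_min)
        duo_counts[i] = rng.multinomial(depth, community.to_numpy() / total)

        # --- dPCR record ------------------------------------------------
        volume = 10 ** rng.normal(config.duo_volume_mean_log10, config.duo_volume_sd_log10)
        true_volumes[did] = volume
        extract_conc = total * volume / config.extract_volume_ul
        measured = (
            extract_conc
            / config.dilution_duodenum
            * 10 ** rng.normal(0.0, config.dpcr_noise_sd_log10)
        )
        missing = rng.random() < config.missing_volume_fraction_duodenum
        dpcr_records.append(
            DPCRRecord(
                sample_id=did,
                dpcr_concentration=measured,
                dilution_factor=config.dilution_duodenum,
                extract_volume=config.extract_volume_ul,
                collected_sample_volume=None if missing else volume,
                sample_type="duodenum",
            )
        )

        # --- culture ----------------------------------------------------
        aero_cfu, anaero_cfu = emit_culture_counts(community, rng, config)
        culture_missing = rng.random() < config.missing_culture_fraction

        # --- symptoms ----------------------------------------------------
        d_load = float(
            sum(community[t] for t in disruptors if t != "Lactobacillus")
        )
        z = math.log10(d_load + 1.0)
        u = rng.normal(0.0, config.symptom_subject_sd)
        p_severe = _sigmoid(config.symptom_intercept + config.symptom_slope * z + u)
        scores: dict[str, float] = {}
        for j, symptom in enumerate(SYMPTOM_NAMES):
            severe = rng.random() < p_severe
            true_severe[i, j] = severe
            raw = rng.beta(5.0, 1.8) if severe else rng.beta(1.5, 4.0)
            scores[symptom] = float(round(100.0 * raw, 1))

        # --- cytokines ----------------------------------------------------
        cyto_missing = rng.random() < config.missing_cytokine_fraction
        cytokines: dict[str, float] = {}
        for name in CYTOKINE_NAMES:
            log_c = rng.normal(config.cytokine_mean_log10, config.cytokine_sd_log10)
            if name == "IL8":
                log_c += config.il8_effect_log10 * z
            cytokines[name] = float(10**log_c)
        if cyto_missing:
            cytokines = {}

        # --- qPCR ----------------------------------------------------------
        entero_16s = float(community["Enterobacteriaceae"] + community["Escherichia-Shigella"])
        if entero_16s >= config.qpcr_trigger_copies_per_ml:
            cq: Optional[float] = None
            if rng.random() < config.klebsiella_detect_probability:
                kleb_genomes_per_ml = (
                    config.klebsiella_fraction_of_entero
                    * (entero_16s / config.copies_per_genome_aerobic)
                    * 10 ** rng.normal(0.0, config.klebsiella_noise_sd_log10)
                )
                conc = kleb_genomes_per_ml * volume / config.extract_volume_ul
                if conc > 0:
                    cq_val = 22.4 - math.log2(conc / 1000.0)
                    cq = cq_val if cq_val < 40.0 else None
            qpcr_records.append(
                QPCRRecord(
                    sample_id=did,
                    cq=cq,
                    dilution_factor=1.0,
                    extract_volume=config.extract_volume_ul,
                    collected_sample_volume=volume,
                )
            )

        # --- metadata -------------------------------------------------------
        abx_current = rng.random() < (
            config.p_antibiotics_current
            * math.exp(-0.8 * (math.log10(total) - config.load_mean_log10))
        )
        sample_records.append(
            SampleRecord(
                sample_id=did,
                subject_id=sid,
                site="duodenum",
                aerobic_cfu_per_ml=None if culture_missing else aero_cfu,
                anaerobic_cfu_per_ml=None if culture_missing else anaero_cfu,
                symptom_scores=scores,
                cytokines=cytokines,
                age=float(np.clip(rng.normal(57.0, 14.0), 18.0, 83.0).round(0)),
                sex="F" if rng.random() < 0.5 else "M",
                ppi=rng.random() < config.p_ppi,
                antibiotics_current=bool(abx_current),
                antibiotics_6mo=rng.random() < config.p_antibiotics_6mo,
                probiotics=rng.random() < config.p_probiotics,
                smoker=rng.random() < config.p_smoker,
            )
        )

        # --- paired saliva ---------------------------------------------------
        if i < config.n_paired_saliva:
            sal_id = sal_ids[i]
            sal_props = _community_from_membership(rng, sal_members, params, taxa)
            sal_total = 10 ** (
                math.log10(total)
                + rng.normal(config.saliva_offset_log10, config.saliva_offset_sd_log10)
            )
            sal_community = sal_props * sal_total
            true_sal_loads[i] = sal_community.to_numpy()
            sal_totals[i] = sal_total
            depth = max(
                int(round(rng.normal(config.depth_mean, config.depth_sd))), config.depth_min
            )
            if sal_props.sum() > 0:
                sal_counts[i] = rng.multinomial(depth, sal_props.to_numpy())
            sal_volume = 10 ** rng.normal(
                config.sal_volume_mean_log10, config.sal_volume_sd_log10
            )
            true_volumes[sal_id] = sal_volume
            extract_conc = sal_total * sal_volume / config.extract_volume_ul
            measured = (
                extract_conc
                / config.dilution_saliva
                * 10 ** rng.normal(0.0, config.dpcr_noise_sd_log10)
            )
            missing = rng.random() < config.missing_volume_fraction_saliva
            dpcr_records.append(
                DPCRRecord(
                    sample_id=sal_id,
                    dpcr_concentration=measured,
                    dilution_factor=config.dilution_saliva,
                    extract_volume=config.extract_volume_ul,
                    collected_sample_volume=None if missing else sal_volume,
                    sample_type="saliva",
                )
            )
            sample_records.append(
                SampleRecord(sample_id=sal_id, subject_id=sid, site="saliva")
            )

    # --- blanks -----------------------------------------------------------
    for b in range(config.n_blanks):
        blank_load = 10 ** rng.normal(config.blank_mean_log10, config.blank_sd_log10)
        dpcr_records.append(
            DPCRRecord(
                sample_id=f"BLK{b + 1:02d}",
                dpcr_concentration=blank_load * 1.0 / config.extract_volume_ul,
                dilution_factor=1.0,
                extract_volume=config.extract_volume_ul,
                collected_sample_volume=1.0,
                sample_type="blank",
            )
        )

    subject_map = {
        subject_ids[i]: (duo_ids[i], sal_ids[i]) for i in range(config.n_paired_saliva)
    }
    duodenum_table = FeatureTable(pd.DataFrame(duo_counts, index=duo_ids, columns=taxa))
    saliva_table = (
        FeatureTable(pd.DataFrame(sal_counts, index=sal_ids, columns=taxa))
        if config.n_paired_saliva
        else None
    )
    disruptor_load_true = pd.Series(
        true_duo_loads[:, [taxa.index(t) for t in disruptors if t != "Lactobacillus"]].sum(axis=1),
        index=duo_ids,
        name="true_disruptor_load",
    )
    truth = {
        "true_total_load": pd.Series(true_totals, index=duo_ids, name="true_total_load"),
        "true_taxon_loads": pd.DataFrame(true_duo_loads, index=duo_ids, columns=taxa),
        "true_saliva_total_load": pd.Series(sal_totals, index=sal_ids, name="true_saliva_total_load"),
        "true_saliva_taxon_loads": pd.DataFrame(true_sal_loads, index=sal_ids, columns=taxa),
        "bloom_primary": bloom_primary,
        "bloom_members": bloom_members,
        "true_disruptor_load": disruptor_load_true,
        "true_severe": pd.DataFrame(true_severe, index=duo_ids, columns=list(SYMPTOM_NAMES)),
        "true_volumes": true_volumes,
        "saliva_membership": saliva_membership,
        "duodenal_membership": duodenal_membership,
        "disruptor_set": disruptors,
    }
    return CohortBundle(
        config=config,
        seed=seed,
        duodenum_counts=duodenum_table,
        saliva_counts=saliva_table,
        dpcr_records=dpcr_records,
        qpcr_records=qpcr_records,
        sample_records=sample_records,
        annotations=annotations,
        subject_map=subject_map,
        truth=truth,
    )
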