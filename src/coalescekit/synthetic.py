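"""Synthetic longitudinal two-site cohort generator with known ground truth.

The generator emulates the *structure* of an induction-chemotherapy
cohort: every patient contributes paired oral and stool 16S-style OTU
count samples from a pre-chemotherapy baseline until neutrophil recovery,
receives a prophylactic fluoroquinolone from day 0 and possibly empiric
escalation antibiotics after a neutropenic-fever day, and may experience
oral-stool community coalescence whose daily onset hazard follows a
proportional-hazards model in the accumulated antimicrobial therapy days:

    h_t = baseline_daily_hazard * exp( sum_d beta_d * cum_d(t) )

where ``cum_d(t)`` counts therapy days of drug ``d`` up to and including
day ``t - 1`` (an exposure can only affect later days).  After onset the
patient's stool target composition mixes toward the oral composition by a
fixed convex-weight increment per day.  Infection outcomes are drawn with
configurable odds ratios conditional on the true coalescence flag.

No distributional choice here is estimated from real data; the generator
is a stand-in whose purpose is to exercise the analysis code under known
truth (see the package methods note for what it does and does not mimic).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .data_io import (
    ExposureLedger,
    OtuTable,
    OutcomeTable,
    TaxonomyMap,
    write_exposures,
    write_otu_table,
    write_outcomes,
    write_taxonomy,
    write_tree,
)

__all__ = [
    "DrugPlan",
    "SimConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_patient",
    "simulate_cohort",
    "write_cohort",
    "simulate_exposure_cohort",
    "simulate_diversity_trajectories",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugPlan:
    """Schedule and effect of one antibiotic.

    ``role`` is ``prophylaxis`` (runs from day 0 until the fever day, or
    until follow-up ends if no fever occurs) or ``empiric`` (starts
    ``lag_lo``..``lag_hi`` days after the fever day with probability
    ``p_receipt`` and runs ``duration`` days, or to the end of follow-up
    when ``duration`` is None).  ``log_hazard`` is the per-therapy-day log
    hazard ratio on coalescence onset.
    """

    name: str
    log_hazard: float
    role: str = "empiric"
    p_receipt: float = 1.0
    lag_lo: int = 0
    lag_hi: int = 0
    duration: int | None = None


def _default_drugs() -> tuple:
    # Moderate generative effects: the headline fitted hazard ratios of the
    # motivating analysis are associations averaged over a cohort, not
    # per-day generative multipliers, and compounding them daily over a
    # month of therapy would drive the hazard to degenerate extremes.
    return (
        DrugPlan("levofloxacin", math.log(0.97), role="prophylaxis"),
        DrugPlan("cefepime", math.log(1.08), role="empiric", p_receipt=1.0, duration=7),
        DrugPlan("meropenem", math.log(1.12), role="empiric", p_receipt=0.4,
                 lag_lo=3, lag_hi=6, duration=None),
        DrugPlan("linezolid", math.log(1.10), role="empiric", p_receipt=0.25,
                 lag_lo=3, lag_hi=6, duration=10),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic cohort."""

    n_patients: int = 100
    n_oral_taxa: int = 40
    n_gut_taxa: int = 60
    n_shared_taxa: int = 20
    depth_mean: float = 5000.0
    sampling_interval_days: int = 3          # roughly twice-weekly sampling
    baseline_day: int = -2                   # pre-chemotherapy sample
    followup_max_days: int = 35
    recovery_lo: int = 18                    # discrete-uniform recovery window,
    recovery_hi: int = 35                    # bracketing ~3 weeks to coalescence
    dirichlet_concentration: float = 0.3
    coalescence_mix_rate: float = 0.15       # convex-weight increment per day
    coalescence_mix_max: float = 0.95
    baseline_daily_hazard: float = 0.006
    drugs: tuple = field(default_factory=_default_drugs)
    p_fever: float = 0.7
    fever_lo: int = 3
    fever_hi: int = 10
    death_prob: float = 0.02
    infection_base_rate_pre: float = 0.25
    infection_base_rate_post: float = 0.20
    infection_odds_ratio_pre: float = 4.93
    infection_odds_ratio_post: float = 2.72
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_oral_taxa", "n_gut_taxa", "n_shared_taxa"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("coalescence_mix_rate", "coalescence_mix_max", "p_fever", "death_prob",
                     "infection_base_rate_pre", "infection_base_rate_post"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.baseline_daily_hazard < 1.0:
            raise ValueError("baseline_daily_hazard must be in (0, 1)")
        if self.infection_odds_ratio_pre <= 0 or self.infection_odds_ratio_post <= 0:
            raise ValueError("infection odds ratios must be positive")
        if isinstance(self.drugs, list):
            object.__setattr__(self, "drugs", tuple(self.drugs))

    @property
    def n_taxa(self) -> int:
        return self.n_oral_taxa + self.n_gut_taxa + self.n_shared_taxa

    @property
    def drug_log_hazards(self) -> dict:
        return {d.name: d.log_hazard for d in self.drugs}

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "drugs" in raw:
            raw["drugs"] = tuple(DrugPlan(**d) for d in raw["drugs"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Per-patient generative truth emitted alongside the cohort files."""

    patient_id: str
    coalesced: bool
    onset_day: int | None
    recovery_day: int
    death_day: int | None
    fever_day: int | None
    infection_pre: bool
    infection_post90: bool

    def __post_init__(self) -> None:
        if self.coalesced != (self.onset_day is not None):
            raise ValueError("onset_day must be present iff coalesced")


# ---------------------------------------------------------------------------
# Tree and taxonomy
# ---------------------------------------------------------------------------


def simulate_tree(n_taxa: int, seed: int = 0, tip_names=None) -> TreeNode:
    """Random rooted strictly bifurcating tree with positive branch lengths.

    Built by repeated random joins (a random-topology coalescent-style
    construction); branch lengths are exponential draws, rounded to six
    decimals so the newick text round-trips exactly.
    """
    if n_taxa < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    if tip_names is None:
        tip_names = [f"OTU{i + 1:04d}" for i in range(n_taxa)]
    if len(tip_names) != n_taxa:
        raise ValueError("tip_names length must equal n_taxa")

    def draw_length() -> float:
        return round(float(rng.exponential(0.1)) + 1e-3, 6)

    nodes = [TreeNode(name=str(t), length=draw_length()) for t in tip_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=draw_length(), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


_ORAL_GENERA = {
    "Streptococcus": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae",
    "Veillonella": "Bacteria;Firmicutes;Negativicutes;Veillonellales;Veillonellaceae",
    "Neisseria": "Bacteria;Proteobacteria;Betaproteobacteria;Neisseriales;Neisseriaceae",
    "Actinomyces": "Bacteria;Actinobacteria;Actinobacteria;Actinomycetales;Actinomycetaceae",
    "Leptotrichia": "Bacteria;Fusobacteria;Fusobacteriia;Fusobacteriales;Leptotrichiaceae",
    "Oribacterium": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae",
    "Fusobacterium": "Bacteria;Fusobacteria;Fusobacteriia;Fusobacteriales;Fusobacteriaceae",
    "Rothia": "Bacteria;Actinobacteria;Actinobacteria;Micrococcales;Micrococcaceae",
    "Prevotella": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Prevotellaceae",
    "Haemophilus": "Bacteria;Proteobacteria;Gammaproteobacteria;Pasteurellales;Pasteurellaceae",
    "Stenotrophomonas": "Bacteria;Proteobacteria;Gammaproteobacteria;Xanthomonadales;Xanthomonadaceae",
    "Granulicatella": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Carnobacteriaceae",
}
_GUT_GENERA = {
    "Bacteroides": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Bacteroidaceae",
    "Blautia": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae",
    "Faecalibacterium": "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae",
    "Clostridium": "Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae",
    "Escherichia": "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae",
    "Bifidobacterium": "Bacteria;Actinobacteria;Actinobacteria;Bifidobacteriales;Bifidobacteriaceae",
    "Roseburia": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae",
    "Akkermansia": "Bacteria;Verrucomicrobia;Verrucomicrobiae;Verrucomicrobiales;Akkermansiaceae",
    "Alistipes": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Rikenellaceae",
    "Ruminococcus": "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae",
}
_SHARED_GENERA = {
    "Streptococcus": _ORAL_GENERA["Streptococcus"],
    "Enterococcus": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Enterococcaceae",
    "Lactobacillus": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae",
    "Staphylococcus": "Bacteria;Firmicutes;Bacilli;Bacillales;Staphylococcaceae",
    "Veillonella": _ORAL_GENERA["Veillonella"],
}


def _make_taxonomy(config: SimConfig):
    """OTU ids, taxonomy map and (oral_support, gut_support) index arrays."""
    otu_ids = [f"OTU{i + 1:04d}" for i in range(config.n_taxa)]
    lineages = {}
    pools = (
        (range(0, config.n_oral_taxa), list(_ORAL_GENERA.items())),
        (range(config.n_oral_taxa, config.n_oral_taxa + config.n_gut_taxa),
         list(_GUT_GENERA.items())),
        (range(config.n_oral_taxa + config.n_gut_taxa, config.n_taxa),
         list(_SHARED_GENERA.items())),
    )
    for indices, genera in pools:
        for k, i in enumerate(indices):
            genus, prefix = genera[k % len(genera)]
            lineages[otu_ids[i]] = f"{prefix};{genus}"
    oral_support = np.r_[0 : config.n_oral_taxa,
                         config.n_oral_taxa + config.n_gut_taxa : config.n_taxa]
    gut_support = np.r_[config.n_oral_taxa : config.n_taxa]
    return otu_ids, TaxonomyMap(lineages), oral_support, gut_support


# ---------------------------------------------------------------------------
# Exposure schedules and onset hazard
# ---------------------------------------------------------------------------


def _draw_schedule(config: SimConfig, rng: np.random.Generator, end_day: int):
    """(therapy-day dict, fever_day) for one patient up to ``end_day``."""
    fever_day = None
    if rng.random() < config.p_fever:
        fever_day = int(rng.integers(config.fever_lo, config.fever_hi + 1))
        if fever_day >= end_day:
            fever_day = None
    therapy = {}
    for plan in config.drugs:
        days: list = []
        if plan.role == "prophylaxis":
            stop = fever_day if fever_day is not None else end_day
            days = list(range(0, stop))
        elif fever_day is not None and rng.random() < plan.p_receipt:
            lag = int(rng.integers(plan.lag_lo, plan.lag_hi + 1))
            start = fever_day + lag
            stop = end_day if plan.duration is None else min(end_day, start + plan.duration)
            days = list(range(start, stop))
        therapy[plan.name] = [d for d in days if 0 <= d < end_day]
    return therapy, fever_day


def daily_hazards(config: SimConfig, therapy: dict, n_days: int) -> np.ndarray:
    """Onset hazard h_t for days t = 1..n_days given a therapy schedule.

    ``h_t`` applies to the interval (t-1, t] and uses the therapy days
    accumulated through day t-1 for each drug.
    """
    betas = config.drug_log_hazards
    h = np.empty(n_days)
    for t in range(1, n_days + 1):
        lp = 0.0
        for drug, days in therapy.items():
            beta = betas.get(drug)
            if beta:
                lp += beta * sum(1 for d in days if d <= t - 1)
        h[t - 1] = config.baseline_daily_hazard * math.exp(lp)
    return h


def _draw_onset(rng: np.random.Generator, hazards: np.ndarray):
    """First day t (1-based) on which the Bernoulli 1-exp(-h_t) draw fires."""
    for t, h in enumerate(hazards, start=1):
        if rng.random() < 1.0 - math.exp(-h):
            return t
    return None


def _infection_prob(base: float, odds_ratio: float, coalesced: bool) -> float:
    odds = base / (1.0 - base)
    if coalesced:
        odds *= odds_ratio
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# Patient-level simulation
# ---------------------------------------------------------------------------


@dataclass
class SampleRecord:
    sample_id: str
    patient_id: str
    site: str
    day: int
    counts: np.ndarray


def simulate_patient(config: SimConfig, patient_index: int):
    """Simulate one patient's sample series and ground truth.

    Returns ``(samples, truth, therapy)`` where ``samples`` is a list of
    :class:`SampleRecord` (both sites at every sampling day), ``truth`` a
    :class:`GroundTruth`, and ``therapy`` the drug -> therapy-day mapping.
    """
    rng = np.random.default_rng([config.seed, patient_index])
    pid = f"P{patient_index + 1:03d}"

    recovery = int(rng.integers(config.recovery_lo, config.recovery_hi + 1))
    recovery = min(recovery, config.followup_max_days)
    death_day = None
    if rng.random() < config.death_prob:
        death_day = int(rng.integers(5, recovery + 1))
    censor = recovery if death_day is None else min(recovery, death_day)

    therapy, fever_day = _draw_schedule(config, rng, censor)
    hazards = daily_hazards(config, therapy, censor)
    onset = _draw_onset(rng, hazards)
    coalesced = onset is not None

    n_oral = config.n_oral_taxa
    oral_support = np.r_[0:n_oral, n_oral + config.n_gut_taxa : config.n_taxa]
    gut_support = np.r_[n_oral : config.n_taxa]
    p_oral = np.zeros(config.n_taxa)
    p_gut = np.zeros(config.n_taxa)
    p_oral[oral_support] = rng.dirichlet(
        np.full(len(oral_support), config.dirichlet_concentration))
    p_gut[gut_support] = rng.dirichlet(
        np.full(len(gut_support), config.dirichlet_concentration))

    days = [config.baseline_day] + list(range(1, censor + 1, config.sampling_interval_days))
    samples = []
    for day in days:
        for site in ("oral", "stool"):
            if site == "oral":
                target = p_oral
            elif coalesced and day >= onset:
                w = min(config.coalescence_mix_max,
                        config.coalescence_mix_rate * (day - onset + 1))
                target = (1.0 - w) * p_gut + w * p_oral
            else:
                target = p_gut
            depth = max(1, int(rng.poisson(config.depth_mean)))
            counts = rng.multinomial(depth, target)
            samples.append(SampleRecord(
                sample_id=f"{pid}_{site}_{day}",
                patient_id=pid, site=site, day=day, counts=counts))

    infection_pre = bool(rng.random() < _infection_prob(
        config.infection_base_rate_pre, config.infection_odds_ratio_pre, coalesced))
    infection_post = bool(rng.random() < _infection_prob(
        config.infection_base_rate_post, config.infection_odds_ratio_post, coalesced))
    truth = GroundTruth(
        patient_id=pid, coalesced=coalesced, onset_day=onset,
        recovery_day=recovery, death_day=death_day, fever_day=fever_day,
        infection_pre=infection_pre, infection_post90=infection_post,
    )
    return samples, truth, therapy


# ---------------------------------------------------------------------------
# Cohort assembly and file output
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    table: OtuTable
    taxonomy: TaxonomyMap
    tree: TreeNode
    ledger: ExposureLedger
    outcomes: OutcomeTable
    truth: list


def simulate_cohort(config: SimConfig) -> Cohort:
    otu_ids, taxonomy, _, _ = _make_taxonomy(config)
    tree = simulate_tree(config.n_taxa, seed=config.seed, tip_names=otu_ids)

    all_samples, truths, exposure_rows, outcome_rows = [], [], [], []
    for i in range(config.n_patients):
        samples, truth, therapy = simulate_patient(config, i)
        all_samples.extend(samples)
        truths.append(truth)
        for drug, days in therapy.items():
            for d in days:
                exposure_rows.append({"patient_id": truth.patient_id, "drug": drug, "day": d})
        outcome_rows.append({
            "patient_id": truth.patient_id,
            "recovery_day": truth.recovery_day,
            "death_day": truth.death_day if truth.death_day is not None else np.nan,
            "infection_pre": truth.infection_pre,
            "infection_post90": truth.infection_post90,
        })

    counts = np.vstack([s.counts for s in all_samples])
    meta = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in all_samples],
            "site": [s.site for s in all_samples],
            "day": [s.day for s in all_samples],
        },
        index=[s.sample_id for s in all_samples],
    )
    table = OtuTable(counts=counts, sample_ids=[s.sample_id for s in all_samples],
                     otu_ids=otu_ids, meta=meta)
    ledger = ExposureLedger(pd.DataFrame(exposure_rows, columns=["patient_id", "drug", "day"]))
    outcomes = OutcomeTable(pd.DataFrame(outcome_rows))
    return Cohort(table, taxonomy, tree, ledger, outcomes, truths)


def write_cohort(config: SimConfig, out_dir) -> dict:
    """Simulate and write the full cohort; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    manifest = {
        "otu_table": out / "otu_table.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "tree": out / "tree.nwk",
        "samples": out / "samples.tsv",
        "exposures": out / "exposures.tsv",
        "outcomes": out / "outcomes.tsv",
        "truth": out / "truth.json",
    }
    write_otu_table(cohort.table, manifest["otu_table"])
    write_taxonomy(cohort.taxonomy, manifest["taxonomy"])
    write_tree(cohort.tree, manifest["tree"])
    meta = cohort.table.meta.copy()
    meta.insert(0, "sample_id", meta.index)
    meta.to_csv(manifest["samples"], sep="\t", index=False)
    write_exposures(cohort.ledger, manifest["exposures"])
    write_outcomes(cohort.outcomes, manifest["outcomes"])
    manifest["truth"].write_text(
        json.dumps([asdict(t) for t in cohort.truth], indent=1) + "\n")
    return {k: str(v) for k, v in manifest.items()}


# ---------------------------------------------------------------------------
# Focused generators for parameter-recovery studies
# ---------------------------------------------------------------------------


def simulate_exposure_cohort(
    n_patients: int,
    log_hr: float,
    drug: str = "drug_a",
    baseline_hazard: float = 0.01,
    p_receipt: float = 0.7,
    start_lo: int = 0,
    start_hi: int = 10,
    followup_lo: int = 25,
    followup_hi: int = 30,
    seed: int = 0,
):
    """Exposure schedules and coalescence events under a known per-day HR.

    Event times are drawn in continuous time from the piecewise-constant
    daily hazard h_t = h0 * exp(log_hr * cum(t)), where cum(t) counts
    therapy days through day t-1, so tied event times have measure zero
    and the counting-process likelihood is exactly the generative model.

    Returns ``(ledger, calls, outcomes)`` ready for
    :func:`coalescekit.survival.build_counting_process`.
    """
    rng = np.random.default_rng(seed)
    exposure_rows, call_rows, outcome_rows = [], [], []
    for i in range(n_patients):
        pid = f"S{i + 1:04d}"
        followup = int(rng.integers(followup_lo, followup_hi + 1))
        exposed = rng.random() < p_receipt
        start = int(rng.integers(start_lo, start_hi + 1)) if exposed else followup
        therapy_days = list(range(start, followup)) if exposed else []

        event_time = None
        for t in range(1, followup + 1):
            cum = sum(1 for d in therapy_days if d <= t - 1)
            h = baseline_hazard * math.exp(log_hr * cum)
            p_event = 1.0 - math.exp(-h)
            if rng.random() < p_event:
                v = rng.random()
                tau = -math.log(1.0 - v * p_event) / h
                event_time = (t - 1) + tau
                break
        coalesced = event_time is not None

        for d in therapy_days:
            if event_time is None or d < event_time:
                exposure_rows.append({"patient_id": pid, "drug": drug, "day": d})
        call_rows.append({
            "patient_id": pid,
            "coalesced": coalesced,
            "event_day": event_time if coalesced else np.nan,
            "eligible": True,
        })
        outcome_rows.append({
            "patient_id": pid, "recovery_day": followup, "death_day": np.nan,
            "infection_pre": False, "infection_post90": False,
        })
    # keep the ledger non-degenerate even if no patient was exposed
    if not exposure_rows:
        exposure_rows.append({"patient_id": "S0001", "drug": drug, "day": 0})
    ledger = ExposureLedger(pd.DataFrame(exposure_rows))
    calls = pd.DataFrame(call_rows)
    outcomes = OutcomeTable(pd.DataFrame(outcome_rows))
    return ledger, calls, outcomes


def simulate_diversity_trajectories(
    n_patients: int = 200,
    frac_coalesced: float = 0.25,
    intercept: float = 1.8,
    slope_day: float = -0.005,
    effect_coalesced: float = -0.1,
    interaction: float = -0.017,
    sd_patient: float = 0.4,
    sd_resid: float = 0.5,
    days=tuple(range(0, 29, 3)),
    seed: int = 0,
) -> pd.DataFrame:
    """Longitudinal Shannon-diversity records from a random-intercept LMM.

    shannon_ij = b0 + b_day * day_ij + b_coal * coal_i
                 + b_int * day_ij * coal_i + u_i + e_ij,
    u_i ~ N(0, sd_patient^2), e_ij ~ N(0, sd_resid^2).
    """
    rng = np.random.default_rng(seed)
    n_coal = int(round(frac_coalesced * n_patients))
    rows = []
    for i in range(n_patients):
        coal = int(i < n_coal)
        u = rng.normal(0.0, sd_patient)
        for day in days:
            mu = intercept + slope_day * day + effect_coalesced * coal + interaction * day * coal
            rows.append({
                "patient_id": f"L{i + 1:04d}",
                "day": int(day),
                "coalesced": coal,
                "shannon": mu + u + rng.normal(0.0, sd_resid),
            })
    return pd.DataFrame(rows)
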