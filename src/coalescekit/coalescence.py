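"""Oral-stool community coalescence calling and its validations.

The central statistic is, for each patient, the minimum beta-diversity
distance over *all* oral x stool sample pairs collected from that patient,
irrespective of collection day.  Patients whose minimum lies in the bottom
quartile of the cohort (rank <= floor(n_eligible / 4) when minima are
ranked ascending) are classified as exhibiting community coalescence.
Patients contributing fewer than ``min_pairs`` cross-site pairs are
ineligible and excluded from ranking.

Validation views: the ratio of shared to unique OTUs between day-matched
oral/stool pairs, and genus-level domination events (> 30% relative
abundance of a single genus in a sample) that occur concordantly at both
body sites of a patient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import OtuTable, TaxonomyMap, UNCLASSIFIED, relative_abundance
from .diversity import DistanceMatrix, beta_diversity

log = logging.getLogger(__name__)

__all__ = [
    "intra_patient_pairs",
    "pair_distances",
    "classify_coalescence",
    "shared_unique_ratio",
    "detect_dominations",
    "concordant_dominations",
    "oral_taxa_site_comparison",
]

PAIR_COLUMNS = ["patient_id", "oral_sample", "stool_sample", "oral_day", "stool_day", "distance"]


def intra_patient_pairs(table: OtuTable, d: DistanceMatrix) -> pd.DataFrame:
    """All oral x stool sample pairs within each patient, with distances.

    Patients lacking samples from one of the two sites contribute no rows
    (logged).  The distance matrix must cover every sample in the table.
    """
    missing = set(table.sample_ids) - set(d.ids)
    if missing:
        raise ValueError(f"distance matrix missing samples: {sorted(missing)}")
    rows = []
    for patient in table.patients:
        oral = table.samples_for(patient, "oral")
        stool = table.samples_for(patient, "stool")
        if oral.empty or stool.empty:
            log.warning("patient %s has no %s samples; no pairs", patient,
                        "oral" if oral.empty else "stool")
            continue
        for o_id, o_row in oral.iterrows():
            for s_id, s_row in stool.iterrows():
                rows.append(
                    {
                        "patient_id": patient,
                        "oral_sample": o_id,
                        "stool_sample": s_id,
                        "oral_day": int(o_row["day"]),
                        "stool_day": int(s_row["day"]),
                        "distance": d[o_id, s_id],
                    }
                )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def pair_distances(table: OtuTable, metric: str = "unifrac-w", tree=None) -> pd.DataFrame:
    """Intra-patient cross-site pair distances computed patient by patient.

    Equivalent to building the full cohort distance matrix and calling
    :func:`intra_patient_pairs`, but only ever materializes one patient's
    submatrix (all three supported metrics are pairwise-local).
    """
    frames = []
    for patient in table.patients:
        ids = table.samples_for(patient).index.tolist()
        sub = table.subset_samples(ids)
        sites = set(sub.meta["site"])
        if len(sites) < 2:
            log.warning("patient %s has samples from only %s; no pairs", patient, sites)
            continue
        d = beta_diversity(sub, metric, tree=tree)
        frames.append(intra_patient_pairs(sub, d))
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)


@dataclass
class CoalescenceCall:
    patient_id: str
    eligible: bool
    exclusion_reason: str | None
    n_pairs: int
    min_distance: float | None
    oral_sample: str | None
    stool_sample: str | None
    event_day: int | None
    rank: int | None
    coalesced: bool


def classify_coalescence(
    pairs: pd.DataFrame, min_pairs: int = 3, patients=None
) -> pd.DataFrame:
    """Bottom-quartile minimum-distance coalescence classification.

    Parameters
    ----------
    pairs
        Output of :func:`intra_patient_pairs` / :func:`pair_distances`.
    min_pairs
        Minimum number of cross-site pairs for a patient to be eligible
        (default 3, i.e. more than two pairs required).
    patients
        Optional full patient list so that patients with zero pairs still
        appear as ineligible rows.

    Eligible patients are ranked ascending by their minimum distance (ties
    broken by earlier event day, then patient id) and the lowest
    floor(n_eligible / 4) are called coalesced.  The event day is the later
    collection day of the minimizing pair.
    """
    all_patients = sorted(set(pairs["patient_id"]) | set(map(str, patients or [])))
    calls = []
    eligible_rows = []
    for patient in all_patients:
        sub = pairs[pairs["patient_id"] == patient]
        n = len(sub)
        if n < min_pairs:
            calls.append(
                CoalescenceCall(patient, False, f"only {n} pairs (< {min_pairs})",
                                n, None, None, None, None, None, False)
            )
            continue
        # minimizing pair; deterministic tie-break on (day, distance order)
        sub = sub.assign(event_day=sub[["oral_day", "stool_day"]].max(axis=1))
        best = sub.sort_values(["distance", "event_day", "oral_sample", "stool_sample"]).iloc[0]
        eligible_rows.append(
            CoalescenceCall(patient, True, None, n, float(best["distance"]),
                            str(best["oral_sample"]), str(best["stool_sample"]),
                            int(best["event_day"]), None, False)
        )
    n_eligible = len(eligible_rows)
    if n_eligible < 4:
        raise ValueError(f"bottom quartile undefined with {n_eligible} eligible patients (< 4)")
    eligible_rows.sort(key=lambda c: (c.min_distance, c.event_day, c.patient_id))
    n_coalesced = math.floor(n_eligible / 4)
    for rank, call in enumerate(eligible_rows, start=1):
        call.rank = rank
        call.coalesced = rank <= n_coalesced
    calls.extend(eligible_rows)
    calls.sort(key=lambda c: c.patient_id)
    return pd.DataFrame([vars(c) for c in calls])


# ---------------------------------------------------------------------------
# Shared : unique OTU ratio
# ---------------------------------------------------------------------------


def _match_pairs(oral: pd.DataFrame, stool: pd.DataFrame, window: int):
    """Greedy nearest-day matching of oral to stool samples within a window."""
    candidates = []
    for s_id, s_row in stool.iterrows():
        for o_id, o_row in oral.iterrows():
            gap = abs(int(s_row["day"]) - int(o_row["day"]))
            if gap <= window:
                candidates.append((gap, int(s_row["day"]), str(o_id), str(s_id)))
    candidates.sort()
    used_o, used_s, out = set(), set(), []
    for gap, day, o_id, s_id in candidates:
        if o_id in used_o or s_id in used_s:
            continue
        used_o.add(o_id)
        used_s.add(s_id)
        out.append((o_id, s_id, day))
    return out


def shared_unique_ratio(table: OtuTable, window: int = 3) -> pd.DataFrame:
    """Shared and unique OTU counts for day-matched oral/stool pairs.

    A pair's shared count is the size of the intersection of the two
    presence sets (count >= 1) and the unique count the size of their
    symmetric difference.  Pairs with no unique OTUs have an undefined
    ratio and are flagged (``defined=False``) so model fits can drop them.
    The pair's day is the stool collection day.
    """
    presence = table.counts > 0
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    rows = []
    for patient in table.patients:
        oral = table.samples_for(patient, "oral")
        stool = table.samples_for(patient, "stool")
        for o_id, s_id, day in _match_pairs(oral, stool, window):
            a, b = presence[idx[o_id]], presence[idx[s_id]]
            shared = int((a & b).sum())
            unique = int((a ^ b).sum())
            rows.append(
                {
                    "patient_id": patient,
                    "day": day,
                    "oral_sample": o_id,
                    "stool_sample": s_id,
                    "shared": shared,
                    "unique": unique,
                    "ratio": shared / unique if unique > 0 else np.nan,
                    "defined": unique > 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "day", "oral_sample", "stool_sample",
                 "shared", "unique", "ratio", "defined"],
    )


# ---------------------------------------------------------------------------
# Domination events
# ---------------------------------------------------------------------------


def detect_dominations(
    table: OtuTable, taxonomy: TaxonomyMap, threshold: float = 0.30
) -> pd.DataFrame:
    """Samples in which a single genus strictly exceeds the threshold.

    The ``unclassified`` bucket is not a genus and never yields an event.
    """
    genus_ra = relative_abundance(table, taxonomy, level="genus")
    rows = []
    for sample_id, props in genus_ra.iterrows():
        meta = table.meta.loc[sample_id]
        for genus, ra in props.items():
            if genus == UNCLASSIFIED:
                continue
            if ra > threshold:
                rows.append(
                    {
                        "patient_id": meta["patient_id"],
                        "sample_id": sample_id,
                        "site": meta["site"],
                        "day": int(meta["day"]),
                        "genus": genus,
                        "relative_abundance": float(ra),
                    }
                )
    return pd.DataFrame(
        rows, columns=["patient_id", "sample_id", "site", "day", "genus", "relative_abundance"]
    )


def concordant_dominations(events: pd.DataFrame) -> pd.DataFrame:
    """Genera dominating at least one oral and one stool sample per patient.

    Concordance does not require the two events to share a collection day.
    """
    rows = []
    for (patient, genus), sub in events.groupby(["patient_id", "genus"]):
        sites = set(sub["site"])
        if {"oral", "stool"} <= sites:
            rows.append({"patient_id": patient, "genus": genus,
                         "n_oral_events": int((sub["site"] == "oral").sum()),
                         "n_stool_events": int((sub["site"] == "stool").sum())})
    return pd.DataFrame(rows, columns=["patient_id", "genus", "n_oral_events", "n_stool_events"])


# ---------------------------------------------------------------------------
# Site comparison records for repeated-measures models
# ---------------------------------------------------------------------------


def oral_taxa_site_comparison(
    table: OtuTable,
    taxonomy: TaxonomyMap,
    genera,
    calls: pd.DataFrame | None = None,
    n_timepoints: int = 4,
) -> pd.DataFrame:
    """Long-format genus abundance records for site-effect testing.

    For each patient, site and genus, the first ``n_timepoints`` samples
    (ordered by day) contribute one record each.  If ``calls`` is given,
    each record is annotated with the patient's coalescence status.
    Genera absent from the taxonomy are skipped with a warning.
    """
    genus_ra = relative_abundance(table, taxonomy, level="genus")
    known = set(genus_ra.columns)
    kept = []
    for g in genera:
        if g in known:
            kept.append(g)
        else:
            log.warning("genus %r absent from taxonomy; skipped", g)
    status = None
    if calls is not None:
        status = calls.set_index("patient_id")["coalesced"].to_dict()
    rows = []
    for patient in table.patients:
        for site in ("oral", "stool"):
            meta = table.samples_for(patient, site).sort_values("day")
            for t, (sample_id, m) in enumerate(meta.iterrows(), start=1):
                if t > n_timepoints:
                    break
                for g in kept:
                    rows.append(
                        {
                            "patient_id": patient,
                            "site": site,
                            "timepoint": t,
                            "day": int(m["day"]),
                            "genus": g,
                            "relative_abundance": float(genus_ra.loc[sample_id, g]),
                            "coalesced": None if status is None else bool(status.get(patient, False)),
                        }
                    )
    return pd.DataFrame(rows)
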