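"""Core data model and plain-text I/O.

The toolkit operates on five tabular/text artifacts describing a
longitudinally sampled two-body-site (oral / stool) cohort:

``otu_table.tsv``
    Samples as rows.  First four columns ``sample_id``, ``patient_id``,
    ``site`` (``oral`` or ``stool``), ``day`` (integer days since start of
    chemotherapy; baseline samples may be negative); remaining columns are
    OTU identifiers holding non-negative integer read counts.
``taxonomy.tsv``
    Two columns, ``otu_id`` and a semicolon-delimited lineage
    (domain;phylum;class;order;family;genus).  Missing ranks are recorded
    with the explicit sentinel ``unclassified``.
``tree.nwk``
    Rooted newick tree with branch lengths whose tips are OTU ids.
``exposures.tsv``
    One row per (patient, drug, calendar day) on which the drug was
    administered.  An antimicrobial therapy day is a calendar day with any
    administration regardless of dose, route or frequency, so duplicate
    rows are collapsed (with a logged warning) on read.
``outcomes.tsv``
    One row per patient: ``recovery_day`` (day of neutrophil recovery,
    PMN > 500 cells/ul), optional ``death_day``, and boolean infection
    flags for the pre-recovery window and the 90 days after recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

log = logging.getLogger(__name__)

SITES = ("oral", "stool")
RANKS = ("domain", "phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"
META_COLS = ["patient_id", "site", "day"]


class SchemaError(ValueError):
    """A file or in-memory table violates the documented schema."""


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Sample x OTU count matrix with per-sample annotations.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per sample.
    sample_ids, otu_ids
        Unique row / column labels.
    meta
        Per-sample annotations indexed by ``sample_id`` with columns
        ``patient_id``, ``site`` and ``day``.

    Samples whose total count is zero are dropped on construction with a
    logged warning; every retained sample therefore has at least one read.
    """

    counts: np.ndarray
    sample_ids: list = field(default_factory=list)
    otu_ids: list = field(default_factory=list)
    meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise SchemaError("counts must be a 2-D samples x OTUs matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)):
                raise SchemaError("counts must be finite")
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                raise SchemaError("counts must be integers")
            counts = rounded
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise SchemaError("counts must be non-negative")
        self.counts = counts

        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise SchemaError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SchemaError("duplicate sample_ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise SchemaError("duplicate otu_ids")

        if self.meta is None:
            raise SchemaError("per-sample metadata is required")
        meta = pd.DataFrame(self.meta)
        missing = [c for c in META_COLS if c not in meta.columns]
        if missing:
            raise SchemaError(f"metadata missing columns: {missing}")
        try:
            meta = meta.loc[self.sample_ids, META_COLS].copy()
        except KeyError as exc:
            raise SchemaError(f"metadata missing samples: {exc}") from exc
        bad_site = sorted(set(meta["site"]) - set(SITES))
        if bad_site:
            raise SchemaError(f"site must be one of {SITES}, got {bad_site}")
        if meta["patient_id"].isna().any():
            raise SchemaError("every sample needs a patient_id")
        meta["patient_id"] = meta["patient_id"].astype(str)
        meta["day"] = pd.to_numeric(meta["day"], errors="raise").astype(int)
        meta.index.name = None
        self.meta = meta

        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            dropped = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            log.warning("dropping %d zero-count sample(s): %s", len(dropped), dropped)
            self._subset_in_place(totals > 0)

    def _subset_in_place(self, keep: np.ndarray) -> None:
        self.counts = self.counts[keep]
        self.sample_ids = [s for s, k in zip(self.sample_ids, keep) if k]
        self.meta = self.meta.loc[self.sample_ids]

    # -- accessors ----------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def patients(self) -> list:
        return sorted(self.meta["patient_id"].unique())

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(str(sample_id))]

    def subset_samples(self, sample_ids) -> "OtuTable":
        sample_ids = [str(s) for s in sample_ids]
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(
            counts=self.counts[idx],
            sample_ids=sample_ids,
            otu_ids=list(self.otu_ids),
            meta=self.meta.loc[sample_ids],
        )

    def samples_for(self, patient_id: str, site: str | None = None) -> pd.DataFrame:
        """Metadata rows for one patient, optionally restricted to a site."""
        m = self.meta[self.meta["patient_id"] == str(patient_id)]
        if site is not None:
            m = m[m["site"] == site]
        return m

    def to_dataframe(self) -> pd.DataFrame:
        df = self.meta.copy()
        df.insert(0, "sample_id", self.sample_ids)
        counts = pd.DataFrame(self.counts, columns=self.otu_ids)
        counts.index = df.index
        return pd.concat([df, counts], axis=1)


def read_otu_table(path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    required = ["sample_id"] + META_COLS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    otu_cols = [c for c in df.columns if c not in required]
    if not otu_cols:
        raise SchemaError(f"{path}: no OTU columns found")
    meta = df[required].set_index("sample_id")
    meta.index = meta.index.astype(str)
    return OtuTable(
        counts=df[otu_cols].to_numpy(),
        sample_ids=df["sample_id"].tolist(),
        otu_ids=otu_cols,
        meta=meta,
    )


def write_otu_table(table: OtuTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyMap:
    """otu_id -> ordered lineage (domain .. genus).

    Lineages shorter than six ranks are padded with the ``unclassified``
    sentinel so that rank lookups never fail.
    """

    lineages: dict

    def __post_init__(self) -> None:
        clean = {}
        for otu, lin in self.lineages.items():
            if isinstance(lin, str):
                lin = [p.strip() for p in lin.split(";")]
            lin = [p if p else UNCLASSIFIED for p in lin][: len(RANKS)]
            lin = list(lin) + [UNCLASSIFIED] * (len(RANKS) - len(lin))
            clean[str(otu)] = tuple(lin)
        self.lineages = clean

    def rank(self, otu_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
        lin = self.lineages.get(str(otu_id))
        if lin is None:
            return UNCLASSIFIED
        return lin[RANKS.index(rank)]

    def genus(self, otu_id: str) -> str:
        return self.rank(otu_id, "genus")

    def validate_covers(self, table: OtuTable) -> None:
        missing = [o for o in table.otu_ids if o not in self.lineages]
        if missing:
            raise SchemaError(f"taxonomy missing OTUs: {missing}")


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"otu_id", "lineage"} <= set(df.columns):
        raise SchemaError(f"{path}: expected columns otu_id, lineage")
    return TaxonomyMap(dict(zip(df["otu_id"], df["lineage"])))


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    rows = [
        {"otu_id": o, "lineage": ";".join(lin)}
        for o, lin in sorted(taxonomy.lineages.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------


def read_tree(path) -> TreeNode:
    """Read and validate a rooted newick tree with branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise SchemaError("tree tip labels are not unique")
    for node in tree.traverse(include_self=True):
        if node.is_root():
            if node.length is None:
                node.length = 0.0
        elif node.length is None:
            raise SchemaError(f"branch above {node.name or 'internal node'} has no length")
        if node.length < 0:
            raise SchemaError("negative branch length")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def validate_tree_covers(table: OtuTable, tree: TreeNode) -> None:
    """Every OTU with a nonzero count anywhere must be a tree tip."""
    tips = {t.name for t in tree.tips()}
    used = [o for o, c in zip(table.otu_ids, table.counts.sum(axis=0)) if c > 0]
    missing = sorted(set(used) - tips)
    if missing:
        raise SchemaError(f"OTUs absent from tree: {missing}")


# ---------------------------------------------------------------------------
# Exposure ledger
# ---------------------------------------------------------------------------


@dataclass
class ExposureLedger:
    """Per-patient per-drug antimicrobial therapy days.

    One row per (patient, drug, calendar day); duplicates collapse to one
    row because a therapy day counts once regardless of dose or frequency.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in ("patient_id", "drug", "day") if c not in df.columns]
        if missing:
            raise SchemaError(f"exposure records missing columns: {missing}")
        df = df[["patient_id", "drug", "day"]].copy()
        df["patient_id"] = df["patient_id"].astype(str)
        df["drug"] = df["drug"].astype(str)
        df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
        if (df["day"] < 0).any():
            bad = df[df["day"] < 0]
            raise SchemaError(f"negative exposure days:\n{bad}")
        n0 = len(df)
        df = df.drop_duplicates().sort_values(["patient_id", "drug", "day"])
        if len(df) < n0:
            log.warning("collapsed %d duplicate exposure row(s)", n0 - len(df))
        self.records = df.reset_index(drop=True)

    @property
    def drugs(self) -> list:
        return sorted(self.records["drug"].unique())

    @property
    def patients(self) -> list:
        return sorted(self.records["patient_id"].unique())

    def days(self, patient_id: str, drug: str) -> list:
        r = self.records
        sel = r[(r["patient_id"] == str(patient_id)) & (r["drug"] == drug)]
        return sorted(sel["day"].tolist())

    def patients_receiving(self, drug: str) -> set:
        r = self.records
        return set(r.loc[r["drug"] == drug, "patient_id"])


def read_exposures(path) -> ExposureLedger:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "drug": str})
    return ExposureLedger(df)


def write_exposures(ledger: ExposureLedger, path) -> None:
    ledger.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------


@dataclass
class OutcomeTable:
    """Per-patient clinical endpoints.

    ``recovery_day`` is the day of neutrophil recovery (> 0); ``death_day``
    is optional; infection flags cover the pre-recovery window and the 90
    days following recovery.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        required = ["patient_id", "recovery_day", "death_day", "infection_pre", "infection_post90"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"outcome records missing columns: {missing}")
        df = df[required].copy()
        df["patient_id"] = df["patient_id"].astype(str)
        if df["patient_id"].duplicated().any():
            raise SchemaError("duplicate patient_id in outcomes")
        df["recovery_day"] = pd.to_numeric(df["recovery_day"], errors="raise").astype(int)
        if (df["recovery_day"] <= 0).any():
            raise SchemaError("recovery_day must be > 0")
        df["death_day"] = pd.to_numeric(df["death_day"], errors="coerce")
        for c in ("infection_pre", "infection_post90"):
            df[c] = df[c].astype(float).astype(bool)
        self.records = df.set_index("patient_id")

    @property
    def patients(self) -> list:
        return sorted(self.records.index)

    def recovery_day(self, patient_id: str) -> int:
        return int(self.records.loc[str(patient_id), "recovery_day"])

    def death_day(self, patient_id: str):
        d = self.records.loc[str(patient_id), "death_day"]
        return None if pd.isna(d) else float(d)

    def censor_day(self, patient_id: str) -> float:
        """End of the at-risk period: recovery or death, whichever first."""
        rec = self.recovery_day(patient_id)
        death = self.death_day(patient_id)
        return rec if death is None else min(rec, death)


def read_outcomes(path) -> OutcomeTable:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    return OutcomeTable(df)


def write_outcomes(outcomes: OutcomeTable, path) -> None:
    outcomes.records.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Relative abundance
# ---------------------------------------------------------------------------


def relative_abundance(
    table: OtuTable, taxonomy: TaxonomyMap | None = None, level: str = "genus"
) -> pd.DataFrame:
    """Per-sample proportions aggregated at a taxonomic rank.

    With ``taxonomy=None`` the OTU level is used directly.  OTUs lacking an
    assignment at the requested rank aggregate into the explicit
    ``unclassified`` column.  Rows sum to one.
    """
    totals = table.counts.sum(axis=1)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise SchemaError(f"zero-sum sample(s): {zero}")
    props = table.counts / totals[:, None]
    df = pd.DataFrame(props, index=table.sample_ids, columns=table.otu_ids)
    if taxonomy is None:
        return df
    groups = [taxonomy.rank(o, level) for o in table.otu_ids]
    out = df.T.groupby(pd.Series(groups, index=df.columns)).sum().T
    out.columns.name = level
    return out


# ---------------------------------------------------------------------------
# Directory-level validation
# ---------------------------------------------------------------------------

COHORT_FILES = (
    "otu_table.tsv",
    "taxonomy.tsv",
    "tree.nwk",
    "exposures.tsv",
    "outcomes.tsv",
)


def read_cohort(directory):
    """Read a full cohort directory; returns (table, taxonomy, tree, ledger, outcomes)."""
    d = Path(directory)
    table = read_otu_table(d / "otu_table.tsv")
    taxonomy = read_taxonomy(d / "taxonomy.tsv")
    tree = read_tree(d / "tree.nwk")
    ledger = read_exposures(d / "exposures.tsv")
    outcomes = read_outcomes(d / "outcomes.tsv")
    taxonomy.validate_covers(table)
    validate_tree_covers(table, tree)
    return table, taxonomy, tree, ledger, outcomes
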