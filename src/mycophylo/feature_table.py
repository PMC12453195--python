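"""OTU feature tables, taxonomy, and sample metadata.

The community observation unit is an OTU x sample count matrix. Taxonomy maps
each OTU to the seven standard ranks (kingdom..species) with an explicit
``NA`` sentinel for unannotated ranks; sample metadata maps each sample to its
host species and family. All downstream beta-diversity, enrichment, and
phylosymbiosis analyses start from these three tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: sentinel for unannotated taxonomy ranks (never the empty string)
NA_RANK = "NA"

#: key under which OTUs without a genus annotation are pooled
UNCLASSIFIED = "unclassified"


class FeatureTableError(ValueError):
    """Malformed feature table, taxonomy, or metadata input."""


@dataclass
class FeatureTable:
    """OTU x sample count matrix with unique row/column labels.

    ``counts`` holds non-negative values; integers after reading from disk,
    possibly fractional after mean-rarefaction (the non-rounded variant).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate OTU ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate sample ids: {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise FeatureTableError("counts must be numeric")
        if arr.size and (arr < 0).any():
            r, s = np.argwhere(arr < 0)[0]
            raise FeatureTableError(
                f"negative count at OTU {c.index[r]!r}, sample {c.columns[s]!r}"
            )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.counts.copy())


def read_feature_table(path) -> FeatureTable:
    """Read a tab-separated OTU x sample table (first column = OTU ids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise FeatureTableError(f"duplicate sample id in header: {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = samples
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FeatureTableError(f"non-numeric cell in {path}: {exc}") from exc
    if (df.to_numpy() % 1 != 0).any():
        raise FeatureTableError(f"non-integer count in {path}")
    return FeatureTable(df.astype(np.int64))


def write_feature_table(ft: FeatureTable, path) -> None:
    out = ft.counts.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    """Read a tab-separated taxonomy table (otu_id + 7 rank columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise FeatureTableError(f"taxonomy missing rank columns: {missing}")
    df = df[list(RANKS)].fillna(NA_RANK)
    df = df.replace("", NA_RANK)
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (required: sample_id, host_species, host_family)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "host_species", "host_family"):
        if col not in df.columns:
            raise FeatureTableError(f"metadata missing column {col!r}")
    return df.set_index("sample_id")


def filter_nonfungal(ft: FeatureTable, tax: pd.DataFrame) -> FeatureTable:
    """Retain only OTUs annotated kingdom = Fungi; sample set unchanged."""
    missing = [o for o in ft.otu_ids if o not in tax.index]
    if missing:
        raise FeatureTableError(f"OTUs missing from taxonomy: {missing}")
    keep = [o for o in ft.otu_ids if tax.loc[o, "kingdom"] == "Fungi"]
    return FeatureTable(ft.counts.loc[keep])


def filter_rare(ft: FeatureTable) -> FeatureTable:
    """Drop putative contaminants and sequencing errors.

    An OTU is removed if it appears in only one sample (prevalence <= 1) or
    occurs fewer than twice across the whole dataset (total count < 2).
    """
    c = ft.counts
    prevalence = (c > 0).sum(axis=1)
    total = c.sum(axis=1)
    keep = (prevalence >= 2) & (total >= 2)
    return FeatureTable(c.loc[keep])


def rarefy_mean(
    ft: FeatureTable,
    depth: int = 2000,
    iters: int = 100,
    seed: int | None = None,
    as_float: bool = False,
) -> FeatureTable:
    """Mean-of-iterations rarefaction to a fixed read depth.

    Each retained sample is subsampled without replacement to ``depth`` reads
    ``iters`` times; per-OTU means are averaged over iterations. Samples whose
    total falls below ``depth`` are dropped with a warning. Rounded output
    rounds half to even; ``as_float=True`` returns the non-rounded means
    (preferred for beta diversity).
    """
    if depth <= 0:
        raise FeatureTableError(f"rarefaction depth must be positive, got {depth}")
    if iters <= 0:
        raise FeatureTableError(f"iters must be positive, got {iters}")
    rng = np.random.default_rng(seed)
    c = ft.counts
    totals = c.sum(axis=0)
    dropped = list(totals.index[totals < depth])
    if dropped:
        logger.warning(
            "dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped
        )
    kept = [s for s in c.columns if s not in set(dropped)]
    out = np.zeros((c.shape[0], len(kept)))
    for j, s in enumerate(kept):
        col = c[s].to_numpy().astype(np.int64)
        if col.sum() == depth:
            out[:, j] = col  # subsample equals the population
            continue
        acc = np.zeros(len(col), dtype=np.float64)
        for _ in range(iters):
            acc += rng.multivariate_hypergeometric(col, depth)
        out[:, j] = acc / iters
    df = pd.DataFrame(out, index=c.index, columns=kept)
    if not as_float:
        df = pd.DataFrame(
            np.rint(df.to_numpy()), index=df.index, columns=df.columns
        ).astype(np.int64)
    df = df.loc[df.sum(axis=1) > 0]
    return FeatureTable(df)


def relative_abundance(ft: FeatureTable) -> pd.DataFrame:
    """Column-normalized proportions; every sample total must be positive."""
    c = ft.counts
    totals = c.sum(axis=0)
    zero = list(totals.index[totals == 0])
    if zero:
        raise FeatureTableError(f"zero-total sample(s): {zero}")
    return c / totals


def collapse_genus(ft: FeatureTable, tax: pd.DataFrame) -> FeatureTable:
    """Sum OTU counts per annotated genus; unannotated pooled as 'unclassified'."""
    genera = []
    for o in ft.otu_ids:
        g = tax.loc[o, "genus"] if o in tax.index else NA_RANK
        genera.append(UNCLASSIFIED if g == NA_RANK else g)
    grouped = ft.counts.groupby(pd.Index(genera, name="genus")).sum()
    return FeatureTable(grouped)


def aggregate_by_host(ft: FeatureTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-host representative profiles: arithmetic mean over that host's samples.

    Returns an OTU x host-species DataFrame of (possibly fractional) means.
    Hosts in the metadata with no samples in the table are excluded with a
    warning.
    """
    hosts = meta.loc[[s for s in ft.sample_ids if s in meta.index], "host_species"]
    missing_meta = [s for s in ft.sample_ids if s not in meta.index]
    if missing_meta:
        raise FeatureTableError(f"samples missing from metadata: {missing_meta}")
    all_hosts = meta["host_species"].unique()
    present = hosts.unique()
    absent = sorted(set(all_hosts) - set(present))
    if absent:
        logger.warning("host species with no samples excluded: %s", absent)
    cols = {}
    for h in sorted(present):
        samples = hosts.index[hosts == h]
        cols[h] = ft.counts[list(samples)].mean(axis=1)
    return pd.DataFrame(cols, index=ft.counts.index)
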