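"""Host-unique genera and human vs NHP differential-abundance models.

Identifies genera found in exactly one host species, compares the unique
proportions with pairwise chi-squared tests, and fits per-genus two-group
linear models on log2 relative abundance (human minus each non-human
primate), with a joint Benjamini-Hochberg correction across every
(genus, NHP) record. Genera significant against at least six of the seven
NHP species form the human signature set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_table import UNCLASSIFIED, FeatureTable

logger = logging.getLogger(__name__)


def genus_presence_by_host(
    genus_table: FeatureTable | pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Genus x host presence: >= 1 count in >= 1 sample of that host."""
    df = genus_table.counts if isinstance(genus_table, FeatureTable) else genus_table
    hosts = meta.loc[list(df.columns), "host_species"]
    out = {}
    for h in sorted(hosts.unique()):
        samples = hosts.index[hosts == h]
        out[h] = (df[list(samples)] > 0).any(axis=1)
    return pd.DataFrame(out)


def unique_genus_sets(
    presence: pd.DataFrame,
) -> tuple[dict[str, set[str]], dict[str, float], int]:
    """Per-host genera absent from every other host, plus proportions.

    The pooled 'unclassified' row is excluded from genus-level statistics.
    Returns (unique sets, proportion of total annotated genera, total).
    """
    pres = presence.drop(index=[UNCLASSIFIED], errors="ignore")
    pres = pres.loc[pres.any(axis=1)]
    total = len(pres)
    n_hosts_with = pres.sum(axis=1)
    uniq: dict[str, set[str]] = {}
    prop: dict[str, float] = {}
    for h in pres.columns:
        mine = set(pres.index[pres[h] & (n_hosts_with == 1)])
        uniq[h] = mine
        prop[h] = len(mine) / total if total else 0.0
    return uniq, prop, total


def pairwise_chisq_unique(
    unique_counts: dict[str, tuple[int, int]]
) -> pd.DataFrame:
    """2x2 chi-squared per host pair on (unique, non-unique) genus counts.

    ``unique_counts`` maps host -> (n_unique, n_total). Continuity-corrected;
    a warning is logged when an expected cell is below 1.
    """
    hosts = sorted(unique_counts)
    rows = []
    for i, a in enumerate(hosts):
        for b in hosts[i + 1:]:
            ua, ta = unique_counts[a]
            ub, tb = unique_counts[b]
            table = np.array([[ua, ta - ua], [ub, tb - ub]], dtype=float)
            if (table.sum(axis=1).reshape(-1, 1)
                    * table.sum(axis=0) / table.sum() < 1).any():
                logger.warning("expected cell < 1 for pair (%s, %s)", a, b)
            if ua == ub and ta == tb:
                chi2, p = 0.0, 1.0
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
            rows.append({"host_a": a, "host_b": b, "chi2": chi2, "p_value": p})
    return pd.DataFrame(rows)


def log2_lfc_scan(
    rel_abund: pd.DataFrame,
    meta: pd.DataFrame,
    ref_host: str = "Homo_sapiens",
    prevalence_min: float = 0.20,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-genus log2 linear models of humans vs each NHP species.

    For each (genus, NHP) pair where the genus is present in at least
    ``prevalence_min`` of the samples of BOTH hosts, fits the two-group model
    on log2(proportion + pseudocount); the coefficient is the log2 fold
    change (positive = higher in humans). The pseudocount defaults to half
    the smallest nonzero proportion in the table. BH-FDR is applied jointly
    across all records.
    """
    df = rel_abund.drop(index=[UNCLASSIFIED], errors="ignore")
    hosts = meta.loc[list(df.columns), "host_species"]
    if ref_host not in set(hosts):
        raise ValueError(f"reference host {ref_host!r} has no samples")
    nhps = [h for h in sorted(hosts.unique()) if h != ref_host]
    if not nhps:
        raise ValueError("no non-reference hosts present")
    nonzero = df.to_numpy()[df.to_numpy() > 0]
    if pseudocount is None:
        pseudocount = float(nonzero.min()) / 2 if nonzero.size else 1e-6
    logt = np.log2(df + pseudocount)
    ref_samples = list(hosts.index[hosts == ref_host])
    rows = []
    for nhp in nhps:
        nhp_samples = list(hosts.index[hosts == nhp])
        prev_ref = (df[ref_samples] > 0).mean(axis=1)
        prev_nhp = (df[nhp_samples] > 0).mean(axis=1)
        ok = (prev_ref >= prevalence_min) & (prev_nhp >= prevalence_min)
        for genus in df.index[ok]:
            a = logt.loc[genus, ref_samples].to_numpy()
            b = logt.loc[genus, nhp_samples].to_numpy()
            lfc = float(a.mean() - b.mean())
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                p = 1.0 if lfc == 0 else 0.0
            else:
                _, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append({"genus": genus, "nhp_species": nhp,
                         "log2_fold_change": lfc, "p_value": float(p)})
    if not rows:
        logger.warning("no genus passed the prevalence filter")
        return pd.DataFrame(
            columns=["genus", "nhp_species", "log2_fold_change",
                     "p_value", "q_value"]
        )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def human_signature(
    results: pd.DataFrame, min_nhp: int = 6, alpha: float = 0.05
) -> list[str]:
    """Genera with Q < alpha against at least ``min_nhp`` NHP species."""
    if len(results) == 0:
        return []
    sig = results[results["q_value"] < alpha]
    counts = sig.groupby("genus")["nhp_species"].nunique()
    return sorted(counts.index[counts >= min_nhp])
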