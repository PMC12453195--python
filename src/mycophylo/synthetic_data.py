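"""Synthetic study-design generator.

Emulates the structure of a cross-sectional primate gut mycobiome survey:
eight host species (four hominids, three cercopithecoids, one strepsirrhine
outgroup), tens of samples per host, sparse zero-inflated OTU counts with a
tunable phylosymbiosis signal, and aligned ITS2-like fungal sequence sets
ranging from perfect cospeciation along the host tree to fully
host-independent transmission. Every generator is deterministic given
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .cophylogeny import HOMINIDS, Alignment
from .feature_table import NA_RANK, RANKS, FeatureTable

SPECIES = (
    "Homo_sapiens",
    "Pan_troglodytes",
    "Gorilla_gorilla",
    "Gorilla_beringei",
    "Cercocebus_agilis",
    "Papio_cynocephalus",
    "Piliocolobus_gordonorum",
    "Indri_indri",
)

HOST_FAMILY = {
    "Homo_sapiens": "Hominidae",
    "Pan_troglodytes": "Hominidae",
    "Gorilla_gorilla": "Hominidae",
    "Gorilla_beringei": "Hominidae",
    "Cercocebus_agilis": "Cercopithecidae",
    "Papio_cynocephalus": "Cercopithecidae",
    "Piliocolobus_gordonorum": "Cercopithecidae",
    "Indri_indri": "Indriidae",
}

# Ultrametric fixture; branch lengths in Ma. Hominid split depths anchor the
# clock analyses: Homo-Pan 6, Homo/Pan-Gorilla 8.15 (midpoint of 7.1-9.2),
# G. gorilla-G. beringei 1.3 (midpoint of 0.15-2.5). Deeper nodes are
# conventional defaults (catarrhine 29, papionin 11, colobine 18, root 74).
HOMINID_FIXTURE_NEWICK = (
    "((((Homo_sapiens:6,Pan_troglodytes:6):2.15,"
    "(Gorilla_gorilla:1.3,Gorilla_beringei:1.3):6.85):20.85,"
    "((Cercocebus_agilis:11,Papio_cynocephalus:11):7,"
    "Piliocolobus_gordonorum:18):11):45,Indri_indri:74);"
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def hominid_tree_fixture() -> TreeNode:
    """Rooted ultrametric 8-species host tree (branch lengths in Ma)."""
    return TreeNode.read([HOMINID_FIXTURE_NEWICK], convert_underscores=False)


@dataclass
class SimulationConfig:
    """All generator knobs; serializable alongside outputs.

    Defaults emulate the study design: 8 host species, 20 samples each,
    300 OTUs with ~47% unannotated at genus level, lognormal sequencing
    depths around 10k reads, moderate zero inflation.
    """

    seed: int = 0
    n_samples_per_host: int = 20
    n_otus: int = 300
    n_genera: int = 60
    frac_unclassified: float = 0.47
    phylosymbiosis_signal: float = 0.5      # s in [0, 1]
    bm_rate: float = 0.3                    # BM sd per sqrt(Ma), log scale
    individual_sd: float = 1.0              # per-sample log-noise sd
    presence_prob: float = 0.8              # per (OTU, host) retention
    depth_log_mean: float = 9.2             # lognormal depth ~ e^9.2 ~ 10k
    depth_log_sd: float = 0.4
    enriched_genera: int = 0                # planted human-enriched genera
    enriched_fold: float = 4.0
    # sequence generator
    sequence_length: int = 300              # L (aligned sites)
    substitution_rate: float = 0.002        # r, subs/site/Ma
    host_independence: float = 0.0          # pi: P(tip reassigned to random host)
    within_host_divergence: float = 0.5     # eps, Ma of extra tip divergence
    n_seqs_per_host: int = 2
    otu_divergence: float = 0.05            # subs/site, genus ancestor -> OTU root
    host_tree_newick: str = HOMINID_FIXTURE_NEWICK

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("phylosymbiosis_signal", 0.0, 1.0),
            ("host_independence", 0.0, 1.0),
            ("presence_prob", 0.0, 1.0),
            ("frac_unclassified", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.sequence_length < 100:
            raise ValueError("sequence_length must be >= 100")
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def host_tree(self) -> TreeNode:
        return TreeNode.read([self.host_tree_newick], convert_underscores=False)


def _node_depths(tree: TreeNode) -> dict[str, float]:
    depths = {}
    for tip in tree.tips():
        depths[tip.name] = tip.accumulate_to_ancestor(tree)
    return depths


def _brownian_host_values(
    tree: TreeNode, rng: np.random.Generator, n_otus: int, scale: float
) -> pd.DataFrame:
    """Per-OTU host values from Brownian motion on the host tree.

    Increment variance on a branch is scale^2 x branch length; scale = 0
    yields identical (exchangeable) host values.
    """
    tips = [t.name for t in tree.tips()]
    vals: dict[int, np.ndarray] = {}
    out = {}
    for node in tree.preorder(include_self=True):
        if node.parent is None:
            vals[id(node)] = np.zeros(n_otus)
        else:
            bl = node.length or 0.0
            step = rng.normal(0.0, scale * np.sqrt(bl), size=n_otus)
            vals[id(node)] = vals[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = vals[id(node)]
    return pd.DataFrame(out, columns=tips)


def simulate_communities(
    cfg: SimulationConfig,
) -> tuple[FeatureTable, pd.DataFrame, pd.DataFrame]:
    """Sparse multinomial count table with a tunable phylosymbiosis signal.

    Per-OTU log-abundance profiles evolve on the host tree by Brownian motion
    with standard deviation sqrt(s) x bm_rate per sqrt(Ma); samples add
    individual-level Gaussian noise on the log scale; counts are multinomial
    at a lognormal per-sample depth; per-(OTU, host) Bernoulli thinning
    induces zero inflation. Optionally plants human-enriched genera at a
    stated fold change. Returns (table, metadata, taxonomy).
    """
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.host_tree()
    hosts = [t.name for t in tree.tips()]

    # taxonomy: OTUs assigned to genera, a fraction left unannotated
    otu_ids = [f"OTU{i + 1}" for i in range(cfg.n_otus)]
    genera_pool = [f"Genus{i + 1}" for i in range(cfg.n_genera)]
    genus_of = {}
    for o in otu_ids:
        if rng.random() < cfg.frac_unclassified:
            genus_of[o] = NA_RANK
        else:
            genus_of[o] = genera_pool[int(rng.integers(cfg.n_genera))]
    tax = pd.DataFrame(
        {r: [NA_RANK] * cfg.n_otus for r in RANKS}, index=pd.Index(otu_ids)
    )
    tax["kingdom"] = "Fungi"
    tax["genus"] = [genus_of[o] for o in otu_ids]

    base = rng.normal(0.0, 1.0, size=cfg.n_otus)
    s = cfg.phylosymbiosis_signal
    bm = _brownian_host_values(tree, rng, cfg.n_otus,
                               np.sqrt(s) * cfg.bm_rate)
    host_log = pd.DataFrame(
        {h: base + bm[h].to_numpy() for h in hosts}, index=pd.Index(otu_ids)
    )

    # planted human enrichment at the genus level
    enriched: list[str] = []
    if cfg.enriched_genera > 0:
        annotated = sorted({g for g in genus_of.values() if g != NA_RANK})
        enriched = list(rng.choice(annotated,
                                   size=min(cfg.enriched_genera, len(annotated)),
                                   replace=False))
        shift = np.log(cfg.enriched_fold)
        mask = np.array([genus_of[o] in set(enriched) for o in otu_ids])
        host_log.loc[mask, "Homo_sapiens"] += shift

    present = rng.random((cfg.n_otus, len(hosts))) < cfg.presence_prob
    # keep planted genera present in every host so they survive prevalence
    if enriched:
        mask = np.array([genus_of[o] in set(enriched) for o in otu_ids])
        present[mask, :] = True

    counts = {}
    meta_rows = []
    for hi, h in enumerate(hosts):
        for k in range(cfg.n_samples_per_host):
            sid = f"{h}_s{k + 1}"
            logab = (host_log[h].to_numpy()
                     + rng.normal(0.0, cfg.individual_sd, size=cfg.n_otus))
            w = np.exp(logab) * present[:, hi]
            if w.sum() == 0:
                w = present[:, hi].astype(float)
            p = w / w.sum()
            depth = int(np.exp(rng.normal(cfg.depth_log_mean, cfg.depth_log_sd)))
            counts[sid] = rng.multinomial(depth, p)
            meta_rows.append({"sample_id": sid, "host_species": h,
                              "host_family": HOST_FAMILY.get(h, "NA"),
                              "study_id": "synthetic"})
    ft = FeatureTable(pd.DataFrame(counts, index=pd.Index(otu_ids)))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    tax.attrs["enriched_genera"] = sorted(enriched)
    return ft, meta, tax


def _evolve_jc(seq: np.ndarray, t_subs: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a base-index sequence for branch length t (subs/site) under JC."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t_subs / 3.0))
    hit = rng.random(seq.size) < p_change
    out = seq.copy()
    if hit.any():
        # jump to one of the three other bases
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate_cospeciating_sequences(
    cfg: SimulationConfig,
    n_otus: int = 10,
    hosts: tuple[str, ...] = HOMINIDS,
    genus: str = "GenusSim",
) -> dict[str, Alignment]:
    """Per-OTU aligned sequence sets evolved along the host tree.

    Sequences evolve under Jukes-Cantor with rate r along the (sheared) host
    tree; each host contributes ``n_seqs_per_host`` tips that diverge from the
    host lineage for an extra ``within_host_divergence`` Ma; with probability
    pi each tip is finally reassigned to a random host (host-independent
    transmission). pi = 0 gives perfect codivergence; pi = 1 erases all host
    signal.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.host_tree().shear(list(hosts))
    r = cfg.substitution_rate
    L = cfg.sequence_length
    # OTUs of one genus descend from a shared ancestor so genus-level trees
    # (and 97%/99% clustering) remain well defined
    genus_root = rng.integers(0, 4, size=L).astype(np.uint8)
    out: dict[str, Alignment] = {}
    for k in range(n_otus):
        otu_root = _evolve_jc(genus_root, cfg.otu_divergence, rng)
        node_seq: dict[int, np.ndarray] = {}
        tip_seqs: dict[str, np.ndarray] = {}
        for node in tree.preorder(include_self=True):
            if node.parent is None:
                node_seq[id(node)] = otu_root
            else:
                t = (node.length or 0.0) * r
                node_seq[id(node)] = _evolve_jc(node_seq[id(node.parent)], t, rng)
            if node.is_tip():
                tip_seqs[node.name] = node_seq[id(node)]
        ids, seqs, assigned = [], [], []
        for h in hosts:
            for j in range(cfg.n_seqs_per_host):
                s = _evolve_jc(tip_seqs[h], cfg.within_host_divergence * r, rng)
                host = h
                if rng.random() < cfg.host_independence:
                    host = hosts[int(rng.integers(len(hosts)))]
                ids.append(f"otu{k + 1}_{h}_{j + 1}")
                seqs.append("".join(chr(_BASES[b]) for b in s))
                assigned.append(host)
        otu_id = f"otu{k + 1}"
        out[otu_id] = Alignment(ids, seqs, assigned, genus,
                                [otu_id] * len(ids))
    return out


def shuffle_tips(tree: TreeNode, seed: int | None = None) -> TreeNode:
    """Uniform random permutation of tip labels; topology and lengths kept."""
    rng = np.random.default_rng(seed)
    out = tree.copy()
    tips = list(out.tips())
    if len(tips) < 2:
        return out
    names = [t.name for t in tips]
    perm = rng.permutation(len(names))
    for tip, i in zip(tips, perm):
        tip.name = names[i]
    return out
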