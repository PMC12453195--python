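"""Genus-scan cophylogeny framework.

For every fungal genus detected in all four hominids (excluding *Aspergillus*,
*Fusarium*, and *Penicillium*, whose ITS sequences do not resolve below the
genus), representative sequences are dereplicated, a neighbor-joining tree is
built from Jukes-Cantor distances, and OTU-level subtrees spanning all four
hominid hosts are tested for congruence with the host phylogeny using both
PACo (Procrustes superimposition of principal-coordinate embeddings, quasiswap
null) and ParaFit (fourth-corner statistic, per-tip host shuffles). An OTU is
called cophylogenetic only when both tests pass Benjamini-Hochberg FDR at
Q < 0.05; a tip-shuffle experiment estimates the procedure's false-positive
rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

HOMINIDS = ("Homo_sapiens", "Pan_troglodytes", "Gorilla_gorilla",
            "Gorilla_beringei")

#: genera whose ITS sequences cannot be distinguished below genus level
GENUS_BLACKLIST = frozenset({"Aspergillus", "Fusarium", "Penicillium"})

_VALID = set(b"ACGT")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Equal-length aligned sequences with per-sequence provenance labels."""

    ids: list[str]
    seqs: list[str]
    hosts: list[str]
    genus: str = ""
    otus: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.seqs) < 2:
            raise ValueError("alignment needs >= 2 sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        bad = set("".join(self.seqs).upper()) - set("ACGT-N")
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(bad)}")
        if not self.otus:
            self.otus = [""] * len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def subset(self, indices) -> "Alignment":
        return Alignment(
            [self.ids[i] for i in indices],
            [self.seqs[i] for i in indices],
            [self.hosts[i] for i in indices],
            self.genus,
            [self.otus[i] for i in indices],
        )

    def matrix(self) -> np.ndarray:
        return np.frombuffer(
            "".join(s.upper() for s in self.seqs).encode(), dtype=np.uint8
        ).reshape(len(self.seqs), self.length)


def read_alignment_fasta(path) -> list[Alignment]:
    """Read aligned FASTA with ``>id|host=SP|genus=NAME[|otu=ID]`` headers.

    Returns one Alignment per genus found in the file.
    """
    from Bio import SeqIO

    by_genus: dict[str, list[tuple[str, str, str, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        meta = {}
        for f in fields[1:]:
            if "=" in f:
                k, v = f.split("=", 1)
                meta[k] = v
        genus = meta.get("genus", "")
        by_genus.setdefault(genus, []).append(
            (fields[0], str(rec.seq), meta.get("host", ""), meta.get("otu", ""))
        )
    out = []
    for genus, rows in by_genus.items():
        out.append(Alignment([r[0] for r in rows], [r[1] for r in rows],
                             [r[2] for r in rows], genus,
                             [r[3] for r in rows]))
    return out


def write_alignment_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for i, (sid, seq, host) in enumerate(zip(aln.ids, aln.seqs, aln.hosts)):
            otu = f"|otu={aln.otus[i]}" if aln.otus[i] else ""
            fh.write(f">{sid}|host={host}|genus={aln.genus}{otu}\n{seq}\n")


# ---------------------------------------------------------------------------
# sequence distances and trees
# ---------------------------------------------------------------------------

def p_distance(aln: Alignment) -> DistanceMatrix:
    """Proportion of differing sites over positions comparable in both rows.

    Gap and N positions are excluded pairwise; a pair with zero comparable
    sites is an error.
    """
    m = aln.matrix()
    valid = np.isin(m, list(_VALID))
    n = len(aln)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            denom = int(comp.sum())
            if denom == 0:
                raise ValueError(
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            out[i, j] = out[j, i] = (m[i, comp] != m[j, comp]).sum() / denom
    return DistanceMatrix(out, ids=aln.ids)


def jc_distance(aln: Alignment) -> DistanceMatrix:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) from p-distances."""
    pd_ = p_distance(aln)
    p = pd_.data
    if (p >= 0.75).any():
        i, j = np.argwhere(p >= 0.75)[0]
        raise ValueError(
            f"saturated pair (p >= 0.75): {pd_.ids[i]!r} vs {pd_.ids[j]!r}"
        )
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=pd_.ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to zero."""
    if np.isnan(dm.data).any():
        raise ValueError("distance matrix contains NaN")
    tree = _skbio_nj(dm)
    clamped = 0
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.warning("clamped %d negative NJ branch length(s) to 0", clamped)
    return tree


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Sum of branch lengths along the path between each leaf pair."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"missing branch length at {node.name!r}")
    return tree.tip_tip_distances()


# ---------------------------------------------------------------------------
# dereplication and OTU clustering
# ---------------------------------------------------------------------------

def dereplicate(aln: Alignment) -> Alignment:
    """Merge exact-duplicate sequences, keeping all host origins.

    The surviving record keeps the first id; merged provenance is stored on
    ``provenance`` as a list of (id, host) tuples per survivor.
    """
    seen: dict[str, int] = {}
    keep: list[int] = []
    provenance: list[list[tuple[str, str]]] = []
    for i, s in enumerate(aln.seqs):
        if s in seen:
            provenance[seen[s]].append((aln.ids[i], aln.hosts[i]))
        else:
            seen[s] = len(keep)
            keep.append(i)
            provenance.append([(aln.ids[i], aln.hosts[i])])
    out = aln.subset(keep)
    out.provenance = provenance  # type: ignore[attr-defined]
    return out


def cluster_otus(aln: Alignment, identity: float = 0.97) -> list[str]:
    """Greedy centroid OTU clustering at the given identity threshold.

    Sequences are visited in order of decreasing abundance (provenance count
    when present, else input order); each joins the first centroid with
    identity (1 - p-distance) >= threshold, otherwise founds a new OTU.
    Returns the OTU id per sequence.
    """
    if not 0 < identity <= 1:
        raise ValueError(f"identity must be in (0, 1], got {identity}")
    pdm = p_distance(aln)
    weights = [len(p) for p in getattr(aln, "provenance", [[0]] * len(aln))]
    order = sorted(range(len(aln)), key=lambda i: (-weights[i], i))
    centroids: list[int] = []
    assign = [""] * len(aln)
    for i in order:
        for k, c in enumerate(centroids):
            if 1.0 - pdm.data[i, c] >= identity:
                assign[i] = f"otu{k + 1}"
                break
        else:
            centroids.append(i)
            assign[i] = f"otu{len(centroids)}"
    return assign


# ---------------------------------------------------------------------------
# genus scan
# ---------------------------------------------------------------------------

@dataclass
class EligibleOTU:
    genus: str
    otu_id: str
    alignment: Alignment
    tree: TreeNode            # induced subtree on the OTU's tips


def genus_scan(
    alignments: list[Alignment],
    hominids: tuple[str, ...] = HOMINIDS,
    identity: float = 0.97,
    min_tips: int = 3,
) -> list[EligibleOTU]:
    """Scan genera for OTU subtrees eligible for cophylogeny testing.

    Keeps genera detected in all four hominids (minus the blacklist), builds
    the genus NJ tree from JC distances after dereplication, clusters OTUs at
    the identity threshold (unless OTU labels are provided on input), and
    retains OTUs whose tips span all four hominid species.
    """
    out: list[EligibleOTU] = []
    for aln in alignments:
        if aln.genus in GENUS_BLACKLIST:
            logger.info("genus %s excluded (ITS unresolvable)", aln.genus)
            continue
        if not set(hominids) <= set(aln.hosts):
            continue
        derep = dereplicate(aln)
        if len(derep) < min_tips:
            logger.info("genus %s skipped: %d tips < %d", aln.genus,
                        len(derep), min_tips)
            continue
        tree = neighbor_joining(jc_distance(derep))
        if any(o == "" for o in derep.otus):
            derep.otus = cluster_otus(derep, identity=identity)
        hosts_of = {derep.ids[i]: _hosts_of(derep, i) for i in range(len(derep))}
        for otu in sorted(set(derep.otus)):
            idx = [i for i, o in enumerate(derep.otus) if o == otu]
            otu_hosts = set().union(*(hosts_of[derep.ids[i]] for i in idx))
            if not set(hominids) <= otu_hosts:
                continue
            if len(idx) < min_tips:
                logger.info("OTU %s/%s skipped: %d tips", aln.genus, otu, len(idx))
                continue
            sub = derep.subset(idx)
            sub.provenance = [getattr(derep, "provenance",
                                      [[(derep.ids[i], derep.hosts[i])]
                                       for i in range(len(derep))])[i]
                              for i in idx]
            subtree = tree.shear([derep.ids[i] for i in idx])
            out.append(EligibleOTU(aln.genus, otu, sub, subtree))
    return out


def _hosts_of(aln: Alignment, i: int) -> set[str]:
    prov = getattr(aln, "provenance", None)
    if prov is None:
        return {aln.hosts[i]}
    return {h for _, h in prov[i]}


def association_matrix(otu: EligibleOTU,
                       hosts: tuple[str, ...] = HOMINIDS) -> pd.DataFrame:
    """Binary host x tip incidence for one eligible OTU."""
    tips = [t.name for t in otu.tree.tips()]
    idx_of = {sid: i for i, sid in enumerate(otu.alignment.ids)}
    a = pd.DataFrame(0, index=list(hosts), columns=tips, dtype=np.int8)
    for tip in tips:
        for h in _hosts_of(otu.alignment, idx_of[tip]):
            if h in a.index:
                a.loc[h, tip] = 1
    if (a.sum(axis=0) == 0).any():
        empty = list(a.columns[a.sum(axis=0) == 0])
        raise ValueError(f"tips with no host link: {empty}")
    return a


# ---------------------------------------------------------------------------
# Cailliez-corrected principal coordinates
# ---------------------------------------------------------------------------

def _gower_center(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def cailliez_constant(d: np.ndarray, tol: float = 1e-8) -> float:
    """Smallest additive constant making a dissimilarity matrix Euclidean.

    Largest real eigenvalue of the 2n x 2n block matrix
    [[0, 2*D1], [-I, -4*D2]] with D1 = center(-0.5 D^2), D2 = center(-0.5 D).
    Returns 0 when the matrix is already Euclidean.
    """
    n = d.shape[0]
    d1 = _gower_center(-0.5 * d**2)
    evals = np.linalg.eigvalsh(d1)
    if evals.min() > -tol:
        return 0.0
    d2 = _gower_center(-0.5 * d)
    block = np.block([
        [np.zeros((n, n)), 2.0 * d1],
        [-np.eye(n), -4.0 * d2],
    ])
    ev = np.linalg.eigvals(block)
    real = ev.real[np.abs(ev.imag) < 1e-8]
    return float(real.max())


def pcoa_cailliez(dm: DistanceMatrix, tol: float = 1e-8) -> pd.DataFrame:
    """Principal coordinates with the Cailliez negative-eigenvalue correction.

    If the Gower-centered matrix has negative eigenvalues, the Cailliez
    constant is added to all off-diagonal dissimilarities and the embedding is
    recomputed; pairwise embedding distances then reproduce the corrected
    dissimilarities. Returns a samples x axes coordinate frame.
    """
    d = dm.data.copy()
    c = cailliez_constant(d, tol=tol)
    if c > tol:
        d = d + c
        np.fill_diagonal(d, 0.0)
        logger.info("Cailliez constant %.6g applied", c)
    g = _gower_center(-0.5 * d**2)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(tol, tol * abs(evals).max())
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    return pd.DataFrame(coords, index=list(dm.ids),
                        columns=[f"PC{i+1}" for i in range(int(keep.sum()))])


# ---------------------------------------------------------------------------
# quasiswap null
# ---------------------------------------------------------------------------

def quasiswap_null(
    assoc: pd.DataFrame | np.ndarray,
    seed: int | None = None,
    n_trials: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Margin-preserving randomization of a binary matrix.

    Runs a chain of 2x2 checkerboard swaps (each preserving row and column
    sums) starting from the observed matrix; the number of attempted swaps
    defaults to 100 x (number of ones). Degenerate margins that admit a
    single matrix return the input with a warning.
    """
    frame = isinstance(assoc, pd.DataFrame)
    a = (assoc.to_numpy() if frame else np.asarray(assoc)).astype(np.int8).copy()
    if not np.isin(a, (0, 1)).all():
        raise ValueError("association matrix must be binary")
    if rng is None:
        rng = np.random.default_rng(seed)
    nr, nc = a.shape
    ones = int(a.sum())
    trials = n_trials if n_trials is not None else 100 * max(ones, 1)
    if nr < 2 or nc < 2:
        logger.warning("degenerate margins: matrix returned unchanged")
        return assoc.copy() if frame else a
    r1 = rng.integers(0, nr, size=trials)
    r2 = rng.integers(0, nr, size=trials)
    c1 = rng.integers(0, nc, size=trials)
    c2 = rng.integers(0, nc, size=trials)
    swapped = 0
    for i in range(trials):
        ra, rb, ca, cb = r1[i], r2[i], c1[i], c2[i]
        if ra == rb or ca == cb:
            continue
        x, y, z, w = a[ra, ca], a[ra, cb], a[rb, ca], a[rb, cb]
        if x == w and y == z and x != y:
            a[ra, ca] = y
            a[ra, cb] = x
            a[rb, ca] = w
            a[rb, cb] = z
            swapped += 1
    if swapped == 0:
        logger.warning("no checkerboard swaps possible; margins may force "
                       "a unique matrix")
    if frame:
        return pd.DataFrame(a, index=assoc.index, columns=assoc.columns)
    return a


# ---------------------------------------------------------------------------
# PACo and ParaFit
# ---------------------------------------------------------------------------

def _procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    """Residual SS of least-squares superimposition of y onto x.

    Both configurations are centered and scaled to unit total sum of squares,
    so m2 = 1 - (sum of singular values of x'y)^2 lies in [0, 1].
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    nx = np.sqrt((xc**2).sum())
    ny = np.sqrt((yc**2).sum())
    if nx == 0 or ny == 0:
        raise ValueError("degenerate configuration (zero spread)")
    xc /= nx
    yc /= ny
    s = np.linalg.svd(xc.T @ yc, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def _pad_columns(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = max(x.shape[1], y.shape[1])
    if x.shape[1] < d:
        x = np.hstack([x, np.zeros((x.shape[0], d - x.shape[1]))])
    if y.shape[1] < d:
        y = np.hstack([y, np.zeros((y.shape[0], d - y.shape[1]))])
    return x, y


@dataclass
class PacoResult:
    m2: float
    R2: float
    p_value: float
    nperm: int


def _paco_from_coords(
    hcoords: np.ndarray,
    fcoords: np.ndarray,
    assoc: np.ndarray,
    nperm: int,
    null: str,
    rng: np.random.Generator,
) -> PacoResult:
    def m2_of(a: np.ndarray) -> float:
        hi, fi = np.nonzero(a)
        x, y = _pad_columns(hcoords[hi], fcoords[fi])
        return _procrustes_m2(x, y)

    m2_obs = m2_of(assoc)
    hits = 0
    for _ in range(nperm):
        if null == "quasiswap":
            a = quasiswap_null(assoc, rng=rng)
        elif null == "free":
            a = assoc.copy()
            for j in range(a.shape[1]):
                a[:, j] = rng.permutation(a[:, j])
        else:
            raise ValueError(f"unknown null {null!r}")
        if m2_of(a) <= m2_obs:
            hits += 1
    p = (1 + hits) / (1 + nperm)
    return PacoResult(m2_obs, 1.0 - m2_obs, p, nperm)


def paco(
    host_dm: DistanceMatrix,
    fungal_dm: DistanceMatrix,
    assoc: pd.DataFrame,
    nperm: int = 99,
    null: str = "quasiswap",
    seed: int | None = None,
) -> PacoResult:
    """Procrustean approach to cophylogeny.

    Host and symbiont distance matrices are embedded with Cailliez-corrected
    PCoA; coordinate rows are replicated once per host-tip link, both
    configurations are scaled to unit sum of squares, and m2 is the residual
    SS of the optimal Procrustes superimposition (R2 = 1 - m2). Significance
    uses margin-preserving quasiswap null association matrices;
    p = (1 + #{m2_null <= m2_obs}) / (1 + nperm).
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    a = assoc.loc[list(host_dm.ids), list(fungal_dm.ids)].to_numpy()
    if (a.sum(axis=0) == 0).any():
        raise ValueError("association column with no links")
    rng = np.random.default_rng(seed)
    h = pcoa_cailliez(host_dm).to_numpy()
    f = pcoa_cailliez(fungal_dm).to_numpy()
    return _paco_from_coords(h, f, a, nperm, null, rng)


@dataclass
class ParafitResult:
    stat: float
    p_value: float
    nperm: int


def _parafit_from_coords(
    hcoords: np.ndarray,
    fcoords: np.ndarray,
    assoc: np.ndarray,
    nperm: int,
    rng: np.random.Generator,
) -> ParafitResult:
    def stat_of(a: np.ndarray) -> float:
        d = fcoords.T @ a.T @ hcoords
        return float((d**2).sum())

    obs = stat_of(assoc)
    hits = 0
    for _ in range(nperm):
        a = assoc.copy()
        for j in range(a.shape[1]):
            a[:, j] = rng.permutation(a[:, j])
        if stat_of(a) >= obs:
            hits += 1
    return ParafitResult(obs, (1 + hits) / (1 + nperm), nperm)


def parafit(
    host_dm: DistanceMatrix,
    fungal_dm: DistanceMatrix,
    assoc: pd.DataFrame,
    nperm: int = 99,
    seed: int | None = None,
) -> ParafitResult:
    """ParaFit global test of host-symbiont association.

    ParaFitGlobal is the sum of squared entries of the fourth-corner matrix
    C' A' B built from Cailliez-corrected principal coordinates of both
    distance matrices; the null independently permutes each association
    column (host assignment shuffle per fungal tip).
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    a = assoc.loc[list(host_dm.ids), list(fungal_dm.ids)].to_numpy()
    rng = np.random.default_rng(seed)
    h = pcoa_cailliez(host_dm).to_numpy()
    f = pcoa_cailliez(fungal_dm).to_numpy()
    return _parafit_from_coords(h, f, a, nperm, rng)


# ---------------------------------------------------------------------------
# dual FDR gate and scan driver
# ---------------------------------------------------------------------------

def dual_test_fdr(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-FDR within each test family; pass requires both Q < alpha.

    ``results`` must carry columns paco_p and parafit_p (one row per OTU).
    """
    if len(results) == 0:
        raise ValueError("no results to correct")
    out = results.copy()
    out["q_paco"] = multipletests(out["paco_p"], method="fdr_bh")[1]
    out["q_parafit"] = multipletests(out["parafit_p"], method="fdr_bh")[1]
    out["pass"] = (out["q_paco"] < alpha) & (out["q_parafit"] < alpha)
    return out


def cophylogeny_scan(
    otus: list[EligibleOTU],
    host_tree: TreeNode,
    nperm: int = 99,
    seed: int | None = None,
    hosts: tuple[str, ...] = HOMINIDS,
) -> pd.DataFrame:
    """Dual PACo + ParaFit test for each eligible OTU, with the FDR gate."""
    host_dm = patristic_distances(host_tree.shear(list(hosts)))
    rng = np.random.default_rng(seed)
    rows = []
    for otu in otus:
        fdm = patristic_distances(otu.tree)
        a = association_matrix(otu, hosts=tuple(host_dm.ids))
        pr = paco(host_dm, fdm, a, nperm=nperm, seed=int(rng.integers(2**31)))
        pf = parafit(host_dm, fdm, a, nperm=nperm, seed=int(rng.integers(2**31)))
        rows.append({
            "genus": otu.genus, "otu_id": otu.otu_id, "n_tips": len(otu.alignment),
            "paco_m2": pr.m2, "paco_R2": pr.R2, "paco_p": pr.p_value,
            "parafit_stat": pf.stat, "parafit_p": pf.p_value,
        })
    return dual_test_fdr(pd.DataFrame(rows))


def fpr_validation(
    otus: list[EligibleOTU],
    host_tree: TreeNode,
    n_shuffles: int = 100,
    nperm: int = 99,
    seed: int | None = None,
    alpha: float = 0.05,
    hosts: tuple[str, ...] = HOMINIDS,
) -> tuple[float, float, pd.DataFrame]:
    """Tip-shuffle false-positive experiment for the dual test.

    For every eligible OTU, the fungal tree's tip labels are shuffled
    ``n_shuffles`` times; each shuffled instance runs PACo and ParaFit.
    Returns (fpr_raw, fpr_fdr, per-instance table): fpr_raw is the fraction
    of instances with both raw p < alpha; fpr_fdr applies BH within each test
    family across all instances and gates on both Q < alpha.
    """
    host_dm = patristic_distances(host_tree.shear(list(hosts)))
    hcoords = pcoa_cailliez(host_dm).to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for otu in otus:
        fdm = patristic_distances(otu.tree)
        fcoords = pcoa_cailliez(fdm).to_numpy()
        a0 = association_matrix(otu, hosts=tuple(host_dm.ids)).to_numpy()
        ntips = a0.shape[1]
        for s in range(n_shuffles):
            # relabeling tips permutes association columns; the tree and its
            # embedding are unchanged
            perm = rng.permutation(ntips)
            a = a0[:, perm]
            pr = _paco_from_coords(hcoords, fcoords, a, nperm, "quasiswap", rng)
            pf = _parafit_from_coords(hcoords, fcoords, a, nperm, rng)
            rows.append({"genus": otu.genus, "otu_id": otu.otu_id, "shuffle": s,
                         "paco_p": pr.p_value, "parafit_p": pf.p_value})
    table = pd.DataFrame(rows)
    both_raw = (table["paco_p"] < alpha) & (table["parafit_p"] < alpha)
    fpr_raw = float(both_raw.mean())
    gated = dual_test_fdr(table, alpha=alpha)
    fpr_fdr = float(gated["pass"].mean())
    return fpr_raw, fpr_fdr, gated
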