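"""Within-gene diversity and recombination from haplotype alignments.

Per gene the pipeline computes the number of segregating sites S,
nucleotide diversity theta_pi, Watterson's theta_W, the Hudson-Kaplan
minimum number of recombination events Rm (four-gamete test plus interval
stabbing), and a pairwise composite-likelihood estimate of the
population-scaled recombination rate rho = 4*Ne*r.  The composite
likelihood follows Hudson's approach: the sampling probability of each
two-site haplotype configuration under a given rho is tabulated once by
Monte-Carlo two-locus coalescent simulation, and the per-gene rho is the
grid maximizer of the summed log-probabilities over all site pairs, with
the pairwise rho scaled by inter-site distance.

Site filtering mirrors standard practice for unphased-free haplotype
data: indel or missing columns, sites with more than two states, and
(optionally) singleton polymorphisms are excluded, keeping only
parsimony-informative biallelic SNPs.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "HaplotypeAlignment",
    "SnpMatrix",
    "GeneStats",
    "TwoLocusTable",
    "read_fasta",
    "filter_sites",
    "check_eligibility",
    "diversity",
    "rm_hudson_kaplan",
    "two_locus_table",
    "composite_rho",
    "gene_stats",
    "MIN_LENGTH_BP",
    "MIN_SEG_SITES",
    "MIN_CHROMOSOMES_EXCL",
]

MIN_LENGTH_BP = 800
MIN_SEG_SITES = 10
MIN_CHROMOSOMES_EXCL = 20  # strictly more than 20 chromosomes required

_MISSING = {"-", "N", "?"}


@dataclass
class HaplotypeAlignment:
    """Aligned haplotype (phased) sequences for one gene."""

    labels: list
    seqs: np.ndarray  # (n, L) array of single characters, uppercase
    positions: Optional[np.ndarray] = None  # 1-based physical positions

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs)
        if self.seqs.ndim != 2:
            raise ValueError("alignment must be 2-D (haplotypes x columns)")
        if self.n < 2:
            raise ValueError("need at least 2 haplotypes")
        if len(self.labels) != self.n:
            raise ValueError("label count mismatch")
        if len(set(self.labels)) != self.n:
            raise ValueError("duplicate sequence labels")

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def length(self) -> int:
        return self.seqs.shape[1]


@dataclass
class SnpMatrix:
    """Binary SNP matrix: 0 = major allele, 1 = minor (ties: first seen)."""

    matrix: np.ndarray  # (n, S) uint8
    positions: np.ndarray  # 1-based column positions within the alignment
    dropped: list = field(default_factory=list)  # (position, reason)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s(self) -> int:
        return self.matrix.shape[1]


@dataclass
class GeneStats:
    gene: str
    n: int
    length: int
    s: int
    theta_pi: float  # per site
    theta_w: float   # per site
    rm: int
    rho_hat: Optional[float] = None   # per gene
    rho_over_theta: Optional[float] = None
    eligible: bool = True
    reasons: list = field(default_factory=list)


def read_fasta(path) -> HaplotypeAlignment:
    """Read an aligned FASTA file; sequences are upper-cased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    labels = [r.id for r in records]
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"unequal sequence lengths in {path}: {sorted(lengths)}")
    seqs = np.array([list(str(r.seq).upper()) for r in records])
    return HaplotypeAlignment(labels=labels, seqs=seqs)


def filter_sites(aln: HaplotypeAlignment, informative_only: bool = True) -> SnpMatrix:
    """Extract biallelic SNP columns, recording why each column dropped.

    Columns containing gaps or missing data are removed ("indel" /
    "missing"), as are invariant columns ("monomorphic") and sites with
    more than two states (">2 states").  With ``informative_only``,
    singletons drop too ("singleton"), leaving only parsimony-informative
    sites (minor allele in >= 2 haplotypes).
    """
    cols, positions, dropped = [], [], []
    for j in range(aln.length):
        col = aln.seqs[:, j]
        pos = j + 1
        if "-" in col:
            dropped.append((pos, "indel"))
            continue
        if any(c in ("N", "?") for c in col):
            dropped.append((pos, "missing"))
            continue
        states, counts = np.unique(col, return_counts=True)
        if len(states) == 1:
            dropped.append((pos, "monomorphic"))
            continue
        if len(states) > 2:
            dropped.append((pos, ">2 states"))
            continue
        # major allele -> 0; tie broken by first occurrence in the column
        if counts[0] > counts[1]:
            major = states[0]
        elif counts[1] > counts[0]:
            major = states[1]
        else:
            major = col[0]
        binary = (col != major).astype(np.uint8)
        if informative_only and min(counts) < 2:
            dropped.append((pos, "singleton"))
            continue
        cols.append(binary)
        positions.append(pos)
    matrix = (np.array(cols).T if cols
              else np.zeros((aln.n, 0), dtype=np.uint8))
    return SnpMatrix(matrix=matrix, positions=np.array(positions, dtype=np.int64),
                     dropped=dropped)


def check_eligibility(aln: HaplotypeAlignment, s: int):
    """Gene inclusion rule: >= 800 bp, >= 10 segregating sites, > 20 chromosomes."""
    reasons = []
    if aln.length < MIN_LENGTH_BP:
        reasons.append("length")
    if s < MIN_SEG_SITES:
        reasons.append("segregating sites")
    if aln.n <= MIN_CHROMOSOMES_EXCL:
        reasons.append("chromosomes")
    return len(reasons) == 0, reasons


def diversity(snp: SnpMatrix, n: Optional[int] = None, length: Optional[int] = None):
    """Per-site nucleotide diversity theta_pi, Watterson's theta_W and S.

    theta_pi averages pairwise differences with the n/(n-1) unbiased
    correction; theta_W is S over the harmonic number a_n = sum_{i<n} 1/i.
    """
    n = n if n is not None else snp.n
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    if not length or length <= 0:
        raise ValueError("alignment length must be positive")
    s = snp.s
    if s == 0:
        return 0.0, 0.0, 0
    p = snp.matrix.mean(axis=0)
    theta_pi = float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1)) / length
    a_n = sum(1.0 / i for i in range(1, n))
    theta_w = s / (a_n * length)
    return theta_pi, theta_w, s


def _incompatible_pairs(matrix: np.ndarray) -> np.ndarray:
    """Boolean (S, S) matrix: four-gamete incompatibility per column pair."""
    A = matrix.T.astype(np.int64)  # (S, n)
    n11 = A @ A.T
    n10 = A @ (1 - A.T)
    n01 = (1 - A) @ A.T
    n00 = (1 - A) @ (1 - A.T)
    return (n00 > 0) & (n01 > 0) & (n10 > 0) & (n11 > 0)


def rm_hudson_kaplan(snp: SnpMatrix) -> int:
    """Hudson-Kaplan minimum number of recombination events.

    Every four-gamete-incompatible site pair (i, j) requires at least one
    crossover strictly between columns i and j.  Rm is the minimum number
    of points stabbing all such open intervals, found by the classical
    greedy sweep on right endpoints (optimal for interval stabbing).
    Intervals sharing only an endpoint count as disjoint: events sit
    strictly between sites.
    """
    if snp.s < 2:
        return 0
    inc = _incompatible_pairs(snp.matrix)
    ii, jj = np.where(np.triu(inc, k=1))
    if len(ii) == 0:
        return 0
    intervals = sorted(zip(jj.tolist(), ii.tolist()))  # by right endpoint
    rm = 0
    last_right = -1
    for right, left in intervals:
        if left >= last_right:
            rm += 1
            last_right = right
    return rm


# -- two-locus composite likelihood ----------------------------------------

def _fold_config(n00: int, n01: int, n10: int, n11: int):
    """Canonical form of a two-locus haplotype count configuration.

    Folds over relabelling alleles at either locus and swapping the two
    loci (8 symmetries); the lexicographically smallest tuple wins.
    """
    best = None
    c = (n00, n01, n10, n11)
    for cfg in (
        c,
        (c[2], c[3], c[0], c[1]),  # flip locus A
        (c[1], c[0], c[3], c[2]),  # flip locus B
        (c[3], c[2], c[1], c[0]),  # flip both
    ):
        for t in (cfg, (cfg[0], cfg[2], cfg[1], cfg[3])):  # swap loci
            if best is None or t < best:
                best = t
    return best


@dataclass
class TwoLocusTable:
    """P(two-site haplotype configuration | rho, n) on a rho grid.

    Built by Monte-Carlo two-locus coalescent simulation: for each grid
    rho, ancestral lineages coalesce at rate k(k-1)/2 and lineages
    ancestral at both loci split at rate rho/2; one mutation per locus is
    placed uniformly by branch length on each marginal tree, and each
    replicate's configuration is weighted by the product of the two total
    tree lengths (the theta -> 0 conditioning on one mutation per locus).
    Configurations are folded over allele relabelling and locus swap.
    """

    n: int
    grid: np.ndarray
    configs: dict           # folded config tuple -> row index
    log_probs: np.ndarray   # (n_configs, n_grid)
    mc_reps: int
    floor: float            # probability floor for unseen configurations

    def pair_log_prob_rows(self, cfgs: Sequence) -> np.ndarray:
        """Log-probability rows (len(cfgs), n_grid); unseen get the floor."""
        out = np.full((len(cfgs), len(self.grid)), math.log(self.floor))
        for i, cfg in enumerate(cfgs):
            row = self.configs.get(cfg)
            if row is not None:
                out[i] = self.log_probs[row]
        return out


def _simulate_two_locus(n: int, rho: float, rng: random.Random):
    """One two-locus coalescent replicate.

    Returns (weight, config) where weight = T_A * T_B (total marginal
    tree lengths) and config = (n00, n01, n10, n11) from one mutation per
    locus placed uniformly by branch length.
    """
    full = (1 << n) - 1
    # lineage = [mask_A, mask_B]; 0 mask = not ancestral at that locus
    lineages = [[1 << i, 1 << i] for i in range(n)]
    done_a = done_b = False
    t_a = t_b = 0.0
    exp_a = []  # (mask, weight) exposure for mutation placement, locus A
    exp_b = []
    while not (done_a and done_b):
        k = len(lineages)
        n_both = sum(1 for lin in lineages if lin[0] and lin[1])
        rate_c = k * (k - 1) / 2.0
        rate_r = n_both * rho / 2.0
        total = rate_c + rate_r
        dt = rng.expovariate(total)
        for lin in lineages:
            if not done_a and lin[0]:
                t_a += dt
                exp_a.append((lin[0], dt))
            if not done_b and lin[1]:
                t_b += dt
                exp_b.append((lin[1], dt))
        if rng.random() < rate_c / total:
            i = rng.randrange(k)
            j = rng.randrange(k - 1)
            if j >= i:
                j += 1
            a, b = lineages[i], lineages[j]
            merged = [a[0] | b[0], a[1] | b[1]]
            if merged[0] == full:
                done_a = True
            if merged[1] == full:
                done_b = True
            if done_a:
                merged[0] = 0
            if done_b:
                merged[1] = 0
            for idx in sorted((i, j), reverse=True):
                lineages.pop(idx)
            if merged[0] or merged[1]:
                lineages.append(merged)
        else:
            cand = [i for i, lin in enumerate(lineages) if lin[0] and lin[1]]
            i = rng.choice(cand)
            a_mask, b_mask = lineages[i]
            lineages[i] = [a_mask, 0]
            lineages.append([0, b_mask])

    def draw(exposures, total):
        u = rng.random() * total
        acc = 0.0
        for mask, w in exposures:
            acc += w
            if u <= acc:
                return mask
        return exposures[-1][0]

    mask_a = draw(exp_a, t_a)
    mask_b = draw(exp_b, t_b)
    n11 = bin(mask_a & mask_b).count("1")
    n10 = bin(mask_a & ~mask_b & full).count("1")
    n01 = bin(~mask_a & mask_b & full).count("1")
    n00 = n - n11 - n10 - n01
    return t_a * t_b, (n00, n01, n10, n11)


def two_locus_table(
    n: int,
    rho_grid: Sequence[float],
    mc_reps: int = 10_000,
    seed: Optional[int] = None,
) -> TwoLocusTable:
    """Tabulate two-locus configuration probabilities by simulation.

    ``rho_grid`` must include 0 and be non-negative; ``mc_reps``
    replicates are run per grid point.  Probabilities are normalized per
    grid point; configurations never seen at some rho get a floor of
    ``1 / (mc_reps + 1)`` when looked up (avoids -inf composite
    log-likelihoods).
    """
    grid = np.asarray(sorted(set(float(r) for r in rho_grid)))
    if np.any(grid < 0):
        raise ValueError("rho grid values must be >= 0")
    if 0.0 not in grid:
        raise ValueError("rho grid must include 0")
    if n < 4:
        raise ValueError("need n >= 4 for two-locus configurations")
    rng = random.Random(seed)
    weights: list = [dict() for _ in grid]
    for gi, rho in enumerate(grid):
        acc = weights[gi]
        for _ in range(mc_reps):
            w, cfg = _simulate_two_locus(n, rho, rng)
            key = _fold_config(*cfg)
            acc[key] = acc.get(key, 0.0) + w
    all_cfgs = sorted(set().union(*[set(d) for d in weights]))
    index = {cfg: i for i, cfg in enumerate(all_cfgs)}
    floor = 1.0 / (mc_reps + 1)
    probs = np.full((len(all_cfgs), len(grid)), floor)
    for gi, acc in enumerate(weights):
        total = sum(acc.values())
        for cfg, w in acc.items():
            probs[index[cfg], gi] = max(w / total, floor)
    return TwoLocusTable(
        n=n,
        grid=grid,
        configs=index,
        log_probs=np.log(probs),
        mc_reps=mc_reps,
        floor=floor,
    )


def _pair_configs(matrix: np.ndarray):
    """Folded two-locus configuration for every ordered column pair i < j."""
    n, s = matrix.shape
    A = matrix.T.astype(np.int64)
    n11 = A @ A.T
    n10 = A @ (1 - A.T)
    n01 = (1 - A) @ A.T
    n00 = n - n11 - n10 - n01
    ii, jj = np.triu_indices(s, k=1)
    cfgs = [
        _fold_config(int(n00[i, j]), int(n01[i, j]), int(n10[i, j]),
                     int(n11[i, j]))
        for i, j in zip(ii, jj)
    ]
    return cfgs, ii, jj


def composite_rho(
    snp: SnpMatrix,
    n: Optional[int] = None,
    table: TwoLocusTable = None,
    positions: Optional[np.ndarray] = None,
    search_grid: Optional[np.ndarray] = None,
):
    """Pairwise composite-likelihood estimate of the per-gene rho.

    For a candidate per-gene rho, each site pair (i, j) contributes
    ``log P(config_ij | rho * d_ij / d_total)`` where d is the physical
    distance (positions if available, else column index spacing) and
    d_total the span of the analysed sites.  Table log-probabilities are
    interpolated linearly in log(1 + rho) between grid points and held
    flat beyond the last grid point.  The estimate is the maximizer over
    a deterministic search grid (boundary at 0 allowed).

    Returns ``(rho_hat, composite_log_likelihood)``.
    """
    if table is None:
        raise ValueError("a TwoLocusTable is required")
    n = n if n is not None else snp.n
    if n != table.n:
        raise ValueError(f"table built for n={table.n}, data has n={n}")
    if snp.s < 2:
        raise ValueError("need at least 2 segregating sites")
    pos = positions if positions is not None else snp.positions
    pos = np.asarray(pos, dtype=float)
    if len(pos) != snp.s:
        pos = np.arange(1, snp.s + 1, dtype=float)
    cfgs, ii, jj = _pair_configs(snp.matrix)
    rows = table.pair_log_prob_rows(cfgs)  # (n_pairs, n_grid)
    d = np.abs(pos[jj] - pos[ii])
    d_total = pos.max() - pos.min()
    if d_total <= 0:
        raise ValueError("zero physical span")
    frac = d / d_total
    if search_grid is None:
        hi = max(float(table.grid.max()) * 2.0, 1.0)
        search_grid = np.concatenate([[0.0], np.geomspace(0.01, hi, 120)])
    gx = np.log1p(table.grid)
    best_rho, best_ll = None, -np.inf
    for rho in search_grid:
        rho_ij = np.minimum(rho * frac, table.grid.max())
        x = np.log1p(rho_ij)
        # vectorized linear interpolation along the grid axis, per pair
        k = np.clip(np.searchsorted(gx, x, side="right") - 1, 0, len(gx) - 2)
        x0, x1 = gx[k], gx[k + 1]
        w = np.where(x1 > x0, (x - x0) / (x1 - x0), 0.0)
        ll = float(np.sum((1 - w) * rows[np.arange(len(cfgs)), k]
                          + w * rows[np.arange(len(cfgs)), k + 1]))
        if ll > best_ll:
            best_ll, best_rho = ll, float(rho)
    return best_rho, best_ll


def gene_stats(
    aln: HaplotypeAlignment,
    gene: str = "",
    informative_only: bool = True,
    table: Optional[TwoLocusTable] = None,
    search_grid: Optional[np.ndarray] = None,
) -> GeneStats:
    """Full per-gene summary: filters, eligibility, diversity, Rm, rho.

    rho is estimated only when a matching :class:`TwoLocusTable` is
    provided and the gene is eligible with >= 2 analysed sites.
    rho_over_theta divides the per-gene rho by the per-gene Watterson
    theta (theta_W per site times length).
    """
    snp = filter_sites(aln, informative_only=informative_only)
    theta_pi, theta_w, s_analysed = diversity(snp, aln.n, aln.length)
    # eligibility is judged on all segregating sites, pre-thinning
    snp_all = filter_sites(aln, informative_only=False)
    s_total = snp_all.s
    eligible, reasons = check_eligibility(aln, s_total)
    rm = rm_hudson_kaplan(snp)
    stats = GeneStats(
        gene=gene,
        n=aln.n,
        length=aln.length,
        s=s_total,
        theta_pi=theta_pi,
        theta_w=theta_w,
        rm=rm,
        eligible=eligible,
        reasons=reasons,
    )
    if table is not None and eligible and snp.s >= 2 and table.n == aln.n:
        rho_hat, _ = composite_rho(snp, aln.n, table, search_grid=search_grid)
        stats.rho_hat = rho_hat
        theta_gene = theta_w * aln.length
        stats.rho_over_theta = (rho_hat / theta_gene) if theta_gene > 0 else None
    return stats
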