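"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of the comparative study's inputs:
an ultrametric phylogeny (pure-birth), continuous traits evolved by
Brownian motion (optionally bivariate and correlated, standing in for
log recombination rate and heterozygosity), clade- or Markov-structured
life-forms with additive effects on the log rate, a species table whose
map lengths and genome sizes back-solve exactly to a chosen latent rate,
and haplotype samples from a coalescent with recombination (ancestral
recombination graph, infinite-sites mutation) for the within-gene stage.

Every generator is a pure function of its parameters and an explicit
seed.
"""

from __future__ import annotations

import math
import random
from typing import Optional, Sequence

import numpy as np

from phylorecomb.tree import PhyloTree
from phylorecomb.genewise import HaplotypeAlignment
from phylorecomb.rates import SpeciesRecord

__all__ = [
    "yule_tree",
    "simulate_bm",
    "assign_life_forms",
    "coalescent_with_recombination",
    "species_table_fixture",
]

# default study conditions: 81 species, moderate phylogenetic residual,
# He slope and life-form effects close to the comparative estimates
DEFAULT_GROUP_EFFECTS = {"herb": -0.9, "shrub": -0.7, "conifer tree": -1.1}
DEFAULT_SLOPE_HE = 0.8
DEFAULT_INTERCEPT = -1.5


def yule_tree(n_tips: int, birth_rate: float = 1.0,
              seed: Optional[int] = None) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree.

    Waiting times between successive birth events are exponential with
    rate ``k * birth_rate`` for k extant lineages; after the n-th lineage
    appears one final interval is drawn before the present, so the
    expected root-to-tip depth is ``sum_{k=2}^{n} 1/(k * birth_rate)``.
    Tips are labelled ``t1..tn`` in birth order.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    # nodes: root = 0 with two children; grow by splitting random tips
    parent = [-1, 0, 0]
    children = [[1, 2], [], []]
    birth_time = [0.0, None, None]  # split time of internal nodes
    active = [1, 2]
    t = 0.0
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (k * birth_rate))
        tip = active.pop(rng.integers(len(active)))
        birth_time[tip] = t
        for _ in range(2):
            nid = len(parent)
            parent.append(tip)
            children[tip].append(nid)
            children.append([])
            birth_time.append(None)
            active.append(nid)
        k += 1
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    present = t
    n_nodes = len(parent)
    bl = np.full(n_nodes, np.nan)
    labels: list = [None] * n_nodes
    tip_counter = 0
    for node in range(1, n_nodes):
        end = birth_time[node] if children[node] else present
        bl[node] = end - birth_time[parent[node]]
    # label tips in preorder for determinism
    labels = [None] * n_nodes
    stack = [0]
    while stack:
        node = stack.pop()
        if not children[node]:
            tip_counter += 1
            labels[node] = f"t{tip_counter}"
        else:
            stack.extend(reversed(children[node]))
    return PhyloTree(parent=np.array(parent), children=children,
                     branch_length=bl, labels=labels, root=0)


def simulate_bm(
    tree: PhyloTree,
    sigma2: float = 1.0,
    root_value=0.0,
    seed: Optional[int] = None,
    covariance: Optional[np.ndarray] = None,
) -> dict:
    """Brownian-motion trait(s) on a calibrated tree.

    Each child value is its parent value plus a Gaussian step with
    variance ``sigma2 * branch_length``.  With a 2x2 ``covariance`` (per
    unit branch length), a bivariate trait is evolved and each tip maps
    to a length-2 array; ``root_value`` is then a length-2 vector.
    Returns ``{tip_label: value}``.
    """
    if not tree.has_branch_lengths():
        raise ValueError("tree must be calibrated (branch lengths present)")
    rng = np.random.default_rng(seed)
    if covariance is not None:
        covariance = np.asarray(covariance, dtype=float)
        eigs = np.linalg.eigvalsh(covariance)
        if np.any(eigs < -1e-12):
            raise ValueError("trait covariance must be positive semi-definite")
        L = np.linalg.cholesky(covariance + 1e-15 * np.eye(2))
        dim = 2
        root = np.broadcast_to(np.asarray(root_value, dtype=float), (2,)).copy()
    else:
        dim = 1
        root = np.array([float(root_value)])
    value = {tree.root: root}
    for node in tree.preorder():
        if node == tree.root:
            continue
        b = tree.branch_length[node]
        z = rng.standard_normal(dim)
        if covariance is not None:
            step = (L @ z) * math.sqrt(b)
        else:
            step = z * math.sqrt(sigma2 * b)
        value[node] = value[tree.parent[node]] + step
    out = {}
    for t in tree.tips():
        v = value[t]
        out[tree.labels[t]] = v if dim == 2 else float(v[0])
    return out


def assign_life_forms(
    tree: PhyloTree,
    levels: Sequence[str] = ("herb", "shrub", "tree"),
    switch_rate: float = 0.05,
    seed: Optional[int] = None,
    base_trait: Optional[dict] = None,
    group_effects: Optional[dict] = None,
    clades: Optional[dict] = None,
    root_state: Optional[str] = None,
) -> tuple:
    """Clade-structured discrete life-forms plus effect-shifted trait.

    By default the life-form evolves along branches as a continuous-time
    Markov chain switching uniformly among ``levels`` at ``switch_rate``
    per Myr, which clusters states in clades.  Alternatively ``clades``
    paints fixed states: a map from an internal/tip node label to a
    level, applied to the whole subtree (later entries in document order
    win on nesting, deepest node wins).

    When ``base_trait`` and ``group_effects`` are given, the returned
    trait is base + effect per tip.  Returns ``(life_form, trait)`` dicts
    keyed by tip label (trait is None without a base trait).
    """
    levels = list(levels)
    if not levels:
        raise ValueError("empty level set")
    rng = np.random.default_rng(seed)
    state = {}
    if clades is not None:
        # default state = first level; paint subtrees
        default = root_state or levels[0]
        node_state = {tree.root: default}
        paint = {}
        for lbl, lvl in clades.items():
            paint[tree.find(lbl)] = lvl
        for node in tree.preorder():
            if node in paint:
                node_state[node] = paint[node]
            elif node != tree.root:
                node_state[node] = node_state[tree.parent[node]]
        for t in tree.tips():
            state[tree.labels[t]] = node_state[t]
    else:
        start = root_state or levels[int(rng.integers(len(levels)))]
        node_state = {tree.root: start}
        for node in tree.preorder():
            if node == tree.root:
                continue
            s = node_state[tree.parent[node]]
            b = tree.branch_length[node]
            if switch_rate > 0 and len(levels) > 1:
                t = rng.exponential(1.0 / switch_rate)
                while t < b:
                    others = [l for l in levels if l != s]
                    s = others[int(rng.integers(len(others)))]
                    t += rng.exponential(1.0 / switch_rate)
            node_state[node] = s
        for t in tree.tips():
            state[tree.labels[t]] = node_state[t]
    trait = None
    if base_trait is not None:
        effects = group_effects or {}
        trait = {lbl: base_trait[lbl] + effects.get(state[lbl], 0.0)
                 for lbl in state}
    return state, trait


# -- coalescent with recombination (ARG, infinite sites) --------------------

def _split_segments(segs, breakpoint):
    """Split a lineage's segment list at a breakpoint in (0, 1)."""
    left, right = [], []
    for l, r, mask in segs:
        if r <= breakpoint:
            left.append((l, r, mask))
        elif l >= breakpoint:
            right.append((l, r, mask))
        else:
            left.append((l, breakpoint, mask))
            right.append((breakpoint, r, mask))
    return left, right


def _merge_segments(a, b, full):
    """Coalesce two segment lists; segments reaching the MRCA are dropped."""
    events = []
    for l, r, mask in a:
        events.append((l, r, mask))
    for l, r, mask in b:
        events.append((l, r, mask))
    # sweep over all boundary points
    bounds = sorted({x for l, r, _ in events for x in (l, r)})
    merged = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mask = 0
        for l, r, m in events:
            if l <= lo and r >= hi:
                mask |= m
        if mask and mask != full:
            merged.append((lo, hi, mask))
    # coalesce adjacent runs with equal mask
    out = []
    for seg in merged:
        if out and out[-1][2] == seg[2] and abs(out[-1][1] - seg[0]) < 1e-15:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(list(seg))
            out[-1] = tuple(out[-1])
    return out


_NUC = "ACGT"


def coalescent_with_recombination(
    n: int,
    theta: float,
    rho: float,
    length: int = 1000,
    seed: Optional[int] = None,
    as_nucleotides: bool = True,
) -> HaplotypeAlignment:
    """Sample haplotypes from the coalescent with recombination.

    Backward-in-time ancestral recombination graph over the unit
    interval: coalescence at rate k(k-1)/2, recombination at rate rho/2
    per unit of breakable ancestral span, with breakpoints uniform on a
    lineage's (leftmost, rightmost) ancestral material.  Segments whose
    sample subset reaches the full sample are dropped (marginal MRCA).
    Mutations are Poisson with rate theta/2 per unit time per unit
    sequence, placed uniformly on the ancestral material (infinite
    sites) and mapped to distinct integer positions in 1..length
    (collisions resampled).  Output is an alignment with a monomorphic
    background and one biallelic SNP per mutation.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if theta < 0 or rho < 0:
        raise ValueError("theta and rho must be >= 0")
    rng = random.Random(seed)
    full = (1 << n) - 1
    lineages = [[(0.0, 1.0, 1 << i)] for i in range(n)]
    exposures = []  # (l, r, mask, time-weight)

    def span(segs):
        return segs[-1][1] - segs[0][0]

    while lineages:
        k = len(lineages)
        spans = [span(s) for s in lineages]
        rate_c = k * (k - 1) / 2.0
        rate_r = rho / 2.0 * sum(spans)
        total = rate_c + rate_r
        if total <= 0:
            break
        dt = rng.expovariate(total)
        for segs in lineages:
            for l, r, mask in segs:
                exposures.append((l, r, mask, dt * (r - l)))
        if rng.random() < rate_c / total:
            i = rng.randrange(k)
            j = rng.randrange(k - 1)
            if j >= i:
                j += 1
            merged = _merge_segments(lineages[i], lineages[j], full)
            for idx in sorted((i, j), reverse=True):
                lineages.pop(idx)
            if merged:
                lineages.append(merged)
            if len(lineages) == 1 and not lineages[0]:
                break
        else:
            u = rng.random() * sum(spans)
            acc = 0.0
            for i, s in enumerate(spans):
                acc += s
                if u <= acc:
                    break
            segs = lineages[i]
            bp = segs[0][0] + rng.random() * span(segs)
            left, right = _split_segments(segs, bp)
            if left and right:
                lineages[i] = left
                lineages.append(right)
        if len(lineages) == 1 and len(lineages[0]) == 0:
            break

    total_w = sum(w for *_ , w in exposures)
    n_mut = _poisson(theta / 2.0 * total_w, rng)
    # sample mutation segments by weight, positions uniform within
    cum = []
    acc = 0.0
    for l, r, mask, w in exposures:
        acc += w
        cum.append(acc)
    muts = []  # (unit position, carrier mask)
    for _ in range(n_mut):
        u = rng.random() * total_w
        lo, hi = 0, len(cum) - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if cum[mid] < u:
                lo = mid + 1
            else:
                hi = mid
        l, r, mask, w = exposures[lo]
        muts.append((l + rng.random() * (r - l), mask))

    # map unit positions to distinct integer bp (resample collisions)
    used = set()
    sites = []
    for upos, mask in muts:
        bp = int(upos * length) + 1
        bp = min(max(bp, 1), length)
        while bp in used:
            bp = rng.randrange(1, length + 1)
        used.add(bp)
        sites.append((bp, mask))
    sites.sort()

    if as_nucleotides:
        background = [_NUC[rng.randrange(4)] for _ in range(length)]
        seqs = np.array([list(background) for _ in range(n)])
        for bp, mask in sites:
            ref = seqs[0, bp - 1]
            alt = rng.choice([c for c in _NUC if c != ref])
            for i in range(n):
                if mask >> i & 1:
                    seqs[i, bp - 1] = alt
    else:
        seqs = np.zeros((n, length), dtype="U1")
        seqs[:] = "0"
        for bp, mask in sites:
            for i in range(n):
                if mask >> i & 1:
                    seqs[i, bp - 1] = "1"
    labels = [f"hap{i + 1}" for i in range(n)]
    return HaplotypeAlignment(labels=labels, seqs=seqs,
                              positions=np.array([bp for bp, _ in sites]))


def _poisson(lam: float, rng: random.Random) -> int:
    """Poisson draw via inversion for small lambda, normal for large."""
    if lam <= 0:
        return 0
    if lam > 700:
        return max(0, int(round(rng.gauss(lam, math.sqrt(lam)))))
    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


# -- species table with exact back-solve ------------------------------------

def species_table_fixture(
    tree: PhyloTree,
    slope_he: float = DEFAULT_SLOPE_HE,
    intercept: float = DEFAULT_INTERCEPT,
    group_effects: Optional[dict] = None,
    noise_sigma2: float = 0.25,
    switch_rate: Optional[float] = None,
    seed: Optional[int] = None,
    conifer_clade: Optional[str] = None,
):
    """Species records whose pipeline round-trip reproduces known rates.

    He is a logistic transform of a Brownian trait squashed into
    [0.3, 0.9] (a realistic SSR heterozygosity range); the latent log
    rate is ``intercept + slope_he * He + group effect + BM deviation``
    with the deviation itself Brownian (variance ``noise_sigma2`` per
    unit depth, so residuals are phylogenetically structured).  Map
    lengths, marker counts and genome sizes are back-solved so that
    :func:`phylorecomb.rates.build_rate_table` returns exactly the
    latent rate: each species gets C chromosomes of equal corrected
    share with 51 markers each, and every record passes the inclusion
    filters by construction.

    ``conifer_clade`` optionally names a node whose subtree is painted
    as conifer trees (taxon_group "conifer", life_form "tree") with the
    "conifer tree" group effect.

    Returns ``(records, truth)`` where truth holds the latent per-species
    log rate, He, life-form and the generating parameters.
    """
    if group_effects is None:
        group_effects = dict(DEFAULT_GROUP_EFFECTS)
    rng = np.random.default_rng(seed)
    s_he, s_dev, s_lf, s_mk = (int(x) for x in
                               rng.integers(0, 2 ** 31 - 1, size=4))
    depth = tree.node_depths()[tree.tips()].max()
    scale = 1.0 / max(depth, 1e-9)
    if switch_rate is None:
        # ~2 expected life-form switches per root-to-tip path: clade
        # structure with all levels usually represented
        switch_rate = 2.0 * scale
    he_raw = simulate_bm(tree, sigma2=scale, seed=s_he)
    he = {k: 0.3 + 0.6 / (1.0 + math.exp(-1.5 * v))
          for k, v in he_raw.items()}
    deviation = simulate_bm(tree, sigma2=noise_sigma2 * scale, seed=s_dev)
    clades = {conifer_clade: "conifer tree"} if conifer_clade else None
    life_form, _ = assign_life_forms(
        tree, levels=("herb", "shrub", "tree"), switch_rate=switch_rate,
        seed=s_lf, clades=clades, root_state="tree",
    )
    mk = np.random.default_rng(s_mk)
    records, truth_rows = [], []
    for lbl in tree.tip_labels:
        lf = life_form[lbl]
        taxon = "conifer" if lf == "conifer tree" else "angiosperm"
        lf_out = "tree" if lf == "conifer tree" else lf
        log_rate = (intercept + slope_he * he[lbl]
                    + group_effects.get(lf, 0.0) + deviation[lbl])
        rate = math.exp(log_rate)
        genome_mb = float(mk.uniform(300.0, 4000.0)) if taxon == "angiosperm" \
            else float(mk.uniform(8000.0, 30000.0))
        corrected = rate * genome_mb
        n_chrom = int(mk.integers(5, 15))
        m = 51  # markers per chromosome
        # corrected = raw_total * (1 + 2 / (m - 1)) for equal chromosomes
        raw_total = corrected / (1.0 + 2.0 / (m - 1))
        if raw_total <= 0:
            raise ValueError("infeasible back-solve: non-positive map length")
        lengths = [raw_total / n_chrom] * n_chrom
        markers = [m] * n_chrom
        records.append(SpeciesRecord(
            species=lbl,
            life_form=lf_out,
            taxon_group=taxon,
            chrom_lengths_cm=lengths,
            chrom_markers=markers,
            genome_size_mb=genome_mb,
            map_coverage=float(mk.uniform(0.7, 1.0)),
            he=he[lbl],
            n_ssr_loci=int(mk.integers(8, 30)),
        ))
        truth_rows.append({"species": lbl, "log_rate": log_rate,
                           "he": he[lbl], "life_form": lf})
    truth = {
        "rows": truth_rows,
        "slope_he": slope_he,
        "intercept": intercept,
        "group_effects": dict(group_effects),
        "noise_sigma2": noise_sigma2,
    }
    return records, truth
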