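"""Synthetic genotype, tag, alignment and tree/state data with truth labels.

The population simulator emits the locus classes the sex-linkage
screens are designed to detect (or be confounded by):

``y_snp``
    A fully penetrant Y- (or W-) specific SNP: every heterogametic
    individual is heterozygous X/Y, every homogametic individual
    homozygous X/X.  With several Y haplotypes each such SNP is
    specific to one haplotype; heterogametic carriers of other
    haplotypes are homozygous X/X.
``sex_limited``
    A RADtag present only in the heterogametic sex (Y-specific tag,
    X null allele, or an under-merged divergent Y allele).
``x_hemizygous``
    A locus present on the X but absent/divergent on the Y, with an
    allele specific to the paternal X: all homogametic individuals are
    called heterozygous and all heterogametic individuals homozygous,
    which mimics the opposite heterogametic system (the pseudo-ZW
    confound on XY data).
``autosomal``
    Hardy-Weinberg genotypes at a sampled minor-allele frequency,
    independent of sex.

Noise is applied after construction: each genotype is miscalled (to a
uniformly chosen different value) with probability ``error_rate`` and
masked with probability ``missing_rate``; tags drop out with
probability ``missing_rate``.  Truth labels accompany every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import dendropy
import numpy as np
import pandas as pd

from sexlinkage.genotype_io import MISSING, GenotypeMatrix, SampleSheet, TagPresenceMatrix

LOCUS_CLASSES = ("autosomal", "y_snp", "sex_limited", "x_hemizygous")


@dataclass
class PopSimParams:
    """Parameters of a single-population RADseq simulation."""

    n_males: int = 20
    n_females: int = 20
    n_loci: int = 2000
    system: str = "XY"  # one of XY, ZW, NONE
    prop_sexlinked: float = 0.05
    prop_y_snp: float = 0.6
    prop_sex_limited: float = 0.2
    prop_x_hemizygous: float = 0.2
    n_y_haplotypes: int = 1
    autosomal_maf_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None
    error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.system not in ("XY", "ZW", "NONE"):
            raise ValueError(f"unknown system {self.system!r}")
        if self.system == "NONE":
            self.prop_sexlinked = 0.0
        for name in (
            "prop_sexlinked",
            "prop_y_snp",
            "prop_sex_limited",
            "prop_x_hemizygous",
            "error_rate",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.prop_y_snp + self.prop_sex_limited + self.prop_x_hemizygous > 1.0 + 1e-12:
            raise ValueError("class fractions of sex-linked loci must sum to <= 1")
        if self.n_y_haplotypes < 1:
            raise ValueError("n_y_haplotypes must be >= 1")
        if self.system != "NONE" and (self.n_males == 0 or self.n_females == 0):
            raise ValueError("both sexes need at least one sample (screens undefined otherwise)")
        if self.n_males + self.n_females < 2:
            raise ValueError("need at least two samples")


@dataclass
class TruthLabels:
    """Simulation ground truth: per-locus class and per-sample Y haplotype.

    ``sample_haplotype`` is -1 for homogametic individuals (and for all
    individuals under system NONE).
    """

    locus_class: np.ndarray
    sample_haplotype: np.ndarray
    seed: int = 0
    system: str = "XY"

    def loci_of_class(self, loci: np.ndarray, cls: str) -> set[str]:
        if cls not in LOCUS_CLASSES:
            raise ValueError(f"unknown locus class {cls!r}")
        return set(np.asarray(loci)[self.locus_class == cls])

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.locus_class == c).sum()) for c in LOCUS_CLASSES}

    def to_tsv(self, loci: np.ndarray, path) -> None:
        pd.DataFrame({"locus_id": loci, "locus_class": self.locus_class}).to_csv(path, sep="\t", index=False)


def _class_layout(params: PopSimParams) -> np.ndarray:
    """Deterministic locus-class assignment.

    Counts use floor rounding at each split (sex-linked total first,
    then classes within it); every remainder is assigned to the
    autosomal class.  Classes occupy contiguous index blocks at the
    start of the locus array.
    """
    n_sl = int(np.floor(params.prop_sexlinked * params.n_loci))
    n_y = int(np.floor(params.prop_y_snp * n_sl))
    n_lim = int(np.floor(params.prop_sex_limited * n_sl))
    n_hemi = int(np.floor(params.prop_x_hemizygous * n_sl))
    classes = np.full(params.n_loci, "autosomal", dtype=object)
    classes[:n_y] = "y_snp"
    classes[n_y : n_y + n_lim] = "sex_limited"
    classes[n_y + n_lim : n_y + n_lim + n_hemi] = "x_hemizygous"
    return classes


def simulate_population(params: PopSimParams) -> tuple[GenotypeMatrix, TagPresenceMatrix, TruthLabels]:
    """Simulate genotypes, tag presence and truth labels for one population."""
    rng = np.random.default_rng(params.seed)
    n = params.n_males + params.n_females
    samples = np.array([f"M{i:03d}" for i in range(params.n_males)] + [f"F{i:03d}" for i in range(params.n_females)], dtype=object)
    male = np.array([True] * params.n_males + [False] * params.n_females)
    loci = np.array([f"L{i:05d}" for i in range(params.n_loci)], dtype=object)
    classes = _class_layout(params)

    # heterogametic sex: males under XY, females under ZW
    het_sex = male if params.system != "ZW" else ~male
    n_het = int(het_sex.sum())

    # Y (or W) haplotype per heterogametic individual, round-robin
    hap = np.full(n, -1, dtype=int)
    if params.system != "NONE" and n_het:
        hap[np.flatnonzero(het_sex)] = np.arange(n_het) % params.n_y_haplotypes

    calls = np.zeros((params.n_loci, n), dtype=np.int8)
    present = np.ones((params.n_loci, n), dtype=np.uint8)

    # autosomal: Hardy-Weinberg at sampled allele-1 frequency
    auto_idx = np.flatnonzero(classes == "autosomal")
    if auto_idx.size:
        if params.autosomal_maf_dist is not None:
            maf = np.asarray(params.autosomal_maf_dist(rng, auto_idx.size), dtype=float)
        else:
            maf = rng.uniform(0.05, 0.5, size=auto_idx.size)
        calls[auto_idx] = rng.binomial(2, maf[:, None], size=(auto_idx.size, n)).astype(np.int8)

    y_idx = np.flatnonzero(classes == "y_snp")
    if y_idx.size:
        # allele 1 is the Y-specific allele; each SNP belongs to one haplotype
        locus_hap = rng.integers(0, params.n_y_haplotypes, size=y_idx.size)
        carrier = hap[None, :] == locus_hap[:, None]
        calls[y_idx] = np.where(carrier, 1, 0).astype(np.int8)

    lim_idx = np.flatnonzero(classes == "sex_limited")
    if lim_idx.size:
        # tag present only in the heterogametic sex; genotype matrix sees
        # a monomorphic call where present and a no-call elsewhere
        present[lim_idx] = het_sex[None, :].astype(np.uint8)
        calls[lim_idx] = np.where(het_sex[None, :], 0, MISSING).astype(np.int8)

    hemi_idx = np.flatnonzero(classes == "x_hemizygous")
    if hemi_idx.size:
        # paternal-X-specific allele: homogametic sex heterozygous,
        # heterogametic sex hemizygous and called homozygous
        calls[hemi_idx] = np.where(het_sex[None, :], 0, 1).astype(np.int8)

    # genotyping noise
    if params.error_rate > 0:
        err = (rng.random(calls.shape) < params.error_rate) & (calls != MISSING)
        shift = rng.integers(1, 3, size=calls.shape)  # move to one of the two other values
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if params.missing_rate > 0:
        drop = rng.random(calls.shape) < params.missing_rate
        calls = np.where(drop, MISSING, calls).astype(np.int8)
        present = np.where(rng.random(present.shape) < params.missing_rate, 0, present).astype(np.uint8)

    gm = GenotypeMatrix(loci, samples, calls)
    tags = TagPresenceMatrix(loci.copy(), samples, present)
    truth = TruthLabels(classes, hap, seed=params.seed, system=params.system)
    return gm, tags, truth


def sample_sheet_for(gm: GenotypeMatrix) -> SampleSheet:
    """Sample sheet implied by the simulator's M*/F* sample naming."""
    sex = np.array(["M" if str(s).startswith("M") else "F" for s in gm.samples], dtype=object)
    return SampleSheet(gm.samples.copy(), sex)


# ---------------------------------------------------------------------------
# sampling designs for the subsample diagnostics experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplingDesign:
    """A subsampling design: sample counts per sex, optionally split by
    Y haplotype for the heterogametic sex."""

    name: str
    n_males: int
    n_females: int
    males_per_haplotype: tuple[int, ...] | None = None


def scenario_catalog() -> list[SamplingDesign]:
    """The standard diagnostics designs: a balanced series from 19/19
    down to 5/5, a male skew (18 M, 9 F), a female skew (9 M, 18 F),
    and a two-Y-haplotype design (6 M hap1 + 6 M hap2 + 12 F)."""
    designs = [SamplingDesign(f"balanced_{k}_{k}", k, k) for k in range(19, 4, -1)]
    designs.append(SamplingDesign("male_skew_18_9", 18, 9))
    designs.append(SamplingDesign("female_skew_9_18", 9, 18))
    designs.append(SamplingDesign("two_haplotypes_6_6_12", 12, 12, males_per_haplotype=(6, 6)))
    return designs


# ---------------------------------------------------------------------------
# chromosome placement and alignment-hit simulation
# ---------------------------------------------------------------------------


def chromosome_names(n: int = 13) -> list[str]:
    return [f"Chr{i:02d}" for i in range(1, n + 1)]


def assign_chromosomes(
    truth: TruthLabels,
    sex_chromosome: str = "Chr05",
    n_chromosomes: int = 13,
    seed: int = 0,
) -> np.ndarray:
    """Place loci on a toy karyotype: sex-linked classes on
    ``sex_chromosome``, autosomal loci uniformly on the others."""
    rng = np.random.default_rng(seed)
    chroms = chromosome_names(n_chromosomes)
    if sex_chromosome not in chroms:
        raise ValueError(f"{sex_chromosome} not among {n_chromosomes} chromosomes")
    others = [c for c in chroms if c != sex_chromosome]
    out = np.empty(len(truth.locus_class), dtype=object)
    sexlinked = truth.locus_class != "autosomal"
    out[sexlinked] = sex_chromosome
    out[~sexlinked] = rng.choice(others, size=int((~sexlinked).sum()))
    return out


def simulate_alignment_hits(
    loci: Sequence[str],
    chrom_of: Sequence[str],
    mappable_fraction: float = 1.0,
    scaffolds_per_chrom: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Emit one strong BLAST-style hit per mappable locus to a scaffold
    of its true chromosome, plus the scaffold->chromosome map."""
    from sexlinkage.genotype_io import BLAST6_COLUMNS

    rng = np.random.default_rng(seed)
    chroms = sorted(set(chrom_of))
    scaffold_map: dict[str, str] = {}
    scaffolds_by_chrom: dict[str, list[str]] = {}
    for c in chroms:
        names = [f"scaf_{c}_{j}" for j in range(scaffolds_per_chrom)]
        scaffolds_by_chrom[c] = names
        for s in names:
            scaffold_map[s] = c
    rows = []
    for locus, chrom in zip(loci, chrom_of):
        if rng.random() > mappable_fraction:
            continue
        scaf = scaffolds_by_chrom[chrom][rng.integers(0, scaffolds_per_chrom)]
        start = int(rng.integers(1, 100000))
        rows.append((locus, scaf, 100.0, 92, 0, 0, 1, 92, start, start + 91, 1e-30, 180.0))
    hits = pd.DataFrame(rows, columns=BLAST6_COLUMNS)
    return hits, scaffold_map


# ---------------------------------------------------------------------------
# trees and character histories
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, root_age: float = 10.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree rescaled so every tip is ``root_age`` Myr
    from the root (ultrametric by construction)."""
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = np.random.default_rng(seed)

    # forward Yule simulation: split a random active lineage at each event
    birth_times = [0.0, 0.0]  # two root children exist at time 0
    parents = [-1, -1]
    t = 0.0
    active = [0, 1]
    nodes = 2
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        split = active[rng.integers(0, len(active))]
        for _ in range(2):
            birth_times.append(t)
            parents.append(split)
            active.append(nodes)
            nodes += 1
        active.remove(split)
    t_end = t + rng.exponential(1.0 / len(active))
    scale = root_age / t_end

    # build newick bottom-up
    children: dict[int, list[int]] = {}
    for i, p in enumerate(parents):
        children.setdefault(p, []).append(i)
    tip_counter = [0]

    def render(node: int) -> str:
        start = birth_times[node] * scale
        if node in children:
            kids = children[node]
            end = birth_times[kids[0]] * scale
            inner = ",".join(render(k) for k in kids)
            return f"({inner}):{end - start:.12f}"
        tip_counter[0] += 1
        return f"t{tip_counter[0]}:{root_age - start:.12f}"

    newick = "(" + ",".join(render(c) for c in children[-1]) + "):0.0;"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    label_internal_nodes(tree)
    return tree


def label_internal_nodes(tree: dendropy.Tree) -> None:
    """Give every unlabelled internal node a stable ``nd<k>`` label
    (preorder numbering)."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.label is None:
            node.label = f"nd{k}"
        k += 1


def validate_rate_matrix(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < 0).any():
        raise ValueError("off-diagonal rates must be >= 0")
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-8):
        raise ValueError("rows of Q must sum to 0")
    return Q


def simulate_states_on_tree(
    tree: dendropy.Tree,
    Q: np.ndarray,
    root_state: int,
    seed: int = 0,
) -> tuple[dict[str, int], list[dict]]:
    """Forward continuous-time Markov simulation of a discrete character.

    Returns the tip states (by taxon label) and the full list of
    transition events, each as a dict with keys ``branch`` (label of
    the child node the branch leads to), ``time`` (Myr from the start
    of the branch), ``from_state`` and ``to_state``.
    """
    Q = validate_rate_matrix(Q)
    K = Q.shape[0]
    if not 0 <= root_state < K:
        raise ValueError("root_state out of range")
    rng = np.random.default_rng(seed)
    label_internal_nodes(tree)

    tip_states: dict[str, int] = {}
    events: list[dict] = []
    state_at: dict = {tree.seed_node: root_state}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        state = state_at[node.parent_node]
        t, blen = 0.0, node.edge.length or 0.0
        while True:
            rate = -Q[state, state]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= blen:
                break
            probs = np.clip(Q[state], 0.0, None)
            probs[state] = 0.0
            new_state = rng.choice(K, p=probs / probs.sum())
            events.append(
                {
                    "branch": node.taxon.label if node.is_leaf() else node.label,
                    "time": t,
                    "from_state": state,
                    "to_state": int(new_state),
                }
            )
            state = int(new_state)
        state_at[node] = state
        if node.is_leaf():
            tip_states[node.taxon.label] = state
    return tip_states, events
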