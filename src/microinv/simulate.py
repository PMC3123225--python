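"""Synthetic alignments with planted microinversions.

The generator runs the analysis' own rate model forward: sequences
evolve down a dated tree, and each branch of length *t* MY receives
``Poisson(lambda_mi * L_Mb * t)`` inversion events at uniform
positions, each applied as the reverse complement of the affected
tract.  Substitutions (single-parameter equal-rates model) and small
indels accumulate alongside.  Optional gamma-distributed per-locus
rate multipliers (shape ``hotspot_k``, mean 1) create hotspot loci
whose marginal counts are negative binomial — the alternative the
rate module's LRT is built to detect.

Homology is tracked explicitly: every residue carries a column id, so
leaf sequences assemble into a truth-aware alignment without any
re-alignment step, and every planted event is recorded in a
:class:`TruthRegistry` with its branch, tract and realized carriers.
Inversions preserve column ids (the tract still aligns positionally
against the uninverted homologs, which is exactly the signature the
detection stage looks for); only indels create or remove columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .detect import reverse_complement
from .io import Alignment, LocusRecord, Phylo, ValidationError

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def default_inversion_lengths() -> tuple[np.ndarray, np.ndarray]:
    """Discrete triangular distribution on [5, 40] bp peaked at 22.

    Matches the observed avian size spectrum: minimum 5 bp, maximum
    below ~40 bp, median ~22 bp.
    """
    lengths = np.arange(5, 41)
    peak = 22.0
    w = np.where(lengths <= peak, lengths - 4.0, 41.0 - lengths)
    return lengths, w / w.sum()


@dataclass
class SimParams:
    """Study-condition knobs for the generator.

    Rates are per MY; ``subst_rate`` is substitutions/site/MY (default
    1.5e-3, a typical avian neutral rate), ``lambda_mi`` is
    inversions/Mb/MY (default 0.39, the pooled avian estimate).
    ``hotspot_k`` switches on gamma rate multipliers across loci.
    """

    seed: int = 0
    n_taxa: int = 20
    birth_rate: float = 0.01          # per MY, for Yule trees
    locus_length: int = 1000          # bp at the root
    subst_rate: float = 1.5e-3
    indel_rate: float = 0.0           # events/site/MY
    indel_mean_length: float = 3.0    # geometric mean length
    lambda_mi: float = 0.39
    hotspot_k: float | None = None
    inv_lengths: tuple = field(default_factory=default_inversion_lengths)

    def __post_init__(self) -> None:
        for name in ("subst_rate", "indel_rate", "lambda_mi"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lengths, _ = self.inv_lengths
        if int(np.min(lengths)) < 5:
            raise ValidationError("inversion length floor is 5 bp")


@dataclass
class PlantedInversion:
    """Ground truth for one planted event."""

    locus_id: str
    branch: str                  # label of the edge's child node
    start: int                   # ungapped position at time of event
    length: int
    carriers: frozenset[str]     # leaves descending from the branch
    column_ids: tuple[int, ...]  # homology columns of the inverted tract


@dataclass
class TruthRegistry:
    """All planted events for one locus plus its realized rate multiplier."""

    locus_id: str
    events: list[PlantedInversion] = field(default_factory=list)
    rate_multiplier: float = 1.0
    #: homology-column ids in alignment column order (set by simulate_locus)
    alignment_columns: tuple[int, ...] = ()

    def event_columns(self, event: PlantedInversion) -> tuple[int, int]:
        """Alignment-column span [first, last) of a planted event."""
        pos = {cid: i for i, cid in enumerate(self.alignment_columns)}
        cols = [pos[cid] for cid in event.column_ids if cid in pos]
        if not cols:
            raise ValidationError("event columns deleted in every leaf")
        return min(cols), max(cols) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "locus": e.locus_id, "branch": e.branch, "start": e.start,
            "length": e.length, "carriers": ",".join(sorted(e.carriers)),
        } for e in self.events])


def write_truth_table(registries: Sequence[TruthRegistry], path) -> None:
    frames = [r.to_frame() for r in registries if r.events]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["locus", "branch", "start", "length",
                                     "carriers"]))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def yule_tree(n_taxa: int, birth_rate: float, seed: int) -> Phylo:
    """A random Yule (pure-birth) tree with branch lengths in MY."""
    import random
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_taxa,
        rng=random.Random(seed))
    tree.is_rooted = True
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i}"
    return Phylo(tree)


def _label_nodes(phylo: Phylo) -> None:
    """Give internal nodes stable labels n0, n1, ... in preorder."""
    i = 0
    for node in phylo.tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            node.label = f"n{i}"
            i += 1


def _node_name(node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


# ---------------------------------------------------------------------------
# per-locus simulation
# ---------------------------------------------------------------------------

class _Lineage:
    """A sequence plus the homology-column id of each residue."""

    __slots__ = ("residues", "ids")

    def __init__(self, residues: list[str], ids: list[int]):
        self.residues = residues
        self.ids = ids

    def copy(self) -> "_Lineage":
        return _Lineage(list(self.residues), list(self.ids))


class _ColumnOrder:
    """Global ordering of homology-column ids across all lineages.

    Every lineage's id list is a subsequence of this master order, so
    inserting new ids immediately after their left neighbour keeps the
    invariant and makes the final alignment assembly a simple lookup.
    """

    def __init__(self, n: int):
        self.order = list(range(n))
        self.next_id = n

    def new_ids(self, count: int, after_id: int | None) -> list[int]:
        ids = list(range(self.next_id, self.next_id + count))
        self.next_id += count
        pos = 0 if after_id is None else self.order.index(after_id) + 1
        self.order[pos:pos] = ids
        return ids

    def rank(self) -> dict[int, int]:
        return {cid: i for i, cid in enumerate(self.order)}


def _rng_for_locus(seed: int, locus_index: int) -> np.random.Generator:
    """Per-locus substream, reproducible independently of run order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(locus_index,)))


def _sample_inv_length(params: SimParams, rng) -> int:
    lengths, probs = params.inv_lengths
    return int(rng.choice(lengths, p=probs))


def _evolve_branch(lin: _Lineage, t: float, params: SimParams,
                   rate_mult: float, rng, order: _ColumnOrder,
                   events_out: list[tuple[int, int, tuple[int, ...]]]) -> None:
    """Apply substitutions, indels and inversions along one branch."""
    L = len(lin.residues)
    if L == 0 or t <= 0:
        return
    # substitutions
    n_sub = rng.poisson(params.subst_rate * L * t)
    for pos in rng.integers(0, len(lin.residues), size=n_sub):
        if not lin.residues:
            break
        pos = int(pos) % len(lin.residues)
        cur = lin.residues[pos]
        choices = [b for b in "ACGT" if b != cur]
        lin.residues[pos] = choices[int(rng.integers(0, 3))]
    # indels
    n_indel = rng.poisson(params.indel_rate * L * t)
    for _ in range(n_indel):
        if not lin.residues:
            break
        length = int(rng.geometric(1.0 / params.indel_mean_length))
        if rng.random() < 0.5 and len(lin.residues) > length:  # deletion
            start = int(rng.integers(0, len(lin.residues) - length + 1))
            del lin.residues[start:start + length]
            del lin.ids[start:start + length]
        else:  # insertion
            start = int(rng.integers(0, len(lin.residues) + 1))
            after = lin.ids[start - 1] if start > 0 else None
            new = order.new_ids(length, after)
            lin.residues[start:start] = list(
                _BASES[rng.integers(0, 4, size=length)])
            lin.ids[start:start] = new
    # inversions: Poisson with exposure L_Mb * t, optionally hotspot-scaled
    mean_inv = params.lambda_mi * rate_mult * (len(lin.residues) / 1e6) * t
    n_inv = rng.poisson(mean_inv)
    for _ in range(n_inv):
        for _attempt in range(100):
            length = _sample_inv_length(params, rng)
            if length <= len(lin.residues):
                break
            logger.info("resampling inversion longer than sequence")
        else:
            continue
        start = int(rng.integers(0, len(lin.residues) - length + 1))
        seg = "".join(lin.residues[start:start + length])
        lin.residues[start:start + length] = list(reverse_complement(seg))
        # column ids stay put: the tract still aligns positionally
        events_out.append((start, length,
                           tuple(lin.ids[start:start + length])))


def simulate_locus(params: SimParams, tree: Phylo,
                   locus_id: str = "locus0", locus_index: int = 0,
                   rate_multiplier: float = 1.0,
                   rng: np.random.Generator | None = None
                   ) -> tuple[Alignment, TruthRegistry]:
    """Evolve one locus down ``tree`` and return (alignment, truth).

    The root sequence is uniform random; each branch receives
    substitutions, optional indels, and Poisson inversions recorded in
    the registry with their realized carrier leaves.
    """
    tree.require_positive_treelength()
    _label_nodes(tree)
    rng = rng if rng is not None else _rng_for_locus(params.seed, locus_index)
    registry = TruthRegistry(locus_id, rate_multiplier=rate_multiplier)

    L = params.locus_length
    order = _ColumnOrder(L)
    root_lin = _Lineage(list(_BASES[rng.integers(0, 4, size=L)]),
                        list(range(L)))

    lineages: dict[object, _Lineage] = {tree.tree.seed_node: root_lin}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        lin = lineages[node.parent_node].copy()
        branch_events: list[tuple[int, int, tuple[int, ...]]] = []
        _evolve_branch(lin, node.edge.length or 0.0, params,
                       rate_multiplier, rng, order, branch_events)
        if branch_events:
            carriers = frozenset(lf.taxon.label for lf in node.leaf_iter())
            for start, length, ids in branch_events:
                registry.events.append(PlantedInversion(
                    locus_id, _node_name(node), start, length, carriers, ids))
        lineages[node] = lin

    # assemble the truth-aware alignment
    leaves = [lf for lf in tree.tree.leaf_node_iter()]
    present: set[int] = set()
    for lf in leaves:
        present.update(lineages[lf].ids)
    columns = [cid for cid in order.order if cid in present]
    col_pos = {cid: i for i, cid in enumerate(columns)}
    rows = []
    for lf in leaves:
        row = ["-"] * len(columns)
        lin = lineages[lf]
        for res, cid in zip(lin.residues, lin.ids):
            row[col_pos[cid]] = res
        rows.append("".join(row))
    aln = Alignment(locus_id, [lf.taxon.label for lf in leaves], rows)
    registry.alignment_columns = tuple(columns)
    return aln, registry


# ---------------------------------------------------------------------------
# study-level simulation
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Everything one simulated survey produces."""

    locus_table: list[LocusRecord]
    alignments: list[Alignment]
    registries: list[TruthRegistry]
    tree: Phylo

    def locus_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus": [r.locus_id for r in self.locus_table],
            "mean_noncoding_length_bp": [r.mean_noncoding_length
                                         for r in self.locus_table],
            "treelength_my": [r.treelength for r in self.locus_table],
            "inversion_count": [r.inversion_count for r in self.locus_table],
        })


def simulate_study(params: SimParams, n_loci: int,
                   tree: Phylo | None = None,
                   locus_lengths: Sequence[int] | None = None) -> StudyResult:
    """Simulate a multi-locus survey with optional hotspot heterogeneity.

    Per-locus rate multipliers are gamma(shape=k, mean 1) when
    ``hotspot_k`` is set (marginal counts negative binomial), else 1.
    The emitted locus table carries the *true* planted counts, so it
    feeds the rate module directly for round-trip checks.
    """
    if n_loci < 1:
        raise ValidationError("n_loci must be >= 1")
    if tree is None:
        tree = yule_tree(params.n_taxa, params.birth_rate, params.seed)
    tree.require_positive_treelength()
    treelength = tree.treelength

    mult_rng = _rng_for_locus(params.seed, 2 ** 20)  # dedicated substream
    records, alignments, registries = [], [], []
    for i in range(n_loci):
        L = int(locus_lengths[i]) if locus_lengths is not None else params.locus_length
        p = replace(params, locus_length=L)
        mult = (float(mult_rng.gamma(params.hotspot_k,
                                     1.0 / params.hotspot_k))
                if params.hotspot_k else 1.0)
        locus_id = f"locus{i}"
        aln, reg = simulate_locus(p, tree, locus_id=locus_id, locus_index=i,
                                  rate_multiplier=mult)
        records.append(LocusRecord(locus_id, float(L), treelength,
                                   len(reg.events)))
        alignments.append(aln)
        registries.append(reg)
    return StudyResult(records, alignments, registries, tree)


# ---------------------------------------------------------------------------
# deterministic planted scenarios
# ---------------------------------------------------------------------------

SCENARIOS = ("clade", "homoplastic_pair", "overlapping_typeI",
             "overlapping_typeII")


def _internal_edges(tree: Phylo):
    root = tree.tree.seed_node
    out = []
    for node in tree.tree.preorder_node_iter():
        if node is root or node.is_leaf():
            continue
        out.append(node)
    return out


def _independent_pair(tree: Phylo):
    """Two non-sister leaf branches: independent events in divergent lineages.

    Using leaves keeps the combined carrier set a small proper subset
    of the taxa, so the resulting character is parsimony-informative.
    """
    leaves = list(tree.tree.leaf_node_iter())
    for a in leaves:
        for b in leaves:
            if b is not a and b.parent_node is not a.parent_node:
                return a, b
    raise ValidationError("tree too small for independent event pair")


def plant_scenario(name: str, tree: Phylo, params: SimParams
                   ) -> tuple[Alignment, TruthRegistry]:
    """Deterministic 1-2 event placements for the canonical cases.

    clade: one event on an internal branch (single origin, RI = 1).
    homoplastic_pair: the same tract inverted independently on two
    branches (two origins, homoplasy).  overlapping_typeI: partially
    overlapping tracts on different branches.  overlapping_typeII:
    nested tracts on different branches.  Multiple events on one
    branch (type III) are deliberately not generated: the detection
    strategy cannot separate them.
    """
    if name not in SCENARIOS:
        raise ValidationError(f"unknown scenario {name!r}; one of {SCENARIOS}")
    clean = replace(params, subst_rate=0.0, indel_rate=0.0, lambda_mi=0.0)
    _label_nodes(tree)
    rng = _rng_for_locus(params.seed, 0)
    aln, registry = simulate_locus(clean, tree, locus_id=name, rng=rng)

    L = aln.n_cols
    mid = L // 2
    if name == "clade":
        targets = [(_pick_clade_node(tree), mid, 24)]
    elif name == "homoplastic_pair":
        a, b = _independent_pair(tree)
        targets = [(a, mid, 24), (b, mid, 24)]
    elif name == "overlapping_typeI":
        a, b = _independent_pair(tree)
        targets = [(a, mid, 24), (b, mid + 12, 24)]
    else:  # overlapping_typeII: nested
        a, b = _independent_pair(tree)
        targets = [(a, mid, 36), (b, mid + 8, 12)]
    if any(start + length > L for _, start, length in targets):
        raise ValidationError("locus too short for the requested scenario")

    rows = {t: list(r) for t, r in zip(aln.taxa, aln.rows)}
    for node, start, length in targets:
        carriers = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if carriers >= set(aln.taxa):
            raise ValidationError("scenario branch covers all taxa")
        for t in carriers:
            seg = "".join(rows[t][start:start + length])
            rows[t][start:start + length] = list(reverse_complement(seg))
        registry.events.append(PlantedInversion(
            name, _node_name(node), start, length, carriers,
            tuple(range(start, start + length))))
    out = Alignment(name, list(aln.taxa), ["".join(rows[t]) for t in aln.taxa])
    return out, registry


def _pick_clade_node(tree: Phylo):
    all_leaves = set(lf.taxon.label for lf in tree.tree.leaf_node_iter())
    for node in _internal_edges(tree):
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        if 2 <= len(leaves) < len(all_leaves):
            return node
    raise ValidationError("tree has no internal branch with a proper clade")
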