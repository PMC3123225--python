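"""Binary inversion characters on a phylogeny.

Each called microinversion becomes a presence/absence character
(1 = inverted orientation).  Minimum change counts use Fitch parsimony
in its Sankoff/Hartigan form, which handles multifurcations and
missing states directly; counting treats the tree as unrooted (for a
symmetric two-state character the rooted Sankoff minimum equals the
unrooted Fitch minimum), while the input root is kept for reporting
polarity and branch placements.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import Phylo, ValidationError

logger = logging.getLogger(__name__)

MISSING = -1
_INF = float("inf")


# ---------------------------------------------------------------------------
# character matrix
# ---------------------------------------------------------------------------

@dataclass
class CharacterMatrix:
    """Taxa x binary characters, states in {0, 1, missing}."""

    taxa: list[str]
    character_ids: list[str]
    #: shape (n_taxa, n_characters), values 0/1/MISSING
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.shape != (len(self.taxa), len(self.character_ids)):
            raise ValidationError("state matrix shape does not match labels")

    def column(self, i: int) -> dict[str, int]:
        """States for character ``i`` as taxon -> {0,1}; missing omitted."""
        return {t: int(s) for t, s in zip(self.taxa, self.states[:, i])
                if s != MISSING}

    def state_symbol(self, taxon: str, i: int) -> str:
        s = self.states[self.taxa.index(taxon), i]
        return "?" if s == MISSING else str(int(s))


def encode_characters(calls: Sequence, taxa: Sequence[str],
                      locus_taxa: Mapping[str, set[str]] | None = None
                      ) -> CharacterMatrix:
    """Code inversion calls as binary characters over ``taxa``.

    Carriers get state 1, taxa sampled at the call's locus get 0, taxa
    absent from that locus get '?'.  A call whose carriers cover every
    sampled taxon has no polarity information and is skipped (logged).
    """
    taxa = list(taxa)
    taxon_set = set(taxa)
    cols, ids = [], []
    for k, call in enumerate(calls):
        carriers = set(call.carrier_taxa)
        if not carriers <= taxon_set:
            raise ValidationError(
                f"call {call.locus_id}:{call.msa_interval} has carriers "
                f"outside the taxon set: {sorted(carriers - taxon_set)}")
        present = (set(locus_taxa[call.locus_id]) if locus_taxa else taxon_set)
        if carriers >= present & taxon_set:
            logger.warning("call %s:%s carried by all sampled taxa; "
                           "uninformative about polarity, skipped",
                           call.locus_id, call.msa_interval)
            continue
        col = [1 if t in carriers else (0 if t in present else MISSING)
               for t in taxa]
        cols.append(col)
        ids.append(f"{call.locus_id}:{call.msa_interval[0] + 1}-{call.msa_interval[1]}")
    states = (np.array(cols, dtype=int).T if cols
              else np.empty((len(taxa), 0), dtype=int))
    return CharacterMatrix(taxa, ids, states)


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def _subtree_costs(phylo: Phylo, states: Mapping[str, int]
                   ) -> dict[object, tuple[float, float]]:
    """Sankoff: per node, min changes below it given node state 0 / 1.

    Leaves without an entry in ``states`` (missing '?') cost 0 either
    way, i.e. they can take any state.
    """
    tree = phylo.tree
    leaf_labels = set(lf.taxon.label for lf in tree.leaf_node_iter())
    unknown = set(states) - leaf_labels
    if unknown:
        raise ValidationError(f"character taxa not in tree: {sorted(unknown)}")
    observed = [s for s in states.values()]
    if len(observed) < 2:
        raise ValidationError("need non-missing states at >=2 leaves")

    cost: dict[object, tuple[float, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states.get(node.taxon.label, MISSING)
            if s == MISSING:
                cost[node] = (0.0, 0.0)
            else:
                cost[node] = (0.0, _INF) if s == 0 else (_INF, 0.0)
        else:
            c0 = c1 = 0.0
            for ch in node.child_nodes():
                ch0, ch1 = cost[ch]
                c0 += min(ch0, ch1 + 1)
                c1 += min(ch0 + 1, ch1)
            cost[node] = (c0, c1)
    return cost


def fitch_count(phylo: Phylo, states: Mapping[str, int]) -> int:
    """Minimum number of state changes of a binary character on the tree."""
    cost = _subtree_costs(phylo, states)
    return int(min(cost[phylo.tree.seed_node]))


@dataclass
class Placement:
    """A state change assigned to one branch (identified by its child)."""

    child_label: str
    from_state: int
    to_state: int
    terminal: bool


@dataclass
class ParsimonyResult:
    """Parsimony summary for one character: s, g, m, placements, RI."""

    character_id: str
    min_changes: int          # s
    max_changes: int          # g: worst case on a star tree
    min_possible: int = 1     # m: 1 for any variable binary character
    placements: list[Placement] = field(default_factory=list)
    terminal_changes: int = 0
    ambiguous: bool = False   # DELTRAN and ACCTRAN placements differ

    @property
    def retention_index(self) -> float:
        g, s, m = self.max_changes, self.min_changes, self.min_possible
        if g == m:
            raise ValidationError(
                f"{self.character_id}: parsimony-uninformative (g == m)")
        return (g - s) / (g - m)


def _node_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return "{" + ",".join(leaves) + "}"


def assign_branches(phylo: Phylo, states: Mapping[str, int],
                    resolution: str = "deltran"):
    """Place the minimum-change events on branches.

    ``deltran`` delays changes toward the tips, ``acctran`` accelerates
    them toward the root; with ``both`` a dict of the two is returned.
    Either way the placement count equals :func:`fitch_count`.  Ties at
    the root prefer state 0 (ancestrally non-inverted).
    """
    if resolution == "both":
        return {r: assign_branches(phylo, states, r)
                for r in ("deltran", "acctran")}
    if resolution not in ("deltran", "acctran"):
        raise ValueError(f"unknown resolution {resolution!r}")

    cost = _subtree_costs(phylo, states)
    tree = phylo.tree
    root = tree.seed_node
    r0, r1 = cost[root]
    root_state = 0 if r0 <= r1 else 1

    assigned: dict[object, int] = {root: root_state}
    placements: list[Placement] = []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        p = assigned[node.parent_node]
        c0, c1 = cost[node]
        total_keep = (c0, c1)[p]
        total_flip = (c0, c1)[1 - p] + 1
        if total_keep < total_flip:
            s = p
        elif total_flip < total_keep:
            s = 1 - p
        else:  # tie: both resolutions are minimum-change
            s = p if resolution == "deltran" else 1 - p
        assigned[node] = s
        if s != p:
            placements.append(Placement(_node_label(node), p, s,
                                        terminal=node.is_leaf()))
    return placements


def parsimony_analysis(phylo: Phylo, matrix: CharacterMatrix,
                       resolution: str = "deltran") -> list[ParsimonyResult]:
    """Per-character change counts, placements and ambiguity flags."""
    results = []
    for i, cid in enumerate(matrix.character_ids):
        states = matrix.column(i)
        n1 = sum(1 for v in states.values() if v == 1)
        n0 = len(states) - n1
        if n0 == 0 or n1 == 0:
            raise ValidationError(f"{cid}: character is not variable")
        s = fitch_count(phylo, states)
        g = min(n0, n1)
        deltran = assign_branches(phylo, states, "deltran")
        acctran = assign_branches(phylo, states, "acctran")
        chosen = deltran if resolution == "deltran" else acctran
        ambiguous = ({(p.child_label, p.to_state) for p in deltran}
                     != {(p.child_label, p.to_state) for p in acctran})
        results.append(ParsimonyResult(
            character_id=cid, min_changes=s, max_changes=g,
            placements=chosen,
            terminal_changes=sum(p.terminal for p in chosen),
            ambiguous=ambiguous))
    return results


def retention_index(results: Sequence[ParsimonyResult]
                    ) -> tuple[float, dict[str, float]]:
    """Ensemble and per-character retention indices.

    RI = (g - s)/(g - m) per character; the ensemble sums g, s, m over
    parsimony-informative characters.  Uninformative characters
    (g == m) are excluded and logged.
    """
    per_char: dict[str, float] = {}
    G = S = M = 0
    for r in results:
        if r.max_changes == r.min_possible:
            logger.info("%s: parsimony-uninformative, excluded from ensemble RI",
                        r.character_id)
            continue
        per_char[r.character_id] = r.retention_index
        G += r.max_changes
        S += r.min_changes
        M += r.min_possible
    if G == M:
        raise ValidationError("no parsimony-informative characters")
    return (G - S) / (G - M), per_char


# ---------------------------------------------------------------------------
# terminal bias
# ---------------------------------------------------------------------------

@dataclass
class TerminalBiasTest:
    """Goodness-of-fit of the observed terminal/internal event split."""

    observed_terminal: int
    total_events: int
    terminal_fraction: float
    chi2: float
    p: float


def terminal_bias_test(observed_terminal: int, total: int,
                       terminal_fraction: float) -> TerminalBiasTest:
    """One-df chi-square test of events vs branch-length expectation.

    Under a uniform Poisson process, events split between terminal and
    internal branches in proportion to their share of the treelength.
    """
    if total < 1:
        raise ValidationError("need at least one event")
    if not 0.0 < terminal_fraction < 1.0:
        raise ValidationError("terminal_fraction must be in (0, 1)")
    if not 0 <= observed_terminal <= total:
        raise ValidationError("observed_terminal must be within [0, total]")
    exp_t = total * terminal_fraction
    exp_i = total * (1.0 - terminal_fraction)
    obs_i = total - observed_terminal
    chi2 = (observed_terminal - exp_t) ** 2 / exp_t + (obs_i - exp_i) ** 2 / exp_i
    p = float(stats.chi2.sf(chi2, df=1))
    return TerminalBiasTest(observed_terminal, total, terminal_fraction,
                            float(chi2), p)
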