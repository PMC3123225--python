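"""Microinversion detection in gapped multiple sequence alignments.

An inverted segment in one lineage shows up as a high-identity *local
alignment between one sequence and the reverse complement of another*.
The scanner therefore runs strand-aware Smith-Waterman over all
unordered taxon pairs, projects each hit back to alignment columns,
clusters nearby hits into candidate regions, and validates each
candidate by re-inversion: flipping the segment in the putative
carriers must raise their identity to the non-carriers.

Palindromic segments are their own reverse complement and produce
spurious complementary-strand hits in *every* pair; they are flagged
and rejected rather than called.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .io import Alignment

logger = logging.getLogger(__name__)

_GAP = "-"
_MASK = "X"
_ALPHABET = "ACGTNRYSWKMBDHV" + _MASK


class UncallableRegionError(ValueError):
    """A candidate region cannot be validated (e.g. all-gap in carriers)."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class ScanParams:
    """Scoring and filtering thresholds for the complementary-strand scan.

    The 5 bp floor on hit/call length reflects the practical limit
    below which inversions cannot be told apart from point mutations;
    the 400 bp ceiling keeps calls within a single sequencing read.
    """

    match_score: float = 1.0
    mismatch_score: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_hit_len: int = 5
    max_inv_len: int = 400
    min_identity: float = 0.75
    min_score: float = 8.0
    cluster_gap: int = 10
    #: hits whose projected endpoints differ by <= this many columns are
    #: treated as supporting the same inversion event
    endpoint_tol: int = 5
    #: identity gain required to promote a candidate to `validated`
    delta_threshold: float = 0.1
    max_hits_per_pair: int = 50

    def __post_init__(self) -> None:
        if self.min_hit_len < 5:
            raise ValueError("min_hit_len must be >= 5 (validation floor)")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an *ungapped* nucleotide string.

    IUPAC ambiguity codes are complemented to their complements
    (R<->Y, K<->M, B<->V, D<->H; S, W, N are self-complementary).
    """
    if _GAP in seq:
        raise ValueError("reverse_complement requires a degapped sequence")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CoordMap:
    """Bidirectional map between alignment columns and ungapped positions."""

    #: alignment column of each ungapped residue (strictly increasing)
    col_of_res: np.ndarray
    #: ungapped index of each column, -1 at gap columns
    res_of_col: np.ndarray

    @classmethod
    def from_row(cls, row: str) -> "CoordMap":
        arr = np.frombuffer(row.encode(), dtype="S1")
        is_res = arr != b"-"
        col_of_res = np.nonzero(is_res)[0]
        res_of_col = np.full(len(row), -1, dtype=int)
        res_of_col[is_res] = np.arange(is_res.sum())
        return cls(col_of_res, res_of_col)

    def to_columns(self, interval: tuple[int, int]) -> tuple[int, int]:
        """Ungapped [s, e) -> spanned alignment columns [first, last)."""
        s, e = interval
        if e <= s:
            raise ValueError(f"empty interval {interval!r}")
        return int(self.col_of_res[s]), int(self.col_of_res[e - 1]) + 1


def degap(row: str) -> str:
    return row.replace(_GAP, "")


def _build_matrix(params: ScanParams) -> Align.substitution_matrices.Array:
    m = Align.substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a == _MASK or b == _MASK:
                m[a, b] = -1000.0
            elif a == b and a in "ACGT":
                m[a, b] = params.match_score
            else:
                # N / ambiguity codes score as mismatches: conservative,
                # avoids false complementary hits through runs of Ns
                m[a, b] = params.mismatch_score
    return m


def _make_aligner(params: ScanParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _build_matrix(params)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    if mode == "global":
        # validation identities should not pay for length differences at the ends
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def _sanitize(seq: str) -> str:
    return "".join(c if c in _ALPHABET and c != _MASK else "N" for c in seq)


def _alignment_identity(alignment) -> float:
    c = alignment.counts()
    span = c.gaps + c.identities + c.mismatches
    return c.identities / span if span else 0.0


def segment_identity(a: str, b: str, params: ScanParams | None = None) -> float:
    """Identity of two ungapped segments under end-gap-free global alignment."""
    if not a or not b:
        return 0.0
    params = params or ScanParams()
    aligner = _make_aligner(params, "global")
    try:
        aln = next(iter(aligner.align(a, b)))
    except StopIteration:  # pragma: no cover
        return 0.0
    return _alignment_identity(aln)


# ---------------------------------------------------------------------------
# pairwise complementary-strand alignment
# ---------------------------------------------------------------------------

@dataclass
class LocalHit:
    """One local alignment of a vs reverse_complement(b), in ungapped coords.

    ``b_interval`` is reported on b's forward strand.
    """

    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    score: float
    identity: float


def pairwise_revcomp_align(a: str, b: str, params: ScanParams | None = None
                           ) -> list[LocalHit]:
    """All non-overlapping local alignments of ``a`` against revcomp(``b``).

    Hits are found greedily best-first; after each acceptance the
    matched stretch of the reverse-complemented ``b`` is masked so the
    next-best non-overlapping hit surfaces.  Hits must clear
    ``min_score``, ``min_hit_len`` aligned span and ``min_identity``.
    """
    params = params or ScanParams()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a = _sanitize(a.upper())
    b_len = len(b)
    b_rc = list(reverse_complement(_sanitize(b.upper())))
    aligner = _make_aligner(params, "local")

    hits: list[LocalHit] = []
    for _ in range(params.max_hits_per_pair):
        target = "".join(b_rc)
        try:
            best = next(iter(aligner.align(a, target)))
        except StopIteration:
            break
        if best.score < params.min_score:
            break
        coords = best.coordinates
        a_s, a_e = int(coords[0][0]), int(coords[0][-1])
        r_s, r_e = int(coords[1][0]), int(coords[1][-1])
        # mask regardless of acceptance so the loop always progresses
        for i in range(r_s, r_e):
            b_rc[i] = _MASK
        if a_e - a_s < params.min_hit_len or r_e - r_s < params.min_hit_len:
            continue
        identity = _alignment_identity(best)
        if identity < params.min_identity:
            continue
        # revcomp coords -> forward strand of b
        hits.append(LocalHit(a_interval=(a_s, a_e),
                             b_interval=(b_len - r_e, b_len - r_s),
                             score=float(best.score), identity=identity))
    hits.sort(key=lambda h: h.a_interval)
    return hits


# ---------------------------------------------------------------------------
# alignment-wide scan
# ---------------------------------------------------------------------------

@dataclass
class RevCompHit:
    """A pairwise complementary-strand hit projected to alignment columns."""

    query_taxon: str
    subject_taxon: str
    query_interval: tuple[int, int]    # ungapped on query
    subject_interval: tuple[int, int]  # ungapped, forward strand of subject
    score: float
    identity: float
    msa_interval: tuple[int, int]      # [first, last) columns
    overlap_mark: int | None = None


def scan_alignment(aln: Alignment, params: ScanParams | None = None
                   ) -> list[RevCompHit]:
    """Complementary-strand scan over all unordered taxon pairs.

    Returns the "overlap table": hits sorted by alignment-column start,
    with hits from different pairs that overlap (or fall within
    ``cluster_gap`` columns) sharing an ``overlap_mark``.
    """
    params = params or ScanParams()
    if aln.n_taxa < 2:
        raise ValueError("scan requires >=2 taxa")
    coord_maps = {t: CoordMap.from_row(aln.row(t)) for t in aln.taxa}
    degapped = {t: degap(aln.row(t)) for t in aln.taxa}

    hits: list[RevCompHit] = []
    for q, s in itertools.combinations(aln.taxa, 2):
        if not degapped[q] or not degapped[s]:
            continue
        for lh in pairwise_revcomp_align(degapped[q], degapped[s], params):
            q_cols = coord_maps[q].to_columns(lh.a_interval)
            s_cols = coord_maps[s].to_columns(lh.b_interval)
            msa = (min(q_cols[0], s_cols[0]), max(q_cols[1], s_cols[1]))
            hits.append(RevCompHit(q, s, lh.a_interval, lh.b_interval,
                                   lh.score, lh.identity, msa))
    hits.sort(key=lambda h: h.msa_interval)

    # shared overlap marks for hits from different pairs in one cluster
    mark = 0
    for cluster in _cluster_indices([h.msa_interval for h in hits],
                                    params.cluster_gap):
        pairs = {(hits[i].query_taxon, hits[i].subject_taxon) for i in cluster}
        if len(pairs) > 1:
            for i in cluster:
                hits[i].overlap_mark = mark
            mark += 1
    return hits


def _cluster_indices(intervals: Sequence[tuple[int, int]], gap: int
                     ) -> list[list[int]]:
    """Single-linkage clusters of intervals closer than ``gap``.

    For 1-D intervals a left-to-right sweep realises the transitive
    closure exactly.
    """
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    clusters: list[list[int]] = []
    cur_end = None
    for i in order:
        s, e = intervals[i]
        if cur_end is not None and s <= cur_end + gap:
            clusters[-1].append(i)
            cur_end = max(cur_end, e)
        else:
            clusters.append([i])
            cur_end = e
    return clusters


# ---------------------------------------------------------------------------
# clustering into candidate regions
# ---------------------------------------------------------------------------

@dataclass
class CandidateRegion:
    """A cluster of complementary-strand hits supporting >=1 inversion."""

    msa_interval: tuple[int, int]
    hits: list[RevCompHit]


def cluster_hits(hits: Sequence[RevCompHit], params: ScanParams | None = None
                 ) -> list[CandidateRegion]:
    """Single-linkage clustering of hits on their alignment-column spans."""
    params = params or ScanParams()
    regions = []
    for idxs in _cluster_indices([h.msa_interval for h in hits],
                                 params.cluster_gap):
        members = [hits[i] for i in idxs]
        lo = min(h.msa_interval[0] for h in members)
        hi = max(h.msa_interval[1] for h in members)
        regions.append(CandidateRegion((lo, hi), members))
    regions.sort(key=lambda r: r.msa_interval)
    return regions


def split_events(region: CandidateRegion, params: ScanParams | None = None
                 ) -> list[CandidateRegion]:
    """Partition a region's hits into distinct inversion events.

    Hits whose projected endpoints agree within ``endpoint_tol``
    columns are taken to witness the same event; partially overlapping
    events (independent inversions of overlapping tracts in different
    lineages) separate here.
    """
    params = params or ScanParams()
    groups: list[list[RevCompHit]] = []
    for h in sorted(region.hits, key=lambda x: x.msa_interval):
        for g in groups:
            ref = g[0].msa_interval
            if (abs(h.msa_interval[0] - ref[0]) <= params.endpoint_tol
                    and abs(h.msa_interval[1] - ref[1]) <= params.endpoint_tol):
                g.append(h)
                break
        else:
            groups.append([h])
    out = []
    for g in groups:
        lo = min(h.msa_interval[0] for h in g)
        hi = max(h.msa_interval[1] for h in g)
        out.append(CandidateRegion((lo, hi), g))
    return out


# ---------------------------------------------------------------------------
# calling and validation
# ---------------------------------------------------------------------------

@dataclass
class InversionCall:
    """A validated (or rejected) microinversion with carriers and endpoints."""

    locus_id: str
    msa_interval: tuple[int, int]
    carrier_taxa: frozenset[str]
    carrier_lengths: dict[str, int]
    validation_delta: float
    status: str  # validated | candidate | rejected
    overlap_group: int | None = None
    palindrome_flag: bool = False


def _segment(aln: Alignment, taxon: str, interval: tuple[int, int]) -> str:
    s, e = interval
    return degap(aln.row(taxon)[s:e])


def _mean_identity(segs_a: list[str], segs_b: list[str],
                   params: ScanParams) -> float:
    vals = [segment_identity(a, b, params)
            for a in segs_a for b in segs_b if a and b]
    return float(np.mean(vals)) if vals else 0.0


def _bipartition(region: CandidateRegion) -> tuple[set[str], set[str], bool]:
    """2-colour taxa on the 'opposite orientation' graph of the hits.

    Returns (side_a, side_b, consistent).  A complementary-strand hit
    between two taxa means they carry the tract in opposite
    orientations; an odd cycle (as produced by palindromes, which hit
    in every pair) makes the graph non-bipartite.
    """
    adj: dict[str, set[str]] = {}
    for h in region.hits:
        adj.setdefault(h.query_taxon, set()).add(h.subject_taxon)
        adj.setdefault(h.subject_taxon, set()).add(h.query_taxon)
    colour: dict[str, int] = {}
    consistent = True
    for start in sorted(adj):
        if start in colour:
            continue
        colour[start] = 0
        queue = [start]
        while queue:
            u = queue.pop()
            for v in sorted(adj[u]):
                if v not in colour:
                    colour[v] = 1 - colour[u]
                    queue.append(v)
                elif colour[v] == colour[u]:
                    consistent = False
    side_a = {t for t, c in colour.items() if c == 0}
    side_b = {t for t, c in colour.items() if c == 1}
    return side_a, side_b, consistent


def call_inversion(region: CandidateRegion, aln: Alignment,
                   params: ScanParams | None = None,
                   outgroup: set[str] | None = None,
                   overlap_group: int | None = None) -> InversionCall:
    """Validate one candidate region and call carriers and endpoints.

    Carriers are the side of the hit-implied bipartition whose
    re-inversion maximises mean identity to the other side;
    ``validation_delta`` is that identity gain.  The call is
    ``validated`` when the gain clears ``delta_threshold`` and the
    carrier tract lengths sit within [5, max_inv_len]; ``rejected``
    when re-inversion does not help at all (the palindrome signature);
    ``candidate`` otherwise.
    """
    params = params or ScanParams()
    if not region.hits:
        raise ValueError("region has no supporting hits")
    interval = region.msa_interval
    side_a, side_b, consistent = _bipartition(region)

    segs = {t: _segment(aln, t, interval) for t in aln.taxa}

    # attach taxa with no hit membership to the side they resemble
    unassigned = [t for t in aln.taxa
                  if t not in side_a and t not in side_b and segs[t]]
    for t in unassigned:
        ia = _mean_identity([segs[t]], [segs[u] for u in sorted(side_a)], params)
        ib = _mean_identity([segs[t]], [segs[u] for u in sorted(side_b)], params)
        (side_a if ia >= ib else side_b).add(t)

    if all(not segs[t] for t in side_a) or all(not segs[t] for t in side_b):
        raise UncallableRegionError(
            f"{aln.locus_id}: region {interval} is all-gap on one side")

    def gain_for(carriers: set[str], others: set[str]) -> tuple[float, float]:
        car = [segs[t] for t in sorted(carriers) if segs[t]]
        oth = [segs[t] for t in sorted(others) if segs[t]]
        base = _mean_identity(car, oth, params)
        flipped = [reverse_complement(s) for s in car]
        return _mean_identity(flipped, oth, params), base

    flip_a, base_a = gain_for(side_a, side_b)
    flip_b, base_b = gain_for(side_b, side_a)
    delta_a, delta_b = flip_a - base_a, flip_b - base_b

    if outgroup is not None and bool(outgroup & side_a) != bool(outgroup & side_b):
        # polarity fixed: the outgroup carries the ancestral orientation
        if outgroup & side_a:
            carriers, delta = side_b, delta_b
        else:
            carriers, delta = side_a, delta_a
    else:
        # re-inversion quality is symmetric between the two orientations
        # up to aligner tie-breaking noise, so compare with a tolerance
        # and fall back to parsimony (the smaller carrier set)
        if flip_a > flip_b + 0.02:
            carriers, delta = side_a, delta_a
        elif flip_b > flip_a + 0.02:
            carriers, delta = side_b, delta_b
        elif len(side_a) != len(side_b):
            carriers, delta = ((side_a, delta_a) if len(side_a) < len(side_b)
                               else (side_b, delta_b))
        else:
            carriers, delta = _pick_side(side_a, delta_a, side_b, delta_b)

    # palindrome: the tract is (nearly) its own reverse complement
    palindrome = any(
        segs[t] and segment_identity(segs[t], reverse_complement(segs[t]),
                                     params) >= params.min_identity
        for t in sorted(carriers))
    if not consistent:
        palindrome = True

    lengths = {t: len(segs[t]) for t in sorted(carriers) if segs[t]}
    if not lengths:
        raise UncallableRegionError(
            f"{aln.locus_id}: region {interval} all-gap in every carrier")

    if carriers >= set(aln.taxa):
        # no polarity information; keep a proper subset for reporting
        drop = sorted(carriers)[-1]
        carriers = carriers - {drop}
        lengths.pop(drop, None)

    if delta <= 0:
        status = "rejected"
    elif (delta >= params.delta_threshold
            and min(lengths.values()) >= params.min_hit_len
            and max(lengths.values()) <= params.max_inv_len):
        status = "validated"
    else:
        status = "candidate"

    return InversionCall(
        locus_id=aln.locus_id, msa_interval=interval,
        carrier_taxa=frozenset(carriers), carrier_lengths=lengths,
        validation_delta=delta, status=status,
        overlap_group=overlap_group, palindrome_flag=palindrome)


def _pick_side(side_a, delta_a, side_b, delta_b):
    if abs(delta_a - delta_b) > 1e-9:
        return (side_a, delta_a) if delta_a > delta_b else (side_b, delta_b)
    # tie: parsimony favours the smaller carrier set
    return (side_a, delta_a) if len(side_a) <= len(side_b) else (side_b, delta_b)


def detect_inversions(aln: Alignment, params: ScanParams | None = None,
                      outgroup: set[str] | None = None) -> list[InversionCall]:
    """Full scan -> cluster -> split -> call pipeline for one locus.

    Calls derived from the same hit cluster (overlapping or adjacent
    events) share an ``overlap_group`` id.  Uncallable regions are
    logged and skipped.
    """
    params = params or ScanParams()
    hits = scan_alignment(aln, params)
    calls: list[InversionCall] = []
    group_id = 0
    for region in cluster_hits(hits, params):
        events = split_events(region, params)
        group = group_id if len(events) > 1 else None
        if len(events) > 1:
            group_id += 1
        for ev in events:
            try:
                calls.append(call_inversion(ev, aln, params, outgroup, group))
            except UncallableRegionError as exc:
                logger.warning("skipping uncallable region: %s", exc)
    return calls


def call_manual(aln: Alignment, interval: tuple[int, int],
                params: ScanParams | None = None,
                outgroup: set[str] | None = None) -> InversionCall:
    """Validate a user-asserted interval (an 'identified by eye' channel).

    Runs the pairwise complementary-strand scan restricted to the
    asserted columns, then the standard re-inversion validation.
    """
    params = params or ScanParams()
    s, e = interval
    if not (0 <= s < e <= aln.n_cols):
        raise ValueError(f"interval {interval!r} outside alignment bounds")
    sub = Alignment(aln.locus_id, list(aln.taxa),
                    [r[s:e] for r in aln.rows])
    keep = [t for t in sub.taxa if degap(sub.row(t))]
    sub = Alignment(aln.locus_id, keep, [sub.row(t) for t in keep])
    hits = scan_alignment(sub, params)
    if not hits:
        raise UncallableRegionError(
            f"{aln.locus_id}: no complementary-strand support in {interval!r}")
    region = CandidateRegion((0, e - s), hits)
    call = call_inversion(region, sub, params, outgroup)
    lo, hi = call.msa_interval
    return InversionCall(
        locus_id=call.locus_id, msa_interval=(s + lo, s + hi),
        carrier_taxa=call.carrier_taxa, carrier_lengths=call.carrier_lengths,
        validation_delta=call.validation_delta, status=call.status,
        overlap_group=None, palindrome_flag=call.palindrome_flag)
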