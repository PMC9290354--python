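"""Cross-species microRNA homology: similarity hits, homology groups, and
neighbor-joining trees on uncorrected distances.

Hairpins of the two species are compared all-against-all with the seeded
local aligner; hits passing the E-value (and, in genome-scan mode, alignment
length) thresholds become edges of an undirected similarity graph whose
connected components are the candidate homology groups, classified by their
per-species member counts.  For visual inspection of multi-member groups a
neighbor-joining tree is built from pairwise uncorrected (p-)distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .align import LocalAlignment, Scoring, evalue, local_align

__all__ = [
    "SimilarityHit",
    "HomologyGroup",
    "DistanceMatrix",
    "TreeNode",
    "find_hits",
    "build_groups",
    "uncorrected_distance",
    "distance_matrix",
    "neighbor_joining",
]

DEFAULT_WORD_SIZE = 10
DEFAULT_EVALUE_PAIRING = 0.1
DEFAULT_EVALUE_SCAN = 0.01
DEFAULT_MIN_ALN_LEN = 60


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    score: int
    evalue: float
    length: int
    identity: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")


def find_hits(
    queries: dict[str, str],
    subjects: dict[str, str],
    scoring: Scoring = Scoring(),
    word_size: int = DEFAULT_WORD_SIZE,
    evalue_max: float = DEFAULT_EVALUE_PAIRING,
    min_aln_len: int | None = None,
) -> list[SimilarityHit]:
    """All query-vs-subject similarity hits with E <= ``evalue_max``.

    A word index over the subjects keeps the search seeded: only pairs sharing
    an exact ``word_size``-mer are aligned (by full dynamic programming).
    ``min_aln_len`` additionally drops short alignments; the genome-scan
    configuration of the pipeline uses ``min_aln_len=60`` with E <= 0.01.

    E-values are computed against the whole comparison's search space
    (total query length x total subject length), i.e. the expected number of
    chance alignments of at least that score anywhere in the all-against-all
    search.  This matches how database search statistics are interpreted, is
    symmetric in the direction of the comparison, and keeps a bare chance
    word match between two hairpins from counting as a significant hit.
    """
    m_total = sum(len(s) for s in queries.values())
    n_total = sum(len(s) for s in subjects.values())
    index: dict[str, set[str]] = {}
    for sid, seq in subjects.items():
        seq = seq.upper()
        for i in range(len(seq) - word_size + 1):
            w = seq[i : i + word_size]
            if "N" not in w:
                index.setdefault(w, set()).add(sid)
    hits: list[SimilarityHit] = []
    for qid in sorted(queries):
        qseq = queries[qid].upper()
        cands: set[str] = set()
        for i in range(len(qseq) - word_size + 1):
            w = qseq[i : i + word_size]
            if "N" not in w:
                cands |= index.get(w, set())
        for sid in sorted(cands):
            sseq = subjects[sid].upper()
            aln = local_align(qseq, sseq, scoring, mode="exhaustive")
            if not aln.is_hit:
                continue
            if min_aln_len is not None and aln.length < min_aln_len:
                continue
            e = evalue(aln.score, m_total, n_total, scoring)
            if e <= evalue_max:
                hits.append(
                    SimilarityHit(
                        query=qid,
                        subject=sid,
                        score=aln.score,
                        evalue=e,
                        length=aln.length,
                        identity=aln.identity,
                        query_interval=aln.query_interval,
                        subject_interval=aln.subject_interval,
                    )
                )
    return hits


@dataclass(frozen=True)
class HomologyGroup:
    """A connected component of the cross-species similarity graph."""

    members1: tuple[str, ...]
    members2: tuple[str, ...]
    cls: str  # one_to_one | one_to_many | many_to_many | unpaired
    tree_newick: str | None = None

    @staticmethod
    def classify(n1: int, n2: int) -> str:
        if n1 == 0 or n2 == 0:
            return "unpaired"
        if n1 == 1 and n2 == 1:
            return "one_to_one"
        if n1 == 1 or n2 == 1:
            return "one_to_many"
        return "many_to_many"


def build_groups(
    hits: Iterable[SimilarityHit],
    ids1: Sequence[str],
    ids2: Sequence[str],
    overrides: Iterable[tuple[str, str]] = (),
) -> list[HomologyGroup]:
    """Connected components of the similarity graph over all loci of both
    species.  Loci with no edges become singleton unpaired groups.

    ``overrides`` adds manual ortholog edges (curated pairings kept for
    consistency with earlier annotations).
    """
    set1, set2 = set(ids1), set(ids2)
    if set1 & set2:
        raise ValueError("locus ids must be disjoint between species")
    g = nx.Graph()
    g.add_nodes_from(ids1)
    g.add_nodes_from(ids2)
    for h in hits:
        if h.query not in g or h.subject not in g:
            raise ValueError(f"hit references unknown locus {h.query}/{h.subject}")
        g.add_edge(h.query, h.subject)
    for a, b in overrides:
        g.add_edge(a, b)
    groups = []
    for comp in nx.connected_components(g):
        m1 = tuple(sorted(comp & set1))
        m2 = tuple(sorted(comp & set2))
        groups.append(
            HomologyGroup(m1, m2, HomologyGroup.classify(len(m1), len(m2)))
        )
    groups.sort(key=lambda gr: (gr.members1 + gr.members2))
    return groups


# ---------------------------------------------------------------------------
# distances and trees


def _global_aligner(scoring: Scoring):
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    return a


def uncorrected_distance(
    seq1: str, seq2: str, scoring: Scoring = Scoring()
) -> float:
    """Uncorrected (p-)distance: mismatches / aligned positions of the global
    alignment, gap columns excluded pairwise."""
    if not seq1 or not seq2:
        raise ValueError("cannot compute a distance for an empty sequence")
    aligner = _global_aligner(scoring)
    aln = aligner.align(seq1.upper(), seq2.upper())[0]
    aligned = 0
    mismatches = 0
    for (q0, q1), (s0, s1) in zip(*aln.aligned):
        aligned += q1 - q0
        for k in range(q1 - q0):
            if seq1.upper()[q0 + k] != seq2.upper()[s0 + k]:
                mismatches += 1
    if aligned == 0:
        raise ValueError("global alignment has no aligned (non-gap) positions")
    return mismatches / aligned


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v


def distance_matrix(
    seqs: dict[str, str], scoring: Scoring = Scoring()
) -> DistanceMatrix:
    labels = tuple(sorted(seqs))
    n = len(labels)
    v = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = uncorrected_distance(seqs[labels[i]], seqs[labels[j]], scoring)
        v[i, j] = v[j, i] = d
    return DistanceMatrix(labels, v)


@dataclass
class TreeNode:
    """Minimal rooted-representation tree node (the NJ tree itself is
    unrooted; the returned node is the last join point)."""

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name or ""]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classic neighbor joining (Saitou-Nei with the standard Q criterion).

    Joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j, assigns
    branch lengths by the split formula, and clamps negative branch lengths
    to zero (recorded in ``tree.negative_branches``-free fashion: clamping is
    silent but deterministic).  Ties in Q break toward the lexicographically
    smallest label pair so results are reproducible.
    """
    labels = list(dm.labels)
    if len(labels) < 2:
        if len(labels) == 1:
            return TreeNode(name=labels[0])
        raise ValueError("need at least two taxa")
    d = dm.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    keys = list(labels)  # sort keys for deterministic tie-breaking

    def clamp(x: float) -> float:
        return x if x > 0 else 0.0

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((keys[i], keys[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.zeros((n - 1, n - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = dk[keep]
        d_new[:-1, -1] = dk[keep]
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        d = d_new

    if len(nodes) == 2:
        half = 0.5 * d[0, 1]
        for nd in nodes:
            nd.length = clamp(half) if nd.length is None else nd.length
        return TreeNode(children=list(nodes))
    # n == 3: solve the three leaf equations exactly
    a = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    b = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    c = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for nd, ln in zip(nodes, (a, b, c)):
        nd.length = clamp(ln)
    return TreeNode(children=list(nodes))
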