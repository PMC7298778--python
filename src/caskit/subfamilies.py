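"""Build subfamily profile collections from per-family protein sequences.

The pipeline mirrors classic protein-family curation: all-against-all local
alignment, filtering of links by score, mutual coverage and positional
consistency, Markov clustering (MCL) of the resulting similarity graph, and
one profile HMM per cluster built from a center-star multiple alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .profiles import (AMINO_ACIDS, AA_INDEX, ROBINSON_BACKGROUND, ModelCollection,
                       ProfileModel)


@dataclass
class SimilarityRecord:
    """Result of one local pairwise comparison."""

    id_a: str
    id_b: str
    score: float
    aln_len: int
    cov_a: float
    cov_b: float
    start_a: int
    end_a: int
    start_b: int
    end_b: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("local alignment score cannot be negative")
        for cov in (self.cov_a, self.cov_b):
            if not 0.0 <= cov <= 1.0:
                raise ValueError("coverage must lie in [0, 1]")
        if self.aln_len > 0 and (self.end_a <= self.start_a or self.end_b <= self.start_b):
            raise ValueError("non-empty alignment must have end > start")

    def swapped(self) -> "SimilarityRecord":
        return SimilarityRecord(self.id_b, self.id_a, self.score, self.aln_len,
                                self.cov_b, self.cov_a, self.start_b, self.end_b,
                                self.start_a, self.end_a)


@dataclass
class ClusterParams:
    """Link-filter and MCL hyperparameters for one collection preset."""

    inflation: float = 2.0
    expansion: int = 2
    prune_eps: float = 1e-5
    max_iter: int = 200
    min_score: float = 50.0
    min_cov: float = 0.5
    max_pos_shift: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.inflation > 1:
            raise ValueError("inflation must exceed 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.prune_eps < 0 or not np.isfinite(self.prune_eps):
            raise ValueError("prune_eps must be finite and >= 0")


def _make_aligner(mode: str, matrix: str | None = "BLOSUM62",
                  gap_open: float = 11.0, gap_extend: float = 1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aligner.mode = mode
    return aligner


def pairwise_similarity(seq_a: str, seq_b: str, id_a: str = "a", id_b: str = "b",
                        matrix: str = "BLOSUM62", gap_open: float = 11.0,
                        gap_extend: float = 1.0) -> SimilarityRecord:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Coverage and spans come from the optimal traceback; an all-negative
    comparison yields score 0 with an empty span.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner("local", matrix, gap_open, gap_extend)
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return SimilarityRecord(id_a, id_b, 0.0, 0, 0.0, 0.0, 0, 0, 0, 0)
    aln = aligner.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    start_a, end_a = int(blocks_a[0][0]), int(blocks_a[-1][1])
    start_b, end_b = int(blocks_b[0][0]), int(blocks_b[-1][1])
    aln_len = aln.length
    return SimilarityRecord(
        id_a, id_b, float(score), int(aln_len),
        cov_a=(end_a - start_a) / len(seq_a),
        cov_b=(end_b - start_b) / len(seq_b),
        start_a=start_a, end_a=end_a, start_b=start_b, end_b=end_b)


def link_criteria(rec: SimilarityRecord, len_a: int, len_b: int,
                  params: ClusterParams) -> bool:
    """Accept a similarity link for clustering.

    Requires score >= ``min_score``, mutual coverage >= ``min_cov``, and the
    aligned regions to sit at comparable relative positions: the alignment
    midpoints, each as a fraction of its sequence length, may differ by at
    most ``max_pos_shift``.
    """
    if rec.score < params.min_score:
        return False
    if min(rec.cov_a, rec.cov_b) < params.min_cov:
        return False
    if rec.aln_len == 0:
        return False
    mid_a = (rec.start_a + rec.end_a) / 2.0 / len_a
    mid_b = (rec.start_b + rec.end_b) / 2.0 / len_b
    return abs(mid_a - mid_b) <= params.max_pos_shift


def mcl_cluster(nodes: list[str], links: dict[tuple[str, str], float] | list,
                params: ClusterParams) -> list[set[str]]:
    """Classic Markov clustering of a weighted undirected graph.

    Self-loops are added internally; the column-stochastic matrix is
    alternately expanded (matrix power) and inflated (entrywise power with
    column renormalization), pruning entries below ``prune_eps``, until the
    iteration is stationary.  Clusters are the weakly connected components of
    the nonzero attractor structure, so every node lands in exactly one
    cluster.
    """
    if not nodes:
        raise ValueError("mcl_cluster requires at least one node")
    if not isinstance(links, dict):
        links = {(a, b): w for a, b, w in links}
    idx = {n: i for i, n in enumerate(nodes)}
    k = len(nodes)
    M = np.zeros((k, k))
    for (a, b), w in links.items():
        if w <= 0:
            raise ValueError("link weights must be positive")
        i, j = idx[a], idx[b]
        M[i, j] = max(M[i, j], w)
        M[j, i] = max(M[j, i], w)
    np.fill_diagonal(M, np.maximum(M.diagonal(), 1.0))
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(params.max_iter):
        prev = M
        M = np.linalg.matrix_power(M, params.expansion)
        M = M ** params.inflation
        M[M < params.prune_eps] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < 1e-8:
            break
    graph = csr_matrix(M + M.T > 0)
    n_comp, labels = connected_components(graph, directed=False)
    clusters: list[set[str]] = [set() for _ in range(n_comp)]
    for node, lab in zip(nodes, labels):
        clusters[lab].add(node)
    clusters.sort(key=lambda c: min(idx[n] for n in c))
    return clusters


# -- center-star multiple alignment and profile construction -------------


def center_star_alignment(seqs: list[str]) -> list[str]:
    """Multiple alignment by the center-star heuristic.

    The center is the sequence maximizing the summed global pairwise score;
    every other sequence is aligned to the center and the pairwise gaps are
    merged column-wise ("once a gap, always a gap").
    """
    if not seqs:
        raise ValueError("cannot align an empty set of sequences")
    if len(seqs) == 1:
        return [seqs[0]]
    aligner = _make_aligner("global")
    nseq = len(seqs)
    scores = np.zeros((nseq, nseq))
    for i in range(nseq):
        for j in range(i + 1, nseq):
            s = aligner.score(seqs[i], seqs[j])
            scores[i, j] = scores[j, i] = s
    center = int(np.argmax(scores.sum(axis=1)))
    c = seqs[center]
    L = len(c)
    # For each sequence: residue aligned to each center position (or gap) and
    # insertions (relative to the center) before each center position.
    aligned_rows: list[tuple[list[str], list[str]]] = []
    max_ins = [0] * (L + 1)
    order = [center] + [i for i in range(nseq) if i != center]
    for i in order[1:]:
        aln = aligner.align(c, seqs[i])[0]
        cidx, sidx = aln.indices
        row = ["-"] * L
        inserts = [""] * (L + 1)
        cpos = 0
        for col in range(len(cidx)):
            ci, si = int(cidx[col]), int(sidx[col])
            if ci >= 0:
                cpos = ci + 1
                if si >= 0:
                    row[ci] = seqs[i][si]
            elif si >= 0:
                inserts[cpos] += seqs[i][si]
        aligned_rows.append((row, inserts))
        for p in range(L + 1):
            max_ins[p] = max(max_ins[p], len(inserts[p]))

    def expand(row: list[str], inserts: list[str]) -> str:
        out = []
        for p in range(L + 1):
            ins = inserts[p]
            out.append(ins + "-" * (max_ins[p] - len(ins)))
            if p < L:
                out.append(row[p])
        return "".join(out)

    msa_by_input: dict[int, str] = {center: expand(list(c), [""] * (L + 1))}
    for i, (row, inserts) in zip(order[1:], aligned_rows):
        msa_by_input[i] = expand(row, inserts)
    return [msa_by_input[i] for i in range(nseq)]


def build_profile_from_cluster(seqs: list[str], pseudocount: float = 0.01,
                               name: str = "cluster", family: str | None = None,
                               background: np.ndarray | None = None) -> ProfileModel:
    """Profile HMM from a cluster: center-star MSA, >=50%-occupancy match
    columns, frequency-plus-pseudocount emissions, occupancy-derived
    transitions, majority-residue consensus."""
    if not seqs:
        raise ValueError("cannot build a profile from an empty cluster")
    if background is None:
        background = ROBINSON_BACKGROUND
    msa = center_star_alignment(seqs)
    ncols = len(msa[0])
    nseq = len(msa)
    occupancy = np.array([sum(row[c] != "-" for row in msa) for c in range(ncols)])
    match_cols = [c for c in range(ncols) if occupancy[c] >= 0.5 * nseq]
    if not match_cols:
        match_cols = [int(np.argmax(occupancy))]
    L = len(match_cols)

    counts = np.zeros((L, 20))
    for k, c in enumerate(match_cols):
        for row in msa:
            aa = row[c]
            if aa in AA_INDEX:
                counts[k, AA_INDEX[aa]] += 1
    match_em = counts + pseudocount
    match_em /= match_em.sum(axis=1, keepdims=True)
    consensus = "".join(AMINO_ACIDS[int(np.argmax(counts[k]))] for k in range(L))

    # State path of each sequence through the match-column skeleton: residue in
    # a match column -> M, gap -> D; residues in non-match columns -> I at the
    # preceding node.  Transition counts + pseudocount, renormalized per state.
    col_node = np.full(ncols, -1)
    for k, c in enumerate(match_cols):
        col_node[c] = k + 1
    tcounts = np.zeros((L + 1, 7))
    from .profiles import MM, MI, MD, IM, II, DM, DD
    for row in msa:
        state, node = "M", 0  # begin treated as M0
        for c in range(ncols):
            if col_node[c] > 0:
                nxt = "M" if row[c] != "-" else "D"
                key = {("M", "M"): MM, ("M", "D"): MD, ("I", "M"): IM,
                       ("D", "M"): DM, ("D", "D"): DD}.get((state, nxt))
                if key is None:  # I -> D and begin-D bookkeeping fold into DM/MD
                    key = MD if state == "I" else None
                if key is not None:
                    tcounts[node, key] += 1
                state, node = nxt, col_node[c]
            elif row[c] != "-":
                if state == "M":
                    tcounts[node, MI] += 1
                elif state == "I":
                    tcounts[node, II] += 1
                else:  # D -> I folded as D->M->I surrogate; count II to stay stochastic
                    tcounts[node, II] += 1
                state = "I"
    trans = tcounts + pseudocount
    for idx_set in ([MM, MI, MD], [IM, II], [DM, DD]):
        block = trans[:, idx_set]
        trans[:, idx_set] = block / block.sum(axis=1, keepdims=True)
    # last node: no onward match/delete; route all mass to MM/IM/DM exits
    trans[L, [MM, MI, MD]] = (1.0, 0.0, 0.0)
    trans[L, [IM, II]] = (1.0, 0.0)
    trans[L, [DM, DD]] = (1.0, 0.0)

    insert_em = np.tile(background, (L + 1, 1))
    return ProfileModel(
        name=name, family=family or name.split("__")[0],
        match_emissions=match_em, insert_emissions=insert_em,
        transitions=trans, background=np.asarray(background, float),
        consensus=consensus)


# -- end-to-end collection construction ----------------------------------


def _read_family_fasta(path) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    return records


def cluster_family(seqs: dict[str, str], params: ClusterParams) -> list[list[str]]:
    """Similarity graph -> link filter -> MCL; returns clusters of sequence ids."""
    ids = list(seqs)
    links: dict[tuple[str, str], float] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            rec = pairwise_similarity(seqs[a], seqs[b], a, b)
            if link_criteria(rec, len(seqs[a]), len(seqs[b]), params):
                links[(a, b)] = rec.score
    return [sorted(c, key=ids.index) for c in mcl_cluster(ids, links, params)]


def build_collection(families: dict[str, object], params: ClusterParams,
                     collection_id: str = "HMM_1",
                     pseudocount: float = 0.01) -> ModelCollection:
    """Build one profile collection from per-family FASTA paths (or in-memory
    ``{id: seq}`` mappings).  Deterministic given params and input order."""
    by_family: dict[str, list[ProfileModel]] = {}
    for family, source in families.items():
        if isinstance(source, (str, Path)):
            try:
                records = _read_family_fasta(source)
            except (OSError, ValueError) as exc:
                raise IOError(f"family {family!r}: cannot read FASTA {source}: {exc}") from exc
            if not records:
                raise IOError(f"family {family!r}: FASTA {source} holds no records")
            seqs = dict(records)
        else:
            seqs = dict(source)
            if not seqs:
                raise IOError(f"family {family!r}: empty sequence set")
        clusters = cluster_family(seqs, params)
        models = []
        for ci, members in enumerate(clusters, start=1):
            model = build_profile_from_cluster(
                [seqs[mid] for mid in members], pseudocount=pseudocount,
                name=f"{family}__cluster{ci}", family=family)
            models.append(model)
        by_family[family] = models
    return ModelCollection(collection_id, by_family, list(families))


#: Illustrative presets for the five collection granularities; the values are
#: package defaults, not published thresholds.
COLLECTION_PRESETS: dict[str, ClusterParams] = {
    "HMM_1": ClusterParams(min_score=80.0, min_cov=0.7, inflation=4.0),
    "HMM_2": ClusterParams(min_score=70.0, min_cov=0.6, inflation=3.0),
    "HMM_3": ClusterParams(min_score=50.0, min_cov=0.5, inflation=2.0),
    "HMM_4": ClusterParams(min_score=40.0, min_cov=0.4, inflation=1.6),
    "HMM_5": ClusterParams(min_score=30.0, min_cov=0.3, inflation=1.4),
}
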