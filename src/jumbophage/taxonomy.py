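"""Proteome-based taxonomy: orthologue detection, shared-orthologue
fractions, a whole-proteome distance tree, and dual-criterion family
demarcation.

Orthologues are reciprocal best hits (Smith–Waterman, BLOSUM62) filtered at
E ≤ 1e-5, identity ≥ 30 % and coverage ≥ 50 % of the shorter protein.  The
shared fraction between two genomes is the orthologue count over the smaller
proteome.  Proteome similarity S is the summed orthologue bit score over the
smaller proteome's self score, and D = 1 − S feeds a neighbour-joining tree.
Two genomes belong to different families only when their patristic distance
is ≥ 0.05 *and* they share < 10 % of orthologous protein clusters; families
are the connected components of the complementary "together" relation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from ._align import (bit_score, karlin_altschul_evalue,
                     protein_local_alignment, protein_self_score,
                     shared_kmer_count)
from .config import DEFAULT_CONFIG, RunConfig

Proteome = dict[str, str]  # protein id → amino-acid sequence


@dataclass
class OrthologuePair:
    id_a: str
    id_b: str
    raw_score: float
    bit_score: float
    evalue: float
    identity: float
    coverage: float


@dataclass
class OrthologueMatrix:
    genome_ids: list[str]
    shared_fraction: np.ndarray        # symmetric, diagonal 1.0
    n_orthologue_pairs: np.ndarray     # symmetric integer matrix

    def fraction(self, a: str, b: str) -> float:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.shared_fraction[i, j])


@dataclass
class ProteomicTree:
    genome_ids: list[str]
    distance_matrix: np.ndarray
    tree: object                       # skbio TreeNode
    newick: str

    def patristic(self, a: str, b: str) -> float:
        ta = self.tree.find(a)
        return float(ta.distance(self.tree.find(b)))

    def patristic_matrix(self) -> np.ndarray:
        dm = self.tree.tip_tip_distances(self.genome_ids)
        return np.asarray(dm.data)


@dataclass
class FamilyAssignment:
    genome_to_family: dict[str, str]
    families: dict[str, list[str]]


# ---------------------------------------------------------------------------
# orthologue detection (reciprocal best hits)
# ---------------------------------------------------------------------------

def _best_hits(qry: Proteome, sub: Proteome,
               config: RunConfig) -> dict[str, tuple[str, float, float, float]]:
    """Best qualifying hit per query protein → (subject, raw, identity, cov).

    A shared-5-peptide prefilter (BLAST-like seeding) skips pairs that cannot
    reach the identity/E-value thresholds.
    """
    out: dict[str, tuple[str, float, float, float]] = {}
    for qid, qseq in qry.items():
        best = None
        for sid, sseq in sub.items():
            if shared_kmer_count(qseq, sseq) < 2:
                continue
            raw, ident, aligned = protein_local_alignment(qseq, sseq)
            if aligned == 0:
                continue
            identity = ident / aligned
            coverage = aligned / min(len(qseq), len(sseq))
            e = karlin_altschul_evalue(raw, len(qseq) * len(sseq),
                                       config.ka_lambda, config.ka_k)
            if (e <= config.orth_evalue_max
                    and identity >= config.orth_identity_min
                    and coverage >= config.orth_coverage_min):
                if best is None or raw > best[1]:
                    best = (sid, raw, identity, coverage)
        if best is not None:
            out[qid] = best
    return out


def detect_orthologues(proteome_a: Proteome, proteome_b: Proteome,
                       config: RunConfig = DEFAULT_CONFIG
                       ) -> list[OrthologuePair]:
    """Reciprocal best hits between two proteomes."""
    if not proteome_a or not proteome_b:
        return []
    ab = _best_hits(proteome_a, proteome_b, config)
    ba = _best_hits(proteome_b, proteome_a, config)
    pairs = []
    for qid, (sid, raw, ident, cov) in sorted(ab.items()):
        back = ba.get(sid)
        if back is not None and back[0] == qid:
            pairs.append(OrthologuePair(
                id_a=qid, id_b=sid, raw_score=raw,
                bit_score=bit_score(raw, config.ka_lambda, config.ka_k),
                evalue=karlin_altschul_evalue(
                    raw, len(proteome_a[qid]) * len(proteome_b[sid]),
                    config.ka_lambda, config.ka_k),
                identity=ident, coverage=cov))
    return pairs


def shared_fraction(pairs: list[OrthologuePair], proteome_a: Proteome,
                    proteome_b: Proteome) -> float:
    """|orthologue pairs| / min(proteome sizes), clamped to [0, 1]."""
    if not proteome_a or not proteome_b:
        raise ValueError("shared fraction undefined for an empty proteome")
    return min(1.0, len(pairs) / min(len(proteome_a), len(proteome_b)))


def proteome_self_bit_score(proteome: Proteome,
                            config: RunConfig = DEFAULT_CONFIG) -> float:
    """Total self-alignment bit score of a proteome."""
    return sum(bit_score(protein_self_score(p), config.ka_lambda,
                         config.ka_k) for p in proteome.values())


def proteomic_distance(pairs: list[OrthologuePair],
                       self_score_a: float, self_score_b: float,
                       config: RunConfig = DEFAULT_CONFIG) -> float:
    """D = 1 − S with S = Σ orthologue bit scores / min(self scores)."""
    denom = min(self_score_a, self_score_b)
    if denom <= 0:
        raise ValueError("zero self score: distance undefined")
    s = sum(p.bit_score for p in pairs) / denom
    return 1.0 - min(1.0, max(0.0, s))


def orthologue_analysis(proteomes: dict[str, Proteome],
                        config: RunConfig = DEFAULT_CONFIG
                        ) -> tuple[OrthologueMatrix, np.ndarray]:
    """All-pairs orthologue detection → (shared-fraction matrix,
    proteomic distance matrix) over the genomes, in sorted-id order."""
    ids = sorted(proteomes)
    n = len(ids)
    frac = np.eye(n)
    counts = np.zeros((n, n), dtype=np.int64)
    dist = np.zeros((n, n))
    selfs = {g: proteome_self_bit_score(proteomes[g], config) for g in ids}
    for g in ids:
        counts[ids.index(g), ids.index(g)] = len(proteomes[g])
    for i, j in itertools.combinations(range(n), 2):
        a, b = ids[i], ids[j]
        pairs = detect_orthologues(proteomes[a], proteomes[b], config)
        f = shared_fraction(pairs, proteomes[a], proteomes[b])
        d = proteomic_distance(pairs, selfs[a], selfs[b], config)
        frac[i, j] = frac[j, i] = f
        counts[i, j] = counts[j, i] = len(pairs)
        dist[i, j] = dist[j, i] = d
    return OrthologueMatrix(ids, frac, counts), dist


# ---------------------------------------------------------------------------
# tree and family demarcation
# ---------------------------------------------------------------------------

def build_tree(distance_matrix: np.ndarray, genome_ids: list[str]
               ) -> ProteomicTree:
    """Neighbour-joining tree from a symmetric zero-diagonal matrix;
    negative branch lengths are clamped to zero (skbio ``neg_as_zero``).

    For an additive input matrix the patristic distances reproduce the
    matrix exactly (the NJ consistency property).
    """
    dm = np.asarray(distance_matrix, dtype=float)
    if len(genome_ids) < 3:
        raise ValueError("neighbour joining needs >= 3 genomes")
    if dm.shape != (len(genome_ids), len(genome_ids)):
        raise ValueError("distance matrix shape does not match genome ids")
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0):
        raise ValueError("distance matrix must be symmetric, zero diagonal")
    tree = nj(DistanceMatrix(dm, genome_ids), neg_as_zero=True)
    return ProteomicTree(genome_ids=list(genome_ids), distance_matrix=dm,
                         tree=tree, newick=str(tree).strip())


def demarcate_families(tree: ProteomicTree,
                       orthologue_matrix: OrthologueMatrix,
                       config: RunConfig = DEFAULT_CONFIG
                       ) -> FamilyAssignment:
    """Families = connected components of the "together" relation:
    a pair stays together iff patristic distance < 0.05 OR shared
    orthologue fraction ≥ 0.10 (a pair is split only when *both* the
    divergence and the distinctness criteria hold).  Labels are the
    lexicographically smallest member of each family."""
    ids = orthologue_matrix.genome_ids
    if sorted(ids) != sorted(tree.genome_ids):
        raise ValueError("tree and orthologue matrix cover different genomes")
    pat = tree.patristic_matrix()
    order = [tree.genome_ids.index(g) for g in ids]
    pat = pat[np.ix_(order, order)]
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, j in itertools.combinations(range(len(ids)), 2):
        together = (pat[i, j] < config.family_patristic_min or
                    orthologue_matrix.shared_fraction[i, j]
                    >= config.family_shared_max)
        if together:
            g.add_edge(ids[i], ids[j])
    genome_to_family = {}
    families = {}
    for comp in nx.connected_components(g):
        label = min(comp)
        families[label] = sorted(comp)
        for member in comp:
            genome_to_family[member] = label
    return FamilyAssignment(genome_to_family=genome_to_family,
                            families=families)
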