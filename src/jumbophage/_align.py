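"""Shared alignment primitives.

Two search strategies live here:

* a BLAST-like translated search — exact peptide seeds followed by ungapped
  X-drop extension along the seed diagonal, scored with BLOSUM62 and assessed
  with ungapped Karlin–Altschul statistics;
* a Smith–Waterman protein aligner (Biopython PairwiseAligner, BLOSUM62,
  gap open 11 / extend 1) with a shared-k-mer prefilter, used for
  reciprocal-best-hit orthologue detection.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

_BLOSUM = substitution_matrices.load("BLOSUM62")

# 128x128 ascii-indexed BLOSUM62 with -4 for anything unknown; X never gains.
_SCORE = np.full((128, 128), -4, dtype=np.int32)
for _a in _BLOSUM.alphabet:
    for _b in _BLOSUM.alphabet:
        _SCORE[ord(_a), ord(_b)] = int(_BLOSUM[_a, _b])
_SCORE[ord("X"), :] = -4
_SCORE[:, ord("X")] = -4


def bit_score(raw_score: float, lam: float, k: float) -> float:
    return (lam * raw_score - math.log(k)) / math.log(2.0)


def karlin_altschul_evalue(raw_score: float, search_space: float,
                           lam: float, k: float) -> float:
    """Ungapped E = K·m·n·exp(−λS)."""
    return k * search_space * math.exp(-lam * raw_score)


def translate_frames(sequence: str) -> list[tuple[str, int, str]]:
    """Six-frame translation → [(strand, frame 0-2, aa string)].

    Codons containing N translate to X, which matches nothing.
    """
    out = []
    rc = str(Seq(sequence).reverse_complement())
    for strand, seq in (("+", sequence), ("-", rc)):
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[:len(sub) - len(sub) % 3]
            aa = str(Seq(sub).translate()) if sub else ""
            out.append((strand, frame, aa))
    return out


def _ungapped_extend(query: str, target: str, qpos: int, tpos: int,
                     seed_len: int, xdrop: int = 30) -> int:
    """Max ungapped local score on the diagonal through a seed hit."""
    score = 0
    for i in range(seed_len):
        score += _SCORE[ord(query[qpos + i]), ord(target[tpos + i])]
    best = score
    # extend right
    run = score
    i = seed_len
    while qpos + i < len(query) and tpos + i < len(target):
        run += _SCORE[ord(query[qpos + i]), ord(target[tpos + i])]
        if run > best:
            best = run
        if best - run > xdrop:
            break
        i += 1
    right_gain = best - score
    # extend left
    run = score
    best_left = score
    i = 1
    while qpos - i >= 0 and tpos - i >= 0:
        run += _SCORE[ord(query[qpos - i]), ord(target[tpos - i])]
        if run > best_left:
            best_left = run
        if best_left - run > xdrop:
            break
        i += 1
    return best_left + right_gain


def translated_search_best_score(genome_sequence: str, marker: str,
                                 seed_len: int = 5) -> float:
    """Best ungapped local score of ``marker`` against any of the six
    translation frames of ``genome_sequence`` (BLAST-like seeded search).

    Returns 0.0 when no seed fires (no exact ``seed_len``-peptide shared);
    a qualifying homologue at the E-value scales in use here always shares
    seeds, so the prefilter does not change any call.
    """
    marker = marker.upper()
    seeds: dict[str, list[int]] = {}
    for i in range(len(marker) - seed_len + 1):
        w = marker[i:i + seed_len]
        if "X" in w or "*" in w:
            continue
        seeds.setdefault(w, []).append(i)
    best = 0.0
    for _strand, _frame, aa in translate_frames(genome_sequence):
        seen_diag: set[tuple[int, int]] = set()
        for j in range(len(aa) - seed_len + 1):
            w = aa[j:j + seed_len]
            positions = seeds.get(w)
            if not positions:
                continue
            for qpos in positions:
                key = (j - qpos, j // 200)  # coarse bucket along the diagonal
                if key in seen_diag:
                    continue
                seen_diag.add(key)
                s = _ungapped_extend(marker, aa, qpos, j, seed_len)
                if s > best:
                    best = float(s)
    return best


# --- Smith–Waterman protein alignment (orthologue detection) ---------------

_ALIGNER = PairwiseAligner(mode="local", substitution_matrix=_BLOSUM,
                           open_gap_score=-11, extend_gap_score=-1)


def protein_self_score(protein: str) -> float:
    """Local self-alignment score: the sum of diagonal BLOSUM62 entries."""
    return float(sum(_SCORE[ord(a), ord(a)] for a in protein.upper()))


def protein_local_alignment(a: str, b: str) -> tuple[float, int, int]:
    """Smith–Waterman of two proteins → (score, identities, aligned_pairs)."""
    alns = _ALIGNER.align(a.upper(), b.upper())
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0, 0
    aln = alns[0]
    counts = aln.counts()
    return float(aln.score), int(counts.identities), \
        int(counts.identities + counts.mismatches)


def shared_kmer_count(a: str, b: str, k: int = 5) -> int:
    """Number of distinct k-peptides shared by two proteins (seed prefilter)."""
    if len(a) < k or len(b) < k:
        return 0
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb)
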