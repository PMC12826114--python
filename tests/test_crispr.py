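import math

import numpy as np
import pytest

from jumbophage.config import RunConfig
from jumbophage.crispr import (CrisprArray, InteractionNetwork,
                               build_interaction_network,
                               detect_crispr_arrays, match_spacers,
                               network_summary)
from jumbophage.io import GenomeRecord, HostPrediction
from jumbophage.synthetic import (generate_community, plant_crispr_targeting,
                                  random_sequence)


# ---------------------------------------------------------------------------
# brute-force oracle for spacer matching (independent implementation)
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def _mism(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b))
            if x != y or x == "N" or y == "N"]


def brute_force_hits(spacer, target_seq, max_mm=1, min_cov=0.95):
    """All qualifying loci on one strand: slide every offset, try every
    end-trim combination, keep the best window per offset, then merge
    overlapping windows keeping the best."""
    L = len(spacer)
    max_trim = L - math.ceil(min_cov * L)
    raw = []
    for o in range(len(target_seq) - L + 1):
        window = target_seq[o:o + L]
        best = None
        for lt in range(max_trim + 1):
            for rt in range(max_trim - lt + 1):
                mm = len(_mism(spacer[lt:L - rt], window[lt:L - rt]))
                if mm <= max_mm:
                    cov = (L - lt - rt) / L
                    cand = (cov, -mm, o + lt, L - lt - rt)
                    if best is None or cand > best:
                        best = cand
        if best is not None:
            cov, neg, start, span = best
            raw.append((start, span, -neg, cov))
    merged = []
    for h in sorted(raw):
        if merged and h[0] < merged[-1][0] + merged[-1][1]:
            if (h[3], -h[2]) > (merged[-1][3], -merged[-1][2]):
                merged[-1] = h
        else:
            merged.append(h)
    return merged


def brute_force_matches(spacer, target: GenomeRecord, max_mm=1, min_cov=0.95):
    out = set()
    fwd = target.sequence
    rev = fwd.translate(_RC)[::-1]
    for strand, seq in (("+", fwd), ("-", rev)):
        for start, span, mm, cov in brute_force_hits(spacer, seq, max_mm,
                                                     min_cov):
            fstart = start if strand == "+" else len(seq) - (start + span)
            out.add((fstart, strand, mm, round(cov, 6)))
    return out


# ---------------------------------------------------------------------------
# array detection
# ---------------------------------------------------------------------------

class TestArrayDetection:
    def test_planted_array_recovered_exactly(self, config):
        genomes, _, _ = generate_community(2, 0, seed=11, config=config)
        planted, truth = plant_crispr_targeting(
            genomes, [("phage_000", "phage_001", 2, 0)], seed=4,
            config=config)
        arrays = detect_crispr_arrays(planted[0], config)
        assert len(arrays) == 1
        a = arrays[0]
        assert len(a.repeats) == 5          # 2 planted + 2 filler spacers
        assert len(set(a.repeats)) == 1     # identical copies
        # the two planted spacers are exact substrings of the target genome
        interior = a.spacers[1:-1]
        assert all(s in planted[1].sequence for s in interior)

    def test_random_genome_has_no_arrays(self, rng, config):
        seq = random_sequence(rng, 100_000)
        # independent check: no 23-mer occurs three or more times at all
        # (a qualifying array needs >= 3 identical repeat copies)
        seen: dict[str, int] = {}
        for i in range(len(seq) - 23 + 1):
            w = seq[i:i + 23]
            seen[w] = seen.get(w, 0) + 1
        assert max(seen.values()) < 3
        assert detect_crispr_arrays(GenomeRecord("r", seq), config) == []

    def test_two_arrays_sorted_by_start(self, rng, config):
        repeat1, repeat2 = random_sequence(rng, 30), random_sequence(rng, 30)
        sp = [random_sequence(rng, 34) for _ in range(6)]
        array1 = repeat1 + sp[0] + repeat1 + sp[1] + repeat1 + sp[2] + repeat1
        array2 = repeat2 + sp[3] + repeat2 + sp[4] + repeat2 + sp[5] + repeat2
        seq = (random_sequence(rng, 20_000) + array1 +
               random_sequence(rng, 50_000) + array2 +
               random_sequence(rng, 20_000))
        arrays = detect_crispr_arrays(GenomeRecord("g", seq), config)
        assert len(arrays) == 2
        assert arrays[0].start < arrays[1].start
        assert arrays[0].spacers == sp[:3] and arrays[1].spacers == sp[3:]


# ---------------------------------------------------------------------------
# spacer matching
# ---------------------------------------------------------------------------

class TestSpacerMatching:
    def test_matches_equal_brute_force_oracle(self, rng, config):
        """Seeded matcher == exhaustive Hamming scan on a 40 kb fixture."""
        target = GenomeRecord("t", random_sequence(rng, 40_000))
        spacers = []
        for mm in (0, 1, 2):
            pos = int(rng.integers(0, 39_000))
            proto = list(target.sequence[pos:pos + 32])
            for i in list(rng.choice(np.arange(4, 28), size=mm,
                                     replace=False)):
                proto[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[proto[i]]
            spacers.append("".join(proto))
        spacers.append(random_sequence(rng, 32))     # random spacer: no hit
        repeat = random_sequence(rng, 30)
        array = CrisprArray("src", 0, [repeat] * (len(spacers) + 1),
                            spacers, repeat)
        source = GenomeRecord("src", random_sequence(rng, 5_000))
        matches = match_spacers([array], [source, target], config)
        for idx, spacer in enumerate(spacers):
            oracle = brute_force_matches(spacer, target)
            got = {(m.target_start, m.strand, m.mismatches,
                    round(m.coverage, 6))
                   for m in matches if m.spacer_index == idx}
            assert got == oracle, f"spacer {idx}"
        # 0-mm and 1-mm planted spacers hit; 2-mm and random do not
        hit_idx = {m.spacer_index for m in matches}
        assert hit_idx == {0, 1}

    def test_spacer_never_matches_its_own_genome(self, config):
        genomes, _, _ = generate_community(2, 0, seed=21, config=config)
        planted, _ = plant_crispr_targeting(
            genomes, [("phage_000", "phage_001", 1, 0)], seed=5,
            config=config)
        arrays = detect_crispr_arrays(planted[0], config)
        matches = match_spacers(arrays, [planted[0]], config)
        assert matches == []


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

def _match(src, tgt):
    from jumbophage.crispr import SpacerMatch
    return SpacerMatch(src, 0, 0, tgt, 100, "+", 0, 1.0)


class TestNetwork:
    def test_mutual_pair(self):
        net = build_interaction_network(
            [_match("A", "B"), _match("B", "A")], ["A", "B"])
        assert len(net.phage_phage_edges) == 2
        assert net.mutual_pairs == {frozenset({"A", "B"})}

    def test_one_way_edge_not_mutual(self):
        net = build_interaction_network([_match("A", "B")], ["A", "B"])
        assert len(net.phage_phage_edges) == 1
        assert net.mutual_pairs == set()

    def test_competitive_requires_shared_host_phylum(self):
        preds = [HostPrediction("A", ("Bacteria", "Bacillota_A")),
                 HostPrediction("B", ("Bacteria", "Bacillota_A")),
                 HostPrediction("C", ("Bacteria", "Bacteroidota"))]
        net = build_interaction_network(
            [_match("A", "B"), _match("A", "C")], ["A", "B", "C"], preds)
        assert net.competitive_pairs == {frozenset({"A", "B"})}

    def test_order_invariance(self):
        matches = [_match("A", "B"), _match("B", "A"), _match("C", "A"),
                   _match("A", "H")]
        n1 = build_interaction_network(matches, ["A", "B", "C"])
        n2 = build_interaction_network(matches[::-1], ["C", "B", "A"])
        assert n1.phage_phage_edges == n2.phage_phage_edges
        assert n1.mutual_pairs == n2.mutual_pairs
        assert n1.phage_host_edges == n2.phage_host_edges

    def test_phage_host_edge_direction(self):
        net = build_interaction_network(
            [_match("H", "A"), _match("A", "G")], ["A"])
        assert net.phage_host_edges[("H", "A")][1] == "host_to_phage"
        assert net.phage_host_edges[("A", "G")][1] == "phage_to_host"

    def test_summary_empty_network(self):
        net = InteractionNetwork({}, {}, set(), set())
        s = network_summary(net)
        assert s["total_pairs"] == 0 and s["mutual_pct_of_phage_phage"] == 0.0

    def test_mutual_count_bounded_by_pairs(self):
        matches = [_match(a, b) for a in "ABC" for b in "ABC" if a != b]
        net = build_interaction_network(matches, list("ABC"))
        s = network_summary(net)
        assert s["mutual_pairs"] <= s["phage_phage_pairs"]
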