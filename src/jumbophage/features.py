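"""Genome-level features: alternative genetic codes and crAss-like phages.

Alternative-code detection compares protein-coding density (fraction of the
genome covered by ORFs) under the standard code 11 against codes that
reassign one stop codon — 15 (TAG), 90 (TAA), 91 (TGA).  A genome whose
recoded density exceeds the code-11 density by at least 10 % is assigned the
alternative code.  The ORF caller is a deterministic six-frame maximal-ORF
scan (starts ATG/GTG/TTG, minimum 90 nt including the stop); ORFs running
into a frame boundary without a stop are kept, so removing a stop codon can
only merge or extend ORFs, never lose one.

crAss-like classification follows a dual homology criterion: a translated
(BLASTx-like) search of the genome against the crAssphage polymerase and
terminase markers (E-value < 1e-10), or fragment-based nucleotide identity
≥95 % over ≥80 % of the genome against a crAssphage reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from Bio.Seq import Seq

from ._align import karlin_altschul_evalue, translated_search_best_score
from .config import DEFAULT_CONFIG, RunConfig
from .io import GenomeRecord

GENETIC_CODES = (11, 15, 90, 91)
# stop codon removed from the standard {TAA, TAG, TGA} set by each code
REASSIGNED_STOP = {11: None, 15: "TAG", 90: "TAA", 91: "TGA"}
# amino acid the reassigned stop is read as (convention; density is
# independent of this choice)
REASSIGNED_AA = {15: "Q", 90: "Q", 91: "W"}

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_STOP_IDS = {"TAA": 48, "TAG": 50, "TGA": 56}


@dataclass
class OrfSet:
    genome_id: str
    code: int
    orfs: list[tuple[int, int, str, int]]  # (start, end) 0-based half-open
    coded_fraction: float


@dataclass
class CodeAssignment:
    genome_id: str
    densities: dict[int, float]
    assigned_code: int
    density_undefined: bool = False  # code-11 density was zero


@dataclass
class CrassCall:
    genome_id: str
    hit_polymerase: bool
    hit_terminase: bool
    best_evalue: float
    nt_identity: float | None
    aligned_fraction: float | None
    is_crass: bool
    reason: str = ""


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _frame_orfs(codes: np.ndarray, frame: int, stop_ids: set[int],
                start_ids: set[int], min_len: int) -> list[tuple[int, int]]:
    """ORF spans (nt, half-open, frame-local strand coordinates) for one frame.

    Codons containing N never act as start or stop.  A segment with no
    terminal stop (frame boundary) still yields an ORF from its first start.
    """
    n_codons = (len(codes) - frame) // 3
    if n_codons <= 0:
        return []
    c = codes[frame:frame + 3 * n_codons].reshape(-1, 3)
    valid = (c < 4).all(axis=1)
    codon_id = c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]
    codon_id[~valid] = -1
    is_stop = np.isin(codon_id, list(stop_ids))
    is_start = np.isin(codon_id, list(start_ids))
    stop_idx = np.flatnonzero(is_stop)
    start_idx = np.flatnonzero(is_start)
    if start_idx.size == 0:
        return []
    seg_begin = np.concatenate([[0], stop_idx + 1])
    seg_end = np.concatenate([stop_idx, [n_codons]])       # exclusive of stop
    has_stop = np.concatenate([np.ones(stop_idx.size, bool), [False]])
    first = np.searchsorted(start_idx, seg_begin, side="left")
    spans = []
    for b, e, stopped, fi in zip(seg_begin, seg_end, has_stop, first):
        if fi >= start_idx.size:
            continue
        s = start_idx[fi]
        if s >= e:
            continue
        end_codon = e + 1 if stopped else e   # span includes the stop codon
        nt_start = frame + 3 * s
        nt_end = frame + 3 * end_codon
        if nt_end - nt_start >= min_len:
            spans.append((nt_start, nt_end))
    return spans


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def find_orfs(genome: GenomeRecord, code: int,
              config: RunConfig = DEFAULT_CONFIG) -> OrfSet:
    """Six-frame maximal-ORF scan under one genetic code."""
    if code not in GENETIC_CODES:
        raise ValueError(f"unsupported genetic code {code}")
    length = genome.length_bp
    if length < config.orf_min_length:
        return OrfSet(genome.genome_id, code, [], 0.0)
    removed = REASSIGNED_STOP[code]
    stop_ids = {v for k, v in _STOP_IDS.items() if k != removed}
    start_ids = {int(_BASE_CODE[ord(s[0])] * 16 + _BASE_CODE[ord(s[1])] * 4 +
                     _BASE_CODE[ord(s[2])])
                 for s in config.orf_start_codons}
    fwd = _encode(genome.sequence)
    rev = _encode(genome.reverse_complement())
    orfs: list[tuple[int, int, str, int]] = []
    intervals: list[tuple[int, int]] = []
    for strand, codes_arr in (("+", fwd), ("-", rev)):
        for frame in range(3):
            for s, e in _frame_orfs(codes_arr, frame, stop_ids, start_ids,
                                    config.orf_min_length):
                if strand == "+":
                    span = (s, e)
                else:
                    span = (length - e, length - s)
                orfs.append((span[0], span[1], strand, frame))
                intervals.append(span)
    orfs.sort()
    return OrfSet(genome.genome_id, code, orfs,
                  _merged_length(intervals) / length)


def assign_genetic_code(genome: GenomeRecord,
                        config: RunConfig = DEFAULT_CONFIG) -> CodeAssignment:
    """Assign an alternative genetic code when its coding density beats the
    code-11 density by at least the configured margin (default 10 %); among
    qualifying codes the densest wins."""
    densities = {c: find_orfs(genome, c, config).coded_fraction
                 for c in GENETIC_CODES}
    d11 = densities[11]
    if d11 == 0.0:
        return CodeAssignment(genome.genome_id, densities, 11,
                              density_undefined=True)
    best_code, best_density = 11, d11
    for code in (15, 90, 91):
        if densities[code] >= (1.0 + config.code_density_margin) * d11 and \
                densities[code] > best_density:
            best_code, best_density = code, densities[code]
    return CodeAssignment(genome.genome_id, densities, best_code)


def translate_with_code(cds: str, code: int) -> str:
    """Translate a CDS under one of the supported codes (stop → '*')."""
    aa = []
    removed = REASSIGNED_STOP[code]
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        if codon == removed:
            aa.append(REASSIGNED_AA[code])
        else:
            aa.append(str(Seq(codon).translate()))
    return "".join(aa)


def crass_classify(genome: GenomeRecord,
                   marker_proteins: dict[str, str],
                   reference_genome: GenomeRecord | None = None,
                   config: RunConfig = DEFAULT_CONFIG) -> CrassCall:
    """Dual-criterion crAss-like call for genomes > 70 kb.

    Criterion 1: translated search against the polymerase/terminase markers,
    hit iff E < 1e-10 (Karlin–Altschul ungapped, search space = genome length
    × marker length × 6 frames).  Criterion 2: the genome is cut into 1-kb
    fragments, each aligned to the reference with banded semi-global edit
    distance; a fragment counts as aligned at ≥95 % identity and the genome
    passes when ≥80 % of fragments align.  Missing reference → criterion 2
    not evaluated (identity/fraction reported as None).
    """
    if genome.length_bp <= config.crass_min_genome_length:
        return CrassCall(genome.genome_id, False, False, float("inf"),
                         None, None, False, reason="size")
    hit_pol = hit_ter = False
    best_e = float("inf")
    for marker_id, marker_seq in marker_proteins.items():
        score = translated_search_best_score(genome.sequence, marker_seq)
        space = genome.length_bp * len(marker_seq) * 6
        e = karlin_altschul_evalue(score, space, config.ka_lambda,
                                   config.ka_k)
        best_e = min(best_e, e)
        if e < config.crass_evalue_max:
            if "polymerase" in marker_id.lower():
                hit_pol = True
            elif "terminase" in marker_id.lower():
                hit_ter = True
            else:
                hit_pol = True  # unnamed marker: counted on the first slot
    nt_identity = aligned_fraction = None
    crit2 = False
    if reference_genome is not None:
        nt_identity, aligned_fraction = _fragment_identity(
            genome.sequence, reference_genome.sequence, config)
        crit2 = aligned_fraction >= config.crass_aligned_fraction_min and \
            nt_identity >= config.crass_nt_identity_min
    is_crass = hit_pol or hit_ter or crit2
    return CrassCall(genome.genome_id, hit_pol, hit_ter, best_e,
                     nt_identity, aligned_fraction, is_crass,
                     reason="" if is_crass else "no criterion met")


def _fragment_identity(query: str, reference: str,
                       config: RunConfig) -> tuple[float, float]:
    """ANI-style approximation: fraction of 1-kb query fragments aligning to
    the reference (either strand) within 5 % edit distance, and the mean
    identity of the aligned fragments.  The denominator is the query genome.
    """
    frag_len = config.crass_fragment_length
    rc = str(Seq(reference).reverse_complement())
    n_aligned = 0
    identities = []
    fragments = [query[i:i + frag_len]
                 for i in range(0, len(query), frag_len)]
    # a trailing sliver shorter than half a fragment joins the previous one
    if len(fragments) > 1 and len(fragments[-1]) < frag_len // 2:
        fragments[-2] += fragments[-1]
        fragments.pop()
    for frag in fragments:
        k = int((1.0 - config.crass_nt_identity_min) * len(frag))
        best_ed = -1
        for target in (reference, rc):
            res = edlib.align(frag, target, mode="HW", task="distance", k=k)
            ed = res["editDistance"]
            if ed != -1 and (best_ed == -1 or ed < best_ed):
                best_ed = ed
        if best_ed != -1:
            n_aligned += 1
            identities.append(1.0 - best_ed / len(frag))
    aligned_fraction = n_aligned / len(fragments) if fragments else 0.0
    nt_identity = float(np.mean(identities)) if identities else 0.0
    return nt_identity, aligned_fraction
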