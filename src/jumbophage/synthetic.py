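"""Synthetic communities with planted, ground-truthed signals.

Every signal the pipeline detects can be planted here with known truth:
virus-keyword gene tables on jumbo-sized genomes, BUSCO-laden bacterial
contaminants, stop-codon-recoded genomes (codes 15/90/91), crAss-marker
genomes, CRISPR arrays whose spacers copy target-genome substrings with an
exact number of substitutions, proteome families with controlled orthologue
sharing, and compositional count matrices with planted log-scale
correlations.

The background sequence model is iid uniform nucleotides: no pipeline stage
relies on realistic composition beyond stop-codon statistics.  Generators
self-validate their planted signals with independent brute-force checks when
``RunConfig.self_validate`` is on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .config import DEFAULT_CONFIG, RunConfig
from .features import (GENETIC_CODES, REASSIGNED_STOP, assign_genetic_code,
                       translate_with_code)
from .io import GeneAnnotation, GenomeRecord, HostPrediction


class GenerationError(RuntimeError):
    """A planted signal could not be realised with the given parameters."""


@dataclass
class SyntheticTruth:
    """Ground-truth labels for everything planted in a synthetic community."""

    is_phage: dict[str, bool] = field(default_factory=dict)
    is_jumbo: dict[str, bool] = field(default_factory=dict)
    busco_ratio_planted: dict[str, float] = field(default_factory=dict)
    genetic_code_planted: dict[str, int] = field(default_factory=dict)
    is_crass: dict[str, bool] = field(default_factory=dict)
    family_planted: dict[str, str] = field(default_factory=dict)
    host_lineage_planted: dict[str, tuple[str, ...]] = field(
        default_factory=dict)
    # (source, target, n_spacers, mismatches)
    spacer_edges: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (taxon_i, taxon_j, sign)
    correlation_sign_planted: list[tuple[int, int, int]] = field(
        default_factory=list)
    latent_log_basis: np.ndarray | None = None

    def update(self, other: "SyntheticTruth") -> None:
        for name in ("is_phage", "is_jumbo", "busco_ratio_planted",
                     "genetic_code_planted", "is_crass", "family_planted",
                     "host_lineage_planted"):
            getattr(self, name).update(getattr(other, name))
        self.spacer_edges.extend(other.spacer_edges)
        self.correlation_sign_planted.extend(other.correlation_sign_planted)
        if other.latent_log_basis is not None:
            self.latent_log_basis = other.latent_log_basis


# ---------------------------------------------------------------------------
# sequence building blocks
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"
_ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
_STOPS = ("TAA", "TAG", "TGA")
_STARTS = ("ATG", "GTG", "TTG")
_NONSTOP = [c for c in _ALL_CODONS if c not in _STOPS]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def random_protein(rng: np.random.Generator, lo: int = 100,
                   hi: int = 400) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(_AA), size=n))


def _gene_cds(rng: np.random.Generator, n_body_codons: int,
              terminal_stop: str, body_alphabet=None,
              internal_codon: str | None = None,
              internal_every: tuple[int, int] = (12, 18)) -> str:
    """Build a CDS: ATG + body + terminal stop; optionally interleave a
    reassigned-stop codon into the body at short intervals."""
    body_alphabet = body_alphabet or _NONSTOP
    body = list(rng.choice(body_alphabet, size=n_body_codons))
    if internal_codon is not None:
        pos = int(rng.integers(*internal_every))
        while pos < len(body):
            body[pos] = internal_codon
            pos += int(rng.integers(*internal_every))
    return "ATG" + "".join(body) + terminal_stop


# Two-codon cassettes planting a stop in each non-coding frame of a gene
# body (forward +1/+2 and all three reverse offsets), in two stop-codon
# flavours each, so reassigning any single stop codon still leaves every
# shifted/reverse frame with in-cycle stops.  No cassette codon is a
# frame-0 stop or start.
_FRAME_STOP_CASSETTES = (
    ("CTA", "ACC"),   # +1 TAA;  reverse offset 3 TAG
    ("CCT", "GAC"),   # +2 TGA
    ("CCT", "TAT"),   # reverse offset 1 TAA
    ("ATC", "ACC"),   # reverse offset 2 TGA
    ("CTG", "ACC"),   # +1 TGA
    ("CCT", "AAC"),   # +2 TAA;  reverse offset 2 TAG
    ("CCT", "CAT"),   # reverse offset 1 TGA
    ("TCA", "CCC"),   # reverse offset 3 TGA
)
# filler codons: none is a frame-0 stop or start; drawn at random so gene
# bodies carry enough sequence entropy that no exact >=23 nt repeat recurs
# at CRISPR-like spacing
_SAFE_FILLERS = ("GCT", "GCA", "GCC", "GCG", "CAT", "CAC", "CCG", "CGT",
                 "ACT", "ACA", "TCT", "TCC", "AGA", "AGG", "CGA", "CGC")


def _recoded_gene_cds(rng: np.random.Generator, n_units: int,
                      terminal_stop: str, internal_codon: str | None) -> str:
    """Gene body for recoded genomes: cassette cycle + safe filler, with the
    reassigned stop codon replacing a filler every 4–6 units.  Standard-code
    ORFs fragment below the minimum length (no internal frame-0 starts, the
    reassigned codon stops them) and no shifted/reverse frame can host a
    long ORF (cassette stops every ≤72 nt in every frame)."""
    body: list[str] = []
    next_internal = int(rng.integers(4, 7))
    order: list[int] = []
    for u in range(n_units):
        if not order:
            # a fresh random permutation each cycle keeps every frame's
            # stops while breaking the sequence periodicity (a strictly
            # periodic body would mimic a CRISPR repeat structure)
            order = list(rng.permutation(len(_FRAME_STOP_CASSETTES)))
        c1, c2 = _FRAME_STOP_CASSETTES[order.pop()]
        filler = _SAFE_FILLERS[int(rng.integers(len(_SAFE_FILLERS)))]
        if internal_codon is not None and u == next_internal:
            filler = internal_codon
            next_internal += int(rng.integers(4, 7))
        body += [c1, c2, filler]
    return "ATG" + "".join(body) + terminal_stop


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    """Encode a protein as an in-frame CDS with random synonymous codons."""
    table = {}
    for codon in _NONSTOP:
        aa = str(Seq(codon).translate())
        table.setdefault(aa, []).append(codon)
    return "".join(rng.choice(table[a]) for a in protein)


# ---------------------------------------------------------------------------
# community generation
# ---------------------------------------------------------------------------

_KEYWORD_PRODUCTS = (
    "terminase large subunit", "major capsid protein", "portal protein",
    "tail fiber protein", "baseplate wedge protein", "prohead protease",
)
_EXCLUSION_PRODUCTS = (
    "50S ribosomal protein L3", "DNA gyrase subunit A",
    "preprotein translocase subunit SecY",
)
_TAIL_RESERVE = 3_000  # gene-free 3' region kept for CRISPR-array planting


def _build_genome_with_genes(rng: np.random.Generator, genome_id: str,
                             length: int, products: list[str],
                             hit_label_of: dict[int, str],
                             busco_genes: set[int],
                             ) -> tuple[GenomeRecord, list[GeneAnnotation]]:
    """Random background with CDS genes written in at tiled positions.

    ``products[i]`` is gene i's product text; genes stop before the reserved
    gene-free tail so later array planting cannot clobber them.
    """
    seq = np.frombuffer(random_sequence(rng, length).encode(), dtype=np.uint8
                        ).copy()
    genes: list[GeneAnnotation] = []
    pos = int(rng.integers(100, 300))
    limit = length - _TAIL_RESERVE
    stop_cycle = itertools.cycle(_STOPS)
    for idx, product in enumerate(products, start=1):
        n_body = int(rng.integers(250, 500))
        cds = _gene_cds(rng, n_body, next(stop_cycle))
        if pos + len(cds) >= limit:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        protein = str(Seq(cds[:-3]).translate())
        written = cds if strand == "+" else \
            str(Seq(cds).reverse_complement())
        seq[pos:pos + len(cds)] = np.frombuffer(written.encode(),
                                                dtype=np.uint8)
        genes.append(GeneAnnotation(
            genome_id=genome_id, gene_index=idx,
            start=pos + 1, end=pos + len(cds), strand=strand,
            protein=protein, product_text=product,
            hit_labels=frozenset({hit_label_of.get(idx - 1, "none")} -
                                 {"none"}),
            busco_hit=(idx - 1) in busco_genes,
        ))
        pos += len(cds) + int(rng.integers(40, 120))
    record = GenomeRecord(genome_id=genome_id, sequence=seq.tobytes().decode())
    return record, genes


def generate_community(n_phage: int, n_contaminant: int, seed: int,
                       config: RunConfig = DEFAULT_CONFIG
                       ) -> tuple[list[GenomeRecord], list[GeneAnnotation],
                                  SyntheticTruth]:
    """Jumbo phage genomes (200–300 kb, ≥2 virus-keyword genes, no exclusion
    terms, BUSCO-free) plus bacterial contaminant contigs (BUSCO hits on
    ~20 % of genes, exclusion terms present)."""
    if n_phage < 0 or n_contaminant < 0:
        raise ValueError("genome counts must be >= 0")
    rng = np.random.default_rng(seed)
    genomes: list[GenomeRecord] = []
    annotations: list[GeneAnnotation] = []
    truth = SyntheticTruth()
    for k in range(n_phage):
        gid = f"phage_{k:03d}"
        length = int(rng.integers(210_000, 300_001))
        n_genes = length // 1_500
        products = ["hypothetical protein"] * n_genes
        n_kw = int(rng.integers(3, 7))
        kw_slots = rng.choice(n_genes, size=n_kw, replace=False)
        for slot in kw_slots:
            products[slot] = str(rng.choice(_KEYWORD_PRODUCTS))
        labels = {i: "viral_family" for i in
                  rng.choice(n_genes, size=max(1, n_genes // 3),
                             replace=False)}
        record, genes = _build_genome_with_genes(
            rng, gid, length, products, labels, set())
        genomes.append(record)
        annotations.extend(genes)
        truth.is_phage[gid] = True
        truth.is_jumbo[gid] = True
        truth.busco_ratio_planted[gid] = 0.0
        truth.genetic_code_planted[gid] = 11
        truth.is_crass[gid] = False
    for k in range(n_contaminant):
        gid = f"contam_{k:03d}"
        length = int(rng.integers(210_000, 300_001))
        n_genes = length // 1_500
        products = ["hypothetical protein"] * n_genes
        n_excl = int(rng.integers(2, 5))
        for slot in rng.choice(n_genes, size=n_excl, replace=False):
            products[slot] = str(rng.choice(_EXCLUSION_PRODUCTS))
        labels = {i: "microbial_family" for i in
                  rng.choice(n_genes, size=max(1, n_genes // 2),
                             replace=False)}
        n_busco = max(1, int(0.2 * n_genes))
        busco = set(rng.choice(n_genes, size=n_busco, replace=False).tolist())
        record, genes = _build_genome_with_genes(
            rng, gid, length, products, labels, busco)
        genomes.append(record)
        annotations.extend(genes)
        truth.is_phage[gid] = False
        truth.is_jumbo[gid] = False
        truth.busco_ratio_planted[gid] = \
            sum(1 for g in genes if g.busco_hit) / len(genes)
        truth.genetic_code_planted[gid] = 11
        truth.is_crass[gid] = False
    if config.self_validate:
        _validate_community(genomes, annotations, truth, config)
    return genomes, annotations, truth


def _validate_community(genomes, annotations, truth, config) -> None:
    from .discovery import count_keyword_genes, has_exclusion_term
    by_genome: dict[str, list[GeneAnnotation]] = {}
    for g in annotations:
        by_genome.setdefault(g.genome_id, []).append(g)
    for record in genomes:
        genes = by_genome.get(record.genome_id, [])
        ratio = sum(1 for g in genes if g.busco_hit) / len(genes) if genes \
            else 0.0
        if truth.is_phage[record.genome_id]:
            ok = (count_keyword_genes(genes, config.virus_keywords) >= 2
                  and not has_exclusion_term(genes, config.exclusion_terms)
                  and ratio < config.busco_max_ratio
                  and record.length_bp > config.jumbo_min_length)
        else:
            ok = ratio > config.busco_max_ratio
        if not ok:
            raise GenerationError(
                f"planted labels not re-detectable for {record.genome_id}")


# ---------------------------------------------------------------------------
# recoded genomes
# ---------------------------------------------------------------------------

def generate_recoded_genome(code: int, length_bp: int, seed: int,
                            config: RunConfig = DEFAULT_CONFIG,
                            genome_id: str | None = None,
                            return_layout: bool = False):
    """A genome whose coding density under ``code`` exceeds the code-11
    density by at least the configured margin (for alternative codes), or a
    clean standard-code genome (code 11).

    Alternative-code genes carry the reassigned stop codon in-frame every
    12–18 codons and no internal start codons, so standard-code ORFs
    fragment below the minimum length; gene bodies avoid the other stops.
    The margin is re-verified at generation time.
    """
    if code not in GENETIC_CODES:
        raise ValueError(f"unsupported genetic code {code}")
    if length_bp < 3_000:
        raise GenerationError(
            f"length {length_bp} too short to realise a coding-density "
            f"margin; use a longer genome (>= 3000 bp)")
    rng = np.random.default_rng(seed)
    gid = genome_id or f"recoded_c{code}_{seed}"
    internal = REASSIGNED_STOP[code]          # None for code 11
    if code == 11:
        terminal_stops = itertools.cycle(_STOPS)
    else:
        remaining = [s for s in _STOPS if s != internal]
        terminal_stops = itertools.cycle(remaining[:1])
    seq = np.frombuffer(random_sequence(rng, length_bp).encode(),
                        dtype=np.uint8).copy()
    layout: list[tuple[int, int, str]] = []   # (start0, end0 excl, cds)
    pos = int(rng.integers(50, 150))
    limit = length_bp - _TAIL_RESERVE if length_bp > 3 * _TAIL_RESERVE \
        else length_bp - 100
    while True:
        if code == 11:
            n_body = int(rng.integers(250, 500))
            cds = _gene_cds(rng, n_body, next(terminal_stops))
        else:
            n_units = int(rng.integers(90, 170))
            cds = _recoded_gene_cds(rng, n_units, next(terminal_stops),
                                    internal)
        if pos + len(cds) >= limit:
            break
        seq[pos:pos + len(cds)] = np.frombuffer(cds.encode(), dtype=np.uint8)
        layout.append((pos, pos + len(cds), cds))
        pos += len(cds) + int(rng.integers(40, 120))
    record = GenomeRecord(genome_id=gid, sequence=seq.tobytes().decode())
    if config.self_validate:
        assignment = assign_genetic_code(record, config)
        d11 = assignment.densities[11]
        margin = 1.0 + config.code_density_margin
        if code == 11:
            gains = [assignment.densities[c] for c in (15, 90, 91)]
            ok = d11 > 0 and all(g < margin * d11 for g in gains)
        else:
            ok = d11 > 0 and \
                assignment.densities[code] >= margin * d11 and \
                assignment.assigned_code == code
        if not ok:
            raise GenerationError(
                f"coding-density margin not realised for code {code} at "
                f"length {length_bp}; advise a larger length")
    if return_layout:
        return record, layout
    return record


def annotations_for_recoded(record: GenomeRecord,
                            layout: list[tuple[int, int, str]],
                            code: int, rng: np.random.Generator
                            ) -> list[GeneAnnotation]:
    """Gene table for a recoded genome (proteins translated under its code);
    a few genes get virus-keyword products so discovery retains the genome."""
    genes = []
    kw_slots = set(rng.choice(len(layout), size=min(4, len(layout)),
                              replace=False).tolist())
    for idx, (s, e, cds) in enumerate(layout):
        product = str(rng.choice(_KEYWORD_PRODUCTS)) if idx in kw_slots \
            else "hypothetical protein"
        genes.append(GeneAnnotation(
            genome_id=record.genome_id, gene_index=idx + 1,
            start=s + 1, end=e, strand="+",
            protein=translate_with_code(cds[3:-3], code),
            product_text=product,
            hit_labels=frozenset({"viral_family"}) if idx in kw_slots
            else frozenset(),
            busco_hit=False))
    return genes


# ---------------------------------------------------------------------------
# crAss-marker genomes
# ---------------------------------------------------------------------------

def generate_crass_genome(marker_proteins: dict[str, str], length_bp: int,
                          seed: int, genome_id: str = "crass_000"
                          ) -> GenomeRecord:
    """Random genome carrying exact in-frame CDS copies of the marker
    proteins (so the translated search scores a full-length exact hit)."""
    if length_bp < 70_000:
        raise GenerationError("crAss-like genomes must exceed 70 kb")
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(random_sequence(rng, length_bp).encode(),
                        dtype=np.uint8).copy()
    pos = 10_000
    for marker in marker_proteins.values():
        cds = _reverse_translate(rng, marker)
        if pos + len(cds) >= length_bp - _TAIL_RESERVE:
            raise GenerationError("genome too short for the markers")
        seq[pos:pos + len(cds)] = np.frombuffer(cds.encode(), dtype=np.uint8)
        pos += len(cds) + 5_000
    return GenomeRecord(genome_id=genome_id, sequence=seq.tobytes().decode())


# ---------------------------------------------------------------------------
# CRISPR targeting
# ---------------------------------------------------------------------------

def plant_crispr_targeting(genomes: list[GenomeRecord],
                           edge_spec: list[tuple[str, str, int, int]],
                           seed: int,
                           config: RunConfig = DEFAULT_CONFIG
                           ) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Insert one repeat-spacer array per source genome whose spacers copy
    target-genome substrings with exactly the requested substitutions.

    The array replaces sequence in the reserved gene-free 3' tail, so gene
    tables built by the community generators stay valid.  Substitutions are
    placed ≥3 positions from the spacer ends, so boundary trimming during
    matching cannot change the planted mismatch count.  Filler spacers pad
    each array to ≥3 repeat copies and their boundary bases are chosen to
    differ from the planted spacers', pinning repeat-boundary detection.
    """
    rng = np.random.default_rng(seed)
    by_id = {g.genome_id: g for g in genomes}
    truth = SyntheticTruth()
    edges_by_source: dict[str, list[tuple[str, int, int]]] = {}
    for source, target, n_spacers, mismatches in edge_spec:
        if source not in by_id or target not in by_id:
            raise ValueError(f"unknown genome in edge {source}->{target}")
        if n_spacers < 1:
            raise ValueError("each edge needs >= 1 spacer")
        edges_by_source.setdefault(source, []).append(
            (target, n_spacers, mismatches))
        truth.spacer_edges.append((source, target, n_spacers, mismatches))
    out: dict[str, GenomeRecord] = dict(by_id)
    for source, edges in edges_by_source.items():
        spacers: list[str] = []
        planted: list[tuple[str, str, int]] = []  # (spacer, target, mism)
        for target, n_spacers, mismatches in edges:
            for _ in range(n_spacers):
                spacer, proto = _planted_spacer(rng, by_id[target].sequence,
                                                mismatches)
                spacers.append(spacer)
                planted.append((spacer, target, mismatches))
        repeat = random_sequence(rng, int(rng.integers(28, 36)))
        f1 = _filler_spacer(rng, avoid_first=spacers[0][0],
                            avoid_last=spacers[0][-1])
        f2 = _filler_spacer(rng)
        ordered = [f1] + spacers + [f2]
        array = repeat + repeat.join(ordered) + repeat
        genome = out[source]
        span = len(array)
        lo = genome.length_bp - _TAIL_RESERVE + 200
        hi = genome.length_bp - 200 - span
        if hi <= lo:
            raise GenerationError(
                f"{source}: genome tail too short for a {span} nt array")
        start = int(rng.integers(lo, hi))
        seq = genome.sequence[:start] + array + \
            genome.sequence[start + span:]
        out[source] = GenomeRecord(genome_id=source, sequence=seq,
                                   sample_id=genome.sample_id,
                                   country=genome.country)
        if config.self_validate:
            for spacer, target, mism in planted:
                if _min_hamming(spacer, by_id[target].sequence) != mism:
                    raise GenerationError(
                        f"planted spacer distance != {mism} for "
                        f"{source}->{target}")
    return [out[g.genome_id] for g in genomes], truth


def _planted_spacer(rng: np.random.Generator, target_seq: str,
                    mismatches: int, length: int = 32) -> tuple[str, str]:
    if mismatches > length:
        raise ValueError("mismatches cannot exceed spacer length")
    pos = int(rng.integers(0, len(target_seq) - length))
    proto = target_seq[pos:pos + length]
    spacer = list(proto)
    # substitutions stay >=3 bases from either end
    sites = rng.choice(np.arange(3, length - 3), size=mismatches,
                       replace=False)
    for i in sites:
        spacer[i] = str(rng.choice([b for b in "ACGT" if b != proto[i]]))
    return "".join(spacer), proto


def _filler_spacer(rng: np.random.Generator, avoid_first: str = "",
                   avoid_last: str = "") -> str:
    s = list(random_sequence(rng, int(rng.integers(30, 41))))
    if avoid_first and s[0] == avoid_first:
        s[0] = str(rng.choice([b for b in "ACGT" if b != avoid_first]))
    if avoid_last and s[-1] == avoid_last:
        s[-1] = str(rng.choice([b for b in "ACGT" if b != avoid_last]))
    return "".join(s)


def _min_hamming(spacer: str, target_seq: str) -> int:
    """Brute-force minimum Hamming distance of ``spacer`` against every
    window of ``target_seq`` (both strands); generation self-check."""
    best = len(spacer)
    rc = str(Seq(spacer).reverse_complement())
    for probe in (spacer, rc):
        arr = np.frombuffer(probe.encode(), dtype=np.uint8)
        t = np.frombuffer(target_seq.encode(), dtype=np.uint8)
        if t.size < arr.size:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(t, arr.size)
        dist = (windows != arr).sum(axis=1).min()
        best = min(best, int(dist))
    return best


# ---------------------------------------------------------------------------
# proteome families
# ---------------------------------------------------------------------------

def generate_proteome_families(family_sizes: list[int], within: float,
                               between: float, seed: int,
                               n_proteins: int = 40,
                               config: RunConfig = DEFAULT_CONFIG
                               ) -> tuple[dict[str, dict[str, str]],
                                          SyntheticTruth]:
    """Proteomes with controlled orthologue sharing: genomes of one family
    share ≥ ``within`` of their proteins (≥95 %-identical copies of a family
    core), genomes of different families share ≤ ``between``."""
    if within <= between:
        raise GenerationError(
            "within-family sharing must exceed between-family sharing")
    rng = np.random.default_rng(seed)
    n_global = round(between * n_proteins)
    n_core = round(within * n_proteins) - n_global
    if n_core <= 0:
        raise GenerationError("within fraction too small for the core size")
    global_pool = [random_protein(rng) for _ in range(n_global)]
    proteomes: dict[str, dict[str, str]] = {}
    truth = SyntheticTruth()
    for f_idx, size in enumerate(family_sizes):
        family = f"F{f_idx}"
        core = [random_protein(rng) for _ in range(n_core)]
        for g_idx in range(size):
            gid = f"fam{f_idx}_g{g_idx}"
            prot: dict[str, str] = {}
            for p_idx, p in enumerate(global_pool):
                prot[f"{gid}|glob{p_idx}"] = _mutate(rng, p, 0.02)
            for p_idx, p in enumerate(core):
                prot[f"{gid}|core{f_idx}_{p_idx}"] = _mutate(rng, p, 0.02)
            n_unique = n_proteins - n_global - n_core
            for p_idx in range(n_unique):
                prot[f"{gid}|uniq{p_idx}"] = random_protein(rng)
            proteomes[gid] = prot
            truth.family_planted[gid] = family
    if config.self_validate:
        _validate_families(proteomes, truth, within, between, n_proteins)
    return proteomes, truth


def _mutate(rng: np.random.Generator, protein: str, rate: float) -> str:
    s = list(protein)
    n_mut = int(round(rate * len(s)))
    for i in rng.choice(len(s), size=n_mut, replace=False):
        s[i] = str(rng.choice([a for a in _AA if a != s[i]]))
    return "".join(s)


def _validate_families(proteomes, truth, within, between,
                       n_proteins) -> None:
    """Count shared planted proteins directly (by construction key)."""
    for a, b in itertools.combinations(sorted(proteomes), 2):
        keys_a = {k.split("|", 1)[1] for k in proteomes[a]
                  if "|uniq" not in k}
        keys_b = {k.split("|", 1)[1] for k in proteomes[b]
                  if "|uniq" not in k}
        shared = len(keys_a & keys_b) / n_proteins
        same = truth.family_planted[a] == truth.family_planted[b]
        if same and shared < within - 1e-9:
            raise GenerationError("within-family sharing below target")
        if not same and shared > between + 1e-9:
            raise GenerationError("between-family sharing above target")


# ---------------------------------------------------------------------------
# full study community
# ---------------------------------------------------------------------------

_PHYLA = ("Bacillota_A", "Bacteroidota", "Fibrobacterota", "Spirochaetota")
_COUNTRIES = ("China", "Denmark", "US", "France")


@dataclass
class StudyCommunity:
    """A complete synthetic study: candidate contigs with gene tables,
    prokaryote genomes carrying spacer evidence, host predictions, lifestyle
    scores, planted proteome families and a planted co-abundance matrix,
    with full ground truth."""

    genomes: list[GenomeRecord]
    annotations: list[GeneAnnotation]
    prokaryote_genomes: list[GenomeRecord]
    host_predictions: list[HostPrediction]
    lifestyle_scores: dict[str, tuple[float, bool]]
    proteomes: dict[str, dict[str, str]]
    counts: np.ndarray
    taxa_ids: list[str]
    sample_ids: list[str]
    sample_countries: dict[str, str]
    crass_markers: dict[str, str]
    truth: SyntheticTruth


def generate_study_community(seed: int,
                             n_phage: int = 20, n_contaminant: int = 5,
                             n_recoded: int = 2, n_crass: int = 1,
                             n_hosts: int = 3, n_samples: int = 200,
                             phage_edges: list[tuple[str, str, int, int]]
                             | None = None,
                             n_families: int = 3,
                             planted_pairs: list[tuple[int, int, int]]
                             | None = None,
                             config: RunConfig = DEFAULT_CONFIG
                             ) -> StudyCommunity:
    """Generate the full study community with every planted signal.

    Defaults mirror the synthetic acceptance conditions: 20 jumbo phages,
    5 bacterial contaminants, 2 stop-codon-recoded genomes (codes 15 and
    91), 1 crAss-marker genome, 10 planted phage–phage spacer edges of which
    two carry 2 mismatches (negative controls), 3 proteome families over the
    retained genomes, and 4 planted ±0.9 co-abundance correlations.
    """
    from . import packaged_crass_markers
    rng = np.random.default_rng(seed)
    genomes, annotations, truth = generate_community(
        n_phage, n_contaminant, int(rng.integers(2**31)), config)

    # recoded genomes (alternate codes cycle over 15, 91, 90)
    for k, code in zip(range(n_recoded), itertools.cycle((15, 91, 90))):
        gid = f"recoded_{k:03d}"
        rec, layout = generate_recoded_genome(
            code, int(rng.integers(220_000, 280_000)),
            int(rng.integers(2**31)), config, genome_id=gid,
            return_layout=True)
        genomes.append(rec)
        annotations.extend(annotations_for_recoded(rec, layout, code, rng))
        truth.is_phage[gid] = True
        truth.is_jumbo[gid] = True
        truth.busco_ratio_planted[gid] = 0.0
        truth.genetic_code_planted[gid] = code
        truth.is_crass[gid] = False

    # crAss-marker genomes (jumbo-sized, keyword genes appended as a table)
    markers = packaged_crass_markers()
    for k in range(n_crass):
        gid = f"crass_{k:03d}"
        rec = generate_crass_genome(markers, int(rng.integers(
            210_000, 260_000)), int(rng.integers(2**31)), genome_id=gid)
        genomes.append(rec)
        annotations.extend(_marker_region_annotations(rec, rng))
        truth.is_phage[gid] = True
        truth.is_jumbo[gid] = True
        truth.busco_ratio_planted[gid] = 0.0
        truth.genetic_code_planted[gid] = 11
        truth.is_crass[gid] = True

    phage_ids = [g for g, v in truth.is_phage.items() if v]
    # prokaryote genomes whose CRISPR arrays give every phage spacer evidence
    prokaryotes = [GenomeRecord(f"host_{h:03d}",
                                random_sequence(rng, 100_000))
                   for h in range(n_hosts)]
    host_edges = []
    if n_hosts:
        for i, pid in enumerate(phage_ids):
            host_edges.append((f"host_{i % n_hosts:03d}", pid, 1, 0))
    # phage–phage edges: default 10, two of them 2-mismatch negatives,
    # two mutual pairs among the positives
    if phage_edges is None and n_phage >= 8:
        p = [f"phage_{k:03d}" for k in range(n_phage)]
        phage_edges = [
            (p[0], p[1], 1, 0), (p[1], p[0], 1, 0),   # mutual pair
            (p[2], p[3], 1, 1), (p[3], p[2], 1, 0),   # mutual pair
            (p[4], p[5], 2, 0),
            (p[5], p[6], 1, 1),
            (p[6], p[7], 1, 0),
            (p[0], p[4], 1, 1),
            (p[2], p[6], 1, 2),                        # negative control
            (p[7], p[3], 1, 2),                        # negative control
        ]
    phage_edges = phage_edges or []
    all_genomes = genomes + prokaryotes
    all_genomes, spacer_truth = plant_crispr_targeting(
        all_genomes, host_edges + phage_edges, int(rng.integers(2**31)),
        config)
    truth.spacer_edges.extend(spacer_truth.spacer_edges)
    genomes = all_genomes[:len(genomes)]
    prokaryotes = all_genomes[len(genomes):]

    # host predictions: mostly one bacterial phylum; one generalist and one
    # archaeal phage when the community is large enough
    host_predictions: list[HostPrediction] = []
    for i, pid in enumerate(phage_ids):
        if i == 1:
            host_predictions.append(HostPrediction(
                pid, ("Bacteria", "Bacillota_A", "Lachnospirales")))
            host_predictions.append(HostPrediction(
                pid, ("Bacteria", "Bacteroidota", "Bacteroidales")))
            truth.host_lineage_planted[pid] = ("Bacteria", "generalist")
        elif i == 2:
            host_predictions.append(HostPrediction(
                pid, ("Archaea", "Methanobacteriota", "Methanobacteriales")))
            truth.host_lineage_planted[pid] = ("Archaea", "Methanobacteriota")
        else:
            phylum = _PHYLA[i % len(_PHYLA)]
            host_predictions.append(HostPrediction(
                pid, ("Bacteria", phylum)))
            truth.host_lineage_planted[pid] = ("Bacteria", phylum)

    lifestyle_scores = {
        pid: (float(rng.uniform(0, 1)), bool(rng.random() < 0.15))
        for pid in phage_ids}

    # proteome families over the retained (phage) genomes
    sizes = [len(phage_ids) // n_families +
             (1 if k < len(phage_ids) % n_families else 0)
             for k in range(n_families)]
    fam_proteomes, fam_truth = generate_proteome_families(
        sizes, within=0.6, between=0.0, seed=int(rng.integers(2**31)),
        config=config)
    proteomes: dict[str, dict[str, str]] = {}
    fam_ids = sorted(fam_proteomes)
    for pid, fam_gid in zip(sorted(phage_ids), fam_ids):
        proteomes[pid] = fam_proteomes[fam_gid]
        truth.family_planted[pid] = fam_truth.family_planted[fam_gid]

    # planted co-abundance structure over the retained genomes
    taxa_ids = sorted(phage_ids)
    if planted_pairs is None:
        planted_pairs = [(i, j, s) for i, j, s in
                         [(0, 1, 1), (2, 3, 1), (4, 5, 1), (6, 7, -1)]
                         if j < len(taxa_ids)]
    counts, abund_truth = generate_abundance_matrix(
        len(taxa_ids), n_samples, planted_pairs,
        int(rng.integers(2**31)), config=config)
    truth.correlation_sign_planted.extend(
        abund_truth.correlation_sign_planted)
    truth.latent_log_basis = abund_truth.latent_log_basis

    sample_ids = [f"S{k:03d}" for k in range(n_samples)]
    sample_countries = {s: _COUNTRIES[k % len(_COUNTRIES)]
                        for k, s in enumerate(sample_ids)}
    return StudyCommunity(
        genomes=genomes, annotations=annotations,
        prokaryote_genomes=prokaryotes,
        host_predictions=host_predictions,
        lifestyle_scores=lifestyle_scores, proteomes=proteomes,
        counts=counts, taxa_ids=taxa_ids, sample_ids=sample_ids,
        sample_countries=sample_countries, crass_markers=markers,
        truth=truth)


def _marker_region_annotations(record: GenomeRecord,
                               rng: np.random.Generator
                               ) -> list[GeneAnnotation]:
    """Minimal keyword-bearing gene table for a crAss-marker genome."""
    genes = []
    for idx in range(6):
        start = 50_000 + idx * 2_000
        product = str(rng.choice(_KEYWORD_PRODUCTS)) if idx < 3 \
            else "hypothetical protein"
        genes.append(GeneAnnotation(
            genome_id=record.genome_id, gene_index=idx + 1,
            start=start + 1, end=start + 900, strand="+",
            protein=random_protein(rng, 100, 300),
            product_text=product,
            hit_labels=frozenset({"viral_family"}) if idx < 3
            else frozenset(),
            busco_hit=False))
    return genes


# ---------------------------------------------------------------------------
# compositional abundance matrices
# ---------------------------------------------------------------------------

def generate_abundance_matrix(n_taxa: int, n_samples: int,
                              planted_pairs: list[tuple[int, int, int]],
                              seed: int, total_depth: float = 1e5,
                              planted_rho: float = 0.9,
                              config: RunConfig = DEFAULT_CONFIG
                              ) -> tuple[np.ndarray, SyntheticTruth]:
    """Log-normal basis abundances with ±0.9 log-scale correlation on the
    planted (disjoint) pairs, converted to compositions and scaled to
    depth-like counts (total ~1e5 per sample so resampling noise is small
    relative to planted effects)."""
    if n_taxa < 3:
        raise ValueError("correlation inference undefined below 3 taxa")
    used: set[int] = set()
    corr = np.eye(n_taxa)
    for i, j, sign in planted_pairs:
        if i == j or not (0 <= i < n_taxa and 0 <= j < n_taxa):
            raise ValueError(f"invalid planted pair ({i}, {j})")
        if {i, j} & used:
            raise ValueError("planted pairs must be disjoint")
        used |= {i, j}
        corr[i, j] = corr[j, i] = planted_rho * (1 if sign > 0 else -1)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_samples, n_taxa)) @ chol.T
    mu = rng.uniform(np.log(50.0), np.log(500.0), size=n_taxa)
    log_basis = mu[None, :] + z
    basis = np.exp(log_basis)
    fractions = basis / basis.sum(axis=1, keepdims=True)
    counts = np.rint(fractions * total_depth).astype(np.int64).T
    truth = SyntheticTruth(
        correlation_sign_planted=[(i, j, 1 if s > 0 else -1)
                                  for i, j, s in planted_pairs],
        latent_log_basis=log_basis)
    if config.self_validate and n_samples >= 100:
        c = np.corrcoef(log_basis, rowvar=False)
        for i, j, sign in planted_pairs:
            if c[i, j] * (1 if sign > 0 else -1) < 0.8:
                raise GenerationError(
                    f"planted correlation ({i},{j}) not realised")
    return counts, truth
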