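"""Jumbo-phage discovery rules.

A contig is screened with four viral signatures, called a phage by the
keyword/exclusion/spacer rule, cleared of bacterial false positives by the
BUSCO ratio, and kept as a *jumbo* phage when longer than 200 kb.  Lifestyle
is assigned from a lysogeny score (virulent < 0.5, uncertain 0.5–0.9,
temperate > 0.9) merged with provirus evidence; host breadth is classified
from host-prediction lineages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Iterable, Sequence

from .config import DEFAULT_CONFIG, RunConfig
from .io import GeneAnnotation, GenomeRecord, HostPrediction


@dataclass
class ViralSignatureResult:
    genome_id: str
    has_viral_families: bool
    lacks_microbial_families: bool
    has_viral_nt_signature: bool
    has_strand_runs: bool

    @property
    def n_signatures(self) -> int:
        return sum((self.has_viral_families, self.lacks_microbial_families,
                    self.has_viral_nt_signature, self.has_strand_runs))


@dataclass
class PhageCall:
    genome_id: str
    n_keyword_genes: int
    has_exclusion_term: bool
    has_spacer_evidence: bool
    is_phage: bool
    busco_hits: int
    n_genes: int
    busco_ratio: float
    passes_busco: bool
    is_jumbo: bool


@dataclass
class LifestyleCall:
    genome_id: str
    score: float
    provirus_flag: bool
    lifestyle: str  # virulent | uncertain | temperate


def score_viral_signatures(
    genome: GenomeRecord,
    annotations: Sequence[GeneAnnotation],
    config: RunConfig = DEFAULT_CONFIG,
    nt_signature_predicate: Callable[[GenomeRecord], bool] | None = None,
) -> ViralSignatureResult:
    """Compute the four-signature viral screen for one contig.

    The nucleotide-signature predicate is pluggable (no trained sequence
    model ships with the package); the default never fires.
    """
    genes = [g for g in annotations if g.genome_id == genome.genome_id]
    n = len(genes)
    viral = sum(1 for g in genes if "viral_family" in g.hit_labels)
    microbial = sum(1 for g in genes if "microbial_family" in g.hit_labels)
    has_viral = n > 0 and viral / n >= config.viral_family_min_fraction
    lacks_microbial = n > 0 and \
        microbial / n <= config.microbial_family_max_fraction
    # longest same-strand run over genes ordered along the genome
    run = best_run = 0
    prev = None
    for g in sorted(genes, key=lambda g: g.start):
        run = run + 1 if g.strand == prev else 1
        prev = g.strand
        best_run = max(best_run, run)
    has_runs = best_run >= config.strand_run_min_genes
    has_nt = bool(nt_signature_predicate(genome)) if nt_signature_predicate \
        else False
    return ViralSignatureResult(
        genome_id=genome.genome_id,
        has_viral_families=has_viral,
        lacks_microbial_families=lacks_microbial,
        has_viral_nt_signature=has_nt,
        has_strand_runs=has_runs,
    )


def count_keyword_genes(annotations: Iterable[GeneAnnotation],
                        keywords: Sequence[str]) -> int:
    """Genes whose product text contains any virus keyword (case-insensitive
    substring; 'tail' inside 'tailless' counts — a documented limitation of
    keyword-list screening)."""
    lowered = [k.lower() for k in keywords]
    return sum(1 for g in annotations
               if any(k in g.product_text.lower() for k in lowered))


def has_exclusion_term(annotations: Iterable[GeneAnnotation],
                       terms: Sequence[str]) -> bool:
    lowered = [t.lower() for t in terms]
    return any(t in g.product_text.lower()
               for g in annotations for t in lowered)


def busco_filter(annotations: Sequence[GeneAnnotation],
                 config: RunConfig = DEFAULT_CONFIG) -> tuple[float, bool]:
    """BUSCO ratio = bacterial-marker hits / total genes; pass iff < 0.067.

    The boundary is strict: a ratio of exactly 0.067 fails.
    """
    n = len(annotations)
    if n == 0:
        raise ValueError("BUSCO ratio undefined for a genome with zero genes")
    ratio = sum(1 for g in annotations if g.busco_hit) / n
    return ratio, ratio < config.busco_max_ratio


def call_phage(genome: GenomeRecord,
               annotations: Sequence[GeneAnnotation],
               spacer_evidence: bool,
               config: RunConfig = DEFAULT_CONFIG) -> PhageCall:
    """Keyword phage rule + BUSCO filter + jumbo size filter for one genome.

    is_phage requires ≥2 virus-keyword genes, no prokaryote-specific
    exclusion term, and (by default) at least one spacer match from a
    prokaryote genome.  is_jumbo additionally requires passing the BUSCO
    ratio and a genome length > 200 kb.
    """
    genes = [g for g in annotations if g.genome_id == genome.genome_id]
    n_kw = count_keyword_genes(genes, config.virus_keywords)
    excl = has_exclusion_term(genes, config.exclusion_terms)
    spacer_ok = spacer_evidence or not config.require_spacer_evidence
    is_phage = (n_kw >= config.min_keyword_genes) and not excl and spacer_ok
    busco_hits = sum(1 for g in genes if g.busco_hit)
    if genes:
        ratio, passes = busco_filter(genes, config)
    else:
        ratio, passes = 0.0, False
    is_jumbo = is_phage and passes and \
        genome.length_bp > config.jumbo_min_length
    return PhageCall(
        genome_id=genome.genome_id,
        n_keyword_genes=n_kw,
        has_exclusion_term=excl,
        has_spacer_evidence=spacer_evidence,
        is_phage=is_phage,
        busco_hits=busco_hits,
        n_genes=len(genes),
        busco_ratio=ratio,
        passes_busco=passes,
        is_jumbo=is_jumbo,
    )


def assign_lifestyle(genome_id: str, score: float, provirus_flag: bool,
                     config: RunConfig = DEFAULT_CONFIG) -> LifestyleCall:
    """Score bands: <0.5 virulent, 0.5–0.9 uncertain (closed interval),
    >0.9 temperate; provirus evidence overrides to temperate."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"lifestyle score must be in [0, 1], got {score}")
    if provirus_flag or score > config.lifestyle_temperate_above:
        lifestyle = "temperate"
    elif score < config.lifestyle_virulent_below:
        lifestyle = "virulent"
    else:
        lifestyle = "uncertain"
    return LifestyleCall(genome_id=genome_id, score=score,
                         provirus_flag=provirus_flag, lifestyle=lifestyle)


def classify_host_breadth(
        host_predictions: Sequence[HostPrediction],
        genome_ids: Iterable[str] = ()) -> dict[str, str]:
    """Per-genome host-breadth label.

    generalist: predicted hosts span ≥2 distinct phyla; archaeal: any host
    domain is Archaea (generalist wins when both apply); specialist
    otherwise; unknown: listed in ``genome_ids`` but has no predictions.
    """
    by_genome: dict[str, list[HostPrediction]] = {}
    for p in host_predictions:
        by_genome.setdefault(p.genome_id, []).append(p)
    out = {g: "unknown" for g in genome_ids if g not in by_genome}
    for genome_id, preds in by_genome.items():
        phyla = {p.phylum for p in preds if p.phylum is not None}
        if len(phyla) >= 2:
            out[genome_id] = "generalist"
        elif any(p.domain == "Archaea" for p in preds):
            out[genome_id] = "archaeal"
        else:
            out[genome_id] = "specialist"
    return out


def summarize_percent(count: int, total: int) -> float:
    """100·count/total, rounded half-up to two decimals (as printed in
    summary tables)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= count <= total:
        raise ValueError("count must be in [0, total]")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
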