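"""End-to-end orchestration: discover → features → network → families →
coabundance, with a machine-readable report of per-stage counts, removal
reasons and the summary percentages.

Stage outputs are pure functions of inputs + config + seed; when an output
directory is given every intermediate table is written there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import crispr as cr
from . import taxonomy as tx
from .config import DEFAULT_CONFIG, RunConfig
from .discovery import (PhageCall, assign_lifestyle, call_phage,
                        classify_host_breadth, summarize_percent)
from .features import assign_genetic_code, crass_classify
from .io import (CoverageTrack, GeneAnnotation, GenomeRecord, HostPrediction,
                 proteomes_from_annotations)

ALL_STAGES = ("discover", "features", "network", "families", "coabundance")


class ConfigurationError(ValueError):
    """A stage is enabled but its required input is missing."""


@dataclass
class PipelineInputs:
    genomes: list[GenomeRecord]
    annotations: list[GeneAnnotation] = field(default_factory=list)
    prokaryote_genomes: list[GenomeRecord] = field(default_factory=list)
    host_predictions: list[HostPrediction] = field(default_factory=list)
    lifestyle_scores: dict[str, tuple[float, bool]] = field(
        default_factory=dict)
    coverage_tracks: list[CoverageTrack] | None = None
    counts: np.ndarray | None = None
    taxa_ids: list[str] | None = None
    sample_ids: list[str] | None = None
    sample_countries: dict[str, str] = field(default_factory=dict)
    proteomes: dict[str, dict[str, str]] | None = None
    crass_markers: dict[str, str] | None = None
    crass_reference: GenomeRecord | None = None


@dataclass
class PipelineReport:
    stage_counts: dict = field(default_factory=dict)
    removal_reasons: dict = field(default_factory=dict)
    phage_calls: dict = field(default_factory=dict)
    lifestyle_counts: dict = field(default_factory=dict)
    host_breadth: dict = field(default_factory=dict)
    host_breadth_percent: dict = field(default_factory=dict)
    genetic_codes: dict = field(default_factory=dict)
    crass_calls: dict = field(default_factory=dict)
    network_summary: dict = field(default_factory=dict)
    spacer_edges: list = field(default_factory=list)
    families: dict = field(default_factory=dict)
    coabundance: dict = field(default_factory=dict)
    prevalence: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True,
                          default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _removal_reason(call: PhageCall, genome: GenomeRecord,
                    config: RunConfig) -> str:
    if call.n_keyword_genes < config.min_keyword_genes:
        return "keyword_fail"
    if call.has_exclusion_term:
        return "exclusion_term"
    if not call.has_spacer_evidence and config.require_spacer_evidence:
        return "spacer_fail"
    if not call.passes_busco:
        return "busco_fail"
    if genome.length_bp <= config.jumbo_min_length:
        return "size_fail"
    return "retained"


def run_pipeline(inputs: PipelineInputs,
                 config: RunConfig = DEFAULT_CONFIG,
                 stages: tuple[str, ...] = ALL_STAGES,
                 outdir: str | Path | None = None) -> PipelineReport:
    """Run the enabled stages and return the report.

    Raises ConfigurationError before any work starts when an enabled stage
    lacks its required input.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    if "coabundance" in stages and inputs.genomes and \
            inputs.coverage_tracks is None and inputs.counts is None:
        raise ConfigurationError(
            "coabundance stage needs coverage_tracks or a counts matrix")
    if "coabundance" in stages and inputs.counts is not None and \
            inputs.taxa_ids is None:
        raise ConfigurationError("counts matrix needs taxa_ids")
    config.validate()
    report = PipelineReport()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    by_genome: dict[str, list[GeneAnnotation]] = {}
    for g in inputs.annotations:
        by_genome.setdefault(g.genome_id, []).append(g)

    retained: list[GenomeRecord] = []
    if "discover" in stages:
        retained = _stage_discover(inputs, config, report, by_genome)
    retained_ids = [g.genome_id for g in retained]

    if "features" in stages:
        _stage_features(inputs, config, report, retained)

    spacer_matches: list[cr.SpacerMatch] = []
    if "network" in stages:
        spacer_matches = _stage_network(inputs, config, report, retained_ids)

    family_map: dict[str, str] = {}
    if "families" in stages:
        family_map = _stage_families(inputs, config, report, retained_ids)

    if "coabundance" in stages:
        _stage_coabundance(inputs, config, report, family_map)

    if out is not None:
        _write_outputs(out, report)
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_discover(inputs, config, report, by_genome):
    # spacer evidence: any spacer carried by a prokaryote genome matching
    # the candidate
    evidence: set[str] = set()
    if inputs.prokaryote_genomes:
        arrays = [a for g in inputs.prokaryote_genomes
                  for a in cr.detect_crispr_arrays(g, config)]
        for m in cr.match_spacers(arrays,
                                  inputs.prokaryote_genomes + inputs.genomes,
                                  config):
            evidence.add(m.target_genome)
        cfg = config
    else:
        # no prokaryote reference set supplied: the spacer-evidence
        # requirement cannot be evaluated and is waived
        cfg = config.replace(require_spacer_evidence=False)
    retained = []
    reasons: dict[str, int] = {}
    for genome in inputs.genomes:
        call = call_phage(genome, by_genome.get(genome.genome_id, []),
                          genome.genome_id in evidence, cfg)
        reason = _removal_reason(call, genome, cfg)
        reasons[reason] = reasons.get(reason, 0) + 1
        report.phage_calls[genome.genome_id] = {
            "is_phage": call.is_phage, "is_jumbo": call.is_jumbo,
            "n_keyword_genes": call.n_keyword_genes,
            "busco_ratio": call.busco_ratio,
            "reason": reason,
        }
        if call.is_jumbo:
            retained.append(genome)
    report.stage_counts["discover"] = {
        "input": len(inputs.genomes), "passed": len(retained),
        "removed": len(inputs.genomes) - len(retained)}
    report.removal_reasons = {k: v for k, v in sorted(reasons.items())
                              if k != "retained"}
    # lifestyle and host breadth for retained genomes
    counts = {"virulent": 0, "uncertain": 0, "temperate": 0}
    for g in retained:
        if g.genome_id in inputs.lifestyle_scores:
            score, flag = inputs.lifestyle_scores[g.genome_id]
            counts[assign_lifestyle(g.genome_id, score, flag,
                                    config).lifestyle] += 1
    report.lifestyle_counts = counts
    breadth = classify_host_breadth(
        [p for p in inputs.host_predictions
         if p.genome_id in {g.genome_id for g in retained}])
    for g in retained:
        breadth.setdefault(g.genome_id, "unknown")
    report.host_breadth = breadth
    if retained:
        total = len(retained)
        labels = sorted(set(breadth.values()))
        report.host_breadth_percent = {
            lab: summarize_percent(
                sum(1 for v in breadth.values() if v == lab), total)
            for lab in labels}
    return retained


def _stage_features(inputs, config, report, retained):
    for genome in retained:
        assignment = assign_genetic_code(genome, config)
        report.genetic_codes[genome.genome_id] = assignment.assigned_code
    if inputs.crass_markers:
        # the 70 kb crAss gate runs on the full candidate pool; the final
        # catalogue keeps only jumbo genomes, so both sets are reported
        retained_ids = {g.genome_id for g in retained}
        for genome in inputs.genomes:
            call = crass_classify(genome, inputs.crass_markers,
                                  inputs.crass_reference, config)
            report.crass_calls[genome.genome_id] = {
                "is_crass": call.is_crass, "reason": call.reason,
                "in_jumbo_catalogue": genome.genome_id in retained_ids}
    report.stage_counts["features"] = {
        "input": len(retained), "passed": len(retained), "removed": 0}


def _stage_network(inputs, config, report, retained_ids):
    pool = [g for g in inputs.genomes if g.genome_id in retained_ids] + \
        list(inputs.prokaryote_genomes)
    arrays = [a for g in pool for a in cr.detect_crispr_arrays(g, config)]
    matches = cr.match_spacers(arrays, pool, config)
    network = cr.build_interaction_network(matches, retained_ids,
                                           inputs.host_predictions, config)
    report.network_summary = cr.network_summary(network)
    report.spacer_edges = [
        {"source": m.source_genome, "target": m.target_genome,
         "mismatches": m.mismatches, "coverage": m.coverage}
        for m in matches]
    report.stage_counts["network"] = {
        "input": len(pool), "passed": len(pool), "removed": 0}
    return matches


def _stage_families(inputs, config, report, retained_ids):
    proteomes = inputs.proteomes if inputs.proteomes is not None else \
        proteomes_from_annotations(inputs.annotations)
    proteomes = {g: p for g, p in proteomes.items()
                 if g in retained_ids and p}
    if len(proteomes) < 3:
        report.families = {}
        report.stage_counts["families"] = {
            "input": len(proteomes), "passed": 0, "removed": len(proteomes)}
        return {}
    matrix, dist = tx.orthologue_analysis(proteomes, config)
    tree = tx.build_tree(dist, matrix.genome_ids)
    assignment = tx.demarcate_families(tree, matrix, config)
    report.families = {label: members
                       for label, members in sorted(assignment.families.items())}
    report.stage_counts["families"] = {
        "input": len(proteomes), "passed": len(proteomes), "removed": 0}
    return assignment.genome_to_family


def _stage_coabundance(inputs, config, report, family_map):
    if inputs.counts is not None:
        counts = np.asarray(inputs.counts)
        taxa = list(inputs.taxa_ids)
        sample_ids = list(inputs.sample_ids) if inputs.sample_ids else \
            [f"S{k}" for k in range(counts.shape[1])]
        zeroed = counts == 0
        mean_depth = counts / config.abundance_pseudocount_scale
    elif inputs.coverage_tracks:
        am = ab.abundance_matrix(inputs.coverage_tracks, config)
        counts = ab.to_pseudocounts(am.mean_depth, config)
        taxa, sample_ids, zeroed = am.genome_ids, am.sample_ids, am.zeroed
        mean_depth = am.mean_depth
    else:
        report.coabundance = {"pairs": [], "n_positive": 0, "n_negative": 0}
        report.stage_counts["coabundance"] = {
            "input": 0, "passed": 0, "removed": 0}
        return
    if counts.shape[0] < 3:
        report.coabundance = {"pairs": [], "n_positive": 0, "n_negative": 0}
        report.stage_counts["coabundance"] = {
            "input": counts.shape[0], "passed": 0,
            "removed": counts.shape[0]}
        return
    rho = ab.sparcc_correlations(counts, seed=config.seed, config=config)
    p = ab.bootstrap_pvalues(counts, rho, seed=config.seed + 1,
                             config=config)
    net = ab.build_coabundance_network(rho, p, config=config)
    report.coabundance = {
        "pairs": [{"i": taxa[i], "j": taxa[j], "rho": r, "p": pv,
                   "sign": s} for i, j, r, pv, s in net.pairs],
        "n_positive": net.n_positive, "n_negative": net.n_negative,
        "n_edges": net.n_positive + net.n_negative,
    }
    report.stage_counts["coabundance"] = {
        "input": counts.shape[0], "passed": counts.shape[0], "removed": 0}
    if family_map and inputs.sample_countries:
        report.prevalence = prevalence_summary(
            mean_depth, taxa, sample_ids, family_map,
            inputs.sample_countries).to_dict(orient="records")


def prevalence_summary(mean_depth: np.ndarray, genome_ids: list[str],
                       sample_ids: list[str], family_map: dict[str, str],
                       sample_countries: dict[str, str]) -> pd.DataFrame:
    """Per-family prevalence: a family is present in a sample iff any member
    has non-zero (post-zero-rule) abundance; prevalence is the percent of
    samples with presence, overall and per country."""
    mean_depth = np.asarray(mean_depth)
    countries = sorted(set(sample_countries.values()))
    rows = []
    for family in sorted(set(family_map.values())):
        members = [i for i, g in enumerate(genome_ids)
                   if family_map.get(g) == family]
        present = (mean_depth[members, :] > 0).any(axis=0) if members else \
            np.zeros(len(sample_ids), dtype=bool)
        row = {"family": family, "n_members": len(members),
               "prevalence_pct": summarize_percent(int(present.sum()),
                                                   len(sample_ids))}
        for country in countries:
            idx = [k for k, s in enumerate(sample_ids)
                   if sample_countries.get(s) == country]
            row[f"prevalence_pct_{country}"] = summarize_percent(
                int(present[idx].sum()), len(idx)) if idx else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _write_outputs(out: Path, report: PipelineReport) -> None:
    (out / "report.json").write_text(report.to_json())
    if report.phage_calls:
        pd.DataFrame.from_dict(report.phage_calls, orient="index"
                               ).rename_axis("genome_id").to_csv(
            out / "phage_calls.tsv", sep="\t")
    if report.spacer_edges:
        pd.DataFrame(report.spacer_edges).to_csv(
            out / "spacer_edges.tsv", sep="\t", index=False)
    if report.families:
        rows = [{"family": fam, "genome_id": g}
                for fam, members in report.families.items()
                for g in members]
        pd.DataFrame(rows).to_csv(out / "families.tsv", sep="\t",
                                  index=False)
    if report.coabundance.get("pairs"):
        pd.DataFrame(report.coabundance["pairs"]).to_csv(
            out / "coabundance_edges.tsv", sep="\t", index=False)
    if report.prevalence:
        pd.DataFrame(report.prevalence).to_csv(
            out / "prevalence.tsv", sep="\t", index=False)
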