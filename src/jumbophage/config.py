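"""Run configuration: every tunable threshold of the pipeline in one place.

Defaults are the published operating points of the analysis this package
implements (jumbo size cut-off, BUSCO ratio, lifestyle score bands,
coding-density margin, spacer match rule, family demarcation thresholds,
breadth-zeroing rule, bootstrap settings).  No other module hides a constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

# Virus-specific product keywords used by the phage-calling rule.  The list is
# kept verbatim (comma-delimited) from the screening protocol, including the
# compound token "tapemeasure neck".
VIRUS_KEYWORDS: tuple[str, ...] = (
    "capsid", "phage", "terminase", "base plate", "baseplate", "prohead",
    "virion", "virus", "viral", "tape measure", "tapemeasure neck", "tail",
    "head", "bacteriophage", "prophage", "portal", "DNA packaging", "T4",
    "p22", "holin",
)

# Prokaryote-specific exclusion terms: one hit disqualifies a genome.
EXCLUSION_TERMS: tuple[str, ...] = (
    "ribosomal protein", "preprotein translocase", "DNA gyrase subunit A",
)


@dataclass
class RunConfig:
    """All tunable thresholds, with their published defaults."""

    seed: int = 0

    # --- phage discovery ---
    jumbo_min_length: int = 200_000          # bp, strict >
    min_keyword_genes: int = 2
    virus_keywords: tuple[str, ...] = VIRUS_KEYWORDS
    exclusion_terms: tuple[str, ...] = EXCLUSION_TERMS
    require_spacer_evidence: bool = True
    busco_max_ratio: float = 0.067           # strict <: ratio 0.067 fails
    # viral-signature thresholds (screening protocol cites no numbers; these
    # are the package's documented conservative choices, all overridable)
    viral_family_min_fraction: float = 0.10
    microbial_family_max_fraction: float = 0.02
    strand_run_min_genes: int = 10
    # lifestyle score bands
    lifestyle_virulent_below: float = 0.5
    lifestyle_temperate_above: float = 0.9

    # --- genetic code / ORFs ---
    orf_min_length: int = 90                 # nt, span includes the stop codon
    orf_start_codons: tuple[str, ...] = ("ATG", "GTG", "TTG")
    code_density_margin: float = 0.10        # alt code needs >=10% density gain

    # --- crAss-like classification ---
    crass_min_genome_length: int = 70_000    # strict >
    crass_evalue_max: float = 1e-10
    crass_nt_identity_min: float = 0.95
    crass_aligned_fraction_min: float = 0.80
    crass_fragment_length: int = 1_000
    # Karlin–Altschul ungapped parameters (BLOSUM62)
    ka_lambda: float = 0.318
    ka_k: float = 0.13

    # --- CRISPR arrays and spacer matching (CRT/MinCED defaults) ---
    crispr_min_repeats: int = 3
    crispr_repeat_len: tuple[int, int] = (23, 47)
    crispr_spacer_len: tuple[int, int] = (26, 50)
    crispr_search_window: int = 8
    spacer_max_mismatches: int = 1
    spacer_min_coverage: float = 0.95

    # --- orthologues / family demarcation ---
    orth_evalue_max: float = 1e-5
    orth_identity_min: float = 0.30
    orth_coverage_min: float = 0.50          # of the shorter protein
    family_patristic_min: float = 0.05       # >= splits families ...
    family_shared_max: float = 0.10          # ... when sharing also < this

    # --- abundance / co-abundance network ---
    breadth_zero_max: float = 0.25           # zeroed iff breadth <= 0.25
    sparcc_estimation_iters: int = 20
    sparcc_exclusion_threshold: float = 0.1
    sparcc_exclusion_rounds: int = 10
    n_bootstrap: int = 1000
    p_cutoff: float = 0.001
    pvalue_add_one: bool = False             # (count+1)/(n+1) estimator if True
    abundance_pseudocount_scale: float = 100.0

    # --- synthetic data ---
    self_validate: bool = True               # generators re-detect planted signals

    def validate(self) -> None:
        if not 0 <= self.busco_max_ratio <= 1:
            raise ValueError("busco_max_ratio must be in [0, 1]")
        if not 0 <= self.breadth_zero_max <= 1:
            raise ValueError("breadth_zero_max must be in [0, 1]")
        if self.code_density_margin < 0:
            raise ValueError("code_density_margin must be >= 0")
        if not (0 <= self.lifestyle_virulent_below
                <= self.lifestyle_temperate_above <= 1):
            raise ValueError("lifestyle thresholds must satisfy 0<=lo<=hi<=1")
        if self.spacer_max_mismatches < 0:
            raise ValueError("spacer_max_mismatches must be >= 0")
        if not 0 < self.spacer_min_coverage <= 1:
            raise ValueError("spacer_min_coverage must be in (0, 1]")
        if self.crispr_min_repeats < 3:
            raise ValueError("crispr_min_repeats must be >= 3")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.p_cutoff <= 1:
            raise ValueError("p_cutoff must be in (0, 1]")

    def replace(self, **kwargs) -> "RunConfig":
        cfg = dataclasses.replace(self, **kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a config from a YAML (or plain key: value) file.

        Unknown keys raise; list values are coerced to tuples.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must map keys to values")
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in raw.items()}
        cfg = cls(**coerced)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d = {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


DEFAULT_CONFIG = RunConfig()
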