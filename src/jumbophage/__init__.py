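"""Jumbo-phage discovery and ecology toolkit for gut metagenomes.

Submodules
----------
io          readers/writers and the domain record types
config      every tunable threshold, with published defaults
synthetic   ground-truthed synthetic community generators
discovery   viral signatures, keyword phage rule, BUSCO filter, lifestyles
features    alternative genetic codes and crAss-like classification
crispr      CRISPR arrays, spacer matching, interaction networks
taxonomy    orthologues, proteomic tree, family demarcation
abundance   breadth-zeroed abundance and SparCC co-abundance networks
pipeline    end-to-end orchestration and the summary report
"""

from importlib import resources

from .config import DEFAULT_CONFIG, RunConfig

__version__ = "0.1.0"


def packaged_crass_markers() -> dict[str, str]:
    """The bundled *synthetic* stand-in crAss marker proteins (polymerase and
    terminase slots).  Replaceable with real markers via config/CLI flag."""
    from .io import read_protein_fasta
    ref = resources.files("jumbophage") / "data" / "synthetic_crass_markers.faa"
    with resources.as_file(ref) as path:
        return read_protein_fasta(path)
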