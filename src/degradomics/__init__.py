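"""degradomics — proteasome degradome analysis.

From peptide identification tables to substrate-anchored cleavage-site
profiles, catalytic-phenotype signatures, 9–10-mer HLA class I ligand
candidates, immunodominant core regions and percentile-rank annotation, with
a stochastic digestion simulator for fully offline testing.
"""

from importlib import resources

from .errors import (
    ConfigError,
    DegradomicsError,
    FormatError,
    StateError,
    ValidationError,
)
from .io_tables import (
    Modification,
    PeptideObservation,
    PredictionRecord,
    SubstrateRecord,
    read_fasta,
    read_peptide_table,
    read_prediction_table,
    write_peptide_table,
    write_prediction_table,
)
from .mapping import LocatedPeptide, locate_peptide, map_table
from .profiles import (
    ActivitySignature,
    CleavageProfile,
    TerminalMatrix,
    activity_signature,
    cleavage_profile,
    filter_mhc1_candidates,
    terminal_matrix,
    tic_normalize,
)
from .compare import ConditionComparison, compare_conditions, enrichment_report
from .cores import CoreRegion, extract_core_regions, region_report
from .hla import (
    AllelePanel,
    AnnotatedCandidate,
    PssmModel,
    annotate_candidates,
    build_panel_models,
    classify_binder,
    default_panel,
    load_panel,
    percentile_rank,
    pssm_score,
)
from .simulate import (
    DigestConfig,
    PhenotypePreset,
    SimulatedDigest,
    cut_probabilities,
    default_presets,
    recovery_check,
    simulate_digest,
)

__version__ = "0.1.0"


def mbp_substrate() -> SubstrateRecord:
    """The bundled human myelin basic protein substrate (18.5 kDa classic
    isoform, UniProt P02686-5), the reference substrate of the package."""
    ref = resources.files("degradomics.data") / "mbp_p02686_5.fasta"
    with resources.as_file(ref) as path:
        return read_fasta(path)[0]


__all__ = [name for name in dir() if not name.startswith("_")]
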