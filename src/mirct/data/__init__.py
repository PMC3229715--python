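"""Bundled reference tables.

``ftld_pgrn_candidate_targets.tsv`` transcribes the published candidate
gene-to-miRNA target assignments for the five miRNAs up-regulated in
both frontal cortex and cerebellum of PGRN-mutation FTLD-TDP patients
(miR-922, miR-516a-3p, miR-571, miR-548b-5p, miR-548c-5p).  It serves as
the worked-example input for the integration stage.
"""

from importlib import resources
from pathlib import Path

#: The five candidate miRNAs validated in both tissues.
CANDIDATE_MIRNAS = ["miR-922", "miR-516a-3p", "miR-571", "miR-548b-5p", "miR-548c-5p"]


def candidate_targets_path() -> Path:
    """Path to the bundled candidate-target TSV."""
    return Path(resources.files(__package__) / "ftld_pgrn_candidate_targets.tsv")
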