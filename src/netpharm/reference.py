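"""Bundled reference tables for the Ephedrae herba / Coicis semen pair.

Two small published tables ship with the package as worked-example
inputs: the TCMSP-derived ADME descriptor table of the 24 screened
compounds of the two herbs, and the degree / betweenness-centrality table
of their 31 key obesity targets as reported from a STRING-derived PPI
network.  They exercise the ADME screen, the Venn partition and the
handshake-lemma bookkeeping without any database access.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_compound_table
from .models import CompoundRecord

__all__ = ["load_reference_compounds", "load_reference_key_targets"]


def _data_path(name: str):
    return resources.files("netpharm").joinpath("data", name)


def load_reference_compounds() -> list[CompoundRecord]:
    """The 24 ADME-screened compounds of the EH-CS pair (15 EH / 7 CS / 2 shared)."""
    with resources.as_file(_data_path("ehcs_compounds.tsv")) as p:
        return read_compound_table(p)


def load_reference_key_targets() -> pd.DataFrame:
    """Reported degree and betweenness of the 31 key EH-CS obesity targets."""
    with resources.as_file(_data_path("ehcs_key_targets.tsv")) as p:
        return pd.read_csv(p, sep="\t")
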