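"""Bundled reference tables.

``conserved_missense_edits.tsv`` is the published catalog of canonical A-to-I
edits in *Drosophila* larval motoneurons that cause significant missense
changes at residues conserved in other insect or mammalian homologs: one row
per edit site with its genomic position, FlyBase annotation status, Pfam
domain, conservation group, and the original/edited codon and amino acid.
It serves as a worked-example input for the codon-consequence and
residue-class machinery.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_MISSING = "."


def load_conserved_missense() -> pd.DataFrame:
    """The conserved-missense edit catalog as a DataFrame ('.' kept as-is)."""
    ref = resources.files("scedit.data").joinpath("conserved_missense_edits.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)
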